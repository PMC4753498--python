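"""Paired-end read quality control.

The filtering procedure, applied per mate in a fixed order:

1. optional exact-prefix adapter removal;
2. discard reads containing any ambiguous base (anything not A/C/G/T);
3. remove the first ``head_trim`` bases (library-construction artifacts such
   as A-tailing skew the initial positions);
4. truncate at the file-wide trim point: the earliest position whose
   first-quartile quality falls below ``q_threshold``, computed per mate file
   independently from the surviving head-trimmed reads;
5. discard reads in which more than ``max_low_frac`` of the remaining bases
   are below ``q_threshold``;
6. discard reads shorter than ``min_len_after_trim``.

A pair survives only if both mates survive; discarded pairs are attributed to
the first failing rule (ambiguous > low quality > orphaned by length), so the
report counts are deterministic and sum to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io_formats import FastqRead, ReadPair, NucSeq

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class QcConfig:
    head_trim: int = 6
    q_threshold: int = 25
    max_low_frac: float = 0.15
    min_len_after_trim: int = 50
    adapter_seqs: tuple = ()
    min_quartile_obs: int = 4  # positions with fewer reads report no quartile

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_low_frac <= 1.0:
            raise ValueError("max_low_frac must be in [0, 1]")
        if self.q_threshold < 0:
            raise ValueError("q_threshold must be >= 0")
        if self.head_trim < 0 or self.min_len_after_trim < 0:
            raise ValueError("trim lengths must be >= 0")


@dataclass(frozen=True)
class QcReport:
    n_input_pairs: int
    n_discarded_ambiguous: int
    n_discarded_lowqual: int
    n_discarded_orphan: int
    n_output_pairs: int
    trim_point: dict = field(default_factory=dict)  # {"r1": int|None, "r2": ...}

    def __post_init__(self) -> None:
        total = (
            self.n_output_pairs
            + self.n_discarded_ambiguous
            + self.n_discarded_lowqual
            + self.n_discarded_orphan
        )
        if total != self.n_input_pairs:
            raise ValueError("QC counts do not sum to the input pair count")

    def as_dict(self) -> dict:
        return {
            "n_input_pairs": self.n_input_pairs,
            "n_discarded_ambiguous": self.n_discarded_ambiguous,
            "n_discarded_lowqual": self.n_discarded_lowqual,
            "n_discarded_orphan": self.n_discarded_orphan,
            "n_output_pairs": self.n_output_pairs,
            "trim_point": self.trim_point,
        }


def positional_quality_quartiles(
    reads: Sequence[FastqRead], min_obs: int = 4
) -> np.ndarray:
    """First-quartile Phred score at each read position.

    Quartiles use linear interpolation between order statistics.  Positions
    observed in fewer than ``min_obs`` reads are reported as NaN (absent).
    """
    if not reads:
        raise ValueError("empty read collection")
    max_len = max(len(r) for r in reads)
    mat = np.full((len(reads), max_len), np.nan)
    for i, r in enumerate(reads):
        mat[i, : len(r)] = r.quals
    counts = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(all="ignore"):
        q1 = np.nanpercentile(mat, 25, axis=0, method="linear")
    q1[counts < min_obs] = np.nan
    return q1


def determine_trim_point(
    q1_profile: np.ndarray, q_threshold: int = 25
) -> Optional[int]:
    """Earliest position with first-quartile quality below the threshold."""
    for pos, q in enumerate(q1_profile):
        if not np.isnan(q) and q < q_threshold:
            return pos
    return None


def _strip_adapter(read: FastqRead, adapters: Sequence[NucSeq]) -> FastqRead:
    for ad in adapters:
        a = ad.bases if hasattr(ad, "bases") else str(ad)
        if read.bases.startswith(a):
            return FastqRead(read.id, read.bases[len(a):], read.quals[len(a):])
    return read


def _truncate(read: FastqRead, start: int, end: Optional[int]) -> FastqRead:
    return FastqRead(read.id, read.bases[start:end], read.quals[start:end])


def qc_filter_pairs(
    pairs: Sequence[ReadPair],
    cfg: QcConfig,
    trim_points: Optional[dict] = None,
) -> tuple[list[ReadPair], QcReport]:
    """Filter read pairs; returns surviving (trimmed) pairs and a report.

    ``trim_points`` ({"r1": int|None, "r2": int|None}) overrides the
    file-wide trim-point computation, e.g. to re-apply a previous run's
    decision.  R1 and R2 are profiled and trimmed independently.
    """
    if not isinstance(cfg, QcConfig):
        raise ValueError("cfg must be a QcConfig")

    # stages 1-3 per mate; remember which pairs are ambiguous
    staged: list[tuple[Optional[FastqRead], Optional[FastqRead]]] = []
    for p in pairs:
        mates: list[Optional[FastqRead]] = []
        for r in (p.r1, p.r2):
            r = _strip_adapter(r, cfg.adapter_seqs)
            if set(r.bases) - _VALID_BASES:
                mates.append(None)  # ambiguous
            else:
                mates.append(_truncate(r, cfg.head_trim, None))
        staged.append((mates[0], mates[1]))

    # stage 4: file-wide trim point per mate, from non-ambiguous reads
    if trim_points is None:
        trim_points = {}
        for key, idx in (("r1", 0), ("r2", 1)):
            survivors = [m[idx] for m in staged if m[idx] is not None and len(m[idx])]
            if survivors:
                profile = positional_quality_quartiles(
                    survivors, min_obs=cfg.min_quartile_obs
                )
                trim_points[key] = determine_trim_point(profile, cfg.q_threshold)
            else:
                trim_points[key] = None

    n_amb = n_low = n_orphan = 0
    out: list[ReadPair] = []
    for r1, r2 in staged:
        if r1 is None or r2 is None:
            n_amb += 1
            continue
        kept: list[FastqRead] = []
        low = short = False
        for key, r in (("r1", r1), ("r2", r2)):
            tp = trim_points.get(key)
            if tp is not None:
                r = _truncate(r, 0, tp)
            if len(r) == 0:
                short = True
                continue
            quals = np.asarray(r.quals)
            if np.mean(quals < cfg.q_threshold) > cfg.max_low_frac:
                low = True
                continue
            if len(r) < cfg.min_len_after_trim:
                short = True
                continue
            kept.append(r)
        if low:
            n_low += 1
        elif short:
            n_orphan += 1
        else:
            out.append(ReadPair(kept[0], kept[1]))

    report = QcReport(
        n_input_pairs=len(pairs),
        n_discarded_ambiguous=n_amb,
        n_discarded_lowqual=n_low,
        n_discarded_orphan=n_orphan,
        n_output_pairs=len(out),
        trim_point=dict(trim_points),
    )
    return out, report
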