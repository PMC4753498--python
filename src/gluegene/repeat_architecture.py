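"""Tandem-repeat architecture: unit length, segmentation, composition.

Glue spidroins are built as a long array of near-identical repeat units
followed by a non-repetitive linker and a conserved carboxyl-terminal region
(CTD).  The unit length is estimated by shifted self-identity (cheap and
deterministic, adequate for near-perfect tandem arrays); segmentation then
anchors the unit grid phase, grows the array while units stay similar to the
running consensus, and assigns the remainder to linker and a fixed-length
CTD suffix.  Nothing in this module is stochastic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .io_formats import NucSeq, ProtSeq

SeqT = Union[NucSeq, ProtSeq]


@dataclass(frozen=True)
class RepeatArchitecture:
    unit_len: int
    unit_intervals: tuple[tuple[int, int], ...]
    unit_consensus: ProtSeq
    linker_interval: tuple[int, int]
    ctd_interval: tuple[int, int]
    mean_intra_unit_identity: float


@dataclass(frozen=True)
class CompositionStats:
    interval: tuple[int, int]
    fractions: dict
    top_residues: tuple  # ((residue, fraction), ...) sorted by abundance


def _seq_str(x) -> str:
    if isinstance(x, NucSeq):
        return x.bases
    if isinstance(x, ProtSeq):
        return x.residues
    return str(x)


def estimate_unit_length(
    seq: SeqT,
    min_len: int = 20,
    max_len: int = 200,
    background: float = 0.5,
) -> tuple[Optional[int], dict[int, float]]:
    """Tandem period by shifted self-identity.

    score(L) = mean per-residue identity between the sequence and itself
    shifted by L, over the length-L overlap.  Returns (best L, profile);
    the best L is None when no candidate beats ``background`` (ties go to the
    smallest L, which resolves the exact multiples that score equally on
    perfect arrays).  For DNA-level repeat detection call with bounds like
    [100, 400].
    """
    s = _seq_str(seq)
    n = len(s)
    if n <= 2 * min_len:
        raise ValueError(f"sequence length {n} too short for min_len {min_len}")
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    profile: dict[int, float] = {}
    hi = min(max_len, n - 1)
    for L in range(min_len, hi + 1):
        profile[L] = float(np.mean(arr[:-L] == arr[L:]))
    if not profile:
        raise ValueError("no candidate periods in range")
    best_L = min(profile, key=lambda L: (-profile[L], L))
    if profile[best_L] < background:
        return None, profile
    return best_L, profile


def _identity(a: str, b: str) -> float:
    m = min(len(a), len(b))
    if m == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:m], b[:m])) / m


def _consensus(blocks: list[str]) -> str:
    out = []
    for col in zip(*blocks):
        out.append(Counter(col).most_common(1)[0][0])
    return "".join(out)


def segment_architecture(
    prot: ProtSeq,
    unit_len: int,
    unit_accept: float = 0.5,
    ctd_len: int = 125,
) -> RepeatArchitecture:
    """Partition a protein into repeat units, linker, and CTD.

    The unit grid phase is chosen to maximize summed identity between
    adjacent unit-length blocks; the array grows outward from its
    best-matching adjacent pair while each next block's identity to the
    running consensus stays >= ``unit_accept``.  The CTD is the fixed-length
    suffix (default ~125 residues, truncated if the sequence ends early) — a
    documented convention, since the linker/CTD boundary is descriptive, not
    algorithmic.  Raises if fewer than 2 units are accepted.
    """
    s = prot.residues
    n = len(s)
    if unit_len < 2 or unit_len * 2 > n:
        raise ValueError("no tandem array: unit_len incompatible with sequence")

    def blocks_for(phase: int) -> list[str]:
        return [
            s[start : start + unit_len]
            for start in range(phase, n - unit_len + 1, unit_len)
        ]

    best_phase, best_sum = 0, -1.0
    for phase in range(unit_len):
        blocks = blocks_for(phase)
        if len(blocks) < 2:
            continue
        total = sum(
            _identity(blocks[i], blocks[i + 1]) for i in range(len(blocks) - 1)
        )
        if total > best_sum:
            best_phase, best_sum = phase, total
    blocks = blocks_for(best_phase)
    if len(blocks) < 2:
        raise ValueError("no tandem array")

    pair_scores = [
        _identity(blocks[i], blocks[i + 1]) for i in range(len(blocks) - 1)
    ]
    seed = int(np.argmax(pair_scores))
    if pair_scores[seed] < unit_accept:
        raise ValueError("no tandem array: no adjacent block pair is repeat-like")
    accepted = [seed, seed + 1]
    while True:
        grew = False
        consensus = _consensus([blocks[i] for i in accepted])
        left, right = accepted[0] - 1, accepted[-1] + 1
        if left >= 0 and _identity(blocks[left], consensus) >= unit_accept:
            accepted.insert(0, left)
            grew = True
        consensus = _consensus([blocks[i] for i in accepted])
        if right < len(blocks) and _identity(blocks[right], consensus) >= unit_accept:
            accepted.append(right)
            grew = True
        if not grew:
            break

    if len(accepted) < 2:
        raise ValueError("no tandem array")
    unit_intervals = tuple(
        (best_phase + i * unit_len, best_phase + (i + 1) * unit_len)
        for i in accepted
    )
    units = [blocks[i] for i in accepted]
    consensus = _consensus(units)
    pairs = [
        _identity(units[i], units[j])
        for i in range(len(units))
        for j in range(i + 1, len(units))
    ]
    ctd_start = max(0, n - ctd_len)
    last_unit_end = unit_intervals[-1][1]
    return RepeatArchitecture(
        unit_len=unit_len,
        unit_intervals=unit_intervals,
        unit_consensus=ProtSeq(f"{prot.id}_unit_consensus", consensus),
        linker_interval=(last_unit_end, max(last_unit_end, ctd_start)),
        ctd_interval=(ctd_start, n),
        mean_intra_unit_identity=float(np.mean(pairs)),
    )


def composition_stats(
    seq: SeqT, interval: Optional[tuple[int, int]] = None
) -> CompositionStats:
    """Exact residue frequency table over an interval (default: whole)."""
    s = _seq_str(seq)
    if interval is None:
        interval = (0, len(s))
    lo, hi = interval
    if not (0 <= lo < hi <= len(s)):
        raise ValueError(f"empty or out-of-range interval {interval}")
    window = s[lo:hi]
    counts = Counter(window)
    total = len(window)
    fractions = {r: c / total for r, c in sorted(counts.items())}
    top = tuple(sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0])))
    return CompositionStats(interval=interval, fractions=fractions, top_residues=top)
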