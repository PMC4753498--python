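"""Exact-seed, mismatch-tolerant ungapped read mapper with coverage tracks.

Chimera detection only needs presence/absence of read support along a
transcript, so the mapper is deliberately simple: forward k-mers of the
reference are indexed; a read's non-overlapping k-mer seeds (both strands)
vote for candidate end-to-end placements, which are scored by Hamming
distance.  Non-overlapping seeds guarantee that any read with fewer
mismatches than seeds still produces at least one exact seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .io_formats import FastqRead, NucSeq, ReadPair

log = logging.getLogger("gluegene.mapping")


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class KmerIndex:
    k: int
    ref_id: str
    ref_len: int
    ref_bytes: np.ndarray
    offsets: dict  # k-mer -> np.ndarray of sorted reference offsets
    n_skipped_n: int = 0


@dataclass(frozen=True)
class Hit:
    read_id: str
    interval: tuple[int, int]  # 0-based half-open on the reference
    strand: str  # "+" or "-"
    mismatches: int


@dataclass
class CoverageTrack:
    ref_id: str
    depth: np.ndarray

    def __len__(self) -> int:
        return len(self.depth)


def build_kmer_index(ref: NucSeq, k: int = 21) -> KmerIndex:
    """Index every forward k-mer of the reference.

    k-mers containing N are skipped (with a logged count); both strands are
    handled at query time, so only the forward strand is stored.
    """
    if k > len(ref):
        raise ValueError(f"k={k} exceeds reference length {len(ref)}")
    if k < 8:
        raise ValueError("k must be >= 8")
    offsets: dict[str, list[int]] = {}
    skipped = 0
    bases = ref.bases
    for i in range(len(bases) - k + 1):
        kmer = bases[i : i + k]
        if "N" in kmer:
            skipped += 1
            continue
        offsets.setdefault(kmer, []).append(i)
    if skipped:
        log.info("skipped %d k-mers containing N in %s", skipped, ref.id)
    packed = {kmer: np.array(pos, dtype=np.int64) for kmer, pos in offsets.items()}
    return KmerIndex(
        k=k,
        ref_id=ref.id,
        ref_len=len(ref),
        ref_bytes=_to_bytes(bases),
        offsets=packed,
        n_skipped_n=skipped,
    )


def map_read(
    read: FastqRead,
    idx: KmerIndex,
    max_mismatch_frac: float = 0.05,
) -> Optional[Hit]:
    """Best end-to-end ungapped placement of a read, or None.

    Candidates come from seed votes on both strands; the best hit has the
    fewest mismatches subject to mismatches <= max_mismatch_frac * read
    length.  Ties break to the leftmost reference offset, then to +.
    Reads overhanging the reference ends are unmapped.
    """
    rl = len(read)
    k = idx.k
    if rl < k:
        return None
    max_mm = int(max_mismatch_frac * rl)

    queries = (
        ("+", read.bases),
        ("-", str(Seq(read.bases).reverse_complement())),
    )
    seed_offsets = list(range(0, rl - k + 1, k))
    if seed_offsets[-1] != rl - k:
        seed_offsets.append(rl - k)

    best: Optional[tuple[int, int, int]] = None  # (mismatches, offset, strand_rank)
    seen: set[tuple[str, int]] = set()
    for strand, qseq in queries:
        qbytes = _to_bytes(qseq)
        for off in seed_offsets:
            kmer = qseq[off : off + k]
            for pos in idx.offsets.get(kmer, ()):
                o = int(pos) - off
                if o < 0 or o + rl > idx.ref_len:
                    continue
                if (strand, o) in seen:
                    continue
                seen.add((strand, o))
                mm = int(np.count_nonzero(idx.ref_bytes[o : o + rl] != qbytes))
                if mm > max_mm:
                    continue
                cand = (mm, o, 0 if strand == "+" else 1)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    mm, o, srank = best
    return Hit(read.id, (o, o + rl), "+" if srank == 0 else "-", mm)


def map_reads(
    reads: Iterable[FastqRead],
    idx: KmerIndex,
    max_mismatch_frac: float = 0.05,
) -> list[Hit]:
    hits = []
    for r in reads:
        h = map_read(r, idx, max_mismatch_frac)
        if h is not None:
            hits.append(h)
    return hits


def map_pairs(
    pairs: Sequence[ReadPair],
    idx: KmerIndex,
    max_mismatch_frac: float = 0.05,
) -> list[Hit]:
    """Map both mates of each pair independently (coverage-only use)."""
    flat: list[FastqRead] = []
    for p in pairs:
        flat.extend((p.r1, p.r2))
    return map_reads(flat, idx, max_mismatch_frac)


def coverage_track(hits: Sequence[Hit], ref: NucSeq) -> CoverageTrack:
    """Per-base depth: depth[i] = number of hit intervals containing i."""
    delta = np.zeros(len(ref) + 1, dtype=int)
    for h in hits:
        s, e = h.interval
        if s < 0 or e > len(ref) or s >= e:
            raise ValueError(f"hit {h} out of range for reference of length {len(ref)}")
        delta[s] += 1
        delta[e] -= 1
    return CoverageTrack(ref.id, np.cumsum(delta[:-1]))
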