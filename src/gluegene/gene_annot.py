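"""Pairwise sequence comparison and ORF/UTR annotation.

Covers the forensic comparisons the pipeline needs: optimal global identity
under simple linear-gap scores, the best locally shared region between two
transcripts in either orientation (e.g. a block present in one cDNA and
reverse-complemented in another), how far a genomic contig extends upstream
of a cDNA, and annotation of start-codon-less coding contigs as
coding + stop + 3' UTR.

Dynamic programming is delegated to Bio.Align.PairwiseAligner; identity is
reported as matches / alignment columns (internal gaps included in the
denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from Bio import Align
from Bio.Seq import Seq

from .io_formats import NucSeq, ProtSeq

SeqT = Union[NucSeq, ProtSeq]

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    matches: int
    columns: int
    identity: float
    score: float


@dataclass(frozen=True)
class SharedRegion:
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]  # always on b's forward strand
    orientation: str  # "forward" | "reverse_complement"
    length: int  # alignment columns
    identity: float
    score: float


@dataclass(frozen=True)
class OrfAnnotation:
    frame: int
    coding_interval: tuple[int, int]
    stop_interval: Optional[tuple[int, int]]
    utr3_interval: tuple[int, int]
    has_start_codon: bool
    protein: Optional[ProtSeq]


def _seq_str(x: SeqT) -> str:
    return x.bases if isinstance(x, NucSeq) else x.residues


def _check_same_kind(a: SeqT, b: SeqT) -> None:
    if isinstance(a, NucSeq) != isinstance(b, NucSeq):
        raise ValueError("mixed alphabets: cannot align nucleotide vs protein")


def _alignment_stats(alignment, sa: str, sb: str):
    """Columns, matches and gapped strings from a Biopython alignment."""
    coords = alignment.coordinates
    cols = 0
    matches = 0
    ga: list[str] = []
    gb: list[str] = []
    for i in range(coords.shape[1] - 1):
        a0, a1 = int(coords[0, i]), int(coords[0, i + 1])
        b0, b1 = int(coords[1, i]), int(coords[1, i + 1])
        da, db = a1 - a0, b1 - b0
        step = max(da, db)
        cols += step
        if da and db:  # diagonal block
            seg_a, seg_b = sa[a0:a1], sb[b0:b1]
            matches += sum(x == y for x, y in zip(seg_a, seg_b))
            ga.append(seg_a)
            gb.append(seg_b)
        elif da:
            ga.append(sa[a0:a1])
            gb.append("-" * da)
        else:
            ga.append("-" * db)
            gb.append(sb[b0:b1])
    return cols, matches, "".join(ga), "".join(gb), coords


def global_identity(
    a: SeqT,
    b: SeqT,
    match: float = 1,
    mismatch: float = -1,
    gap: float = -2,
    end_gap_free: bool = False,
) -> GlobalAlignment:
    """Optimal global alignment under linear gap scores.

    ``end_gap_free=True`` gives the semi-global variant (end gaps cost
    nothing) for cDNA-vs-genomic comparisons where 5'/3' overhangs should not
    depress identity.  Identity = matches / alignment columns.
    """
    _check_same_kind(a, b)
    sa, sb = _seq_str(a), _seq_str(b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    if end_gap_free:
        aligner.target_end_open_gap_score = 0
        aligner.target_end_extend_gap_score = 0
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    alignment = aligner.align(sa, sb)[0]
    cols, matches, ga, gb, _ = _alignment_stats(alignment, sa, sb)
    return GlobalAlignment(
        aligned_a=ga,
        aligned_b=gb,
        matches=matches,
        columns=cols,
        identity=matches / cols if cols else 0.0,
        score=float(alignment.score),
    )


def _local_align(sa: str, sb: str, match: float, mismatch: float, gap: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    alignments = aligner.align(sa, sb)
    return alignments[0] if len(alignments) else None


def find_shared_region(
    a: NucSeq,
    b: NucSeq,
    min_len: int = 30,
    min_identity: float = 0.9,
    match: float = 2,
    mismatch: float = -3,
    gap: float = -5,
) -> Optional[SharedRegion]:
    """Best locally shared region between two transcripts, either orientation.

    Local alignments of a vs b and of a vs revcomp(b) are compared by score;
    the winner is returned if it reaches ``min_len`` alignment columns and
    ``min_identity``.  Reverse-complement hits are reported in coordinates on
    b's forward strand.
    """
    if not (isinstance(a, NucSeq) and isinstance(b, NucSeq)):
        raise ValueError("find_shared_region requires nucleotide inputs")
    sa = a.bases
    candidates = []
    for orientation, sb in (
        ("forward", b.bases),
        ("reverse_complement", str(Seq(b.bases).reverse_complement())),
    ):
        aln = _local_align(sa, sb, match, mismatch, gap)
        if aln is None:
            continue
        cols, matches, _, _, coords = _alignment_stats(aln, sa, sb)
        if cols == 0:
            continue
        ia = (int(coords[0, 0]), int(coords[0, -1]))
        ib = (int(coords[1, 0]), int(coords[1, -1]))
        if orientation == "reverse_complement":
            ib = (len(b) - ib[1], len(b) - ib[0])
        candidates.append(
            SharedRegion(
                interval_a=ia,
                interval_b=ib,
                orientation=orientation,
                length=cols,
                identity=matches / cols,
                score=float(aln.score),
            )
        )
    if not candidates:
        return None
    # tie between orientations goes to forward (listed first)
    best = max(candidates, key=lambda r: r.score)
    if best.length < min_len or best.identity < min_identity:
        return None
    return best


def annotate_orf(seq: NucSeq) -> OrfAnnotation:
    """Annotate a (possibly 5'-truncated) coding contig.

    For each frame, the stop-codon-free prefix of complete codons is
    measured.  Frames whose prefix terminates at an in-frame stop are
    preferred (the contig then reads coding + stop + 3' UTR, the structure of
    a 3'-anchored capture contig); among those the longest prefix wins.  If
    no frame contains a stop, the longest prefix wins.  Ties go to the lowest
    frame index.
    """
    if len(seq) < 6:
        raise ValueError("sequence too short to annotate (< 6 bases)")
    s = seq.bases
    n = len(s)
    results = []  # (frame, prefix_nt, has_stop)
    for f in range(3):
        prefix = 0
        has_stop = False
        i = f
        while i + 3 <= n:
            if s[i : i + 3] in STOP_CODONS:
                has_stop = True
                break
            prefix += 3
            i += 3
        results.append((f, prefix, has_stop))

    with_stop = [r for r in results if r[2]]
    pool = with_stop if with_stop else results
    frame, prefix, has_stop = max(pool, key=lambda r: (r[1], -r[0]))

    coding = (frame, frame + prefix)
    if has_stop:
        stop: Optional[tuple[int, int]] = (coding[1], coding[1] + 3)
        utr3 = (stop[1], n)
    else:
        stop = None
        utr3 = (n, n)
    protein = None
    if prefix >= 3:
        protein = ProtSeq(
            f"{seq.id}_orf",
            str(Seq(s[coding[0] : coding[1]]).translate()),
        )
    return OrfAnnotation(
        frame=frame,
        coding_interval=coding,
        stop_interval=stop,
        utr3_interval=utr3,
        has_start_codon=s[coding[0] : coding[0] + 3] == "ATG" and prefix >= 3,
        protein=protein,
    )


def upstream_extension(
    cdna: NucSeq,
    genomic: NucSeq,
    min_identity: float = 0.9,
    min_coverage: float = 0.5,
    match: float = 2,
    mismatch: float = -3,
    gap: float = -5,
) -> int:
    """Genomic bases 5' of the cDNA's aligned start.

    The cDNA is anchored on the genomic contig by local alignment; the anchor
    must reach ``min_identity`` over at least ``min_coverage`` of the cDNA,
    otherwise an error is raised.
    """
    aln = _local_align(genomic.bases, cdna.bases, match, mismatch, gap)
    if aln is None:
        raise ValueError("no confident anchor of cDNA on genomic contig")
    cols, matches, _, _, coords = _alignment_stats(aln, genomic.bases, cdna.bases)
    if cols == 0:
        raise ValueError("no confident anchor of cDNA on genomic contig")
    identity = matches / cols
    cdna_span = int(coords[1, -1]) - int(coords[1, 0])
    if identity < min_identity or cdna_span < min_coverage * len(cdna):
        raise ValueError(
            f"no confident anchor: identity {identity:.3f}, "
            f"cDNA coverage {cdna_span / len(cdna):.3f}"
        )
    g0, c0 = int(coords[0, 0]), int(coords[1, 0])
    return max(0, g0 - c0)
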