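"""Alignment conservation classes, identity clustering, and NJ bootstrap trees.

Column conservation is classified against a declared physiochemical partition
of the 20 residues (printed in every report so results are auditable);
identity-threshold single-linkage clustering turns a pairwise identity matrix
into a lower bound on locus count (diploid assumption: one cluster = one
locus); and a neighbor-joining tree with column-resampling bootstrap serves
as a lightweight phylogenetic summary, mid-point rooted for display only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .io_formats import NucSeq, ProtSeq
from . import gene_annot

GAP = "-"

#: default physiochemical partition of the 20 residues
DEFAULT_CLASSES: tuple[str, ...] = (
    "AG", "ST", "DE", "NQ", "KRH", "ILVM", "FWY", "C", "P",
)


@dataclass(frozen=True)
class Msa:
    """An aligned set of >= 2 equal-length rows (gap symbol '-')."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an MSA needs at least 2 rows")
        if len(set(len(r) for r in self.rows)) != 1:
            raise ValueError("ragged MSA: rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_records(cls, records: Sequence[Union[NucSeq, ProtSeq]]) -> "Msa":
        rows = tuple(
            r.bases if isinstance(r, NucSeq) else r.residues for r in records
        )
        return cls(tuple(r.id for r in records), rows)

    @classmethod
    def from_fasta(cls, path) -> "Msa":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class AlignmentConservation:
    labels: tuple[str, ...]  # per-column: invariant/class_conserved/variable/gapped
    counts: dict
    fractions: dict
    n_columns: int
    classes: tuple[str, ...]


@dataclass(frozen=True)
class LocusAssignment:
    ids: tuple[str, ...]
    matrix: np.ndarray
    threshold: float
    clusters: tuple[tuple[str, ...], ...]
    locus_count: int


@dataclass(frozen=True)
class PhyloTree:
    taxa: tuple[str, ...]
    tree: object  # skbio TreeNode, unrooted
    supports: dict  # canonical bipartition (frozenset) -> percentage
    n_bootstrap: int

    def to_newick(self, midpoint: bool = True) -> str:
        """Newick with bootstrap percentages as internal node labels."""
        t = self.tree.copy()
        if midpoint:
            t = t.root_at_midpoint()
        taxa = frozenset(self.taxa)
        for node in t.non_tips(include_self=True):
            side = frozenset(tip.name for tip in node.tips())
            key = _canonical(side, taxa)
            if key in self.supports:
                node.name = f"{self.supports[key]:.0f}"
        buf = io.StringIO()
        t.write(buf, format="newick")
        return buf.getvalue().strip()


def _validate_classes(classes: Sequence[str]) -> dict:
    member: dict[str, int] = {}
    for i, cls in enumerate(classes):
        for aa in cls:
            if aa in member:
                raise ValueError(f"residue {aa} in more than one class")
            member[aa] = i
    if set(member) != set("ACDEFGHIKLMNPQRSTVWY"):
        raise ValueError("classes must partition the 20 standard residues")
    return member


def classify_columns(
    msa: Msa, classes: Sequence[str] = DEFAULT_CLASSES
) -> AlignmentConservation:
    """Label every column invariant / class_conserved / variable / gapped.

    Any gap makes a column 'gapped'; identical residues 'invariant'; residues
    all within one declared class (but not identical) 'class_conserved';
    anything else (including X, which belongs to no class) 'variable'.
    """
    member = _validate_classes(classes)
    labels = []
    for col in zip(*msa.rows):
        if GAP in col:
            labels.append("gapped")
        elif len(set(col)) == 1:
            labels.append("invariant")
        else:
            cls = {member.get(aa, -1 - i) for i, aa in enumerate(col)}
            labels.append("class_conserved" if len(cls) == 1 else "variable")
    counts = {
        lab: labels.count(lab)
        for lab in ("invariant", "class_conserved", "variable", "gapped")
    }
    n = len(labels)
    fractions = {lab: c / n for lab, c in counts.items()}
    return AlignmentConservation(
        labels=tuple(labels),
        counts=counts,
        fractions=fractions,
        n_columns=n,
        classes=tuple(classes),
    )


def identity_matrix(
    seqs: Union[Sequence[Union[NucSeq, ProtSeq]], Msa],
    mode: str = "global",
) -> tuple[tuple[str, ...], np.ndarray]:
    """Symmetric pairwise identity matrix with unit diagonal.

    mode='global': optimal global alignment identity per pair (unaligned
    inputs).  mode='aligned_msa': column matching over an existing MSA,
    counting only columns where neither row has a gap.
    """
    if mode == "aligned_msa":
        if not isinstance(seqs, Msa):
            raise ValueError("aligned_msa mode requires an Msa")
        ids, rows = seqs.ids, seqs.rows
        n = len(rows)
        mat = np.eye(n)
        arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in rows]
        gap = ord(GAP)
        for i in range(n):
            for j in range(i + 1, n):
                both = (arrs[i] != gap) & (arrs[j] != gap)
                tot = int(both.sum())
                ident = (
                    float(np.sum((arrs[i] == arrs[j]) & both)) / tot if tot else 0.0
                )
                mat[i, j] = mat[j, i] = ident
        return ids, mat
    if mode != "global":
        raise ValueError(f"unknown mode {mode!r}")
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    kinds = {isinstance(s, NucSeq) for s in seqs}
    if len(kinds) != 1:
        raise ValueError("mixed alphabets in identity matrix input")
    n = len(seqs)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = gene_annot.global_identity(seqs[i], seqs[j])
            mat[i, j] = mat[j, i] = aln.identity
    return tuple(s.id for s in seqs), mat


def infer_locus_clusters(
    ids: Sequence[str], matrix: np.ndarray, threshold: float = 0.97
) -> LocusAssignment:
    """Single-linkage clusters at an identity threshold -> locus lower bound.

    Pairs with identity >= threshold are linked; under the diploid default a
    cluster of any size maps to one locus, so the inferred locus count is the
    number of clusters.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    n = len(ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    clusters = tuple(
        tuple(sorted(g)) for g in sorted(groups.values(), key=lambda g: sorted(g)[0])
    )
    return LocusAssignment(
        ids=tuple(ids),
        matrix=np.asarray(matrix),
        threshold=threshold,
        clusters=clusters,
        locus_count=len(clusters),
    )


# ---------------------------------------------------------------------------
# neighbor joining with column-resampling bootstrap


def _pairwise_state(msa: Msa):
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    gap = ord(GAP)
    n = len(arrs)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    mismatch = np.stack(
        [(arrs[i] != arrs[j]) for i, j in pairs]
    )
    valid = np.stack(
        [((arrs[i] != gap) & (arrs[j] != gap)) for i, j in pairs]
    )
    mismatch = mismatch & valid
    return pairs, mismatch, valid


def p_distance_matrix(msa: Msa, columns: Optional[np.ndarray] = None):
    """Proportion of mismatched non-gap columns per pair (skbio DistanceMatrix)."""
    from skbio import DistanceMatrix

    pairs, mismatch, valid = _pairwise_state(msa)
    if columns is not None:
        mismatch, valid = mismatch[:, columns], valid[:, columns]
    n = len(msa.ids)
    mat = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        tot = int(valid[k].sum())
        d = float(mismatch[k].sum()) / tot if tot else 1.0
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=list(msa.ids))


def _canonical(side: frozenset, taxa: frozenset) -> frozenset:
    other = taxa - side
    return side if sorted(side) <= sorted(other) else frozenset(other)


def _bipartitions(tree, taxa: frozenset) -> set:
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if 2 <= len(side) <= len(taxa) - 2:
            bips.add(_canonical(side, taxa))
    return bips


def nj_tree(msa_or_dm) -> object:
    """Neighbor joining (standard Q-criterion) via scikit-bio."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = (
        msa_or_dm
        if isinstance(msa_or_dm, DistanceMatrix)
        else p_distance_matrix(msa_or_dm)
    )
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa for a tree")
    return nj(dm)


def nj_bootstrap_tree(
    msa: Msa, n_bootstrap: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree on p-distances with column-resampling bootstrap support.

    Support for each internal edge of the full-alignment tree is the
    percentage of bootstrap replicates (columns resampled with replacement)
    whose NJ tree contains the same bipartition.  Deterministic given seed.
    """
    if len(msa.ids) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    rng = np.random.default_rng(seed)
    taxa = frozenset(msa.ids)
    main = nj_tree(msa)
    main_bips = _bipartitions(main, taxa)

    hits = {b: 0 for b in main_bips}
    for _ in range(n_bootstrap):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rep = nj_tree(p_distance_matrix(msa, columns=cols))
        rep_bips = _bipartitions(rep, taxa)
        for b in main_bips:
            if b in rep_bips:
                hits[b] += 1
    supports = {
        b: 100.0 * h / n_bootstrap if n_bootstrap else 0.0 for b, h in hits.items()
    }
    return PhyloTree(
        taxa=tuple(msa.ids), tree=main, supports=supports, n_bootstrap=n_bootstrap
    )


# ---------------------------------------------------------------------------
# naive progressive alignment (center-star, pairwise global merges)


def progressive_align(seqs: Sequence[Union[NucSeq, ProtSeq]]) -> Msa:
    """Center-star progressive alignment.

    Every sequence is globally aligned to the longest input (the center) and
    the pairwise gaps are merged into one consistent column space.  Adequate
    for the near-indel-free alignments this package consumes; curated or
    external alignments can be imported with :meth:`Msa.from_fasta` instead.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    center_idx = max(range(len(seqs)), key=lambda i: len(seqs[i]))
    center = seqs[center_idx]
    c_str = center.bases if isinstance(center, NucSeq) else center.residues
    nc = len(c_str)

    # per sequence: inserted run before each center boundary + residue at
    # each center position ('-' when deleted)
    per_seq = []
    for i, s in enumerate(seqs):
        if i == center_idx:
            continue
        aln = gene_annot.global_identity(center, s)
        inserts = [""] * (nc + 1)
        aligned = ["-"] * nc
        k = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca == GAP:
                inserts[k] += cb
            else:
                aligned[k] = cb
                k += 1
        per_seq.append((i, inserts, aligned))

    master_ins = [0] * (nc + 1)
    for _, inserts, _ in per_seq:
        for k, ins in enumerate(inserts):
            master_ins[k] = max(master_ins[k], len(ins))

    def build_row(inserts, aligned) -> str:
        parts = []
        for k in range(nc):
            parts.append(inserts[k].ljust(master_ins[k], GAP))
            parts.append(aligned[k])
        parts.append(inserts[nc].ljust(master_ins[nc], GAP))
        return "".join(parts)

    rows: dict[int, str] = {
        center_idx: build_row([""] * (nc + 1), list(c_str))
    }
    for i, inserts, aligned in per_seq:
        rows[i] = build_row(inserts, aligned)
    return Msa(
        tuple(s.id for s in seqs), tuple(rows[i] for i in range(len(seqs)))
    )
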