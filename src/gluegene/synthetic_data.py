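"""Synthetic fixtures with the statistical structure of spider glue loci.

The generators emulate the sequence architecture this pipeline is built to
analyse: a genomic contig that is a tandem array of near-identical repeat
units (89-99 aa at the protein level) followed by a linker, a conserved
carboxyl-terminal coding region, a stop codon and a 3' UTR; a chimeric cDNA
carrying a reverse-complement foreign insertion flanked by duplicated direct
repeats (the classic cloning-artifact signature); and ~500 bp genomic
fragments sequenced as 2x300 bp read pairs with position-decaying quality.

Every generator is a pure function of its spec, including the seed: reruns
are bitwise identical, and each generator returns an explicit ground-truth
record so downstream detectors are tested against planted truth rather than
against themselves.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import NucSeq, ProtSeq, ReadPair, FastqRead

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DNA4 = "ACGT"

#: default repeat-unit residue frequencies: threonine-enriched (12%), the
#: remaining mass uniform — glue-spidroin repeats are threonine rich (9-15%).
DEFAULT_REPEAT_FREQS = {aa: (0.12 if aa == "T" else 0.88 / 19) for aa in AA20}

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOP_CODONS = tuple(sorted(_CODON_TABLE.stop_codons))
_AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_CODON_TABLE.forward_table.items()):
    _AA_TO_CODONS.setdefault(_aa, ())
    _AA_TO_CODONS[_aa] = _AA_TO_CODONS[_aa] + (_codon,)


# ---------------------------------------------------------------------------
# tandem-repeat protein locus


@dataclass(frozen=True)
class LocusSpec:
    """Parameters of a synthetic glue-spidroin-like locus.

    unit_len_aa=None draws the per-species unit length uniformly from
    [89, 99].  n_repeat_units defaults to 8: assembled contigs show at least
    three units and full spidroin coding regions exceed 10 kb, so the array
    dominates the protein as it does in real loci while staying desk-scale.
    """

    n_repeat_units: int = 8
    unit_len_aa: Optional[int] = None
    unit_mut_rate: float = 0.05
    linker_len_aa: int = 250
    ctd_len_aa: int = 125
    utr3_len: int = 430
    seed: int = 0
    repeat_freqs: Optional[dict] = None

    def __post_init__(self) -> None:
        for name in ("n_repeat_units", "linker_len_aa", "ctd_len_aa", "utr3_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.unit_mut_rate <= 1.0:
            raise ValueError("unit_mut_rate must be in [0, 1]")


@dataclass(frozen=True)
class LocusTruth:
    unit_len: int
    unit_intervals: tuple[tuple[int, int], ...]
    linker_interval: tuple[int, int]
    ctd_interval: tuple[int, int]
    master_unit: str


def _draw_residues(rng: np.random.Generator, n: int, freqs: dict | None) -> str:
    """Random residues; with ``freqs``, exact largest-remainder counts.

    Fixing the counts (rather than iid draws) keeps the realized composition
    of a repeat unit at the target fractions, so per-locus repeat composition
    stays inside the narrow empirical band instead of inheriting master-unit
    sampling noise.
    """
    if freqs is None:
        return "".join(rng.choice(list(AA20), size=n))
    letters = sorted(freqs)
    probs = np.array([freqs[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    ideal = probs * n
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    pool = [aa for aa, c in zip(letters, counts) for _ in range(int(c))]
    rng.shuffle(pool)
    return "".join(pool)


def generate_repeat_protein(spec: LocusSpec) -> tuple[ProtSeq, LocusTruth]:
    """Build repeat-array + linker + CTD protein with a truth record.

    Each unit is an independently mutated copy of one random master unit
    (per-residue substitution probability ``unit_mut_rate``, always to a
    different residue).  Intervals in the truth record are 0-based half-open.
    """
    rng = np.random.default_rng(spec.seed)
    unit_len = (
        int(rng.integers(89, 100)) if spec.unit_len_aa is None else spec.unit_len_aa
    )
    if not 10 <= unit_len <= 500:
        raise ValueError(f"unit_len_aa {unit_len} outside [10, 500]")

    freqs = spec.repeat_freqs if spec.repeat_freqs is not None else DEFAULT_REPEAT_FREQS
    master = _draw_residues(rng, unit_len, freqs)

    units: list[str] = []
    for _ in range(spec.n_repeat_units):
        residues = list(master)
        hits = np.nonzero(rng.random(unit_len) < spec.unit_mut_rate)[0]
        for i in hits:
            alternatives = AA20.replace(residues[i], "")
            residues[i] = alternatives[int(rng.integers(len(alternatives)))]
        units.append("".join(residues))

    linker = _draw_residues(rng, spec.linker_len_aa, None)
    ctd = _draw_residues(rng, spec.ctd_len_aa, None)
    protein = "".join(units) + linker + ctd

    unit_intervals = tuple(
        (i * unit_len, (i + 1) * unit_len) for i in range(spec.n_repeat_units)
    )
    rep_end = spec.n_repeat_units * unit_len
    truth = LocusTruth(
        unit_len=unit_len,
        unit_intervals=unit_intervals,
        linker_interval=(rep_end, rep_end + spec.linker_len_aa),
        ctd_interval=(rep_end + spec.linker_len_aa, len(protein)),
        master_unit=master,
    )
    return ProtSeq(f"locus_seed{spec.seed}", protein), truth


# ---------------------------------------------------------------------------
# reverse translation to a DNA-level gene fixture


@dataclass(frozen=True)
class GeneTruth:
    coding_interval: tuple[int, int]
    stop_interval: tuple[int, int]
    utr3_interval: tuple[int, int]


def reverse_translate_gene(
    prot: ProtSeq, utr3_len: int = 430, seed: int = 0
) -> tuple[NucSeq, GeneTruth]:
    """Reverse-translate a protein into coding sequence + stop + 3' UTR.

    Codons are drawn uniformly among synonymous codons (standard code); the
    coding interval therefore contains no in-frame stop by construction, and
    translating it recovers the input protein exactly.
    """
    rng = np.random.default_rng(seed)
    codons = [
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))]
        for aa in prot.residues
    ]
    coding = "".join(codons)
    stop = _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
    utr3 = "".join(rng.choice(list(DNA4), size=utr3_len))
    bases = coding + stop + utr3
    n = len(coding)
    truth = GeneTruth(
        coding_interval=(0, n),
        stop_interval=(n, n + 3),
        utr3_interval=(n + 3, n + 3 + utr3_len),
    )
    return NucSeq(f"{prot.id}_gene", bases), truth


def random_nucseq(length: int, seed: int = 0, seq_id: str = "rand") -> NucSeq:
    rng = np.random.default_rng(seed)
    return NucSeq(seq_id, "".join(rng.choice(list(DNA4), size=length)))


# ---------------------------------------------------------------------------
# chimeric cDNA with duplicated direct repeats


@dataclass(frozen=True)
class ChimeraSpec:
    """Geometry of a planted cloning-artifact insertion.

    The foreign block and the duplicated direct repeat are parameterized
    independently; the defaults (363 + 60) make the total excess over the
    base cDNA 423 bp.  ``insertion_point=None`` plants the artifact at the
    midpoint of the base sequence.
    """

    direct_repeat_len: int = 60
    foreign_len: int = 363
    foreign_orientation: str = "reverse_complement"
    insertion_point: Optional[int] = None

    def __post_init__(self) -> None:
        if self.direct_repeat_len < 0 or self.foreign_len < 0:
            raise ValueError("lengths must be non-negative")
        if self.foreign_orientation not in ("forward", "reverse_complement"):
            raise ValueError(f"bad orientation {self.foreign_orientation!r}")


@dataclass(frozen=True)
class ChimeraTruth:
    insertion_point: int
    inserted_interval: tuple[int, int]
    left_repeat: Optional[tuple[int, int]]
    right_repeat: Optional[tuple[int, int]]
    foreign_interval: tuple[int, int]
    donor_interval: Optional[tuple[int, int]]
    orientation: str


def build_chimeric_cdna(
    base: NucSeq,
    spec: ChimeraSpec,
    seed: int = 0,
    donor: Optional[NucSeq] = None,
) -> tuple[NucSeq, ChimeraTruth]:
    """Insert a foreign block plus a duplicated direct-repeat flank.

    Output = base[0:p] + foreign + base[p-d:p] + base[p:], i.e. the d bases
    immediately left of the insertion point reappear after the foreign block,
    so the two repeat copies are 100% identical.  The foreign block is drawn
    independently of the base cDNA — either random, or a segment of ``donor``
    (reverse-complemented under the default orientation, emulating a shared
    region present in another transcript in the opposite orientation).
    """
    rng = np.random.default_rng(seed)
    d = spec.direct_repeat_len
    f = spec.foreign_len
    p = spec.insertion_point if spec.insertion_point is not None else len(base) // 2
    if p < d:
        raise ValueError(f"insertion_point {p} < direct_repeat_len {d}")
    if p > len(base):
        raise ValueError("insertion_point beyond base sequence")

    donor_interval = None
    if donor is not None:
        if len(donor) < f:
            raise ValueError("donor shorter than foreign_len")
        start = int(rng.integers(0, len(donor) - f + 1))
        segment = donor.bases[start : start + f]
        donor_interval = (start, start + f)
    else:
        segment = "".join(rng.choice(list(DNA4), size=f))

    if spec.foreign_orientation == "reverse_complement":
        foreign = str(Seq(segment).reverse_complement())
    else:
        foreign = segment

    bases = base.bases[:p] + foreign + base.bases[p - d : p] + base.bases[p:]
    truth = ChimeraTruth(
        insertion_point=p,
        inserted_interval=(p, p + f + d),
        left_repeat=(p - d, p) if d > 0 else None,
        right_repeat=(p + f, p + f + d) if d > 0 else None,
        foreign_interval=(p, p + f),
        donor_interval=donor_interval,
        orientation=spec.foreign_orientation,
    )
    return NucSeq(f"{base.id}_chimera", bases), truth


# ---------------------------------------------------------------------------
# paired-end read simulation


@dataclass(frozen=True)
class ReadSimSpec:
    """2x300 bp MiSeq-style paired-end simulation over ~500 bp fragments.

    Per-base quality decays linearly qual_start -> qual_end along the read
    (defaults 37 -> 22, with Gaussian jitter), and substitution errors are
    injected at the Phred-implied rate times ``error_rate_scale``.
    """

    fragment_len_mean: int = 500
    fragment_len_sd: float = 50.0
    read_len: int = 300
    depth: float = 30.0
    qual_start: int = 37
    qual_end: int = 22
    qual_jitter_sd: float = 3.0
    error_rate_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len > self.fragment_len_mean:
            raise ValueError("read_len must be <= fragment_len_mean")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass(frozen=True)
class ReadSimTruth:
    fragment_intervals: tuple[tuple[int, int], ...]
    coverage: np.ndarray  # per-base depth implied by the simulated reads


def _quality_profile(spec: ReadSimSpec, rng: np.random.Generator) -> np.ndarray:
    pos = np.arange(spec.read_len)
    denom = max(spec.read_len - 1, 1)
    base = spec.qual_start + (spec.qual_end - spec.qual_start) * pos / denom
    q = base + rng.normal(0.0, spec.qual_jitter_sd, size=spec.read_len)
    return np.clip(np.rint(q), 2, 41).astype(int)


def _inject_errors(
    bases: str, quals: np.ndarray, scale: float, rng: np.random.Generator
) -> str:
    if scale <= 0:
        return bases
    p_err = np.power(10.0, -quals / 10.0) * scale
    hits = np.nonzero(rng.random(len(bases)) < p_err)[0]
    if len(hits) == 0:
        return bases
    out = list(bases)
    for i in hits:
        if out[i] in DNA4:
            alternatives = DNA4.replace(out[i], "")
            out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def simulate_paired_reads(
    ref: NucSeq, spec: ReadSimSpec
) -> tuple[list[ReadPair], ReadSimTruth]:
    """Shear ``ref`` into fragments and sequence both ends.

    Mate 1 is the fragment's 5' prefix; mate 2 is the reverse complement of
    its 3' suffix.  Fragment count is chosen so realized coverage matches
    ``spec.depth`` in expectation.  Deterministic given ``spec.seed``.
    """
    if len(ref) < spec.read_len:
        raise ValueError(
            f"reference ({len(ref)} bp) shorter than read_len {spec.read_len}"
        )
    rng = np.random.default_rng(spec.seed)
    n_frags = max(1, round(spec.depth * len(ref) / (2 * spec.read_len)))

    pairs: list[ReadPair] = []
    fragments: list[tuple[int, int]] = []
    coverage = np.zeros(len(ref), dtype=int)
    for i in range(n_frags):
        flen = int(np.rint(rng.normal(spec.fragment_len_mean, spec.fragment_len_sd)))
        flen = int(np.clip(flen, spec.read_len, len(ref)))
        start = int(rng.integers(0, len(ref) - flen + 1))
        frag = ref.bases[start : start + flen]
        fragments.append((start, start + flen))

        q1 = _quality_profile(spec, rng)
        q2 = _quality_profile(spec, rng)
        m1 = _inject_errors(frag[: spec.read_len], q1, spec.error_rate_scale, rng)
        tail = frag[flen - spec.read_len :]
        m2_fwd = _inject_errors(tail, q2[::-1], spec.error_rate_scale, rng)
        m2 = str(Seq(m2_fwd).reverse_complement())

        coverage[start : start + spec.read_len] += 1
        coverage[start + flen - spec.read_len : start + flen] += 1
        pairs.append(
            ReadPair(
                FastqRead(f"{ref.id}_frag{i}/1", m1, tuple(int(q) for q in q1)),
                FastqRead(f"{ref.id}_frag{i}/2", m2, tuple(int(q) for q in q2)),
            )
        )
    return pairs, ReadSimTruth(tuple(fragments), coverage)


# ---------------------------------------------------------------------------
# capture probe design


@dataclass(frozen=True)
class Probe:
    target_id: str
    start: int
    end: int
    seq: str


def design_tiling_probes(
    targets: Sequence[NucSeq], probe_len: int = 120, tiling: int = 5
) -> list[Probe]:
    """Tile each target with ``probe_len``-mers at step probe_len / tiling.

    With the defaults (120-mers, 5x tiling) the step is 24 bases and every
    internal base is covered by exactly ``tiling`` probes.
    """
    if probe_len % tiling != 0:
        raise ValueError(f"probe_len {probe_len} not divisible by tiling {tiling}")
    step = probe_len // tiling
    probes: list[Probe] = []
    for t in targets:
        if len(t) < probe_len:
            raise ValueError(f"target {t.id!r} shorter than probe_len {probe_len}")
        for off in range(0, len(t) - probe_len + 1, step):
            probes.append(Probe(t.id, off, off + probe_len, t.bases[off : off + probe_len]))
    return probes


# ---------------------------------------------------------------------------
# protein alignments evolved on a species tree

#: araneoid-shaped 6-taxon tree: three orb-weavers vs three cob-web weavers.
DEFAULT_SPECIES_TREE = (
    "((Nclavipes:0.20,(Aargentata:0.15,Adiadematus:0.15):0.10):0.10,"
    "((Lhesperus:0.15,Sgrossa:0.15):0.10,Ptepidariorum:0.20):0.10);"
)


@dataclass(frozen=True)
class CtdAlignmentSpec:
    """Conservation structure of a carboxyl-terminal region alignment.

    Defaults mirror the conservation classes of the glue-spidroin CTD: 123
    columns of which 21 evolve under absolute constraint (invariant), 23
    under physiochemical-class constraint, and the rest freely.  Free and
    class columns substitute at ``rate`` expected events per unit branch
    length; free columns can still come out identical by chance, so measured
    conservation counts are at least the designed ones.
    """

    n_columns: int = 123
    n_invariant: int = 21
    n_class_conserved: int = 23
    rate: float = 2.5
    tree_newick: str = DEFAULT_SPECIES_TREE
    seed: int = 0


def _parse_tree(newick: str):
    from skbio import TreeNode

    return TreeNode.read(io.StringIO(newick))


def simulate_alignment_on_tree(
    tree_newick: str,
    n_columns: int,
    seed: int = 0,
    rate: float = 1.0,
    column_allowed: Optional[list[str]] = None,
    column_rates: Optional[np.ndarray] = None,
) -> list[ProtSeq]:
    """Evolve an indel-free protein alignment along a newick tree.

    Per column, substitutions on a branch of length t arrive as
    Poisson(rate_col * t) jumps to a uniformly drawn different letter within
    the column's allowed set.  Returns one (already aligned, gap-free) record
    per leaf, in tree leaf order.
    """
    rng = np.random.default_rng(seed)
    tree = _parse_tree(tree_newick)
    if column_allowed is None:
        column_allowed = [AA20] * n_columns
    if column_rates is None:
        column_rates = np.full(n_columns, rate)

    root_seq = [
        allowed[int(rng.integers(len(allowed)))] for allowed in column_allowed
    ]

    leaves: dict[str, str] = {}

    def descend(node, seq: list[str]) -> None:
        for child in node.children:
            t = child.length or 0.0
            child_seq = list(seq)
            n_subs = rng.poisson(column_rates * t)
            for col in np.nonzero(n_subs)[0]:
                allowed = column_allowed[col]
                if len(allowed) < 2:
                    continue
                for _ in range(int(n_subs[col])):
                    alternatives = allowed.replace(child_seq[col], "")
                    child_seq[col] = alternatives[int(rng.integers(len(alternatives)))]
            if child.is_tip():
                leaves[str(child.name)] = "".join(child_seq)
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    order = [str(tip.name) for tip in tree.tips()]
    return [ProtSeq(name, leaves[name]) for name in order]


def generate_ctd_alignment(spec: CtdAlignmentSpec) -> tuple[list[ProtSeq], dict]:
    """Six-species CTD-like alignment with designed conservation classes.

    Returns the aligned records plus a truth dict with the designed column
    categories ('invariant' / 'class' / 'free') in alignment order.
    """
    from .conservation_phylo import DEFAULT_CLASSES

    rng = np.random.default_rng(spec.seed)
    n_free = spec.n_columns - spec.n_invariant - spec.n_class_conserved
    if n_free < 0:
        raise ValueError("designed conserved columns exceed n_columns")
    categories = (
        ["invariant"] * spec.n_invariant
        + ["class"] * spec.n_class_conserved
        + ["free"] * n_free
    )
    rng.shuffle(categories)

    multi_classes = [c for c in DEFAULT_CLASSES if len(c) > 1]
    allowed: list[str] = []
    rates = np.zeros(spec.n_columns)
    for i, cat in enumerate(categories):
        if cat == "invariant":
            allowed.append(AA20[int(rng.integers(20))])
            rates[i] = 0.0
        elif cat == "class":
            allowed.append(multi_classes[int(rng.integers(len(multi_classes)))])
            rates[i] = spec.rate
        else:
            allowed.append(AA20)
            rates[i] = spec.rate

    records = simulate_alignment_on_tree(
        spec.tree_newick,
        spec.n_columns,
        seed=spec.seed + 1,
        column_allowed=allowed,
        column_rates=rates,
    )
    return records, {"categories": categories, "allowed": allowed}
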