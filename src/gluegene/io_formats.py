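"""Readers and writers for the plain-text formats the pipeline touches.

Sequence containers are thin frozen dataclasses with strict alphabets; all
coordinates everywhere in the package are 0-based half-open.  FASTA and FASTQ
parsing/writing is delegated to Biopython's SeqIO; the FASTQ dialect is fixed
to Phred+33 (Illumina >= 1.8) and apparent Phred+64 input is rejected.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("gluegene")

NUC_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: highest Phred score a Phred+33 (Sanger/Illumina 1.8+) file may carry
MAX_PHRED33 = 41


@dataclass(frozen=True)
class NucSeq:
    """A nucleotide sequence over {A,C,G,T,N}."""

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"empty sequence for id {self.id!r}")
        bad = set(self.bases) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"invalid nucleotide characters {sorted(bad)} in {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def revcomp(self, new_id: str | None = None) -> "NucSeq":
        return NucSeq(
            new_id or f"{self.id}_rc",
            str(Seq(self.bases).reverse_complement()),
            self.description,
        )


@dataclass(frozen=True)
class ProtSeq:
    """A protein sequence over the 20 IUPAC one-letter codes plus X."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for id {self.id!r}")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"invalid residue characters {sorted(bad)} in {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FastqRead:
    """A single quality-scored read; quals are Phred integers (>= 0)."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality scores"
            )
        if self.quals and min(self.quals) < 0:
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadPair:
    """A mated pair of reads — the unit of QC and (chimera) mapping."""

    r1: FastqRead
    r2: FastqRead


SeqRecordT = Union[NucSeq, ProtSeq]


def _strip_mate_suffix(read_id: str) -> str:
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def read_fasta(path: str | Path) -> list[SeqRecordT]:
    """Parse a (possibly wrapped) multi-record FASTA file.

    Sequences are upper-cased and whitespace-joined.  Records whose alphabet
    fits {A,C,G,T,N} come back as :class:`NucSeq`, anything else as
    :class:`ProtSeq`.  Empty files and duplicate ids are errors.
    """
    records: list[SeqRecordT] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace(" ", "")
        desc = rec.description[len(rec.id):].strip()
        if set(seq) <= NUC_ALPHABET:
            records.append(NucSeq(rec.id, seq, desc))
        else:
            records.append(ProtSeq(rec.id, seq, desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SeqRecordT], path: str | Path) -> None:
    """Write records as 60-column wrapped FASTA; round-trips via read_fasta."""
    if not records:
        raise ValueError("no records to write")
    out = []
    for r in records:
        seq = r.bases if isinstance(r, NucSeq) else r.residues
        out.append(SeqRecord(Seq(seq), id=r.id, description=r.description))
    SeqIO.write(out, str(path), "fasta")


def _read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        if quals and max(quals) > MAX_PHRED33 + 1:
            raise ValueError(
                f"{path}: Phred score {max(quals)} exceeds the Phred+33 "
                "range; input looks Phred+64 encoded, which is not supported"
            )
        reads.append(FastqRead(rec.id, str(rec.seq).upper(), quals))
    return reads


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path
) -> list[ReadPair]:
    """Read two Phred+33 FASTQ files into mate pairs matched by order.

    Ids must agree up to a trailing ``/1``, ``/2`` (or whitespace-separated
    mate token, which SeqIO already strips); unequal record counts are an
    error.
    """
    r1s, r2s = _read_fastq(path_r1), _read_fastq(path_r2)
    if len(r1s) != len(r2s):
        raise ValueError(
            f"unequal record counts: {len(r1s)} in {path_r1} vs "
            f"{len(r2s)} in {path_r2}"
        )
    pairs = []
    for a, b in zip(r1s, r2s):
        if _strip_mate_suffix(a.id) != _strip_mate_suffix(b.id):
            raise ValueError(f"mate id mismatch: {a.id!r} vs {b.id!r}")
        pairs.append(ReadPair(a, b))
    return pairs


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qline = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qline}\n")


def write_fastq_pairs(
    pairs: Sequence[ReadPair],
    path_r1: str | Path,
    path_r2: str | Path,
    interleaved_path: str | Path | None = None,
) -> None:
    write_fastq((p.r1 for p in pairs), path_r1)
    write_fastq((p.r2 for p in pairs), path_r2)
    if interleaved_path is not None:
        inter: list[FastqRead] = []
        for p in pairs:
            inter.extend((p.r1, p.r2))
        write_fastq(inter, interleaved_path)


def write_coverage_bed(track, path: str | Path) -> None:
    """Write a per-base depth track as BED4 (chrom, start, end, depth).

    Adjacent positions of equal depth are merged into one 0-based half-open
    interval (plain run-length encoding).
    """
    depth = getattr(track, "depth", None)
    ref_id = getattr(track, "ref_id", None)
    if depth is None or len(depth) == 0:
        raise ValueError("empty coverage track")
    with open(path, "w") as fh:
        start = 0
        cur = int(depth[0])
        for i in range(1, len(depth)):
            d = int(depth[i])
            if d != cur:
                fh.write(f"{ref_id}\t{start}\t{i}\t{cur}\n")
                start, cur = i, d
        fh.write(f"{ref_id}\t{start}\t{len(depth)}\t{cur}\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def setup_logging(verbose: bool = False) -> None:
    """Line-oriented logging to stderr; DEBUG when verbose."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
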