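"""Shared fixtures: one synthetic glue locus and its derived fixtures."""

import pytest

from gluegene import (
    ChimeraSpec,
    LocusSpec,
    ReadSimSpec,
    build_chimeric_cdna,
    generate_repeat_protein,
    reverse_translate_gene,
    simulate_paired_reads,
)


@pytest.fixture(scope="session")
def locus():
    """(protein, truth) for a default tandem-repeat locus."""
    return generate_repeat_protein(LocusSpec(seed=11))


@pytest.fixture(scope="session")
def gene(locus):
    """(gene, truth): the locus reverse-translated with stop + 430 bp 3' UTR."""
    prot, _ = locus
    return reverse_translate_gene(prot, utr3_len=430, seed=12)


@pytest.fixture(scope="session")
def chimeric_cdna(gene):
    """(chimera, truth): gene cDNA with the default 363+60 bp planted artifact."""
    g, _ = gene
    return build_chimeric_cdna(g, ChimeraSpec(), seed=13)


@pytest.fixture(scope="session")
def genomic_reads(gene):
    """(pairs, truth): 2x300 bp pairs simulated from the clean gene at depth 30."""
    g, _ = gene
    return simulate_paired_reads(g, ReadSimSpec(depth=30, seed=14))
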