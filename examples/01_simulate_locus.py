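"""Build a synthetic glue-spidroin locus and a chimeric cDNA from it.

Generates a tandem-repeat protein (repeat array + linker + CTD), reverse
translates it into a gene with stop codon and 3' UTR, and plants a
reverse-complement foreign insertion flanked by a duplicated 60 bp direct
repeat — the geometry this pipeline is built to detect.
"""

from gluegene import (
    ChimeraSpec,
    LocusSpec,
    build_chimeric_cdna,
    generate_repeat_protein,
    reverse_translate_gene,
)

prot, locus_truth = generate_repeat_protein(LocusSpec(seed=1))
gene, gene_truth = reverse_translate_gene(prot, utr3_len=430, seed=2)
chimera, chim_truth = build_chimeric_cdna(gene, ChimeraSpec(), seed=3)

print(f"protein: {len(prot)} aa, unit length {locus_truth.unit_len} aa x "
      f"{len(locus_truth.unit_intervals)} units")
print(f"linker {locus_truth.linker_interval}, CTD {locus_truth.ctd_interval}")
print(f"gene: {len(gene)} bp = coding {gene_truth.coding_interval[1]} bp "
      f"+ stop + 3' UTR {gene_truth.utr3_interval[1] - gene_truth.utr3_interval[0]} bp")
print(f"chimeric cDNA: {len(chimera)} bp "
      f"({len(chimera) - len(gene)} bp of extra material)")
print(f"planted insertion {chim_truth.inserted_interval}, direct repeat copies "
      f"at {chim_truth.left_repeat} and {chim_truth.right_repeat}")
print()
print("The chimera carries 423 bp the real gene does not have: a 363 bp "
      "reverse-complement foreign block plus one duplicated 60 bp repeat copy.")
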