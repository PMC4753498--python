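"""Pairwise comparisons and ORF/UTR annotation.

Shows the three comparison modes — global identity, best shared region in
either orientation, genomic upstream extension — plus annotation of a
start-codon-less coding contig as coding + stop + 3' UTR.
"""

from gluegene import (
    ChimeraSpec,
    LocusSpec,
    NucSeq,
    annotate_orf,
    build_chimeric_cdna,
    find_shared_region,
    generate_repeat_protein,
    global_identity,
    reverse_translate_gene,
    upstream_extension,
)
from gluegene.synthetic_data import random_nucseq

prot, _ = generate_repeat_protein(LocusSpec(seed=1))
gene, _ = reverse_translate_gene(prot, 430, seed=2)
donor = random_nucseq(1500, seed=5, seq_id="donor_transcript")
chimera, _ = build_chimeric_cdna(gene, ChimeraSpec(), seed=3, donor=donor)
genomic = NucSeq("genomic", random_nucseq(246, seed=6).bases + gene.bases)

aln = global_identity(NucSeq("a", "ACGT"), NucSeq("b", "ACGA"))
print(f"global identity ACGT vs ACGA: {aln.matches}/{aln.columns} = {aln.identity:.2f}")

region = find_shared_region(chimera, donor)
print(f"chimera vs donor: {region.length} columns shared in "
      f"{region.orientation} orientation, identity {region.identity:.2f}")

ann = annotate_orf(gene)
print(f"gene contig: frame {ann.frame}, coding {ann.coding_interval}, "
      f"stop {ann.stop_interval}, 3' UTR "
      f"{ann.utr3_interval[1] - ann.utr3_interval[0]} bp, "
      f"start codon present: {ann.has_start_codon}")

print(f"genomic contig extends {upstream_extension(gene, genomic)} bp "
      "upstream of the cDNA")
print()
print("A block shared in reverse-complement orientation between two unrelated "
      "transcripts is a hallmark of a cloning artifact, not overlapping genes.")
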