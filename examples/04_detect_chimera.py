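"""Full chimera call: gap -> direct repeats -> excision -> re-map validation.

The caller finds the coverage desert, locates the duplicated direct repeat
flanking it, excises the insertion keeping exactly one repeat copy, re-maps
the reads to the edited transcript, and validates that the junction is now
covered.
"""

from gluegene import (
    ChimeraConfig,
    ChimeraSpec,
    LocusSpec,
    build_chimeric_cdna,
    call_chimera,
    generate_repeat_protein,
    reverse_translate_gene,
)

prot, _ = generate_repeat_protein(LocusSpec(seed=1))
gene, _ = reverse_translate_gene(prot, 430, seed=2)
chimera, truth = build_chimeric_cdna(gene, ChimeraSpec(), seed=3)

calls = call_chimera(chimera, genomic=gene, cfg=ChimeraConfig(seed=4))
for c in calls:
    print(f"excised {c.excised_interval} ({c.excised_len} bp), "
          f"validated={c.validated} (junction min depth {c.junction_min_depth})")
    if c.repeats:
        print(f"direct repeat: {c.repeats.length} bp at {c.repeats.left} / "
              f"{c.repeats.right}, identity {c.repeats.identity:.0%}")
    print(f"edited transcript equals the true gene: "
          f"{c.edited_seq.bases == gene.bases}")

control = call_chimera(gene, genomic=gene, cfg=ChimeraConfig(seed=4))
print(f"control (clean transcript): {len(control)} calls")
print()
print("One validated 423 bp excision restoring the true cDNA byte-for-byte, "
      "and zero calls on the clean control, is the expected outcome.")
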