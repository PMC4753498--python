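# gluegene

Comparative-genomic forensics for spider aggregate-glue genes — and, more
generally, for any transcript suspected of being a cloning chimera.

Spiders in the superfamily Araneoidea coat their capture threads with a
viscous glue produced by aggregate silk glands. Two cDNAs from the golden
orb-weaver *Nephila clavipes* — Aggregate Spider Glue 1 and 2 (*ASG1*,
*ASG2*) — were long taken at face value, even though they share a ~353 bp
block that appears in one transcript in the forward orientation and in the
other as its reverse complement. Genomic evidence resolves the puzzle: the
shared block in the *ASG2* cDNA is a cloning artifact. When independent
genomic reads are mapped back onto the cDNA, the foreign block is a
**coverage desert** flanked by a **duplicated 60 bp direct repeat** (the
classic recombination/cloning signature); excising it restores a transcript
the genome actually supports, and what remains has unmistakable spidroin
(spider fibroin) architecture: tandem repeat units of 89–99 aa, a linker,
and a conserved ~125 aa carboxyl-terminal region.

`gluegene` implements that whole forensic pipeline as a tested Python
library, for sequence analysts who want each step scriptable and verifiable:

- **io_formats** — strict FASTA/FASTQ (Phred+33) containers, BED4 coverage
  output, YAML config; 0-based half-open coordinates everywhere.
- **synthetic_data** — generators that emulate glue-locus structure (repeat
  array + linker + CTD + stop + 3′ UTR; chimeric insertions with duplicated
  direct repeats; 2×300 bp read pairs over ~500 bp fragments with
  position-decaying quality), each returning an explicit ground-truth record.
- **read_qc** — discard reads with ambiguous bases; head-trim; truncate at
  the first position whose first-quartile quality drops below Q25; drop
  reads with >15% of bases below Q25; keep only intact pairs.
- **mapping** — exact-seed, mismatch-tolerant, ungapped k-mer mapper with
  per-base coverage tracks.
- **chimera** — coverage-gap detection, flanking direct-repeat search,
  excision (keeping one repeat copy) and re-mapping validation.
- **gene_annot** — global/local pairwise alignment (identity =
  matches / alignment columns), best shared region in either orientation,
  ORF + stop + 3′ UTR annotation of start-codon-less contigs, genomic
  upstream-extension measurement.
- **repeat_architecture** — tandem-unit length by shifted self-identity,
  array segmentation, residue composition.
- **conservation_phylo** — alignment column classes (invariant /
  physiochemically conserved / variable), identity-threshold locus
  clustering, neighbor-joining trees with column-resampling bootstrap.

A thin `gluegene` CLI wraps the library (`simulate`, `qc`, `map`, `chimera`,
`annotate`, `compare`, `architecture`, `conserve`, `loci`, `tree`), and
`examples/` holds one short narrative script per capability, including
`examples/08_accession_analysis.py`, which runs the workflow on
locally downloaded GenBank FASTAs (EU780014, EU780015, KU132353).

## Worked example

```python
from gluegene import (ChimeraConfig, ChimeraSpec, LocusSpec,
                      build_chimeric_cdna, call_chimera,
                      generate_repeat_protein, reverse_translate_gene)

prot, _ = generate_repeat_protein(LocusSpec(seed=1))     # repeat array + linker + CTD
gene, _ = reverse_translate_gene(prot, 430, seed=2)      # coding + stop + 430 bp UTR
chimera, truth = build_chimeric_cdna(gene, ChimeraSpec(), seed=3)

for c in call_chimera(chimera, genomic=gene, cfg=ChimeraConfig(seed=4)):
    print(c.excised_interval, c.excised_len, c.validated,
          c.repeats.length, c.edited_seq.bases == gene.bases)
```

prints

```
(1907, 2330) 423 True 60 True
```

Reads simulated from the true gene leave a coverage desert over the planted
insertion; the caller finds the 60 bp direct repeat flanking it, excises 423
bp (363 bp foreign block + one duplicated repeat copy), re-maps, confirms
the junction is covered — and the edited transcript equals the real cDNA
byte for byte. Running the same caller on the clean transcript returns no
calls. `examples/04_detect_chimera.py` is the annotated version of this
snippet.

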