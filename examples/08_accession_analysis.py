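"""Run the forensic workflow on user-supplied GenBank accession FASTAs.

This script performs the real-data analysis on locally downloaded sequences
(no network access is attempted).  Fetch the three N. clavipes records as
FASTA first, e.g. from https://www.ncbi.nlm.nih.gov/nuccore/:

    EU780014   ASG1 cDNA
    EU780015   ASG2 cDNA (the putatively chimeric transcript)
    KU132353   ASG2 genomic capture contig

Usage:
    python examples/08_accession_analysis.py --asg1 EU780014.fa \
        --asg2-cdna EU780015.fa --asg2-genomic KU132353.fa

It measures: the shared region between the two cDNAs (expected ~353 bp,
reverse-complement orientation), the coverage desert and direct repeats of
the ASG2 cDNA against genomic evidence (expected 423 bp excision with a 60 bp
repeat), the ORF/UTR structure of the genomic contig (expected 430 bp 3'
UTR, no start codon), and how far the genomic contig extends upstream of the
edited cDNA (expected ~246 bp).
"""

import argparse
import sys

from gluegene import (
    ChimeraConfig,
    annotate_orf,
    call_chimera,
    find_shared_region,
    read_fasta,
    upstream_extension,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--asg1", required=True, help="ASG1 cDNA FASTA (EU780014)")
    ap.add_argument("--asg2-cdna", required=True, help="ASG2 cDNA FASTA (EU780015)")
    ap.add_argument("--asg2-genomic", required=True,
                    help="ASG2 genomic contig FASTA (KU132353)")
    args = ap.parse_args()

    asg1 = read_fasta(args.asg1)[0]
    cdna = read_fasta(args.asg2_cdna)[0]
    genomic = read_fasta(args.asg2_genomic)[0]

    region = find_shared_region(asg1, cdna)
    if region:
        print(f"ASG1 vs ASG2 cDNA: {region.length} columns shared, "
              f"{region.orientation} orientation, identity {region.identity:.2f}")
    else:
        print("no shared region between the cDNAs above thresholds")

    calls = call_chimera(cdna, genomic=genomic, cfg=ChimeraConfig(seed=0))
    if not calls:
        print("no coverage desert detected in the ASG2 cDNA")
        sys.exit(0)
    for c in calls:
        print(f"coverage desert {c.gap.interval}; excised {c.excised_len} bp, "
              f"validated={c.validated}")
        if c.repeats:
            print(f"direct repeat {c.repeats.length} bp, "
                  f"identity {c.repeats.identity:.0%}")

    edited = calls[0].edited_seq
    ann = annotate_orf(genomic)
    print(f"genomic contig: coding {ann.coding_interval}, "
          f"3' UTR {ann.utr3_interval[1] - ann.utr3_interval[0]} bp, "
          f"start codon: {ann.has_start_codon}")
    print(f"genomic contig extends {upstream_extension(edited, genomic)} bp "
          "upstream of the edited cDNA")


if __name__ == "__main__":
    main()
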