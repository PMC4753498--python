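"""Quality-filter simulated 2x300 bp read pairs.

Simulates MiSeq-style pairs with position-decaying quality, corrupts a few
(ambiguous bases, uniformly low quality), and applies the QC rules: discard
reads with any non-ACGT base, head-trim 6 bases, truncate at the first
position whose first-quartile quality drops below Q25, and drop reads with
more than 15% of bases below Q25.
"""

from gluegene import (
    FastqRead,
    QcConfig,
    ReadPair,
    ReadSimSpec,
    qc_filter_pairs,
    simulate_paired_reads,
)
from gluegene.synthetic_data import random_nucseq

ref = random_nucseq(20_000, seed=1, seq_id="contig")
pairs, _ = simulate_paired_reads(ref, ReadSimSpec(depth=30, seed=2))

doctored = list(pairs)
p = doctored[0]
doctored[0] = ReadPair(FastqRead(p.r1.id, "N" + p.r1.bases[1:], p.r1.quals), p.r2)
p = doctored[1]
doctored[1] = ReadPair(FastqRead(p.r1.id, p.r1.bases, (12,) * len(p.r1)), p.r2)

kept, report = qc_filter_pairs(doctored, QcConfig())
print(report.as_dict())
print()
print(f"Of {report.n_input_pairs} pairs, {report.n_output_pairs} survive; the "
      "trim points are where the per-position first-quartile quality first "
      "falls below Q25 (reads are truncated there before the 15% rule).")
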