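# Methods

This note documents the models, parameters, numerical conventions and design
choices behind `gluegene`, and what the synthetic-data generators do and do
not emulate. Coordinates are 0-based half-open throughout; FASTQ is fixed to
Phred+33 (apparent Phred+64 input is rejected with an explicit error).

## Chimera model and detection procedure

A cloning chimera is modelled as a transcript of the form

    base[0:p] + foreign + base[p-d:p] + base[p:]

i.e. a foreign block of length *f* inserted at point *p*, followed by a
duplicate of the *d* bases immediately left of *p*. The two repeat copies
are therefore 100% identical, and the excess length over the true transcript
is *f + d* (defaults 363 + 60 = 423 bp). The foreign block is drawn
independently of the base — either random sequence or a segment of a donor
transcript, reverse-complemented by default, which emulates a block shared
between two otherwise unrelated cDNAs in opposite orientations.

Detection maps independent (genomic) reads onto the suspect transcript and
proceeds: coverage desert → flanking direct repeats → excision → re-map →
junction validation.

- **Coverage gaps** are maximal runs of depth ≤ `max_gap_depth` (default 0,
  i.e. complete absence of reads), at least `min_gap_len` (50) long and not
  overlapping the first/last `end_margin` (25) bases, where read-edge
  effects thin out real coverage. Because the mapper tolerates up to 5%
  mismatches, reads overhanging the insertion boundaries by a few bases can
  still map, and reads containing the repeat map into the gap's right edge
  (the repeat occurs twice); the *detected* desert is therefore typically a
  few tens of bases narrower than the planted insertion. This does not harm
  excision accuracy because excision is anchored on the repeat pair, not on
  the gap edges.
- **Direct repeats**: the longest pair of equal-length, same-orientation
  copies with one copy ending within `max_offset` (100) of the gap start and
  the other beginning within `max_offset` of the gap end, allowing
  `max_mismatch` (0) differences and at least `min_repeat` (20) bases. Ties
  break to the longer pair, then the pair closest to the gap, then leftmost.
  The search is an incremental diagonal extension over the two anchor
  windows (O(window² · expected extension)); tests check it against an
  O(n²·L) brute-force reference. A detected pair may extend a base or two
  past the duplicated block when the flanking base coincides by chance;
  this leaves the edited sequence unchanged.
- **Excision** removes `[left_repeat.end, right_repeat.end)` — any cut point
  inside a direct repeat yields the same edited sequence, so we canonicalize
  to "keep the left copy". Without a repeat pair the bare gap is removed.
- **Validation** re-maps the same reads to the edited transcript with the
  same mapper parameters (avoiding circularity disputes) and requires
  minimum depth ≥ `validation_min_depth` (1) across ±2 read lengths around
  the junction. A true sequencing dropout fails this check: reads genuinely
  spanning the removed region are discordant across the new junction.

## Read mapper

Chimera detection needs presence/absence of coverage, not indel-aware
alignment, so the mapper is ungapped and end-to-end: forward k-mers
(default k = 21) of the reference are indexed; a read contributes
non-overlapping seeds (plus one flush to the 3′ end) on both strands, each
seed voting for a candidate offset; candidates are scored by Hamming
distance and accepted if mismatches ≤ `max_mismatch_frac` (0.05) × read
length. Ties break to the leftmost offset, then the + strand — so a read
from a repeat array is counted at the leftmost identical copy. Pairing is
not enforced; mates are placed independently. With ⌈300/21⌉ = 14 seeds a
read with up to 13 mismatches is guaranteed at least one clean seed, far
above the ~1 error per 300 bp read implied by the simulated quality model.

## Read QC

Per mate, in order: exact-prefix adapter removal (optional); discard on any
non-ACGT base; head trim (default 6 bases — library-construction artifacts
concentrate there); truncation at the file-wide trim point; discard if the
fraction of remaining bases below Q25 exceeds 15%; discard below
`min_len_after_trim` (50). A pair survives only if both mates do, and each
discarded pair is attributed to the first failing rule (ambiguous → low
quality → orphaned), making reports deterministic and additive.

The trim point is the earliest position whose first-quartile quality falls
below `q_threshold` (25), computed independently for R1 and R2 from the
head-trimmed, non-ambiguous reads of that file; quartiles use linear
interpolation between order statistics (positions observed in fewer than 4
reads report no quartile). The head trim is a single per-run integer: the
within-run choice is a judgment call made from quality plots, which we do
not automate. The 15% rule is evaluated after trimming. A second pass with
`head_trim=0` over the output is a no-op (the recomputed trim point is
`None` by construction), which the tests assert.

## Pairwise alignment and ORF annotation

Global and local alignments use Biopython's `PairwiseAligner` (linear gap
scores; global defaults 1/−1/−2, local defaults 2/−3/−5 — ordinary
parameter choices for diverged nucleotide comparisons). Identity is
matches / alignment columns, internal gaps included in the denominator; an
end-gap-free (semi-global) mode serves cDNA-vs-genomic comparisons so 5′/3′
overhangs do not depress identity. Tests pin the aligners to exhaustive
enumeration oracles on short inputs; among co-optimal alignments the
library's deterministic first choice is reported.

`find_shared_region` runs the local aligner against the partner and its
reverse complement and returns the higher-scoring orientation (ties →
forward), with reverse-complement coordinates reported on the forward
strand. Note that a maximal-scoring local alignment may extend a few noisy
columns beyond a planted exact copy whenever the extension's matches outpay
its mismatches; reported lengths are alignment columns.

ORF annotation measures, per frame, the stop-codon-free prefix of complete
codons. Frames whose prefix terminates at an in-frame stop are preferred —
a 3′-anchored capture contig reads coding + stop + 3′ UTR, and that
structure is what the annotation is for — with the longest prefix winning
among them (no stop anywhere: longest prefix; ties → lowest frame). Stop
codons are TAA/TAG/TGA (standard code only). The coding interval excludes
the stop codon; the 3′ UTR begins immediately after it.

`upstream_extension` anchors the cDNA on a genomic contig by local
alignment and requires identity ≥ 0.9 over ≥ 50% of the cDNA; the reported
value is the genomic offset of the anchor extrapolated to the cDNA's first
base (clamped at 0).

## Repeat architecture

Unit length is the shift L ∈ [20, 200] maximizing mean self-identity
between the sequence and itself shifted by L (the overlap includes
linker/CTD positions, which contribute background ≈ Σ f² ≈ 0.06; with the
default eight units the true period still scores ≈ 0.6). Exact multiples of
the period score equally on perfect arrays, so ties break to the smallest
L; an estimate below the `background` threshold (0.5) returns none. For
DNA-level repeat detection (mucin-like repeats) the same estimator is run
with bounds [100, 400].

Segmentation fixes the unit grid phase by maximizing summed adjacent-block
identity, seeds the array at the best-matching adjacent pair (which must
itself reach `unit_accept` = 0.5), and grows outward while each next
block's identity to the running column-majority consensus stays above that
threshold. The CTD is the fixed-length suffix (default 125 residues,
truncated if the sequence is shorter): the linker/CTD boundary is
descriptive in this protein family, not algorithmic, so the fixed suffix is
a documented convention. The linker is whatever lies between the last
accepted unit and the CTD.

## Conservation, loci, and trees

Column classes: any gap → `gapped`; all residues identical → `invariant`;
all residues within one class of the declared partition → `class_conserved`;
otherwise `variable`. The default physiochemical partition is
{A,G} {S,T} {D,E} {N,Q} {K,R,H} {I,L,V,M} {F,W,Y} {C} {P}; it is printed in
every report because different partitions shift the invariant /
class-conserved split, and X belongs to no class.

Locus inference single-links sequences at pairwise identity ≥ `threshold`
(default 0.97); under the diploid assumption a cluster of any size is one
locus, so the inferred count is the number of clusters — a lower bound.
Raising the threshold can only split clusters (monotonicity is tested).

Trees: p-distances (proportion of mismatched non-gap columns) feed
scikit-bio's neighbor joining; bootstrap support for each internal edge of
the full-alignment tree is the percentage of column-resampled replicates
whose NJ tree contains the same bipartition. NJ on an exactly additive
matrix reproduces the generating topology and branch lengths (tested on 4-
and 6-taxon matrices). Trees are mid-point rooted for display only;
supports are attached as internal node labels in the Newick output. NJ with
p-distances is a deliberately lightweight summary — it is not a
maximum-likelihood analysis, and support values should be read as
congruence checks, not as publishable phylogenetics. A naive center-star
progressive aligner is bundled for convenience; curated alignments can be
imported as FASTA and are first-class inputs.

## Synthetic data: what is and is not emulated

The generators are pure functions of their spec (including the seed);
reruns are bitwise identical and every generator returns a ground-truth
record validated by the tests.

- **Locus**: one random master unit copied `n_repeat_units` (default 8)
  times with per-residue substitution probability `unit_mut_rate` (default
  0.05, always to a different residue), then a 250 aa random linker and a
  125 aa random CTD. Real glue-spidroin repeat regions are far longer than
  any assembled contig (full spidroin coding regions exceed 10 kb); eight
  units keeps the array dominant, as in real loci, at desk scale. The
  master unit's composition is threonine-enriched at 12% via exact
  largest-remainder counts (randomly arranged), so the realized repeat
  composition sits inside the 9–15% band observed across species instead of
  inheriting sampling noise. Unit length is drawn uniformly from
  [89, 99] aa when unspecified, matching the observed per-species range.
- **Gene**: codons drawn uniformly among synonymous codons (no codon-usage
  table), one stop codon, then a random 3′ UTR (default 430 bp). The coding
  interval contains no in-frame stop by construction and translates back to
  the input protein exactly.
- **Reads**: fragments ~N(500, 50) truncated at the read length; mate 1 is
  the fragment's 5′ prefix, mate 2 the reverse complement of its 3′ suffix
  (2×300 bp defaults, so mates overlap by ~100 bp mid-fragment). Quality
  decays linearly 37 → 22 with Gaussian jitter (σ = 3), and substitution
  errors are injected at the Phred-implied rate × `error_rate_scale`.
  Not emulated: indels, adapter contamination, barcode structure, GC bias,
  duplicate fragments, and intron-containing gene models — so passing tests
  demonstrate the pipeline's logic under its stated error model, not
  robustness to every real-library pathology.
- **Capture probes**: 120-mers at step probe_len/tiling (default 5× → 24 bp
  step), every internal base covered by exactly `tiling` probes.
- **CTD alignment**: 123 columns evolved on a fixed six-taxon tree shaped
  like the araneoid phylogeny (three orb-weavers vs three cob-web weavers;
  total length ≈ 1.55), with 21 columns invariant (rate 0), 23 constrained
  to one physiochemical class, and the rest free; constrained/free columns
  substitute at rate 2.5 per unit branch length (Poisson jumps to a uniform
  different allowed letter). Designed counts are a floor, not the expected
  measurement: a free column stays identical with probability ≈ e^(−3.9) ≈
  0.02, and a two-letter class column can collapse to identity, so measured
  invariant counts typically land a few columns above 21.

## Problem sizes and determinism

The test suite and the acceptance script run the chimera study over 20
replicate seeds (depth 30, 2×300 bp reads, ~3.5–4 kb transcripts), QC on
10,000 doctored pairs, 200 random short-pair alignment-oracle comparisons,
50 planted direct-repeat oracle cases, and 20-seed NJ bootstrap recovery
with 100–1000 replicates — sizes chosen to exercise every code path with
comfortable statistical margins while staying desk-scale. All randomness
flows through explicit seeds; the acceptance summary reports, among other
quantities, the minimum detected repeat length across replicates (chance
extension can only lengthen a detected pair, so the minimum reflects the
planted duplication).

## Known limitations

- The mapper is ungapped: indel-bearing reads near a junction are unmapped
  rather than clipped, slightly widening detected deserts.
- Gap-free validation means a chimera whose foreign block shares long exact
  stretches with the true transcript could evade desert detection; the
  direct-repeat search would still flag the duplication.
- Identity-threshold locus counting assumes diploidy and cannot separate
  recent paralogs above the threshold; it is a lower bound by design.
- The fixed-suffix CTD convention misplaces the linker/CTD boundary
  whenever a real CTD deviates substantially from 125 residues.
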