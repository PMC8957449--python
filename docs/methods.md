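# Methods

## The problem and the model

Structural variants (SVs) — deletions, insertions, inversions,
translocations and the three duplication classes (tandem, interspersed,
inverted) — disrupt the collinearity between a sequenced genome and its
reference. At each disruption point ("breakpoint") short-read alignments
show characteristic anomalies: reads that span the junction come back
soft-clipped (a matched block plus an unaligned tail, `70M30S`-style), and
read pairs that straddle it show insert sizes or orientations incompatible
with the fragment-length distribution.

svbreak turns this evidence into a per-site classification problem:

1. **Evidence extraction.** Filtered alignments (mapped, primary,
   non-duplicate, MAPQ ≥ 20) are distilled into per-site booleans: does an
   MS clip boundary fall here, an SM boundary, a clip from an
   orientation-anomalous read, and is the site spanned by pairs whose
   distance is below / inside / above the insert-size band
   `mean ± k·sd` (k = 3)?
2. **Ternary features.** Each candidate site becomes a 12-vector over
   {−1, 0, 1} — RMR, RMSM, RMMS, MSM, MMS, MDS, MDE, MDL, PSM, PMS, NSM,
   NMS — where 1 means the pattern is present, −1 means reads are present
   but the pattern is not, and 0 means the evidence cannot be assessed
   (no reads, or no spanning pairs for the distance features). The last
   four features look at the nearest breakpoint-candidate site strictly
   before/after the target (within 1 kb) and report its SM/MS status,
   linking the paired junctions of one SV.
3. **Seven one-vs-rest CNNs.** Feature rows are assembled in site order
   into 10000-row batches, z-scored per column (statistics fitted on
   training data only; constant columns get scale 1), and scored by seven
   binary convolutional networks — one per SV type. Each network sees a
   sliding window of 16 consecutive rows centered on the target site and
   outputs a sigmoid score in [0, 1].
4. **Largest-score calling.** A site is called as the type with the
   largest of the seven scores if that score reaches the threshold
   (default 0.5); otherwise it is a non-breakpoint.

## Network architecture

Each classifier is a fixed stack of five 5×5 stride-1 same-padded
convolutions with ReLU, 2×2 max pooling after stages 1, 2 and 4, and three
fully connected layers ending in one logit. Default widths are
(8, 16, 16, 32, 32) convolutional channels and (64, 32, 1) dense units —
compact enough for single-CPU training; widths are configurable.
Weights are Gaussian-initialized; by default the spread is He-scaled
(`sd = sqrt(2/fan_in)`), which keeps activations from shrinking through
five layers (a fixed small sd can be forced via `init_sd`).

The input has **two channels**: the feature window and a center-row
indicator plane. Pooling makes the stack partly translation-invariant, so
without a positional cue the network cannot tell "the breakpoint pattern is
at the target row" from "it is two rows away"; empirically this confusion
dominated false calls at background sites adjacent (in row order) to real
breakpoint clusters, and the indicator plane removes it.

The window default of 16 rows reflects the geometry of the data: one SV's
evidence spans 2–3 candidate rows, and wider windows of mostly unrelated
rows encouraged memorization (perfect training fit, poor held-out F1).

The whole network stack (im2col convolutions, pooling, Adam, binary
cross-entropy with logits) is implemented in numpy; all passes are BLAS
matrix products, deterministic for a fixed seed in a single process, and
backpropagation is verified against numerical gradients in the test suite.

## Training

Candidate sites are every site with clip evidence plus ~1000 random
background sites per Mb (the "noise" negatives). Sites within ±5 bp of a
simulated truth breakpoint inherit its type; everything else is labeled
non-breakpoint. The labeled set is split by cyclic cross-validation at
8 : 2 (five rotating 20% test blocks after a seeded shuffle); the deployed
bundle uses fold 0. Normalization statistics come from the training fold
only, and early stopping monitors an internal 10% validation split carved
from the training fold, so no test-fold row ever touches weights or
statistics.

For each SV type, the positives are that type's sites and the negatives
are drawn from all other sites (other SV types plus noise) at 4 negatives
per positive. Optimization is Adam (lr 1e-3), batch 64, up to 40 epochs
with patience 8. The default training corpus is 48 independently simulated
1 Mb genomes (twelve at each of 10x/20x/30x/40x), about 80,000 labeled sites —
a desk-scale stand-in for a much larger training-group design; smaller
corpora train but with visibly higher between-run variance for the
rarest class (insertions contribute one breakpoint each).

## The synthetic benchmark

The simulator builds an i.i.d. reference (GC 0.41 by default), implants
`n_per_type` = 20 SVs of each of the seven categories with sizes uniform in
[200, 2000] bp and mutual spacing ≥ 2 insert lengths, and samples
paired-end reads (100 bp, insert 350 ± 30 bp, substitution errors at
0.2%) at the configured coverage. An exact piecewise liftover maps donor
to reference coordinates; reference-collinear neighbours are merged so
only true junctions exist.

Reads are then **projected** back to the reference deterministically: a
read inside one liftover block maps contiguously; a read spanning a
junction is anchored on its longest reference-mapped flank (ties to the
left, minimum anchor 20 bp) with the remainder soft-clipped; reads inside
inverted segments flip strand; reads living entirely in novel inserted
sequence come back unmapped. Template lengths are reference-projected pair
distances. Breakpoint conventions: DEL/INV/TDUP contribute their two
segment boundaries, INS its insertion point, and TRA/IDUP/INVDUP the
source boundaries plus the distant insertion point (three each).

Mapping quality models aligner confidence: full-length alignments get
MAPQ 60; a clipped record whose matched block is shorter than 70 bp — the
canonical confident split being 70 matched + 30 clipped at 100 bp reads —
gets MAPQ 10 and falls to the default filter. This is what makes usable
split-read evidence scale with coverage: at 10x a junction side retains on
the order of 2–3 confident split reads, at 40x around ten.

What the generator does **not** emulate: repetitive sequence and true
multi-mapping, indel sequencing errors, microhomology at junctions (clip
boundaries are exact, so called positions are exact and the ±5 bp matching
tolerance is generous), base-quality structure, diploidy/heterozygosity,
and aligner-specific artifacts. Consequently passing benchmarks here show
that the method recovers breakpoints from clean, truth-consistent
split-read and pair-distance signals; they do not bound performance on
real tumor data.

## Evaluation

Calls match truth breakpoints one-to-one within ±5 bp, requiring type
agreement by default. Matching maximizes the number of matched pairs and
then minimizes total distance (solved as an assignment problem); this
coincides with nearest-first pairing except in rare chains where the
nearest pick would block a second match. Sensitivity is tp/(tp+fn) over
truth breakpoints (per type, and pooled for ALL), precision tp/(tp+fp)
over calls, F1 their harmonic mean; undefined ratios are 0. The coverage
sweep trains one bundle on independent simulations and then, per coverage
and replicate, simulates/extracts/predicts/matches, averaging metrics over
replicates. Everything is driven by one seed.

## Numerical and degenerate-input choices

- Insert-size estimation: median and 1.4826·MAD over proper-pair
  |template length| (≥ 50 pairs required), sd floored at 1 bp so the
  equal-band never collapses on noise-free data.
- Soft clips shorter than 5 bp are ignored (base-error territory).
- Pair-distance evidence attaches to the pair's outer span but is capped
  at one equal-band upper bound from each anchor; without the cap a single
  translocation pair whose mates map hundreds of kb apart would blanket
  everything in between with "distance above" evidence.
- Orientation-anomalous ("reversely mapped") means the two mates map on
  the same strand — the signature inversions and inverted duplications
  produce; for unpaired reads the read's own strand flag is used.
- Batch padding rows are zeroed after normalization and never scored.
- Argmax ties break to the lowest type index; thresholds are half-open
  (score ≥ threshold calls).

## Known limitations

Ternary presence/absence features saturate once each evidence kind has a
single supporting read, so per-type accuracy at high coverage is limited
by *typing ambiguity* rather than detection. In particular, the source-
segment edges of an interspersed duplication are feature-identical to a
tandem duplication's joint sites (same clip topology, same ternary
distance classes), which caps interspersed-duplication sensitivity well
below the other types — it is consistently the weakest category in the
benchmark — and coverage cannot resolve this aliasing. Count-valued or
distance-valued features would, but the encoding is deliberately strictly
ternary.

A second consequence: pooled F1 does not grow monotonically forever.
Between 30x and 40x the benchmark shows a small dip, because completed
evidence at type-aliased sites turns borderline *no-calls* (a false
negative only) into confident *wrong-type calls* (a false negative plus a
false positive), so precision can fall slightly faster than sensitivity
rises once detection has saturated.
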