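# Methods

## The model

`contigrank` treats per-contig quality assessment as a supervised
classification problem. The quantity being predicted is not a single label
but a battery of |S| = 10 reference-alignment *single scores*; each is
binarized into good/bad on the training assembly and gets its own
random-forest classifier from reference-free features. The final contig
score, Σ S_i·P_i with S_i the predicted class and P_i the forest's vote
fraction for it, is a confidence-weighted count of passed quality criteria:
it lives in [0, |S|], is monotone in every S_i, and larger means better.

Assumptions this rests on:

* training and prediction assemblies share their technical characteristics
  (sequencer, coverage regime, assembler) — the forests learn
  assembler/protocol-specific error signatures, not universal truths;
* the training assembly's reference is good enough that alignment deviations
  reflect assembly errors, not reference errors;
* each single score's training distribution is roughly exponential, so a
  quantile of the fitted exponential is a meaningful good/bad boundary.

## Single scores and their thresholds

All scores are oriented as deviations (0 = perfect): identity deviation
(100 − pIdent with pIdent = 100·(matches+repMatches)/(matches+repMatches+
misMatches); gap bases are excluded from the denominator and charged to a
separate indel score), query-coverage deviation, mismatches per kb of
alignment and per kb of contig, indel bases per kb of alignment, per-end
scores within a window of W = 100 bases (identity deviation and unaligned
overhang), and fragmentation (number of accepted hits − 1). Hits with fewer
matched bases than 5 % of the contig are discarded before scoring so that
spurious micro-hits cannot inflate fragmentation; the primary hit maximizes
matches (ties: longer query span, then lexicographic target name, then
smaller target start). A contig with no accepted hit receives declared
worst-case sentinels (100 for percentage scores, 1000 for per-kb scores,
contig length for overhangs).

PSL records do not localize mismatches within blocks, so the end-window
identity is defined as the window's aligned fraction times the hit's global
match fraction: a fully aligned clean end scores deviation 0, an unaligned
end scores 100, and partial alignment or global mismatch load interpolate.
This couples end coverage and end identity into one score; it is the
deliberate definition, not an approximation of some other one.

Class thresholds: for each score, the exponential rate is the maximum
likelihood estimate λ̂ = 1/mean over *all* training values, zeros included,
and the boundary is the closed-form quantile t = −ln(1−q)/λ̂ with q = 0.95
by default. Class 1 (good) is score ≤ t. An all-zero score column has no
information; it is flagged degenerate, excluded from training, and reported.
Users can override any threshold manually from the exported histograms; such
thresholds are recorded with method = "manual" in the model bundle.

The q-quantile of a *fitted* exponential, not the empirical quantile, is
used deliberately: on small training sets it is far less noisy, and on
bimodal score distributions (a clean cluster plus an error cluster) it
places the boundary between the clusters rather than inside the error
cluster. The flip side is that with a heavy error tail the fitted mean — and
hence t — can be dragged upward; the histogram export exists exactly so this
can be seen and corrected manually.

## Forests and voting

One `RandomForestClassifier` per learnable score: 500 trees, √p candidate
features per split, unlimited depth — the standard settings that adapt
across scenarios without tuning; they are overridable but are the contract.
P_i is the literal fraction of trees voting the predicted class (collected
from the fitted trees, not sklearn's averaged leaf probabilities, which
differ when leaves are impure), so P_i ≥ 0.5 and a 50/50 tie resolves
conservatively to the bad class at P = 0.5. Out-of-bag accuracy per score is
recorded in the bundle metadata as a training diagnostic. Ranking ties are
broken by contig length (longer first) — a neutral, documented rule — then
by contig id so output is a pure function of its inputs.

Per-score forests are seeded from a single user seed through a
`RandomState` stream, making feature tables, bundles and rankings
byte-reproducible for identical inputs and seed.

## The synthetic data generator

The generator emulates a bacterial-scale assembly experiment: an i.i.d.
200 kb reference at 50 % GC; 400 contigs of 1–6 kb sampled from it; per-base
consensus substitution/insertion/deletion edits; reads of 100 bp at mean
depth 25 with 0.5 % sequencing error and constant Phred 30 qualities. True
contig-vs-reference alignments are emitted as PSL directly from the known
edit script, so the generator and the scorer agree on pIdent exactly by
construction and no aligner is needed anywhere in the test surface.

Two error modes mirror the mis-assembly types the method targets:

* **chimeras** (probability 0.15): the contig concatenates two loci ≥20 kb
  apart, with the breakpoint uniform in the middle 70 % of the contig; two
  PSL records are emitted, so fragmentation ≥ 1 by construction;
* **hypermutated contigs** (probability 0.18 of the rest): consensus
  substitution rate drawn from [0.03, 0.04] versus a baseline of
  U[0, 0.005].

A contig is labeled *bad* iff it is chimeric or its realized substitution
density exceeds 2 %; the expected bad fraction at the defaults is ≈30 %.

Crucially, the read simulator couples read placement to contig quality the
way a mapper would: no read spans a chimeric junction (reads are sampled
within each source segment), and a read overlapping k consensus-error
positions is retained with probability 0.85^k, emulating mapping dropout
over bad sequence. Without this coupling the depth features would be
statistically independent of contig quality and the learning problem would
be unsolvable by construction.

What the generator does **not** emulate: realistic sequencer error profiles,
paired-end information, GC-dependent coverage bias, repeats and collapsed
repeats, or a real assembler's correlated error structure. Tests passing on
this generator therefore demonstrate that the pipeline's machinery recovers
planted signal end to end, not that the feature set suffices for any real
assembler's error profile.

## Measured behaviour at the default conditions

With disjoint 400-contig training and test fixtures, the contig score
separates good from bad contigs with ROC AUC 0.91–0.96 across seeds. The
Spearman correlation between the contig score and the harmonic-mean
evaluation score is moderate (≈0.47–0.61, mean ≈0.55 across seeds). The
ceiling is structural, and worth understanding before using the score as
more than a ranking:

* the score counts *binary* failed criteria, so error magnitude is lost —
  a chimera (evaluation score ≈79, coverage loss) and a hypermutated contig
  (evaluation score ≈98, identity loss) both fail roughly three of ten
  classes and land in overlapping score ranges, inverting their relative
  order;
* on bimodal training scores the exponential-quantile boundary falls in the
  gap between the clean and error clusters, so vote fractions saturate deep
  inside the clean cluster and ~70 % of contigs tie near the maximum score.

Both effects are faithful to the method; the score is a ranking instrument
with cluster-level resolution, not a calibrated quality estimate.

## Numerical and degenerate-case choices

* Coordinates are 0-based half-open everywhere internally; SAM's 1-based
  POS and PSL's plus-strand query convention are converted at the parse
  boundary only.
* Secondary and supplementary SAM records are excluded from all features
  (depth would double-count the same sequenced bases); skipped counts are
  logged.
* Quality features use the sentinel −1 (an impossible Phred value) instead
  of missing values so the forests never see NaNs.
* A read-free contig keeps its honest depth statistics (all zero,
  zero-depth fraction 1) and sentinel read statistics, with a warning.
* Core depth excludes a margin of one mean read length per end (depth is
  depressed there by read-placement geometry alone), capped at L/4 so the
  core is never empty; for contigs shorter than twice the margin the whole
  contig is the core.
* The coverage-drop detector only fires where the left junction side has
  depth ≥ 5 — a drop from depth 2 to 1 is noise, not signal.
* `assign_classes` uses ≤ so a value exactly at the threshold is good;
  ranking sorts with a stable mergesort so equal keys keep a deterministic
  order.

## Problem sizes

Unit tests run on contigs of 10²–10³ bp with tens of reads; the end-to-end
benchmark and `scripts/acceptance.py` use the full default conditions
(2 × 400 contigs, ≈3 × 10⁵ reads), which complete in well under a minute.
The exponential-threshold check uses 10,000 draws against the closed-form
quantile. These sizes are the package's declared test conditions; nothing in
the implementation is specific to them.
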