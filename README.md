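# contigrank

Supervised quality scoring and ranking of contigs within a de novo assembly.

De novo assemblies have no built-in ground truth: aggregate metrics such as
the N50 say nothing about which individual contigs are trustworthy.
`contigrank` takes the supervised route. From a *training* assembly of a
related organism whose reference genome is known, it learns what
reference-free contig characteristics look like for good and for bad contigs;
on a *new* assembly (no reference needed) it predicts a quality score per
contig and sorts the assembly, so downstream analysis, validation and
finishing can focus on the reliable contigs first.

## Method

**Features** (reference-free, per contig): padded/unpadded length; pileup
depth statistics from the read alignments (mean/sd/min/max, zero-depth
fraction, core depth away from the contig ends); *coverage confirmation*
(fraction of adjacent-position junctions spanned by at least one single read
block — a contiguity signal); *coverage drops* per kb (junctions where depth
falls to ≤½ of its left neighbour); read count/length/quality statistics;
contig base-quality statistics when a FASTQ is given.

**Reference scores** (training only): contigs are aligned to the reference
(BLAT PSL input) and each contig gets a vector of non-negative *deviation*
scores where 0 is perfect — identity deviation `100 − pIdent`, query-coverage
deviation, mismatch and indel rates per kb under contig- and alignment-length
normalizations, per-end window identity and unaligned overhangs, and
fragmentation (extra accepted hits).

**Classes**: each score is fitted with an exponential distribution by maximum
likelihood (rate `λ̂ = 1/mean`) and split at its q-quantile
`t = −ln(1−q)/λ̂` (default q = 0.95) into good (`score ≤ t`, class 1) and bad
(class 0). Histograms are exported so thresholds can be set manually instead.

**Model**: one random-forest classifier per score (500 trees, √p features per
split) maps features → class. At prediction time, with `S_i ∈ {0,1}` the
majority class of forest *i* and `P_i` its vote fraction, the contig score is

    score = Σ_{i=1..|S|} S_i · P_i   ∈ [0, |S|]

and contigs are ranked by it in descending order. Scores whose training
classes have no variance (typical for near-perfect training assemblies) are
excluded from the model with a warning rather than fitted to noise.

**Evaluation**: given truth alignments, each contig's evaluation score is the
harmonic mean of pIdent and query coverage (qcovhsp); a ranking is judged by
ROC/AUC over a high/low grouping of that score and by Pearson/Spearman
correlation against it.

A synthetic-data module generates complete truth-labeled inputs (reference,
contigs with substitutions/indels/chimeric mis-joins, reads as SAM, true
alignments as PSL emitted from the known edit script), so the whole pipeline
is testable without any external data.

## Worked example

Train on one simulated assembly, rank a second, disjoint one:

```sh
contigrank --seed 7 simulate --out train_fx --n-contigs 200
contigrank --seed 8 simulate --out test_fx  --n-contigs 200

contigrank features --contigs train_fx/contigs.fasta --reads train_fx/reads.sam \
                    --out train_features.tsv
contigrank score    --contigs train_fx/contigs.fasta --psl train_fx/truth.psl \
                    --out train_scores.tsv --classes train_classes.tsv
contigrank --seed 7 train --features train_features.tsv --classes train_classes.tsv \
                    --out model.bundle

contigrank features --contigs test_fx/contigs.fasta --reads test_fx/reads.sam \
                    --out test_features.tsv
contigrank predict  --model model.bundle --features test_features.tsv --out ranking.tsv
contigrank evaluate --ranking ranking.tsv --truth-psl test_fx/truth.psl \
                    --cutoff 99 --out eval.tsv
```

which prints (abridged):

```
trained 10 per-score forests (excluded: none); bundle at model.bundle
wrote ranking of 200 contigs to ranking.tsv
Pearson vs eval score: 0.1751; Spearman: 0.4387
ROC AUC (high/low grouping at 99.0): 0.8642
```

`ranking.tsv` starts with the best contigs (scores near the maximum of 10,
i.e. all ten forests vote "good" with high confidence) and ends with the
worst:

```
rank  contig_id     surankco_score
1     contig_0072   9.962
2     contig_0160   9.956
...
200   contig_0169   5.29
```

The AUC of 0.86 says the ranking separates contigs whose evaluation score
(harmonic mean of identity and coverage) is ≥99 from the rest. The rank
correlation is moderate by construction: the contig score counts *how many*
quality criteria a contig fails, not by how much, so heavily and mildly
failing contigs with the same failure count tie (see `docs/methods.md`).

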