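# Methods

## Model

A sample's host reads are summarized by two normalized coverage statistics
computed from per-chromosome mapped-read counts. With coverage
`cov(c) = mapped(c) / effective_length(c)`:

* `rx` — the arithmetic mean over autosomes `i` of
  `cov(homogametic) / cov(autosome_i)`. Under a diploid autosomal
  background, two copies of X (or Z) give rx ≈ 1 and one copy gives
  rx ≈ 0.5.
* `ry` — `Y / (X + Y)` mapped reads (`W / (Z + W)` in ZW systems); ≈ 0 for
  the homogametic karyotype and, for the heterogametic one, centered on the
  effective-length ratio `L_Y / (L_X + L_Y)`.

Classification is a two-class Bayes rule with a reject option. Each
karyotype class (homogametic / heterogametic) gets a 2-D Gaussian KDE
`f_s(rx, ry)` fitted to labeled training samples; posteriors combine the
likelihoods with priors `π_s` (0.5/0.5 by default, configurable for cohorts
with known composition). The sample is assigned to the more probable class
only if its posterior ≥ threshold `t` (default 0.80, valid range (0.5, 1]);
otherwise it is `uncertain`. Phenotype labels follow the system: XY maps
homogametic→female, ZW maps homogametic→male.

Assumptions: euploid sex chromosomes (XX/XY or ZZ/ZW; aneuploidies such as
XXY or X0 are not modeled and will be miscalled or abstained), a diploid
autosomal background, and counts produced by an upstream pipeline whose
biases are stable between training and application.

## KDE details

* Kernel: product Gaussian with independent per-dimension bandwidths; the
  joint (rx, ry) is modeled untransformed. Evaluation uses a KD-tree
  Gaussian kernel sum on bandwidth-scaled coordinates, which is exact (unit
  tests compare against an explicit double-loop kernel sum at 1e-10
  relative tolerance).
* Bandwidths: Silverman's rule per dimension on each class's training
  points, `h_i = s_i (4/((d+2)n))^(1/(d+4))` with `d = 2`, floored at 1e-4.
  The floor matters: the homogametic class's ry dimension is nearly a point
  mass at 0, and an unfloored bandwidth would make its covariance singular.
* Numerics: likelihoods are computed and combined in log space; posteriors
  come from a log-sum-exp normalization, so they sum to 1 to machine
  precision. If both class log-densities fall below log(1e-300) the query
  is outside the support of both models and the sample abstains with
  posteriors reported as 0.5/0.5. Undefined rx or ry likewise abstains —
  the conservative reading of the uncertainty class.
* Exact posterior ties resolve to `uncertain` at any threshold.
* Training pools all depths into the two class models. Samples with
  undefined rx or ry are excluded from training (count logged); a class
  left with fewer than 2 points raises a training error.
* Serialization: a versioned flat JSON file holding system, training
  points, bandwidths, prior, density floor and training seed. Floats
  round-trip exactly, so a reloaded model reproduces posteriors
  bit-for-bit; a version mismatch fails loudly. No pre-trained model file
  ships in the repository — training is deterministic given a seed and
  takes seconds, so `metasex train --seed <s>` regenerates any model
  artifact exactly, which is a stronger reproducibility guarantee than a
  checked-in binary blob.

## Metric edge policies

* Autosomes with zero mapped reads are skipped in the rx mean (their ratio
  is a 0-division, not evidence) and `n_autosomes_used` is recorded; if
  fewer than 5 autosomes (configurable) retain coverage, rx is undefined.
  This keeps rx defined at the 150-read design point, where one or two
  empty autosomes are routine.
* Zero homogametic coverage yields rx = 0.0, a defined value: a
  heterogametic individual with no X reads at tiny depth is real data.
* ry is undefined exactly when X + Y mapped reads are 0.
* Coverage uses effective lengths. Exclusion regions (e.g.
  pseudoautosomal regions, where X and Y are homologous and reads
  cross-map) are applied as BED intervals that reduce effective length;
  counts are never altered, since count filtering happens upstream.
  Intervals are merged before subtraction and recorded on the record, so
  re-applying the same BED is a no-op. By default no exclusions are
  applied; supply `--exclude-bed` (a human PAR BED ships in
  `metasex/data/`) when the upstream pipeline did not mask them.

## Synthetic data

The classifier consumes only per-chromosome totals, so the count
distribution is the sufficient statistic of a read-level simulation. A
sample of depth `N` is a single multinomial draw over non-ignored
chromosomes with weights ∝ copy_number(c, sex) × effective_length(c),
perturbed by two noise knobs:

* `per_chrom_bias_sd` (default 0.05) — log-normal multiplicative bias per
  chromosome, standing in for mappability/GC coverage bias. The default is
  a few percent, the scale of per-chromosome coverage bias in short-read
  data.
* `mismap_to_hetero_rate` (default 0.002) — for homogametic-pair
  individuals, this fraction of the homogametic sex-chromosome weight is
  reassigned to the absent heterogametic chromosome, mimicking residual
  X/Y (Z/W) homologous mismapping after MAPQ filtering. The true rate
  depends on the aligner and filters; the default is deliberately small
  and configurable, and is echoed in output headers.

Depth is exact (counts sum to `N`), matching a downsampling design.
Multinomial (with replacement) rather than hypergeometric sampling is used;
when drawing ≤1M reads from a 10M-read pool the difference is negligible.
Replicate RNG streams derive from `(seed, depth, sex, replicate)`, so any
grid cell regenerates bit-identically in isolation.

Grids: the benchmark grid is 9 depths {150, 250, 350, 450, 1,000, 5,000,
10,000, 100,000, 1,000,000} × 2 sexes × 1,000 replicates (18,000 samples);
the training grid adds {500, 2,500, 50,000} — three interpolating depths
chosen to keep the low/mid-depth region well covered — for 12 depths and
24,000 samples. Evaluation seeds are the training seed plus a fixed offset
(1,000,003), so train and test never share RNG streams.

What the simulator does **not** emulate: sequencing error, read length and
pairing, duplicate reads, and — most consequentially — the strong
mappability deficit of the repetitive Y/W chromosome in real MAPQ-filtered
alignments. With length-proportional weights a simulated male receives
Y reads in proportion to the full assembly length of Y (E[ry] ≈ 0.27 for
the bundled human spec), whereas real filtered data yields male ry nearer
0.08, i.e. real low-depth males frequently lack Y evidence entirely.
Passing the synthetic benchmark therefore demonstrates correctness of the
statistics, the KDE machinery and the decision rule under the stated count
model; it overstates how easy low-depth males are in real alignments, where
abstention rates on males will be higher. Users working with a genome
whose Y/W mappable fraction is well characterized can encode it via
`effective_length` in their genome spec.

## Evaluation conventions

Per-sex precision, recall and F1 plus overall accuracy
(correct / n_total) and uncertainty rate. Two recall conventions are
reported, because a classifier with a reject option admits both:

* `paper` mode: false negatives are the abstained true-class samples only —
  recall_c = TP_c / (TP_c + abstained_c);
* `standard` mode: false negatives also include miscalls —
  recall_c = TP_c / n_true_c.

Precision is TP_c / (TP_c + FP_c) in both; F1 is 0 when precision + recall
is 0. `insufficient_reads` results count as abstentions. Fixed-cutoff
baselines on rx (call homogametic ≥ 0.8, heterogametic ≤ 0.6) and ry
(homogametic ≤ 0.016, heterogametic ≥ 0.075) are provided for benchmark
context; the cutoffs are conventional values from coverage-based sexing
practice and are configurable.

## Problem sizes

The test suite exercises the depth-sweep at reduced replication (250
training / 200 evaluation replicates per cell) and finishes in well under a
minute; `scripts/acceptance.py` runs the full 24,000-sample training and
18,000-sample evaluation design in under a minute on one CPU. Default
minimum host reads: 100; samples below it are reported, not dropped, so
output rows always match input samples.

## Known limitations

* Count-level simulation fidelity as discussed above; the pooled male F1 on
  the synthetic benchmark is higher than what read-level pipelines report,
  because simulated males are never short of Y evidence.
* Sex-chromosome aneuploidies and chimerism are out of scope.
* The tool infers chromosomal sex only; it cannot and does not infer
  gender, and applications to human data must stay within the consent and
  approvals governing the source material.
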