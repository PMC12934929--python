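# metasex

Host sex inference from metagenomic sequencing data, using nothing but the
per-chromosome mapped-read counts that `samtools idxstats` reports.

Shotgun metagenomic samples (stool, oral, nasal, cecal, ...) always carry
some host-derived reads. When host sex metadata is missing or suspect —
field-collected wildlife samples, public datasets with stripped metadata,
suspected sample swaps — the dosage of the sex chromosomes in those reads
is enough to recover it, even when only a few hundred host reads survive
alignment and filtering. `metasex` turns an idxstats table into a
probabilistic sex call for any host with a heterogametic sex-determination
system (XY mammals, ZW birds and others).

## The statistics and the classifier

For a sample with mapped-read count `n_c` on chromosome `c` with effective
length `L_c` (coverage `cov(c) = n_c / L_c`), two normalized statistics are
computed against a genome spec that designates autosomes and the two sex
chromosomes:

```
Rx = (1/n) Σ_i  cov(X) / cov(autosome_i)        (mean over n autosomes)
Ry = Y_reads / (X_reads + Y_reads)
```

An XX (or ZZ) individual has two copies of the homogametic chromosome, so
Rx ≈ 1 and Ry ≈ 0; an XY (or ZW) individual has one copy of each, so
Rx ≈ 0.5 and Ry sits at the Y-to-X+Y length ratio. At low depth both
statistics are noisy, so instead of fixed cutoffs the classifier models the
joint distribution of (Rx, Ry) for each sex with a 2-D Gaussian kernel
density estimate trained on simulated samples spanning 150–1,000,000 host
reads. For a new sample the two class likelihoods `f_F`, `f_M` are combined
with priors (equal by default) into posteriors

```
P(sex = s | Rx, Ry) = π_s f_s(Rx, Ry) / Σ_t π_t f_t(Rx, Ry)
```

and a sex is reported only when the winning posterior reaches the decision
threshold (default 0.80); otherwise the call is `uncertain`. Samples with
fewer than 100 host reads are reported as `insufficient_reads`. Metric
names are role-based: in a ZW genome "Rx" is Z-versus-autosomes, "Ry" is
W/(Z+W), and the heterogametic karyotype is labeled female.

## Worked example

Train a model (deterministic for a given seed), simulate a few samples, and
classify them. Bundled genome specs: `human` (22+X+Y), `mouse` (19+X+Y),
`chicken` (33+Z+W); supply your own YAML for other hosts.

```console
$ metasex train --replicates 200 --seed 17 --output model.json
$ metasex simulate --depths 500,20000 --replicates 1 --seed 99 --outdir sims
$ metasex classify --idxstats sims --scaffolds scaffolds.txt --model model.json
# metasex v1.0.0
# command: classify
# sex_system: XY
# threshold: 0.8
# min_reads: 100
# model: model.json
# n_samples: 4
sample_id	total_host_reads	rx	ry	posterior	call
sim_d20000_female_r0000	20000	0.9876966904661963	0.0019723865877712033	0.9993111868541087	female
sim_d20000_male_r0000	20000	0.4587631767718196	0.26275115919629055	0.9999999876493781	male
sim_d500_female_r0000	500	0.9591609469276083	0.0	0.999056735243449	female
sim_d500_male_r0000	500	0.4292822692998003	0.21428571428571427	1.0	male
```

The two XX samples sit at Rx ≈ 0.96–0.99 with Ry ≈ 0, the two XY samples at
Rx ≈ 0.43–0.46 with Ry ≈ 0.21–0.26; all four posteriors exceed 0.999, so
all four are called. `--scaffolds` is a plain-text file listing the
reference-sequence IDs to use (the inclusion filter); `--metadata` amends a
sample table with the calls; `--threshold` trades recall for precision
(sweep it with `metasex sweep`). Real data should first be aligned,
deduplicated and MAPQ-filtered upstream — see `metasex classify --help`,
including the note on consent and ethics for human-derived data.

`metasex benchmark` reruns the depth-sweep evaluation (correct / uncertain /
miscalled fractions per depth, pooled per-sex precision/recall/F1 under
both false-negative conventions) against simple Rx- and Ry-cutoff
baselines.

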