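"""Count-level simulation of per-chromosome read counts.

The classifier consumes only per-chromosome mapped-read counts, so the
count distribution is the sufficient statistic of a read-level simulation:
a sample of N host reads is modeled as a multinomial draw over chromosomes
with probabilities proportional to copy number x effective length.  Two
noise knobs stand in for residual alignment artifacts:

* ``per_chrom_bias_sd`` — a log-normal multiplicative perturbation of each
  chromosome's weight, capturing mappability and GC-coverage bias;
* ``mismap_to_hetero_rate`` — the fraction of a homogametic-pair
  individual's sex-chromosome weight reassigned to the absent heterogametic
  chromosome (an XX sample still shows occasional Y-mapped reads because of
  residual X/Y homology surviving the upstream MAPQ filter).

Counts always sum exactly to the requested depth (the benchmark design
downsamples to exact read totals).  Every replicate draws from its own RNG
stream derived deterministically from (seed, depth, sex, replicate index),
so any grid cell can be regenerated independently and bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import GenomeSpec, Role, SexClass, sex_label
from .idxstats import IdxstatsRow, IdxstatsTable
from .metrics import SexMetrics, compute_metrics

__all__ = [
    "BENCHMARK_DEPTHS",
    "TRAINING_DEPTHS",
    "SimParams",
    "SimulatedSample",
    "chromosome_weights",
    "simulate_sample",
    "simulate_cell",
    "simulate_grid",
    "cell_rng",
    "samples_to_metrics",
]

#: The nine benchmark read-depth targets.
BENCHMARK_DEPTHS: tuple[int, ...] = (150, 250, 350, 450, 1_000, 5_000, 10_000, 100_000, 1_000_000)

#: The twelve training depths: the benchmark grid plus three interpolating
#: depths chosen to keep the low/mid-depth region well covered.
TRAINING_DEPTHS: tuple[int, ...] = tuple(
    sorted(BENCHMARK_DEPTHS + (500, 2_500, 50_000))
)


@dataclass(frozen=True)
class SimParams:
    """Study-design parameters for a simulation grid."""

    spec: GenomeSpec
    depth_targets: tuple[int, ...] = BENCHMARK_DEPTHS
    replicates_per_cell: int = 1_000
    seed: int = 0
    mismap_to_hetero_rate: float = 0.002
    per_chrom_bias_sd: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth_targets", tuple(int(d) for d in self.depth_targets))
        if any(d < 1 for d in self.depth_targets):
            raise ValueError("depth targets must be positive")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if self.mismap_to_hetero_rate < 0 or self.per_chrom_bias_sd < 0:
            raise ValueError("noise rates must be non-negative")


@dataclass(frozen=True)
class SimulatedSample:
    """One simulated idxstats table with its ground truth."""

    sample_id: str
    sex_class: SexClass
    label: str
    depth: int
    replicate: int
    table: IdxstatsTable


def chromosome_weights(spec: GenomeSpec, sex: SexClass) -> tuple[list[str], np.ndarray]:
    """Multinomial category weights: copies(c, sex) x effective_length(c).

    Ignored scaffolds receive no reads.  Before mismapping noise, the
    heterogametic chromosome has weight exactly 0 for the homogametic-pair
    sex (an XX individual has no Y to sequence).
    """
    sex = SexClass(sex)
    ids, raw = [], []
    for rec in spec.chromosomes:
        if rec.role is Role.IGNORED:
            continue
        ids.append(rec.id)
        raw.append(spec.copy_number(rec, sex) * rec.effective_length)
    weights = np.asarray(raw, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all chromosome weights are zero")
    return ids, weights / total


def cell_rng(seed: int, depth: int, sex: SexClass, replicate: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one replicate of one grid cell."""
    code = 0 if SexClass(sex) is SexClass.HOMOGAMETIC else 1
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), int(depth), code, int(replicate)))
    )


def simulate_sample(
    params: SimParams,
    sex: SexClass,
    depth: int,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> IdxstatsTable:
    """Draw one per-chromosome count table summing exactly to ``depth``."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sex = SexClass(sex)
    spec = params.spec
    ids, weights = chromosome_weights(spec, sex)
    w = weights.copy()
    if params.per_chrom_bias_sd > 0:
        bias = rng.lognormal(mean=0.0, sigma=params.per_chrom_bias_sd, size=w.size)
        w = w * np.where(weights > 0, bias, 0.0)
    if params.mismap_to_hetero_rate > 0 and sex is SexClass.HOMOGAMETIC:
        i_homo = ids.index(spec.homogametic.id)
        i_het = ids.index(spec.heterogametic.id)
        moved = params.mismap_to_hetero_rate * w[i_homo]
        w[i_homo] -= moved
        w[i_het] += moved
    w = w / w.sum()
    counts = rng.multinomial(int(depth), w)
    rows = {
        cid: IdxstatsRow(length=spec.record(cid).length, mapped=int(c), unmapped=0)
        for cid, c in zip(ids, counts)
    }
    rows["*"] = IdxstatsRow(length=0, mapped=0, unmapped=0)
    return IdxstatsTable(sample_id=sample_id, rows=rows)


def simulate_cell(
    params: SimParams, sex: SexClass, depth: int, replicates: int | None = None
) -> list[SimulatedSample]:
    """All replicates for one (depth, sex) cell, regenerable in isolation."""
    sex = SexClass(sex)
    label = sex_label(params.spec.system, sex)
    n = params.replicates_per_cell if replicates is None else replicates
    out = []
    for rep in range(n):
        rng = cell_rng(params.seed, depth, sex, rep)
        sid = f"sim_d{depth}_{label}_r{rep:04d}"
        table = simulate_sample(params, sex, depth, rng, sample_id=sid)
        out.append(
            SimulatedSample(
                sample_id=sid, sex_class=sex, label=label, depth=depth,
                replicate=rep, table=table,
            )
        )
    return out


def simulate_grid(params: SimParams) -> list[SimulatedSample]:
    """Full grid: every depth target x both sexes x all replicates."""
    out: list[SimulatedSample] = []
    for depth in params.depth_targets:
        for sex in (SexClass.HOMOGAMETIC, SexClass.HETEROGAMETIC):
            out.extend(simulate_cell(params, sex, depth))
    return out


def samples_to_metrics(
    samples: Sequence[SimulatedSample], spec: GenomeSpec
) -> list[tuple[SexMetrics, str]]:
    """Labeled (metrics, phenotype-label) pairs, ready for training or scoring."""
    return [(compute_metrics(s.table, spec), s.label) for s in samples]
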