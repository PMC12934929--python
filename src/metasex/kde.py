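"""Per-sex kernel density models and Bayesian posterior sex calls.

The classifier models the joint distribution of (rx, ry) separately for the
two karyotype classes with 2-D Gaussian kernel density estimates using
independent per-dimension bandwidths.  For a query sample the two class
likelihoods are combined with prior class probabilities (equal by default)
into posteriors; the more probable sex is reported only when its posterior
reaches the decision threshold (default 0.80), otherwise the sample is
called ``uncertain``.  Abstention is also the outcome for any degenerate
query: undefined rx or ry, or both densities below the floor (the query
lies outside the support of both models).

Bandwidths default to Silverman's rule per dimension on each class's
training points, floored at a small positive value because the homogametic
class's ry dimension is nearly a point mass at zero and would otherwise
collapse the kernel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.special import logsumexp
from sklearn.neighbors import KernelDensity

from .genome import GenomeSpec, SexClass, SexSystem, sex_label
from .idxstats import IdxstatsTable, ResultRow
from .metrics import SexMetrics, compute_metrics

__all__ = [
    "GaussianKDE2D",
    "KdeSexModel",
    "SexCall",
    "TrainingError",
    "ModelFormatError",
    "silverman_bandwidth",
    "fit_kde",
    "train_model",
    "classify",
    "classify_many",
    "call_sample",
    "sweep_threshold",
    "DEFAULT_THRESHOLD",
    "DEFAULT_BANDWIDTH_FLOOR",
    "DEFAULT_DENSITY_FLOOR",
    "MODEL_FORMAT_VERSION",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.80
DEFAULT_BANDWIDTH_FLOOR = 1e-4
DEFAULT_DENSITY_FLOOR = 1e-300
MODEL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    pass


class ModelFormatError(ValueError):
    pass


def silverman_bandwidth(
    points: np.ndarray, floor: float = DEFAULT_BANDWIDTH_FLOOR
) -> np.ndarray:
    """Per-dimension Silverman bandwidth, h_i = s_i * (4 / ((d+2) n))^(1/(d+4)).

    For d = 2 the factor reduces to n^(-1/6).  Dimensions with (near-)zero
    sample standard deviation are floored at ``floor``.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    if n < 2:
        raise ValueError("need at least 2 points for a bandwidth estimate")
    sd = points.std(axis=0, ddof=1)
    factor = (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
    return np.maximum(sd * factor, floor)


class GaussianKDE2D:
    """Product-Gaussian KDE with independent per-dimension bandwidths.

    The density at query q is (1/N) sum_j prod_i N(q_i; p_ji, h_i^2).
    Evaluation is delegated to a KD-tree kernel sum on bandwidth-scaled
    coordinates, which is exact for the Gaussian kernel at zero tolerance.
    """

    def __init__(self, points: np.ndarray, bandwidth: Sequence[float]):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if points.shape[0] < 2:
            raise ValueError("need at least 2 training points")
        if not np.all(np.isfinite(points)):
            raise ValueError("training points must be finite")
        bandwidth = np.asarray(bandwidth, dtype=float)
        if bandwidth.shape != (2,) or np.any(bandwidth <= 0):
            raise ValueError("bandwidth must be a strictly positive 2-vector")
        self.points = points
        self.bandwidth = bandwidth
        self._kd = KernelDensity(kernel="gaussian", bandwidth=1.0)
        self._kd.fit(points / bandwidth)
        self._log_h = float(np.log(bandwidth).sum())

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def logpdf(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        return self._kd.score_samples(queries / self.bandwidth) - self._log_h

    def pdf(self, queries: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(queries))


def fit_kde(
    points: np.ndarray,
    bandwidth_rule: Union[str, Sequence[float]] = "silverman",
    bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR,
) -> GaussianKDE2D:
    """Fit a :class:`GaussianKDE2D` with a named rule or explicit bandwidths."""
    points = np.asarray(points, dtype=float)
    if isinstance(bandwidth_rule, str):
        if bandwidth_rule != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
        bw = silverman_bandwidth(points, floor=bandwidth_floor)
    else:
        bw = np.asarray(bandwidth_rule, dtype=float)
    return GaussianKDE2D(points, bw)


@dataclass
class KdeSexModel:
    """Trained per-sex density models plus decision parameters.

    ``points_homogametic`` / ``points_heterogametic`` hold the (rx, ry)
    training pairs for the two karyotype classes; the phenotypic meaning of
    each class follows from ``system`` (XY: homogametic = female; ZW:
    homogametic = male).
    """

    system: SexSystem
    points_homogametic: np.ndarray
    points_heterogametic: np.ndarray
    bandwidth_homogametic: np.ndarray
    bandwidth_heterogametic: np.ndarray
    prior_homogametic: float = 0.5
    density_floor: float = DEFAULT_DENSITY_FLOOR
    seed: int | None = None
    _kdes: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.system = SexSystem(self.system)
        self.points_homogametic = np.asarray(self.points_homogametic, dtype=float)
        self.points_heterogametic = np.asarray(self.points_heterogametic, dtype=float)
        self.bandwidth_homogametic = np.asarray(self.bandwidth_homogametic, dtype=float)
        self.bandwidth_heterogametic = np.asarray(self.bandwidth_heterogametic, dtype=float)
        if not 0.0 < self.prior_homogametic < 1.0:
            raise ValueError("prior_homogametic must lie in (0, 1)")
        for pts in (self.points_homogametic, self.points_heterogametic):
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
                raise ValueError("each class needs >= 2 finite (rx, ry) training points")
            if not np.all(np.isfinite(pts)):
                raise ValueError("training points must be finite")
        for bw in (self.bandwidth_homogametic, self.bandwidth_heterogametic):
            if bw.shape != (2,) or np.any(bw <= 0):
                raise ValueError("bandwidths must be strictly positive 2-vectors")

    def kde(self, sex_class: SexClass) -> GaussianKDE2D:
        sex_class = SexClass(sex_class)
        if sex_class not in self._kdes:
            if sex_class is SexClass.HOMOGAMETIC:
                self._kdes[sex_class] = GaussianKDE2D(
                    self.points_homogametic, self.bandwidth_homogametic
                )
            else:
                self._kdes[sex_class] = GaussianKDE2D(
                    self.points_heterogametic, self.bandwidth_heterogametic
                )
        return self._kdes[sex_class]

    def log_likelihoods(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(log f_homogametic, log f_heterogametic) at the query points."""
        return (
            self.kde(SexClass.HOMOGAMETIC).logpdf(queries),
            self.kde(SexClass.HETEROGAMETIC).logpdf(queries),
        )

    def label(self, sex_class: SexClass) -> str:
        return sex_label(self.system, sex_class)

    # -- serialization -----------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Serialize to a versioned flat JSON file; floats round-trip exactly."""
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "system": self.system.value,
            "prior_homogametic": self.prior_homogametic,
            "density_floor": self.density_floor,
            "seed": self.seed,
            "bandwidth_homogametic": self.bandwidth_homogametic.tolist(),
            "bandwidth_heterogametic": self.bandwidth_heterogametic.tolist(),
            "points_homogametic": self.points_homogametic.tolist(),
            "points_heterogametic": self.points_heterogametic.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "KdeSexModel":
        with open(path) as fh:
            payload = json.load(fh)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"model file {path} has format version {version!r}; "
                f"this build reads version {MODEL_FORMAT_VERSION}"
            )
        return cls(
            system=SexSystem(payload["system"]),
            points_homogametic=np.array(payload["points_homogametic"], dtype=float),
            points_heterogametic=np.array(payload["points_heterogametic"], dtype=float),
            bandwidth_homogametic=np.array(payload["bandwidth_homogametic"], dtype=float),
            bandwidth_heterogametic=np.array(payload["bandwidth_heterogametic"], dtype=float),
            prior_homogametic=float(payload["prior_homogametic"]),
            density_floor=float(payload["density_floor"]),
            seed=payload.get("seed"),
        )


@dataclass(frozen=True)
class SexCall:
    """Posterior sex call for one sample.

    ``degenerate`` marks samples that abstain regardless of threshold
    (undefined metrics or both densities under the floor); their posteriors
    are reported as 0.5/0.5.
    """

    metrics: SexMetrics
    posterior_homogametic: float
    posterior_heterogametic: float
    call: str
    threshold: float
    degenerate: bool = False

    @property
    def max_posterior(self) -> float:
        return max(self.posterior_homogametic, self.posterior_heterogametic)


def _check_threshold(threshold: float) -> None:
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0.5, 1], got {threshold}")


def train_model(
    training_samples: Iterable[tuple[SexMetrics, str]],
    system: SexSystem,
    bandwidth_rule: Union[str, Sequence[float]] = "silverman",
    prior_homogametic: float = 0.5,
    bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR,
    density_floor: float = DEFAULT_DENSITY_FLOOR,
    seed: int | None = None,
) -> KdeSexModel:
    """Fit one KDE per sex from labeled (metrics, phenotype-label) pairs.

    All training depths are pooled into the two class models.  Samples with
    undefined rx or ry are excluded (the count is logged); a class left
    empty after filtering raises :class:`TrainingError`.
    """
    system = SexSystem(system)
    points: dict[SexClass, list[list[float]]] = {c: [] for c in SexClass}
    n_dropped = 0
    labels = {sex_label(system, c): c for c in SexClass}
    for metrics, label in training_samples:
        if label not in labels:
            raise TrainingError(f"unknown training label {label!r} for system {system.value}")
        if not metrics.defined:
            n_dropped += 1
            continue
        points[labels[label]].append([metrics.rx, metrics.ry])
    if n_dropped:
        logger.info("train_model: excluded %d samples with undefined rx/ry", n_dropped)
    for cls, pts in points.items():
        if len(pts) < 2:
            raise TrainingError(
                f"class {cls.value!r} has {len(pts)} usable training samples (need >= 2)"
            )

    def _bw(pts: np.ndarray) -> np.ndarray:
        if isinstance(bandwidth_rule, str):
            if bandwidth_rule != "silverman":
                raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
            return silverman_bandwidth(pts, floor=bandwidth_floor)
        return np.asarray(bandwidth_rule, dtype=float)

    homo = np.array(points[SexClass.HOMOGAMETIC], dtype=float)
    het = np.array(points[SexClass.HETEROGAMETIC], dtype=float)
    return KdeSexModel(
        system=system,
        points_homogametic=homo,
        points_heterogametic=het,
        bandwidth_homogametic=_bw(homo),
        bandwidth_heterogametic=_bw(het),
        prior_homogametic=prior_homogametic,
        density_floor=density_floor,
        seed=seed,
    )


def classify_many(
    metrics_list: Sequence[SexMetrics],
    model: KdeSexModel,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[SexCall]:
    """Vectorized posterior sex calls for a batch of samples."""
    _check_threshold(threshold)
    defined_idx = [i for i, m in enumerate(metrics_list) if m.defined]
    calls: list[SexCall | None] = [None] * len(metrics_list)
    for i, m in enumerate(metrics_list):
        if not m.defined:
            calls[i] = SexCall(
                metrics=m,
                posterior_homogametic=0.5,
                posterior_heterogametic=0.5,
                call="uncertain",
                threshold=threshold,
                degenerate=True,
            )
    if defined_idx:
        queries = np.array(
            [[metrics_list[i].rx, metrics_list[i].ry] for i in defined_idx], dtype=float
        )
        log_f_homo, log_f_het = model.log_likelihoods(queries)
        log_floor = np.log(model.density_floor)
        log_priors = np.log([model.prior_homogametic, 1.0 - model.prior_homogametic])
        joint = np.stack([log_f_homo + log_priors[0], log_f_het + log_priors[1]], axis=1)
        log_norm = logsumexp(joint, axis=1)
        post_homo = np.exp(joint[:, 0] - log_norm)
        label_homo = model.label(SexClass.HOMOGAMETIC)
        label_het = model.label(SexClass.HETEROGAMETIC)
        for row, i in enumerate(defined_idx):
            if max(log_f_homo[row], log_f_het[row]) < log_floor:
                calls[i] = SexCall(
                    metrics=metrics_list[i],
                    posterior_homogametic=0.5,
                    posterior_heterogametic=0.5,
                    call="uncertain",
                    threshold=threshold,
                    degenerate=True,
                )
                continue
            p_homo = float(post_homo[row])
            p_het = 1.0 - p_homo
            if p_homo >= p_het:
                winner, p_max = label_homo, p_homo
            else:
                winner, p_max = label_het, p_het
            calls[i] = SexCall(
                metrics=metrics_list[i],
                posterior_homogametic=p_homo,
                posterior_heterogametic=p_het,
                call=winner if p_max >= threshold else "uncertain",
                threshold=threshold,
            )
    return calls  # type: ignore[return-value]


def classify(
    metrics: SexMetrics, model: KdeSexModel, threshold: float = DEFAULT_THRESHOLD
) -> SexCall:
    """Posterior sex call for a single sample (see :func:`classify_many`)."""
    return classify_many([metrics], model, threshold=threshold)[0]


def call_sample(
    table: IdxstatsTable,
    spec: GenomeSpec,
    model: KdeSexModel,
    threshold: float = DEFAULT_THRESHOLD,
    min_reads: int = 100,
) -> ResultRow:
    """Full per-sample pipeline: metrics, minimum-reads filter, posterior call.

    Samples below ``min_reads`` total host reads are reported as
    ``insufficient_reads`` rather than dropped, so every input sample yields
    an output row.
    """
    m = compute_metrics(table, spec)
    if m.total_host_reads < min_reads:
        return ResultRow(
            sample_id=table.sample_id,
            total_host_reads=m.total_host_reads,
            rx=m.rx,
            ry=m.ry,
            posterior=None,
            call="insufficient_reads",
        )
    call = classify(m, model, threshold=threshold)
    return ResultRow(
        sample_id=table.sample_id,
        total_host_reads=m.total_host_reads,
        rx=m.rx,
        ry=m.ry,
        posterior=call.max_posterior,
        call=call.call,
    )


def sweep_threshold(
    calls: Sequence[SexCall],
    truth: Sequence[str],
    model: KdeSexModel,
    thresholds: Sequence[float] | None = None,
    mode: str = "paper",
):
    """Per-threshold classification metrics over a labeled call set.

    Re-derives each sample's call at every threshold from its stored
    posteriors and scores it; the abstention count is non-decreasing in the
    threshold.  Returns a DataFrame with one row per threshold.
    """
    import pandas as pd

    from .evaluate import score

    if thresholds is None:
        thresholds = np.round(np.arange(0.50, 1.00, 0.01), 2)
    label_homo = model.label(SexClass.HOMOGAMETIC)
    label_het = model.label(SexClass.HETEROGAMETIC)
    rows = []
    for t in thresholds:
        if not 0.5 <= t <= 1.0:
            raise ValueError(f"sweep threshold {t} outside [0.5, 1]")
        labels = []
        for c in calls:
            if c.degenerate or c.posterior_homogametic == c.posterior_heterogametic:
                labels.append("uncertain")
                continue
            if c.posterior_homogametic > c.posterior_heterogametic:
                winner, p = label_homo, c.posterior_homogametic
            else:
                winner, p = label_het, c.posterior_heterogametic
            labels.append(winner if p >= t else "uncertain")
        report = score(labels, truth, mode=mode)
        row = {"threshold": float(t), "accuracy": report.accuracy,
               "uncertainty_rate": report.uncertainty_rate,
               "n_uncertain": report.counts.n_uncertain}
        for cls in ("female", "male"):
            row[f"precision_{cls}"] = report.precision[cls]
            row[f"recall_{cls}"] = report.recall[cls]
            row[f"f1_{cls}"] = report.f1[cls]
        rows.append(row)
    return pd.DataFrame(rows)
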