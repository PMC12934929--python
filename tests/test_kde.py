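"""KDE density oracle checks, posterior arithmetic and classifier invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasex.genome import SexClass, SexSystem, sex_label
from metasex.kde import (
    GaussianKDE2D,
    KdeSexModel,
    TrainingError,
    ModelFormatError,
    classify,
    classify_many,
    fit_kde,
    silverman_bandwidth,
    sweep_threshold,
    train_model,
)
from metasex.metrics import SexMetrics


def brute_force_density(points, bandwidth, queries):
    """Explicit double-loop product-Gaussian kernel sum."""
    points = np.asarray(points, float)
    h1, h2 = bandwidth
    out = []
    for q in np.atleast_2d(queries):
        total = 0.0
        for p in points:
            z1 = (q[0] - p[0]) / h1
            z2 = (q[1] - p[1]) / h2
            total += math.exp(-0.5 * (z1 * z1 + z2 * z2)) / (2 * math.pi * h1 * h2)
        out.append(total / len(points))
    return np.array(out)


def _metrics(rx, ry, reads=1000):
    return SexMetrics(rx=rx, ry=ry, total_host_reads=reads, n_autosomes_used=22)


def _point_mass_model(homo_at, het_at, bw=(0.5, 0.5), prior=0.5):
    """Two classes, each a pair of coincident points: closed-form densities."""
    return KdeSexModel(
        system=SexSystem.XY,
        points_homogametic=np.array([homo_at, homo_at], float),
        points_heterogametic=np.array([het_at, het_at], float),
        bandwidth_homogametic=np.array(bw),
        bandwidth_heterogametic=np.array(bw),
        prior_homogametic=prior,
    )


class TestGaussianKDE:
    def test_matches_brute_force_kernel_sum(self, rng):
        points = rng.normal(size=(50, 2)) * [0.3, 0.05] + [0.7, 0.1]
        bw = np.array([0.07, 0.011])
        kde = GaussianKDE2D(points, bw)
        queries = rng.normal(size=(20, 2)) * [0.5, 0.2] + [0.7, 0.1]
        expected = brute_force_density(points, bw, queries)
        np.testing.assert_allclose(kde.pdf(queries), expected, rtol=1e-10)

    def test_density_at_repeated_point(self):
        h1, h2 = 0.3, 0.05
        kde = GaussianKDE2D(np.tile([[1.0, 0.2]], (7, 1)), [h1, h2])
        assert kde.pdf([[1.0, 0.2]])[0] == pytest.approx(1 / (2 * math.pi * h1 * h2), rel=1e-12)

    def test_unimodal_cluster_peaks_near_mean(self, rng):
        points = rng.normal(size=(200, 2))
        kde = fit_kde(points)
        center = points.mean(axis=0)
        far = center + 10 * kde.bandwidth * np.array([50, 50])
        assert kde.pdf([center])[0] >= kde.pdf([far])[0]

    def test_silverman_two_dim_factor_and_floor(self, rng):
        pts = rng.normal(size=(1000, 2))
        bw = silverman_bandwidth(pts)
        expected = pts.std(axis=0, ddof=1) * (4 / (4 * 1000)) ** (1 / 6)
        np.testing.assert_allclose(bw, expected, rtol=1e-12)
        degenerate = np.column_stack([rng.normal(size=100), np.zeros(100)])
        bw = silverman_bandwidth(degenerate, floor=1e-4)
        assert bw[1] == 1e-4  # degenerate dimension floored, never a crash
        fit_kde(degenerate)  # and fitting succeeds


class TestTraining:
    def test_class_separation_at_canonical_points(self, rng):
        samples = []
        for _ in range(200):
            samples.append((_metrics(rng.normal(1.0, 0.05), abs(rng.normal(0, 0.004))), "female"))
            samples.append((_metrics(rng.normal(0.5, 0.05), rng.normal(0.25, 0.03)), "male"))
        model = train_model(samples, SexSystem.XY)
        log_f, log_m = model.log_likelihoods(np.array([[1.0, 0.0]]))
        assert log_f[0] > log_m[0]

    def test_single_class_training_fails(self):
        samples = [(_metrics(1.0, 0.0), "female")] * 10
        with pytest.raises(TrainingError):
            train_model(samples, SexSystem.XY)

    def test_undefined_metrics_excluded_from_training(self, rng):
        samples = [(_metrics(None, None), "female")] * 5
        samples += [(_metrics(1.0 + 0.01 * i, 0.001 * i), "female") for i in range(10)]
        samples += [(_metrics(0.5 + 0.01 * i, 0.2 + 0.001 * i), "male") for i in range(10)]
        model = train_model(samples, SexSystem.XY)
        assert model.points_homogametic.shape == (10, 2)

    def test_serialization_round_trip_preserves_posteriors(self, tmp_path, small_model, rng):
        path = tmp_path / "model.json"
        small_model.save(path)
        back = KdeSexModel.load(path)
        queries = np.column_stack([rng.uniform(0.3, 1.3, 100), rng.uniform(0, 0.4, 100)])
        metrics = [_metrics(rx, ry) for rx, ry in queries]
        calls_a = classify_many(metrics, small_model)
        calls_b = classify_many(metrics, back)
        for a, b in zip(calls_a, calls_b):
            assert a.posterior_homogametic == b.posterior_homogametic
            assert a.call == b.call

    def test_version_mismatch_fails_loudly(self, tmp_path, small_model):
        path = tmp_path / "model.json"
        small_model.save(path)
        import json

        payload = json.loads(path.read_text())
        payload["format_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError):
            KdeSexModel.load(path)


class TestClassify:
    def test_posterior_arithmetic_against_closed_form(self):
        """Posterior equals pi_f f_F / (pi_f f_F + pi_m f_M) for known Gaussians."""
        model = _point_mass_model([1.0, 0.0], [0.5, 0.0], bw=(0.5, 0.5))
        q = [0.8, 0.0]
        f_homo = brute_force_density(model.points_homogametic, (0.5, 0.5), [q])[0]
        f_het = brute_force_density(model.points_heterogametic, (0.5, 0.5), [q])[0]
        expected = f_homo / (f_homo + f_het)
        call = classify(_metrics(*q), model, threshold=0.8)
        assert call.posterior_homogametic == pytest.approx(expected, rel=1e-10)

    def test_posterior_below_threshold_abstains(self):
        # symmetric point-mass classes: a query nearer the homogametic class
        # by 0.1 bandwidths gives a posterior between 0.5 and 0.8
        model = _point_mass_model([1.0, 0.0], [0.5, 0.0], bw=(0.5, 0.5))
        call = classify(_metrics(0.8, 0.0), model, threshold=0.8)
        assert 0.5 < call.posterior_homogametic < 0.8
        assert call.call == "uncertain"
        confident = classify(_metrics(1.6, 0.0), model, threshold=0.8)
        assert confident.posterior_homogametic > 0.8
        assert confident.call == "female"

    def test_equal_densities_abstain_at_any_threshold(self):
        model = _point_mass_model([1.0, 0.0], [0.5, 0.0])
        for t in (0.51, 0.8, 0.99):
            call = classify(_metrics(0.75, 0.0), model, threshold=t)
            assert call.posterior_homogametic == pytest.approx(0.5, abs=1e-12)
            assert call.call == "uncertain"

    def test_undefined_metrics_yield_uncertain_half_half(self, small_model):
        call = classify(_metrics(None, None), small_model)
        assert call.call == "uncertain"
        assert call.degenerate
        assert call.posterior_homogametic == 0.5

    def test_out_of_support_query_hits_density_floor(self, small_model):
        call = classify(_metrics(1e6, 1.0), small_model)
        assert call.call == "uncertain"
        assert call.degenerate

    def test_threshold_validation(self, small_model):
        for bad in (0.5, 0.2, 1.5):
            with pytest.raises(ValueError):
                classify(_metrics(1.0, 0.0), small_model, threshold=bad)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(rx=st.floats(0.0, 2.0), ry=st.floats(0.0, 0.5))
    def test_posteriors_sum_to_one(self, rx, ry):
        model = _point_mass_model([1.0, 0.0], [0.5, 0.25], bw=(0.3, 0.1))
        call = classify(_metrics(rx, ry), model)
        assert call.posterior_homogametic + call.posterior_heterogametic == pytest.approx(1.0)

    def test_prior_limit_forces_homogametic_calls(self, rng):
        queries = np.column_stack([rng.uniform(0.3, 1.3, 50), rng.uniform(0, 0.4, 50)])
        model = _point_mass_model([1.0, 0.0], [0.5, 0.25], bw=(0.3, 0.1), prior=0.999999)
        label_homo = sex_label(model.system, SexClass.HOMOGAMETIC)
        for rx, ry in queries:
            call = classify(_metrics(rx, ry), model, threshold=0.8)
            if not call.degenerate:
                assert call.call == label_homo
        # symmetric limit
        model_het = _point_mass_model([1.0, 0.0], [0.5, 0.25], bw=(0.3, 0.1), prior=1e-6)
        label_het = sex_label(model_het.system, SexClass.HETEROGAMETIC)
        for rx, ry in queries:
            call = classify(_metrics(rx, ry), model_het, threshold=0.8)
            if not call.degenerate:
                assert call.call == label_het

    def test_threshold_monotonicity(self, small_model, rng):
        """Raising the threshold never turns an abstention into a sex call."""
        queries = np.column_stack([rng.uniform(0.3, 1.3, 200), rng.uniform(0, 0.35, 200)])
        metrics = [_metrics(rx, ry) for rx, ry in queries]
        prev_uncertain = None
        for t in (0.51, 0.6, 0.7, 0.8, 0.9, 0.99):
            calls = classify_many(metrics, small_model, threshold=t)
            uncertain = {i for i, c in enumerate(calls) if c.call == "uncertain"}
            if prev_uncertain is not None:
                assert prev_uncertain <= uncertain
            prev_uncertain = uncertain

    def test_label_swap_symmetry(self, rng):
        """Retraining with sex labels swapped swaps the posteriors exactly."""
        samples = []
        for _ in range(100):
            samples.append((_metrics(rng.normal(1.0, 0.1), abs(rng.normal(0, 0.01))), "female"))
            samples.append((_metrics(rng.normal(0.5, 0.1), rng.normal(0.25, 0.05)), "male"))
        swapped = [(m, "male" if lab == "female" else "female") for m, lab in samples]
        model = train_model(samples, SexSystem.XY)
        model_swapped = train_model(swapped, SexSystem.XY)
        queries = [_metrics(rng.uniform(0.3, 1.3), rng.uniform(0, 0.4)) for _ in range(50)]
        for a, b in zip(classify_many(queries, model), classify_many(queries, model_swapped)):
            assert a.posterior_homogametic == pytest.approx(b.posterior_heterogametic, rel=1e-12)


class TestSweep:
    def _calls_and_truth(self, small_model, rng, n=300):
        truth, metrics = [], []
        for _ in range(n // 2):
            metrics.append(_metrics(rng.normal(1.0, 0.15), abs(rng.normal(0, 0.02))))
            truth.append("female")
            metrics.append(_metrics(rng.normal(0.5, 0.15), abs(rng.normal(0.25, 0.08))))
            truth.append("male")
        return classify_many(metrics, small_model), truth

    def test_abstentions_non_decreasing_in_threshold(self, small_model, rng):
        calls, truth = self._calls_and_truth(small_model, rng)
        table = sweep_threshold(calls, truth, small_model)
        n_unc = table["n_uncertain"].to_numpy()
        assert (np.diff(n_unc) >= 0).all()
        assert table["threshold"].iloc[0] == 0.50
        assert table["threshold"].iloc[-1] == 0.99

    def test_rows_match_independent_reclassification(self, small_model, rng):
        """Each sweep row equals scoring classify() re-run at that threshold."""
        from metasex.evaluate import score

        calls, truth = self._calls_and_truth(small_model, rng)
        metrics = [c.metrics for c in calls]
        table = sweep_threshold(calls, truth, small_model, thresholds=(0.55, 0.8, 0.95))
        for _, row in table.iterrows():
            re_calls = classify_many(metrics, small_model, threshold=row["threshold"])
            rep = score(re_calls, truth, mode="paper")
            assert row["accuracy"] == rep.accuracy
            assert row["recall_male"] == rep.recall["male"]
            assert row["precision_female"] == rep.precision["female"]

    def test_threshold_half_only_abstains_on_degenerates(self, small_model, rng):
        calls, truth = self._calls_and_truth(small_model, rng)
        table = sweep_threshold(calls, truth, small_model, thresholds=(0.5,))
        n_degenerate = sum(
            c.degenerate or c.posterior_homogametic == c.posterior_heterogametic
            for c in calls
        )
        assert table["n_uncertain"].iloc[0] == n_degenerate
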