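import numpy as np
import pytest
from scipy import stats as sstats

from mammoband.evaluation import (
    BUILTIN_METRICS,
    FIRST_ORDER_NAMES,
    FeatureTable,
    MetricPlugin,
    anova_oneway,
    build_feature_table,
    compute_gmsd,
    compute_ssim,
    feature_drift_report,
    first_order_features,
    metric_report,
    strip_experiment,
    tukey_hsd,
)
from mammoband.phantom import PhantomSpec, generate_phantom_with_truth


def noisy_pair(seed=0, shape=(96, 96), sigma=12.0):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 256, shape).astype(np.uint8)
    b = np.clip(a + rng.normal(0, sigma, shape), 0, 255).astype(np.uint8)
    return a, b


class TestSSIM:
    def test_identity_and_constant(self, phantom):
        assert compute_ssim(phantom, phantom) == pytest.approx(1.0)
        c = np.full((64, 64), 100, np.uint8)
        assert compute_ssim(c, c) == pytest.approx(1.0)

    def test_symmetry(self):
        a, b = noisy_pair(3)
        assert compute_ssim(a, b) == pytest.approx(compute_ssim(b, a), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_reference(self, seed):
        from skimage.metrics import structural_similarity

        a, b = noisy_pair(seed)
        expected = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=255,
        )
        assert compute_ssim(a, b) == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compute_ssim(np.zeros((4, 4), np.uint8), np.zeros((4, 5), np.uint8))


def _gmsd_oracle(ref, test):
    """Independent re-derivation: explicit padding/slicing arithmetic."""
    c = 170.0

    def down(a):
        a = a.astype(float)
        p = np.pad(a, ((1, 0), (1, 0)), mode="edge")
        h, w = a.shape
        pooled = (p[:-1, :-1] + p[:-1, 1:] + p[1:, :-1] + p[1:, 1:]) / 4.0
        return pooled[::2, ::2]

    def grad(a):
        p = np.pad(a, 1, mode="edge")
        h, w = a.shape
        gx = sum(p[i : i + h, 0:w] - p[i : i + h, 2 : 2 + w] for i in range(3)) / 3.0
        gy = sum(p[0:h, j : j + w] - p[2 : 2 + h, j : j + w] for j in range(3)) / 3.0
        return np.sqrt(gx * gx + gy * gy)

    r, t = down(ref), down(test)
    gr, gt = grad(r), grad(t)
    gms = (2 * gr * gt + c) / (gr * gr + gt * gt + c)
    return float(np.std(gms))


class TestGMSD:
    def test_identity_is_zero(self, phantom):
        assert compute_gmsd(phantom, phantom) == pytest.approx(0.0, abs=1e-12)

    def test_gradient_free_pair_is_zero(self):
        a = np.full((32, 32), 40, np.uint8)
        b = np.full((32, 32), 200, np.uint8)
        assert compute_gmsd(a, b) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_rederivation(self, seed):
        a, b = noisy_pair(seed, shape=(80, 90))
        assert compute_gmsd(a, b) == pytest.approx(_gmsd_oracle(a, b), abs=1e-6)

    def test_positive_on_distorted_pair(self):
        a, b = noisy_pair(5)
        assert compute_gmsd(a, b) > 0


class TestMetricReport:
    def test_reference_scores_identity_values(self, phantom):
        report = metric_report(phantom, {"original": phantom})
        for plugin in BUILTIN_METRICS:
            assert report.value(plugin.name, "original") == pytest.approx(
                plugin.identity, abs=1e-9
            )

    def test_empty_candidates(self, phantom):
        report = metric_report(phantom, {})
        assert all(row["values"] == {} for row in report.rows.values())

    def test_failing_plugin_marked_unavailable(self, phantom):
        def boom(ref, test):
            raise RuntimeError("no weights")

        plugins = list(BUILTIN_METRICS) + [
            MetricPlugin("BRISQUE", "lower-better", boom, identity=0.0)
        ]
        report = metric_report(phantom, {"x": phantom}, plugins)
        assert report.rows["BRISQUE"]["available"] is False
        assert report.rows["SSIM"]["available"] is True


class TestStripExperiment:
    def test_zero_width_gives_identity_scores(self, phantom):
        report = strip_experiment(phantom, col=100, width=0)
        for plugin in BUILTIN_METRICS:
            for method in ("background", "interpolation", "overlay"):
                assert report.value(plugin.name, method) == pytest.approx(
                    plugin.identity, abs=1e-9
                )

    def test_deterministic(self, phantom):
        a = strip_experiment(phantom, col=150, width=5)
        b = strip_experiment(phantom, col=150, width=5)
        for name in a.rows:
            assert a.rows[name]["values"] == b.rows[name]["values"]

    def test_all_methods_close_to_reference(self, phantom):
        report = strip_experiment(phantom, col=150, width=5)
        for method in ("background", "interpolation", "overlay"):
            assert report.value("SSIM", method) > 0.99
            assert report.value("GMSD", method) < 0.05

    def test_strip_outside_image_rejected(self, phantom):
        with pytest.raises(ValueError):
            strip_experiment(phantom, col=510, width=5)


class TestFirstOrderFeatures:
    def test_constant_region(self):
        img = np.full((10, 10), 100, np.uint8)
        f = first_order_features(img, np.ones(img.shape, bool))
        assert f["Mean"] == f["Median"] == f["Minimum"] == f["Maximum"] == 100
        assert f["Range"] == 0 and f["Variance"] == 0
        assert f["Uniformity"] == pytest.approx(1.0)
        assert f["Entropy"] == pytest.approx(0.0)
        assert f["Skewness"] == 0 and f["Kurtosis"] == 0

    def test_two_point_mass(self):
        img = np.zeros((2, 10), np.uint8)
        img[1] = 200
        f = first_order_features(img, np.ones(img.shape, bool))
        assert f["Mean"] == pytest.approx(100.0)
        assert f["Range"] == 200.0
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(200.0**2 / 2))

    def test_against_bruteforce_definitions(self, phantom_and_truth):
        img, truth = phantom_and_truth
        f = first_order_features(img, truth.breast_mask)
        x = img[truth.breast_mask].astype(float)
        n = x.size
        assert f["Energy"] == pytest.approx((x**2).sum())
        assert f["Mean"] == pytest.approx(x.mean())
        assert f["Median"] == pytest.approx(np.median(x))
        assert f["Minimum"] == x.min() and f["Maximum"] == x.max()
        assert f["10Percentile"] == pytest.approx(np.percentile(x, 10))
        assert f["90Percentile"] == pytest.approx(np.percentile(x, 90))
        assert f["InterquartileRange"] == pytest.approx(
            np.percentile(x, 75) - np.percentile(x, 25)
        )
        assert f["Range"] == pytest.approx(x.max() - x.min())
        assert f["MeanAbsoluteDeviation"] == pytest.approx(np.abs(x - x.mean()).mean())
        sel = (x >= np.percentile(x, 10)) & (x <= np.percentile(x, 90))
        assert f["RobustMeanAbsoluteDeviation"] == pytest.approx(
            np.abs(x[sel] - x[sel].mean()).mean()
        )
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt((x**2).mean()))
        assert f["Variance"] == pytest.approx(x.var())
        assert f["Skewness"] == pytest.approx(sstats.skew(x, bias=True))
        assert f["Kurtosis"] == pytest.approx(sstats.kurtosis(x, fisher=False, bias=True))
        # discretized features from the binned histogram
        counts = np.bincount(x.astype(int) // 25)
        p = counts[counts > 0] / n
        assert f["Entropy"] == pytest.approx(-(p * np.log2(p)).sum())
        assert f["Uniformity"] == pytest.approx((p**2).sum())
        assert set(f) == set(FIRST_ORDER_NAMES)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            first_order_features(np.zeros((4, 4), np.uint8), np.zeros((4, 4), bool))


class TestAnova:
    def test_identical_groups(self):
        res = anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.F == 0.0 and res.p == 1.0

    def test_separated_constant_groups(self):
        res = anova_oneway({"a": [0, 0, 0], "b": [1, 1, 1]})
        assert res.p == 0.0 and np.isinf(res.F)

    def test_all_constant(self):
        res = anova_oneway({"a": [5, 5], "b": [5, 5]})
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_scipy_on_random_groups(self):
        rng = np.random.default_rng(0)
        groups = {k: list(rng.normal(i * 0.3, 1, 12)) for i, k in enumerate("abcd")}
        res = anova_oneway(groups)
        F, p = sstats.f_oneway(*groups.values())
        assert res.F == pytest.approx(F) and res.p == pytest.approx(p)

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1, 2]})
        with pytest.raises(ValueError):
            anova_oneway({"a": [1, 2], "b": [1]})


class TestTukey:
    def test_equal_means_give_zero_q(self):
        res = tukey_hsd({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        q, p = res.pair("a", "b")
        assert q == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_two_group_case(self):
        # groups {0, 2} and {4, 6}: means 1 and 5, MSW = (2+2)/2 = 2,
        # Q = 4 / sqrt(2/2) = 4, dof = N - k = 2
        res = tukey_hsd({"a": [0.0, 2.0], "b": [4.0, 6.0]})
        q, p = res.pair("a", "b")
        assert q == pytest.approx(4.0)
        assert p == pytest.approx(float(sstats.studentized_range.sf(4.0, 2, 2)))

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
        res = tukey_hsd(groups)
        ref = sstats.tukey_hsd(*groups.values())
        labels = list(groups)
        for i in range(3):
            for j in range(i + 1, 3):
                _, p = res.pair(labels[i], labels[j])
                assert p == pytest.approx(ref.pvalue[i, j], abs=1e-9)

    def test_location_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i, 1, 6) for i, k in enumerate("abc")}
        base = tukey_hsd(groups)
        shifted = tukey_hsd({k: v + 100 for k, v in groups.items()})
        scaled = tukey_hsd({k: v * 3 for k, v in groups.items()})
        for pair in base.q:
            assert shifted.q[pair] == pytest.approx(base.q[pair], abs=1e-9)
            # Q is scale-invariant (numerator and sqrt(MSW) both scale by s)
            assert scaled.q[pair] == pytest.approx(base.q[pair], abs=1e-9)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1, 2, 3], "b": [1, 2]})

    def test_flags_imply_anova_significance(self):
        """Tukey-flagged pairs virtually always come with a significant
        ANOVA on the same data."""
        rng = np.random.default_rng(3)
        consistent = total = 0
        for _ in range(150):
            groups = {k: list(rng.normal(0, 1, 5)) for k in "abcd"}
            tk = tukey_hsd(groups)
            if tk.significant:
                total += 1
                if anova_oneway(groups).p < 0.05:
                    consistent += 1
        if total:
            assert consistent / total >= 0.8
        # and on clearly separated data both always fire
        groups = {"a": [0, 0.1, -0.1], "b": [5, 5.1, 4.9], "c": [0.05, -0.05, 0.0]}
        assert tukey_hsd(groups).significant
        assert anova_oneway(groups).p < 0.05


class TestDriftReport:
    @staticmethod
    def _phantom_group(seeds, shift=0):
        imgs, masks = [], []
        for s in seeds:
            img, truth = generate_phantom_with_truth(
                PhantomSpec(height=128, width=128, seed=s, n_fibers=8, n_streaks=2)
            )
            arr = img.astype(np.int64)
            arr[truth.breast_mask] = np.clip(arr[truth.breast_mask] + shift, 0, 255)
            imgs.append(arr.astype(np.uint8))
            masks.append(truth.breast_mask)
        return imgs, masks

    def test_identical_groups_zero_drift(self):
        imgs, masks = self._phantom_group(range(4))
        table = build_feature_table(
            {"orig": imgs, "copy": imgs}, {"orig": masks, "copy": masks}
        )
        report = feature_drift_report(table, original="orig")
        assert report.percent_drifted["first-order"]["copy"] == 0.0

    def test_shift_flags_location_sensitive_features_only(self):
        seeds = range(6)
        imgs, masks = self._phantom_group(seeds)
        shifted, _ = self._phantom_group(seeds, shift=50)
        table = build_feature_table(
            {"orig": imgs, "shift": shifted}, {"orig": masks, "shift": masks}
        )
        report = feature_drift_report(table, original="orig")
        location_sensitive = {
            "Energy", "TotalEnergy", "Minimum", "10Percentile", "90Percentile",
            "Maximum", "Mean", "Median", "RootMeanSquared",
        }
        flagged = {f for f, flags in report.tukey_flag.items() if flags["shift"]}
        assert flagged == location_sensitive
        assert report.percent_drifted["first-order"]["shift"] == pytest.approx(50.0)

    def test_unbalanced_table_rejected(self):
        with pytest.raises(ValueError):
            FeatureTable(groups=["a", "b"],
                         features={n: {"a": [1.0, 2.0], "b": [1.0]}
                                   for n in FIRST_ORDER_NAMES})
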