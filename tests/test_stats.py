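"""Beta accuracy/precision machinery, multi-class threshold search,
diagnostic metrics and group comparison."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize as sciopt, stats as scistats

from hisims import (
    BeatClass, beta_mode, beta_percentiles, bootstrap_ci, compare_groups,
    diagnostic_metrics, fit_beta_mle, optimize_thresholds,
    summarize_beta_fit,
)
from hisims.classification import ThresholdSet


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _beta_pdf(x, a, b):
    logp = ((a - 1) * math.log(x) + (b - 1) * math.log1p(-x)
            - (math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)))
    return math.exp(logp)


def _percentile_oracle(a, b, p, tol=1e-12):
    """Invert the quadrature CDF of the beta density by bisection."""
    def cdf(x):
        val, _ = integrate.quad(_beta_pdf, 0.0, x, args=(a, b), limit=200)
        return val
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _mode_oracle(a, b):
    res = sciopt.minimize_scalar(lambda x: -_beta_pdf(x, a, b),
                                 bounds=(1e-9, 1 - 1e-9), method="bounded",
                                 options={"xatol": 1e-12})
    return float(res.x)


def _youden_J(scores, labels, c_low, c_high):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    rvp = scores[labels == "RVP"]
    ns = scores[labels == "NS_HBP"]
    s = scores[labels == "S_HBP"]
    return (np.mean(rvp < c_low) + np.mean((ns >= c_low) & (ns < c_high))
            + np.mean(s >= c_high))


def _youden_oracle_max(scores, labels):
    """Exhaustive search over all candidate midpoint pairs."""
    uniq = np.unique(scores)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    best = -np.inf
    for i in range(len(mids)):
        for j in range(i + 1, len(mids)):
            best = max(best, _youden_J(scores, labels, mids[i], mids[j]))
    return best


# ---------------------------------------------------------------------------
# beta machinery
# ---------------------------------------------------------------------------

class TestBetaMode:
    @pytest.mark.parametrize("a,b,expected", [
        (2.0, 2.0, 0.5),
        (5.0, 2.0, 0.8),
        (0.5, 2.0, 0.0),   # boundary mode
        (2.0, 0.5, 1.0),
        (1.0, 1.0, 0.5),   # flat: conventional value
    ])
    def test_known_modes(self, a, b, expected):
        assert beta_mode(a, b) == pytest.approx(expected)

    def test_interior_mode_matches_density_maximum(self):
        for a, b in [(3.0, 5.0), (20.5, 2.2), (8.0, 8.0)]:
            assert beta_mode(a, b) == pytest.approx(_mode_oracle(a, b),
                                                    abs=1e-8)

    def test_invalid_shapes(self):
        with pytest.raises(ValueError):
            beta_mode(0.0, 1.0)


class TestBetaPercentiles:
    def test_uniform_is_identity(self):
        lo, hi = beta_percentiles(1.0, 1.0)
        assert lo == pytest.approx(0.0225)
        assert hi == pytest.approx(0.975)

    def test_matches_quadrature_oracle(self):
        for a, b, p in [(3.0, 5.0, 0.5), (3.0, 5.0, 0.0225),
                        (12.0, 2.0, 0.975)]:
            got = beta_percentiles(a, b, [p])[0]
            assert got == pytest.approx(_percentile_oracle(a, b, p),
                                        abs=1e-8)

    def test_invalid_probs(self):
        with pytest.raises(ValueError):
            beta_percentiles(2.0, 2.0, [0.0, 0.5])


class TestFitBetaMle:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        fit = fit_beta_mle(rng.beta(2.0, 2.0, size=10_000))
        assert 1.85 <= fit.alpha <= 2.15
        assert 1.85 <= fit.beta <= 2.15
        assert fit.converged

    def test_recovery_within_ten_percent_across_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fit = fit_beta_mle(rng.beta(20.0, 2.5, size=10_000))
            assert abs(fit.alpha - 20.0) / 20.0 < 0.10
            assert abs(fit.beta - 2.5) / 2.5 < 0.10

    def test_agrees_with_reference_mle(self):
        # independent route: scipy's own constrained beta MLE
        rng = np.random.default_rng(7)
        x = rng.beta(6.0, 3.0, size=5000)
        fit = fit_beta_mle(x)
        a_ref, b_ref, _, _ = scistats.beta.fit(np.clip(x, 1e-4, 1 - 1e-4),
                                               floc=0, fscale=1)
        assert fit.alpha == pytest.approx(a_ref, rel=1e-3)
        assert fit.beta == pytest.approx(b_ref, rel=1e-3)

    def test_boundary_values_are_clamped(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.beta(8, 2, size=50), [1.0, 1.0]])
        fit = fit_beta_mle(x)
        assert fit.converged and fit.alpha > 0

    def test_small_and_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_mle([0.5] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            fit_beta_mle([0.5] * 50)


class TestBootstrap:
    def _fit(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return summarize_beta_fit(fit_beta_mle(rng.beta(20, 2, size=n)))

    def test_reproducible_for_fixed_seed(self):
        fit = self._fit(300)
        a = bootstrap_ci(fit, reps=120, seed=9)
        b = bootstrap_ci(fit, reps=120, seed=9)
        assert a.ci_mode_pct == b.ci_mode_pct
        assert a.ci_lower_pct == b.ci_lower_pct

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {n: [] for n in (150, 1500)}
        for seed in range(5):
            for n in widths:
                fit = self._fit(n, seed)
                boot = bootstrap_ci(fit, reps=120, seed=seed)
                widths[n].append(boot.ci_mode_pct[1] - boot.ci_mode_pct[0])
        assert np.median(widths[1500]) < np.median(widths[150])

    def test_ci_contains_plug_in_mode(self):
        hits = 0
        for seed in range(10):
            fit = self._fit(354, seed)
            boot = bootstrap_ci(fit, reps=100, seed=seed + 1)
            lo, hi = boot.ci_mode_pct
            hits += lo <= fit.mode_pct <= hi
        assert hits >= 9


# ---------------------------------------------------------------------------
# thresholds and metrics
# ---------------------------------------------------------------------------

class TestOptimizeThresholds:
    def test_perfect_separation_plateau_midpoints(self):
        scores = [90, 95, 80, 85, 10, 20]
        labels = [BeatClass.S_HBP] * 2 + [BeatClass.NS_HBP] * 2 \
            + [BeatClass.RVP] * 2
        ts = optimize_thresholds(scores, labels)
        assert ts.c_low_pct == pytest.approx(50.0)
        assert ts.c_high_pct == pytest.approx(87.5)
        assert _youden_J(scores, [l.value for l in labels],
                         ts.c_low_pct, ts.c_high_pct) == pytest.approx(3.0)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(9, 30))
            labels = np.array(["S_HBP", "NS_HBP", "RVP"]
                              [:3] * (n // 3 + 1))[:n]
            centers = {"S_HBP": 92, "NS_HBP": 82, "RVP": 45}
            scores = np.array([
                rng.normal(centers[l], 8) for l in labels]).round(1)
            ts = optimize_thresholds(scores, [BeatClass(l) for l in labels])
            got = _youden_J(scores, labels, ts.c_low_pct, ts.c_high_pct)
            assert got == pytest.approx(_youden_oracle_max(scores, labels),
                                        abs=1e-9)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            optimize_thresholds([90, 80], [BeatClass.S_HBP,
                                           BeatClass.NS_HBP])


class TestDiagnosticMetrics:
    def test_perfect_prediction(self):
        labels = [BeatClass.S_HBP] * 5 + [BeatClass.NS_HBP] * 4 \
            + [BeatClass.RVP] * 3
        mt = diagnostic_metrics(labels, labels)
        for cm in mt.per_class.values():
            for name in ("sensitivity", "specificity", "ppv", "npv"):
                assert getattr(cm, name).value == pytest.approx(1.0)

    def test_hand_computed_confusion(self):
        # one-vs-rest cells TP=9, FN=1, FP=2, TN=88
        truth = [BeatClass.S_HBP] * 10 + [BeatClass.NS_HBP] * 90
        pred = ([BeatClass.S_HBP] * 9 + [BeatClass.NS_HBP]
                + [BeatClass.S_HBP] * 2 + [BeatClass.NS_HBP] * 88)
        cm = diagnostic_metrics(pred, truth).per_class["S_HBP"]
        assert cm.sensitivity.value == pytest.approx(0.90)
        assert cm.specificity.value == pytest.approx(88 / 90)
        assert cm.ppv.value == pytest.approx(9 / 11)
        assert cm.npv.value == pytest.approx(88 / 89)
        assert cm.sensitivity.ci_low < 0.90 < cm.sensitivity.ci_high

    def test_cells_sum_to_n_and_swap_duality(self, rng):
        classes = [BeatClass.S_HBP, BeatClass.NS_HBP, BeatClass.RVP]
        truth = [classes[i] for i in rng.integers(0, 3, size=200)]
        pred = [classes[i] for i in rng.integers(0, 3, size=200)]
        mt = diagnostic_metrics(pred, truth)
        for cm in mt.per_class.values():
            assert cm.tp + cm.fn + cm.fp + cm.tn == mt.n
        swapped = diagnostic_metrics(truth, pred)
        for cls in mt.per_class:
            a, b = mt.per_class[cls], swapped.per_class[cls]
            assert a.sensitivity.value == pytest.approx(b.ppv.value)
            assert a.specificity.value == pytest.approx(b.npv.value)

    def test_undefined_ratio_is_nan_not_zero(self):
        truth = [BeatClass.S_HBP, BeatClass.S_HBP]
        pred = [BeatClass.S_HBP, BeatClass.S_HBP]
        cm = diagnostic_metrics(pred, truth).per_class["S_HBP"]
        assert math.isnan(cm.specificity.value)  # no true negatives exist
        assert math.isnan(cm.npv.value)


class TestCompareGroups:
    def test_identical_groups(self):
        p = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_exact_enumeration_small_sample(self):
        # 2/20 orderings are as extreme as complete separation
        assert compare_groups([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_large_samples_use_tie_corrected_normal(self, rng):
        a = rng.normal(0, 1, size=100).round(1)
        b = rng.normal(0.8, 1, size=100).round(1)
        p = compare_groups(a, b)
        ref = scistats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])
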