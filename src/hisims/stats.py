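"""Statistical analysis of IMS distributions and classifier performance.

Scores live on [0, 100]%; divided by 100 they are modelled as draws from a
beta distribution.  *Accuracy* of the morphology matcher is the mode of the
fitted beta, *precision* the interval between its 2.25th and 97.5th
percentiles (the printed convention; a 2.5th-percentile switch is
available), with 95% CIs from a parametric bootstrap.  Optimal IMS cutoffs
for the three-class pacing response come from a generalized Youden search,
and per-class diagnostic metrics carry exact Clopper-Pearson CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.proportion import proportion_confint

from .classification import ThresholdSet
from .synthetic_ecg import BeatClass

__all__ = [
    "BetaFit",
    "MetricCI",
    "MetricsTable",
    "fit_beta_mle",
    "beta_mode",
    "beta_percentiles",
    "summarize_beta_fit",
    "bootstrap_ci",
    "optimize_thresholds",
    "diagnostic_metrics",
    "compare_groups",
]

#: The printed percentile pair defining the precision interval.
DEFAULT_PRECISION_PROBS = (0.0225, 0.975)
#: Symmetric alternative in case the 2.25 was meant to be 2.5.
SYMMETRIC_PRECISION_PROBS = (0.025, 0.975)


# ---------------------------------------------------------------------------
# Beta accuracy / precision machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaFit:
    """MLE beta fit with derived accuracy/precision summaries (percent)."""

    alpha: float
    beta: float
    n: int
    converged: bool
    mode_pct: float | None = None
    precision_interval_pct: tuple[float, float] | None = None
    ci_mode_pct: tuple[float, float] | None = None
    ci_lower_pct: tuple[float, float] | None = None
    ci_upper_pct: tuple[float, float] | None = None
    bootstrap_reps: int | None = None
    bootstrap_seed: int | None = None

    @property
    def accuracy_error_pct(self) -> float | None:
        return None if self.mode_pct is None else 100.0 - self.mode_pct


def _clamp(values, eps: float) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return np.clip(v, eps, 1.0 - eps)


def fit_beta_mle(values, clamp_eps: float = 1e-4) -> BetaFit:
    """Maximum-likelihood beta fit of proportions in (0, 1).

    Values are clamped into [eps, 1-eps] first (scores of exactly 0% or
    100% are representable).  Requires n >= 10; an all-identical sample is
    degenerate.  Optimizes the log-likelihood in log-shape coordinates from
    a method-of-moments start.
    """
    x = _clamp(values, clamp_eps)
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 values to fit, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate sample: all values identical after clamping")

    m = float(x.mean())
    v = float(x.var())
    common = m * (1.0 - m) / max(v, 1e-12) - 1.0
    a0 = max(m * common, 1e-3)
    b0 = max((1.0 - m) * common, 1e-3)

    slx = float(np.mean(np.log(x)))
    sl1x = float(np.mean(np.log1p(-x)))

    def nll(theta):
        a, b = np.exp(theta)
        return -( (a - 1.0) * slx + (b - 1.0) * sl1x - special.betaln(a, b) )

    def grad(theta):
        a, b = np.exp(theta)
        psi_ab = special.digamma(a + b)
        da = -(slx - special.digamma(a) + psi_ab)
        db = -(sl1x - special.digamma(b) + psi_ab)
        return np.array([da * a, db * b])  # chain rule for log coordinates

    res = optimize.minimize(nll, np.log([a0, b0]), jac=grad, method="L-BFGS-B")
    a, b = np.exp(res.x)
    return BetaFit(alpha=float(a), beta=float(b), n=n,
                   converged=bool(res.success))


def beta_mode(alpha: float, beta: float) -> float:
    """Mode of Beta(alpha, beta), the accuracy summary of a score sample.

    Interior mode (a-1)/(a+b-2) when both shapes exceed 1; boundary modes 0
    or 1 when only one does.  The flat a = b = 1 case has no unique mode and
    returns 0.5 by convention.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("shape parameters must be positive")
    if alpha > 1 and beta > 1:
        return (alpha - 1.0) / (alpha + beta - 2.0)
    if alpha <= 1 and beta <= 1:
        if alpha == beta:
            return 0.5  # flat or bathtub: no unique interior mode
        return 0.0 if alpha < beta else 1.0
    return 1.0 if alpha > 1 else 0.0


def beta_percentiles(alpha: float, beta: float,
                     probs=DEFAULT_PRECISION_PROBS) -> np.ndarray:
    """Inverse regularized incomplete beta at each probability."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("shape parameters must be positive")
    p = np.asarray(probs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    return stats.beta.ppf(p, alpha, beta)


def summarize_beta_fit(fit: BetaFit,
                       probs=DEFAULT_PRECISION_PROBS) -> BetaFit:
    """Fill in accuracy (mode) and precision (percentile interval), percent."""
    mode = beta_mode(fit.alpha, fit.beta)
    lo, hi = beta_percentiles(fit.alpha, fit.beta, probs)
    return replace(fit, mode_pct=100.0 * mode,
                   precision_interval_pct=(100.0 * lo, 100.0 * hi))


def bootstrap_ci(fit: BetaFit, reps: int = 1000, seed: int = 0,
                 probs=DEFAULT_PRECISION_PROBS,
                 max_failure_rate: float = 0.05) -> BetaFit:
    """Parametric-bootstrap 95% CIs for mode and precision bounds.

    Each replicate draws n values from Beta(alpha-hat, beta-hat), refits by
    the same optimizer, and recomputes the three statistics; the 2.5th and
    97.5th percentiles across replicates form each CI.  Reproducible for a
    fixed seed; errors out if more than 5% of replicate fits fail.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    rng = np.random.default_rng(seed)
    stats_rep = []
    failed = 0
    for _ in range(reps):
        sample = rng.beta(fit.alpha, fit.beta, size=fit.n)
        try:
            f = fit_beta_mle(sample)
            if not f.converged:
                raise ValueError("replicate fit did not converge")
            lo, hi = beta_percentiles(f.alpha, f.beta, probs)
            stats_rep.append((beta_mode(f.alpha, f.beta), lo, hi))
        except ValueError:
            failed += 1
    if failed > max_failure_rate * reps:
        raise RuntimeError(
            f"bootstrap unstable: {failed}/{reps} replicate fits failed "
            f"(alpha={fit.alpha:.3g}, beta={fit.beta:.3g}, n={fit.n})")
    arr = 100.0 * np.asarray(stats_rep)
    cis = [tuple(np.percentile(arr[:, j], [2.5, 97.5])) for j in range(3)]
    return replace(fit, ci_mode_pct=cis[0], ci_lower_pct=cis[1],
                   ci_upper_pct=cis[2], bootstrap_reps=reps,
                   bootstrap_seed=seed)


# ---------------------------------------------------------------------------
# Multi-class optimal thresholds (generalized Youden)
# ---------------------------------------------------------------------------

_ORDERED = (BeatClass.RVP, BeatClass.NS_HBP, BeatClass.S_HBP)


def _class_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([BeatClass(l).value for l in labels])
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    out = {}
    for cls in _ORDERED:
        vals = np.sort(scores[labels == cls.value])
        if vals.size == 0:
            raise ValueError(f"class {cls.value} missing from the sample")
        out[cls] = vals
    return scores, out


def _frac_below(sorted_vals: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_vals, cuts, side="left") / sorted_vals.size


def optimize_thresholds(scores, labels) -> ThresholdSet:
    """Optimal (c_low, c_high) for the three-class pacing response.

    Candidate cuts are the midpoints between adjacent distinct observed
    scores.  The objective is the generalized Youden sum of per-class
    correct fractions: RVP below c_low, NS-HBP in [c_low, c_high), S-HBP at
    or above c_high.  Ties are broken by the larger minimum per-class
    correct fraction; the reported cutoffs are the midpoints of the optimal
    plateau (the full run of equally optimal adjacent candidate intervals).
    """
    scores, per_class = _class_scores(scores, labels)
    uniq = np.unique(scores)
    if uniq.size < 3:
        raise ValueError("need at least 3 distinct scores to place two cutoffs")
    mids = 0.5 * (uniq[:-1] + uniq[1:])

    g_rvp = _frac_below(per_class[BeatClass.RVP], mids)
    g_ns = _frac_below(per_class[BeatClass.NS_HBP], mids)
    g_s = _frac_below(per_class[BeatClass.S_HBP], mids)
    f_low = g_rvp - g_ns           # gain of placing c_low at mids[j]
    f_high = g_ns - g_s            # gain of placing c_high at mids[k]

    m = mids.size
    joint = f_low[:, None] + f_high[None, :] + 1.0
    jj, kk = np.triu_indices(m, k=1)  # enforce c_low < c_high
    vals = joint[jj, kk]
    best = vals.max()
    tied = np.flatnonzero(vals >= best - 1e-12)

    if tied.size > 1:
        # maximize the minimum per-class correct fraction
        min_frac = np.minimum.reduce([
            g_rvp[jj[tied]],
            g_ns[kk[tied]] - g_ns[jj[tied]],
            1.0 - g_s[kk[tied]],
        ])
        tied = tied[min_frac >= min_frac.max() - 1e-12]

    j_opt = np.unique(jj[tied])
    k_opt = np.unique(kk[tied])

    def plateau_mid(idx: np.ndarray) -> float:
        # merge the contiguous run of optimal candidate intervals containing
        # the smallest optimal index, and report the midpoint of the merged
        # interval between its bounding observed scores
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        run = runs[0]
        return 0.5 * (uniq[run[0]] + uniq[run[-1] + 1])

    c_low = max(0.0, plateau_mid(j_opt))
    c_high = min(100.0, plateau_mid(k_opt))
    return ThresholdSet(c_low, c_high)


# ---------------------------------------------------------------------------
# Diagnostic metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricCI:
    value: float  # NaN when the defining denominator is zero
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ClassMetrics:
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI
    tp: int
    fn: int
    fp: int
    tn: int


@dataclass(frozen=True)
class MetricsTable:
    """One-vs-rest diagnostic metrics per class with exact binomial CIs."""

    per_class: dict
    confusion: pd.DataFrame
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, cm in self.per_class.items():
            row = {"class": cls}
            for name in ("sensitivity", "specificity", "ppv", "npv"):
                mc: MetricCI = getattr(cm, name)
                row[name] = mc.value
                row[f"{name}_ci_low"] = mc.ci_low
                row[f"{name}_ci_high"] = mc.ci_high
            rows.append(row)
        return pd.DataFrame(rows)


def _ratio_ci(count: int, nobs: int) -> MetricCI:
    if nobs == 0:
        return MetricCI(math.nan, math.nan, math.nan)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="beta")
    return MetricCI(count / nobs, float(lo), float(hi))


def diagnostic_metrics(predicted, truth) -> MetricsTable:
    """Sensitivity/specificity/PPV/NPV per class, Clopper-Pearson 95% CIs.

    Undefined ratios (zero denominator) are reported as NaN, never as 0.
    """
    pred = np.asarray([BeatClass(p).value for p in predicted])
    true = np.asarray([BeatClass(t).value for t in truth])
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    n = pred.size
    classes = [c.value for c in _ORDERED if c.value in set(true) | set(pred)]
    confusion = pd.crosstab(pd.Series(true, name="truth"),
                            pd.Series(pred, name="predicted"), dropna=False)
    per_class = {}
    for cls in classes:
        tp = int(np.sum((pred == cls) & (true == cls)))
        fn = int(np.sum((pred != cls) & (true == cls)))
        fp = int(np.sum((pred == cls) & (true != cls)))
        tn = n - tp - fn - fp
        per_class[cls] = ClassMetrics(
            sensitivity=_ratio_ci(tp, tp + fn),
            specificity=_ratio_ci(tn, tn + fp),
            ppv=_ratio_ci(tp, tp + fp),
            npv=_ratio_ci(tn, tn + fn),
            tp=tp, fn=fn, fp=fp, tn=tn,
        )
    return MetricsTable(per_class=per_class, confusion=confusion, n=n)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_groups(scores_a, scores_b) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact enumeration for small samples (both n <= 20, no ties); the normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
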