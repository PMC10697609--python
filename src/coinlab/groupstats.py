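"""Group-level inference for coin-task metrics.

The battery mirrors the study design this package emulates: correlations of
per-participant metrics with a CAPE-P-like psychotic-like-experience score
(Pearson on the log-transformed score for approximately linear metrics,
Spearman on the raw score otherwise), percentile-bootstrap confidence
intervals over participants, a small fixed Bonferroni family, signed-rank
tests against the normative benchmarks, condition ANOVAs and paired t-tests,
and the Fisher-z power computation for a correlation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GroupResult",
    "correlate",
    "bonferroni",
    "wilcoxon_vs_optimal",
    "paired_t",
    "two_way_anova",
    "power_n_correlation",
    "correlation_power",
    "run_headline_analyses",
    "HEADLINE_FAMILY",
]

#: the four comparisons in the Bonferroni family: psychotic-like-experience
#: score against (1) global sensory weight, (2) trial-wise weight variance,
#: (3) subjective likelihood variance, (4) subjective prior variance.
HEADLINE_FAMILY = (
    "sw_global~log_cape_p",
    "trial_sw_variance~cape_p",
    "subj_lik_var~cape_p",
    "subj_prior_var~cape_p",
)


@dataclass
class GroupResult:
    """One statistical comparison."""

    name: str
    estimator: str
    statistic: float
    p_value: float
    n_used: int
    ci_low: float | None = None
    ci_high: float | None = None
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimator": self.estimator,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_adjusted": self.p_adjusted,
        }


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def _pearson_r_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation for (B, n) matrices."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc * yc).sum(axis=1) / denom


def _bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    method: str,
    n_boot: int,
    rng: np.random.Generator,
    level: float = 0.95,
) -> tuple[float, float]:
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    if method == "spearman":
        xs = stats.rankdata(xs, axis=1)
        ys = stats.rankdata(ys, axis=1)
    r = _pearson_r_rows(xs, ys)
    alpha = 100 * (1 - level) / 2
    lo, hi = np.nanpercentile(r, [alpha, 100 - alpha])
    return float(lo), float(hi)


def correlate(
    x,
    y,
    method: str = "pearson",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    name: str = "",
) -> GroupResult:
    """Pearson or Spearman correlation with a percentile-bootstrap CI.

    Missing pairs are dropped listwise; Spearman uses average ranks for ties.
    ``n_boot = 0`` skips the bootstrap (no CI).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    x, y = _complete_pairs(x, y)
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    ci_low = ci_high = None
    if n_boot > 0:
        rng = rng if rng is not None else np.random.default_rng()
        ci_low, ci_high = _bootstrap_ci(x, y, method, n_boot, rng)
    return GroupResult(
        name=name or f"{method}_correlation",
        estimator=method,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=len(x),
        ci_low=ci_low,
        ci_high=ci_high,
    )


def bonferroni(p_values, m: int = 4):
    """Bonferroni adjustment: ``min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, m * p)
    return float(out) if np.ndim(p_values) == 0 else out


def wilcoxon_vs_optimal(values, target: float, name: str = "") -> GroupResult:
    """One-sample Wilcoxon signed-rank test of ``values - target`` against 0.

    Two-sided; zero differences dropped; normal approximation with continuity
    correction for more than 25 non-zero differences, exact otherwise.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 6:
        raise ValueError("need at least 6 values")
    d = v - target
    nonzero = int(np.count_nonzero(d))
    if nonzero == 0:
        return GroupResult(name=name or "wilcoxon", estimator="wilcoxon_signed_rank_vs_value",
                           statistic=0.0, p_value=1.0, n_used=len(v))
    mode = "exact" if nonzero <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(mode == "approx"), method=mode)
    return GroupResult(
        name=name or "wilcoxon",
        estimator="wilcoxon_signed_rank_vs_value",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=len(v),
    )


def paired_t(a, b, name: str = "") -> GroupResult:
    """Paired two-sided t-test; reports the mean difference's 95% CI."""
    a, b = _complete_pairs(a, b)
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):  # identical vectors: no effect by convention
            return GroupResult(name=name or "paired_t", estimator="paired_t",
                               statistic=0.0, p_value=1.0, n_used=len(d),
                               ci_low=0.0, ci_high=0.0)
        raise ValueError("zero-variance differences")
    res = stats.ttest_rel(a, b)
    se = np.std(d, ddof=1) / math.sqrt(len(d))
    tcrit = stats.t.ppf(0.975, df=len(d) - 1)
    return GroupResult(
        name=name or "paired_t",
        estimator="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=len(d),
        ci_low=float(d.mean() - tcrit * se),
        ci_high=float(d.mean() + tcrit * se),
    )


def two_way_anova(
    long: pd.DataFrame,
    value: str = "value",
    prior: str = "prior_cond",
    lik: str = "lik_cond",
    participant: str = "participant_id",
) -> dict[str, GroupResult]:
    """Fixed-effects two-factor ANOVA with interaction on a long table.

    Each participant must contribute one value per condition cell.  Returns
    results keyed ``prior``, ``likelihood`` and ``interaction``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = long.groupby(participant)[value].count()
    n_cells = long[prior].nunique() * long[lik].nunique()
    bad = counts[counts != n_cells]
    if len(bad):
        raise ValueError(f"missing condition cells for participant(s): {list(bad.index[:5])}")
    d = long.rename(columns={value: "y", prior: "pf", lik: "lf"})
    model = smf.ols("y ~ C(pf) * C(lf)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    n = int(len(d))
    keymap = {"C(pf)": "prior", "C(lf)": "likelihood", "C(pf):C(lf)": "interaction"}
    out = {}
    for row, key in keymap.items():
        out[key] = GroupResult(
            name=f"anova_{key}",
            estimator="two_way_anova",
            statistic=float(table.loc[row, "F"]),
            p_value=float(table.loc[row, "PR(>F)"]),
            n_used=n,
        )
    return out


def correlation_power(r: float, n: float, alpha: float = 0.05) -> float:
    """Power of the two-sided test of zero correlation via Fisher's z.

    Uses the bias-corrected mean ``atanh(r) + r / (2 (n - 1))`` and standard
    deviation ``1 / sqrt(n - 3)`` of the z-transformed sample correlation.
    """
    if n <= 4:
        return 0.0
    zr = math.atanh(r) + r / (2.0 * (n - 1.0))
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    scale = math.sqrt(n - 3.0)
    # two-sided rejection; the wrong-sign tail is negligible for r > 0
    return float(
        stats.norm.sf(zcrit - zr * scale) + stats.norm.cdf(-zcrit - zr * scale)
    )


def power_n_correlation(r: float, power: float = 0.80, alpha: float = 0.05) -> int:
    """Smallest n at which the correlation test reaches the target power."""
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    def gap(n: float) -> float:
        return correlation_power(r, n, alpha) - power

    lo, hi = 4.5, 10.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e9:
            raise RuntimeError("required sample size exceeds 1e9")
    root = optimize.brentq(gap, lo, hi, xtol=1e-9)
    n = int(math.ceil(root - 1e-9))
    while correlation_power(r, n, alpha) < power:  # guard against rounding
        n += 1
    return n


def _merged(metrics: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    orphans = sorted(set(metrics["participant_id"]) ^ set(participants["participant_id"]))
    if orphans:
        raise ValueError(f"participant_id mismatch between tables: {orphans[:10]}")
    d = metrics.merge(participants, on="participant_id", how="inner")
    return d[~d["excluded"].astype(bool)]


def run_headline_analyses(
    metrics: pd.DataFrame,
    participants: pd.DataFrame,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    bonferroni_m: int = 4,
    battery: str = "full",
) -> list[GroupResult]:
    """The ordered battery of trait correlations.

    The four family members (global sensory weight vs log score; trial-weight
    variance, subjective likelihood variance and subjective prior variance vs
    raw score) carry Bonferroni-adjusted p-values.  ``battery='full'`` adds
    sensitivity-to-prior-change, per-condition weights and prior variances,
    spatial-span correlations and CAPE subscale correlations.
    """
    rng = rng if rng is not None else np.random.default_rng()
    d = _merged(metrics, participants)
    if len(d) < 10:
        raise ValueError(f"only {len(d)} participants after exclusions; need >= 10")
    d = d.assign(log_cape_p=np.log(d["cape_p"].astype(float)))

    results: list[GroupResult] = []

    def corr(name, xcol, ycol, method):
        results.append(
            correlate(d[xcol], d[ycol], method=method, n_boot=n_boot, rng=rng, name=name)
        )

    corr("sw_global~log_cape_p", "log_cape_p", "sw_global", "pearson")
    corr("trial_sw_variance~cape_p", "cape_p", "trial_sw_variance", "spearman")
    corr("subj_lik_var~cape_p", "cape_p", "subj_lik_var", "spearman")
    corr("subj_prior_var~cape_p", "cape_p", "subj_prior_var", "spearman")
    adjusted = bonferroni([r.p_value for r in results], m=bonferroni_m)
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)

    if battery == "full":
        corr("sensitivity_prior_change~cape_p", "cape_p", "sensitivity_prior_change", "spearman")
        for c in ("PnLn", "PnLw", "PwLn", "PwLw"):
            corr(f"sw_{c}~log_cape_p", "log_cape_p", f"sw_{c}", "pearson")
        for c in ("PnLn", "PnLw", "PwLn", "PwLw"):
            corr(f"subj_prior_var_{c}~cape_p", "cape_p", f"subj_prior_var_{c}", "spearman")
        corr("subj_prior_var~spatial_span", "spatial_span", "subj_prior_var", "spearman")
        corr("subj_lik_var~spatial_span", "spatial_span", "subj_lik_var", "spearman")
        for sub in ("cape_n", "cape_d"):
            corr(f"sw_global~{sub}", sub, "sw_global", "spearman")
    return results
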