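"""Per-participant behavioural estimators for the coin task.

All quantities the analysis defines per participant:

* mean estimation error (calibration task vs splash centre; main task vs the
  true coin), overall and per condition;
* the sensory weight ``sw`` — the OLS slope (intercept included) of responses
  on the splash centroid — overall, per condition and per block;
* sensitivity to prior change: mean absolute change in the block-wise slope
  across consecutive blocks;
* trial-wise sensory weight ``(X_est - mu_P) / (mu_L - mu_P)``, passed
  through a logistic to bound it on (0, 1), and its session variance;
* subjective likelihood variance: mean squared centroid-estimation error in
  the calibration task (population, i.e. 1/nTrials, denominator);
* subjective prior variance: the algebraic inversion
  ``sigma_SL^2 * sw / (1 - sw)`` of the optimal-weight formula;
* the normative benchmarks: optimal weights ``sigma_P^2 / (sigma_P^2 +
  sigma_L^2)`` with the design's true variances, and the "imposed" prior
  variance they imply;
* three-sigma exclusion flags on the two mean-error criteria.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import TaskDesign

__all__ = [
    "CONDITION_LABELS",
    "METRIC_COLUMNS",
    "mean_estimation_error",
    "fit_sensory_weight",
    "optimal_sensory_weight",
    "optimal_benchmarks",
    "imposed_prior_variance",
    "sensitivity_to_prior_change",
    "trial_sensory_weight",
    "trial_sw_variance",
    "subjective_likelihood_variance",
    "subjective_prior_variance",
    "exclude_outliers",
    "compute_all_metrics",
]

#: the four main-task cells, prior x likelihood.
CONDITION_LABELS = ("PnLn", "PnLw", "PwLn", "PwLw")

_COND_PAIRS = {
    "PnLn": ("narrow", "narrow"),
    "PnLw": ("narrow", "wide"),
    "PwLn": ("wide", "narrow"),
    "PwLw": ("wide", "wide"),
}

#: literal reading of the printed optimal likelihood variances (exposed for
#: comparison only; the canonical interpretation is the centroid variance
#: splash_sd^2 / n_splashes).
_LITERAL_LIK_VARIANCE = {"narrow": 0.09625, "wide": 0.2425}

METRIC_COLUMNS = (
    ["participant_id"]
    + ["mean_est_error_likonly", "mean_est_error_likonly_Ln", "mean_est_error_likonly_Lw"]
    + ["mean_est_error_main"]
    + [f"mean_est_error_main_{c}" for c in CONDITION_LABELS]
    + ["sw_global"]
    + [f"sw_{c}" for c in CONDITION_LABELS]
    + [f"sw_block_{b}" for b in (1, 2, 3, 4)]
    + ["sensitivity_prior_change", "trial_sw_variance"]
    + ["subj_lik_var", "subj_lik_var_Ln", "subj_lik_var_Lw"]
    + ["subj_prior_var"]
    + [f"subj_prior_var_{c}" for c in CONDITION_LABELS]
    + ["excluded", "exclusion_reason"]
)


def _filtered(trials: pd.DataFrame, prior_cond=None, lik_cond=None) -> pd.DataFrame:
    out = trials
    if prior_cond is not None:
        out = out[out["prior_cond"] == prior_cond]
    if lik_cond is not None:
        out = out[out["lik_cond"] == lik_cond]
    return out


def mean_estimation_error(
    trials: pd.DataFrame,
    reference: str = "coin",
    prior_cond: str | None = None,
    lik_cond: str | None = None,
) -> float:
    """Mean absolute distance between response and reference position.

    ``reference='centroid'`` scores against the splash centre (calibration
    task); ``reference='coin'`` against the true coin (main task).
    """
    if reference not in ("coin", "centroid"):
        raise ValueError("reference must be 'coin' or 'centroid'")
    sub = _filtered(trials, prior_cond, lik_cond)
    if len(sub) == 0:
        raise ValueError("no trials match the requested filter")
    ref = sub["coin_pos"] if reference == "coin" else sub["mu_L"]
    return float(np.abs(sub["response"] - ref).mean())


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    """OLS slope of y on x with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 trials to fit a sensory weight")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("degenerate regressor: variance of mu_L is zero")
    return float(xc @ (y - y.mean()) / sxx)


def fit_sensory_weight(
    trials: pd.DataFrame,
    prior_cond: str | None = None,
    lik_cond: str | None = None,
    block_index: int | None = None,
) -> float:
    """Sensory weight: slope of the regression of responses on the splash centroid."""
    sub = _filtered(trials, prior_cond, lik_cond)
    if block_index is not None:
        sub = sub[sub["block_index"] == block_index]
    if sub["response"].isna().any():
        raise ValueError("trials have missing responses")
    return _slope(sub["mu_L"].to_numpy(), sub["response"].to_numpy())


def optimal_sensory_weight(
    design: TaskDesign,
    prior_cond: str,
    lik_cond: str,
    variance_mode: str = "centroid",
) -> float:
    """Normative weight on the likelihood given the design's true variances.

    ``variance_mode='centroid'`` (canonical) takes the likelihood variance as
    the variance of the 5-splash centroid, ``splash_sd^2 / n_splashes``;
    ``'literal'`` uses the printed constants 0.09625 / 0.2425 as variances
    (only defined for the default splash spreads).
    """
    vp = design.prior_var(prior_cond)
    vl = _likelihood_variance(design, lik_cond, variance_mode)
    return vp / (vp + vl)


def _likelihood_variance(design: TaskDesign, lik_cond: str, variance_mode: str) -> float:
    if variance_mode == "centroid":
        return design.centroid_var(lik_cond)
    if variance_mode == "literal":
        if (design.splash_sd_narrow, design.splash_sd_wide, design.n_splashes) != (0.096, 0.24, 5):
            raise ValueError("literal variance mode is defined only for the default splash spreads")
        return _LITERAL_LIK_VARIANCE[lik_cond]
    raise ValueError("variance_mode must be 'centroid' or 'literal'")


def imposed_prior_variance(
    design: TaskDesign, prior_cond: str, lik_cond: str, variance_mode: str = "centroid"
) -> float:
    """'Imposed' prior variance: the inversion formula fed the true likelihood
    variance and the optimal weight (algebraically, the true prior variance)."""
    sw = optimal_sensory_weight(design, prior_cond, lik_cond, variance_mode)
    vl = _likelihood_variance(design, lik_cond, variance_mode)
    return vl * sw / (1.0 - sw)


def optimal_benchmarks(design: TaskDesign, variance_mode: str = "centroid") -> dict:
    """Per-condition normative weights and imposed prior variances."""
    return {
        "sw_opt": {
            c: optimal_sensory_weight(design, *_COND_PAIRS[c], variance_mode)
            for c in CONDITION_LABELS
        },
        "prior_var_imposed": {
            c: imposed_prior_variance(design, *_COND_PAIRS[c], variance_mode)
            for c in CONDITION_LABELS
        },
    }


def sensitivity_to_prior_change(block_slopes: Sequence[float]) -> float:
    """Mean absolute slope change across consecutive blocks."""
    slopes = np.asarray(list(block_slopes), dtype=float)
    if len(slopes) < 2:
        raise ValueError("need at least 2 block slopes")
    if np.isnan(slopes).any():
        raise ValueError("missing block slope")
    return float(np.abs(np.diff(slopes)).mean())


def trial_sensory_weight(response, mu_L, mu_P: float = 0.0, clamp: float = 50.0):
    """Trial-wise weight ``(X_est - mu_P) / (mu_L - mu_P)`` and its logistic.

    Returns ``(raw, logistic)``.  Trials with ``mu_L == mu_P`` are undefined
    and returned as NaN; the raw value is clamped to ``+-clamp`` before the
    logistic so near-degenerate trials cannot overflow.
    """
    response = np.asarray(response, dtype=float)
    mu_L = np.asarray(mu_L, dtype=float)
    denom = mu_L - mu_P
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(denom == 0.0, np.nan, (response - mu_P) / denom)
    clamped = np.clip(raw, -clamp, clamp)
    logistic = 1.0 / (1.0 + np.exp(-clamped))
    if np.ndim(raw) == 0:
        return float(raw), float(logistic)
    return raw, logistic


def trial_sw_variance(trials: pd.DataFrame, mu_P: float = 0.0) -> float:
    """Sample variance (n-1 denominator) of the logistic trial-wise weights."""
    _, logistic = trial_sensory_weight(
        trials["response"].to_numpy(), trials["mu_L"].to_numpy(), mu_P
    )
    logistic = logistic[~np.isnan(logistic)]
    if len(logistic) < 2:
        raise ValueError("need at least 2 defined trial weights")
    return float(np.var(logistic, ddof=1))


def subjective_likelihood_variance(trials: pd.DataFrame, lik_cond: str | None = None) -> float:
    """Mean squared centroid-estimation error (population denominator)."""
    sub = _filtered(trials, lik_cond=lik_cond)
    if len(sub) == 0:
        raise ValueError("no trials match the requested filter")
    err = sub["response"].to_numpy() - sub["mu_L"].to_numpy()
    return float(np.mean(err**2))


def subjective_prior_variance(subj_lik_var, sw):
    """Invert the weight formula: ``sigma_P^2 = sigma_SL^2 * sw / (1 - sw)``.

    ``sw >= 1`` is undefined (returned as NaN rather than an infinite or
    negative variance); ``sw <= 0`` is clamped to 0 with a warning.
    """
    subj_lik_var = np.asarray(subj_lik_var, dtype=float)
    sw = np.asarray(sw, dtype=float)
    out = np.full(np.broadcast(subj_lik_var, sw).shape, np.nan)
    subj_lik_var, sw = np.broadcast_arrays(subj_lik_var, sw)
    ok = (sw > 0) & (sw < 1)
    out[ok] = subj_lik_var[ok] * sw[ok] / (1.0 - sw[ok])
    neg = sw <= 0
    if np.any(neg & ~np.isnan(sw)):
        warnings.warn("sensory weight <= 0: subjective prior variance clamped to 0", stacklevel=2)
        out[neg & ~np.isnan(sw)] = 0.0
    if np.ndim(out) == 0 or out.shape == ():
        return float(out)
    return out


def exclude_outliers(values: pd.Series, z_thresh: float = 3.0) -> pd.Series:
    """Flag values more than ``z_thresh`` SDs from the mean (z-score rule).

    NaNs are never flagged; a zero or undefined SD flags nobody.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 participants for outlier detection")
    x = values.astype(float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        return pd.Series(False, index=values.index)
    z = (x - x.mean()).abs() / sd
    return (z > z_thresh).fillna(False)


# ---------------------------------------------------------------------------
# vectorised helpers for whole-cohort trial tables
# ---------------------------------------------------------------------------


def _grouped_slopes(trials: pd.DataFrame, by: list[str]) -> pd.Series:
    """OLS slope of response on mu_L per group, via sufficient statistics."""
    d = pd.DataFrame(
        {
            "x": trials["mu_L"].to_numpy(),
            "y": trials["response"].to_numpy(),
        }
    )
    for k in by:
        d[k] = trials[k].to_numpy()
    d["xy"] = d["x"] * d["y"]
    d["xx"] = d["x"] * d["x"]
    g = d.groupby(by, sort=True).agg(
        n=("x", "size"), sx=("x", "sum"), sy=("y", "sum"), sxy=("xy", "sum"), sxx=("xx", "sum")
    )
    sxx_c = g["sxx"] - g["sx"] ** 2 / g["n"]
    sxy_c = g["sxy"] - g["sx"] * g["sy"] / g["n"]
    slope = sxy_c / sxx_c
    slope[(g["n"] < 3) | (sxx_c <= 0)] = np.nan
    return slope


def compute_all_metrics(
    trials_main: pd.DataFrame,
    trials_likonly: pd.DataFrame,
    design: TaskDesign,
    variance_mode: str = "centroid",
) -> pd.DataFrame:
    """All per-participant metrics for a cohort, one row per participant.

    Participants missing either task are flagged excluded with reason
    ``missing_task`` and carry NaN metrics.  Exclusion passes mirror the
    study's procedure: a z > 3 rule on mean calibration-task error first,
    then the same rule on mean main-task error among survivors.
    """
    ids = sorted(
        set(trials_main["participant_id"].unique()) | set(trials_likonly["participant_id"].unique())
    )
    out = pd.DataFrame({"participant_id": ids}).set_index("participant_id")

    # --- calibration task -------------------------------------------------
    lo = trials_likonly.copy()
    lo["abs_err"] = (lo["response"] - lo["mu_L"]).abs()
    lo["sq_err"] = (lo["response"] - lo["mu_L"]) ** 2
    out["mean_est_error_likonly"] = lo.groupby("participant_id")["abs_err"].mean()
    per_cond = lo.groupby(["participant_id", "lik_cond"])["abs_err"].mean().unstack()
    out["mean_est_error_likonly_Ln"] = per_cond.get("narrow")
    out["mean_est_error_likonly_Lw"] = per_cond.get("wide")
    out["subj_lik_var"] = lo.groupby("participant_id")["sq_err"].mean()
    slv = lo.groupby(["participant_id", "lik_cond"])["sq_err"].mean().unstack()
    out["subj_lik_var_Ln"] = slv.get("narrow")
    out["subj_lik_var_Lw"] = slv.get("wide")

    # --- main task --------------------------------------------------------
    mt = trials_main.copy()
    mt["abs_err"] = (mt["response"] - mt["coin_pos"]).abs()
    mt["cond"] = "P" + mt["prior_cond"].str[0] + "L" + mt["lik_cond"].str[0]
    out["mean_est_error_main"] = mt.groupby("participant_id")["abs_err"].mean()
    per_cond = mt.groupby(["participant_id", "cond"])["abs_err"].mean().unstack()
    for c in CONDITION_LABELS:
        out[f"mean_est_error_main_{c}"] = per_cond.get(c)

    out["sw_global"] = _grouped_slopes(mt, ["participant_id"])
    sw_cond = _grouped_slopes(mt, ["participant_id", "cond"]).unstack()
    for c in CONDITION_LABELS:
        out[f"sw_{c}"] = sw_cond.get(c)
    sw_block = _grouped_slopes(mt, ["participant_id", "block_index"]).unstack()
    for b in range(1, design.n_blocks + 1):
        out[f"sw_block_{b}"] = sw_block.get(b)
    block_cols = [f"sw_block_{b}" for b in range(1, design.n_blocks + 1)]
    blocks = out[block_cols].to_numpy()
    with np.errstate(invalid="ignore"):
        sens = np.abs(np.diff(blocks, axis=1)).mean(axis=1)
    out["sensitivity_prior_change"] = sens

    _, logistic = trial_sensory_weight(
        mt["response"].to_numpy(), mt["mu_L"].to_numpy(), design.prior_mean
    )
    mt["logistic_sw"] = logistic
    out["trial_sw_variance"] = mt.groupby("participant_id")["logistic_sw"].var(ddof=1)

    # --- subjective prior variance (inversion) -----------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["subj_prior_var"] = subjective_prior_variance(
            out["subj_lik_var"].to_numpy(), out["sw_global"].to_numpy()
        )
        for c in CONDITION_LABELS:
            lik_col = "subj_lik_var_Ln" if c.endswith("Ln") else "subj_lik_var_Lw"
            out[f"subj_prior_var_{c}"] = subjective_prior_variance(
                out[lik_col].to_numpy(), out[f"sw_{c}"].to_numpy()
            )

    # --- exclusions ---------------------------------------------------------
    out["excluded"] = False
    out["exclusion_reason"] = ""
    missing = out["mean_est_error_likonly"].isna() | out["mean_est_error_main"].isna()
    out.loc[missing, ["excluded", "exclusion_reason"]] = [True, "missing_task"]
    candidates = out.loc[~missing]
    if len(candidates) >= 3:
        flag1 = exclude_outliers(candidates["mean_est_error_likonly"])
        out.loc[flag1[flag1].index, ["excluded", "exclusion_reason"]] = [
            True,
            "likelihood_only_error_z3",
        ]
        survivors = candidates.index[~flag1]
        if len(survivors) >= 3:
            flag2 = exclude_outliers(out.loc[survivors, "mean_est_error_main"])
            out.loc[flag2[flag2].index, ["excluded", "exclusion_reason"]] = [
                True,
                "main_error_z3",
            ]

    out = out.reset_index()
    return out[METRIC_COLUMNS]
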