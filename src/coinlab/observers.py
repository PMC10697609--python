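"""Synthetic cohorts of noisy Bayesian observers.

Each observer combines the trial's perceived splash centroid with the block's
prior by precision weighting (posterior mean of two Gaussians), using
*subjective* variances that may deviate from the true task variances.  A
latent standard-normal trait — the stand-in for individual differences in
psychotic-like experiences — shifts the log subjective variances, so that a
cohort exhibits weak trait–uncertainty associations of the kind the group
analysis is designed to detect.  The trait also generates a CAPE-P-like
questionnaire score through a right-skewed (lognormal) map.

Response model (the data-generating side the closed-form estimators are later
checked against):

* perceived centroid = true centroid + Gaussian encoding noise whose SD
  defaults to the observer's subjective centroid SD (so the calibration-task
  variance estimator recovers it);
* main task: response = posterior mean of prior and perceived centroid
  (subjective variances) + Gaussian motor noise; with a small lapse
  probability the response is instead uniform over the screen;
* calibration task: response = perceived centroid + motor noise (no prior
  integration, no lapse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .design import (
    TaskDesign,
    generate_likelihood_only_task,
    generate_main_task,
    participant_stream,
)

__all__ = [
    "ObserverParams",
    "CohortSpec",
    "SimulatedCohort",
    "posterior_mean",
    "ideal_estimate",
    "sample_observer",
    "simulate_response",
    "simulate_cohort",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "cape_p",
    "cape_n",
    "cape_d",
    "cape_total",
    "spatial_span",
    "age",
    "gender",
]


@dataclass
class ObserverParams:
    """One synthetic participant's generative parameters."""

    participant_id: str
    #: latent standard-normal psychotic-like-experience trait.
    trait: float
    cape_p: int
    cape_n: int
    cape_d: int
    spatial_span: float
    #: perceived splash-centroid SD per likelihood condition (screen units).
    subj_lik_sd: dict[str, float] = field(default_factory=dict)
    #: perceived prior SD per prior condition (screen units).
    subj_prior_sd: dict[str, float] = field(default_factory=dict)
    #: SD of internal centroid-encoding noise; None means "use the subjective
    #: centroid SD of the trial's condition" (self-consistent observer).
    perceptual_noise_sd: Optional[float] = None
    motor_noise_sd: float = 0.02
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        for d in (self.subj_lik_sd, self.subj_prior_sd):
            for v in d.values():
                if v < 0:
                    raise ValueError("subjective SDs must be >= 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if not 20 <= self.cape_p <= 80:
            raise ValueError("cape_p outside instrument range [20, 80]")

    def subj_lik_var(self, lik_cond: str) -> float:
        return self.subj_lik_sd[lik_cond] ** 2

    def subj_prior_var(self, prior_cond: str) -> float:
        return self.subj_prior_sd[prior_cond] ** 2

    def perceptual_sd(self, lik_cond: str) -> float:
        if self.perceptual_noise_sd is not None:
            return self.perceptual_noise_sd
        return self.subj_lik_sd[lik_cond]

    def generating_weight(self, prior_cond: str, lik_cond: str) -> float:
        """The observer's Bayesian weight on the likelihood in one condition."""
        vp = self.subj_prior_var(prior_cond)
        vl = self.subj_lik_var(lik_cond)
        if vp + vl == 0:
            raise ValueError("both subjective variances are zero: weight undefined")
        return vp / (vp + vl)

    def generating_global_weight(self, design: TaskDesign, include_lapse: bool = True) -> float:
        """Population value of the pooled response-on-centroid regression slope.

        Pooling trials across the four conditions, the OLS slope converges to
        the average of the per-condition weights weighted by each condition's
        trial share and centroid variance; uniform lapses (mean = screen
        centre = prior mean) shrink it by ``1 - lapse_rate``.
        """
        num = 0.0
        den = 0.0
        for pc in ("narrow", "wide"):
            for lc in ("narrow", "wide"):
                var_mu_L = design.prior_var(pc) + design.centroid_var(lc)
                w = self.generating_weight(pc, lc)
                num += var_mu_L * w
                den += var_mu_L
        slope = num / den
        if include_lapse:
            slope *= 1.0 - self.lapse_rate
        return slope


class CohortSpec(BaseModel):
    """Generative specification of a synthetic cohort.

    ``beta_prior`` and ``beta_lik`` are the slopes of the latent trait on the
    log subjective prior / likelihood (centroid) variances; ``sigma_between``
    is the between-participant jitter SD on the same log scale.  Defaults are
    chosen so that the trait links to the two subjective-variance families
    are weakly positive and the implied trait–sensory-weight association is
    weakly positive as well (see docs/methods.md).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_participants: int = Field(default=200, ge=3)
    beta_prior: float = 0.10
    beta_lik: float = 0.04
    sigma_between: float = Field(default=0.55, ge=0.0)
    cape_p_mean: float = 27.0
    cape_p_sd: float = 6.0
    perceptual_noise_sd: Optional[float] = None
    motor_noise_sd: float = Field(default=0.02, ge=0.0)
    lapse_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    seed: int = 0

    @classmethod
    def null(cls, **overrides) -> "CohortSpec":
        """A cohort with no trait effect on either subjective variance."""
        overrides.setdefault("beta_prior", 0.0)
        overrides.setdefault("beta_lik", 0.0)
        return cls(**overrides)

    @classmethod
    def for_sw_correlation(cls, rho: float, **overrides) -> "CohortSpec":
        """Tune ``beta_prior`` for a target latent trait–sensory-weight correlation.

        The log variance ratio driving the weight is ``beta_prior * trait``
        plus two independent jitters of SD ``sigma_between``, so the latent
        Pearson correlation with the trait is
        ``beta_prior / sqrt(beta_prior^2 + 2 sigma_between^2)``; invert for
        ``beta_prior`` with ``beta_lik = 0``.
        """
        if not 0 < rho < 1:
            raise ValueError("rho must be in (0, 1)")
        sigma = overrides.get("sigma_between", cls.model_fields["sigma_between"].default)
        beta = rho * math.sqrt(2.0) * sigma / math.sqrt(1.0 - rho**2)
        overrides["beta_prior"] = beta
        overrides["beta_lik"] = 0.0
        return cls(**overrides)


def _lognormal_coeffs(mean_excess: float, sd: float) -> tuple[float, float]:
    """(a, b) such that exp(a + b Z) has the requested mean and SD."""
    b2 = math.log1p(sd**2 / mean_excess**2)
    a = math.log(mean_excess) - b2 / 2.0
    return a, math.sqrt(b2)


def _likert_score(trait_component: float, floor: int, ceil_: int, mean: float, sd: float) -> int:
    a, b = _lognormal_coeffs(mean - floor, sd)
    return int(np.clip(round(floor + math.exp(a + b * trait_component)), floor, ceil_))


def sample_observer(
    spec: CohortSpec,
    design: TaskDesign,
    participant_id: str,
    rng: np.random.Generator,
) -> ObserverParams:
    """Draw one observer from the cohort's generative model.

    Log subjective variances equal the log true variances plus a trait effect
    and a participant-level jitter (one jitter per family, shared across the
    family's two conditions, so the narrow/wide ratio stays at its true
    value).  CAPE-P is a clipped, rounded lognormal map of the trait,
    reproducing the instrument's right skew on its [20, 80] range.
    """
    trait = float(rng.standard_normal())
    jitter_prior, jitter_lik = rng.normal(0.0, spec.sigma_between, size=2)
    subj_prior_sd = {
        c: math.sqrt(design.prior_var(c) * math.exp(spec.beta_prior * trait + jitter_prior))
        for c in ("narrow", "wide")
    }
    subj_lik_sd = {
        c: math.sqrt(design.centroid_var(c) * math.exp(spec.beta_lik * trait + jitter_lik))
        for c in ("narrow", "wide")
    }
    cape_p = _likert_score(trait, 20, 80, spec.cape_p_mean, spec.cape_p_sd)
    # secondary covariates: partially trait-linked, purely synthetic plumbing
    z_n, z_d, z_s = rng.standard_normal(3)
    cape_n = _likert_score(0.6 * trait + 0.8 * z_n, 14, 56, 26.0, 7.0)
    cape_d = _likert_score(0.6 * trait + 0.8 * z_d, 8, 32, 15.0, 4.3)
    spatial_span = float(
        np.clip(round(5.5 + 1.2 * (-0.3 * trait + math.sqrt(1 - 0.09) * z_s), 1), 2.0, 9.0)
    )
    return ObserverParams(
        participant_id=participant_id,
        trait=trait,
        cape_p=cape_p,
        cape_n=cape_n,
        cape_d=cape_d,
        spatial_span=spatial_span,
        subj_lik_sd=subj_lik_sd,
        subj_prior_sd=subj_prior_sd,
        perceptual_noise_sd=spec.perceptual_noise_sd,
        motor_noise_sd=spec.motor_noise_sd,
        lapse_rate=spec.lapse_rate,
    )


def posterior_mean(mu_P: float, var_P, mu_L, var_L):
    """Posterior mean of two Gaussians (precision-weighted average)."""
    var_P = np.asarray(var_P, dtype=float)
    var_L = np.asarray(var_L, dtype=float)
    if np.any((var_P == 0) & (var_L == 0)):
        raise ValueError("both variances are zero: posterior weight undefined")
    with np.errstate(invalid="ignore"):
        w = np.where(np.isinf(var_P), 1.0, var_P / (var_P + var_L))
        w = np.where(np.isinf(var_L) & ~np.isinf(var_P), 0.0, w)
    out = (1.0 - w) * mu_P + w * np.asarray(mu_L, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def ideal_estimate(
    mu_L_perceived,
    params: ObserverParams,
    prior_cond: str,
    lik_cond: str,
    prior_mean: float = 0.0,
):
    """The observer's noiseless estimate: posterior mean with subjective variances."""
    return posterior_mean(
        prior_mean,
        params.subj_prior_var(prior_cond),
        mu_L_perceived,
        params.subj_lik_var(lik_cond),
    )


def _perceptual_sds(params: ObserverParams, lik_cond: np.ndarray) -> np.ndarray:
    if params.perceptual_noise_sd is not None:
        return np.full(len(lik_cond), params.perceptual_noise_sd)
    narrow = lik_cond == "narrow"
    return np.where(narrow, params.subj_lik_sd["narrow"], params.subj_lik_sd["wide"])


def _main_responses(
    mu_L: np.ndarray,
    prior_cond: np.ndarray,
    lik_cond: np.ndarray,
    params: ObserverParams,
    design: TaskDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(mu_L)
    perc_sd = _perceptual_sds(params, lik_cond)
    w_table = {
        (pc, lc): params.generating_weight(pc, lc)
        for pc in ("narrow", "wide")
        for lc in ("narrow", "wide")
    }
    prior_narrow = prior_cond == "narrow"
    lik_narrow = lik_cond == "narrow"
    w = np.select(
        [prior_narrow & lik_narrow, prior_narrow & ~lik_narrow, ~prior_narrow & lik_narrow],
        [w_table[("narrow", "narrow")], w_table[("narrow", "wide")], w_table[("wide", "narrow")]],
        default=w_table[("wide", "wide")],
    )
    perceived = mu_L + rng.normal(0.0, 1.0, size=n) * perc_sd
    resp = (1.0 - w) * design.prior_mean + w * perceived
    resp = resp + rng.normal(0.0, 1.0, size=n) * params.motor_noise_sd
    lapse = rng.random(n) < params.lapse_rate
    if lapse.any():
        resp[lapse] = rng.uniform(
            -design.screen_halfwidth, design.screen_halfwidth, size=int(lapse.sum())
        )
    return resp


def _likonly_responses(
    mu_L: np.ndarray,
    lik_cond: np.ndarray,
    params: ObserverParams,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(mu_L)
    perc_sd = _perceptual_sds(params, lik_cond)
    perceived = mu_L + rng.normal(0.0, 1.0, size=n) * perc_sd
    return perceived + rng.normal(0.0, 1.0, size=n) * params.motor_noise_sd


def simulate_response(trial, params: ObserverParams, rng: np.random.Generator, design: TaskDesign):
    """Simulate a single trial's response (scalar convenience wrapper)."""
    t = dict(trial)
    mu_L = np.array([float(t["mu_L"])])
    lik = np.array([t["lik_cond"]], dtype=object)
    if t["task"] == "likelihood_only":
        return float(_likonly_responses(mu_L, lik, params, rng)[0])
    prior = np.array([t["prior_cond"]], dtype=object)
    return float(_main_responses(mu_L, prior, lik, params, design, rng)[0])


@dataclass
class SimulatedCohort:
    """Everything a simulated study produces, plus the generating truth."""

    participants: pd.DataFrame
    trials_main: pd.DataFrame
    trials_likonly: pd.DataFrame
    observers: list[ObserverParams]


def simulate_cohort(spec: CohortSpec, design: TaskDesign) -> SimulatedCohort:
    """Simulate a full cohort: observers, both tasks, and responses.

    Each participant runs the 100-trial calibration task and then the 4x75
    main task.  Thrower order is counterbalanced: even-indexed participants
    follow the design's block order, odd-indexed the flipped order.  All
    randomness flows through per-participant streams derived from
    ``spec.seed``, so a cohort is reproducible and order-independent.
    """
    from .design import _likonly_arrays, _main_task_arrays

    observers: list[ObserverParams] = []
    part_rows = []
    main_chunks: list[dict] = []
    likonly_chunks: list[dict] = []
    flipped = design.flipped_block_order()
    for i in range(spec.n_participants):
        pid = f"P{i + 1:04d}"
        rng = participant_stream(spec.seed, pid)
        params = sample_observer(spec, design, pid, rng)
        observers.append(params)

        lo = _likonly_arrays(design, rng)
        lo["response"] = _likonly_responses(lo["mu_L"], lo["lik_cond"], params, rng)
        lo["participant_id"] = pid
        likonly_chunks.append(lo)

        order = design.block_prior_order if i % 2 == 0 else flipped
        mt = _main_task_arrays(design, rng, block_prior_order=order)
        mt["response"] = _main_responses(
            mt["mu_L"], mt["prior_cond"], mt["lik_cond"], params, design, rng
        )
        mt["participant_id"] = pid
        main_chunks.append(mt)

        age = int(np.clip(round(rng.normal(32.0, 11.0)), 18, 80))
        gender = str(rng.choice(["female", "male", "other"], p=[0.47, 0.5, 0.03]))
        part_rows.append(
            {
                "participant_id": pid,
                "cape_p": params.cape_p,
                "cape_n": params.cape_n,
                "cape_d": params.cape_d,
                "cape_total": params.cape_p + params.cape_n + params.cape_d,
                "spatial_span": params.spatial_span,
                "age": age,
                "gender": gender,
            }
        )
    participants = pd.DataFrame(part_rows, columns=PARTICIPANT_COLUMNS)
    return SimulatedCohort(
        participants=participants,
        trials_main=_stack_chunks("main", main_chunks, design),
        trials_likonly=_stack_chunks("likelihood_only", likonly_chunks, design),
        observers=observers,
    )


def _stack_chunks(task: str, chunks: list[dict], design: TaskDesign) -> pd.DataFrame:
    """Concatenate per-participant trial arrays into one trial table."""
    n_per = len(chunks[0]["mu_L"])
    data = {
        "participant_id": np.repeat([c["participant_id"] for c in chunks], n_per),
        "task": task,
    }
    for key in ("block_index", "trial_index", "prior_cond", "lik_cond"):
        data[key] = np.concatenate([c[key] for c in chunks])
    splashes = np.concatenate([c["splashes"] for c in chunks], axis=0)
    for j in range(design.n_splashes):
        data[f"splash_{j + 1}"] = splashes[:, j]
    for key in ("mu_L", "coin_pos", "response"):
        data[key] = np.concatenate([c[key] for c in chunks])
    return pd.DataFrame(data)  # key order matches TRIAL_COLUMNS
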