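"""Coin-task paradigm: design constants and stimulus-stream generation.

The task asks participants to place a "net" where they believe a hidden coin
fell into a pond.  On every trial five "splash" positions are drawn around the
(hidden) coin; the coin itself is drawn from a Gaussian prior centred on the
screen.  Prior spread is manipulated block-wise (two "throwers" of different
accuracy alternate between blocks) and splash spread trial-wise, yielding a
2x2 factorial design: {narrow, wide} prior x {narrow, wide} likelihood.

Coordinates are expressed in screen units on ``[-screen_halfwidth,
+screen_halfwidth]``.  With the default half-width 0.8 the screen width is
1.6, which is the unit system in which the canonical spreads are stated:
splash SD 0.096 (6% of width) / 0.24 (15%), prior SD 0.04 (2.5%) / 0.136
(8.5%).

A calibration task ("likelihood only") precedes the main task: splash sets
are shown without any prior structure and the target is, by construction, the
centre of the displayed splashes.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

__all__ = [
    "ConfigurationError",
    "TaskDesign",
    "TRIAL_COLUMNS",
    "make_design",
    "participant_stream",
    "sample_coin_position",
    "sample_splashes",
    "generate_main_task",
    "generate_likelihood_only_task",
    "score_trial",
]

#: Canonical column order of a trial table (one row per trial).
TRIAL_COLUMNS = [
    "participant_id",
    "task",
    "block_index",
    "trial_index",
    "prior_cond",
    "lik_cond",
    "splash_1",
    "splash_2",
    "splash_3",
    "splash_4",
    "splash_5",
    "mu_L",
    "coin_pos",
    "response",
]

_CONDS = ("narrow", "wide")


class ConfigurationError(ValueError):
    """Invalid task-design or run configuration."""


class TaskDesign(BaseModel):
    """Immutable bundle of the paradigm's constants.

    All lengths are in screen units (screen spans ``[-screen_halfwidth,
    +screen_halfwidth]``).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    screen_halfwidth: float = 0.8
    prior_sd_narrow: float = 0.04
    prior_sd_wide: float = 0.136
    splash_sd_narrow: float = 0.096
    splash_sd_wide: float = 0.24
    n_splashes: int = 5
    prior_mean: float = 0.0
    n_blocks: int = 4
    trials_per_block: int = 75
    n_likelihood_only_trials: int = 100
    #: half-width of the net; used only for gamified trial scoring.
    net_halfwidth: float = 0.04
    #: radius of the revealed coin; a trial scores if any part of the coin
    #: overlaps the net (scoring only, never used in analysis).
    coin_radius: float = 0.01
    block_prior_order: tuple[str, ...] = ("narrow", "wide", "narrow", "wide")
    #: if True, sampled positions are clipped to the screen.  Off by default
    #: so that sample moments match the generating parameters exactly.
    clip_positions: bool = False

    @model_validator(mode="after")
    def _check(self) -> "TaskDesign":
        for field in (
            "screen_halfwidth",
            "prior_sd_narrow",
            "prior_sd_wide",
            "splash_sd_narrow",
            "splash_sd_wide",
            "net_halfwidth",
        ):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.coin_radius < 0:
            raise ValueError("coin_radius must be non-negative")
        if self.prior_sd_narrow >= self.prior_sd_wide:
            raise ValueError("prior_sd_narrow must be < prior_sd_wide")
        if self.splash_sd_narrow >= self.splash_sd_wide:
            raise ValueError("splash_sd_narrow must be < splash_sd_wide")
        if self.n_splashes < 1:
            raise ValueError("n_splashes must be >= 1")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_likelihood_only_trials < 2 or self.n_likelihood_only_trials % 2:
            raise ValueError("n_likelihood_only_trials must be even and >= 2")
        if len(self.block_prior_order) != self.n_blocks:
            raise ValueError("block_prior_order must have n_blocks entries")
        for label in self.block_prior_order:
            if label not in _CONDS:
                raise ValueError(f"unknown prior label {label!r} in block_prior_order")
        for a, b in zip(self.block_prior_order, self.block_prior_order[1:]):
            if a == b:
                raise ValueError(
                    "block_prior_order must alternate (throwers A/B alternate between blocks)"
                )
        return self

    # -- convenience accessors -------------------------------------------
    def prior_sd(self, prior_cond: str) -> float:
        _check_cond(prior_cond, "prior_cond")
        return self.prior_sd_narrow if prior_cond == "narrow" else self.prior_sd_wide

    def splash_sd(self, lik_cond: str) -> float:
        _check_cond(lik_cond, "lik_cond")
        return self.splash_sd_narrow if lik_cond == "narrow" else self.splash_sd_wide

    def prior_var(self, prior_cond: str) -> float:
        return self.prior_sd(prior_cond) ** 2

    def centroid_var(self, lik_cond: str) -> float:
        """Variance of the splash centroid around the coin: splash_sd^2 / n."""
        return self.splash_sd(lik_cond) ** 2 / self.n_splashes

    def flipped_block_order(self) -> tuple[str, ...]:
        """The thrower order with A and B swapped (for counterbalancing)."""
        return tuple("wide" if c == "narrow" else "narrow" for c in self.block_prior_order)

    @property
    def n_main_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def _check_cond(label: str, what: str) -> None:
    if label not in _CONDS:
        raise ValueError(f"{what} must be one of {_CONDS}, got {label!r}")


def make_design(overrides: Mapping | None = None, **kwargs) -> TaskDesign:
    """Build a :class:`TaskDesign`, applying overrides to the defaults.

    Unknown fields and invalid values raise :class:`ConfigurationError`
    naming the offending field.
    """
    merged = dict(overrides or {})
    merged.update(kwargs)
    try:
        return TaskDesign(**merged)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<design>"
        raise ConfigurationError(f"invalid task design: {loc}: {first['msg']}") from err


def participant_stream(seed: int, participant_id: str, label: str = "") -> np.random.Generator:
    """Deterministic per-participant random stream.

    Derived by stable hashing of ``(seed, participant_id, label)`` so that a
    participant's stimuli and responses do not depend on cohort composition
    or iteration order.
    """
    digest = hashlib.sha256(f"{participant_id}|{label}".encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def _maybe_clip(design: TaskDesign, x: np.ndarray | float):
    if design.clip_positions:
        return np.clip(x, -design.screen_halfwidth, design.screen_halfwidth)
    return x


def sample_coin_position(
    design: TaskDesign,
    prior_cond: str,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw hidden coin position(s) from the block's Gaussian prior."""
    if prior_cond == "none":
        raise ValueError("coin positions are sampled in the main task only (prior_cond='none')")
    sd = design.prior_sd(prior_cond)
    return _maybe_clip(design, rng.normal(design.prior_mean, sd, size=size))


def sample_splashes(
    design: TaskDesign,
    coin_pos,
    lik_cond: str,
    rng: np.random.Generator,
):
    """Draw the splash set around the coin; return ``(splashes, mu_L)``.

    ``coin_pos`` may be a scalar (one trial, splashes shape ``(n_splashes,)``)
    or a length-n array (splashes shape ``(n, n_splashes)``); ``mu_L`` is the
    arithmetic mean of each splash set.
    """
    sd = design.splash_sd(lik_cond)
    coin = np.asarray(coin_pos, dtype=float)
    shape = coin.shape + (design.n_splashes,)
    splashes = rng.normal(coin[..., None], sd, size=shape)
    splashes = _maybe_clip(design, splashes)
    mu_L = splashes.mean(axis=-1)
    if np.ndim(coin_pos) == 0:
        return splashes, float(mu_L)
    return splashes, mu_L


def _block_lik_conditions(design: TaskDesign, block: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffled likelihood labels for one block, counts as even as possible.

    With an odd block length the extra trial goes to the narrow condition in
    even-numbered blocks and to the wide condition in odd-numbered blocks, so
    session totals balance exactly (e.g. 38/37 alternating -> 150/150).
    """
    n = design.trials_per_block
    n_narrow = (n + 1) // 2 if block % 2 == 0 else n // 2
    labels = np.array(["narrow"] * n_narrow + ["wide"] * (n - n_narrow))
    return rng.permutation(labels)


def _trial_frame(
    participant_id: str,
    task: str,
    block_index: np.ndarray,
    trial_index: np.ndarray,
    prior_cond: Iterable[str],
    lik_cond: Iterable[str],
    splashes: np.ndarray,
    mu_L: np.ndarray,
    coin_pos: np.ndarray,
) -> pd.DataFrame:
    data = {
        "participant_id": participant_id,
        "task": task,
        "block_index": np.asarray(block_index, dtype=int),
        "trial_index": np.asarray(trial_index, dtype=int),
        "prior_cond": list(prior_cond),
        "lik_cond": list(lik_cond),
    }
    for j in range(splashes.shape[1]):
        data[f"splash_{j + 1}"] = splashes[:, j]
    data["mu_L"] = mu_L
    data["coin_pos"] = coin_pos
    data["response"] = np.full(len(mu_L), np.nan)
    return pd.DataFrame(data, columns=TRIAL_COLUMNS[: 6 + splashes.shape[1]] + TRIAL_COLUMNS[-3:])


def _main_task_arrays(
    design: TaskDesign,
    rng: np.random.Generator,
    block_prior_order: Sequence[str] | None = None,
) -> dict:
    """Array-level main-task generation (one participant-session)."""
    order = tuple(block_prior_order) if block_prior_order is not None else design.block_prior_order
    if len(order) != design.n_blocks:
        raise ConfigurationError("block_prior_order must have n_blocks entries")
    n_b = design.trials_per_block
    n = design.n_main_trials
    prior_cond = np.empty(n, dtype=object)
    lik_cond = np.empty(n, dtype=object)
    coin = np.empty(n)
    splashes = np.empty((n, design.n_splashes))
    for b, pc in enumerate(order):
        _check_cond(pc, "prior_cond")
        sl = slice(b * n_b, (b + 1) * n_b)
        lik = _block_lik_conditions(design, b, rng)
        c = sample_coin_position(design, pc, rng, size=n_b)
        sp = np.empty((n_b, design.n_splashes))
        for cond in _CONDS:
            mask = lik == cond
            if mask.any():
                sp[mask], _ = sample_splashes(design, c[mask], cond, rng)
        prior_cond[sl] = pc
        lik_cond[sl] = lik
        coin[sl] = c
        splashes[sl] = sp
    return {
        "block_index": np.repeat(np.arange(1, design.n_blocks + 1), n_b),
        "trial_index": np.tile(np.arange(1, n_b + 1), design.n_blocks),
        "prior_cond": prior_cond,
        "lik_cond": lik_cond,
        "splashes": splashes,
        "mu_L": splashes.mean(axis=1),
        "coin_pos": coin,
    }


def _likonly_arrays(design: TaskDesign, rng: np.random.Generator) -> dict:
    """Array-level calibration-task generation (one participant-session)."""
    n = design.n_likelihood_only_trials
    lik = rng.permutation(np.array(["narrow"] * (n // 2) + ["wide"] * (n // 2), dtype=object))
    centres = rng.uniform(-0.5 * design.screen_halfwidth, 0.5 * design.screen_halfwidth, size=n)
    splashes = np.empty((n, design.n_splashes))
    for cond in _CONDS:
        mask = lik == cond
        if mask.any():
            splashes[mask], _ = sample_splashes(design, centres[mask], cond, rng)
    mu_L = splashes.mean(axis=1)
    return {
        "block_index": np.zeros(n, dtype=int),
        "trial_index": np.arange(1, n + 1),
        "prior_cond": np.full(n, "none", dtype=object),
        "lik_cond": lik,
        "splashes": splashes,
        "mu_L": mu_L,
        "coin_pos": mu_L.copy(),
    }


def _arrays_to_frame(participant_id: str, task: str, arrays: dict) -> pd.DataFrame:
    return _trial_frame(
        participant_id,
        task,
        arrays["block_index"],
        arrays["trial_index"],
        arrays["prior_cond"],
        arrays["lik_cond"],
        arrays["splashes"],
        arrays["mu_L"],
        arrays["coin_pos"],
    )


def generate_main_task(
    design: TaskDesign,
    rng: np.random.Generator,
    participant_id: str = "P0000",
    block_prior_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate the main-task trial table (responses left missing).

    Prior condition follows ``block_prior_order`` (the design's by default);
    likelihood condition is shuffled within block with counts counterbalanced
    across the session.
    """
    return _arrays_to_frame(
        participant_id, "main", _main_task_arrays(design, rng, block_prior_order)
    )


def generate_likelihood_only_task(
    design: TaskDesign,
    rng: np.random.Generator,
    participant_id: str = "P0000",
) -> pd.DataFrame:
    """Generate the calibration task: splash sets with no prior structure.

    Splash-set centres are drawn uniformly on the central half of the screen;
    the target ("coin") is defined as the centre of the displayed splashes,
    so ``coin_pos == mu_L`` on every trial and ``prior_cond == 'none'``.
    """
    return _arrays_to_frame(
        participant_id, "likelihood_only", _likonly_arrays(design, rng)
    )


def score_trial(design: TaskDesign, coin_pos, response):
    """Gamified point scoring: 1 iff any part of the coin lies within the net.

    Closed boundary: a gap exactly equal to ``net_halfwidth + coin_radius``
    still scores.  Never used in the analysis.
    """
    gap = np.abs(np.asarray(coin_pos, dtype=float) - np.asarray(response, dtype=float))
    hit = gap <= design.net_halfwidth + design.coin_radius
    if np.ndim(hit) == 0:
        return int(hit)
    return hit.astype(int)
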