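"""Synthetic careers and win/loss sequences with known ground truth.

Two career modes:

``null_iid``
    Scores drawn i.i.d. from a zero-inflated geometric family — the kind of
    heavy right tail and frequent ducks (zero scores) seen in batting
    careers, with no serial dependence. This is the null condition every
    calibration test runs against.

``hot_hawkes``
    A self-excited Hawkes process is simulated on the performance-time axis
    (thinning algorithm) and inverted through the subordination: the t-th
    score is round(1 / gap_t) clamped to [1, s_max]. Strong scores therefore
    arrive in genuine self-excited clusters, with the generating (mu,
    branching ratio) returned as ground truth.

Win/loss sequences use a two-state Markov chain: the first outcome is
Bernoulli(p_win); each later outcome repeats the previous one with
probability rho and is otherwise a fresh Bernoulli(p_win). rho = 0 is the
i.i.d. null; rho > 0 produces streakier sequences with the same marginal
win rate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np

from .hawkes_em import ExponentialKernel, HistogramKernel, ZeroKernel
from .io_model import CareerRecord, Discipline, Format, Outcome

__all__ = [
    "CareerSimConfig",
    "OutcomeSimConfig",
    "HorizonError",
    "SupercriticalError",
    "simulate_hawkes",
    "synthesize_career",
    "synthesize_outcomes",
]


class SupercriticalError(ValueError):
    """Kernel integral >= 1: the process would explode."""


class HorizonError(RuntimeError):
    """The requested number of events was not reached within the horizon."""


@dataclass(frozen=True)
class CareerSimConfig:
    """Ground-truth configuration for one synthetic career.

    mu is the background rate in events per unit performance time; with
    branching ratio n the stationary event rate is mu/(1-n), so the mean
    gap is (1-n)/mu and the typical score is its reciprocal. The defaults
    (mu=10, n=0.6, score mean 25) give cricket-scale batting scores.
    """

    career_length: int = 100
    mode: Literal["null_iid", "hot_hawkes"] = "null_iid"
    score_mean: float = 25.0
    zero_inflation: float = 0.08
    mu: float = 10.0
    branching: float = 0.6
    kernel_scale: float = 0.1
    s_max: int = 500
    horizon: float | None = None  # None -> adaptive (scaled to the target length)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.career_length < 1:
            raise ValueError("career_length must be >= 1")
        if not 0 <= self.branching < 1:
            raise ValueError("branching must be in [0, 1) (subcritical)")
        if self.score_mean <= 0:
            raise ValueError("score_mean must be > 0")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")


@dataclass(frozen=True)
class OutcomeSimConfig:
    length: int = 100
    p_win: float = 0.5
    persistence: float = 0.0  # rho: probability of repeating the last outcome
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0 <= self.p_win <= 1:
            raise ValueError("p_win must be in [0, 1]")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")


def simulate_hawkes(
    mu: float,
    kernel: HistogramKernel | ExponentialKernel | ZeroKernel,
    horizon: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate Hawkes event times on (0, horizon] by Ogata thinning.

    The proposal bound is recomputed from each event's *remaining* maximal
    kernel value, which stays valid for non-monotone histogram kernels.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if kernel.integral >= 1:
        raise SupercriticalError(
            f"kernel integral {kernel.integral:.3f} >= 1: process is supercritical"
        )
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    events: list[float] = []
    hist = np.empty(0)
    t = 0.0
    while t < horizon:
        lam_bar = mu + float(np.sum(kernel.max_remaining(t - hist))) if hist.size else mu
        if lam_bar <= 0:
            break
        t += rng.exponential(1.0 / lam_bar)
        if t > horizon:
            break
        lam_t = mu + (float(np.sum(kernel.value(t - hist))) if hist.size else 0.0)
        if rng.uniform() * lam_bar <= lam_t:
            events.append(t)
            hist = np.asarray(events)
            # prune history whose future contribution is negligible
            cutoff = getattr(kernel, "scale", None)
            prune = kernel.support if np.isfinite(kernel.support) else (
                46.0 * cutoff if cutoff else np.inf
            )
            if np.isfinite(prune):
                hist = hist[hist > t - prune]
    return np.asarray(events)


def _draw_scores(rng: np.random.Generator, n: int, mean: float, zero_inflation: float) -> np.ndarray:
    """Zero-inflated geometric on {0, 1, 2, ...} with the stated mean for the
    geometric component."""
    p = 1.0 / (1.0 + mean)
    scores = rng.geometric(p, size=n) - 1
    if zero_inflation > 0:
        scores[rng.uniform(size=n) < zero_inflation] = 0
    return scores.astype(np.int64)


def synthesize_career(config: CareerSimConfig) -> tuple[CareerRecord, dict]:
    """Generate one synthetic career plus its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    L = config.career_length

    if config.mode == "null_iid":
        scores = _draw_scores(rng, L, config.score_mean, config.zero_inflation)
    elif config.mode == "hot_hawkes":
        kernel = ExponentialKernel(branching=config.branching, scale=config.kernel_scale)
        rate = config.mu / (1.0 - config.branching)
        adaptive = config.horizon is None
        horizon = 1.5 * L / rate if adaptive else config.horizon
        events = simulate_hawkes(config.mu, kernel, horizon, rng)
        tries = 0
        while events.size < L:
            tries += 1
            if not adaptive or tries > 6:
                raise HorizonError(
                    f"only {events.size}/{L} events within horizon {horizon:.3g}; "
                    "increase mu, extend the horizon, or reduce career_length"
                )
            horizon *= 2.0
            events = simulate_hawkes(config.mu, kernel, horizon, rng)
        gaps = np.diff(events[:L], prepend=0.0)
        scores = np.clip(np.round(1.0 / gaps), 1, config.s_max).astype(np.int64)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    career = CareerRecord(
        player_id=f"sim-{config.mode}-{config.seed}",
        format=Format.ODI,
        discipline=Discipline.BATTING,
        scores=scores,
    )
    truth = asdict(config)
    if config.mode == "hot_hawkes":
        truth["event_gaps"] = gaps.tolist()  # pre-rounding inter-event gaps
    return career, truth


def synthesize_outcomes(config: OutcomeSimConfig) -> tuple[Outcome, ...]:
    """Win/loss sequence with optional Markov persistence (see module docs)."""
    rng = np.random.default_rng(config.seed)
    wins = np.empty(config.length, dtype=bool)
    wins[0] = rng.uniform() < config.p_win
    repeat = rng.uniform(size=config.length) < config.persistence
    fresh = rng.uniform(size=config.length) < config.p_win
    for i in range(1, config.length):
        wins[i] = wins[i - 1] if repeat[i] else fresh[i]
    return tuple(Outcome.WIN if w else Outcome.LOSS for w in wins)
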