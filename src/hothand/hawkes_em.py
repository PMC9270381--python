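"""Self-exciting Hawkes model on the performance-time axis.

The conditional intensity is

    lambda(t) = mu + sum_{t_i < t} phi(t - t_i),

with a non-negative background rate mu and a memory kernel phi that is left
nonparametric: a histogram with bin edges 0 = e_0 < e_1 < ... < e_B and
heights h_1..h_B. The branching ratio

    n = integral_0^inf phi(t) dt = sum_b h_b (e_b - e_{b-1})

is the mean number of first-generation events triggered per event; n -> 1
means strong self-excitation, n = 0 a homogeneous Poisson process.

Fitting uses expectation–maximization over the latent branching structure:
the E-step assigns each event a probability of being background
(p_ii ∝ mu) or triggered by each earlier event (p_ij ∝ phi(t_i - t_j));
the M-step re-estimates mu and the histogram heights from those
responsibilities with a boundary correction (a lag bin only counts events
whose bin window fits inside the observation span). Everything is
deterministic given the events and the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HistogramKernel",
    "ExponentialKernel",
    "HawkesModel",
    "FitResult",
    "intensity",
    "loglik",
    "em_fit",
    "branching_ratio",
    "residual_gof",
]


@dataclass(frozen=True)
class HistogramKernel:
    """Piecewise-constant memory kernel on bins (e_{b-1}, e_b]; zero beyond."""

    edges: np.ndarray  # shape (B+1,), edges[0] == 0, strictly increasing
    heights: np.ndarray  # shape (B,), non-negative

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must start at 0 and be strictly increasing")
        if heights.shape != (edges.size - 1,):
            raise ValueError("need one height per bin")
        if np.any(heights < 0):
            raise ValueError("kernel heights must be non-negative")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "heights", heights)

    @property
    def support(self) -> float:
        return float(self.edges[-1])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def integral(self) -> float:
        """Branching ratio n: exact histogram integral sum_b h_b * width_b."""
        return float(np.dot(self.heights, self.widths))

    def value(self, lag: np.ndarray | float) -> np.ndarray:
        """phi(lag); 0 for lag <= 0 or beyond the support."""
        lag = np.asarray(lag, dtype=float)
        idx = np.searchsorted(self.edges, lag, side="left") - 1
        inside = (lag > 0) & (lag <= self.support)
        out = np.zeros_like(lag)
        out[inside] = self.heights[np.clip(idx[inside], 0, self.heights.size - 1)]
        return out

    def cdf(self, lag: np.ndarray | float) -> np.ndarray:
        """Phi(lag) = integral_0^lag phi; piecewise linear, saturating at n."""
        lag = np.asarray(lag, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self.heights * self.widths)])
        clipped = np.clip(lag, 0.0, self.support)
        idx = np.clip(np.searchsorted(self.edges, clipped, side="left") - 1, 0, self.heights.size - 1)
        return cum[idx] + self.heights[idx] * (clipped - self.edges[idx])

    def max_remaining(self, lag: np.ndarray | float) -> np.ndarray:
        """sup_{l >= lag} phi(l) — the thinning bound for a possibly
        non-monotone histogram."""
        lag = np.asarray(lag, dtype=float)
        suffix = np.maximum.accumulate(self.heights[::-1])[::-1]
        idx = np.clip(np.searchsorted(self.edges, lag, side="left") - 1, 0, self.heights.size - 1)
        out = suffix[idx]
        return np.where(lag >= self.support, 0.0, out)


@dataclass(frozen=True)
class ExponentialKernel:
    """phi(l) = (n / scale) * exp(-l / scale): the standard parametric
    comparison kernel, used by the simulator as ground truth."""

    branching: float
    scale: float

    def __post_init__(self) -> None:
        if self.branching < 0 or self.scale <= 0:
            raise ValueError("need branching >= 0 and scale > 0")

    @property
    def support(self) -> float:
        return np.inf

    @property
    def integral(self) -> float:
        return float(self.branching)

    def value(self, lag):
        lag = np.asarray(lag, dtype=float)
        return np.where(lag > 0, self.branching / self.scale * np.exp(-lag / self.scale), 0.0)

    def cdf(self, lag):
        lag = np.asarray(lag, dtype=float)
        return self.branching * -np.expm1(-np.clip(lag, 0, None) / self.scale)

    def max_remaining(self, lag):
        lag = np.asarray(lag, dtype=float)
        return self.value(np.clip(lag, 1e-300, None)) if np.ndim(lag) else self.value(max(lag, 1e-300))


@dataclass(frozen=True)
class ZeroKernel:
    """phi ≡ 0 (homogeneous Poisson); convenient null model."""

    support: float = 0.0
    integral: float = 0.0

    def value(self, lag):
        return np.zeros_like(np.asarray(lag, dtype=float))

    def cdf(self, lag):
        return np.zeros_like(np.asarray(lag, dtype=float))

    def max_remaining(self, lag):
        return np.zeros_like(np.asarray(lag, dtype=float))


@dataclass(frozen=True)
class HawkesModel:
    mu: float
    kernel: HistogramKernel | ExponentialKernel | ZeroKernel

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("background rate mu must be >= 0")

    @property
    def branching_ratio(self) -> float:
        return float(self.kernel.integral)

    @property
    def supercritical(self) -> bool:
        return self.branching_ratio >= 1.0


@dataclass
class FitResult:
    model: HawkesModel
    loglik_trace: np.ndarray
    iterations: int
    converged: bool
    config: dict = field(default_factory=dict)

    @property
    def branching_ratio(self) -> float:
        return self.model.branching_ratio


def branching_ratio(model: HawkesModel) -> float:
    """n = integral of the kernel (exact for the histogram)."""
    return model.branching_ratio


def _check_sorted(events: np.ndarray) -> np.ndarray:
    events = np.asarray(events, dtype=float)
    if events.size and np.any(np.diff(events) < 0):
        raise ValueError("event history must be sorted")
    return events


def intensity(model: HawkesModel, history: Sequence[float], t: float) -> float:
    """lambda(t) = mu + sum over strictly earlier events of phi(t - t_i)."""
    history = _check_sorted(np.asarray(history, dtype=float))
    if t < 0:
        raise ValueError("t must be >= 0")
    past = history[history < t]
    if past.size == 0:
        return float(model.mu)
    return float(model.mu + model.kernel.value(t - past).sum())


def loglik(
    model: HawkesModel,
    events: Sequence[float],
    window: tuple[float, float],
    history: Sequence[float] | None = None,
) -> float:
    """Point-process log-likelihood of ``events`` on the window (a, b]:

        sum_i log lambda(t_i) - integral_a^b lambda(s) ds,

    with lambda conditioned on ``history`` (events at times <= a) as well as
    earlier in-window events. The compensator integral is exact for
    piecewise-constant kernels. Returns -inf if lambda vanishes at an event
    (degenerate fit).
    """
    a, b = float(window[0]), float(window[1])
    if b < a:
        raise ValueError("window must satisfy a <= b")
    events = _check_sorted(events)
    history = _check_sorted(history if history is not None else [])
    if events.size and (events.min() <= a or events.max() > b):
        raise ValueError("events must lie in (a, b]")
    if history.size and history.max() > a:
        raise ValueError("conditioning history must be <= window start")

    all_src = np.concatenate([history, events])  # sources of excitation
    log_term = 0.0
    for t in events:
        past = all_src[all_src < t]
        lam = model.mu + (model.kernel.value(t - past).sum() if past.size else 0.0)
        if lam <= 0:
            return -np.inf
        log_term += np.log(lam)

    # compensator: mu*(b-a) + sum over sources of Phi(b - t_s) - Phi(a - t_s)
    comp = model.mu * (b - a)
    if all_src.size:
        comp += float(np.sum(model.kernel.cdf(b - all_src) - model.kernel.cdf(a - all_src)))
    return float(log_term - comp)


def _default_support(events: np.ndarray) -> float:
    gaps = np.diff(events)
    if gaps.size == 0:
        return 1.0
    q = float(np.quantile(gaps, 0.95))
    return 2.0 * q if q > 0 else 2.0 * float(gaps.max() if gaps.max() > 0 else 1.0)


def em_fit(
    events: Sequence[float],
    horizon: float,
    n_bins: int = 8,
    support: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Nonparametric-kernel Hawkes EM on events in (0, horizon].

    The kernel support defaults to twice the 95th percentile of the observed
    inter-event gaps, divided into ``n_bins`` equal bins. Initialization is
    mu_0 = 0.5 N/T with a uniform kernel of branching ratio 0.5. The
    per-iteration log-likelihood trace is non-decreasing (EM guarantee);
    convergence is declared when its relative change drops below ``tol``.
    """
    events = _check_sorted(events)
    T = float(horizon)
    N = events.size
    if N < 10:
        raise ValueError(f"need at least 10 events to fit, got {N}")
    if T <= 0 or events.max() > T:
        raise ValueError("horizon must be positive and cover all events")
    if support is None:
        support = _default_support(events)
    if support <= 0:
        raise ValueError("kernel support must be > 0")

    edges = np.linspace(0.0, support, n_bins + 1)
    widths = np.diff(edges)

    # lag pairs (i, j<i) with 0 < t_i - t_j <= support, flattened
    lefts = np.searchsorted(events, events - support, side="left")
    counts = np.arange(N) - lefts
    pair_i = np.repeat(np.arange(N), counts)
    pair_j = np.concatenate([np.arange(l, i) for i, l in enumerate(lefts)]) if counts.sum() else np.empty(0, int)
    lags = events[pair_i] - events[pair_j]
    keep = lags > 0  # simultaneous events carry no excitation
    pair_i, lags = pair_i[keep], lags[keep]
    bin_idx = np.clip(np.searchsorted(edges, lags, side="left") - 1, 0, n_bins - 1)

    # boundary correction: only events whose bin-b window fits in (0, T]
    n_exposed = np.searchsorted(events, T - edges[1:], side="right").astype(float)
    exposure = widths * n_exposed

    # compensator pieces that depend on the heights only linearly:
    # integral of sum phi(. - t_j) over (0,T] = sum_b h_b * overlap_b where
    # overlap_b = total length of bin-b lag windows inside the horizon
    tail = np.clip(T - events[:, None], 0.0, None)  # (N, 1)
    overlap = np.clip(tail - edges[:-1][None, :], 0.0, widths[None, :]).sum(axis=0)

    mu = 0.5 * N / T
    heights = np.full(n_bins, 0.5 / support)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        phi_vals = heights[bin_idx]
        lam = mu + np.bincount(pair_i, weights=phi_vals, minlength=N)
        ll = float(np.sum(np.log(lam)) - mu * T - np.dot(heights, overlap))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
        # E-step responsibilities, M-step in one pass
        p_bg = mu / lam
        w = phi_vals / lam[pair_i]
        mu = float(p_bg.sum()) / T
        with np.errstate(invalid="ignore", divide="ignore"):
            heights = np.where(
                exposure > 0,
                np.bincount(bin_idx, weights=w, minlength=n_bins) / np.where(exposure > 0, exposure, 1.0),
                0.0,
            )

    model = HawkesModel(mu=mu, kernel=HistogramKernel(edges, heights))
    return FitResult(
        model=model,
        loglik_trace=np.asarray(trace),
        iterations=it,
        converged=converged,
        config={"n_bins": n_bins, "support": float(support), "tol": tol,
                "max_iter": max_iter, "horizon": T, "n_events": int(N)},
    )


def residual_gof(
    model: HawkesModel, events: Sequence[float], horizon: float
) -> tuple[np.ndarray, float, float]:
    """Time-rescaling goodness of fit.

    The compensator Lambda(t) = mu t + sum_{t_i < t} Phi(t - t_i) maps the
    events to a unit-rate Poisson process under the true model, so the
    rescaled gaps Lambda(t_i) - Lambda(t_{i-1}) should be Exp(1); they are
    tested with a one-sample KS test. Returns (gaps, KS statistic, p-value).
    """
    events = _check_sorted(events)
    if events.size < 10:
        raise ValueError("need at least 10 events for the residual test")
    lam_int = np.empty(events.size)
    for i, t in enumerate(events):
        past = events[:i]
        lam_int[i] = model.mu * t + (float(model.kernel.cdf(t - past).sum()) if past.size else 0.0)
    gaps = np.diff(lam_int, prepend=0.0)
    stat, p = stats.kstest(gaps, "expon")
    return gaps, float(stat), float(p)
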