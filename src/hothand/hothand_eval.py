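"""Per-career hot-hand evaluation against shuffle-null controls.

The experiment, run independently for every career (or team series viewed
as a pseudo-career):

1. Split the career chronologically: first 80% of games train, the rest
   validate.
2. Transform both parts to performance time, fit the nonparametric Hawkes
   model on the training segment, and score the validation segment's
   log-likelihood conditioned on the training history -> L_model.
3. Repeat with the training *scores* shuffled (validation untouched —
   its stamps are bit-identical because the total training time is a
   permutation invariant) -> an ensemble of control log-likelihoods.
4. delta = (L_model - median control) / median control, plus two p-values:
   a one-sided Wilcoxon signed-rank test on the differences
   L_model - L_control_i, and an add-one permutation rank p-value
   (1 + #{controls >= L_model}) / (n_controls + 1).
5. Branching ratios: n from a fit to the full career versus an ensemble of
   fits to whole-career shuffles, with the same two tests.

The permutation rank p is the calibrated test: under the no-hot-hand null
the real ordering is exchangeable with its shuffles, so the rank of the
real statistic in the control ensemble is uniform and the test is exact.
The signed-rank p is reported as a diagnostic only — its 100 differences
share the one random L_model, which makes it badly anticonservative (it
essentially asks whether L_model beats the control median, a coin flip
under the null) — so per-career significance uses the permutation p.

Cohort-level: the count k of significant careers out of N is weighed
against Binomial(N, alpha) — the number of false rejections expected if no
career were hot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hawkes_em import FitResult, em_fit, loglik
from .io_model import CareerRecord
from .performance_time import DEFAULT_S_MIN, to_performance_time

logger = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "EvaluationResult",
    "CohortSummary",
    "split_career",
    "evaluate_career",
    "binomial_meta",
    "cohort_summary",
    "wilcoxon_greater",
    "permutation_rank_p",
]


@dataclass(frozen=True)
class EvalConfig:
    """Knobs of the evaluation experiment (shuffle counts, split, EM set-up)."""

    train_fraction: float = 0.8
    n_shuffles: int = 100
    s_min: float = DEFAULT_S_MIN
    n_bins: int = 8
    support: float | None = None  # None -> per-career gap-quantile rule
    tol: float = 1e-6
    max_iter: int = 500
    compute_loglik: bool = True
    compute_branching: bool = True
    max_invalid_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_shuffles < 0:
            raise ValueError("n_shuffles must be >= 0")


@dataclass
class EvaluationResult:
    player_id: str
    L_model: float = np.nan
    L_controls: np.ndarray = field(default_factory=lambda: np.empty(0))
    delta: float = np.nan
    wilcoxon_p_loglik: float = np.nan
    perm_p_loglik: float = np.nan
    n_real: float = np.nan
    n_nulls: np.ndarray = field(default_factory=lambda: np.empty(0))
    wilcoxon_p_branching: float = np.nan
    perm_p_branching: float = np.nan
    n_invalid: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def control_median(self) -> float:
        return float(np.median(self.L_controls)) if self.L_controls.size else np.nan

    @property
    def null_median(self) -> float:
        return float(np.median(self.n_nulls)) if self.n_nulls.size else np.nan

    @property
    def model_beats_control(self) -> bool:
        return bool(self.L_model > self.control_median)


@dataclass(frozen=True)
class CohortSummary:
    n_careers: int
    k_significant: int
    fraction_significant: float
    meta_p_at_least: float  # P(X >= k) under Binomial(N, alpha)
    meta_p_exactly: float
    fraction_model_beats_control: float
    alpha: float
    which_test: str


def split_career(
    career: CareerRecord, train_fraction: float = 0.8
) -> tuple[CareerRecord, CareerRecord]:
    """Chronological split: first floor(train_fraction * tau) games train,
    the remainder validate."""
    tau = career.career_length
    n_train = int(np.floor(train_fraction * tau))
    if n_train < 1 or tau - n_train < 2:
        raise ValueError(
            f"career {career.player_id!r}: tau={tau} leaves fewer than 2 validation games"
        )
    return career.with_scores(career.scores[:n_train]), career.with_scores(career.scores[n_train:])


def wilcoxon_greater(diffs: np.ndarray) -> float:
    """One-sample Wilcoxon signed-rank p-value, alternative 'greater'.

    Exact null distribution for <= 25 non-zero pairs without ties; the
    normal approximation with tie/zero corrections otherwise.
    """
    diffs = np.asarray(diffs, float)
    diffs = diffs[np.isfinite(diffs)]
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0
    exact_ok = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
    method = "exact" if exact_ok else "approx"
    return float(stats.wilcoxon(diffs, alternative="greater", method=method).pvalue)


def permutation_rank_p(observed: float, ensemble: np.ndarray) -> float:
    """Add-one permutation p-value: probability, under exchangeability, that
    a control value is at least the observed one. Exact under the shuffle
    null; never returns 0."""
    ensemble = np.asarray(ensemble, float)
    ensemble = ensemble[np.isfinite(ensemble)]
    if not np.isfinite(observed) or ensemble.size == 0:
        return np.nan
    return float((1 + (ensemble >= observed).sum()) / (ensemble.size + 1))


def _validation_loglik(fit: FitResult, train_stamps: np.ndarray, val_stamps: np.ndarray) -> float:
    a = float(train_stamps[-1])
    b = float(val_stamps[-1])
    return loglik(fit.model, val_stamps, (a, b), history=train_stamps)


def evaluate_career(
    career: CareerRecord,
    config: EvalConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> EvaluationResult:
    """Run the full shuffle-control experiment for one career."""
    config = config or EvalConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    result = EvaluationResult(player_id=career.player_id)

    if config.compute_loglik:
        train, val = split_career(career, config.train_fraction)
        train_pt = to_performance_time(train, config.s_min)
        full_pt = to_performance_time(career, config.s_min)
        # validation stamps continue from the training end; the offset
        # sum(1/S~) over training is invariant under training shuffles
        val_stamps = full_pt.stamps[train.career_length:]

        def fit_and_score(train_scores: np.ndarray) -> float:
            pt = to_performance_time(career.with_scores(train_scores), config.s_min)
            fit = em_fit(
                pt.stamps, pt.horizon, n_bins=config.n_bins,
                support=config.support, tol=config.tol, max_iter=config.max_iter,
            )
            return _validation_loglik(fit, pt.stamps, val_stamps)

        result.L_model = fit_and_score(train.scores)
        controls = np.asarray(
            [fit_and_score(rng.permutation(train.scores)) for _ in range(config.n_shuffles)]
        )
        valid = np.isfinite(controls)
        result.n_invalid += int((~valid).sum())
        result.L_controls = controls[valid]
        if not np.isfinite(result.L_model):
            result.flags.append("degenerate_model_fit")
        elif result.L_controls.size:
            med = result.control_median
            result.delta = (result.L_model - med) / med
            result.wilcoxon_p_loglik = wilcoxon_greater(result.L_model - result.L_controls)
            result.perm_p_loglik = permutation_rank_p(result.L_model, result.L_controls)

    if config.compute_branching:
        full_pt = to_performance_time(career, config.s_min)

        def fit_branching(scores: np.ndarray) -> float:
            pt = to_performance_time(career.with_scores(scores), config.s_min)
            fit = em_fit(
                pt.stamps, pt.horizon, n_bins=config.n_bins,
                support=config.support, tol=config.tol, max_iter=config.max_iter,
            )
            return fit.branching_ratio

        result.n_real = fit_branching(career.scores)
        nulls = np.asarray(
            [fit_branching(rng.permutation(career.scores)) for _ in range(config.n_shuffles)]
        )
        valid = np.isfinite(nulls)
        result.n_invalid += int((~valid).sum())
        result.n_nulls = nulls[valid]
        if result.n_nulls.size:
            result.wilcoxon_p_branching = wilcoxon_greater(result.n_real - result.n_nulls)
            result.perm_p_branching = permutation_rank_p(result.n_real, result.n_nulls)

    expected = config.n_shuffles * (int(config.compute_loglik) + int(config.compute_branching))
    if expected and result.n_invalid > config.max_invalid_fraction * expected:
        result.flags.append("unevaluable")
        logger.warning(
            "career %s: %d/%d degenerate fits", career.player_id, result.n_invalid, expected
        )
    return result


def binomial_meta(k: int, n: int, p: float = 0.05, mode: str = "more_than") -> float:
    """Probability of exactly k (mode='exactly') or more than k
    (mode='more_than') successes under Binomial(n, p); exact summation."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if mode == "exactly":
        return float(stats.binom.pmf(k, n, p))
    if mode == "more_than":
        return float(stats.binom.sf(k, n, p))
    raise ValueError(f"unknown mode {mode!r}")


def cohort_summary(
    results: list[EvaluationResult],
    alpha: float = 0.05,
    which_test: str = "loglik",
) -> CohortSummary:
    """Count significant careers and weigh the count against the false-positive
    expectation Binomial(N, alpha)."""
    usable = [r for r in results if "unevaluable" not in r.flags]
    if not usable:
        raise ValueError("no evaluable career in the cohort")
    attr = {
        "loglik": "perm_p_loglik",
        "branching": "perm_p_branching",
        "loglik_wilcoxon": "wilcoxon_p_loglik",
        "branching_wilcoxon": "wilcoxon_p_branching",
    }[which_test]
    pvals = np.asarray([getattr(r, attr) for r in usable])
    valid = np.isfinite(pvals)
    n = int(valid.sum())
    k = int((pvals[valid] < alpha).sum())
    beats = [r.model_beats_control for r in usable if np.isfinite(r.L_model) and r.L_controls.size]
    at_least = 1.0 if k == 0 else binomial_meta(k - 1, n, alpha, "more_than")
    return CohortSummary(
        n_careers=n,
        k_significant=k,
        fraction_significant=k / n if n else np.nan,
        meta_p_at_least=at_least if n else np.nan,
        meta_p_exactly=binomial_meta(k, n, alpha, "exactly") if n else np.nan,
        fraction_model_beats_control=float(np.mean(beats)) if beats else np.nan,
        alpha=alpha,
        which_test=which_test,
    )
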