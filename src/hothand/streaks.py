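"""Winning-streak statistics against permutation nulls.

A winning streak is a maximal run of consecutive wins; anything that is not
a win (loss, draw, tie, no-result) terminates it. For one team's observed
streak table {length n -> frequency f} the null is an ensemble of uniform
permutations of the outcome sequence (win count preserved), from which two
Monte-Carlo tail probabilities are estimated per observed (n, f):

    p(n)   — probability a null trajectory contains a streak of length >= n;
    p(n_f) — probability it contains at least f maximal streaks of
             length >= n (so p(n_1) == p(n)).

Both use the add-one correction (count+1)/(M+1) so they never vanish.
Because one team yields several (n, f) tests, the raw p-values pass through
the standard multiple-testing corrections (Bonferroni, Holm, Hochberg,
Benjamini-Hochberg, Benjamini-Yekutieli; all five are reported). A streak is
labelled ``extreme`` when either adjusted p(n) or adjusted p(n_f) clears the
significance level under the headline correction (Holm by default),
``probable`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_model import Outcome

__all__ = [
    "StreakTable",
    "StreakSignificance",
    "CORRECTION_METHODS",
    "extract_streaks",
    "null_streak_ensemble",
    "streak_pvalues",
    "adjust_pvalues",
    "flag_extreme",
]

#: method name -> statsmodels identifier
CORRECTION_METHODS: dict[str, str] = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "benjamini_hochberg": "fdr_bh",
    "benjamini_yekutieli": "fdr_by",
}

DEFAULT_CORRECTION = "holm"


@dataclass(frozen=True)
class StreakTable:
    """Maximal win-run lengths n -> count f for one outcome sequence."""

    counts: dict[int, int]
    total_wins: int

    @property
    def max_length(self) -> int:
        return max(self.counts, default=0)

    def at_least(self, n: int) -> int:
        """Number of maximal streaks of length >= n."""
        return sum(f for length, f in self.counts.items() if length >= n)


@dataclass
class StreakSignificance:
    """Raw and adjusted p-values for each observed (length, frequency)."""

    lengths: np.ndarray
    frequencies: np.ndarray
    p_n: np.ndarray
    p_nf: np.ndarray
    adjusted: dict = field(default_factory=dict)  # method -> (adj p_n, adj p_nf)
    labels: list = field(default_factory=list)


def _is_win(outcome) -> bool:
    return outcome == Outcome.WIN or str(outcome).strip().lower() in {"win", "w", "won"}


def extract_streaks(outcomes: Sequence) -> StreakTable:
    """Tabulate maximal runs of consecutive wins."""
    counts: dict[int, int] = {}
    run = 0
    total = 0
    for o in outcomes:
        if _is_win(o):
            run += 1
            total += 1
        elif run:
            counts[run] = counts.get(run, 0) + 1
            run = 0
    if run:
        counts[run] = counts.get(run, 0) + 1
    return StreakTable(counts=counts, total_wins=total)


def null_streak_ensemble(
    outcomes: Sequence,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[StreakTable]:
    """Streak tables of uniformly permuted copies of the outcome sequence."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.asarray(list(outcomes), dtype=object)
    return [extract_streaks(rng.permutation(arr)) for _ in range(n_shuffles)]


def streak_pvalues(
    observed: StreakTable, ensemble: Iterable[StreakTable]
) -> StreakSignificance:
    """Monte-Carlo tail p-values p(n) and p(n_f) for every observed (n, f)."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("null ensemble is empty")
    m = len(ensemble)
    lengths = np.asarray(sorted(observed.counts), dtype=int)
    freqs = np.asarray([observed.counts[n] for n in lengths], dtype=int)

    max_lengths = np.asarray([t.max_length for t in ensemble])
    p_n = np.empty(lengths.size)
    p_nf = np.empty(lengths.size)
    for i, (n, f) in enumerate(zip(lengths, freqs)):
        p_n[i] = ((max_lengths >= n).sum() + 1) / (m + 1)
        hits = sum(1 for t in ensemble if t.at_least(int(n)) >= f)
        p_nf[i] = (hits + 1) / (m + 1)
    return StreakSignificance(lengths=lengths, frequencies=freqs, p_n=p_n, p_nf=p_nf)


def adjust_pvalues(pvalues: Sequence[float], method: str) -> np.ndarray:
    """Adjusted p-values for one correction method, clipped to 1."""
    if method not in CORRECTION_METHODS:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(CORRECTION_METHODS)}"
        )
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(multipletests(p, method=CORRECTION_METHODS[method])[1], 1.0)


def flag_extreme(
    sig: StreakSignificance,
    alpha: float = 0.05,
    correction: str = DEFAULT_CORRECTION,
) -> list[str]:
    """Label each observed streak 'extreme' if either adjusted p(n) or
    adjusted p(n_f) is below alpha under the chosen correction, else
    'probable'. Fills ``sig.adjusted`` for all methods and ``sig.labels``."""
    for method in CORRECTION_METHODS:
        sig.adjusted[method] = (
            adjust_pvalues(sig.p_n, method),
            adjust_pvalues(sig.p_nf, method),
        )
    adj_n, adj_nf = sig.adjusted[correction]
    sig.labels = [
        "extreme" if (pn < alpha or pnf < alpha) else "probable"
        for pn, pnf in zip(adj_n, adj_nf)
    ]
    return sig.labels
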