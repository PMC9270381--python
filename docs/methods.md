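# Methods

## Data model and population

A career is an ordered sequence of non-negative integer scores S(t),
t = 1..τ, for one player, one format (ODI or Test) and one discipline
(batting or bowling); game order is an explicit integer index column, not a
date. Analyses run on careers with at least 30 games (inclusive filter):
below that the Hawkes fit is too poorly constrained to be meaningful, and
the evaluation split would leave almost no validation data. Team series
carry one performance value per game (the sum of the individual scores in
that game) plus a win/loss/other outcome; draws, ties and no-results all
map to `other`. A team series is evaluated by viewing it as a pseudo-career,
so the individual and team analyses share one code path.

## The performance-time subordination

H(t) = Σ_{i≤t} 1/S̃(i) maps the career onto a strictly increasing sequence
of event stamps: a high score contributes a small increment, so runs of
strong performances become tight clusters of points. The map is exactly
invertible (S = 1/ΔH) for positive scores.

**Zero scores.** 1/S is undefined at S = 0, and ducks are common in batting
careers. The package floors the score at `s_min` (default 0.5, a config
knob recorded in every output): a duck then contributes the largest
possible increment (2.0), strictly above the worst positive score's
increment (1.0), preserving the worse-score ⇒ longer-gap ordering while
keeping H finite. This is the single most consequential free choice in the
whole pipeline; results for heavily duck-laden careers should be checked
for sensitivity to it. The H axis is deliberately not rescaled per player —
the Hawkes fit is per-career, so the overall scale is absorbed by μ and the
kernel support.

## Hawkes model and EM estimation

Intensity λ(t) = μ + Σ_{t_i<t} φ(t − t_i) with a histogram kernel
(piecewise constant on B bins over (0, A]). The branching ratio
n = ∫φ = Σ h_b·w_b is the mean number of directly triggered events per
event; n → 1 means strong self-excitation, n = 0 a homogeneous Poisson
process.

Fitting is EM over the latent branching structure. E-step: event i is
background with responsibility μ/λ(t_i) and triggered by an earlier event j
with responsibility φ(t_i − t_j)/λ(t_i) (responsibilities sum to one per
event by construction). M-step: μ = (Σ p_ii)/T and
h_b = (Σ_{lag∈bin b} p_ij)/(w_b · N_exposed(b)), where N_exposed(b) counts
events whose bin-b lag window fits inside the observation span — without
this boundary correction the kernel tail is biased low near the horizon.

Numerical choices, with defaults:

- **Kernel support**: 2 × the 95th percentile of the observed inter-event
  gaps, 8 equal bins. The gap-quantile rule adapts the memory window to each
  career's own time scale; for an exponential ground truth at the simulated
  settings it covers ≳90% of the kernel mass, so recovered branching ratios
  carry a small (few percent) truncation bias, visible in the recovery
  numbers.
- **Initialization**: μ₀ = 0.5·N/T, uniform kernel with n₀ = 0.5.
- **Convergence**: relative log-likelihood change < 1e-6, max 500
  iterations; the trace is non-decreasing (EM guarantee, asserted in tests);
  non-convergence is flagged on the result, not raised.
- **No subcriticality constraint** during EM; fits with n ≥ 1 are flagged
  `supercritical` and kept, because the shuffle-null comparison needs the
  unconstrained value.
- The log-likelihood and the compensator are computed in closed form (the
  kernel CDF is piecewise linear), so out-of-sample scores and the
  time-rescaling goodness-of-fit residuals are exact, not quadrature
  approximations. Degenerate evaluations (λ = 0 at an event) return −inf
  and are excluded with a logged count; a career with > 20% degenerate
  control fits is flagged unevaluable.

Fits are fully deterministic given the events and the configuration.

## Shuffle-control evaluation

Per career: the first ⌊0.8τ⌋ games train, the rest validate, in
chronological order. The validation log-likelihood conditions on the
training events' stamps, because excitation crossing the split boundary is
exactly the phenomenon under test. The total training span Σ1/S̃ is a
permutation invariant, so the validation stamps are bit-identical across
all controls — only the model changes. 100 controls refit the model on
shuffled training scores; δ = (L_model − median L_control)/median
L_control. Branching-ratio nulls come from 100 whole-career shuffles,
distinct from the training-only shuffles used for prediction controls.

**Significance.** Two p-values are reported per career and per test:

- a one-sided Wilcoxon signed-rank on the differences (real − control_i),
  exact for ≤ 25 untied pairs, normal approximation with tie/zero handling
  otherwise. This pairing is kept as a descriptive diagnostic, but it is
  **not calibrated**: its 100 differences share the single random real
  value, so under the null it effectively asks whether the real value beats
  the control median — a coin flip — and rejects ~50% of null careers.
- an add-one permutation rank p-value, (1 + #{controls ≥ real})/(#controls
  + 1). Under the no-hot-hand null the real ordering is exchangeable with
  its shuffles, so this test is exact; it is the basis of all per-career
  significance calls and of the cohort summaries.

Cohort level: the count k of significant careers among N is weighed against
Binomial(N, α) — P(X ≥ k) and P(X = k) by exact summation, never a normal
approximation.

**Raw branching ratios are not comparable across score distributions.** An
i.i.d. career with a heavy-tailed score law already produces bursty gaps
(many tiny increments from high scores), which an unconstrained Hawkes fit
absorbs as a large absolute n — larger, in the synthetic conditions below,
than a genuinely self-excited career with a milder marginal. Only the
within-career contrast against shuffles of the same score multiset is
meaningful, which is why every test here is shuffle-relative.

## Best-performance co-location

Top-3 indices use earliest-game tie-breaking at each rank (deterministic
and order-stable). Δ statistics satisfy Δ¹² + Δ²³ = Δ¹³ exactly. Histograms
use 0.05-wide bins on [−1, 1]; the cohort null pools 10 shuffles per career;
R = P/P′ uses additive smoothing ε = 1/(shuffled count) and is undefined
(NaN), not infinite, where P′ has no mass. Note that R in a sparsely
populated bin is dominated by the real histogram's sampling noise — the
calibration tests therefore compare bin probabilities on the binomial
z-score scale rather than thresholding raw ratios. The 2-D two-sample KS
statistic probes all four quadrants anchored at every pooled data point
(Peacock's construction); p-values come from label permutations (default
999) with the add-one correction, since asymptotic 2-D KS distributions are
only approximate.

## Winning streaks

A streak is a maximal run of consecutive wins; anything that is not a win
breaks it. Nulls permute the outcome sequence itself (win count preserved),
1000 trajectories by default. p(n) is the fraction of trajectories whose
longest streak reaches n; the frequency-conditional p(n_f) is
operationalized as "at least f maximal streaks of length ≥ n", which makes
it a proper tail probability with p(n_f) ≤ p(n) for f ≥ 1 (an "exactly f"
variant is available). Both use the add-one Monte-Carlo correction so no
p-value is zero. All five standard corrections (Bonferroni, Holm, Hochberg,
Benjamini-Hochberg, Benjamini-Yekutieli) are computed and reported; the
headline `extreme` label (either corrected p below α) uses Holm — valid
under arbitrary dependence, less conservative than Bonferroni — with the
method a config option.

## Synthetic data: what it emulates, and what it does not

`null_iid` careers draw scores i.i.d. from a zero-inflated geometric on
{0, 1, ...} (geometric mean 25, 8% extra mass at zero): the heavy right
tail and frequent ducks of batting scores, with no serial structure.
`hot_hawkes` careers simulate a Hawkes process on the performance-time axis
by Ogata thinning (the proposal bound uses each event's remaining maximal
kernel value, which stays valid for non-monotone histogram kernels and is
recomputed after every accepted event) and invert the subordination:
S(t) = round(1/ΔH_t) clamped to [1, 500]. Defaults μ = 10 events per unit
H, branching 0.6, exponential kernel with scale 0.1: the stationary rate
μ/(1−n) = 25 then makes typical scores cricket-sized (~25) and the
excitation memory spans a few games. The clamp ties top scores in strongly
excited careers, a visible artefact in the Δ analysis (tie-breaking then
forces Δ¹² ≤ 0). Win/loss sequences are a two-state Markov chain: repeat
the previous outcome with probability ρ, else a fresh Bernoulli(p_win);
ρ = 0 is the i.i.d. null.

What passing the synthetic suites does **not** show: real careers are
non-stationary (form, age, opposition strength, rule changes), scores are
censored (not-out innings), bowling "performance" is not a single
non-negative number, and the generator's score family is only a caricature
of real batting distributions. The synthetic results certify the machinery
— calibration, power, parameter recovery — not any claim about cricket.

## Problem sizes in the shipped checks

The acceptance suite runs EM recovery at horizon 2000 over 20 simulation
seeds, calibration and power on cohorts of 200 careers (lengths 100 and
150) with 100 controls each, the streak oracle at 10⁴ permutations, and the
null-team streak calibration over 50 teams of 100 games — sizes chosen to
give stable Monte-Carlo estimates at desk scale.

## Known limitations

- The background rate is constant per career; seasonal or age-related
  drift is absorbed into spurious excitation or lost.
- The zero-score floor is a modelling choice, not data; very duck-heavy
  careers deserve a sensitivity scan over `s_min`.
- The histogram kernel's support rule truncates long-memory excitation;
  slowly decaying kernels will be under-measured.
- The out-of-sample log-likelihood test has low power for short careers
  (the validation window of a 100-game career holds 20 events); the
  branching-ratio test is the more sensitive instrument at these sizes.
- Wilcoxon signed-rank p-values against a shared ensemble are reported for
  comparability but must not be read as calibrated significance (see
  above).
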