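# Methods

## The measures

A scan path is the temporally ordered sequence of fixated areas of
interest (AOIs), `x = (x_1, ..., x_n)`, over a finite alphabet
`{1, ..., A}` (default `A = 8`).  The package estimates, in bits, with
plug-in (relative-frequency) probabilities:

* **Stationary gaze entropy** `H(X_t)` — dispersion of gaze over AOIs.
* **Gaze transition entropy (GTE)**
  `H(X_t | X_{t-1}) = H(X_t, X_{t-1}) - H(X_{t-1})` — the residual
  uncertainty in the next fixation given the previous one.  GTE models the
  scan path as a first-order Markov chain.
* **Active information storage (AIS)**
  `I(X_t^-; X_t) = H(X_t) + H(X_t^-) - H(X_t, X_t^-)` — the information the
  past state `X_t^- = {X_{t-l} : l in L}` carries about the next fixation;
  a direct measure of predictability that does not presuppose first-order
  structure.
* **Local variants** (LAIS, LGTE) evaluate the same estimated
  probabilities at individual realizations:
  `lais(t) = log2 p(x_t | x_t^-) / p(x_t)` (can be negative — a
  misinformative past) and `lgte(t) = -log2 p(x_t | x_{t-1})`
  (non-negative).  Local values average exactly to the global measures,
  and for `L = {1}` the complementarity `GTE + AIS = H(X_t)` holds per
  sample.  Note the local conditional entropy obeys the chain rule
  `h(x_t|x_{t-1}) = h(x_t, x_{t-1}) - h(x_{t-1})`.

Probabilities are estimated once from **all** eligible samples of the full
sequence; locality refers to evaluation, not estimation.  For a lag set
with maximum lag `L_max`, the eligible samples are `t in {L_max+1, ..., n}`
(`n_eff = n - L_max`).  When measures with different lag sets are compared
(e.g. GTE vs an optimized-lag AIS), each uses its own eligible set; an
`eligible_from` override forces a common set where an exact inequality is
needed (e.g. the monotonicity of empirical mutual information under
growing past states).  Logarithms are base 2 throughout.  No analytic bias
correction is applied — finite-sample bias is handled by the permutation
tests below.

## Past-state optimization (non-uniform embedding)

The predictive past state is selected per individual by greedy forward
selection over candidate lags `1..l_max` (default `l_max = 5`):

1. For every remaining candidate, compute the plug-in conditional mutual
   information (CMI) with `X_t` given the already selected lags, on the
   common eligible set `t > max(candidates ∪ selected)`.
2. Test the largest CMI with a max-statistic permutation test: each
   surrogate round independently shuffles every candidate's realizations
   (target and conditioning intact) and records the maximum CMI across
   candidates.  The +1-corrected p-value is the fraction of rounds whose
   maximum reaches the observed winner.  Taking the maximum over
   candidates controls the family-wise error rate of the step; the
   surrogate distribution simultaneously absorbs the plug-in estimator's
   positive bias.
3. If `p <= alpha` (default 0.05, 200 permutations), admit the winner and
   repeat; otherwise stop.

An empty selection means no significant storage (the participant is
excluded from AIS-based analysis).  Ties in CMI break toward the smallest
lag.  Surrogate seeds derive deterministically from a master seed and the
step index, so results are exactly reproducible.  A backward pruning pass
over the selected lags is available but off by default: the procedure is
forward selection with a termination criterion.

At the second and later steps the surrogate max-CMI distribution is
conservative: shuffling a candidate destroys not only its dependence on
the target but also its dependence on the conditioning variables, and a
shuffled candidate spreads over more conditioning strata than a real,
autocorrelated one, inflating the surrogate bias relative to the null.
Observed false-inclusion rates at later steps are therefore below the
nominal alpha (the i.i.d. first-step calibration is exact).

## Synthetic scan paths with analytic ground truth

`build_chain` constructs order-`m` Markov chains as a mixture of a base
marginal and deterministic single-lag maps:

    p(x_t | past) = (1 - rho) * base + (rho / |S|) * sum_{l in S} delta(f_l(x_{t-l}))

with coupling `rho in [0, 1]` and active lags `S`.  Two map families are
provided: `shift` (`f_l(s) = ((s - 1 + l) mod A) + 1`; `rho = 1` with a
single lag gives the deterministic cycle, and the stationary marginal
flattens as `rho` grows) and `repeat` (`f_l(s) = s`, gaze perseveration;
the stationary marginal equals the base marginal for every `rho`, so
coupling changes have no marginal footprint).  The per-lag mixture makes
every active lag individually informative; a joint deterministic map of
several lags (e.g. a modular sum) would make the dependence purely
synergistic and unrecoverable by any forward-selection screen, which is a
property of such parity-like constructions, not of the estimator.

The stationary law is computed exactly by lifting the chain to first
order on symbol tuples and solving `pi P = pi` (with a strong-connectivity
check that exactly one closed communicating class exists — periodic
chains such as cycles are fine, reducible ones raise).  `exact_measures`
then enumerates the joint law of `(X_t, X_t^-)` for any lag set, yielding
exact AIS, conditional entropy and `H(X_t)`; these are the oracles the
plug-in estimates are tested against (agreement within 0.02 bits at
n = 100,000 for A ≤ 4, order ≤ 2).

## The synthetic cohort

`simulate_cohort` emulates the structure of a driving-simulator session
with overtaking trials.  Defaults (the package's study conditions):

* 11 participants: six with true lag set `{1}`, four with storage strictly
  beyond lag 1 (`{2}`, `{3}`, `{4}`, `{2,4}`), one memoryless (i.i.d.) —
  the analogue of a 6/4 order split plus one excluded participant.
* Sequence lengths drawn from Normal(866, 74) fixations.
* 12 trials per participant (6 easy / 6 hard, shuffled), each trial a
  run of before-lane-change fixations (Poisson mean 15) followed by
  after-lane-change fixations (Poisson mean 22); the 5 fixations
  preceding a trial onset form its baseline.  Onsets and log-normal
  durations (means 630/530/500 ms for baseline/inter-trial, before and
  after lane change) are synthesized for I/O realism only.
* Chains use the `repeat` (perseveration) maps with base coupling
  `rho = 0.55`.  Baseline/inter-trial driving uses a skewed marginal with
  0.8 mass on AOIs 5 and 8 (dashboard and ego lane); the task periods use
  a flatter marginal (higher entropy — the visual field is explored more
  thoroughly during overtaking).
* The injected state change: coupling rises to `rho = 0.70` after the
  lane change.  With `repeat` maps this changes *only* the temporal
  structure — the marginal, and hence the entropy terms, carry no trace
  of it.  Because the `l > 1` participants' storage lives strictly beyond
  lag 1 (interleaved subchains are mutually independent, so their lag-1
  mutual information is exactly zero), the increase is visible to the
  optimized-past-state AIS but invisible in principle to a first-order
  measure.
* The i.i.d. participant keeps one constant marginal across periods:
  piecewise marginal switches would themselves induce apparent storage in
  pooled plug-in estimates and corrupt the "no storage" ground truth.

What the generator does *not* emulate: saliency- or scene-driven gaze,
oculomotor dynamics, continuous coordinates, merged repeated fixations,
drifts within a period (periods are piecewise-stationary), or tracker
noise (confidences are 1.0).  Passing pipeline tests therefore show that
the estimators and the analysis chain behave correctly on sequences with
known higher-order structure — not that real gaze obeys this generative
model.

### Calibration of the injected effect

The injection strength was fixed at `rho_alc = 0.70` after observing a
genuine limitation of pooled local plug-in estimation: samples contribute
to the very probability tables they are evaluated under, so the long
perseveration runs produced by a strong coupling boost inflate their own
pair counts and depress local LGTE inside the boosted period — a
persistence-correlated small-sample bias that leaks an "effect" into the
first-order measure even when the true lag-1 dependence is exactly zero.
At 0.70 the storage effect remains large (mixed-model t around 4–6 on the
normalized LAIS contrast) while the leak stays within noise.  This is a
one-off design calibration of the study conditions, not a tunable.

## Analysis pipeline

Per participant: quality-filter fixations (duration within [100, 1500] ms
inclusive, confidence >= 0.9 — boundary values are retained since the
exclusion rules drop only what lies strictly below/above), label periods,
optimize the past state on the full consecutive symbol sequence, estimate
local LAIS (selected lags) and local LGTE (always lag 1), average each
local series within every (trial, period) cell, and normalize: mean LAIS
by the mean local joint entropy of `(x_t, x_t^-)` (the full optimized
past state), mean LGTE by the mean local joint entropy of the lag-1 pair.
Normalization controls for period differences in overall information
content — without it, a mere change in dispersion moves both measures.
Cells with fewer than 2 defined samples or non-positive mean joint
entropy are flagged undefined.  Baseline cells inherit the upcoming
trial's difficulty (required by the full factorial model).

Participants are split by detected Markov order: `order1` (only lag 1
selected), `order_gt1` (any selected lag > 1), `excluded` (no significant
storage).

## Mixed-effects stage

One observation per (participant, trial, period); a participant-level
mode (pooling trials) is available.  Fixed effects: difficulty
(deviation-coded, easy = +1 vs the grand mean), trial period
(Helmert-coded: baseline vs before lane change at ±1/2; their mean vs
after lane change at −1/3, −1/3, +2/3 — scaling affects coefficients,
not t or p), and their interaction.  Random structure: per-participant
intercept and slopes on the two period contrasts, with an automatic
fall-back to a random intercept when the fitted structure is singular or
near-singular (vanishing variance relative to the residual scale, or a
random-effect correlation above 0.98 — with a handful of participants
such estimates sit on the parameter-space boundary and their information
matrix is unusable).  REML fitting is delegated to statsmodels'
`MixedLM`; a sequence of optimizers is tried because single methods can
step through degenerate covariances.

Satterthwaite degrees of freedom are computed here (statsmodels does not
provide them): `df_j = 2 C_jj^2 / (g_j' A g_j)` where `C` is the
fixed-effect covariance, `g_j` its gradient with respect to the variance
parameters and `A` the inverse observed information of the restricted
log-likelihood.  Both derivatives are taken numerically in the
Cholesky-factor parametrization of the random-effect covariance (smooth
and positive-semidefinite by construction), after polishing the delegated
fitter's estimate to a genuine critical point of an independently
implemented restricted likelihood (optimizer stopping points are not
always critical points, and the Hessian is meaningless away from one).
Near-null information directions are dropped; if the information matrix
is unusable the residual df (n − p) is used and flagged.  df are clipped
to [1, n − p].  The stage is cross-checked against R's lmerTest in the
test suite (estimates to 1e-4, SE to 1%, df to 10% on a well-conditioned
fit).  No multiple-testing correction is applied across the two response
measures and two groups; p-values are reported per model.

## Problem sizes and numerical choices

* Identities are exact properties of the plug-in construction and are
  verified to 1e-10 on 100 random sequences (n = 500, A = 8).
* Oracle agreement uses n = 100,000 simulations (tolerance 0.02 bits).
* Embedding recovery uses rho = 0.8, n = 5000, l_max = 5, 200
  permutations, 20 seeds per lag set (≥ 80% exact recovery); false-positive
  calibration uses 200 i.i.d. sequences of n = 5000.
* The cohort analogue uses 50 pipeline replicates in the test suite;
  `scripts/acceptance.py` reports the same rates at reduced replicate
  counts (20 cohort replicates, 10 recovery seeds per lag set, 100
  calibration sequences), chosen to keep a single-CPU run in minutes.
* The exact group split (4, 6, 1) requires seven independent terminal
  permutation tests (six order-1 participants and the i.i.d. one) to all
  stay below alpha; with alpha = 0.05 and the conservative later-step
  behavior the expected exact-split rate is roughly 0.75–0.85 — an
  intrinsic ceiling of the specified per-step alpha, not an estimator
  property that more data would change.
* `0 log 0 = 0`; entropies are clamped at 0 against float round-off;
  plug-in distributions store observed support only (unobserved tuples
  have probability 0, which can only arise for out-of-sample queries).
* Stationary solves replace one redundant balance equation with the
  normalization row and verify the residual to 1e-8.

## Known limitations

* Plug-in local measures share samples between estimation and evaluation;
  strongly persistent spells inflate their own conditional probabilities
  (see the calibration note above).  At n ≈ 866 and A = 8 this bias is
  visible; permutation testing controls it for inclusion decisions but
  not for downstream local averages.
* Satterthwaite df at boundary fits are inherently unstable in any
  implementation; the fall-back hierarchy (simpler random structure,
  then residual df) makes the choice explicit rather than silent.
* The pipeline treats each recording as one stationary sequence per the
  estimation design; slow drifts would be attributed to stored structure.
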