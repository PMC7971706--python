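# scanpath-ais

Information-theoretic analysis of AOI-coded eye-movement scan paths for
researchers studying gaze behavior in dynamic tasks (e.g. driving):
how predictable is the next fixation from the past, how far back does
that past reach, and does predictability change with task state?

The classical measures treat a scan path — the ordered sequence of
fixated areas of interest (AOIs) `x_1, ..., x_n` over an alphabet
`{1..A}` — as a first-order Markov chain:

* stationary gaze entropy `SGE = H(X_t)` (dispersion),
* gaze transition entropy `GTE = H(X_t | X_{t-1})` (first-order
  regularity).

This package centers on **active information storage**,

    AIS = I(X_t^- ; X_t),     X_t^- = { X_{t-l} : l in L },

the mutual information between the next fixation and an *optimized* past
state: the lag set `L` is selected per individual by greedy forward
selection of conditional mutual information with max-statistic
permutation testing (family-wise error controlled within each step, with
an automatic stopping criterion).  When `L = {1}`, GTE and AIS are
complementary: `GTE + AIS = H(X_t)`.  Local (per-fixation) variants
`lais(t) = log2 p(x_t|x_t^-)/p(x_t)` and `lgte(t) = -log2 p(x_t|x_{t-1})`
let period-resolved averages be computed from probabilities estimated on
the full recording.

Alongside the estimators the package ships:

* a preprocessing layer for delimited fixation/trial-event tables
  (duration and confidence filters, trial-period labeling, symbol coding),
* a higher-order Markov scan-path simulator with exactly computable
  stationary laws and AIS (the analytic oracle for every estimator, and a
  study-shaped synthetic cohort generator),
* the statistical stage: per-period averaging, joint-entropy
  normalization, a Markov-order group split, and contrast-coded linear
  mixed models (Helmert/deviation coding, Satterthwaite degrees of
  freedom, random intercept+slope with singular-fit fall-back),
* a CLI (`scanpath-ais preprocess | measures | embed | simulate-cohort |
  run-pipeline`).

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import numpy as np
from scanpath_ais import (
    PermutationConfig, build_chain, simulate_scanpath, optimize_past_state,
    active_information_storage, gaze_transition_entropy, exact_measures,
)

# a scan path whose next fixation copies the one 2 steps back (70% of the
# time) over 8 AOIs -- a second-order process with no lag-1 structure
chain = build_chain(A=8, active_lags=(2,), rho=0.7, map_kind="repeat")
path = simulate_scanpath(chain, n=5000, seed=1)

res = optimize_past_state(path, l_max=5, cfg=PermutationConfig(seed=7))
print("selected lags:", res.selected)

ais = active_information_storage(path, res.lag_set)
gte = gaze_transition_entropy(path)
exact, _, _ = exact_measures(chain, (2,))
print(f"AIS {ais:.3f} bits (exact {exact:.3f}), GTE {gte:.3f} bits")
```

Output:

```
selected lags: (2,)
AIS 1.422 bits (exact 1.433), GTE 2.971 bits
```

The optimization finds the true lag set `{2}`.  The storage measure
reports ~1.4 bits of predictability (matching the analytic value for the
generating chain), while the first-order GTE is near its ceiling of
3 bits — under a violated first-order assumption the transition entropy
sees almost none of the structure that is actually there.

Running the full pipeline on the default 11-participant synthetic cohort
(`scanpath-ais simulate-cohort --outdir data --seed 0`, then
`scanpath-ais run-pipeline --fixations data/fixations.csv --events
data/events.csv --out results`) prints the per-participant lag sets and
group assignment — the generated cohort is designed as 6 first-order,
4 higher-order and 1 memoryless participant — and writes
`period_summaries.csv` and `model_results.csv` with the mixed-model
contrasts on the normalized local measures.

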