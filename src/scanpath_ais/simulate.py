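"""Synthetic AOI scan paths from higher-order Markov chains with known
ground truth.

The generative model is a mixture of a base marginal and deterministic
single-lag maps: for a chain with active lags ``S ⊆ {1..m}`` and coupling
``rho``,

    p(x_t | x_{t-1..t-m}) = (1 - rho) * base_marginal
                            + (rho / |S|) * sum_{l in S} delta( f_l(x_{t-l}) ),

where each map ``f_l`` is either a lag-specific cyclic shift or the
identity (perseveration), so every active lag carries individually
visible information.  ``rho = 0`` gives an i.i.d. sequence from the base
marginal; ``rho = 1`` with a single active shift lag gives a
deterministic cycle.  A custom joint deterministic map is supported.  The
construction keeps the stationary law and every entropy/AIS quantity
exactly computable by enumeration (see
:func:`scanpath_ais.embedding.exact_measures`), while coupling strength is
a single interpretable knob.

:func:`simulate_cohort` emulates the structure of a driving-simulator
session: per-participant chains of individual Markov order, 12 overtaking
trials (half easy, half hard) each with a 5-fixation baseline, a
before-lane-change and an after-lane-change period, heavily skewed AOI
marginals during baseline driving, a flatter marginal (higher entropy)
during the task, and a coupling increase after the lane change.  Period
effects are piecewise-stationary parameter switches; the analysis pipeline
still treats each recording as one sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .infotheory import ScanPath

__all__ = [
    "MarkovChainSpec",
    "CohortConfig",
    "CohortData",
    "build_chain",
    "stationary_distribution",
    "simulate_scanpath",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkovChainSpec:
    """Order-``m`` transition law over the AOI alphabet.

    ``cond[u, s]`` is the probability of next symbol ``s+1`` given the
    lagged tuple with code ``u = sum_j (x_{t-j} - 1) A^(j-1)``, j = 1..m.
    ``active_lags`` lists the lags that actually influence the
    conditionals; an empty tuple means i.i.d. sampling from
    ``base_marginal``.
    """

    A: int
    order: int
    active_lags: tuple[int, ...]
    rho: float
    base_marginal: np.ndarray
    cond: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.cond.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each conditional distribution must sum to 1")
        if self.cond.shape != (self.A**self.order, self.A):
            raise ValueError("conditional table has wrong shape")

    def tuple_code(self, lagged: tuple[int, ...]) -> int:
        """Code of a lagged tuple ``(x_{t-1}, ..., x_{t-m})``."""
        code = 0
        for j, s in enumerate(lagged):
            code += (int(s) - 1) * self.A**j
        return code

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "order": self.order,
            "active_lags": list(self.active_lags),
            "rho": self.rho,
            "base_marginal": self.base_marginal.tolist(),
        }


def _shift_target(symbol: int, lag: int, A: int) -> int:
    """Lag-specific cyclic shift: next = ((x_{t-l} - 1 + l) mod A) + 1."""
    return (symbol - 1 + lag) % A + 1


def build_chain(
    A: int,
    active_lags,
    rho: float,
    base_marginal=None,
    det_map=None,
    map_kind: str = "shift",
) -> MarkovChainSpec:
    """Mixture-of-deterministic-and-base chain with analytic ground truth.

    Parameters
    ----------
    A
        Alphabet size (>= 2).
    active_lags
        Lags in ``{1..m}`` that influence the next symbol; the chain order
        is ``m = max(active_lags)`` (0 for the empty set, i.e. i.i.d.).
    rho
        Coupling in [0, 1]; weight of the deterministic map.
    base_marginal
        Base distribution over symbols (default uniform).
    det_map
        Callable mapping the lagged tuple ``(x_{t-1}, ..., x_{t-m})`` to
        the deterministic next symbol; must depend only on active lags.
    map_kind
        With the default per-lag mixture: ``"shift"`` moves each active
        lag's symbol cyclically by the lag (``rho = 1`` with a single lag
        gives the deterministic cycle; the stationary marginal flattens
        as ``rho`` grows), ``"repeat"`` copies the lagged symbol
        (perseveration; the stationary marginal equals ``base_marginal``
        exactly for every ``rho``, so coupling changes leave no marginal
        footprint).  Ignored when ``det_map`` is given.
    """
    active_lags = tuple(sorted(int(l) for l in active_lags))
    if any(l < 1 for l in active_lags):
        raise ValueError("active lags must be positive")
    if len(set(active_lags)) != len(active_lags):
        raise ValueError("active lags must be unique")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if A < 2:
        raise ValueError("A must be >= 2")
    base = np.full(A, 1.0 / A) if base_marginal is None else np.asarray(base_marginal, float)
    if base.shape != (A,) or np.any(base < 0) or abs(base.sum() - 1.0) > 1e-9:
        raise ValueError("base_marginal must be a distribution over A symbols")
    base = base / base.sum()

    m = max(active_lags) if active_lags else 0
    if m == 0 or rho == 0.0:
        # i.i.d.; keep at least order 1 so the lifted chain is well defined
        order = max(m, 1)
        cond = np.tile(base, (A**order, 1))
        return MarkovChainSpec(A, order, active_lags if rho > 0 else (), float(rho), base, cond)

    cond = np.tile((1.0 - rho) * base, (A**m, 1))
    digits = np.empty((A**m, m), dtype=np.int64)
    rem = np.arange(A**m)
    for j in range(m):
        digits[:, j] = rem % A + 1  # x_{t-(j+1)}
        rem = rem // A
    if det_map is not None:
        for u in range(A**m):
            target = int(det_map(tuple(digits[u])))
            if not 1 <= target <= A:
                raise ValueError("det_map must return a symbol in 1..A")
            cond[u, target - 1] += rho
    else:
        # equal per-lag mixture of single-lag maps: every active lag
        # carries individually visible information (a pure function of the
        # joint tuple, e.g. a modular sum, would be invisible to any
        # pairwise screen); a single active lag reduces to one map
        if map_kind not in ("shift", "repeat"):
            raise ValueError(f"unknown map_kind {map_kind!r}")
        share = rho / len(active_lags)
        for l in active_lags:
            for u in range(A**m):
                s = int(digits[u, l - 1])
                target = _shift_target(s, l, A) if map_kind == "shift" else s
                cond[u, target - 1] += share
    return MarkovChainSpec(A, m, active_lags, float(rho), base, cond)


# ---------------------------------------------------------------------------
# stationary law
# ---------------------------------------------------------------------------


def _lifted_transition(spec: MarkovChainSpec, k: int) -> sp.csr_matrix:
    """First-order transition matrix on ``A^k`` tuples, ``k >= order``.

    State code ``u = sum_j (x_{t-j}-1) A^(j-1)`` for j = 1..k; observing
    symbol ``s`` moves to ``(s-1) + A * (u mod A^(k-1))``.
    """
    A, m = spec.A, spec.order
    if k < m:
        raise ValueError("lift dimension must be >= chain order")
    n_states = A**k
    u = np.arange(n_states)
    probs = spec.cond[u % (A**m)]  # conditionals depend on the first m coords
    rows = np.repeat(u, A)
    succ_base = (u % (A ** (k - 1))) * A
    cols = (np.repeat(succ_base, A) + np.tile(np.arange(A), n_states))
    return sp.csr_matrix((probs.ravel(), (rows, cols)), shape=(n_states, n_states))


def stationary_distribution(spec: MarkovChainSpec, k: int | None = None) -> np.ndarray:
    """Stationary distribution of the lifted chain on ``A^k`` tuples.

    Solves ``pi P = pi`` directly (handles periodic chains such as
    deterministic cycles).  Raises if the chain does not have a unique
    stationary distribution (more than one closed communicating class).
    """
    k = spec.order if k is None else int(k)
    P = _lifted_transition(spec, k)
    n = P.shape[0]

    # uniqueness: exactly one closed communicating class
    n_comp, labels = connected_components(P > 0, directed=True, connection="strong")
    closed = []
    indptr, indices = P.indptr, P.indices
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        out = np.unique(indices[np.concatenate([np.arange(indptr[i], indptr[i + 1]) for i in members])])
        if np.all(labels[out] == c):
            closed.append(c)
    if len(closed) != 1:
        raise ValueError(
            f"chain has {len(closed)} closed communicating classes; "
            "stationary distribution is not unique"
        )

    M = (P.T - sp.identity(n, format="csr")).tolil()
    M[0, :] = 1.0  # replace one redundant balance equation by normalization
    b = np.zeros(n)
    b[0] = 1.0
    pi = spsolve(M.tocsr(), b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(pi @ P - pi).max()
    if resid > 1e-8:
        raise ValueError(f"stationary solve failed (residual {resid:.2e})")
    return pi


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _sample_initial_state(spec: MarkovChainSpec, rng: np.random.Generator) -> int:
    pi = stationary_distribution(spec)
    return int(rng.choice(pi.size, p=pi))


def simulate_scanpath(
    spec: MarkovChainSpec,
    n: int,
    seed,
    burn_in: int | None = None,
    init: str = "stationary",
) -> ScanPath:
    """Sample a scan path of length ``n`` from a known chain.

    ``init='stationary'`` draws the initial lagged tuple from the exact
    stationary law (no burn-in needed); ``init='uniform'`` starts from a
    uniform random tuple and discards ``burn_in`` samples (default
    ``100 * order``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    A, m = spec.A, spec.order
    if init == "stationary":
        state = _sample_initial_state(spec, rng)
        discard = 0
    elif init == "uniform":
        state = int(rng.integers(A**m))
        discard = int(burn_in) if burn_in is not None else 100 * m
    else:
        raise ValueError("init must be 'stationary' or 'uniform'")
    cum = np.cumsum(spec.cond, axis=1)
    u = rng.random(n + discard)
    out = np.empty(n + discard, dtype=np.int64)
    mod = A ** (m - 1)
    for t in range(n + discard):
        s = int(np.searchsorted(cum[state], u[t], side="right"))
        out[t] = s + 1
        state = s + A * (state % mod)
    return ScanPath(symbols=out[discard:], A=A)


def _sample_piecewise(
    specs: dict[str, MarkovChainSpec],
    periods: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one sequence whose conditional law switches with the period.

    All specs must share alphabet; state is carried across switches at the
    maximum order over the specs.
    """
    A = next(iter(specs.values())).A
    m = max(s.order for s in specs.values())
    cums = {p: np.cumsum(s.cond, axis=1) for p, s in specs.items()}
    orders = {p: s.order for p, s in specs.items()}
    first = specs[periods[0]]
    state = _sample_initial_state(first, rng)
    # embed the initial state of the first spec into the max-order state
    if first.order < m:
        pad = int(rng.integers(A ** (m - first.order)))
        state = state + pad * (A**first.order)
    n = periods.size
    u = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    mod = A ** (m - 1)
    for t in range(n):
        p = periods[t]
        row = state % (A ** orders[p])
        s = int(np.searchsorted(cums[p][row], u[t], side="right"))
        out[t] = s + 1
        state = s + A * (state % mod)
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# study-condition defaults: 8 AOIs, ~80% of baseline fixations on the
# dashboard (AOI 5) and ego lane (AOI 8), flatter marginal during the task
_BASELINE_MARGINAL = np.array([0.02, 0.02, 0.03, 0.03, 0.35, 0.04, 0.06, 0.45])
_TASK_MARGINAL = np.array([0.06, 0.08, 0.08, 0.06, 0.22, 0.10, 0.10, 0.30])

# 11-participant analogue of the observed split: 6 first-order, 4 with
# storage strictly beyond lag 1 (delays up to four fixations; no lag-1
# component, so their predictability is invisible to a first-order
# measure), 1 memoryless (excluded downstream)
_DEFAULT_LAG_SETS = (
    (1,), (1,), (1,), (1,), (1,), (1,),
    (2,), (3,), (4,), (2, 4),
    (),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-shaped cohort: sizes, trial layout and period effects.

    ``rho`` applies to baseline/inter-trial driving and the before-lane-
    change period; ``rho_after_lane_change`` injects the predictability
    increase during the overtaking completion.  Marginal skew switches
    between ``baseline_marginal`` (concentrated) and ``task_marginal``
    (dispersed) in the task periods.  A participant with an empty lag set
    is i.i.d. with constant marginal throughout (no period effects), so
    that its ground truth is genuinely "no storage".
    """

    n_participants: int = 11
    lag_sets: tuple[tuple[int, ...], ...] = _DEFAULT_LAG_SETS
    A: int = 8
    rho: float = 0.55
    rho_after_lane_change: float = 0.70
    map_kind: str = "repeat"  # perseveration: marginals are rho-invariant
    baseline_marginal: np.ndarray = field(default_factory=_BASELINE_MARGINAL.copy)
    task_marginal: np.ndarray = field(default_factory=_TASK_MARGINAL.copy)
    n_fixations_mean: float = 866.0
    n_fixations_sd: float = 74.0
    n_trials: int = 12
    baseline_len: int = 5
    blc_len_mean: float = 15.0
    alc_len_mean: float = 22.0
    duration_means_ms: dict = field(
        default_factory=lambda: {
            "baseline": 630.0, "none": 630.0,
            "before_lane_change": 530.0, "after_lane_change": 500.0,
        }
    )
    duration_log_sd: float = 0.3
    saccade_gap_s: float = 0.05

    def __post_init__(self) -> None:
        if len(self.lag_sets) != self.n_participants:
            raise ValueError("one lag set per participant required")


@dataclass
class CohortData:
    """Simulated cohort: fixation and event tables plus ground truth."""

    fixations: pd.DataFrame
    events: pd.DataFrame
    manifest: dict

    def participant_tables(self, participant: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        fx = self.fixations[self.fixations["participant"] == participant].reset_index(drop=True)
        ev = self.events[self.events["participant"] == participant].reset_index(drop=True)
        return fx, ev

    def write(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fixations.to_csv(outdir / "fixations.csv", index=False)
        self.events.to_csv(outdir / "events.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def _participant_layout(cfg: CohortConfig, rng: np.random.Generator):
    """Per-fixation period labels and trial block boundaries."""
    n_fix = max(400, int(round(rng.normal(cfg.n_fixations_mean, cfg.n_fixations_sd))))
    blc = np.maximum(6, rng.poisson(cfg.blc_len_mean, cfg.n_trials))
    alc = np.maximum(8, rng.poisson(cfg.alc_len_mean, cfg.n_trials))
    task_total = int(blc.sum() + alc.sum())
    n_gaps = cfg.n_trials + 1
    min_gap = cfg.baseline_len + 3
    n_fix = max(n_fix, task_total + n_gaps * min_gap)
    rest = n_fix - task_total
    gaps = np.full(n_gaps, rest // n_gaps)
    gaps[-1] += rest - gaps.sum()
    periods, trial_ids = [], []
    for i in range(cfg.n_trials):
        periods.extend(["none"] * int(gaps[i]))
        trial_ids.extend([0] * int(gaps[i]))
        periods.extend(["before_lane_change"] * int(blc[i]))
        periods.extend(["after_lane_change"] * int(alc[i]))
        trial_ids.extend([i + 1] * int(blc[i] + alc[i]))
    periods.extend(["none"] * int(gaps[-1]))
    trial_ids.extend([0] * int(gaps[-1]))
    return np.array(periods), np.array(trial_ids), blc, alc


def simulate_cohort(cfg: CohortConfig | None = None, seed=0) -> CohortData:
    """Generate fixation tables, trial events and a ground-truth manifest.

    Onsets and durations are synthesized (log-normal durations with
    period-specific means) to make the I/O realistic; confidences are 1.0.
    The manifest records every true lag set, coupling per period and
    marginals, sufficient to reproduce the analytic AIS each estimator
    should converge to.
    """
    cfg = cfg if cfg is not None else CohortConfig()
    root = np.random.SeedSequence(seed)
    part_seeds = root.spawn(cfg.n_participants)
    fix_frames, ev_frames = [], []
    manifest = {"seed": int(seed), "participants": {}}
    for i, (lag_set, ss) in enumerate(zip(cfg.lag_sets, part_seeds)):
        pid = f"P{i+1:02d}"
        rng = np.random.default_rng(ss)
        periods, trial_ids, blc, alc = _participant_layout(cfg, rng)
        n_fix = periods.size

        if lag_set:
            specs = {
                "none": build_chain(cfg.A, lag_set, cfg.rho, cfg.baseline_marginal, map_kind=cfg.map_kind),
                "before_lane_change": build_chain(cfg.A, lag_set, cfg.rho, cfg.task_marginal, map_kind=cfg.map_kind),
                "after_lane_change": build_chain(
                    cfg.A, lag_set, cfg.rho_after_lane_change, cfg.task_marginal, map_kind=cfg.map_kind
                ),
            }
            rho_by_period = {
                "none": cfg.rho,
                "before_lane_change": cfg.rho,
                "after_lane_change": cfg.rho_after_lane_change,
            }
        else:  # memoryless participant, constant marginal
            iid = build_chain(cfg.A, (), 0.0, cfg.baseline_marginal)
            specs = {p: iid for p in ("none", "before_lane_change", "after_lane_change")}
            rho_by_period = {p: 0.0 for p in specs}
        symbols = _sample_piecewise(specs, periods, rng)

        # durations (ms) and onsets (s)
        mu = np.array([np.log(cfg.duration_means_ms[p]) for p in periods])
        mu -= cfg.duration_log_sd**2 / 2
        durations = np.exp(rng.normal(mu, cfg.duration_log_sd))
        onsets = np.concatenate(
            [[0.0], np.cumsum(durations[:-1] / 1000.0 + cfg.saccade_gap_s)]
        )
        fix_frames.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "session": "S1",
                    "onset": onsets,
                    "duration_ms": durations,
                    "aoi": symbols,
                    "confidence": 1.0,
                }
            )
        )

        difficulty = np.array(["easy"] * (cfg.n_trials // 2) + ["hard"] * (cfg.n_trials - cfg.n_trials // 2))
        rng.shuffle(difficulty)
        rows = []
        for t in range(1, cfg.n_trials + 1):
            in_trial = trial_ids == t
            blc_idx = np.flatnonzero(in_trial & (periods == "before_lane_change"))
            alc_idx = np.flatnonzero(in_trial & (periods == "after_lane_change"))
            rows.append(
                {
                    "participant": pid,
                    "trial_id": t,
                    "onset": onsets[blc_idx[0]],
                    "lane_change": onsets[alc_idx[0]],
                    "end": onsets[alc_idx[-1]] + durations[alc_idx[-1]] / 1000.0,
                    "difficulty": difficulty[t - 1],
                    "valid": True,
                }
            )
        ev_frames.append(pd.DataFrame(rows))
        manifest["participants"][pid] = {
            "true_lags": list(lag_set),
            "rho_by_period": rho_by_period,
            "n_fixations": int(n_fix),
            "baseline_marginal": cfg.baseline_marginal.tolist() if lag_set else cfg.baseline_marginal.tolist(),
            "task_marginal": cfg.task_marginal.tolist(),
        }
    return CohortData(
        fixations=pd.concat(fix_frames, ignore_index=True),
        events=pd.concat(ev_frames, ignore_index=True),
        manifest=manifest,
    )
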