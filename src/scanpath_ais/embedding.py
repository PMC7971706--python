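"""Data-driven optimization of the predictive past state.

Greedy forward selection of past lags (non-uniform embedding): starting
from an empty past state, each step computes the plug-in conditional
mutual information (CMI) of every remaining candidate lag with the next
fixation, given the already selected lags, and admits the best candidate
if it survives a max-statistic permutation test.  The test compares the
winning CMI against the distribution of the *maximum* CMI over all
candidates under independent shuffling of each candidate's realizations
(target and conditioning left intact), which controls the family-wise
error rate across candidates within a step and simultaneously absorbs the
finite-sample bias of the plug-in estimator.  Selection stops when no
candidate adds significant information, giving an automatic order
estimate per sequence; an empty selection means no significant storage.

:func:`exact_measures` provides the analytic counterpart on a known chain
(exact stationary law by enumeration), used as the oracle that plug-in
estimates must converge to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .infotheory import (
    InsufficientDataError,
    LagSet,
    ScanPath,
    _cmi_from_codes,
    _encode,
    _entropy_from_counts,
)
from .simulate import MarkovChainSpec, stationary_distribution

__all__ = [
    "PermutationConfig",
    "StepRecord",
    "EmbeddingResult",
    "max_statistic_test",
    "optimize_past_state",
    "exact_measures",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the surrogate test.

    ``n_permutations`` must give enough resolution to reach ``alpha``
    (``n_permutations >= 1/alpha - 1``); the p-value uses the +1-corrected
    estimate ``(1 + #{surrogate >= observed}) / (1 + n_permutations)`` so
    it can never be exactly zero.
    """

    n_permutations: int = 200
    alpha: float = 0.05
    seed: int = 0
    surrogate_scheme: str = "shuffle-candidate"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1.0 / self.alpha - 1.0:
            raise ValueError(
                f"{self.n_permutations} permutations cannot resolve alpha={self.alpha}"
            )
        if self.surrogate_scheme != "shuffle-candidate":
            raise ValueError(f"unknown surrogate scheme {self.surrogate_scheme!r}")


@dataclass(frozen=True)
class StepRecord:
    """Outcome of one greedy step (the tested candidate set and winner)."""

    candidates: tuple[int, ...]
    lag: int
    cmi: float
    p_value: float
    surrogate_max_mean: float
    surrogate_max_sd: float
    surrogate_max_q95: float
    significant: bool


@dataclass(frozen=True)
class EmbeddingResult:
    """Selected past state with the per-step testing trail."""

    selected: tuple[int, ...]  # selection order preserved
    steps: tuple[StepRecord, ...]
    terminated_reason: str  # 'no-significant-candidate' | 'l_max-exhausted'
    significant: bool
    l_max: int
    config: PermutationConfig

    def __post_init__(self) -> None:
        if not self.significant and self.selected:
            raise ValueError("insignificant result must carry an empty selection")

    @property
    def lag_set(self) -> LagSet:
        return LagSet(tuple(sorted(self.selected)), l_max=self.l_max)

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "significant": self.significant,
            "terminated_reason": self.terminated_reason,
            "l_max": self.l_max,
            "config": {
                "n_permutations": self.config.n_permutations,
                "alpha": self.config.alpha,
                "seed": self.config.seed,
                "surrogate_scheme": self.config.surrogate_scheme,
            },
            "steps": [
                {
                    "candidates": list(s.candidates),
                    "lag": s.lag,
                    "cmi_bits": s.cmi,
                    "p_value": s.p_value,
                    "surrogate_max_mean": s.surrogate_max_mean,
                    "surrogate_max_sd": s.surrogate_max_sd,
                    "surrogate_max_q95": s.surrogate_max_q95,
                    "significant": s.significant,
                }
                for s in self.steps
            ],
        }


# ---------------------------------------------------------------------------
# permutation testing
# ---------------------------------------------------------------------------


def _step_cmis(tgt, cands, cond_code, A):
    if cond_code is None:
        zero = np.zeros_like(tgt)
        return np.array([_cmi_from_codes(tgt, c, zero, A) for c in cands])
    return np.array([_cmi_from_codes(tgt, c, cond_code, A) for c in cands])


def max_statistic_test(
    path: ScanPath,
    candidates,
    conditioning: LagSet | tuple[int, ...] = (),
    cfg: PermutationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, float, float, dict]:
    """Max-statistic permutation test of candidate lags.

    All candidates are evaluated on the common eligible-sample set
    ``t >= max(candidates + conditioning)`` so that the surrogate maximum
    is exchangeable across candidates.  Each surrogate round permutes
    every candidate's realizations independently while leaving the target
    and the conditioning variables intact; the p-value of the winning
    (largest-CMI) candidate is the +1-corrected fraction of rounds whose
    maximum CMI reaches the observed winning CMI.

    Returns ``(winning lag, CMI bits, p-value, surrogate summary)``.
    Ties in CMI are broken toward the smallest lag.
    """
    cfg = cfg if cfg is not None else PermutationConfig()
    cond = tuple(conditioning.lags if isinstance(conditioning, LagSet) else conditioning)
    candidates = tuple(sorted(int(c) for c in candidates))
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    if set(candidates) & set(cond):
        raise ValueError("candidates must be disjoint from the conditioning set")
    t0 = max(candidates + cond)
    if path.n <= t0:
        raise InsufficientDataError(
            f"sequence of length {path.n} too short for max lag {t0}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    x = path.symbols
    A, n = path.A, path.n
    tgt = x[t0:n] - 1
    cand_cols = [x[t0 - c : n - c] - 1 for c in candidates]
    cond_code = _encode([x[t0 - l : n - l] - 1 for l in cond], A) if cond else None

    observed = _step_cmis(tgt, cand_cols, cond_code, A)
    winner = int(np.argmax(observed))  # candidates sorted -> first max = smallest lag
    obs_cmi = float(observed[winner])

    n_eff = tgt.size
    sur_max = np.empty(cfg.n_permutations)
    zero = np.zeros_like(tgt)
    cc = cond_code if cond_code is not None else zero
    for r in range(cfg.n_permutations):
        best = -np.inf
        for col in cand_cols:
            perm = col[rng.permutation(n_eff)]
            v = _cmi_from_codes(tgt, perm, cc, A)
            if v > best:
                best = v
        sur_max[r] = best
    p = (1.0 + np.sum(sur_max >= obs_cmi - 1e-12)) / (1.0 + cfg.n_permutations)
    summary = {
        "mean": float(sur_max.mean()),
        "sd": float(sur_max.std()),
        "q95": float(np.quantile(sur_max, 0.95)),
    }
    return candidates[winner], obs_cmi, float(p), summary


def optimize_past_state(
    path: ScanPath,
    l_max: int = 5,
    cfg: PermutationConfig | None = None,
    prune: bool = False,
) -> EmbeddingResult:
    """Greedy forward selection of the predictive past state up to ``l_max``.

    Surrogate randomness is derived deterministically from ``cfg.seed``
    and the step index, so identical inputs give identical results.  The
    optional backward pruning pass (off by default) re-tests every
    selected lag against the others after forward selection and drops
    non-significant ones.
    """
    cfg = cfg if cfg is not None else PermutationConfig()
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    if path.n <= 10 * path.A:
        raise InsufficientDataError(
            f"sequence of length {path.n} below the guard of 10*A={10 * path.A} samples"
        )
    remaining = list(range(1, l_max + 1))
    selected: list[int] = []
    steps: list[StepRecord] = []
    reason = "l_max-exhausted"
    step_idx = 0
    while remaining:
        rng = np.random.default_rng([cfg.seed, step_idx])
        lag, cmi, p, summary = max_statistic_test(
            path, tuple(remaining), tuple(selected), cfg, rng
        )
        significant = p <= cfg.alpha
        steps.append(
            StepRecord(
                candidates=tuple(remaining),
                lag=lag,
                cmi=cmi,
                p_value=p,
                surrogate_max_mean=summary["mean"],
                surrogate_max_sd=summary["sd"],
                surrogate_max_q95=summary["q95"],
                significant=significant,
            )
        )
        if not significant:
            reason = "no-significant-candidate"
            break
        selected.append(lag)
        remaining.remove(lag)
        step_idx += 1

    if prune and len(selected) > 1:
        selected = _prune(path, selected, cfg, step_offset=step_idx + 1)

    return EmbeddingResult(
        selected=tuple(selected),
        steps=tuple(steps),
        terminated_reason=reason,
        significant=bool(selected),
        l_max=l_max,
        config=cfg,
    )


def _prune(path, selected, cfg, step_offset):
    """Drop selected lags that are no longer significant given the rest."""
    kept = list(selected)
    changed = True
    step = step_offset
    while changed and len(kept) > 1:
        changed = False
        for lag in list(kept):
            others = tuple(l for l in kept if l != lag)
            rng = np.random.default_rng([cfg.seed, step])
            step += 1
            _, _, p, _ = max_statistic_test(path, (lag,), others, cfg, rng)
            if p > cfg.alpha:
                kept.remove(lag)
                changed = True
                break
    return kept


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------


def exact_measures(
    chain: MarkovChainSpec, lags: LagSet | tuple[int, ...]
) -> tuple[float, float, float]:
    """Exact AIS, conditional entropy and H(X_t) for a known chain.

    Computes the stationary law of the chain lifted to first order on
    ``k``-tuples (``k = max(order, max lag)``), then the exact joint of
    ``(X_t, X_{t-l} : l in lags)`` by enumeration over the finite support.
    Returns ``(AIS, H(X_t | X_t^-), H(X_t))`` in bits; the three satisfy
    ``AIS + H(X_t | X_t^-) = H(X_t)`` exactly.
    """
    lag_tuple = tuple(sorted(lags.lags if isinstance(lags, LagSet) else lags))
    if not lag_tuple:
        raise ValueError("exact_measures requires a non-empty lag set")
    A = chain.A
    k = max(chain.order, max(lag_tuple))
    pi = stationary_distribution(chain, k)  # over (x_{t-1}, ..., x_{t-k})

    # joint mass of (x_t, u): pi(u) * p(x_t | first `order` coords of u)
    n_states = A**k
    u = np.arange(n_states)
    cond_rows = chain.cond[u % (A**chain.order)]
    joint = pi[:, None] * cond_rows  # shape (A^k, A)

    # project u onto the selected lag coordinates
    sel_code = np.zeros(n_states, dtype=np.int64)
    for j, l in enumerate(lag_tuple):
        digit = (u // (A ** (l - 1))) % A
        sel_code += digit * (A**j)
    n_sel = A ** len(lag_tuple)
    # p(x_t, x_sel) by aggregation
    flat_code = np.repeat(sel_code, A) * A + np.tile(np.arange(A), n_states)
    p_joint = np.bincount(flat_code, weights=joint.ravel(), minlength=n_sel * A)
    p_sel = np.bincount(sel_code, weights=pi, minlength=n_sel)
    p_t = joint.sum(axis=0)

    # _entropy_from_counts is scale-invariant, so it applies to masses directly
    h_t = _entropy_from_counts(p_t)
    h_sel = _entropy_from_counts(p_sel)
    h_joint = _entropy_from_counts(p_joint)
    ais = h_t + h_sel - h_joint
    return ais, h_t - ais, h_t
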