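"""Plug-in information-theoretic measures on discrete AOI scan paths.

A scan path is an ordered sequence of AOI symbols ``x = (x_1, ..., x_n)``
over a finite alphabet ``{1, ..., A}``.  All measures here are plug-in
(relative-frequency) estimates in bits.  Global quantities:

* stationary gaze entropy  ``H(X_t)`` -- spatial dispersion of gaze,
* gaze transition entropy  ``GTE = H(X_t | X_{t-1})`` -- first-order
  regularity of transitions,
* active information storage ``AIS = I(X_t^-; X_t)`` -- predictability of
  the next fixation from a (possibly non-contiguous) past state
  ``X_t^- = {X_{t-l} : l in lags}``.

Local (per-fixation) variants are obtained by evaluating the estimated
probabilities at individual realizations instead of averaging:
``lais(t) = log2 p(x_t | x_t^-) / p(x_t)`` and
``lgte(t) = -log2 p(x_t | x_{t-1})``.  Local values average back to the
global measures exactly, and for the single-lag past state the
complementarity ``GTE + AIS = H(X_t)`` holds per sample.

Eligible-sample convention: for a lag set with maximum lag L, all
distributions are estimated over the samples with a complete past,
``t in {L+1, ..., n}`` (1-based), so ``n_eff = n - L``.  The LGTE always
conditions on lag 1 and by default uses its own eligible set; an explicit
``eligible_from`` lets callers force a common sample set when comparing
measures across lag sets.

No bias correction is applied: finite-sample bias is handled downstream by
permutation testing (see :mod:`scanpath_ais.embedding`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

__all__ = [
    "InsufficientDataError",
    "ScanPath",
    "LagSet",
    "JointDistribution",
    "LocalMeasureSeries",
    "plugin_distribution",
    "shannon_entropy",
    "stationary_gaze_entropy",
    "gaze_transition_entropy",
    "active_information_storage",
    "conditional_mutual_information",
    "local_measures",
]

_LOG2 = np.log(2.0)


class InsufficientDataError(ValueError):
    """Raised when a sequence is too short for the requested estimate."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanPath:
    """An AOI symbol sequence with an optional back-index into source rows.

    Parameters
    ----------
    symbols
        Integer AOI labels in ``{1, ..., A}`` in temporal order.
    A
        Alphabet size (fixed by configuration, not inferred, so unseen
        symbols are caught as errors).
    back_index
        Optional row labels mapping each symbol to its source fixation
        record; lets local measures be re-attached to the fixation table.
    """

    symbols: np.ndarray
    A: int
    back_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        sym = np.asarray(self.symbols, dtype=np.int64)
        object.__setattr__(self, "symbols", sym)
        if sym.ndim != 1 or sym.size < 1:
            raise ValueError("scan path must be a non-empty 1-d sequence")
        if self.A < 2:
            raise ValueError("alphabet size A must be >= 2")
        if sym.min() < 1 or sym.max() > self.A:
            bad = np.flatnonzero((sym < 1) | (sym > self.A))
            raise ValueError(
                f"symbols outside alphabet 1..{self.A} at positions {bad[:10].tolist()}"
            )
        if self.back_index is not None:
            bi = np.asarray(self.back_index)
            if bi.shape != sym.shape:
                raise ValueError("back_index must align with symbols")
            object.__setattr__(self, "back_index", bi)

    @property
    def n(self) -> int:
        return int(self.symbols.size)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class LagSet:
    """A strictly increasing set of positive lags defining the past state.

    The empty lag set is permitted and means "no predictive past".
    """

    lags: tuple[int, ...]
    l_max: int | None = None

    def __post_init__(self) -> None:
        lags = tuple(int(l) for l in self.lags)
        object.__setattr__(self, "lags", lags)
        if any(l < 1 for l in lags):
            raise ValueError("lags must be positive integers")
        if any(b <= a for a, b in zip(lags, lags[1:])):
            raise ValueError("lags must be strictly increasing")
        lm = self.l_max if self.l_max is not None else (max(lags) if lags else 0)
        if lags and max(lags) > lm:
            raise ValueError(f"lag {max(lags)} exceeds l_max={lm}")
        object.__setattr__(self, "l_max", int(lm))

    @property
    def max_lag(self) -> int:
        return max(self.lags) if self.lags else 0

    def __len__(self) -> int:
        return len(self.lags)

    def __iter__(self):
        return iter(self.lags)


@dataclass(frozen=True)
class JointDistribution:
    """Plug-in joint distribution over tuples ``(x_t, x_{t-l1}, ...)``.

    Probabilities are stored for observed support only; querying an
    unobserved tuple returns 0.
    """

    support: np.ndarray  # (n_support, k+1) symbol tuples
    probs: np.ndarray  # (n_support,)
    n_eff: int
    A: int
    lags: tuple[int, ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not np.all(self.probs >= 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")
        idx = {tuple(row): p for row, p in zip(self.support.tolist(), self.probs)}
        object.__setattr__(self, "_index", idx)

    def prob(self, symbols: tuple[int, ...]) -> float:
        """Probability of an ``(x_t, x_{t-l1}, ...)`` tuple; 0 if unobserved."""
        return float(self._index.get(tuple(int(s) for s in symbols), 0.0))


@dataclass(frozen=True)
class LocalMeasureSeries:
    """Per-fixation local measures aligned to the scan path.

    All arrays have length ``n`` and are NaN where the required past is
    incomplete.  ``lais`` and the joint/marginal terms for the optimized
    past state are defined from ``t0 = max(lags)``; the lag-1 terms
    (``lgte``, ``h_joint_lag1``, ``h_past_lag1``) from index 1.  ``lais``
    may be negative (a misinformative past); ``lgte`` is non-negative.
    """

    lais: np.ndarray
    lgte: np.ndarray
    h_local: np.ndarray  # -log2 p(x_t), marginal over the lag-set eligible samples
    h_joint: np.ndarray  # -log2 p(x_t, x_t^-)
    h_joint_lag1: np.ndarray  # -log2 p(x_t, x_{t-1})
    h_past_lag1: np.ndarray  # -log2 p(x_{t-1}) over the lag-1 eligible samples
    lags: tuple[int, ...]
    t0: int

    @property
    def n(self) -> int:
        return int(self.lais.size)


# ---------------------------------------------------------------------------
# integer-coded counting kernels
# ---------------------------------------------------------------------------


def _check_lags(path: ScanPath, lags, eligible_from: int | None) -> tuple[tuple[int, ...], int]:
    lags = tuple(lags.lags if isinstance(lags, LagSet) else lags)
    max_lag = max(lags) if lags else 0
    t0 = max_lag if eligible_from is None else int(eligible_from)
    if t0 < max_lag:
        raise ValueError("eligible_from must be >= max(lags)")
    if path.n <= t0:
        raise InsufficientDataError(
            f"sequence of length {path.n} too short for history of {t0} samples"
        )
    return lags, t0


def _columns(x: np.ndarray, lags: tuple[int, ...], t0: int) -> list[np.ndarray]:
    """0-based symbol columns [x_t, x_{t-l1}, ...] over eligible t >= t0."""
    n = x.size
    cols = [x[t0:n] - 1]
    cols.extend(x[t0 - l : n - l] - 1 for l in lags)
    return cols


def _encode(cols: list[np.ndarray], A: int) -> np.ndarray:
    code = np.zeros_like(cols[0])
    for c in cols:
        code = code * A + c
    return code


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    return max(float(np.log2(n) - xlogy(counts, counts).sum() / (n * _LOG2)), 0.0)


def _entropy_from_codes(codes: np.ndarray, n_states: int) -> float:
    return _entropy_from_counts(np.bincount(codes, minlength=0))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def plugin_distribution(
    path: ScanPath, lags: LagSet | tuple[int, ...], eligible_from: int | None = None
) -> JointDistribution:
    """Relative frequencies of ``(x_t, x_{t-l1}, ...)`` tuples.

    Counts run over all t with a complete past, ``t in {max(lags)+1, ..., n}``
    (1-based), so ``n_eff = n - max(lags)``.
    """
    lags, t0 = _check_lags(path, lags, eligible_from)
    cols = _columns(path.symbols, lags, t0)
    stacked = np.stack(cols, axis=1) + 1
    tuples, counts = np.unique(stacked, axis=0, return_counts=True)
    n_eff = path.n - t0
    return JointDistribution(
        support=tuples, probs=counts / n_eff, n_eff=n_eff, A=path.A, lags=lags
    )


def shannon_entropy(dist) -> float:
    """Shannon entropy in bits, ``-sum p log2 p`` with ``0 log 0 = 0``.

    Accepts a :class:`JointDistribution` or any array of probabilities.
    """
    p = dist.probs if isinstance(dist, JointDistribution) else np.asarray(dist, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    return float(-xlogy(p, p).sum() / _LOG2)


def stationary_gaze_entropy(path: ScanPath) -> float:
    """Entropy of the marginal AOI distribution (spatial gaze dispersion)."""
    counts = np.bincount(path.symbols - 1, minlength=path.A)
    return _entropy_from_counts(counts)


def gaze_transition_entropy(path: ScanPath, eligible_from: int | None = None) -> float:
    """First-order conditional entropy ``H(X_t | X_{t-1})`` in bits.

    Computed as ``H(X_t, X_{t-1}) - H(X_{t-1})`` with both plug-in
    distributions estimated on the identical transition sample set.
    """
    if path.n < 2:
        raise InsufficientDataError("GTE requires at least 2 fixations")
    _, t0 = _check_lags(path, (1,), eligible_from)
    cols = _columns(path.symbols, (1,), t0)
    h_joint = _entropy_from_codes(_encode(cols, path.A), path.A**2)
    h_prev = _entropy_from_codes(cols[1], path.A)
    return h_joint - h_prev


def active_information_storage(
    path: ScanPath, lags: LagSet | tuple[int, ...], eligible_from: int | None = None
) -> float:
    """Mutual information ``I(X_t^-; X_t)`` between past state and next AOI.

    An empty lag set means no predictive past and yields 0 with a warning.
    """
    lag_tuple = tuple(lags.lags if isinstance(lags, LagSet) else lags)
    if not lag_tuple:
        warnings.warn("empty lag set: AIS defined as 0", stacklevel=2)
        return 0.0
    lag_tuple, t0 = _check_lags(path, lag_tuple, eligible_from)
    cols = _columns(path.symbols, lag_tuple, t0)
    a = path.A
    h_t = _entropy_from_codes(cols[0], a)
    h_past = _entropy_from_codes(_encode(cols[1:], a), a ** len(lag_tuple))
    h_joint = _entropy_from_codes(_encode(cols, a), a ** (len(lag_tuple) + 1))
    return h_t + h_past - h_joint


def conditional_mutual_information(
    path: ScanPath,
    candidate_lag: int,
    conditioning: LagSet | tuple[int, ...] = (),
    eligible_from: int | None = None,
) -> float:
    """Plug-in ``I(X_{t-candidate}; X_t | X_conditioning)`` in bits.

    With empty conditioning this reduces to the plain mutual information
    between the lagged variable and the next fixation.
    """
    cond = tuple(conditioning.lags if isinstance(conditioning, LagSet) else conditioning)
    candidate_lag = int(candidate_lag)
    if candidate_lag in cond:
        raise ValueError("candidate lag must not be in the conditioning set")
    all_lags = tuple(sorted(cond + (candidate_lag,)))
    _, t0 = _check_lags(path, all_lags, eligible_from)
    x = path.symbols
    a = path.A
    n = path.n
    tgt = x[t0:n] - 1
    cand = x[t0 - candidate_lag : n - candidate_lag] - 1
    if cond:
        cond_code = _encode([x[t0 - l : n - l] - 1 for l in cond], a)
        return _cmi_from_codes(tgt, cand, cond_code, a)
    h_c = _entropy_from_codes(cand, a)
    h_t = _entropy_from_codes(tgt, a)
    h_tc = _entropy_from_codes(tgt * a + cand, a * a)
    return h_c + h_t - h_tc


def _cmi_from_codes(tgt: np.ndarray, cand: np.ndarray, cond_code: np.ndarray, A: int) -> float:
    """I(cand; tgt | cond) = H(cand,cond) + H(tgt,cond) - H(tgt,cand,cond) - H(cond)."""
    n_cond = cond_code.max() + 1 if cond_code.size else 1
    h_s = _entropy_from_codes(cond_code, n_cond)
    h_cs = _entropy_from_codes(cand * n_cond + cond_code, A * n_cond)
    h_ts = _entropy_from_codes(tgt * n_cond + cond_code, A * n_cond)
    h_tcs = _entropy_from_codes((tgt * A + cand) * n_cond + cond_code, A * A * n_cond)
    return h_cs + h_ts - h_tcs - h_s


def local_measures(path: ScanPath, lags: LagSet | tuple[int, ...]) -> LocalMeasureSeries:
    """Per-fixation LAIS, LGTE and local (joint) entropies.

    The probability tables are estimated once from all eligible samples of
    the full sequence ("local" values, globally estimated distributions).
    The LAIS block uses the eligible set of the given lag set; the LGTE
    block always conditions on lag 1 with its own eligible set, matching
    the first-order comparison design.  With an empty lag set only the
    lag-1 block is defined.
    """
    lag_tuple = tuple(lags.lags if isinstance(lags, LagSet) else lags)
    x = path.symbols
    a = path.A
    n = path.n
    if n < 2:
        raise InsufficientDataError("local measures require at least 2 fixations")

    nan = np.full(n, np.nan)
    lais, h_local, h_joint = nan.copy(), nan.copy(), nan.copy()
    t0 = max(lag_tuple) if lag_tuple else 0
    if lag_tuple:
        if n <= t0:
            raise InsufficientDataError(
                f"sequence of length {n} too short for max lag {t0}"
            )
        cols = _columns(x, lag_tuple, t0)
        tgt = cols[0]
        past_code = _encode(cols[1:], a)
        joint_code = tgt * (a ** len(lag_tuple)) + past_code
        n_eff = n - t0
        cnt_t = np.bincount(tgt, minlength=a)
        cnt_p = np.bincount(past_code)
        cnt_j = np.bincount(joint_code)
        # lais = log2 [ (c_joint / c_past) / (c_target / n_eff) ]
        lais[t0:] = np.log2(cnt_j[joint_code] * n_eff / (cnt_p[past_code] * cnt_t[tgt]))
        h_local[t0:] = -np.log2(cnt_t[tgt] / n_eff)
        h_joint[t0:] = -np.log2(cnt_j[joint_code] / n_eff)

    # lag-1 block (always defined from t = 1)
    tgt1 = x[1:] - 1
    prev1 = x[:-1] - 1
    pair_code = tgt1 * a + prev1
    cnt_prev = np.bincount(prev1, minlength=a)
    cnt_pair = np.bincount(pair_code, minlength=a * a)
    lgte, h_joint_lag1, h_past_lag1 = nan.copy(), nan.copy(), nan.copy()
    lgte[1:] = -np.log2(cnt_pair[pair_code] / cnt_prev[prev1])
    h_joint_lag1[1:] = -np.log2(cnt_pair[pair_code] / (n - 1))
    h_past_lag1[1:] = -np.log2(cnt_prev[prev1] / (n - 1))

    return LocalMeasureSeries(
        lais=lais,
        lgte=lgte,
        h_local=h_local,
        h_joint=h_joint,
        h_joint_lag1=h_joint_lag1,
        h_past_lag1=h_past_lag1,
        lags=lag_tuple,
        t0=t0,
    )
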