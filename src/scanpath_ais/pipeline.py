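"""Full analysis chain: per-participant past-state optimization, local
measures on the complete scan path, per-period averaging with
joint-entropy normalization, the Markov-order group split, fixation
statistics, and contrast-coded linear mixed-effects models.

The observation unit for the mixed model is (participant x trial x
period).  The trial-period factor is Helmert-coded (baseline vs before
lane change; both vs after lane change), difficulty is deviation-coded
(easy = +1 vs the grand mean), and the random structure allows a
per-participant intercept and slope with an automatic fall-back to a
random intercept when the richer structure is singular.  REML fitting is
delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
denominator degrees of freedom use Satterthwaite's approximation,
computed here from the numerical gradient of the fixed-effect covariance
with respect to the variance parameters and the observed information of
the REML log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .embedding import EmbeddingResult, PermutationConfig, optimize_past_state
from .infotheory import LocalMeasureSeries, local_measures
from .io import PERIODS, encode_symbols

__all__ = [
    "ModelSpec",
    "ModelResult",
    "ParticipantResult",
    "PipelineConfig",
    "PipelineResult",
    "analyze_participant",
    "summarize_periods",
    "local_series_frame",
    "split_by_markov_order",
    "build_design",
    "fit_lmem",
    "fixation_statistics",
    "run_pipeline",
]

# contrast codings (zero-sum, mutually orthogonal):
# Helmert for trial period -- the two planned comparisons
_HELMERT = {
    #              baseline vs BLC      (baseline+BLC) vs ALC
    "baseline": (-0.5, -1.0 / 3.0),
    "before_lane_change": (0.5, -1.0 / 3.0),
    "after_lane_change": (0.0, 2.0 / 3.0),
}
# deviation coding for difficulty: easy vs grand mean
_DEVIATION = {"easy": 1.0, "hard": -1.0}


# ---------------------------------------------------------------------------
# per-participant analysis
# ---------------------------------------------------------------------------


@dataclass
class ParticipantResult:
    participant: str
    embedding: EmbeddingResult
    series: LocalMeasureSeries
    summaries: pd.DataFrame
    excluded: bool


def local_series_frame(labeled: pd.DataFrame, series: LocalMeasureSeries) -> pd.DataFrame:
    """Local measures aligned row-by-row to the labeled fixation table."""
    out = pd.DataFrame(
        {
            "t": np.arange(series.n),
            "aoi": labeled["aoi"].to_numpy(),
            "period": labeled["period"].to_numpy() if "period" in labeled else "none",
            "trial_id": labeled["trial_id"].to_numpy() if "trial_id" in labeled else 0,
            "lais": series.lais,
            "lgte": series.lgte,
            "h_local": series.h_local,
            "h_joint_local": series.h_joint,
            "h_joint_lag1_local": series.h_joint_lag1,
        }
    )
    return out


def summarize_periods(
    labeled: pd.DataFrame, series: LocalMeasureSeries, excluded: bool = False
) -> pd.DataFrame:
    """Average local measures per (trial, period) and normalize.

    Mean LAIS is normalized by the mean local joint entropy of the next
    fixation and the full optimized past state; mean LGTE by the mean
    joint entropy of the lag-1 pair, each over the same period samples.
    A cell with fewer than 2 defined samples or a non-positive mean joint
    entropy is flagged undefined (NaN).  Excluded participants (no
    significant storage) produce LGTE-only summaries.
    """
    if len(labeled) != series.n:
        raise ValueError("labeled table and local series are misaligned")
    participant = labeled["participant"].iloc[0]
    rows = []
    for (trial, period), grp in labeled.groupby(["trial_id", "period"], sort=True):
        if trial == 0 or period not in PERIODS:
            continue
        pos = labeled.index.get_indexer(grp.index)
        rec = {
            "participant": participant,
            "trial_id": int(trial),
            "difficulty": grp["difficulty"].iloc[0] if "difficulty" in grp else "",
            "period": period,
            "n_fixations_in_period": len(grp),
        }
        for name, num, den in (
            ("lais", series.lais[pos], series.h_joint[pos]),
            ("lgte", series.lgte[pos], series.h_joint_lag1[pos]),
        ):
            ok = np.isfinite(num)
            mean_num = float(np.mean(num[ok])) if ok.sum() else np.nan
            mean_den = float(np.mean(den[ok])) if ok.sum() else np.nan
            defined = ok.sum() >= 2 and np.isfinite(mean_den) and mean_den > 0
            if name == "lais" and excluded:
                defined = False
            rec[f"mean_{name}"] = mean_num if ok.sum() else np.nan
            rec[f"mean_joint_entropy_{'ais' if name == 'lais' else 'gte'}"] = mean_den
            rec[f"normalized_{name}"] = mean_num / mean_den if defined else np.nan
            rec[f"{name}_defined"] = bool(defined)
        rows.append(rec)
    return pd.DataFrame(rows)


def analyze_participant(
    labeled: pd.DataFrame,
    l_max: int = 5,
    perm_cfg: PermutationConfig | None = None,
    A: int = 8,
) -> ParticipantResult:
    """Optimize the past state on the full scan path, estimate local
    measures and build per-period summaries for one participant.

    The embedding runs on the complete consecutive symbol sequence; local
    LAIS uses the selected lags while local LGTE always conditions on the
    single previous fixation.  A participant whose optimization finds no
    significant storage is flagged excluded and keeps LGTE-only summaries.
    """
    path = encode_symbols(labeled, A=A)
    emb = optimize_past_state(path, l_max=l_max, cfg=perm_cfg)
    series = local_measures(path, emb.lag_set if emb.significant else ())
    summaries = summarize_periods(labeled, series, excluded=not emb.significant)
    return ParticipantResult(
        participant=str(labeled["participant"].iloc[0]),
        embedding=emb,
        series=series,
        summaries=summaries,
        excluded=not emb.significant,
    )


def split_by_markov_order(embeddings: dict[str, EmbeddingResult]) -> dict[str, str]:
    """Group participants by the optimized past state.

    ``order1`` if only lag 1 was selected, ``order_gt1`` if any selected
    lag exceeds 1, ``excluded`` if no significant storage was found.
    """
    out = {}
    for pid, emb in embeddings.items():
        if not emb.significant:
            out[pid] = "excluded"
        elif max(emb.selected) > 1:
            out[pid] = "order_gt1"
        else:
            out[pid] = "order1"
    return out


# ---------------------------------------------------------------------------
# design and mixed model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect layout of the mixed model.

    ``response`` names a column of the period summaries; period is
    Helmert-coded, difficulty deviation-coded, and the interaction block
    holds their products.  ``random_structure`` is ``"intercept"`` or
    ``"intercept+period"`` (per-participant slopes on the two period
    contrasts).
    """

    response: str = "normalized_lais"
    include_interaction: bool = True
    random_structure: str = "intercept+period"

    coding: dict = field(
        default_factory=lambda: {
            "difficulty": {"scheme": "deviation", "easy": 1.0, "hard": -1.0},
            "period": {"scheme": "helmert", "contrasts": dict(_HELMERT)},
        }
    )


def build_design(summaries: pd.DataFrame, spec: ModelSpec | None = None):
    """Design matrix, response and grouping for the mixed model.

    One observation per (participant, trial, period); rows whose response
    is undefined are dropped.  Returns ``(X, y, groups, Z, report)``
    where ``Z`` holds the random-effect columns and ``report`` lists
    missing factor levels per participant.
    """
    spec = spec if spec is not None else ModelSpec()
    df = summaries.dropna(subset=[spec.response]).copy()
    if df.empty:
        raise ValueError(f"no defined observations for response {spec.response!r}")
    c1 = df["period"].map({k: v[0] for k, v in _HELMERT.items()})
    c2 = df["period"].map({k: v[1] for k, v in _HELMERT.items()})
    d = df["difficulty"].map(_DEVIATION)
    if d.isna().any() or c1.isna().any():
        raise ValueError("unknown difficulty or period level in summaries")
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "difficulty": d.to_numpy(float),
            "period_blc": c1.to_numpy(float),
            "period_alc": c2.to_numpy(float),
        },
        index=df.index,
    )
    if spec.include_interaction:
        X["difficulty:period_blc"] = X["difficulty"] * X["period_blc"]
        X["difficulty:period_alc"] = X["difficulty"] * X["period_alc"]
    y = df[spec.response].to_numpy(float)
    groups = df["participant"].to_numpy()
    if spec.random_structure == "intercept+period":
        Z = X[["intercept", "period_blc", "period_alc"]].copy()
    elif spec.random_structure == "intercept":
        Z = X[["intercept"]].copy()
    else:
        raise ValueError(f"unknown random structure {spec.random_structure!r}")

    report = []
    full = {(p, q) for p in df["period"].unique() for q in df["difficulty"].unique()}
    for pid, grp in df.groupby("participant"):
        have = set(zip(grp["period"], grp["difficulty"]))
        missing = sorted(full - have)
        if missing:
            report.append({"participant": pid, "missing_levels": missing})
    return X, y, groups, Z, report


@dataclass
class ModelResult:
    """Fixed-effect table with Satterthwaite df plus fit diagnostics."""

    table: pd.DataFrame  # term, estimate, se, df, t, p
    converged: bool
    singular: bool
    random_structure: str
    fallback: bool
    metadata: dict


def _group_blocks(X, Z, y, groups):
    order = np.argsort(groups, kind="stable")
    Xs, Zs, ys, gs = X[order], Z[order], y[order], groups[order]
    blocks = []
    start = 0
    for i in range(1, len(gs) + 1):
        if i == len(gs) or gs[i] != gs[start]:
            blocks.append((Xs[start:i], Zs[start:i], ys[start:i]))
            start = i
    return blocks


def _vech(G):
    q = G.shape[0]
    return np.array([G[i, j] for i in range(q) for j in range(i + 1)])


def _vech_inv(v, q):
    G = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            G[i, j] = G[j, i] = v[k]
            k += 1
    return G


def _reml_pieces(theta, blocks, q):
    """(-2 restricted loglike pieces, fixed-effect covariance) at theta."""
    G = _vech_inv(theta[:-1], q)
    s2 = theta[-1]
    if s2 <= 0:
        return None
    p = blocks[0][0].shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for Xi, Zi, yi in blocks:
        V = Zi @ G @ Zi.T + s2 * np.eye(len(yi))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdet += 2.0 * np.log(np.diag(L)).sum()
        Wx = np.linalg.solve(L, Xi)
        Wy = np.linalg.solve(L, yi)
        XtViX += Wx.T @ Wx
        XtViy += Wx.T @ Wy
        ytViy += Wy @ Wy
    C = np.linalg.inv(XtViX)
    beta = C @ XtViy
    quad = ytViy - beta @ XtViy
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    ll = -0.5 * (logdet + logdet_xvx + quad)
    return ll, C, beta


def _num_grad(f, x, h):
    g = np.zeros_like(x)
    for j in range(x.size):
        e = np.zeros_like(x)
        e[j] = h[j]
        fp, fm = f(x + e), f(x - e)
        g[j] = (fp - fm) / (2 * h[j])
    return g


def _num_hess(f, x, h):
    d = x.size
    H = np.zeros((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        for j in range(i, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _chol_to_theta(params, q):
    """(vech(L), s2) -> (vech(G), s2) with G = L L'."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = params[k]
            k += 1
    G = L @ L.T
    return np.append(_vech(G), params[-1])


def _satterthwaite_df(theta, blocks, q, n_obs, p):
    """Per-coefficient Satterthwaite df at the REML optimum.

    df_j = 2 [C]_jj^2 / (g_j' A g_j), with g_j the gradient of the j-th
    fixed-effect variance w.r.t. the variance parameters and A the inverse
    observed information of the restricted log-likelihood.  Both are
    evaluated in the Cholesky-factor parametrization of the random-effect
    covariance (smooth, PSD by construction), after polishing the fitted
    estimate to a critical point of the restricted likelihood.  Falls
    back to the residual df (n - p) when the information matrix is not
    usable (e.g. variance estimates on the boundary).
    """
    from scipy.optimize import minimize

    resid_df = max(n_obs - p, 1)
    G = _vech_inv(theta[:-1], q)
    s2 = max(theta[-1], 1e-10)
    eig, vec = np.linalg.eigh(G)
    G_psd = (vec * np.clip(eig, 0.0, None)) @ vec.T
    try:
        L = np.linalg.cholesky(G_psd + 1e-12 * s2 * np.eye(q))
    except np.linalg.LinAlgError:
        return np.full(p, float(resid_df)), True
    params = np.append(_vech(L), s2)

    def negll(pr):
        out = _reml_pieces(_chol_to_theta(pr, q), blocks, q)
        return np.inf if out is None else -out[0]

    # polish: optimizer stopping points of the delegated fitter are not
    # always critical points of the restricted likelihood, and the
    # Hessian below is meaningless away from one
    opt = minimize(negll, params, method="Nelder-Mead",
                   options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8})
    if np.isfinite(opt.fun):
        params = opt.x

    scale = max(abs(params[-1]), 1e-10)
    h = 1e-4 * np.maximum(np.abs(params), 0.05 * np.sqrt(scale))
    h[-1] = 1e-4 * max(abs(params[-1]), 0.05 * scale)

    def ll_of(pr):
        out = _reml_pieces(_chol_to_theta(pr, q), blocks, q)
        return np.nan if out is None else out[0]

    def cjj_of(pr, j):
        out = _reml_pieces(_chol_to_theta(pr, q), blocks, q)
        return np.nan if out is None else out[1][j, j]

    H = _num_hess(ll_of, params, h)
    if not np.all(np.isfinite(H)):
        return np.full(p, float(resid_df)), True
    info = -H
    # drop near-null information directions (boundary fits); treating them
    # as known is the lesser evil compared to exploding variances
    ev, V = np.linalg.eigh(info)
    keep = ev > 1e-8 * max(ev.max(), 1e-300)
    if not keep.any():
        return np.full(p, float(resid_df)), True
    A = (V[:, keep] / ev[keep]) @ V[:, keep].T
    base = _reml_pieces(_chol_to_theta(params, q), blocks, q)
    dfs = np.empty(p)
    fell_back = False
    for j in range(p):
        g = _num_grad(lambda pr: cjj_of(pr, j), params, h)
        denom = float(g @ A @ g)
        if not np.isfinite(denom) or denom <= 0 or not np.all(np.isfinite(g)):
            dfs[j] = resid_df
            fell_back = True
            continue
        dfs[j] = np.clip(2.0 * base[1][j, j] ** 2 / denom, 1.0, resid_df)
    return dfs, fell_back


def _is_singular(cov_re: np.ndarray, scale: float, eig_tol=1e-8, corr_tol=0.999) -> bool:
    """Boundary (rank-deficient) random structure.

    Flags vanishing random-effect variance directions (relative to the
    residual scale) and essentially perfect correlations between random
    effects.  Interior but poorly identified fits are NOT flagged: they
    keep the full structure, and the Satterthwaite stage handles them;
    discarding genuinely present variance components would understate the
    fixed-effect uncertainty.
    """
    eig = np.linalg.eigvalsh(cov_re)
    if eig.min() < eig_tol * max(scale, 1e-12):
        return True
    sd = np.sqrt(np.clip(np.diag(cov_re), 1e-300, None))
    corr = cov_re / np.outer(sd, sd)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    return bool(off.size and np.abs(off).max() > corr_tol)


def fit_lmem(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    Z: pd.DataFrame | None = None,
    reml: bool = True,
) -> ModelResult:
    """REML mixed model with Satterthwaite-approximate df per coefficient.

    Random structure is given by the columns of ``Z`` (default: intercept
    only).  A singular richer structure (any random-effect variance
    estimated at the boundary) triggers an automatic refit with a random
    intercept only, recorded in the result.
    """
    import statsmodels.api as sm

    Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(Xv.shape[1])]
    Zv = (
        Z.to_numpy(float)
        if isinstance(Z, pd.DataFrame)
        else (np.ones((len(y), 1)) if Z is None else np.asarray(Z, float))
    )
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("mixed model requires at least 2 participants")

    def _fit(Zmat):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, Xv, groups=groups, exog_re=Zmat)
            # optimizers can step through degenerate covariances; try a
            # sequence of methods before giving up
            for method in (["lbfgs", "bfgs"], ["powell"], ["cg"]):
                try:
                    return model.fit(reml=reml, method=method, maxiter=500)
                except (np.linalg.LinAlgError, ValueError):
                    continue
            raise np.linalg.LinAlgError("mixed-model optimization failed")

    res = _fit(Zv)
    structure = "intercept+slope" if Zv.shape[1] > 1 else "intercept"
    cov_re = np.atleast_2d(res.cov_re.to_numpy() if hasattr(res.cov_re, "to_numpy") else res.cov_re)
    singular = _is_singular(cov_re, res.scale) or not res.converged
    fallback = False
    if singular and Zv.shape[1] > 1:
        warnings.warn("singular random structure; refitting with random intercept only", stacklevel=2)
        Zv = np.ones((len(y), 1))
        res = _fit(Zv)
        structure = "intercept"
        fallback = True
        cov_re = np.atleast_2d(res.cov_re.to_numpy() if hasattr(res.cov_re, "to_numpy") else res.cov_re)
        singular = _is_singular(cov_re, res.scale) or not res.converged

    q = Zv.shape[1]
    theta = np.append(_vech(cov_re), res.scale)
    blocks = _group_blocks(Xv, Zv, y, groups)
    pieces = _reml_pieces(theta, blocks, q)
    if pieces is None:  # scale at 0: nudge for the covariance evaluation
        theta[-1] = max(theta[-1], 1e-10)
        pieces = _reml_pieces(theta, blocks, q)
    _, C, beta = pieces
    se = np.sqrt(np.diag(C))
    dfs, df_fallback = _satterthwaite_df(theta, blocks, q, len(y), Xv.shape[1])
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
    table = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se,
            "df": dfs,
            "t": tvals,
            "p": pvals,
        }
    )
    return ModelResult(
        table=table,
        converged=bool(res.converged),
        singular=singular,
        random_structure=structure,
        fallback=fallback,
        metadata={
            "reml": reml,
            "scale": float(res.scale),
            "cov_re": cov_re.tolist(),
            "df_method": "satterthwaite" + (" (residual fallback)" if df_fallback else ""),
            "coding": {
                "difficulty": "deviation (easy=+1, hard=-1)",
                "period": "Helmert (baseline vs BLC; both vs ALC), +/-1/2 and +/-1/3 scaling",
            },
        },
    )


# ---------------------------------------------------------------------------
# fixation statistics
# ---------------------------------------------------------------------------


@dataclass
class FixationStatistics:
    aoi_proportions: pd.DataFrame  # period x aoi, rows sum to 1
    mean_durations: pd.DataFrame  # participant x condition means (ms)
    spearman: pd.DataFrame  # condition x condition correlation matrix
    spearman_p: pd.DataFrame


def fixation_statistics(labeled: pd.DataFrame, A: int = 8) -> FixationStatistics:
    """AOI proportions per period, per-participant mean durations, and the
    Spearman consistency of inter-individual duration differences across
    conditions (average-rank ties)."""
    task = labeled[labeled["period"].isin(PERIODS)]
    prop = (
        task.groupby("period")["aoi"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=range(1, A + 1), fill_value=0.0)
    )

    frames = []
    per_period = task.groupby(["participant", "period"])["duration_ms"].mean().unstack()
    frames.append(per_period)
    if "difficulty" in task.columns:
        per_diff = task.groupby(["participant", "difficulty"])["duration_ms"].mean().unstack()
        frames.append(per_diff)
    means = pd.concat(frames, axis=1)

    conds = list(means.columns)
    if len(means) < 2:
        raise ValueError("Spearman consistency requires >= 2 participants")
    r = pd.DataFrame(np.eye(len(conds)), index=conds, columns=conds)
    pv = pd.DataFrame(np.zeros((len(conds), len(conds))), index=conds, columns=conds)
    for i, a in enumerate(conds):
        for j, b in enumerate(conds):
            if i < j:
                rho, p = stats.spearmanr(means[a], means[b], nan_policy="omit")
                r.loc[a, b] = r.loc[b, a] = rho
                pv.loc[a, b] = pv.loc[b, a] = p
    return FixationStatistics(
        aoi_proportions=prop, mean_durations=means, spearman=r, spearman_p=pv
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    l_max: int = 5
    alpha: float = 0.05
    n_permutations: int = 200
    seed: int = 0
    A: int = 8
    min_duration_ms: float = 100.0
    max_duration_ms: float = 1500.0
    min_confidence: float = 0.9
    baseline_len: int = 5
    normalize: bool = True
    trial_level: bool = True  # (participant x trial x period) observations
    random_structure: str = "intercept+period"


@dataclass
class PipelineResult:
    summaries: pd.DataFrame
    embeddings: dict[str, EmbeddingResult]
    groups: dict[str, str]
    model_results: pd.DataFrame
    fixation_stats: FixationStatistics
    filter_log: object
    participants: dict[str, ParticipantResult]


def _participant_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def run_pipeline(
    fixations: pd.DataFrame, events: pd.DataFrame, cfg: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full study pipeline on a cohort of fixation recordings.

    Filters fixations, assigns trial periods, optimizes each participant's
    past state, estimates local measures on the full sequences, averages
    and normalizes per (trial, period), splits participants by detected
    Markov order and fits the contrast-coded mixed models per group and
    measure (normalized LAIS for included participants; normalized LGTE
    for everyone).
    """
    from .io import assign_periods, filter_fixations, validate_fixation_table

    cfg = cfg if cfg is not None else PipelineConfig()
    fixations = validate_fixation_table(fixations, A=cfg.A)
    filtered, flog = filter_fixations(
        fixations, cfg.min_duration_ms, cfg.max_duration_ms, cfg.min_confidence
    )
    labeled = assign_periods(filtered, events, baseline_len=cfg.baseline_len)

    participants = {}
    for i, (pid, sub) in enumerate(labeled.groupby("participant", sort=True)):
        perm_cfg = PermutationConfig(
            n_permutations=cfg.n_permutations,
            alpha=cfg.alpha,
            seed=_participant_seed(cfg.seed, i),
        )
        participants[str(pid)] = analyze_participant(
            sub.reset_index(drop=True), l_max=cfg.l_max, perm_cfg=perm_cfg, A=cfg.A
        )

    embeddings = {pid: r.embedding for pid, r in participants.items()}
    groups = split_by_markov_order(embeddings)
    summaries = pd.concat([r.summaries for r in participants.values()], ignore_index=True)

    model_rows = []
    for group_name in ("order_gt1", "order1"):
        members = [pid for pid, g in groups.items() if g == group_name]
        if len(members) < 2:
            continue
        sub = summaries[summaries["participant"].isin(members)]
        if not cfg.trial_level:
            sub = (
                sub.groupby(["participant", "period", "difficulty"], as_index=False)
                .mean(numeric_only=True)
            )
        for measure in ("normalized_lais", "normalized_lgte"):
            response = measure if cfg.normalize else measure.replace("normalized_", "mean_")
            spec = ModelSpec(response=response, random_structure=cfg.random_structure)
            try:
                X, y, grp, Z, _ = build_design(sub, spec)
                res = fit_lmem(X, y, grp, Z)
            except ValueError:
                continue
            t = res.table.copy()
            t.insert(0, "measure", measure)
            t.insert(0, "group", group_name)
            t["singular_fallback"] = res.fallback
            model_rows.append(t)
    model_results = (
        pd.concat(model_rows, ignore_index=True) if model_rows else pd.DataFrame()
    )
    fstats = fixation_statistics(labeled, A=cfg.A)
    return PipelineResult(
        summaries=summaries,
        embeddings=embeddings,
        groups=groups,
        model_results=model_results,
        fixation_stats=fstats,
        filter_log=flog,
        participants=participants,
    )
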