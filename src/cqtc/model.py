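"""Pre-specified linear mixed-effects concentration-QTc models.

Two model kinds are supported, both regressions of dQTcF (ms) on plasma
concentration with class effects:

* ``parent`` - fixed effects: intercept, treatment, Day-7, deviation of the
  period baseline from the grand mean, nominal-time class (reference 0 h),
  parent-drug concentration slope, and a Day-7 x slope interaction; random
  intercept and random concentration slope per subject (11 fixed-effect
  columns).
* ``parent_metabolite`` - adds a metabolite concentration slope, its Day-7
  interaction, and a random metabolite slope (13 fixed-effect columns).

Estimation is maximum likelihood: fixed effects are profiled out by
generalized least squares at each variance-parameter iterate, and the
variance components (random-effects covariance G via a log-Cholesky
parameterization, residual variance via log sigma) are optimized by bounded
quasi-Newton.  A simplification ladder mirrors standard practice when the
unstructured random-effects covariance does not converge: unstructured ->
diagonal -> intercept-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceFailure, DesignMatrixError, ModelFitError, RankError

#: Post-dose nominal-time class levels; 0 h is the reference level.
NTIME_LEVELS = (1.0, 2.0, 4.0, 8.0, 24.0)
ALLOWED_NTIMES = (0.0,) + NTIME_LEVELS

LADDER = ("unstructured", "diagonal", "intercept_only")

_LOG_SD_BOUNDS = (np.log(1e-5), np.log(1e4))
_LOG_SIGMA_FLOOR = 0.5 * np.log(1e-10)  # sigma^2 >= 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Which analytes enter the fixed and random effects."""

    kind: str = "parent"  # "parent" | "parent_metabolite"

    def __post_init__(self):
        if self.kind not in ("parent", "parent_metabolite"):
            raise DesignMatrixError(f"unknown model kind {self.kind!r}")

    @property
    def analytes(self):
        return ("parent", "metabolite") if self.kind == "parent_metabolite" else ("parent",)

    @property
    def fixed_effect_names(self):
        names = ["intercept", "trt", "day7", "baseline_dev",
                 *(f"ntime_{t:g}" for t in NTIME_LEVELS),
                 "cp_parent", "day7_cp_parent"]
        if self.kind == "parent_metabolite":
            names += ["cp_metabolite", "day7_cp_metabolite"]
        return names

    @property
    def random_effect_names(self):
        names = ["intercept", "cp_parent"]
        if self.kind == "parent_metabolite":
            names.append("cp_metabolite")
        return names


@dataclass
class DesignData:
    """Design matrices plus bookkeeping, as consumed by ``fit_ml``."""

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    groups: np.ndarray  # integer subject codes, one per row
    fe_names: list
    re_names: list
    subject_ids: list   # code -> original id


def build_design(obs: pd.DataFrame, spec: ModelSpec,
                 include_day1_predose: bool = False) -> DesignData:
    """Code the matched analysis table into fixed (X) and random (Z) designs.

    Reference levels are placebo, Day 1 and nominal time 0.  Day-1 pre-dose
    rows are structural zeros of dQTcF (the baseline is that same triplicate
    average) and are excluded from fitting by default; the time-0 class level
    remains populated by Day-7 pre-dose (trough) rows.
    """
    df = obs
    if not include_day1_predose and "predose_day1" in df.columns:
        df = df[~df["predose_day1"].astype(bool)]
    df = df.reset_index(drop=True)
    if df.empty:
        raise DesignMatrixError("no rows to model")

    ntime = df["nominal_time_h"].astype(float).to_numpy()
    bad = ~np.isin(ntime, ALLOWED_NTIMES)
    if bad.any():
        raise DesignMatrixError(
            f"unseen nominal-time class level(s): {sorted(set(ntime[bad]))}"
        )
    trt = df["trt"].astype(float).to_numpy()
    day7 = df["day7"].astype(float).to_numpy()
    if not set(np.unique(trt)) <= {0.0, 1.0} or not set(np.unique(day7)) <= {0.0, 1.0}:
        raise DesignMatrixError("trt and day7 must be 0/1 indicators")

    cp_p = df["cp_parent"].astype(float).to_numpy()
    if np.isnan(cp_p).any():
        raise DesignMatrixError("cp_parent contains missing values")
    cols = [np.ones(len(df)), trt, day7, df["baseline_dev_ms"].astype(float).to_numpy()]
    cols += [(ntime == t).astype(float) for t in NTIME_LEVELS]
    cols += [cp_p, day7 * cp_p]
    z_cols = [np.ones(len(df)), cp_p]
    if spec.kind == "parent_metabolite":
        cp_m = df["cp_metabolite"].astype(float).to_numpy()
        if np.isnan(cp_m[trt == 1]).any():
            raise DesignMatrixError(
                "parent+metabolite model requires a metabolite concentration "
                "on every active row"
            )
        cp_m = np.nan_to_num(cp_m)  # placebo rows are structurally 0
        cols += [cp_m, day7 * cp_m]
        z_cols += [cp_m]

    X = np.column_stack(cols)
    Z = np.column_stack(z_cols)
    y = df["dqtcf_ms"].astype(float).to_numpy()
    codes, uniques = pd.factorize(df["subject_id"])
    return DesignData(X, Z, y, codes.astype(int), spec.fixed_effect_names,
                      spec.random_effect_names, list(uniques))


@dataclass
class FitResult:
    """ML estimates of a fitted C-QTc mixed model."""

    beta: np.ndarray
    beta_cov: np.ndarray
    fe_names: list
    re_cov: np.ndarray
    re_names: list
    sigma2: float
    loglik: float
    converged: bool
    structure_used: str
    df_method: str
    n_obs: int
    n_subjects: int
    attempts: list = field(default_factory=list)
    # internals kept for Satterthwaite df and diagnostics
    _blocks: list = field(default_factory=list, repr=False)
    _theta: np.ndarray = None
    _structure: object = None
    _theta_cov: np.ndarray = None

    @property
    def residual_df(self) -> float:
        return float(self.n_obs - len(self.beta))

    def contrast(self, L, df_method=None):
        """Estimate, SE and df for the linear combination L'beta."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.beta)
        se = float(np.sqrt(L @ self.beta_cov @ L))
        method = df_method or self.df_method
        if method == "satterthwaite":
            df = _satterthwaite_df(self, L)
        else:
            df = self.residual_df
        return est, se, df


# ---------------------------------------------------------------------------
# variance-parameter structures (log-Cholesky)
# ---------------------------------------------------------------------------

class _VarStructure:
    """Maps an unconstrained parameter vector to (G, sigma^2).

    The last parameter is always log(sigma); the leading ones parameterize
    the random-effects covariance G = L L' with log-diagonal L (so G is
    positive semidefinite by construction).
    """

    def __init__(self, name: str, q_full: int):
        self.name = name
        if name == "unstructured":
            self.q = q_full
            self.n_g = q_full * (q_full + 1) // 2
        elif name == "diagonal":
            self.q = q_full
            self.n_g = q_full
        elif name == "intercept_only":
            self.q = 1
            self.n_g = 1
        elif name == "none":
            self.q = 0
            self.n_g = 0
        else:
            raise ValueError(f"unknown random-effects structure {name!r}")
        self.n_params = self.n_g + 1

    def z_slice(self, Z):
        return Z[:, : self.q] if self.q else Z[:, :0]

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        q = self.q
        Lmat = np.zeros((q, q))
        if self.name == "unstructured":
            k = 0
            for i in range(q):
                for j in range(i + 1):
                    Lmat[i, j] = np.exp(theta[k]) if i == j else theta[k]
                    k += 1
        elif self.name in ("diagonal", "intercept_only"):
            Lmat[np.arange(q), np.arange(q)] = np.exp(theta[: self.n_g])
        G = Lmat @ Lmat.T
        sigma2 = float(np.exp(2.0 * theta[-1]))
        return G, sigma2

    def bounds(self):
        lo_sd, hi_sd = _LOG_SD_BOUNDS
        b = []
        if self.name == "unstructured":
            for i in range(self.q):
                for j in range(i + 1):
                    b.append((lo_sd, hi_sd) if i == j else (-1e4, 1e4))
        else:
            b += [(lo_sd, hi_sd)] * self.n_g
        b.append((_LOG_SIGMA_FLOOR, _LOG_SD_BOUNDS[1]))
        return b

    def start(self, sigma0, z_scales):
        """Heuristic start: modest RE variances on the scale of each Z column."""
        sd0 = [max(0.5 * sigma0 / max(z_scales[i], 1e-8), 2e-5) for i in range(self.q)]
        theta = []
        if self.name == "unstructured":
            for i in range(self.q):
                for j in range(i + 1):
                    theta.append(np.log(sd0[i]) if i == j else 0.0)
        else:
            theta += [np.log(s) for s in sd0]
        theta.append(np.log(max(sigma0, 1e-4)))
        return np.array(theta)


# ---------------------------------------------------------------------------
# profiled likelihood machinery
# ---------------------------------------------------------------------------

def _make_blocks(X, Z, y, groups):
    """Group rows by subject, then batch subjects of equal block size into
    3-D arrays so each likelihood evaluation is a handful of batched
    Cholesky factorizations instead of a per-subject Python loop."""
    order = np.argsort(groups, kind="stable")
    Xs, Zs, ys, gs = X[order], Z[order], y[order], groups[order]
    edges = np.flatnonzero(np.diff(gs)) + 1
    by_size = {}
    for Xi, Zi, yi in zip(np.split(Xs, edges), np.split(Zs, edges), np.split(ys, edges)):
        by_size.setdefault(len(yi), []).append((Xi, Zi, yi))
    batches = []
    for ni in sorted(by_size):
        items = by_size[ni]
        batches.append((np.stack([it[0] for it in items]),
                        np.stack([it[1] for it in items]),
                        np.stack([it[2] for it in items])))
    return batches


def _profile_eval(blocks, G, sigma2, q):
    """One pass over subject blocks: GLS beta, profiled ML log-likelihood.

    V_i = Z_i G Z_i' + sigma^2 I per subject; returns (loglik, beta, A) with
    A = sum X_i' V_i^-1 X_i (the inverse of the fixed-effects covariance).
    """
    p = blocks[0][0].shape[2]
    A = np.zeros((p, p))
    b = np.zeros(p)
    css = 0.0
    logdet = 0.0
    n = 0
    for Xb, Zb, yb in blocks:
        m, ni, _ = Xb.shape
        n += m * ni
        if q:
            Zq = Zb[:, :, :q]
            V = sigma2 * np.eye(ni) + Zq @ G @ np.swapaxes(Zq, 1, 2)
            c = np.linalg.cholesky(V)
            Xw = solve_triangular_batched(c, Xb)
            yw = solve_triangular_batched(c, yb[:, :, None])[:, :, 0]
            logdet += 2.0 * np.sum(np.log(np.diagonal(c, axis1=1, axis2=2)))
        else:
            s = np.sqrt(sigma2)
            Xw, yw = Xb / s, yb / s
            logdet += m * ni * np.log(sigma2)
        A += np.einsum("mij,mik->jk", Xw, Xw)
        b += np.einsum("mij,mi->j", Xw, yw)
        css += float(np.sum(yw * yw))
    beta = np.linalg.solve(A, b)
    quad = css - b @ beta
    loglik = -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    return loglik, beta, A


def solve_triangular_batched(c, B):
    """Solve lower-triangular c x = B for stacked (m, n, n) / (m, n, k)."""
    return np.linalg.solve(c, B)


def _neg_mean_loglik(theta, blocks, structure, n):
    G, s2 = structure.unpack(theta)
    try:
        ll, _, _ = _profile_eval(blocks, G, s2, structure.q)
    except np.linalg.LinAlgError:
        return np.inf
    return -ll / n


def _central_gradient(f, theta, rel_h=1e-5):
    g = np.empty_like(theta)
    for j in range(len(theta)):
        h = rel_h * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        g[j] = (f(tp) - f(tm)) / (2.0 * h)
    return g


def _central_hessian(f, theta, rel_h=5e-4):
    k = len(theta)
    H = np.empty((k, k))
    hs = [rel_h * max(1.0, abs(t)) for t in theta]
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            ti = theta.copy()
            if i == j:
                ti[i] += hs[i]
                fp = f(ti)
                ti[i] -= 2 * hs[i]
                fm = f(ti)
                H[i, i] = (fp - 2 * f0 + fm) / hs[i] ** 2
            else:
                vals = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    t = theta.copy()
                    t[i] += si * hs[i]
                    t[j] += sj * hs[j]
                    vals.append(f(t))
                H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * hs[i] * hs[j]
                )
    return H


def beta_at_variance(X, Z, y, groups, G, sigma2):
    """GLS fixed effects at given variance components (G may be 0)."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    q = G.shape[0] if G.size else 0
    blocks = _make_blocks(X, Z, y, groups)
    _, beta, _ = _profile_eval(blocks, G, sigma2, q)
    return beta


def fit_ml(X, Z, y, groups, re_structure="unstructured", *,
           grad_tol=1e-6, max_restarts=3, seed=0,
           fe_names=None, re_names=None, df_method="satterthwaite") -> FitResult:
    """Maximum-likelihood fit of the mixed model.

    Fixed effects are profiled out by GLS; the variance parameters are
    optimized by L-BFGS-B on the log-Cholesky scale, with up to
    ``max_restarts`` seeded restarts before declaring non-convergence.
    Convergence requires optimizer success, a projected gradient of the mean
    log-likelihood below ``grad_tol``, and a positive-definite fixed-effects
    covariance; otherwise a :class:`ConvergenceFailure` carrying the best
    iterate is raised (consumed by :func:`fit_with_ladder`).
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if n <= p:
        raise DesignMatrixError(f"n_obs={n} must exceed n fixed effects={p}")
    n_subjects = len(np.unique(groups))
    if n_subjects < 2:
        raise DesignMatrixError("need at least 2 subjects")
    if np.linalg.matrix_rank(X) < p:
        raise RankError("fixed-effects design matrix is rank deficient")

    structure = _VarStructure(re_structure, Z.shape[1])
    blocks = _make_blocks(X, Z, y, groups)

    fe_names = list(fe_names) if fe_names is not None else [f"x{i}" for i in range(p)]
    re_names = list(re_names) if re_names is not None else [f"z{i}" for i in range(Z.shape[1])]

    if re_structure == "none":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = max(float(resid @ resid / n), 1e-10)
        ll, beta, A = _profile_eval(blocks, np.zeros((0, 0)), sigma2, 0)
        return FitResult(beta, np.linalg.inv(A), fe_names, np.zeros((0, 0)), [],
                         sigma2, float(ll), True, "none", df_method, n, n_subjects,
                         attempts=[("none", "converged")], _blocks=blocks,
                         _theta=np.array([0.5 * np.log(sigma2)]), _structure=structure)

    # starting values from the OLS residual scale
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    ms_resid = float(np.mean((y - X @ beta_ols) ** 2))
    if ms_resid < 1e-12 * max(1.0, float(np.mean(y ** 2))):
        # perfect linear fit: the likelihood is maximized at the variance
        # floor with no random effects; return the closed form directly
        q = structure.q
        sigma2 = 1e-10
        ll, beta, A = _profile_eval(blocks, np.zeros((q, q)), sigma2, q)
        return FitResult(beta, np.linalg.inv(A), fe_names, np.zeros((q, q)),
                         re_names[:q], sigma2, float(ll), True, re_structure,
                         df_method, n, n_subjects,
                         attempts=[(re_structure, "converged (perfect fit; "
                                    "variance floor)")],
                         _blocks=blocks, _structure=structure)
    sigma0 = float(np.sqrt(max(ms_resid, 1e-8)))
    z_scales = [float(np.sqrt(np.mean(Z[:, j] ** 2))) for j in range(structure.q)]
    theta0 = structure.start(sigma0, z_scales)
    bounds = structure.bounds()

    fun = lambda th: _neg_mean_loglik(th, blocks, structure, n)
    rng = np.random.default_rng(seed)
    best = None
    last_err = "optimizer failure"
    for attempt in range(max_restarts):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.5, len(theta0))
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            fun, start, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-8, "maxiter": 1000, "maxfun": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
        if not res.success:
            last_err = f"optimizer: {res.message}"
            continue
        # projected gradient: ignore components pushing outside an active bound
        g = _central_gradient(fun, res.x)
        for j, (lo, hi) in enumerate(bounds):
            if (res.x[j] <= lo + 1e-9 and g[j] > 0) or (res.x[j] >= hi - 1e-9 and g[j] < 0):
                g[j] = 0.0
        if np.max(np.abs(g)) > grad_tol:
            last_err = f"projected gradient norm {np.max(np.abs(g)):.2e} > {grad_tol:g}"
            continue
        G, sigma2 = structure.unpack(res.x)
        ll, beta, A = _profile_eval(blocks, G, sigma2, structure.q)
        try:
            np.linalg.cholesky(A)
            beta_cov = np.linalg.inv(A)
            np.linalg.cholesky(0.5 * (beta_cov + beta_cov.T) +
                               1e-12 * np.trace(beta_cov) / p * np.eye(p))
        except np.linalg.LinAlgError:
            last_err = "fixed-effects covariance not positive definite"
            continue
        return FitResult(beta, beta_cov, fe_names, G,
                         re_names[: structure.q], sigma2, float(ll), True,
                         re_structure, df_method, n, n_subjects,
                         attempts=[(re_structure, "converged")],
                         _blocks=blocks, _theta=res.x, _structure=structure)

    # best iterate, for the ladder's records
    G, sigma2 = structure.unpack(best.x)
    try:
        ll, beta, A = _profile_eval(blocks, G, sigma2, structure.q)
        best_fit = FitResult(beta, np.linalg.pinv(A), fe_names, G,
                             re_names[: structure.q], sigma2, float(ll), False,
                             re_structure, df_method, n, n_subjects,
                             _blocks=blocks, _theta=best.x, _structure=structure)
    except np.linalg.LinAlgError:
        best_fit = None
    raise ConvergenceFailure(
        f"{re_structure} random-effects fit did not converge ({last_err})",
        best=best_fit,
    )


def fit_with_ladder(obs, spec: ModelSpec, *, include_day1_predose=False,
                    ladder=LADDER, df_method="satterthwaite", seed=0,
                    grad_tol=1e-6) -> FitResult:
    """Fit with the pre-specified simplification ladder.

    Attempts the unstructured random-effects covariance first and demotes to
    diagonal, then intercept-only, on non-convergence; the structure used and
    every attempt are recorded on the result.
    """
    design = obs if isinstance(obs, DesignData) else build_design(
        obs, spec, include_day1_predose=include_day1_predose)
    attempts = []
    for structure in ladder:
        try:
            fit = fit_ml(design.X, design.Z, design.y, design.groups, structure,
                         fe_names=design.fe_names, re_names=design.re_names,
                         df_method=df_method, seed=seed, grad_tol=grad_tol)
            fit.attempts = attempts + [(structure, "converged")]
            return fit
        except ConvergenceFailure as exc:
            attempts.append((structure, str(exc)))
    raise ModelFitError(
        "no random-effects structure converged; attempts: "
        + "; ".join(f"{s}: {m}" for s, m in attempts)
    )


def _satterthwaite_df(fit: FitResult, L) -> float:
    """Satterthwaite df for L'beta: 2 v^2 / Var(v), v = L' C(theta) L.

    The gradient of v and the variance-parameter covariance (inverse observed
    information of the profiled ML log-likelihood) are both taken in the
    internal log-Cholesky coordinates, so the parameterization cancels.
    Falls back to residual df when the information matrix is degenerate.
    """
    if fit._theta is None or not fit._blocks:
        return fit.residual_df
    structure, blocks = fit._structure, fit._blocks
    if structure.name == "none" or structure.n_params == 1 and structure.q == 0:
        return fit.residual_df
    L = np.asarray(L, dtype=float)

    def v_of(theta):
        G, s2 = structure.unpack(theta)
        _, _, A = _profile_eval(blocks, G, s2, structure.q)
        C = np.linalg.inv(A)
        return float(L @ C @ L)

    def nll(theta):
        G, s2 = structure.unpack(theta)
        ll, _, _ = _profile_eval(blocks, G, s2, structure.q)
        return -ll

    try:
        if fit._theta_cov is None:
            H = _central_hessian(nll, fit._theta)
            fit._theta_cov = np.linalg.pinv(H)
        g = _central_gradient(v_of, fit._theta, rel_h=1e-4)
        v = v_of(fit._theta)
        var_v = float(g @ fit._theta_cov @ g)
        if not np.isfinite(var_v) or var_v <= 0:
            return fit.residual_df
        df = 2.0 * v ** 2 / var_v
    except np.linalg.LinAlgError:
        return fit.residual_df
    return float(np.clip(df, 1.0, fit.residual_df))


@dataclass
class SlopeSummary:
    """Day-specific concentration slope with its two-sided 95% CI."""

    day: int
    analyte: str
    estimate: float
    se: float
    df: float
    ci_low: float
    ci_high: float


def slope_summaries(fit: FitResult, spec: ModelSpec, alpha=0.05,
                    df_method=None) -> list:
    """Day-1 and Day-7 concentration slopes per analyte.

    The Day-7 slope is the contrast slope + Day7-interaction; its variance
    comes from L' beta_cov L.  Intervals are symmetric two-sided t-intervals.
    """
    if not fit.converged:
        raise ModelFitError("slope summaries require a converged fit")
    out = []
    names = fit.fe_names
    for analyte in spec.analytes:
        base = names.index(f"cp_{analyte}")
        inter = names.index(f"day7_cp_{analyte}")
        for day in (1, 7):
            L = np.zeros(len(names))
            L[base] = 1.0
            if day == 7:
                L[inter] = 1.0
            est, se, df = fit.contrast(L, df_method=df_method)
            tcrit = stats.t.ppf(1 - alpha / 2, df)
            out.append(SlopeSummary(day, analyte, est, se, df,
                                    est - tcrit * se, est + tcrit * se))
    return out


def parameter_table(fit: FitResult, alpha=0.05, df_method=None) -> pd.DataFrame:
    """Per-term estimates, SEs, df, t, p and CIs (report-table shape)."""
    rows = []
    for i, name in enumerate(fit.fe_names):
        L = np.zeros(len(fit.fe_names))
        L[i] = 1.0
        est, se, df = fit.contrast(L, df_method=df_method)
        t = est / se if se > 0 else np.nan
        pval = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        rows.append({"term": name, "estimate": est, "se": se, "df": df,
                     "t": t, "p": pval,
                     "ci_low": est - tcrit * se, "ci_high": est + tcrit * se})
    return pd.DataFrame(rows)
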