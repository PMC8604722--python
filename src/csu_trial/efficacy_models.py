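"""Longitudinal efficacy analysis: MMRM, sensitivity ANCOVA, subgroups,
and the biomarker-response correlation.

The primary analysis is a mixed model for repeated measures (MMRM): for
patient i with observed post-baseline visits V_i,

    y_i ~ MVN(X_i beta, Sigma[V_i, V_i])

with fixed effects for country, treatment arm, visit and the arm-by-visit
interaction (parameterized directly as arm-by-visit cell means plus country
contrasts) and a completely unstructured visit-by-visit covariance Sigma.
Estimation is restricted maximum likelihood with beta profiled out and Sigma
parameterized through its Cholesky factor (log-diagonal), optimized by
L-BFGS-B with a compound-symmetry restart on failure.  Missing visits
contribute through the observed-data likelihood; no imputation is performed
(the missing-at-random assumption of MMRM).

Treatment effects are least-squares mean differences versus the reference
arm at a visit, with t-based confidence intervals.  Denominator degrees of
freedom use the Satterthwaite approximation (labelled in the output; at these
sample sizes it is practically indistinguishable from Kenward-Roger) or a
fast between-subject count for simulation studies.

Sensitivity analyses impute the week-8 change by last or best observation
carried forward and fit a covariate-adjusted ANCOVA; subgroup analyses extend
the MMRM cell means with a marker stratum (three-way interaction); the
biomarker-response association is a Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "MmrmFit",
    "ContrastEstimate",
    "build_longitudinal_dataset",
    "fit_mmrm",
    "estimate_contrasts",
    "ls_means",
    "ancova_with_imputation",
    "fit_subgroup_mmrm",
    "correlate_biomarker_response",
]


@dataclass
class ContrastEstimate:
    """LS-mean difference (arm vs reference) at one visit, with 95% CI."""

    label: str
    arm: str
    visit: int
    estimate: float
    se: float
    dof: float
    lower: float
    upper: float
    dof_method: str


@dataclass
class MmrmFit:
    arms: list[str]
    weeks: list[int]
    countries: list[str]
    strata: list | None
    beta: pd.Series
    sigma: pd.DataFrame
    vcov_beta: np.ndarray
    loglik: float
    converged: bool
    n_subjects: int
    dof_method: str
    loglik_history: list[float]
    _theta: np.ndarray = field(repr=False, default=None)
    _negloglik: object = field(repr=False, default=None)
    _cnames: list[str] = field(repr=False, default=None)


def build_longitudinal_dataset(
    changes: pd.DataFrame,
    profiles: pd.DataFrame,
    weeks: tuple[int, ...] = tuple(range(1, 9)),
    endpoint: str = "uas7_change",
    bhra: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble MMRM rows: one per patient-visit with a valid change value.

    Patients with no valid post-baseline value are excluded from the model
    rows (MMRM cannot use them); they are simply absent from the output.
    """
    w = changes[changes["week"].isin(weeks) & changes["valid"]]
    w = w[w[endpoint].notna()]
    meta = profiles.set_index("patient_id")
    out = pd.DataFrame(
        {
            "patient_id": w["patient_id"].to_numpy(),
            "arm": w["patient_id"].map(meta["arm"]).to_numpy(),
            "country": w["patient_id"].map(meta["country"]).to_numpy(),
            "week": w["week"].to_numpy(),
            "value": w[endpoint].to_numpy(dtype=float),
        }
    )
    if bhra is not None:
        out["stratum"] = out["patient_id"].map(bhra).to_numpy()
    return out


# --------------------------------------------------------------------------
# internals
# --------------------------------------------------------------------------

def _theta_to_sigma(theta: np.ndarray, T: int) -> np.ndarray:
    L = np.zeros((T, T))
    tril = np.tril_indices(T)
    L[tril] = theta
    L[np.diag_indices(T)] = np.exp(np.diag(L))
    return L @ L.T


def _sigma_to_theta(sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(sigma)
    M = L.copy()
    M[np.diag_indices_from(M)] = np.log(np.diag(L))
    return M[np.tril_indices_from(M)]


def _design(df: pd.DataFrame, arms, weeks, countries, strata=None):
    """Cell-means design: one column per arm x week (x stratum) cell plus
    deviation-coded country contrasts (first country as reference)."""
    cells = []
    if strata is None:
        for a in arms:
            for w in weeks:
                cells.append(("cell", a, w, None))
    else:
        for s in strata:
            for a in arms:
                for w in weeks:
                    cells.append(("cell", a, w, s))
    names = [
        f"{a}:wk{w}" + (f":{s}" if s is not None else "") for _, a, w, s in cells
    ]
    n = len(df)
    X = np.zeros((n, len(cells) + max(len(countries) - 1, 0)))
    arm_v = df["arm"].to_numpy()
    week_v = df["week"].to_numpy()
    strat_v = df["stratum"].to_numpy() if strata is not None else None
    for j, (_, a, w, s) in enumerate(cells):
        m = (arm_v == a) & (week_v == w)
        if s is not None:
            m &= strat_v == s
        X[m, j] = 1.0
    for k, c in enumerate(countries[1:]):
        X[df["country"].to_numpy() == c, len(cells) + k] = 1.0
        names.append(f"country[{c}]")
    return X, names


def _group_patterns(df: pd.DataFrame, X: np.ndarray, weeks: list[int]):
    """Group patients by observed-visit pattern for vectorized likelihood."""
    widx = {w: i for i, w in enumerate(weeks)}
    groups: dict[tuple, list] = {}
    for pid, g in df.groupby("patient_id", sort=True):
        order = np.argsort(g["week"].to_numpy())
        rows = g.index.to_numpy()[order]
        pat = tuple(widx[w] for w in g["week"].to_numpy()[order])
        groups.setdefault(pat, []).append(rows)
    out = []
    pos = {ix: i for i, ix in enumerate(df.index)}
    for pat, members in groups.items():
        ridx = np.array([[pos[r] for r in rows] for rows in members])
        Y = df["value"].to_numpy()[ridx]  # (n_g, k)
        Xg = X[ridx]                       # (n_g, k, p)
        out.append((np.array(pat), Y, Xg))
    return out


def _make_negloglik(patterns, p: int, T: int):
    """Profiled (beta eliminated) negative REML log-likelihood of theta."""

    def negloglik(theta, want_beta=False):
        sigma = _theta_to_sigma(theta, T)
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdet = 0.0
        for pat, Y, Xg in patterns:
            S = sigma[np.ix_(pat, pat)]
            try:
                Lc = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                return (np.inf, None, None) if want_beta else np.inf
            Sinv = np.linalg.inv(S)
            n_g = Y.shape[0]
            logdet += 2.0 * n_g * np.log(np.diag(Lc)).sum()
            XtWX += np.einsum("nkp,kl,nlq->pq", Xg, Sinv, Xg, optimize=True)
            XtWy += np.einsum("nkp,kl,nl->p", Xg, Sinv, Y, optimize=True)
            ytWy += np.einsum("nk,kl,nl->", Y, Sinv, Y, optimize=True)
        sign, ld2 = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return (np.inf, None, None) if want_beta else np.inf
        beta = np.linalg.solve(XtWX, XtWy)
        quad = ytWy - beta @ XtWy
        nll = 0.5 * (logdet + ld2 + quad)
        if want_beta:
            return nll, beta, XtWX
        return nll

    return negloglik


def fit_mmrm(
    data: pd.DataFrame,
    reference_arm: str | None = None,
    dof_method: str = "satterthwaite",
    maxiter: int = 500,
) -> MmrmFit:
    """Fit the MMRM by REML.  ``data`` needs columns patient_id, arm,
    country, week, value (and optionally stratum for subgroup models).

    Raises on non-convergence (after a compound-symmetry restart); a single
    country level is dropped from the design with a warning.
    """
    df = data.reset_index(drop=True)
    arms = sorted(df["arm"].unique())
    if reference_arm is not None:
        arms = [reference_arm] + [a for a in arms if a != reference_arm]
    weeks = sorted(int(w) for w in df["week"].unique())
    countries = sorted(df["country"].unique())
    strata = sorted(df["stratum"].unique()) if "stratum" in df.columns else None
    if strata is not None and len(strata) < 2:
        strata = None
    if len(weeks) < 1 or len(arms) < 2:
        raise ValueError("MMRM needs >= 2 arms and >= 1 visit")
    if len(countries) < 2:
        if len(countries) == 1:
            warnings.warn("single country level; country dropped from the design")
        countries = countries[:1]

    X, names = _design(df, arms, weeks, countries, strata)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"singular design ({X.shape[1]} columns, rank {rank}); "
            "check for empty arm-visit cells"
        )
    T = len(weeks)
    patterns = _group_patterns(df, X, weeks)
    negloglik = _make_negloglik(patterns, X.shape[1], T)

    # initial covariance: compound symmetry from per-cell residual variance
    resid_var = float(df.groupby(["arm", "week"])["value"].var().mean())
    if not np.isfinite(resid_var) or resid_var <= 0:
        resid_var = max(float(df["value"].var()), 1e-3)
    inits = [
        _sigma_to_theta(resid_var * (0.6 * np.eye(T) + 0.4 * np.ones((T, T)))),
        _sigma_to_theta(resid_var * np.eye(T)),
    ]

    best = None
    history: list[float] = []
    for theta0 in inits:
        hist: list[float] = []
        res = minimize(
            negloglik, theta0, method="L-BFGS-B",
            callback=lambda th: hist.append(float(negloglik(th))),
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best, history = res, hist
        if res.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("MMRM REML optimization failed to produce a finite fit")
    # accept: optimizer success, a flat final step, or a (near-)zero gradient
    # (the line search aborts with nit=0 when the init already sits at the
    # optimum, e.g. single-visit saturated models)
    grad_ok = (
        getattr(best, "jac", None) is not None
        and np.max(np.abs(best.jac)) < 1e-3 * max(1.0, abs(best.fun))
    )
    converged = bool(
        best.success
        or grad_ok
        or (len(history) > 1 and abs(history[-1] - history[-2]) < 1e-6)
    )
    if not converged:
        raise RuntimeError(
            f"MMRM did not converge: {best.message}; "
            f"loglik trace {[-h for h in history[-5:]]}"
        )

    nll, beta, XtWX = negloglik(best.x, want_beta=True)
    sigma = _theta_to_sigma(best.x, T)
    return MmrmFit(
        arms=arms,
        weeks=weeks,
        countries=countries,
        strata=strata,
        beta=pd.Series(beta, index=names),
        sigma=pd.DataFrame(sigma, index=weeks, columns=weeks),
        vcov_beta=np.linalg.inv(XtWX),
        loglik=-float(nll),
        converged=converged,
        n_subjects=df["patient_id"].nunique(),
        dof_method=dof_method,
        loglik_history=[-h for h in history],
        _theta=best.x,
        _negloglik=negloglik,
        _cnames=names,
    )


def _observed_information(fit: MmrmFit, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of the negative REML criterion at the
    optimum (cached on the fit: several contrasts share one Hessian)."""
    cached = getattr(fit, "_obs_info", None)
    if cached is not None:
        return cached
    theta = fit._theta
    m = len(theta)
    H = np.empty((m, m))
    f0 = float(fit._negloglik(theta))
    fp = np.empty(m)
    fm = np.empty(m)
    for j in range(m):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        fp[j] = float(fit._negloglik(tp))
        fm[j] = float(fit._negloglik(tm))
    for j in range(m):
        H[j, j] = (fp[j] - 2 * f0 + fm[j]) / h**2
        for k in range(j + 1, m):
            tpp = theta.copy(); tpp[[j, k]] += h
            tmm = theta.copy(); tmm[[j, k]] -= h
            H[j, k] = H[k, j] = (
                float(fit._negloglik(tpp)) - fp[j] - fp[k] + 2 * f0
                - fm[j] - fm[k] + float(fit._negloglik(tmm))
            ) / (2 * h**2)
    fit._obs_info = H
    return H


def _satterthwaite_dof(fit: MmrmFit, c: np.ndarray) -> float:
    """Satterthwaite dof: 2 v^2 / Var(v), v = c' Vbeta c, via the delta
    method with the observed information of the covariance parameters."""
    theta = fit._theta
    m = len(theta)
    h = 1e-4

    def var_of_contrast(th):
        nll, beta, XtWX = fit._negloglik(th, want_beta=True)
        return float(c @ np.linalg.inv(XtWX) @ c)

    v0 = var_of_contrast(theta)
    grad = np.empty(m)
    for j in range(m):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        grad[j] = (var_of_contrast(tp) - var_of_contrast(tm)) / (2 * h)

    H = _observed_information(fit, h)
    try:
        var_v = float(grad @ np.linalg.solve(H, grad))
    except np.linalg.LinAlgError:
        var_v = float(grad @ np.linalg.pinv(H) @ grad)
    if var_v <= 0:
        return float(fit.n_subjects - len(fit.arms))
    return max(2.0 * v0**2 / var_v, 1.0)


def _contrast_vector(fit: MmrmFit, arm: str, visit: int, stratum=None) -> np.ndarray:
    suffix = f":{stratum}" if stratum is not None else ""
    c = np.zeros(len(fit._cnames))
    c[fit._cnames.index(f"{arm}:wk{visit}{suffix}")] = 1.0
    c[fit._cnames.index(f"{fit.arms[0]}:wk{visit}{suffix}")] = -1.0
    return c


def estimate_contrasts(
    fit: MmrmFit, visit: int, dof_method: str | None = None
) -> list[ContrastEstimate]:
    """LS-mean difference vs the reference arm at ``visit`` for each active
    arm (within each stratum for subgroup fits), with unadjusted 95% CIs."""
    if visit not in fit.weeks:
        raise ValueError(f"visit {visit} not in the fitted model (weeks {fit.weeks})")
    if not fit.converged:
        raise RuntimeError("contrasts require a converged fit")
    method = dof_method or fit.dof_method
    out = []
    strata = fit.strata if fit.strata is not None else [None]
    for s in strata:
        for arm in fit.arms[1:]:
            c = _contrast_vector(fit, arm, visit, s)
            est = float(c @ fit.beta.to_numpy())
            se = float(np.sqrt(c @ fit.vcov_beta @ c))
            if method == "satterthwaite":
                dof = _satterthwaite_dof(fit, c)
            else:
                dof = float(fit.n_subjects - len(fit.arms))
            tq = stats.t.ppf(0.975, dof)
            label = f"{arm} vs {fit.arms[0]} at week {visit}"
            if s is not None:
                label += f" [{s}]"
            out.append(
                ContrastEstimate(
                    label=label, arm=arm, visit=visit, estimate=est, se=se,
                    dof=dof, lower=est - tq * se, upper=est + tq * se,
                    dof_method=method,
                )
            )
    return out


def ls_means(fit: MmrmFit, visit: int) -> pd.DataFrame:
    """Model-adjusted (LS) mean change per arm at a visit, averaging country
    effects with equal weights, with t-based 95% CIs (between-subject dof)."""
    rows = []
    ncell = len(fit._cnames) - max(len(fit.countries) - 1, 0)
    strata = fit.strata if fit.strata is not None else [None]
    for s in strata:
        for arm in fit.arms:
            suffix = f":{s}" if s is not None else ""
            c = np.zeros(len(fit._cnames))
            c[fit._cnames.index(f"{arm}:wk{visit}{suffix}")] = 1.0
            if len(fit.countries) > 1:
                c[ncell:] = 1.0 / len(fit.countries)
            est = float(c @ fit.beta.to_numpy())
            se = float(np.sqrt(c @ fit.vcov_beta @ c))
            dof = float(fit.n_subjects - len(fit.arms))
            tq = stats.t.ppf(0.975, dof)
            rows.append(
                {"arm": arm, "stratum": s, "visit": visit, "lsmean": est,
                 "se": se, "lower": est - tq * se, "upper": est + tq * se}
            )
    return pd.DataFrame(rows)


def fit_subgroup_mmrm(
    data: pd.DataFrame, reference_arm: str | None = None, **kw
) -> MmrmFit:
    """MMRM extended with a marker stratum (arm x visit x stratum cells).

    ``data`` must carry a ``stratum`` column (e.g. BHRA status).  With a
    single stratum level present this reduces exactly to :func:`fit_mmrm`.
    Empty stratum cells make the design singular; callers should check
    subgroup occupancy.
    """
    if "stratum" not in data.columns:
        raise ValueError("subgroup MMRM needs a 'stratum' column")
    return fit_mmrm(data, reference_arm=reference_arm, **kw)


# --------------------------------------------------------------------------
# sensitivity ANCOVA with simple imputation
# --------------------------------------------------------------------------

def _impute_week8(changes: pd.DataFrame, method: str, week: int = 8,
                  endpoint: str = "uas7_change") -> pd.DataFrame:
    rows = []
    for pid, g in changes[changes["week"] >= 1].groupby("patient_id", sort=True):
        g = g[g["valid"] & g[endpoint].notna() & (g["week"] <= week)].sort_values("week")
        if g.empty:
            continue  # no post-baseline data: excluded
        at8 = g[g["week"] == week]
        if len(at8):
            val = float(at8[endpoint].iloc[0])
        elif method == "locf":
            val = float(g[endpoint].iloc[-1])
        elif method == "bocf":
            val = float(g[endpoint].min())  # most negative change = best
        else:
            raise ValueError(f"unknown imputation method {method!r}")
        rows.append({"patient_id": pid, "value": val})
    return pd.DataFrame(rows)


def ancova_with_imputation(
    changes: pd.DataFrame,
    profiles: pd.DataFrame,
    method: str = "locf",
    week: int = 8,
    endpoint: str = "uas7_change",
    reference_arm: str | None = None,
) -> list[ContrastEstimate]:
    """Week-8 ANCOVA of change on arm + country after LOCF/BOCF imputation.

    LOCF carries the last available post-baseline change forward; BOCF the
    most favorable (most negative) one.  Patients without any post-baseline
    value are excluded.  Returns arm-vs-reference contrasts with 95% CIs.
    """
    import statsmodels.api as sm

    imp = _impute_week8(changes, method=method, week=week, endpoint=endpoint)
    meta = profiles.set_index("patient_id")
    imp["arm"] = imp["patient_id"].map(meta["arm"])
    imp["country"] = imp["patient_id"].map(meta["country"])
    arms = sorted(imp["arm"].unique())
    if reference_arm is not None:
        arms = [reference_arm] + [a for a in arms if a != reference_arm]
    X = pd.get_dummies(imp[["arm", "country"]], drop_first=False)
    cols = [f"arm_{a}" for a in arms[1:]]
    ccols = [c for c in X.columns if c.startswith("country_")][1:]
    Xm = sm.add_constant(X[cols + ccols].astype(float))
    fit = sm.OLS(imp["value"].astype(float), Xm).fit()
    out = []
    for a in arms[1:]:
        name = f"arm_{a}"
        est = float(fit.params[name])
        se = float(fit.bse[name])
        dof = float(fit.df_resid)
        tq = stats.t.ppf(0.975, dof)
        out.append(
            ContrastEstimate(
                label=f"{a} vs {arms[0]} at week {week} ({method.upper()})",
                arm=a, visit=week, estimate=est, se=se, dof=dof,
                lower=est - tq * se, upper=est + tq * se, dof_method="residual",
            )
        )
    return out


def correlate_biomarker_response(pct_change_rr, uas7_changes) -> tuple[float, int]:
    """Spearman rank correlation (average ranks for ties) over complete pairs.

    Returns (rho, n); rho is NaN with a warning when fewer than 3 complete
    pairs are available.
    """
    x = np.asarray(pct_change_rr, dtype=float)
    y = np.asarray(uas7_changes, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        warnings.warn(f"Spearman correlation undefined with n={n} complete pairs")
        return float("nan"), n
    rho = stats.spearmanr(x[ok], y[ok]).statistic
    return float(rho), n
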