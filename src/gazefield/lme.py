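"""Random-intercept linear mixed-effects contrasts.

The amplitude and connectivity analyses share one model: the response (mean
broadband percent change, or Spearman ρ) per (electrode, condition) row is
regressed on condition and electrode type with treatment coding against the
(AV, mouth) baseline cell, their interaction, and a per-electrode random
intercept.  Estimation is REML (statsmodels ``MixedLM``); degrees of freedom
for the fixed-effect t statistics use the Satterthwaite approximation,
computed here from the closed-form random-intercept REML log-likelihood
(its numerical gradient and Hessian in the two variance parameters), which
is what yields the fractional df this kind of analysis reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CONDITIONS = ("AV", "Vis", "Aud")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class LMEDesign:
    """Treatment-coded fixed-effect design with electrode grouping."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    columns: list[str]
    baseline: tuple[str, str]
    dropped_interactions: bool = False

    @property
    def n_obs(self) -> int:
        return len(self.y)


def build_design(data: pd.DataFrame,
                 response: str = "response",
                 baseline: tuple[str, str] = ("AV", "mouth"),
                 conditions: tuple[str, ...] = DEFAULT_CONDITIONS) -> LMEDesign:
    """Long-format table -> treatment-coded design.

    ``data`` needs columns ``electrode``, ``condition``, ``etype`` and the
    response.  The baseline cell is (AV, mouth); non-baseline conditions and
    electrode types get dummy columns plus their interactions.  A missing
    expected level raises an error naming it; a single-type design drops the
    type and interaction columns (flagged on the result).
    """
    required = {"electrode", "condition", "etype", response}
    missing_cols = required - set(data.columns)
    if missing_cols:
        raise ValueError(f"data lacks columns: {sorted(missing_cols)}")

    present_conditions = list(pd.unique(data["condition"]))
    for level in conditions:
        if level not in present_conditions:
            raise ValueError(f"condition level {level!r} absent from the data")
    present_types = list(pd.unique(data["etype"]))
    single_type = len(present_types) == 1
    if not single_type and baseline[1] not in present_types:
        raise ValueError(f"electrode type level {baseline[1]!r} absent from the data")

    dup = data.groupby(["electrode", "condition"]).size()
    if (dup > 1).any():
        bad = dup[dup > 1].index[0]
        raise ValueError(f"electrode {bad[0]!r} contributes more than one row "
                         f"for condition {bad[1]!r}")

    other_conditions = [c for c in conditions if c != baseline[0]]
    other_types = sorted(t for t in present_types if t != baseline[1])

    cols = [np.ones(len(data))]
    names = ["Baseline"]
    cond = data["condition"].to_numpy()
    etype = data["etype"].to_numpy()
    for c in other_conditions:
        cols.append((cond == c).astype(float))
        names.append(str(c))
    if not single_type:
        for t in other_types:
            cols.append((etype == t).astype(float))
            names.append(str(t))
        for c in other_conditions:
            for t in other_types:
                cols.append(((cond == c) & (etype == t)).astype(float))
                names.append(f"{c}:{t}")

    return LMEDesign(X=np.column_stack(cols),
                     y=data[response].to_numpy(float),
                     groups=data["electrode"].to_numpy(),
                     columns=names, baseline=baseline,
                     dropped_interactions=single_type)


# ---------------------------------------------------------------------------
# REML machinery for the random-intercept model
# ---------------------------------------------------------------------------

def _group_slices(groups: np.ndarray) -> list[np.ndarray]:
    idx: dict = {}
    for i, g in enumerate(groups):
        idx.setdefault(g, []).append(i)
    return [np.asarray(v) for v in idx.values()]


def reml_loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                slices: list[np.ndarray]) -> float:
    """REML log-likelihood (up to a constant) at variance components
    ``theta = (sigma_b^2, sigma_e^2)`` for y = Xβ + Zb + ε."""
    sb2, se2 = float(theta[0]), float(theta[1])
    if se2 <= 0 or sb2 < 0:
        return -np.inf
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for sl in slices:
        xi, yi = X[sl], y[sl]
        ni = len(sl)
        a = sb2 / (se2 * (se2 + ni * sb2))   # V^-1 = I/se2 - a*J
        sx = xi.sum(axis=0)
        sy = yi.sum()
        xtvx += xi.T @ xi / se2 - a * np.outer(sx, sx)
        xtvy += xi.T @ yi / se2 - a * sx * sy
        ytvy += yi @ yi / se2 - a * sy * sy
        logdet += (ni - 1) * np.log(se2) + np.log(se2 + ni * sb2)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy
    return -0.5 * (logdet + logdet_xtvx + quad)


def _beta_cov(theta: np.ndarray, X: np.ndarray,
              slices: list[np.ndarray]) -> np.ndarray:
    """GLS covariance of the fixed effects, C(θ) = (X' V^-1 X)^-1."""
    sb2, se2 = float(theta[0]), float(theta[1])
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    for sl in slices:
        xi = X[sl]
        ni = len(sl)
        a = sb2 / (se2 * (se2 + ni * sb2))
        sx = xi.sum(axis=0)
        xtvx += xi.T @ xi / se2 - a * np.outer(sx, sx)
    return np.linalg.inv(xtvx)


def _gls_beta(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
              slices: list[np.ndarray]) -> np.ndarray:
    sb2, se2 = float(theta[0]), float(theta[1])
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for sl in slices:
        xi, yi = X[sl], y[sl]
        ni = len(sl)
        a = sb2 / (se2 * (se2 + ni * sb2))
        sx = xi.sum(axis=0)
        xtvx += xi.T @ xi / se2 - a * np.outer(sx, sx)
        xtvy += xi.T @ yi / se2 - a * sx * yi.sum()
    return np.linalg.solve(xtvx, xtvy)


def satterthwaite_df(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                     slices: list[np.ndarray]) -> np.ndarray:
    """Satterthwaite denominator df for each fixed-effect coefficient.

    df_j = 2 f_j² / (∇f_j' A ∇f_j) with f_j(θ) the j-th diagonal of the GLS
    covariance and A the inverse observed REML information in θ.  Both
    derivative objects are computed by central finite differences (one-sided
    at a variance boundary).
    """
    theta = np.asarray(theta, float)
    n, p = X.shape
    fallback = np.full(p, float(n - p))
    steps = np.maximum(1e-4 * np.maximum(theta, theta.sum()), 1e-8)

    def diag_cov(t: np.ndarray) -> np.ndarray:
        return np.diag(_beta_cov(t, X, slices))

    # gradient of each f_j
    grads = np.zeros((p, 2))
    for i in range(2):
        h = steps[i]
        up = theta.copy(); up[i] += h
        lo = theta.copy(); lo[i] -= h
        if lo[i] < 0:  # one-sided at the boundary
            grads[:, i] = (diag_cov(up) - diag_cov(theta)) / h
        else:
            grads[:, i] = (diag_cov(up) - diag_cov(lo)) / (2 * h)

    # observed information: negative Hessian of the REML log-likelihood
    def ll(t: np.ndarray) -> float:
        tt = t.copy()
        tt[0] = max(tt[0], 0.0)
        return reml_loglik(tt, X, y, slices)

    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            hi, hj = steps[i], steps[j]
            tpp = theta.copy(); tpp[i] += hi; tpp[j] += hj
            tpm = theta.copy(); tpm[i] += hi; tpm[j] -= hj
            tmp = theta.copy(); tmp[i] -= hi; tmp[j] += hj
            tmm = theta.copy(); tmm[i] -= hi; tmm[j] -= hj
            hess[i, j] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * hi * hj)
    info = -hess
    try:
        cov_theta = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return fallback
    if not np.all(np.isfinite(cov_theta)) or np.any(np.diag(cov_theta) <= 0):
        return fallback

    f = diag_cov(theta)
    denom = np.array([g @ cov_theta @ g for g in grads])
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * f**2 / denom
    df = np.where(np.isfinite(df) & (df > 0), df, fallback)
    # df cannot exceed the residual df of the fixed-effects-only model
    return np.minimum(df, n - p)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class LMEResult:
    """Fixed-effect table plus variance components of a random-intercept fit."""

    table: pd.DataFrame            # effect, estimate, std_error, df, t_value, p_value
    sigma_b2: float                # random-intercept variance
    sigma_e2: float                # residual variance
    n_obs: int
    singular: bool = False
    note: str = ""

    def estimate(self, effect: str) -> float:
        return float(self.table.set_index("effect").loc[effect, "estimate"])

    def confint(self, effect: str, level: float = 0.95) -> tuple[float, float]:
        row = self.table.set_index("effect").loc[effect]
        half = stats.t.ppf(0.5 + level / 2.0, row["df"]) * row["std_error"]
        return float(row["estimate"] - half), float(row["estimate"] + half)


def _ols_result(design: LMEDesign, note: str) -> LMEResult:
    X, y = design.X, design.y
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dfres = max(n - p, 1)
    s2 = float(resid @ resid) / dfres
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
    pvals = 2.0 * stats.t.sf(np.abs(t), dfres)
    table = pd.DataFrame({
        "effect": design.columns, "estimate": beta,
        "std_error": se, "df": float(dfres), "t_value": t, "p_value": pvals,
    })
    return LMEResult(table=table, sigma_b2=0.0, sigma_e2=s2, n_obs=n,
                     singular=True, note=note)


def fit_lme(design: LMEDesign, reml: bool = True) -> LMEResult:
    """REML fit of the random-intercept model with Satterthwaite df.

    Degenerate inputs (residual variance numerically zero, or a singular
    random-effects fit) fall back to ordinary least squares with residual
    df; the result is flagged ``singular`` and the fixed effects are still
    reported (for a balanced design they equal the GLS estimates anyway).
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    X, y = design.X, design.y
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough rows to estimate the fixed effects")
    groups = design.groups
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 electrodes (grouping levels)")

    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ols_resid = y - X @ ols_beta
    scale0 = float(ols_resid @ ols_resid) / max(n - p, 1)
    if scale0 < 1e-12 * max(1.0, float(y @ y) / n):
        return _ols_result(design, note="zero residual variance; OLS fallback")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        try:
            fit = model.fit(reml=reml, method=["lbfgs", "bfgs", "powell"])
        except Exception as exc:  # pragma: no cover - statsmodels internals
            return _ols_result(design, note=f"mixed-model fit failed: {exc}")

    sigma_e2 = float(fit.scale)
    sigma_b2 = float(np.asarray(fit.cov_re)[0, 0])
    singular = sigma_b2 < 1e-8 * (sigma_b2 + sigma_e2)

    slices = _group_slices(groups)
    theta = np.array([sigma_b2, sigma_e2])
    beta = _gls_beta(theta, X, y, slices)
    cov = _beta_cov(theta, X, slices)
    se = np.sqrt(np.diag(cov))
    if singular:
        df = np.full(p, float(n - p))
        note = "random-intercept variance estimated at zero"
    else:
        df = satterthwaite_df(theta, X, y, slices)
        note = ""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    table = pd.DataFrame({
        "effect": design.columns, "estimate": beta, "std_error": se,
        "df": df, "t_value": t, "p_value": pvals,
    })
    return LMEResult(table=table, sigma_b2=sigma_b2, sigma_e2=sigma_e2,
                     n_obs=n, singular=singular, note=note)


def amplitude_table(bb, rf_labels: dict[str, str],
                    window: tuple[float, float] = (200.0, 1500.0),
                    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
                    ) -> pd.DataFrame:
    """Long-format amplitude table (electrode, condition, etype, response)."""
    rows = []
    for name, etype in rf_labels.items():
        for cond in conditions:
            means = bb.window_means(name, window, condition=cond)
            if len(means) == 0:
                continue
            rows.append({"electrode": name, "condition": cond,
                         "etype": etype, "response": float(means.mean())})
    return pd.DataFrame(rows)
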