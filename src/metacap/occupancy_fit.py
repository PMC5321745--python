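"""Equilibrium incidence model and its two-stage estimation of the
extinction threshold.

At equilibrium a patch is occupied with probability C/(C + E).  Under the
standard area/connectivity forms this becomes

    p_i = V_i / (V_i + delta),   V_i = A_i^x * exp(y*Q_i) * R_i,

where R_i is the target-area-free connectivity sum, x = ex + im combines
the extinction and immigration area exponents, y scales the composite
habitat-quality index, and delta = e/c is the extinction threshold.  The
model is fitted to the multi-year average incidence of patches in large,
well-occupied networks: stage 1 without the quality term (y = 0), stage 2
with it.  A logistic regression of observed incidence on the stage-1
prediction plus the four raw quality variables quantifies how much each
quality dimension adds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .capacity import SpomParams, patch_connectivity
from .landscape import Landscape, OccupancyIncidence, QualityIndex
from .networks import NetworkAssignment


@dataclass(frozen=True)
class IncidenceFit:
    """Point estimates and 95% CIs for (delta, x[, y])."""

    delta_hat: float
    x_hat: float
    y_hat: float
    ci95: dict
    stage: int
    n_patches_used: int
    n_networks_used: int
    residual_ss: float
    covariance: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class QualityLogisticFit:
    """Logistic regression of observed incidence on predicted incidence
    plus the raw quality variables."""

    summary: pd.DataFrame = field(repr=False)
    pseudo_r2: float
    model: object = field(repr=False)


def predict_incidence(A, q_tilde, R, delta: float, x: float, y: float = 0.0):
    """Equilibrium occupancy probability p = V/(V + delta) with
    V = A^x * exp(y*Q) * R.  R = 0 gives p = 0 (uncolonizable)."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    A = np.asarray(A, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(A <= 0) or np.any(R < 0):
        raise ValueError("need A > 0 and R >= 0")
    V = A**x * np.exp(y * np.asarray(q_tilde, dtype=float)) * R
    out = V / (V + delta)
    return float(out) if out.ndim == 0 else out


def select_networks(
    incidence: OccupancyIncidence,
    assignment: NetworkAssignment,
    min_patches: int = 50,
    min_occupancy: float = 0.05,
) -> np.ndarray:
    """Network ids of large (> min_patches patches), well-occupied
    (mean incidence > min_occupancy) networks — those likely to hold
    viable metapopulations and hence to be near occupancy equilibrium."""
    ids = np.asarray(assignment.network_id)
    keep = []
    for k in range(assignment.n_networks):
        m = ids == k
        pb = incidence.p_bar[m]
        pb = pb[~np.isnan(pb)]
        if m.sum() > min_patches and pb.size and pb.mean() > min_occupancy:
            keep.append(k)
    return np.asarray(keep, dtype=int)


def _fit_incidence(
    incidence: OccupancyIncidence,
    landscape: Landscape,
    q: QualityIndex | None,
    assignment: NetworkAssignment,
    stage: int,
    min_patches: int,
    min_occupancy: float,
    params_conn: SpomParams,
    fix_y: float | None = None,
) -> IncidenceFit:
    networks = select_networks(incidence, assignment, min_patches, min_occupancy)
    if networks.size == 0:
        raise ValueError("no network passes the size/occupancy filter")
    p_obs_all = np.nan_to_num(incidence.p_bar)  # connectivity uses observed means
    _, R = patch_connectivity(landscape, np.clip(p_obs_all, 0, 1),
                              params_conn, return_area_free=True)
    in_fit = np.isin(np.asarray(assignment.network_id), networks) & incidence.defined
    A = landscape.areas[in_fit]
    Rf = R[in_fit]
    Q = (np.asarray(q.q_tilde, dtype=float)[in_fit] if q is not None
         else np.zeros(in_fit.sum()))
    pbar = incidence.p_bar[in_fit]
    if np.all(pbar > 0.999):
        raise RuntimeError("all patches always occupied: delta at the zero "
                           "boundary, fit diverges")

    y_free = stage == 2 and fix_y is None
    y_fixed_val = 0.0 if stage == 1 else (fix_y or 0.0)
    if y_free:
        theta0 = np.array([np.log(5.0), 0.5, 1.0])
    else:
        theta0 = np.array([np.log(3.0), 0.5])

    def residuals(theta):
        delta = np.exp(theta[0])
        x = theta[1]
        y = theta[2] if y_free else y_fixed_val
        return predict_incidence(A, Q, Rf, delta, x, y) - pbar

    res = optimize.least_squares(residuals, theta0, method="lm", max_nfev=20000)
    if not res.success:
        raise RuntimeError(f"incidence fit did not converge: {res.message}")
    # asymptotic covariance on the internal scale, then delta by delta-method
    dof = max(len(pbar) - len(res.x), 1)
    s2 = 2 * res.cost / dof
    JtJ = res.jac.T @ res.jac
    cov = s2 * np.linalg.pinv(JtJ)
    delta_hat = float(np.exp(res.x[0]))
    grad = np.ones(len(res.x))
    grad[0] = delta_hat  # d(delta)/d(log delta)
    se = np.sqrt(np.diag(cov)) * grad
    zc = stats.norm.ppf(0.975)
    est = np.array([delta_hat, res.x[1], res.x[2] if y_free else y_fixed_val])
    names = ["delta", "x", "y"]
    ci = {}
    for i, nm in enumerate(names[: len(res.x)]):
        ci[nm] = (est[i] - zc * se[i], est[i] + zc * se[i])
    if not y_free:
        ci["y"] = (y_fixed_val, y_fixed_val)
    return IncidenceFit(
        delta_hat=delta_hat, x_hat=float(res.x[1]),
        y_hat=float(res.x[2]) if y_free else y_fixed_val,
        ci95=ci, stage=stage,
        n_patches_used=int(in_fit.sum()), n_networks_used=int(networks.size),
        residual_ss=float(2 * res.cost), covariance=cov,
    )


def fit_stage1(incidence, landscape, assignment,
               min_patches: int = 50, min_occupancy: float = 0.05,
               params_conn: SpomParams | None = None) -> IncidenceFit:
    """Stage 1: nonlinear least squares for (delta, x) with y fixed at 0.

    Connectivity uses the observed mean occupancies as source weights with
    fixed alpha = 1 and em = 0.2 (no iteration), following the incidence
    function fitting tradition.
    """
    params_conn = params_conn or SpomParams()
    return _fit_incidence(incidence, landscape, None, assignment, 1,
                          min_patches, min_occupancy, params_conn)


def fit_stage2(incidence, landscape, q: QualityIndex, assignment,
               min_patches: int = 50, min_occupancy: float = 0.05,
               params_conn: SpomParams | None = None,
               fix_y: float | None = None) -> IncidenceFit:
    """Stage 2: free (delta, x, y) with the habitat-quality term exp(y*Q).

    ``fix_y`` pins the quality effect (fix_y=0 reproduces stage 1 exactly).
    """
    params_conn = params_conn or SpomParams()
    return _fit_incidence(incidence, landscape, q, assignment, 2,
                          min_patches, min_occupancy, params_conn, fix_y=fix_y)


def fit_quality_logistic(
    incidence: OccupancyIncidence,
    predicted_p: np.ndarray,
    quality: pd.DataFrame,
    n_years: np.ndarray | None = None,
) -> QualityLogisticFit:
    """Logistic regression of observed incidence on the model-predicted
    occupancy plus raw quality variables.

    The response is the per-patch fraction of years occupied; with
    ``n_years`` given, each patch is weighted by its number of observed
    years (a binomial-counts likelihood).  Pseudo-R² is the squared
    Pearson correlation between observed and fitted values.
    """
    keep = incidence.defined & np.isfinite(predicted_p)
    yobs = incidence.p_bar[keep]
    X = pd.DataFrame({"predicted_p": np.asarray(predicted_p)[keep]})
    for col in quality.columns:
        v = quality[col].to_numpy(dtype=float)[keep]
        if np.std(v) == 0:
            warnings.warn(f"constant quality column {col!r} dropped")
            continue
        X[col] = v
    X = sm.add_constant(X)
    w = (np.asarray(n_years)[keep] if n_years is not None
         else np.ones(keep.sum()))
    model = sm.GLM(yobs, X, family=sm.families.Binomial(), freq_weights=w)
    try:
        fit = model.fit()
    except Exception as err:  # pragma: no cover
        raise RuntimeError(f"quality logistic regression failed: {err}")
    if np.any(np.abs(fit.params) > 50):
        warnings.warn("very large coefficients: possible perfect separation")
    fitted = fit.predict(X)
    r = np.corrcoef(yobs, fitted)[0, 1]
    summary = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "z": fit.tvalues,
        "p": fit.pvalues,
    })
    return QualityLogisticFit(summary=summary, pseudo_r2=float(r**2), model=fit)


def network_fit_statistics(network_table: pd.DataFrame, delta: float) -> dict:
    """Goodness of fit of the equilibrium prediction at network level.

    ``r_viable``: Pearson correlation (with its t-test) between observed
    mean weighted occupancy and the equilibrium prediction
    1 - delta/lambda_M over the viable (lambda_M > delta) networks.
    ``R2_all``: R² of the linear regression of observed mean weighted
    occupancy on lambda_M over all networks.
    """
    t = network_table
    lam = t["lambda_M"].to_numpy(dtype=float)
    obs = t["mean_p_lambda"].to_numpy(dtype=float)
    fit_all = sm.OLS(obs, sm.add_constant(lam)).fit()
    out = {"R2_all": float(fit_all.rsquared),
           "F_all": float(fit_all.fvalue),
           "n_all": len(t)}
    viable = lam > delta
    if viable.sum() >= 3:
        pred = 1.0 - delta / lam[viable]
        ov = obs[viable]
        if np.std(ov) == 0 or np.std(pred) == 0:
            warnings.warn("zero variance among viable networks: r undefined")
            out.update({"r_viable": np.nan, "n_viable": int(viable.sum())})
        else:
            r, p = stats.pearsonr(ov, pred)
            n = int(viable.sum())
            tstat = r * np.sqrt((n - 2) / max(1 - r**2, 1e-300))
            out.update({"r_viable": float(r), "t_viable": float(tstat),
                        "p_viable": float(p), "n_viable": n})
    else:
        out.update({"r_viable": np.nan, "n_viable": int(viable.sum())})
    return out
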