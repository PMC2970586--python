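"""Two-level random-intercept logistic regression of late-stage risk.

Model: individual cases i nested in spatial units j (zones or blocks),

    logit P(y_ij = 1) = g00 + b1*AGE<50 + b2*AGE 50-70 + b3*BLACK
                        + g01 * d_j + U_0j,      U_0j ~ N(0, tau^2)

with reference categories nonblack and age >= 70, and d_j the unit's
shortest network travel distance (meters) to the nearest mammography
facility.  The random intercept is integrated out of the likelihood by
Gauss-Hermite quadrature and the marginal likelihood maximised by
L-BFGS-B with an analytic gradient.  tau is optimised on the log scale;
a fit driven to the lower bound (tau^2 < 1e-8) is re-polished as a plain
logistic model at tau^2 = 0 exactly and flagged ``boundary``.

Wald standard errors come from the observed information (numerical
Hessian of the marginal log-likelihood at the MLE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import MissingCovariateError, NonConvergenceError

#: Fixed-effect names in design-matrix column order.
TERMS = ("intercept", "age_lt50", "age_50to70", "black", "distance_m")

_LOG_TAU_MIN = np.log(1e-4)   # tau^2 = 1e-8 boundary
_LOG_TAU_MAX = np.log(20.0)


@dataclass
class ModelSpec:
    """Estimation settings for the random-intercept logistic fit."""

    quadrature_nodes: int = 15
    tol: float = 1e-8
    max_iter: int = 200


@dataclass
class FitResult:
    """Fixed effects with Wald inference plus the random-intercept variance.

    ``params`` et al. are keyed by term name (see :data:`TERMS`).  The
    latent-scale level-1 residual variance is the standard logistic value
    pi^2/3, fixed, not estimated.  ``tau2`` is the variance of the unit
    intercepts U_0j; a boundary fit reports tau2 = 0 with ``boundary=True``.
    """

    params: dict
    se: dict
    p_values: dict
    conf_int: dict  # term -> (low, high)
    tau2: float
    loglik: float
    converged: bool
    boundary: bool = False
    separation: bool = False
    n_obs: int = 0
    n_units: int = 0
    terms: tuple = TERMS

    def one_sided_p(self, term: str) -> float:
        """One-sided p-value in the direction of the estimated sign."""
        z = self.params[term] / self.se[term]
        return float(stats.norm.sf(abs(z)))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": t,
                "coefficient": self.params[t],
                "std_error": self.se[t],
                "p_value": self.p_values[t],
                "ci_low": self.conf_int[t][0],
                "ci_high": self.conf_int[t][1],
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)


def build_design(
    staged: pd.DataFrame,
    case_units: np.ndarray | pd.Series,
    unit_distances: dict | pd.Series,
) -> pd.DataFrame:
    """Assemble the model frame: outcome, dummies, unit index, distance.

    Parameters
    ----------
    staged
        Filtered cases with ``late``, ``age_band`` and ``race_cat``.
    case_units
        Unit (zone or block) id per case, aligned with ``staged`` rows.
    unit_distances
        Mapping unit id -> distance in meters; every unit that appears in
        ``case_units`` must be present.

    Units are re-indexed densely (0..J-1) over units that received at
    least one case.
    """
    units = np.asarray(case_units)
    dist_map = dict(unit_distances) if not isinstance(unit_distances, dict) else unit_distances
    missing = sorted({str(u) for u in units if u not in dist_map})
    if missing:
        raise MissingCovariateError(f"units lacking a distance covariate: {missing[:5]}")

    df = pd.DataFrame({
        "y": staged["late"].to_numpy(dtype=int),
        "x_age_lt50": (staged["age_band"] == "lt50").to_numpy(dtype=int),
        "x_age_50to70": (staged["age_band"] == "50to69").to_numpy(dtype=int),
        "x_black": (staged["race_cat"] == "black").to_numpy(dtype=int),
        "unit_id": units,
    })
    df["d_j"] = [float(dist_map[u]) for u in units]
    codes, _ = pd.factorize(df["unit_id"], sort=True)
    df["unit_index"] = codes
    return df


def _pack(design: pd.DataFrame):
    """Sort by unit and return (y, X, unit starts, case->unit row map)."""
    df = design.sort_values("unit_index", kind="stable").reset_index(drop=True)
    y = df["y"].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(df)),
        df["x_age_lt50"].to_numpy(dtype=float),
        df["x_age_50to70"].to_numpy(dtype=float),
        df["x_black"].to_numpy(dtype=float),
        df["d_j"].to_numpy(dtype=float),
    ])
    unit = df["unit_index"].to_numpy()
    starts = np.flatnonzero(np.r_[1, np.diff(unit)])
    # dense re-map in sorted order
    unit_row = np.cumsum(np.r_[0, np.diff(unit) != 0])
    return y, X, starts, unit_row


def _neg_loglik_grad(params, y, X, starts, unit_row, nodes, logw):
    """Negative marginal log-likelihood and gradient.

    params = (beta[5], log tau).  Quadrature: U = sqrt(2)*tau*z_k with GH
    nodes z_k and weights w_k/sqrt(pi).
    """
    beta, log_tau = params[:-1], params[-1]
    tau = np.exp(log_tau)
    eta = X @ beta
    offs = np.sqrt(2.0) * tau * nodes                     # (K,)
    lin = eta[:, None] + offs[None, :]                    # (n, K)
    ll = y[:, None] * lin - np.logaddexp(0.0, lin)        # log f per case/node
    S = np.add.reduceat(ll, starts, axis=0)               # (J, K)
    A = logw[None, :] + S
    Amax = A.max(axis=1)
    expA = np.exp(A - Amax[:, None])
    sumA = expA.sum(axis=1)
    Lj = Amax + np.log(sumA)                              # (J,)
    q = expA / sumA[:, None]                              # posterior node weights
    resid = y[:, None] - special.expit(lin)               # (n, K)
    qi = q[unit_row]                                      # (n, K)
    g_beta = X.T @ (qi * resid).sum(axis=1)
    Rsum = np.add.reduceat(resid, starts, axis=0)         # (J, K)
    g_tau = np.sum(q * Rsum * (np.sqrt(2.0) * nodes)[None, :])
    g_logtau = tau * g_tau
    grad = np.append(g_beta, g_logtau)
    return -float(Lj.sum()), -grad


def _plain_logit(y, X, tol=1e-10, max_iter=100):
    """Newton-Raphson logistic MLE (tau^2 = 0 profile)."""
    beta = np.zeros(X.shape[1])
    # distance column can be O(1e4); scale for stable Newton steps
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    Xs = X / scale
    for _ in range(max_iter):
        p = special.expit(Xs @ beta)
        W = p * (1 - p)
        grad = Xs.T @ (y - p)
        H = (Xs * W[:, None]).T @ Xs
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    p = special.expit(Xs @ beta)
    ll = float(np.sum(y * np.log(np.clip(p, 1e-300, 1)) +
                      (1 - y) * np.log(np.clip(1 - p, 1e-300, 1))))
    return beta / scale, ll


def _hessian(fun, x, eps):
    """Central-difference Hessian of a gradient-returning function."""
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        step = np.zeros(k)
        step[i] = eps[i]
        _, g_plus = fun(x + step)
        _, g_minus = fun(x - step)
        H[i] = (g_plus - g_minus) / (2 * eps[i])
    return (H + H.T) / 2


def fit_random_intercept_logit(
    design: pd.DataFrame,
    spec: ModelSpec | None = None,
    start: dict | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the two-level random-intercept logit.

    Parameters
    ----------
    design
        Model frame from :func:`build_design`.
    spec
        Quadrature and convergence settings.
    start
        Optional warm start: fixed-effect values keyed by term name plus
        ``tau2``; useful when fitting many similar replicate designs.

    Raises
    ------
    NonConvergenceError
        If the optimizer fails within ``spec.max_iter``; carries the last
        iterate.
    """
    spec = spec or ModelSpec()
    if design["unit_index"].nunique() < 2:
        raise ValueError("need >= 2 level-2 units")
    if design["y"].nunique() < 2:
        raise ValueError("outcome is constant")

    y, X, starts, unit_row = _pack(design)
    nodes, weights = np.polynomial.hermite.hermgauss(spec.quadrature_nodes)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    # distance in meters is O(1e3-1e4); scale columns for the optimizer
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    Xs = X / scale

    if start is not None:
        beta0 = np.array([start[t] for t in TERMS]) * scale
        tau0 = max(np.sqrt(max(start.get("tau2", 0.09), 0.0)), 2e-4)
        x0 = np.append(beta0, np.log(tau0))
    else:
        beta0, _ = _plain_logit(y, Xs)
        x0 = np.append(beta0, np.log(0.3))

    def objective(params):
        return _neg_loglik_grad(params, y, Xs, starts, unit_row, nodes, logw)

    bounds = [(None, None)] * 5 + [(_LOG_TAU_MIN, _LOG_TAU_MAX)]
    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": spec.max_iter, "ftol": spec.tol, "gtol": 1e-7},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise NonConvergenceError(
            f"marginal likelihood optimizer failed: {res.message}", last_params=res.x
        )

    # the log-likelihood is flat in log(tau) as tau -> 0 (the gradient in tau
    # vanishes at 0 by symmetry), so small tau iterates stall above the bound;
    # declare a boundary fit whenever the tau^2 = 0 profile matches the optimum
    boundary = res.x[-1] <= _LOG_TAU_MIN + 1e-6
    if not boundary and np.exp(res.x[-1]) < 0.02:
        beta_p, ll0 = _plain_logit(y, Xs)
        boundary = ll0 >= -res.fun - 1e-3
    if boundary:
        beta_s, ll = _plain_logit(y, Xs)
        tau2 = 0.0
        theta = np.append(beta_s, _LOG_TAU_MIN)
    else:
        beta_s = res.x[:-1]
        tau2 = float(np.exp(res.x[-1]) ** 2)
        theta = res.x
        ll = -res.fun

    # observed information on the scaled parameterisation
    eps = np.maximum(1e-5, 1e-5 * np.abs(theta))
    H = _hessian(lambda p: objective(p), theta, eps)
    k = 5 if boundary else 6
    cov_s = np.full((6, 6), np.nan)
    separation = False
    try:
        cov_block = np.linalg.inv(H[:k, :k])
        if (np.diag(cov_block) <= 0).any():
            raise np.linalg.LinAlgError
        cov_s[:k, :k] = cov_block
    except np.linalg.LinAlgError:
        separation = True
        cov_s[:k, :k] = np.linalg.pinv(H[:k, :k])

    beta = beta_s / scale
    se = np.sqrt(np.abs(np.diag(cov_s)[:5])) / scale
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    zc = stats.norm.ppf(0.975)

    return FitResult(
        params={t: float(beta[i]) for i, t in enumerate(TERMS)},
        se={t: float(se[i]) for i, t in enumerate(TERMS)},
        p_values={t: float(pvals[i]) for i, t in enumerate(TERMS)},
        conf_int={
            t: (float(beta[i] - zc * se[i]), float(beta[i] + zc * se[i]))
            for i, t in enumerate(TERMS)
        },
        tau2=tau2,
        loglik=float(ll),
        converged=True,
        boundary=boundary,
        separation=separation,
        n_obs=len(y),
        n_units=len(starts),
    )


def predict_risk(params: dict, profile: dict | None = None, distance_m: float = 0.0) -> float:
    """Population-median predicted late-stage probability (U_0j = 0).

    ``profile`` supplies the three dummies (``age_lt50``, ``age_50to70``,
    ``black``); omitted entries default to 0, i.e. the reference person
    (non-black, age >= 70).
    """
    profile = profile or {}
    eta = (
        params.get("intercept", 0.0)
        + params.get("age_lt50", 0.0) * profile.get("age_lt50", 0)
        + params.get("age_50to70", 0.0) * profile.get("age_50to70", 0)
        + params.get("black", 0.0) * profile.get("black", 0)
        + params.get("distance_m", 0.0) * distance_m
    )
    return float(special.expit(eta))
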