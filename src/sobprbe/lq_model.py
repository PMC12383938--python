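"""Linear-quadratic photon survival model and its nonlinear fit.

The LQ model S(D) = exp(-(alpha*D + beta*D^2)) is fitted to photon
dose-survival data by unweighted nonlinear least squares on the untransformed
SF scale, with every replicate point entering individually.  Both parameters
are unconstrained: radioresistant lines can genuinely fit with a small
negative alpha, producing a shouldered curve and a negative alpha/beta ratio.

Confidence intervals are asymptotic t-intervals from the Jacobian at the
optimum, matching standard nonlinear-regression practice; R^2 is computed on
the SF scale and dof = n_points - 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitError, InsufficientDataError


@dataclass(frozen=True)
class LQFit:
    """Fitted LQ parameters with 95% CIs, alpha/beta, R^2 and dof."""

    alpha: float
    beta: float
    alpha_ci95: tuple[float, float]
    beta_ci95: tuple[float, float]
    alpha_beta_ratio: float
    r_squared: float
    dof: int


def lq_survival(dose, alpha: float, beta: float):
    """LQ surviving fraction exp(-(alpha*D + beta*D^2)); vectorized over dose.

    May exceed 1 for negative alpha at small doses; that is a property of the
    model, not an error.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    out = np.exp(-(alpha * d + beta * d * d))
    return out if out.ndim else float(out)


def fit_lq(doses, sfs) -> LQFit:
    """Fit the LQ model to replicate-level photon survival points.

    Requires at least three points at three distinct doses and strictly
    positive surviving fractions.  Initialization takes alpha0 as the
    origin-constrained slope of -ln(SF) against dose and beta0 = 0, which is
    robust for both upward- and downward-curving data.
    """
    d = np.asarray(doses, dtype=float)
    sf = np.asarray(sfs, dtype=float)
    if d.shape != sf.shape or d.ndim != 1:
        raise ValueError("doses and sfs must be 1-D arrays of equal length")
    if np.any(sf <= 0):
        raise InsufficientDataError("surviving fractions must be > 0 to fit the LQ model")
    if d.size < 3 or np.unique(d).size < 3:
        raise InsufficientDataError(
            f"need >= 3 points at >= 3 distinct doses, got {d.size} points "
            f"at {np.unique(d).size} dose(s)"
        )

    y = -np.log(sf)
    denom = float(np.sum(d * d))
    alpha0 = float(np.sum(d * y) / denom) if denom > 0 else 0.0

    def residuals(p):
        a, b = p
        return np.exp(-(a * d + b * d * d)) - sf

    def jac(p):
        a, b = p
        s = np.exp(-(a * d + b * d * d))
        return np.column_stack([-d * s, -d * d * s])

    res = optimize.least_squares(
        residuals,
        x0=[alpha0, 0.0],
        jac=jac,
        method="lm",
        ftol=1e-10,
        xtol=1e-10,
        gtol=1e-10,
        max_nfev=200 * 3,
    )
    if not res.success:
        raise FitError(f"LQ fit did not converge: {res.message}")
    alpha, beta = map(float, res.x)

    n = d.size
    dof = n - 2
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((sf - sf.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    J = jac(res.x)
    try:
        cov = np.linalg.inv(J.T @ J) * (ss_res / dof)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular Jacobian at the optimum: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    tcrit = float(stats.t.ppf(0.975, dof))
    alpha_ci = (alpha - tcrit * se[0], alpha + tcrit * se[0])
    beta_ci = (beta - tcrit * se[1], beta + tcrit * se[1])

    ratio = alpha / beta if beta != 0 else float("inf") * np.sign(alpha)
    return LQFit(
        alpha=alpha,
        beta=beta,
        alpha_ci95=(float(alpha_ci[0]), float(alpha_ci[1])),
        beta_ci95=(float(beta_ci[0]), float(beta_ci[1])),
        alpha_beta_ratio=float(ratio),
        r_squared=r_squared,
        dof=dof,
    )
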