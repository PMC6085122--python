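"""Shared robust straight-line fit (IRLS with a bisquare weight).

Both the compensation-slope and return-map estimators use the same contract:
iteratively reweighted least squares with Tukey's bounded-influence bisquare
weight (tuning constant 4.685), MAD scale, convergence 1e-8, at most 200
iterations, and 95% confidence intervals from the asymptotic covariance
(z = 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["RobustLine", "robust_line", "binned_curve"]

_Z95 = 1.959963984540054


@dataclass
class RobustLine:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    ci95: tuple[float, float]  # on the slope
    n: int
    residuals: np.ndarray

    @property
    def resid_var(self) -> float:
        n = len(self.residuals)
        dof = max(n - 2, 1)
        return float(np.sum(self.residuals**2) / dof)


def robust_line(x, y, c: float = 4.685, tol: float = 1e-8, maxiter: int = 200) -> RobustLine:
    """Robust linear regression of ``y`` on ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 finite points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: x has zero variance")
    X = sm.add_constant(x)
    # fast path when the IRLS scale (MAD) would collapse to zero:
    # near-perfect fits make the bisquare weights ill-defined
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad <= 1e-10 * (1.0 + np.max(np.abs(y))):
        s2 = float(np.sum(resid**2) / max(n - 2, 1))
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = float(np.sqrt(s2 / sxx))
        slope = float(beta[1])
        return RobustLine(slope, float(beta[0]), se,
                          float(np.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))),
                          (slope - _Z95 * se, slope + _Z95 * se), n, resid)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=c))
    fit = model.fit(maxiter=maxiter, tol=tol, scale_est="mad")
    slope = float(fit.params[1])
    intercept = float(fit.params[0])
    se = float(fit.bse[1])
    resid = np.asarray(fit.resid)
    return RobustLine(
        slope,
        intercept,
        se,
        float(fit.bse[0]),
        (slope - _Z95 * se, slope + _Z95 * se),
        n,
        resid,
    )


def binned_curve(x, y, n_bins: int = 10):
    """Equal-count binned means of ``y`` along ``x`` (for plotting overlays)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    edges = np.array_split(np.arange(len(x)), n_bins)
    xm = np.array([x[i].mean() for i in edges if len(i)])
    ym = np.array([y[i].mean() for i in edges if len(i)])
    return xm, ym
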