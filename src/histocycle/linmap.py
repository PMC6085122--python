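"""Noisy linear map of daughter birth size and its analytic noise prediction.

Successive daughter birth volumes follow ``V_{n+1} = p V_n + (1-p) V_eq + eta``
with ``p = r * a``: ``r`` the fraction of division volume handed to the
daughter and ``a = s_tot + 1`` the efficiency of size control.  For
``0 <= p < 1`` the stationary Fano factor is

    Fano = (<eta^2> / V_eq) / ((1 - p) (1 + p))

and the lineage relaxes to equilibrium at rate ``lambda = -ln(p) / <T_div>``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import binned_curve, robust_line

__all__ = [
    "LinearMapModel",
    "fit_return_map",
    "fano_prediction",
    "fit_intrinsic_noise",
    "convergence_rate",
    "convergence_trajectories",
]


@dataclass
class LinearMapModel:
    """Fitted linear-map description of one strain."""

    strain: str = ""
    p: float = math.nan
    p_ci95: tuple[float, float] = (math.nan, math.nan)
    V_eq: float = math.nan
    eta_var: float = math.nan
    r: float = math.nan
    a: float = math.nan
    s_tot: float = math.nan
    fano_pred: float = math.nan
    lambda_rate: float = math.nan
    T_div_mean: float = math.nan
    n: int = 0
    divergent: bool = False

    def __post_init__(self) -> None:
        if (
            math.isfinite(self.r)
            and math.isfinite(self.s_tot)
            and math.isfinite(self.a)
            and abs(self.a - (self.s_tot + 1.0)) > 1e-9
        ):
            raise ValueError("inconsistent model: a != s_tot + 1")
        if (
            math.isfinite(self.r)
            and math.isfinite(self.a)
            and math.isfinite(self.p)
            and abs(self.p - self.r * self.a) > 1e-9
        ):
            raise ValueError("inconsistent model: p != r * a")


def fit_return_map(V_n, V_next, min_pairs: int = 200):
    """Estimate ``(p, V_eq, eta_var)`` from consecutive daughter birth sizes.

    Robust regression of ``V_{n+1}`` on ``V_n`` gives ``p`` (slope);
    ``V_eq = intercept / (1 - p)``; ``eta_var`` is the variance of the robust
    residuals.  Returns a dict with CIs and an equal-count binned curve for
    the return-map plot.  A slope >= 1 flags the map as non-stationary
    (``V_eq`` undefined).
    """
    x = np.asarray(V_n, dtype=float)
    y = np.asarray(V_next, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_pairs:
        raise ValueError(f"need >= {min_pairs} consecutive pairs, got {len(x)}")
    fit = robust_line(x, y)
    p = fit.slope
    divergent = p >= 1.0
    V_eq = fit.intercept / (1.0 - p) if not divergent else math.nan
    eta_var = fit.resid_var
    bx, by = binned_curve(x, y)
    return {
        "p": p,
        "p_ci95": fit.ci95,
        "V_eq": V_eq,
        "eta_var": eta_var,
        "n": fit.n,
        "divergent": divergent,
        "binned_x": bx,
        "binned_y": by,
    }


def fano_prediction(p: float, eta_var: float, V_eq: float) -> float:
    """Stationary Fano factor of the map; infinite at ``p >= 1``."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if V_eq <= 0:
        raise ValueError("V_eq must be > 0")
    if p >= 1.0:
        return math.inf  # loss of size homeostasis
    return (eta_var / V_eq) / ((1.0 - p) * (1.0 + p))


def fit_intrinsic_noise(p_values, fano_values, ci_level: float = 0.99):
    """One-parameter fit of ``Fano_i = c / ((1 - p_i)(1 + p_i))`` across strains.

    Returns ``(c, (lo, hi))`` where the interval is the ``ci_level`` profile
    of the residual sum of squares.  Strains with ``p >= 1`` are excluded
    with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    f = np.asarray(fano_values, dtype=float)
    ok = np.isfinite(p) & np.isfinite(f) & (p >= 0)
    if np.any(ok & (p >= 1)):
        warnings.warn("strains with p >= 1 excluded from the intrinsic-noise fit")
        ok &= p < 1
    p, f = p[ok], f[ok]
    n = len(p)
    if n < 3:
        raise ValueError("need at least 3 strains with 0 <= p < 1")
    g = 1.0 / ((1.0 - p) * (1.0 + p))
    Sgg = float(g @ g)
    c = float(f @ g) / Sgg
    rss_min = float(np.sum((f - c * g) ** 2))
    # profile the quadratic RSS(c) against the F(1, n-1) threshold
    fcrit = stats.f.ppf(ci_level, 1, n - 1)
    bound = rss_min * (1.0 + fcrit / (n - 1))
    half = math.sqrt(max(bound - rss_min, 0.0) / Sgg)
    return c, (c - half, c + half)


def convergence_rate(p: float, T_div_mean: float) -> float:
    """Exponential relaxation rate ``lambda = -ln(p) / <T_div>``."""
    if T_div_mean <= 0:
        raise ValueError("T_div_mean must be > 0")
    if p <= 0:
        return math.inf  # one-generation convergence
    if p >= 1:
        return 0.0  # no convergence
    return -math.log(p) / T_div_mean


def convergence_trajectories(
    chains,
    V_eq: float,
    upper_frac: float = 1.5,
    lower_frac: float = 0.7,
    n_gen: int = 6,
    min_founders: int = 30,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean normalized size per generation for deviant-founder lineages.

    ``chains`` is an iterable of sequences of successive first-daughter birth
    volumes (founder first).  Founders above ``upper_frac * V_eq`` form the
    "large" class, those below ``lower_frac * V_eq`` the "small" class; each
    chain is truncated to ``n_gen`` generations, normalized by ``V_eq`` and
    averaged per generation with bootstrap 95% CIs over founders.  Classes
    with fewer than ``min_founders`` chains are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mats = {"large": [], "small": []}
    for chain in chains:
        v = np.asarray(chain, dtype=float)
        if len(v) < n_gen:
            continue
        v = v[:n_gen]
        if v[0] > upper_frac * V_eq:
            mats["large"].append(v / V_eq)
        elif v[0] < lower_frac * V_eq:
            mats["small"].append(v / V_eq)
    rows = []
    for cls, arrs in mats.items():
        if len(arrs) < min_founders:
            continue
        m = np.vstack(arrs)
        means = m.mean(axis=0)
        idx = rng.integers(0, len(arrs), size=(n_boot, len(arrs)))
        bs = m[idx].mean(axis=1)  # (n_boot, n_gen)
        lo, hi = np.percentile(bs, [2.5, 97.5], axis=0)
        for gen in range(n_gen):
            rows.append(
                {
                    "founder_class": cls,
                    "generation": gen,
                    "mean_norm_V": float(means[gen]),
                    "ci_lo": float(lo[gen]),
                    "ci_hi": float(hi[gen]),
                    "n_founders": len(arrs),
                }
            )
    return pd.DataFrame(rows)


def build_model(
    strain: str,
    return_map: dict,
    T_div_mean: float,
    r: float = math.nan,
    s_tot: float = math.nan,
) -> LinearMapModel:
    """Assemble a :class:`LinearMapModel` from a return-map fit and summaries."""
    p = return_map["p"]
    divergent = return_map["divergent"] or p >= 1
    model = LinearMapModel(
        strain=strain,
        p=p,
        p_ci95=tuple(return_map["p_ci95"]),
        V_eq=return_map["V_eq"],
        eta_var=return_map["eta_var"],
        T_div_mean=T_div_mean,
        n=return_map["n"],
        divergent=divergent,
    )
    # p and s_tot come from independent estimators here, so fill the
    # descriptive fields after construction: the exact p = r*a consistency
    # check in __post_init__ applies only to models built from one source
    model.r = r
    model.s_tot = s_tot
    model.a = s_tot + 1.0 if math.isfinite(s_tot) else math.nan
    if not divergent and 0 <= p < 1 and model.V_eq > 0:
        model.fano_pred = fano_prediction(p, model.eta_var, model.V_eq)
        if T_div_mean > 0:
            model.lambda_rate = convergence_rate(p, T_div_mean)
    return model
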