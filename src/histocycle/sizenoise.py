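"""Cell-size variability along the cycle: CV, Fano factor, and fold-changes.

The Fano factor (variance/mean, in fL) is computed on raw volumes.  Under the
scaling ``CV = sqrt(F / V)`` it is the size-independent noise strength, which
is why the power-law fit below estimates a single ``F`` across checkpoints.
Bootstrap errors resample cells, preserving within-cell coupling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHECKPOINTS",
    "NoiseProfile",
    "noise_profile",
    "fit_fano_scaling",
    "fano_fold_change",
]

#: ordered checkpoints along the cycle (bud first, then the daughter it becomes)
CHECKPOINTS = [
    "bud_S_end",
    "bud_ana_onset",
    "daughter_birth",
    "daughter_G1_end",
    "daughter_division",
]

#: mapping from checkpoint to (variables.csv column, lineage class filter)
CHECKPOINT_COLUMNS = {
    "bud_S_end": ("Vb_S", None),
    "bud_ana_onset": ("Vb_G2M", None),
    "daughter_birth": ("V_birth", "daughter"),
    "daughter_G1_end": ("V_G1", "daughter"),
    "daughter_division": ("V_div", "daughter"),
}


@dataclass
class NoiseProfile:
    checkpoint: str
    mean_V: float
    cv: float
    fano: float
    cv_se: float
    fano_se: float
    n: int


def _cv_fano(v: np.ndarray) -> tuple[float, float]:
    m = v.mean()
    var = v.var(ddof=1) if len(v) > 1 else 0.0
    return math.sqrt(var) / m, var / m


def noise_profile(
    volumes: dict[str, np.ndarray],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    min_n: int = 100,
) -> list[NoiseProfile]:
    """CV and Fano factor per checkpoint with bootstrap standard errors.

    ``volumes`` maps checkpoint name to a 1-D array of volumes.  Checkpoints
    with fewer than ``min_n`` finite values are skipped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[NoiseProfile] = []
    for name, vals in volumes.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        n = len(v)
        if n < min_n:
            warnings.warn(f"checkpoint {name!r} skipped: n={n} < {min_n}")
            continue
        cv, fano = _cv_fano(v)
        idx = rng.integers(0, n, size=(n_boot, n))
        bs = v[idx]
        means = bs.mean(axis=1)
        vars_ = bs.var(axis=1, ddof=1)
        cv_se = float(np.std(np.sqrt(vars_) / means, ddof=1))
        fano_se = float(np.std(vars_ / means, ddof=1))
        out.append(NoiseProfile(name, float(v.mean()), cv, fano, cv_se, fano_se, n))
    return out


def profile_from_variables(
    variables: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    min_n: int = 100,
) -> list[NoiseProfile]:
    """Noise profile over the canonical checkpoints of a variables table."""
    vols = {}
    for name in CHECKPOINTS:
        col, cls = CHECKPOINT_COLUMNS[name]
        sub = variables
        if cls is not None and "lineage_class" in sub.columns:
            sub = sub[sub["lineage_class"] == cls]
        if col in sub.columns:
            vols[name] = sub[col].to_numpy()
    return noise_profile(vols, n_boot=n_boot, seed=seed, min_n=min_n)


def fit_fano_scaling(mean_V, cv) -> tuple[float, np.ndarray]:
    """Fit ``CV = sqrt(F / V)`` across checkpoints by least squares in logs.

    Regresses ``log CV`` on ``-1/2 log V`` with the intercept ``1/2 log F``
    free; returns ``F`` and the per-checkpoint log-residuals.  Points with a
    non-positive CV are dropped.
    """
    V = np.asarray(mean_V, dtype=float)
    c = np.asarray(cv, dtype=float)
    ok = np.isfinite(V) & np.isfinite(c) & (c > 0) & (V > 0)
    V, c = V[ok], c[ok]
    if len(V) < 3:
        raise ValueError("need at least 3 checkpoints")
    # log cv + 0.5 log V = 0.5 log F  (slope fixed at -1/2, intercept free)
    z = np.log(c) + 0.5 * np.log(V)
    half_logF = z.mean()
    F = float(math.exp(2.0 * half_logF))
    resid = z - half_logF
    return F, resid


def fano_fold_change(
    start_volumes,
    end_volumes,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """Ratio of end to start Fano factors with a paired-bootstrap 95% CI.

    Inputs must be paired per cell (same length and order); the bootstrap
    resamples cells so that start and end are drawn jointly.
    """
    s = np.asarray(start_volumes, dtype=float)
    e = np.asarray(end_volumes, dtype=float)
    if len(s) != len(e):
        raise ValueError("start and end checkpoints must be paired per cell")
    ok = np.isfinite(s) & np.isfinite(e)
    s, e = s[ok], e[ok]
    n = len(s)
    if n < 3:
        raise ValueError("too few paired cells")
    _, fano_s = _cv_fano(s)
    _, fano_e = _cv_fano(e)
    if fano_s == 0:
        raise ZeroDivisionError("start checkpoint has zero Fano factor")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bs_s = s[idx]
    bs_e = e[idx]
    f_s = bs_s.var(axis=1, ddof=1) / bs_s.mean(axis=1)
    f_e = bs_e.var(axis=1, ddof=1) / bs_e.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = f_e / f_s
    ratios = ratios[np.isfinite(ratios)]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return float(fano_e / fano_s), (float(lo), float(hi))
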