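"""Per-cycle variables, cohort summaries, correlograms and compensation slopes.

The 15 per-cycle variables are the four phase durations plus the total, the
mother volume at each phase boundary, the bud volume at three checkpoints,
the total volume at division, and the linear growth rates of the unbudded
and budded periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import RobustLine, binned_curve, robust_line
from .simkit import Trace
from .tracefit import PhaseSegmentation

__all__ = [
    "VARIABLES",
    "CompensationFit",
    "compute_variables",
    "summarize_durations",
    "compare_strains",
    "correlogram",
    "compensation_slope",
]

#: canonical correlogram variable order
VARIABLES = [
    "T_G1", "T_S", "T_G2M", "T_Ana", "T_div",
    "V_birth", "V_G1", "V_S", "V_G2M",
    "Vb_S", "Vb_G2M", "Vb_Ana", "V_div",
    "mu_unb", "mu_bud",
]


@dataclass
class CompensationFit:
    """Robust slope of volume added during a phase vs volume at phase start."""

    phase: str  # "G1", "G2M" or "full_cycle"
    lineage_class: str
    slope: float
    ci95: tuple[float, float]
    intercept: float
    n: int
    binned_x: np.ndarray
    binned_y: np.ndarray


def _nearest_frame(t: np.ndarray, time: float) -> int:
    return int(np.clip(round((time - t[0]) / (t[1] - t[0])), 0, len(t) - 1))


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    if len(t) < 2 or np.ptp(t) == 0:
        return math.nan
    return float(np.polyfit(t, y, 1)[0])


def compute_variables(
    seg: PhaseSegmentation,
    trace: Trace,
    lineage_class: str = "",
    replicative_age: int = -1,
) -> dict:
    """Read the per-cycle variables off a fitted segmentation and its trace.

    Volumes are taken at the nearest frame to each fitted boundary; growth
    rates are least-squares slopes of the mother volume over the unbudded
    interval and of the total volume over the budded interval.  The bud
    volume at anaphase end is the maximum over the drop interval (the frame
    at the drop end may already lie past cytokinesis, where the bud is gone),
    and ``V_div`` is the mother-plus-bud total at that point.
    """
    t = trace.t
    out: dict = {
        "cell_id": seg.cell_id,
        "cycle_index": seg.cycle_index,
        "lineage_class": lineage_class,
        "replicative_age": replicative_age,
        "T_G1": seg.T_G1,
        "T_S": seg.T_S,
        "T_G2M": seg.T_G2M,
        "T_Ana": seg.T_Ana,
        "T_div": seg.T_G1 + seg.T_S + seg.T_G2M + seg.T_Ana,
    }

    def vol_at(time, arr):
        if not math.isfinite(time) or time < t[0] - 1e-9 or time > t[-1] + 1e-9:
            return math.nan
        return float(arr[_nearest_frame(t, time)])

    out["V_birth"] = vol_at(seg.t_cyto_prev, trace.V)
    out["V_G1"] = vol_at(seg.t1, trace.V)
    out["V_S"] = vol_at(seg.t2, trace.V)
    out["V_G2M"] = vol_at(seg.t_ana, trace.V)
    out["Vb_S"] = vol_at(seg.t2, trace.Vb)
    out["Vb_G2M"] = vol_at(seg.t_ana, trace.Vb)
    i_on = _nearest_frame(t, seg.t_ana) if math.isfinite(seg.t_ana) else None
    i_end = _nearest_frame(t, seg.t_ana_end) if math.isfinite(seg.t_ana_end) else None
    if i_on is not None and i_end is not None and i_end >= i_on:
        vb_ana = float(np.max(trace.Vb[i_on:i_end + 1]))
        out["Vb_Ana"] = vb_ana
        out["V_div"] = out["V_G2M"] + vb_ana if math.isfinite(out["V_G2M"]) else math.nan
    else:
        out["Vb_Ana"] = math.nan
        out["V_div"] = math.nan

    if math.isfinite(seg.t_cyto_prev) and math.isfinite(seg.t1):
        lo = _nearest_frame(t, seg.t_cyto_prev)
        hi = _nearest_frame(t, seg.t1)
        out["mu_unb"] = _slope(t[lo:hi + 1], trace.V[lo:hi + 1])
    else:
        out["mu_unb"] = math.nan
    if math.isfinite(seg.t1) and i_on is not None:
        lo = _nearest_frame(t, seg.t1)
        tot = trace.V + trace.Vb
        out["mu_bud"] = _slope(t[lo:i_on + 1], tot[lo:i_on + 1])
    else:
        out["mu_bud"] = math.nan
    out["flagged"] = any(
        not math.isfinite(out[v]) for v in VARIABLES if v in out
    )
    return out


def summarize_durations(cycles: pd.DataFrame, by=("strain", "lineage_class")) -> pd.DataFrame:
    """Mean, SEM (sd/sqrt(n)), median and n of each duration per group."""
    by = [b for b in by if b in cycles.columns]
    cols = [c for c in ("T_G1", "T_S", "T_G2M", "T_Ana", "T_div") if c in cycles.columns]
    rows = []
    grouped = cycles.groupby(list(by)) if by else [((), cycles)]
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        for col in cols:
            vals = grp[col].dropna().to_numpy()
            if len(vals) == 0:
                continue
            rows.append(
                dict(
                    zip(by, key),
                    variable=col,
                    mean=vals.mean(),
                    sem=vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else math.nan,
                    median=float(np.median(vals)),
                    n=len(vals),
                )
            )
    return pd.DataFrame(rows)


def compare_strains(sample_a, sample_b, min_n: int = 20):
    """Two-sample Kolmogorov-Smirnov test with the usual star levels."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"need >= {min_n} observations per sample")
    res = stats.ks_2samp(a, b)
    p = float(res.pvalue)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"
    return float(res.statistic), p, stars


def correlogram(
    variables: pd.DataFrame,
    class_column: str = "lineage_class",
    min_pairs: int = 50,
) -> pd.DataFrame:
    """Pearson correlation matrix of the per-cycle variables.

    Mother-class correlations fill the upper triangle, daughter-class the
    lower triangle (diagonal 1).  Missing values are dropped pairwise; an
    entry with fewer than ``min_pairs`` complete pairs or a zero-variance
    variable is left NaN.
    """
    cols = [c for c in VARIABLES if c in variables.columns]
    mats = {}
    for cls in ("mother", "daughter"):
        sub = variables[variables[class_column] == cls][cols]
        m = pd.DataFrame(np.nan, index=cols, columns=cols)
        for i, a in enumerate(cols):
            for b in cols[i:]:
                pair = sub[[a, b]].dropna()
                if len(pair) < min_pairs:
                    continue
                xa, xb = pair[a].to_numpy(), pair[b].to_numpy()
                if np.std(xa) == 0 or np.std(xb) == 0:
                    continue
                r = float(np.corrcoef(xa, xb)[0, 1]) if a != b else 1.0
                m.loc[a, b] = r
                m.loc[b, a] = r
        mats[cls] = m
    out = pd.DataFrame(np.nan, index=cols, columns=cols)
    iu = np.triu_indices(len(cols), k=1)
    il = np.tril_indices(len(cols), k=-1)
    out.values[iu] = mats["mother"].values[iu]
    out.values[il] = mats["daughter"].values[il]
    np.fill_diagonal(out.values, 1.0)
    return out


def compensation_slope(
    V_init,
    delta_V,
    phase: str = "",
    lineage_class: str = "",
    n_bins: int = 10,
    min_n: int = 50,
) -> CompensationFit:
    """Robust-regression slope of ``delta_V`` on ``V_init`` with 95% CI.

    Slope -1 marks an ideal Sizer (constant final volume), 0 an Adder
    (added volume independent of the initial one) and +1 an ideal Timer
    under exponential growth with mean doubling.
    """
    x = np.asarray(V_init, dtype=float)
    y = np.asarray(delta_V, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_n:
        raise ValueError(f"need >= {min_n} cycles, got {len(x)}")
    fit = robust_line(x, y)
    bx, by = binned_curve(x, y, n_bins=n_bins)
    return CompensationFit(
        phase=phase,
        lineage_class=lineage_class,
        slope=fit.slope,
        ci95=fit.ci95,
        intercept=fit.intercept,
        n=fit.n,
        binned_x=bx,
        binned_y=by,
    )
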