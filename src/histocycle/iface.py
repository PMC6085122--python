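"""File formats, configuration and the end-to-end pipeline driver.

All tables are CSV with a ``#``-prefixed metadata header carrying the root
seed and a hash of the configuration, so that reruns with identical inputs
are byte-identical.  Times are minutes, volumes fL, fluorescence AU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cyclestats, linmap, simkit, sizenoise, tracefit
from .simkit import SimConfig, Trace
from .tracefit import QCPolicy

__all__ = [
    "RunConfig",
    "ValidationError",
    "StageError",
    "read_traces",
    "write_table",
    "read_table",
    "run_pipeline",
]

TRACE_COLUMNS = ["cell_id", "frame", "t_min", "fluo_au", "vol_mother_fl", "vol_bud_fl"]
LINEAGE_COLUMNS = ["cell_id", "mother_id", "strain"]


class ValidationError(ValueError):
    """Malformed input (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "out"
    traces_path: str | None = None  # None: simulate first
    lineage_path: str | None = None
    strain: str = "sim"
    seed: int = 0
    cyto_offset_min: float = tracefit.DEFAULT_CYTO_OFFSET_MIN
    drop_frac: float = 0.25
    n_boot: int = 1000
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCPolicy = field(default_factory=QCPolicy)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        qc = QCPolicy(**raw.pop("qc", {}))
        return cls(sim=sim, qc=qc, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where outputs land must not change their bytes
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, seed: int, config_hash: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# seed={seed}\n# config_sha={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_traces(path: str | Path, lineage_path: str | Path | None = None):
    """Load and validate a traces CSV (plus optional lineage sidecar).

    Returns ``(traces: dict[cell_id, Trace], order: list[cell_id],
    lineage: DataFrame | None)``.  Rows may arrive in any order; per-cell
    frame grids must be uniform and complete, values non-negative.
    """
    df = read_table(path)
    if list(df.columns) != TRACE_COLUMNS:
        raise ValidationError(
            f"{path}: expected columns {TRACE_COLUMNS}, got {list(df.columns)}"
        )
    df = df.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)
    for col in ("t_min", "fluo_au", "vol_mother_fl", "vol_bud_fl"):
        bad = df.index[df[col] < 0]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValidationError(
                f"{path}: negative {col} for cell {row.cell_id} frame {int(row.frame)}"
            )
    traces: dict[str, Trace] = {}
    order: list[str] = []
    for cid, grp in df.groupby("cell_id", sort=False):
        frames = grp["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            dup = int(frames[np.argmax(np.diff(frames) == 0)])
            raise ValidationError(f"{path}: duplicate frame {dup} for cell {cid}")
        t = grp["t_min"].to_numpy(dtype=float)
        if len(t) > 1:
            dts = np.diff(t)
            if np.ptp(dts) > 1e-6 * max(dts.mean(), 1.0) or dts.min() <= 0:
                k = int(np.argmax(np.abs(dts - dts.mean())))
                raise ValidationError(
                    f"{path}: nonuniform frame spacing for cell {cid} "
                    f"near frame {int(frames[k + 1])}"
                )
        traces[str(cid)] = Trace(
            t, grp["fluo_au"].to_numpy(), grp["vol_mother_fl"].to_numpy(),
            grp["vol_bud_fl"].to_numpy(),
        )
        order.append(str(cid))
    lineage = None
    if lineage_path is not None:
        lineage = read_table(lineage_path)
        missing = [c for c in LINEAGE_COLUMNS if c not in lineage.columns]
        if missing:
            raise ValidationError(f"{lineage_path}: missing columns {missing}")
        lineage["mother_id"] = lineage["mother_id"].fillna("")
    return traces, order, lineage


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def fit_stage(traces, order, lineage, cfg: RunConfig):
    """Segment every trace and QC the resulting cycles."""
    mothers = {}
    if lineage is not None:
        mothers = dict(zip(lineage.cell_id.astype(str), lineage.mother_id.astype(str)))
    segs = []
    for cid in order:
        trace = traces[cid]
        if len(trace) < 10:
            continue
        born_observed = bool(mothers.get(cid, ""))
        segs.extend(
            tracefit.segment_trace(
                trace,
                cell_id=cid,
                birth_is_cytokinesis=born_observed,
                cyto_offset_min=cfg.cyto_offset_min,
                drop_frac=cfg.drop_frac,
            )
        )
    passed, rejected, tally = tracefit.qc_filter(segs, cfg.qc)
    return segs, passed, tally


def segs_to_frame(segs) -> pd.DataFrame:
    rows = []
    for s in segs:
        rows.append(
            {
                "cell_id": s.cell_id,
                "cycle_index": s.cycle_index,
                "t_cyto_prev": s.t_cyto_prev,
                "t1": s.t1,
                "t2": s.t2,
                "t_ana": s.t_ana,
                "t_ana_end": s.t_ana_end,
                "F1": s.F1,
                "F2": s.F2,
                "ramp_slope": s.ramp_slope,
                "T_G1": s.T_G1,
                "T_S": s.T_S,
                "T_G2M": s.T_G2M,
                "T_Ana": s.T_Ana,
                "rss": s.rss,
                "r2": s.r2,
                "qc_pass": s.qc_pass,
                "qc_reason": s.qc_reason,
            }
        )
    return pd.DataFrame(rows)


def variables_stage(passed, traces, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for seg in passed:
        cls = "daughter" if seg.cycle_index == 0 else "mother"
        rows.append(
            cyclestats.compute_variables(
                seg, traces[seg.cell_id], lineage_class=cls,
                replicative_age=seg.cycle_index,
            )
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["strain"] = cfg.strain
    return df


def map_stage(variables: pd.DataFrame, lineage: pd.DataFrame | None,
              traces, cfg: RunConfig):
    """Return-map fit over first-daughter birth pairs plus trajectories."""
    if lineage is None or variables.empty:
        raise StageError("map stage needs lineage information and variables")
    birth = {}
    start_time = {cid: float(tr.t[0]) for cid, tr in traces.items()}
    d0 = variables[variables.cycle_index == 0]
    for _, row in d0.iterrows():
        birth[row.cell_id] = row.V_birth
    mothers = dict(zip(lineage.cell_id.astype(str), lineage.mother_id.astype(str)))
    # first daughter of each mother = earliest-born child
    children: dict[str, list[str]] = {}
    for cid, mid in mothers.items():
        if mid:
            children.setdefault(mid, []).append(cid)
    first_daughter = {
        mid: min(kids, key=lambda c: start_time.get(c, math.inf))
        for mid, kids in children.items()
    }
    pairs = [
        (birth[m], birth[d])
        for m, d in first_daughter.items()
        if m in birth and d in birth
        and np.isfinite(birth[m]) and np.isfinite(birth[d])
    ]
    if len(pairs) < 3:
        raise StageError(f"map stage: only {len(pairs)} usable daughter pairs")
    vn, vnext = np.array(pairs).T
    try:
        rm = linmap.fit_return_map(vn, vnext, min_pairs=min(len(pairs), 200))
    except ValueError as exc:
        raise StageError(f"map stage: {exc}") from exc
    T_div_mean = float(variables["T_div"].mean())
    daughters = variables[variables.lineage_class == "daughter"]
    s_tot = math.nan
    if len(daughters) >= 50:
        try:
            comp = cyclestats.compensation_slope(
                daughters.V_birth, daughters.V_div - daughters.V_birth,
                phase="full_cycle", lineage_class="daughter",
            )
            s_tot = comp.slope
        except ValueError:
            pass
    model = linmap.build_model(cfg.strain, rm, T_div_mean, s_tot=s_tot)

    chains = []
    for cid in birth:
        chain = [birth[cid]]
        cur = cid
        while cur in first_daughter and first_daughter[cur] in birth:
            cur = first_daughter[cur]
            chain.append(birth[cur])
        if len(chain) > 1:
            chains.append(chain)
    traj = pd.DataFrame()
    if not model.divergent and math.isfinite(model.V_eq):
        traj = linmap.convergence_trajectories(
            chains, model.V_eq, min_founders=5, seed=cfg.seed,
        )
    return model, traj


def model_to_frame(model: linmap.LinearMapModel) -> pd.DataFrame:
    d = dataclasses.asdict(model)
    d["p_ci_lo"], d["p_ci_hi"] = d.pop("p_ci95")
    return pd.DataFrame([d])


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

_STAGE_ORDER = ("fit", "stats", "noise", "map")


def run_pipeline(cfg: RunConfig, until: str = "map") -> dict:
    """simulate (optional) -> fit -> stats -> noise -> map; write all tables.

    ``until`` truncates the pipeline after the named stage.  Returns the run
    manifest (also written to ``manifest.json``).
    """
    if until not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {until!r}")
    last = _STAGE_ORDER.index(until)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed, sha = cfg.seed, cfg.config_hash
    manifest: dict = {"seed": seed, "config_sha": sha, "strain": cfg.strain, "stages": {}}

    # --- input ------------------------------------------------------------
    if cfg.traces_path is None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        cells = simkit.simulate_lineage(sim_cfg)
        traces_df, truth_df, lineage_df = simkit.lineage_tables(cells, strain=cfg.strain)
        write_table(traces_df, out / "traces.csv", seed, sha)
        write_table(truth_df, out / "truth.csv", seed, sha)
        write_table(lineage_df, out / "lineage.csv", seed, sha)
        traces, order, lineage = read_traces(out / "traces.csv", out / "lineage.csv")
        manifest["stages"]["simulate"] = {"n_cycles": len(cells), "n_cells": len(traces)}
    else:
        traces, order, lineage = read_traces(cfg.traces_path, cfg.lineage_path)
        manifest["stages"]["read"] = {"n_cells": len(traces)}
    if not traces:
        raise ValidationError("no traces in input")

    # --- fit --------------------------------------------------------------
    try:
        segs, passed, tally = fit_stage(traces, order, lineage, cfg)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"fit stage failed: {exc}") from exc
    cycles_df = segs_to_frame(segs)
    write_table(cycles_df, out / "cycles.csv", seed, sha)
    manifest["stages"]["fit"] = {
        "n_cycles": len(segs),
        "n_pass": len(passed),
        "qc_rejections": dict(sorted(tally.items())),
    }
    if last < 1:
        return _finish(out, manifest)

    # --- stats ------------------------------------------------------------
    variables = variables_stage(passed, traces, cfg)
    write_table(variables, out / "variables.csv", seed, sha)
    summary = cyclestats.summarize_durations(variables)
    write_table(summary, out / "summary.csv", seed, sha)
    if len(variables) >= 50:
        corr = cyclestats.correlogram(variables, min_pairs=min(50, len(variables)))
        write_table(corr.reset_index(names="variable"), out / "correlogram.csv", seed, sha)
    slope_rows = []
    for cls in ("daughter", "mother"):
        sub = variables[variables.lineage_class == cls] if not variables.empty else variables
        for phase, (x, y) in {
            "G1": ("V_birth", "V_G1"),
            "G2M": ("Vb_S", "Vb_G2M"),
            "full_cycle": ("V_birth", "V_div"),
        }.items():
            if len(sub) < 50:
                continue
            try:
                fit = cyclestats.compensation_slope(
                    sub[x], sub[y] - sub[x], phase=phase, lineage_class=cls
                )
            except ValueError:
                continue
            slope_rows.append(
                {
                    "phase": phase, "lineage_class": cls, "slope": fit.slope,
                    "ci_lo": fit.ci95[0], "ci_hi": fit.ci95[1],
                    "intercept": fit.intercept, "n": fit.n,
                }
            )
    slopes = pd.DataFrame(slope_rows)
    write_table(slopes, out / "slopes.csv", seed, sha)
    manifest["stages"]["stats"] = {"n_variables": len(variables), "n_slopes": len(slopes)}
    if last < 2:
        return _finish(out, manifest)

    # --- noise ------------------------------------------------------------
    profiles = sizenoise.profile_from_variables(
        variables, n_boot=cfg.n_boot, seed=cfg.seed, min_n=min(100, max(len(variables) // 2, 3)),
    ) if not variables.empty else []
    prof_df = pd.DataFrame([dataclasses.asdict(p) for p in profiles])
    write_table(prof_df, out / "noise_profile.csv", seed, sha)
    fold_rows = []
    if not variables.empty:
        d = variables[variables.lineage_class == "daughter"]
        pairs = {"G1": ("V_birth", "V_G1"), "G2M": ("Vb_S", "Vb_G2M")}
        for phase, (a, b) in pairs.items():
            sub = variables if phase == "G2M" else d
            s, e = sub[a].to_numpy(), sub[b].to_numpy()
            try:
                ratio, ci = sizenoise.fano_fold_change(s, e, n_boot=cfg.n_boot, seed=cfg.seed)
            except (ValueError, ZeroDivisionError):
                continue
            fold_rows.append(
                {"phase": phase, "fold_change": ratio, "ci_lo": ci[0], "ci_hi": ci[1]}
            )
    write_table(pd.DataFrame(fold_rows), out / "fano_foldchange.csv", seed, sha)
    manifest["stages"]["noise"] = {"n_checkpoints": len(profiles)}
    if last < 3:
        return _finish(out, manifest)

    # --- map --------------------------------------------------------------
    try:
        model, traj = map_stage(variables, lineage, traces, cfg)
        write_table(model_to_frame(model), out / "linmap.csv", seed, sha)
        write_table(traj, out / "trajectories.csv", seed, sha)
        manifest["stages"]["map"] = {
            "p": model.p, "V_eq": model.V_eq, "fano_pred": model.fano_pred,
        }
    except StageError as exc:
        manifest["stages"]["map"] = {"skipped": str(exc)}

    return _finish(out, manifest)


def _finish(out: Path, manifest: dict) -> dict:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
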