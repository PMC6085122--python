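"""Synthetic lineages of growing, dividing cells carrying a nuclear reporter.

The generator produces per-cell time series of total nuclear fluorescence and
mother/bud volumes, together with exact ground truth (phase durations, volumes
at phase boundaries, per-phase size-control strength), so that every
downstream stage of the pipeline can be validated without real microscopy
data.

Signal model
------------
Each cell cycle consists of four intervals:

* **G1** (unbudded): the mother compartment grows until its volume reaches a
  noisy compensation target ``a_G1 * V_birth + (1 - a_G1) * V_target_G1 + eta``.
  The retention coefficient ``a`` is the ground-truth handle on size control:
  the slope of added volume versus initial volume is exactly ``a - 1``
  (``a = 0`` ideal Sizer, ``a = 1`` Adder-like, ``a = 2`` anti-Sizer).
* **S**: a bud appears, its volume grows, and reporter production doubles the
  total histone pool linearly over the (randomly drawn) S duration.
* **G2/M**: the bud grows until it reaches the analogous bud-volume target.
* **Anaphase**: fixed duration; the nuclear signal assigned to the mother
  ramps down linearly as the divided nucleus is handed to the bud.  At
  cytokinesis the daughter inherits the bud volume and a
  ``dm_fluo_asymmetry``-weighted half of the reporter pools.

Division asymmetry is exact by construction: during anaphase the bud is grown
(or mildly shrunk) to ``r_div / (1 - r_div) * V_mother`` so that the daughter
receives exactly the fraction ``r_div`` of the total division volume.  This
makes the effective linear-map coefficient ``p = r_div * a_G1 / (1 - r_div)``
an exact ground truth as well.

Reporter maturation is modelled as first-order two-compartment kinetics
(immature -> mature with time constant ``tau_mat_min``) integrated exactly
per interval of constant production; observed fluorescence is the mature pool
plus optional Gaussian measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Trace",
    "SimCell",
    "simulate_lineage",
    "apply_maturation",
    "simulate_linear_map",
    "lineage_tables",
    "sizer_cohort",
    "adder_cohort",
    "timer_cohort",
]

_MAX_RETRIES = 100


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the lineage simulator.

    Defaults give a wild-type-like cohort: ~85 min daughter cycles sampled
    every 3 min, moderate G1/G2M size compensation, fast-maturing reporter.

    Notes
    -----
    Phase-duration noise enters through Gaussian ``eta`` on the volume
    targets and a Gaussian S duration; the distribution families are model
    assumptions, not measured facts.
    """

    frame_interval_min: float = 3.0
    n_cells: int = 20
    n_generations: int = 4
    growth_mode: str = "linear"  # "linear" or "exponential"
    mu_unb: float = 0.45  # fL/min, unbudded (mother) growth rate
    mu_bud: float = 0.5  # fL/min, bud growth rate
    k_growth: float = 0.0075  # 1/min, exponential mode
    a_G1: float = 0.4  # retention coefficient; slope ground truth = a - 1
    a_G2M: float = 0.3
    V_target_G1: float = 48.0  # fL
    Vb_target_G2M: float = 27.0  # fL
    T_S_mean: float = 27.0  # min
    T_S_sd: float = 3.0
    T_Ana_mean: float = 9.0
    eta_sd: float = 2.0  # fL, Langevin noise on volume targets
    r_div: float = 0.4  # fraction of division volume going to the daughter
    dm_fluo_asymmetry: float = 1.0  # daughter share = 0.5 * this
    tau_mat_min: float = 5.0  # fluorophore maturation time constant
    sigma_F: float = 0.0  # AU, fluorescence measurement noise
    sigma_V: float = 0.0  # fL, volume measurement noise
    seed: int = 0
    # floors keeping degenerate phases (e.g. mothers already past their
    # size target) at a nonzero duration
    min_T_G1: float = 6.0
    min_T_G2M: float = 3.0
    founder_V_mean: float | None = None  # default: 0.8 * V_target_G1
    founder_V_sd: float = 3.0
    founder_F0: float = 100.0  # initial mature reporter amount, AU

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ConfigError("frame_interval_min must be > 0")
        if not (0 < self.r_div <= 0.5):
            raise ConfigError("r_div must lie in (0, 1/2]")
        if self.tau_mat_min < 0:
            raise ConfigError("tau_mat_min must be >= 0")
        for name in ("T_S_mean", "T_Ana_mean", "min_T_G1", "min_T_G2M"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.growth_mode not in ("linear", "exponential"):
            raise ConfigError(f"unknown growth_mode {self.growth_mode!r}")
        if self.growth_mode == "linear" and (self.mu_unb <= 0 or self.mu_bud <= 0):
            raise ConfigError(
                "volume targets are unreachable under linear growth with mu <= 0"
            )
        if self.growth_mode == "exponential" and self.k_growth <= 0:
            raise ConfigError("exponential growth requires k_growth > 0")
        if not (0 <= self.dm_fluo_asymmetry <= 2):
            raise ConfigError("dm_fluo_asymmetry must lie in [0, 2]")


@dataclass
class Trace:
    """One cell's sampled time series on a uniform frame grid."""

    t: np.ndarray  # minutes, strictly increasing, uniform
    F: np.ndarray  # AU, total nuclear fluorescence
    V: np.ndarray  # fL, mother compartment
    Vb: np.ndarray  # fL, bud compartment (0 before budding)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.Vb = np.asarray(self.Vb, dtype=float)
        n = len(self.t)
        if not (len(self.F) == len(self.V) == len(self.Vb) == n):
            raise ValueError("Trace arrays must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise ValueError("need >= 2 frames to infer frame interval")
        return float(self.t[1] - self.t[0])


@dataclass
class SimCell:
    """Ground truth for one cell cycle of one physical cell."""

    cell_id: str
    mother_id: str | None
    lineage_class: str  # "daughter" (first full cycle) or "mother"
    replicative_age: int
    true_T_G1: float
    true_T_S: float
    true_T_G2M: float
    true_T_Ana: float
    true_V_birth: float
    true_V_G1: float
    true_Vb_S: float
    true_Vb_G2M: float
    # bookkeeping beyond the headline truth fields
    birth_time: float  # global minutes of this cycle's start
    t_ana_onset: float  # global minutes, start of the fluorescence drop
    t_div: float  # global minutes, cytokinesis / end of the drop
    daughter_id: str | None
    daughter_V_birth: float
    retries: int
    trace: Trace | None = None

    @property
    def true_T_div(self) -> float:
        return self.true_T_G1 + self.true_T_S + self.true_T_G2M + self.true_T_Ana


# ---------------------------------------------------------------------------
# maturation kinetics
# ---------------------------------------------------------------------------

def _mat_step(I: float, M: float, P: float, tau: float, dt: float):
    """Exact update of (immature, mature) pools over dt with constant P."""
    if dt <= 0:
        return I, M
    if tau == 0.0:
        return 0.0, M + I + P * dt
    e = math.exp(-dt / tau)
    I_new = I * e + P * tau * (1.0 - e)
    M_new = M + P * dt - (I_new - I)
    return I_new, M_new


def apply_maturation(production: Sequence[float], tau_mat: float, dt: float) -> np.ndarray:
    """Mature-fluorophore amount produced by a piecewise-constant rate series.

    ``production[k]`` is the synthesis rate (amount per minute) held constant
    over the bin ``[k*dt, (k+1)*dt)``.  The returned array gives the mature
    amount at the *end* of each bin, obtained by exact integration of the
    two-compartment kinetics ``dI/dt = P - I/tau``, ``dM/dt = I/tau``.
    ``tau_mat = 0`` means instantaneous maturation (cumulative production).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if tau_mat < 0:
        raise ValueError("tau_mat must be >= 0")
    P = np.asarray(production, dtype=float)
    if np.any(P < 0):
        raise ValueError("production rates must be nonnegative")
    if tau_mat == 0.0:
        return np.cumsum(P) * dt
    out = np.empty_like(P)
    I = M = 0.0
    for k, p in enumerate(P):
        I, M = _mat_step(I, M, float(p), tau_mat, dt)
        out[k] = M
    return out


# ---------------------------------------------------------------------------
# linear map
# ---------------------------------------------------------------------------

def simulate_linear_map(
    p: float,
    V_eq: float,
    eta_sd: float,
    n_steps: int,
    V0: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Iterate ``V_{n+1} = p V_n + (1 - p) V_eq + eta_n``.

    Returns the sequence including ``V0`` (length ``n_steps + 1``).  Draws
    producing a non-positive volume are resampled (at most 100 tries per
    step) so that moments stay interpretable.
    """
    if eta_sd < 0:
        raise ValueError("eta_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = np.empty(n_steps + 1, dtype=float)
    V[0] = V0
    for n in range(n_steps):
        base = p * V[n] + (1.0 - p) * V_eq
        for _ in range(_MAX_RETRIES):
            v = base + (rng.normal(0.0, eta_sd) if eta_sd else 0.0)
            if v > 0:
                break
        else:
            v = max(base, 1e-6)
        V[n + 1] = v
    return V


# ---------------------------------------------------------------------------
# lineage simulation
# ---------------------------------------------------------------------------

@dataclass
class _CyclePlan:
    T_G1: float
    T_S: float
    T_G2M: float
    T_Ana: float
    V_birth: float
    V_G1: float
    Vb_S: float
    Vb_G2M: float
    Vb_div: float
    retries: int

    @property
    def boundaries(self):
        b1 = self.T_G1
        b2 = b1 + self.T_S
        b3 = b2 + self.T_G2M
        return b1, b2, b3, b3 + self.T_Ana


def _draw_target(rng, a, v_init, v_target, eta_sd):
    """Noisy compensation target; resample eta while the target is not above
    the current volume.  Returns (target, retries)."""
    retries = 0
    attempts = _MAX_RETRIES if eta_sd > 0 else 1
    for _ in range(attempts):
        eta = rng.normal(0.0, eta_sd) if eta_sd > 0 else 0.0
        target = a * v_init + (1.0 - a) * v_target + eta
        if target > v_init:
            return target, retries
        retries += 1
    return v_init, retries  # fall back to the minimum-duration floor


def _plan_cycle(cfg: SimConfig, rng: np.random.Generator, V_birth: float) -> _CyclePlan:
    retries = 0

    # G1: grow the mother to its (noisy) volume target
    target, r = _draw_target(rng, cfg.a_G1, V_birth, cfg.V_target_G1, cfg.eta_sd)
    retries += r
    if cfg.growth_mode == "linear":
        T_G1 = max((target - V_birth) / cfg.mu_unb, cfg.min_T_G1)
        V_G1 = V_birth + cfg.mu_unb * T_G1
    else:
        T_G1 = max(math.log(max(target, V_birth) / V_birth) / cfg.k_growth, cfg.min_T_G1)
        V_G1 = V_birth * math.exp(cfg.k_growth * T_G1)

    # S: duration-driven (Timer-like); bud appears at S onset
    if cfg.T_S_sd > 0:
        for _ in range(_MAX_RETRIES):
            T_S = rng.normal(cfg.T_S_mean, cfg.T_S_sd)
            if T_S > 0:
                break
            retries += 1
        else:
            T_S = cfg.T_S_mean
    else:
        T_S = cfg.T_S_mean
    if cfg.growth_mode == "linear":
        Vb_S = cfg.mu_bud * T_S
    else:
        Vb_S = V_G1 * (math.exp(cfg.k_growth * T_S) - 1.0)

    # G2/M: grow the bud to its target
    target_b, r = _draw_target(rng, cfg.a_G2M, Vb_S, cfg.Vb_target_G2M, cfg.eta_sd)
    retries += r
    if cfg.growth_mode == "linear":
        T_G2M = max((target_b - Vb_S) / cfg.mu_bud, cfg.min_T_G2M)
        Vb_G2M = Vb_S + cfg.mu_bud * T_G2M
    else:
        tot_S = V_G1 + Vb_S
        T_G2M = max(
            math.log(max(V_G1 + target_b, tot_S) / tot_S) / cfg.k_growth, cfg.min_T_G2M
        )
        Vb_G2M = tot_S * math.exp(cfg.k_growth * T_G2M) - V_G1

    # anaphase: fixed duration; the bud is brought to the volume that makes
    # division asymmetry exactly r_div
    Vb_div = cfg.r_div / (1.0 - cfg.r_div) * V_G1
    return _CyclePlan(
        T_G1, T_S, T_G2M, cfg.T_Ana_mean, V_birth, V_G1, Vb_S, Vb_G2M, Vb_div, retries
    )


def _cycle_volumes(plan: _CyclePlan, cfg: SimConfig, s: np.ndarray):
    """Mother/bud volumes at times ``s`` (minutes since cycle start)."""
    b1, b2, b3, b4 = plan.boundaries
    V = np.full_like(s, plan.V_G1)
    Vb = np.zeros_like(s)
    g1 = s < b1
    if cfg.growth_mode == "linear":
        V[g1] = plan.V_birth + cfg.mu_unb * s[g1]
    else:
        V[g1] = plan.V_birth * np.exp(cfg.k_growth * s[g1])
    in_S = (s >= b1) & (s < b2)
    in_G2M = (s >= b2) & (s < b3)
    in_Ana = s >= b3
    if cfg.growth_mode == "linear":
        Vb[in_S] = cfg.mu_bud * (s[in_S] - b1)
        Vb[in_G2M] = plan.Vb_S + cfg.mu_bud * (s[in_G2M] - b2)
    else:
        Vb[in_S] = plan.V_G1 * (np.exp(cfg.k_growth * (s[in_S] - b1)) - 1.0)
        Vb[in_G2M] = (plan.V_G1 + plan.Vb_S) * np.exp(
            cfg.k_growth * (s[in_G2M] - b2)
        ) - plan.V_G1
    if plan.T_Ana > 0:
        frac = (s[in_Ana] - b3) / plan.T_Ana
    else:
        frac = np.ones(int(in_Ana.sum()))
    Vb[in_Ana] = plan.Vb_G2M + frac * (plan.Vb_div - plan.Vb_G2M)
    return V, Vb


def _cycle_fluorescence(plan: _CyclePlan, cfg: SimConfig, I0: float, M0: float,
                        s: np.ndarray, d_frac: float):
    """Observed mother-ROI fluorescence at times ``s`` plus end-of-cycle pools.

    Production runs at (I0 + M0) / T_S during S, doubling the total reporter
    pool.  During anaphase the signal ramps linearly from the full level to
    the mother share, modelling nuclear division; the pools themselves are
    partitioned at cytokinesis.
    """
    b1, b2, b3, b4 = plan.boundaries
    H = I0 + M0
    R = H / plan.T_S if plan.T_S > 0 else 0.0
    bounds = [0.0, b1, b2, b3, b4]
    rates = [0.0, R, 0.0, 0.0]
    # pool state at each segment boundary
    states = [(I0, M0)]
    for j in range(4):
        I, M = states[-1]
        states.append(_mat_step(I, M, rates[j], cfg.tau_mat_min, bounds[j + 1] - bounds[j]))
    F = np.empty_like(s)
    for j in range(4):
        sel = (s >= bounds[j]) & (s < bounds[j + 1]) if j < 3 else (s >= bounds[j])
        if not np.any(sel):
            continue
        I, M = states[j]
        tau = cfg.tau_mat_min
        ds = s[sel] - bounds[j]
        if tau == 0.0:
            Mv = M + I + rates[j] * ds
        else:
            e = np.exp(-ds / tau)
            Iv = I * e + rates[j] * tau * (1.0 - e)
            Mv = M + rates[j] * ds - (Iv - I)
        w = np.ones_like(ds)
        if j == 3 and plan.T_Ana > 0:
            w = 1.0 - (ds / plan.T_Ana) * d_frac
        F[sel] = w * Mv
    I_end, M_end = states[-1]
    return F, I_end, M_end


def _simulate_physical(cfg, ss, cell_id, mother_id, V0, I0, M0, t_birth,
                       n_rounds, sink, spawn_queue):
    """Simulate one physical cell for ``n_rounds`` consecutive cycles."""
    rng = np.random.default_rng(ss)
    d_frac = 0.5 * cfg.dm_fluo_asymmetry
    dt = cfg.frame_interval_min

    frames_t, frames_F, frames_V, frames_Vb = [], [], [], []
    cycle_slices = []
    cells: list[SimCell] = []
    c0 = 0.0  # cycle start, minutes since this cell's birth
    V, I, M = V0, I0, M0
    for age in range(n_rounds):
        plan = _plan_cycle(cfg, rng, V)
        b4 = plan.boundaries[3]
        k0 = math.ceil(c0 / dt - 1e-9)
        k1 = math.ceil((c0 + b4) / dt - 1e-9)  # frames with c0 <= k*dt < c0+b4
        s = np.arange(k0, k1) * dt - c0
        Vm, Vb = _cycle_volumes(plan, cfg, s)
        F, I_end, M_end = _cycle_fluorescence(plan, cfg, I, M, s, d_frac)
        frames_t.append(t_birth + c0 + s)
        frames_F.append(F)
        frames_V.append(Vm)
        frames_Vb.append(Vb)
        cycle_slices.append((sum(len(a) for a in frames_t[:-1]), len(s)))

        daughter_id = f"{cell_id}.{age}"
        t_div = t_birth + c0 + b4
        cells.append(
            SimCell(
                cell_id=cell_id,
                mother_id=mother_id,
                lineage_class="daughter" if age == 0 else "mother",
                replicative_age=age,
                true_T_G1=plan.T_G1,
                true_T_S=plan.T_S,
                true_T_G2M=plan.T_G2M,
                true_T_Ana=plan.T_Ana,
                true_V_birth=plan.V_birth,
                true_V_G1=plan.V_G1,
                true_Vb_S=plan.Vb_S,
                true_Vb_G2M=plan.Vb_G2M,
                birth_time=t_birth + c0,
                t_ana_onset=t_birth + c0 + plan.boundaries[2],
                t_div=t_div,
                daughter_id=daughter_id,
                daughter_V_birth=plan.Vb_div,
                retries=plan.retries,
            )
        )
        rounds_left = n_rounds - age - 1
        if rounds_left > 0:
            spawn_queue.append(
                (daughter_id, cell_id, plan.Vb_div, d_frac * I_end, d_frac * M_end,
                 t_div, rounds_left)
            )
        V = plan.V_G1
        I = (1.0 - d_frac) * I_end
        M = (1.0 - d_frac) * M_end
        c0 += b4

    if frames_t:
        t = np.concatenate(frames_t)
        F = np.concatenate(frames_F)
        Vm = np.concatenate(frames_V)
        Vb = np.concatenate(frames_Vb)
        if cfg.sigma_F > 0:
            F = np.clip(F + rng.normal(0.0, cfg.sigma_F, size=F.shape), 0.0, None)
        if cfg.sigma_V > 0:
            Vm = np.clip(Vm + rng.normal(0.0, cfg.sigma_V, size=Vm.shape), 0.1, None)
            noise = rng.normal(0.0, cfg.sigma_V, size=Vb.shape)
            Vb = np.where(Vb > 0, np.clip(Vb + noise, 0.0, None), 0.0)
        for cell, (i0, n) in zip(cells, cycle_slices):
            cell.trace = Trace(t[i0:i0 + n], F[i0:i0 + n], Vm[i0:i0 + n], Vb[i0:i0 + n])
    sink.extend(cells)


def simulate_lineage(config: SimConfig, with_traces: bool = True) -> list[SimCell]:
    """Simulate ``n_cells`` founder lineages over ``n_generations`` rounds.

    Every division spawns a daughter that is itself simulated for the
    remaining rounds, so the output holds ``n_cells * (2**n_generations - 1)``
    cell cycles.  ``with_traces=False`` skips frame sampling and returns the
    ground-truth records only (much faster for statistical tests).

    Randomness uses one root seed with per-cell child streams: adding
    founders never perturbs existing cells.
    """
    cfg = config
    v_mean = cfg.founder_V_mean if cfg.founder_V_mean is not None else 0.8 * cfg.V_target_G1

    sink: list[SimCell] = []
    sim = _simulate_physical if with_traces else _simulate_truth_only
    for i in range(cfg.n_cells):
        # per-founder streams keyed by index, so adding founders never
        # perturbs existing cells
        v0_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, i)))
        V0 = v_mean + (v0_rng.normal(0.0, cfg.founder_V_sd) if cfg.founder_V_sd else 0.0)
        V0 = max(V0, 2.0)
        queue = [(f"c{i:04d}", None, V0, 0.0, cfg.founder_F0, 0.0, cfg.n_generations)]
        cell_ss = {f"c{i:04d}": np.random.SeedSequence(cfg.seed, spawn_key=(0, i))}
        while queue:
            cid, mid, V, I0, M0, t0, rounds = queue.pop(0)
            ss = cell_ss.pop(cid)
            spawned: list = []
            sim(cfg, ss, cid, mid, V, I0, M0, t0, rounds, sink, spawned)
            children = ss.spawn(len(spawned)) if spawned else []
            for child_ss, rec in zip(children, spawned):
                cell_ss[rec[0]] = child_ss
                queue.append(rec)
    return sink


def _simulate_truth_only(cfg, ss, cell_id, mother_id, V0, I0, M0, t_birth,
                         n_rounds, sink, spawn_queue):
    """Ground-truth-only twin of :func:`_simulate_physical` (no frames)."""
    rng = np.random.default_rng(ss)
    d_frac = 0.5 * cfg.dm_fluo_asymmetry
    V = V0
    c0 = 0.0
    for age in range(n_rounds):
        plan = _plan_cycle(cfg, rng, V)
        b4 = plan.boundaries[3]
        daughter_id = f"{cell_id}.{age}"
        t_div = t_birth + c0 + b4
        sink.append(
            SimCell(
                cell_id=cell_id,
                mother_id=mother_id,
                lineage_class="daughter" if age == 0 else "mother",
                replicative_age=age,
                true_T_G1=plan.T_G1,
                true_T_S=plan.T_S,
                true_T_G2M=plan.T_G2M,
                true_T_Ana=plan.T_Ana,
                true_V_birth=plan.V_birth,
                true_V_G1=plan.V_G1,
                true_Vb_S=plan.Vb_S,
                true_Vb_G2M=plan.Vb_G2M,
                birth_time=t_birth + c0,
                t_ana_onset=t_birth + c0 + plan.boundaries[2],
                t_div=t_div,
                daughter_id=daughter_id,
                daughter_V_birth=plan.Vb_div,
                retries=plan.retries,
            )
        )
        rounds_left = n_rounds - age - 1
        if rounds_left > 0:
            spawn_queue.append((daughter_id, cell_id, plan.Vb_div, 0.0, 0.0, t_div, rounds_left))
        V = plan.V_G1
        c0 += b4


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def lineage_tables(cells: Iterable[SimCell], strain: str = "sim"):
    """Build (traces, truth, lineage) DataFrames from simulated cells.

    ``traces`` has one row per frame per physical cell (consecutive cycles of
    the same cell concatenated); ``truth`` one row per cell cycle;
    ``lineage`` one row per physical cell.
    """
    cells = list(cells)
    truth = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "cycle_index": [c.replicative_age for c in cells],
            "mother_id": [c.mother_id if c.mother_id is not None else "" for c in cells],
            "lineage_class": [c.lineage_class for c in cells],
            "replicative_age": [c.replicative_age for c in cells],
            "birth_time_min": [c.birth_time for c in cells],
            "t_ana_onset_min": [c.t_ana_onset for c in cells],
            "t_div_min": [c.t_div for c in cells],
            "true_T_G1": [c.true_T_G1 for c in cells],
            "true_T_S": [c.true_T_S for c in cells],
            "true_T_G2M": [c.true_T_G2M for c in cells],
            "true_T_Ana": [c.true_T_Ana for c in cells],
            "true_T_div": [c.true_T_div for c in cells],
            "true_V_birth": [c.true_V_birth for c in cells],
            "true_V_G1": [c.true_V_G1 for c in cells],
            "true_Vb_S": [c.true_Vb_S for c in cells],
            "true_Vb_G2M": [c.true_Vb_G2M for c in cells],
            "daughter_id": [c.daughter_id or "" for c in cells],
            "daughter_V_birth": [c.daughter_V_birth for c in cells],
            "retries": [c.retries for c in cells],
        }
    )
    rows = []
    frames = {}
    for c in cells:
        if c.trace is None:
            continue
        frames.setdefault(c.cell_id, []).append(c)
    for cid, cyc in frames.items():
        cyc = sorted(cyc, key=lambda c: c.birth_time)
        t = np.concatenate([c.trace.t for c in cyc])
        F = np.concatenate([c.trace.F for c in cyc])
        V = np.concatenate([c.trace.V for c in cyc])
        Vb = np.concatenate([c.trace.Vb for c in cyc])
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cid,
                    "frame": np.arange(len(t)),
                    "t_min": t,
                    "fluo_au": F,
                    "vol_mother_fl": V,
                    "vol_bud_fl": Vb,
                }
            )
        )
    traces = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["cell_id", "frame", "t_min", "fluo_au", "vol_mother_fl", "vol_bud_fl"]
        )
    )
    lineage = (
        truth[truth.cycle_index == 0][["cell_id", "mother_id"]]
        .drop_duplicates("cell_id")
        .assign(strain=strain)
        .reset_index(drop=True)
    )
    return traces, truth, lineage


# ---------------------------------------------------------------------------
# direct calibration cohorts (no trace machinery)
# ---------------------------------------------------------------------------

def sizer_cohort(n, rng, v_mean=40.0, v_sd=8.0, v_final=80.0, final_sd=2.0):
    """(V_i, dV) with constant final volume: ideal Sizer, slope -1."""
    rng = np.random.default_rng(rng)
    vi = rng.normal(v_mean, v_sd, size=n)
    vf = v_final + (rng.normal(0.0, final_sd, size=n) if final_sd else 0.0)
    return vi, vf - vi


def adder_cohort(n, rng, v_mean=40.0, v_sd=8.0, dv_mean=40.0, dv_sd=8.0):
    """(V_i, dV) with added volume independent of V_i: ideal Adder, slope 0."""
    rng = np.random.default_rng(rng)
    vi = rng.normal(v_mean, v_sd, size=n)
    return vi, rng.normal(dv_mean, dv_sd, size=n)


def timer_cohort(n, rng, v_mean=40.0, v_sd=8.0, noise_cv=0.05):
    """(V_i, dV) for a fixed-duration phase under exponential growth chosen so
    the mean volume doubles: ideal Timer, slope +1."""
    rng = np.random.default_rng(rng)
    vi = rng.normal(v_mean, v_sd, size=n)
    vf = 2.0 * vi * np.exp(rng.normal(0.0, noise_cv, size=n)) if noise_cv else 2.0 * vi
    return vi, vf - vi
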