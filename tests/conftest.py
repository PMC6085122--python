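import numpy as np
import pandas as pd
import pytest

from histocycle import simkit, tracefit


def aligned_config(**overrides) -> simkit.SimConfig:
    """Noiseless config whose phase boundaries land exactly on the frame grid:
    T_G1=30, T_S=27, T_G2M=21, T_Ana=9 for the founder generation."""
    base = dict(
        n_cells=1,
        n_generations=2,
        seed=0,
        eta_sd=0.0,
        T_S_sd=0.0,
        sigma_F=0.0,
        sigma_V=0.0,
        a_G1=0.0,
        a_G2M=0.0,
        V_target_G1=48.0,
        Vb_target_G2M=24.0,
        mu_unb=0.45,
        mu_bud=0.5,
        T_S_mean=27.0,
        T_Ana_mean=9.0,
        tau_mat_min=0.0,
        founder_V_mean=34.5,
        founder_V_sd=0.0,
    )
    base.update(overrides)
    return simkit.SimConfig(**base)


def physical_traces(cells) -> dict[str, simkit.Trace]:
    """Concatenate per-cycle traces into one Trace per physical cell."""
    groups: dict[str, list] = {}
    for c in cells:
        groups.setdefault(c.cell_id, []).append(c)
    out = {}
    for cid, cyc in groups.items():
        cyc = sorted(cyc, key=lambda c: c.birth_time)
        out[cid] = simkit.Trace(
            np.concatenate([c.trace.t for c in cyc]),
            np.concatenate([c.trace.F for c in cyc]),
            np.concatenate([c.trace.V for c in cyc]),
            np.concatenate([c.trace.Vb for c in cyc]),
        )
    return out


def segment_cohort(cells, cyto_offset_min=0.0, drop_frac=0.25):
    """Segment every physical cell and pair fitted cycles with ground truth.

    Returns a DataFrame with fitted (T_*) and true (true_T_*) durations, one
    row per cycle, only for cells where the number of detected cycles equals
    the number of simulated cycles (mismatches counted in attrs).
    """
    traces = physical_traces(cells)
    truth: dict[str, list] = {}
    for c in cells:
        truth.setdefault(c.cell_id, []).append(c)
    rows = []
    mismatched = 0
    for cid, trace in traces.items():
        cyc = sorted(truth[cid], key=lambda c: c.birth_time)
        if len(trace) < 10:
            continue
        segs = tracefit.segment_trace(
            trace, cid, birth_is_cytokinesis=True,
            cyto_offset_min=cyto_offset_min, drop_frac=drop_frac,
        )
        if len(segs) != len(cyc):
            mismatched += 1
            continue
        for seg, tc in zip(segs, cyc):
            rows.append(
                {
                    "cell_id": cid,
                    "cycle_index": seg.cycle_index,
                    "T_G1": seg.T_G1, "T_S": seg.T_S,
                    "T_G2M": seg.T_G2M, "T_Ana": seg.T_Ana,
                    "t1": seg.t1, "t2": seg.t2,
                    "t_ana": seg.t_ana, "t_ana_end": seg.t_ana_end,
                    "F1": seg.F1, "F2": seg.F2, "r2": seg.r2,
                    "true_T_G1": tc.true_T_G1, "true_T_S": tc.true_T_S,
                    "true_T_G2M": tc.true_T_G2M, "true_T_Ana": tc.true_T_Ana,
                    "true_t_ana": tc.t_ana_onset, "true_t_div": tc.t_div,
                    "last_cycle": tc is cyc[-1],
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["mismatched_cells"] = mismatched
    return df


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noiseless multi-generation cohort (tau=0) with varied founder sizes."""
    cfg = aligned_config(n_cells=30, n_generations=3, founder_V_sd=4.0, seed=11)
    return simkit.simulate_lineage(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort with 2%-of-plateau fluorescence noise, >=500 cycles."""
    cfg = aligned_config(
        n_cells=90, n_generations=3, founder_V_sd=4.0, seed=23, sigma_F=2.0,
        eta_sd=1.5, T_S_sd=2.0, a_G1=0.4, a_G2M=0.3,
    )
    return simkit.simulate_lineage(cfg)


@pytest.fixture(scope="session")
def wt_like_truth():
    """Large truth-only cohort with moderate G1/G2M control (default config)."""
    cfg = simkit.SimConfig(n_cells=60, n_generations=6, seed=5)
    cells = simkit.simulate_lineage(cfg, with_traces=False)
    _, truth, _ = simkit.lineage_tables(cells)
    return truth
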