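# histocycle

Cell-cycle phenotyping from nuclear histone-reporter traces, and downstream
size-homeostasis analysis, in one tested pipeline:

* **simkit** — simulate lineages of growing, dividing cells with a nuclear
  reporter: plateau / ramp / plateau / drop fluorescence dynamics, per-phase
  size compensation with exact ground truth (slope `s = a − 1`), division
  asymmetry, first-order fluorophore maturation, measurement noise, and the
  noisy linear map `V_{n+1} = p·V_n + (1−p)·V_eq + η`.
* **tracefit** — detect anaphase fluorescence drops, fit the continuous
  plateau–ramp–plateau model between drops by exhaustive breakpoint search,
  convert breakpoints into G1/S/G2M/anaphase durations (cytokinesis is placed
  5.6 min after the end of the drop by default), and apply explicit QC.
* **cyclestats** — per-cycle variables, duration summaries, two-sample
  Kolmogorov–Smirnov comparisons, mother/daughter Pearson correlograms, and
  robust (IRLS bisquare) compensation slopes with 95% CIs
  (Sizer −1 / Adder 0 / Timer +1 calibration).
* **sizenoise** — CV and Fano factor per cell-cycle checkpoint with bootstrap
  errors, the `CV = sqrt(F/V)` power-law fit, and per-phase Fano fold-changes.
* **linmap** — return-map estimation of `(p, V_eq, η²)`, the analytic Fano
  prediction `F = (η²/V_eq) / ((1−p)(1+p))`, the one-parameter intrinsic-noise
  fit across strains, convergence rates `λ = −ln(p)/⟨T_div⟩`, and
  convergence-trajectory analysis of deviant founder lineages.
* **iface** — CSV formats, YAML configuration, the pipeline driver and CLI.

## CLI

```sh
# simulate a synthetic cohort, then run everything on it
histocycle all --out-dir out --seed 1

# or stage by stage on existing tables
histocycle simulate --out-dir out --seed 1 --n-cells 20 --n-generations 4
histocycle fit   --traces out/traces.csv --lineage out/lineage.csv --out-dir out
histocycle stats --traces out/traces.csv --lineage out/lineage.csv --out-dir out
histocycle noise --traces out/traces.csv --lineage out/lineage.csv --out-dir out
histocycle map   --traces out/traces.csv --lineage out/lineage.csv --out-dir out
```

All numeric defaults can be overridden by a YAML config (`--config run.yaml`)
whose keys mirror the `RunConfig`, `SimConfig` and `QCPolicy` field names 1:1.
Outputs are CSV tables (`traces.csv`, `truth.csv`, `cycles.csv`,
`variables.csv`, `summary.csv`, `correlogram.csv`, `slopes.csv`,
`noise_profile.csv`, `fano_foldchange.csv`, `linmap.csv`,
`trajectories.csv`) with a `# seed=… / # config_sha=…` header, plus a
`manifest.json` with per-stage counts and the QC rejection histogram.
Re-running with an identical configuration reproduces every output
byte-for-byte. Exit codes: 0 success, 2 validation error, 3 stage failure.

Input format: `traces.csv` with columns
`cell_id, frame, t_min, fluo_au, vol_mother_fl, vol_bud_fl` (uniform frame
grid per cell; minutes / AU / fL) and a lineage sidecar
`cell_id, mother_id, strain`.

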