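# switchnet

Dynamic brain-network switching-rate analysis for node-level fMRI time
courses, with a synthetic cohort generator for validation by parameter
recovery.

## The problem

After a stroke, the brain's large-scale functional networks reorganize,
and the *rate* at which regions shift their community affiliation over
time — the network switching rate, a.k.a. flexibility — has been
proposed as a marker of recovery capacity. Estimating it requires a
chain of steps: condition the node time courses, estimate time-resolved
connectivity in sliding windows, couple the windows into one multilayer
temporal network, find a joint module assignment by maximizing
multilayer modularity, count label changes, and compare groups.
`switchnet` implements that chain as a tested, reusable pipeline for
anyone analyzing node x time activity matrices (e.g. independent-
component time courses), and — since clinical fMRI data are rarely
shareable — ships a generator that plants known switching dynamics so
the whole chain can be validated end to end.

## The model

Windows of width 20 frames (step 1) give per-window Pearson
correlation matrices; negatives are set to zero. Layers `A[s]` are
coupled by ordinal links of weight ω between each node and itself in
adjacent layers, and a joint assignment g of every (node, layer) slot
is scored by the multilayer modularity

    Q = (1/2μ) Σ_{ijsr} [ (A_ijs − γ k_is k_js / 2m_s) δ_sr
                          + δ_ij ω 1(|s−r|=1) ] δ(g_is, g_jr)

optimized by generalized Louvain (γ = 0.9, ω = 0.75, 50 seeded
repetitions, metrics averaged). A node's switching rate is the
fraction of layer transitions with a changed label; subnetwork and
global rates are node averages. Groups are compared with a
KS-normality-gated t / Mann–Whitney test (Benjamini–Hochberg FDR within
the node and subnetwork families), and motor recovery is predicted by
single-predictor least-squares models reported with B, β, p, R², RMSE
and AIC.

## Worked example

```python
from switchnet import (SimulationConfig, WindowSpec, MultilayerParams,
                       RunConfig, run_pipeline)

config = RunConfig(
    simulation=SimulationConfig(n_nodes=12, n_frames=183, n_per_group=10,
                                n_subnetworks=9, smoothing_kernel=1),
    window=WindowSpec(width_frames=6, step_frames=3),
    community=MultilayerParams(gamma=0.9, omega=0.5, n_repetitions=4),
    seed=7,
)
bundle = run_pipeline(config)
```

This simulates a 20-subject two-group cohort (patients switch three
times faster in the three affected subnetworks), runs every stage, and
returns the metrics table plus all statistics. Inspecting the bundle
prints:

```
         global_rate  q_mean
control       0.1641  0.4056
patient       0.1951  0.3901

global test: t, p = 4.11e-06 (patient>control)

    metric    p_fdr       direction
subnet_SN1 0.009049 patient>control
subnet_SN2 0.001290 patient>control
subnet_SN3 0.001290 patient>control

  model       variable        B   beta    R2   RMSE    AIC
Model 1 baseline_score   -2.504 -0.584 0.341  8.937 47.805
Model 2    global_rate -281.924 -0.107 0.011 10.951 51.868
```

Reading the numbers: the patient group's mean global switching rate
(0.195) exceeds the controls' (0.164) and the uncorrected global test
flags it; exactly the three planted subnetworks (SN1–SN3) survive FDR,
the other six do not. Modularity Q itself barely differs between
groups. Model 2's near-zero R² is expected here: every simulated
patient shares one hazard, so between-patient variation in true
switching is tiny and the recovered rate is mostly measurement noise —
the regression stage's arithmetic is instead validated exactly against
closed-form least-squares algebra in the test suite, where a noiseless
behavioral coupling yields R² = 1.

The same run is available from the shell:

```bash
switchnet all --seed 7 --out-dir runs/demo          # full pipeline
switchnet sweep --seed 7 --out-dir runs/sweep       # robustness grid
```

`sweep` re-analyzes one cohort over window width {20, 50},
γ {0.9, 1, 1.1} and ω {0.5, 0.75, 1} and reports, per cell, whether the
same metrics are significant in the same direction as the base setting.

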