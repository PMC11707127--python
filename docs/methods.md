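# Methods

`switchnet` implements a dynamic brain-network analysis chain for
node-level activity time courses, together with a synthetic cohort
generator that makes every stage testable by parameter recovery. This
note records the models, the defaults and why they were chosen, the
numerical conventions, and what the validation suite does and does not
establish.

## Pipeline model

**Input.** A node x frame real matrix per subject (43 independent-
component time courses of 229 frames at TR = 2 s in the full-scale
configuration), a node -> subnetwork map (nine resting-state systems:
VIS, SMN, DAN, VAN, LIM, FPN, DMN, SCN, CBN), and per-subject
covariates (group, age, sex, baseline motor score, score change).

**Conditioning.** Per node: least-squares linear detrending; robust-z
despiking (samples beyond a median/MAD z of 4 are shrunk to the
threshold boundary, sign preserved); zero-phase band-pass filtering
(order-2 Butterworth applied forward-backward), default band
0.01-0.08 Hz, the conventional range for resting-state fluctuations.
The despiking rule and filter band are this package's explicit
stand-ins — robust-z clipping was chosen over soft squashing because
its effect on any single sample is exactly testable. A bypass flag
skips the stage for synthetic data that needs no conditioning.

**Dynamic network.** Sliding windows of 20 frames, step 1 (a 229-frame
series gives 210 windows). Within each window the Pearson correlation
of every node pair is computed; negative entries are truncated to zero
and the diagonal is set to zero, so each layer is symmetric and
nonnegative. No window tapering is applied. The self-connectivity
exclusion (zero diagonal) keeps the modularity null model's strength
terms well defined. A node with zero variance inside a window gets zero
correlations with a logged warning rather than aborting a batch run.

**Multilayer coupling.** Layers are joined into a super-adjacency of
order `n_nodes * n_layers` (layer-major: node i of layer t at row
`t*n_nodes + i`) with uniform, undirected ordinal couplings: weight
omega between a node and itself in adjacent layers only. Categorical
(all-layer) coupling is out of scope.

**Community detection.** Joint assignments g[i,t] of every
(node, layer) slot are scored by the multilayer modularity

    Q = (1/2mu) * sum_{ijsr} [ (A[s]_ij - gamma k[s]_i k[s]_j / 2m_s) d(s,r)
                               + d(i,j) * omega * [|s-r|=1] ] * d(g_is, g_jr)

with per-layer strengths k, half-total-weights m_s, and
`2mu = sum_s 2m_s + 2*omega*n*(L-1)`. The diagonal null-model terms
(i = j, s = r) are included, which makes the single-layer restriction
the standard Newman-Girvan form (two disconnected equal cliques split
by clique score Q = 0.5). A zero-weight layer contributes no null-model
term. Q is optimized by a generalized Louvain heuristic: greedy local
moving of slots over the modularity operator (gains are plain sums of
operator entries because the null model is already embedded), then
aggregation of modules into super-nodes, iterated to convergence.
Defaults gamma = 0.9, omega = 0.75, 50 repetitions per subject whose
node-visit orders come from per-repetition streams seeded
`seed + repetition`; metrics are averaged over repetitions. Equal-gain
moves keep the current assignment (stability bias); the minimum Q gain
to accept a move is 1e-10; labels are canonicalized by first appearance
in layer-major order. By contract the returned partition is never worse
than the all-singletons or all-in-one baselines. An exhaustive
set-partition oracle (guarded at <= 12 slots) provides exact maxima for
testing; on random small instances best-of-20-restart Louvain matches
the oracle's maximum in well over 90% of instances and can never
exceed it.

**Switching metrics.** A node's switching rate is the fraction of
layer-to-layer transitions at which its module label changes,
`rate_i = #{t: g[i,t] != g[i,t+1]} / (L-1)`. The transitions
denominator (L-1, not L) makes the rate a proportion with range exactly
[0, 1]; a frames denominator is available as a sensitivity option.
Because the ordinal coupling carries labels through time, raw label
changes are meaningful without relabel matching. Rates are averaged per
node over repetitions first, then over subnetwork members and over all
nodes; the two averaging orders commute and this is asserted in tests.

**Statistics.** Per metric, a one-sample Kolmogorov-Smirnov check per
group (against a normal with estimated moments — the Lilliefors caveat
is logged) gates an independent-sample t-test versus a Mann-Whitney
U-test at alpha = 0.05. Node-level and subnetwork-level families are
corrected with Benjamini-Hochberg FDR separately; the single
global-network test is reported uncorrected. Demographics use the gated
test for age and chi-square for sex. Behavioral correlations are
Pearson (Spearman by flag) on score-bearing subjects only, uncorrected.
Motor-recovery prediction fits two separate single-predictor OLS models
(change ~ baseline score; change ~ global switching rate) and reports
B, the standardized beta, p, R^2, RMSE = sqrt(RSS/n), and the
constant-free AIC `n*ln(RSS/n) + 2k` with k = 2 (slope + intercept).
The AIC variant omits the `n*ln(2*pi) + n` constant; this shifts
absolute values but never model rankings.

## Synthetic cohort generator

The generator plants a ground truth that the pipeline should recover.

* **Memberships.** Each node follows an independent Markov chain over
  `n_modules` (default 4) latent modules: after the first frame it
  leaves its module with a per-frame hazard, resampling uniformly among
  the other modules. All random draws are made up front, so two runs
  from a shared stream at different hazards produce *coupled* chains —
  the lower hazard's switch set is nested in the higher's — which is
  the paired design the hazard-recovery validations use. Patients'
  elevated hazard (default 0.15 vs 0.05 per frame) applies only to
  nodes of the affected subnetworks (default FPN, DMN and CBN at the
  43-node layout, mirroring the group-difference pattern the analysis
  is meant to detect); other patient nodes switch at the control rate.
* **Signals.** `x_it = sqrt(rho) z_{m(i,t),t} + sqrt(1-rho) * noise_sd * eps_it`
  with shared per-module signals z and i.i.d. eps, so at the default
  `noise_sd = 1` the instantaneous correlation of two same-module nodes
  is exactly `rho` (`within_module_corr`, default 0.8). The
  equicorrelation block is checked for positive definiteness before
  sampling. A moving-average kernel (default 3 frames) gives the series
  enough temporal smoothness for windowed correlation to see the
  planted structure.
* **Behavior.** Patient change scores follow
  `intercept + slope * (true global switch rate) + N(0, noise_sd)`,
  defaults 5 + 150*rate with SD 8 points, placing scores near the
  clinical range of a moderate-impairment stroke cohort (change
  ~26 +/- 9 points); ages, sexes and baseline scores are drawn to match
  that cohort's demographics. Controls carry no scores.
* **Reproducibility.** One named stream per subject, derived from the
  master seed with a spawn key, so enlarging a cohort never perturbs
  existing subjects.

What the generator does **not** emulate: hemodynamics (no BOLD
convolution), spatial maps or lesion geometry, realistic scan-to-scan
autocorrelation (the smoothing kernel is a stand-in), or coordinated
whole-module regime shifts (switching is per-node and independent, so
the ground-truth rate is unambiguous). Passing recovery tests therefore
show that the chain of estimators is consistent with its own generative
assumptions — not that those assumptions hold for real fMRI.

## Desk-scale validation geometry

The full-scale configuration (43 nodes x 229 frames, 210 layers, 50
repetitions, 40 subjects) is what the package defaults to, but the
Monte-Carlo validation suites shrink the problem so hundreds of
complete pipeline runs finish quickly.

**Resolution limit.** A sliding window of width W acts as a majority
filter on each node's latent chain: module dwell times shorter than
roughly the window width cannot be resolved, and the recovered
switching rate *saturates* — and can even decrease — as the planted
per-frame hazard grows beyond ~1/W. With a 20-frame window this
turnover begins near hazard 0.1. This is a property of sliding-window
dynamic connectivity itself, not of the optimizer: wider windows
estimate each layer better but blur fast dynamics.

**Hazard-recovery geometry** (`validation.RecoveryGeometry`): 20 nodes
in 4 modules, 300 frames, window width 6 with step 3 (99 layers),
gamma 0.9, omega 0.5, 8 repetitions, within-module correlation 0.9, no
smoothing kernel. The short, coarsely-stepped window resolves dwell
times down to ~5 frames so the whole hazard band up to 0.2 sits inside
the monotone region of the transfer curve; omega 0.5 (one of the
values in the parameter-robustness grid) anchors labels weakly enough
that recovered rates track the planted hazard; consecutive layers
share no frames, which decorrelates layer estimates and sharpens the
per-subject rate. Hazard-recovery replicates simulate one subject per
hazard from a common stream; because the generator draws all switching
randomness up front, the chains are coupled (nested switch sets),
giving a paired comparison.

**Cohort-level studies** (type-I calibration, planted-effect power) use
12 nodes in 9 subnetworks (sizes 2,2,2,1,...,1; the first three are the
affected set), 183 frames (60 layers at the same window), 2 repetitions
per subject, and 10 (null) or 20 (power) subjects per group. Under the
null both test branches are calibrated within binomial error; with the
patient hazard at 3x control the planted pattern — every affected
subnetwork at FDR < 0.05 plus the uncorrected global test — is
detected in essentially every cohort.

## Known limitations

* Negative correlations are discarded (upstream truncation); no signed
  or negative-weight modularity variant is provided.
* The Louvain heuristic is greedy; only repetition averaging addresses
  its run-to-run variability, as in standard practice.
* Group sizes below ~10 per group leave the KS gate underpowered, so
  the t-branch is chosen almost always on Gaussian-ish metrics.
* The behavioral coupling is linear by construction; the regression
  stage's R^2 on synthetic cohorts says nothing about real-world
  effect sizes.
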