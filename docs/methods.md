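# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `netchange`, in the order the pipeline runs them.

## Synthetic cohorts

`netchange.synthetic` generates two-session cohorts that emulate a
resting-state treatment study: per subject, a pre- and a post-treatment
node × time series with planted modular correlation structure, motion
artifacts, and a clinical table whose follow-up outcome is linked to the
subject's measured pre-treatment network topology.

**Signal model.** Node *i* in module *m(i)* is

    x_i(t) = baseline + signal_sd · (a·g(t) + b·f_{m(i)}(t) + c·e_i(t)),

with global factor *g*, module factors *f_m*, idiosyncratic noise *e_i*
(all iid standard normal) and loadings solved analytically from the target
correlations: a² = between_r, b² = within_r − between_r, c² = 1 − within_r.
This factor construction guarantees a positive-definite covariance for any
valid (between_r, within_r), costs O(n) memory, and makes the targets exact
in expectation (verified to ±0.02 at 20 000 volumes in the tests).
Infeasible targets (between_r > within_r or within_r ≥ 1) are rejected with
a diagnostic rather than silently clipped.

**Defaults** mirror a 17-subject, 160-node, 208-volume (TR = 2 s) design:
`n_subjects=17, n_nodes=160, n_timepoints=208, tr=2.0`. Module structure
uses 6 equal modules with `within_r=0.4, between_r=0.1` — within-module
resting-state correlations of ~0.4 against a weak global background are
typical of functional parcellations. `baseline=100` and `signal_sd=7` put
the DVARS percent scale near the ~10 % values real scans show. Motion
spikes hit each volume with probability 0.02 at 4 SD amplitude with a
common sign across nodes (motion displaces the whole head); spiked volume
indices are recorded in provenance.

**Clinical model.** Pre-treatment YBOCS ~ N(23.12, 3.04); the percent
reduction to post-treatment ~ N(40.4, 16.4), so post scores are coupled to
pre scores the way real within-subject scores are. HAMA, MADRS, GAS and
Stroop scores are drawn from matching pre/post Gaussians. All scores are
rounded to integers and clamped to instrument ranges (instruments are
integer-valued), with a warning when clamping occurs. CGI is a deterministic
map of the realised percent reduction (≥65 % → 1, ≥35 % → 2, ≥15 % → 3,
else 4), so responder status (≥35 % reduction and CGI ≤ 2) is coherent with
the score trajectory. Follow-up covariates — months to follow-up
(N(7, 4.53) clamped to 1–12), medication months, CBT sessions (present with
probabilities 6/17 and 10/17) — are independent of outcome.

**Planted outcome effect.** The follow-up symptom change (YBOCS at
follow-up minus post; positive = worsening) is

    Δ = effect_beta · z(σ_AUC,pre) + ε,   ε ~ N(0, outcome_noise_sd²),

where z(σ_AUC,pre) is the subject's *realised* pre-treatment
small-worldness AUC — computed from the generated time series by the
package's own partial-correlation + thresholded-metrics stack
(`metric_grid`, `metric_n_rand` in the spec) — standardised across the
cohort. Planting the effect on the realised rather than a latent value
makes downstream recovery a true end-to-end test. Defaults
`effect_beta=4, outcome_noise_sd=3` give an R² regime (16/25 = 0.64) in
which a 17-subject study has high power for the slope's sign, matching the
strength of association such studies report.

**Treatment effect on topology.** The post session is generated with
`within_r + post_within_r_delta` (default +0.05), which raises clustering
and small-worldness; both AUCs were verified to increase monotonically in
the delta.

## Preprocessing

Stage order is fixed and logged: discard initial volumes → band-pass →
confound regression → DVARS. Filtering is a zero-phase forward–backward
Butterworth (order 2 per pass; the effective response is the square), by
default 0.009–0.08 Hz; with `low_hz=0` it degenerates to a low-pass.
Confound regression projects out six motion parameters, white-matter and
CSF signals, and their backward-difference temporal derivatives (first
element 0), always with an intercept; rank-deficient designs drop dependent
columns with a warning (or fail, per configuration). Residuals are
orthogonal to every retained regressor to < 1e−8 relative.

DVARS_t = √(mean over nodes of (x_t − x_{t−1})²), reported as percent of
the scan's grand mean **absolute** signal — a percent-style exclusion rule
("mean DVARS > 25 %") needs a reference signal, and the grand mean absolute
signal is the natural choice that also behaves on demeaned data; a raw-unit
mode exists and is the automatic fallback when the reference is ~0. Scans
exceeding the threshold are *flagged*, never silently dropped; exclusion is
the orchestrator's decision. By default the pipeline computes DVARS on the
raw (post-discard) series, where percent scaling is interpretable; a
cleaned-series mode is available.

ROI extraction from registered 4-D NIfTI volumes averages voxels whose
centre lies within `radius_mm` of each node centre (world/mm coordinates
via the image affine, RAS); an empty sphere is an error naming the node.

## Connectivity

Partial correlations condition each node pair on all remaining nodes via
the precision matrix: ρ_ij = −P_ij/√(P_ii P_jj), symmetrised and clipped to
[−1, 1], diagonal set to exactly 0 so thresholding can never select
self-connections. With n nodes ≈ n volumes the sample covariance is
near-singular, and how the conditioning is made feasible is a genuine
analysis choice: the default is Ledoit–Wolf analytic shrinkage toward a
scaled-identity target (deterministic and parameter-free; the chosen
intensity is recorded on the matrix and in the sidecar JSON), with a
fixed-intensity mode shrinking toward the covariance diagonal. At
shrinkage 0 a singular covariance fails with guidance to enable shrinkage.

A note on the shrinkage path: the *aggregate* magnitude of partial
correlations (mean and max over edges) decreases monotonically toward 0 as
the intensity rises, but individual edges need not be monotone — the tests
assert the aggregate behaviour.

## Graph metrics

Thresholding retains the `round(S·n(n−1)/2)` strongest positive edges with
their weights (ranking by signed weight; negative edges are discarded
because path metrics are undefined for them, and an absolute-value ranking
mode exists). Ties at the cutoff break deterministically by lexicographic
node-pair order. Metrics are computed on the *weighted* thresholded graph;
the implementations are vectorised numpy:

* Onnela clustering C_i = ((Ŵ^{1/3})³)_ii / (k_i(k_i−1)) with Ŵ = W/max W;
  degree < 2 contributes 0. Scale-invariant by construction.
* Shortest paths on d = 1/w by vectorised Floyd–Warshall. L averages over
  *connected* ordered pairs (disconnected pairs excluded and counted —
  at S ≥ 0.10 these graphs are near-connected); E_glob averages 1/d with
  1/∞ = 0 and so degrades gracefully under disconnection.
* Local efficiency of node i = global efficiency of the weighted subgraph
  induced on i's neighbours; 0 for degree < 2.
* Modularity: exact set-partition enumeration for graphs of ≤ 8 nodes
  (where exhaustive search is cheap and heuristics cannot guarantee the
  optimum), Louvain with 20 seeded restarts above; Q is always recomputed
  from the returned partition with the Newman weighted formula, independent
  of the optimiser's internal score.
* Null model: Maslov–Sneppen double-edge swaps on the topology (10 attempts
  per edge), then the original weight multiset reassigned to surviving
  edges in random order — degree sequence and weight multiset are preserved
  exactly. Graphs admitting no swap fall back to a weight shuffle with a
  warning.
* Normalisation: γ = C/⟨C_rand⟩, λ = L/⟨L_rand⟩, σ = γ/λ over `n_rand=100`
  nulls per (graph, S); normalised efficiencies are computed analogously
  and reported alongside the raw values (both are kept in the AUC table);
  Q is reported raw. Nulls with zero clustering are excluded from the
  clustering null mean and counted; if *every* null is triangle-free the
  graph is too sparse for γ/σ and NaN is returned with a warning.

Per-(scan, S) null seeds are spawned deterministically from the analysis
seed, keyed on the sparsity *value* (not its grid index), so refining the
grid never changes values at shared points and parallel or partial reruns
are reproducible.

## Aggregation and inference

Metric curves are integrated over the sparsity grid by the trapezoid rule
(AUC), giving one threshold-free number per subject × session × metric.
Before paired comparisons each metric's AUCs are residualised on scan-level
DVARS (both sessions pooled; residual + grand mean preserves scale). The
paired pre/post test applies Shapiro–Wilk (α = 0.05) to the differences:
normal-looking differences get a paired t-test, otherwise a two-sided
one-sample sign-flip permutation test — exhaustive over all 2^n sign
patterns when 2^n ≤ 131 072 (always true at n = 17, so small cohorts get
exact p values), else 10 000 Monte-Carlo flips with the add-one correction.
Degenerate all-zero differences return p = 1 with a flag.

Change–change associations use partial correlation (residual-on-residual,
t-based p with df = n − k − 2), controlling the mean of pre and post DVARS.
Follow-up prediction is OLS of ΔYBOCS(follow-up − post) on the
pre-treatment metric AUC plus months to follow-up, medication months, CBT
sessions, and pre-treatment DVARS; it reports the overall F with
(5, n − 6) df, adjusted R², and per-coefficient estimates, fails on
collinear designs (condition number > 1e10) and drops zero-variance
covariates with a warning (small simulated cohorts can have, e.g., nobody
medicated).

Of the five global metrics, three are treated as statistically independent
(clustering, global efficiency, modularity — small-worldness is a function
of clustering and path length, and local efficiency tracks clustering),
giving the Bonferroni family α/3 = 0.017; secondary families use α/6 =
0.0083 and α/12 = 0.004, and node-level exploratory tests use
Benjamini–Hochberg FDR at q = 0.05/4 = 0.0125 within each metric.
Outcome classification: responder = ≥ 35 % YBOCS reduction and CGI ≤ 2;
remitter = post YBOCS ≤ 14; clinically significant worsening = ≥ 5-point
YBOCS increase from post-treatment to follow-up.

All inference results carry method, statistic, df, p, effect, n and seed,
sufficient to re-execute bit-identically.

## Problem sizes used by the test suite and acceptance script

Exhaustive-oracle tests run on ≤ 8-node graphs (set-partition and
simple-path enumeration are exact there). Small-world sanity checks use
60-node Watts–Strogatz (k = 6, rewiring 0.1) and Erdős–Rényi (p = 0.3)
graphs with 100 nulls. Statistical calibration runs 500 replicate null
cohorts at n = 17 with 16-node networks, a two-point sparsity grid and a
reduced null ensemble — type-I error is a property of the inference chain,
not of network size, so the calibration uses the smallest estimable
networks. The acceptance script demonstrates the full nine-point grid on a
60-node, 208-volume, 17-subject cohort with 20 nulls per graph.

Synthetic cohorts are analysed with `preprocess=False`: the generator's
signals are stationary and spectrally flat, so band-pass filtering removes
no artifact and only discards effective degrees of freedom (roughly
halving detection power in side-by-side runs). For real BOLD data —
whose nuisance power is concentrated outside the passband — the filter
defaults to on.

## What the generator does and does not emulate

It emulates: modular correlation structure at realistic within/between
levels, a treatment-linked rise in within-module coupling, motion-artifact
spikes detectable by DVARS, integer-valued clinical instruments with
plausible means/SDs and coupled pre/post trajectories, and a planted,
recoverable association between pre-treatment topology and follow-up
worsening.

It does **not** emulate: hemodynamic-response or neural-mass dynamics, the
1/f spectral shape of BOLD (signals are white; see the filtering note
above), scanner drift or physiological noise beyond Gaussian + spikes,
subject-stable trait topology across sessions (pre and post series are
independent draws given the spec, so paired tests face the full
measurement noise), spatially realistic node geometry, or any fitted
distribution of edge weights — the generator targets correlation *levels*,
not an empirical weight distribution. Passing tests therefore certify the
pipeline's correctness and calibration, not the physiological realism of
any particular effect size.

## Known limitations

* Characteristic path length over connected pairs only; severely
  fragmented graphs (far below S = 0.10 on small n) make L optimistic —
  the disconnected-pair count is logged.
* γ/σ are undefined on graphs whose null ensemble is entirely
  triangle-free (tiny, very sparse graphs); NaN with a warning.
* The repeated-measures ANOVA across three clinical time points is
  reproduced descriptively (means/SDs) only; the package's inferential
  claims rest on the paired tests and the follow-up regression.
* CLI stage caching compares config/spec digests and output presence; it
  does not hash every intermediate file's content.
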