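# netchange

Graph-theory analysis of resting-state functional connectomes for
two-session (pre/post treatment) studies, with prediction of follow-up
clinical outcome — plus a synthetic-cohort generator so the whole pipeline
is testable without access to patient data.

## The problem

Intensive treatment (for example cognitive-behavioral therapy for
obsessive–compulsive disorder) changes the topology of resting-state brain
networks, and the network topology a patient brings *into* treatment may
carry prognostic information about relapse. Quantifying this requires a
long chain of steps — time-series cleaning, connectivity estimation, graph
construction across sparsity thresholds, null-model normalisation,
threshold-free aggregation, and covariate-adjusted inference on a small
cohort — each of which must be reproducible and statistically calibrated.
`netchange` implements that chain as a tested, seeded library.

## The model

For each scan, node time series are cleaned (initial-volume discard,
zero-phase 0.009–0.08 Hz Butterworth band-pass, nuisance regression) and
screened with DVARS, the root-mean-square volume-to-volume signal change.
Connectivity is the matrix of pairwise **partial correlations**
ρ<sub>ij</sub> = −P<sub>ij</sub>/√(P<sub>ii</sub>P<sub>jj</sub>) from the
(shrinkage-regularised) precision matrix P, or plain Pearson correlation.
The matrix is thresholded at each sparsity S ∈ {0.10, 0.15, …, 0.50}
(retaining the strongest S·n(n−1)/2 positive edges with weights), and on
each weighted graph we compute:

* mean clustering coefficient **C** (Onnela geometric-mean triangle weights),
* characteristic path length **L** and global efficiency
  **E<sub>glob</sub>** on distances 1/w,
* mean local efficiency **E<sub>loc</sub>**,
* modularity **Q** (Louvain; exact enumeration on very small graphs),
* normalised values γ = C/⟨C<sub>rand</sub>⟩, λ = L/⟨L<sub>rand</sub>⟩ and
  small-worldness **σ = γ/λ**, against 100 degree-preserving
  (Maslov–Sneppen) null networks per graph.

Each metric curve is collapsed to its **area under the curve (AUC)** over
the sparsity grid, residualised on scan-level DVARS, and carried into
inference: paired pre/post tests (paired *t* or exact sign-flip permutation,
selected by a Shapiro–Wilk check), partial correlations of metric change
with symptom change controlling motion, and an OLS regression predicting
follow-up symptom change (YBOCS points, follow-up minus post; positive =
worsening) from the pre-treatment metric AUC plus four nuisance covariates,
with Bonferroni (0.05/3) and Benjamini–Hochberg control.

## Worked example

```python
import netchange as nc

spec = nc.CohortSpec(seed=1, n_subjects=17, n_nodes=60, n_timepoints=208,
                     n_modules=6, metric_grid=(0.1, 0.2, 0.3, 0.4, 0.5),
                     metric_n_rand=8)
cohort = nc.generate_cohort(spec)          # planted structure + outcomes
config = nc.AnalysisConfig(seed=1, preprocess=False, n_rand=20, n_restarts=5)
results = nc.ConnectomeStudy.from_cohort(cohort, config).fit()
print(results.summary())
```

prints (abridged):

```
Clinical outcome
------------------------------------------------------------
  YBOCS reduction pre->post: 47.1 +/- 14.8 %
  responders: 88.2 %   remitters: 70.6 %   worsened at follow-up: 17.6 %

Paired pre/post change in metric AUC (motion-adjusted; alpha = 0.0167)
------------------------------------------------------------
  metric              method               stat        p  mean diff
  sigma               paired_t            3.355   0.0040     0.0225
  clustering          paired_t            1.187   0.2526     0.0017
  ...

Follow-up YBOCS change predicted from pre-treatment metric AUC (+4 covariates)
------------------------------------------------------------
  metric                adj R2       F        df        p     beta
  sigma                  0.485    4.01    (5,11)   0.0257  160.999
  ...
```

The clinical block reports the simulated cohort's response/remission/
worsening rates (the generator's score distributions are calibrated to a
moderately ill OCD cohort: pre-treatment YBOCS ≈ 23 ± 3 with ≈ 40 ± 16 %
mean reduction). The paired block tests whether each metric's
motion-adjusted AUC changed from pre to post treatment: the planted
within-module coupling increase (+0.05) appears as a significant rise in
small-worldness AUC at n = 17. The follow-up block recovers the planted
association between pre-treatment small-worldness and later symptom
worsening (positive slope, adjusted R² ≈ 0.49 for this seed; the
acceptance script additionally reports the planted-slope estimate on the
standardised predictor scale, ≈ 3.8 for a planted value of 4 YBOCS points
per SD).

A command-line interface wraps the same pipeline:

```bash
netchange run --seed 1 --outdir runs/demo          # simulate + analyse
netchange simulate --seed 2 --outdir runs/cohort   # cohort only
```

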