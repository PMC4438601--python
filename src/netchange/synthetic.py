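"""Synthetic multi-subject cohorts with planted network and clinical structure.

The generator emulates a two-session (pre/post treatment) resting-state
study: per subject, node x time BOLD-like series with a planted modular
correlation structure, optional motion-artifact spikes, and a clinical table
(symptom scores, follow-up covariates) whose follow-up symptom change is
linearly linked to the subject's realised pre-treatment small-worldness AUC.

Time series use a factor model: node i in module m(i) is

    x_i(t) = baseline + noise_sd * (a * g(t) + b * f_m(t) + c * e_i(t))

with a global factor g, module factors f_m and idiosyncratic noise e_i, all
iid standard normal, and loadings solved analytically from the target
correlations: a^2 = between_r, b^2 = within_r - between_r,
c^2 = 1 - within_r.  This guarantees a positive-definite covariance for any
valid (between_r, within_r) and costs O(n) memory.

Clinical scores are drawn from configurable Gaussian distributions whose
defaults match the severity levels typical of a moderately ill OCD cohort
entering intensive therapy (pre YBOCS ~ 23 +/- 3, ~40% mean reduction),
rounded to integers and clamped to instrument ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import TimeSeriesMatrix, compute_dvars
from .connectivity import partial_correlation_matrix
from .graphmetrics import metric_curves
from .stats import auc_table

__all__ = [
    "ClinicalParams",
    "CohortSpec",
    "SyntheticCohort",
    "generate_modular_timeseries",
    "inject_motion_spikes",
    "generate_clinical_table",
    "generate_cohort",
]


@dataclass
class ClinicalParams:
    """(mean, sd) pairs for the simulated psychometric instruments.

    YBOCS post-treatment is derived from the pre score via a percent
    reduction draw, so that pre and post are positively coupled the way real
    within-subject scores are.
    """

    ybocs_pre: tuple = (23.12, 3.04)
    pct_reduction: tuple = (40.4, 16.4)
    hama_pre: tuple = (11.94, 4.78)
    hama_post: tuple = (8.06, 4.66)
    madrs_pre: tuple = (12.12, 5.51)
    madrs_post: tuple = (9.53, 9.71)
    gas_pre: tuple = (59.06, 6.65)
    gas_post: tuple = (74.06, 13.66)
    stroop_pre: tuple = (54.59, 7.37)
    stroop_post: tuple = (54.47, 7.88)
    months_followup: tuple = (7.0, 4.53)


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; cohorts are a pure function
    of the spec (identical spec + seed => bit-identical cohort).

    ``effect_beta`` is the planted slope (YBOCS points per SD) of follow-up
    symptom change on the standardised pre-treatment small-worldness AUC;
    ``post_within_r_delta`` shifts within-module correlation for the post
    session, raising clustering/small-worldness when positive.
    """

    seed: int
    n_subjects: int = 17
    n_nodes: int = 160
    n_timepoints: int = 208
    tr: float = 2.0
    n_modules: int = 6
    within_r: float = 0.4
    between_r: float = 0.1
    post_within_r_delta: float = 0.05
    motion_spike_rate: float = 0.02
    spike_amplitude: float = 4.0
    signal_sd: float = 7.0
    baseline: float = 100.0
    effect_beta: float = 4.0
    outcome_noise_sd: float = 3.0
    clinical_params: ClinicalParams = field(default_factory=ClinicalParams)
    # settings used to realise each subject's pre-treatment small-worldness
    # AUC (the planted predictor); kept light so generation stays fast
    metric_grid: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    metric_n_rand: int = 8
    metric_shrinkage: float | str = "auto"

    def __post_init__(self) -> None:
        if not 0 <= self.between_r < self.within_r < 1:
            raise ValueError("need 0 <= between_r < within_r < 1")
        if not 0 <= self.within_r + self.post_within_r_delta < 1:
            raise ValueError("post-session within_r out of [0, 1)")
        if self.n_timepoints < 50:
            raise ValueError("n_timepoints >= 50 enforced for estimability")
        if not 0 <= self.motion_spike_rate <= 1:
            raise ValueError("motion_spike_rate must lie in [0, 1]")
        if self.n_subjects < 1 or self.n_nodes < 2 or self.n_modules < 1:
            raise ValueError("counts must be positive")
        if self.n_modules > self.n_nodes:
            raise ValueError("more modules than nodes")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """Generated cohort: per-scan time series, module labels, clinical table.

    ``timeseries`` maps (subject_id, session) -> TimeSeriesMatrix with
    session in {"pre", "post"}.  ``realized_sigma_auc`` holds the planted
    predictor (pre-treatment small-worldness AUC per subject) actually used
    to construct follow-up outcomes.
    """

    spec: CohortSpec
    timeseries: Mapping
    membership: np.ndarray
    clinical: pd.DataFrame
    realized_sigma_auc: np.ndarray

    @property
    def subject_ids(self) -> list[str]:
        return list(self.clinical["subject"])


def _loadings(within_r: float, between_r: float) -> tuple[float, float, float]:
    a2 = between_r
    b2 = within_r - between_r
    c2 = 1.0 - within_r
    if min(a2, b2, c2) < 0:
        raise ValueError("correlation targets imply a non-positive-definite "
                         "structure (need 0 <= between_r <= within_r < 1)")
    return np.sqrt(a2), np.sqrt(b2), np.sqrt(c2)


def generate_modular_timeseries(n_nodes: int, n_timepoints: int, membership,
                                within_r: float, between_r: float,
                                noise_sd: float = 1.0,
                                seed: int | np.random.Generator | None = None,
                                baseline: float = 0.0,
                                tr: float = 2.0) -> TimeSeriesMatrix:
    """Node x time series with target within/between-module correlations.

    ``membership`` assigns each node to a module; expected pairwise
    correlation is ``within_r`` inside modules and ``between_r`` across.
    ``noise_sd`` scales the overall signal amplitude (correlations are
    scale-invariant); ``baseline`` adds a constant offset so DVARS percent
    scaling behaves like raw scanner data.
    """
    membership = np.asarray(membership)
    if membership.size != n_nodes:
        raise ValueError("membership must label every node")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    a, b, c = _loadings(within_r, between_r)
    labels, inverse = np.unique(membership, return_inverse=True)
    g = rng.standard_normal(n_timepoints)
    f = rng.standard_normal((labels.size, n_timepoints))
    eps = rng.standard_normal((n_nodes, n_timepoints))
    x = baseline + noise_sd * (a * g[None, :] + b * f[inverse] + c * eps)
    return TimeSeriesMatrix(
        x, tr=tr, node_ids=[f"node{i:03d}" for i in range(n_nodes)],
        meta={"within_r": within_r, "between_r": between_r,
              "membership": membership.tolist()})


def inject_motion_spikes(ts: TimeSeriesMatrix, spike_rate: float,
                         spike_amplitude: float,
                         seed: int | np.random.Generator | None = None,
                         ) -> TimeSeriesMatrix:
    """Add motion-like artifact spikes at random volumes.

    Each volume is spiked independently with probability ``spike_rate``; a
    spike adds ``spike_amplitude`` times the node's own SD, with a common
    random sign across nodes (motion displaces the whole head).  Spiked
    volume indices are recorded in ``meta['spike_volumes']``.
    """
    if spike_amplitude <= 0:
        raise ValueError("spike_amplitude must be positive")
    if not 0 <= spike_rate <= 1:
        raise ValueError("spike_rate must lie in [0, 1]")
    if spike_rate == 0:
        return ts.copy_with(ts.values, spike_volumes=[])
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    spiked = np.flatnonzero(rng.random(ts.n_time) < spike_rate)
    values = ts.values.copy()
    sd = values.std(axis=1, keepdims=True)
    signs = rng.choice((-1.0, 1.0), size=spiked.size)
    for s, vol in zip(signs, spiked):
        values[:, vol] += s * spike_amplitude * sd[:, 0]
    return ts.copy_with(values, spike_volumes=spiked.tolist())


def _draw_scores(rng, mean_sd, n, lo, hi):
    m, s = mean_sd
    raw = rng.normal(m, s, size=n)
    scores = np.clip(np.rint(raw), lo, hi)
    if np.any(raw < lo) or np.any(raw > hi):
        warnings.warn("clinical scores clamped to instrument range "
                      f"[{lo}, {hi}]")
    return scores.astype(int)


def generate_clinical_table(params: ClinicalParams, n_subjects: int,
                            sigma_z: np.ndarray, effect_beta: float,
                            outcome_noise_sd: float,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Clinical table with a planted follow-up outcome association.

    ``sigma_z`` is the standardised pre-treatment small-worldness AUC per
    subject; follow-up YBOCS change (follow-up minus post, positive =
    worsening) is ``effect_beta * sigma_z + noise``, before rounding and
    clamping to the instrument range.
    """
    sigma_z = np.asarray(sigma_z, float)
    if sigma_z.size != n_subjects:
        raise ValueError("sigma_z must have one value per subject")
    p = params
    ybocs_pre = _draw_scores(rng, p.ybocs_pre, n_subjects, 0, 40)
    if np.any(ybocs_pre == 0):
        ybocs_pre = np.maximum(ybocs_pre, 1)
    reduction = rng.normal(*p.pct_reduction, size=n_subjects)
    ybocs_post = np.clip(
        np.rint(ybocs_pre * (1 - reduction / 100.0)), 0, 40).astype(int)
    fu_change = effect_beta * sigma_z + \
        rng.normal(0, outcome_noise_sd, size=n_subjects)
    ybocs_fu = np.clip(np.rint(ybocs_post + fu_change), 0, 40).astype(int)
    # CGI tracks the realised percent reduction: 1 = very much improved
    realized_red = 100.0 * (ybocs_pre - ybocs_post) / ybocs_pre
    cgi = np.select(
        [realized_red >= 65, realized_red >= 35, realized_red >= 15],
        [1, 2, 3], default=4).astype(int)
    months_fu = np.clip(np.rint(rng.normal(*p.months_followup,
                                           size=n_subjects)), 1, 12)
    med_flag = rng.random(n_subjects) < 6 / 17
    cbt_flag = rng.random(n_subjects) < 10 / 17
    med_months = np.where(
        med_flag, rng.integers(1, 13, size=n_subjects), 0)
    med_months = np.minimum(med_months, months_fu).astype(int)
    cbt_sessions = np.where(
        cbt_flag, rng.integers(1, 21, size=n_subjects), 0).astype(int)
    table = pd.DataFrame({
        "subject": [f"sub{i:03d}" for i in range(n_subjects)],
        "ybocs_pre": ybocs_pre,
        "ybocs_post": ybocs_post,
        "ybocs_followup": ybocs_fu,
        "cgi_post": cgi,
        "hama_pre": _draw_scores(rng, p.hama_pre, n_subjects, 0, 56),
        "hama_post": _draw_scores(rng, p.hama_post, n_subjects, 0, 56),
        "madrs_pre": _draw_scores(rng, p.madrs_pre, n_subjects, 0, 60),
        "madrs_post": _draw_scores(rng, p.madrs_post, n_subjects, 0, 60),
        "gas_pre": _draw_scores(rng, p.gas_pre, n_subjects, 1, 100),
        "gas_post": _draw_scores(rng, p.gas_post, n_subjects, 1, 100),
        "stroop_pre": _draw_scores(rng, p.stroop_pre, n_subjects, 20, 80),
        "stroop_post": _draw_scores(rng, p.stroop_post, n_subjects, 20, 80),
        "months_followup": months_fu.astype(int),
        "medication_months": med_months,
        "cbt_sessions": cbt_sessions,
    })
    return table


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=0)
    if sd < 1e-15:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def realized_sigma_auc(ts: TimeSeriesMatrix, spec: CohortSpec,
                       seed: int) -> float:
    """Small-worldness AUC of one scan under the spec's metric settings."""
    conn = partial_correlation_matrix(ts, shrinkage=spec.metric_shrinkage)
    curves = metric_curves(conn, sparsity_grid=spec.metric_grid,
                           n_rand=spec.metric_n_rand, seed=seed,
                           n_restarts=5, normalize_efficiency=False,
                           subject_id=ts.subject_id, session=ts.session)
    tab = auc_table(curves)
    return float(tab.loc[tab["metric"] == "sigma", "auc"].iloc[0])


def paint_spheres_nifti(ts: TimeSeriesMatrix, centers, shape=(24, 24, 24),
                        voxel_mm: float = 3.0, radius_mm: float = 5.0):
    """Render a node time series as a 4-D NIfTI of painted spheres.

    Each node's series is written into every voxel whose centre lies within
    ``radius_mm`` of the node centre (world mm via a diagonal affine, RAS).
    Useful for exercising ROI extraction end to end.
    """
    import nibabel as nib

    centers = np.atleast_2d(np.asarray(centers, float))
    if centers.shape[0] != ts.n_nodes:
        raise ValueError("need one centre per node")
    data = np.zeros(tuple(shape) + (ts.n_time,), dtype=np.float32)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                indexing="ij"), axis=-1) * voxel_mm
    for idx, c in enumerate(centers):
        mask = np.linalg.norm(grid - c, axis=-1) <= radius_mm
        if not mask.any():
            raise ValueError(f"node {ts.node_ids[idx]} paints no voxels")
        data[mask] = ts.values[idx].astype(np.float32)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((voxel_mm,) * 3 + (ts.tr,))
    return img


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full two-session cohort from a spec.

    The post session uses ``within_r + post_within_r_delta`` so clustering
    and small-worldness rise when the delta is positive.  Follow-up symptom
    change is planted on each subject's *realised* pre-treatment
    small-worldness AUC (computed from the generated data with the spec's
    metric settings), so downstream recovery of ``effect_beta`` is a true
    end-to-end test.
    """
    root = np.random.SeedSequence(spec.seed)
    membership = np.arange(spec.n_nodes) % spec.n_modules
    membership.sort()
    timeseries: dict = {}
    sigma_aucs = np.empty(spec.n_subjects)
    for i in range(spec.n_subjects):
        subj = f"sub{i:03d}"
        for session, within in (("pre", spec.within_r),
                                ("post", spec.within_r
                                 + spec.post_within_r_delta)):
            ss = np.random.SeedSequence(
                (spec.seed, i, 0 if session == "pre" else 1))
            rng = np.random.default_rng(ss)
            ts = generate_modular_timeseries(
                spec.n_nodes, spec.n_timepoints, membership,
                within, spec.between_r, noise_sd=spec.signal_sd,
                seed=rng, baseline=spec.baseline, tr=spec.tr)
            ts = inject_motion_spikes(
                ts, spec.motion_spike_rate, spec.spike_amplitude, seed=rng) \
                if spec.motion_spike_rate > 0 else ts
            ts.subject_id = subj
            ts.session = session
            timeseries[(subj, session)] = ts
        metric_seed = int(np.random.SeedSequence(
            (spec.seed, i, 2)).generate_state(1)[0] % (2 ** 31))
        sigma_aucs[i] = realized_sigma_auc(timeseries[(subj, "pre")], spec,
                                           seed=metric_seed)
    if not np.all(np.isfinite(sigma_aucs)):
        raise ValueError(
            "realised small-worldness AUC is non-finite for some subjects; "
            "the metric settings are too sparse for this network size "
            "(raise metric_n_rand, the grid's lower end, or n_nodes)")
    clin_rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, 999_983)))
    clinical = generate_clinical_table(
        spec.clinical_params, spec.n_subjects, _standardize(sigma_aucs),
        spec.effect_beta, spec.outcome_noise_sd, clin_rng)
    # scan-level motion summaries from the generated data themselves
    for session in ("pre", "post"):
        clinical[f"dvars_{session}"] = [
            compute_dvars(timeseries[(s, session)]).dvars_mean
            for s in clinical["subject"]]
    return SyntheticCohort(spec=spec, timeseries=timeseries,
                           membership=membership, clinical=clinical,
                           realized_sigma_auc=sigma_aucs)
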