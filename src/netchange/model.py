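"""Study-level model object tying the pipeline stages together.

:class:`ConnectomeStudy` is constructed from per-scan node time series and a
clinical table (real data via :mod:`netchange.io`, or a synthetic cohort via
:meth:`ConnectomeStudy.from_cohort`).  ``fit()`` runs

    temporal cleaning -> connectivity -> thresholded graph metrics over the
    sparsity grid -> AUC -> motion residualisation -> inference

and returns a :class:`ConnectomeStudyResults` carrying the AUC table, the
paired pre/post tests, change-score partial correlations, the follow-up
prediction regressions, outcome classification, and a ``summary()`` report.
All randomness is derived deterministically from ``config.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _version
from .preprocess import TimeSeriesMatrix, clean_timeseries
from .connectivity import pearson_matrix, partial_correlation_matrix
from .graphmetrics import (DEFAULT_SPARSITY_GRID, metric_curves,
                           threshold_proportional, node_level_metrics)
from .stats import (auc_table, residualize_on_motion, paired_change_test,
                    partial_corr, fit_followup_regression, bonferroni_alpha,
                    classify_outcomes, describe_timepoints,
                    node_level_change_analysis)
from .io import array_hash

__all__ = ["AnalysisConfig", "ConnectomeStudy", "ConnectomeStudyResults",
           "PRIMARY_METRICS"]

#: global metrics carried into inference; sigma is null-normalised by
#: construction, the others are analysed raw (normalised variants are kept
#: in the AUC table as *_norm / gamma / lambda rows)
PRIMARY_METRICS = ("sigma", "clustering", "global_efficiency",
                   "local_efficiency", "modularity")

#: the three statistically independent metrics (small-worldness is a
#: function of clustering and path length; local efficiency tracks
#: clustering), giving the 0.05/3 family correction
INDEPENDENT_METRICS = ("clustering", "global_efficiency", "modularity")


@dataclass
class AnalysisConfig:
    """All tunable pipeline settings, fully serialisable.

    Defaults reproduce the reference analysis conditions: band-pass
    0.009-0.08 Hz, partial correlations with analytic shrinkage, sparsity
    grid 0.10-0.50 in steps of 0.05, 100 degree-preserving nulls per graph,
    and a 0.05/3 Bonferroni family for the three independent metrics.
    """

    seed: int = 0
    # preprocessing
    preprocess: bool = True
    n_discard: int = 2
    low_hz: float = 0.009
    high_hz: float = 0.08
    dvars_threshold: float = 25.0
    dvars_on: str = "raw"  # percent scaling needs the signal baseline
    # connectivity
    method: str = "partial"  # or "pearson"
    shrinkage: float | str = "auto"
    # graph metrics
    sparsity_grid: tuple = DEFAULT_SPARSITY_GRID
    n_rand: int = 100
    n_swaps_per_edge: int = 10
    n_restarts: int = 20
    normalize_efficiency: bool = True
    # statistics
    n_perm: int = 10_000
    family_alpha: float = 0.05
    n_independent_metrics: int = 3
    node_level: bool = False
    node_level_q: float = 0.0125

    def __post_init__(self) -> None:
        grid = tuple(float(s) for s in self.sparsity_grid)
        if not grid or sorted(grid) != list(grid) \
                or not all(0 < s < 1 for s in grid):
            raise ValueError("sparsity_grid must be sorted and within (0, 1)")
        self.sparsity_grid = grid
        if self.method not in ("partial", "pearson"):
            raise ValueError("method must be 'partial' or 'pearson'")
        if self.n_rand < 1 or self.n_restarts < 1:
            raise ValueError("n_rand and n_restarts must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


def _scan_seed(base: int, subject: str, session: str) -> int:
    import hashlib

    digest = hashlib.sha256(f"{subject}|{session}".encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    ss = np.random.SeedSequence((int(base), key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


class ConnectomeStudy:
    """Two-session connectome study: data + config; ``fit()`` -> results.

    Parameters
    ----------
    timeseries : mapping (subject_id, session) -> TimeSeriesMatrix
        session in {"pre", "post"}; every subject in the clinical table must
        have both sessions.
    clinical : DataFrame
        One row per subject (see :data:`netchange.io.CLINICAL_COLUMNS`).
    config : AnalysisConfig
    """

    def __init__(self, timeseries: Mapping, clinical: pd.DataFrame,
                 config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        self.clinical = clinical.reset_index(drop=True)
        self.timeseries = dict(timeseries)
        if "subject" not in self.clinical:
            raise ValueError("clinical table needs a 'subject' column")
        for subj in self.clinical["subject"]:
            for session in ("pre", "post"):
                if (subj, session) not in self.timeseries:
                    raise ValueError(f"missing scan ({subj}, {session})")

    @classmethod
    def from_cohort(cls, cohort, config: AnalysisConfig | None = None,
                    ) -> "ConnectomeStudy":
        """Build a study from a :class:`netchange.synthetic.SyntheticCohort`.

        Synthetic series are generated stationary and baseline-shifted, so
        by default the initial-volume discard is skipped (magnetisation
        equilibration is a scanner artifact the generator does not emulate).
        """
        if config is None:
            config = AnalysisConfig(seed=cohort.spec.seed, n_discard=0)
        return cls(cohort.timeseries, cohort.clinical, config)

    @classmethod
    def from_files(cls, timeseries_dir, clinical_csv, tr: float,
                   config: AnalysisConfig | None = None) -> "ConnectomeStudy":
        """Load scans named ``<subject>_<session>.tsv`` plus a clinical CSV."""
        from .io import read_clinical, read_timeseries

        clinical = read_clinical(clinical_csv)
        tsdir = Path(timeseries_dir)
        series = {}
        for subj in clinical["subject"]:
            for session in ("pre", "post"):
                path = tsdir / f"{subj}_{session}.tsv"
                if not path.exists():
                    raise FileNotFoundError(str(path))
                series[(subj, session)] = read_timeseries(
                    path, tr=tr, subject_id=subj, session=session)
        return cls(series, clinical, config)

    # ------------------------------------------------------------------
    def fit(self) -> "ConnectomeStudyResults":
        cfg = self.config
        curves_frames = []
        dvars = {}
        node_metrics: dict = {"pre": {}, "post": {}}
        for subj in self.clinical["subject"]:
            for session in ("pre", "post"):
                ts = self.timeseries[(subj, session)]
                if cfg.preprocess:
                    cleaned, qc = clean_timeseries(
                        ts, n_discard=cfg.n_discard, low_hz=cfg.low_hz,
                        high_hz=cfg.high_hz,
                        dvars_threshold=cfg.dvars_threshold,
                        dvars_on=cfg.dvars_on)
                else:
                    from .preprocess import compute_dvars
                    cleaned, qc = ts, compute_dvars(
                        ts, threshold=cfg.dvars_threshold)
                dvars[(subj, session)] = qc.dvars_mean
                if cfg.method == "partial":
                    conn = partial_correlation_matrix(
                        cleaned, shrinkage=cfg.shrinkage)
                else:
                    conn = pearson_matrix(cleaned)
                scan_seed = _scan_seed(cfg.seed, subj, session)
                curves_frames.append(metric_curves(
                    conn, sparsity_grid=cfg.sparsity_grid, n_rand=cfg.n_rand,
                    seed=scan_seed, n_swaps_per_edge=cfg.n_swaps_per_edge,
                    n_restarts=cfg.n_restarts,
                    normalize_efficiency=cfg.normalize_efficiency,
                    subject_id=subj, session=session))
                if cfg.node_level:
                    mid_s = cfg.sparsity_grid[len(cfg.sparsity_grid) // 2]
                    nm = node_level_metrics(
                        threshold_proportional(conn, mid_s))
                    for key in ("degree", "clustering", "local_efficiency",
                                "betweenness"):
                        node_metrics[session].setdefault(key, []).append(
                            getattr(nm, key))
        curves = pd.concat(curves_frames, ignore_index=True)
        table = auc_table(curves)
        primary = table[table["metric"].isin(PRIMARY_METRICS)]
        adjusted = residualize_on_motion(primary, dvars)

        alpha3 = bonferroni_alpha(cfg.family_alpha,
                                  cfg.n_independent_metrics)
        paired, change_corr, followup = {}, {}, {}
        wide = adjusted.pivot_table(index="subject", columns=["metric",
                                                              "session"],
                                    values="auc")
        wide = wide.loc[self.clinical["subject"]]
        dv_pre = np.array([dvars[(s, "pre")]
                           for s in self.clinical["subject"]])
        dv_post = np.array([dvars[(s, "post")]
                            for s in self.clinical["subject"]])
        dv_mean = (dv_pre + dv_post) / 2.0
        d_ybocs = (self.clinical["ybocs_post"]
                   - self.clinical["ybocs_pre"]).to_numpy(float)
        clinical = self.clinical.copy()
        # prefer pipeline-computed motion over any tabulated values
        clinical["dvars_pre"] = dv_pre
        clinical["dvars_post"] = dv_post
        for metric in PRIMARY_METRICS:
            pre_v = wide[(metric, "pre")].to_numpy(float)
            post_v = wide[(metric, "post")].to_numpy(float)
            res = paired_change_test(pre_v, post_v, n_perm=cfg.n_perm,
                                     seed=cfg.seed)
            res.alpha_corrected = alpha3
            paired[metric] = res
            cc = partial_corr(post_v - pre_v, d_ybocs, dv_mean)
            cc.alpha_corrected = alpha3
            change_corr[metric] = cc
            fu = fit_followup_regression(clinical, pre_v,
                                         predictor_name=f"{metric}_auc_pre")
            fu.alpha_corrected = alpha3
            followup[metric] = fu
        outcome_flags, outcome_rates = classify_outcomes(self.clinical)
        node_table = None
        if cfg.node_level:
            pre_m = {k: np.array(v) for k, v in node_metrics["pre"].items()}
            post_m = {k: np.array(v) for k, v in node_metrics["post"].items()}
            node_table = node_level_change_analysis(
                pre_m, post_m, q=cfg.node_level_q, n_perm=cfg.n_perm,
                seed=cfg.seed)
        return ConnectomeStudyResults(
            config=cfg, curves=curves, auc=table, auc_adjusted=adjusted,
            dvars=dvars, paired_tests=paired, change_correlations=change_corr,
            followup_regressions=followup, outcome_flags=outcome_flags,
            outcome_rates=outcome_rates, node_level=node_table,
            clinical=clinical)


@dataclass
class ConnectomeStudyResults:
    """Fitted study: estimates, uncertainties, diagnostics and exports."""

    config: AnalysisConfig
    curves: pd.DataFrame
    auc: pd.DataFrame
    auc_adjusted: pd.DataFrame
    dvars: dict
    paired_tests: dict
    change_correlations: dict
    followup_regressions: dict
    outcome_flags: pd.DataFrame
    outcome_rates: dict
    clinical: pd.DataFrame
    node_level: pd.DataFrame | None = None

    def summary(self) -> str:
        """Human-readable report of every fitted quantity."""
        cfg = self.config
        lines = []
        lines.append("Connectome treatment-change analysis")
        lines.append("=" * 60)
        lines.append(f"subjects: {len(self.clinical)}   "
                     f"connectivity: {cfg.method}   "
                     f"grid: {cfg.sparsity_grid[0]:.2f}-"
                     f"{cfg.sparsity_grid[-1]:.2f} "
                     f"({len(cfg.sparsity_grid)} pts)   "
                     f"nulls/graph: {cfg.n_rand}")
        lines.append("")
        lines.append("Clinical outcome")
        lines.append("-" * 60)
        r = self.outcome_rates
        lines.append(
            f"  YBOCS reduction pre->post: {r['mean_pct_reduction']:.1f} "
            f"+/- {r['sd_pct_reduction']:.1f} %")
        lines.append(f"  responders: {r['response_rate_pct']:.1f} %   "
                     f"remitters: {r['remission_rate_pct']:.1f} %   "
                     + (f"worsened at follow-up: "
                        f"{r['worsening_rate_pct']:.1f} %"
                        if "worsening_rate_pct" in r else ""))
        lines.append("")
        a = next(iter(self.paired_tests.values())).alpha_corrected
        lines.append(f"Paired pre/post change in metric AUC "
                     f"(motion-adjusted; alpha = {a:.4f})")
        lines.append("-" * 60)
        lines.append(f"  {'metric':<20}{'method':<16}{'stat':>9}"
                     f"{'p':>9}{'mean diff':>11}")
        for m, res in self.paired_tests.items():
            lines.append(f"  {m:<20}{res.method:<16}{res.statistic:>9.3f}"
                         f"{res.p:>9.4f}{res.effect:>11.4f}")
        lines.append("")
        lines.append("Partial correlation of metric change with YBOCS change "
                     "(controlling mean DVARS)")
        lines.append("-" * 60)
        lines.append(f"  {'metric':<20}{'r':>8}{'p':>9}{'df':>5}")
        for m, res in self.change_correlations.items():
            lines.append(f"  {m:<20}{res.effect:>8.3f}{res.p:>9.4f}"
                         f"{res.df:>5d}")
        lines.append("")
        lines.append("Follow-up YBOCS change predicted from pre-treatment "
                     "metric AUC (+4 covariates)")
        lines.append("-" * 60)
        lines.append(f"  {'metric':<20}{'adj R2':>8}{'F':>8}{'df':>10}"
                     f"{'p':>9}{'beta':>9}")
        for m, res in self.followup_regressions.items():
            df = f"({res.df[0]},{res.df[1]})"
            lines.append(f"  {m:<20}{res.effect:>8.3f}{res.statistic:>8.2f}"
                         f"{df:>10}{res.p:>9.4f}"
                         f"{res.extra['predictor_coef']:>9.3f}")
        if self.node_level is not None:
            lines.append("")
            nrej = int(self.node_level["rejected"].sum())
            lines.append(f"Node-level changes: {nrej} rejections at "
                         f"q = {self.config.node_level_q}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_metric_curves(self, metrics=PRIMARY_METRICS, ax=None):
        """Mean +/- SD of each metric across sparsity, pre vs post."""
        import matplotlib.pyplot as plt

        metrics = list(metrics)
        if ax is None:
            fig, axes = plt.subplots(1, len(metrics),
                                     figsize=(3.2 * len(metrics), 3))
        else:
            axes = np.atleast_1d(ax)
            fig = axes[0].figure
        for axis, metric in zip(np.ravel(axes), metrics):
            sub = self.curves[self.curves["metric"] == metric]
            for session, color in (("pre", "k"), ("post", "r")):
                g = sub[sub["session"] == session].groupby("sparsity")["value"]
                mean, sd = g.mean(), g.std()
                axis.errorbar(mean.index, mean, yerr=sd, color=color,
                              label=session, capsize=2)
            axis.set_title(metric)
            axis.set_xlabel("sparsity")
        np.ravel(axes)[0].legend()
        fig.tight_layout()
        return fig

    def save(self, outdir) -> Path:
        """Write all result tables plus a reproducibility manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.curves.to_csv(outdir / "metric_curves.csv", index=False,
                           float_format="%.10g")
        self.auc.to_csv(outdir / "auc.csv", index=False, float_format="%.10g")
        self.auc_adjusted.to_csv(outdir / "auc_motion_adjusted.csv",
                                 index=False, float_format="%.10g")
        self.outcome_flags.to_csv(outdir / "outcomes.csv", index=False)
        describe_timepoints(self.clinical).to_csv(
            outdir / "clinical_descriptives.csv", index=False,
            float_format="%.10g")
        dv = pd.DataFrame([(s, sess, v) for (s, sess), v in
                           sorted(self.dvars.items())],
                          columns=["subject", "session", "dvars"])
        dv.to_csv(outdir / "dvars.csv", index=False, float_format="%.10g")
        stats_payload = {
            "paired_tests": {m: r.as_dict()
                             for m, r in self.paired_tests.items()},
            "change_correlations": {m: r.as_dict() for m, r in
                                    self.change_correlations.items()},
            "followup_regressions": {m: r.as_dict() for m, r in
                                     self.followup_regressions.items()},
            "outcome_rates": self.outcome_rates,
        }
        (outdir / "statistics.json").write_text(
            json.dumps(stats_payload, indent=2, default=_jsonable) + "\n")
        if self.node_level is not None:
            self.node_level.to_csv(outdir / "node_level.csv", index=False,
                                   float_format="%.10g")
        manifest = {
            "package_version": _version,
            "config": self.config.as_dict(),
            "n_subjects": int(len(self.clinical)),
            "auc_hash": array_hash(
                self.auc["auc"].to_numpy()),
            "curves_hash": array_hash(self.curves["value"].to_numpy()),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_jsonable) + "\n")
        (outdir / "report.md").write_text(
            "```\n" + self.summary() + "\n```\n")
        return outdir


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
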