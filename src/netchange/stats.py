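"""AUC aggregation, motion adjustment, inference, and clinical classification.

Metric curves are collapsed to one number per subject x session x metric by
trapezoidal integration over the sparsity grid (AUC).  Before paired
pre/post comparisons, AUCs are residualised on scan-level motion (DVARS).
Paired change is tested with a paired t-test when the differences pass a
Shapiro-Wilk normality check, otherwise with a one-sample sign-flip
permutation test (exhaustive for small n).  Prediction of follow-up symptom
change uses ordinary least squares with four nuisance covariates.  Multiple
testing is handled with Bonferroni-corrected alphas and Benjamini-Hochberg
FDR; clinical status is classified into responder / remitter / worsened
flags from standard score-based definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "auc",
    "auc_table",
    "residualize_on_motion",
    "paired_change_test",
    "partial_corr",
    "fit_followup_regression",
    "bonferroni_alpha",
    "fdr_bh",
    "classify_outcomes",
    "node_level_change_analysis",
]

# YBOCS-based outcome definitions
RESPONSE_MIN_PCT_REDUCTION = 35.0
RESPONSE_MAX_CGI = 2
REMISSION_MAX_YBOCS = 14
WORSENING_MIN_POINTS = 5


@dataclass
class StatResult:
    """A generic inference result with full provenance."""

    method: str
    statistic: float
    p: float
    n: int
    df: float | tuple | None = None
    effect: float | None = None
    effect_name: str = ""
    seed: int | None = None
    alpha_corrected: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0 <= self.p <= 1):
            raise ValueError("p must lie in [0, 1]")

    def as_dict(self) -> dict:
        d = {"method": self.method, "statistic": self.statistic,
             "df": self.df, "p": self.p, "effect": self.effect,
             "effect_name": self.effect_name, "n": self.n,
             "seed": self.seed, "alpha_corrected": self.alpha_corrected}
        d.update(self.extra)
        return d


def auc(curve, grid) -> float:
    """Trapezoidal integral of a metric curve over the sparsity grid."""
    curve = np.asarray(curve, float)
    grid = np.asarray(grid, float)
    if curve.shape != grid.shape:
        raise ValueError("curve and grid must have matching shape")
    if grid.size < 2:
        raise ValueError("need at least 2 grid points to integrate")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return float(np.trapezoid(curve, grid))


def auc_table(curves: pd.DataFrame) -> pd.DataFrame:
    """Collapse tidy metric curves to one AUC per subject x session x metric.

    Expects columns (subject, session, sparsity, metric, value) as produced
    by :func:`netchange.graphmetrics.metric_curves`.
    """
    wide = curves.pivot_table(index=["subject", "session", "metric"],
                              columns="sparsity", values="value", sort=True)
    grid = np.asarray(wide.columns, float)
    if grid.size < 2:
        raise ValueError("need at least 2 sparsity points to integrate")
    vals = np.trapezoid(wide.to_numpy(), grid, axis=1)
    out = wide.index.to_frame(index=False)
    out["auc"] = vals
    return out


def residualize_on_motion(table: pd.DataFrame,
                          dvars: pd.DataFrame | dict) -> pd.DataFrame:
    """Replace each metric's AUCs by motion-adjusted values.

    Per metric, AUC is regressed on scan-level DVARS across all scans (both
    sessions pooled) and replaced by residual + grand mean, removing the
    linear motion confound while preserving the metric's scale.

    Parameters
    ----------
    table : frame with columns (subject, session, metric, auc)
    dvars : frame with columns (subject, session, dvars) or mapping
        (subject, session) -> dvars value; one value per scan.
    """
    if isinstance(dvars, dict):
        dv = pd.DataFrame(
            [(s, sess, v) for (s, sess), v in dvars.items()],
            columns=["subject", "session", "dvars"])
    else:
        dv = dvars[["subject", "session", "dvars"]]
    merged = table.merge(dv, on=["subject", "session"], how="left",
                         validate="many_to_one")
    if merged["dvars"].isna().any():
        missing = merged.loc[merged["dvars"].isna(),
                             ["subject", "session"]].drop_duplicates()
        raise ValueError(f"missing DVARS for scans:\n{missing}")
    out = []
    for metric, grp in merged.groupby("metric", sort=False):
        y = grp["auc"].to_numpy(float)
        x = grp["dvars"].to_numpy(float)
        if np.std(x) < 1e-15:
            warnings.warn("DVARS has zero variance; motion residualisation "
                          "is an identity transform")
            adj = y.copy()
        else:
            X = np.column_stack([np.ones_like(x), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            adj = y - X @ beta + y.mean()
        g = grp.copy()
        g["auc"] = adj
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    return res[["subject", "session", "metric", "auc"]]


def _exhaustive_signflip_p(d: np.ndarray) -> float:
    """Two-sided exact p of the mean under all 2^n sign assignments."""
    n = d.size
    if n > 24:
        raise ValueError("exhaustive enumeration limited to n <= 24")
    obs = abs(d.sum())
    idx = np.arange(2 ** n, dtype=np.uint32)
    bits = ((idx[:, None] >> np.arange(n, dtype=np.uint32)) & 1)
    signs = 1.0 - 2.0 * bits
    stats_all = np.abs(signs @ d)
    return float(np.mean(stats_all >= obs - 1e-12))


def paired_change_test(pre, post, normality_alpha: float = 0.05,
                       n_perm: int = 10_000, seed: int | None = None,
                       max_exact: int = 131_072) -> StatResult:
    """Paired pre/post comparison with automatic branch selection.

    Differences ``post - pre`` are tested with Shapiro-Wilk; if consistent
    with normality (p >= ``normality_alpha``) a paired t-test is used,
    otherwise a two-sided one-sample sign-flip permutation test on the
    differences.  The permutation branch enumerates all ``2**n`` sign
    patterns exactly when that count is at most ``max_exact`` (true up to
    n = 17); otherwise it draws ``n_perm`` random sign flips and applies the
    add-one correction ``(b + 1) / (n_perm + 1)``.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D vectors")
    n = pre.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = post - pre
    if np.allclose(d, d[0]):
        if np.allclose(d, 0):
            return StatResult(method="degenerate", statistic=0.0, p=1.0,
                              n=n, df=n - 1, effect=0.0,
                              effect_name="mean_difference",
                              extra={"degenerate": True})
        # constant nonzero shift: no variance, t undefined; fall through to
        # permutation which handles it (all sign patterns distinct)
    sw_p = float(sps.shapiro(d).pvalue) if np.std(d) > 0 else 0.0
    if np.std(d) > 0 and sw_p >= normality_alpha:
        t, p = sps.ttest_rel(post, pre)
        return StatResult(method="paired_t", statistic=float(t), p=float(p),
                          n=n, df=n - 1, effect=float(d.mean()),
                          effect_name="mean_difference",
                          extra={"shapiro_p": sw_p})
    if 2 ** n <= max_exact:
        p = _exhaustive_signflip_p(d)
        method = "signflip_exact"
        used_seed = None
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
        stats_all = np.abs(signs @ d)
        b = int(np.sum(stats_all >= abs(d.sum()) - 1e-12))
        p = (b + 1) / (n_perm + 1)
        method = "signflip_mc"
        used_seed = seed
    return StatResult(method=method, statistic=float(d.mean()), p=float(p),
                      n=n, df=None, effect=float(d.mean()),
                      effect_name="mean_difference", seed=used_seed,
                      extra={"shapiro_p": sw_p, "n_perm": n_perm})


def partial_corr(x, y, covariates=None) -> StatResult:
    """Partial Pearson correlation of x and y given covariates.

    Computed as the correlation of the OLS residuals of x and y on the
    covariates (with intercept); the p value is t-based with
    df = n - n_covariates - 2.  With no covariates this is the plain Pearson
    correlation.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or (hasattr(covariates, "size")
                              and np.size(covariates) == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate length must equal n")
        Z = np.column_stack([np.ones(n), cov])
        k = cov.shape[1]
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("rank-deficient covariates")
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip ** 2))
    p = float(2 * sps.t.sf(abs(t), df))
    return StatResult(method="partial_correlation", statistic=float(t), p=p,
                      n=n, df=df, effect=r, effect_name="partial_r",
                      extra={"n_covariates": k})


def fit_followup_regression(clinical: pd.DataFrame, predictor: np.ndarray,
                            predictor_name: str = "metric_auc",
                            covariate_cols=("months_followup",
                                            "medication_months",
                                            "cbt_sessions", "dvars_pre"),
                            outcome: str | np.ndarray = "ybocs_change_followup",
                            ) -> StatResult:
    """OLS prediction of follow-up symptom change from a pre-treatment metric.

    The outcome is the change in YBOCS from post-treatment to follow-up
    (positive = worsening).  The design is the pre-treatment metric AUC plus
    four nuisance covariates: months to follow-up, months of medication and
    number of CBT sessions in the follow-up period, and pre-treatment scan
    DVARS.  Reports the overall F with (p, n - p - 1) df, its p value,
    adjusted R^2, and per-coefficient estimates.
    """
    predictor = np.asarray(predictor, float).ravel()
    n = len(clinical)
    if predictor.size != n:
        raise ValueError("predictor length must match clinical rows")
    if isinstance(outcome, str):
        if outcome == "ybocs_change_followup" and outcome not in clinical:
            y = (clinical["ybocs_followup"] - clinical["ybocs_post"]
                 ).to_numpy(float)
        else:
            y = clinical[outcome].to_numpy(float)
    else:
        y = np.asarray(outcome, float).ravel()
    X = pd.DataFrame({predictor_name: predictor})
    for c in covariate_cols:
        v = clinical[c].to_numpy(float)
        if np.std(v) < 1e-15:
            warnings.warn(f"covariate '{c}' has zero variance; dropped")
            continue
        X[c] = v
    k = X.shape[1]
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} complete cases for {k} predictors")
    Xc = sm.add_constant(X)
    cond = np.linalg.cond(Xc.to_numpy())
    if cond > 1e10:
        raise ValueError(f"collinear design (condition number {cond:.3g})")
    fit = sm.OLS(y, Xc).fit()
    return StatResult(
        method="ols", statistic=float(fit.fvalue), p=float(fit.f_pvalue),
        n=n, df=(int(fit.df_model), int(fit.df_resid)),
        effect=float(fit.rsquared_adj), effect_name="adjusted_r2",
        extra={
            "params": fit.params.to_dict(),
            "bse": fit.bse.to_dict(),
            "pvalues": fit.pvalues.to_dict(),
            "predictor_coef": float(fit.params[predictor_name]),
            "predictor_se": float(fit.bse[predictor_name]),
            "predictor_p": float(fit.pvalues[predictor_name]),
            "r2": float(fit.rsquared),
            "condition_number": float(cond),
        })


def bonferroni_alpha(family_alpha: float, m: int, decimals: int | None = None) -> float:
    """Bonferroni-corrected per-test alpha, optionally rounded for reporting."""
    if m < 1:
        raise ValueError("m must be >= 1")
    a = family_alpha / m
    return round(a, decimals) if decimals is not None else a


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (rejected indices into the input, BH-adjusted p values).
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.array([], dtype=int), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return np.flatnonzero(reject), p_adj


def classify_outcomes(clinical: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-subject clinical outcome flags and cohort rates.

    * responder: >= 35% YBOCS reduction pre -> post AND post CGI <= 2
    * remitter:  post YBOCS <= 14
    * worsened:  YBOCS increase of >= 5 points from post to follow-up
    """
    req = ["ybocs_pre", "ybocs_post"]
    for c in req:
        if c not in clinical:
            raise ValueError(f"missing required column '{c}'")
    pre = clinical["ybocs_pre"].to_numpy(float)
    post = clinical["ybocs_post"].to_numpy(float)
    if np.any(pre == 0):
        raise ValueError("ybocs_pre contains 0; percent change undefined")
    pct = 100.0 * (pre - post) / pre
    flags = pd.DataFrame({"subject": clinical["subject"]
                          if "subject" in clinical else np.arange(len(pre))})
    flags["pct_reduction"] = pct
    cgi = clinical["cgi_post"].to_numpy(float) if "cgi_post" in clinical \
        else np.full(len(pre), np.nan)
    flags["responder"] = (pct >= RESPONSE_MIN_PCT_REDUCTION) & \
        (cgi <= RESPONSE_MAX_CGI)
    flags["remitter"] = post <= REMISSION_MAX_YBOCS
    if "ybocs_followup" in clinical:
        fu = clinical["ybocs_followup"].to_numpy(float)
        flags["worsened"] = (fu - post) >= WORSENING_MIN_POINTS
    rates = {
        "mean_pct_reduction": float(pct.mean()),
        "sd_pct_reduction": float(pct.std(ddof=1)) if pct.size > 1 else 0.0,
        "response_rate_pct": float(100 * flags["responder"].mean()),
        "remission_rate_pct": float(100 * flags["remitter"].mean()),
    }
    if "worsened" in flags:
        rates["worsening_rate_pct"] = float(100 * flags["worsened"].mean())
    return flags, rates


def describe_timepoints(clinical: pd.DataFrame,
                        instruments=("ybocs", "hama", "madrs", "gas",
                                     "stroop")) -> pd.DataFrame:
    """Descriptive mean +/- SD of each instrument at each available
    time point (pre / post / follow-up).

    Purely descriptive: the package's inferential claims rest on the paired
    tests and the follow-up regression, not on an omnibus ANOVA across
    time points.
    """
    rows = []
    for inst in instruments:
        for tp in ("pre", "post", "followup"):
            col = f"{inst}_{tp}"
            if col in clinical:
                v = clinical[col].to_numpy(float)
                rows.append((inst, tp, float(v.mean()),
                             float(v.std(ddof=1)) if v.size > 1 else 0.0,
                             int(v.size)))
    return pd.DataFrame(rows, columns=["instrument", "timepoint", "mean",
                                       "sd", "n"])


def node_level_change_analysis(pre: dict, post: dict, q: float = 0.0125,
                               n_perm: int = 10_000,
                               seed: int | None = None) -> pd.DataFrame:
    """Per-node paired pre/post tests with FDR control within each metric.

    Parameters
    ----------
    pre, post : mapping metric name -> (n_subjects, n_nodes) array
        Node-level metric values per subject and session; node columns must
        correspond across sessions.
    q : float
        FDR level applied within each metric family.

    Returns the full table (metric, node, statistic, p, p_adj, rejected)
    regardless of significance.
    """
    if set(pre) != set(post):
        raise ValueError("pre and post must contain the same metrics")
    rows = []
    for metric in sorted(pre):
        a = np.asarray(pre[metric], float)
        b = np.asarray(post[metric], float)
        if a.shape != b.shape:
            raise ValueError(f"mismatched node sets for metric '{metric}'")
        pvals, stats_ = [], []
        for j in range(a.shape[1]):
            res = paired_change_test(a[:, j], b[:, j], n_perm=n_perm,
                                     seed=seed)
            pvals.append(res.p)
            stats_.append(res.statistic)
        rej_idx, p_adj = fdr_bh(pvals, q=q)
        rejected = np.zeros(a.shape[1], dtype=bool)
        rejected[rej_idx] = True
        for j in range(a.shape[1]):
            rows.append((metric, j, stats_[j], pvals[j], p_adj[j],
                         bool(rejected[j])))
    return pd.DataFrame(rows, columns=["metric", "node", "statistic", "p",
                                       "p_adj", "rejected"])
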