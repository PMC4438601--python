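"""Temporal cleaning and quality control of node BOLD time series.

This module operates downstream of image-space preprocessing (slice timing,
realignment, registration): its inputs are node x time matrices, either read
from text files or extracted from a registered 4-D NIfTI volume with a node
coordinate table.  The cleaning chain is

    discard initial volumes -> band-pass filter -> nuisance regression -> DVARS

Each step is a pure function returning a new :class:`TimeSeriesMatrix`; the
original is never mutated.  DVARS (root-mean-square signal change between
consecutive volumes) is the motion/artifact index used both for scan-level
exclusion and as a covariate in downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import signal

__all__ = [
    "TimeSeriesMatrix",
    "ConfoundSet",
    "QCReport",
    "discard_initial_volumes",
    "bandpass_filter",
    "regress_confounds",
    "compute_dvars",
    "extract_node_timeseries",
    "clean_timeseries",
]


@dataclass
class TimeSeriesMatrix:
    """Node x time BOLD signal for one scan session.

    Parameters
    ----------
    values : ndarray, shape (n_nodes, n_time)
        Signal matrix; must be finite with at least 3 time points.
    tr : float
        Sampling interval (repetition time) in seconds.
    node_ids : sequence of str
        Unique node labels, one per row.
    subject_id, session : str
        Identifying metadata; ``session`` is conventionally ``"pre"`` or
        ``"post"`` in a two-session treatment design.
    meta : dict
        Free-form provenance (e.g. injected spike indices, processing log).
    """

    values: np.ndarray
    tr: float
    node_ids: Sequence[str]
    subject_id: str = ""
    session: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D node x time matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.values.shape[1] < 3:
            raise ValueError("need at least 3 time points")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        self.node_ids = list(map(str, self.node_ids))
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length must match number of rows")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray, **meta_updates) -> "TimeSeriesMatrix":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return replace(self, values=np.asarray(values, float), meta=meta)


@dataclass
class ConfoundSet:
    """Per-volume nuisance regressors: six rigid-body motion parameters plus
    mean white-matter and CSF signals.

    ``design_matrix`` appends backward-difference temporal derivatives of
    every column (first element 0), matching the convention of removing both
    a confound and its rate of change.
    """

    motion: np.ndarray  # (n_time, 6)
    white_matter: np.ndarray  # (n_time,)
    csf: np.ndarray  # (n_time,)

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, float))
        if self.motion.shape[1] != 6:
            raise ValueError("motion must have six columns")
        self.white_matter = np.asarray(self.white_matter, float).ravel()
        self.csf = np.asarray(self.csf, float).ravel()
        n = self.motion.shape[0]
        if not (len(self.white_matter) == len(self.csf) == n):
            raise ValueError("all confound regressors must share n_time")

    @property
    def n_time(self) -> int:
        return self.motion.shape[0]

    def design_matrix(self, derivatives: bool = True,
                      allow_zero_columns: bool = False) -> np.ndarray:
        """Stack regressors (and optionally their temporal derivatives) into
        an (n_time, k) design matrix, without intercept."""
        base = np.column_stack(
            [self.motion, self.white_matter, self.csf])
        if derivatives:
            deriv = np.diff(base, axis=0, prepend=base[:1])
            deriv[0] = 0.0
            base = np.column_stack([base, deriv])
        if not allow_zero_columns:
            zero = np.all(base == 0.0, axis=1)
            del zero  # rows, not columns -- checked below
            zero_cols = np.all(base == 0.0, axis=0)
            if np.any(zero_cols):
                warnings.warn(
                    f"dropping {int(zero_cols.sum())} all-zero confound "
                    "column(s); pass allow_zero_columns=True to keep them")
                base = base[:, ~zero_cols]
        return base


@dataclass
class QCReport:
    """DVARS-based scan quality report.

    ``dvars_series`` has one value per volume-to-volume transition
    (length ``n_time - 1``).  When ``unit == "percent"`` values are scaled to
    percent of the scan's grand mean absolute signal; a scan whose mean DVARS
    exceeds ``threshold`` is flagged (never silently dropped).
    """

    dvars_series: np.ndarray
    dvars_mean: float
    threshold: float
    excluded: bool
    unit: str  # "percent" or "raw"
    subject_id: str = ""
    session: str = ""


def discard_initial_volumes(ts: TimeSeriesMatrix, k: int) -> TimeSeriesMatrix:
    """Drop the first ``k`` volumes (magnetisation-equilibrium dummies)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= ts.n_time - 2:
        raise ValueError(
            f"discarding k={k} volumes leaves fewer than 3 of {ts.n_time}")
    if k == 0:
        return ts.copy_with(ts.values)
    return ts.copy_with(ts.values[:, k:], discarded_volumes=k)


def bandpass_filter(ts: TimeSeriesMatrix, low_hz: float = 0.009,
                    high_hz: float = 0.08, order: int = 2) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass filter applied per node.

    The filter is applied forward and backward (``sosfiltfilt``) so that it
    introduces no phase distortion; the effective attenuation is the square
    of a single pass of the given order.  With ``low_hz == 0`` the filter
    degenerates to a low-pass.  The default band 0.009-0.08 Hz isolates the
    low-frequency fluctuations conventionally used for resting-state
    connectivity.
    """
    nyquist = 0.5 / ts.tr
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist:.4g} Hz for tr={ts.tr}")
    fs = 1.0 / ts.tr
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                            fs=fs, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=fs,
                            output="sos")
    # demean first: filtfilt edge handling behaves better on zero-mean data
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    filtered = signal.sosfiltfilt(sos, x, axis=1)
    return ts.copy_with(filtered, bandpass=(low_hz, high_hz, order))


def regress_confounds(ts: TimeSeriesMatrix, confounds: ConfoundSet | np.ndarray,
                      derivatives: bool = True,
                      on_rank_deficient: str = "drop") -> TimeSeriesMatrix:
    """Remove nuisance regressors from every node series by OLS projection.

    Residuals are orthogonal to every retained confound column.  An
    intercept is always included, so the output is mean-centred per node.

    Parameters
    ----------
    on_rank_deficient : {"drop", "fail"}
        What to do when the confound matrix is rank deficient after
        duplicate-column removal: drop dependent columns with a warning, or
        raise.
    """
    if isinstance(confounds, ConfoundSet):
        X = confounds.design_matrix(derivatives=derivatives)
    else:
        X = np.atleast_2d(np.asarray(confounds, float))
        if X.shape[0] != ts.n_time and X.shape[1] == ts.n_time:
            X = X.T
    if X.shape[0] != ts.n_time:
        raise ValueError("confound length must equal n_time")
    X = np.column_stack([np.ones(ts.n_time), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if on_rank_deficient == "fail":
            raise ValueError("confound design matrix is rank deficient")
        # QR with column pivoting to identify an independent subset
        q, r, piv = _qr_pivot(X)
        keep = np.sort(piv[:rank])
        warnings.warn(
            f"confound design rank deficient ({rank}/{X.shape[1]}); "
            f"dropping {X.shape[1] - rank} dependent column(s)")
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    resid = ts.values.T - X @ beta
    return ts.copy_with(resid.T, confounds_regressed=X.shape[1] - 1)


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def compute_dvars(ts: TimeSeriesMatrix, threshold: float = 25.0,
                  unit: str = "percent") -> QCReport:
    """DVARS: per transition t, ``sqrt(mean_i (x[i,t] - x[i,t-1])**2)``.

    In ``"percent"`` mode the series is expressed as percent of the scan's
    grand mean absolute signal (the reference a percent-style exclusion rule
    such as "mean DVARS > 25%" presupposes).  If that reference is
    numerically zero the report falls back to raw units with a warning.
    """
    diffs = np.diff(ts.values, axis=1)
    dvars = np.sqrt(np.mean(diffs ** 2, axis=0))
    used_unit = unit
    if unit == "percent":
        ref = np.mean(np.abs(ts.values))
        if ref < 1e-12:
            warnings.warn("grand mean absolute signal ~ 0; DVARS reported "
                          "in raw units")
            used_unit = "raw"
        else:
            dvars = 100.0 * dvars / ref
    elif unit != "raw":
        raise ValueError("unit must be 'percent' or 'raw'")
    mean = float(dvars.mean())
    return QCReport(dvars_series=dvars, dvars_mean=mean, threshold=threshold,
                    excluded=bool(mean > threshold), unit=used_unit,
                    subject_id=ts.subject_id, session=ts.session)


def extract_node_timeseries(image, centers: np.ndarray, radius_mm: float = 5.0,
                            node_ids: Sequence[str] | None = None,
                            tr: float | None = None) -> TimeSeriesMatrix:
    """Average a registered 4-D image over spherical ROIs.

    Parameters
    ----------
    image : str | Path | nibabel image
        4-D NIfTI volume already registered to the coordinate frame of
        ``centers`` (world/mm coordinates via the image affine, RAS).
    centers : ndarray, shape (n_nodes, 3)
        Sphere centres in mm.
    radius_mm : float
        Sphere radius; a voxel belongs to a node when its centre lies within
        ``radius_mm`` of the node centre.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    img = nib.load(str(image)) if not hasattr(image, "get_fdata") else image
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D image")
    centers = np.atleast_2d(np.asarray(centers, float))
    if centers.shape[1] != 3:
        raise ValueError("centers must be (n_nodes, 3) in mm")
    if node_ids is None:
        node_ids = [f"node{i:03d}" for i in range(centers.shape[0])]
    affine = img.affine
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in data.shape[:3]],
                             indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(),
                           np.ones(ii.size)])
    world = (vox @ affine.T)[:, :3]
    flat = data.reshape(-1, data.shape[3])
    series = np.empty((centers.shape[0], data.shape[3]))
    for idx, (c, name) in enumerate(zip(centers, node_ids)):
        mask = np.linalg.norm(world - c, axis=1) <= radius_mm
        if not mask.any():
            raise ValueError(f"node '{name}' sphere contains no voxels")
        series[idx] = flat[mask].mean(axis=0)
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return TimeSeriesMatrix(series, tr=tr, node_ids=node_ids)


def clean_timeseries(ts: TimeSeriesMatrix, n_discard: int = 2,
                     low_hz: float = 0.009, high_hz: float = 0.08,
                     confounds: ConfoundSet | np.ndarray | None = None,
                     dvars_threshold: float = 25.0,
                     dvars_on: str = "cleaned") -> tuple[TimeSeriesMatrix, QCReport]:
    """Run the full cleaning chain and return (cleaned series, QC report).

    Fixed stage order: discard -> band-pass -> confound regression -> DVARS.
    ``dvars_on`` selects whether DVARS is computed on the cleaned series
    (default) or on the raw post-discard series (``"raw"``), since percent
    scaling is more interpretable on data that retain their baseline.
    """
    out = discard_initial_volumes(ts, n_discard)
    raw = out
    out = bandpass_filter(out, low_hz=low_hz, high_hz=high_hz)
    if confounds is not None:
        out = regress_confounds(out, confounds)
    qc = compute_dvars(raw if dvars_on == "raw" else out,
                       threshold=dvars_threshold)
    return out, qc
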