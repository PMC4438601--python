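"""Reading and writing the pipeline's plain-text interchange formats.

Conventions
-----------
* Time series: tab-separated, one row per volume, one column per node, with
  a header row of node IDs (so the on-disk orientation is time x nodes; the
  in-memory matrix is nodes x time).
* Clinical table: CSV with one row per subject; column dictionary documented
  in :data:`CLINICAL_COLUMNS`.
* Connectivity matrices: tab-separated square matrix with a node-ID header,
  plus a JSON sidecar recording method, shrinkage and an input hash.
* Node coordinates: whitespace/comma-delimited 3-column (x, y, z) table in
  mm, world coordinates, RAS convention.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityMatrix
from .preprocess import TimeSeriesMatrix

__all__ = [
    "read_timeseries", "write_timeseries",
    "read_clinical", "write_clinical",
    "read_connectivity", "write_connectivity",
    "read_coordinates", "read_config", "write_config",
    "write_cohort", "array_hash", "CLINICAL_COLUMNS",
]

#: clinical table column dictionary
CLINICAL_COLUMNS = {
    "subject": "subject identifier",
    "ybocs_pre": "YBOCS total pre-treatment (0-40)",
    "ybocs_post": "YBOCS total post-treatment (0-40)",
    "ybocs_followup": "YBOCS total at follow-up (0-40)",
    "cgi_post": "Clinical Global Improvement post-treatment (1-7)",
    "hama_pre": "Hamilton Anxiety pre", "hama_post": "Hamilton Anxiety post",
    "madrs_pre": "MADRS depression pre", "madrs_post": "MADRS depression post",
    "gas_pre": "Global Assessment Scale pre", "gas_post": "GAS post",
    "stroop_pre": "Stroop interference pre", "stroop_post": "Stroop interference post",
    "months_followup": "months from post-treatment to follow-up assessment",
    "medication_months": "months of medication during follow-up",
    "cbt_sessions": "number of CBT sessions during follow-up",
    "dvars_pre": "mean DVARS of the pre-treatment scan (percent)",
    "dvars_post": "mean DVARS of the post-treatment scan (percent)",
}


def array_hash(a: np.ndarray) -> str:
    """Stable content hash of an array (shape + little-endian float64 bytes)."""
    a = np.ascontiguousarray(np.asarray(a, dtype="<f8"))
    h = hashlib.sha256()
    h.update(str(a.shape).encode())
    h.update(a.tobytes())
    return h.hexdigest()[:16]


def write_timeseries(ts: TimeSeriesMatrix, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ts.values.T, columns=ts.node_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_timeseries(path, tr: float, subject_id: str = "",
                    session: str = "") -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(df.to_numpy(float).T, tr=tr,
                            node_ids=list(df.columns),
                            subject_id=subject_id, session=session)


def write_clinical(clinical: pd.DataFrame, path) -> Path:
    path = Path(path)
    clinical.to_csv(path, index=False)
    return path


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject" not in df.columns:
        raise ValueError("clinical table must have a 'subject' column")
    return df


def write_connectivity(conn: ConnectivityMatrix, path) -> Path:
    path = Path(path)
    pd.DataFrame(conn.values, columns=conn.node_ids).to_csv(
        path, sep="\t", index=False, float_format="%.12g")
    sidecar = {"method": conn.method, "shrinkage": conn.shrinkage,
               "n_nodes": conn.n_nodes, "hash": array_hash(conn.values)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_connectivity(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    sidecar_path = Path(str(path) + ".json")
    method, shrink = "pearson", None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        method = meta.get("method", method)
        shrink = meta.get("shrinkage")
    return ConnectivityMatrix(df.to_numpy(float), method=method,
                              node_ids=list(df.columns), shrinkage=shrink)


def read_coordinates(path) -> np.ndarray:
    """3-column (x, y, z in mm, RAS) node-centre table."""
    arr = np.atleast_2d(np.loadtxt(path, delimiter=None, comments="#"))
    if arr.shape[1] != 3:
        arr2 = np.atleast_2d(np.loadtxt(path, delimiter=",", comments="#"))
        if arr2.shape[1] == 3:
            return arr2
        raise ValueError("coordinate table must have exactly 3 columns")
    return arr


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a key-value mapping")
    return cfg


def write_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def write_cohort(cohort, outdir) -> Path:
    """Write a synthetic cohort as plain text: one TSV per scan, the clinical
    CSV, module labels, and the generating spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsdir = outdir / "timeseries"
    tsdir.mkdir(exist_ok=True)
    for (subj, session), ts in sorted(cohort.timeseries.items()):
        write_timeseries(ts, tsdir / f"{subj}_{session}.tsv")
    write_clinical(cohort.clinical, outdir / "clinical.csv")
    np.savetxt(outdir / "membership.txt", cohort.membership, fmt="%d")
    spec = cohort.spec.as_dict()
    spec["clinical_params"] = {k: list(v) for k, v in
                               spec["clinical_params"].items()}
    write_config({"cohort": spec}, outdir / "cohort_spec.yaml")
    np.savetxt(outdir / "realized_sigma_auc.txt", cohort.realized_sigma_auc)
    return outdir
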