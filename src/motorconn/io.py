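"""Delimited-text interchange formats for every pipeline stage.

All artifacts are plain text: per-session series as tab-separated matrices
(header row of channel labels, one column per channel), the clinical table
and manifest as CSV, the ground-truth ledger as JSON, and all result tables
as tidy CSV. Series round-trip losslessly (full float precision); integer
tables round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .series import MultichannelSeries
from .synthetic import FAC_RANGE, FMA_RANGE


def write_series(series: MultichannelSeries, path) -> None:
    """Write a series as TSV: header of labels, one column per channel."""
    path = Path(path)
    header = "\t".join(series.labels)
    np.savetxt(path, series.values.T, delimiter="\t", header=header,
               comments="", fmt="%.17g")


def read_series(path, fs: float) -> MultichannelSeries:
    """Read a TSV series written by :func:`write_series`."""
    path = Path(path)
    with open(path) as fh:
        labels = tuple(fh.readline().rstrip("\n").split("\t"))
    if any(not lbl for lbl in labels):
        raise ValueError(f"{path}: missing channel label in header")
    values = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if values.shape[1] != len(labels):
        raise ValueError(
            f"{path}: {values.shape[1]} data columns but {len(labels)} labels"
        )
    return MultichannelSeries(values.T, fs, labels)


def write_clinical_table(subjects, path) -> None:
    """Clinical scores as CSV: subject, FMA_T0, FMA_T1, FAC_T0, FAC_T1."""
    rows = [{
        "subject": s.subject_id,
        "FMA_T0": s.fma_t0, "FMA_T1": s.fma_t1,
        "FAC_T0": s.fac_t0, "FAC_T1": s.fac_t1,
    } for s in subjects]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_clinical_table(path) -> pd.DataFrame:
    """Read and validate the clinical score table."""
    df = pd.read_csv(path)
    required = ["subject", "FMA_T0", "FMA_T1", "FAC_T0", "FAC_T1"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    for col in ("FMA_T0", "FMA_T1"):
        bad = df[(df[col] < FMA_RANGE[0]) | (df[col] > FMA_RANGE[1])]
        if len(bad):
            raise ValueError(
                f"clinical table column {col}: value outside {FMA_RANGE} "
                f"for subject(s) {bad['subject'].tolist()}"
            )
    for col in ("FAC_T0", "FAC_T1"):
        bad = df[(df[col] < FAC_RANGE[0]) | (df[col] > FAC_RANGE[1])]
        if len(bad):
            raise ValueError(
                f"clinical table column {col}: value outside {FAC_RANGE} "
                f"for subject(s) {bad['subject'].tolist()}"
            )
    return df


def write_truth_ledger(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth_ledger(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_population(subjects, truth, outdir, fs: float) -> pd.DataFrame:
    """Write all per-subject series, the manifest, clinical table and ledger.

    Returns the manifest DataFrame (subject, session, path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        for sess, ser in (("T0", s.series_t0), ("T1", s.series_t1)):
            fname = f"{s.subject_id}_{sess}.tsv"
            write_series(ser, outdir / fname)
            rows.append({"subject": s.subject_id, "session": sess,
                         "path": fname, "fs": fs})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    write_clinical_table(subjects, outdir / "clinical.csv")
    write_truth_ledger(truth, outdir / "truth.json")
    return manifest


def read_population_series(outdir):
    """Load the manifest and all series; returns (manifest, dict).

    The dict maps (subject, session) -> MultichannelSeries.
    """
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    series = {}
    for _, row in manifest.iterrows():
        series[(row["subject"], row["session"])] = read_series(
            outdir / row["path"], float(row["fs"])
        )
    return manifest, series


def connectivity_matrix_frame(matrix: np.ndarray, labels) -> pd.DataFrame:
    """Long-format frame of an (M, M) matrix: source, target, value.

    Orientation: entry (i, j) flows from source column j to receiver row i.
    """
    rows = []
    for i, tgt in enumerate(labels):
        for j, src in enumerate(labels):
            rows.append({"source": src, "target": tgt,
                         "value": float(matrix[i, j])})
    return pd.DataFrame(rows)


def edge_list_frame(matrix: np.ndarray, labels, weight_name: str = "weight",
                    drop_zero: bool = True) -> pd.DataFrame:
    """Directed edge list of an (M, M) matrix for network rendering."""
    df = connectivity_matrix_frame(matrix, labels)
    df = df.rename(columns={"value": weight_name})
    df = df[df["source"] != df["target"]]
    if drop_zero:
        df = df[df[weight_name] != 0.0]
    return df.reset_index(drop=True)
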