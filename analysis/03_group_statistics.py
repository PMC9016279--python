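"""Longitudinal group statistics on the detected motor network.

Reads the per-epoch band DC values, the per-epoch surrogate detections and
the ICW tables written by 02_connectivity_detection.py and runs the three
group analyses: paired one-tailed Wilcoxon tests on epoch-averaged band DC
(T1 vs T0), exact-binomial McNemar tests on the paired per-epoch detections,
and Spearman correlations between per-subject Delta %ICW and the clinical
deltas -- each FDR-corrected. Prints the significant connections and writes
the tidy result tables plus a Delta %ICW edge list under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from motorconn import io as mio
from motorconn.group import (clinical_correlation, dc_group_comparison,
                             icw_group_comparison, population_icw_percentage)
from motorconn.series import MOTOR_ROIS

OUT = Path("results")
BANDS = ("alpha", "beta")
IDX = {lbl: i for i, lbl in enumerate(MOTOR_ROIS)}


def _dc_arrays(dc: pd.DataFrame, subjects):
    """Subject-level band DC: mean over epochs, as (S, M, M) per band."""
    out = {}
    for sess in ("T0", "T1"):
        out[sess] = {}
        for band in BANDS:
            arr = np.zeros((len(subjects), 5, 5))
            sel = dc[(dc.session == sess) & (dc.band == band)]
            mean = sel.groupby(["subject", "source", "target"]).dc.mean()
            for (subj, src, tgt), v in mean.items():
                arr[subjects.index(subj), IDX[tgt], IDX[src]] = v
            out[sess][band] = arr
    return out


def _flag_arrays(det: pd.DataFrame, subjects, n_epochs):
    out = {}
    for sess in ("T0", "T1"):
        out[sess] = {}
        for band in BANDS:
            arr = np.zeros((len(subjects), n_epochs, 5, 5), dtype=bool)
            sel = det[(det.session == sess) & (det.band == band)]
            for row in sel.itertuples():
                arr[subjects.index(row.subject), row.epoch,
                    IDX[row.target], IDX[row.source]] = row.flag
            out[sess][band] = arr
    return out


def main() -> None:
    dc = pd.read_csv(OUT / "dc_band.csv")
    det = pd.read_csv(OUT / "detections.csv")
    clinical = mio.read_clinical_table(OUT / "population" / "clinical.csv")
    subjects = sorted(clinical.subject)
    n_epochs = int(det.epoch.max()) + 1

    dc_arr = _dc_arrays(dc, subjects)
    flags = _flag_arrays(det, subjects, n_epochs)
    icw = {sess: {b: flags[sess][b].mean(axis=1) for b in BANDS}
           for sess in ("T0", "T1")}

    wilcoxon = dc_group_comparison(dc_arr["T0"], dc_arr["T1"], MOTOR_ROIS)
    mcnemar = icw_group_comparison(flags["T0"], flags["T1"], MOTOR_ROIS)

    clinical = clinical.set_index("subject").loc[subjects]
    delta_pct = {b: (icw["T1"][b] - icw["T0"][b]) * 100.0 for b in BANDS}
    spearman = clinical_correlation(
        delta_pct,
        {"FMA": (clinical.FMA_T1 - clinical.FMA_T0).to_numpy(),
         "FAC": (clinical.FAC_T1 - clinical.FAC_T0).to_numpy()},
        MOTOR_ROIS)

    wilcoxon.table.to_csv(OUT / "dc_wilcoxon.csv", index=False)
    mcnemar.table.to_csv(OUT / "icw_mcnemar.csv", index=False)
    spearman.table.to_csv(OUT / "clinical_spearman.csv", index=False)

    # population percentages and the Delta %ICW edge list for rendering
    pct_rows, edges = [], []
    for band in BANDS:
        for sess in ("T0", "T1"):
            mat = population_icw_percentage(icw[sess][band])
            frame = mio.connectivity_matrix_frame(mat, MOTOR_ROIS)
            frame.insert(0, "band", band)
            frame.insert(0, "session", sess)
            pct_rows.append(frame)
    pd.concat(pct_rows, ignore_index=True).rename(
        columns={"value": "pct_icw"}).to_csv(
            OUT / "population_icw_pct.csv", index=False)
    sig = mcnemar.significant()
    sig[["band", "source", "target", "delta_pct_icw", "raw_p", "adj_p",
         "direction"]].to_csv(OUT / "delta_icw_edges.csv", index=False)

    print("== McNemar (FDR q=0.05): connections with changed ICW grading ==")
    print(sig[["band", "source", "target", "delta_pct_icw", "adj_p",
               "direction"]].to_string(index=False))
    wsig = wilcoxon.table[wilcoxon.table.raw_p <= 0.05]
    print("\n== Wilcoxon on band DC (raw p <= 0.05, T1 > T0) ==")
    print(wsig[["band", "source", "target", "raw_p", "adj_p"]]
          .to_string(index=False))
    ssig = spearman.table[(spearman.table.raw_p.notna())
                          & (spearman.table.adj_p <= 0.05)]
    print("\n== Spearman Delta %ICW vs clinical deltas (FDR q=0.05) ==")
    print(ssig[["band", "score", "source", "target", "rho", "adj_p"]]
          .to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
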