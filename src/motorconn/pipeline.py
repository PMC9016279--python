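"""End-to-end orchestration: simulate/load -> fit -> connectivity ->
surrogates -> ICW -> group statistics, with reproducible seeding.

Stages are plain functions over in-memory objects so they can be driven by
the numbered analysis scripts, by tests, or all at once via
:func:`run_pipeline`. Every output table is deterministic under a fixed
master seed, and the written bundle records the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .group import (clinical_correlation, compute_icw, dc_group_comparison,
                    icw_group_comparison, population_icw_percentage)
from .mvar import fit_mvar
from .series import MOTOR_ROIS, epoch_series
from .spectral import BandDefinition, compute_iaf, \
    directed_coherence_squared, welch_psd
from .surrogate import (BAND_NAMES, build_null, detect_connections,
                        observed_band_gpdc, threshold_matrix)
from .synthetic import SyntheticPopulationConfig, generate_population

log = logging.getLogger("motorconn")

SESSIONS = ("T0", "T1")


@dataclass
class PipelineConfig:
    """All analysis parameters in one validated record.

    Defaults encode the study's analysis constants: 128 Hz sampling, 10 s
    epochs, MVAR order 8, a 0.125 Hz frequency grid, 100 IAAFT surrogates at
    significance level 0.01, and group-test FDR level q = 0.05.
    """

    synthetic: SyntheticPopulationConfig = field(
        default_factory=SyntheticPopulationConfig)
    fs: float = 128.0
    epoch_seconds: float = 10.0
    order: int = 8
    grid_resolution: float = 0.125
    n_surrogates: int = 100
    detection_alpha: float = 0.01
    q_fdr: float = 0.05
    welch_segment_seconds: float = 4.0
    master_seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.epoch_seconds <= 0:
            raise ValueError("fs and epoch_seconds must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.detection_alpha < 1:
            raise ValueError("detection_alpha must lie in (0, 1)")
        if self.n_surrogates < 1.0 / self.detection_alpha:
            raise ValueError(
                "n_surrogates too small to resolve the detection percentile"
            )
        if not 0 < self.q_fdr < 1:
            raise ValueError("q_fdr must lie in (0, 1)")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")
        # band feasibility at the population-mean alpha peak
        BandDefinition(self.synthetic.iaf_mean).validate(self.fs)
        if self.synthetic.iaf_mean + 2.0 >= self.fs / 2.0:
            raise ValueError("alpha band upper edge exceeds the Nyquist frequency")
        if self.synthetic.fs != self.fs:
            raise ValueError("synthetic fs and pipeline fs disagree")

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        syn = d.pop("synthetic", {})
        # tuples serialize as lists; restore hashable forms
        if "planted_changes" in syn:
            syn["planted_changes"] = tuple(tuple(c) for c in syn["planted_changes"])
        if "clinical_connection" in syn:
            syn["clinical_connection"] = tuple(syn["clinical_connection"])
        return cls(synthetic=SyntheticPopulationConfig(**syn), **d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _session_seed(config: PipelineConfig, subject_idx: int, session_idx: int,
                  epoch_idx: int) -> np.random.SeedSequence:
    """Stable surrogate seed for one epoch of one subject session."""
    return np.random.SeedSequence(
        [config.master_seed, 7001, subject_idx, session_idx, epoch_idx]
    )


def subject_iaf(series, config: PipelineConfig) -> float:
    """Estimate a subject's IAF from the Welch PSD of all channels."""
    freqs, psd = welch_psd(series, config.welch_segment_seconds)
    return compute_iaf(freqs, psd)


def analyze_session(series, bands: BandDefinition, config: PipelineConfig,
                    subject_idx: int, session_idx: int) -> dict:
    """Run one session through epoching, DC/gPDC and surrogate detection.

    Returns per-band arrays: epoch-wise band DC (E, M, M), epoch-wise
    detections (E, M, M) plus observed gPDC and thresholds, and the ICW
    matrices.
    """
    epochs = epoch_series(series, config.epoch_seconds)
    m = series.n_channels
    out = {
        "dc": {b: [] for b in BAND_NAMES},
        "gpdc": {b: [] for b in BAND_NAMES},
        "flags": {b: [] for b in BAND_NAMES},
        "thresholds": {b: [] for b in BAND_NAMES},
    }
    for e_idx, epoch in enumerate(epochs):
        model = fit_mvar(epoch, config.order)
        bins = {
            b: _band_freqs(bands.band(b), config)
            for b in BAND_NAMES
        }
        for b in BAND_NAMES:
            dc = directed_coherence_squared(model, bins[b])
            out["dc"][b].append(dc.values.mean(axis=0))
        observed = observed_band_gpdc(
            epoch, config.order, bands, grid_resolution=config.grid_resolution
        )
        ensemble = build_null(
            epoch, config.n_surrogates, config.order, bands,
            _session_seed(config, subject_idx, session_idx, e_idx),
            alpha=config.detection_alpha,
            grid_resolution=config.grid_resolution,
        )
        for b in BAND_NAMES:
            thr = threshold_matrix(ensemble, b)
            out["gpdc"][b].append(observed[b])
            out["thresholds"][b].append(thr)
            out["flags"][b].append(detect_connections(observed[b], thr))
    for key in out:
        out[key] = {b: np.asarray(v) for b, v in out[key].items()}
    out["icw"] = {b: compute_icw(out["flags"][b]) for b in BAND_NAMES}
    return out


def _band_freqs(band, config: PipelineConfig) -> np.ndarray:
    grid = np.arange(0.0, config.fs / 2.0 + config.grid_resolution / 2,
                     config.grid_resolution)
    mask = (grid >= band[0]) & (grid <= band[1])
    if not np.any(mask):
        raise ValueError(f"no grid bins inside band {band}")
    return grid[mask]


def analyze_population(subjects, config: PipelineConfig):
    """Per-subject, per-session connectivity analysis of a population.

    Returns a dict keyed by (subject_id, session) of session analyses, plus
    the per-subject IAF estimates (from the T0 recording).
    """
    results = {}
    iafs = {}
    for s_idx, subj in enumerate(subjects):
        iaf = subject_iaf(subj.series_t0, config)
        bands = BandDefinition(iaf)
        bands.validate(config.fs)
        iafs[subj.subject_id] = iaf
        for sess_idx, (sess, ser) in enumerate(
                (("T0", subj.series_t0), ("T1", subj.series_t1))):
            log.info("analyzing %s %s (IAF %.2f Hz)", subj.subject_id, sess, iaf)
            results[(subj.subject_id, sess)] = analyze_session(
                ser, bands, config, s_idx, sess_idx
            )
    return results, iafs


def group_statistics(subjects, results, config: PipelineConfig,
                     labels=MOTOR_ROIS):
    """All three group-level analyses over a population's session results."""
    sids = [s.subject_id for s in subjects]
    dc = {sess: {b: np.array([results[(sid, sess)]["dc"][b].mean(axis=0)
                              for sid in sids]) for b in BAND_NAMES}
          for sess in SESSIONS}
    flags = {sess: {b: np.array([results[(sid, sess)]["flags"][b]
                                 for sid in sids]) for b in BAND_NAMES}
             for sess in SESSIONS}
    icw = {sess: {b: np.array([results[(sid, sess)]["icw"][b]
                               for sid in sids]) for b in BAND_NAMES}
           for sess in SESSIONS}

    wilcoxon = dc_group_comparison(dc["T0"], dc["T1"], labels, q=config.q_fdr)
    mcnemar = icw_group_comparison(flags["T0"], flags["T1"], labels,
                                   q=config.q_fdr)
    delta_pct = {b: (icw["T1"][b] - icw["T0"][b]) * 100.0 for b in BAND_NAMES}
    clinical = clinical_correlation(
        delta_pct,
        {"FMA": [s.delta_fma for s in subjects],
         "FAC": [s.delta_fac for s in subjects]},
        labels, q=config.q_fdr,
    )
    pct = []
    for sess in SESSIONS:
        for b in BAND_NAMES:
            mat = population_icw_percentage(icw[sess][b])
            frame = mio.connectivity_matrix_frame(mat, labels)
            frame.insert(0, "band", b)
            frame.insert(0, "session", sess)
            pct.append(frame)
    percentages = pd.concat(pct, ignore_index=True).rename(
        columns={"value": "pct_icw"})
    return {"wilcoxon": wilcoxon, "mcnemar": mcnemar,
            "clinical": clinical, "percentages": percentages,
            "icw": icw, "dc": dc}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write the result bundle under ``outdir``.

    Reruns with an identical config reproduce all numeric outputs exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    (outdir / "config_hash.txt").write_text(
        f"{config.config_hash()} seed={config.master_seed}\n")

    log.info("stage simulate: %d subjects", config.synthetic.n_subjects)
    subjects, truth = generate_population(config.synthetic)
    mio.write_population(subjects, truth, outdir / "population", config.fs)

    log.info("stage connectivity + surrogates")
    results, iafs = analyze_population(subjects, config)
    pd.DataFrame(
        [{"subject": k, "iaf_hz": v} for k, v in iafs.items()]
    ).to_csv(outdir / "iaf.csv", index=False)
    write_session_tables(subjects, results, outdir)

    log.info("stage group statistics")
    stats = group_statistics(subjects, results, config)
    stats["wilcoxon"].table.to_csv(outdir / "dc_wilcoxon.csv", index=False)
    stats["mcnemar"].table.to_csv(outdir / "icw_mcnemar.csv", index=False)
    stats["clinical"].table.to_csv(outdir / "clinical_spearman.csv", index=False)
    stats["percentages"].to_csv(outdir / "population_icw_pct.csv", index=False)
    return {"subjects": subjects, "truth": truth, "results": results,
            "iafs": iafs, "stats": stats}


def write_session_tables(subjects, results, outdir: Path) -> None:
    """Long-format detection and ICW tables across the population."""
    det_rows = []
    icw_rows = []
    labels = MOTOR_ROIS
    for subj in subjects:
        for sess in SESSIONS:
            res = results[(subj.subject_id, sess)]
            for b in BAND_NAMES:
                flags = res["flags"][b]
                obs = res["gpdc"][b]
                thr = res["thresholds"][b]
                for e in range(flags.shape[0]):
                    for i, tgt in enumerate(labels):
                        for j, src in enumerate(labels):
                            if i == j:
                                continue
                            det_rows.append({
                                "subject": subj.subject_id, "session": sess,
                                "band": b, "epoch": e, "source": src,
                                "target": tgt,
                                "flag": bool(flags[e, i, j]),
                                "observed": float(obs[e, i, j]),
                                "threshold": float(thr[e, i, j]),
                            })
                icw = res["icw"][b]
                for i, tgt in enumerate(labels):
                    for j, src in enumerate(labels):
                        if i == j:
                            continue
                        icw_rows.append({
                            "subject": subj.subject_id, "session": sess,
                            "band": b, "source": src, "target": tgt,
                            "icw": float(icw[i, j]),
                        })
    pd.DataFrame(det_rows).to_csv(outdir / "detections.csv", index=False)
    pd.DataFrame(icw_rows).to_csv(outdir / "icw.csv", index=False)
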