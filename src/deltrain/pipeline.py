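"""Orchestration: simulate a cohort, run all three analyses, report.

The pipeline mirrors the analysis order of the study it models:

1. pitch--MEG coherence during the entrainment phase (cluster statistics
   on the 0.6 vs 0.9 Hz contrast within and between conditions);
2. sensor power during the target phase at the same frequencies;
3. source-level DICS maps -> ROI responses -> RSR and the condition x
   frequency interaction;
4. the omission ERF contrast on SHORT sentences (300--600 ms and
   0--120 ms windows) with an LCMV source map.

Trial QC precedes every analysis: absolute-amplitude bound, median-filter
jump detection (z threshold 75) and a high-band muscle analog
(110--124 Hz, z threshold 20).  Thresholds are expressed in simulation
units; the absolute bound plays the role of the recording hardware's
field-amplitude limit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sp_signal
from scipy.ndimage import median_filter

from . import erf as erf_mod
from . import sources, spectral, stats, stimuli
from .simulate import (
    EpochSet,
    SensorModel,
    SimConfig,
    build_sensor_model,
    simulate_subject,
    subject_seeds,
    generate_plan_for,
)
from .spectral import SpectralGrid
from .stimuli import FAST, SLOW

logger = logging.getLogger("deltrain")

__all__ = [
    "QCConfig",
    "RunConfig",
    "Report",
    "reject_trials_qc",
    "run_pipeline",
    "write_report",
    "subject_spectra",
]

FREQS_OF_INTEREST = (0.6, 0.9)


class EmptyDataError(ValueError):
    pass


@dataclass
class QCConfig:
    """Trial-rejection thresholds (simulation units / z scores)."""

    abs_threshold: float = 25.0      # absolute-amplitude analog of +-6 pT
    jump_z: float = 75.0
    muscle_z: float = 20.0
    muscle_band: tuple = (110.0, 124.0)
    median_order: int = 9


@dataclass
class RunConfig:
    """Everything needed to regenerate a full report."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    n_perm: int = 5000
    cluster_alpha: float = 0.05
    min_channels: int = 3
    beamformer_lambda: float = 0.05
    csd_pad_s: float = 20.0
    late_window_ms: tuple = (300.0, 600.0)
    early_window_ms: tuple = (0.0, 120.0)
    outdir: str | None = None
    use_cache: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            sim_d = {
                k: tuple(v) if k.endswith("_rois") and v is not None else v
                for k, v in d["sim"].items()
            }
            d["sim"] = SimConfig(**sim_d)
        if isinstance(d.get("qc"), dict):
            d["qc"] = QCConfig(**{
                k: tuple(v) if k == "muscle_band" else v
                for k, v in d["qc"].items()
            })
        for k in ("late_window_ms", "early_window_ms"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path=None) -> str:
        def _clean(v):
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return list(v)
            return v

        text = yaml.safe_dump(_clean(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def smoke(self) -> "RunConfig":
        """Reduced-scale variant for fast end-to-end runs."""
        cfg = RunConfig.from_dict(self.to_dict())
        cfg.sim.n_subjects = 5
        cfg.sim.n_trials = 40
        cfg.n_perm = 500
        return cfg


@dataclass
class Report:
    """All tables of one pipeline run; regenerable from config + seed."""

    config: dict
    peaks: pd.DataFrame
    clusters: dict                  # name -> list[ClusterResult]
    coherence_foi: pd.DataFrame     # subject x condition x frequency x channel
    power_foi: pd.DataFrame
    rsr_entrainment: pd.DataFrame
    rsr_target: pd.DataFrame
    interaction_entrainment: pd.DataFrame
    interaction_target: pd.DataFrame
    erf_direction: pd.DataFrame
    lcmv_tmap: pd.DataFrame
    qc_log: pd.DataFrame
    timings: dict


# ---------------------------------------------------------------------------
# trial QC
# ---------------------------------------------------------------------------

def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return float(1.4826 * mad) or float(x.std()) or 1.0


def reject_trials_qc(epochs: EpochSet, config: QCConfig) -> tuple:
    """Drop trials failing amplitude, jump or muscle rules.

    Returns ``(clean_epochs, log)`` where the log lists every rejected
    trial with the rule that fired and its statistic.  Raises
    :class:`EmptyDataError` when nothing survives.
    """
    data = epochs.data
    n_tr = epochs.n_trials
    rows = []
    bad = np.zeros(n_tr, dtype=bool)

    amp = np.max(np.abs(data), axis=(1, 2)) if n_tr else np.zeros(0)
    for i in np.flatnonzero(amp > config.abs_threshold):
        bad[i] = True
        rows.append({"trial": int(epochs.metadata['trial'].iloc[i]), "rule": "amplitude", "statistic": float(amp[i])})

    if n_tr:
        # jump rule: z of the time derivative of ninth-order median-filtered
        # data; the median filter suppresses spiky noise so a discontinuity
        # stands out in the derivative
        filtered = median_filter(data, size=(1, 1, config.median_order), mode="nearest")
        deriv = np.abs(np.diff(filtered, axis=2))
        sd = np.array(
            [_robust_sd(deriv[:, c, :].ravel()) for c in range(epochs.n_channels)]
        )
        z = deriv / sd[None, :, None]
        jump_stat = z.max(axis=(1, 2))
        for i in np.flatnonzero(jump_stat > config.jump_z):
            if not bad[i]:
                bad[i] = True
                rows.append({"trial": int(epochs.metadata['trial'].iloc[i]), "rule": "jump", "statistic": float(jump_stat[i])})

        lo, hi = config.muscle_band
        nyq = epochs.sample_rate / 2.0
        if hi < nyq and n_tr >= 3:
            sos = sp_signal.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
            pad = int(epochs.sample_rate)  # zero-pad to dodge edge artifacts
            padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)))
            band = sp_signal.sosfiltfilt(sos, padded, axis=2)[:, :, pad:-pad]
            bp = np.mean(band**2, axis=2)          # (trials, channels)
            mu = np.median(bp, axis=0)
            sd_bp = np.array([_robust_sd(bp[:, c]) for c in range(bp.shape[1])])
            zm = (bp - mu) / sd_bp
            muscle_stat = zm.max(axis=1)
            for i in np.flatnonzero(muscle_stat > config.muscle_z):
                if not bad[i]:
                    bad[i] = True
                    rows.append({"trial": int(epochs.metadata['trial'].iloc[i]), "rule": "muscle", "statistic": float(muscle_stat[i])})

    log = pd.DataFrame(rows, columns=["trial", "rule", "statistic"])
    if n_tr and bad.all():
        raise EmptyDataError("QC rejected every trial")
    return epochs.select(~bad), log


# ---------------------------------------------------------------------------
# per-subject analyses
# ---------------------------------------------------------------------------

def subject_spectra(
    recording,
    qc: QCConfig | None = None,
    grid: SpectralGrid | None = None,
) -> dict:
    """Entrainment coherence and target power per condition for one subject.

    Returns ``{'coherence': {cond: CoherenceSpectrum},
    'power': {cond: PowerSpectrum}, 'epochs': ..., 'qc_log': DataFrame}``.
    """
    grid = grid or SpectralGrid()
    out = {"coherence": {}, "power": {}, "entrain_epochs": {}, "target_epochs": {}}
    logs = []
    for cond in (SLOW, FAST):
        ent = spectral.extract_epochs(recording, phase="entrainment", condition=cond)
        tgt = spectral.extract_epochs(recording, phase="target", condition=cond)
        if qc is not None:
            ent, log1 = reject_trials_qc(ent, qc)
            tgt, log2 = reject_trials_qc(tgt, qc)
            logs += [log1.assign(phase="entrainment", condition=cond),
                     log2.assign(phase="target", condition=cond)]
        ref = spectral.reference_epochs(ent)
        out["coherence"][cond] = spectral.coherence_spectrum(ref, ent, grid)
        out["power"][cond] = spectral.power_spectrum(tgt, grid)
        out["entrain_epochs"][cond] = ent
        out["target_epochs"][cond] = tgt
    logs = [l for l in logs if not l.empty]
    out["qc_log"] = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["trial", "rule", "statistic", "phase", "condition"])
    )
    return out


def _subject_source_responses(
    spectra: dict,
    model: SensorModel,
    lam: float,
    pad_s: float,
) -> tuple:
    """DICS ROI responses (entrainment coherence, target power) for one subject."""
    rows_ent, rows_tgt = [], []
    for f in FREQS_OF_INTEREST:
        for phase, key, value_col, rows in (
            ("entrainment", "entrain_epochs", "coherence", rows_ent),
            ("target", "target_epochs", "power", rows_tgt),
        ):
            csds = {}
            for cond in (SLOW, FAST):
                ep = spectra[key][cond]
                ref = spectral.reference_epochs(ep)
                csds[cond] = sources.compute_csd(ep, ref, f, pad_s)
            pooled = sources.CSDMatrix(
                f,
                (csds[SLOW].matrix * csds[SLOW].n_trials
                 + csds[FAST].matrix * csds[FAST].n_trials)
                / (csds[SLOW].n_trials + csds[FAST].n_trials),
                csds[SLOW].n_trials + csds[FAST].n_trials,
            )
            filt = sources.dics_common_filter(pooled, model.leadfield, lam)
            for cond in (SLOW, FAST):
                smap = sources.apply_filter(filt, csds[cond], model)
                roi = sources.roi_average(smap, model, value_col)
                roi["condition"] = cond
                roi["frequency"] = f
                rows.append(roi)
    ent = pd.concat(rows_ent, ignore_index=True).rename(columns={"value": "R"})
    tgt = pd.concat(rows_tgt, ignore_index=True).rename(columns={"value": "R"})
    return ent, tgt


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _foi_array(spec_by_subject: list, f: float, grid: SpectralGrid) -> np.ndarray:
    """subjects x channels array of a spectrum at one frequency bin."""
    b = grid.bin_of(f)
    return np.array([s.values[:, b] for s in spec_by_subject])


def _cached(config: RunConfig, stage: str, fn):
    if not (config.use_cache and config.outdir):
        return fn()
    key = hashlib.sha1(
        (config.to_yaml() + stage).encode()
    ).hexdigest()[:16]
    cache = Path(config.outdir) / "cache" / f"{stage}_{key}.pkl"
    if cache.exists():
        logger.info("stage %s: cache hit (%s)", stage, cache.name)
        return pickle.loads(cache.read_bytes())
    out = fn()
    cache.parent.mkdir(parents=True, exist_ok=True)
    cache.write_bytes(pickle.dumps(out))
    return out


def run_pipeline(config: RunConfig, model: SensorModel | None = None) -> Report:
    """Simulate, analyze and summarize one synthetic cohort."""
    timings = {}
    t_all = time.perf_counter()
    rng_master = config.seed
    grid = SpectralGrid()
    model = model or build_sensor_model(seed=config.sim.seed)

    def _per_subject():
        coh = {SLOW: [], FAST: []}
        pow_ = {SLOW: [], FAST: []}
        roi_ent_rows, roi_tgt_rows = [], []
        erfs, qc_logs = [], []
        lcmv_rows = []
        for s, rng in enumerate(subject_seeds(config.sim.seed, config.sim.n_subjects)):
            plan = generate_plan_for(config.sim, subject=s)
            rec, truth = simulate_subject(config.sim, plan, model, rng)
            spectra = subject_spectra(rec, config.qc, grid)
            qc_logs.append(spectra["qc_log"].assign(subject=s))
            for cond in (SLOW, FAST):
                coh[cond].append(spectra["coherence"][cond])
                pow_[cond].append(spectra["power"][cond])
            ent, tgt = _subject_source_responses(
                spectra, model, config.beamformer_lambda, config.csd_pad_s
            )
            roi_ent_rows.append(ent.assign(subject=s))
            roi_tgt_rows.append(tgt.assign(subject=s))
            # omission ERF + LCMV
            om = erf_mod.omission_epochs(rec)
            om, qlog = reject_trials_qc(om, config.qc)
            qc_logs.append(qlog.assign(phase="erf", condition="both", subject=s))
            e = erf_mod.condition_erf(om)
            erfs.append(e)
            cov = sources.erf_covariance([om])
            maps = sources.lcmv_filter_apply(
                cov,
                model.leadfield,
                config.beamformer_lambda,
                e.averages,
                e.times,
                config.late_window_ms,
                model,
            )
            for cond, m in maps.items():
                t = m.table[["node", "value"]].copy()
                t["condition"] = cond
                t["subject"] = s
                lcmv_rows.append(t)
            logger.info("subject %d analyzed", s)
        return coh, pow_, roi_ent_rows, roi_tgt_rows, erfs, qc_logs, lcmv_rows

    t0 = time.perf_counter()
    coh, pow_, roi_ent_rows, roi_tgt_rows, erfs, qc_logs, lcmv_rows = _cached(
        config, "subjects", _per_subject
    )
    timings["per_subject"] = time.perf_counter() - t0

    # --- sensor-level group statistics -----------------------------------
    t0 = time.perf_counter()
    clusters = {}
    foi = {}
    for meas, spec in (("coherence", coh), ("power", pow_)):
        for cond in (SLOW, FAST):
            for f in FREQS_OF_INTEREST:
                foi[(meas, cond, f)] = _foi_array(spec[cond], f, grid)
        seed_off = 0 if meas == "coherence" else 1
        a, b = foi[(meas, SLOW, 0.6)], foi[(meas, SLOW, 0.9)]
        clusters[f"{meas}_slow_06_vs_09"] = stats.cluster_permutation(
            a, b, model.neighborhood, config.n_perm, config.cluster_alpha,
            config.min_channels, seed=rng_master * 13 + seed_off,
        )
        a, b = foi[(meas, FAST, 0.6)], foi[(meas, FAST, 0.9)]
        clusters[f"{meas}_fast_06_vs_09"] = stats.cluster_permutation(
            a, b, model.neighborhood, config.n_perm, config.cluster_alpha,
            config.min_channels, seed=rng_master * 17 + seed_off,
        )
        d_slow = foi[(meas, SLOW, 0.6)] - foi[(meas, SLOW, 0.9)]
        d_fast = foi[(meas, FAST, 0.6)] - foi[(meas, FAST, 0.9)]
        clusters[f"{meas}_interaction"] = stats.cluster_permutation(
            d_slow, d_fast, model.neighborhood, config.n_perm,
            config.cluster_alpha, config.min_channels,
            seed=rng_master * 19 + seed_off,
        )

    peaks = []
    for meas, spec in (("coherence", coh), ("power", pow_)):
        for cond in (SLOW, FAST):
            group = np.mean([s.channel_mean() for s in spec[cond]], axis=0)
            peaks.append(
                {
                    "measure": meas,
                    "condition": cond,
                    "peak_hz": spectral.peak_frequency(
                        group, band=(0.1, 1.5), frequencies=grid.frequencies
                    ),
                }
            )
    peaks = pd.DataFrame(peaks)
    timings["sensor_stats"] = time.perf_counter() - t0

    # --- source-level ROI statistics --------------------------------------
    t0 = time.perf_counter()
    roi_ent = pd.concat(roi_ent_rows, ignore_index=True)
    roi_tgt = pd.concat(roi_tgt_rows, ignore_index=True)
    rsr_ent = stats.rsr_index(roi_ent)
    rsr_tgt = stats.rsr_index(roi_tgt)
    inter_ent = stats.interaction_contrast(roi_ent, config.n_perm, seed=rng_master * 23)
    inter_tgt = stats.interaction_contrast(roi_tgt, config.n_perm, seed=rng_master * 29)
    timings["source_stats"] = time.perf_counter() - t0

    # --- omission ERF ------------------------------------------------------
    t0 = time.perf_counter()
    direction_rows = []
    for name, window in (
        ("late", config.late_window_ms),
        ("early", config.early_window_ms),
    ):
        cls, direction = erf_mod.window_contrast(
            erfs, window, model.neighborhood, config.n_perm,
            seed=rng_master * 31 + (0 if name == "late" else 1),
            min_channels=config.min_channels,
        )
        clusters[f"erf_{name}"] = cls
        if not direction.empty:
            direction_rows.append(direction.assign(window=name))
    erf_direction = (
        pd.concat(direction_rows, ignore_index=True)
        if direction_rows
        else pd.DataFrame()
    )

    lcmv = pd.concat(lcmv_rows, ignore_index=True)
    wide = lcmv.pivot_table(index=["subject", "node"], columns="condition", values="value")
    nodes = sorted(wide.index.get_level_values("node").unique())
    a = wide[SLOW].unstack("node").to_numpy()
    b = wide[FAST].unstack("node").to_numpy()
    t_map = stats.paired_t_map(a, b)
    from scipy.stats import t as t_dist

    n_sub = a.shape[0]
    p_unc = 2 * t_dist.sf(np.abs(t_map), n_sub - 1)
    lcmv_tmap = model.roi_table().assign(t=t_map, p_uncorrected=p_unc)
    timings["erf"] = time.perf_counter() - t0

    qc_logs = [q for q in qc_logs if not q.empty]
    qc_log = (
        pd.concat(qc_logs, ignore_index=True)
        if qc_logs
        else pd.DataFrame(columns=["trial", "rule", "statistic", "subject"])
    )
    timings["total"] = time.perf_counter() - t_all
    for k, v in timings.items():
        logger.info("timing %s: %.1f s", k, v)

    coh_foi = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject": s,
                    "condition": cond,
                    "frequency": f,
                    "channel": np.arange(arr.shape[1]),
                    "value": arr[s],
                }
            )
            for (meas, cond, f), arr in foi.items()
            if meas == "coherence"
            for s in range(arr.shape[0])
        ],
        ignore_index=True,
    )
    pow_foi = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject": s,
                    "condition": cond,
                    "frequency": f,
                    "channel": np.arange(arr.shape[1]),
                    "value": arr[s],
                }
            )
            for (meas, cond, f), arr in foi.items()
            if meas == "power"
            for s in range(arr.shape[0])
        ],
        ignore_index=True,
    )

    return Report(
        config=config.to_dict(),
        peaks=peaks,
        clusters=clusters,
        coherence_foi=coh_foi,
        power_foi=pow_foi,
        rsr_entrainment=rsr_ent,
        rsr_target=rsr_tgt,
        interaction_entrainment=inter_ent,
        interaction_target=inter_tgt,
        erf_direction=erf_direction,
        lcmv_tmap=lcmv_tmap,
        qc_log=qc_log,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

SUMMARY_SCHEMA = {
    "type": "object",
    "required": ["seed", "peaks", "significant_clusters", "timings"],
}


def write_report(report: Report, outdir) -> list:
    """Write all report tables as TSV/JSON; returns the written paths."""
    outdir = Path(outdir)
    if not outdir.exists():
        logger.info("creating output directory %s", outdir)
        outdir.mkdir(parents=True)
    written = []

    def _tsv(df: pd.DataFrame, name: str):
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        written.append(p)

    _tsv(report.peaks, "peaks.tsv")
    _tsv(report.coherence_foi, "coherence_foi.tsv")
    _tsv(report.power_foi, "power_foi.tsv")
    _tsv(report.rsr_entrainment, "rsr_entrainment.tsv")
    _tsv(report.rsr_target, "rsr_target.tsv")
    _tsv(report.interaction_entrainment, "interaction_entrainment.tsv")
    _tsv(report.interaction_target, "interaction_target.tsv")
    _tsv(report.erf_direction, "erf_direction.tsv")
    _tsv(report.lcmv_tmap, "lcmv_tmap.tsv")
    _tsv(report.qc_log, "qc_log.tsv")
    for name, cls in report.clusters.items():
        p = outdir / f"clusters_{name}.json"
        stats.clusters_to_json(cls, p)
        written.append(p)

    summary = {
        "seed": report.config["seed"],
        "config": report.config,
        "peaks": report.peaks.to_dict(orient="records"),
        "significant_clusters": {
            name: sum(c.significant for c in cls)
            for name, cls in report.clusters.items()
        },
        "timings": report.timings,
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, default=float))
    written.append(p)
    return written
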