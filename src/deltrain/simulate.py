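"""Synthetic MEG-like sessions through a toy forward model.

The generator emulates a 102-magnetometer recording at 250 Hz with three
planted effects, mirroring the phenomena the analysis pipeline must
recover:

* an *entrained* cycle-locked source in right auditory nodes (rEAC/rSTG)
  during contour presentation -- one response kernel per contour cycle, so
  its spectrum carries the cycle rate and its harmonics;
* a *sustained* oscillation at the trial's contour rate (free phase per
  trial) in left frontal nodes (lFOP/lEAC) during the visual sentence;
* an *omission* evoked deflection (biphasic: early lobe ~60 ms, late lobe
  ~400 ms) at the missing-verb onset of SHORT sentences preceded by SLOW
  contours, in frontal / right temporo-parieto-occipital nodes.

Sources mix linearly to sensors through an inverse-square-distance
leadfield with depth-normalized columns; 1/f plus white sensor noise is
added.  Sensor units are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stimuli
from .stimuli import FAST, SHORT, SLOW

__all__ = [
    "SensorModel",
    "SimConfig",
    "Recording",
    "EpochSet",
    "GroundTruth",
    "build_sensor_model",
    "simulate_subject",
    "simulate_cohort",
    "entrainment_kernel",
    "one_over_f_noise",
    "save_recording",
    "load_recording",
]

#: ROI labels of the toy atlas (hemisphere prefix l/r + area name)
NAMED_ROIS = [
    "rEAC", "rSTG", "lEAC", "lSTG",
    "lIFG", "rIFG", "lFOP", "rFOP",
    "lBA4", "rBA4", "lBA6", "rBA6",
    "lDLPFC", "rDLPFC", "lTPOJ", "rTPOJ",
]

ENTRAIN_ROIS = ("rEAC", "rSTG")
SUSTAIN_ROIS = ("lFOP", "lEAC")
OMISSION_ROIS = ("lIFG", "lFOP", "lDLPFC", "rTPOJ")

#: stereotyped unit directions per area (x lateral, y anterior, z superior);
#: right hemisphere mirrors the sign of x
AREA_DIRECTIONS = {
    "EAC": (-0.95, -0.10, 0.05),
    "STG": (-0.90, -0.30, -0.05),
    "IFG": (-0.75, 0.55, 0.10),
    "FOP": (-0.80, 0.45, 0.00),
    "BA4": (-0.45, -0.05, 0.85),
    "BA6": (-0.45, 0.20, 0.85),
    "DLPFC": (-0.60, 0.60, 0.50),
    "TPOJ": (-0.85, -0.50, 0.20),
}


@dataclass
class SensorModel:
    """Toy forward model: sensors on a unit sphere, labelled source nodes.

    ``leadfield`` columns (one per node) are norm-normalized, removing the
    depth bias of the raw inverse-square gains.  ``neighborhood`` is the
    symmetric k-nearest channel adjacency used by cluster statistics;
    ``node_neighbors`` the analogous node graph used by recovery checks.
    """

    n_sensors: int
    sensor_pos: np.ndarray          # (n_sensors, 3)
    neighborhood: np.ndarray        # (n_sensors, n_sensors) bool
    node_pos: np.ndarray            # (n_nodes, 3)
    node_labels: list               # len n_nodes
    leadfield: np.ndarray           # (n_sensors, n_nodes)
    node_neighbors: np.ndarray      # (n_nodes, n_nodes) bool

    @property
    def n_nodes(self) -> int:
        return self.node_pos.shape[0]

    @property
    def channel_names(self) -> list:
        return [f"MEG{i:03d}" for i in range(self.n_sensors)]

    def nodes_for(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.node_labels) == label)

    def nodes_for_rois(self, rois) -> np.ndarray:
        return np.concatenate([self.nodes_for(r) for r in rois])

    def roi_table(self) -> pd.DataFrame:
        """One row per node: label, area, hemisphere."""
        labels = list(self.node_labels)
        return pd.DataFrame(
            {
                "node": np.arange(self.n_nodes),
                "label": labels,
                "area": [l[1:] for l in labels],
                "hemisphere": [
                    "left" if l[0] == "l" else "right" for l in labels
                ],
            }
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    theta = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _knn_adjacency(pos: np.ndarray, k: int) -> np.ndarray:
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    adj = np.zeros(d.shape, dtype=bool)
    idx = np.argsort(d, axis=1)[:, :k]
    rows = np.repeat(np.arange(pos.shape[0]), k)
    adj[rows, idx.ravel()] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    return adj


def build_sensor_model(
    n_sensors: int = 102,
    n_nodes: int = 90,
    seed: int = 0,
    k_neighbors: int = 6,
    nodes_per_roi: int = 2,
) -> SensorModel:
    """Construct the toy array: sensors on the unit sphere, nodes inside.

    Each named ROI receives ``nodes_per_roi`` nodes in its hemisphere; the
    remaining nodes are hemisphere-labelled fillers.  Leadfield gains follow
    an inverse-square distance falloff with a random fixed orientation per
    node; columns are then normalized to unit norm (depth-bias removal).
    """
    if n_sensors < 4 or n_nodes < 4:
        raise ValueError("need at least 4 sensors and 4 nodes")
    if n_nodes < nodes_per_roi * len(NAMED_ROIS):
        raise ValueError("n_nodes too small for the named ROI set")
    rng = np.random.default_rng(seed)
    sensor_pos = _fibonacci_sphere(n_sensors)

    labels: list = []
    for roi in NAMED_ROIS:
        labels.extend([roi] * nodes_per_roi)
    n_fill = n_nodes - len(labels)
    for i in range(n_fill):
        hemi = "l" if i % 2 == 0 else "r"
        labels.append(f"{hemi}FIL{i // 2:02d}")

    node_pos = np.empty((n_nodes, 3))
    for j, lab in enumerate(labels):
        want_left = lab[0] == "l"
        area = lab[1:]
        if area in AREA_DIRECTIONS:
            # anatomically stereotyped placement with a small seeded scatter,
            # so nodes of one area (and of adjacent areas) cluster spatially
            v = np.array(AREA_DIRECTIONS[area], dtype=float)
            if not want_left:
                v = v * np.array([-1.0, 1.0, 1.0])
            v = v / np.linalg.norm(v) + rng.normal(0.0, 0.06, 3)
            v /= np.linalg.norm(v)
            radius = rng.uniform(0.70, 0.85)
        else:
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            radius = rng.uniform(0.35, 0.85)
        if (v[0] < 0) != want_left:
            v[0] = -v[0]
        node_pos[j] = radius * v

    # nodes of one named area share an orientation up to a small scatter,
    # as dipoles of a cortical patch do; fillers are oriented at random
    area_orient = {
        a: rng.standard_normal(3) for a in AREA_DIRECTIONS
    }
    orientations = np.empty((n_nodes, 3))
    for j, lab in enumerate(labels):
        area = lab[1:]
        if area in area_orient:
            o = area_orient[area].copy()
            o[0] *= -1.0 if lab[0] == "r" else 1.0
            o = o / np.linalg.norm(o) + rng.normal(0.0, 0.1, 3)
        else:
            o = rng.standard_normal(3)
        orientations[j] = o
    orientations /= np.linalg.norm(orientations, axis=1, keepdims=True)
    diff = sensor_pos[:, None, :] - node_pos[None, :, :]   # (S, N, 3)
    dist = np.linalg.norm(diff, axis=-1)
    unit = diff / dist[..., None]
    gain = np.einsum("snk,nk->sn", unit, orientations) / dist**2
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)

    return SensorModel(
        n_sensors=n_sensors,
        sensor_pos=sensor_pos,
        neighborhood=_knn_adjacency(sensor_pos, k_neighbors),
        node_pos=node_pos,
        node_labels=labels,
        leadfield=gain,
        node_neighbors=_knn_adjacency(node_pos, k_neighbors),
    )


@dataclass
class SimConfig:
    """Amplitudes, noise and scale of a synthetic cohort.

    Source amplitudes are in arbitrary units relative to unit-variance
    sensor noise through unit-norm leadfield columns.  Defaults are chosen
    so a 20+-subject cohort reproduces the qualitative group effects
    (coherence / power peaks at the stimulation rates, omission cluster).
    """

    n_subjects: int = 20
    n_trials: int = 160
    n_blocks: int = 5
    sample_rate: float = 250.0
    entrain_amp: float = 0.6
    sustain_amp: float = 8.0
    omission_amp: float = 1.5
    word_evoked_amp: float = 0.0
    noise_exponent: float = 0.8
    sensor_noise_sd: float = 1.0
    phase_jitter_sd: float = 0.3  # trial-to-trial response alignment (rad)
    #: the sustained oscillation keeps the contour *rate*; its phase is
    #: redrawn uniformly per trial (an endogenous rhythm, not stimulus-locked),
    #: which leaves the phase-blind power analysis intact and keeps the
    #: oscillation out of trial-averaged evoked fields
    sustain_phase_uniform: bool = True
    #: ROI label sets carrying each planted effect
    entrain_rois: tuple = ENTRAIN_ROIS
    sustain_rois: tuple = SUSTAIN_ROIS
    omission_rois: tuple = OMISSION_ROIS
    iti_ms: float = 1000.0
    tail_ms: float = 1500.0
    lead_mode: str = "total"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("entrain_amp", "sustain_amp", "omission_amp", "word_evoked_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sample_rate <= 2 * 4.0:  # highest generated frequency < 4 Hz band edge
            raise ValueError("sample_rate must exceed twice the generated band")


@dataclass
class Recording:
    """One subject's continuous multichannel session."""

    data: np.ndarray                # (channels, samples) float32
    sample_rate: float
    trial_onsets_s: np.ndarray      # (n_trials,) trial-start times
    plan: list                      # list[TrialSchedule]
    channel_names: list

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Trials x channels x samples with per-trial metadata.

    Epochs of unequal nominal duration (e.g. SLOW vs FAST entrainment) are
    right-padded with zeros to a common array length; ``metadata.n_samples``
    records each trial's true length, which taper-based spectral estimation
    respects.  ``t0`` is the epoch start relative to its alignment event.
    """

    data: np.ndarray
    sample_rate: float
    t0: float
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.sample_rate

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            self.data[mask],
            self.sample_rate,
            self.t0,
            self.metadata.iloc[mask].reset_index(drop=True),
        )


@dataclass
class GroundTruth:
    """What was planted where, for parameter-recovery tests."""

    entrain_nodes: np.ndarray
    sustain_nodes: np.ndarray
    omission_nodes: np.ndarray
    word_nodes: np.ndarray
    condition_freq_hz: dict
    omission_trials: np.ndarray
    trial_shift_s: np.ndarray


# ---------------------------------------------------------------------------
# source waveform building blocks
# ---------------------------------------------------------------------------

def entrainment_kernel(
    condition: str,
    sample_rate: float = 250.0,
    lowpass_hz: float = 1.2,
) -> np.ndarray:
    """Cycle-locked source kernel: the contour's low-passed F0 modulation.

    One cycle of the interpolated repeated-contour F0 track, smoothed by a
    zero-phase first-order low-pass at ``lowpass_hz`` (the neural response
    follows the slow pitch modulation, not its fine structure), demeaned
    and scaled to unit RMS.  Being smooth but non-sinusoidal, its
    repetition puts energy at the cycle rate and its harmonics.
    """
    from scipy import signal as sp_signal

    track = stimuli.repeated_contour_track(condition, sample_rate)
    cycle_n = int(round(stimuli.cycle_duration_ms(condition) / 1000.0 * sample_rate))
    k = track.f0[:cycle_n] - track.f0[:cycle_n].mean()
    if lowpass_hz is not None:
        sos = sp_signal.butter(1, lowpass_hz / (sample_rate / 2.0), output="sos")
        # filter the periodically extended cycle to avoid edge transients
        ext = sp_signal.sosfiltfilt(sos, np.tile(k, 5))
        k = ext[2 * cycle_n : 3 * cycle_n]
        k = k - k.mean()
    return k / np.sqrt(np.mean(k**2))


def _kernel_fundamental_phase(kernel: np.ndarray) -> float:
    """Phase of the kernel's first harmonic at its first sample."""
    coef = np.fft.rfft(kernel)[1]
    return float(np.angle(coef))


def _hann_lobe(n: int) -> np.ndarray:
    return np.hanning(max(n, 3))


def one_over_f_noise(
    shape: tuple,
    sample_rate: float,
    exponent: float,
    rng: np.random.Generator,
    f_floor: float = 0.1,
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum (flat below
    ``f_floor`` to keep variance finite), unit variance per channel."""
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    n = shape[-1]
    n_fast = next_fast_len(n)  # pad to a friendly FFT length, then truncate
    freqs = rfftfreq(n_fast, 1.0 / sample_rate)
    shaping = 1.0 / np.maximum(freqs, f_floor) ** (exponent / 2.0)
    shaping[0] = 0.0
    white = rng.standard_normal(shape[:-1] + (n_fast,))
    spec = rfft(white, axis=-1) * shaping
    x = np.ascontiguousarray(irfft(spec, n=n_fast, axis=-1)[..., :n])
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


# ---------------------------------------------------------------------------
# session synthesis
# ---------------------------------------------------------------------------

def simulate_subject(
    config: SimConfig,
    plan: list,
    model: SensorModel,
    rng: np.random.Generator | int | None = None,
) -> tuple:
    """Synthesize one subject's continuous recording for a session plan.

    Returns ``(Recording, GroundTruth)``.  Trials are laid back to back
    with ``iti_ms`` of silence in between; all planted sources mix to the
    sensors through the leadfield before noise is added.
    """
    if not plan:
        raise ValueError("plan must be non-empty")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sr = config.sample_rate
    step_ms = 1000.0 / sr

    entrain_nodes = model.nodes_for_rois(config.entrain_rois)
    sustain_nodes = model.nodes_for_rois(config.sustain_rois)
    omission_nodes = model.nodes_for_rois(config.omission_rois)
    # visual word responses planted at the most posterior filler nodes
    fillers = np.flatnonzero(
        np.char.find(np.asarray(model.node_labels), "FIL") >= 0
    )
    word_nodes = fillers[np.argsort(model.node_pos[fillers, 1])[:4]]

    kernels = {c: entrainment_kernel(c, sr) for c in (SLOW, FAST)}
    kernel_phase = {c: _kernel_fundamental_phase(kernels[c]) for c in (SLOW, FAST)}

    trial_onsets = np.empty(len(plan))
    t = 0.0
    trial_len_samp = []
    for i, sched in enumerate(plan):
        trial_onsets[i] = t
        dur_s = (sched.duration_ms + config.tail_ms) / 1000.0
        trial_len_samp.append(int(round(dur_s * sr)))
        t += dur_s + config.iti_ms / 1000.0
    n_total = int(round(t * sr))

    data = np.zeros((model.n_sensors, n_total), dtype=np.float32)
    shifts = np.empty(len(plan))
    omission_trials = []

    for i, sched in enumerate(plan):
        cond = sched.contour_condition
        f_c = stimuli.cycle_rate_hz(cond)
        cycle_n = int(round(stimuli.cycle_duration_ms(cond) / 1000.0 * sr))
        kern = kernels[cond]
        n_trial = trial_len_samp[i]
        src = {}  # node set id -> waveform

        # per-trial phase jitter expressed as a time shift of the response
        jit = rng.normal(0.0, config.phase_jitter_sd)
        shift_s = jit / (2 * np.pi * f_c)
        shifts[i] = shift_s
        shift_n = int(round(shift_s * sr))

        trial_sig = np.zeros((model.n_nodes, n_trial), dtype=np.float64)
        onset0 = int(round(sched.entrainment_onset_ms / 1000.0 * sr))

        if config.entrain_amp > 0:
            ent = np.zeros(n_trial)
            for r in range(stimuli.N_REPETITIONS):
                a = onset0 + r * cycle_n + shift_n
                b = a + cycle_n
                lo, hi = max(a, 0), min(b, n_trial)
                if hi > lo:
                    ent[lo:hi] += kern[lo - a : hi - a]
            trial_sig[entrain_nodes] += config.entrain_amp * ent

        if config.sustain_amp > 0:
            s_on = int(round(sched.sentence_onset_ms / 1000.0 * sr))
            s_len = int(round(sched.sentence_length * stimuli.WORD_DURATION_MS / 1000.0 * sr))
            tt = (np.arange(s_len) + s_on) / sr
            t_ref = (onset0 + shift_n) / sr
            if config.sustain_phase_uniform:
                extra = rng.uniform(0.0, 2 * np.pi)
            else:
                # strict continuation of the entrainment kernel's fundamental
                extra = 0.0
            phase = 2 * np.pi * f_c * (tt - t_ref) + kernel_phase[cond] + extra
            sus = np.cos(phase)
            trial_sig[sustain_nodes, s_on : s_on + s_len] += config.sustain_amp * sus

        if (
            config.omission_amp > 0
            and sched.sentence_length == SHORT
            and cond == SLOW
        ):
            omission_trials.append(i)
            o_on = int(round(sched.omission_point_ms / 1000.0 * sr))
            resp = np.zeros(n_trial)
            early_n = int(round(0.12 * sr))           # lobe peaking ~60 ms
            late_a = int(round(0.25 * sr))            # lobe 250-550 ms, peak ~400
            late_n = int(round(0.30 * sr))
            b = min(o_on + early_n, n_trial)
            resp[o_on:b] += _hann_lobe(early_n)[: b - o_on]
            a2 = o_on + late_a
            b2 = min(a2 + late_n, n_trial)
            resp[a2:b2] -= 1.2 * _hann_lobe(late_n)[: b2 - a2]
            trial_sig[omission_nodes] += config.omission_amp * resp

        if config.word_evoked_amp > 0:
            wk_n = int(round(0.10 * sr))
            wk = _hann_lobe(wk_n)
            wresp = np.zeros(n_trial)
            for w_ms in sched.word_onsets_ms:
                a = int(round(w_ms / 1000.0 * sr))
                b = min(a + wk_n, n_trial)
                wresp[a:b] += wk[: b - a]
            trial_sig[word_nodes] += config.word_evoked_amp * wresp

        active = np.flatnonzero(np.any(trial_sig != 0, axis=1))
        if active.size:
            a = int(round(trial_onsets[i] * sr))
            data[:, a : a + n_trial] += (
                model.leadfield[:, active] @ trial_sig[active]
            ).astype(np.float32)

    if config.sensor_noise_sd > 0:
        pink = one_over_f_noise(
            (model.n_sensors, n_total), sr, config.noise_exponent, rng
        )
        white = rng.standard_normal((model.n_sensors, n_total))
        data += (config.sensor_noise_sd * (0.8 * pink + 0.6 * white)).astype(
            np.float32
        )

    rec = Recording(data, sr, trial_onsets, plan, model.channel_names)
    truth = GroundTruth(
        entrain_nodes=entrain_nodes,
        sustain_nodes=sustain_nodes,
        omission_nodes=omission_nodes,
        word_nodes=word_nodes,
        condition_freq_hz={SLOW: stimuli.cycle_rate_hz(SLOW), FAST: stimuli.cycle_rate_hz(FAST)},
        omission_trials=np.array(omission_trials, dtype=int),
        trial_shift_s=shifts,
    )
    return rec, truth


def subject_seeds(master_seed: int, n_subjects: int) -> list:
    """Independent per-subject generators derived from one master seed."""
    return [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(master_seed).spawn(n_subjects)
    ]


def simulate_cohort(
    config: SimConfig,
    model: SensorModel | None = None,
) -> list:
    """Simulate ``config.n_subjects`` subjects with a shared design.

    Every subject receives the same session-plan structure (fresh
    randomization per subject) and an independent noise stream; returns a
    list of ``(Recording, GroundTruth)`` pairs.
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    model = model or build_sensor_model(seed=config.seed)
    out = []
    for s, rng in enumerate(subject_seeds(config.seed, config.n_subjects)):
        plan = generate_plan_for(config, subject=s)
        out.append(simulate_subject(config, plan, model, rng))
    return out


def generate_plan_for(config: SimConfig, subject: int = 0) -> list:
    """Deterministic per-subject session plan under the master seed."""
    return stimuli.generate_session_plan(
        config.n_trials,
        config.n_blocks,
        seed=int(np.random.SeedSequence([config.seed, 7919 + subject]).generate_state(1)[0] % (2**31)),
        sample_rate=config.sample_rate,
        lead_mode=config.lead_mode,
    )


# ---------------------------------------------------------------------------
# array-container I/O (.npz + JSON sidecar)
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path) -> None:
    """Store a recording as ``.npz`` with a JSON sidecar and events TSV."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(
        path,
        data=rec.data,
        trial_onsets_s=rec.trial_onsets_s,
    )
    sidecar = {
        "sample_rate": rec.sample_rate,
        "channel_names": rec.channel_names,
        "n_trials": len(rec.plan),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    stimuli.schedules_to_events_tsv(rec.plan, path.with_suffix(".events.tsv"))


def load_recording(path) -> Recording:  # pragma: no cover - thin I/O
    import json
    from pathlib import Path

    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    events = pd.read_csv(path.with_suffix(".events.tsv"), sep="\t")
    plan = []
    for trial, g in events.groupby("trial"):
        sched = stimuli.TrialSchedule(
            g["condition"].iloc[0],
            int(g["sentence_length"].iloc[0]),
            [(r.trial_type, r.onset * 1000.0) for r in g.itertuples()],
            block=int(g["block"].iloc[0]),
        )
        plan.append(sched)
    return Recording(
        arrays["data"],
        float(sidecar["sample_rate"]),
        arrays["trial_onsets_s"],
        plan,
        list(sidecar["channel_names"]),
    )
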