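"""Delexicalized prosodic contour synthesis and trial-timeline construction.

The paradigm exposes listeners to a repetitive pitch contour (the
*entrainment phase*) and then presents a visual sentence word by word (the
*target phase*).  Two contour conditions exist: SLOW contours last 1,570 ms
and FAST contours 942 ms, each repeated three times with 160 ms pauses, so
the cycle rates are ~0.6 Hz (SLOW) and ~0.9 Hz (FAST).  Sentences are SHORT
(5 words) or LONG (6 words) at a fixed 314 ms word rate, so a SHORT sentence
matches one SLOW contour in duration minus one word -- the missing sixth
word position is the *omission point*.

Contours are rendered with the PURR rule: a sine at the fundamental
frequency plus the second harmonic at 1/4 and the third at 1/16 of the
amplitude, so only pitch dynamics survive delexicalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.io import wavfile

__all__ = [
    "PitchTrack",
    "ContourSpec",
    "TrialSchedule",
    "SLOW",
    "FAST",
    "SHORT",
    "LONG",
    "WORD_DURATION_MS",
    "PAUSE_MS",
    "contour_spec",
    "cycle_duration_ms",
    "cycle_rate_hz",
    "entrainment_duration_ms",
    "lead_pause_ms",
    "synthesize_purr",
    "interpolate_f0_gaps",
    "synthetic_contour_pitch",
    "repeated_contour_track",
    "make_trial_schedule",
    "generate_session_plan",
    "read_f0_tsv",
    "write_f0_tsv",
    "write_wav",
    "schedules_to_events_tsv",
]

SLOW = "SLOW"
FAST = "FAST"
SHORT = 5
LONG = 6

#: contour durations in ms, matched to the average spoken-sentence durations
CONTOUR_MS = {SLOW: 1570.0, FAST: 942.0}
PAUSE_MS = 160.0
N_REPETITIONS = 3
WORD_DURATION_MS = 314.0
PITCH_SHIFT_HZ = -55.0
HARMONIC_AMPLITUDES = (1.0, 0.25, 0.0625)

#: synthetic F0 statistics of the source recordings (Hz)
F0_MIN = 116.0
F0_MAX = 267.0
F0_MEAN = 191.5


class InvalidPitchError(ValueError):
    """F0 non-positive where a voiced value is required."""


class AliasingError(ValueError):
    """Sample rate too low for the requested harmonics."""


class InsufficientDataError(ValueError):
    """Too few voiced samples to interpolate."""


@dataclass
class PitchTrack:
    """A sampled F0 trajectory with a voicing mask.

    ``times`` must be strictly increasing; ``f0`` must be positive wherever
    ``voiced`` is true.  Unvoiced samples (pauses) carry no meaningful f0
    until :func:`interpolate_f0_gaps` fills them.
    """

    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.voiced is None:
            self.voiced = np.isfinite(self.f0) & (self.f0 > 0)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if self.times.ndim != 1 or self.times.shape != self.f0.shape:
            raise ValueError("times and f0 must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.voiced & ~(self.f0 > 0)):
            raise InvalidPitchError("voiced samples must have f0 > 0")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Track duration in seconds (0 for empty tracks)."""
        if self.times.size == 0:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def shifted(self, delta_hz: float) -> "PitchTrack":
        """Return a copy with ``delta_hz`` added to the voiced F0 values."""
        f0 = self.f0 + delta_hz
        if np.any(self.voiced & ~(f0 > 0)):
            raise InvalidPitchError("pitch shift would make voiced f0 non-positive")
        return PitchTrack(self.times.copy(), f0, self.voiced.copy())


@dataclass(frozen=True)
class ContourSpec:
    """Timing and synthesis parameters of one contour condition."""

    condition: str
    contour_duration_ms: float
    pause_duration_ms: float = PAUSE_MS
    n_repetitions: int = N_REPETITIONS
    pitch_shift_hz: float = PITCH_SHIFT_HZ
    harmonic_amplitudes: tuple = HARMONIC_AMPLITUDES

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    @property
    def cycle_duration_ms(self) -> float:
        return self.contour_duration_ms + self.pause_duration_ms

    @property
    def cycle_rate_hz(self) -> float:
        return 1000.0 / self.cycle_duration_ms

    @property
    def entrainment_duration_ms(self) -> float:
        return self.n_repetitions * self.cycle_duration_ms


def contour_spec(condition: str) -> ContourSpec:
    if condition not in CONTOUR_MS:
        raise ValueError(f"unknown contour condition {condition!r}")
    return ContourSpec(condition, CONTOUR_MS[condition])


def cycle_duration_ms(condition: str) -> float:
    """One contour plus its trailing pause: 1,730 ms SLOW, 1,102 ms FAST."""
    return contour_spec(condition).cycle_duration_ms


def cycle_rate_hz(condition: str) -> float:
    """Stimulation rate: ~0.578 Hz SLOW, ~0.907 Hz FAST (printed 0.6 / 0.9)."""
    return contour_spec(condition).cycle_rate_hz


def entrainment_duration_ms(condition: str) -> float:
    """Three cycles: 5,190 ms SLOW, 3,306 ms FAST."""
    return contour_spec(condition).entrainment_duration_ms


def lead_pause_ms(condition: str, mode: str = "total") -> float:
    """Silent lead-in before FAST entrainment equalizing condition durations.

    ``mode='total'`` (default) pads by the total three-cycle difference
    (1,884 ms) so the entrainment phases of both conditions last 5,190 ms;
    ``mode='per_repetition'`` pads by the single-cycle difference (628 ms).
    """
    if condition == SLOW:
        return 0.0
    diff = entrainment_duration_ms(SLOW) - entrainment_duration_ms(FAST)
    if mode == "total":
        return diff
    if mode == "per_repetition":
        return diff / N_REPETITIONS
    raise ValueError(f"unknown lead-pause mode {mode!r}")


# ---------------------------------------------------------------------------
# F0 handling and PURR synthesis
# ---------------------------------------------------------------------------

def interpolate_f0_gaps(pitch: PitchTrack) -> PitchTrack:
    """Fill unvoiced gaps (pauses) with a cubic spline through voiced samples.

    Voiced samples are returned unchanged.  Requires at least two voiced
    samples; a fully voiced track is returned as-is.
    """
    voiced = pitch.voiced
    if int(voiced.sum()) < 2:
        raise InsufficientDataError("need >= 2 voiced samples to interpolate")
    if voiced.all():
        return pitch
    spline = CubicSpline(pitch.times[voiced], pitch.f0[voiced])
    f0 = pitch.f0.copy()
    f0[~voiced] = spline(pitch.times[~voiced])
    if np.any(f0 <= 0):
        raise InvalidPitchError("interpolation produced non-positive f0")
    return PitchTrack(pitch.times.copy(), f0, np.ones_like(voiced))


def synthesize_purr(
    pitch: PitchTrack,
    sample_rate: float,
    amplitude: float = 0.5,
) -> np.ndarray:
    """Render an F0 track as a PURR waveform.

    The signal is ``A * [sin(phi) + 1/4 sin(2 phi) + 1/16 sin(3 phi)]`` with
    the phase ``phi(t) = 2 pi * integral_0^t f0`` accumulated over the track,
    so pitch glides remain phase-continuous.  ``amplitude`` is the peak
    amplitude of the fundamental (peak normalization; no absolute SPL
    calibration exists in software).

    The track must be fully voiced (interpolate gaps first) and
    ``sample_rate`` must be at least four times the maximum f0 so the third
    harmonic stays below Nyquist with headroom.
    """
    if len(pitch) == 0:
        return np.zeros(0)
    if not pitch.voiced.all() or np.any(pitch.f0 <= 0):
        raise InvalidPitchError("track must be fully voiced with positive f0")
    if sample_rate < 4.0 * float(pitch.f0.max()):
        raise AliasingError(
            f"sample rate {sample_rate} Hz < 4 x max f0 {pitch.f0.max():.1f} Hz"
        )
    n = int(round(pitch.duration * sample_rate))
    t = pitch.times[0] + np.arange(n) / sample_rate
    f0 = np.interp(t, pitch.times, pitch.f0)
    phase = 2.0 * np.pi * cumulative_trapezoid(f0, t, initial=0.0)
    a1, a2, a3 = HARMONIC_AMPLITUDES
    return amplitude * (
        a1 * np.sin(phase) + a2 * np.sin(2 * phase) + a3 * np.sin(3 * phase)
    )


def synthetic_contour_pitch(
    condition: str,
    sample_rate: float = 250.0,
    rng: np.random.Generator | None = None,
    wobble_hz: float = 0.0,
) -> PitchTrack:
    """Stylized two-accent F0 contour for one contour repetition.

    A main accent gaussian (peak a third of the way in) and a smaller late
    accent span the configured F0 range 116--267 Hz, giving a smooth,
    clearly non-sinusoidal trajectory whose repetition at the cycle rate
    carries energy at the rate and its harmonics.  ``wobble_hz`` adds seeded
    low-frequency jitter for non-identical tokens.
    """
    dur = CONTOUR_MS[condition] / 1000.0 if condition in CONTOUR_MS else float(condition)
    n = int(round(dur * sample_rate))
    t = np.arange(n) / sample_rate
    bump = np.exp(-0.5 * ((t - 0.33 * dur) / (0.16 * dur)) ** 2)
    bump = bump + 0.7 * np.exp(-0.5 * ((t - 0.70 * dur) / (0.09 * dur)) ** 2)
    f0 = F0_MIN + (F0_MAX - F0_MIN) * bump / bump.max()
    if wobble_hz > 0:
        rng = np.random.default_rng() if rng is None else rng
        slow = rng.standard_normal(4)
        for k, c in enumerate(slow, start=1):
            f0 = f0 + wobble_hz * c * np.sin(2 * np.pi * k * t / dur + k)
    return PitchTrack(t, f0, np.ones(n, dtype=bool))


def repeated_contour_track(
    condition: str,
    sample_rate: float = 250.0,
    interpolate: bool = True,
) -> PitchTrack:
    """F0 track of the full entrainment phase: 3 x (contour + 160 ms pause).

    Pause samples are unvoiced; with ``interpolate`` (default) they are
    spline-filled, yielding the reference signal used for pitch--MEG
    coherence.
    """
    spec = contour_spec(condition)
    one = synthetic_contour_pitch(condition, sample_rate)
    cycle_n = int(round(spec.cycle_duration_ms / 1000.0 * sample_rate))
    contour_n = len(one)
    total_n = spec.n_repetitions * cycle_n
    f0 = np.full(total_n, np.nan)
    voiced = np.zeros(total_n, dtype=bool)
    for r in range(spec.n_repetitions):
        sl = slice(r * cycle_n, r * cycle_n + contour_n)
        f0[sl] = one.f0
        voiced[sl] = True
    track = PitchTrack(np.arange(total_n) / sample_rate, f0, voiced)
    return interpolate_f0_gaps(track) if interpolate else track


# ---------------------------------------------------------------------------
# Trial schedules and session plans
# ---------------------------------------------------------------------------

#: delay between sentence offset and (potential) question onset
DELAY_BASE_MS = 500.0
DELAY_JITTER_MAX_MS = 250.0


@dataclass
class TrialSchedule:
    """Event timeline of one trial, onsets in ms from trial start."""

    contour_condition: str
    sentence_length: int
    events: list = field(default_factory=list)  # (label, onset_ms)
    jitter_ms: float = 0.0
    block: int = 0

    def onset(self, label: str) -> float:
        for lab, t in self.events:
            if lab == label:
                return t
        raise KeyError(f"no event {label!r} in schedule")

    @property
    def entrainment_onset_ms(self) -> float:
        """First contour onset (after the FAST lead-in pause, if any)."""
        return self.onset("cycle_onset")

    @property
    def sentence_onset_ms(self) -> float:
        return self.onset("sentence_onset")

    @property
    def omission_point_ms(self) -> float:
        """Theoretical onset of the never-presented 6th word (SHORT only)."""
        return self.onset("omission_point")

    @property
    def word_onsets_ms(self) -> list:
        return [t for lab, t in self.events if lab == "word_onset"]

    @property
    def duration_ms(self) -> float:
        return self.events[-1][1]

    @property
    def cell(self) -> tuple:
        return (self.contour_condition, self.sentence_length)


def make_trial_schedule(
    contour_condition: str,
    sentence_length: int,
    jitter_seed: int | np.random.Generator | None = None,
    sample_rate: float = 250.0,
    lead_mode: str = "total",
    block: int = 0,
) -> TrialSchedule:
    """Lay out one trial: [lead pause] -> 3 x (contour, pause) -> RSVP words
    -> jittered delay -> question slot.

    The FAST condition is preceded by a silent lead-in pause so the
    entrainment phase lasts 5,190 ms in both conditions.  Words run at
    314 ms; SHORT sentences leave the sixth word slot empty (the omission
    point, 1,570 ms after sentence onset).  The 500 + U(0, 250) ms delay is
    quantized to the sample grid.
    """
    if sentence_length not in (SHORT, LONG):
        raise ValueError("sentence_length must be 5 (SHORT) or 6 (LONG)")
    spec = contour_spec(contour_condition)
    rng = (
        jitter_seed
        if isinstance(jitter_seed, np.random.Generator)
        else np.random.default_rng(jitter_seed)
    )
    step = 1000.0 / sample_rate
    jitter = np.floor(rng.uniform(0.0, DELAY_JITTER_MAX_MS) / step) * step

    events: list = []
    t = 0.0
    lead = lead_pause_ms(contour_condition, lead_mode)
    if lead > 0:
        events.append(("lead_pause", t))
        t += lead
    for _ in range(spec.n_repetitions):
        events.append(("cycle_onset", t))
        t += spec.contour_duration_ms
        events.append(("cycle_offset", t))
        events.append(("pause", t))
        t += spec.pause_duration_ms
    events.append(("sentence_onset", t))
    sentence_onset = t
    for w in range(sentence_length):
        events.append(("word_onset", sentence_onset + w * WORD_DURATION_MS))
    t = sentence_onset + sentence_length * WORD_DURATION_MS
    if sentence_length == SHORT:
        events.append(("omission_point", sentence_onset + SHORT * WORD_DURATION_MS))
    events.append(("delay", t))
    t += DELAY_BASE_MS + jitter
    events.append(("question_onset", t))
    return TrialSchedule(contour_condition, sentence_length, events, jitter, block)


CELLS = [(SLOW, SHORT), (SLOW, LONG), (FAST, SHORT), (FAST, LONG)]


def generate_session_plan(
    n_trials: int = 300,
    n_blocks: int = 5,
    seed: int | None = 0,
    sample_rate: float = 250.0,
    lead_mode: str = "total",
) -> list:
    """Balanced, adjacency-constrained session of trial schedules.

    Equal counts of the four condition cells, with no identical cell on
    adjacent trials; deterministic under ``seed``.
    """
    if n_trials % 4 != 0:
        raise ValueError("n_trials must be divisible by 4 for balanced cells")
    rng = np.random.default_rng(seed)
    per_cell = n_trials // 4
    for _attempt in range(1000):
        remaining = dict.fromkeys(range(4), per_cell)
        order: list = []
        ok = True
        for _ in range(n_trials):
            choices = [c for c, n in remaining.items() if n > 0]
            if order:
                choices = [c for c in choices if c != order[-1]] or []
            if not choices:
                ok = False
                break
            weights = np.array([remaining[c] for c in choices], dtype=float)
            pick = int(rng.choice(choices, p=weights / weights.sum()))
            order.append(pick)
            remaining[pick] -= 1
        if ok:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not satisfy adjacency constraint")
    block_size = max(1, n_trials // n_blocks)
    plan = []
    for i, c in enumerate(order):
        cond, slen = CELLS[c]
        plan.append(
            make_trial_schedule(
                cond, slen, rng, sample_rate, lead_mode, block=i // block_size
            )
        )
    return plan


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------

def read_f0_tsv(path) -> PitchTrack:
    """Read a 2-column TSV (time_s, f0_hz); empty/NaN f0 marks unvoiced."""
    df = pd.read_csv(path, sep="\t", header=0)
    t = df.iloc[:, 0].to_numpy(float)
    f0 = df.iloc[:, 1].to_numpy(float)
    voiced = np.isfinite(f0) & (f0 > 0)
    f0 = np.where(voiced, f0, np.nan)
    return PitchTrack(t, f0, voiced)


def write_f0_tsv(pitch: PitchTrack, path) -> None:
    f0 = np.where(pitch.voiced, pitch.f0, np.nan)
    pd.DataFrame({"time_s": pitch.times, "f0_hz": f0}).to_csv(
        path, sep="\t", index=False
    )


def write_wav(waveform: np.ndarray, path, sample_rate: int = 22050) -> None:
    """Write a mono 16-bit PCM WAV, peak-scaled to 90% full range."""
    peak = float(np.max(np.abs(waveform))) if waveform.size else 1.0
    scale = 0.9 * 32767 / peak if peak > 0 else 1.0
    wavfile.write(path, int(sample_rate), (waveform * scale).astype(np.int16))


def schedules_to_events_tsv(plan, path=None) -> pd.DataFrame:
    """Export schedules as a BIDS-events-style table (one row per event)."""
    rows = []
    for i, sched in enumerate(plan):
        for lab, onset in sched.events:
            rows.append(
                {
                    "trial": i,
                    "onset": onset / 1000.0,
                    "duration": 0.0,
                    "trial_type": lab,
                    "condition": sched.contour_condition,
                    "sentence_length": sched.sentence_length,
                    "block": sched.block,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
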