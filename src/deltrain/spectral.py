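"""Epoch extraction and frequency-domain estimation.

All sensor-space spectral quantities live on a fixed 0--3 Hz grid with
0.1 Hz spacing (31 bins), obtained by Hann-tapering each epoch over its
data length and zero-padding to 10 s before the DFT.  With a 250 Hz
sampling rate and 10 s padding the stimulation rates 0.6, 0.9 and the
1.2 Hz harmonic fall exactly on DFT bins, so no off-grid interpolation is
ever needed.

Coherence between the interpolated F0 reference and every sensor is
magnitude-squared coherence pooled across trials,

    C(f) = |sum_k X_k(f) conj(Y_k(f))|^2
           / (sum_k |X_k(f)|^2 * sum_k |Y_k(f)|^2),

whose expectation for independent signals is ~1/K for K trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stimuli
from .simulate import EpochSet, Recording
from .stimuli import FAST, SHORT, SLOW

__all__ = [
    "SpectralGrid",
    "CoherenceSpectrum",
    "PowerSpectrum",
    "extract_epochs",
    "epoch_duration_s",
    "spectrum_hann_padded",
    "reference_epochs",
    "coherence_spectrum",
    "power_spectrum",
    "peak_frequency",
    "spectra_to_tsv",
]

ERF_PRE_S = 0.25
ERF_POST_S = 1.0


@dataclass(frozen=True)
class SpectralGrid:
    """Frequency grid of the padded DFT.

    The analysis band is 0--3 Hz at 0.1 Hz resolution; ``pad_duration`` is
    10 s for sensor analyses and 20 s for the source-space CSD.
    """

    pad_duration: float = 10.0
    band: tuple = (0.0, 3.0)
    resolution: float = 0.1

    def __post_init__(self) -> None:
        steps = self.resolution * self.pad_duration
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError(
                "grid resolution must be an integer multiple of 1/pad_duration"
            )

    @property
    def frequencies(self) -> np.ndarray:
        n = int(round((self.band[1] - self.band[0]) / self.resolution)) + 1
        return self.band[0] + self.resolution * np.arange(n)

    @property
    def n_bins(self) -> int:
        return self.frequencies.size

    def n_fft(self, sample_rate: float) -> int:
        return int(round(self.pad_duration * sample_rate))

    def bin_indices(self, sample_rate: float) -> np.ndarray:
        idx = self.frequencies * self.pad_duration
        out = np.round(idx).astype(int)
        if not np.allclose(idx, out, atol=1e-9):
            raise ValueError("grid frequencies not representable at padded resolution")
        return out

    def bin_of(self, f: float) -> int:
        k = (f - self.band[0]) / self.resolution
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"{f} Hz is off the {self.resolution} Hz grid")
        return int(round(k))


@dataclass
class PowerSpectrum:
    """Trial-averaged power per channel on the grid."""

    values: np.ndarray          # (channels, bins), >= 0
    frequencies: np.ndarray
    n_trials: int

    def channel_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class CoherenceSpectrum(PowerSpectrum):
    """Pitch--MEG coherence per channel on the grid; values in [0, 1]."""


def epoch_duration_s(condition: str, phase: str) -> float:
    """Nominal epoch duration for a condition and analysis phase.

    Entrainment epochs span the three contour cycles from contour onset
    (5.19 s SLOW, 3.306 s FAST); target epochs span one cycle from sentence
    onset (1.73 s SLOW, 1.102 s FAST); ERF epochs span -250 ms to +1 s
    around the omission point.
    """
    if phase == "entrainment":
        return stimuli.entrainment_duration_ms(condition) / 1000.0
    if phase == "target":
        return stimuli.cycle_duration_ms(condition) / 1000.0
    if phase == "erf":
        return ERF_PRE_S + ERF_POST_S
    raise ValueError(f"unknown phase {phase!r}")


class EpochBoundsError(IndexError):
    pass


def extract_epochs(
    recording: Recording,
    plan: list | None = None,
    phase: str = "entrainment",
    condition: str | None = None,
    demean: bool = True,
) -> EpochSet:
    """Cut phase-specific epochs out of a continuous recording.

    Entrainment epochs start at contour onset; target epochs at sentence
    onset; ERF epochs at the omission point minus 250 ms (SHORT trials
    only).  Sample counts are floored to the grid (5.19 s at 250 Hz ->
    1,297 samples).  Epochs of unequal duration are right-padded to a
    common array length, recorded per trial in ``metadata.n_samples``.
    With ``demean`` each epoch is demeaned over its data length.
    """
    plan = recording.plan if plan is None else plan
    sr = recording.sample_rate
    rows, chunks = [], []
    t0 = -ERF_PRE_S if phase == "erf" else 0.0
    for i, sched in enumerate(plan):
        if condition is not None and sched.contour_condition != condition:
            continue
        if phase == "erf" and sched.sentence_length != SHORT:
            continue
        if phase == "entrainment":
            align_ms = sched.entrainment_onset_ms
        elif phase == "target":
            align_ms = sched.sentence_onset_ms
        elif phase == "erf":
            align_ms = sched.omission_point_ms - ERF_PRE_S * 1000.0
        else:
            raise ValueError(f"unknown phase {phase!r}")
        n_samp = int(np.floor(epoch_duration_s(sched.contour_condition, phase) * sr))
        start = int(round((recording.trial_onsets_s[i] + align_ms / 1000.0) * sr))
        if start < 0 or start + n_samp > recording.n_samples:
            raise EpochBoundsError(f"epoch for trial {i} exceeds recording bounds")
        seg = np.asarray(recording.data[:, start : start + n_samp], dtype=float)
        if demean:
            seg = seg - seg.mean(axis=1, keepdims=True)
        chunks.append(seg)
        rows.append(
            {
                "trial": i,
                "contour_condition": sched.contour_condition,
                "sentence_length": sched.sentence_length,
                "phase": phase,
                "n_samples": n_samp,
                "block": sched.block,
            }
        )
    meta = pd.DataFrame(
        rows,
        columns=[
            "trial", "contour_condition", "sentence_length",
            "phase", "n_samples", "block",
        ],
    )
    if not rows:
        n_ch = recording.data.shape[0]
        return EpochSet(np.zeros((0, n_ch, 0)), sr, t0, meta)
    max_n = max(r["n_samples"] for r in rows)
    data = np.zeros((len(chunks), chunks[0].shape[0], max_n))
    for k, seg in enumerate(chunks):
        data[k, :, : seg.shape[1]] = seg
    return EpochSet(data, sr, t0, meta)


def _taper_pad_fft(
    data: np.ndarray,
    n_samples: np.ndarray,
    n_fft: int,
    bins: np.ndarray,
) -> np.ndarray:
    """Hann-taper each trial over its true length, pad, DFT at grid bins."""
    out = np.empty(data.shape[:-1] + (bins.size,), dtype=complex)
    for n in np.unique(n_samples):
        if n > n_fft:
            raise ValueError(f"epoch length {n} exceeds pad length {n_fft}")
        sel = n_samples == n
        taper = np.hanning(int(n))
        tapered = data[sel][..., : int(n)] * taper
        spec = np.fft.rfft(tapered, n=n_fft, axis=-1)
        out[sel] = spec[..., bins]
    return out


def spectrum_hann_padded(
    epochs: EpochSet,
    grid: SpectralGrid = SpectralGrid(),
) -> np.ndarray:
    """Complex Fourier coefficients per trial x channel x grid bin."""
    if epochs.n_trials == 0:
        return np.zeros((0, epochs.n_channels, grid.n_bins), dtype=complex)
    n_fft = grid.n_fft(epochs.sample_rate)
    bins = grid.bin_indices(epochs.sample_rate)
    n_samples = epochs.metadata["n_samples"].to_numpy()
    return _taper_pad_fft(epochs.data, n_samples, n_fft, bins)


def reference_epochs(epochs: EpochSet, demean: bool = True) -> EpochSet:
    """Build matching F0-reference epochs for pitch--MEG coherence.

    The reference is the interpolated repeated-contour F0 track of each
    trial's condition, resampled to the MEG rate, truncated to the epoch
    length and demeaned per epoch, replicated as a single 'channel'.
    """
    tracks = {
        c: stimuli.repeated_contour_track(c, epochs.sample_rate).f0
        for c in (SLOW, FAST)
    }
    data = np.zeros((epochs.n_trials, 1, epochs.data.shape[2]))
    for k in range(epochs.n_trials):
        cond = epochs.metadata["contour_condition"].iloc[k]
        n = int(epochs.metadata["n_samples"].iloc[k])
        ref = tracks[cond][:n].astype(float).copy()
        if ref.size < n:  # pad rare off-by-one with the last value
            ref = np.pad(ref, (0, n - ref.size), mode="edge")
        if demean:
            ref -= ref.mean()
        data[k, 0, :n] = ref
    return EpochSet(data, epochs.sample_rate, epochs.t0, epochs.metadata.copy())


class UndefinedCoherenceError(ValueError):
    pass


def coherence_spectrum(
    ref_epochs: EpochSet,
    meg_epochs: EpochSet,
    grid: SpectralGrid = SpectralGrid(),
) -> CoherenceSpectrum:
    """Magnitude-squared pitch--MEG coherence across trials, per channel."""
    if meg_epochs.n_trials < 2:
        raise UndefinedCoherenceError("coherence needs at least 2 trials")
    if ref_epochs.n_trials != meg_epochs.n_trials:
        raise ValueError("reference and MEG trial counts differ")
    if ref_epochs.data.shape[2] != meg_epochs.data.shape[2]:
        raise ValueError("reference and MEG epoch lengths differ")
    X = spectrum_hann_padded(ref_epochs, grid)[:, 0, :]      # (K, bins)
    Y = spectrum_hann_padded(meg_epochs, grid)               # (K, C, bins)
    cross = np.einsum("kb,kcb->cb", X, np.conj(Y))
    sx = np.sum(np.abs(X) ** 2, axis=0)                      # (bins,)
    sy = np.sum(np.abs(Y) ** 2, axis=0)                      # (C, bins)
    denom = sx[None, :] * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(cross) ** 2 / denom
    coh = np.where(denom > 0, coh, 0.0)
    return CoherenceSpectrum(coh, grid.frequencies, meg_epochs.n_trials)


def power_spectrum(
    meg_epochs: EpochSet,
    grid: SpectralGrid = SpectralGrid(),
) -> PowerSpectrum:
    """Squared DFT magnitude averaged over trials, per channel and bin."""
    if meg_epochs.n_trials < 1:
        raise ValueError("power spectrum needs at least 1 trial")
    Y = spectrum_hann_padded(meg_epochs, grid)
    return PowerSpectrum(
        np.mean(np.abs(Y) ** 2, axis=0), grid.frequencies, meg_epochs.n_trials
    )


def peak_frequency(
    spectrum: PowerSpectrum | np.ndarray,
    band: tuple = (0.0, 3.0),
    frequencies: np.ndarray | None = None,
) -> float:
    """Frequency of the maximal channel-averaged value within ``band``.

    Ties break toward the lower frequency (argmax of the first maximum).
    """
    if isinstance(spectrum, PowerSpectrum):
        values = spectrum.channel_mean()
        frequencies = spectrum.frequencies
    else:
        values = np.asarray(spectrum)
        if values.ndim == 2:
            values = values.mean(axis=0)
        if frequencies is None:
            raise ValueError("frequencies required for raw arrays")
    mask = (frequencies >= band[0] - 1e-9) & (frequencies <= band[1] + 1e-9)
    if not mask.any():
        raise ValueError("band contains no grid frequencies")
    sub = values[mask]
    return float(frequencies[mask][int(np.argmax(sub))])


def spectra_to_tsv(
    spectra: dict,
    channel_names: list,
    path=None,
) -> pd.DataFrame:
    """Long-format export: subject, condition, channel, frequency, value."""
    rows = []
    for (subject, condition), spec in spectra.items():
        for c, name in enumerate(channel_names):
            for f, v in zip(spec.frequencies, spec.values[c]):
                rows.append(
                    {
                        "subject": subject,
                        "condition": condition,
                        "channel": name,
                        "frequency": f,
                        "value": v,
                    }
                )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
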