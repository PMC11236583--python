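"""Omission evoked-response analysis.

When a SHORT (5-word) sentence follows a SLOW contour, the contour's
duration predicts a sixth word that never appears; the epoch around that
theoretical verb onset (-250 ms to +1,000 ms) should carry an evoked
deflection absent after FAST contours.  Only SHORT trials enter the
analysis -- the physical stimulation at the omission point is identical
across prosodic conditions, so any SLOW-vs-FAST difference reflects the
prior context.

Condition contrasts use window-averaged channel amplitudes (a-priori
windows 300--600 ms and 0--120 ms) passed to the cluster-based sign-flip
permutation test.  Cluster polarity is reported but not interpreted as
effect direction (MEG field polarity depends on source orientation);
direction is read off the condition-mean amplitudes over the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import spectral, stats
from .simulate import EpochSet, Recording
from .stimuli import FAST, SHORT, SLOW

__all__ = [
    "ERFSet",
    "omission_epochs",
    "condition_erf",
    "window_contrast",
    "erf_snr",
    "group_window_contrast",
    "erfs_to_tsv",
]

BASELINE_S = (-0.25, 0.0)
LATE_WINDOW_MS = (300.0, 600.0)
EARLY_WINDOW_MS = (0.0, 120.0)


@dataclass
class ERFSet:
    """Per-condition trial-average ERFs of one subject.

    ``averages`` maps condition -> channels x samples on the common
    [-250, 1000] ms axis; baseline-corrected so the pre-onset mean is ~0.
    """

    averages: dict
    times: np.ndarray
    n_trials: dict

    def window_mean(self, window_ms: tuple) -> dict:
        lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
        mask = (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)
        if not mask.any():
            raise ValueError("window outside the epoch")
        return {c: a[:, mask].mean(axis=1) for c, a in self.averages.items()}


def omission_epochs(recording: Recording, plan: list | None = None) -> EpochSet:
    """SHORT-trial epochs aligned to the omission point, baseline-corrected.

    Epochs span -250 ms to +1,000 ms around the theoretical onset of the
    missing verb and are demeaned by the 250 ms pre-onset interval.
    """
    epochs = spectral.extract_epochs(recording, plan, phase="erf", demean=False)
    if epochs.n_trials == 0:
        raise ValueError("plan contains no SHORT trials")
    times = epochs.times
    base = (times >= BASELINE_S[0] - 1e-9) & (times <= BASELINE_S[1] + 1e-9)
    data = epochs.data - epochs.data[:, :, base].mean(axis=2, keepdims=True)
    return EpochSet(data, epochs.sample_rate, epochs.t0, epochs.metadata)


def condition_erf(epochs: EpochSet) -> ERFSet:
    """Trial-average ERF per prosodic condition for one subject."""
    averages, counts = {}, {}
    for cond in (SLOW, FAST):
        mask = (epochs.metadata["contour_condition"] == cond).to_numpy()
        if not mask.any():
            raise ValueError(f"no epochs in condition {cond}")
        averages[cond] = epochs.data[mask].mean(axis=0)
        counts[cond] = int(mask.sum())
    return ERFSet(averages, epochs.times, counts)


def group_window_contrast(
    erfs: list,
    window_ms: tuple,
) -> tuple:
    """Stack subject window-mean amplitudes into (slow, fast) arrays."""
    slow, fast = [], []
    for e in erfs:
        wm = e.window_mean(window_ms)
        slow.append(wm[SLOW])
        fast.append(wm[FAST])
    return np.array(slow), np.array(fast)


def window_contrast(
    erfs: list,
    window_ms: tuple,
    graph: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
    min_channels: int = 3,
) -> tuple:
    """SLOW-vs-FAST cluster test on window-averaged amplitudes.

    Returns ``(clusters, direction)`` where ``direction`` is a DataFrame
    of per-cluster condition-mean amplitudes over the member channels --
    the quantity from which effect direction is read.
    """
    times = erfs[0].times
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError("window outside the epoch")
    slow, fast = group_window_contrast(erfs, window_ms)
    clusters = stats.cluster_permutation(
        slow, fast, graph, n_perm=n_perm, seed=seed, min_channels=min_channels
    )
    rows = []
    for k, cl in enumerate(clusters):
        rows.append(
            {
                "cluster": k,
                "polarity": cl.polarity,
                "p_mc": cl.p_mc,
                "slow_mean": float(slow[:, cl.members].mean()),
                "fast_mean": float(fast[:, cl.members].mean()),
                "abs_slow_mean": float(np.abs(slow[:, cl.members].mean(axis=0)).mean()),
                "abs_fast_mean": float(np.abs(fast[:, cl.members].mean(axis=0)).mean()),
            }
        )
    return clusters, pd.DataFrame(
        rows,
        columns=[
            "cluster", "polarity", "p_mc",
            "slow_mean", "fast_mean", "abs_slow_mean", "abs_fast_mean",
        ],
    )


def erf_snr(epochs: EpochSet) -> np.ndarray:
    """Heuristic per-trial SNR: post-onset RMS over baseline RMS.

    Offered as an optional QC metric only; the estimator behind the
    original recordings' reported SNR is not specified, so this is a
    plausible stand-in, not a reproduction.
    """
    times = epochs.times
    base = (times >= BASELINE_S[0]) & (times <= BASELINE_S[1])
    post = times > 0
    rms_b = np.sqrt(np.mean(epochs.data[:, :, base] ** 2, axis=(1, 2)))
    rms_p = np.sqrt(np.mean(epochs.data[:, :, post] ** 2, axis=(1, 2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(rms_b > 0, rms_p / rms_b, np.inf)


def erfs_to_tsv(erfs: list, channel_names: list, path=None) -> pd.DataFrame:
    """Long-format export: subject, condition, channel, time, amplitude."""
    rows = []
    for s, e in enumerate(erfs):
        for cond, avg in e.averages.items():
            for c, name in enumerate(channel_names):
                rows.extend(
                    {
                        "subject": s,
                        "condition": cond,
                        "channel": name,
                        "time": t,
                        "amplitude": a,
                    }
                    for t, a in zip(e.times, avg[c])
                )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
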