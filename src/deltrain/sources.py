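"""Toy-forward-model beamforming: DICS and LCMV with common spatial filters.

Frequency-domain source maps come from dynamic imaging of coherent
sources (DICS): cross-spectral density (CSD) matrices over all sensors
plus the pitch-reference channel are computed at each frequency of
interest with Hann tapering and zero-padding to 20 s, a spatial filter is
built per source node from the *pooled* (condition-common) CSD,

    w_j = (L_j^T C^-1 L_j)^-1 L_j^T C^-1,   C = Re(CSD) + lambda mean(diag) I,

and that common filter is applied to the per-condition CSDs, avoiding
single-condition bias.  Node power is w C w^T and node--reference
coherence |w c_ref|^2 / (power * S_ref).  The time-domain analog (LCMV)
replaces the CSD with a covariance matrix pooled over SHORT trials of
both conditions, and projects per-condition ERFs to node time courses.

The leadfield is the scalar fixed-orientation toy model of
:mod:`deltrain.simulate`; columns are unit-norm, so depth bias is already
removed and recovered node values are comparable across depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EpochSet, SensorModel
from .spectral import SpectralGrid, spectrum_hann_padded

__all__ = [
    "CSDMatrix",
    "SpatialFilter",
    "SourceMap",
    "compute_csd",
    "dics_common_filter",
    "apply_filter",
    "erf_covariance",
    "lcmv_filter",
    "lcmv_filter_apply",
    "roi_average",
    "source_map_to_tsv",
]

CSD_PAD_S = 20.0
DEFAULT_LAMBDA = 0.05


@dataclass
class CSDMatrix:
    """Trial-averaged cross-spectral density at one frequency.

    ``matrix`` is (sensors+1) x (sensors+1) complex, conjugate-symmetric,
    with the pitch-reference channel last.
    """

    frequency: float
    matrix: np.ndarray
    n_trials: int

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def sensor_block(self) -> np.ndarray:
        return self.matrix[:-1, :-1]

    @property
    def ref_cross(self) -> np.ndarray:
        """Sensor-to-reference cross terms."""
        return self.matrix[:-1, -1]

    @property
    def ref_power(self) -> float:
        return float(np.real(self.matrix[-1, -1]))


@dataclass
class SpatialFilter:
    """Beamformer weights, one row per source node."""

    weights: np.ndarray          # (nodes, sensors)
    tag: object                  # frequency (DICS) or window label (LCMV)
    regularization: float


@dataclass
class SourceMap:
    """Per-node values with condition / frequency tags."""

    table: pd.DataFrame          # node, label, hemisphere, value columns
    tag: object
    condition: str | None = None


class SingularMatrixError(np.linalg.LinAlgError):
    pass


def compute_csd(
    epochs: EpochSet,
    reference: EpochSet,
    f: float,
    pad_duration: float = CSD_PAD_S,
) -> CSDMatrix:
    """CSD at ``f`` over sensors plus the pitch reference.

    ``f`` must lie on the padded DFT grid (integer multiple of
    ``1/pad_duration``).  Coefficients are Hann-tapered over each trial's
    data length and zero-padded to ``pad_duration``; the CSD is the
    trial-averaged outer product.
    """
    steps = f * pad_duration
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(f"{f} Hz is off the {1 / pad_duration} Hz padded grid")
    if epochs.n_trials != reference.n_trials:
        raise ValueError("reference and MEG trial counts differ")
    res = 1.0 / pad_duration
    grid = SpectralGrid(pad_duration=pad_duration, band=(f, f), resolution=res)
    Y = spectrum_hann_padded(epochs, grid)[:, :, 0]        # (K, C)
    X = spectrum_hann_padded(reference, grid)[:, 0, 0]     # (K,)
    V = np.concatenate([Y, X[:, None]], axis=1)            # (K, C+1)
    csd = (V[:, :, None] * np.conj(V[:, None, :])).mean(axis=0)
    return CSDMatrix(f, csd, epochs.n_trials)


def _regularized_inverse(C: np.ndarray, lam: float) -> np.ndarray:
    n = C.shape[0]
    reg = C + lam * float(np.mean(np.diag(C))) * np.eye(n)
    if lam <= 0 and (not np.all(np.isfinite(reg)) or np.linalg.cond(reg) > 1e12):
        raise SingularMatrixError(
            "(cross-)spectral matrix is singular; use regularization lambda > 0"
        )
    return np.linalg.inv(reg)


def _beamformer_weights(
    C_real: np.ndarray, leadfield: np.ndarray, lam: float
) -> np.ndarray:
    Cinv = _regularized_inverse(C_real, lam)
    CL = Cinv @ leadfield                                  # (S, N)
    denom = np.einsum("sn,sn->n", leadfield, CL)           # L^T C^-1 L per node
    if np.any(np.abs(denom) < 1e-300):
        raise SingularMatrixError("degenerate leadfield column in inversion")
    return (CL / denom).T                                  # (N, S)


def dics_common_filter(
    csd_pooled: CSDMatrix,
    leadfield: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
) -> SpatialFilter:
    """DICS weights from the condition-pooled CSD at one frequency.

    The real part of the regularized CSD is inverted (coherence is later
    computed from the complex cross terms); the filter is stored for reuse
    on each condition's own CSD.
    """
    C = np.real(csd_pooled.sensor_block)
    W = _beamformer_weights(C, np.asarray(leadfield, dtype=float), lam)
    return SpatialFilter(W, csd_pooled.frequency, lam)


def apply_filter(
    filt: SpatialFilter,
    csd_condition: CSDMatrix,
    model: SensorModel | None = None,
) -> SourceMap:
    """Project a per-condition CSD through a common filter.

    Returns node power ``w C w^T`` and node--reference coherence
    ``|w c_ref|^2 / (power * S_ref)``, both per node.
    """
    if isinstance(filt.tag, (int, float)) and not np.isclose(
        filt.tag, csd_condition.frequency
    ):
        raise ValueError(
            f"filter frequency {filt.tag} != CSD frequency {csd_condition.frequency}"
        )
    W = filt.weights
    C = csd_condition.sensor_block
    power = np.real(np.einsum("ns,st,nt->n", W, C, W))
    power = np.maximum(power, 0.0)
    cross = W @ csd_condition.ref_cross
    s_ref = csd_condition.ref_power
    denom = power * s_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(cross) ** 2 / denom
    coh = np.clip(np.where(denom > 0, coh, 0.0), 0.0, 1.0)
    table = pd.DataFrame({"node": np.arange(W.shape[0]), "power": power, "coherence": coh})
    if model is not None:
        roi = model.roi_table()
        table["label"] = roi["label"]
        table["hemisphere"] = roi["hemisphere"]
    return SourceMap(table, filt.tag)


def erf_covariance(epoch_sets: list) -> np.ndarray:
    """Sensor covariance pooled over baseline-corrected SHORT-trial epochs."""
    segs = [e.data.transpose(1, 0, 2).reshape(e.n_channels, -1) for e in epoch_sets]
    X = np.concatenate(segs, axis=1)
    X = X - X.mean(axis=1, keepdims=True)
    return X @ X.T / X.shape[1]


def lcmv_filter(
    covariance_pooled: np.ndarray,
    leadfield: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    tag: object = "erf",
) -> SpatialFilter:
    """LCMV weights: the DICS formula with a covariance matrix."""
    W = _beamformer_weights(
        np.asarray(covariance_pooled, dtype=float),
        np.asarray(leadfield, dtype=float),
        lam,
    )
    return SpatialFilter(W, tag, lam)


def lcmv_filter_apply(
    covariance_pooled: np.ndarray,
    leadfield: np.ndarray,
    lam: float,
    erf_by_condition: dict,
    times: np.ndarray,
    window_ms: tuple = (300.0, 600.0),
    model: SensorModel | None = None,
) -> dict:
    """Common LCMV filter applied to per-condition ERFs.

    ``erf_by_condition`` maps condition -> channels x samples average; the
    node time courses ``w . ERF`` are averaged over ``window_ms`` and
    returned as one :class:`SourceMap` per condition.
    """
    filt = lcmv_filter(covariance_pooled, leadfield, lam)
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not mask.any():
        raise ValueError("window outside the ERF epoch")
    out = {}
    for cond, erf in erf_by_condition.items():
        course = filt.weights @ np.asarray(erf, dtype=float)   # (N, T)
        value = course[:, mask].mean(axis=1)
        table = pd.DataFrame({"node": np.arange(value.size), "value": value})
        if model is not None:
            roi = model.roi_table()
            table["label"] = roi["label"]
            table["hemisphere"] = roi["hemisphere"]
        out[cond] = SourceMap(table, tuple(window_ms), cond)
    return out


def roi_average(
    source_map: SourceMap,
    model: SensorModel,
    value_column: str = "coherence",
) -> pd.DataFrame:
    """Mean node value per ROI x hemisphere.

    Every node must carry a label; the hemisphere is the label's l/r
    prefix and the area its remainder, so filler nodes aggregate into
    their own filler ROIs.
    """
    roi = model.roi_table()
    if len(roi) != len(source_map.table):
        raise ValueError("source map and model node counts differ")
    df = source_map.table.copy()
    df["area"] = roi["area"]
    df["hemisphere"] = roi["hemisphere"]
    if df["area"].isna().any():
        raise ValueError("unlabelled node in source map")
    out = (
        df.groupby(["area", "hemisphere"])[value_column]
        .mean()
        .rename("value")
        .reset_index()
        .rename(columns={"area": "roi"})
    )
    return out


def source_map_to_tsv(maps: dict, path=None) -> pd.DataFrame:
    """Export node values: node, label, hemisphere, condition, tag, value."""
    rows = []
    for key, m in maps.items():
        t = m.table.copy()
        t["condition"] = m.condition if m.condition is not None else key
        t["tag"] = str(m.tag)
        rows.append(t)
    df = pd.concat(rows, ignore_index=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
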