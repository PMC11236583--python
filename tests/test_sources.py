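"""Beamforming (DICS / LCMV) and ROI-aggregation tests."""

import numpy as np
import pandas as pd
import pytest

from deltrain import sources
from deltrain.simulate import EpochSet, SensorModel
from deltrain.sources import (
    CSDMatrix,
    apply_filter,
    compute_csd,
    dics_common_filter,
    lcmv_filter,
    lcmv_filter_apply,
    roi_average,
)
from deltrain.stimuli import FAST, SLOW

SR = 250.0
N_SAMP = 1297  # one SLOW entrainment epoch
F = 0.6


def wrap_epochs(data, sr=SR):
    k, _, n = data.shape
    meta = pd.DataFrame(
        {
            "trial": np.arange(k),
            "contour_condition": SLOW,
            "sentence_length": 5,
            "phase": "entrainment",
            "n_samples": n,
            "block": 0,
        }
    )
    return EpochSet(np.asarray(data, float), sr, 0.0, meta)


def planted_epochs(model, nodes, k=30, noise=1.0, amp=1.0, seed=0, f=F,
                   phase_sd=0.3):
    """Trials driven by sinusoidal sources at ``nodes`` plus sensor noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(N_SAMP) / SR
    n_ch = model.n_sensors
    data = np.zeros((k, n_ch, N_SAMP))
    refs = np.zeros((k, 1, N_SAMP))
    for i in range(k):
        ph = rng.normal(0.0, phase_sd)
        refs[i, 0] = np.cos(2 * np.pi * f * t + ph)
        s = amp * np.cos(2 * np.pi * f * t + ph)
        for j in np.atleast_1d(nodes):
            data[i] += np.outer(model.leadfield[:, j], s)
        if noise:
            data[i] += noise * rng.standard_normal((n_ch, N_SAMP))
    return wrap_epochs(data), wrap_epochs(refs)


class TestCSD:
    def test_matches_per_trial_loop_oracle(self, small_model):
        ep, ref = planted_epochs(small_model, [3], k=8, seed=1)
        csd = compute_csd(ep, ref, F)
        # direct re-computation, one trial at a time
        from deltrain.spectral import SpectralGrid, spectrum_hann_padded

        grid = SpectralGrid(pad_duration=20.0, band=(F, F), resolution=1 / 20.0)
        acc = 0
        for i in range(8):
            y = spectrum_hann_padded(ep.select([i]), grid)[0, :, 0]
            x = spectrum_hann_padded(ref.select([i]), grid)[0, 0, 0]
            v = np.concatenate([y, [x]])
            acc = acc + np.outer(v, np.conj(v))
        np.testing.assert_allclose(csd.matrix, acc / 8, atol=1e-10)

    def test_noiseless_single_source_is_rank_one(self, small_model):
        ep, ref = planted_epochs(small_model, [2], k=6, noise=0.0, phase_sd=0.0)
        csd = compute_csd(ep, ref, F)
        sv = np.linalg.svd(csd.matrix, compute_uv=False)
        assert sv[1] < 1e-8 * sv[0]

    def test_reference_equal_to_sensor_matches_autoterm(self, small_model):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, small_model.n_sensors, 600))
        ep = wrap_epochs(data)
        ref = wrap_epochs(data[:, :1, :])
        csd = compute_csd(ep, ref, F)
        assert csd.ref_cross[0] == pytest.approx(csd.matrix[0, 0], abs=1e-12)
        assert csd.ref_power == pytest.approx(np.real(csd.matrix[0, 0]))

    def test_conjugate_symmetric_nonnegative_diagonal(self, small_model):
        ep, ref = planted_epochs(small_model, [0], k=10, seed=3)
        csd = compute_csd(ep, ref, F)
        np.testing.assert_allclose(csd.matrix, csd.matrix.conj().T, atol=1e-12)
        assert np.all(np.real(np.diag(csd.matrix)) >= 0)

    def test_off_grid_frequency_rejected(self, small_model):
        ep, ref = planted_epochs(small_model, [0], k=3)
        with pytest.raises(ValueError):
            compute_csd(ep, ref, 0.617)


class TestDICS:
    def test_identity_csd_gives_matched_filter(self, small_model):
        n = small_model.n_sensors
        csd = CSDMatrix(F, np.eye(n + 1, dtype=complex), 10)
        filt = dics_common_filter(csd, small_model.leadfield, lam=0.0)
        for j in (0, 5):
            w = filt.weights[j]
            L = small_model.leadfield[:, j]
            np.testing.assert_allclose(w / np.linalg.norm(w), L, atol=1e-10)

    def test_unit_gain_at_source_node(self, small_model):
        """Noiseless single source: estimated power matches source power."""
        amp = 2.0
        ep, ref = planted_epochs(
            small_model, [4], k=8, noise=0.0, amp=amp, phase_sd=0.0
        )
        csd = compute_csd(ep, ref, F)
        filt = dics_common_filter(csd, small_model.leadfield, lam=1e-10)
        smap = apply_filter(filt, csd, small_model)
        # oracle: project the planted source waveform itself
        src = wrap_epochs(
            (amp * np.cos(2 * np.pi * F * np.arange(N_SAMP) / SR))[None, None, :]
        )
        from deltrain.spectral import SpectralGrid, spectrum_hann_padded

        grid = SpectralGrid(pad_duration=20.0, band=(F, F), resolution=1 / 20.0)
        expected = float(np.abs(spectrum_hann_padded(src, grid)[0, 0, 0]) ** 2)
        assert smap.table.loc[4, "power"] == pytest.approx(expected, rel=1e-6)

    def test_singular_csd_without_regularization_raises(self, small_model):
        ep, ref = planted_epochs(small_model, [1], k=2, noise=0.0, phase_sd=0.0)
        csd = compute_csd(ep, ref, F)
        with pytest.raises(sources.SingularMatrixError):
            dics_common_filter(csd, small_model.leadfield, lam=0.0)

    def test_common_filter_gives_identical_maps_for_identical_csds(
        self, small_model
    ):
        ep, ref = planted_epochs(small_model, [3], k=12, seed=4)
        csd = compute_csd(ep, ref, F)
        filt = dics_common_filter(csd, small_model.leadfield)
        m1 = apply_filter(filt, csd, small_model)
        m2 = apply_filter(filt, csd, small_model)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_condition_swap_permutes_maps_without_changing_values(
        self, small_model
    ):
        epA, refA = planted_epochs(small_model, [3], k=12, seed=5)
        epB, refB = planted_epochs(small_model, [8], k=12, seed=6)
        csdA = compute_csd(epA, refA, F)
        csdB = compute_csd(epB, refB, F)
        pooled = CSDMatrix(F, (csdA.matrix + csdB.matrix) / 2, 24)
        filt = dics_common_filter(pooled, small_model.leadfield)
        mA = apply_filter(filt, csdA, small_model)
        mB = apply_filter(filt, csdB, small_model)
        np.testing.assert_allclose(
            apply_filter(filt, csdB, small_model).table["coherence"],
            mB.table["coherence"],
        )
        assert not np.allclose(mA.table["coherence"], mB.table["coherence"])

    def test_coherence_values_bounded(self, small_model):
        ep, ref = planted_epochs(small_model, [7], k=15, seed=7)
        csd = compute_csd(ep, ref, F)
        filt = dics_common_filter(csd, small_model.leadfield)
        coh = apply_filter(filt, csd, small_model).table["coherence"]
        assert (coh >= 0).all() and (coh <= 1).all()

    def test_frequency_mismatch_rejected(self, small_model):
        ep, ref = planted_epochs(small_model, [0], k=4)
        csd06 = compute_csd(ep, ref, 0.6)
        csd09 = compute_csd(ep, ref, 0.9)
        filt = dics_common_filter(csd06, small_model.leadfield)
        with pytest.raises(ValueError):
            apply_filter(filt, csd09)

    def test_zero_csd_gives_zero_map(self, small_model):
        n = small_model.n_sensors
        filt = dics_common_filter(
            CSDMatrix(F, np.eye(n + 1, dtype=complex), 1), small_model.leadfield
        )
        smap = apply_filter(filt, CSDMatrix(F, np.zeros((n + 1, n + 1), complex), 1))
        assert np.allclose(smap.table["power"], 0)
        assert np.allclose(smap.table["coherence"], 0)


class TestDepthBias:
    def test_equal_sources_at_different_depths_within_factor_two(self):
        """Column normalization keeps deep and shallow estimates comparable."""
        model = _two_depth_model()
        vals = []
        for j in (0, 1):
            t = np.arange(N_SAMP) / SR
            s = np.cos(2 * np.pi * F * t)
            data = np.outer(model.leadfield[:, j], s)[None, :, :]
            ep = wrap_epochs(np.repeat(data, 4, axis=0))
            ref = wrap_epochs(np.repeat(s[None, None, :], 4, axis=0))
            csd = compute_csd(ep, ref, F)
            filt = dics_common_filter(csd, model.leadfield, lam=1e-8)
            vals.append(float(apply_filter(filt, csd).table.loc[j, "power"]))
        ratio = vals[0] / vals[1]
        assert 0.5 <= ratio <= 2.0


def _two_depth_model():
    from deltrain import simulate as sim

    model = sim.build_sensor_model(n_sensors=32, n_nodes=40, seed=2)
    # force node 0 shallow and node 1 deep along the same direction
    direction = np.array([0.8, 0.3, 0.5])
    direction /= np.linalg.norm(direction)
    model.node_pos[0] = 0.85 * direction
    model.node_pos[1] = 0.35 * direction
    diff = model.sensor_pos[:, None, :] - model.node_pos[None, :2, :]
    dist = np.linalg.norm(diff, axis=-1)
    unit = diff / dist[..., None]
    orient = np.array([0.0, 1.0, 0.0])
    gain = (unit @ orient) / dist**2
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    model.leadfield[:, :2] = gain
    return model


class TestLCMV:
    def test_identical_condition_erfs_give_zero_contrast(self, small_model):
        rng = np.random.default_rng(8)
        cov = np.eye(small_model.n_sensors)
        erf = rng.standard_normal((small_model.n_sensors, 313))
        times = -0.25 + np.arange(313) / SR
        maps = lcmv_filter_apply(
            cov, small_model.leadfield, 0.05,
            {SLOW: erf, FAST: erf.copy()}, times, (300.0, 600.0), small_model,
        )
        np.testing.assert_allclose(
            maps[SLOW].table["value"], maps[FAST].table["value"], atol=1e-12
        )

    def test_window_outside_epoch_rejected(self, small_model):
        times = -0.25 + np.arange(313) / SR
        with pytest.raises(ValueError):
            lcmv_filter_apply(
                np.eye(small_model.n_sensors), small_model.leadfield, 0.05,
                {SLOW: np.zeros((small_model.n_sensors, 313))},
                times, (1500.0, 1800.0),
            )

    def test_unit_gain_through_filter(self, small_model):
        """w_j L_j = 1: the filter passes its own node with unit gain."""
        cov = np.eye(small_model.n_sensors) * 2.0
        filt = lcmv_filter(cov, small_model.leadfield, lam=0.0)
        gains = np.einsum("ns,sn->n", filt.weights, small_model.leadfield)
        np.testing.assert_allclose(gains, 1.0, atol=1e-10)


class TestRoiAverage:
    def test_single_node_roi_equals_node_value(self, small_model):
        table = pd.DataFrame(
            {"node": np.arange(small_model.n_nodes),
             "coherence": np.arange(small_model.n_nodes, dtype=float)}
        )
        smap = sources.SourceMap(table, F)
        out = roi_average(smap, small_model)
        roi = small_model.roi_table()
        fil = roi[roi["area"].str.startswith("FIL")].iloc[0]
        got = out[(out["roi"] == fil["area"]) & (out["hemisphere"] == fil["hemisphere"])]
        assert got["value"].iloc[0] == pytest.approx(float(fil["node"]))

    def test_uniform_map_gives_constant_rois(self, small_model):
        table = pd.DataFrame(
            {"node": np.arange(small_model.n_nodes),
             "coherence": np.full(small_model.n_nodes, 3.25)}
        )
        out = roi_average(sources.SourceMap(table, F), small_model)
        np.testing.assert_allclose(out["value"], 3.25)

    def test_node_count_mismatch_rejected(self, small_model):
        table = pd.DataFrame({"node": [0, 1], "coherence": [0.0, 1.0]})
        with pytest.raises(ValueError):
            roi_average(sources.SourceMap(table, F), small_model)

    def test_entrained_cohort_strongest_in_right_auditory_rois(self, cohort):
        """Group entrainment coherence is maximal in right EAC, with STG high."""
        df = cohort["roi_ent"]
        sel = df[(df["condition"] == SLOW) & (df["frequency"] == 0.6)]
        g = sel.groupby(["roi", "hemisphere"])["R"].mean().sort_values(
            ascending=False
        )
        top = list(g.index[:4])
        assert ("EAC", "right") in top[:2]
        assert ("STG", "right") in top


def test_source_map_export(tmp_path, small_model):
    table = small_model.roi_table()[["node", "label", "hemisphere"]].assign(
        power=1.0, coherence=0.5
    )
    maps = {SLOW: sources.SourceMap(table, F, SLOW)}
    df = sources.source_map_to_tsv(maps, tmp_path / "maps.tsv")
    assert len(df) == small_model.n_nodes
    assert (df["condition"] == SLOW).all()
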