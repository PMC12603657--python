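import numpy as np
import pytest

from vssr import beamform, simulate
from vssr.beamform import (CrossSpectralDensity, compute_csd,
                           envelope_long_table, envelope_timeseries,
                           extract_virtual_sensor, fit_envelope_slope,
                           grand_average_and_peak, lcmv_image)
from vssr.forward import (HeadModel, build_leadfield, occipital_slab_grid)
from vssr.preprocess import Epochs, epoch_recording
from vssr.simulate import CohortSpec, SourceSpec, SubjectTruth

FS = 1000.0
TIME = -0.9 + np.arange(2900) / FS


def make_epochs(data):
    data = np.asarray(data, dtype=float)
    return Epochs(data, TIME, FS, list(range(data.shape[0])))


@pytest.fixture(scope="module")
def slab(head):
    return occipital_slab_grid(head, spacing=0.01)


@pytest.fixture(scope="module")
def slab_leadfield(head, slab):
    from vssr.forward import default_sensor_array
    return build_leadfield(slab, head, default_sensor_array(head=head))


def single_source_setup(head, sensors, slab, seed, noise="default",
                        slope=2.1, n_trials=25):
    """Simulated subject with one occipital source at a grid voxel."""
    v_true = slab.nearest_voxel(simulate.OCCIPITAL_LOC)
    loc = slab.voxel_coords[v_true]
    spec = CohortSpec(1, 1, n_trials=n_trials, seed=seed)
    truth = SubjectTruth("s", "CHH", slope, 0.0, 0.0, 50.0, 60.0,
                         100.0, 10.0, "M")
    sources = {"occipital": SourceSpec(loc, base_amplitude=25e-9)}
    kw = {} if noise == "default" else {"noise": None}
    rec = simulate.simulate_subject_recording(truth, spec, head, sensors,
                                              sources=sources, seed=seed,
                                              **kw)
    return v_true, loc, epoch_recording(rec)


class TestCSD:
    def test_zero_epochs_give_zero_matrix(self):
        csd = compute_csd(make_epochs(np.zeros((3, 2, 2900))),
                          (14, 16), (0.3, 1.0))
        assert np.all(csd.matrix == 0)

    def test_hermitian_and_psd(self, rng):
        csd = compute_csd(make_epochs(rng.standard_normal((6, 4, 2900))),
                          (8, 30), (0.3, 1.0))
        H = csd.matrix
        assert np.abs(H - H.conj().T).max() < 1e-10 * np.abs(H).max()
        eig = np.linalg.eigvalsh(H)
        assert eig.min() > -1e-10 * eig.max()

    def test_identical_channels_rank_one(self, rng):
        x = rng.standard_normal((5, 1, 2900))
        data = np.concatenate([x, x], axis=1)
        csd = compute_csd(make_epochs(data), (10, 20), (0.0, 1.0))
        eig = np.linalg.eigvalsh(csd.matrix.real)
        assert eig[0] < 1e-6 * eig[-1]

    def test_diagonal_matches_periodogram_oracle(self, rng):
        """White noise: CSD diagonal ≈ flat PSD level from Welch."""
        from scipy import signal as sp_signal
        x = rng.standard_normal((40, 1, 2900))
        csd = compute_csd(make_epochs(x), (20, 80), (-0.9, 2.0))
        f, P = sp_signal.welch(x[:, 0, :], fs=FS, nperseg=512)
        level = P[:, (f >= 20) & (f <= 80)].mean()
        assert csd.matrix[0, 0].real == pytest.approx(level, rel=0.1)

    def test_window_shorter_than_cycle_raises(self, rng):
        with pytest.raises(ValueError, match="cycle"):
            compute_csd(make_epochs(np.zeros((2, 2, 2900))),
                        (2, 4), (0.3, 0.5))


class TestLCMV:
    def _toy_csds(self, rng, n_ch=10):
        A = rng.standard_normal((n_ch, n_ch))
        Ca = A @ A.T / n_ch + np.eye(n_ch)
        B = rng.standard_normal((n_ch, n_ch))
        Cp = B @ B.T / n_ch + np.eye(n_ch)
        mk = lambda C: CrossSpectralDensity(C.astype(complex), (14, 16),
                                            (0.3, 1.0), 20)
        cp = CrossSpectralDensity(Cp.astype(complex), (14, 16),
                                  (-0.8, -0.1), 20)
        return mk(Ca), cp

    def test_unit_gain_constraint(self, head, slab, slab_leadfield, rng):
        ca, cp = self._toy_csds(rng, slab_leadfield.sensors.n_channels)
        res = lcmv_image(ca, cp, slab_leadfield, 0.05)
        valid = np.flatnonzero(res.image.valid)
        for v in valid[:: max(1, len(valid) // 10)]:
            WtL = res.weights[v].T @ slab_leadfield.matrix[v]
            assert np.abs(WtL - np.eye(2)).max() < 1e-8

    def test_weights_match_constrained_least_squares_oracle(self, rng):
        """KKT-system solution of min tr(WᵀCW) s.t. WᵀL = I."""
        from dataclasses import dataclass
        from vssr.forward import LeadField, SourceGrid

        n_ch = 10
        ca, cp = self._toy_csds(rng, n_ch)
        L = rng.standard_normal((1, n_ch, 2)) * 1e-11
        grid = SourceGrid(0.01, np.array([[0.0, -0.06, 0.01]]),
                          (1, 1, 1), np.zeros((1, 3), dtype=int))
        lf = LeadField(L, np.zeros((1, 2, 3)), grid, HeadModel(), None)
        res = lcmv_image(ca, cp, lf, regularization=0.05)

        C = 0.5 * (ca.matrix.real + cp.matrix.real)
        C = C + 0.05 * np.trace(C) / n_ch * np.eye(n_ch)
        W_oracle = np.empty((n_ch, 2))
        for k in range(2):
            kkt = np.block([[C, L[0]], [L[0].T, np.zeros((2, 2))]])
            rhs = np.concatenate([np.zeros(n_ch), np.eye(2)[k]])
            W_oracle[:, k] = np.linalg.solve(kkt, rhs)[:n_ch]
        assert np.abs(res.weights[0] - W_oracle).max() \
            < 1e-8 * np.abs(W_oracle).max()

    def test_scaling_invariance(self, slab_leadfield, rng):
        """Multiplying the data by k leaves pseudo-t unchanged."""
        n_ch = slab_leadfield.sensors.n_channels
        ca, cp = self._toy_csds(rng, n_ch)
        res1 = lcmv_image(ca, cp, slab_leadfield, 0.05)
        k2 = 3.7 ** 2
        ca2 = CrossSpectralDensity(ca.matrix * k2, ca.band, ca.window, 20)
        cp2 = CrossSpectralDensity(cp.matrix * k2, cp.band, cp.window, 20)
        res2 = lcmv_image(ca2, cp2, slab_leadfield, 0.05)
        v = res1.image.valid
        assert np.allclose(res1.image.pseudo_t[v], res2.image.pseudo_t[v],
                           rtol=1e-9)

    def test_mismatched_windows_raise(self, slab_leadfield, rng):
        ca, cp = self._toy_csds(rng, slab_leadfield.sensors.n_channels)
        bad = CrossSpectralDensity(cp.matrix, cp.band, (-0.8, 0.0), 20)
        with pytest.raises(ValueError, match="duration"):
            lcmv_image(ca, bad, slab_leadfield)

    def test_localizes_single_source(self, head, sensors, slab,
                                     slab_leadfield):
        v_true, _loc, ep = single_source_setup(head, sensors, slab, seed=0)
        ca = compute_csd(ep, (14, 16), (0.3, 1.0))
        cp = compute_csd(ep, (14, 16), (-0.8, -0.1))
        res = lcmv_image(ca, cp, slab_leadfield, 0.05)
        assert res.image.peak_voxel() == v_true

    def test_forward_inverse_power_consistency(self, head, sensors, slab,
                                               slab_leadfield):
        """Noise-free loop: source power recovered within 1%."""
        v_true, loc, ep = single_source_setup(head, sensors, slab, seed=1,
                                              noise=None)
        ca = compute_csd(ep, (14, 16), (0.3, 1.0))
        cp = compute_csd(ep, (14, 16), (-0.8, -0.1))
        res = lcmv_image(ca, cp, slab_leadfield, regularization=0.05)
        W = res.weights[v_true]
        p_rec = np.trace(W.T @ ca.matrix.real @ W)
        # oracle: the same spectral estimate applied to the true moment
        wave = simulate.entrainment_source_waveform(
            SourceSpec(loc, base_amplitude=25e-9, envelope_slope=2.1),
            2.0, FS)
        moment = np.zeros((1, 1, 2900))
        moment[0, 0, 900:] = wave
        p_true = compute_csd(
            Epochs(np.repeat(moment, ep.n_trials, 0), TIME, FS,
                   list(range(ep.n_trials))),
            (14, 16), (0.3, 1.0)).matrix[0, 0].real
        assert p_rec == pytest.approx(p_true, rel=0.01)


class TestVirtualSensor:
    def test_reconstructs_source_waveform_noise_free(
            self, head, sensors, slab, slab_leadfield):
        v_true, loc, ep = single_source_setup(head, sensors, slab, seed=2,
                                              noise=None)
        ca = compute_csd(ep, (14, 16), (0.3, 1.0))
        cp = compute_csd(ep, (14, 16), (-0.8, -0.1))
        res = lcmv_image(ca, cp, slab_leadfield, 0.05)
        vs = extract_virtual_sensor(res, v_true, ep)
        wave = simulate.entrainment_source_waveform(
            SourceSpec(loc, base_amplitude=25e-9, envelope_slope=2.1),
            2.0, FS)
        rec = vs.chosen[0, 900:]
        r = np.corrcoef(rec, wave)[0, 1]
        assert abs(r) > 0.95

    def test_orientation_with_stronger_response_chosen(
            self, head, sensors, slab, slab_leadfield, rng):
        """Source driven along each tangential axis in turn."""
        v = slab.nearest_voxel(simulate.OCCIPITAL_LOC)
        for k in (0, 1):
            ori = slab_leadfield.orientations[v, k]
            g = np.asarray([np.dot(slab_leadfield.matrix[v][:, 0], 0)])
            wave = simulate.entrainment_source_waveform(
                SourceSpec(slab.voxel_coords[v], base_amplitude=25e-9),
                2.0, FS)
            from vssr.forward import sarvas_dipole_field
            gain = sarvas_dipole_field(slab.voxel_coords[v], ori,
                                       HeadModel(), slab_leadfield.sensors)
            moment = np.zeros(2900)
            moment[900:] = wave
            data = np.tile(gain[:, None] * moment[None, :], (4, 1, 1))
            ep = make_epochs(data)
            ca = compute_csd(ep, (14, 16), (0.3, 1.0))
            cp = compute_csd(ep, (14, 16), (-0.8, -0.1))
            res = lcmv_image(ca, cp, slab_leadfield, 0.05)
            vs = extract_virtual_sensor(res, v, ep)
            assert vs.chosen_orientation == k

    def test_zero_data_defaults_to_first_orientation(
            self, slab, slab_leadfield, rng):
        ca_m = np.eye(slab_leadfield.sensors.n_channels).astype(complex)
        ca = CrossSpectralDensity(ca_m, (14, 16), (0.3, 1.0), 4)
        cp = CrossSpectralDensity(ca_m * 0.9, (14, 16), (-0.8, -0.1), 4)
        res = lcmv_image(ca, cp, slab_leadfield, 0.05)
        v = int(np.flatnonzero(res.image.valid)[0])
        ep = make_epochs(np.zeros((3, slab_leadfield.sensors.n_channels,
                                   2900)))
        vs = extract_virtual_sensor(res, v, ep)
        assert vs.chosen_orientation == 0
        assert np.all(vs.series == 0)


class TestEnvelope:
    def test_constant_sinusoid_gives_flat_envelope(self):
        from vssr.beamform import VirtualSensorSeries
        x = np.sin(2 * np.pi * 15 * TIME)
        series = np.tile(x, (5, 1))[:, None, :]
        series = np.concatenate([series, np.zeros_like(series)], axis=1)
        vs = VirtualSensorSeries(series, 0, 0, TIME, FS)
        env = envelope_timeseries(vs, 15.0)
        assert np.all(env.values > 0)
        inner = (env.time_axis > -0.5) & (env.time_axis < 1.6)
        assert env.values[inner].std() / env.values[inner].mean() < 0.02

    def test_envelope_slope_recovery(self, head, sensors, slab,
                                     slab_leadfield):
        """Planted relative-power slope recovered within 20%."""
        est = []
        for seed in (3, 4, 5):
            v_true, _loc, ep = single_source_setup(head, sensors, slab,
                                                   seed=seed)
            ca = compute_csd(ep, (14, 16), (0.3, 1.0))
            cp = compute_csd(ep, (14, 16), (-0.8, -0.1))
            res = lcmv_image(ca, cp, slab_leadfield, 0.05)
            vs = extract_virtual_sensor(res, v_true, ep)
            env = envelope_timeseries(vs, 15.0)
            est.append(fit_envelope_slope(env))
        assert np.mean(est) == pytest.approx(2.1, rel=0.2)

    def test_envelope_near_one_off_frequency(self, head, sensors, slab,
                                             slab_leadfield):
        """No source content at 55 Hz: envelope level ≈ 1.

        Individual 50 ms bins of a 1 Hz-bandwidth power estimate carry
        few effective degrees of freedom, so the check is on the mean
        level over the epoch interior, not per bin.
        """
        v_true, _loc, ep = single_source_setup(head, sensors, slab, seed=6)
        ca = compute_csd(ep, (54, 56), (0.3, 1.0))
        cp = compute_csd(ep, (54, 56), (-0.8, -0.1))
        res = lcmv_image(ca, cp, slab_leadfield, 0.05)
        vs = extract_virtual_sensor(res, v_true, ep, f0=55.0)
        env = envelope_timeseries(vs, 55.0)
        inner = (env.time_axis > -0.6) & (env.time_axis < 1.6)
        assert np.all(env.values > 0)
        assert env.values[inner].mean() == pytest.approx(1.0, abs=0.2)

    def test_long_table_layout(self):
        from vssr.beamform import EnvelopeSeries
        t_axis = -0.875 + 0.05 * np.arange(57)
        env = EnvelopeSeries(np.ones(57), t_axis, 15.0, (-0.9, -0.1))
        tab = envelope_long_table({"a": env, "b": env},
                                  {"a": "CNH", "b": "CHH"})
        assert len(tab) == 28
        assert sorted(tab.time_ms.unique()) == pytest.approx(
            list(325 + 50.0 * np.arange(14)))


class TestGrandAverage:
    def _image(self, slab, values):
        from vssr.beamform import SourceImage
        return SourceImage(values, slab, (14, 16), (0.3, 1.0), (-0.8, -0.1))

    def test_identical_images_mean_equals_input(self, slab, rng):
        vals = rng.standard_normal(slab.n_voxels)
        mean, peak = grand_average_and_peak(
            [self._image(slab, vals)] * 3)
        assert np.allclose(mean.pseudo_t, vals)
        assert peak == int(np.argmax(vals))

    def test_opposite_signs_cancel(self, slab, rng):
        vals = rng.standard_normal(slab.n_voxels)
        mean, _ = grand_average_and_peak(
            [self._image(slab, vals), self._image(slab, -vals)])
        assert np.allclose(mean.pseudo_t, 0.0)

    def test_mismatched_grids_raise(self, head, slab, rng):
        other = occipital_slab_grid(head, spacing=0.02)
        a = self._image(slab, rng.standard_normal(slab.n_voxels))
        b = self._image(other, rng.standard_normal(other.n_voxels))
        with pytest.raises(ValueError, match="grid"):
            grand_average_and_peak([a, b])
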