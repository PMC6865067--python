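import numpy as np
import pytest

from delaysum.circuit import GlutUnit, group_kinetics_at
from delaysum.receptive_fields import (
    StRF,
    StRFVolume,
    control_threshold,
    partition_temporal_filters,
    reverse_correlate,
    spatial_rf_from_events,
    strf_profile,
    strf_slope_and_activation,
    temporal_rf,
)
from delaysum.stimuli import make_dense_noise
from delaysum.synth import unit_response
from delaysum.traces import Trace


@pytest.fixture(scope="module")
def noise():
    return make_dense_noise(px_size_um=40.0, grid=(12, 12), refresh_hz=20.0,
                            duration_s=240.0, seed=21)


class TestReverseCorrelate:
    def test_delta_filter_recovered(self, noise):
        """A response that copies one pixel with a delay concentrates the
        volume at that pixel and delay."""
        delay_frames = 6
        px = (4, 7)
        r = np.roll(noise.frames[px], delay_frames)
        r[:delay_frames] = 0.0
        vol = reverse_correlate(Trace(r, noise.refresh_hz), noise, max_lag_s=1.0)
        i, j = vol.peak_pixel()
        assert (i, j) == px
        assert np.argmax(np.abs(vol.values[i, j])) == delay_frames

    def test_zero_response_zero_volume(self, noise):
        vol = reverse_correlate(Trace(np.zeros(noise.n_frames), 20.0), noise, 1.0)
        assert np.all(vol.values == 0)

    def test_linearity_exact(self, noise):
        rng = np.random.default_rng(3)
        r1 = rng.normal(size=noise.n_frames)
        r2 = rng.normal(size=noise.n_frames)
        a, b = 1.7, -0.4
        va = reverse_correlate(Trace(r1, 20.0), noise, 1.0).values
        vb = reverse_correlate(Trace(r2, 20.0), noise, 1.0).values
        vab = reverse_correlate(Trace(a * r1 + b * r2, 20.0), noise, 1.0).values
        assert np.allclose(vab, a * va + b * vb, atol=1e-12)

    def test_excessive_lag_rejected(self, noise):
        with pytest.raises(ValueError):
            reverse_correlate(Trace(np.zeros(noise.n_frames), 20.0), noise,
                              max_lag_s=500.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ln_filter_recovery(self, seed):
        """A unit's kernel is recovered from ten minutes of dense noise with
        correlation > 0.95 up to scale."""
        from delaysum.model import temporal_filter_kernel

        noise10 = make_dense_noise(px_size_um=40.0, grid=(10, 10),
                                   refresh_hz=20.0, duration_s=600.0,
                                   seed=100 + seed)
        unit = GlutUnit(group="G3", pos_um=(-20.0, -20.0),
                        kinetics=group_kinetics_at("G3", -20.0))
        tr = unit_response(unit, noise10, apply_envelope=False)
        vol = reverse_correlate(Trace(tr.values, tr.rate_hz), noise10,
                                max_lag_s=2.0)
        i, j = vol.peak_pixel()
        rec = vol.values[i, j]
        k = temporal_filter_kernel(unit.kinetics)
        # the 50 ms frame hold and the response binning each convolve the
        # kernel with a 50 ms box before it is sampled on the lag grid
        per = int(round(0.05 / 0.001))
        box = np.ones(per) / per
        expected = np.convolve(np.convolve(k, box), box)
        cc = max(
            np.corrcoef(rec[: min(rec.size, expected[o::per].size)],
                        expected[o::per][: min(rec.size, expected[o::per].size)])[0, 1]
            for o in (0, per // 2, per - 1)
        )
        assert cc > 0.95


class TestControlThreshold:
    def test_gaussian_volume_threshold_near_three_sigma(self):
        # white response against independent white noise: control values are
        # ~N(0, sigma/sqrt(n)); the threshold lands at ~3 SD of that
        noise = make_dense_noise(grid=(8, 8), refresh_hz=20.0,
                                 duration_s=240.0, seed=5)
        rng = np.random.default_rng(8)
        r = Trace(rng.normal(size=noise.n_frames), 20.0)
        thr = control_threshold(r, noise, max_lag_s=1.0, k=3.0)
        n_avg = noise.n_frames - 21
        assert thr == pytest.approx(3.0 / np.sqrt(n_avg), rel=0.15)

    def test_k_zero_gives_mean(self):
        noise = make_dense_noise(grid=(6, 6), duration_s=60.0, seed=6)
        rng = np.random.default_rng(9)
        r = Trace(rng.normal(size=noise.n_frames), 20.0)
        thr0 = control_threshold(r, noise, 1.0, k=0.0)
        vol = reverse_correlate(r, noise, 1.0)
        assert thr0 == pytest.approx(vol.values.mean())

    def test_monotone_in_k(self):
        noise = make_dense_noise(grid=(6, 6), duration_s=60.0, seed=6)
        rng = np.random.default_rng(9)
        r = Trace(rng.normal(size=noise.n_frames), 20.0)
        ts = [control_threshold(r, noise, 1.0, k=k) for k in (1.0, 2.0, 3.0)]
        assert ts[0] < ts[1] < ts[2]

    def test_shared_seed_rejected(self):
        noise = make_dense_noise(grid=(6, 6), duration_s=60.0, seed=6)
        r = Trace(np.zeros(noise.n_frames), 20.0, meta={"stimulus_seed": 6})
        with pytest.raises(ValueError):
            control_threshold(r, noise, 1.0)


class TestStrfProfile:
    def _volume(self, values, px=40.0):
        return StRFVolume(values, lag_step_s=0.05, max_lag_s=1.0, px_size_um=px,
                          origin=(-(values.shape[0] - 1) / 2 * px,
                                  -(values.shape[1] - 1) / 2 * px))

    def test_isotropic_volume_profile_axis_independent(self):
        n = 15
        x = np.arange(n) - n // 2
        X, Y = np.meshgrid(x, x, indexing="ij")
        spatial = np.exp(-(X**2 + Y**2) / 8.0)
        lagf = np.exp(-(np.arange(21) - 8) ** 2 / 10.0)
        vol = self._volume(spatial[:, :, None] * lagf[None, None, :])
        p0 = strf_profile(vol, 0.0, width_um=80.0, length_um=400.0,
                          center_um=(0.0, 0.0))
        p90 = strf_profile(vol, 90.0, width_um=80.0, length_um=400.0,
                           center_um=(0.0, 0.0))
        assert np.allclose(p0.values, p90.values, atol=1e-6)

    def test_latency_ramp_reproduced(self):
        n, nlag = 15, 30
        vals = np.zeros((n, n, nlag))
        for i in range(n):
            lag = 4 + i  # latency increases along x
            vals[i, :, min(lag, nlag - 1)] = 1.0
        vol = self._volume(vals)
        prof = strf_profile(vol, 0.0, width_um=80.0, length_um=480.0,
                            center_um=(0.0, 0.0))
        peaks = np.argmax(prof.values, axis=1)
        assert np.all(np.diff(peaks) >= 0)
        assert peaks[-1] > peaks[0]

    def test_rectangle_outside_volume_rejected(self):
        vol = self._volume(np.zeros((9, 9, 10)))
        with pytest.raises(ValueError):
            strf_profile(vol, 0.0, width_um=80.0, length_um=5000.0,
                         center_um=(0.0, 0.0))


class TestSlopeAndActivation:
    def _ramp_strf(self, slope_s_per_um=0.004, n_cols=17, spacing=25.0,
                   base=0.2):
        lags = np.arange(0, 1.5, 0.02)
        pos = (np.arange(n_cols) - n_cols // 2) * spacing
        vals = np.stack([
            np.exp(-((lags - (base + slope_s_per_um * p)) / 0.05) ** 2)
            for p in pos
        ])
        return StRF(vals, pos, 0.02, threshold=0.5)

    def test_constructed_ramp_recovered(self):
        st = strf_slope_and_activation(self._ramp_strf(0.004))
        assert st.slope_s_per_um == pytest.approx(0.004, rel=0.05)
        assert st.optimal_speed_um_s == pytest.approx(250.0, rel=0.05)

    def test_separable_strf_has_zero_slope(self):
        st = strf_slope_and_activation(self._ramp_strf(0.0))
        assert st.slope_s_per_um == pytest.approx(0.0, abs=1e-9)

    def test_too_few_columns_flagged(self):
        strf = self._ramp_strf(0.004, n_cols=17)
        strf.threshold = 10.0  # nothing suprathreshold
        st = strf_slope_and_activation(strf)
        assert not st.ok

    def test_activation_precedes_peak(self):
        st = strf_slope_and_activation(self._ramp_strf(0.004))
        assert np.all(st.activation_times_s <= st.peak_times_s)

    def test_end_to_end_tilt_recovery(self):
        """The bipolar sheet's calibrated 5 ms/um tilt inverts to a predicted
        optimum within 20 % of 200 um/s."""
        from delaysum.circuit import make_ground_truth_cell
        from delaysum.synth import synthesize_epsc

        c = make_ground_truth_cell(
            counts_by_group={"G1": 32, "G2": 25, "G3": 26, "G4": 34, "G5": 56},
            seed=0, latency_jitter_sd_s=0.0,
        )
        noise = make_dense_noise(px_size_um=40.0, grid=(20, 20),
                                 refresh_hz=20.0, duration_s=480.0, seed=11)
        resp = synthesize_epsc(c, noise, apply_envelope=False)
        resp = Trace(resp.values, resp.rate_hz, kind="current",
                     meta={"stimulus_seed": 11})
        vol = reverse_correlate(resp, noise, max_lag_s=2.5)
        ctrl = make_dense_noise(px_size_um=40.0, grid=(20, 20),
                                refresh_hz=20.0, duration_s=480.0, seed=12)
        thr = control_threshold(resp, ctrl, max_lag_s=2.5)
        prof = strf_profile(vol, 0.0, width_um=120.0, length_um=640.0,
                            center_um=(0.0, 0.0))
        st = strf_slope_and_activation(prof, thr)
        assert st.ok
        assert st.optimal_speed_um_s == pytest.approx(200.0, rel=0.2)


class TestSpatialRF:
    def test_gaussian_rf_width_recovered(self):
        noise = make_dense_noise(px_size_um=20.0, grid=(16, 16),
                                 refresh_hz=20.0, duration_s=600.0, seed=31)
        unit = GlutUnit(group="G2", pos_um=(10.0, -10.0),
                        kinetics=group_kinetics_at("G2", 10.0),
                        rf_sigma_um=(20.0, 20.0))
        tr = unit_response(unit, noise, apply_envelope=False)
        # a noiseless linear trace is symmetric, so a 2 SD event threshold
        # yields enough transients for a stable triggered average
        rf = spatial_rf_from_events(Trace(tr.values, tr.rate_hz), noise,
                                    k=2.0, seed=1)
        assert rf.ok and rf.n_events >= 10
        # recovered sigma within 30 %: the 20 um stimulus pixels add ~px/sqrt(12)
        # of blur to the true 20 um Gaussian
        sx, sy = rf.gauss_fit["sigma_um"]
        assert sx == pytest.approx(20.0, rel=0.3)
        assert sy == pytest.approx(20.0, rel=0.3)

    def test_random_events_give_negligible_area(self):
        noise = make_dense_noise(px_size_um=20.0, grid=(12, 12),
                                 refresh_hz=20.0, duration_s=300.0, seed=32)
        rng = np.random.default_rng(2)
        r = np.zeros(noise.n_frames)
        r[rng.integers(50, noise.n_frames, 60)] = 5.0
        rf = spatial_rf_from_events(Trace(r, 20.0), noise, seed=3)
        total = noise.frames.shape[0] * noise.frames.shape[1] * 20.0**2
        assert rf.area_um2 < 0.02 * total

    def test_too_few_events_flagged(self):
        noise = make_dense_noise(grid=(6, 6), duration_s=60.0, seed=33)
        r = np.zeros(noise.n_frames)
        r[200] = 10.0
        rf = spatial_rf_from_events(Trace(r, 20.0), noise)
        assert not rf.ok


class TestTemporalRF:
    def _volume_with_filter(self, f):
        vals = np.zeros((9, 9, f.size))
        vals[4, 4] = f
        return StRFVolume(vals, 0.05, f.size * 0.05, 20.0)

    def test_delta_filter_peak_lag(self):
        f = np.zeros(20)
        f[7] = 1.0
        tf = temporal_rf(self._volume_with_filter(f))
        assert tf.peak_latency_s == pytest.approx(0.35)

    def test_biphasic_zero_crossing_recovered(self):
        lags = np.arange(20) * 0.05
        f = np.exp(-((lags - 0.2) / 0.08) ** 2) - 0.8 * np.exp(
            -((lags - 0.45) / 0.10) ** 2
        )
        tf = temporal_rf(self._volume_with_filter(f))
        # zero crossing between the two lobes
        zc_true = np.nonzero(np.diff(np.sign(f)))[0][0]
        zc_rec = np.nonzero(np.diff(np.sign(tf.values)))[0][0]
        assert abs(zc_rec - zc_true) <= 1

    def test_flat_volume_flat_filter(self):
        vol = StRFVolume(np.ones((5, 5, 12)), 0.05, 0.6, 20.0)
        tf = temporal_rf(vol)
        assert np.allclose(tf.values, 1.0)


class TestPartition:
    def _strf(self, latencies, amps=None, spacing=25.0):
        lags = np.arange(0, 1.5, 0.02)
        n = len(latencies)
        pos = (np.arange(n) - n // 2) * spacing
        amps = amps or [1.0] * n
        vals = np.stack([
            a * np.exp(-((lags - lat) / 0.06) ** 2)
            for a, lat in zip(amps, latencies)
        ])
        return StRF(vals, pos, 0.02, threshold=0.3)

    def test_symmetric_strf_gives_identical_sides(self):
        lat = [0.5] * 9
        amps = [0.6, 0.7, 0.8, 0.9, 1.0, 0.9, 0.8, 0.7, 0.6]
        parts = partition_temporal_filters(self._strf(lat, amps))
        assert np.allclose(parts["preferred"].values, parts["null"].values,
                           atol=1e-9)

    def test_null_side_is_faster_than_preferred_side(self):
        # latency decreasing along +u, as in the calibrated circuit; the
        # centre column carries the strongest filter
        lat = list(np.linspace(1.0, 0.3, 9))
        amps = [0.7, 0.75, 0.8, 0.9, 1.0, 0.9, 0.8, 0.75, 0.7]
        parts = partition_temporal_filters(self._strf(lat, amps))
        assert parts["null"].peak_latency_s < parts["preferred"].peak_latency_s

    def test_sides_share_only_the_centre_column(self):
        lat = list(np.linspace(1.0, 0.3, 9))
        amps = [0.5] * 4 + [1.0] + [0.5] * 4
        parts = partition_temporal_filters(self._strf(lat, amps))
        p = set(parts["preferred"].meta["columns"])
        q = set(parts["null"].meta["columns"])
        assert p & q == {4}

    def test_one_sided_strf_flags_missing_side(self):
        lat = [0.5] * 6
        amps = [0.1, 0.1, 0.1, 1.0, 0.9, 0.8]  # suprathreshold right side only
        parts = partition_temporal_filters(self._strf(lat, amps))
        assert parts["preferred"] is None
        assert parts["null"] is not None
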