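"""Event binning and vanadium/beam-power corrections."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toflaue import geometry as g
from toflaue import histogram as hm
from toflaue import simulate as sim


def make_instrument(n_pixels=16, tof_range=(0.0, 40000.0)):
    det = g.DetectorGeometry(detector_id=0, n_pixels_x=n_pixels,
                             n_pixels_y=n_pixels, pixel_pitch=13.3 / n_pixels)
    return g.Instrument(detectors=(det,), tof_range=tof_range,
                        wavelength_band=(0.06, 6.76))


def events_frame(x, y, t, det=0):
    return pd.DataFrame({"detector_id": det, "x": x, "y": y, "tof_us": t,
                         "weight": 1.0})


class TestBinning:
    def test_default_channel_width_is_40us(self):
        inst = make_instrument()
        ev = hm.EventList(events=events_frame([1], [1], [100.0]))
        h = hm.bin_events(ev, inst, n_channels=1000)[0]
        assert np.allclose(np.diff(h.edges), 40.0)

    def test_event_on_interior_edge_goes_to_upper_channel(self):
        inst = make_instrument()
        ev = hm.EventList(events=events_frame([1], [1], [40.0]))
        h = hm.bin_events(ev, inst, n_channels=1000)[0]
        assert h.counts[1, 1, 1] == 1 and h.counts[1, 1, 0] == 0

    def test_uniform_events_fill_channels_evenly(self, rng):
        inst = make_instrument(n_pixels=4)
        n = 10_000
        ev = hm.EventList(events=events_frame(
            rng.integers(0, 4, n), rng.integers(0, 4, n),
            rng.uniform(0, 40000, n)))
        h = hm.bin_events(ev, inst, n_channels=100)[0]
        per_channel = h.counts.sum(axis=(0, 1))
        mean = n / 100
        assert h.counts.sum() == n
        assert np.all(np.abs(per_channel - mean) < 5 * np.sqrt(mean))

    def test_outside_events_counted_not_binned(self):
        inst = make_instrument(tof_range=(1000.0, 2000.0))
        ev = hm.EventList(events=events_frame([0, 0, 0], [0, 0, 0],
                                              [500.0, 1500.0, 2500.0]))
        h = hm.bin_events(ev, inst, n_channels=10)[0]
        assert h.counts.sum() == 1
        assert h.n_outside == 2

    def test_empty_range_rejected(self):
        inst = make_instrument()
        ev = hm.EventList(events=events_frame([1], [1], [10.0]))
        with pytest.raises(ValueError):
            hm.bin_events(ev, inst, n_channels=10, tof_range=(5.0, 5.0))


class TestVanadiumMerge:
    def _lists(self, inst, t_short, t_long, n_short=1.0, n_long=1.0):
        evs = hm.EventList(events=events_frame([2] * len(t_short),
                                               [2] * len(t_short), t_short),
                           n_neutron=n_short)
        evl = hm.EventList(events=events_frame([2] * len(t_long),
                                               [2] * len(t_long), t_long),
                           n_neutron=n_long)
        return evs, evl

    def test_partition_at_connecting_wavelength(self):
        inst = make_instrument()
        # wavelengths 1..6 A at the (2,2) pixel path
        det = inst.detectors[0]
        L = inst.L1 + np.sqrt(g.pixel_distance_sq(2, 2, det)) / 100.0
        lams = np.array([1.0, 2.0, 3.0, 3.8, 4.5, 6.0])
        T = g.wavelength_to_tof(lams, L)
        evs, evl = self._lists(inst, T, T)
        merged = hm.merge_vanadium(evs, evl, inst, connect_lambda=3.4)
        lam_m = np.sort(hm._event_wavelengths(merged, inst))
        assert np.allclose(lam_m, sorted(lams), atol=1e-9)
        assert merged.events["weight"].sum() == len(lams)

    def test_long_band_weight_is_count_ratio(self):
        inst = make_instrument()
        det = inst.detectors[0]
        L = inst.L1 + np.sqrt(g.pixel_distance_sq(2, 2, det)) / 100.0
        T = g.wavelength_to_tof(np.array([4.0]), L)
        evs, evl = self._lists(inst, np.array([]), T, n_short=1.0, n_long=2.0)
        merged = hm.merge_vanadium(evs, evl, inst, connect_lambda=3.4)
        assert np.allclose(merged.events["weight"].to_numpy(), 0.5)

    def test_connecting_wavelength_must_be_in_overlap(self):
        inst = make_instrument()
        evs, evl = self._lists(inst, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            hm.merge_vanadium(evs, evl, inst, connect_lambda=1.0)

    def test_merged_rate_continuous_at_connection(self, rng):
        """With flux-consistent band statistics, the merged per-wavelength
        rate has no step at the connecting wavelength."""
        inst = sim.default_instrument(n_detectors=1)
        beam = sim.BeamModel()
        eff = {0: np.ones((64, 64))}
        van_s, van_l = sim.generate_vanadium(
            beam, inst, eff, seed=5, events_per_detector=200_000)
        merged = hm.merge_vanadium(van_s, van_l, inst)
        lam = hm._event_wavelengths(merged, inst)
        w = merged.events["weight"].to_numpy()
        below = ((lam > 3.1) & (lam < 3.4))
        above = ((lam >= 3.4) & (lam < 3.7))
        r_below = w[below].sum() / 0.3
        r_above = w[above].sum() / 0.3
        # spectral shape changes slowly there; a band-scaling error would
        # show as a factor-of-two step
        assert r_above / r_below == pytest.approx(
            beam.spectrum(3.55) / beam.spectrum(3.25), rel=0.15)


class TestHxy:
    def test_ideal_vanadium_gives_unity(self, rng):
        inst = make_instrument(n_pixels=8)
        det = inst.detectors[0]
        xg, yg = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        d = g.pixel_distance_sq(xg, yg, det)
        counts = rng.poisson(5e7 / d)[:, :, None] * np.ones((1, 1, 4))
        h = hm.Histogram3D(counts=counts.astype(float),
                           edges=np.linspace(0, 4000, 5), detector_id=0)
        hxy, active = hm.compute_Hxy(h, det, 0, 4000)
        assert active.all()
        assert np.allclose(hxy, 1.0, atol=0.05)

    def test_double_efficiency_pixel_recovered(self, rng):
        inst = make_instrument(n_pixels=8)
        det = inst.detectors[0]
        xg, yg = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        d = g.pixel_distance_sq(xg, yg, det)
        eff = np.ones((8, 8)); eff[3, 4] = 2.0
        lam_counts = 2e7 * eff / d
        counts = rng.poisson(lam_counts)[:, :, None].astype(float)
        h = hm.Histogram3D(counts=counts, edges=np.array([0.0, 100.0]),
                           detector_id=0)
        hxy, _ = hm.compute_Hxy(h, det, 0, 100)
        others = np.delete(hxy.ravel(), 3 * 8 + 4)
        assert hxy[3, 4] / np.mean(others) == pytest.approx(2.0, rel=0.1)

    def test_dead_pixel_flagged_and_excluded(self):
        inst = make_instrument(n_pixels=4)
        det = inst.detectors[0]
        counts = np.full((4, 4, 1), 100.0); counts[1, 2, 0] = 0.0
        h = hm.Histogram3D(counts=counts, edges=np.array([0.0, 10.0]),
                           detector_id=0)
        hxy, active = hm.compute_Hxy(h, det, 0, 10)
        assert not active[1, 2]
        assert hxy[1, 2] == 0.0
        assert np.mean(hxy[active]) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_vanadium_rejected(self):
        inst = make_instrument(n_pixels=4)
        h = hm.Histogram3D(counts=np.zeros((4, 4, 1)),
                           edges=np.array([0.0, 10.0]), detector_id=0)
        with pytest.raises(ValueError):
            hm.compute_Hxy(h, inst.detectors[0], 0, 10)


class TestHtof:
    def _hist(self, per_channel, edges):
        counts = np.zeros((2, 2, len(per_channel)))
        counts[0, 0, :] = per_channel
        return hm.Histogram3D(counts=counts, edges=np.asarray(edges, float),
                              detector_id=0)

    def test_flat_spectrum_gives_unity(self):
        h = self._hist([10, 10, 10, 10], np.linspace(0, 4, 5))
        assert np.allclose(hm.compute_Htof(h, 0, 4), 1.0)

    def test_doubled_channel(self):
        h = self._hist([10, 20, 10, 10], np.linspace(0, 4, 5))
        htof = hm.compute_Htof(h, 0, 4)
        assert htof[1] / htof[0] == pytest.approx(2.0)

    def test_maxwellian_shape_recovered_with_mean_one(self):
        beam = sim.BeamModel()
        edges = np.linspace(5000, 40000, 101)
        centers = 0.5 * (edges[:-1] + edges[1:])
        lam = g.tof_to_wavelength(centers, 40.49)
        spec = beam.spectrum(lam)
        h = self._hist(spec * 1e4, edges)
        htof = hm.compute_Htof(h, 5000, 40000)
        assert np.mean(htof) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(htof, spec / spec.mean(), rtol=1e-9)

    def test_binning_mismatch_rejected_and_rebin_fixes(self):
        h = self._hist([10, 10, 10, 10], np.linspace(0, 4, 5))
        sample_edges = np.linspace(0, 4, 9)
        with pytest.raises(ValueError):
            hm.compute_Htof(h, 0, 4, sample_edges=sample_edges)
        hr = hm.rebin_to_channels(h, sample_edges)
        assert hr.counts.sum() == pytest.approx(h.counts.sum())
        assert np.allclose(hm.compute_Htof(hr, 0, 4, sample_edges=sample_edges), 1.0)


class TestPowerScale:
    def test_equal_counts(self):
        assert np.allclose(hm.compute_C([5, 5, 5]), 1.0)

    def test_double_count_halves_scale(self):
        assert hm.compute_C([1000, 2000])[1] == 0.5

    def test_direct_evaluation(self):
        assert np.allclose(hm.compute_C([1000, 800, 1250]), [1.0, 1.25, 0.8])

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            hm.compute_C([100, 0])


class TestApplyCorrections:
    def _model(self, nx=4, nt=3, C=(1.0, 0.5)):
        return hm.CorrectionModel(
            H_xy={0: np.ones((nx, nx))}, H_tof={0: np.ones(nt)},
            active={0: np.ones((nx, nx), dtype=bool)},
            C=np.asarray(C), t_window=(0, 30),
        )

    def _hist(self, counts, orientation_id=0):
        return hm.Histogram3D(counts=counts,
                              edges=np.linspace(0, 30, counts.shape[2] + 1),
                              detector_id=0, orientation_id=orientation_id)

    def test_unit_corrections_scale_by_C(self, rng):
        counts = rng.poisson(5.0, (4, 4, 3)).astype(float)
        out = hm.apply_corrections(self._hist(counts, orientation_id=1),
                                   self._model())
        assert np.allclose(out.counts, counts * 0.5)
        assert out.corrected

    def test_small_factor_zeroing_rule(self):
        m = self._model()
        m.H_xy[0][2, 2] = 1e-6  # product below the 1e-5 threshold
        counts = np.full((4, 4, 3), 7.0)
        out = hm.apply_corrections(self._hist(counts), m)
        assert np.all(out.counts[2, 2, :] == 0.0)
        assert np.all(out.counts[0, 0, :] == 7.0)

    def test_linear_in_raw_counts(self, rng):
        m = self._model()
        m.H_xy[0] = rng.uniform(0.5, 2.0, (4, 4))
        a = rng.poisson(5.0, (4, 4, 3)).astype(float)
        b = rng.poisson(5.0, (4, 4, 3)).astype(float)
        out_sum = hm.apply_corrections(self._hist(a + b), m)
        out_a = hm.apply_corrections(self._hist(a), m)
        out_b = hm.apply_corrections(self._hist(b), m)
        assert np.allclose(out_sum.counts, out_a.counts + out_b.counts)

    def test_shape_mismatch_rejected(self, rng):
        m = self._model(nx=5)
        with pytest.raises(ValueError):
            hm.apply_corrections(self._hist(np.zeros((4, 4, 3))), m)


class TestCorrectionClosure:
    def test_flat_field_closure(self):
        """Sample data generated from the vanadium's own efficiency and
        spectrum model correct to a uniform histogram (chi^2 test)."""
        inst = sim.default_instrument(n_detectors=1)
        beam = sim.BeamModel()
        eff = sim.default_efficiency_maps(inst, amplitude=0.15, seed=3)
        van_s, van_l = sim.generate_vanadium(
            beam, inst, eff, seed=6, events_per_detector=2_000_000)
        van = hm.merge_vanadium(van_s, van_l, inst)
        corr = hm.build_correction_model(van, inst, [1.0], *inst.tof_range,
                                         n_channels=50)
        flat = sim.generate_flat_events(beam, inst, eff, rate_per_pixel=200.0,
                                        seed=7)
        raw = hm.bin_events(flat, inst, n_channels=50)[0]
        out = hm.apply_corrections(raw, corr)
        per_pixel = out.counts.sum(axis=2)
        var_pixel = out.variance.sum(axis=2)
        # variance model for the chi^2 denominator:
        # (a) sample counting noise, pooled across pixels (up to the 1/eff
        #     scale) so the estimate is independent of each pixel's own
        #     fluctuation,
        # (b) the vanadium counting noise inside H_xy; the merged vanadium
        #     has weighted events so its variance is the sum of w^2
        hxy = corr.H_xy[0]
        var_sample = float(np.mean(var_pixel * hxy)) / hxy
        vhist = hm.bin_events(van, inst, n_channels=50)[0]
        van_sq = hm.EventList(
            events=van.events.assign(weight=van.events.weight**2),
            n_neutron=van.n_neutron)
        vhist2 = hm.bin_events(van_sq, inst, n_channels=50)[0]
        H2 = vhist.counts.sum(axis=2)
        H2_var = vhist2.counts.sum(axis=2)
        var_total = var_sample + per_pixel**2 * H2_var / H2**2
        mean = per_pixel.mean()
        chi2 = float(np.sum((per_pixel - mean) ** 2 / var_total))
        dof = per_pixel.size - 1
        lo, hi = stats.chi2.ppf([0.005, 0.995], dof)
        assert lo < chi2 < hi

    def test_corrections_invariant_to_vanadium_rescale(self, rng):
        inst = make_instrument(n_pixels=8)
        det = inst.detectors[0]
        counts = rng.poisson(50.0, (8, 8, 5)).astype(float)
        h1 = hm.Histogram3D(counts=counts, edges=np.linspace(0, 50, 6),
                            detector_id=0)
        h2 = hm.Histogram3D(counts=3.7 * counts, edges=np.linspace(0, 50, 6),
                            detector_id=0)
        a1, _ = hm.compute_Hxy(h1, det, 0, 50)
        a2, _ = hm.compute_Hxy(h2, det, 0, 50)
        assert np.allclose(a1, a2)
        assert np.allclose(hm.compute_Htof(h1, 0, 50),
                           hm.compute_Htof(h2, 0, 50))


def test_histogram_h5_round_trip(tmp_path, rng):
    counts = rng.poisson(3.0, (4, 4, 6)).astype(float)
    h = hm.Histogram3D(counts=counts, edges=np.linspace(0, 60, 7),
                       detector_id=2, orientation_id=1)
    hm.write_histogram(h, tmp_path / "h.h5")
    back = hm.read_histogram(tmp_path / "h.h5")
    assert np.array_equal(back.counts, h.counts)
    assert back.detector_id == 2 and back.orientation_id == 1


def test_slice_maps_are_projections(rng):
    counts = rng.poisson(2.0, (4, 4, 6)).astype(float)
    h = hm.Histogram3D(counts=counts, edges=np.linspace(0, 60, 7), detector_id=0)
    maps = hm.slice_maps(h)
    assert np.array_equal(maps["xy"], counts.sum(axis=2))
    assert np.array_equal(maps["xt"], counts.sum(axis=1))
    assert np.array_equal(maps["yt"], counts.sum(axis=0))
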