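"""Reflection prediction, integration, overlap rejection and Lorentz."""

import math

import numpy as np
import pytest

from toflaue import geometry as g
from toflaue import histogram as hm
from toflaue import integrate as ig
from toflaue import indexing as ix
from toflaue import simulate as sim
from toflaue import pipeline as pl


def small_region(**kw):
    kw.setdefault("half_x", 3.5)
    kw.setdefault("half_y", 3.5)
    kw.setdefault("half_t", 2)
    kw.setdefault("bg_margin_xy", 2)
    kw.setdefault("bg_margin_t", 3)
    return ig.IntegrationRegion(**kw)


class TestPredictAll:
    def test_generator_peaks_all_predicted(self, reduction):
        """Every planted reflection appears in the prediction list at the
        planted position (within half a pixel / one channel)."""
        truth = reduction.truth
        M = pl.basis_change(reduction.refinement.ub,
                            reduction.fixture.crystal.ub())
        pred_map = {
            (r.orientation_id, r.detector_id, r.h, r.k, r.l): r
            for r in reduction.predictions
        }
        width = float(np.mean(
            next(iter(reduction.hists.values())).channel_widths))
        n_found = 0
        for _, row in truth.iterrows():
            hf = M @ np.array([int(row.h), int(row.k), int(row.l)])
            key = (int(row.orientation_id), int(row.detector_id),
                   int(hf[0]), int(hf[1]), int(hf[2]))
            r = pred_map.get(key)
            if r is None:
                continue
            n_found += 1
            assert abs(r.x_p - row.x_p) < 0.5
            assert abs(r.y_p - row.y_p) < 0.5
            assert abs(r.t_p - row.t_p) < width
        assert n_found >= 0.98 * len(truth)

    def test_body_centering_extinction(self):
        ub = ix.ub_from_cell((24.0, 25.0, 26.0, 90, 90, 90))
        inst = sim.default_instrument(n_detectors=2)
        gonios = {0: g.GoniometerSetting()}
        preds = ig.predict_all(ub, gonios, inst, centering="I",
                               resolution_range=(1.3, 30.0))
        assert preds
        assert all((p.h + p.k + p.l) % 2 == 0 for p in preds)

    def test_bragg_consistency_of_predictions(self):
        ub = ix.ub_from_cell((24.0, 25.0, 26.0, 90, 90, 90))
        inst = sim.default_instrument(n_detectors=3)
        preds = ig.predict_all(ub, {0: g.GoniometerSetting()}, inst,
                               resolution_range=(1.3, 30.0))
        for p in preds[:200]:
            assert p.lam == pytest.approx(
                2 * p.d * math.sin(math.radians(p.two_theta / 2)), abs=1e-9)

    def test_near_border_reflection_flagged_edge(self, reduction):
        region = small_region()
        hx = region.half_x + region.bg_margin_xy
        det = reduction.fixture.instrument.detectors[0]
        for p in reduction.predictions:
            near = (p.x_p - hx < -0.5 or p.x_p + hx > det.n_pixels_x - 0.5
                    or p.y_p - hx < -0.5 or p.y_p + hx > det.n_pixels_y - 0.5)
            if near:
                assert p.status in ("edge",)


def flat_hist(shape=(32, 32, 40), level=0.0):
    counts = np.full(shape, level, dtype=float)
    return hm.Histogram3D(counts=counts,
                          edges=np.linspace(0, 400 * shape[2], shape[2] + 1),
                          detector_id=0)


def refl_at(x, y, t, det=0, oid=0):
    return ig.PredictedReflection(
        h=1, k=2, l=3, detector_id=det, x_p=x, y_p=y, t_p=t,
        lam=2.0, d=5.0, two_theta=60.0, orientation_id=oid,
    )


class TestSummation:
    def test_planted_counts_recovered_exactly_noise_free(self):
        h = flat_hist(level=2.0)
        r = refl_at(16.0, 16.0, 8000.0)
        region = small_region()
        S = 500.0
        # put all the signal on the central voxel
        h.counts[16, 16, 19] += S
        out = ig.integrate_summation(h, r, region)
        assert out.raw_intensity == pytest.approx(S, rel=1e-12)

    def test_zero_counts_give_zero_with_background_sigma(self):
        h = flat_hist(level=0.0)
        r = refl_at(16.0, 16.0, 8000.0)
        out = ig.integrate_summation(h, r, small_region())
        assert out.raw_intensity == 0.0
        assert out.raw_sigma >= 0.0

    def test_matches_naive_voxel_loop_exactly(self, rng):
        """Bit-for-bit agreement with an independent voxel-by-voxel
        implementation on random data."""
        counts = rng.poisson(4.0, (32, 32, 40)).astype(float)
        h = hm.Histogram3D(counts=counts, edges=np.linspace(0, 16000, 41),
                           detector_id=0)
        region = small_region()
        r = refl_at(15.3, 17.8, 7800.0)
        out = ig.integrate_summation(h, r, region)

        # -- independent oracle ------------------------------------------
        centers = h.channel_centers
        c_idx = int(np.argmin(np.abs(centers - r.t_p)))
        bx = region.half_x + region.bg_margin_xy
        by = region.half_y + region.bg_margin_xy
        bt = region.half_t + region.bg_margin_t
        core_vals, shell_vals = [], []
        for i in range(int(math.floor(r.x_p - bx)), int(math.ceil(r.x_p + bx)) + 1):
            for j in range(int(math.floor(r.y_p - by)), int(math.ceil(r.y_p + by)) + 1):
                for c in range(c_idx - bt, c_idx + bt + 1):
                    in_core = (
                        ((i - r.x_p) / region.half_x) ** 2
                        + ((j - r.y_p) / region.half_y) ** 2 <= 1.0
                        and abs(c - c_idx) <= region.half_t
                    )
                    (core_vals if in_core else shell_vals).append(counts[i, j, c])
        shell_vals = np.array(shell_vals)
        keep = np.ones(len(shell_vals), dtype=bool)
        for _ in range(2):
            m, s = shell_vals[keep].mean(), shell_vals[keep].std()
            if s == 0:
                break
            new = np.abs(shell_vals - m) <= 3.0 * s
            if new.sum() < max(4, len(shell_vals) // 4):
                break
            keep = new
        b = shell_vals[keep].mean()
        expect = float(np.sum(core_vals) - len(core_vals) * b)
        assert out.raw_intensity == expect

    def test_region_outside_histogram_rejected(self):
        h = flat_hist()
        with pytest.raises(ValueError):
            ig.integrate_summation(h, refl_at(2.0, 16.0, 8000.0), small_region())


class TestOverlap:
    def test_far_apart_not_overlapped(self):
        region = small_region()
        a = refl_at(10.0, 10.0, 8000.0)
        b = refl_at(28.0, 28.0, 8000.0)
        assert not ig.detect_overlap(a, [b], region)

    def test_concentric_overlapped(self):
        region = small_region()
        a = refl_at(10.0, 10.0, 8000.0)
        b = refl_at(10.0, 10.0, 8000.0)
        b.h = 9
        assert ig.detect_overlap(a, [b], region)

    def test_matches_point_sampling_oracle(self, rng):
        """Ellipse-ellipse in-plane test against dense containment
        sampling over random center separations."""
        region = small_region()
        a1 = region.half_x + region.bg_margin_xy
        b1 = region.half_y + region.bg_margin_xy
        a2, b2 = region.half_x, region.half_y
        n_bad = 0
        for _ in range(2000):
            dx, dy = rng.uniform(-12, 12, 2)
            got = ig._ellipses_intersect(dx, dy, a1, b1, a2, b2)
            th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
            rr = np.linspace(0, 1, 25)[None, :]
            ex = (dx + a2 * (np.cos(th)[:, None] * rr)).ravel()
            ey = (dy + b2 * (np.sin(th)[:, None] * rr)).ravel()
            expect = bool(np.any((ex / a1) ** 2 + (ey / b1) ** 2 <= 1.0))
            if got != expect:
                n_bad += 1
        assert n_bad <= 2  # only razor-thin tangential cases may disagree

    def test_no_flagged_reflection_in_output(self, reduction):
        ok_keys = {(r.orientation_id, r.detector_id, r.hkl)
                   for r in reduction.predictions if r.status == "ok"}
        for r in reduction.reflections:
            assert (r.orientation_id, r.detector_id, r.hkl) in ok_keys


class TestProfileFit:
    def _planted_profile_hist(self, area, mu_ch, sigma, tau, level, rng=None):
        h = flat_hist(level=level, shape=(32, 32, 40))
        centers = h.channel_centers
        width = centers[1] - centers[0]
        shape = ig.emg_profile(centers, area * width, centers[mu_ch], sigma, tau)
        # place the profile on one pixel inside the core
        h.counts[16, 16, :] += shape / width * width
        if rng is not None:
            h.counts = rng.poisson(h.counts).astype(float)
        return h

    def test_noise_free_area_recovered(self):
        h = self._planted_profile_hist(area=3000.0, mu_ch=20, sigma=600.0,
                                       tau=900.0, level=1.0)
        r = refl_at(16.0, 16.0, float(h.channel_centers[20]))
        region = small_region(half_t=6, bg_margin_t=8)
        out = ig.integrate_profile_fit(h, r, region)
        assert not out.fit_fallback
        assert out.raw_intensity == pytest.approx(3000.0, rel=1e-4)

    def test_noisy_replicates_unbiased_and_sigma_calibrated(self, rng):
        area, sigma, tau = 3000.0, 600.0, 900.0
        vals, sigs = [], []
        for _ in range(120):
            h = self._planted_profile_hist(area=area, mu_ch=20, sigma=sigma,
                                           tau=tau, level=4.0, rng=rng)
            r = refl_at(16.0, 16.0, float(h.channel_centers[20]))
            out = ig.integrate_profile_fit(
                h, r, small_region(half_t=6, bg_margin_t=8))
            if not out.fit_fallback:
                vals.append(out.raw_intensity)
                sigs.append(out.raw_sigma)
        vals, sigs = np.array(vals), np.array(sigs)
        assert len(vals) > 100
        assert vals.mean() == pytest.approx(area, rel=0.02)
        assert np.mean(sigs) == pytest.approx(vals.std(), rel=0.25)

    def test_flat_profile_falls_back(self):
        h = flat_hist(level=5.0)
        r = refl_at(16.0, 16.0, 8000.0)
        out = ig.integrate_profile_fit(h, r, small_region(half_t=6,
                                                          bg_margin_t=8))
        assert out.fit_fallback
        assert out.method == "profile_fit"

    def test_sigma_not_below_cramer_rao(self, rng):
        """The reported sigma equals the Fisher-information bound computed
        from the model at the fitted parameters (within 1%)."""
        h = self._planted_profile_hist(area=5000.0, mu_ch=20, sigma=600.0,
                                       tau=900.0, level=4.0, rng=rng)
        r = refl_at(16.0, 16.0, float(h.channel_centers[20]))
        region = small_region(half_t=6, bg_margin_t=8)
        out = ig.integrate_profile_fit(h, r, region)
        assert not out.fit_fallback
        # recompute the CRB: J^T W J at the fitted parameters
        sl, core, shell, c_idx = ig._region_masks(h, r, region)
        box = h.counts[sl]
        in_xy = core.any(axis=2)
        prof = box[in_xy, :].sum(axis=0)
        centers = h.channel_centers[sl[2]]
        w = np.clip(box[in_xy, :].sum(axis=0), 1.0, None)

        # refit to obtain the parameter vector (area in us units)
        from scipy.optimize import curve_fit
        width = float(np.mean(np.diff(centers)))
        p0 = [out.raw_intensity * width, centers[np.argmax(prof)], 600.0,
              900.0, prof.min(), 0.0]
        popt, pcov = curve_fit(ig._profile_model, centers, prof, p0=p0,
                               sigma=np.sqrt(w), absolute_sigma=True,
                               maxfev=5000)
        eps = 1e-6
        J = np.empty((len(centers), len(popt)))
        for k in range(len(popt)):
            dp = np.array(popt); dp[k] += eps * max(1.0, abs(popt[k]))
            dm = np.array(popt); dm[k] -= eps * max(1.0, abs(popt[k]))
            J[:, k] = (ig._profile_model(centers, *dp)
                       - ig._profile_model(centers, *dm)) / (
                           2 * eps * max(1.0, abs(popt[k])))
        F = J.T @ (J / w[:, None])
        crb = math.sqrt(np.linalg.inv(F)[0, 0]) / width
        assert out.raw_sigma >= crb * 0.99


class TestLorentz:
    def test_backscatter_unit_wavelength_factor_one(self):
        I, s = ig.lorentz_correct(10.0, 1.0, 1.0, 180.0)
        assert I == pytest.approx(10.0) and s == pytest.approx(1.0)

    def test_lambda_fourth_law(self):
        I1, _ = ig.lorentz_correct(16.0, 1.0, 1.0, 60.0)
        I2, _ = ig.lorentz_correct(16.0, 1.0, 2.0, 60.0)
        assert I1 / I2 == pytest.approx(16.0)

    def test_equivalents_agree_only_after_correction(self, reduction):
        """Equivalent reflections measured at different wavelengths show a
        wavelength trend in raw intensities that the correction removes."""
        from scipy import stats as st

        groups = {}
        for m in reduction.merged.reflections.values():
            if m.multiplicity >= 2:
                lams = [o.lam for o in m.observations]
                if max(lams) - min(lams) > 0.4:
                    groups[m.hkl] = m.observations
        assert len(groups) >= 10
        raw_ratio, cor_ratio = [], []
        for obs in groups.values():
            obs = sorted(obs, key=lambda o: o.lam)
            lo_l, hi_l = obs[0], obs[-1]
            if lo_l.raw_intensity > 0 and lo_l.intensity > 0:
                raw_ratio.append(np.log(max(hi_l.raw_intensity, 1e-9)
                                        / lo_l.raw_intensity))
                cor_ratio.append(np.log(max(hi_l.intensity, 1e-12)
                                        / lo_l.intensity))
        raw_ratio, cor_ratio = np.array(raw_ratio), np.array(cor_ratio)
        # raw: systematically brighter at longer wavelength
        assert np.median(raw_ratio) > 0.5
        # corrected: no systematic trend
        assert abs(np.median(cor_ratio)) < np.median(raw_ratio) / 4

    def test_invalid_angle_rejected(self):
        with pytest.raises(ValueError):
            ig.lorentz_correct(1.0, 0.1, 1.0, 0.0)


class TestGrouping:
    def test_single_group(self):
        inst = sim.default_instrument()
        groups = ig.group_by_scattering_angle(inst, [])
        assert groups[0] == [d.detector_id for d in inst.detectors]

    def test_boundaries_partition_detectors(self):
        inst = sim.default_instrument()
        groups = ig.group_by_scattering_angle(inst, [60.0, 120.0])
        all_ids = sorted(i for ids in groups.values() for i in ids)
        assert all_ids == sorted(d.detector_id for d in inst.detectors)
        assert len(groups) == 3

    def test_unsorted_boundaries_rejected(self):
        inst = sim.default_instrument()
        with pytest.raises(ValueError):
            ig.group_by_scattering_angle(inst, [120.0, 60.0])


def test_reflection_table_round_trip(tmp_path, reduction):
    refls = reduction.reflections[:30]
    ig.write_reflections(refls, tmp_path / "r.tsv")
    back = ig.read_reflections(tmp_path / "r.tsv")
    assert len(back) == 30
    for a, b in zip(back, refls):
        assert a.hkl == b.hkl
        assert a.intensity == pytest.approx(b.intensity)
        assert a.method == b.method
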