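"""Reflection prediction and intensity integration.

Given a refined UB, every reflection that can land on a detector inside the
TOF window is predicted: the Miller-index bounding box is spanned by the
Q-vectors of the four detector corners at both TOF extremes, the centering
extinction rule prunes forbidden indices, and each surviving (h, k, l) is
traced to a detector pixel and arrival time.  Reflections whose integration
region would cross a detector edge, or whose regions overlap a neighbour's,
are discarded rather than integrated.

Intensities come from either plain summation (core counts minus a shell
background estimate) or a 1D profile fit along TOF of an exponentially
modified Gaussian - the asymmetric pulse shape a coupled moderator
produces - on top of a linear background.  The TOF-Laue Lorentz factor
``sin^2(theta) / lambda^4`` puts observations at different wavelengths on a
common scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import exponnorm

from .geometry import (
    DetectorGeometry,
    GoniometerSetting,
    Instrument,
    QVector,
    lab_to_q_array,
    pixel_to_lab,
    q_to_zero_setting,
    scattering_angle_deg,
    tof_to_wavelength,
)
from .histogram import Histogram3D
from .indexing import UBState
from .peaksearch import TofOffsetModel

CENTERING_RULES = {
    "P": lambda h, k, l: np.ones_like(h, dtype=bool),
    "I": lambda h, k, l: (h + k + l) % 2 == 0,
    "F": lambda h, k, l: ((h % 2 == k % 2) & (k % 2 == l % 2)),
    "C": lambda h, k, l: (h + k) % 2 == 0,
    "A": lambda h, k, l: (k + l) % 2 == 0,
    "B": lambda h, k, l: (h + l) % 2 == 0,
    "H": lambda h, k, l: (-h + k + l) % 3 == 0,
}


@dataclass(frozen=True)
class IntegrationRegion:
    """Core + background-shell geometry of one reflection's region.

    In-plane half-sizes are pixels (rectangle half-widths or ellipse
    semi-axes), the TOF half-length is channels.  The background shell is
    the margin-grown box minus the core.
    """

    shape: str = "elliptic_cylinder"   # or "rectangle"
    half_x: float = 5.0
    half_y: float = 5.0
    half_t: int = 10
    bg_margin_xy: int = 3
    bg_margin_t: int = 5

    def __post_init__(self):
        if self.shape not in ("rectangle", "elliptic_cylinder"):
            raise ValueError("shape must be rectangle or elliptic_cylinder")
        if self.bg_margin_xy <= 0 or self.bg_margin_t <= 0:
            raise ValueError("background shell must strictly contain the core")


@dataclass
class PredictedReflection:
    h: int
    k: int
    l: int
    detector_id: int
    x_p: float
    y_p: float
    t_p: float          # us, TOF offset included
    lam: float
    d: float            # A
    two_theta: float    # degrees
    orientation_id: int
    status: str = "ok"  # ok | edge | overlapped | out_of_band

    @property
    def hkl(self):
        return (self.h, self.k, self.l)


@dataclass
class IntegratedReflection:
    h: int
    k: int
    l: int
    intensity: float          # Lorentz-corrected
    sigma: float
    raw_intensity: float
    raw_sigma: float
    lam: float
    d: float
    two_theta: float
    detector_id: int
    orientation_id: int
    method: str               # summation | profile_fit
    fit_fallback: bool = False
    fit_chi2: float = float("nan")
    fit_background: tuple = ()

    @property
    def hkl(self):
        return (self.h, self.k, self.l)


# --- prediction ------------------------------------------------------------

def _hkl_bounding_box(
    ub: UBState, g: GoniometerSetting, det: DetectorGeometry,
    instrument: Instrument, margin: int = 1,
):
    """Integer index ranges spanned by the detector corners x TOF extremes."""
    corners = [(0.0, 0.0), (det.n_pixels_x - 1.0, 0.0),
               (0.0, det.n_pixels_y - 1.0),
               (det.n_pixels_x - 1.0, det.n_pixels_y - 1.0)]
    t_lo, t_hi = instrument.tof_range
    UB_inv = np.linalg.inv(ub.UB)
    fracs = []
    lam_lo, lam_hi = instrument.wavelength_band
    for (cx, cy) in corners:
        pos = pixel_to_lab(cx, cy, det)
        L_tot = instrument.L1 + pos.L_prime_m
        for T in (t_lo, t_hi):
            lam = float(np.clip(tof_to_wavelength(max(T, 1.0), L_tot), lam_lo, lam_hi))
            q = lab_to_q_array(pos.as_array()[None, :], np.array([lam]))[0]
            q0 = q_to_zero_setting(QVector(*q), g).as_array()
            fracs.append(UB_inv @ q0)
    fracs = np.array(fracs)
    lo = np.floor(fracs.min(axis=0)).astype(int) - margin
    hi = np.ceil(fracs.max(axis=0)).astype(int) + margin
    return lo, hi


def predict_all(
    ub: UBState,
    goniometers: dict,
    instrument: Instrument,
    centering: str = "P",
    resolution_range: tuple = (0.5, 1e6),   # d_min, d_max in A
    tof_range: tuple | None = None,
    region: IntegrationRegion | None = None,
    tof_offset_model: TofOffsetModel | None = None,
) -> list[PredictedReflection]:
    """Predict all observable reflections on every detector/orientation.

    Centering-forbidden indices are dropped; reflections whose integration
    region would cross the detector edge are kept but flagged ``edge``.
    """
    if centering not in CENTERING_RULES:
        raise ValueError(f"unknown centering {centering!r}")
    rule = CENTERING_RULES[centering]
    region = region or IntegrationRegion()
    offset = tof_offset_model or TofOffsetModel()
    t_lo, t_hi = tof_range if tof_range is not None else instrument.tof_range
    d_min, d_max = resolution_range
    out: list[PredictedReflection] = []
    for oid, g in sorted(goniometers.items()):
        for det in instrument.detectors:
            lo, hi = _hkl_bounding_box(ub, g, det, instrument)
            hh, kk, ll = np.meshgrid(
                np.arange(lo[0], hi[0] + 1),
                np.arange(lo[1], hi[1] + 1),
                np.arange(lo[2], hi[2] + 1),
                indexing="ij",
            )
            hh, kk, ll = hh.ravel(), kk.ravel(), ll.ravel()
            keep = rule(hh, kk, ll) & ~((hh == 0) & (kk == 0) & (ll == 0))
            hh, kk, ll = hh[keep], kk[keep], ll[keep]
            hkls = np.column_stack([hh, kk, ll]).astype(float)
            qn = np.linalg.norm(hkls @ ub.UB.T, axis=1)
            with np.errstate(divide="ignore"):
                ds = 1.0 / qn
            sel = (ds >= d_min) & (ds <= d_max)
            hkls, ds_sel = hkls[sel], ds[sel]
            if not len(hkls):
                continue
            from .indexing import _predict_arrays
            from .geometry import goniometer_matrix

            R = goniometer_matrix(g)
            q_lab = (hkls @ ub.UB.T) @ R.T
            xp, yp, tp, lam, valid = _predict_arrays(q_lab, det, instrument.L1)
            lam_lo, lam_hi = instrument.wavelength_band
            with np.errstate(invalid="ignore"):
                in_band = valid & (lam >= lam_lo) & (lam <= lam_hi)
                on_det = (
                    (xp >= -0.5) & (xp <= det.n_pixels_x - 0.5)
                    & (yp >= -0.5) & (yp <= det.n_pixels_y - 0.5)
                )
                t_pred = tp + offset(lam)
                in_tof = (t_pred >= t_lo) & (t_pred <= t_hi)
                keep = in_band & on_det & in_tof
                hx = region.half_x + region.bg_margin_xy
                hy = region.half_y + region.bg_margin_xy
                edge = (
                    (xp - hx < -0.5) | (xp + hx > det.n_pixels_x - 0.5)
                    | (yp - hy < -0.5) | (yp + hy > det.n_pixels_y - 0.5)
                )
            for i in np.nonzero(keep)[0]:
                # scattering angle from |Q| = 2 sin(theta) / lambda
                s = min(1.0, lam[i] / (2.0 * ds_sel[i]))
                two_theta = 2.0 * math.degrees(math.asin(s))
                out.append(
                    PredictedReflection(
                        h=int(hkls[i, 0]), k=int(hkls[i, 1]), l=int(hkls[i, 2]),
                        detector_id=det.detector_id,
                        x_p=float(xp[i]), y_p=float(yp[i]), t_p=float(t_pred[i]),
                        lam=float(lam[i]), d=float(ds_sel[i]),
                        two_theta=two_theta,
                        orientation_id=oid,
                        status="edge" if edge[i] else "ok",
                    )
                )
    return out


# --- overlap rejection -----------------------------------------------------

def _point_to_ellipse_inside_or_near(cx, cy, ax, ay, px, py) -> float:
    """Distance measure: value <= 1 iff (px, py) lies inside the
    axis-aligned ellipse centered at (cx, cy) with semi-axes (ax, ay)."""
    return ((px - cx) / ax) ** 2 + ((py - cy) / ay) ** 2


def _ellipses_intersect(dx: float, dy: float, a1, b1, a2, b2,
                        n_boundary: int = 256) -> bool:
    """Do two axis-aligned ellipses (centers separated by (dx, dy)) overlap?

    Exact containment tests for the two centers plus a dense boundary
    sampling of the smaller ellipse against the larger's interior; the
    sampling resolves the lens-shaped partial overlaps the center tests
    miss.
    """
    # quick accept / reject via support-function bounds
    d2 = (dx / (a1 + a2)) ** 2 + (dy / (b1 + b2)) ** 2
    if d2 <= 1.0:
        # inner bound of the Minkowski sum: certain overlap
        return True
    r1 = math.hypot(dx / a1, dy / b1)
    # if even the most generous reach cannot touch, reject quickly
    if math.hypot(dx, dy) > math.hypot(a1, b1) + math.hypot(a2, b2):
        return False
    th = np.linspace(0, 2 * math.pi, n_boundary, endpoint=False)
    ex = dx + a2 * np.cos(th)
    ey = dy + b2 * np.sin(th)
    if np.any((ex / a1) ** 2 + (ey / b1) ** 2 <= 1.0):
        return True
    ex1 = a1 * np.cos(th)
    ey1 = b1 * np.sin(th)
    return bool(np.any(((ex1 - dx) / a2) ** 2 + ((ey1 - dy) / b2) ** 2 <= 1.0))


def detect_overlap(
    refl: PredictedReflection,
    neighbors: list[PredictedReflection],
    region: IntegrationRegion,
) -> bool:
    """Overlapped iff any neighbour's core intersects this reflection's
    core-or-background region (same detector and orientation only)."""
    tgt_ax = region.half_x + region.bg_margin_xy
    tgt_ay = region.half_y + region.bg_margin_xy
    tgt_t0 = refl.t_p  # channel comparisons handled in TOF units by caller
    for nb in neighbors:
        if nb is refl:
            continue
        if nb.detector_id != refl.detector_id or nb.orientation_id != refl.orientation_id:
            continue
        dx = nb.x_p - refl.x_p
        dy = nb.y_p - refl.y_p
        if abs(dx) > tgt_ax + region.half_x + 1 or abs(dy) > tgt_ay + region.half_y + 1:
            continue
        if not _tof_intervals_overlap(refl, nb, region):
            continue
        if region.shape == "rectangle":
            if abs(dx) <= tgt_ax + region.half_x and abs(dy) <= tgt_ay + region.half_y:
                return True
        else:
            if _ellipses_intersect(dx, dy, tgt_ax, tgt_ay, region.half_x, region.half_y):
                return True
    return False


def _tof_intervals_overlap(a: PredictedReflection, b: PredictedReflection,
                           region: IntegrationRegion) -> bool:
    # half_t is in channels; compare in channel units via the caller-set
    # channel width attribute, defaulting to a generous TOF window
    w = getattr(region, "_channel_width_us", None)
    half_a = (region.half_t + region.bg_margin_t)
    half_b = region.half_t
    if w is None:
        return True
    return abs(a.t_p - b.t_p) <= (half_a + half_b) * w


def flag_overlaps(
    predictions: list[PredictedReflection],
    region: IntegrationRegion,
    channel_width_us: float | None = None,
) -> list[PredictedReflection]:
    """Mark overlapped reflections in place (status 'overlapped')."""
    if channel_width_us is not None:
        object.__setattr__(region, "_channel_width_us", channel_width_us)
    by_frame: dict = {}
    for r in predictions:
        by_frame.setdefault((r.detector_id, r.orientation_id), []).append(r)
    for frame in by_frame.values():
        for r in frame:
            if r.status != "ok":
                continue
            if detect_overlap(r, frame, region):
                r.status = "overlapped"
    return predictions


# --- summation integration -------------------------------------------------

def _region_masks(h: Histogram3D, refl: PredictedReflection,
                  region: IntegrationRegion):
    """Boolean (core, shell) voxel masks of the region in the histogram."""
    nx, ny, nt = h.counts.shape
    centers = h.channel_centers
    c_idx = int(np.argmin(np.abs(centers - refl.t_p)))
    cx, cy = refl.x_p, refl.y_p
    hx, hy, ht = region.half_x, region.half_y, region.half_t
    bx, by, bt = hx + region.bg_margin_xy, hy + region.bg_margin_xy, ht + region.bg_margin_t
    x0, x1 = int(math.floor(cx - bx)), int(math.ceil(cx + bx))
    y0, y1 = int(math.floor(cy - by)), int(math.ceil(cy + by))
    c0, c1 = c_idx - bt, c_idx + bt
    if x0 < 0 or y0 < 0 or c0 < 0 or x1 >= nx or y1 >= ny or c1 >= nt:
        raise ValueError("integration region crosses the histogram boundary")
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    cs = np.arange(c0, c1 + 1)
    X, Y, C = np.meshgrid(xs, ys, cs, indexing="ij")
    in_t_core = np.abs(C - c_idx) <= ht
    if region.shape == "rectangle":
        in_xy_core = (np.abs(X - cx) <= hx) & (np.abs(Y - cy) <= hy)
    else:
        in_xy_core = ((X - cx) / hx) ** 2 + ((Y - cy) / hy) ** 2 <= 1.0
    core = in_xy_core & in_t_core
    shell = ~core
    return (slice(x0, x1 + 1), slice(y0, y1 + 1), slice(c0, c1 + 1)), core, shell, c_idx


def _background_mean(vals: np.ndarray, var: np.ndarray,
                     n_sigma: float = 3.0, passes: int = 2):
    """Shell background with iterated outlier rejection against neighbour
    tails.  Returns (mean, variance of the mean, mask used)."""
    keep = np.ones(len(vals), dtype=bool)
    for _ in range(passes):
        m = vals[keep].mean()
        s = vals[keep].std()
        if s == 0:
            break
        new = np.abs(vals - m) <= n_sigma * s
        if new.sum() < max(4, len(vals) // 4):
            break
        keep = new
    n = keep.sum()
    mean = vals[keep].mean()
    var_mean = var[keep].sum() / n**2
    return float(mean), float(var_mean), keep


def integrate_summation(
    h: Histogram3D,
    refl: PredictedReflection,
    region: IntegrationRegion,
) -> IntegratedReflection:
    """Background-subtracted summation over the core region.

    ``I = sum(core) - n_core * <background>``; the variance combines the
    per-voxel (corrected-count) variances of the core and the background
    mean.
    """
    sl, core, shell, _ = _region_masks(h, refl, region)
    box = h.counts[sl]
    var = h.variance[sl] if h.variance is not None else box.copy()
    if shell.sum() == 0:
        raise ValueError("empty background shell")
    b_mean, b_var, _ = _background_mean(box[shell], var[shell])
    n_core = int(core.sum())
    raw_I = float(box[core].sum() - n_core * b_mean)
    raw_var = float(var[core].sum() + n_core**2 * b_var)
    raw_sigma = math.sqrt(max(raw_var, 0.0))
    I, sig = lorentz_correct(raw_I, raw_sigma, refl.lam, refl.two_theta)
    return IntegratedReflection(
        h=refl.h, k=refl.k, l=refl.l,
        intensity=I, sigma=sig, raw_intensity=raw_I, raw_sigma=raw_sigma,
        lam=refl.lam, d=refl.d, two_theta=refl.two_theta,
        detector_id=refl.detector_id, orientation_id=refl.orientation_id,
        method="summation",
    )


# --- profile fitting -------------------------------------------------------

def emg_profile(t, area, mu, sigma, tau):
    """Exponentially modified Gaussian scaled to a given integrated area."""
    sigma = abs(sigma)
    tau = abs(tau)
    K = max(tau / sigma, 1e-6)
    return area * exponnorm.pdf(t, K, loc=mu, scale=sigma)


def _profile_model(t, area, mu, sigma, tau, b0, b1):
    return emg_profile(t, area, mu, sigma, tau) + b0 + b1 * (t - t.mean())


def integrate_profile_fit(
    h: Histogram3D,
    refl: PredictedReflection,
    region: IntegrationRegion,
    chi2_cutoff: float = 10.0,
    min_bins: int = 7,
) -> IntegratedReflection:
    """Fit the in-plane-summed 1D TOF profile with an asymmetric peak.

    The model is a Gaussian convolved with a single decaying exponential
    (pulse broadening from a coupled moderator) on a linear background;
    the intensity is the analytic area of the fitted peak and its sigma
    comes from the fit covariance.  Falls back to summation (flagged) when
    the fit fails or fits poorly.
    """
    sl, core, shell, c_idx = _region_masks(h, refl, region)
    box = h.counts[sl]
    var = h.variance[sl] if h.variance is not None else box.copy()
    in_xy_core = core.any(axis=2)
    prof = box[in_xy_core, :].sum(axis=0)
    prof_var = var[in_xy_core, :].sum(axis=0)
    centers = h.channel_centers[sl[2]]
    if len(centers) < min_bins:
        return _fallback(h, refl, region, "too few TOF bins")
    width = float(np.mean(np.diff(centers)))
    # background first guess from the outer TOF bins
    edge = max(2, region.bg_margin_t // 2)
    b0 = float(np.concatenate([prof[:edge], prof[-edge:]]).mean())
    area0 = float((prof - b0).sum()) * width  # model area is counts * us
    if area0 <= 0:
        return _fallback(h, refl, region, "no net counts")
    mu0 = float(centers[int(np.clip(np.argmax(prof), 0, len(centers) - 1))])
    sigma0 = max(1.0 * width, 1e-3)
    tau0 = sigma0
    w = np.sqrt(np.clip(prof_var, 1.0, None))
    span = centers[-1] - centers[0]
    try:
        popt, pcov = curve_fit(
            _profile_model, centers, prof,
            p0=[area0, mu0, sigma0, tau0, b0, 0.0],
            sigma=w, absolute_sigma=True, maxfev=5000,
            bounds=(
                [0.0, centers[0], width / 20.0, width / 20.0, -np.inf, -np.inf],
                [np.inf, centers[-1], span, span, np.inf, np.inf],
            ),
        )
    except Exception:
        return _fallback(h, refl, region, "fit did not converge")
    resid = (prof - _profile_model(centers, *popt)) / w
    dof = max(len(prof) - 6, 1)
    chi2 = float(resid @ resid / dof)
    if not np.isfinite(pcov).all() or chi2 > chi2_cutoff or popt[0] <= 0:
        return _fallback(h, refl, region, "poor fit")
    # the model is a density in us while counts are per channel: the
    # fitted area parameter carries one factor of the channel width
    raw_I = float(popt[0]) / width
    raw_sigma = float(math.sqrt(max(pcov[0, 0], 0.0))) / width
    I, sig = lorentz_correct(raw_I, raw_sigma, refl.lam, refl.two_theta)
    return IntegratedReflection(
        h=refl.h, k=refl.k, l=refl.l,
        intensity=I, sigma=sig, raw_intensity=raw_I, raw_sigma=raw_sigma,
        lam=refl.lam, d=refl.d, two_theta=refl.two_theta,
        detector_id=refl.detector_id, orientation_id=refl.orientation_id,
        method="profile_fit", fit_chi2=chi2,
        fit_background=(float(popt[4]), float(popt[5])),
    )


def _fallback(h, refl, region, reason: str) -> IntegratedReflection:
    out = integrate_summation(h, refl, region)
    out.method = "profile_fit"
    out.fit_fallback = True
    return out


def profile_fit_plot_data(
    h: Histogram3D, refl: PredictedReflection, region: IntegrationRegion,
    result: IntegratedReflection,
) -> pd.DataFrame:
    """Observed / fitted / background TOF profile for one reflection."""
    sl, core, _, _ = _region_masks(h, refl, region)
    box = h.counts[sl]
    in_xy_core = core.any(axis=2)
    prof = box[in_xy_core, :].sum(axis=0)
    centers = h.channel_centers[sl[2]]
    if result.fit_background:
        b0, b1 = result.fit_background
        bg = b0 + b1 * (centers - centers.mean())
    else:
        bg = np.full_like(centers, np.nan)
    return pd.DataFrame({"tof_us": centers, "observed": prof, "background": bg})


# --- Lorentz correction ----------------------------------------------------

def lorentz_correct(I: float, sigma: float, lam: float, two_theta: float):
    """TOF-Laue Lorentz correction: multiply by ``sin^2(theta)/lambda^4``."""
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    if not 0.0 < two_theta <= 180.0:
        raise ValueError("scattering angle must be in (0, 180) degrees")
    s = math.sin(math.radians(two_theta / 2.0))
    f = s * s / lam**4
    return I * f, sigma * f


# --- detector grouping -----------------------------------------------------

def group_by_scattering_angle(
    instrument: Instrument, boundaries: list[float]
) -> dict[int, list[int]]:
    """Assign detectors to 2-theta groups by their face-center angle.

    ``boundaries`` are sorted group edges in degrees; group g holds
    detectors with ``boundaries[g-1] <= 2theta < boundaries[g]``.
    """
    if sorted(boundaries) != list(boundaries):
        raise ValueError("boundaries must be sorted")
    groups: dict[int, list[int]] = {g: [] for g in range(len(boundaries) + 1)}
    for det in sorted(instrument.detectors, key=lambda d: d.detector_id):
        pos = pixel_to_lab((det.n_pixels_x - 1) / 2.0, (det.n_pixels_y - 1) / 2.0, det)
        tt = scattering_angle_deg(pos)
        g = int(np.searchsorted(boundaries, tt, side="right"))
        groups[g].append(det.detector_id)
    return groups


# --- pipeline driver -------------------------------------------------------

def integrate_all(
    hists: dict,
    predictions: list[PredictedReflection],
    region: IntegrationRegion | None = None,
    method: str = "summation",
) -> list[IntegratedReflection]:
    """Integrate every ok-status prediction found in ``hists``.

    ``hists`` maps (orientation_id, detector_id) -> corrected Histogram3D.
    Edge and overlapped reflections are skipped, as are regions that fall
    outside the histogram.
    """
    region = region or IntegrationRegion()
    out = []
    for refl in predictions:
        if refl.status != "ok":
            continue
        key = (refl.orientation_id, refl.detector_id)
        if key not in hists:
            continue
        h = hists[key]
        try:
            if method == "summation":
                out.append(integrate_summation(h, refl, region))
            elif method == "profile_fit":
                out.append(integrate_profile_fit(h, refl, region))
            else:
                raise ValueError(f"unknown method {method!r}")
        except ValueError:
            continue
    return out


# --- reflection table I/O --------------------------------------------------

REFL_COLUMNS = [
    "h", "k", "l", "intensity", "sigma", "raw_intensity", "raw_sigma",
    "lam", "d", "two_theta", "detector_id", "orientation_id", "method",
    "fit_fallback",
]


def reflections_to_frame(refls: list[IntegratedReflection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {c: getattr(r, c) for c in REFL_COLUMNS}
            for r in refls
        ],
        columns=REFL_COLUMNS,
    )


def write_reflections(refls: list[IntegratedReflection], path) -> None:
    reflections_to_frame(refls).to_csv(path, sep="\t", index=False)


def read_reflections(path) -> list[IntegratedReflection]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            IntegratedReflection(
                h=int(r["h"]), k=int(r["k"]), l=int(r["l"]),
                intensity=float(r["intensity"]), sigma=float(r["sigma"]),
                raw_intensity=float(r["raw_intensity"]),
                raw_sigma=float(r["raw_sigma"]),
                lam=float(r["lam"]), d=float(r["d"]),
                two_theta=float(r["two_theta"]),
                detector_id=int(r["detector_id"]),
                orientation_id=int(r["orientation_id"]),
                method=str(r["method"]),
                fit_fallback=bool(r["fit_fallback"]),
            )
        )
    return out
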