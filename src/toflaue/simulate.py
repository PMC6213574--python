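"""Synthetic diffraction fixtures with exact ground truth.

The generator emulates the inputs of the reduction pipeline from a known
crystal and instrument model: Bragg-peak event lists per crystal
orientation, vanadium calibration runs in two wavelength bands, and
per-orientation incident-neutron counts.  The generative chain is built to
be the exact inverse of the correction/integration chain, so the reduced
output should recover the planted cell and intensities up to counting
noise:

* detected peak counts carry the planted intensity times the incident
  spectrum, the detector efficiency and the *inverse* Lorentz factor
  ``lambda^4 / sin^2(theta)``, which the pipeline's corrections undo;
* the vanadium runs are flat incoherent scatter: spatial density
  proportional to efficiency / distance^2, wavelengths drawn from the
  same spectrum;
* event TOF is broadened by the asymmetric moderator pulse (Gaussian
  convolved with a decaying exponential) and shifted by the emission-time
  offset model.

What it does not emulate: absorption, extinction, detector dead time,
mosaic-spread wavelength coupling, or inter-reflection profile variation
beyond the pulse model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    DetectorGeometry,
    GoniometerSetting,
    Instrument,
    pixel_distance_sq,
    tof_to_wavelength,
    wavelength_to_tof,
)
from .histogram import EventList
from .indexing import UBState, ub_from_cell
from .integrate import IntegrationRegion, predict_all
from .peaksearch import TofOffsetModel
from .merge import SymmetrySpec


# --- models ----------------------------------------------------------------

@dataclass
class CrystalModel:
    """Planted crystal: cell, centering, orientation and intensity law.

    True squared structure factors are Wilson distributed (exponential with
    mean ``intensity_scale``) per symmetry-unique reflection, damped by an
    overall displacement factor ``exp(-2 B (sin(theta)/lambda)^2)``.
    ``sigma_x/sigma_y`` are the in-plane peak spreads in pixels.
    """

    cell: tuple = (25.2, 26.0, 27.1, 90.0, 90.0, 90.0)
    centering: str = "P"
    U: np.ndarray = field(default_factory=lambda: np.eye(3))
    intensity_scale: float = 1.0
    b_factor: float = 8.0          # A^2
    sigma_x: float = 1.1           # pixels
    sigma_y: float = 1.1
    symmetry: SymmetrySpec | None = None

    def ub(self) -> UBState:
        return ub_from_cell(self.cell, U=self.U, centering=self.centering)


@dataclass
class BeamModel:
    """Incident beam: band, spectrum shape, pulse shape and TOF offset.

    The spectrum is a Maxwellian peaked at ``lambda_peak`` plus a ``1/lambda``
    epithermal tail of weight ``epithermal_weight``.  The pulse is Gaussian
    (width ``pulse_sigma0 + pulse_sigma1*lambda`` us) convolved with a
    decaying exponential (constant ``pulse_tau0 + pulse_tau1*lambda`` us) -
    the asymmetric shape of a coupled-moderator source.
    """

    band: tuple = (0.7, 4.2)         # A
    lambda_peak: float = 1.9         # A
    epithermal_weight: float = 0.05
    pulse_sigma0: float = 8.0        # us
    pulse_sigma1: float = 4.0        # us per A
    pulse_tau0: float = 12.0         # us
    pulse_tau1: float = 6.0          # us per A
    tof_offset: TofOffsetModel | None = None   # None -> emission mean delay

    @property
    def offset_model(self) -> TofOffsetModel:
        """TOF-offset model: explicit coefficients when supplied, else the
        mean emission delay implied by the pulse shape.

        The Gaussian part of the pulse is centred, so the mean delay is the
        exponential constant ``tau0 + tau1*lambda`` - a linear model.
        """
        if self.tof_offset is not None:
            return self.tof_offset
        return TofOffsetModel((self.pulse_tau0, self.pulse_tau1))

    def spectrum(self, lam) -> np.ndarray:
        """Unnormalised spectral density on the band (positive)."""
        lam = np.asarray(lam, dtype=float)
        x = self.lambda_peak / np.clip(lam, 1e-6, None)
        maxwell = x**5 * np.exp(2.5 * (1 - x * x))  # peak value 1 at lambda_peak
        return maxwell + self.epithermal_weight / np.clip(lam, 1e-6, None)

    def pulse_sigma(self, lam) -> np.ndarray:
        return self.pulse_sigma0 + self.pulse_sigma1 * np.asarray(lam, dtype=float)

    def pulse_tau(self, lam) -> np.ndarray:
        return self.pulse_tau0 + self.pulse_tau1 * np.asarray(lam, dtype=float)

    def sample_lambda(self, rng, n: int, band: tuple | None = None) -> np.ndarray:
        """Inverse-CDF sampling of the spectrum restricted to a band."""
        lo, hi = band if band is not None else self.band
        grid = np.linspace(lo, hi, 2001)
        pdf = self.spectrum(grid)
        cdf = np.cumsum(pdf)
        cdf = cdf / cdf[-1]
        u = rng.random(n)
        return np.interp(u, cdf, grid)

    def sample_pulse_delay(self, rng, lam: np.ndarray) -> np.ndarray:
        """Asymmetric emission-time broadening in us."""
        lam = np.asarray(lam, dtype=float)
        return rng.normal(0.0, self.pulse_sigma(lam)) + rng.exponential(
            self.pulse_tau(lam)
        )


# --- helpers ---------------------------------------------------------------

def spectrum_channel_norm(
    beam: BeamModel, instrument: Instrument, det: DetectorGeometry,
    edges: np.ndarray, window: tuple,
) -> float:
    """Channel-mean of the spectrum at the detector face center.

    This is the normalisation the vanadium-derived per-channel correction
    converges to, so dividing planted counts by it makes the corrected data
    carry the planted intensity with no spectrum imprint.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    sel = (centers >= window[0]) & (centers <= window[1])
    L_tot = instrument.L1 + det.L2 / 100.0
    lam = tof_to_wavelength(centers[sel], L_tot)
    return float(np.mean(beam.spectrum(lam)))


def _canonical_key(hkl, sym: SymmetrySpec | None):
    if sym is not None:
        from .merge import map_to_asu

        return map_to_asu(hkl, sym)
    h = tuple(int(v) for v in hkl)
    return max(h, tuple(-v for v in h))


def assign_true_intensities(
    predictions, crystal: CrystalModel, rng,
) -> dict:
    """Wilson-distributed true intensity per symmetry-unique reflection."""
    keys = sorted({_canonical_key(p.hkl, crystal.symmetry) for p in predictions})
    return {key: rng.exponential(crystal.intensity_scale) for key in keys}


def true_intensity(hkl, d, crystal: CrystalModel, table: dict) -> float:
    key = _canonical_key(hkl, crystal.symmetry)
    s2 = 1.0 / (4 * d * d)
    return table[key] * math.exp(-2.0 * crystal.b_factor * s2)


# --- Bragg event generation ------------------------------------------------

def generate_bragg_events(
    crystal: CrystalModel,
    beam: BeamModel,
    instrument: Instrument,
    goniometers: dict,
    exposure: float = 2500.0,
    seed: int = 0,
    efficiency_maps: dict | None = None,
    n_neutron: dict | None = None,
    background_rate: float = 0.05,
    resolution_range: tuple = (1.2, 30.0),
    edge_region: IntegrationRegion | None = None,
    n_channels: int = 250,
) -> tuple[list[EventList], pd.DataFrame]:
    """Simulate Bragg + background events for every orientation.

    Returns (event lists, ground-truth table).  ``exposure`` scales the
    expected counts of a unit-intensity reflection; ``background_rate`` is
    the expected background count per voxel of the default histogram
    binning before efficiency/spectrum modulation.  ``n_neutron`` maps
    orientation_id -> incident neutron count (defaults to equal counts).
    """
    rng = np.random.default_rng(seed)
    ub = crystal.ub()
    region = edge_region or IntegrationRegion()
    # geometric arrival times; the emission delay is added per event below,
    # so the observable peak position is t_geom + mean delay, which is what
    # the beam's offset model reports
    preds = predict_all(
        ub, goniometers, instrument, centering=crystal.centering,
        resolution_range=resolution_range, region=region,
        tof_offset_model=None,
    )
    preds = [p for p in preds if p.status == "ok"
             and beam.band[0] <= p.lam <= beam.band[1]]
    itable = assign_true_intensities(preds, crystal, rng)
    if n_neutron is None:
        n_neutron = {oid: 1.0e6 for oid in goniometers}
    first = n_neutron[min(n_neutron)]
    edges = np.linspace(*instrument.tof_range, n_channels + 1)
    norms = {
        det.detector_id: spectrum_channel_norm(
            beam, instrument, det, edges, instrument.tof_range
        )
        for det in instrument.detectors
    }
    eff = efficiency_maps or {
        d.detector_id: np.ones((d.n_pixels_x, d.n_pixels_y))
        for d in instrument.detectors
    }

    # exposure is calibrated to the median Lorentz weight so the expected
    # counts of a unit-intensity reflection are ~exposure regardless of the
    # band/geometry; the spread of lambda^4/sin^2(theta) around the median
    # still spans orders of magnitude, as in real Laue data
    inv_lorentz_all = np.array(
        [p.lam**4 / math.sin(math.radians(p.two_theta / 2.0)) ** 2 for p in preds]
    )
    med_lorentz = float(np.median(inv_lorentz_all)) if len(preds) else 1.0

    truth_rows = []
    events_by_orient: dict = {oid: [] for oid in goniometers}
    for p, inv_lorentz in zip(preds, inv_lorentz_all):
        det = instrument.detector(p.detector_id)
        I_true = true_intensity(p.hkl, p.d, crystal, itable)
        power = n_neutron[p.orientation_id] / first
        mu = exposure * I_true * beam.spectrum(p.lam) / norms[p.detector_id]
        mu *= (inv_lorentz / med_lorentz) * power
        e = eff[p.detector_id]
        e_max = float(e.max())
        # oversample by e_max then thin by e/e_max: the detected expectation
        # at pixel p is exactly mu * pdf(p) * e(p), which the efficiency
        # correction divides back out without bias
        n = rng.poisson(mu * e_max)
        if n > 0:
            x = rng.normal(p.x_p, crystal.sigma_x, n)
            y = rng.normal(p.y_p, crystal.sigma_y, n)
            t = np.full(n, p.t_p) + beam.sample_pulse_delay(rng, np.full(n, p.lam))
            inb = (
                (x > -0.5) & (x < det.n_pixels_x - 0.5)
                & (y > -0.5) & (y < det.n_pixels_y - 0.5)
            )
            x, y, t = x[inb], y[inb], t[inb]
            xi = np.rint(x).astype(int)
            yi = np.rint(y).astype(int)
            keep = rng.random(len(x)) < e[xi, yi] / e_max
            n_kept = int(keep.sum())
            events_by_orient[p.orientation_id].append(
                pd.DataFrame(
                    {
                        "detector_id": p.detector_id,
                        "x": xi[keep],
                        "y": yi[keep],
                        "tof_us": t[keep],
                        "weight": 1.0,
                    }
                )
            )
        else:
            n_kept = 0
        truth_rows.append(
            {
                "orientation_id": p.orientation_id,
                "detector_id": p.detector_id,
                "h": p.h, "k": p.k, "l": p.l,
                "I_true": I_true,
                # expected Lorentz-corrected integrated intensity in the
                # pipeline's output units
                "I_scaled": exposure * I_true / med_lorentz,
                "x_p": p.x_p, "y_p": p.y_p,
                "t_p": p.t_p + float(beam.offset_model(p.lam)),
                "lam": p.lam, "d": p.d, "two_theta": p.two_theta,
                "mu": mu, "n_detected": n_kept,
            }
        )

    # uniform background modulated by efficiency and spectrum
    if background_rate > 0:
        for oid in goniometers:
            power = n_neutron[oid] / first
            for det in instrument.detectors:
                e = eff[det.detector_id]
                n_vox = det.n_pixels_x * det.n_pixels_y * n_channels
                n_bg = rng.poisson(background_rate * n_vox * power)
                if n_bg == 0:
                    continue
                # pixel probability follows the efficiency map, wavelength
                # follows the spectrum, so corrected background is flat
                pe = e.ravel() / e.sum()
                idx = rng.choice(e.size, size=n_bg, p=pe)
                xi, yi = np.unravel_index(idx, e.shape)
                xi = np.asarray(xi)
                yi = np.asarray(yi)
                lam = beam.sample_lambda(rng, n_bg)
                d2 = pixel_distance_sq(xi, yi, det)
                L_tot = instrument.L1 + np.sqrt(d2) / 100.0
                t = wavelength_to_tof(lam, L_tot)
                sel = (t >= instrument.tof_range[0]) & (t < instrument.tof_range[1])
                events_by_orient[oid].append(
                    pd.DataFrame(
                        {
                            "detector_id": det.detector_id,
                            "x": xi[sel], "y": yi[sel], "tof_us": t[sel],
                            "weight": 1.0,
                        }
                    )
                )

    event_lists = []
    for oid in sorted(goniometers):
        frames = events_by_orient[oid]
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["detector_id", "x", "y", "tof_us", "weight"])
        )
        event_lists.append(
            EventList(events=df, orientation_id=oid, n_neutron=n_neutron[oid])
        )
    truth = pd.DataFrame(truth_rows)
    return event_lists, truth


def generate_flat_events(
    beam: BeamModel,
    instrument: Instrument,
    efficiency_maps: dict,
    rate_per_pixel: float,
    seed: int = 0,
) -> EventList:
    """Featureless 'sample': pixel probability follows the efficiency map,
    wavelength follows the spectrum.

    After the vanadium corrections such data should be uniform across
    pixels and channels up to counting noise (the flat-field closure
    property).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for det in instrument.detectors:
        e = efficiency_maps[det.detector_id]
        n_ev = rng.poisson(rate_per_pixel * e.size)
        pe = e.ravel() / e.sum()
        idx = rng.choice(e.size, size=n_ev, p=pe)
        xi, yi = np.unravel_index(idx, e.shape)
        lam = beam.sample_lambda(rng, n_ev)
        d2 = pixel_distance_sq(np.asarray(xi), np.asarray(yi), det)
        t = wavelength_to_tof(lam, instrument.L1 + np.sqrt(d2) / 100.0)
        sel = (t >= instrument.tof_range[0]) & (t < instrument.tof_range[1])
        frames.append(
            pd.DataFrame(
                {"detector_id": det.detector_id, "x": np.asarray(xi)[sel],
                 "y": np.asarray(yi)[sel], "tof_us": t[sel], "weight": 1.0}
            )
        )
    return EventList(events=pd.concat(frames, ignore_index=True),
                     orientation_id=0, n_neutron=1.0)


# --- vanadium generation ---------------------------------------------------

def generate_vanadium(
    beam: BeamModel,
    instrument: Instrument,
    efficiency_maps: dict | None = None,
    seed: int = 0,
    events_per_detector: int = 300_000,
    band_short: tuple = (0.06, 3.94),
    band_long: tuple = (2.88, 6.76),
    n_short: float = 1.0e7,
    n_long: float = 0.5e7,
) -> tuple[EventList, EventList]:
    """Two vanadium calibration runs (short/long wavelength band).

    Incoherent scatter: pixel probability proportional to
    efficiency / d(x, y); wavelengths from the spectrum restricted to each
    band; event counts of the long band scale with its irradiation count.
    """
    rng = np.random.default_rng(seed)
    eff = efficiency_maps or {
        d.detector_id: np.ones((d.n_pixels_x, d.n_pixels_y))
        for d in instrument.detectors
    }
    # expected event counts follow irradiation x band-integrated flux, as
    # they do for a real incoherent scatterer; this is what makes the
    # irradiation-count scaling of the band merge produce a continuous
    # spectral rate at the connecting wavelength
    grid_s = np.linspace(*band_short, 2001)
    grid_l = np.linspace(*band_long, 2001)
    flux_s = float(np.trapezoid(beam.spectrum(grid_s), grid_s))
    flux_l = float(np.trapezoid(beam.spectrum(grid_l), grid_l))
    lists = []
    for band, n_irr, base in (
        (band_short, n_short, events_per_detector),
        (band_long, n_long,
         events_per_detector * (n_long / n_short) * (flux_l / flux_s)),
    ):
        frames = []
        for det in instrument.detectors:
            e = eff[det.detector_id]
            xg, yg = np.meshgrid(
                np.arange(det.n_pixels_x), np.arange(det.n_pixels_y), indexing="ij"
            )
            d2 = pixel_distance_sq(xg, yg, det)
            p = (e / d2).ravel()
            p = p / p.sum()
            n_ev = rng.poisson(base)
            idx = rng.choice(len(p), size=n_ev, p=p)
            xi, yi = np.unravel_index(idx, e.shape)
            lam = beam.sample_lambda(rng, n_ev, band=band)
            L_tot = instrument.L1 + np.sqrt(d2[xi, yi]) / 100.0
            t = wavelength_to_tof(lam, L_tot)
            frames.append(
                pd.DataFrame(
                    {"detector_id": det.detector_id, "x": xi, "y": yi,
                     "tof_us": t, "weight": 1.0}
                )
            )
        lists.append(
            EventList(events=pd.concat(frames, ignore_index=True),
                      orientation_id=0, n_neutron=n_irr)
        )
    return lists[0], lists[1]


def default_efficiency_maps(
    instrument: Instrument, amplitude: float = 0.1, seed: int = 7
) -> dict:
    """Smooth mean-1 per-pixel efficiency variation for each detector."""
    rng = np.random.default_rng(seed)
    maps = {}
    for det in instrument.detectors:
        nx, ny = det.n_pixels_x, det.n_pixels_y
        x = np.linspace(0, 2 * math.pi, nx)[:, None]
        y = np.linspace(0, 2 * math.pi, ny)[None, :]
        ph = rng.uniform(0, 2 * math.pi, size=4)
        e = 1.0 + amplitude * (
            0.6 * np.sin(x + ph[0]) * np.cos(y + ph[1])
            + 0.4 * np.cos(2 * x + ph[2]) * np.sin(2 * y + ph[3])
        )
        maps[det.detector_id] = e / e.mean()
    return maps


# --- the CI fixture --------------------------------------------------------

@dataclass
class SyntheticFixture:
    instrument: Instrument
    crystal: CrystalModel
    beam: BeamModel
    goniometers: dict
    efficiency_maps: dict
    n_neutron: dict
    n_channels: int = 250
    exposure: float = 2500.0
    background_rate: float = 0.05
    resolution_range: tuple = (1.2, 30.0)


def default_instrument(
    n_detectors: int = 6, n_pixels: int = 64, tof_range=(4000.0, 44000.0),
    band=(0.7, 4.2),
) -> Instrument:
    """Small iBIX-like layout: detectors ringed around the sample."""
    placements = [
        (0.0, 45.0), (0.0, -45.0), (12.0, 90.0),
        (-12.0, -90.0), (8.0, 135.0), (-8.0, -135.0),
        (20.0, 60.0), (-20.0, -60.0), (0.0, 105.0), (0.0, -105.0),
    ]
    dets = tuple(
        DetectorGeometry(
            detector_id=i,
            n_pixels_x=n_pixels,
            n_pixels_y=n_pixels,
            pixel_pitch=13.3 / n_pixels,
            L2=49.0,
            Rot_x=placements[i][0],
            Rot_y=placements[i][1],
            R_x=0.3 * ((i % 3) - 1),
            R_y=0.2 * ((i % 2) * 2 - 1),
            R_z=0.4 * (((i + 1) % 3) - 1),
        )
        for i in range(n_detectors)
    )
    return Instrument(L1=40.0, detectors=dets, tof_range=tof_range,
                      wavelength_band=band)


def default_fixture(seed: int = 0, n_orientations: int = 5) -> SyntheticFixture:
    """The compact study fixture: ~26 A orthorhombic cell, 6 detectors of
    64x64 pixels, 250 TOF channels, 5 orientations."""
    rng = np.random.default_rng(seed)
    instrument = default_instrument()
    U = _random_rotation(rng)
    crystal = CrystalModel(
        U=U, symmetry=SymmetrySpec.from_spacegroup("P 21 21 21")
    )
    beam = BeamModel()
    gonios = {
        i: GoniometerSetting(
            omega=18.0 * i, chi=15.0, phi=36.0 * i, orientation_id=i
        )
        for i in range(n_orientations)
    }
    n_neutron = {
        i: 1.0e6 * float(rng.uniform(0.85, 1.15)) if i else 1.0e6
        for i in range(n_orientations)
    }
    return SyntheticFixture(
        instrument=instrument,
        crystal=crystal,
        beam=beam,
        goniometers=gonios,
        efficiency_maps=default_efficiency_maps(instrument, seed=seed + 7),
        n_neutron=n_neutron,
    )


def _random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
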