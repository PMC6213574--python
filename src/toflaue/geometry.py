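"""Instrument geometry for a TOF Laue neutron single-crystal diffractometer.

Coordinate conventions
----------------------
The diffractometer (lab) frame is right-handed with the incident neutron
beam travelling along +z and the sample at the origin.  Each area detector
has its own 2D pixel frame whose x and z axes point opposite to the lab
frame, so pixel coordinates are axis-reversed before any rotation.

A detector is placed by, in order:

1. centering: pixel indices -> cm offsets from the face center,
2. axis reversal of x (and z, trivially, since the face plane is z=0),
3. mis-setting rotations ``Rz' @ Ry' @ Rx'`` about the face center,
4. translation by L2 along +z,
5. position rotations ``Ry(Rot_y) @ Rx(Rot_x)`` about the sample.

The goniometer carries the crystal through ``R = R_omega @ R_chi @ R_phi``
with omega about lab +y, chi about lab +x and phi about the spindle
(lab +y at zero chi); any self-consistent convention reproduces the
pipeline and this one is fixed package-wide.

Reciprocal-space vectors use the crystallographic convention (no 2*pi):
``|Q*| = 2 sin(theta) / lambda = 1/d``.

Units: detector-frame lengths in cm, flight paths in m, TOF in microseconds,
wavelength in Angstrom.  CODATA 2018 constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

# --- physical constants (CODATA 2018) -------------------------------------
PLANCK_H = 6.62607015e-34      # J s
NEUTRON_MASS = 1.67492749804e-27  # kg

#: lambda[A] = TOF_TO_LAMBDA * T[us] / L[m]
TOF_TO_LAMBDA = PLANCK_H / NEUTRON_MASS * 1e-6 / 1e-10  # ~3.956e-3 A m / us


def rot_x(deg: float) -> np.ndarray:
    """Proper rotation about +x."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    """Proper rotation about +y."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    """Proper rotation about +z."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# --- domain types ----------------------------------------------------------

@dataclass(frozen=True)
class DetectorGeometry:
    """One position-sensitive area detector.

    Rot_x/Rot_y place the detector around the sample; R_x/R_y/R_z are small
    mis-setting corrections about the face center.  L2 is the sample to
    face-center distance in cm.
    """

    detector_id: int
    n_pixels_x: int = 256
    n_pixels_y: int = 256
    pixel_pitch: float = 13.3 / 256  # cm per pixel (133 mm active area)
    L2: float = 49.0                 # cm
    Rot_x: float = 0.0
    Rot_y: float = 0.0
    R_x: float = 0.0
    R_y: float = 0.0
    R_z: float = 0.0

    def __post_init__(self):
        if self.n_pixels_x <= 0 or self.n_pixels_y <= 0:
            raise ValueError("pixel counts must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.L2 <= 0:
            raise ValueError("L2 must be positive")
        for a in (self.Rot_x, self.Rot_y, self.R_x, self.R_y, self.R_z):
            if not math.isfinite(a):
                raise ValueError("angles must be finite")

    # cached transforms ----------------------------------------------------
    @property
    def missetting_matrix(self) -> np.ndarray:
        """Rz' @ Ry' @ Rx' about the face center."""
        return rot_z(self.R_z) @ rot_y(self.R_y) @ rot_x(self.R_x)

    @property
    def position_matrix(self) -> np.ndarray:
        """Ry(Rot_y) @ Rx(Rot_x) about the sample."""
        return rot_y(self.Rot_y) @ rot_x(self.Rot_x)


@dataclass(frozen=True)
class Instrument:
    """Full instrument: flight path, detector bank, TOF window and band."""

    L1: float = 40.0  # moderator-to-sample distance, m
    detectors: tuple = ()
    tof_range: tuple = (0.0, 40000.0)   # us
    wavelength_band: tuple = (0.3, 6.76)  # A

    def __post_init__(self):
        if self.L1 <= 0:
            raise ValueError("L1 must be positive")
        ids = [d.detector_id for d in self.detectors]
        if len(ids) != len(set(ids)):
            raise ValueError("detector_ids must be unique")

    def detector(self, detector_id: int) -> DetectorGeometry:
        for d in self.detectors:
            if d.detector_id == detector_id:
                return d
        raise KeyError(f"no detector with id {detector_id}")


@dataclass(frozen=True)
class GoniometerSetting:
    """One crystal orientation on the omega/chi/phi goniometer (degrees)."""

    omega: float = 0.0
    chi: float = 0.0
    phi: float = 0.0
    orientation_id: int = 0

    def __post_init__(self):
        if self.orientation_id < 0:
            raise ValueError("orientation_id must be >= 0")


@dataclass(frozen=True)
class LabPosition:
    """A point in the diffractometer frame, cm."""

    x: float
    y: float
    z: float

    @property
    def D(self) -> float:
        """Distance from the sample, cm."""
        return math.sqrt(self.x * self.x + self.y * self.y + self.z * self.z)

    @property
    def L_prime_m(self) -> float:
        """Sample-to-pixel flight path in metres."""
        return self.D / 100.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class QVector:
    """Reciprocal-space vector in A^-1 (crystallographic, no 2*pi)."""

    qx: float
    qy: float
    qz: float

    def as_array(self) -> np.ndarray:
        return np.array([self.qx, self.qy, self.qz])

    @property
    def norm(self) -> float:
        return math.sqrt(self.qx ** 2 + self.qy ** 2 + self.qz ** 2)


# --- pixel -> lab ----------------------------------------------------------

def _pixel_to_centered_cm(xD, yD, det: DetectorGeometry):
    """Pixel indices (centers, 0-based) -> cm offsets from the face center.

    The face center sits between pixels at index (N-1)/2.
    """
    xc = (np.asarray(xD, dtype=float) - (det.n_pixels_x - 1) / 2.0) * det.pixel_pitch
    yc = (np.asarray(yD, dtype=float) - (det.n_pixels_y - 1) / 2.0) * det.pixel_pitch
    return xc, yc


def pixel_to_lab_array(xD, yD, det: DetectorGeometry, check: bool = True) -> np.ndarray:
    """Vectorized pixel->lab transform; returns (..., 3) array in cm."""
    xD = np.asarray(xD, dtype=float)
    yD = np.asarray(yD, dtype=float)
    if check:
        if np.any(xD < -0.5) or np.any(xD > det.n_pixels_x - 0.5) or \
           np.any(yD < -0.5) or np.any(yD > det.n_pixels_y - 0.5):
            raise ValueError("pixel index out of detector range")
    xc, yc = _pixel_to_centered_cm(xD, yD, det)
    # axis reversal: detector x (and z) run opposite to the lab frame
    v = np.stack([-xc, yc, np.zeros_like(xc)], axis=-1)
    v = v @ det.missetting_matrix.T
    v = v + np.array([0.0, 0.0, det.L2])
    v = v @ det.position_matrix.T
    return v


def pixel_to_lab(xD: float, yD: float, det: DetectorGeometry) -> LabPosition:
    """Map a pixel position to the diffractometer frame (cm)."""
    v = pixel_to_lab_array(xD, yD, det)
    return LabPosition(float(v[0]), float(v[1]), float(v[2]))


def pixel_distance_sq(xD, yD, det: DetectorGeometry):
    """Squared sample->pixel distance d(x, y) in cm^2 (mis-setting included).

    The position rotations are orthogonal, so this equals
    ``|pixel_to_lab|^2``.
    """
    v = pixel_to_lab_array(xD, yD, det)
    return np.sum(v * v, axis=-1)


# --- TOF <-> wavelength ----------------------------------------------------

def tof_to_wavelength(T, L_total):
    """de Broglie: lambda[A] from TOF [us] over total flight path [m]."""
    T = np.asarray(T, dtype=float)
    if np.any(np.asarray(L_total) <= 0):
        raise ValueError("flight path must be positive")
    return TOF_TO_LAMBDA * T / L_total


def wavelength_to_tof(lam, L_total):
    """Inverse of :func:`tof_to_wavelength`."""
    if np.any(np.asarray(L_total) <= 0):
        raise ValueError("flight path must be positive")
    return np.asarray(lam, dtype=float) * L_total / TOF_TO_LAMBDA


# --- lab -> reciprocal space ----------------------------------------------

def lab_to_q(pos: LabPosition, lam: float) -> QVector:
    """Scattering vector of a detected neutron.

    With the incident beam along +z and the detected position p at distance
    D, ``Q* = (x/(D lam), y/(D lam), (z/D - 1)/lam)``; its norm is
    ``2 sin(theta)/lambda``.
    """
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    D = pos.D
    if D <= 0:
        raise ValueError("position must be off the sample")
    return QVector(pos.x / (D * lam), pos.y / (D * lam), (pos.z / D - 1.0) / lam)


def lab_to_q_array(pos: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Vectorized :func:`lab_to_q`; pos (...,3) cm, lam (...) A."""
    pos = np.asarray(pos, dtype=float)
    lam = np.asarray(lam, dtype=float)
    D = np.linalg.norm(pos, axis=-1)
    u = pos / D[..., None]
    u = u - np.array([0.0, 0.0, 1.0])
    return u / lam[..., None]


# --- goniometer ------------------------------------------------------------

def goniometer_matrix(g: GoniometerSetting) -> np.ndarray:
    """R = R_omega(y) @ R_chi(x) @ R_phi(spindle)."""
    return rot_y(g.omega) @ rot_x(g.chi) @ rot_y(g.phi)


def q_to_zero_setting(q: QVector, g: GoniometerSetting) -> QVector:
    """Rotate an observed Q* back to the omega=chi=phi=0 setting."""
    R = goniometer_matrix(g)
    v = R.T @ q.as_array()
    return QVector(*v)


def q_from_zero_setting(q: QVector, g: GoniometerSetting) -> QVector:
    """Rotate a zero-setting Q*' into the goniometer setting g."""
    R = goniometer_matrix(g)
    v = R @ q.as_array()
    return QVector(*v)


# --- reflection prediction -------------------------------------------------

@dataclass(frozen=True)
class DetectorHit:
    """Predicted detector intersection of a diffracted ray."""

    xD: float
    yD: float
    T: float          # us
    lam: float        # A
    two_theta: float  # degrees
    lab: LabPosition
    on_detector: bool
    in_band: bool


def diffracted_ray(q: np.ndarray):
    """Wavelength and unit ray direction that satisfy the Laue condition.

    For incident wavevector (0, 0, 1/lam) and elastic scattering,
    ``|lam q + z| = 1`` fixes ``lam = -2 q_z / |q|^2``; the diffracted unit
    direction is ``lam q + z``.  Returns (lam, u) or (None, None) when the
    geometry cannot scatter (q_z >= 0).
    """
    q = np.asarray(q, dtype=float)
    n2 = float(q @ q)
    if n2 == 0:
        raise ValueError("zero scattering vector")
    lam = -2.0 * q[2] / n2
    if lam <= 0:
        return None, None
    u = lam * q + np.array([0.0, 0.0, 1.0])
    nu = np.linalg.norm(u)
    return lam, u / nu


def predict_detector_position(
    q: QVector,
    g: GoniometerSetting,
    det: DetectorGeometry,
    L1: float,
    wavelength_band: tuple | None = None,
    allow_outside: bool = False,
) -> DetectorHit | None:
    """Predict where a zero-setting reciprocal-lattice point lands.

    ``q`` is rotated into the setting ``g``; the Bragg wavelength and ray
    direction follow from the Laue condition and the ray is intersected with
    the detector plane by inverting the pixel->lab chain.  Returns ``None``
    for a miss (no Bragg solution, ray behind the detector, outside the
    active area, or wavelength out of band) unless ``allow_outside``.
    """
    qr = q_from_zero_setting(q, g).as_array()
    try:
        lam, u = diffracted_ray(qr)
    except ValueError:
        raise
    if lam is None:
        return None
    in_band = True
    if wavelength_band is not None:
        lo, hi = wavelength_band
        in_band = lo <= lam <= hi
        if not in_band and not allow_outside:
            return None
    # invert position rotations, then intersect the mis-set face plane z'=0
    P = det.position_matrix
    M = det.missetting_matrix
    a = M.T @ (P.T @ u)
    b = M.T @ np.array([0.0, 0.0, det.L2])
    if abs(a[2]) < 1e-15:
        return None
    t = b[2] / a[2]
    if t <= 0:
        return None
    w = t * a - b  # face-plane coordinates (-xc, yc, 0)
    xc, yc = -w[0], w[1]
    xD = xc / det.pixel_pitch + (det.n_pixels_x - 1) / 2.0
    yD = yc / det.pixel_pitch + (det.n_pixels_y - 1) / 2.0
    on_det = (-0.5 <= xD <= det.n_pixels_x - 0.5) and (-0.5 <= yD <= det.n_pixels_y - 0.5)
    if not on_det and not allow_outside:
        return None
    lab_v = t * u  # the hit point in the lab frame (cm)
    pos = LabPosition(*lab_v)
    L_total = L1 + pos.L_prime_m
    T = wavelength_to_tof(lam, L_total)
    ct = min(1.0, max(-1.0, lab_v[2] / np.linalg.norm(lab_v)))
    two_theta = math.degrees(math.acos(ct))
    return DetectorHit(float(xD), float(yD), float(T), float(lam), two_theta,
                       pos, on_det, in_band)


def scattering_angle_deg(pos: LabPosition) -> float:
    """2*theta between the incident beam (+z) and a lab position."""
    return math.degrees(math.acos(min(1.0, max(-1.0, pos.z / pos.D))))


# --- instrument config I/O -------------------------------------------------

def instrument_to_dict(inst: Instrument) -> dict:
    return {
        "L1": inst.L1,
        "tof_range": list(inst.tof_range),
        "wavelength_band": list(inst.wavelength_band),
        "detectors": [
            {
                "id": d.detector_id,
                "n_pixels_x": d.n_pixels_x,
                "n_pixels_y": d.n_pixels_y,
                "pixel_pitch": d.pixel_pitch,
                "L2": d.L2,
                "Rot_x": d.Rot_x,
                "Rot_y": d.Rot_y,
                "R_x": d.R_x,
                "R_y": d.R_y,
                "R_z": d.R_z,
            }
            for d in inst.detectors
        ],
    }


def instrument_from_dict(cfg: dict) -> Instrument:
    dets = tuple(
        DetectorGeometry(
            detector_id=int(b["id"]),
            n_pixels_x=int(b.get("n_pixels_x", 256)),
            n_pixels_y=int(b.get("n_pixels_y", 256)),
            pixel_pitch=float(b.get("pixel_pitch", 13.3 / 256)),
            L2=float(b.get("L2", 49.0)),
            Rot_x=float(b.get("Rot_x", 0.0)),
            Rot_y=float(b.get("Rot_y", 0.0)),
            R_x=float(b.get("R_x", 0.0)),
            R_y=float(b.get("R_y", 0.0)),
            R_z=float(b.get("R_z", 0.0)),
        )
        for b in cfg.get("detectors", [])
    )
    return Instrument(
        L1=float(cfg.get("L1", 40.0)),
        detectors=dets,
        tof_range=tuple(cfg.get("tof_range", (0.0, 40000.0))),
        wavelength_band=tuple(cfg.get("wavelength_band", (0.3, 6.76))),
    )


def write_instrument(inst: Instrument, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(instrument_to_dict(inst), fh, sort_keys=False)


def read_instrument(path) -> Instrument:
    with open(path) as fh:
        return instrument_from_dict(yaml.safe_load(fh))
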