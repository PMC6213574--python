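"""Bragg-peak search in 3D histograms.

Protein reflections measured with a weak neutron beam are broad and only a
few counts high, so candidates are looked for in data that have first been
rebinned along TOF (tens of channels summed per slab) and smoothed in-plane
with a small weighted-average kernel.  The chain is:

1. rebin TOF channels into slabs, smooth each slab in x-y;
2. (x, y) candidates: strict local maxima over the 3x3 neighbourhood above
   a threshold, in any slab;
3. TOF candidates: per (x, y) candidate, smooth the original-resolution TOF
   profile and take local maxima over 3 consecutive bins above threshold;
4. consolidation: within a Chebyshev radius (and overlapping TOF slabs)
   only the highest-count candidate survives;
5. centroid refinement of x, y from background-subtracted counts;
6. TOF-offset correction (moderator emission-time lag, wavelength
   dependent) and mapping to reciprocal space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    GoniometerSetting,
    Instrument,
    QVector,
    lab_to_q,
    pixel_to_lab,
    q_to_zero_setting,
    tof_to_wavelength,
)
from .histogram import Histogram3D

BINOMIAL_3X3 = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0
BINOMIAL_3 = np.array([1.0, 2.0, 1.0]) / 4.0


@dataclass
class TofOffsetModel:
    """Polynomial emission-time offset in us as a function of wavelength.

    ``offset(lam) = c0 + c1*lam + c2*lam^2 + ...``; the default (no
    coefficients) is a zero offset.
    """

    coefficients: tuple = ()

    def __call__(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        out = np.zeros_like(lam)
        for k, c in enumerate(self.coefficients):
            out = out + c * lam ** k
        return out


@dataclass
class SearchParams:
    """Tunable knobs of the peak search."""

    rebin_factor: int = 32
    xy_kernel: np.ndarray = field(default_factory=lambda: BINOMIAL_3X3.copy())
    tof_kernel: np.ndarray = field(default_factory=lambda: BINOMIAL_3.copy())
    count_threshold: float | None = None   # None -> median + 5 MAD per detector
    tof_threshold: float | None = None     # None -> count_threshold / rebin_factor
    consolidation_radius: int = 3          # Chebyshev, pixels
    consolidation_slabs: int = 1           # +- rebinned TOF slabs
    centroid_box: tuple = (4, 4)           # half-widths in x, y
    tof_offset_model: TofOffsetModel = field(default_factory=TofOffsetModel)

    def __post_init__(self):
        if self.rebin_factor < 1:
            raise ValueError("rebin_factor must be >= 1")
        self.xy_kernel = np.asarray(self.xy_kernel, dtype=float)
        self.tof_kernel = np.asarray(self.tof_kernel, dtype=float)
        if not math.isclose(self.xy_kernel.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("xy_kernel must sum to 1")
        if not math.isclose(self.tof_kernel.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("tof_kernel must sum to 1")


@dataclass
class PeakObservation:
    """A located reflection candidate."""

    detector_id: int
    x_o: float           # refined pixel position
    y_o: float
    t_o: float           # offset-corrected TOF, us
    lam: float           # A
    q: QVector           # at the measuring goniometer setting
    q_zero: QVector      # rotated to the zero setting
    orientation_id: int
    raw_count: float     # peak height in the original histogram
    centroid_fallback: bool = False


# --- rebinning and smoothing ----------------------------------------------

def rebin_tof(h: Histogram3D, factor: int) -> Histogram3D:
    """Sum groups of ``factor`` TOF channels; trailing partial group kept."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = h.n_channels
    if factor > n:
        raise ValueError("factor exceeds number of channels")
    if factor == 1:
        return h
    n_full = n // factor
    remainder = n - n_full * factor
    pieces = [
        h.counts[:, :, : n_full * factor]
        .reshape(h.counts.shape[0], h.counts.shape[1], n_full, factor)
        .sum(axis=3)
    ]
    new_edges = list(h.edges[: n_full * factor + 1 : factor])
    partial = False
    if remainder:
        pieces.append(h.counts[:, :, n_full * factor :].sum(axis=2)[:, :, None])
        new_edges.append(h.edges[-1])
        partial = True
    counts = np.concatenate(pieces, axis=2)
    return replace(
        h, counts=counts, edges=np.array(new_edges), variance=None,
        partial_last_channel=partial,
    )


def _smooth2d(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Weighted average with the kernel renormalised over in-bounds pixels."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    num = np.zeros_like(img, dtype=float)
    den = np.zeros_like(img, dtype=float)
    nx, ny = img.shape
    for di in range(-ph, ph + 1):
        for dj in range(-pw, pw + 1):
            w = kernel[di + ph, dj + pw]
            if w == 0:
                continue
            src = img[
                max(0, -di) : nx - max(0, di), max(0, -dj) : ny - max(0, dj)
            ]
            num[max(0, di) : nx - max(0, -di), max(0, dj) : ny - max(0, -dj)] += w * src
            den[max(0, di) : nx - max(0, -di), max(0, dj) : ny - max(0, -dj)] += w
    return num / den


def smooth_xy(h: Histogram3D, kernel: np.ndarray | None = None) -> Histogram3D:
    """Smooth every TOF slab in-plane with a normalised kernel.

    Edge pixels use the kernel renormalised over in-bounds neighbours, so a
    constant image is exactly unchanged (the price is that totals are only
    conserved exactly away from the edges).
    """
    if kernel is None:
        kernel = BINOMIAL_3X3
    kernel = np.asarray(kernel, dtype=float)
    out = np.empty_like(h.counts, dtype=float)
    for c in range(h.n_channels):
        out[:, :, c] = _smooth2d(h.counts[:, :, c], kernel)
    return replace(h, counts=out, variance=None)


def smooth_1d(profile: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """1D weighted average with edge renormalisation."""
    k = len(kernel)
    p = k // 2
    n = len(profile)
    num = np.zeros(n)
    den = np.zeros(n)
    for d in range(-p, p + 1):
        w = kernel[d + p]
        if w == 0:
            continue
        src = profile[max(0, -d) : n - max(0, d)]
        num[max(0, d) : n - max(0, -d)] += w * src
        den[max(0, d) : n - max(0, -d)] += w
    return num / den


# --- candidate search ------------------------------------------------------

def robust_threshold(smoothed_slabs: np.ndarray, n_mad: float = 5.0) -> float:
    """Default threshold: median + n_mad * MAD of the smoothed counts."""
    med = float(np.median(smoothed_slabs))
    mad = float(np.median(np.abs(smoothed_slabs - med)))
    return med + n_mad * max(mad, 1e-12)


@dataclass
class RawCandidate:
    x: int
    y: int
    t_channel: int       # original-resolution channel of the TOF maximum
    slab: int            # rebinned slab index
    slab_count: float    # smoothed rebinned count at (x, y, slab)
    raw_count: float     # original histogram count at (x, y, t_channel)


def _local_maxima_2d(img: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Strict 3x3 local maxima above the threshold.

    Plateau ties are broken toward the lowest (x, then y) so the result is
    deterministic: a pixel wins only if it is >= all neighbours and strictly
    greater than every neighbour that precedes it in raster order.
    """
    nx, ny = img.shape
    pad = np.full((nx + 2, ny + 2), -np.inf)
    pad[1:-1, 1:-1] = img
    center = pad[1:-1, 1:-1]
    ok = center > threshold
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nb = pad[1 + di : nx + 1 + di, 1 + dj : ny + 1 + dj]
            # earlier in raster order => must beat it strictly
            earlier = (di < 0) or (di == 0 and dj < 0)
            ok &= (center > nb) if earlier else (center >= nb)
    return [tuple(p) for p in np.argwhere(ok)]


def find_candidates(
    h_rebinned_smoothed: Histogram3D,
    h_original: Histogram3D,
    p: SearchParams,
) -> list[RawCandidate]:
    """Three-stage candidate search (see module docstring)."""
    slabs = h_rebinned_smoothed.counts
    threshold = (
        p.count_threshold
        if p.count_threshold is not None
        else robust_threshold(slabs)
    )
    tof_threshold = (
        p.tof_threshold if p.tof_threshold is not None else threshold / p.rebin_factor
    )
    cands: list[RawCandidate] = []
    for slab in range(slabs.shape[2]):
        img = slabs[:, :, slab]
        for (x, y) in _local_maxima_2d(img, threshold):
            profile = smooth_1d(h_original.counts[x, y, :], p.tof_kernel)
            # restrict to channels of this slab so each slab candidate gets
            # its own TOF; local maxima over 3 consecutive bins
            c0 = slab * p.rebin_factor
            c1 = min(c0 + p.rebin_factor, len(profile))
            for c in range(c0, c1):
                v = profile[c]
                if v <= tof_threshold:
                    continue
                left = profile[c - 1] if c > 0 else -np.inf
                right = profile[c + 1] if c < len(profile) - 1 else -np.inf
                if v > left and v >= right:
                    cands.append(
                        RawCandidate(
                            x=int(x), y=int(y), t_channel=int(c), slab=int(slab),
                            slab_count=float(img[x, y]),
                            raw_count=float(h_original.counts[x, y, c]),
                        )
                    )
    return consolidate(cands, p)


def consolidate(cands: list[RawCandidate], p: SearchParams) -> list[RawCandidate]:
    """Keep only the highest-count candidate within each crowded region.

    Regions are Chebyshev balls of ``consolidation_radius`` pixels and
    ``consolidation_slabs`` rebinned TOF slabs.  Ties break toward the
    lowest (x, y, t).
    """
    order = sorted(
        cands, key=lambda c: (-c.slab_count, -c.raw_count, c.x, c.y, c.t_channel)
    )
    kept: list[RawCandidate] = []
    for c in order:
        crowded = False
        for k in kept:
            if (
                abs(c.x - k.x) <= p.consolidation_radius
                and abs(c.y - k.y) <= p.consolidation_radius
                and abs(c.slab - k.slab) <= p.consolidation_slabs
            ):
                crowded = True
                break
        if not crowded:
            kept.append(c)
    kept.sort(key=lambda c: (c.x, c.y, c.t_channel))
    return kept


# --- refinement ------------------------------------------------------------

def refine_centroid(
    h_original: Histogram3D, cand: RawCandidate, box: tuple = (4, 4),
    tof_halfwidth: int = 3,
) -> tuple[float, float, bool]:
    """Background-subtracted center of gravity of the candidate in x, y.

    The background is the mean of the box-perimeter pixels; counts are
    summed over ``+-tof_halfwidth`` channels around the candidate TOF.
    Falls back to the candidate position (flagged) when the net count is
    not positive.
    """
    bx, by = box
    nx, ny, nt = h_original.counts.shape
    x0, x1 = max(0, cand.x - bx), min(nx, cand.x + bx + 1)
    y0, y1 = max(0, cand.y - by), min(ny, cand.y + by + 1)
    c0, c1 = max(0, cand.t_channel - tof_halfwidth), min(nt, cand.t_channel + tof_halfwidth + 1)
    patch = h_original.counts[x0:x1, y0:y1, c0:c1].sum(axis=2)
    mask = np.zeros(patch.shape, dtype=bool)
    mask[0, :] = mask[-1, :] = True
    mask[:, 0] = mask[:, -1] = True
    background = patch[mask].mean()
    net = np.clip(patch - background, 0.0, None)
    total = net.sum()
    if total <= 0:
        return float(cand.x), float(cand.y), True
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    x_o = float((net.sum(axis=1) * xs).sum() / total)
    y_o = float((net.sum(axis=0) * ys).sum() / total)
    return x_o, y_o, False


def correct_tof_offset(t_searched, lam, model: TofOffsetModel):
    """``t_o = t_searched - offset(lambda)`` (single pass; the wavelength
    used to evaluate the offset is the one implied by the searched TOF)."""
    return np.asarray(t_searched, dtype=float) - model(lam)


# --- assembly --------------------------------------------------------------

def find_peaks(
    h_original: Histogram3D,
    instrument: Instrument,
    goniometer: GoniometerSetting,
    params: SearchParams | None = None,
) -> list[PeakObservation]:
    """Full peak search on one detector histogram."""
    p = params or SearchParams()
    det = instrument.detector(h_original.detector_id)
    h_reb = rebin_tof(h_original, p.rebin_factor)
    h_sm = smooth_xy(h_reb, p.xy_kernel)
    cands = find_candidates(h_sm, h_original, p)
    centers = h_original.channel_centers
    peaks: list[PeakObservation] = []
    for c in cands:
        x_o, y_o, fallback = refine_centroid(h_original, c, p.centroid_box)
        pos = pixel_to_lab(x_o, y_o, det)
        L_total = instrument.L1 + pos.L_prime_m
        t_raw = float(centers[c.t_channel])
        lam_raw = tof_to_wavelength(t_raw, L_total)
        t_o = float(correct_tof_offset(t_raw, lam_raw, p.tof_offset_model))
        lam = float(tof_to_wavelength(t_o, L_total))
        if lam <= 0:
            continue
        try:
            q = lab_to_q(pos, lam)
        except ValueError:
            continue
        if q.norm == 0:
            continue
        peaks.append(
            PeakObservation(
                detector_id=h_original.detector_id,
                x_o=x_o, y_o=y_o, t_o=t_o, lam=lam,
                q=q, q_zero=q_to_zero_setting(q, goniometer),
                orientation_id=h_original.orientation_id,
                raw_count=c.raw_count,
                centroid_fallback=fallback,
            )
        )
    return peaks


def strongest_peaks(peaks: list[PeakObservation], n: int) -> list[PeakObservation]:
    """The n highest peaks; autoindexing is usually run on these."""
    return sorted(peaks, key=lambda p: -p.raw_count)[:n]


# --- peak list I/O ---------------------------------------------------------

PEAK_COLUMNS = [
    "detector_id", "x_o", "y_o", "t_o", "lam",
    "qx", "qy", "qz", "q0x", "q0y", "q0z",
    "height", "orientation_id",
]


def peaks_to_frame(peaks: list[PeakObservation]) -> pd.DataFrame:
    rows = [
        {
            "detector_id": p.detector_id, "x_o": p.x_o, "y_o": p.y_o,
            "t_o": p.t_o, "lam": p.lam,
            "qx": p.q.qx, "qy": p.q.qy, "qz": p.q.qz,
            "q0x": p.q_zero.qx, "q0y": p.q_zero.qy, "q0z": p.q_zero.qz,
            "height": p.raw_count, "orientation_id": p.orientation_id,
        }
        for p in peaks
    ]
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def frame_to_peaks(df: pd.DataFrame) -> list[PeakObservation]:
    out = []
    for _, r in df.iterrows():
        out.append(
            PeakObservation(
                detector_id=int(r["detector_id"]),
                x_o=float(r["x_o"]), y_o=float(r["y_o"]), t_o=float(r["t_o"]),
                lam=float(r["lam"]),
                q=QVector(r["qx"], r["qy"], r["qz"]),
                q_zero=QVector(r["q0x"], r["q0y"], r["q0z"]),
                orientation_id=int(r["orientation_id"]),
                raw_count=float(r["height"]),
            )
        )
    return out


def write_peaks(peaks: list[PeakObservation], path) -> None:
    peaks_to_frame(peaks).to_csv(path, sep="\t", index=False)


def read_peaks(path) -> list[PeakObservation]:
    return frame_to_peaks(pd.read_csv(path, sep="\t"))
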