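"""Event-to-histogram conversion and vanadium-based corrections.

Raw data are neutron event lists: (detector, pixel x, pixel y, TOF) per
detected neutron, one list per crystal orientation, plus the number of
neutrons that irradiated the sample at each orientation.  Histogramming
bins TOF into equal-width channels; corrections remove

* per-pixel detection-efficiency variation, ``H_xy`` (from a vanadium run,
  with a 1/r^2 solid-angle compensation),
* the wavelength dependence of the incident spectrum and detector
  efficiency, ``H_tof``,
* accelerator-power variation between orientations, ``C(i)``.

The corrected counts are ``cnt' = cnt * C(i) / (H_xy * H_tof)``; wherever
``H_xy * H_tof`` falls below a threshold (1e-5 by default) the corrected
count is set to zero instead of being blown up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    DetectorGeometry,
    GoniometerSetting,
    Instrument,
    pixel_distance_sq,
    tof_to_wavelength,
)

ZERO_THRESHOLD_DEFAULT = 1e-5

EVENT_COLUMNS = ["detector_id", "x", "y", "tof_us", "weight"]


@dataclass
class EventList:
    """Events of one crystal orientation (all detectors).

    ``events`` is a DataFrame with columns detector_id, x, y, tof_us and a
    ``weight`` column (1.0 for raw data; vanadium band merging introduces
    fractional weights).  ``n_neutron`` is the incident-neutron count for
    the orientation.
    """

    events: pd.DataFrame
    orientation_id: int = 0
    n_neutron: float = 1.0

    def __post_init__(self):
        ev = self.events
        if "weight" not in ev.columns:
            ev = ev.assign(weight=1.0)
        self.events = ev[EVENT_COLUMNS].reset_index(drop=True)

    def for_detector(self, detector_id: int) -> pd.DataFrame:
        return self.events[self.events["detector_id"] == detector_id]

    def __len__(self):
        return len(self.events)


@dataclass
class Run:
    """A measurement: one EventList per orientation + goniometer settings."""

    orientations: list           # of EventList
    goniometers: list            # of GoniometerSetting, same order

    def n_neutrons(self) -> np.ndarray:
        return np.array([o.n_neutron for o in self.orientations], dtype=float)


@dataclass
class Histogram3D:
    """Per-detector counts on an (x, y, TOF-channel) grid.

    ``edges`` are the channel edges in us (length n_channels+1, strictly
    increasing); binning is half-open [edge, next_edge).  After correction,
    ``variance`` carries the propagated per-voxel variance.
    """

    counts: np.ndarray
    edges: np.ndarray
    detector_id: int
    orientation_id: int = 0
    corrected: bool = False
    variance: np.ndarray | None = None
    n_outside: int = 0
    partial_last_channel: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("channel edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[2]

    @property
    def channel_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def channel_widths(self) -> np.ndarray:
        return np.diff(self.edges)


# --- binning ---------------------------------------------------------------

def bin_events(
    ev: EventList,
    instrument: Instrument,
    n_channels: int = 1000,
    tof_range: tuple | None = None,
) -> dict[int, Histogram3D]:
    """Histogram one orientation's events, per detector.

    Equal-width channels over ``tof_range`` (default: the instrument's TOF
    window), half-open so an event exactly on an interior edge goes to the
    upper channel.  Events outside the range are excluded and counted in
    ``n_outside``.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    t_lo, t_hi = tof_range if tof_range is not None else instrument.tof_range
    if not t_hi > t_lo:
        raise ValueError("empty tof_range")
    edges = np.linspace(t_lo, t_hi, n_channels + 1)
    out: dict[int, Histogram3D] = {}
    for det in instrument.detectors:
        sub = ev.for_detector(det.detector_id)
        x = sub["x"].to_numpy()
        y = sub["y"].to_numpy()
        t = sub["tof_us"].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float)
        inside = (t >= t_lo) & (t < t_hi)
        xi = np.rint(x[inside]).astype(int)
        yi = np.rint(y[inside]).astype(int)
        # half-open channels; digitize(right=False) puts an edge value up
        ci = np.digitize(t[inside], edges) - 1
        counts = np.zeros((det.n_pixels_x, det.n_pixels_y, n_channels))
        np.add.at(counts, (xi, yi, ci), w[inside])
        out[det.detector_id] = Histogram3D(
            counts=counts,
            edges=edges,
            detector_id=det.detector_id,
            orientation_id=ev.orientation_id,
            n_outside=int(np.sum(~inside)),
        )
    return out


# --- vanadium band merging -------------------------------------------------

def _event_wavelengths(ev: EventList, instrument: Instrument) -> np.ndarray:
    """Per-event wavelength using each event's own pixel flight path."""
    lam = np.empty(len(ev), dtype=float)
    det_ids = ev.events["detector_id"].to_numpy()
    x = ev.events["x"].to_numpy(dtype=float)
    y = ev.events["y"].to_numpy(dtype=float)
    t = ev.events["tof_us"].to_numpy(dtype=float)
    for det in instrument.detectors:
        m = det_ids == det.detector_id
        if not np.any(m):
            continue
        d2 = pixel_distance_sq(x[m], y[m], det)  # cm^2
        L_total = instrument.L1 + np.sqrt(d2) / 100.0
        lam[m] = tof_to_wavelength(t[m], L_total)
    return lam


def merge_vanadium(
    ev_short: EventList,
    ev_long: EventList,
    instrument: Instrument,
    connect_lambda: float = 3.4,
    band_short: tuple = (0.06, 3.94),
    band_long: tuple = (2.88, 6.76),
) -> EventList:
    """Combine the two vanadium wavelength-band runs into one event list.

    Events of the short-band run below the connecting wavelength keep unit
    weight; long-band events at or above it are weighted by the ratio of
    irradiating-neutron counts N_short/N_long so both bands share the
    short-band normalisation.  Wavelengths are computed per event with that
    event's own flight path.
    """
    lo = max(band_short[0], band_long[0])
    hi = min(band_short[1], band_long[1])
    if not lo <= connect_lambda <= hi:
        raise ValueError(
            f"connecting wavelength {connect_lambda} outside band overlap [{lo}, {hi}]"
        )
    lam_s = _event_wavelengths(ev_short, instrument)
    lam_l = _event_wavelengths(ev_long, instrument)
    keep_s = ev_short.events[lam_s < connect_lambda].copy()
    keep_l = ev_long.events[lam_l >= connect_lambda].copy()
    scale = ev_short.n_neutron / ev_long.n_neutron
    keep_l["weight"] = keep_l["weight"] * scale
    merged = pd.concat([keep_s, keep_l], ignore_index=True)
    return EventList(events=merged, orientation_id=ev_short.orientation_id,
                     n_neutron=ev_short.n_neutron)


# --- correction model ------------------------------------------------------

@dataclass
class CorrectionModel:
    """Per-detector pixel/TOF corrections + per-orientation power scales."""

    H_xy: dict            # detector_id -> (nx, ny) array, mean 1 on active pixels
    H_tof: dict           # detector_id -> (n_channels,) array, mean 1 in window
    active: dict          # detector_id -> boolean (nx, ny) mask
    C: np.ndarray         # per-orientation scale, C[0] = 1
    zero_threshold: float = ZERO_THRESHOLD_DEFAULT
    t_window: tuple = (0.0, 40000.0)
    # per-pixel vanadium statistics behind H_xy: summed (weighted) counts
    # and summed squared weights, for calibration-noise estimates
    H2_counts: dict = field(default_factory=dict)
    H2_var: dict = field(default_factory=dict)


def compute_Hxy(
    vanadium_hist: Histogram3D,
    det: DetectorGeometry,
    t_min: float,
    t_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel efficiency correction from a vanadium histogram.

    ``H_xy = H2 * d / <H2 * d>`` where H2 sums vanadium counts over the
    sample TOF window and d is the squared sample-pixel distance (vanadium
    scatter falls off as 1/d, so the product isolates efficiency).  Pixels
    with no vanadium counts are flagged inactive and excluded from the
    mean.  Returns (H_xy, active_mask).
    """
    edges = vanadium_hist.edges
    if t_min < edges[0] - 1e-9 or t_max > edges[-1] + 1e-9:
        raise ValueError("vanadium histogram does not cover the sample TOF window")
    sel = (edges[:-1] >= t_min - 1e-9) & (edges[1:] <= t_max + 1e-9)
    H2 = vanadium_hist.counts[:, :, sel].sum(axis=2)
    if not np.any(H2 > 0):
        raise ValueError("vanadium histogram is empty in the sample TOF window")
    xg, yg = np.meshgrid(
        np.arange(det.n_pixels_x), np.arange(det.n_pixels_y), indexing="ij"
    )
    d = pixel_distance_sq(xg, yg, det)
    active = H2 > 0
    prod = H2 * d
    H_xy = np.zeros_like(prod)
    H_xy[active] = prod[active] / prod[active].mean()
    return H_xy, active


def rebin_to_channels(vanadium_hist: Histogram3D, edges: np.ndarray) -> Histogram3D:
    """Rebin a vanadium histogram onto the sample channel edges.

    Explicit pre-step for when the vanadium and sample TOF binnings differ;
    counts are reassigned assuming a uniform density within each source
    channel.
    """
    src_edges = vanadium_hist.edges
    nx, ny, _ = vanadium_hist.counts.shape
    n_new = len(edges) - 1
    new = np.zeros((nx, ny, n_new))
    for j in range(len(src_edges) - 1):
        a, b = src_edges[j], src_edges[j + 1]
        lo = np.clip(edges[:-1], a, b)
        hi = np.clip(edges[1:], a, b)
        frac = np.clip(hi - lo, 0, None) / (b - a)
        if frac.any():
            new += vanadium_hist.counts[:, :, j][:, :, None] * frac[None, None, :]
    return replace(vanadium_hist, counts=new, edges=np.asarray(edges, dtype=float))


def compute_Htof(
    vanadium_hist: Histogram3D, t_min: float, t_max: float,
    sample_edges: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel spectrum correction: ``(H1/W) / <H1/W>`` over the window.

    Requires the vanadium binning to match the sample binning; rebin first
    with :func:`rebin_to_channels` otherwise.
    """
    if sample_edges is not None:
        if len(sample_edges) != len(vanadium_hist.edges) or not np.allclose(
            sample_edges, vanadium_hist.edges
        ):
            raise ValueError(
                "vanadium/sample TOF binning mismatch; rebin the vanadium "
                "histogram with rebin_to_channels first"
            )
    H1 = vanadium_hist.counts.sum(axis=(0, 1))
    W = vanadium_hist.channel_widths
    rate = H1 / W
    centers = vanadium_hist.channel_centers
    sel = (centers >= t_min) & (centers <= t_max)
    if not np.any(rate[sel] > 0):
        raise ValueError("vanadium spectrum empty in the sample TOF window")
    return rate / rate[sel].mean()


def compute_C(n_neutron) -> np.ndarray:
    """Accelerator-power scales ``C(i) = N_first / N(i)``; C[0] = 1."""
    n = np.asarray(n_neutron, dtype=float)
    if np.any(n <= 0):
        raise ValueError("neutron counts must be positive")
    return n[0] / n


def build_correction_model(
    vanadium: EventList,
    instrument: Instrument,
    n_neutron_per_orientation,
    t_min: float,
    t_max: float,
    n_channels: int = 1000,
    zero_threshold: float = ZERO_THRESHOLD_DEFAULT,
) -> CorrectionModel:
    """Assemble H_xy, H_tof and C from a (merged) vanadium run."""
    vhists = bin_events(vanadium, instrument, n_channels=n_channels)
    van_sq = EventList(
        events=vanadium.events.assign(weight=vanadium.events.weight**2),
        orientation_id=vanadium.orientation_id,
        n_neutron=vanadium.n_neutron,
    )
    vhists_sq = bin_events(van_sq, instrument, n_channels=n_channels)
    H_xy, H_tof, active, H2_counts, H2_var = {}, {}, {}, {}, {}
    for det in instrument.detectors:
        vh = vhists[det.detector_id]
        hxy, act = compute_Hxy(vh, det, t_min, t_max)
        H_xy[det.detector_id] = hxy
        active[det.detector_id] = act
        H_tof[det.detector_id] = compute_Htof(vh, t_min, t_max)
        sel = (vh.edges[:-1] >= t_min - 1e-9) & (vh.edges[1:] <= t_max + 1e-9)
        H2_counts[det.detector_id] = vh.counts[:, :, sel].sum(axis=2)
        H2_var[det.detector_id] = (
            vhists_sq[det.detector_id].counts[:, :, sel].sum(axis=2)
        )
    return CorrectionModel(
        H_xy=H_xy,
        H_tof=H_tof,
        active=active,
        C=compute_C(n_neutron_per_orientation),
        zero_threshold=zero_threshold,
        t_window=(t_min, t_max),
        H2_counts=H2_counts,
        H2_var=H2_var,
    )


def apply_corrections(raw: Histogram3D, corr: CorrectionModel) -> Histogram3D:
    """``cnt' = cnt * C(i) / (H_xy * H_tof)`` with the small-factor zeroing.

    Voxels where ``H_xy * H_tof`` is below ``zero_threshold`` are zeroed.
    Per-voxel variances ``(C/(H_xy H_tof))^2 * cnt`` are stored for later
    error propagation.
    """
    det_id = raw.detector_id
    if det_id not in corr.H_xy:
        raise ValueError(f"correction model has no detector {det_id}")
    hxy = corr.H_xy[det_id]
    htof = corr.H_tof[det_id]
    if hxy.shape != raw.counts.shape[:2] or len(htof) != raw.n_channels:
        raise ValueError("correction/histogram shape mismatch")
    C_i = corr.C[raw.orientation_id]
    factor = hxy[:, :, None] * htof[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(factor >= corr.zero_threshold, C_i / factor, 0.0)
    counts = raw.counts * gain
    variance = raw.counts * gain * gain
    return replace(raw, counts=counts, variance=variance, corrected=True)


# --- event file I/O --------------------------------------------------------

def write_events(ev: EventList, path) -> None:
    ev.events.to_csv(path, index=False)


def read_events(path, orientation_id: int = 0, n_neutron: float = 1.0) -> EventList:
    df = pd.read_csv(path)
    return EventList(events=df, orientation_id=orientation_id, n_neutron=n_neutron)


def write_histogram(h: Histogram3D, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        # track_times=False keeps repeat runs byte-identical
        f.create_dataset("counts", data=h.counts, compression="gzip", track_times=False)
        f.create_dataset("edges", data=h.edges, track_times=False)
        if h.variance is not None:
            f.create_dataset("variance", data=h.variance, compression="gzip",
                             track_times=False)
        f.attrs["detector_id"] = h.detector_id
        f.attrs["orientation_id"] = h.orientation_id
        f.attrs["corrected"] = h.corrected
        f.attrs["n_outside"] = h.n_outside


def read_histogram(path) -> Histogram3D:
    import h5py

    with h5py.File(path, "r") as f:
        return Histogram3D(
            counts=f["counts"][...],
            edges=f["edges"][...],
            variance=f["variance"][...] if "variance" in f else None,
            detector_id=int(f.attrs["detector_id"]),
            orientation_id=int(f.attrs["orientation_id"]),
            corrected=bool(f.attrs["corrected"]),
            n_outside=int(f.attrs["n_outside"]),
        )


def slice_maps(h: Histogram3D) -> dict[str, np.ndarray]:
    """X-Y, X-TOF and Y-TOF projections (sums) of a histogram."""
    return {
        "xy": h.counts.sum(axis=2),
        "xt": h.counts.sum(axis=1),
        "yt": h.counts.sum(axis=0),
    }


def export_slice_maps(h: Histogram3D, prefix) -> list:
    """Write the three projection maps as PNG images; returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    labels = {"xy": ("x pixel", "y pixel"), "xt": ("x pixel", "TOF channel"),
              "yt": ("y pixel", "TOF channel")}
    for name, img in slice_maps(h).items():
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(img.T, origin="lower", aspect="auto", interpolation="nearest")
        ax.set_xlabel(labels[name][0])
        ax.set_ylabel(labels[name][1])
        ax.set_title(f"det {h.detector_id} orient {h.orientation_id} {name}")
        p = f"{prefix}_{name}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths
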