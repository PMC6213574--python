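"""In-memory end-to-end reduction driver.

Convenience wrapper used by scripted analyses and tests: runs the whole
chain (simulate -> histogram+correct -> peak search -> autoindex ->
index -> refine -> predict+integrate -> scale+merge) on a synthetic
fixture and returns every intermediate product together with the ground
truth, so each stage can be scored.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import histogram as hm
from . import indexing as ix
from . import integrate as ig
from . import merge as mg
from . import peaksearch as ps
from . import simulate as sim


@dataclass
class ReductionResult:
    fixture: sim.SyntheticFixture
    truth: pd.DataFrame
    hists: dict
    correction: hm.CorrectionModel
    vanadium_totals: dict
    peaks: list
    ub_found: ix.UBState
    indexed: list
    indexed_rate: float
    refinement: ix.RefinementReport
    predictions: list
    reflections: list
    scaled: list
    merged: mg.MergedDataset
    statistics: mg.ShellStatistics
    timings: dict = field(default_factory=dict)


def reduce_fixture(
    seed: int = 0,
    fixture: sim.SyntheticFixture | None = None,
    n_directions: int = 12000,
    use_strongest: int = 500,
    rebin_factor: int = 25,
    d_max: float = 32.0,
    method: str = "summation",
    constraints: str = "triclinic",
    spacegroup: str = "P 21 21 21",
    resolution_range: tuple | None = None,
    count_threshold: float | None = 10.0,
    region: ig.IntegrationRegion | None = None,
) -> ReductionResult:
    """Run the full reduction on the default synthetic fixture."""
    t: dict = {}
    tic = time.time()
    fx = fixture or sim.default_fixture(seed=seed)
    res_range = resolution_range or fx.resolution_range
    # regions sized for the fixture's 64-pixel detectors and ~1-pixel peaks
    region = region or ig.IntegrationRegion(
        half_x=3.5, half_y=3.5, half_t=2, bg_margin_xy=2, bg_margin_t=3
    )
    events, truth = sim.generate_bragg_events(
        fx.crystal, fx.beam, fx.instrument, fx.goniometers,
        exposure=fx.exposure, seed=seed, efficiency_maps=fx.efficiency_maps,
        n_neutron=fx.n_neutron, background_rate=fx.background_rate,
        resolution_range=res_range, n_channels=fx.n_channels,
        edge_region=region,
    )
    van_s, van_l = sim.generate_vanadium(
        fx.beam, fx.instrument, fx.efficiency_maps, seed=seed + 1
    )
    t["simulate"] = time.time() - tic; tic = time.time()

    vanadium = hm.merge_vanadium(van_s, van_l, fx.instrument)
    corr = hm.build_correction_model(
        vanadium, fx.instrument, [e.n_neutron for e in events],
        *fx.instrument.tof_range, n_channels=fx.n_channels,
    )
    hists = {}
    for ev in events:
        for det_id, h in hm.bin_events(ev, fx.instrument, n_channels=fx.n_channels).items():
            hists[(ev.orientation_id, det_id)] = hm.apply_corrections(h, corr)
    vtot = {
        int(d): float(
            vanadium.events.loc[vanadium.events.detector_id == d, "weight"].sum()
        )
        for d in sorted(vanadium.events.detector_id.unique())
    }
    t["event_to_hist"] = time.time() - tic; tic = time.time()

    params = ps.SearchParams(
        rebin_factor=rebin_factor, count_threshold=count_threshold,
        tof_offset_model=fx.beam.offset_model,
    )
    peaks = []
    for (oid, det_id), h in hists.items():
        peaks.extend(ps.find_peaks(h, fx.instrument, fx.goniometers[oid], params))
    t["peak_search"] = time.time() - tic; tic = time.time()

    strong = ps.strongest_peaks(peaks, use_strongest)
    ub_found = ix.fft_autoindex(
        [p.q_zero for p in strong], d_max,
        ix.FFTIndexParams(n_directions=n_directions),
    )
    indexed, rate = ix.index_peaks(peaks, ub_found)
    refinement = ix.refine_ub(
        indexed, ub_found, fx.instrument, fx.goniometers, constraints=constraints
    )
    t["indexing"] = time.time() - tic; tic = time.time()

    predictions = ig.predict_all(
        refinement.ub, fx.goniometers, fx.instrument,
        centering=fx.crystal.centering, resolution_range=res_range,
        region=region, tof_offset_model=fx.beam.offset_model,
    )
    any_h = next(iter(hists.values()))
    ig.flag_overlaps(
        predictions, region,
        channel_width_us=float(np.mean(any_h.channel_widths)),
    )
    reflections = ig.integrate_all(hists, predictions, region, method=method)
    t["integration"] = time.time() - tic; tic = time.time()

    symmetry = mg.SymmetrySpec.from_spacegroup(spacegroup)
    scaled = mg.scale_detectors(reflections, vtot)
    merged = mg.merge_equivalents(scaled, symmetry)
    statistics = mg.compute_statistics(
        scaled, merged, symmetry, fx.crystal.cell
    )
    t["merge"] = time.time() - tic

    return ReductionResult(
        fixture=fx, truth=truth, hists=hists, correction=corr,
        vanadium_totals=vtot,
        peaks=peaks, ub_found=ub_found, indexed=indexed, indexed_rate=rate,
        refinement=refinement, predictions=predictions, reflections=reflections,
        scaled=scaled, merged=merged, statistics=statistics, timings=t,
    )


def match_cell(found_cell, true_cell) -> dict:
    """Compare cells up to axis permutation: returns max edge error (%) and
    max angle deviation from the true angles (degrees)."""
    fe = np.sort(np.asarray(found_cell[:3]))
    te = np.sort(np.asarray(true_cell[:3]))
    edge_err = float(np.max(np.abs(fe - te) / te * 100.0))
    fa = np.sort(np.asarray(found_cell[3:]))
    ta = np.sort(np.asarray(true_cell[3:]))
    ang_err = float(np.max(np.abs(fa - ta)))
    return {"edge_err_percent": edge_err, "angle_err_deg": ang_err}


def basis_change(found: ix.UBState, planted: ix.UBState) -> np.ndarray:
    """Integer change of basis M with h_found = M @ h_planted.

    The autoindexed lattice is equivalent to the planted one only up to a
    unimodular transformation; observed and planted Miller indices must be
    compared through it.
    """
    M = np.linalg.inv(found.UB) @ planted.UB
    Mi = np.rint(M).astype(int)
    if abs(abs(np.linalg.det(Mi)) - 1) > 1e-9:
        raise ValueError("found and planted lattices are not equivalent")
    return Mi


def intensity_regression(result: ReductionResult) -> dict:
    """Regress Lorentz-corrected integrated intensities on the planted
    values; slope ~ 1 and R^2 ~ 1 when the chain inverts the generator."""
    truth = result.truth
    M = basis_change(result.refinement.ub, result.fixture.crystal.ub())
    key = {}
    for _, r in truth.iterrows():
        hf = M @ np.array([int(r.h), int(r.k), int(r.l)])
        key[(int(r.orientation_id), int(r.detector_id),
             int(hf[0]), int(hf[1]), int(hf[2]))] = float(r.I_scaled)
    xs, ys = [], []
    for refl in result.reflections:
        k = (refl.orientation_id, refl.detector_id, refl.h, refl.k, refl.l)
        if k in key:
            xs.append(key[k])
            ys.append(refl.intensity)
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope = float((x * y).sum() / (x * x).sum())
    ss_res = float(((y - slope * x) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return {
        "n_matched": len(x),
        "slope": slope,
        "r2": 1.0 - ss_res / ss_tot,
    }
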