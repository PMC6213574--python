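# toflaue

Data reduction for **time-of-flight (TOF) Laue neutron single-crystal
diffraction**, the measurement mode of pulsed-source protein
diffractometers: a stationary crystal in a white neutron beam, a bank of
time-resolved area detectors, and the neutron wavelength encoded in its
flight time via de Broglie's relation
λ = h·T / (mₙ·(L₁ + L′)).

The package takes raw neutron *event lists* — one (detector, x-pixel,
y-pixel, TOF) record per detected neutron, collected at several crystal
orientations together with vanadium calibration runs — and produces merged
`hkl` intensity data with quality statistics. It is aimed at method
developers and instrument scientists who need a transparent, fully tested
reference implementation of this reduction chain, exercised end-to-end on
synthetic data with exact ground truth.

## The reduction chain

1. **Event histogramming and correction** (`toflaue.histogram`) — events are
   binned into (x, y, TOF-channel) histograms; corrected counts are

   cnt′(x,y,t,i) = cnt(x,y,t,i) · C(i) / (H_xy(x,y) · H_tof(t)),

   with H_xy = H₂·d/⟨H₂·d⟩ the per-pixel efficiency from vanadium
   incoherent scatter (d is the squared sample–pixel distance, compensating
   the 1/r² fall-off), H_tof = (H₁/W)/⟨H₁/W⟩ the wavelength/spectrum
   correction, and C(i) = N_first/N(i) the accelerator-power scale.
   Corrected counts are zeroed wherever H_xy·H_tof < 10⁻⁵. Two vanadium
   wavelength bands (0.06–3.94 and 2.88–6.76 Å) are merged per event at a
   connecting wavelength.
2. **Peak search** (`toflaue.peaksearch`) — TOF rebinning plus in-plane
   3×3 weighted-average smoothing, local-maximum/threshold candidate
   selection, region consolidation, background-subtracted centroid
   refinement, and wavelength-dependent TOF-offset (moderator emission
   lag) correction; each peak gets a reciprocal-space vector
   **Q**\* = (x₄/Dλ, y₄/Dλ, (1/λ)(z₄/D − 1)) with |**Q**\*| = 2 sinθ/λ.
3. **Autoindexing and UB refinement** (`toflaue.indexing`) — FFT
   direction-search autoindexing of the zero-setting **Q**\*′ =
   (R_ω R_χ R_φ)⁻¹ **Q**\* yields a primitive UB; Miller indices come from
   **h** = UB⁻¹**Q**\*′ with an indexing threshold of 0.2; reduced-cell
   analysis proposes primitive→centered transformations UB_N = UB_O·UB_t;
   nine parameters (three orientation, six cell) are refined by least
   squares on detector-space residuals
   ε² = (x_o−x_p)² + (y_o−y_p)² + C²(t_o−t_p)² with C = 10⁻⁴, and quality
   is judged by ε_hkl, the distance of the real-valued indices from
   integers.
4. **Prediction and integration** (`toflaue.integrate`) — all reflections
   reaching the detectors within the wavelength band are predicted
   (centering extinctions removed), edge and overlapped reflections are
   discarded, and intensities come from background-subtracted summation or
   a 1-D TOF profile fit (Gaussian ⊗ decaying exponential — the asymmetric
   coupled-moderator pulse — over a linear background). The TOF-Laue
   Lorentz factor sin²θ/λ⁴ is applied.
5. **Merging and statistics** (`toflaue.merge`) — inter-detector scaling by
   vanadium totals, mapping to a canonical index under the point group,
   systematic-absence filtering, inverse-variance merging, and shell tables
   of N_obs, N_unique, multiplicity, completeness, R_merge, R_p.i.m. and
   I/σ by resolution, wavelength, 2θ, detector or orientation, plus a
   Wilson-type ln⟨I⟩ vs (sinθ/λ)² plot and SCALEPACK / SHELX HKLF-4 / GSAS
   writers.
6. **Synthetic data** (`toflaue.simulate`) — generates all of the above
   inputs from a known crystal/beam/instrument model (Wilson-distributed
   intensities, Maxwellian spectrum, asymmetric pulse, per-pixel efficiency
   maps, Poisson counting) so every stage can be scored against ground
   truth.

## Worked example

```python
from toflaue import pipeline as pl

res = pl.reduce_fixture(seed=1)          # full chain on the synthetic fixture
print(tuple(round(v, 3) for v in res.refinement.ub.cell))
print(round(res.indexed_rate, 3), round(res.refinement.frac_eps_below_0p1, 3))
reg = pl.intensity_regression(res)
print(round(reg["slope"], 3), round(reg["r2"], 4))
st = res.statistics.overall
print(round(st["r_merge"], 4), round(st["r_pim"], 4))
```

prints

```
(25.198, 25.999, 27.098, 90.0, 89.997, 89.999)
0.994 0.959
1.006 0.9961
0.0294 0.0294
```

— the planted 25.2 × 26.0 × 27.1 Å orthorhombic cell is recovered to
better than 0.01%, 99% of found peaks index, the integrated intensities
regress on the planted ones with slope 1.006 (R² = 0.996), and the
equivalent-reflection agreement R_merge ≈ 2.9% is at the level set by
counting statistics.

The same chain is available stage-by-stage from the shell:

```
toflaue --config config.yaml simulate
toflaue --config config.yaml event2hist
toflaue --config config.yaml findpeaks
...
toflaue --config config.yaml merge      # writes merged.sca/.hkl + statistics
```

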