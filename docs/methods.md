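# Methods

This note records the models, conventions and numerical choices behind the
package, in the spirit of a software methods section.

## Coordinate conventions

The diffractometer frame is right-handed with the incident beam along +z
and the sample at the origin. Detector pixel frames have their x (and z)
axes opposite to the lab frame, so pixel coordinates are axis-reversed
before any rotation. A pixel maps to the lab frame through, in order:
centering (0-based pixel indices address pixel centers; the face center
sits at index (N−1)/2), axis reversal, mis-setting rotations
R_z′·R_y′·R_x′ about the face center, translation by L₂ along +z, and
position rotations R_y(Rot_y)·R_x(Rot_x) about the sample. The squared
sample–pixel distance d(x,y) used by the vanadium correction and by
per-pixel flight paths is the squared norm of this lab position.

The goniometer composition is **R = R_ω(y)·R_χ(x)·R_φ(y)**: ω about lab
+y, χ about the ω-rotated +x, φ about the spindle. The figure defining the
physical axes of the instrument does not fix signs unambiguously; any
self-consistent convention reproduces the pipeline (generator and reducer
share this one constant), and adapting to a real instrument means editing
only `geometry.py`.

Reciprocal space uses the crystallographic convention without 2π:
|**Q**\*| = 2 sinθ/λ = 1/d. The UB matrix has the reciprocal basis vectors
a\*, b\*, c\* as *columns* in the lab frame at goniometer zero, so
**Q**\*′ = UB·**h** and the rows of UB⁻¹ are the direct-lattice vectors.
Units are cm (detector frame), m (flight path), µs (TOF) and Å
(wavelength), with CODATA 2018 constants.

## Event histogramming and corrections

TOF channels are equal-width and half-open, [edge, next); an event exactly
on an interior edge belongs to the upper channel. This is the single
binning convention pipeline-wide.

The per-pixel correction is H_xy = H₂·d/⟨H₂·d⟩: vanadium counts
compensated for the 1/r² fall-off of incoherent scatter, then normalized
to mean 1 over *active* pixels (pixels with zero vanadium counts are
flagged inactive and excluded from the mean and from correction). For an
ideal detector this gives H_xy ≡ 1. The per-channel correction is
H_tof = (H₁/W)/⟨H₁/W⟩ over the sample TOF window; a vanadium histogram on
a different binning must be rebinned first (uniform-density reassignment,
provided as an explicit pre-step). Corrected counts are
cnt·C(i)/(H_xy·H_tof), zeroed where H_xy·H_tof < 10⁻⁵ rather than divided
by a vanishing factor; C(i) multiplies (power normalization scales counts
up for weaker pulses). Per-voxel variances (C/(H_xy·H_tof))²·cnt are
stored for downstream error propagation.

The two vanadium wavelength bands are connected per event in wavelength —
each event's own pixel flight path, not the face-center path — with
long-band events weighted by N_short/N_long. The connecting wavelength is
a parameter; the default 3.4 Å sits mid-overlap of the 0.06–3.94 and
2.88–6.76 Å bands, which are not tied to a published value.

## Peak search

Defaults: TOF rebinning factor 32 (tens of channels summed), 3×3 binomial
in-plane kernel and (1,2,1)/4 TOF kernel — the smallest kernels consistent
with a weighted-average smoothing; both configurable. Edge pixels
renormalize the kernel over in-bounds neighbours, so a constant image is
exactly unchanged (totals are then conserved exactly only away from
edges). The default threshold is robust (median + 5·MAD of the smoothed
rebinned counts per detector), overridable by an absolute count; the
pipeline driver for the compact fixture uses an absolute threshold of 10
smoothed counts per slab, which suppresses the ~5σ Poisson excursions
that a million-voxel search volume otherwise promotes to candidates.
Tie-breaks for equal-count maxima go to the lowest (x, y, t);
consolidation keeps the highest-count candidate within a Chebyshev radius
of 3 pixels and ±1 rebinned slab. Centroids are background-subtracted
centers of gravity in x and y only (box perimeter mean as background,
fallback to the candidate position when no net counts); TOF is refined
only by the offset subtraction, in a single pass.

The TOF offset — the wavelength-dependent lag between T = 0 and the pulse
maximum at the moderator — is a configurable polynomial in λ (default
zero). The synthetic beam model reports its own offset as the *mean*
emission delay τ₀ + τ₁λ of its pulse shape, which is the appropriate
statistic when channels are much wider than the pulse.

## Autoindexing

Direction search on a spherical-Fibonacci hemisphere grid (default 45 000
directions ≈ 1° spacing; the in-package drivers use 12 000, which is
sufficient at the fixture's cell size): project all **Q**\*′ onto each
direction, histogram (length 2048), FFT, and score the strongest frequency
whose direct-space period lies in [2 Å, d_max]. Directions within 2.5° of
a better one are suppressed; each survivor's 1-D period is refined by
maximizing |Σ exp(2πi L t_j)|, and the vector is then *snapped* to the
nearest genuine lattice vector by solving Q·v ≈ round(Q·v) in least
squares (this collapses noisy grid-neighbours of one axis onto it, and
duplicates closer than 0.5 Å are removed). Among the remaining candidate
direct vectors, the triple maximizing the indexed fraction (ties to the
smaller cell) is chosen; vectors shorter than 2 Å and near-coplanar
triples are excluded, since a degenerate basis trivially "indexes"
everything. The basis is polished by iterated linear least squares against
the indexed peaks, Buerger-reduced to shortest vectors, and made
right-handed. Autoindexing is run on the ~500 strongest peaks, standard
practice that keeps threshold-level spurious candidates out of the
direction scores.

## Reduced-cell transformation

Candidates for the primitive→centered transformation are found by
reducing the primitive basis to shortest vectors and then *exhaustively*
enumerating integer basis matrices with entries in [−2, 2], determinant
equal to the centering order (2 for C/I, 3 for H-obverse, 4 for F), and
admissible centering vectors (v·T integral for each centering translation
v). Each surviving conventional cell is scored by its deviation from the
metric constraints of the crystal systems that allow the target centering;
candidates are deduplicated and sorted by (score, volume, standard
a ≤ b ≤ c setting, matrix). This is equivalent in effect to matching the
44 reduced-cell lattice characters, but compact and directly testable by
forward construction. The caller picks one candidate, mirroring the
interactive selection step, and applies it as UB_N = UB_O·UB_t with
UB_t = T⁻¹.

## UB refinement

Nine parameters: three small rotations composed onto the orientation part
and the six cell parameters (optionally constrained to a crystal system;
unrestrained/triclinic is the default so that the recovered angles are a
genuine diagnostic). Residuals per indexed peak are (Δx, Δy) in cm and
C·Δt with C = 10⁻⁴ balancing µs against cm; predicted positions come from
the exact inverse of the observation chain. Levenberg–Marquardt with
finite differences, tolerances 10⁻¹²; peaks whose predictions leave the
detector during a trial step get a 1 cm penalty residual. The report
carries per-peak ε and ε_hkl = |frac − round(frac)|₂ and the fraction
below 0.1 — the conventional "accurate UB" criterion.

## Integration

The hkl search box per detector/orientation spans the fractional indices
of the four detector corners at both TOF extremes (wavelengths clamped to
the instrument band), padded by one. Centering-forbidden indices are
dropped before prediction. Regions are rectangles or elliptic cylinders;
reflections whose core+background would cross the detector edge are
flagged and skipped, and elliptic-cylinder overlap (neighbour core against
target core-or-background, exact axis-aligned ellipse test with boundary
sampling, TOF intervals in channels) removes overlapped reflections
entirely — no deconvolution is attempted. Summation integration subtracts
a shell-background mean with two passes of 3σ outlier rejection (resists
neighbour tails); σ² combines core variances with the background-mean
variance. Profile fitting sums the core in-plane and fits the 1-D TOF
profile with an exponentially modified Gaussian (position, width, decay,
area) plus linear background by weighted least squares; the intensity is
the analytic area, σ comes from the fit covariance, and failures or
χ²/dof > 10 fall back to summation with a flag. The model area parameter
is a density in µs and is divided by the channel width to give counts.

Default region sizes follow the 256-pixel detector geometry (5-pixel
semi-axes, ±10 channels, +3/+5 background margins); the 64-pixel fixture
drivers use 3.5-pixel semi-axes and ±2 channels, matched to its ~1-pixel
peaks and 160 µs channels. The Lorentz correction is the TOF-Laue factor
sin²θ/λ⁴ (any global constant cancels in merging); the
equivalents-agree-only-after-correction property in the test suite pins
the form.

## Merging and statistics

Observations are first divided by (detector vanadium total)/(mean total) —
invariant to a global vanadium rescale. The canonical index is the
lexicographic maximum over the point-group orbit, Friedel mates included
by default (no anomalous target). Merged intensity is the 1/σ²-weighted
mean; merged σ is the larger of the propagated error and the scatter-based
standard error, a guard against under-estimated integration σ.
R_merge = ΣΣ|Iᵢ−⟨I⟩| / ΣΣIᵢ and R_p.i.m. adds the √(1/(n−1)) multiplicity
weight; multiplicity-1 reflections are excluded from both numerator and
denominator. Completeness denominators enumerate all symmetry-unique,
non-absent indices in the resolution shell directly. Absence rules are
reflection-condition strings ("h00: h=2n") parsed into predicates, with a
built-in table for common space groups; space-group operators come from
symbol lookup and the parsed rules are cross-checked against the full
symmetry calculation in the tests. Writers: merged SCALEPACK (3-line
header, 3I4+2F8.1 records), SHELX HKLF-4 (3I4+2F8.2 with terminating zero
record), and a GSAS-style reflection text (title, CELL line, 3I4+2F12.4);
values that overflow a field raise rather than silently truncate.

## The synthetic fixture

The study fixture is deliberately compact so the whole chain runs in
seconds: a 25.2 × 26.0 × 27.1 Å orthorhombic cell with 2₁2₁2₁-type screw
axes, random orientation; six 64×64-pixel detectors (13.3 cm active area,
L₂ = 49 cm) ringed around the sample; L₁ = 40 m; TOF window 4–44 ms in
250 channels (160 µs); wavelength band 0.7–4.2 Å; five orientations with
±15% accelerator-power variation. Intensities are Wilson-distributed
(exponential, mean 1) per symmetry-unique reflection with B = 8 Å²; peaks
spread σ = 1.1 pixels in-plane; the moderator pulse is Gaussian
(8 + 4λ µs) convolved with a decaying exponential (12 + 6λ µs); detector
efficiency maps are smooth ±10% patterns; the vanadium runs put ~300 000
events per detector in the short band with the long-band count following
the irradiation × band-flux ratio, which is what makes the band merge
spectrally continuous. The expected counts of a unit-intensity reflection
("exposure", default 2500) are calibrated at the median inverse-Lorentz
weight λ⁴/sin²θ, so generated counts stay within sane bounds while
spanning the orders of magnitude real Laue data show.

The generative chain is the exact inverse of the correction chain:
detected peak counts carry intensity × spectrum × efficiency × inverse
Lorentz × power, the vanadium spatial density is efficiency/d, and the
background follows efficiency × spectrum. Passing end-to-end tests
therefore demonstrates that the pipeline inverts its own stated model to
counting precision — not that it handles absorption, extinction,
dead-time, λ-dependent mosaic coupling or profile-shape drift, none of
which are modelled. The ground-truth table suffices to score peak
recall, indexing, intensity recovery and R statistics without external
data.

A note on error budgets: with ~73 vanadium counts per pixel the H_xy
correction itself carries ~2% per-reflection calibration noise, which
dominates the equivalent-reflection scatter of strong reflections. The
consistency checks therefore compare R_merge against a Monte-Carlo null
that includes both the integration σ and this calibration term
(relative variance ≈ Σf²_p/H₂ with Gaussian pixel fractions f).

## Known limitations

* Overlapped reflections are rejected, not deconvolved.
* No absorption or extinction corrections.
* Centering/space group are user inputs; there is no automatic
  determination from systematic absences.
* One crystal, one dataset: no cross-crystal scaling or post-refinement.
* The GSAS writer targets a single documented fixed-width dialect.
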