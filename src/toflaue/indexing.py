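"""Autoindexing, Miller-index assignment and UB-matrix refinement.

The UB matrix is the 3x3 matrix whose columns are the reciprocal-lattice
vectors a*, b*, c* in the lab frame at the goniometer zero setting, so that
``Q*' = UB @ (h, k, l)``.  Equivalently the rows of ``inv(UB)`` are the
direct-lattice vectors a, b, c.

Pipeline order:

1. :func:`fft_autoindex` - direction search on a hemisphere grid; for each
   direction the peak Q*' values are projected, histogrammed and Fourier
   transformed, and the strongest periodicity below the longest-axis bound
   scores the direction.  The best non-coplanar directions give direct
   vectors from which a primitive UB is built.
2. :func:`index_peaks` - fractional indices ``UB^-1 R^-1 Q*`` rounded to
   integers when all three residuals are below a threshold (default 0.2).
3. :func:`reduced_cell_transform` - candidate primitive-to-centered basis
   transformations from reduced-cell analysis.
4. :func:`refine_ub` - least-squares refinement of the 9 degrees of freedom
   (3 orientation + 6 cell) against observed detector positions, with the
   TOF term scaled by a factor C (default 1e-4) to balance units.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .geometry import (
    DetectorGeometry,
    GoniometerSetting,
    Instrument,
    QVector,
    goniometer_matrix,
    rot_x,
    rot_y,
    rot_z,
    wavelength_to_tof,
)
from .peaksearch import PeakObservation

INDEX_THRESHOLD_DEFAULT = 0.2
UB_SCALE_C_DEFAULT = 1e-4

CENTERING_ORDER = {"P": 1, "C": 2, "I": 2, "F": 4, "H": 3}

#: conventional -> primitive direct-basis transformation (rows of the
#: primitive vectors in conventional fractional coordinates)
CENTERING_TO_PRIMITIVE = {
    "P": np.eye(3),
    "C": np.array([[0.5, -0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]]),
    "I": np.array([[-0.5, 0.5, 0.5], [0.5, -0.5, 0.5], [0.5, 0.5, -0.5]]),
    "F": np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]),
    "H": np.array(
        [[2 / 3, 1 / 3, 1 / 3], [-1 / 3, 1 / 3, 1 / 3], [-1 / 3, -2 / 3, 1 / 3]]
    ),
}


# --- cell algebra ----------------------------------------------------------

def metric_from_cell(cell) -> np.ndarray:
    """Direct metric tensor G from (a, b, c, alpha, beta, gamma)."""
    a, b, c, al, be, ga = cell
    ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
    return np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )


def cell_from_metric(G: np.ndarray):
    a, b, c = (math.sqrt(G[i, i]) for i in range(3))
    al = math.degrees(math.acos(max(-1, min(1, G[1, 2] / (b * c)))))
    be = math.degrees(math.acos(max(-1, min(1, G[0, 2] / (a * c)))))
    ga = math.degrees(math.acos(max(-1, min(1, G[0, 1] / (a * b)))))
    return (a, b, c, al, be, ga)


def cell_volume(cell) -> float:
    return math.sqrt(max(np.linalg.det(metric_from_cell(cell)), 0.0))


def b_matrix(cell) -> np.ndarray:
    """Reciprocal-basis matrix B: columns a*, b*, c* with a* along +x.

    Crystallographic convention (no 2*pi); ``UB = U @ B`` for an
    orientation U.
    """
    a, b, c, al, be, ga = cell
    ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
    sa = math.sin(math.radians(al))
    sb = math.sin(math.radians(be))
    sg = math.sin(math.radians(ga))
    V = a * b * c * math.sqrt(
        max(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0)
    )
    a_s = b * c * sa / V
    b_s = a * c * sb / V
    c_s = a * b * sg / V
    ca_s = (cb * cg - ca) / (sb * sg)
    cb_s = (ca * cg - cb) / (sa * sg)
    cg_s = (ca * cb - cg) / (sa * sb)
    sg_s = math.sqrt(max(1 - cg_s * cg_s, 0.0))
    return np.array(
        [
            [a_s, b_s * cg_s, c_s * cb_s],
            [0.0, b_s * sg_s, -c_s * math.sqrt(max(1 - cb_s**2, 0.0)) * ca],
            [0.0, 0.0, 1.0 / c],
        ]
    )


def _b_matrix_exact(cell) -> np.ndarray:
    """B via direct construction (used to sidestep rounding in b_matrix)."""
    A = direct_basis_from_cell(cell)
    return np.linalg.inv(A)


def direct_basis_from_cell(cell) -> np.ndarray:
    """Canonical direct basis: rows a, b, c with a along +x, b in the
    x-y plane."""
    a, b, c, al, be, ga = cell
    ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
    sg = math.sin(math.radians(ga))
    cx, cy = c * cb, c * (ca - cb * cg) / sg
    cz = math.sqrt(max(c * c - cx * cx - cy * cy, 0.0))
    return np.array(
        [[a, 0.0, 0.0], [b * cg, b * sg, 0.0], [cx, cy, cz]]
    )


# --- UB state --------------------------------------------------------------

@dataclass
class UBState:
    """Orientation/metric matrix plus derived cell parameters."""

    UB: np.ndarray
    provenance: str = "found"  # found | transformed | refined
    centering: str = "P"

    def __post_init__(self):
        self.UB = np.asarray(self.UB, dtype=float)
        if abs(np.linalg.det(self.UB)) < 1e-15:
            raise ValueError("UB matrix is singular")

    @property
    def direct_basis(self) -> np.ndarray:
        """Rows are the direct vectors a, b, c in the lab frame."""
        return np.linalg.inv(self.UB)

    @property
    def cell(self):
        A = self.direct_basis
        G = A @ A.T
        return cell_from_metric(G)

    @property
    def volume(self) -> float:
        return abs(np.linalg.det(self.direct_basis))

    def q_from_hkl(self, hkl) -> np.ndarray:
        return np.asarray(hkl, dtype=float) @ self.UB.T

    def hkl_from_q(self, q_zero) -> np.ndarray:
        return np.asarray(q_zero, dtype=float) @ np.linalg.inv(self.UB).T


def ub_from_cell(cell, U: np.ndarray | None = None, **kw) -> UBState:
    """Build a UB from cell parameters and an optional orientation U."""
    B = _b_matrix_exact(cell)
    U = np.eye(3) if U is None else np.asarray(U, dtype=float)
    return UBState(UB=U @ B, **kw)


# --- primitive longest axis ------------------------------------------------

def primitive_cell(cell, centering: str):
    """Cell parameters of the primitive lattice of a centered cell."""
    if centering not in CENTERING_TO_PRIMITIVE:
        raise ValueError(f"unknown centering {centering!r}")
    M = CENTERING_TO_PRIMITIVE[centering]
    G = metric_from_cell(cell)
    Gp = M @ G @ M.T
    return cell_from_metric(Gp)


def primitive_longest_axis(cell, centering: str) -> float:
    """Longest primitive-cell edge, the length bound FFT indexing needs."""
    pc = primitive_cell(cell, centering)
    return max(pc[0], pc[1], pc[2])


# --- basis reduction -------------------------------------------------------

def buerger_reduce(vectors: np.ndarray, max_iter: int = 100):
    """Shortest-vector (Buerger-style) reduction of a 3-vector basis.

    Returns (reduced rows sorted by length, unimodular integer matrix N with
    ``reduced = N @ vectors``).
    """
    V = np.array(vectors, dtype=float)
    N = np.eye(3, dtype=int)
    for _ in range(max_iter):
        changed = False
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                # integer Gram-Schmidt step
                mu = round(float(V[i] @ V[j] / (V[j] @ V[j])))
                if mu != 0 and np.linalg.norm(V[i] - mu * V[j]) < np.linalg.norm(V[i]) - 1e-12:
                    V[i] -= mu * V[j]
                    N[i] -= mu * N[j]
                    changed = True
        if not changed:
            break
    order = np.argsort([np.linalg.norm(v) for v in V], kind="stable")
    V, N = V[order], N[order]
    if np.linalg.det(V) < 0:
        V[2] *= -1
        N[2] *= -1
    return V, N


# --- FFT autoindexing ------------------------------------------------------

@dataclass
class FFTIndexParams:
    """Knobs of the direction-search autoindexer."""

    n_directions: int = 45000        # hemisphere grid (~1 degree spacing)
    histogram_length: int = 2048     # projection histogram / FFT size
    d_min_axis: float = 2.0          # shortest admissible axis, A
    n_candidates: int = 24           # directions kept after suppression
    suppression_angle: float = 2.5   # degrees between kept directions
    min_peaks: int = 20
    direction_chunk: int = 4096
    index_tolerance: float = 0.2     # for scoring candidate triples


def hemisphere_directions(n: int) -> np.ndarray:
    """Spherical-Fibonacci points on the z >= 0 hemisphere, (n, 3)."""
    i = np.arange(n)
    golden = (1 + math.sqrt(5)) / 2
    z = (i + 0.5) / n            # uniform in z on (0, 1]
    phi = 2 * math.pi * i / golden
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _refine_period(ts: np.ndarray, L0: float, dL: float) -> float:
    """Maximize |sum exp(2*pi*i*L*t)| over L near L0."""

    def neg_power(L):
        ph = 2 * np.pi * L * ts
        return -(np.cos(ph).sum() ** 2 + np.sin(ph).sum() ** 2)

    res = minimize_scalar(neg_power, bounds=(L0 - dL, L0 + dL), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def fft_autoindex(
    qs,
    d_max: float,
    params: FFTIndexParams | None = None,
) -> UBState:
    """Determine a primitive UB from zero-setting Q*' vectors.

    ``d_max`` is the longest primitive axis to allow (from
    :func:`primitive_longest_axis` when the cell is known in advance).
    Raises ``ValueError`` for too few peaks or degenerate (coplanar) input.
    """
    p = params or FFTIndexParams()
    Q = np.asarray(
        [q.as_array() if isinstance(q, QVector) else q for q in qs], dtype=float
    )
    if len(Q) < p.min_peaks:
        raise ValueError(f"need at least {p.min_peaks} peaks, got {len(Q)}")
    qmax = float(np.linalg.norm(Q, axis=1).max())
    half = qmax * 1.05
    R_tot = 2 * half
    m = p.histogram_length
    k_hi = min(int(math.floor(d_max * R_tot)), m // 2 - 1)
    k_lo = max(2, int(math.ceil(p.d_min_axis * R_tot)))
    if k_hi <= k_lo:
        raise ValueError("d_max too small for the observed Q range")

    dirs = hemisphere_directions(p.n_directions)
    best_score = np.empty(p.n_directions)
    best_k = np.empty(p.n_directions, dtype=int)
    scale = m / R_tot
    for start in range(0, p.n_directions, p.direction_chunk):
        chunk = dirs[start : start + p.direction_chunk]
        proj = chunk @ Q.T                      # (nc, N)
        bins = np.clip(((proj + half) * scale).astype(int), 0, m - 1)
        nc = len(chunk)
        offs = (np.arange(nc)[:, None] * m + bins).ravel()
        hist = np.bincount(offs, minlength=nc * m).reshape(nc, m).astype(float)
        F = np.abs(np.fft.rfft(hist, axis=1))
        band = F[:, k_lo : k_hi + 1]
        best_k[start : start + nc] = band.argmax(axis=1) + k_lo
        best_score[start : start + nc] = band.max(axis=1)

    # non-maximum suppression on the direction sphere
    order = np.argsort(-best_score, kind="stable")
    kept: list[int] = []
    cos_sup = math.cos(math.radians(p.suppression_angle))
    for idx in order:
        u = dirs[idx]
        if all(abs(u @ dirs[j]) < cos_sup for j in kept):
            kept.append(int(idx))
        if len(kept) >= p.n_candidates:
            break
    if len(kept) < 3:
        raise ValueError("direction search found fewer than 3 distinct directions")

    # refine the 1D period of each kept direction -> candidate direct vectors
    cand = []
    for idx in kept:
        u = dirs[idx]
        ts = Q @ u
        L0 = best_k[idx] / R_tot
        L = _refine_period(ts, L0, 0.75 / R_tot)
        cand.append(L * u)
    cand = np.array(cand)

    # snap each candidate to the nearest genuine lattice vector: solve
    # Q v ~= round(Q v) over the peaks the vector already projects close to
    # integers on; noisy grid directions around one axis collapse onto it
    tol = p.index_tolerance
    snapped = []
    for v in cand:
        for _ in range(3):
            r = Q @ v
            n_int = np.rint(r)
            sel = (np.abs(r - n_int) < tol) & (np.abs(n_int) > 0)
            if sel.sum() < 6:
                break
            v_new, *_ = np.linalg.lstsq(Q[sel], n_int[sel], rcond=None)
            if np.linalg.norm(v_new) < 1e-6:
                break
            v = v_new
        snapped.append(v)
    # dedupe collapsed duplicates (keep the first = higher-scoring one)
    cand = []
    for v in snapped:
        if np.linalg.norm(v) < p.d_min_axis:
            continue
        if any(np.linalg.norm(v - w) < 0.5 or np.linalg.norm(v + w) < 0.5
               for w in cand):
            continue
        cand.append(v)
    if len(cand) < 3:
        raise ValueError("fewer than 3 distinct lattice directions survive "
                         "period refinement")
    cand = np.array(cand)

    # choose the triple that indexes the most peaks; tie-break on volume
    best = None
    lengths = np.linalg.norm(cand, axis=1)
    for combo in itertools.combinations(range(len(cand)), 3):
        if np.any(lengths[list(combo)] < p.d_min_axis):
            continue  # a degenerate short vector would index anything
        A = cand[list(combo)]
        vol = abs(np.linalg.det(A))
        if vol < 0.05 * lengths[list(combo)].prod():
            continue  # (near-)coplanar
        frac = Q @ A.T
        res = np.abs(frac - np.rint(frac))
        # ignore peaks the basis maps to the origin: they carry no
        # indexing evidence and reward spuriously small bases
        nontrivial = np.any(np.abs(np.rint(frac)) > 0, axis=1)
        ok = np.all(res < tol, axis=1) & nontrivial
        rate = float(np.mean(ok))
        key = (round(rate, 3), -vol)
        if best is None or key > best[0]:
            best = (key, A)
    if best is None:
        raise ValueError("no three linearly independent directions found "
                         "(peaks may be coplanar in reciprocal space)")
    A = best[1]
    # polish: linear least squares of the direct basis against the peaks
    # the triple already indexes (removes direction-grid quantisation)
    for _ in range(3):
        frac = Q @ A.T
        hkl = np.rint(frac)
        res = np.abs(frac - hkl)
        sel = np.all(res < tol, axis=1) & np.any(hkl != 0, axis=1)
        if sel.sum() < 9:
            break
        # rows of A solve Q @ A.T ~= hkl
        A_new, *_ = np.linalg.lstsq(Q[sel], hkl[sel], rcond=None)
        A_new = A_new.T
        if abs(np.linalg.det(A_new)) < 1e-6:
            break
        A = A_new
    A, _ = buerger_reduce(A)
    return UBState(UB=np.linalg.inv(A), provenance="found")


# --- index assignment ------------------------------------------------------

@dataclass
class IndexedPeak:
    """A peak with (fractional and rounded) Miller indices."""

    peak: PeakObservation
    frac: np.ndarray
    hkl: tuple
    eps_hkl: float
    indexed: bool


def index_peaks(
    peaks: list[PeakObservation],
    ub: UBState,
    goniometers: dict | None = None,
    threshold: float = INDEX_THRESHOLD_DEFAULT,
) -> tuple[list[IndexedPeak], float]:
    """Assign Miller indices; a peak is indexed when every fractional index
    is within ``threshold`` of an integer.  Returns (peaks, indexed rate).

    ``goniometers`` maps orientation_id -> GoniometerSetting and is only
    needed when the peaks do not carry a cached zero-setting Q*'.
    """
    UB_inv = np.linalg.inv(ub.UB)
    out: list[IndexedPeak] = []
    n_indexed = 0
    for pk in peaks:
        if pk.q_zero is not None:
            q0 = pk.q_zero.as_array()
        else:
            R = goniometer_matrix(goniometers[pk.orientation_id])
            q0 = R.T @ pk.q.as_array()
        frac = UB_inv @ q0
        hkl = np.rint(frac).astype(int)
        res = frac - hkl
        eps = float(np.linalg.norm(res))
        ok = bool(np.all(np.abs(res) < threshold))
        n_indexed += ok
        out.append(IndexedPeak(peak=pk, frac=frac, hkl=tuple(int(v) for v in hkl),
                               eps_hkl=eps, indexed=ok))
    rate = n_indexed / len(peaks) if peaks else 0.0
    return out, rate


# --- reduced-cell transformation -------------------------------------------

_SYSTEMS_FOR_CENTERING = {
    # target centering -> list of (system name, constraint function)
    "I": ["cubic", "tetragonal", "orthorhombic"],
    "F": ["cubic", "orthorhombic"],
    "C": ["orthorhombic", "monoclinic"],
    "H": ["rhombohedral"],
    "P": ["any"],
}


def _constraint_score(cell, system: str) -> float:
    """Deviation (degrees / percent mix) of a cell from a system's metric
    constraints; 0 means exact."""
    a, b, c, al, be, ga = cell
    dev = 0.0
    if system == "cubic":
        dev += abs(al - 90) + abs(be - 90) + abs(ga - 90)
        m = (a + b + c) / 3
        dev += 100 * (abs(a - m) + abs(b - m) + abs(c - m)) / m
    elif system == "tetragonal":
        dev += abs(al - 90) + abs(be - 90) + abs(ga - 90)
        m = (a + b) / 2
        dev += 100 * abs(a - b) / m
    elif system == "orthorhombic":
        dev += abs(al - 90) + abs(be - 90) + abs(ga - 90)
    elif system == "monoclinic":
        dev += abs(al - 90) + abs(ga - 90)
    elif system == "rhombohedral":
        # hexagonal-axes setting: a = b, alpha = beta = 90, gamma = 120
        dev += abs(al - 90) + abs(be - 90) + abs(ga - 120)
        dev += 100 * abs(a - b) / ((a + b) / 2)
    elif system == "any":
        dev = 0.0
    else:
        raise ValueError(f"unknown system {system}")
    return dev


def _constraint_scores_vec(aa, bb, cc, al, be, ga, system: str) -> np.ndarray:
    """Vectorized :func:`_constraint_score` over arrays of cell parameters."""
    if system == "cubic":
        m = (aa + bb + cc) / 3
        return (np.abs(al - 90) + np.abs(be - 90) + np.abs(ga - 90)
                + 100 * (np.abs(aa - m) + np.abs(bb - m) + np.abs(cc - m)) / m)
    if system == "tetragonal":
        m = (aa + bb) / 2
        return (np.abs(al - 90) + np.abs(be - 90) + np.abs(ga - 90)
                + 100 * np.abs(aa - bb) / m)
    if system == "orthorhombic":
        return np.abs(al - 90) + np.abs(be - 90) + np.abs(ga - 90)
    if system == "monoclinic":
        return np.abs(al - 90) + np.abs(ga - 90)
    if system == "rhombohedral":
        m = (aa + bb) / 2
        return (np.abs(al - 90) + np.abs(be - 90) + np.abs(ga - 120)
                + 100 * np.abs(aa - bb) / m)
    if system == "any":
        return np.zeros_like(aa)
    raise ValueError(f"unknown system {system}")


def _centering_admissible(T: np.ndarray, centering: str) -> np.ndarray:
    """Vectorized check that the primitive lattice, expressed in the
    conventional basis T @ primitive, contains the centering vectors.

    T has shape (n, 3, 3); a centering vector v (conventional fractional
    coordinates) belongs to the primitive lattice iff v @ T is integral.
    """
    if centering == "P":
        return np.ones(len(T), dtype=bool)
    if centering == "I":
        s = T.sum(axis=1)  # column sums
        return np.all(s % 2 == 0, axis=1)
    if centering == "C":
        s = T[:, 0, :] + T[:, 1, :]
        return np.all(s % 2 == 0, axis=1)
    if centering == "F":
        s1 = T[:, 1, :] + T[:, 2, :]
        s2 = T[:, 0, :] + T[:, 2, :]
        return np.all(s1 % 2 == 0, axis=1) & np.all(s2 % 2 == 0, axis=1)
    if centering == "H":
        s = 2 * T[:, 0, :] + T[:, 1, :] + T[:, 2, :]
        return np.all(s % 3 == 0, axis=1)
    raise ValueError(f"unknown centering {centering!r}")


@dataclass
class TransformCandidate:
    UB_t: np.ndarray          # apply as UB_new = UB_old @ UB_t
    T: np.ndarray             # integer primitive->conventional basis matrix
    cell: tuple
    system: str
    score: float


_ENUM_CACHE: dict = {}


def _integer_matrices(lo: int = -2, hi: int = 2) -> np.ndarray:
    key = (lo, hi)
    if key not in _ENUM_CACHE:
        vals = np.arange(lo, hi + 1, dtype=np.int64)
        grids = np.meshgrid(*([vals] * 9), indexing="ij")
        M = np.stack([g.ravel() for g in grids], axis=1).reshape(-1, 3, 3)
        _ENUM_CACHE[key] = M
    return _ENUM_CACHE[key]


def _det3(M: np.ndarray) -> np.ndarray:
    return (
        M[:, 0, 0] * (M[:, 1, 1] * M[:, 2, 2] - M[:, 1, 2] * M[:, 2, 1])
        - M[:, 0, 1] * (M[:, 1, 0] * M[:, 2, 2] - M[:, 1, 2] * M[:, 2, 0])
        + M[:, 0, 2] * (M[:, 1, 0] * M[:, 2, 1] - M[:, 1, 1] * M[:, 2, 0])
    )


def reduced_cell_transform(
    ub_primitive: UBState,
    target_centering: str,
    tolerance: float = 2.0,
    max_candidates: int = 10,
) -> list[TransformCandidate]:
    """Candidate primitive-to-centered transformations.

    The primitive basis is first reduced to its shortest vectors; integer
    basis matrices with the centering's determinant and admissible
    centering vectors are then enumerated exhaustively and scored by the
    deviation of the resulting conventional cell from the metric
    constraints of the crystal systems that allow the target centering.
    Sorted by (score, volume, matrix); empty when nothing is within
    ``tolerance``.
    """
    if target_centering not in CENTERING_ORDER:
        raise ValueError(f"unknown centering {target_centering!r}")
    n_c = CENTERING_ORDER[target_centering]
    A0 = ub_primitive.direct_basis
    A_red, N = buerger_reduce(A0)
    if target_centering == "P":
        cands = [
            TransformCandidate(
                UB_t=np.eye(3), T=np.eye(3, dtype=int),
                cell=ub_primitive.cell, system="any", score=0.0,
            )
        ]
        # also offer the reduced setting when it differs
        if not np.array_equal(N, np.eye(3, dtype=int)):
            Tfull = N
            cands.append(
                TransformCandidate(
                    UB_t=np.linalg.inv(Tfull), T=Tfull,
                    cell=cell_from_metric(A_red @ A_red.T), system="any", score=0.0,
                )
            )
        return cands[:max_candidates]

    M = _integer_matrices()
    dets = _det3(M)
    M = M[dets == n_c]
    M = M[_centering_admissible(M, target_centering)]
    G = A_red @ A_red.T
    Gc = np.einsum("nij,jk,nlk->nil", M.astype(float), G, M.astype(float))
    aa = np.sqrt(Gc[:, 0, 0])
    bb = np.sqrt(Gc[:, 1, 1])
    cc = np.sqrt(Gc[:, 2, 2])
    al = np.degrees(np.arccos(np.clip(Gc[:, 1, 2] / (bb * cc), -1, 1)))
    be = np.degrees(np.arccos(np.clip(Gc[:, 0, 2] / (aa * cc), -1, 1)))
    ga = np.degrees(np.arccos(np.clip(Gc[:, 0, 1] / (aa * bb), -1, 1)))
    cells = np.column_stack([aa, bb, cc, al, be, ga])

    results: list[TransformCandidate] = []
    for system in _SYSTEMS_FOR_CENTERING[target_centering]:
        scores = _constraint_scores_vec(aa, bb, cc, al, be, ga, system)
        for i in np.nonzero(scores <= tolerance)[0]:
            Tfull = M[i] @ N  # back through the reduction step
            results.append(
                TransformCandidate(
                    UB_t=np.linalg.inv(Tfull.astype(float)),
                    T=Tfull,
                    cell=tuple(cells[i]),
                    system=system,
                    score=float(scores[i]),
                )
            )
    # dedupe identical conventional cells, keep best-scoring representative
    results.sort(
        key=lambda r: (
            r.score,
            cell_volume(r.cell),
            0 if r.cell[0] <= r.cell[1] <= r.cell[2] else 1,  # standard a<=b<=c
            r.T.ravel().tolist(),
        )
    )
    unique: list[TransformCandidate] = []
    for r in results:
        if any(
            np.allclose(r.cell, u.cell, atol=1e-6) and r.system == u.system
            for u in unique
        ):
            continue
        unique.append(r)
        if len(unique) >= max_candidates:
            break
    return unique


def apply_transform(ub_old: UBState, ub_t: np.ndarray) -> UBState:
    """``UB_new = UB_old @ UB_t`` (reciprocal-side composition)."""
    ub_t = np.asarray(ub_t, dtype=float)
    if abs(np.linalg.det(ub_t)) < 1e-15:
        raise ValueError("singular transformation")
    return UBState(UB=ub_old.UB @ ub_t, provenance="transformed",
                   centering=ub_old.centering)


# --- UB refinement ---------------------------------------------------------

_CONSTRAINT_PARAMS = {
    # name -> (n free cell params, expand(free)->(a,b,c,al,be,ga))
    "triclinic": (6, lambda p: tuple(p)),
    "monoclinic": (4, lambda p: (p[0], p[1], p[2], 90.0, p[3], 90.0)),
    "orthorhombic": (3, lambda p: (p[0], p[1], p[2], 90.0, 90.0, 90.0)),
    "tetragonal": (2, lambda p: (p[0], p[0], p[1], 90.0, 90.0, 90.0)),
    "cubic": (1, lambda p: (p[0], p[0], p[0], 90.0, 90.0, 90.0)),
    "hexagonal": (2, lambda p: (p[0], p[0], p[1], 90.0, 90.0, 120.0)),
    "rhombohedral": (2, lambda p: (p[0], p[0], p[0], p[1], p[1], p[1])),
}


def _predict_arrays(q_lab: np.ndarray, det: DetectorGeometry, L1: float):
    """Vectorized Bragg prediction for q vectors in the current setting.

    Returns (xD, yD, T, lam, valid); invalid entries are NaN.
    """
    q = np.asarray(q_lab, dtype=float)
    n2 = np.einsum("ij,ij->i", q, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = -2.0 * q[:, 2] / n2
    valid = lam > 1e-9
    u = lam[:, None] * q + np.array([0.0, 0.0, 1.0])
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    P = det.position_matrix
    Mm = det.missetting_matrix
    a = u @ (Mm.T @ P.T).T
    b = Mm.T @ np.array([0.0, 0.0, det.L2])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b[2] / a[:, 2]
    valid &= t > 0
    w = t[:, None] * a - b
    xD = -w[:, 0] / det.pixel_pitch + (det.n_pixels_x - 1) / 2.0
    yD = w[:, 1] / det.pixel_pitch + (det.n_pixels_y - 1) / 2.0
    hit = t[:, None] * u  # lab cm
    L_tot = L1 + np.linalg.norm(hit, axis=1) / 100.0
    T = wavelength_to_tof(lam, L_tot)
    xD = np.where(valid, xD, np.nan)
    yD = np.where(valid, yD, np.nan)
    T = np.where(valid, T, np.nan)
    return xD, yD, T, lam, valid


@dataclass
class RefinementReport:
    ub: UBState
    eps: np.ndarray            # per-peak detector-space distance
    eps_hkl: np.ndarray        # per-peak index residual norm
    frac_eps_below_0p1: float
    converged: bool
    cost: float
    n_peaks: int


def refine_ub(
    indexed_peaks: list[IndexedPeak],
    ub0: UBState,
    instrument: Instrument,
    goniometers: dict,
    scale_C: float = UB_SCALE_C_DEFAULT,
    constraints: str = "triclinic",
    max_iter: int = 200,
) -> RefinementReport:
    """Least-squares refinement of UB against observed peak positions.

    Minimizes ``sum eps^2`` with
    ``eps^2 = (x_o - x_p)^2 + (y_o - y_p)^2 + C^2 (t_o - t_p)^2``
    (x, y in cm, t in us) over 3 orientation angles and the free cell
    parameters of the chosen constraint class (9 parameters total for
    triclinic).  ``goniometers`` maps orientation_id to its setting.
    """
    use = [ip for ip in indexed_peaks if ip.indexed]
    if len(use) < 9:
        raise ValueError("need at least 9 indexed peaks to refine 9 parameters")
    cell0 = ub0.cell
    B0 = _b_matrix_exact(cell0)
    U0 = ub0.UB @ np.linalg.inv(B0)
    # re-orthogonalize against numerical drift
    uu, _, vv = np.linalg.svd(U0)
    U0 = uu @ vv

    n_cell, expand = _CONSTRAINT_PARAMS[constraints]
    free0 = {
        "triclinic": list(cell0),
        "monoclinic": [cell0[0], cell0[1], cell0[2], cell0[4]],
        "orthorhombic": [cell0[0], cell0[1], cell0[2]],
        "tetragonal": [(cell0[0] + cell0[1]) / 2, cell0[2]],
        "cubic": [sum(cell0[:3]) / 3],
        "hexagonal": [(cell0[0] + cell0[1]) / 2, cell0[2]],
        "rhombohedral": [sum(cell0[:3]) / 3, sum(cell0[3:]) / 3],
    }[constraints]
    x0 = np.concatenate([[0.0, 0.0, 0.0], free0])

    hkls = np.array([ip.hkl for ip in use], dtype=float)
    obs_x = np.array([ip.peak.x_o for ip in use])
    obs_y = np.array([ip.peak.y_o for ip in use])
    obs_t = np.array([ip.peak.t_o for ip in use])
    det_ids = np.array([ip.peak.detector_id for ip in use])
    orient = np.array([ip.peak.orientation_id for ip in use])
    groups = {}
    for gi, (d, o) in enumerate(zip(det_ids, orient)):
        groups.setdefault((int(d), int(o)), []).append(gi)
    R_by_orient = {oid: goniometer_matrix(g) for oid, g in goniometers.items()}
    pitch = {d.detector_id: d.pixel_pitch for d in instrument.detectors}

    def build_ub(x):
        rx, ry, rz = x[:3]
        cell = expand(x[3:])
        Rsmall = rot_z(math.degrees(rz)) @ rot_y(math.degrees(ry)) @ rot_x(math.degrees(rx))
        return Rsmall @ U0 @ _b_matrix_exact(cell)

    def residuals(x):
        UB = build_ub(x)
        out = np.empty(3 * len(use))
        q_zero = hkls @ UB.T
        for (d, o), idx in groups.items():
            det = instrument.detector(d)
            R = R_by_orient[o]
            q_lab = q_zero[idx] @ R.T
            xp, yp, tp, lam, valid = _predict_arrays(q_lab, det, instrument.L1)
            dx = (obs_x[idx] - xp) * det.pixel_pitch
            dy = (obs_y[idx] - yp) * det.pixel_pitch
            dt = scale_C * (obs_t[idx] - tp)
            bad = ~valid
            dx[bad] = dy[bad] = dt[bad] = 1.0  # cm-scale penalty
            for j, gi in enumerate(idx):
                out[3 * gi] = dx[j]
                out[3 * gi + 1] = dy[j]
                out[3 * gi + 2] = dt[j]
        return out

    sol = least_squares(
        residuals, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        max_nfev=max_iter * (len(x0) + 1),
    )
    UB = build_ub(sol.x)
    ub = UBState(UB=UB, provenance="refined", centering=ub0.centering)
    r = residuals(sol.x).reshape(-1, 3)
    eps = np.linalg.norm(r, axis=1)
    UB_inv = np.linalg.inv(UB)
    eps_hkl = np.empty(len(use))
    for i, ip in enumerate(use):
        q0 = ip.peak.q_zero.as_array()
        f = UB_inv @ q0
        eps_hkl[i] = np.linalg.norm(f - np.rint(f))
    return RefinementReport(
        ub=ub,
        eps=eps,
        eps_hkl=eps_hkl,
        frac_eps_below_0p1=float(np.mean(eps_hkl < 0.1)),
        converged=bool(sol.success),
        cost=float(2 * sol.cost),
        n_peaks=len(use),
    )


# --- UB file I/O -----------------------------------------------------------

def write_ub(ub: UBState, path) -> None:
    cell = ub.cell
    with open(path, "w") as fh:
        fh.write(f"# UB matrix (columns a*, b*, c*), provenance={ub.provenance}\n")
        for row in ub.UB:
            fh.write(" ".join(f"{v: .12e}" for v in row) + "\n")
        fh.write("cell " + " ".join(f"{v:.6f}" for v in cell) + "\n")
        fh.write(f"centering {ub.centering}\n")


def read_ub(path) -> UBState:
    rows = []
    centering = "P"
    provenance = "found"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "provenance=" in line:
                    provenance = line.split("provenance=")[1].strip()
                continue
            if line.startswith("cell"):
                continue
            if line.startswith("centering"):
                centering = line.split()[1]
                continue
            if line:
                rows.append([float(v) for v in line.split()])
    return UBState(UB=np.array(rows), provenance=provenance, centering=centering)
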