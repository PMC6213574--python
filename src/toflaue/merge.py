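"""Inter-detector scaling, symmetry merging and data-quality statistics.

Equivalent observations are mapped to a canonical index under the point
group (optionally including Friedel mates), systematic absences are
filtered out, and the survivors are merged by inverse-variance weighting.
Shell tables report N_obs, N_unique, multiplicity, completeness,
R_merge, R_p.i.m. and mean I/sigma by resolution or by wavelength,
scattering angle, detector or orientation.  Merged intensities can be
written in SCALEPACK, SHELX HKLF-4 and GSAS reflection-text formats.

R_merge  = sum_hkl sum_i |I_i - <I>| / sum_hkl sum_i I_i
R_p.i.m. = sum_hkl sqrt(1/(n-1)) sum_i |I_i - <I>| / sum_hkl sum_i I_i

with multiplicity-1 reflections excluded from both numerator and
denominator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .integrate import IntegratedReflection


# --- symmetry --------------------------------------------------------------

def _closure(mats: list[np.ndarray]) -> list[np.ndarray]:
    seen = {}
    for m in mats:
        seen[m.tobytes()] = m
    changed = True
    while changed:
        changed = False
        for a in list(seen.values()):
            for b in list(seen.values()):
                c = a @ b
                if c.tobytes() not in seen:
                    seen[c.tobytes()] = c
                    changed = True
    return list(seen.values())


@dataclass
class ReflectionCondition:
    """One parsed rule like ``h00: h=2n`` or ``hkl: h+k+l=2n``.

    The zone pattern fixes which index classes the rule applies to (0 means
    the index must be zero; a letter means free); the right side is a
    linear combination of h, k, l required to be divisible by n.
    """

    zone: str
    coeffs: tuple
    modulus: int

    def applies(self, h: int, k: int, l: int) -> bool:
        for idx, ch in zip((h, k, l), self.zone):
            if ch == "0" and idx != 0:
                return False
        return True

    def allowed(self, h: int, k: int, l: int) -> bool:
        if not self.applies(h, k, l):
            return True
        v = self.coeffs[0] * h + self.coeffs[1] * k + self.coeffs[2] * l
        return v % self.modulus == 0


_COND_RE = re.compile(
    r"^\s*([hkl0]{3})\s*:\s*([+-]?[hkl](?:\s*[+-]\s*[hkl])*)\s*=\s*(\d+)n\s*$"
)


def parse_condition(text: str) -> ReflectionCondition:
    """Parse a reflection-condition string, e.g. ``"h00: h=2n"``."""
    m = _COND_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse reflection condition {text!r}")
    zone, combo, n = m.group(1), m.group(2), int(m.group(3))
    coeffs = [0, 0, 0]
    for term in re.finditer(r"([+-]?)\s*([hkl])", combo):
        sign = -1 if term.group(1) == "-" else 1
        coeffs["hkl".index(term.group(2))] += sign
    return ReflectionCondition(zone=zone, coeffs=tuple(coeffs), modulus=n)


#: reflection conditions of a few frequently used space groups
BUILTIN_CONDITIONS = {
    "P1": [],
    "P212121": ["h00: h=2n", "0k0: k=2n", "00l: l=2n"],
    "P21212": ["h00: h=2n", "0k0: k=2n"],
    "I222": ["hkl: h+k+l=2n"],
    "I212121": ["hkl: h+k+l=2n", "h00: h=2n", "0k0: k=2n", "00l: l=2n"],
    "C2": ["hkl: h+k=2n"],
    "F222": ["hkl: h+k=2n", "hkl: k+l=2n"],
    "P43212": ["00l: l=4n", "h00: h=2n"],
}


@dataclass
class SymmetrySpec:
    """Point-group operators on hkl plus absence rules.

    Operators are integer 3x3 matrices acting on the (row) index vector;
    the set is closed under composition and contains the identity.
    """

    operators: list
    conditions: list = field(default_factory=list)
    friedel: bool = True
    name: str = ""

    def __post_init__(self):
        ops = [np.asarray(m, dtype=int) for m in self.operators]
        if not any(np.array_equal(m, np.eye(3, dtype=int)) for m in ops):
            ops.append(np.eye(3, dtype=int))
        self.operators = _closure(ops)

    @classmethod
    def from_spacegroup(cls, symbol: str, friedel: bool = True) -> "SymmetrySpec":
        """Build from a space-group symbol via its symmetry operations.

        Rotation parts give the point group; absence rules come from the
        built-in condition table when available, otherwise from the
        operators themselves.
        """
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise ValueError(f"unknown space group {symbol!r}")
        den = gemmi.Op.DEN
        mats = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=int) // den
            mats.append(rot)
        key = symbol.replace(" ", "")
        conds = [parse_condition(c) for c in BUILTIN_CONDITIONS.get(key, [])]
        spec = cls(operators=mats, conditions=conds, friedel=friedel, name=symbol)
        spec._gemmi_ops = sg.operations()
        return spec

    def is_absent(self, h: int, k: int, l: int) -> bool:
        ops = getattr(self, "_gemmi_ops", None)
        if ops is not None:
            return bool(ops.is_systematically_absent([int(h), int(k), int(l)]))
        return not all(c.allowed(h, k, l) for c in self.conditions)

    def orbit(self, hkl) -> set:
        v = np.asarray(hkl, dtype=int)
        out = set()
        for m in self.operators:
            w = v @ m
            out.add(tuple(int(x) for x in w))
            if self.friedel:
                out.add(tuple(int(x) for x in -w))
        return out


def map_to_asu(hkl, sym: SymmetrySpec) -> tuple:
    """Canonical representative: lexicographic maximum over the orbit."""
    return max(sym.orbit(hkl))


# --- scaling ---------------------------------------------------------------

def scale_detectors(
    reflections: list[IntegratedReflection],
    vanadium_totals: dict,
) -> list[IntegratedReflection]:
    """Divide each observation by its detector's relative vanadium total.

    The per-detector total neutron count of the correction data measures
    relative detector efficiency; dividing by total/mean makes the scaling
    invariant to a global rescale of the vanadium data.
    """
    present = sorted({r.detector_id for r in reflections})
    missing = [d for d in present if d not in vanadium_totals]
    if missing:
        raise ValueError(f"missing vanadium totals for detectors {missing}")
    totals = {d: float(vanadium_totals[d]) for d in present}
    if any(v <= 0 for v in totals.values()):
        raise ValueError("vanadium totals must be positive")
    mean = np.mean(list(totals.values()))
    out = []
    for r in reflections:
        s = totals[r.detector_id] / mean
        out.append(
            IntegratedReflection(
                **{
                    **r.__dict__,
                    "intensity": r.intensity / s,
                    "sigma": r.sigma / s,
                }
            )
        )
    return out


# --- merging ---------------------------------------------------------------

@dataclass
class MergedReflection:
    hkl: tuple
    intensity: float
    sigma: float
    multiplicity: int
    d: float
    observations: list = field(default_factory=list)


@dataclass
class MergedDataset:
    reflections: dict            # canonical hkl -> MergedReflection
    n_absent_rejected: int = 0
    rejected: list = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "h": hkl[0], "k": hkl[1], "l": hkl[2],
                "intensity": m.intensity, "sigma": m.sigma,
                "multiplicity": m.multiplicity, "d": m.d,
            }
            for hkl, m in sorted(self.reflections.items())
        ]
        return pd.DataFrame(rows, columns=["h", "k", "l", "intensity", "sigma",
                                           "multiplicity", "d"])


def merge_equivalents(
    reflections: list[IntegratedReflection],
    sym: SymmetrySpec,
) -> MergedDataset:
    """Merge symmetry-equivalent observations.

    Weighted mean with weights 1/sigma^2; the merged sigma is the larger of
    the propagated error ``1/sqrt(sum w)`` and the scatter-based standard
    error of the weighted mean, which guards against under-estimated
    integration sigmas.  Systematically absent observations are rejected
    and counted.
    """
    groups: dict = {}
    n_absent = 0
    rejected = []
    for r in reflections:
        if sym.is_absent(*r.hkl):
            n_absent += 1
            rejected.append(r)
            continue
        key = map_to_asu(r.hkl, sym)
        groups.setdefault(key, []).append(r)
    merged = {}
    for key, obs in groups.items():
        I = np.array([o.intensity for o in obs])
        sig = np.array([max(o.sigma, 1e-30) for o in obs])
        w = 1.0 / sig**2
        mean = float((w * I).sum() / w.sum())
        sig_prop = float(1.0 / math.sqrt(w.sum()))
        if len(obs) > 1:
            scat = float(
                math.sqrt((w * (I - mean) ** 2).sum() / ((len(obs) - 1) * w.sum()))
            )
        else:
            scat = 0.0
        merged[key] = MergedReflection(
            hkl=key,
            intensity=mean,
            sigma=max(sig_prop, scat),
            multiplicity=len(obs),
            d=float(np.mean([o.d for o in obs])),
            observations=obs,
        )
    return MergedDataset(reflections=merged, n_absent_rejected=n_absent,
                         rejected=rejected)


# --- statistics ------------------------------------------------------------

def _r_factors(groups: list[list[float]]):
    """R_merge and R_p.i.m. over groups of equivalent intensities;
    multiplicity-1 groups are excluded from numerator and denominator."""
    num_m = num_p = den = 0.0
    for I in groups:
        n = len(I)
        if n < 2:
            continue
        mean = float(np.mean(I))
        dev = float(np.sum(np.abs(np.asarray(I) - mean)))
        num_m += dev
        num_p += math.sqrt(1.0 / (n - 1)) * dev
        den += float(np.sum(I))
    if den == 0:
        return float("nan"), float("nan")
    return num_m / den, num_p / den


def count_unique_in_shell(cell, sym: SymmetrySpec, d_lo: float, d_hi: float) -> int:
    """Completeness denominator: symmetry-unique, non-absent hkl with
    d in (d_lo, d_hi]."""
    from .indexing import metric_from_cell

    G = metric_from_cell(cell)
    G_star = np.linalg.inv(G)
    # bound the index ranges by the resolution sphere radius 1/d_lo
    qmax = 1.0 / d_lo
    lengths = np.sqrt(np.diag(G))  # direct axes
    hmax = np.ceil(qmax * lengths).astype(int)
    uniq = set()
    hs = np.arange(-hmax[0], hmax[0] + 1)
    ks = np.arange(-hmax[1], hmax[1] + 1)
    ls = np.arange(-hmax[2], hmax[2] + 1)
    H, K, L = np.meshgrid(hs, ks, ls, indexing="ij")
    HKL = np.column_stack([H.ravel(), K.ravel(), L.ravel()])
    q2 = np.einsum("ni,ij,nj->n", HKL.astype(float), G_star, HKL.astype(float))
    with np.errstate(divide="ignore"):
        d = 1.0 / np.sqrt(q2)
    sel = (d > d_lo) & (d <= d_hi) & np.isfinite(d)
    for hkl in HKL[sel]:
        t = tuple(int(v) for v in hkl)
        if sym.is_absent(*t):
            continue
        uniq.add(map_to_asu(t, sym))
    return len(uniq)


def shell_edges_equal_count(ds: np.ndarray, n_shells: int) -> np.ndarray:
    """Resolution shell edges with (nearly) equal observation counts."""
    qs = np.sort(1.0 / np.asarray(ds))
    edges_q = np.quantile(qs, np.linspace(0, 1, n_shells + 1))
    edges_d = 1.0 / edges_q[::-1]
    edges_d[0] = edges_d[0] * 1.0001 + 1e-9
    edges_d[-1] = edges_d[-1] * 0.9999 - 1e-9
    return edges_d  # decreasing d: [d_max ... d_min]


@dataclass
class ShellStatistics:
    table: pd.DataFrame
    overall: dict
    group_by: str = "resolution"


def compute_statistics(
    observations: list[IntegratedReflection],
    merged: MergedDataset,
    sym: SymmetrySpec,
    cell,
    n_shells: int = 10,
    shell_edges: np.ndarray | None = None,
    group_by: str = "resolution",
) -> ShellStatistics:
    """Shell-resolved and overall merging statistics.

    ``group_by`` is "resolution" (shells of d, default equal-count) or one
    of "wavelength", "two_theta", "detector", "orientation" (categorical /
    equal-count binning of observations; completeness is only defined for
    resolution shells).
    """
    obs = [o for o in observations if not sym.is_absent(*o.hkl)]
    if not obs:
        raise ValueError("no observations after absence filtering")
    rows = []
    if group_by == "resolution":
        ds = np.array([m.d for m in merged.reflections.values()])
        obs_d = np.array([o.d for o in obs])
        edges = (
            np.asarray(shell_edges)
            if shell_edges is not None
            else shell_edges_equal_count(obs_d, n_shells)
        )
        for si in range(len(edges) - 1):
            d_hi, d_lo = edges[si], edges[si + 1]  # decreasing
            in_shell = [
                m for m in merged.reflections.values() if d_lo < m.d <= d_hi
            ]
            shell_obs = [o for o in obs if d_lo < o.d <= d_hi]
            rows.append(
                _shell_row(
                    f"{d_hi:.3f}-{d_lo:.3f}", in_shell, shell_obs,
                    n_expected=count_unique_in_shell(cell, sym, d_lo, d_hi),
                )
            )
    else:
        key = {
            "wavelength": lambda o: o.lam,
            "two_theta": lambda o: o.two_theta,
            "detector": lambda o: o.detector_id,
            "orientation": lambda o: o.orientation_id,
        }[group_by]
        if group_by in ("detector", "orientation"):
            labels = sorted({key(o) for o in obs})
            bins = {lab: [o for o in obs if key(o) == lab] for lab in labels}
        else:
            vals = np.array([key(o) for o in obs])
            edges = np.quantile(vals, np.linspace(0, 1, n_shells + 1))
            edges[-1] += 1e-9
            bins = {}
            for si in range(n_shells):
                lab = f"{edges[si]:.3f}-{edges[si+1]:.3f}"
                bins[lab] = [
                    o for o in obs if edges[si] <= key(o) < edges[si + 1]
                ]
        for lab, shell_obs in bins.items():
            groups: dict = {}
            for o in shell_obs:
                groups.setdefault(map_to_asu(o.hkl, sym), []).append(o)
            in_shell = [
                MergedReflection(
                    hkl=k2,
                    intensity=float(np.mean([o.intensity for o in v])),
                    sigma=1.0,
                    multiplicity=len(v),
                    d=float(np.mean([o.d for o in v])),
                    observations=v,
                )
                for k2, v in groups.items()
            ]
            rows.append(_shell_row(str(lab), in_shell, shell_obs, n_expected=None))

    table = pd.DataFrame(rows)
    all_merged = list(merged.reflections.values())
    overall = _shell_row(
        "overall", all_merged, obs,
        n_expected=count_unique_in_shell(cell, sym, edges[-1], edges[0])
        if group_by == "resolution"
        else None,
    )
    return ShellStatistics(table=table, overall=overall, group_by=group_by)


def _shell_row(label, merged_list, obs_list, n_expected):
    groups = {}
    for m in merged_list:
        groups[m.hkl] = [o.intensity for o in m.observations]
    r_merge, r_pim = _r_factors(list(groups.values()))
    n_obs = len(obs_list)
    n_unique = len(merged_list)
    mult = n_obs / n_unique if n_unique else float("nan")
    i_over_sig = (
        float(np.mean([m.intensity / m.sigma for m in merged_list if m.sigma > 0]))
        if merged_list
        else float("nan")
    )
    row = {
        "shell": label,
        "n_obs": n_obs,
        "n_unique": n_unique,
        "multiplicity": mult,
        "completeness": (100.0 * n_unique / n_expected) if n_expected else float("nan"),
        "r_merge": r_merge,
        "r_pim": r_pim,
        "i_over_sigma": i_over_sig,
    }
    return row


# --- Wilson-type plot ------------------------------------------------------

def wilson_plot_data(merged: MergedDataset, n_bins: int = 20) -> pd.DataFrame:
    """ln of the mean merged intensity per (sin(theta)/lambda)^2 interval.

    ``(sin(theta)/lambda)^2 = 1/(4 d^2)``; bins whose mean intensity is
    not positive are omitted (flagged in the ``omitted`` column of the
    returned attrs).
    """
    ms = list(merged.reflections.values())
    s2 = np.array([1.0 / (4 * m.d**2) for m in ms])
    I = np.array([m.intensity for m in ms])
    edges = np.linspace(s2.min(), s2.max() * (1 + 1e-9), n_bins + 1)
    rows, omitted = [], 0
    for i in range(n_bins):
        sel = (s2 >= edges[i]) & (s2 < edges[i + 1])
        if not sel.any():
            continue
        mean_I = float(I[sel].mean())
        if mean_I <= 0:
            omitted += 1
            continue
        rows.append(
            {"s2": float(0.5 * (edges[i] + edges[i + 1])),
             "ln_mean_I": math.log(mean_I), "n": int(sel.sum())}
        )
    df = pd.DataFrame(rows, columns=["s2", "ln_mean_I", "n"])
    df.attrs["omitted_bins"] = omitted
    return df


# --- hkl writers -----------------------------------------------------------

def _check_field(value: float, width: int, decimals: int, record: str):
    txt = f"{value:{width}.{decimals}f}"
    if len(txt) > width:
        raise ValueError(f"value {value} does not fit field width {width} "
                         f"in record {record!r}")
    return txt


def write_scalepack(merged: MergedDataset, cell, spacegroup: str, path) -> None:
    """Merged SCALEPACK (.sca) output: 3-line header then
    %4d%4d%4d%8.1f%8.1f records."""
    with open(path, "w") as fh:
        fh.write("    1\n")
        fh.write(" -987\n")
        fh.write(
            "".join(f"{v:10.3f}" for v in cell)
            + " " + spacegroup.replace(" ", "").lower() + "\n"
        )
        for hkl, m in sorted(merged.reflections.items()):
            rec = f"{hkl[0]:4d}{hkl[1]:4d}{hkl[2]:4d}"
            rec += _check_field(m.intensity, 8, 1, rec)
            rec += _check_field(m.sigma, 8, 1, rec)
            fh.write(rec + "\n")


def read_scalepack(path):
    out = []
    with open(path) as fh:
        lines = fh.readlines()[3:]
    for line in lines:
        if not line.strip():
            continue
        h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
        I, sig = float(line[12:20]), float(line[20:28])
        out.append(((h, k, l), I, sig))
    return out


def write_shelx(data, path, merged: bool = True) -> None:
    """SHELX HKLF-4 fixed format (3I4, 2F8.2) with the terminating record."""
    if isinstance(data, MergedDataset):
        records = [(hkl, m.intensity, m.sigma)
                   for hkl, m in sorted(data.reflections.items())]
    else:
        records = [((r.h, r.k, r.l), r.intensity, r.sigma) for r in data]
    with open(path, "w") as fh:
        for (h, k, l), I, sig in records:
            rec = f"{h:4d}{k:4d}{l:4d}"
            rec += _check_field(I, 8, 2, rec)
            rec += _check_field(sig, 8, 2, rec)
            fh.write(rec + "\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def read_shelx(path):
    out = []
    with open(path) as fh:
        for line in fh:
            if len(line.rstrip("\n")) < 28:
                continue
            h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
            if h == 0 and k == 0 and l == 0:
                break
            out.append(((h, k, l), float(line[12:20]), float(line[20:28])))
    return out


def write_gsas(merged: MergedDataset, cell, path) -> None:
    """GSAS-style single-crystal reflection text: a title line, a cell
    line, then (3I4, 2F12.4) h k l Fo^2 sigma records."""
    with open(path, "w") as fh:
        fh.write("single-crystal reflection data\n")
        fh.write("CELL " + " ".join(f"{v:10.4f}" for v in cell) + "\n")
        for hkl, m in sorted(merged.reflections.items()):
            rec = f"{hkl[0]:4d}{hkl[1]:4d}{hkl[2]:4d}"
            rec += _check_field(m.intensity, 12, 4, rec)
            rec += _check_field(m.sigma, 12, 4, rec)
            fh.write(rec + "\n")


def write_statistics_csv(stats: ShellStatistics, path) -> None:
    stats.table.to_csv(path, index=False)


def format_statistics(stats: ShellStatistics) -> str:
    """Aligned text table of the shell statistics."""
    lines = [
        f"{'shell':>16} {'N_obs':>7} {'N_uniq':>7} {'mult':>6} "
        f"{'compl%':>7} {'Rmerge':>8} {'Rpim':>8} {'I/sig':>7}"
    ]
    for _, r in stats.table.iterrows():
        lines.append(
            f"{r['shell']:>16} {r['n_obs']:7d} {r['n_unique']:7d} "
            f"{r['multiplicity']:6.2f} {r['completeness']:7.1f} "
            f"{r['r_merge']:8.4f} {r['r_pim']:8.4f} {r['i_over_sigma']:7.2f}"
        )
    o = stats.overall
    lines.append(
        f"{'overall':>16} {o['n_obs']:7d} {o['n_unique']:7d} "
        f"{o['multiplicity']:6.2f} {o['completeness']:7.1f} "
        f"{o['r_merge']:8.4f} {o['r_pim']:8.4f} {o['i_over_sigma']:7.2f}"
    )
    return "\n".join(lines)
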