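"""Ringer analysis: χ1 electron-density sampling and curve comparison.

For each residue with a γ heavy atom, the γ atom is swept around the Cα→Cβ
axis — preserving the model's own Cβ–γ bond length and Cα–Cβ–γ angle — and
the σ-scaled map density is sampled at each candidate position.  Curves from
two conditions are compared by Pearson correlation; residues whose curves
correlate below a threshold (0.5 by convention) are flagged as having a
changed side-chain density distribution.  Only χ1 is sampled; Gly and Ala
have no γ atom and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import dihedral, place_atom, rotation_about_axis
from .structure_io import CrystalStructure, DensityMap, map_values_at

__all__ = [
    "RingerCurve",
    "CurveComparison",
    "GAMMA_PRIORITY",
    "strip_to_single_conformer",
    "ringer_curve",
    "ringer_curves",
    "curve_cc",
    "compare_curves",
    "flag_changed_residues",
    "find_peaks",
]

#: γ-atom name priority when several branches exist (e.g. Thr OG1 vs CG2).
GAMMA_PRIORITY = ("CG", "OG", "SG", "CG1", "OG1")
IDEAL_GAMMA_BOND = 1.52
IDEAL_GAMMA_ANGLE = 114.0
NO_CHI1_RESIDUES = frozenset({"GLY", "ALA"})


@dataclass
class RingerCurve:
    residue_id: tuple
    resname: str
    chi_index: int
    step_deg: float
    angles: np.ndarray  # degrees in [0, 360), uniform step
    values: np.ndarray  # density in σ units

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        steps = np.diff(self.angles)
        if len(self.angles) < 2 or not np.allclose(steps, steps[0]):
            raise ValueError("curve angles must be uniform and increasing")

    @property
    def is_flat(self) -> bool:
        return float(self.values.std()) == 0.0


@dataclass
class CurveComparison:
    residue_id: tuple
    resname: str
    cc: float | None  # None = undefined (flat curve)
    changed: bool


def strip_to_single_conformer(structure: CrystalStructure,
                              policy: str = "highest-occupancy") -> CrystalStructure:
    """Collapse every residue to one conformer, with occupancies set to 1.

    ``policy`` is either ``"highest-occupancy"`` or an explicit altloc letter
    (falling back to highest occupancy where that letter is absent).  The
    choice made per residue is recorded in ``structure.warnings``.
    """
    out = structure.copy(structure.label + "+mono")
    keep: list = []
    for rid, res_atoms in out.residues(kind=None).items():
        letters = sorted({a.altloc for a in res_atoms if a.altloc})
        if not letters:
            keep.extend(res_atoms)
            continue
        if policy != "highest-occupancy" and policy in letters:
            chosen = policy
        else:
            occ = {lt: sum(a.occupancy for a in res_atoms if a.altloc == lt)
                   for lt in letters}
            chosen = max(letters, key=lambda lt: (occ[lt], -ord(lt[0])))
        out.warnings.append(f"residue {rid}: kept conformer {chosen!r}")
        keep.extend(a for a in res_atoms if a.altloc in ("", chosen))
    for a in keep:
        a.altloc = ""
        a.occupancy = 1.0
    out.atoms = keep
    return out


def _gamma_atom(res_atoms: dict, resname: str):
    for name in GAMMA_PRIORITY:
        if name in res_atoms:
            return name
    return None


def ringer_curve(dmap: DensityMap, structure: CrystalStructure, residue_id,
                 step: float = 10.0, mode: str = "trilinear") -> RingerCurve:
    """Sample σ-scaled density at every candidate γ position around χ1.

    For each angle θ in {0°, step, …, 360°−step} the γ atom is rotated about
    the Cα→Cβ axis so the N–Cα–Cβ–γ torsion equals θ, keeping the model's own
    Cβ–γ bond length and Cα–Cβ–γ angle (ideal geometry 1.52 Å / 114° when the
    γ atom is missing from the model).
    """
    residue_id = tuple(residue_id)
    res = {a.name: a.pos for a in structure.atoms if a.residue_id == residue_id}
    names = [a.resname for a in structure.atoms if a.residue_id == residue_id]
    if not names:
        raise ValueError(f"no residue {residue_id}")
    resname = names[0]
    if resname in NO_CHI1_RESIDUES:
        raise ValueError(f"{resname} has no χ1; residue {residue_id} skipped")
    for need in ("N", "CA", "CB"):
        if need not in res:
            raise ValueError(f"residue {residue_id} missing {need}")
    n, ca, cb = res["N"], res["CA"], res["CB"]
    gname = _gamma_atom(res, resname)
    if gname is not None:
        gamma0 = res[gname]
        chi0 = dihedral(n, ca, cb, gamma0)
    else:
        gamma0 = place_atom(n, ca, cb, IDEAL_GAMMA_BOND, IDEAL_GAMMA_ANGLE, 0.0)
        chi0 = 0.0

    angles = np.arange(0.0, 360.0, float(step))
    axis = cb - ca
    points = np.empty((len(angles), 3))
    for i, theta in enumerate(angles):
        R = rotation_about_axis(axis, theta - chi0)
        points[i] = cb + R @ (gamma0 - cb)
    values = map_values_at(dmap, points, mode=mode, scale="sigma")
    return RingerCurve(residue_id, resname, 1, float(step), angles, values)


def ringer_curves(dmap: DensityMap, structure: CrystalStructure,
                  step: float = 10.0, mode: str = "trilinear") -> dict:
    """Ringer curves for every eligible residue: {residue_id: RingerCurve}."""
    out: dict = {}
    for rid, res_atoms in structure.residues("polymer").items():
        if res_atoms[0].resname in NO_CHI1_RESIDUES:
            continue
        try:
            out[rid] = ringer_curve(dmap, structure, rid, step, mode)
        except ValueError:
            continue  # incomplete residue
    return out


def curve_cc(c1: RingerCurve, c2: RingerCurve) -> float | None:
    """Pearson correlation between two curves on identical angle grids.

    Returns ``None`` (undefined) when either curve is flat.
    """
    if not np.array_equal(c1.angles, c2.angles):
        raise ValueError("curves sampled on different angle grids")
    x, y = c1.values, c2.values
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def compare_curves(curves_a: dict, curves_b: dict,
                   threshold: float = 0.5) -> list:
    """Pairwise CCs for residues present in both curve sets."""
    out = []
    for rid in sorted(set(curves_a) & set(curves_b)):
        cc = curve_cc(curves_a[rid], curves_b[rid])
        out.append(CurveComparison(rid, curves_a[rid].resname, cc,
                                   cc is not None and cc < threshold))
    return out


def flag_changed_residues(comparisons: list, threshold: float = 0.5,
                          exclude: list | None = None) -> dict:
    """Residues with defined CC below threshold, minus excluded ranges.

    ``exclude`` is a list of (first, last) author-number ranges (e.g. a
    flexible loop).  Returns flagged ids, counts, the percentage of evaluated
    residues, and the list of residues with undefined (flat-curve) CC.
    """
    exclude = exclude or []

    def _excluded(rid):
        return any(lo <= rid[1] <= hi for lo, hi in exclude)

    evaluated = [c for c in comparisons if c.cc is not None and not _excluded(c.residue_id)]
    undefined = [c.residue_id for c in comparisons if c.cc is None]
    flagged = [c.residue_id for c in evaluated if c.cc < threshold]
    return {
        "flagged": flagged,
        "n_flagged": len(flagged),
        "n_evaluated": len(evaluated),
        "percent_flagged": 100.0 * len(flagged) / len(evaluated) if evaluated else 0.0,
        "undefined": undefined,
        "threshold": threshold,
        "excluded_ranges": list(exclude),
    }


def find_peaks(curve: RingerCurve, min_sigma: float = 0.3) -> list:
    """Circular local maxima of a curve above ``min_sigma``, highest first.

    Returns ``[(angle_deg, height_sigma), ...]``; the first entry is the
    dominant peak.
    """
    v = curve.values
    n = len(v)
    peaks = []
    for i in range(n):
        left, right = v[(i - 1) % n], v[(i + 1) % n]
        if v[i] > min_sigma and v[i] >= left and v[i] > right:
            peaks.append((float(curve.angles[i]), float(v[i])))
    peaks.sort(key=lambda p: -p[1])
    return peaks
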