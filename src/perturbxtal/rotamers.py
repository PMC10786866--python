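"""Side-chain χ angles, rotamer naming, and between-structure rotamer census.

Rotamer naming follows the field's p/t/m convention for staggered χ angles:
``p`` near +60°, ``t`` near 180°, ``m`` near −60°.  Full names concatenate
one symbol per χ (e.g. ``"mtp"`` for Met χ1≈−65°, χ2≈180°, χ3≈+65°); residue
types with an sp2 terminal χ (Asp/Asn/Glu/Gln and the aromatics) use curated
modes with a numeric terminal-angle suffix.  A conformer whose best-matching
mode still leaves any χ more than 40° away is reported as ``OUTLIER``.

The mode table shipped here (``ROTAMER_MODES``, version ``perturbxtal-1``) is
a compact nominal-mode table: idealized staggered modes for aliphatic χs plus
curated modes for sp2-terminal types.  It is intentionally small and fully
reproducible rather than a copy of any statistical rotamer library.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from ._geom import angular_difference, dihedral, wrap_angle
from .structure_io import CrystalStructure

__all__ = [
    "CHI_ATOMS",
    "ROTAMER_MODES",
    "RotamerAssignment",
    "RotamerDiff",
    "dihedral",
    "chi1_class",
    "residue_chi_angles",
    "name_rotamer",
    "assign_rotamers",
    "rotamer_diff",
]

MODE_TABLE_VERSION = "perturbxtal-1"
OUTLIER_DEVIATION_DEG = 40.0

#: χ torsion atom quadruples per residue type, in χ1..χn order.
CHI_ATOMS: dict = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

_STAGGERED = {"p": 62.0, "t": 180.0, "m": -65.0}


def _staggered_product(n_chi: int) -> dict:
    out = {}
    for combo in itertools.product("ptm", repeat=n_chi):
        out["".join(combo)] = tuple(_STAGGERED[c] for c in combo)
    return out


def _with_terminal(n_stag: int, terminal_modes: list) -> dict:
    """Staggered modes for the first n χs crossed with curated terminal modes."""
    out = {}
    for combo in itertools.product("ptm", repeat=n_stag):
        for term in terminal_modes:
            name = "".join(combo) + f"{term:g}"
            out[name] = tuple(_STAGGERED[c] for c in combo) + (float(term),)
    return out


#: Modal χ values per rotamer name per residue type.
ROTAMER_MODES: dict = {
    "SER": _staggered_product(1),
    "CYS": _staggered_product(1),
    "THR": _staggered_product(1),
    "VAL": _staggered_product(1),
    "LEU": _staggered_product(2),
    "ILE": _staggered_product(2),
    "MET": _staggered_product(3),
    "LYS": _staggered_product(4),
    "ARG": _with_terminal(3, [-85, 85, 180]),
    "ASP": _with_terminal(1, [-30, 0, 30]),
    "ASN": _with_terminal(1, [-60, -20, 30, 90]),
    "GLU": _with_terminal(2, [-30, 0, 30]),
    "GLN": _with_terminal(2, [-90, -30, 20, 90]),
    "PHE": _with_terminal(1, [-90, -30, 30, 90]),
    "TYR": _with_terminal(1, [-90, -30, 30, 90]),
    "TRP": _with_terminal(1, [-105, -90, 0, 90]),
    "HIS": _with_terminal(1, [-80, -70, 60, 80, 170]),
    "PRO": {"Cg_endo": (30.0,), "Cg_exo": (-25.0,)},
}


def chi1_class(chi1: float) -> str:
    """χ1 class: ``p`` for [0°, 120°), ``t`` for [120°, 240°), ``m`` otherwise."""
    a = float(chi1) % 360.0
    if a < 120.0:
        return "p"
    if a < 240.0:
        return "t"
    return "m"


@dataclass
class RotamerAssignment:
    residue_id: tuple
    resname: str
    altloc: str
    chis: tuple  # degrees in (−180, 180]
    name: str  # full rotamer name or "OUTLIER"
    chi1_class: str


def residue_chi_angles(atoms_by_name: dict, resname: str) -> tuple:
    """χ angles for one conformer given a name -> position mapping.

    Raises ``KeyError`` for an unknown residue type and ``ValueError`` when a
    χ-defining atom is missing.
    """
    if resname not in CHI_ATOMS:
        raise KeyError(f"no χ definition for residue type {resname!r}")
    chis = []
    for quad in CHI_ATOMS[resname]:
        try:
            pts = [atoms_by_name[n] for n in quad]
        except KeyError as exc:
            raise ValueError(f"missing atom {exc} for {resname} χ{len(chis) + 1}")
        chis.append(dihedral(*pts))
    return tuple(chis)


def name_rotamer(resname: str, chis) -> str:
    """Nearest-mode rotamer name for a χ tuple, or ``OUTLIER``.

    The nearest mode minimizes the summed wrapped angular distance over all
    χs; if the winning mode still deviates more than 40° on any single χ the
    conformer is an outlier.
    """
    if resname not in ROTAMER_MODES:
        raise KeyError(f"no rotamer modes for residue type {resname!r}")
    chis = tuple(float(c) for c in chis)
    modes = ROTAMER_MODES[resname]
    expected = len(next(iter(modes.values())))
    if len(chis) != expected:
        raise ValueError(
            f"{resname} expects {expected} χ values, got {len(chis)}")
    best_name, best_cost, best_worst = None, float("inf"), float("inf")
    for name, mode in modes.items():
        devs = [angular_difference(c, m) for c, m in zip(chis, mode)]
        cost = sum(devs)
        if cost < best_cost:
            best_name, best_cost, best_worst = name, cost, max(devs)
    if best_worst > OUTLIER_DEVIATION_DEG:
        return "OUTLIER"
    return best_name


def _conformers(res_atoms: list) -> dict:
    """Split a residue's atoms into conformers; blank altloc is shared."""
    letters = sorted({a.altloc for a in res_atoms if a.altloc})
    if not letters:
        return {"": res_atoms}
    blank = [a for a in res_atoms if not a.altloc]
    return {lt: blank + [a for a in res_atoms if a.altloc == lt] for lt in letters}


def assign_rotamers(structure: CrystalStructure) -> dict:
    """Per-residue, per-conformer rotamer assignments.

    Returns ``{residue_id: [RotamerAssignment, ...]}`` for every polymer
    residue with a complete χ atom set; residues of χ-less types (Gly/Ala) or
    with missing side-chain atoms are omitted.
    """
    out: dict = {}
    for rid, res_atoms in structure.residues("polymer").items():
        resname = res_atoms[0].resname
        if resname not in CHI_ATOMS:
            continue
        assignments = []
        for altloc, atoms in _conformers(res_atoms).items():
            by_name = {a.name: a.pos for a in atoms}
            try:
                chis = residue_chi_angles(by_name, resname)
            except ValueError:
                continue
            chis = tuple(wrap_angle(c) for c in chis)
            assignments.append(RotamerAssignment(
                rid, resname, altloc, chis,
                name_rotamer(resname, chis), chi1_class(chis[0])))
        if assignments:
            out[rid] = assignments
    return out


@dataclass
class RotamerDiff:
    """Census of rotamer differences between two structures."""

    changed: list  # residue ids counted as changed
    n_changed: int
    n_evaluated: int
    policy: str
    excluded: list
    multi_rotamer_a: list  # residues with >1 distinct rotamer name within a
    multi_rotamer_b: list
    names_a: dict
    names_b: dict

    @property
    def percent_changed(self) -> float:
        if self.n_evaluated == 0:
            return 0.0
        return 100.0 * self.n_changed / self.n_evaluated


def _in_ranges(resseq: int, ranges) -> bool:
    return any(lo <= resseq <= hi for lo, hi in ranges)


def rotamer_diff(a: CrystalStructure, b: CrystalStructure,
                 exclude: list | None = None,
                 policy: str = "any-match") -> RotamerDiff:
    """Count residues whose rotamer differs between two structures.

    Under the default ``"any-match"`` policy a residue is unchanged when any
    conformer name in ``a`` matches any conformer name in ``b`` (the
    conservative reading when alternate conformations are present); the
    ``"primary"`` policy compares only the highest-occupancy conformers.
    ``exclude`` is a list of ``(first, last)`` author-numbering ranges (e.g.
    a flexible loop) removed from the census.
    """
    if policy not in ("any-match", "primary"):
        raise ValueError(f"unknown policy {policy!r}")
    exclude = list(exclude or [])
    ra, rb = assign_rotamers(a), assign_rotamers(b)

    def _names(assignments, res_atoms_struct, rid):
        if policy == "any-match":
            return {x.name for x in assignments}
        # primary: highest total occupancy conformer
        occ = {}
        for at in res_atoms_struct.residues("polymer").get(rid, []):
            if at.altloc:
                occ[at.altloc] = occ.get(at.altloc, 0.0) + at.occupancy
        if not occ:
            return {assignments[0].name}
        best = max(occ, key=lambda k: (occ[k], -ord(k[0])))
        for x in assignments:
            if x.altloc == best:
                return {x.name}
        return {assignments[0].name}

    changed, names_a, names_b = [], {}, {}
    n_eval = 0
    for rid in sorted(set(ra) & set(rb)):
        if _in_ranges(rid[1], exclude):
            continue
        na = _names(ra[rid], a, rid)
        nb = _names(rb[rid], b, rid)
        names_a[rid], names_b[rid] = sorted(na), sorted(nb)
        n_eval += 1
        if not na & nb:
            changed.append(rid)

    def _multi(assignments_map):
        return sorted(rid for rid, xs in assignments_map.items()
                      if not _in_ranges(rid[1], exclude)
                      and len({x.name for x in xs}) > 1)

    return RotamerDiff(changed, len(changed), n_eval, policy, exclude,
                       _multi(ra), _multi(rb), names_a, names_b)
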