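"""Synthetic crystal systems with known ground truth.

Builds a small γ-branched polypeptide with ideal geometry in a P2₁2₁2₁ cell,
places ordered waters clear of all symmetry contacts, synthesizes a
space-group-symmetric Gaussian-atom density map, and applies controlled
perturbations (χ1 rotamer flips, rigid loop shifts, water displacements,
B-factor inflation, dual-conformer loops) while recording what each analysis
stage is expected to detect.  Every pipeline stage can therefore be tested
end-to-end with no external data.

The map model is deliberately simple: each atom contributes an isotropic
Gaussian with variance ``σ² = B/(8π²) + (h/2)²`` (``h`` = grid spacing; the
second term is an anti-aliasing smoothing) and amplitude proportional to its
electron count, summed over all space-group images with periodic wrapping.
This reproduces the features the samplers care about — peak positions, σ
scaling, crystallographic symmetry — not diffraction physics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._geom import dihedral, place_atom, rotation_about_axis
from .structure_io import (
    Atom,
    CrystalStructure,
    DensityMap,
    UnitCell,
    spacegroup_operators,
    symmetry_images,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruthRecord",
    "GroundTruth",
    "build_toy_crystal",
    "simulate_map",
    "perturb",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20240112

Z_EFF = {"C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0, "H": 1.0}

# ideal backbone internal coordinates (Engh-Huber-like nominal values)
_BB = dict(n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231,
           ang_n_ca_c=111.2, ang_ca_c_n=116.2, ang_c_n_ca=121.7,
           ang_ca_c_o=120.8)

# side-chain topology: atom -> (element, (a, b, c) frame atoms, bond Å,
# angle deg, (chi index, offset deg)).  Torsion = χ_k + offset.
_SIDE_CHAINS: dict = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, (1, 0.0))],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, (1, 0.0))],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, (1, 0.0)),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, (1, -120.0))],
    "VAL": [("CG1", "C", ("N", "CA", "CB"), 1.527, 110.4, (1, 0.0)),
            ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.4, (1, 122.0))],
    "LEU": [("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, (1, 0.0)),
            ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, (2, 0.0)),
            ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, (2, 122.0))],
    "MET": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, (1, 0.0)),
            ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, (2, 0.0)),
            ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, (3, 0.0))],
}

#: default sequence: a γ-branched mix so Ringer/rotamer stages all have targets
DEFAULT_SEQUENCE = ("MET", "SER", "LEU", "CYS", "THR", "SER", "VAL", "LEU",
                    "MET", "CYS", "SER", "LEU", "THR", "CYS", "SER")

#: default χ1 per residue (degrees; None for χ-less types)
DEFAULT_CHI1 = (-65.0, 180.0, -65.0, 180.0, 62.0, 62.0, 180.0, -65.0,
                -65.0, 180.0, -65.0, 180.0, 62.0, 180.0, 62.0)


@dataclass
class SyntheticConfig:
    """Study conditions for the toy crystal.

    Defaults: a 15-residue α-helical peptide (φ=−57°, ψ=−47°) of Ser/Cys/Thr/
    Val/Leu/Met in a 34×38×46 Å P2₁2₁2₁ cell with 20 ordered waters, uniform
    B = 30 Å² and a 0.3 Å map grid.
    """

    sequence: tuple = DEFAULT_SEQUENCE
    chi1: tuple = DEFAULT_CHI1
    phi: float = -57.0
    psi: float = -47.0
    cell: UnitCell = field(default_factory=lambda: UnitCell(34.0, 38.0, 46.0))
    spacegroup: str = "P 21 21 21"
    n_waters: int = 20
    grid: float = 0.3
    b_iso: float = 30.0
    noise_sigma: float = 0.0
    seed: int = DEFAULT_SEED
    center_frac: tuple = (0.23, 0.20, 0.14)
    water_min_dist: float = 2.4
    water_max_dist: float = 5.0


@dataclass
class GroundTruthRecord:
    kind: str  # rotamer-flip | loop-shift | water-move | b-inflate | dual-loop
    ids: list  # residue ids or water ids affected
    magnitude: float  # degrees (flips) or Å (shifts/moves) or factor (B)
    expected: dict  # analysis stage -> should-detect flag


@dataclass
class GroundTruth:
    records: list = field(default_factory=list)

    def ids_for(self, stage: str) -> set:
        """All entity ids a given analysis stage should flag."""
        out: set = set()
        for r in self.records:
            if r.expected.get(stage):
                out.update(tuple(i) if isinstance(i, list) else i for i in r.ids)
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump([r.__dict__ for r in self.records], fh, indent=1, default=list)


def _build_peptide(config: SyntheticConfig) -> list:
    seq, phi, psi = config.sequence, config.phi, config.psi
    coords: list[dict] = []
    # seed the first three backbone atoms explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BB["n_ca"], 0.0, 0.0])
    t = math.radians(180.0 - _BB["ang_n_ca_c"])
    c0 = ca0 + _BB["ca_c"] * np.array([math.cos(t), math.sin(t), 0.0])
    for i, resname in enumerate(seq):
        res = {}
        if i == 0:
            res["N"], res["CA"], res["C"] = n0, ca0, c0
        else:
            prev = coords[i - 1]
            res["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                  _BB["c_n"], _BB["ang_ca_c_n"], psi)
            res["CA"] = place_atom(prev["CA"], prev["C"], res["N"],
                                   _BB["n_ca"], _BB["ang_c_n_ca"], 180.0)
            res["C"] = place_atom(prev["C"], res["N"], res["CA"],
                                  _BB["ca_c"], _BB["ang_n_ca_c"], phi)
            # carbonyl O of the previous residue: torsion N-CA-C-O = ψ + 180
            prev["O"] = place_atom(res["N"], prev["CA"], prev["C"],
                                   _BB["c_o"], _BB["ang_ca_c_o"], 180.0)
        coords.append(res)
    # last carbonyl O from the ψ default
    last = coords[-1]
    last["O"] = place_atom(last["N"], last["CA"], last["C"],
                           _BB["c_o"], _BB["ang_ca_c_o"], psi + 180.0)
    # side chains
    for i, resname in enumerate(seq):
        res = coords[i]
        if resname != "GLY":
            # Cβ from the +120° L-configuration improper about Cα
            res["CB"] = place_atom(res["N"], res["C"], res["CA"],
                                   1.530, 110.1, 120.0)
        chi1 = config.chi1[i] if config.chi1[i] is not None else 180.0
        chis = {1: chi1, 2: 180.0, 3: 180.0, 4: 180.0}
        for name, elem, frame, bond, angle, (k, off) in _SIDE_CHAINS.get(resname, []):
            a, b, c = (res[x] for x in frame)
            res[name] = place_atom(a, b, c, bond, angle, chis[k] + off)
    return coords


_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _atom_element(name: str) -> str:
    if name in _ELEMENT_OF:
        return _ELEMENT_OF[name]
    return {"S": "S", "O": "O"}.get(name[0], "C")


def _min_symmetry_clash(frac_points: np.ndarray, ops, cell: UnitCell) -> float:
    """Minimum distance between the point set and its non-identity images."""
    orth = cell.orthogonalize(frac_points)
    best = float("inf")
    r = np.arange(-1, 2)
    shifts = np.array(np.meshgrid(r, r, r, indexing="ij")).reshape(3, -1).T
    for k, op in enumerate(ops):
        imgs = frac_points @ op.rot.T + op.tran
        for s in shifts:
            if k == 0 and not s.any():
                continue  # identity copy
            d = orth[:, None, :] - cell.orthogonalize(imgs + s)[None, :, :]
            best = min(best, float(np.sqrt((d * d).sum(-1)).min()))
    return best


def build_toy_crystal(config: SyntheticConfig | None = None) -> CrystalStructure:
    """Deterministic toy crystal: ideal-geometry peptide + ordered waters.

    Raises ``ValueError`` if the peptide cannot be placed without symmetry
    contacts under 2 Å, or if waters cannot satisfy their 2.4 Å spacing.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    cell, ops = config.cell, spacegroup_operators(config.spacegroup)
    coords = _build_peptide(config)

    # center the peptide at the requested fractional position
    all_xyz = np.array([p for res in coords for p in res.values()])
    shift = cell.orthogonalize(np.array(config.center_frac)) - all_xyz.mean(0)

    atoms: list[Atom] = []
    for i, (resname, res) in enumerate(zip(config.sequence, coords)):
        for name, pos in res.items():
            atoms.append(Atom(_atom_element(name), name, "", 1.0, config.b_iso,
                              pos + shift, "A", i + 1, "", resname, "polymer"))

    frac = cell.fractionalize(np.array([a.pos for a in atoms]))
    clash = _min_symmetry_clash(frac, ops, cell)
    if clash < 2.0:
        raise ValueError(
            f"cell too small: closest symmetry contact {clash:.2f} Å < 2.0 Å")

    # ordered waters within the solvation shell, clear of all symmetry images
    prot_frac = frac
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < config.n_waters:
        attempts += 1
        if attempts > 20000:
            raise ValueError("could not place waters with 2.4 Å spacing")
        f = rng.random(3)
        dprot = _point_set_distance(f, prot_frac, ops, cell)
        if not config.water_min_dist <= dprot <= config.water_max_dist:
            continue
        if placed and _point_set_distance(f, np.vstack(placed), ops, cell) \
                < config.water_min_dist:
            continue
        if _min_symmetry_clash(np.atleast_2d(f), ops, cell) < config.water_min_dist:
            continue
        placed.append(np.atleast_2d(f))
    for j, f in enumerate(placed):
        atoms.append(Atom("O", "O", "", 1.0, config.b_iso,
                          cell.orthogonalize(f[0]), "S", 101 + j, "", "HOH", "water"))

    st = CrystalStructure("synthetic", atoms, cell, config.spacegroup, ops)
    st.validate_altloc_occupancy()
    return st


def _point_set_distance(frac_point, frac_set, ops, cell) -> float:
    """Min distance (Å) from one fractional point to all images of a point set."""
    frac_set = np.atleast_2d(frac_set)
    p = cell.orthogonalize(np.asarray(frac_point))
    best = float("inf")
    r = np.arange(-1, 2)
    shifts = np.array(np.meshgrid(r, r, r, indexing="ij")).reshape(3, -1).T
    for op in ops:
        imgs = frac_set @ op.rot.T + op.tran
        for s in shifts:
            d = p[None, :] - cell.orthogonalize(imgs + s)
            best = min(best, float(np.sqrt((d * d).sum(-1)).min()))
    return best


def simulate_map(structure: CrystalStructure, grid: float = 0.3,
                 noise_sigma: float = 0.0, seed: int = DEFAULT_SEED) -> DensityMap:
    """Gaussian-atom density map obeying the space group by construction.

    Every atom (and each of its space-group images) adds a normalized 3-D
    Gaussian of weight ``occupancy × Z_eff`` and variance
    ``B/(8π²) + (grid/2)²``.  ``noise_sigma`` adds seeded white noise scaled
    to that fraction of the noiseless map's rms.
    """
    cell = structure.cell
    min_b = min(a.b_iso for a in structure.atoms)
    min_width = math.sqrt(min_b / (8.0 * math.pi ** 2))
    if grid > 0.5 * min_width + 1e-9:
        raise ValueError(
            f"grid {grid} Å too coarse for atomic width {min_width:.2f} Å "
            "(need grid <= width/2)")
    shape = tuple(max(2, int(math.ceil(edge / grid)))
                  for edge in (cell.a, cell.b, cell.c))
    data = np.zeros(shape, dtype=np.float64)
    nx, ny, nz = shape
    M = cell.orthogonalization_matrix

    frac_all = cell.fractionalize(np.array([a.pos for a in structure.atoms]))
    for atom, f in zip(structure.atoms, frac_all):
        var = atom.b_iso / (8.0 * math.pi ** 2) + (grid / 2.0) ** 2
        sigma = math.sqrt(var)
        amp = atom.occupancy * Z_EFF.get(atom.element, 6.0) / \
            ((2.0 * math.pi) ** 1.5 * sigma ** 3)
        cut = 4.0 * sigma
        for op in structure.operators:
            fc = (f @ op.rot.T + op.tran) % 1.0
            g = fc * shape
            # local block (unwrapped indices; stored modulo the grid)
            half = int(math.ceil(cut / grid)) + 1
            lo = np.floor(g).astype(int) - half
            hi = np.floor(g).astype(int) + half + 1
            ii = np.arange(lo[0], hi[0])
            jj = np.arange(lo[1], hi[1])
            kk = np.arange(lo[2], hi[2])
            fi = np.array(np.meshgrid(ii / nx, jj / ny, kk / nz,
                                      indexing="ij"))
            rel = np.tensordot(M, fi - fc[:, None, None, None], axes=(1, 0))
            d2 = (rel ** 2).sum(0)
            block = amp * np.exp(-d2 / (2.0 * var))
            np.add.at(data, np.ix_(ii % nx, jj % ny, kk % nz), block)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sigma * data.std(), size=data.shape)
    return DensityMap(data, cell)


# ---------------------------------------------------------------------------
# controlled perturbations
# ---------------------------------------------------------------------------

def _side_chain_atoms(structure: CrystalStructure, rid) -> list:
    bb = {"N", "CA", "C", "O", "CB"}
    return [a for a in structure.atoms
            if a.residue_id == rid and a.kind == "polymer" and a.name not in bb]


def _rotate_chi1(structure: CrystalStructure, rid, target_chi1: float) -> float:
    """Rotate everything beyond Cβ about the Cα→Cβ axis to the target χ1."""
    res = {a.name: a for a in structure.atoms if a.residue_id == rid}
    for needed in ("N", "CA", "CB"):
        if needed not in res:
            raise ValueError(f"residue {rid} lacks {needed}; cannot flip χ1")
    movers = _side_chain_atoms(structure, rid)
    if not movers:
        raise ValueError(f"residue {rid} has no γ atoms to rotate")
    gamma = movers[0]
    current = dihedral(res["N"].pos, res["CA"].pos, res["CB"].pos, gamma.pos)
    R = rotation_about_axis(res["CB"].pos - res["CA"].pos, target_chi1 - current)
    for a in movers:
        a.pos = res["CB"].pos + R @ (a.pos - res["CB"].pos)
    return current


def _check_clashes(structure: CrystalStructure, moved: list,
                   exclude_ids: set, min_dist: float = 1.5) -> None:
    """Moved atoms must stay >= min_dist from everything outside exclude_ids.

    ``exclude_ids`` covers the perturbed residues and their peptide-bond
    neighbors (a rigid shift legitimately strains the flanking bonds).
    """
    rest = [a for a in structure.atoms if a.residue_id not in exclude_ids]
    if not moved or not rest:
        return
    mp = np.array([a.pos for a in moved])
    rp = np.array([a.pos for a in rest])
    d = np.sqrt(((mp[:, None, :] - rp[None, :, :]) ** 2).sum(-1))
    if d.min() < min_dist:
        i, j = np.unravel_index(d.argmin(), d.shape)
        raise ValueError(
            f"clash after perturbation: {moved[i].residue_id}/{moved[i].name} "
            f"vs {rest[j].residue_id}/{rest[j].name} at {d.min():.2f} Å")


def perturb(structure: CrystalStructure, requests: list,
            seed: int = DEFAULT_SEED) -> tuple:
    """Apply a list of perturbation requests; returns (new structure, truth).

    Request dictionaries (residue/water ids are ``(chain, resseq, icode)``):

    * ``{"kind": "rotamer-flip", "residue": rid, "target_chi1": deg}``
    * ``{"kind": "loop-shift", "first": int, "last": int, "magnitude": Å}``
      (or an explicit ``"vector"``)
    * ``{"kind": "water-move", "water": rid, "distance": Å}``
    * ``{"kind": "b-inflate", "first": int, "last": int, "factor": x}``
    * ``{"kind": "dual-loop", "first": int, "last": int, "vector": Å-3-vector,
      "occupancies": (a, b)}``
    """
    rng = np.random.default_rng(seed)
    out = structure.copy(structure.label + "+perturbed")
    truth = GroundTruth()
    for req in requests:
        kind = req["kind"]
        if kind == "rotamer-flip":
            rid = tuple(req["residue"])
            old = _rotate_chi1(out, rid, float(req["target_chi1"]))
            _check_clashes(out, _side_chain_atoms(out, rid), {rid})
            delta = abs((float(req["target_chi1"]) - old + 180.0) % 360.0 - 180.0)
            # sub-rotameric nudges (< 40°) are not expected to change the
            # rotamer name or decorrelate the Ringer curve
            detectable = delta > 40.0
            truth.records.append(GroundTruthRecord(
                kind, [rid], delta,
                {"rotamer_diff": detectable, "ringer_cc": detectable}))
        elif kind == "loop-shift":
            first, last = int(req["first"]), int(req["last"])
            if "vector" in req:
                vec = np.asarray(req["vector"], dtype=float)
            else:
                v = rng.normal(size=3)
                vec = float(req["magnitude"]) * v / np.linalg.norm(v)
            rids, moved = [], []
            for a in out.atoms:
                if a.kind == "polymer" and first <= a.resseq <= last:
                    a.pos = a.pos + vec
                    moved.append(a)
                    if a.residue_id not in rids:
                        rids.append(a.residue_id)
            if not rids:
                raise ValueError(f"loop-shift range {first}-{last} matches nothing")
            flank = {(c, n, i) for (c, n, i) in (a.residue_id for a in out.atoms)
                     if first - 1 <= n <= last + 1}
            _check_clashes(out, moved, flank)
            mag = float(np.linalg.norm(vec))
            truth.records.append(GroundTruthRecord(
                kind, rids, mag, {"displacement": mag > 0.3}))
        elif kind == "water-move":
            rid = tuple(req["water"])
            dist = float(req["distance"])
            waters = [a for a in out.atoms if a.residue_id == rid and a.kind == "water"]
            if not waters:
                raise ValueError(f"no water {rid}")
            w = waters[0]
            cell, ops = out.cell, out.operators
            # clearance is symmetry-aware so a planted move cannot land next
            # to an image of another water and confound uniqueness analysis
            others_frac = cell.fractionalize(
                np.array([a.pos for a in out.atoms if a is not w]))
            old_frac = cell.fractionalize(w.pos)[None, :]
            for _ in range(500):
                v = rng.normal(size=3)
                cand = w.pos + dist * v / np.linalg.norm(v)
                cand_frac = cell.fractionalize(cand)
                if _point_set_distance(cand_frac, others_frac, ops, cell) < 2.2:
                    continue
                if dist > 2.0 and _point_set_distance(
                        cand_frac, old_frac, ops, cell) < min(2.2, dist - 1e-9):
                    continue  # an image of the old site is closer than the move
                break
            else:
                raise ValueError(f"cannot move water {rid} by {dist} Å without clash")
            w.pos = cand
            truth.records.append(GroundTruthRecord(
                kind, [rid], dist, {"unique_waters": dist > 2.0}))
        elif kind == "b-inflate":
            first, last = int(req["first"]), int(req["last"])
            factor = float(req["factor"])
            rids = []
            for a in out.atoms:
                if a.kind == "polymer" and first <= a.resseq <= last:
                    a.b_iso *= factor
                    if a.residue_id not in rids:
                        rids.append(a.residue_id)
            truth.records.append(GroundTruthRecord(kind, rids, factor, {}))
        elif kind == "dual-loop":
            first, last = int(req["first"]), int(req["last"])
            vec = np.asarray(req["vector"], dtype=float)
            occ_a, occ_b = req.get("occupancies", (0.6, 0.4))
            new_atoms, rids = [], []
            for a in out.atoms:
                if a.kind == "polymer" and first <= a.resseq <= last:
                    b = a.copy()
                    a.altloc, a.occupancy = "A", float(occ_a)
                    b.altloc, b.occupancy = "B", float(occ_b)
                    b.pos = b.pos + vec
                    new_atoms.append(b)
                    if a.residue_id not in rids:
                        rids.append(a.residue_id)
            out.atoms.extend(new_atoms)
            truth.records.append(GroundTruthRecord(
                kind, rids, float(np.linalg.norm(vec)),
                {"altloc_separation": True}))
        else:
            raise ValueError(f"unknown perturbation kind {kind!r}")
    out.validate_altloc_occupancy()
    return out, truth
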