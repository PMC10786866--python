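"""Per-residue Cα displacement analysis between crystal structures.

Covers rigid-body (Kabsch) superposition, pairwise Cα distance profiles in
either a superposed or the shared crystal frame, multi-structure Cα RMSF, and
the Cα separation between alternate conformations within one structure.
Distances under ~0.3 Å are conventionally treated as structural noise when
comparing refined models; that threshold is a descriptive cut applied by the
report layer, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import CrystalStructure

__all__ = [
    "DisplacementRecord",
    "DisplacementProfile",
    "superpose",
    "ca_distance_profile",
    "ca_rmsf",
    "altloc_ca_separation",
]


@dataclass
class DisplacementRecord:
    residue_id: tuple
    altloc_a: str
    altloc_b: str
    ca_dist_A: float


@dataclass
class DisplacementProfile:
    reference_label: str
    mobile_label: str
    mode: str  # "superposed" | "crystal-frame"
    altloc_policy: str
    records: list = field(default_factory=list)
    only_in_a: list = field(default_factory=list)
    only_in_b: list = field(default_factory=list)
    rmsd_A: float | None = None  # fit RMSD when superposed

    def as_dict(self) -> dict:
        return {r.residue_id: r.ca_dist_A for r in self.records}


def _ca_by_residue(structure: CrystalStructure) -> dict:
    """residue id -> {altloc: CA position}; blank altloc key "" when single."""
    out: dict = {}
    for a in structure.atoms:
        if a.kind == "polymer" and a.name == "CA":
            out.setdefault(a.residue_id, {})[a.altloc] = (a.pos, a.occupancy)
    return out


def _primary_ca(conformers: dict) -> np.ndarray:
    """Highest-occupancy CA (blank altloc wins ties as the common conformer)."""
    if "" in conformers:
        return conformers[""][0]
    best = max(conformers, key=lambda k: (conformers[k][1], -ord(k[0])))
    return conformers[best][0]


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation R and translation t with P @ R.T + t ≈ Q."""
    cp, cq = P.mean(0), Q.mean(0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def superpose(mobile: CrystalStructure, reference: CrystalStructure,
              selection: set | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition of shared Cα atoms.

    ``selection`` restricts the fit to the given author residue numbers.
    Returns ``(rotation, translation, rmsd)`` with the proper-rotation
    constraint (det = +1) enforced; apply as ``x @ R.T + t``.
    """
    ca_m, ca_r = _ca_by_residue(mobile), _ca_by_residue(reference)
    shared = [rid for rid in ca_m if rid in ca_r
              and (selection is None or rid[1] in selection)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared Cα atoms, found {len(shared)}")
    P = np.array([_primary_ca(ca_m[rid]) for rid in shared])
    Q = np.array([_primary_ca(ca_r[rid]) for rid in shared])
    return _kabsch(P, Q)


def _pair_altlocs(ca_a: dict, ca_b: dict, policy: str) -> list:
    """Altloc pairing for one residue: like-with-like, else highest occupancy."""
    la = [k for k in ca_a if k] or [""]
    lb = [k for k in ca_b if k] or [""]
    if policy == "paired":
        common = sorted(set(la) & set(lb))
        if common:
            return [(x, x) for x in common]
    # fall back (and the "primary" policy): single highest-occupancy pair
    pa = "" if "" in ca_a else max(ca_a, key=lambda k: (ca_a[k][1], -ord(k[0])))
    pb = "" if "" in ca_b else max(ca_b, key=lambda k: (ca_b[k][1], -ord(k[0])))
    return [(pa, pb)]


def ca_distance_profile(a: CrystalStructure, b: CrystalStructure,
                        mode: str = "superposed",
                        altloc_policy: str = "paired",
                        fit_exclude: list | None = None) -> DisplacementProfile:
    """Per-residue |Cα_a − Cα_b| profile.

    ``mode="superposed"`` first rigid-body fits ``b`` onto ``a`` over shared
    single-conformer Cαs (optionally excluding author-number ranges in
    ``fit_exclude`` — e.g. a shifted loop — from the fit);
    ``mode="crystal-frame"`` compares raw coordinates, appropriate for
    isomorphous structures in the same frame.  With alternate conformations,
    the default policy pairs matching altloc letters (A with A, B with B) and
    emits one record per pair.
    """
    if mode not in ("superposed", "crystal-frame"):
        raise ValueError(f"unknown mode {mode!r}")
    ca_a, ca_b = _ca_by_residue(a), _ca_by_residue(b)
    shared = sorted(set(ca_a) & set(ca_b))
    if not shared:
        raise ValueError("no shared residues between the two structures")

    transform = None
    rmsd = None
    if mode == "superposed":
        excl = fit_exclude or []
        sel = {rid[1] for rid in shared
               if not any(lo <= rid[1] <= hi for lo, hi in excl)}
        R, t, rmsd = superpose(b, a, selection=sel)
        transform = (R, t)

    prof = DisplacementProfile(a.label, b.label, mode, altloc_policy, rmsd_A=rmsd)
    prof.only_in_a = sorted(set(ca_a) - set(ca_b))
    prof.only_in_b = sorted(set(ca_b) - set(ca_a))
    for rid in shared:
        for la, lb in _pair_altlocs(ca_a[rid], ca_b[rid], altloc_policy):
            pa = ca_a[rid][la][0] if la in ca_a[rid] else _primary_ca(ca_a[rid])
            pb = ca_b[rid][lb][0] if lb in ca_b[rid] else _primary_ca(ca_b[rid])
            if transform is not None:
                R, t = transform
                pb = R @ pb + t
            prof.records.append(DisplacementRecord(
                rid, la, lb, float(np.linalg.norm(pa - pb))))
    return prof


def ca_rmsf(structures: list, superpose_to_first: bool = True) -> dict:
    """Per-residue Cα RMSF across a set of structures.

    RMSF(res) = sqrt(mean over structures of |Cα − mean Cα|²), computed over
    residues shared by all structures; models are superposed to the first by
    default.
    """
    if len(structures) < 2:
        raise ValueError("RMSF needs >= 2 structures")
    cas = [_ca_by_residue(s) for s in structures]
    shared = sorted(set.intersection(*(set(c) for c in cas)))
    if not shared:
        raise ValueError("no residues shared by all structures")
    coords = []
    for s, c in zip(structures, cas):
        P = np.array([_primary_ca(c[rid]) for rid in shared])
        if superpose_to_first and s is not structures[0]:
            R, t, _ = superpose(s, structures[0])
            P = P @ R.T + t
        coords.append(P)
    X = np.stack(coords)  # (n_struct, n_res, 3)
    mean = X.mean(0)
    rmsf = np.sqrt(((X - mean) ** 2).sum(-1).mean(0))
    return dict(zip(shared, rmsf.tolist()))


def altloc_ca_separation(structure: CrystalStructure, residue_id) -> list:
    """Pairwise Cα–Cα distances between a residue's alternate conformations.

    Returns ``[((altloc_i, altloc_j), distance), ...]``; empty when the
    residue has fewer than two Cα conformers.
    """
    residue_id = tuple(residue_id)
    ca = _ca_by_residue(structure).get(residue_id, {})
    letters = sorted(k for k in ca if k)
    out = []
    for i in range(len(letters)):
        for j in range(i + 1, len(letters)):
            d = float(np.linalg.norm(ca[letters[i]][0] - ca[letters[j]][0]))
            out.append(((letters[i], letters[j]), d))
    return out
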