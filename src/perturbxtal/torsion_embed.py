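"""Reduced-dimensionality embedding of structures in torsion-angle space.

Each structure is summarized by its backbone (φ, ψ) and side-chain (χ1..χ4)
torsions; torsions shared by all structures are vectorized as (sin θ, cos θ)
pairs — which removes the ±180° branch cut — mean-centered, and decomposed by
PCA (SVD).  With n structures at most n−1 components carry variance; the sign
of each component is fixed by making its largest-magnitude loading positive,
so the embedding is deterministic and independent of input order.

This is a PCA of circular torsion features, designed to expose the same
qualitative geometry as torsion-space embeddings of structural ensembles
(cluster memberships and directions of perturbation), not to reproduce any
specific tool's coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import dihedral
from .rotamers import CHI_ATOMS
from .structure_io import CrystalStructure

__all__ = ["TorsionVector", "TorsionEmbedding", "extract_torsions", "embed"]

_BACKBONE_BREAK_DIST = 2.0  # Å: C(i-1)–N(i) beyond this means a chain break


@dataclass
class TorsionVector:
    label: str
    torsions: dict  # (residue_id, torsion name) -> angle degrees


@dataclass
class TorsionEmbedding:
    labels: list
    coordinates: np.ndarray  # (n_structures, n_components)
    explained_variance: np.ndarray  # fractions, non-increasing
    loadings: np.ndarray  # (n_components, n_features)
    feature_names: list  # (residue_id, torsion, "sin"|"cos")


def _primary_conformer(res_atoms: list) -> dict:
    """name -> position for the highest-occupancy conformer of one residue."""
    letters = sorted({a.altloc for a in res_atoms if a.altloc})
    if letters:
        occ = {lt: sum(a.occupancy for a in res_atoms if a.altloc == lt)
               for lt in letters}
        best = max(letters, key=lambda lt: (occ[lt], -ord(lt[0])))
        res_atoms = [a for a in res_atoms if a.altloc in ("", best)]
    return {a.name: a.pos for a in res_atoms}


def extract_torsions(structure: CrystalStructure,
                     altloc: str | None = None) -> TorsionVector:
    """φ, ψ and χ torsions of every residue (highest-occupancy conformer).

    ``altloc`` forces a specific conformer letter where present (used to
    analyze each state of a dual-conformation loop separately).  Torsions
    undefined at chain breaks or incomplete residues are simply absent; the
    embedding step masks to the torsions shared by all inputs.
    """
    residues = structure.residues("polymer")
    rids = list(residues)
    torsions: dict = {}
    confs = {}
    for rid, res_atoms in residues.items():
        if altloc is not None:
            forced = [a for a in res_atoms if a.altloc in ("", altloc)]
            has_letter = any(a.altloc == altloc for a in res_atoms)
            confs[rid] = ({a.name: a.pos for a in forced} if has_letter
                          else _primary_conformer(res_atoms))
        else:
            confs[rid] = _primary_conformer(res_atoms)

    def _contiguous(prev_rid, rid) -> bool:
        if prev_rid[0] != rid[0]:
            return False
        p, q = confs[prev_rid], confs[rid]
        if "C" not in p or "N" not in q:
            return False
        return float(np.linalg.norm(p["C"] - q["N"])) < _BACKBONE_BREAK_DIST

    for i, rid in enumerate(rids):
        res = confs[rid]
        resname = residues[rid][0].resname
        try:
            if i > 0 and _contiguous(rids[i - 1], rid):
                prev = confs[rids[i - 1]]
                torsions[(rid, "phi")] = dihedral(prev["C"], res["N"],
                                                  res["CA"], res["C"])
            if i + 1 < len(rids) and _contiguous(rid, rids[i + 1]):
                nxt = confs[rids[i + 1]]
                torsions[(rid, "psi")] = dihedral(res["N"], res["CA"],
                                                  res["C"], nxt["N"])
        except (KeyError, ValueError):
            pass
        for k, quad in enumerate(CHI_ATOMS.get(resname, []), start=1):
            try:
                pts = [res[n] for n in quad]
                torsions[(rid, f"chi{k}")] = dihedral(*pts)
            except (KeyError, ValueError):
                pass
    return TorsionVector(structure.label, torsions)


def embed(vectors: list, n_components: int = 2,
          weights: dict | None = None) -> TorsionEmbedding:
    """PCA embedding of torsion vectors with circular (sin, cos) features.

    ``weights`` optionally maps a torsion name (``"phi"``, ``"chi1"``, …) to a
    multiplicative feature weight (uniform by default).  Requires at least 3
    structures and a non-empty shared-torsion mask.
    """
    if len(vectors) < 3:
        raise ValueError("embedding needs >= 3 structures")
    keys = sorted(set.intersection(*(set(v.torsions) for v in vectors)),
                  key=lambda k: (k[0], k[1]))
    if not keys:
        raise ValueError("no torsions shared by all structures")
    feats, names = [], []
    for v in vectors:
        row = []
        for key in keys:
            w = 1.0 if weights is None else float(weights.get(key[1], 1.0))
            theta = np.radians(v.torsions[key])
            row.extend([w * np.sin(theta), w * np.cos(theta)])
        feats.append(row)
    for key in keys:
        names.extend([(key[0], key[1], "sin"), (key[0], key[1], "cos")])
    X = np.asarray(feats)
    X = X - X.mean(0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(len(S)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    total = float((S ** 2).sum())
    n_components = min(n_components, len(S))
    coords = U[:, :n_components] * S[:n_components]
    ev = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return TorsionEmbedding([v.label for v in vectors], coords, ev,
                            Vt[:n_components], names)
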