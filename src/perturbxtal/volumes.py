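"""Expansion/compression metrics: cell and protein volumes, percent changes,
and Welch's t-test on pocket-volume tables.

The protein volume is a defined grid method: voxels inside any van der Waals
sphere, plus voxels a water-sized probe cannot reach from outside (interior
cavities and inter-atomic interstices), make up the molecular volume.  It is
a reproducible analog of solvent-excluded volume, not a re-implementation of
any particular closed-source volume program, so absolute values are validated
by convergence and closed-form properties rather than against published
per-structure numbers; percent-change arithmetic is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .structure_io import CrystalStructure, cell_volume

__all__ = [
    "VDW_RADII",
    "VolumeReport",
    "protein_volume",
    "percent_change",
    "welch_t_test",
    "read_pocket_table",
]

#: Built-in van der Waals radii (Å); hydrogens count only if modeled.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}
DEFAULT_RADIUS = 1.70


@dataclass
class VolumeReport:
    label: str
    cell_volume_A3: float
    protein_volume_A3: float
    grid_A: float
    probe_A: float


def protein_volume(structure: CrystalStructure, grid: float = 0.3,
                   probe: float = 1.4, include_waters: bool = False) -> float:
    """Molecular volume (Å³) of the polymer by the probe-excluded grid method.

    Algorithm: on a Cartesian grid over the padded bounding box, (1) mark
    voxels inside any vdW sphere, (2) dilate by the probe radius and flood
    fill the complement from the box boundary to find probe-accessible
    solvent, (3) dilate the solvent region back by the probe; everything the
    dilated solvent cannot touch — vdW interior, interstices, and cavities
    too small for the probe — is protein volume.
    """
    if not 0.2 <= grid <= 1.0:
        raise ValueError(f"grid spacing must be in [0.2, 1.0] Å, got {grid}")
    atoms = [a for a in structure.atoms
             if a.kind == "polymer" or (include_waters and a.kind == "water")]
    if not any(a.kind == "polymer" for a in atoms):
        raise ValueError("structure has no polymer atoms")
    pos = np.array([a.pos for a in atoms])
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_RADIUS) for a in atoms])

    pad = radii.max() + probe + 2.0 * grid
    lo = pos.min(0) - pad
    hi = pos.max(0) + pad
    shape = np.ceil((hi - lo) / grid).astype(int) + 1

    occupied = np.zeros(shape, dtype=bool)
    for p, r in zip(pos, radii):
        g = (p - lo) / grid
        half = int(np.ceil(r / grid)) + 1
        sl = [np.arange(max(0, int(g[d]) - half), min(shape[d], int(g[d]) + half + 1))
              for d in range(3)]
        dd = [(s * grid + lo[d] - p[d]) ** 2 for d, s in zip(range(3), [sl[0], sl[1], sl[2]])]
        d2 = dd[0][:, None, None] + dd[1][None, :, None] + dd[2][None, None, :]
        occupied[np.ix_(*sl)] |= d2 <= r * r

    # probe-dilated obstacle set, then flood fill from the box boundary
    dist_out = ndimage.distance_transform_edt(~occupied, sampling=grid)
    blocked = dist_out <= probe  # includes occupied (distance 0)
    labels, _ = ndimage.label(~blocked)
    edge_labels = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
    edge_labels = edge_labels[edge_labels != 0]
    solvent = np.isin(labels, edge_labels)

    # re-dilate the reachable solvent by the probe: its complement is protein
    dist_solv = ndimage.distance_transform_edt(~solvent, sampling=grid)
    protein = (dist_solv > probe) | occupied
    return float(protein.sum()) * grid ** 3


def percent_change(reference: float, other: float) -> float:
    """Signed percent change vs a reference, reported to one decimal."""
    if reference <= 0:
        raise ValueError("reference volume must be positive")
    return round(100.0 * (other - reference) / reference, 1)


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sample t-test (unequal variances).

    Returns ``(t, df, p)`` with ``t = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂)``, the
    Welch–Satterthwaite degrees of freedom, and the two-sided p-value from
    the t distribution.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("A", a), ("B", b)):
        if g.size < 2:
            raise ValueError(f"group {name} needs >= 2 values")
        if g.var(ddof=1) == 0:
            raise ValueError(f"group {name} has zero variance")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def read_pocket_table(path: str) -> dict:
    """Read a pocket-volume CSV (columns structure, pocket_id, volume_A3).

    Pocket volumes come from an external pocket-detection tool; they are
    consumed here only for group statistics.  Returns
    ``{structure_label: [volumes...]}``.
    """
    df = pd.read_csv(path)
    required = {"structure", "volume_A3"}
    if not required <= set(df.columns):
        raise ValueError(f"pocket table needs columns {sorted(required)}")
    if (df["volume_A3"] < 0).any():
        raise ValueError("pocket volumes must be >= 0")
    return {label: grp["volume_A3"].tolist()
            for label, grp in df.groupby("structure")}


def volume_report(structure: CrystalStructure, grid: float = 0.3,
                  probe: float = 1.4) -> VolumeReport:
    return VolumeReport(structure.label, cell_volume(structure.cell),
                        protein_volume(structure, grid, probe), grid, probe)
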