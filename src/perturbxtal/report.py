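"""Multi-condition comparison pipeline and combined report.

Runs every analysis stage against a named reference structure and aggregates
the results into one :class:`ComparisonReport`.  Every number in the report
is produced by the stage modules — the report layer only formats and counts.
Default thresholds follow the field's conventions: 2.0 Å water uniqueness,
CC < 0.5 for changed Ringer curves, 0.3 Å descriptive Cα displacement cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import ringer as ringer_mod
from .displacement import ca_distance_profile
from .rotamers import rotamer_diff
from .solvent import unique_waters
from .structure_io import CrystalStructure, DensityMap, cell_volume
from .torsion_embed import embed, extract_torsions
from .volumes import percent_change, protein_volume

__all__ = ["PipelineConfig", "ComparisonReport", "run_pipeline", "format_float"]

DEFAULT_THRESHOLDS = {
    "water_A": 2.0,
    "cc": 0.5,
    "displacement_A": 0.3,
    "exclude_ranges": [],
}


def format_float(x: float) -> str:
    """Fixed 6-significant-digit formatting so re-runs are byte-identical."""
    return f"{x:.6g}"


@dataclass
class PipelineConfig:
    reference: str
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    displacement_mode: str = "superposed"
    water_frame: str = "fractional"
    grid_A: float = 0.3
    probe_A: float = 1.4
    seed: int = 0


@dataclass
class ComparisonReport:
    reference: str
    volumes: dict = field(default_factory=dict)
    waters: dict = field(default_factory=dict)
    displacement: dict = field(default_factory=dict)
    ringer_cc: dict = field(default_factory=dict)
    rotamers: dict = field(default_factory=dict)
    embedding: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            import numpy as np
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)
        return json.dumps(self.__dict__, indent=1, default=_default)

    def summary(self) -> str:
        lines = [f"reference: {self.reference}"]
        for label, v in self.volumes.items():
            lines.append(
                f"{label}: cell {format_float(v['cell_volume_A3'])} A^3 "
                f"({v['cell_change_pct']:+.1f}%), protein "
                f"{format_float(v['protein_volume_A3'])} A^3 "
                f"({v['protein_change_pct']:+.1f}%)")
        for label, w in self.waters.items():
            lines.append(f"{label}: {w['n_unique']}/{w['n_total']} waters unique "
                         f"(> {w['threshold_A']} A from reference waters)")
        for label, d in self.displacement.items():
            lines.append(f"{label}: {d['n_above_cut']} residues with Ca shift "
                         f"> {d['cut_A']} A (max {format_float(d['max_A'])} A)")
        for label, r in self.ringer_cc.items():
            lines.append(f"{label}: {r['n_flagged']}/{r['n_evaluated']} residues "
                         f"with Ringer CC < {r['threshold']}")
        for label, r in self.rotamers.items():
            lines.append(f"{label}: {r['n_changed']}/{r['n_evaluated']} residues "
                         "with changed rotamer")
        return "\n".join(lines)


def run_pipeline(structures: list, config: PipelineConfig,
                 maps: dict | None = None) -> ComparisonReport:
    """Execute all applicable stages for a structure set vs the reference.

    ``structures`` is a list of :class:`CrystalStructure`; ``maps`` optionally
    maps structure labels to :class:`DensityMap` objects (the Ringer/CC stage
    runs only for labels with maps, including the reference).  The embedding
    stage runs when at least 3 structures are given.
    """
    if len(structures) < 2:
        raise ValueError("pipeline needs >= 2 structures")
    by_label = {s.label: s for s in structures}
    if config.reference not in by_label:
        raise ValueError(f"reference {config.reference!r} not among inputs")
    ref = by_label[config.reference]
    others = [s for s in structures if s.label != config.reference]
    thr = {**DEFAULT_THRESHOLDS, **config.thresholds}
    exclude = [tuple(r) for r in thr["exclude_ranges"]]
    maps = maps or {}

    report = ComparisonReport(config.reference, thresholds=thr)

    # volumes
    ref_cell_v = cell_volume(ref.cell)
    ref_prot_v = protein_volume(ref, config.grid_A, config.probe_A)
    for s in structures:
        cv = cell_volume(s.cell)
        pv = ref_prot_v if s is ref else protein_volume(s, config.grid_A, config.probe_A)
        report.volumes[s.label] = {
            "cell_volume_A3": cv,
            "protein_volume_A3": pv,
            "cell_change_pct": percent_change(ref_cell_v, cv),
            "protein_change_pct": percent_change(ref_prot_v, pv),
        }

    # waters
    for s in others:
        try:
            rep = unique_waters(s, [ref], thr["water_A"], config.water_frame)
        except ValueError:
            continue  # a structure without waters is simply not compared
        report.waters[s.label] = {
            "n_unique": rep.n_unique,
            "n_shared": rep.n_shared,
            "n_total": rep.n_total,
            "percent_unique": rep.percent_unique,
            "threshold_A": rep.threshold_A,
            "frame_mode": rep.frame_mode,
        }

    # displacement
    for s in others:
        prof = ca_distance_profile(ref, s, mode=config.displacement_mode)
        dists = [r.ca_dist_A for r in prof.records]
        cut = thr["displacement_A"]
        report.displacement[s.label] = {
            "n_residues": len(dists),
            "n_above_cut": sum(d > cut for d in dists),
            "cut_A": cut,
            "max_A": max(dists),
            "mode": prof.mode,
        }

    # Ringer CC (needs maps for the reference and the other structure)
    if config.reference in maps:
        ref_mono = ringer_mod.strip_to_single_conformer(ref)
        ref_curves = ringer_mod.ringer_curves(maps[config.reference], ref_mono)
        for s in others:
            if s.label not in maps:
                continue
            mono = ringer_mod.strip_to_single_conformer(s)
            curves = ringer_mod.ringer_curves(maps[s.label], mono)
            comps = ringer_mod.compare_curves(ref_curves, curves, thr["cc"])
            report.ringer_cc[s.label] = ringer_mod.flag_changed_residues(
                comps, thr["cc"], exclude)

    # rotamers
    for s in others:
        diff = rotamer_diff(ref, s, exclude=exclude)
        report.rotamers[s.label] = {
            "n_changed": diff.n_changed,
            "n_evaluated": diff.n_evaluated,
            "percent_changed": diff.percent_changed,
            "changed": [list(r) for r in diff.changed],
            "policy": diff.policy,
            "multi_rotamer_reference": [list(r) for r in diff.multi_rotamer_a],
            "multi_rotamer_other": [list(r) for r in diff.multi_rotamer_b],
        }

    # torsion embedding
    if len(structures) >= 3:
        vecs = [extract_torsions(s) for s in structures]
        emb = embed(vecs)
        report.embedding = {
            "labels": emb.labels,
            "coordinates": emb.coordinates.tolist(),
            "explained_variance": emb.explained_variance.tolist(),
        }
    return report
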