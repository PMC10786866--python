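"""Ringer χ1 sampling, curve correlation, change flagging, peak finding."""

import numpy as np
import pytest

from perturbxtal._geom import dihedral
from perturbxtal.ringer import (
    RingerCurve,
    compare_curves,
    curve_cc,
    find_peaks,
    flag_changed_residues,
    ringer_curve,
    ringer_curves,
    strip_to_single_conformer,
)
from perturbxtal.structure_io import DensityMap, UnitCell
from perturbxtal.synthetic import (
    SyntheticConfig,
    build_toy_crystal,
    perturb,
    simulate_map,
)


def _curve(values, step=10.0, rid=("A", 1, ""), resname="SER"):
    angles = np.arange(0.0, 360.0, step)
    return RingerCurve(rid, resname, 1, step, angles, np.asarray(values, float))


class TestStripToSingleConformer:
    def test_no_altlocs_unchanged(self, toy):
        mono = strip_to_single_conformer(toy)
        assert len(mono.atoms) == len(toy.atoms)
        assert all(a.occupancy == 1.0 for a in mono.atoms)

    def test_highest_occupancy_kept(self, toy):
        pert, _ = perturb(toy, [{"kind": "dual-loop", "first": 5, "last": 7,
                                 "vector": [0.0, 1.0, 0.0],
                                 "occupancies": (0.6, 0.4)}], seed=1)
        mono = strip_to_single_conformer(pert)
        assert len(mono.atoms) == len(toy.atoms)
        for a, b in zip(mono.atoms, toy.atoms):  # A state = original coords
            assert np.linalg.norm(a.pos - b.pos) < 1e-9

    def test_explicit_altloc_label_selected(self, toy):
        """Requesting the B state keeps the shifted loop coordinates."""
        vec = np.array([0.0, 1.0, 0.0])
        pert, _ = perturb(toy, [{"kind": "dual-loop", "first": 5, "last": 7,
                                 "vector": vec.tolist(),
                                 "occupancies": (0.6, 0.4)}], seed=1)
        mono = strip_to_single_conformer(pert, policy="B")
        for a, orig in zip(mono.atoms, toy.atoms):
            expect = orig.pos + vec if 5 <= orig.resseq <= 7 and orig.kind == "polymer" \
                else orig.pos
            assert np.linalg.norm(a.pos - expect) < 1e-9


class TestRingerCurve:
    def test_reconstructed_gamma_matches_model(self, toy, toy_map):
        """At θ equal to the model's own χ1, the swept γ position coincides
        with the model's γ atom."""
        from perturbxtal.ringer import GAMMA_PRIORITY
        from perturbxtal._geom import rotation_about_axis
        rid = ("A", 2, "")  # Ser with χ1 = 180°
        res = {a.name: a.pos for a in toy.atoms if a.residue_id == rid}
        gamma = res["OG"]
        chi0 = dihedral(res["N"], res["CA"], res["CB"], gamma)
        R = rotation_about_axis(res["CB"] - res["CA"], chi0 - chi0)
        assert np.linalg.norm((res["CB"] + R @ (gamma - res["CB"])) - gamma) < 1e-3

    def test_curve_peaks_at_model_chi1(self, toy, toy_map):
        cfg = SyntheticConfig()
        for rid, expected in ((("A", 2, ""), 180.0), (("A", 5, ""), 62.0)):
            c = ringer_curve(toy_map, toy, rid, step=10.0)
            top_angle = c.angles[int(np.argmax(c.values))]
            delta = abs((top_angle - expected + 180) % 360 - 180)
            assert delta <= 10.0

    def test_constant_map_raw_curve_flat(self, toy):
        m = DensityMap(np.full((16, 16, 16), 1.0), toy.cell)
        with pytest.raises(ValueError):
            ringer_curve(m, toy, ("A", 2, ""))  # σ-scaling undefined

    def test_gly_ala_skipped(self, toy, toy_map):
        cfg = SyntheticConfig(sequence=("ALA", "SER", "GLY"),
                              chi1=(None, 180.0, None), n_waters=0)
        st = build_toy_crystal(cfg)
        with pytest.raises(ValueError, match="skip"):
            ringer_curve(toy_map, st, ("A", 1, ""))
        curves = ringer_curves(toy_map, st)
        assert set(curves) == {("A", 2, "")}

    def test_two_conformer_map_shows_two_chi1_peaks(self):
        """A map baked from Ser conformers at χ1 = 180° and +60° yields local
        maxima near both angles (the dual-rotamer signature)."""
        cfg = SyntheticConfig(sequence=("MET", "SER", "LEU"),
                              chi1=(-65.0, 180.0, -65.0), n_waters=0)
        st = build_toy_crystal(cfg)
        rid = ("A", 2, "")
        dual, _ = perturb(st, [{"kind": "rotamer-flip", "residue": rid,
                                "target_chi1": 60.0}], seed=1)
        # overlay both states at half occupancy
        for struct in (st, dual):
            for a in struct.atoms:
                if a.residue_id == rid and a.name == "OG":
                    a.occupancy = 0.5
        both = st.copy("dual")
        both.atoms.extend(a.copy() for a in dual.atoms
                          if a.residue_id == rid and a.name == "OG")
        m = simulate_map(both, grid=0.3)
        c = ringer_curve(m, st, rid, step=10.0)
        peaks = find_peaks(c, min_sigma=0.3)
        assert len(peaks) >= 2
        angles = sorted(a for a, _ in peaks[:2])
        assert min(abs((a - 60) % 360) for a in angles) <= 20
        assert min(abs((a - 180) % 360) for a in angles) <= 20

    def test_affine_map_transform_leaves_sigma_curve_unchanged(self, toy, toy_map):
        rid = ("A", 4, "")
        c0 = ringer_curve(toy_map, toy, rid)
        shifted = DensityMap(3.0 * toy_map.data + 7.0, toy.cell)
        c1 = ringer_curve(shifted, toy, rid)
        assert c1.values == pytest.approx(c0.values, abs=1e-4)


class TestCurveCC:
    def test_self_correlation_is_one(self, rng):
        c = _curve(rng.normal(size=36))
        assert curve_cc(c, c) == pytest.approx(1.0)

    def test_negated_curve_anticorrelates(self, rng):
        v = rng.normal(size=36)
        c = _curve(v)
        neg = _curve(2 * v.mean() - v)
        assert curve_cc(c, neg) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=36), rng.normal(size=36)
            expected = (((x - x.mean()) * (y - y.mean())).sum()
                        / np.sqrt(((x - x.mean()) ** 2).sum()
                                  * ((y - y.mean()) ** 2).sum()))
            assert curve_cc(_curve(x), _curve(y)) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        x, y = rng.normal(size=36), rng.normal(size=36)
        cc = curve_cc(_curve(x), _curve(y))
        assert cc == curve_cc(_curve(y), _curve(x))
        assert -1.0 <= cc <= 1.0

    def test_flat_curve_undefined(self, rng):
        flat = _curve(np.zeros(36))
        assert curve_cc(flat, _curve(rng.normal(size=36))) is None

    def test_mismatched_grids_rejected(self, rng):
        with pytest.raises(ValueError):
            curve_cc(_curve(rng.normal(size=36), step=10),
                     _curve(rng.normal(size=72), step=5))


class TestFlagging:
    def test_all_correlated_none_flagged(self, rng):
        curves = {("A", i, ""): _curve(rng.normal(size=36)) for i in range(5)}
        res = flag_changed_residues(compare_curves(curves, curves))
        assert res["n_flagged"] == 0

    def test_exclusion_arithmetic(self):
        comps = []
        from perturbxtal.ringer import CurveComparison
        for i in range(1, 11):
            resseq = 370 + i  # 371..380; 375-380 inside the excluded loop
            comps.append(CurveComparison(("A", resseq, ""), "SER", 0.2, True))
        res = flag_changed_residues(comps, threshold=0.5, exclude=[(375, 383)])
        assert res["n_flagged"] == 4  # 371, 372, 373, 374

    def test_planted_flips_recovered_exactly(self, toy):
        """Low-noise maps: flagged set equals the planted χ1-flip set."""
        # default χ1s are 180, 62, -65, 62 at these residues: each target flips
        flips = [("A", 2, ""), ("A", 5, ""), ("A", 11, ""), ("A", 15, "")]
        targets = {("A", 2, ""): 62.0, ("A", 5, ""): 180.0,
                   ("A", 11, ""): 62.0, ("A", 15, ""): 180.0}
        reqs = [{"kind": "rotamer-flip", "residue": rid,
                 "target_chi1": targets[rid]} for rid in flips]
        pert, truth = perturb(toy, reqs, seed=21)
        m0 = simulate_map(toy, 0.3, noise_sigma=0.1, seed=31)
        m1 = simulate_map(pert, 0.3, noise_sigma=0.1, seed=32)
        comps = compare_curves(ringer_curves(m0, toy), ringer_curves(m1, pert))
        res = flag_changed_residues(comps)
        assert set(res["flagged"]) == truth.ids_for("ringer_cc") == set(flips)


class TestFindPeaks:
    def test_single_gaussian_bump(self):
        angles = np.arange(0.0, 360.0, 10.0)
        v = np.exp(-0.5 * ((angles - 180) / 30.0) ** 2)
        peaks = find_peaks(_curve(v))
        assert len(peaks) == 1
        assert peaks[0][0] == 180.0

    def test_flat_below_threshold_empty(self):
        assert find_peaks(_curve(np.full(36, 0.1))) == []

    def test_two_bumps_match_exhaustive_scan(self, rng):
        angles = np.arange(0.0, 360.0, 10.0)
        v = (np.exp(-0.5 * ((angles - 60) / 25.0) ** 2)
             + 0.7 * np.exp(-0.5 * ((angles - 200) / 25.0) ** 2))
        c = _curve(v)
        peaks = find_peaks(c, min_sigma=0.3)
        brute = [(float(angles[i]), float(v[i])) for i in range(36)
                 if v[i] > 0.3 and v[i] >= v[(i - 1) % 36] and v[i] > v[(i + 1) % 36]]
        brute.sort(key=lambda p: -p[1])
        assert peaks == brute
        assert [p[0] for p in peaks] == [60.0, 200.0]
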