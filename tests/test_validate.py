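import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from clashfix.structures import BondGraph, infer_topology
from clashfix.validate import (
    IDEAL_GEOMETRY,
    backbone_rmsd,
    detect_clashes,
    geometry_outliers,
    hbond_survey,
    kabsch_superpose,
    load_survey_table,
    sas_volume,
    survey_stats,
)
from clashfix.synthdata import make_toy_chain

from conftest import make_atoms, random_rotation


class TestClashDetection:
    @staticmethod
    def _pair_structure(overlap):
        # two oxygens (contact 2.80 A) plus a distant H to satisfy the
        # hydrogen-complete protocol
        d = 2.80 - overlap
        s = make_atoms(
            [
                ("O", "O", (0.0, 0.0, 0.0), 1),
                ("O", "O", (d, 0.0, 0.0), 2),
                ("C", "C", (30.0, 0.0, 0.0), 3),
                ("H", "H", (31.09, 0.0, 0.0), 3),
            ]
        )
        return s, infer_topology(s)

    def test_threshold_boundary(self):
        s, g = self._pair_structure(0.39)
        assert detect_clashes(s, g).clashes == []
        s, g = self._pair_structure(0.40)
        report = detect_clashes(s, g)
        assert len(report.clashes) == 1
        assert report.clashes[0].overlap == pytest.approx(0.40)

    def test_bonded_pair_never_clashes(self, two_atom_factory):
        s, g = two_atom_factory("O", "O", 1.2)
        assert g.bonded(0, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert detect_clashes(s, g).clashes == []

    def test_no_hydrogen_warning(self, two_atom_factory):
        s, g = two_atom_factory("O", "O", 5.0)
        with pytest.warns(UserWarning, match="no hydrogens"):
            detect_clashes(s, g)

    def test_clashscore_normalization_identity(self):
        s, g, ledger = make_toy_chain(20, planted_clashes=2, overlaps=(0.5, 0.45))
        report = detect_clashes(s, g)
        assert report.clashscore == pytest.approx(1000.0 * len(report.clashes) / len(s))
        assert len(report.clashes) == 2

    def test_hbond_pairs_excluded(self):
        # N-H donor pointing straight at an acceptor O at 1.9 A
        s = make_atoms(
            [
                ("N", "N", (0.0, 0.0, 0.0), 1),
                ("H", "H", (1.01, 0.0, 0.0), 1),
                ("O", "O", (2.91, 0.0, 0.0), 2),
                ("C", "C", (2.91, 1.23, 0.0), 2),
            ]
        )
        g = BondGraph(4, [(0, 1), (2, 3)])
        with_excl = detect_clashes(s, g, hbond_exclusions=True)
        without = detect_clashes(s, g, hbond_exclusions=False)
        ho_pairs = [
            (c.i, c.j) for c in without.clashes if {s.elements[c.i], s.elements[c.j]} == {"H", "O"}
        ]
        assert (1, 2) in ho_pairs
        assert (1, 2) not in [(c.i, c.j) for c in with_excl.clashes]

    def test_clashscore_rigid_motion_and_order_invariant(self):
        s, g, _ = make_toy_chain(8, planted_clashes=2, overlaps=(0.5, 0.6))
        score0 = detect_clashes(s, g).clashscore
        rng = np.random.default_rng(3)
        rot = random_rotation(rng)
        moved = s.with_coords(s.coords @ rot.T + np.array([-4.0, 2.0, 9.0]))
        assert detect_clashes(moved, g).clashscore == pytest.approx(score0)


class TestBackboneRmsd:
    def test_identical_structures(self, toy_chain):
        s, _ = toy_chain
        assert backbone_rmsd(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_gives_zero(self, toy_chain):
        s, _ = toy_chain
        rng = np.random.default_rng(1)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        theta = math.radians(37.0)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + math.sin(theta) * k + (1 - math.cos(theta)) * (k @ k)
        moved = s.with_coords(s.coords @ rot.T + np.array([5.0, -3.0, 2.0]))
        assert backbone_rmsd(s, moved) < 1e-9

    def test_symmetry(self, toy_chain):
        s, _ = toy_chain
        rng = np.random.default_rng(2)
        moved = s.with_coords(s.coords + 0.1 * rng.normal(size=(len(s), 3)))
        assert backbone_rmsd(s, moved) == pytest.approx(backbone_rmsd(moved, s), rel=1e-10)

    def test_single_displaced_atom_bound(self, toy_chain):
        s, _ = toy_chain
        coords = s.coords
        # displace one backbone nitrogen by d
        idx = next(i for i, a in enumerate(s.atoms) if a.name == "N")
        d = 0.8
        coords[idx] += np.array([d, 0, 0])
        moved = s.with_coords(coords)
        n_bb = sum(1 for a in s.atoms if a.name in ("N", "CA", "C"))
        assert backbone_rmsd(s, moved) <= d / math.sqrt(n_bb) + 1e-9

    def test_mismatch_reports_first_difference(self, toy_chain):
        s, _ = toy_chain
        other, _, _ = make_toy_chain(5)
        with pytest.raises(ValueError, match="mismatch"):
            backbone_rmsd(s, other)

    def test_agrees_with_numeric_superposition_oracle(self, toy_chain):
        """Kabsch result matches an independent numeric minimization over
        rotation vectors (multi-start Nelder-Mead) to 1e-6 A."""
        s, _ = toy_chain
        bb = np.array([a.xyz for a in s.atoms if a.name in ("N", "CA", "C")])
        rng = np.random.default_rng(0)

        def oracle_rmsd(p, q):
            pc = p - p.mean(axis=0)
            qc = q - q.mean(axis=0)

            def cost(rv):
                theta = np.linalg.norm(rv)
                if theta < 1e-12:
                    rot = np.eye(3)
                else:
                    k = rv / theta
                    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
                    rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
                return float(np.sqrt(np.mean(np.sum(((rot @ qc.T).T - pc) ** 2, axis=1))))

            best = np.inf
            for start in np.vstack([np.zeros(3), rng.uniform(-np.pi, np.pi, size=(11, 3))]):
                res = minimize(cost, start, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
                best = min(best, res.fun)
            return best

        for trial in range(50):
            rot = random_rotation(rng)
            noisy = bb @ rot.T + rng.normal(size=3) + 0.15 * rng.normal(size=bb.shape)
            _, _, rmsd = kabsch_superpose(bb, noisy)
            assert rmsd == pytest.approx(oracle_rmsd(bb, noisy), abs=1e-6)

    def test_proper_rotation_enforced(self):
        # a mirrored point set must not be matched by a reflection
        rng = np.random.default_rng(5)
        p = rng.normal(size=(10, 3))
        q = p * np.array([-1.0, 1.0, 1.0])
        r, _, rmsd = kabsch_superpose(p, q)
        assert np.linalg.det(r) == pytest.approx(1.0)
        assert rmsd > 0.1


class TestSasVolume:
    def test_single_sphere(self):
        s = make_atoms([("X", "C", (0, 0, 0))])
        radii = np.array([1.5])
        vol = sas_volume(s, probe_radius=1.4, grid_spacing=0.2, radii=radii)
        exact = 4.0 / 3.0 * math.pi * 2.9**3
        assert vol == pytest.approx(exact, rel=0.02)

    def test_distant_spheres_additive(self):
        s1 = make_atoms([("C", "C", (0, 0, 0))])
        s2 = make_atoms([("C", "C", (0, 0, 0)), ("C", "C", (100.0, 0, 0))])
        v1 = sas_volume(s1, 1.4, 0.3)
        v2 = sas_volume(s2, 1.4, 0.3)
        assert v2 == pytest.approx(2 * v1, rel=0.02)

    def test_two_sphere_union_matches_lens_formula(self):
        r = 1.75 + 1.4
        d = 2.0
        s = make_atoms([("C", "C", (0, 0, 0)), ("C", "C", (d, 0, 0))])
        vol = sas_volume(s, 1.4, 0.15)
        sphere = 4.0 / 3.0 * math.pi * r**3
        lens = math.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0
        assert vol == pytest.approx(2 * sphere - lens, rel=0.02)

    def test_union_volume_monotone_in_separation(self):
        vols = []
        for d in (1.0, 2.0, 3.0, 4.0):
            s = make_atoms([("C", "C", (0, 0, 0)), ("C", "C", (d, 0, 0))])
            vols.append(sas_volume(s, 1.4, 0.2))
        assert all(v1 <= v2 + 1e-9 for v1, v2 in zip(vols, vols[1:]))


class TestHBondSurvey:
    @staticmethod
    def _water_on_acceptor(d):
        # water with both hydrogens at distance d from one peptide oxygen
        half = math.radians(104.5 / 2)
        oh = 0.958
        hx, hy = oh * math.cos(half), oh * math.sin(half)
        # acceptor placed on the bisector, equidistant from both hydrogens
        acc_x = hx + math.sqrt(max(d**2 - hy**2, 0.0))
        s = make_atoms(
            [
                ("O", "O", (0.0, 0.0, 0.0), 1),
                ("H1", "H", (hx, hy, 0.0), 1),
                ("H2", "H", (hx, -hy, 0.0), 1),
                ("O", "O", (acc_x, 0.0, 0.0), 2),
                ("C", "C", (acc_x + 1.23, 0.0, 0.0), 2),
            ]
        )
        g = BondGraph(5, [(0, 1), (0, 2), (3, 4)])
        return s, g

    def test_double_donation_flagged(self):
        s, g = self._water_on_acceptor(2.01)
        survey = hbond_survey(s, g)
        assert survey.double_donations == [(0, 3)]
        assert survey.n_contacts == 2
        bin_idx = int((2.01 - 1.5) / 0.1)
        assert survey.counts[bin_idx] == 2

    def test_no_contacts_empty_survey(self):
        s, g = self._water_on_acceptor(2.01)
        far = s.with_coords(s.coords + np.array([[0, 0, 0]] * 3 + [[30, 0, 0]] * 2))
        survey = hbond_survey(far, g)
        assert survey.n_contacts == 0
        assert survey.double_donations == []
        assert survey.counts.sum() == 0

    def test_single_contact_binned(self):
        s = make_atoms(
            [
                ("O", "O", (0, 0, 0), 1),
                ("H", "H", (0.958, 0, 0), 1),
                ("O", "O", (0.958 + 1.85, 0, 0), 2),
                ("C", "C", (0.958 + 1.85 + 1.4, 0, 0), 2),
            ]
        )
        g = BondGraph(4, [(0, 1), (2, 3)])
        survey = hbond_survey(s, g)
        assert survey.n_contacts == 1
        assert survey.counts[int((1.85 - 1.5) / 0.1)] == 1
        assert survey.counts.sum() == 1


class TestGeometryOutliers:
    @staticmethod
    def _his_fragment(stretch=1.0):
        d = 1.321 * stretch
        s = make_atoms([("ND1", "N", (0, 0, 0)), ("CE1", "C", (d, 0, 0))])
        for a in s.atoms:
            a.residue_name = "HIS"
        g = BondGraph(2, [(0, 1)])
        return s, g

    def test_stretched_his_bond_flagged(self):
        s, g = self._his_fragment(1.03)  # 3% too long
        out = geometry_outliers(s, g)
        assert len(out) == 1
        assert out[0].kind == "bond"
        assert out[0].deviation == pytest.approx(0.03 * 1.321, abs=1e-9)

    def test_exact_geometry_clean(self):
        s, g = self._his_fragment(1.0)
        assert geometry_outliers(s, g) == []

    def test_closed_angle_flagged(self):
        ref = 113.8
        theta = math.radians(ref - 6.0)
        s = make_atoms(
            [
                ("CA", "C", (1.52, 0, 0)),
                ("CB", "C", (0, 0, 0)),
                ("CG", "C", (1.52 * math.cos(theta), 1.52 * math.sin(theta), 0)),
            ]
        )
        g = BondGraph(3, [(0, 1), (1, 2)])
        out = geometry_outliers(s, g)
        assert len(out) == 1
        assert out[0].kind == "angle"
        assert out[0].deviation == pytest.approx(-6.0, abs=1e-6)

    def test_clean_toy_chain_has_no_outliers(self, toy_chain):
        s, g = toy_chain
        assert geometry_outliers(s, g) == []


class TestSurveyStats:
    def test_mean_and_exclusions(self):
        t = pd.DataFrame({"v": [1.0, 2.0, 6.0]}, index=["a", "b", "c"])
        assert survey_stats(t, "v", "mean") == pytest.approx(3.0)
        assert survey_stats(t, "v", "mean", exclude_rows=["c"]) == pytest.approx(1.5)
        with pytest.raises(ValueError):
            survey_stats(t, "v", "mean", exclude_rows=["a", "b", "c"])

    def test_count_weighted_mean(self):
        t = pd.DataFrame({"v": [1.0, 3.0], "n": [1, 3]})
        assert survey_stats(t, "v", "count_weighted_mean", counts_column="n") == pytest.approx(2.5)

    def test_normal_sample_kurtosis_near_zero(self):
        rng = np.random.default_rng(123)
        t = pd.DataFrame({"v": rng.standard_normal(10**6)})
        assert abs(survey_stats(t, "v", "excess_kurtosis")) < 0.02

    def test_unknown_inputs_rejected(self):
        t = pd.DataFrame({"v": [1.0]})
        with pytest.raises(KeyError):
            survey_stats(t, "missing", "mean")
        with pytest.raises(ValueError):
            survey_stats(t, "v", "median")


def test_shipped_tables_load_and_are_rectangular():
    shapes = {
        "interaction_sets": (7, 4),
        "protein_clashscores": (21, 5),
        "protein_backbone_rmsd": (21, 3),
        "protein_volumes": (21, 7),
    }
    for name, shape in shapes.items():
        t = load_survey_table(name)
        assert t.shape == shape
    with pytest.raises(KeyError):
        load_survey_table("nonexistent")
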