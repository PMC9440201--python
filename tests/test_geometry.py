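"""Domain splits, orientation CVs, salt bridges, restraint energies."""

import numpy as np
import pandas as pd
import pytest

import deerfit as df
from deerfit.geometry import Restraint, RestraintSet
from deerfit.simulate import generate_saltbridge_trajectory


def point_structure(points, resnames=None):
    """One CA pseudo-atom per residue at the given coordinates."""
    rows = []
    for i in range(len(points)):
        rows.append(
            {"chain": "A", "resid": i + 1,
             "resname": (resnames or {}).get(i + 1, "ALA"),
             "name": "CA", "element": "C"}
        )
    return df.StructureModel(pd.DataFrame(rows), np.asarray(points, float)[None])


class TestSplitDomains:
    def test_even_by_sequence(self, toy_bundle):
        split = df.split_domains(toy_bundle, (1, 24), (25, 48))
        assert len(split.n_intra) == 12 and len(split.n_extra) == 12

    def test_odd_count_extra_in_first_half(self, toy_bundle):
        split = df.split_domains(toy_bundle, (1, 25), (26, 48))
        assert len(split.n_intra) == 13 and len(split.n_extra) == 12

    def test_by_z_matches_enumeration(self):
        # helix along z: residues with CA z below the median go intracellular
        z = np.arange(0.0, 41.0, 2.0)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        pts2 = pts + [10.0, 0.0, 0.0]
        s = point_structure(np.vstack([pts, pts2]))
        split = df.split_domains(s, (1, len(z)), (len(z) + 1, 2 * len(z)), mode="by-z")
        median = np.median(z)
        expected = [i + 1 for i in range(len(z)) if z[i] < median]
        assert split.n_intra == expected

    def test_overlapping_ranges_rejected(self, toy_bundle):
        with pytest.raises(ValueError, match="overlap"):
            df.split_domains(toy_bundle, (1, 30), (25, 48))


class TestAlphaBeta:
    def test_collinear_is_180(self):
        # N-intra at -x, C-intra at +x, extra halves at the origin vertex
        pts = [[-10, 0, 0], [0, 0, 5], [0, 0, -5], [10, 0, 0]]
        s = point_structure(pts)
        split = df.DomainSplit(n_intra=[1], n_extra=[2], c_intra=[4], c_extra=[3])
        cv = df.compute_alpha_beta(s, split)
        assert cv.alpha == pytest.approx(180.0, abs=1e-9)

    def test_right_angle_is_90(self):
        pts = [[10, 0, 0], [0, 0, 0], [0, 0, 1e-6], [0, 10, 0]]
        s = point_structure(pts)
        split = df.DomainSplit(n_intra=[1], n_extra=[2], c_intra=[4], c_extra=[3])
        cv = df.compute_alpha_beta(s, split)
        assert cv.alpha == pytest.approx(90.0, abs=1e-6)

    def test_matches_independent_com_arccos(self, toy_bundle):
        split = df.split_domains(toy_bundle, (1, 24), (25, 48))
        cv = df.compute_alpha_beta(toy_bundle, split)

        # independent all-atom mass-weighted COM + arccos implementation
        masses = {"C": 12.011, "N": 14.007, "O": 15.999}

        def com(resids):
            sel = toy_bundle.atoms["resid"].isin(resids).to_numpy()
            m = np.array([masses[e] for e in toy_bundle.atoms.loc[sel, "element"]])
            return (m[:, None] * toy_bundle.coords[0, sel]).sum(0) / m.sum()

        def ang(a, v, b):
            u, w = a - v, b - v
            return np.degrees(
                np.arccos(u @ w / (np.linalg.norm(u) * np.linalg.norm(w)))
            )

        alpha = ang(com(split.n_intra), com(split.n_extra + split.c_extra),
                    com(split.c_intra))
        beta = ang(com(split.n_extra), com(split.n_intra + split.c_intra),
                   com(split.c_extra))
        assert cv.alpha == pytest.approx(alpha, abs=1e-9)
        assert cv.beta == pytest.approx(beta, abs=1e-9)

    def test_rigid_body_invariance(self, toy_bundle):
        from scipy.spatial.transform import Rotation

        split = df.split_domains(toy_bundle, (1, 24), (25, 48))
        cv0 = df.compute_alpha_beta(toy_bundle, split)
        R = Rotation.from_euler("xyz", [17, -40, 120], degrees=True).as_matrix()
        moved = df.StructureModel(
            toy_bundle.atoms.copy(),
            (toy_bundle.coords[0] @ R.T + np.array([3.0, -8.0, 2.0]))[None],
        )
        cv1 = df.compute_alpha_beta(moved, split)
        assert cv1.alpha == pytest.approx(cv0.alpha, abs=1e-9)
        assert cv1.beta == pytest.approx(cv0.beta, abs=1e-9)

    def test_geometric_equals_mass_weighted_for_equal_masses(self):
        rng = np.random.default_rng(2)
        s = point_structure(rng.normal(0, 10, (12, 3)))  # all carbon
        split = df.DomainSplit(
            n_intra=[1, 2, 3], n_extra=[4, 5, 6], c_intra=[7, 8, 9],
            c_extra=[10, 11, 12],
        )
        a = df.compute_alpha_beta(s, split, mass_weighted=True)
        b = df.compute_alpha_beta(s, split, mass_weighted=False)
        assert a.alpha == pytest.approx(b.alpha, abs=1e-9)

    def test_degenerate_geometry_errors(self):
        pts = [[0, 0, 0], [0, 0, 0], [0, 0, 0], [1, 0, 0]]
        s = point_structure(pts)
        split = df.DomainSplit(n_intra=[1], n_extra=[2], c_intra=[4], c_extra=[3])
        with pytest.raises(ValueError, match="degenerate"):
            df.compute_alpha_beta(s, split)


class TestSaltBridge:
    def test_static_trajectory(self):
        traj, _ = generate_saltbridge_trajectory(10, 3.0, 8.0, 10, jitter=0.0)
        pair = df.SaltBridgePair(("A", 2), ("A", 1), formed_cutoff=4.0)
        out = df.salt_bridge_series(traj, pair, window=3)
        assert np.allclose(out["distance"], 3.0)
        assert np.allclose(out["moving_avg"], 3.0)
        assert out.attrs["formed_fraction"] == 1.0

    def test_switch_schedule(self):
        traj, truth = generate_saltbridge_trajectory(40, 3.0, 8.0, 20, jitter=0.2,
                                                     seed=3)
        pair = df.SaltBridgePair(("A", 2), ("A", 1), formed_cutoff=4.0)
        out = df.salt_bridge_series(traj, pair, window=5)
        assert out.attrs["formed_fraction"] == pytest.approx(0.5, abs=1 / 80)
        assert list(out["formed"]) == [d < 4.0 for d in truth["offsets"]]

    def test_window_one_is_identity(self):
        traj, _ = generate_saltbridge_trajectory(15, 3.0, 8.0, 7, jitter=0.3, seed=1)
        pair = df.SaltBridgePair(("A", 2), ("A", 1))
        out = df.salt_bridge_series(traj, pair, window=1)
        assert np.allclose(out["moving_avg"], out["distance"])

    def test_moving_average_commutes_with_offset(self):
        traj, _ = generate_saltbridge_trajectory(20, 3.0, 8.0, 10, jitter=0.3, seed=2)
        pair = df.SaltBridgePair(("A", 2), ("A", 1))
        out = df.salt_bridge_series(traj, pair, window=4)
        shifted = df.StructureModel(traj.atoms.copy(), traj.coords.copy())
        # offsetting all donor atoms along +x adds a constant to the distance
        don = shifted.residue_mask("A", 2)
        shifted.coords[:, don, 0] += 2.0
        out2 = df.salt_bridge_series(shifted, pair, window=4)
        assert np.allclose(out2["moving_avg"], out["moving_avg"] + 2.0, atol=1e-9)

    def test_invalid_atoms_rejected(self):
        with pytest.raises(ValueError, match="donor atoms"):
            df.SaltBridgePair(("A", 2), ("A", 1), donor_atoms=["CA"])


class TestRestraintEnergy:
    def test_zero_at_targets(self):
        rs = RestraintSet([Restraint("a", "b", 3.0, 10.0)])
        E, terms = df.restraint_energy([3.0], rs)
        assert E == 0.0

    def test_half_k_convention_closed_form(self):
        # 1 Å displacement at k = 10 kcal/mol/Å²: E = ½·10·1² = 5 kcal/mol
        rs = RestraintSet([Restraint("a", "b", 3.0, 10.0)])
        E, _ = df.restraint_energy([3.1], rs)
        assert E == pytest.approx(5.0, abs=1e-9)
        E_full, _ = df.restraint_energy([3.1], rs, half_factor=False)
        assert E_full == pytest.approx(10.0, abs=1e-9)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(7)
        targets = rng.uniform(2.0, 6.0, 5)
        ks = rng.uniform(1.0, 20.0, 5)
        disp = rng.normal(0.0, 0.1, 5)
        rs = RestraintSet(
            [Restraint(f"s{i}", f"t{i}", targets[i], ks[i]) for i in range(5)]
        )
        E, terms = df.restraint_energy(targets + disp, rs)
        oracle = sum(
            0.5 * ks[i] * (disp[i] * 10.0) ** 2 for i in range(5)
        )
        assert E == pytest.approx(oracle, abs=1e-12)

    def test_quadratic_scaling(self):
        rs = RestraintSet([Restraint("a", "b", 3.0, 10.0),
                           Restraint("c", "d", 4.0, 5.0)])
        E1, _ = df.restraint_energy([3.05, 4.1], rs)
        E2, _ = df.restraint_energy([3.10, 4.2], rs)
        assert E2 == pytest.approx(4.0 * E1, rel=1e-12)

    def test_misaligned_lists_rejected(self):
        rs = RestraintSet([Restraint("a", "b", 3.0, 10.0)])
        with pytest.raises(ValueError, match="misaligned"):
            df.restraint_energy([3.0, 4.0], rs)
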