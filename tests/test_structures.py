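"""PDB handling, accessible-volume label clouds, distance prediction."""

import numpy as np
import pandas as pd
import pytest

import deerfit as df
from deerfit.structures import LabelSite, write_pdb


def two_residue_fixture(offset=(30.0, 0.0, 0.0)):
    """Two isolated labelled residues with ideal N/CA/CB frames."""
    rows, coords = [], []
    for resid, origin in ((1, np.zeros(3)), (2, np.asarray(offset, float))):
        for name, elem, xyz in (
            ("N", "N", origin + [-1.2, 0.8, 0.0]),
            ("CA", "C", origin),
            ("CB", "C", origin + [1.53, 0.0, 0.0]),
        ):
            rows.append(
                {"chain": "A", "resid": resid, "resname": "CYS",
                 "name": name, "element": elem}
            )
            coords.append(xyz)
    return df.StructureModel(pd.DataFrame(rows), np.asarray(coords)[None])


class TestReadWrite:
    def test_roundtrip_single_model(self, tmp_path):
        s = two_residue_fixture()
        path = tmp_path / "fix.pdb"
        write_pdb(s, path)
        back = df.read_structure(path)
        assert len(back.atoms) == len(s.atoms)
        assert np.allclose(back.coords, s.coords, atol=1e-3)
        assert list(back.atoms["resid"]) == list(s.atoms["resid"])

    def test_multi_model_becomes_trajectory(self, tmp_path):
        s = two_residue_fixture()
        traj = df.StructureModel(s.atoms, np.repeat(s.coords, 3, axis=0))
        path = tmp_path / "traj.pdb"
        write_pdb(traj, path)
        back = df.read_structure(path)
        assert back.n_models == 3

    def test_missing_cb_names_site(self, tmp_path):
        s = two_residue_fixture()
        keep = ~((s.atoms["resid"] == 2) & (s.atoms["name"] == "CB")).to_numpy()
        s2 = df.StructureModel(
            s.atoms[keep].reset_index(drop=True), s.coords[:, keep]
        )
        with pytest.raises(ValueError, match="A:2.*CB|CB"):
            LabelSite.from_structure(s2, "A", 2)

    def test_glycine_rejected(self):
        s = two_residue_fixture()
        s.atoms.loc[s.atoms["resid"] == 1, "resname"] = "GLY"
        with pytest.raises(ValueError, match="glycine"):
            LabelSite.from_structure(s, "A", 1)


class TestLabelCloud:
    def test_isolated_site_geometry(self):
        s = two_residue_fixture()
        cloud = df.build_label_cloud(s, ("A", 1), tether_length=7.0, seed=0,
                                     n_samples=500)
        assert len(cloud.positions) == 500  # nothing to clash with
        cb = s.coords[0, s.atom_index("A", 1, "CB")]
        dists = np.linalg.norm(cloud.positions - cb, axis=1)
        assert np.allclose(dists, 7.0, atol=1e-9)
        assert cloud.weights.sum() == pytest.approx(1.0)

    def test_seed_determinism(self):
        s = two_residue_fixture()
        a = df.build_label_cloud(s, ("A", 1), seed=4)
        b = df.build_label_cloud(s, ("A", 1), seed=4)
        assert np.array_equal(a.positions, b.positions)

    def test_wall_clash_matches_enumeration(self):
        # plane of atoms 3 Å from CB on the +y side: survivors must match a
        # brute-force distance check over the identical candidate set
        s = two_residue_fixture()
        cb = s.coords[0, s.atom_index("A", 1, "CB")]
        wall_rows, wall_coords = [], []
        span = np.arange(-10, 10.5, 1.0)
        for i, x in enumerate(span):
            for j, z in enumerate(span):
                wall_rows.append(
                    {"chain": "B", "resid": 100 + i * len(span) + j,
                     "resname": "WAL", "name": "C", "element": "C"}
                )
                wall_coords.append(cb + np.array([x, 3.0, z]))
        atoms = pd.concat([s.atoms, pd.DataFrame(wall_rows)], ignore_index=True)
        coords = np.concatenate([s.coords[0], np.asarray(wall_coords)])[None]
        walled = df.StructureModel(atoms, coords)

        cutoff = 2.5
        cloud_free = df.build_label_cloud(s, ("A", 1), seed=11, n_samples=2000,
                                          clash_cutoff=cutoff)
        cloud = df.build_label_cloud(walled, ("A", 1), seed=11, n_samples=2000,
                                     clash_cutoff=cutoff)
        # brute-force enumeration over the same candidate set
        from scipy.spatial.distance import cdist

        cand = cloud_free.positions  # same seed → same candidates
        dmin = cdist(cand, np.asarray(wall_coords)).min(axis=1)
        expected = cand[dmin >= cutoff]
        assert len(cloud.positions) == len(expected)
        assert np.allclose(np.sort(cloud.positions, axis=0),
                           np.sort(expected, axis=0), atol=1e-9)

    def test_cutoff_monotonicity(self):
        s = two_residue_fixture(offset=(9.0, 0.0, 0.0))
        counts = [
            len(df.build_label_cloud(s, ("A", 1), seed=3, clash_cutoff=c).positions)
            for c in (1.0, 2.5, 4.0)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_buried_site_errors(self):
        s = two_residue_fixture(offset=(3.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="buried"):
            df.build_label_cloud(s, ("A", 1), clash_cutoff=20.0)


class TestPredictDistribution:
    def test_two_point_clouds(self):
        c1 = df.LabelCloud(np.array([[0.0, 0.0, 0.0]]))
        c2 = df.LabelCloud(np.array([[30.0, 0.0, 0.0]]))
        dist = df.predict_distribution(c1, c2, smoothing_sigma=0.05)
        r = dist.grid.values
        assert np.trapezoid(dist.density, r) == pytest.approx(1.0, abs=1e-6)
        assert r[np.argmax(dist.density)] == pytest.approx(3.0, abs=0.02)
        assert dist.mean == pytest.approx(3.0, abs=1e-3)

    def test_argument_symmetry(self):
        rng = np.random.default_rng(0)
        c1 = df.LabelCloud(rng.normal(0, 2, (40, 3)))
        c2 = df.LabelCloud(rng.normal(0, 2, (40, 3)) + [35, 0, 0])
        d12 = df.predict_distribution(c1, c2)
        d21 = df.predict_distribution(c2, c1)
        assert np.allclose(d12.density, d21.density, atol=1e-12)

    def test_mean_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        c1 = df.LabelCloud(rng.normal(0, 3, (100, 3)))
        c2 = df.LabelCloud(rng.normal(0, 3, (100, 3)) + [40, 0, 0])
        dist = df.predict_distribution(c1, c2)
        # brute-force weighted mean pairwise distance
        acc = 0.0
        for i, p in enumerate(c1.positions):
            for j, q in enumerate(c2.positions):
                acc += c1.weights[i] * c2.weights[j] * np.linalg.norm(p - q)
        assert dist.mean == pytest.approx(0.1 * acc, abs=1e-3)

    def test_grid_range_error(self):
        c1 = df.LabelCloud(np.array([[0.0, 0.0, 0.0]]))
        c2 = df.LabelCloud(np.array([[100.0, 0.0, 0.0]]))  # 10 nm > grid max
        with pytest.raises(ValueError, match="does not cover"):
            df.predict_distribution(c1, c2)

    def test_rigid_body_invariance(self):
        s = two_residue_fixture()
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [31.0, -12.0, 77.0], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        moved = df.StructureModel(
            s.atoms.copy(), (s.coords[0] @ R.T + shift)[None]
        )
        kwargs = dict(seed=5, n_samples=400)
        d1 = df.predict_distribution(
            df.build_label_cloud(s, ("A", 1), **kwargs),
            df.build_label_cloud(s, ("A", 2), **kwargs),
        )
        d2 = df.predict_distribution(
            df.build_label_cloud(moved, ("A", 1), **kwargs),
            df.build_label_cloud(moved, ("A", 2), **kwargs),
        )
        assert np.allclose(d1.density, d2.density, atol=1e-9)
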