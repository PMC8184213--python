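"""Trajectory-ensemble metrics against brute-force oracles and
constructions with known answers."""

import numpy as np
import pandas as pd
import pytest

from pisawheel import (ContactSpec, HBondSpec, TrajectoryEnsemble,
                       backbone_pca, contact_frequency, hbond_table,
                       helix_axis_and_topology, kld_convergence,
                       project_structure, tilt_correlation_map)
from pisawheel.ensemble import per_frame_tilts
from pisawheel.synthetic import SyntheticSpec, make_helix_ensemble


def _single_helix(n_frames=1, tilt=0.0, seed=0):
    spec = SyntheticSpec(seed=seed, n_frames=n_frames, tilt_means=(tilt,),
                         tilt_sds=(0.0,))
    return make_helix_ensemble(spec)


def _point_ensemble(coords, names=None, resids=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    atoms = pd.DataFrame({
        "name": names or ["C"] * n,
        "resid": resids if resids is not None else np.arange(1, n + 1),
        "resname": ["UNK"] * n,
        "chain": ["A"] * n,
        "element": [(names or ["C"] * n)[i][0] for i in range(n)],
    })
    return TrajectoryEnsemble(coordinates=coords, atoms=atoms)


# ---------------------------------------------------------------------------
# helix topology from coordinates

class TestHelixTopology:
    def test_axial_helix_has_zero_tilt(self):
        se = _single_helix(tilt=0.0)
        th, _ = helix_axis_and_topology(se.ensemble, np.arange(1, 21),
                                        chain="A")
        assert th == pytest.approx(0.0, abs=1e-6)

    def test_rotated_helix_recovers_tilt(self):
        se = _single_helix(tilt=30.0)
        th, _ = helix_axis_and_topology(se.ensemble, np.arange(1, 21),
                                        chain="A")
        assert th == pytest.approx(30.0, abs=0.5)

    def test_random_rotation_matches_linear_algebra_oracle(self, rng):
        from scipy.spatial.transform import Rotation
        se = _single_helix(tilt=0.0)
        ens = se.ensemble
        axis0 = np.array([0.0, 0.0, 1.0])
        for _ in range(10):
            rot = Rotation.random(random_state=rng).as_matrix()
            rotated = TrajectoryEnsemble(
                coordinates=ens.coordinates @ rot.T, atoms=ens.atoms)
            th, _ = helix_axis_and_topology(rotated, np.arange(1, 21),
                                            chain="A")
            want = np.degrees(np.arccos(np.clip((rot @ axis0)[2], -1, 1)))
            assert th == pytest.approx(want, abs=1e-6)

    def test_too_few_residues_rejected(self):
        se = _single_helix()
        with pytest.raises(ValueError, match="at least 7"):
            helix_axis_and_topology(se.ensemble, np.arange(1, 6), chain="A")

    def test_axial_rho_is_undefined(self):
        se = _single_helix(tilt=0.0)
        _, rho = helix_axis_and_topology(se.ensemble, np.arange(1, 21),
                                         chain="A")
        assert np.isnan(rho)

    def test_axial_rotation_shifts_rho_with_package_handedness(self):
        # rotating the helix about its own axis by +g (right-handed, N->C)
        # must decrease the reported rho by g: same gauge as the wheel fit
        se = _single_helix(tilt=30.0)
        ens = se.ensemble
        g = 25.0
        a = np.deg2rad(g)
        rz = np.array([[np.cos(a), -np.sin(a), 0.0],
                       [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]])
        # rotate about the helix axis: undo the tilt, spin, re-tilt
        b = np.deg2rad(30.0)
        ry = np.array([[np.cos(b), 0.0, np.sin(b)], [0.0, 1.0, 0.0],
                       [-np.sin(b), 0.0, np.cos(b)]])
        spun = TrajectoryEnsemble(
            coordinates=ens.coordinates @ (ry @ rz @ ry.T).T,
            atoms=ens.atoms)
        _, rho0 = helix_axis_and_topology(ens, np.arange(1, 21), chain="A",
                                          reference_residue=10)
        _, rho1 = helix_axis_and_topology(spun, np.arange(1, 21), chain="A",
                                          reference_residue=10)
        assert (rho0 - rho1) % 360.0 == pytest.approx(g, abs=1e-6)


# ---------------------------------------------------------------------------
# contacts

class TestContacts:
    def test_pair_inside_cutoff_counts_every_frame(self):
        ens = _point_ensemble(np.tile([[0, 0, 0], [3.4, 0, 0]], (5, 1, 1)))
        out = contact_frequency(ens, [0], [1])
        assert out.loc[1, "fraction"] == 1.0
        assert out.loc[1, "mean_contacts"] == 1.0

    def test_pair_outside_cutoff_never_counts(self):
        ens = _point_ensemble(np.tile([[0, 0, 0], [3.6, 0, 0]], (5, 1, 1)))
        out = contact_frequency(ens, [0], [1])
        assert out.loc[1, "fraction"] == 0.0

    def test_empty_selection_rejected(self):
        ens = _point_ensemble(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError, match="empty"):
            contact_frequency(ens, [], [1])

    @pytest.mark.parametrize("n_a,n_b", [(12, 9), (260, 180)])
    def test_matches_brute_force_double_loop(self, rng, n_a, n_b):
        # the second size triggers the tree-accelerated path; both must be
        # identical to the O(N^2) reference
        n_frames = 100 if n_a < 50 else 3
        coords = rng.uniform(0, 12, size=(n_frames, n_a + n_b, 3))
        resids = np.concatenate([np.repeat(np.arange(1, 5), n_a // 4)[:n_a],
                                 np.full(n_b, 99)])
        ens = _point_ensemble(coords, resids=resids)
        ga, gb = np.arange(n_a), np.arange(n_a, n_a + n_b)
        out = contact_frequency(ens, ga, gb, ContactSpec(cutoff=3.5))
        for r in np.unique(resids[:n_a]):
            sel = np.flatnonzero(resids[:n_a] == r)
            frac = cnt = 0.0
            for f in range(n_frames):
                c = 0
                for i in sel:
                    for j in gb:
                        if np.linalg.norm(coords[f, i] - coords[f, j]) < 3.5:
                            c += 1
                cnt += c
                frac += 1.0 if c else 0.0
            assert out.loc[r, "fraction"] == pytest.approx(frac / n_frames)
            assert out.loc[r, "mean_contacts"] == pytest.approx(cnt / n_frames)

    def test_minimum_image_option(self):
        box = np.array([10.0, 10.0, 10.0])
        ens = _point_ensemble([[[0.5, 0, 0], [9.5, 0, 0]]])
        assert contact_frequency(ens, [0], [1]).loc[1, "fraction"] == 0.0
        assert contact_frequency(ens, [0], [1],
                                 box=box).loc[1, "fraction"] == 1.0


# ---------------------------------------------------------------------------
# hydrogen bonds

def _hbond_ens(d_a_dist, angle_deg):
    a = np.deg2rad(angle_deg)
    acceptor = np.array([d_a_dist * np.cos(a), d_a_dist * np.sin(a), 0.0])
    coords = np.array([[[0, 0, 0], [1.0, 0, 0], acceptor]])
    return _point_ensemble(coords, names=["N", "H", "O"],
                           resids=[1, 1, 2])


class TestHBonds:
    def test_close_and_linear_is_counted(self):
        ens = _hbond_ens(2.9, 10.0)
        out = hbond_table(ens, [(0, 1)], [2])
        assert out["mean_per_frame"].tolist() == [1.0]

    def test_bent_geometry_not_counted(self):
        # donor-acceptor at 2.9 A but 25 deg off-linear at the A-D-H vertex
        # gives an even larger D-H...A deviation
        ens = _hbond_ens(2.9, 25.0)
        assert len(hbond_table(ens, [(0, 1)], [2])) == 0

    def test_distance_violation_not_counted(self):
        ens = _hbond_ens(3.2, 0.0)
        assert len(hbond_table(ens, [(0, 1)], [2])) == 0

    def test_donor_without_hydrogen_named_in_error(self):
        ens = _point_ensemble([[[0, 0, 0], [3.0, 0, 0]]],
                              names=["N", "O"], resids=[1, 2])
        with pytest.raises(ValueError, match="no attached hydrogen"):
            hbond_table(ens, [0], [1])

    def test_hydrogen_autodetected_from_donor_index(self):
        ens = _hbond_ens(2.9, 0.0)
        out = hbond_table(ens, [0], [2])
        assert out["mean_per_frame"].tolist() == [1.0]

    def test_synthetic_frames_match_construction_record(self):
        from pisawheel.synthetic import make_hbond_frames
        hb = make_hbond_frames(n_pairs=10, fraction_bonded=0.4, seed=9,
                               n_frames=20)
        out = hbond_table(hb.ensemble, hb.donors, hb.acceptors)
        total = out["mean_per_frame"].sum() * hb.ensemble.n_frames
        assert total == pytest.approx(hb.bonded.sum())
        # per donor residue too
        per_res = hb.bonded.sum(axis=0)
        got = dict(zip(out["donor_resid"], out["mean_per_frame"] * 20))
        for p in range(10):
            assert got.get(p + 1, 0.0) == pytest.approx(per_res[p])


# ---------------------------------------------------------------------------
# PCA

class TestPCA:
    def test_identical_frames_have_zero_variance(self):
        frame = np.arange(30, dtype=float).reshape(10, 3)
        ens = _point_ensemble(np.tile(frame, (6, 1, 1)))
        pca = backbone_pca(ens)
        assert np.allclose(pca.eigenvalues, 0.0, atol=1e-20)

    def test_single_direction_displacement(self, rng):
        # breathing mode: radial expansion about the centroid carries no
        # rigid-body component, so superposition leaves it untouched
        base = rng.uniform(-5, 5, size=(12, 3))
        base -= base.mean(axis=0)
        direction = base / np.linalg.norm(base)
        amplitudes = np.linspace(-0.5, 0.5, 9)
        coords = np.stack([base + amp * direction for amp in amplitudes])
        pca = backbone_pca(_point_ensemble(coords))
        assert pca.variance_fractions[0] == pytest.approx(1.0, abs=1e-8)
        pc1 = pca.eigenvectors[:, 0].reshape(12, 3)
        overlap = abs(np.sum(pc1 * direction))
        assert overlap == pytest.approx(1.0, abs=1e-6)

    def test_eigenvalues_match_covariance_oracle(self, rng):
        coords = rng.normal(size=(15, 6, 3))
        pca = backbone_pca(_point_ensemble(coords))
        # brute-force oracle: re-fit with the returned mean, then eigh of
        # the explicit covariance built row by row
        from pisawheel.ensemble import _kabsch
        fitted = np.stack([_kabsch(c, pca.mean_coordinates) for c in coords])
        flat = (fitted - pca.mean_coordinates).reshape(15, -1)
        cov = np.zeros((18, 18))
        for row in flat:
            cov += np.outer(row, row)
        cov /= 15
        want = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(pca.eigenvalues, want, atol=1e-8)

    def test_variance_fractions_sum_to_one(self, rng):
        coords = rng.normal(size=(10, 5, 3))
        pca = backbone_pca(_point_ensemble(coords))
        assert pca.variance_fractions.sum() == pytest.approx(1.0)

    def test_projections_have_zero_mean(self, rng):
        coords = rng.normal(size=(20, 5, 3))
        pca = backbone_pca(_point_ensemble(coords))
        proj = np.concatenate(pca.projections)
        assert np.allclose(proj.mean(axis=0), 0.0, atol=1e-9)

    def test_atom_mismatch_rejected(self, rng):
        a = _point_ensemble(rng.normal(size=(3, 5, 3)))
        b = _point_ensemble(rng.normal(size=(3, 6, 3)))
        with pytest.raises(ValueError, match="different atom sets"):
            backbone_pca([a, b])

    def test_projection_consistency(self, rng):
        coords = rng.normal(scale=0.1, size=(12, 6, 3)) \
            + rng.normal(size=(1, 6, 3))
        ens = _point_ensemble(coords)
        pca = backbone_pca(ens)
        assert project_structure(pca, pca.mean_coordinates) == \
            pytest.approx((0.0, 0.0), abs=1e-9)
        stored = pca.projections[0][3][:2]
        again = project_structure(pca, coords[3])
        assert again == pytest.approx(tuple(stored), abs=1e-6)

    def test_mean_plus_pc1_projects_to_c(self):
        # displace the PCA mean along PC1 by a scalar c -> projection (c, 0)
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(10, 6, 3))
        pca = backbone_pca(_point_ensemble(coords))
        # small amplitude: the rigid-body refit of a finitely displaced
        # frame is identity only to first order
        c = 0.01
        frame = pca.mean_coordinates \
            + c * pca.eigenvectors[:, 0].reshape(6, 3)
        p1, p2 = project_structure(pca, frame)
        assert p1 == pytest.approx(c, abs=1e-5)
        assert p2 == pytest.approx(0.0, abs=1e-5)


# ---------------------------------------------------------------------------
# KLD

class TestKLD:
    def test_final_time_is_exactly_zero(self, rng):
        proj = rng.normal(size=(400, 2))
        out = kld_convergence(proj, times=np.array([100, 250, 400]))
        assert out["kld"].iloc[-1] == 0.0

    def test_half_uniform_construction_gives_ln2(self):
        # first half occupies the left bins uniformly, the full set all
        # bins uniformly: KLD(half) = ln 2 from the defining formula
        n = 100
        xs = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        ys = np.tile([0.0, 1.0], n // 2)
        proj = np.column_stack([xs, ys])
        out = kld_convergence(proj, n_bins_per_axis=2,
                              times=np.array([n // 2, n]))
        assert out["kld"].iloc[0] == pytest.approx(np.log(2.0))
        assert out["kld"].iloc[1] == 0.0

    def test_nonnegative_on_random_walks(self, rng):
        proj = np.cumsum(rng.normal(size=(300, 2)), axis=0)
        out = kld_convergence(proj)
        assert (out["kld"].to_numpy() >= -1e-12).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kld_convergence(np.zeros((1, 2)))


# ---------------------------------------------------------------------------
# tilt correlations

class TestTiltCorrelations:
    def test_self_correlation_is_one(self):
        spec = SyntheticSpec(seed=2, n_frames=60, tilt_means=(30.0, 35.0),
                             tilt_sds=(2.0, 2.0), tilt_correlation=0.0)
        se = make_helix_ensemble(spec)
        resids = np.arange(1, 21)
        cm = tilt_correlation_map(se.ensemble, [resids, resids],
                                  chains=["A", "A"])
        assert cm.matrix[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_helices_uncorrelated(self):
        spec = SyntheticSpec(seed=4, n_frames=800, tilt_means=(30.0, 35.0),
                             tilt_sds=(2.0, 2.0), tilt_correlation=0.0)
        se = make_helix_ensemble(spec)
        resids = np.arange(1, 21)
        cm = tilt_correlation_map(se.ensemble, [resids, resids],
                                  chains=["A", "B"])
        assert abs(cm.matrix[0, 1]) < 0.1

    def test_shared_tilt_series_fully_correlated(self):
        spec = SyntheticSpec(seed=6, n_frames=50, tilt_means=(30.0, 30.0),
                             tilt_sds=(2.0, 2.0), tilt_correlation=1.0)
        se = make_helix_ensemble(spec)
        resids = np.arange(1, 21)
        cm = tilt_correlation_map(se.ensemble, [resids, resids],
                                  chains=["A", "B"])
        assert cm.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_constant_series_reported_undefined(self):
        se = _single_helix(n_frames=20, tilt=30.0)
        resids = np.arange(1, 21)
        cm = tilt_correlation_map(se.ensemble, [resids, resids],
                                  chains=["A", "A"])
        assert np.isnan(cm.matrix[0, 1])

    def test_too_few_frames_rejected(self):
        se = _single_helix(n_frames=3, tilt=30.0)
        with pytest.raises(ValueError, match="frames"):
            tilt_correlation_map(se.ensemble,
                                 [np.arange(1, 21), np.arange(1, 21)],
                                 chains=["A", "A"])


# ---------------------------------------------------------------------------
# PDB round trip

class TestPDBRoundTrip:
    def test_multi_model_round_trip(self, tmp_path):
        spec = SyntheticSpec(seed=8, n_frames=3, tilt_means=(25.0,),
                             tilt_sds=(2.0,))
        se = make_helix_ensemble(spec)
        path = tmp_path / "ens.pdb"
        se.ensemble.to_pdb(path)
        back = TrajectoryEnsemble.from_pdb(path)
        assert back.n_frames == 3
        assert back.n_atoms == se.ensemble.n_atoms
        assert np.allclose(back.coordinates, se.ensemble.coordinates,
                           atol=1e-2)
        assert list(back.atoms["name"]) == list(se.ensemble.atoms["name"])
        th0 = per_frame_tilts(se.ensemble, np.arange(1, 21), chain="A")
        th1 = per_frame_tilts(back, np.arange(1, 21),
                              chain=back.atoms["chain"].iloc[0])
        assert np.allclose(th0, th1, atol=0.05)
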