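"""Structural observables: Rg/Ree, maps, secondary structure, RMSD, clustering."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare

from idpchar.conformation import (
    assign_secondary_structure,
    contact_map,
    distance_map,
    end_to_end,
    gromos_cluster,
    kabsch_rmsd,
    pairwise_rmsd_matrix,
    pca_backbone,
    radius_of_gyration,
    ramachandran_histogram,
    series_diagnostics,
)
from idpchar.ensembles import (
    CapabilityError,
    Conformation,
    Ensemble,
    build_backbone,
    fjc_ensemble,
    sample_ensemble,
)
from idpchar.sequence import parse_sequence


def _ca_conformation(points):
    points = np.asarray(points, dtype=float)
    seq = parse_sequence("G" * len(points))
    return Conformation(points[:, None, :], seq, atom_names=("CA",))


def _rigid_move(ens: Ensemble, seed=0) -> Ensemble:
    rng = np.random.default_rng(seed)
    rot = Rotation.from_euler("xyz", rng.uniform(-180, 180, 3), degrees=True)
    shift = rng.uniform(-20, 20, 3)
    flat = ens.coords.reshape(-1, 3)
    moved = (rot.apply(flat) + shift).reshape(ens.coords.shape)
    return Ensemble(moved, ens.sequence, ens.atom_names, weights=ens.weights)


class TestChainDimensions:
    def test_single_point_rg_is_zero(self):
        conf = _ca_conformation([[1.0, 2.0, 3.0]])
        assert radius_of_gyration(conf) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_mass_points(self):
        conf = _ca_conformation([[0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(conf, weighting="uniform") == pytest.approx(1.0)

    def test_fjc_rg_matches_closed_form(self):
        n_beads, bond = 50, 3.8
        ens = fjc_ensemble(n_beads, bond, n_frames=5000, seed=13)
        rg2 = radius_of_gyration(ens, weighting="uniform") ** 2
        expected = bond**2 * (n_beads**2 - 1) / (6 * n_beads)
        assert abs(rg2.mean() - expected) < 3 * rg2.std(ddof=1) / np.sqrt(len(ens))

    def test_mass_weighting_equals_uniform_for_equal_masses(self):
        ens = fjc_ensemble(10, n_frames=5, seed=1)  # poly-G: equal site masses
        np.testing.assert_allclose(
            radius_of_gyration(ens, "mass"), radius_of_gyration(ens, "uniform")
        )

    def test_single_frame_ensemble_equals_conformation(self, small_ensemble):
        conf = small_ensemble[0]
        ens1 = Ensemble(conf.coords[None], conf.sequence, conf.atom_names)
        assert radius_of_gyration(ens1)[0] == radius_of_gyration(conf)

    def test_two_bead_ree(self):
        ens = fjc_ensemble(2, bond=3.8, n_frames=3, seed=2)
        np.testing.assert_allclose(end_to_end(ens), 3.8)

    def test_helix_ree_matches_rise(self, keif):
        conf = build_backbone(keif, [(-57.0, -47.0)] * 33)
        assert end_to_end(conf) == pytest.approx(1.5 * 32, rel=0.10)

    def test_rigid_motion_invariance(self, small_ensemble):
        moved = _rigid_move(small_ensemble, seed=3)
        np.testing.assert_allclose(
            radius_of_gyration(moved), radius_of_gyration(small_ensemble), atol=1e-8
        )
        np.testing.assert_allclose(
            end_to_end(moved), end_to_end(small_ensemble), atol=1e-8
        )


class TestDistanceMap:
    def test_symmetry_and_zero_diagonal(self, small_ensemble):
        dm = distance_map(small_ensemble)
        np.testing.assert_allclose(dm.matrix, dm.matrix.T)
        np.testing.assert_allclose(np.diag(dm.matrix), 0.0)
        assert np.all(dm.matrix >= 0)

    def test_extended_chain_distances_increase_along_rows(self, keif):
        conf = build_backbone(keif, [(-120.0, 130.0)] * 33)
        dm = distance_map(conf, definition="ca_only")
        row = dm.matrix[0]
        assert np.all(np.diff(row) > 0)

    def test_three_residue_toy_against_brute_force(self):
        seq = parse_sequence("AGA")
        conf = build_backbone(seq, [(-70.0, 140.0)] * 3)
        dm = distance_map(conf)
        # brute force: minimum over all backbone-atom pairs of residues 0, 2
        brute = min(
            np.linalg.norm(conf.coords[0, a] - conf.coords[2, b])
            for a in range(4)
            for b in range(4)
        )
        assert dm.matrix[0, 2] == pytest.approx(brute)

    def test_ca_only_ensembles_need_ca_definition(self, fjc_toy):
        with pytest.raises(CapabilityError):
            distance_map(fjc_toy, definition="min_backbone_atom")
        dm = distance_map(fjc_toy, definition="ca_only")
        assert dm.matrix.shape == (10, 10)

    def test_rigid_motion_invariance(self, small_ensemble):
        moved = _rigid_move(small_ensemble, seed=4)
        np.testing.assert_allclose(
            distance_map(moved).matrix, distance_map(small_ensemble).matrix, atol=1e-8
        )


class TestContactMap:
    def test_single_frame_is_thresholded_distance_map(self, small_ensemble):
        conf = small_ensemble[0]
        cm = contact_map(conf, cutoff=6.0, neighbor_exclusion=2)
        dm = distance_map(conf)
        n = dm.matrix.shape[0]
        for i in range(n):
            for j in range(n):
                if abs(i - j) <= 2:
                    assert cm.matrix[i, j] == 0.0
                else:
                    assert cm.matrix[i, j] == float(dm.matrix[i, j] < 6.0)

    def test_neighbor_band_is_zero(self, small_ensemble):
        cm = contact_map(small_ensemble)
        n = cm.matrix.shape[0]
        ii, jj = np.indices((n, n))
        assert np.all(cm.matrix[np.abs(ii - jj) <= 2] == 0.0)

    def test_probabilities_bounded(self, small_ensemble):
        cm = contact_map(small_ensemble)
        assert cm.matrix.min() >= 0.0 and cm.matrix.max() <= 1.0

    def test_helix_backbone_hydrogen_bond_partners_in_contact(self, keif):
        conf = build_backbone(keif, [(-57.0, -47.0)] * 33)
        cm = contact_map(Ensemble.from_conformations([conf]), cutoff=4.0)
        inner = [cm.matrix[i, i + 4] for i in range(5, 25)]
        assert np.mean(inner) > 0.9


class TestSecondaryStructure:
    def test_ideal_helix_is_all_h(self, keif):
        conf = build_backbone(keif, [(-57.0, -47.0)] * 33)
        labels = assign_secondary_structure(conf).labels[0]
        assert set(labels[1:-1]) == {"H"}
        assert labels[0] == "C" and labels[-1] == "C"

    def test_ideal_ppii_is_all_p(self, keif):
        conf = build_backbone(keif, [(-75.0, 145.0)] * 33)
        labels = assign_secondary_structure(conf).labels[0]
        assert set(labels[1:-1]) == {"P"}

    def test_fractions_sum_to_one(self, small_ensemble):
        fractions = assign_secondary_structure(small_ensemble).fractions()
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_equal_mixture_recovered(self, helix_ppii_ensemble):
        fractions = assign_secondary_structure(helix_ppii_ensemble).fractions(
            exclude_terminal=True
        )
        assert fractions["H"] == pytest.approx(0.5, abs=0.05)
        assert fractions["P"] == pytest.approx(0.5, abs=0.05)

    def test_singleton_windows_fall_back_to_coil(self, keif):
        # one helix residue inside a PPII stretch cannot form a helix run
        dihedrals = [(-75.0, 145.0)] * 33
        dihedrals[15] = (-57.0, -47.0)
        labels = assign_secondary_structure(
            build_backbone(keif, dihedrals)
        ).labels[0]
        assert labels[15] in ("C", "T")
        assert "H" not in labels


class TestRamachandran:
    def test_count_conservation(self, small_ensemble):
        hist = ramachandran_histogram(small_ensemble)
        assert hist.total == len(small_ensemble) * (small_ensemble.n_residues - 2)

    def test_ppii_ensemble_modal_bin(self, keif):
        ens = Ensemble.from_conformations(
            [build_backbone(keif, [(-75.0, 145.0)] * 33)]
        )
        (phi_lo, phi_hi), (psi_lo, psi_hi) = ramachandran_histogram(ens).modal_bin()
        assert phi_lo <= -75.0 <= phi_hi
        assert psi_lo <= 145.0 <= psi_hi

    def test_bin_must_divide_360(self, small_ensemble):
        with pytest.raises(ValueError):
            ramachandran_histogram(small_ensemble, bin=7.0)

    def test_uniform_dihedrals_pass_uniformity_test(self):
        rng = np.random.default_rng(99)
        seq = parse_sequence("A" * 27)  # 25 interior residues
        n_frames = 400  # 10^4 interior (phi, psi) samples
        confs = [
            build_backbone(seq, rng.uniform(-180.0, 180.0, (27, 2)))
            for _ in range(n_frames)
        ]
        hist = ramachandran_histogram(
            Ensemble.from_conformations(confs), bin=30.0
        )
        _, p = chisquare(hist.counts.ravel())
        assert p > 0.001


class TestKabschRMSD:
    def test_identical_frames(self, small_ensemble):
        assert kabsch_rmsd(small_ensemble[0], small_ensemble[0]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_rigid_copy_is_zero(self, small_ensemble):
        moved = _rigid_move(small_ensemble, seed=8)
        assert kabsch_rmsd(small_ensemble[0], moved[0]) == pytest.approx(0.0, abs=1e-6)

    def test_four_point_toy_against_rotation_search(self, rng):
        """Brute force: dense Euler grid + local refinement over rotations."""
        a = _ca_conformation(rng.normal(scale=3.0, size=(4, 3)))
        b = _ca_conformation(rng.normal(scale=3.0, size=(4, 3)))
        ours = kabsch_rmsd(a, b, atoms=("CA",))

        pa = a.ca - a.ca.mean(axis=0)
        pb = b.ca - b.ca.mean(axis=0)

        def rmsd_of(angles):
            rot = Rotation.from_euler("xyz", angles, degrees=True)
            return np.sqrt(np.mean(np.sum((pa - rot.apply(pb)) ** 2, axis=1)))

        grid = np.arange(-180.0, 180.0, 20.0)
        best = min(
            ((rmsd_of((x, y, z)), (x, y, z)) for x in grid for y in grid for z in grid),
            key=lambda t: t[0],
        )
        refined = minimize(rmsd_of, best[1], method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-12})
        assert ours == pytest.approx(refined.fun, abs=1e-3)
        assert ours <= refined.fun + 1e-6  # Kabsch is the global optimum

    def test_collinear_selection_rejected(self):
        line = _ca_conformation([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_rmsd(line, line, atoms=("CA",))

    def test_too_few_atoms(self):
        a = _ca_conformation([[0, 0, 0], [1, 1, 1]])
        with pytest.raises(ValueError):
            kabsch_rmsd(a, a, atoms=("CA",))


def _greedy_oracle(dist, cutoff, weights):
    """Exhaustive neighbor-count clustering oracle on a distance matrix."""
    n = dist.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        counts = {
            i: sum(1 for j in remaining if dist[i, j] <= cutoff) for i in remaining
        }
        best = max(counts.values())
        center = min(i for i, c in counts.items() if c == best)
        members = sorted(
            j for j in remaining if dist[center, j] <= cutoff
        )
        clusters.append((center, members, 100.0 * sum(weights[j] for j in members)))
        remaining -= set(members)
    clusters.sort(key=lambda c: -c[2])
    return clusters


class TestGromosClustering:
    def test_single_cluster_when_cutoff_exceeds_all(self, fjc_toy):
        d = pairwise_rmsd_matrix(fjc_toy)
        res = gromos_cluster(fjc_toy, cutoff=d.max() + 1.0, rmsd_matrix=d)
        assert res.n_clusters == 1
        assert res.populations[0] == pytest.approx(100.0)

    def test_all_singletons_below_min_rmsd(self, fjc_toy):
        d = pairwise_rmsd_matrix(fjc_toy)
        res = gromos_cluster(fjc_toy, cutoff=d[d > 0].min() * 0.5, rmsd_matrix=d)
        assert res.n_clusters == len(fjc_toy)

    def test_toy_ensemble_matches_exhaustive_oracle(self, fjc_toy):
        d = pairwise_rmsd_matrix(fjc_toy)
        cutoff = float(np.median(d))
        res = gromos_cluster(fjc_toy, cutoff=cutoff, rmsd_matrix=d)
        oracle = _greedy_oracle(d, cutoff, fjc_toy.weights)
        assert res.representatives == tuple(c[0] for c in oracle)
        assert res.populations == pytest.approx(tuple(c[2] for c in oracle))
        for rank, (_, members, _) in enumerate(oracle):
            assert all(res.assignment[m] == rank for m in members)

    def test_populations_sum_to_100(self, small_ensemble):
        sub = Ensemble(
            small_ensemble.coords[:20],
            small_ensemble.sequence,
            small_ensemble.atom_names,
        )
        d = pairwise_rmsd_matrix(sub)
        res = gromos_cluster(sub, cutoff=float(np.median(d)), rmsd_matrix=d)
        assert sum(res.populations) == pytest.approx(100.0, abs=1e-6)
        assert np.all(res.assignment >= 0)

    def test_greedy_consistency_after_removing_top_cluster(self, small_ensemble):
        sub = Ensemble(
            small_ensemble.coords[:20],
            small_ensemble.sequence,
            small_ensemble.atom_names,
        )
        d = pairwise_rmsd_matrix(sub)
        cutoff = float(np.quantile(d[d > 0], 0.3))
        full = gromos_cluster(sub, cutoff=cutoff, rmsd_matrix=d)
        first = np.flatnonzero(full.assignment == 0)
        keep = np.setdiff1d(np.arange(len(sub)), first)
        rest = Ensemble(
            sub.coords[keep], sub.sequence, sub.atom_names
        )
        res2 = gromos_cluster(rest, cutoff=cutoff, rmsd_matrix=d[np.ix_(keep, keep)])
        # remaining clusters reproduce the original partition (as index sets)
        orig = [
            frozenset(keep.tolist().index(f) for f in np.flatnonzero(full.assignment == k))
            for k in range(1, full.n_clusters)
        ]
        new = [
            frozenset(np.flatnonzero(res2.assignment == k).tolist())
            for k in range(res2.n_clusters)
        ]
        assert sorted(orig, key=sorted) == sorted(new, key=sorted)


class TestSeriesDiagnostics:
    def test_acf_starts_at_one(self, rng):
        d = series_diagnostics(rng.normal(size=256))
        assert d.acf[0] == pytest.approx(1.0)

    def test_white_noise_acf_within_bound(self, rng):
        n = 2000
        d = series_diagnostics(rng.normal(size=n))
        assert np.all(np.abs(d.acf[1:21]) < 3.0 / np.sqrt(n))

    def test_constant_series_zero_block_error(self):
        d = series_diagnostics(np.full(64, 3.14))
        assert np.all(d.block_se == 0.0)
        assert d.acf[0] == 1.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            series_diagnostics(np.ones(3))


class TestPCA:
    def test_explained_variance_ordered(self, small_ensemble):
        res = pca_backbone(small_ensemble, n_components=2)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_projection_centroid_is_zero(self, small_ensemble):
        res = pca_backbone(small_ensemble)
        np.testing.assert_allclose(res.projections.mean(axis=0), 0.0, atol=1e-9)

    def test_single_linear_mode_dominates(self, rng):
        base = rng.normal(scale=4.0, size=(12, 3))
        mode = rng.normal(size=(12, 3))
        mode /= np.linalg.norm(mode)
        ts = np.linspace(-3, 3, 40)
        coords = np.stack([base + t * mode for t in ts])[:, :, None, :]
        ens = Ensemble(coords, parse_sequence("G" * 12), atom_names=("CA",))
        res = pca_backbone(ens, n_components=2)
        assert res.explained_variance_ratio[0] > 0.99

    def test_needs_two_frames(self, small_ensemble):
        one = Ensemble(
            small_ensemble.coords[:1],
            small_ensemble.sequence,
            small_ensemble.atom_names,
        )
        with pytest.raises(ValueError):
            pca_backbone(one)
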