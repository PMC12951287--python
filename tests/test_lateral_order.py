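"""Leaflets, clustering vs union-find oracle, RDF sanity, S_CD oracle."""

import numpy as np
import pandas as pd
import pytest

from lipidobs.core_io import Topology, Trajectory, select
from lipidobs.lateral_order import (assign_leaflets, cluster_lipids,
                                    nnc_report, order_change_summary,
                                    order_parameters, rdf)
from lipidobs.synthetic import (TABLE_COMPOSITION, make_brownian_bilayer,
                                make_ordered_chains, make_planted_clusters,
                                membrane_composition_fixture)


class TestLeaflets:
    def test_symmetric_fixture_splits_evenly(self):
        traj, topo, _ = make_brownian_bilayer({"MAIPG": 10}, {"MAIPG": 0.0},
                                              2, 1.0, seed=0)
        blank = topo.with_leaflets(["none"] * topo.n_atoms)
        out = assign_leaflets(traj.coords[0], blank)
        counts = out.atoms["leaflet"].value_counts()
        assert counts["upper"] == counts["lower"] == 10

    def test_all_above_center_all_upper(self):
        rows = [dict(atom_id=i, name="P", atomic_number=15,
                     residue_name="MAIPG", residue_index=i + 1,
                     molecule_id=i + 1, species="MAIPG", charge=-1.0,
                     lj_sigma=0.3, lj_epsilon=0.1, mass=31.0,
                     leaflet="none") for i in range(4)]
        # one heavy lipid below pulls the COM down; heads all above it
        coords = np.array([[1, 1, 3.0], [2, 2, 3.1], [3, 3, 3.2],
                           [1, 3, 0.5]])
        rows[3]["mass"] = 1e6
        topo = Topology(pd.DataFrame(rows))
        out = assign_leaflets(coords, topo)
        assert list(out.atoms["leaflet"][:3]) == ["upper"] * 3

    def test_composition_fixture_upper_leaflet_is_100(self):
        traj, topo, _ = make_brownian_bilayer(
            {sp: v[2] for sp, v in TABLE_COMPOSITION.items()},
            {sp: 0.0 for sp in TABLE_COMPOSITION}, 2, 1.0, seed=1)
        blank = topo.with_leaflets(["none"] * topo.n_atoms)
        out = assign_leaflets(traj.coords[0], blank)
        assert (out.atoms["leaflet"] == "upper").sum() == 100

    def test_no_lipids_rejected(self):
        rows = [dict(atom_id=0, name="CA", atomic_number=6,
                     residue_name="G", residue_index=1, molecule_id=1,
                     species="PEPTIDE", charge=0.0, lj_sigma=0.3,
                     lj_epsilon=0.1, mass=12.0, leaflet="none")]
        with pytest.raises(ValueError):
            assign_leaflets(np.zeros((1, 3)), Topology(pd.DataFrame(rows)))


def _union_find_clusters(coords, box, topo, species, threshold):
    """Independent brute-force single-linkage oracle."""
    a = topo.atoms
    mask = (a["species"] == species) & (a["leaflet"] == "upper")
    mols = [grp.index.to_numpy() for _, grp in a[mask].groupby("molecule_id")]
    n = len(mols)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    box = np.asarray(box, float)
    for i in range(n):
        for j in range(i + 1, n):
            hit = False
            for ai in mols[i]:
                for aj in mols[j]:
                    d = coords[ai] - coords[aj]
                    d -= box * np.floor(d / box + 0.5)
                    if np.linalg.norm(d) <= threshold:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


class TestClustering:
    def test_planted_clusters_found_exactly(self):
        traj, topo, truth = make_planted_clusters(5, 4, 0.3, 3.0)
        found = cluster_lipids(traj.coords[0], traj.boxes[0], topo,
                               "MAIPG", 0.35)
        assert len(found) == truth.parameters["k_clusters"] == 5
        assert sorted(len(c) for c in found) == [4] * 5

    def test_pair_below_threshold_merges(self):
        traj, topo, _ = make_planted_clusters(1, 2, 0.30, 3.0)
        assert len(cluster_lipids(traj.coords[0], traj.boxes[0], topo,
                                  "MAIPG", 0.35)) == 1

    def test_pair_above_threshold_stays_split(self):
        traj, topo, _ = make_planted_clusters(1, 2, 0.40, 3.0)
        assert len(cluster_lipids(traj.coords[0], traj.boxes[0], topo,
                                  "MAIPG", 0.35)) == 2

    def test_unknown_species_rejected(self):
        traj, topo, _ = make_planted_clusters(2, 2, 0.3, 3.0)
        with pytest.raises(ValueError):
            cluster_lipids(traj.coords[0], traj.boxes[0], topo, "DPPE", 0.35)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        box = (6.0, 6.0, 6.0)
        rows = [dict(atom_id=i, name="P", atomic_number=15,
                     residue_name="AIPG", residue_index=i + 1,
                     molecule_id=i + 1, species="AIPG", charge=-1.0,
                     lj_sigma=0.3, lj_epsilon=0.1, mass=31.0,
                     leaflet="upper") for i in range(n)]
        topo = Topology(pd.DataFrame(rows))
        coords = rng.uniform(0, 6.0, size=(n, 3))
        found = cluster_lipids(coords, box, topo, "AIPG", 0.8)
        expected = _union_find_clusters(coords, box, topo, "AIPG", 0.8)
        assert len(found) == expected


class TestNNC:
    def test_all_isolated_gives_nnc_one(self):
        traj, topo, _ = make_planted_clusters(6, 1, 0.3, 3.0)
        rep = nnc_report(traj, topo, "MAIPG", 0.35)
        assert rep.NNC == 1.0

    def test_single_blob_gives_nnc_one_over_n(self):
        traj, topo, _ = make_planted_clusters(1, 8, 0.3, 3.0)
        rep = nnc_report(traj, topo, "MAIPG", 0.35)
        assert rep.NNC == pytest.approx(1 / 8)

    def test_planted_k_of_m_gives_k_over_km(self):
        traj, topo, _ = make_planted_clusters(5, 4, 0.3, 3.0)
        rep = nnc_report(traj, topo, "MAIPG", 0.35)
        assert rep.NC == 5.0
        assert rep.NNC == pytest.approx(5 / 20)

    def test_bounds_hold_on_random_frames(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(2, 30))
            rows = [dict(atom_id=i, name="P", atomic_number=15,
                         residue_name="DPPG", residue_index=i + 1,
                         molecule_id=i + 1, species="DPPG", charge=-1.0,
                         lj_sigma=0.3, lj_epsilon=0.1, mass=31.0,
                         leaflet="upper") for i in range(n)]
            topo = Topology(pd.DataFrame(rows))
            coords = rng.uniform(0, 5.0, size=(5, n, 3))
            traj = Trajectory(np.arange(5.0), np.full((5, 3), 5.0), coords)
            rep = nnc_report(traj, topo, "DPPG", 0.5)
            assert 1 / n - 1e-12 <= rep.NNC <= 1 + 1e-12


class TestRDF:
    def test_poisson_points_give_unit_g(self):
        rng = np.random.default_rng(5)
        n = 600
        box = (8.0, 8.0, 8.0)
        rows = [dict(atom_id=i, name="P", atomic_number=15,
                     residue_name="MAIPG", residue_index=i + 1,
                     molecule_id=i + 1, species="MAIPG", charge=-1.0,
                     lj_sigma=0.3, lj_epsilon=0.1, mass=31.0,
                     leaflet="upper") for i in range(n)]
        topo = Topology(pd.DataFrame(rows))
        coords = rng.uniform(0, 8.0, size=(10, n, 3))
        traj = Trajectory(np.arange(10.0), np.full((10, 3), 8.0), coords)
        idx = select(topo, "species == MAIPG")
        curve = rdf(traj, topo, idx, idx, r_max=2.0, bin=0.1)
        dens = (n - 1) / np.prod(box)
        for k in range(1, len(curve.r)):
            shell = 4 / 3 * np.pi * ((curve.r[k] + 0.05) ** 3
                                     - (curve.r[k] - 0.05) ** 3)
            counting_sigma = 1 / np.sqrt(10 * n * dens * shell)
            assert abs(curve.g[k] - 1.0) <= 3.5 * counting_sigma

    def test_fixed_pair_single_spike(self):
        rows = [dict(atom_id=i, name="P", atomic_number=15,
                     residue_name="MAIPG", residue_index=i + 1,
                     molecule_id=i + 1, species="MAIPG", charge=-1.0,
                     lj_sigma=0.3, lj_epsilon=0.1, mass=31.0,
                     leaflet="upper") for i in range(2)]
        topo = Topology(pd.DataFrame(rows))
        coords = np.array([[[1.0, 1.0, 1.0], [1.0, 1.0, 1.75]]])
        traj = Trajectory([0.0], np.full((1, 3), 6.0), coords)
        idx = select(topo, "species == MAIPG")
        curve = rdf(traj, topo, idx, idx, r_max=2.0, bin=0.1)
        nz = np.nonzero(curve.g)[0]
        assert len(nz) == 1
        assert curve.r[nz[0]] == pytest.approx(0.75)

    def test_nrdf_with_single_molecule_equals_rdf(self):
        rows = [dict(atom_id=i, name="P", atomic_number=15,
                     residue_name="PAICL", residue_index=1,
                     molecule_id=1, species="PAICL", charge=-2.0,
                     lj_sigma=0.3, lj_epsilon=0.1, mass=31.0,
                     leaflet="upper") for i in range(2)]
        for i, r in enumerate(rows):
            r["atom_id"] = i
        topo = Topology(pd.DataFrame(rows))
        coords = np.array([[[1.0, 1.0, 1.0], [1.0, 1.0, 1.4]]])
        traj = Trajectory([0.0], np.full((1, 3), 6.0), coords)
        idx = select(topo, "species == PAICL")
        curve = rdf(traj, topo, idx, idx, r_max=2.0, bin=0.1, n_normalize=1)
        np.testing.assert_array_equal(curve.normalized, curve.g)

    def test_r_max_beyond_half_box_rejected(self):
        traj, topo, _ = make_planted_clusters(2, 2, 0.3, 2.5,
                                              box=(6.0, 6.0, 6.0))
        idx = select(topo, "species == MAIPG")
        with pytest.raises(ValueError):
            rdf(traj, topo, idx, idx, r_max=4.0)


class TestOrderParameters:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, 1.0), (90.0, 0.5), (54.7356103, 0.0), (10.0, None),
        (20.0, None), (30.0, None), (45.0, None), (60.0, None),
        (75.0, None), (120.0, None)])
    def test_scd_matches_closed_form(self, theta, expected):
        traj, topo, truth = make_ordered_chains(theta, 3, 4, seed=2)
        analytic = truth.parameters["expected_scd"]
        if expected is not None:
            assert analytic == pytest.approx(expected, abs=1e-6)
        for chain in ("SN1", "SN2"):
            prof = order_parameters(traj, topo, "MAIPG", chain)
            np.testing.assert_allclose(prof.S_CD, analytic, atol=1e-6)

    def test_isotropic_orientations_average_to_zero(self):
        rng = np.random.default_rng(12)
        # P2 of uniformly random orientations has zero mean
        u = rng.normal(size=(10_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        p2 = (3 * u[:, 2] ** 2 - 1) / 2
        assert abs(p2.mean()) <= 0.02

    def test_missing_chain_map_rejected(self):
        traj, topo, _ = make_planted_clusters(2, 2, 0.3, 3.0)
        with pytest.raises(ValueError):
            order_parameters(traj, topo, "MAIPG", "SN1")

    def test_change_summary_arithmetic(self):
        t, topo, _ = make_ordered_chains(0.0, 2, 4, seed=0)
        a = order_parameters(t, topo, "MAIPG", "SN1")
        t2, topo2, _ = make_ordered_chains(90.0, 2, 4, seed=0)
        b = order_parameters(t2, topo2, "MAIPG", "SN1")
        assert order_change_summary(a, a) == 0.0
        # |1 - 0.5| on 4 carbons -> 2.0; symmetric in the arguments
        assert order_change_summary(a, b) == pytest.approx(2.0, abs=1e-9)
        assert order_change_summary(b, a) == order_change_summary(a, b)
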