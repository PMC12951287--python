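"""IO round trips, selection grammar, periodic geometry and block stats."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidobs.core_io import (BlockEstimate, SelectionError, Topology,
                              TopologyError, Trajectory, TrajectoryError,
                              block_average, minimum_image_displacement,
                              read_topology, read_trajectory, select,
                              slice_time, write_topology, write_trajectory)
from lipidobs.synthetic import TABLE_COMPOSITION, membrane_composition_fixture


class TestTopology:
    def test_packaged_composition_counts_and_charges(self, composition_fixture):
        counts = composition_fixture.atoms.groupby(
            ["species", "leaflet"]).size()
        assert counts[("MAIPG", "upper")] == 22
        assert counts[("MAIPG", "lower")] == 22
        paicl = composition_fixture.atoms.query("species == 'PAICL'")
        assert (paicl["charge"] == -2).all()
        aipg = composition_fixture.atoms.query("species == 'AIPG'")
        assert (aipg["charge"] == -1).all()

    def test_per_leaflet_total_is_sum_of_composition(self, composition_fixture):
        expected = sum(v[2] for v in TABLE_COMPOSITION.values())
        upper = (composition_fixture.atoms["leaflet"] == "upper").sum()
        assert upper == expected == 100

    def test_leaflet_compositions_symmetric(self, composition_fixture):
        by = composition_fixture.atoms.groupby(["leaflet", "species"]).size()
        assert by["upper"].to_dict() == by["lower"].to_dict()

    def test_empty_atom_list_rejected(self):
        with pytest.raises(TopologyError, match="empty"):
            Topology(pd.DataFrame())

    def test_json_round_trip(self, tmp_path, small_topology):
        p = tmp_path / "topo.json"
        write_topology(small_topology, p)
        back = read_topology(p)
        pd.testing.assert_frame_equal(
            back.atoms[small_topology.atoms.columns], small_topology.atoms)

    def test_missing_field_named_in_error(self, tmp_path):
        doc = {"version": 1, "atoms": [{"atom_id": 0, "name": "P"}]}
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(TopologyError, match="atomic_number"):
            read_topology(p)

    def test_unknown_species_rejected(self, small_topology, tmp_path):
        doc = small_topology.to_dict()
        doc["atoms"][0]["species"] = "XYZ"
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(TopologyError, match="XYZ"):
            read_topology(p)


class TestTrajectoryIO:
    @pytest.mark.parametrize("suffix", [".gro", ".pdb"])
    def test_write_read_round_trip(self, tmp_path, small_topology,
                                   small_trajectory, suffix):
        p = tmp_path / f"traj{suffix}"
        write_trajectory(small_trajectory, small_topology, p)
        back = read_trajectory(p, small_topology)
        assert back.n_frames == small_trajectory.n_frames
        np.testing.assert_allclose(back.coords, small_trajectory.coords,
                                   atol=5.5e-4)  # 3-decimal nm / 3-decimal A
        np.testing.assert_allclose(back.boxes, small_trajectory.boxes,
                                   atol=1e-4)

    def test_gro_round_trip_matches_mdtraj(self, tmp_path, small_topology,
                                           small_trajectory):
        mdtraj = pytest.importorskip("mdtraj")
        p = tmp_path / "traj.gro"
        write_trajectory(small_trajectory, small_topology, p)
        ref = mdtraj.load(str(p))
        assert ref.n_frames == small_trajectory.n_frames
        np.testing.assert_allclose(ref.xyz, small_trajectory.coords,
                                   atol=5.5e-4)

    def test_gro_times_read_from_headers(self, tmp_path, small_topology,
                                         small_trajectory):
        p = tmp_path / "traj.gro"
        write_trajectory(small_trajectory, small_topology, p)
        back = read_trajectory(p, small_topology)
        np.testing.assert_allclose(back.times, small_trajectory.times)
        back_ns = read_trajectory(p, small_topology, time_unit="ns")
        np.testing.assert_allclose(back_ns.times,
                                   small_trajectory.times * 1000)

    def test_single_frame_file(self, tmp_path, small_topology,
                               small_trajectory):
        one = Trajectory(small_trajectory.times[:1],
                         small_trajectory.boxes[:1],
                         small_trajectory.coords[:1])
        p = tmp_path / "one.gro"
        write_trajectory(one, small_topology, p)
        assert read_trajectory(p, small_topology).n_frames == 1

    def test_missing_atom_error_names_frame(self, tmp_path, small_topology,
                                            small_trajectory):
        p = tmp_path / "traj.gro"
        write_trajectory(small_trajectory, small_topology, p)
        lines = p.read_text().splitlines(keepends=True)
        # frame 2 starts at line 2*(2+3+1); drop one atom, fix its count
        start = 2 * 6
        lines[start + 1] = "2\n"
        del lines[start + 3]
        p.write_text("".join(lines))
        with pytest.raises(TrajectoryError, match="frame 2"):
            read_trajectory(p, small_topology)

    def test_unparseable_frame_reports_line(self, tmp_path, small_topology,
                                            small_trajectory):
        p = tmp_path / "traj.gro"
        write_trajectory(small_trajectory, small_topology, p)
        lines = p.read_text().splitlines(keepends=True)
        lines[2] = lines[2][:20] + "   x.yzw" + lines[2][28:]
        p.write_text("".join(lines))
        with pytest.raises(TrajectoryError, match="line 3"):
            read_trajectory(p, small_topology)

    def test_triclinic_box_rejected(self, tmp_path, small_topology,
                                    small_trajectory):
        p = tmp_path / "traj.gro"
        write_trajectory(small_trajectory, small_topology, p)
        lines = p.read_text().splitlines(keepends=True)
        lines[5] = lines[5].rstrip("\n") + "   0.0 0.0 0.5 0.0 0.0 0.0\n"
        p.write_text("".join(lines))
        with pytest.raises(TrajectoryError, match="triclinic"):
            read_trajectory(p, small_topology)


class TestSelect:
    def test_species_and_leaflet(self, composition_fixture):
        idx = select(composition_fixture,
                     "species == MAIPG and leaflet == upper")
        assert len(idx) == 22
        assert np.all(np.diff(idx) > 0)

    def test_or_combines(self, composition_fixture):
        idx = select(composition_fixture,
                     "species == DPPE or species == PAIPE")
        assert len(idx) == 2 * (3 + 4)

    def test_empty_result_allowed(self, small_topology):
        assert len(select(small_topology, "species == DPPE")) == 0

    def test_unknown_species_raises(self, small_topology):
        with pytest.raises(SelectionError, match="XYZ"):
            select(small_topology, "species == XYZ")

    def test_parse_error_reports_position(self, small_topology):
        with pytest.raises(SelectionError, match="position"):
            select(small_topology, "species = MAIPG")

    def test_residue_index_and_name(self, small_topology):
        assert list(select(small_topology, "residue_index == 19")) == [0]
        assert list(select(small_topology, "name == P")) == [1]


class TestMinimumImage:
    def test_wrap_case(self):
        d = minimum_image_displacement((0.5, 0, 0), (9.5, 0, 0), (10, 10, 10))
        assert np.linalg.norm(d) == pytest.approx(1.0)

    def test_identical_points(self):
        np.testing.assert_array_equal(
            minimum_image_displacement((1, 2, 3), (1, 2, 3), (5, 5, 5)),
            np.zeros(3))

    def test_half_box_boundary_convention(self):
        d = minimum_image_displacement((0, 0, 0), (5, 0, 0), (10, 10, 10))
        assert np.linalg.norm(d) == pytest.approx(5.0)
        assert d[0] == -5.0  # component lies in [-L/2, L/2)

    def test_zero_box_rejected(self):
        with pytest.raises(ValueError):
            minimum_image_displacement((0, 0, 0), (1, 0, 0), (0, 5, 5))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3),
           st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_antisymmetry(self, r1, r2):
        box = np.array([7.0, 9.0, 11.0])
        d12 = minimum_image_displacement(r1, r2, box)
        d21 = minimum_image_displacement(r2, r1, box)
        # antisymmetric up to re-wrapping of the boundary image
        s = d12 + d21
        np.testing.assert_allclose(s - box * np.round(s / box), 0,
                                   atol=1e-9)
        assert np.all(d12 >= -box / 2) and np.all(d12 < box / 2)


class TestSliceTime:
    def test_inclusive_window(self):
        t = np.arange(101.0)
        traj = Trajectory(t, np.ones((101, 3)), np.zeros((101, 1, 3)))
        sub = slice_time(traj, 50, 100)
        assert sub.n_frames == 51
        assert sub.times[0] == 50

    def test_full_window_is_identity(self, small_trajectory):
        sub = slice_time(small_trajectory, -1, 1e9)
        np.testing.assert_array_equal(sub.coords, small_trajectory.coords)

    def test_empty_window_raises(self, small_trajectory):
        with pytest.raises(ValueError):
            slice_time(small_trajectory, 200, 300)


class TestBlockAverage:
    def test_constant_series(self):
        est = block_average([3.5] * 20, 4)
        assert est.mean == 3.5
        assert est.error == 0.0

    def test_iid_error_near_sem(self):
        """5-block error tracks the i.i.d. SEM 1/sqrt(n) within 3x."""
        n = 10_000
        ratios = []
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(n)
            est = block_average(x, 5)
            ratios.append(est.error * np.sqrt(n))
        mean_ratio = np.mean(ratios)
        assert 1 / 3 < mean_ratio < 3

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            block_average([1.0, 2.0, 3.0], 5)

    def test_n_blocks_equal_length_reduces_to_sem(self):
        x = np.random.default_rng(0).standard_normal(64)
        est = block_average(x, len(x))
        assert est.mean == pytest.approx(x.mean())
        assert est.error == pytest.approx(x.std(ddof=1) / np.sqrt(len(x)))

    def test_block_estimate_invariants(self):
        with pytest.raises(ValueError):
            BlockEstimate(0.0, -1.0, 5)
        with pytest.raises(ValueError):
            BlockEstimate(0.0, 0.0, 1)
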