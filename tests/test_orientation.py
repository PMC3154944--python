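"""Orientation descriptors: angles, COM separation, tilts, peak selection."""

import math

import numpy as np
import pytest

from memtun import synthetic as syn
from memtun.geometry import DegenerateGeometryError, rotation_about_axis
from memtun.orientation import (IncompleteWindowError, NoRepresentativeError,
                                OrientationConfig, angle_variance_control,
                                com_distance_z, compute_vectors,
                                height_above_membrane, helix_tilt, heme_tilt,
                                histogram_peak, histogram_peak_select,
                                orientation_angles, orientation_records)
from memtun.structio import StructureModel, assign_roles


def _point_model(points, roles, elements=None, names=None, res_seq=None):
    n = len(points)
    rn = np.array(["ALA" if r == "protein" else
                   "LIP" if r == "lipid" else "HEM" for r in roles])
    return StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=np.array(names if names is not None else ["CA"] * n),
        element=np.array(elements if elements is not None else ["C"] * n),
        residue_seq=np.array(res_seq if res_seq is not None else range(1, n + 1)),
        residue_name=rn,
        chain=np.full(n, "A"),
        xyz=np.asarray(points, float),
        role=np.array(roles))


class TestOrientationAngles:
    @pytest.mark.parametrize("v, expected", [
        ((0, 0, 1), 0.0), ((1, 0, 0), 90.0), ((1, 0, 1), 45.0),
        ((0, 0, -1), 180.0),
    ])
    def test_closed_forms(self, v, expected):
        a, _ = orientation_angles(np.array(v, float), np.array([1.0, 0, 0]))
        assert a == pytest.approx(expected, abs=1e-9)

    def test_matches_arccos_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.normal(size=3)
            a, _ = orientation_angles(v, np.array([1.0, 0, 0]))
            oracle = math.degrees(math.acos(v[2] / math.sqrt(sum(x * x for x in v))))
            assert a == pytest.approx(oracle, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            orientation_angles(np.zeros(3), np.ones(3))


class TestComputeVectors:
    def test_toy_protein_windows_on_axes(self, toy_protein):
        v1, v2 = compute_vectors(toy_protein)
        assert np.allclose(v1 / np.linalg.norm(v1), [0, 0, 1], atol=1e-9)
        assert np.allclose(v2 / np.linalg.norm(v2), [1, 0, 0], atol=1e-9)

    def test_single_atom_windows_are_coordinate_differences(self):
        pts = [[0, 0, 0], [3, 4, 12], [1, 1, 1], [2, 2, 2]]
        m = _point_model(pts, ["protein"] * 4, res_seq=[285, 312, 127, 197])
        cfg = OrientationConfig(v1_window_a=(285, 285), v1_window_b=(312, 312),
                                v2_window_a=(127, 127), v2_window_b=(197, 197))
        v1, v2 = compute_vectors(m, cfg)
        np.testing.assert_allclose(v1, [3, 4, 12])
        np.testing.assert_allclose(v2, [1, 1, 1])

    def test_midpoints_match_mean_oracle(self, toy_protein):
        v1, _ = compute_vectors(toy_protein)
        m = toy_protein
        mids = []
        for lo, hi in ((285, 289), (312, 316)):
            acc, cnt = np.zeros(3), 0
            for i in range(m.n_atoms):
                if lo <= m.residue_seq[i] <= hi and m.atom_name[i] == "CA":
                    acc += m.xyz[i]
                    cnt += 1
            mids.append(acc / cnt)
        np.testing.assert_allclose(v1, mids[1] - mids[0], atol=1e-12)

    def test_missing_window_residue_reported(self, toy_protein):
        cfg = OrientationConfig(v1_window_a=(5000, 5004))
        with pytest.raises(IncompleteWindowError, match="5000"):
            compute_vectors(toy_protein, cfg)


class TestComDistanceZ:
    def test_point_protein_over_membrane(self):
        m = _point_model([[0, 0, 40], [0, 0, 1], [0, 0, -1]],
                         ["protein", "lipid", "lipid"],
                         names=["CA", "C31", "C31"])
        assert com_distance_z(m) == pytest.approx(40.0)

    def test_symmetric_masses_cancel(self):
        m = _point_model([[0, 0, 5], [0, 0, -5], [1, 0, 0], [-1, 0, 0]],
                         ["protein", "protein", "lipid", "lipid"],
                         names=["CA", "CA", "C31", "C31"])
        assert com_distance_z(m) == pytest.approx(0.0)

    def test_heterogeneous_masses_match_weighted_oracle(self):
        from memtun.constants import element_mass
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 10, (8, 3))
        roles = ["protein"] * 4 + ["lipid"] * 4
        els = ["C", "N", "O", "S", "P", "C", "N", "O"]
        m = _point_model(pts, roles, elements=els,
                         names=["CA"] * 4 + ["C31"] * 4)
        got = com_distance_z(m)
        wp = np.array([element_mass(e) for e in els[:4]])
        wm = np.array([element_mass(e) for e in els[4:]])
        oracle = (np.average(pts[:4, 2], weights=wp)
                  - np.average(pts[4:, 2], weights=wm))
        assert got == pytest.approx(oracle, abs=1e-12)


class TestTilts:
    def test_aligned_helix_has_zero_tilt(self):
        traj, _ = syn.generate_helix_tilt_trajectory(0.0, 0.0, 1, seed=0)
        assert helix_tilt(traj.frame(0)) == pytest.approx(0.0, abs=1e-6)

    def test_rotation_equivariance(self):
        traj, _ = syn.generate_helix_tilt_trajectory(0.0, 0.0, 1, seed=0)
        m = traj.frame(0)
        R = rotation_about_axis([1, 0, 0], 30.0)
        rotated = m.with_coords(m.xyz @ R.T)
        assert helix_tilt(rotated) == pytest.approx(30.0, abs=1e-6)

    def test_noisy_helix_matches_total_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        traj, _ = syn.generate_helix_tilt_trajectory(20.0, 0.0, 1, seed=1)
        m = traj.frame(0)
        noisy = m.with_coords(m.xyz + rng.normal(0, 0.3, m.xyz.shape))
        got = helix_tilt(noisy)
        ca = noisy.xyz[noisy.atom_name == "CA"]
        centred = ca - ca.mean(axis=0)
        w, v = np.linalg.eigh(centred.T @ centred)
        axis = v[:, -1]
        oracle = math.degrees(math.acos(abs(axis[2]) / np.linalg.norm(axis)))
        assert got == pytest.approx(oracle, abs=1.0)

    def test_heme_tilt_parallel_and_perpendicular(self, toy_protein):
        assert heme_tilt(toy_protein) == pytest.approx(0.0, abs=1e-9)
        R = rotation_about_axis([1, 0, 0], 90.0)
        rotated = toy_protein.with_coords(toy_protein.xyz @ R.T)
        assert heme_tilt(rotated) == pytest.approx(90.0, abs=1e-6)

    def test_heme_tilt_matches_cross_product_oracle(self, toy_protein):
        R = rotation_about_axis([2, 1, 0.5], 37.0)
        m = toy_protein.with_coords(toy_protein.xyz @ R.T)
        got = heme_tilt(m)
        heme = m.role == "heme"
        pos = {nm: m.xyz[heme & (m.atom_name == nm)][0]
               for nm in ("NA", "NB", "NC", "ND")}
        n = np.cross(pos["NC"] - pos["NA"], pos["ND"] - pos["NB"])
        c = abs(n[2]) / np.linalg.norm(n)
        assert got == pytest.approx(math.degrees(math.acos(c)), abs=1e-9)


class TestHeight:
    def test_constructed_height(self, combined_system):
        got = height_above_membrane(combined_system)
        m = combined_system
        lip = m.role == "lipid"
        heads = lip & np.isin(m.atom_name, ["P", "N4"]) & (m.xyz[:, 2] > 0)
        oracle = (m.xyz[(m.role == "protein") & m.is_heavy()][:, 2].max()
                  - m.xyz[heads][:, 2].mean())
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_protein_below_plane_is_negative(self):
        pts = [[0, 0, -30]] + [[x, y, z] for x in (0, 5) for y in (0, 5)
                               for z in (20, -20)]
        roles = ["protein"] + ["lipid"] * 8
        names = ["CA"] + ["P"] * 8
        m = _point_model(pts, roles, names=names)
        assert height_above_membrane(m) < 0


class TestInvariances:
    """alpha/beta must ignore translations and rotations about z."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_translation_and_z_rotation(self, toy_protein, seed):
        rng = np.random.default_rng(seed)
        v1, v2 = compute_vectors(toy_protein)
        a0, b0 = orientation_angles(v1, v2)
        shift = rng.normal(0, 20, 3)
        Rz = rotation_about_axis([0, 0, 1], rng.uniform(0, 360))
        moved = toy_protein.with_coords(toy_protein.xyz @ Rz.T + shift)
        v1m, v2m = compute_vectors(moved)
        am, bm = orientation_angles(v1m, v2m)
        assert am == pytest.approx(a0, abs=1e-9)
        assert bm == pytest.approx(b0, abs=1e-9)


class TestHistogramPeakSelect:
    def _records(self, d, a, b):
        import pandas as pd
        n = len(d)
        return pd.DataFrame({"frame": range(n), "d": d, "alpha": a, "beta": b})

    def test_identical_records_select_frame_zero(self):
        rec = self._records([39.5] * 5, [100.0] * 5, [123.0] * 5)
        sel = histogram_peak_select(rec)
        assert sel.frame == 0
        assert sel.peaks["alpha"] == pytest.approx(100.0, abs=0.5)

    def test_recovers_generating_modes_within_one_bin(self):
        rng = np.random.default_rng(4)
        n = 20_000
        rec = self._records(rng.normal(39.5, 2.5, n), rng.normal(100, 9, n),
                            rng.normal(123, 8, n))
        sel = histogram_peak_select(rec, bins=(0.5, 1.0, 1.0))
        assert abs(sel.peaks["d"] - 39.5) <= 0.5
        assert abs(sel.peaks["alpha"] - 100.0) <= 1.0
        assert abs(sel.peaks["beta"] - 123.0) <= 1.0

    def test_zero_window_only_accepts_exact_peak_centers(self):
        # frames 0 and 1 sit exactly at the (unambiguous) peak-bin centres
        rec = self._records([39.75, 39.75, 10.0], [100.5, 100.5, 100.5],
                            [123.5, 123.5, 123.5])
        sel = histogram_peak_select(rec, bins=(0.5, 1.0, 1.0), window_frac=0.0)
        assert sel.frame == 0
        with pytest.raises(NoRepresentativeError):
            histogram_peak_select(
                self._records([39.6, 39.6], [100.5, 100.5], [123.5, 123.5]),
                bins=(0.5, 1.0, 1.0), window_frac=0.0)

    def test_no_representative_reports_best_frames(self):
        rec = self._records([10.1, 10.1], [100.2, 100.2], [120.3, 120.3])
        with pytest.raises(NoRepresentativeError) as exc:
            histogram_peak_select(rec, window_frac=0.0)
        assert set(exc.value.best_frames) == {"d", "alpha", "beta"}

    def test_smoothing_off_reduces_to_raw_argmax(self):
        vals = np.array([1.1, 1.2, 2.1, 2.2, 2.3, 4.5])
        # bins [1,2):2  [2,3):3  [3,4):0  [4,5):1 → raw argmax bin centre 2.5
        assert histogram_peak(vals, 1.0, smooth_bins=0) == pytest.approx(2.5)


class TestAngleVarianceControl:
    def test_rigid_body_trajectory_gives_zero_deviation(self, small_system):
        sched = syn.OrientationSchedule(d=40.0, alpha=95.0, beta=100.0,
                                        sigma_d=1.0, sigma_alpha=4.0,
                                        sigma_beta=4.0)
        traj, _ = syn.generate_rigid_body_trajectory(small_system, sched, 30,
                                                     seed=7)
        dev = angle_variance_control(traj)
        np.testing.assert_allclose(dev["delta_alpha"], 0.0, atol=1e-6)
        np.testing.assert_allclose(dev["delta_beta"], 0.0, atol=1e-6)

    def test_reference_frame_has_exactly_zero_deviation(self, small_system):
        sched = syn.OrientationSchedule(d=40.0, alpha=95.0, beta=100.0)
        traj, _ = syn.generate_rigid_body_trajectory(small_system, sched, 5,
                                                     seed=8)
        dev = angle_variance_control(traj)
        ref = dev.attrs["reference_frame"]
        assert dev.loc[ref, "delta_alpha"] == pytest.approx(0.0, abs=1e-12)

    def test_window_jitter_keeps_deviations_small(self, small_system):
        sched = syn.OrientationSchedule(d=40.0, alpha=95.0, beta=100.0,
                                        sigma_alpha=5.0)
        traj, _ = syn.generate_rigid_body_trajectory(small_system, sched, 40,
                                                     seed=9)
        rng = np.random.default_rng(10)
        win = np.isin(traj.topology.residue_seq,
                      list(range(285, 290)) + list(range(312, 317))
                      + list(range(127, 132)) + list(range(197, 202)))
        frames = traj.frames.copy()
        frames[:, win] += rng.normal(0, 0.2, (traj.n_frames, win.sum(), 3))
        jittered = syn.Trajectory(traj.topology, frames)
        dev = angle_variance_control(jittered)
        assert dev["delta_alpha"].std() < 2.0
        assert dev["delta_beta"].std() < 2.0


class TestOrientationRecordsGroundTruth:
    def test_noiseless_records_match_truth_exactly(self, small_system):
        sched = syn.OrientationSchedule(d=41.0, alpha=100.0, beta=123.0)
        traj, truth = syn.generate_rigid_body_trajectory(small_system, sched,
                                                         10, seed=11)
        rec = orientation_records(traj)
        np.testing.assert_allclose(rec["d"], truth.d, atol=1e-6)
        np.testing.assert_allclose(rec["alpha"], truth.alpha, atol=1e-6)
        np.testing.assert_allclose(rec["beta"], truth.beta, atol=1e-6)

    def test_noisy_records_match_recorded_truth(self, small_system):
        sched = syn.OrientationSchedule(d=39.5, alpha=100.0, beta=123.0,
                                        sigma_d=2.5, sigma_alpha=9.0,
                                        sigma_beta=8.0)
        traj, truth = syn.generate_rigid_body_trajectory(small_system, sched,
                                                         200, seed=12)
        rec = orientation_records(traj)
        np.testing.assert_allclose(rec["alpha"], truth.alpha, atol=1e-6)
        np.testing.assert_allclose(rec["d"], truth.d, atol=1e-6)
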