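import numpy as np
import pytest

import afmrigid as ar
from afmrigid.errors import SearchError
from afmrigid.search import _z_offset_values

from oracles import naive_exhaustive_fit


class TestSphereDirections:
    def test_octahedron_at_90_degrees(self):
        dirs = ar.sphere_directions(90.0)
        assert len(dirs) == 6
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
        # two poles and four equatorial points
        assert np.sum(np.abs(dirs[:, 2]) > 0.99) == 2

    def test_count_closed_form_at_10_degrees(self):
        # 2 poles + 4n points on rings n = 1..17
        assert len(ar.sphere_directions(10.0)) == 2 + 4 * (17 * 18 // 2) == 614

    def test_equator_spacing_equals_step(self):
        step = 10.0
        dirs = ar.sphere_directions(step)
        eq = dirs[np.abs(dirs[:, 2]) < 1e-9]
        azim = np.sort(np.degrees(np.arctan2(eq[:, 1], eq[:, 0])) % 360)
        gaps = np.diff(np.concatenate([azim, [azim[0] + 360]]))
        np.testing.assert_allclose(gaps, step, atol=1e-9)

    def test_literal_ring_population(self):
        # ring n divided into n azimuths: 2 poles + sum(1..17)
        assert len(ar.sphere_directions(10.0, ring_multiplier=1)) == 2 + 17 * 18 // 2

    @pytest.mark.parametrize("bad", [7.0, 120.0, -10.0])
    def test_invalid_step_rejected(self, bad):
        with pytest.raises(ValueError):
            ar.sphere_directions(bad)


class TestOrientations:
    def test_octahedral_group_at_90_degrees(self):
        rots = ar.orientations(90.0)
        assert len(rots) == 24
        # all distinct proper rotations: the rotational octahedral group
        flat = np.round(rots, 9).reshape(24, -1)
        assert len(np.unique(flat, axis=0)) == 24

    def test_count_at_10_degrees(self):
        assert len(ar.orientations(10.0)) == 614 * 36

    def test_all_proper_rotations(self):
        rots = ar.orientations(45.0)
        for r in rots:
            np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_identity_included(self):
        rots = ar.orientations(90.0)
        np.testing.assert_allclose(rots[0], np.eye(3), atol=1e-12)


class TestTranslationGrid:
    def make_sim(self, h, w, frame=(6, 6)):
        arr = np.zeros(frame)
        arr[1 : 1 + h, 1 : 1 + w] = 1.0
        return ar.HeightMap(arr, 1.0)

    def test_counts(self):
        ref5 = ar.HeightMap(np.zeros((5, 5)), 1.0)
        assert len(ar.translation_grid(self.make_sim(3, 3), ref5)) == 9
        assert len(ar.translation_grid(self.make_sim(5, 5, (7, 7)), ref5)) == 1
        ref = ar.HeightMap(np.zeros((6, 10)), 1.0)
        assert len(ar.translation_grid(self.make_sim(2, 4), ref)) == 35

    def test_oversized_window_empty(self):
        ref = ar.HeightMap(np.zeros((3, 3)), 1.0)
        assert ar.translation_grid(self.make_sim(4, 4, (6, 6)), ref) == []

    def test_row_major_order(self):
        ref = ar.HeightMap(np.zeros((4, 4)), 1.0)
        grid = ar.translation_grid(self.make_sim(3, 3), ref)
        assert grid == [(0, 0), (0, 1), (1, 0), (1, 1)]


class TestZOffsets:
    def test_taller_sim_no_offsets(self):
        np.testing.assert_array_equal(_z_offset_values(5.0, 4.0, 0.064), [0.0])

    def test_equal_heights_no_offsets(self):
        np.testing.assert_array_equal(_z_offset_values(4.0, 4.0, 0.064), [0.0])

    def test_gap_scanned_in_steps(self):
        vals = _z_offset_values(4.0, 4.2, 0.064)
        np.testing.assert_allclose(vals, [0.0, 0.064, 0.128, 0.192])

    def test_heightmap_wrapper(self, random_map):
        taller = random_map.with_heights(random_map.heights + 1.0)
        vals = ar.z_offsets(random_map, taller, 0.5)
        assert vals[0] == 0.0 and vals[-1] <= 1.0


class TestExhaustiveFit:
    @pytest.fixture
    def tiny_setup(self):
        model = ar.ground_on_stage(ar.make_blob(12, (3.0, 2.0, 1.5), seed=5))
        probes = [ar.ProbeShape(0.8, 10.0), ar.ProbeShape(1.5, 20.0)]
        # noisy reference so all candidate costs are distinct
        ref, _, _ = ar.make_reference(model, probes[1], 1.0, 0.3, 17, margin_px=2)
        return model, ref, probes

    @pytest.mark.parametrize("score", ["cosine", "correlation", "pixel_rmsd", "penalty"])
    def test_equals_naive_quadruple_loop(self, tiny_setup, score):
        """The vectorized search must reproduce an independent scalar
        quadruple loop over orientations, offsets, z shifts and probes."""
        model, ref, probes = tiny_setup
        got = ar.exhaustive_fit(model, ref, probes, score, step=90.0, top_k=1)[0]
        cost, o, row, col, zi, p = naive_exhaustive_fit(
            model, ref, probes, score, 90.0, ar.DEFAULT_Z_STEP
        )
        assert (got.orientation_index, got.offset_px, got.z_index, got.probe_index) == (
            o, (row, col), zi, p
        )
        assert got.cost == pytest.approx(cost, abs=1e-10)

    def test_self_fit_recovers_truth_with_zero_cost(self):
        model = ar.ground_on_stage(ar.make_blob(25, (5.0, 3.5, 2.0), seed=9))
        probe = ar.ProbeShape(2.0, 20.0)
        ref, truth, _ = ar.make_reference(model, probe, 1.0, 0.0, 1, margin_px=3)
        probes = [ar.ProbeShape(1.0, 10.0), probe, ar.ProbeShape(3.0, 20.0)]
        best = ar.exhaustive_fit(model, ref, probes, "cosine", step=90.0, top_k=1)[0]
        assert best.cost == pytest.approx(0.0, abs=1e-12)
        assert best.probe == probe
        assert ar.structure_rmsd(best.place(model), truth) == pytest.approx(0.0, abs=1e-9)

    def test_ranked_costs_non_decreasing(self, tiny_setup):
        model, ref, probes = tiny_setup
        results = ar.exhaustive_fit(model, ref, probes, "cosine", step=90.0, top_k=10)
        costs = [r.cost for r in results]
        assert costs == sorted(costs)

    def test_scale_invariance_of_argmin(self, tiny_setup):
        """Scaling the reference must not move the cosine/correlation argmin."""
        model, ref, probes = tiny_setup
        scaled = ref.with_heights(1.7 * ref.heights)
        for score in ("cosine", "correlation"):
            a = ar.exhaustive_fit(model, ref, probes, score, step=90.0, top_k=1)[0]
            b = ar.exhaustive_fit(model, scaled, probes, score, step=90.0, top_k=1)[0]
            assert (a.orientation_index, a.offset_px, a.probe_index) == (
                b.orientation_index, b.offset_px, b.probe_index
            )

    def test_shift_invariance_of_correlation_argmin(self, tiny_setup):
        model, ref, probes = tiny_setup
        shifted = ref.with_heights(ref.heights + 0.8)
        a = ar.exhaustive_fit(model, ref, probes, "correlation", step=90.0, top_k=1)[0]
        b = ar.exhaustive_fit(model, shifted, probes, "correlation", step=90.0, top_k=1)[0]
        assert (a.orientation_index, a.offset_px, a.probe_index) == (
            b.orientation_index, b.offset_px, b.probe_index
        )

    def test_empty_grids_raise(self, tiny_setup):
        model, ref, _ = tiny_setup
        with pytest.raises(SearchError):
            ar.exhaustive_fit(model, ref, [], "cosine", step=90.0)
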