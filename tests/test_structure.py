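import numpy as np
import pytest

import afmrigid as ar
from afmrigid.errors import DegenerateGeometryError, ShapeMismatchError
from afmrigid.structure import pca_obb_axes

from conftest import write_minimal_pdb


class TestReadStructure:
    def test_angstrom_to_nm_conversion(self, tmp_path):
        path = write_minimal_pdb(tmp_path / "one.pdb", [(10.0, 0.0, 0.0)])
        model = ar.read_structure(path)
        assert len(model) == 1
        np.testing.assert_allclose(model.positions[0], [1.0, 0.0, 0.0], atol=1e-6)

    def test_uniform_radius_scheme(self, tmp_path):
        path = write_minimal_pdb(tmp_path / "one.pdb", [(0, 0, 0), (1, 1, 1)])
        model = ar.read_structure(path, radius_scheme="uniform", uniform_radius_nm=0.2)
        np.testing.assert_array_equal(model.radii, [0.2, 0.2])

    def test_vdw_radii_by_element(self, tmp_path):
        path = write_minimal_pdb(
            tmp_path / "el.pdb", [(0, 0, 0), (1, 0, 0), (2, 0, 0)], ["C", "N", "S"]
        )
        model = ar.read_structure(path)
        np.testing.assert_allclose(model.radii, [0.170, 0.155, 0.180])

    def test_centroid_matches_hand_mean(self, tmp_path):
        coords = [(1.0, 2.0, 3.0), (4.0, 5.0, 6.0), (7.0, 8.0, 0.0)]
        path = write_minimal_pdb(tmp_path / "three.pdb", coords)
        model = ar.read_structure(path)
        np.testing.assert_allclose(model.centroid, [0.4, 0.5, 0.3], atol=1e-6)

    def test_unparseable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("")
        with pytest.raises(Exception):
            ar.read_structure(bad)

    def test_roundtrip_preserves_coordinates(self, tmp_path, small_blob):
        out = tmp_path / "rt.pdb"
        ar.write_structure(small_blob, out)
        back = ar.read_structure(out, radius_scheme="uniform", uniform_radius_nm=0.5)
        # PDB stores 3 decimals in Angstrom -> 1e-4 nm resolution
        np.testing.assert_allclose(back.positions, small_blob.positions, atol=1e-4)


class TestGroundOnStage:
    def box(self, lx, ly, lz):
        pts = np.array(
            [(x, y, z) for x in (0, lx) for y in (0, ly) for z in (0, lz)],
            dtype=float,
        )
        # interior points break exact PCA degeneracy of a perfect cuboid
        rng = np.random.default_rng(5)
        extra = rng.uniform((0.1, 0.1, 0.1), (lx - 0.1, ly - 0.1, lz - 0.1), (40, 3))
        return ar.AtomicModel(np.vstack([pts, extra]), np.full(48, 0.1))

    def test_largest_face_down(self):
        standing = self.box(4.0, 2.0, 1.0).transformed(
            ar.RigidTransform(
                np.array([[0, 0, 1.0], [0, 1.0, 0], [-1.0, 0, 0]]), np.zeros(3)
            )
        )
        g = ar.ground_on_stage(standing)
        spans = g.positions.max(0) - g.positions.min(0)
        assert spans[0] > spans[1] > spans[2]
        assert spans[2] == pytest.approx(1.0, abs=0.2)

    def test_rests_on_stage(self, small_blob):
        assert np.min(small_blob.positions[:, 2] - small_blob.radii) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_idempotent(self, small_blob):
        again = ar.ground_on_stage(small_blob)
        np.testing.assert_allclose(again.positions, small_blob.positions, atol=1e-9)

    def test_random_rotation_recovers_descending_extents(self):
        model = self.box(4.0, 2.0, 1.0)
        rot = ar.random_axis_rotation(11)
        g = ar.ground_on_stage(model.transformed(ar.RigidTransform(rot, (1.0, -2.0, 3.0))))
        _, extents = pca_obb_axes(g.positions)
        spans = g.positions.max(0) - g.positions.min(0)
        assert spans[0] >= spans[1] >= spans[2]
        assert sorted(extents, reverse=True) == pytest.approx(list(extents))

    def test_collinear_points_raise(self):
        line = ar.AtomicModel(
            np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)]),
            np.full(5, 0.1),
        )
        with pytest.raises(DegenerateGeometryError):
            ar.ground_on_stage(line)


class TestStructureRmsd:
    def test_identical_is_zero(self, small_blob):
        assert ar.structure_rmsd(small_blob, small_blob) == 0.0

    def test_pure_translation_gives_norm(self, small_blob):
        shifted = small_blob.translated((0.3, 0.4, 0.0))
        assert ar.structure_rmsd(small_blob, shifted) == pytest.approx(0.5, abs=1e-12)

    def test_matches_loop_oracle(self, rng, small_blob):
        other = ar.AtomicModel(
            small_blob.positions + rng.normal(0, 0.5, small_blob.positions.shape),
            small_blob.radii,
        )
        loop = np.sqrt(
            np.mean(
                [
                    np.sum((a - b) ** 2)
                    for a, b in zip(small_blob.positions, other.positions)
                ]
            )
        )
        assert ar.structure_rmsd(small_blob, other) == pytest.approx(loop, rel=1e-12)

    def test_translation_covariant(self, rng, small_blob):
        other = ar.AtomicModel(
            small_blob.positions + rng.normal(0, 0.5, small_blob.positions.shape),
            small_blob.radii,
        )
        base = ar.structure_rmsd(small_blob, other)
        t = (1.7, -2.1, 0.4)
        assert ar.structure_rmsd(
            small_blob.translated(t), other.translated(t)
        ) == pytest.approx(base, rel=1e-12)

    def test_count_mismatch_raises(self, small_blob):
        sub = ar.AtomicModel(small_blob.positions[:5], small_blob.radii[:5])
        with pytest.raises(ShapeMismatchError):
            ar.structure_rmsd(small_blob, sub)


class TestWindowedFilamentRmsd:
    @pytest.fixture
    def filament_pair(self):
        monomer = ar.make_blob(8, (2.0, 1.5, 1.2), seed=3)
        truth = ar.make_filament(monomer, 7, rise=2.75, twist=-166.7, ground=False)
        return monomer, truth

    def test_first_and_last_window_zero(self, filament_pair):
        monomer, truth = filament_pair
        n = len(monomer)
        first = ar.AtomicModel(truth.positions[: 3 * n], truth.radii[: 3 * n])
        last = ar.AtomicModel(truth.positions[-3 * n :], truth.radii[-3 * n :])
        assert ar.windowed_filament_rmsd(first, truth, n) == 0.0
        assert ar.windowed_filament_rmsd(last, truth, n) == 0.0

    def test_matches_explicit_window_loop(self, filament_pair, rng):
        monomer, truth = filament_pair
        n = len(monomer)
        pred = ar.AtomicModel(
            truth.positions[n : 4 * n] + rng.normal(0, 0.3, (3 * n, 3)),
            truth.radii[n : 4 * n],
        )
        explicit = min(
            ar.structure_rmsd(
                pred,
                ar.AtomicModel(
                    truth.positions[s * n : (s + 3) * n],
                    truth.radii[s * n : (s + 3) * n],
                ),
            )
            for s in range(5)
        )
        assert ar.windowed_filament_rmsd(pred, truth, n) == pytest.approx(
            explicit, rel=1e-12
        )

    def test_oversized_window_raises(self, filament_pair):
        monomer, truth = filament_pair
        with pytest.raises(ShapeMismatchError):
            ar.windowed_filament_rmsd(truth, monomer, len(monomer))
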