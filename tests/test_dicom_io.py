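"""DICOM CT/RT-DOSE/RT-STRUCT readers, rasterisation, research-format IO."""

import numpy as np
import pytest

from shrinkreg.dicom_io import (
    StructureSet,
    rasterize_structure,
    read_ct_series,
    read_rtdose,
    read_rtstruct,
    read_volume,
    write_ct_series,
    write_rtdose,
    write_rtstruct,
    write_volume,
)
from shrinkreg.errors import FormatError, LookupError_
from shrinkreg.grid import DisplacementField, VolumeImage


@pytest.fixture()
def hu_volume(rng):
    vals = np.round(rng.uniform(-1000, 1500, (10, 16, 16)))
    return VolumeImage(vals, (3.0, 2.0, 2.0), (5.0, -10.0, -20.0))


class TestCtSeries:
    def test_roundtrip_is_bit_identical_in_hu(self, hu_volume, tmp_path):
        write_ct_series(hu_volume, tmp_path)
        back = read_ct_series(tmp_path)
        np.testing.assert_array_equal(back.values, hu_volume.values)
        np.testing.assert_allclose(back.spacing, hu_volume.spacing)
        np.testing.assert_allclose(back.origin, hu_volume.origin)

    def test_rescale_arithmetic(self, tmp_path):
        # slope 1, intercept -1024: stored 1024 must read back as 0 HU
        img = VolumeImage(np.zeros((2, 4, 4)), (3.0, 1.0, 1.0))
        paths = write_ct_series(img, tmp_path)
        import pydicom

        ds = pydicom.dcmread(paths[0])
        assert float(ds.RescaleIntercept) == -1024.0
        assert ds.pixel_array[0, 0] == 1024
        assert read_ct_series(tmp_path).values[0, 0, 0] == 0.0

    def test_order_independence(self, hu_volume, tmp_path, rng):
        paths = write_ct_series(hu_volume, tmp_path)
        shuffled = list(paths)
        rng.shuffle(shuffled)
        back = read_ct_series(shuffled)
        np.testing.assert_array_equal(back.values, hu_volume.values)

    def test_mixed_series_uids_rejected(self, hu_volume, tmp_path):
        write_ct_series(hu_volume, tmp_path / "a")
        write_ct_series(hu_volume, tmp_path / "b")
        files = sorted((tmp_path / "a").glob("*.dcm")) + sorted((tmp_path / "b").glob("*.dcm"))
        with pytest.raises(FormatError):
            read_ct_series(files)


class TestRtDose:
    def test_scaling_arithmetic(self, tmp_path):
        dose = VolumeImage(np.full((2, 3, 3), 70.0), (4.0, 4.0, 4.0))
        path = write_rtdose(dose, tmp_path / "dose.dcm", scaling=0.01)
        import pydicom

        ds = pydicom.dcmread(path)
        assert ds.pixel_array[0, 0, 0] == 7000
        assert read_rtdose(path).values[0, 0, 0] == pytest.approx(70.0)

    def test_roundtrip_preserves_values(self, rng, tmp_path):
        dose = VolumeImage(rng.uniform(0, 75, (5, 6, 6)), (4.0, 4.0, 4.0), (1.3, -2.0, 7.5))
        path = write_rtdose(dose, tmp_path / "dose.dcm")
        back = read_rtdose(path)
        np.testing.assert_allclose(back.values, dose.values, atol=1e-3)
        np.testing.assert_allclose(back.origin, dose.origin)

    def test_missing_scaling_is_format_error(self, tmp_path):
        dose = VolumeImage(np.zeros((2, 2, 2)), (4.0, 4.0, 4.0))
        path = write_rtdose(dose, tmp_path / "dose.dcm")
        import pydicom

        ds = pydicom.dcmread(path)
        del ds.DoseGridScaling
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(FormatError):
            read_rtdose(path)

    def test_grid_offset_world_geometry(self, tmp_path):
        # voxel (k,j,i) center must sit at origin + k*dz etc.
        dose = VolumeImage(np.zeros((3, 2, 2)), (4.0, 2.0, 2.0), (10.0, 4.0, -6.0))
        back = read_rtdose(write_rtdose(dose, tmp_path / "d.dcm"))
        # hand-computed: third frame center z = 10 + 2*4 = 18
        assert back.origin[0] + 2 * back.spacing[0] == pytest.approx(18.0)


def _square_contour(z, lo, hi):
    return np.array(
        [[lo, lo, z], [hi, lo, z], [hi, hi, z], [lo, hi, z]], dtype=float
    )


class TestRtStruct:
    def test_roundtrip(self, tmp_path):
        ss = StructureSet(
            {
                "GTV": [_square_contour(0.0, 2.0, 8.0), _square_contour(3.0, 2.0, 8.0)],
                "empty": [],
            }
        )
        back = read_rtstruct(write_rtstruct(ss, tmp_path / "ss.dcm"))
        assert set(back.names()) == {"GTV", "empty"}
        np.testing.assert_allclose(back["GTV"][0], ss.structures["GTV"][0])

    def test_unknown_name_raises(self):
        ss = StructureSet({"GTV": []})
        with pytest.raises(LookupError_):
            ss["PTV"]


class TestRasterize:
    def _ref(self, nz=2, ny=10, nx=10):
        return VolumeImage(np.zeros((nz, ny, nx)), (3.0, 1.0, 1.0))

    def test_square_matches_point_in_polygon_oracle(self):
        ref = self._ref()
        poly = _square_contour(0.0, 1.5, 6.5)
        mask = rasterize_structure(StructureSet({"t": [poly]}), "t", ref)

        def inside(px, py):
            # even-odd ray casting along +x
            pts = poly[:, :2]
            n, hit = len(pts), False
            for a in range(n):
                x1, y1 = pts[a]
                x2, y2 = pts[(a + 1) % n]
                if (y1 > py) != (y2 > py):
                    xc = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xc:
                        hit = not hit
            return hit

        expected = np.zeros(ref.shape, bool)
        for j in range(ref.shape[1]):
            for k in range(ref.shape[2]):
                expected[0, j, k] = inside(k * 1.0, j * 1.0)
        np.testing.assert_array_equal(mask.values, expected)

    def test_empty_structure_gives_empty_mask(self):
        ref = self._ref()
        mask = rasterize_structure(StructureSet({"t": []}), "t", ref)
        assert mask.voxel_count() == 0

    def test_circle_area_within_perimeter_of_analytic(self):
        ref = self._ref(nz=1, ny=24, nx=24)
        r, c = 5.0, 11.5
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        poly = np.column_stack([c + r * np.cos(theta), c + r * np.sin(theta), np.zeros(100)])
        mask = rasterize_structure(StructureSet({"t": [poly]}), "t", ref)
        assert abs(mask.voxel_count() - np.pi * r**2) <= 2 * np.pi * r

    def test_vertex_order_is_irrelevant(self):
        ref = self._ref()
        poly = _square_contour(0.0, 1.5, 6.5)
        a = rasterize_structure(StructureSet({"t": [poly]}), "t", ref)
        b = rasterize_structure(StructureSet({"t": [poly[::-1]]}), "t", ref)
        np.testing.assert_array_equal(a.values, b.values)


class TestResearchFormats:
    @pytest.mark.parametrize("ext", ["nii", "mha"])
    def test_hu_and_dose_volumes_roundtrip(self, hu_volume, tmp_path, ext):
        path = tmp_path / f"vol.{ext}"
        write_volume(hu_volume, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.values, hu_volume.values, atol=1e-9)
        np.testing.assert_allclose(back.spacing, hu_volume.spacing)
        np.testing.assert_allclose(back.origin, hu_volume.origin)

    @pytest.mark.parametrize("ext", ["nii", "mha"])
    def test_displacement_field_roundtrip(self, rng, tmp_path, ext):
        vec = rng.normal(0, 3, (3, 4, 6, 6))
        field = DisplacementField(vec, (3.0, 2.0, 2.0), (1.0, 2.0, 3.0))
        path = tmp_path / f"field.{ext}"
        write_volume(field, path)
        back = read_volume(path, field=True)
        np.testing.assert_allclose(back.vectors, vec, atol=1e-9)
        np.testing.assert_allclose(back.spacing, field.spacing)
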