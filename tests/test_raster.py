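import numpy as np
import pytest

from cropcycles import classify_pixel_year
from cropcycles.evi import AlgorithmConfig
from cropcycles.raster import (
    GeoRef,
    IntensityMap,
    QcMap,
    apply_cropland_mask,
    compute_intensity_maps,
    compute_intensity_maps_from_arrays,
    difference_map,
    read_evi_stack,
    read_geotiff,
    read_map,
    upscale_intensity,
    write_geotiff,
    write_map,
    write_scene,
)
from cropcycles.simulate import NODATA, SyntheticParams, generate_scene


@pytest.fixture(scope="module")
def clean_scene():
    return generate_scene(
        8, 8, class_mix=(0, 0, 1, 0), years=3,
        template=SyntheticParams(noise_sd=0.0, cloud_prob=0.0), seed=4,
    )


@pytest.fixture(scope="module")
def mixed_scene():
    return generate_scene(8, 8, years=3, noncropland_frac=0.2, seed=5)


class TestGeoTiffRoundTrip:
    @pytest.mark.parametrize(
        "array,nodata",
        [
            (np.arange(12, dtype=np.int16).reshape(3, 4) * 100, None),
            (np.array([[0, 1], [3, 255]], dtype=np.uint8), 255),
            (np.linspace(0, 1, 6, dtype=np.float32).reshape(2, 3), None),
        ],
    )
    def test_values_georef_nodata_survive(self, tmp_path, array, nodata):
        georef = GeoRef(x0=100.0, y0=30.0, px=0.002, py=0.002, epsg=4326)
        p = tmp_path / "band.tif"
        write_geotiff(p, array, georef, nodata=nodata)
        back, georef2, nodata2 = read_geotiff(p)
        np.testing.assert_array_equal(back, array)
        assert back.dtype == array.dtype
        assert georef2 == georef
        assert (nodata2 is None) == (nodata is None)
        if nodata is not None:
            assert int(nodata2) == nodata

    def test_map_roundtrip(self, tmp_path):
        m = IntensityMap(
            data=np.array([[0, 1], [3, NODATA]], dtype=np.uint8),
            georef=GeoRef(x0=10.0, y0=50.0, px=0.01, py=0.01),
            year=2002,
        )
        write_map(tmp_path / "m.tif", m)
        back = read_map(tmp_path / "m.tif", year=2002)
        np.testing.assert_array_equal(back.data, m.data)
        assert back.georef == m.georef
        assert back.nodata == NODATA


class TestReadEviStack:
    def test_small_stack_yields_all_series(self, tmp_path, clean_scene):
        paths = write_scene(clean_scene, tmp_path)
        series = dict(read_evi_stack(paths["evi"], paths["flags"]))
        assert len(series) == 64
        s = series[(0, 0)]
        assert len(s) == 69
        # raw 16-bit values scaled to physical EVI
        raw = clean_scene.evi_raw[:, 0, 0].astype(float) * 1e-4
        np.testing.assert_allclose(s.values, np.clip(raw, -0.2, 1.0), atol=1e-12)

    def test_scale_contract(self, tmp_path):
        write_geotiff(tmp_path / "evi_2001-01-01.tif", np.full((1, 1), 3500, dtype=np.int16))
        write_geotiff(tmp_path / "flag_2001-01-01.tif", np.zeros((1, 1), dtype=np.uint8))
        write_geotiff(tmp_path / "evi_2001-01-17.tif", np.full((1, 1), 7000, dtype=np.int16))
        write_geotiff(tmp_path / "flag_2001-01-17.tif", np.zeros((1, 1), dtype=np.uint8))
        (_, s), = list(
            read_evi_stack(
                [tmp_path / "evi_2001-01-01.tif", tmp_path / "evi_2001-01-17.tif"],
                [tmp_path / "flag_2001-01-01.tif", tmp_path / "flag_2001-01-17.tif"],
            )
        )
        assert s.values[0] == pytest.approx(0.35)
        assert s.times.tolist() == [0, 16]

    def test_mismatched_grids_rejected(self, tmp_path):
        write_geotiff(tmp_path / "evi_2001-01-01.tif", np.zeros((2, 2), dtype=np.int16))
        write_geotiff(tmp_path / "evi_2001-01-17.tif", np.zeros((3, 3), dtype=np.int16))
        write_geotiff(tmp_path / "f1.tif", np.zeros((2, 2), dtype=np.uint8))
        write_geotiff(tmp_path / "f2.tif", np.zeros((2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="grid"):
            list(
                read_evi_stack(
                    [tmp_path / "evi_2001-01-01.tif", tmp_path / "evi_2001-01-17.tif"],
                    [tmp_path / "f1.tif", tmp_path / "f2.tif"],
                )
            )


class TestCroplandMask:
    def test_threshold_is_strict(self):
        grid = np.array([[1, 2], [3, 0]], dtype=np.uint8)
        prob = np.array([[0.05, 0.10], [0.101, 1.0]])
        out = apply_cropland_mask(grid, prob)
        assert out[0, 0] == NODATA  # below threshold
        assert out[0, 1] == NODATA  # exactly 10%: excluded (strict >)
        assert out[1, 0] == 3
        assert out[1, 1] == 0

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            apply_cropland_mask(np.zeros((2, 2)), np.zeros((3, 3)))


class TestComputeIntensityMaps:
    def test_clean_double_crop_scene_maps_all_two_best(self, clean_scene):
        imap, qmap = compute_intensity_maps_from_arrays(
            clean_scene.evi_physical(), clean_scene.flags, clean_scene.dates,
            clean_scene.cropland_prob, 2002,
        )
        np.testing.assert_array_equal(imap.data, np.full((8, 8), 2, dtype=np.uint8))
        np.testing.assert_array_equal(qmap.data, np.zeros((8, 8), dtype=np.uint8))

    def test_noncropland_is_nodata_in_both_maps(self, mixed_scene):
        imap, qmap = compute_intensity_maps_from_arrays(
            mixed_scene.evi_physical(), mixed_scene.flags, mixed_scene.dates,
            mixed_scene.cropland_prob, 2002,
        )
        noncrop = mixed_scene.cropland_prob <= 0.10
        assert noncrop.any()
        assert (imap.data[noncrop] == NODATA).all()
        assert (qmap.data[noncrop] == NODATA).all()
        assert (qmap.data == NODATA).sum() == (imap.data == NODATA).sum()

    def test_mostly_cloudy_year_degrades_qc(self, clean_scene):
        flags = clean_scene.flags.copy()
        evi = clean_scene.evi_physical()
        # 13 of the 23 in-year composites cloudy for pixel (0, 0)
        year_layers = [i for i, d in enumerate(clean_scene.dates) if d.year == 2002]
        for i in year_layers[:13]:
            flags[i, 0, 0] = 3
            evi[i, 0, 0] = 0.05
        _, qmap = compute_intensity_maps_from_arrays(
            evi, flags, clean_scene.dates, clean_scene.cropland_prob, 2002
        )
        assert qmap.data[0, 0] >= 1

    def test_file_pipeline_matches_per_pixel_api(self, tmp_path, mixed_scene):
        paths = write_scene(mixed_scene, tmp_path)
        imap, qmap = compute_intensity_maps(paths["evi"], paths["flags"], paths["cropland"], 2002)
        config = AlgorithmConfig()
        for (r, c), series in read_evi_stack(paths["evi"], paths["flags"], config):
            if mixed_scene.cropland_prob[r, c] <= config.cropland_prob_threshold:
                assert imap.data[r, c] == NODATA
                continue
            res = classify_pixel_year(series, 2002, config)
            assert imap.data[r, c] == res.intensity
            assert qmap.data[r, c] == res.qc_code

    def test_result_independent_of_block_size(self, tmp_path, mixed_scene):
        paths = write_scene(mixed_scene, tmp_path)
        a, _ = compute_intensity_maps(paths["evi"], paths["flags"], paths["cropland"], 2002, block_rows=128)
        b, _ = compute_intensity_maps(paths["evi"], paths["flags"], paths["cropland"], 2002, block_rows=3)
        np.testing.assert_array_equal(a.data, b.data)


class TestUpscale:
    def _map(self, data):
        return IntensityMap(data=np.asarray(data, dtype=np.uint8), georef=GeoRef(), year=2002)

    def test_majority_wins(self):
        m = self._map([[1, 1], [2, NODATA]])
        assert upscale_intensity(m, 2).data[0, 0] == 1

    def test_tie_takes_lower_code(self):
        m = self._map([[1, 1], [2, 2]])
        assert upscale_intensity(m, 2).data[0, 0] == 1

    def test_all_nodata_block_stays_nodata(self):
        m = self._map(np.full((2, 2), NODATA))
        assert upscale_intensity(m, 2).data[0, 0] == NODATA

    def test_padding_and_georef_scaling(self):
        m = IntensityMap(
            data=np.ones((3, 3), dtype=np.uint8), georef=GeoRef(px=0.002, py=0.002), year=2002
        )
        up = upscale_intensity(m, 2)
        assert up.data.shape == (2, 2)
        assert up.data[0, 0] == 1
        assert up.data[1, 1] == 1  # single valid pixel dominates padding
        assert up.georef.px == pytest.approx(0.004)


class TestDifferenceMap:
    def _map(self, data):
        return IntensityMap(data=np.asarray(data, dtype=np.uint8), georef=GeoRef(), year=2002)

    def test_identical_maps_give_zero(self):
        m = self._map([[0, 1], [2, 3]])
        d = difference_map(m, m)
        assert (d.filled(99) == 0).all()

    def test_signed_range(self):
        a = self._map([[3, 0]])
        b = self._map([[0, 3]])
        d = difference_map(a, b)
        assert d[0, 0] == 3
        assert d[0, 1] == -3

    def test_nodata_propagates(self):
        a = self._map([[1, NODATA]])
        b = self._map([[NODATA, 1]])
        d = difference_map(a, b)
        assert d.mask.all()

    def test_misaligned_rejected(self):
        a = self._map([[1]])
        b = IntensityMap(data=np.ones((1, 1), dtype=np.uint8), georef=GeoRef(x0=5.0), year=2002)
        with pytest.raises(ValueError):
            difference_map(a, b)
        with pytest.raises(ValueError):
            difference_map(self._map([[1]]), self._map([[1, 2]]))


def test_qc_map_nodata_matches_intensity_map(mixed_scene):
    imap, qmap = compute_intensity_maps_from_arrays(
        mixed_scene.evi_physical(), mixed_scene.flags, mixed_scene.dates,
        mixed_scene.cropland_prob, 2002,
    )
    np.testing.assert_array_equal(imap.data == NODATA, qmap.data == NODATA)
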