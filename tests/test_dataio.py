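import numpy as np
import pandas as pd
import imageio.v3 as iio
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from dexaseg import dataio


class TestReadImage:
    @pytest.mark.parametrize(
        "dtype,value,expected",
        [
            (np.uint8, 255, 1.0),
            (np.uint8, 0, 0.0),
            (np.uint16, 0, 0.0),
            (np.uint16, 65535, 1.0),
            (np.uint8, 128, 128 / 255),
        ],
    )
    def test_dtype_max_scaling(self, tmp_path, dtype, value, expected):
        path = tmp_path / "img.png"
        iio.imwrite(path, np.full((4, 5), value, dtype=dtype))
        arr = dataio.read_image(path)
        assert arr.shape == (4, 5)
        assert np.allclose(arr, expected, atol=1e-7)

    def test_normalization_is_monotone(self, tmp_path):
        path = tmp_path / "ramp.png"
        ramp = np.arange(256, dtype=np.uint8).reshape(16, 16)
        iio.imwrite(path, ramp)
        arr = dataio.read_image(path)
        assert np.all(np.diff(arr.ravel()) > 0)
        assert arr.min() == 0.0 and arr.max() == 1.0

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            dataio.read_image(tmp_path / "nope.png")

    def test_color_requires_flag(self, tmp_path):
        path = tmp_path / "rgb.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="multi-channel"):
            dataio.read_image(path)
        assert dataio.read_image(path, allow_color=True).shape == (4, 4)


class TestLabelmap:
    def test_all_background(self, tmp_path):
        path = tmp_path / "m.png"
        iio.imwrite(path, np.zeros((6, 6), dtype=np.uint8))
        assert (dataio.read_labelmap(path) == 0).all()

    def test_three_classes_roundtrip(self, tmp_path):
        path = tmp_path / "m.png"
        lab = np.array([[0, 1], [2, 0]], dtype=np.uint8)
        dataio.write_labelmap(path, lab)
        out = dataio.read_labelmap(path)
        assert np.array_equal(out, lab)
        assert set(np.unique(out)) == {0, 1, 2}

    def test_invalid_code_named_in_error(self, tmp_path):
        path = tmp_path / "bad.png"
        iio.imwrite(path, np.full((3, 3), 3, dtype=np.uint8))
        with pytest.raises(dataio.InvalidLabelError, match="3"):
            dataio.read_labelmap(path)


class TestOneHot:
    def test_channel_counts(self):
        lab = np.array([[0, 1], [2, 0]])
        oh = dataio.one_hot(lab)
        assert oh.shape == (3, 2, 2)
        assert oh.sum(axis=(1, 2)).tolist() == [2.0, 1.0, 1.0]
        assert np.array_equal(oh.sum(axis=0), np.ones((2, 2)))

    def test_all_zeros(self):
        oh = dataio.one_hot(np.zeros((3, 4), dtype=int))
        assert (oh[0] == 1).all() and (oh[1:] == 0).all()

    def test_too_few_classes(self):
        with pytest.raises(ValueError, match="n_classes"):
            dataio.one_hot(np.array([[2]]), n_classes=2)

    @settings(derandomize=True, max_examples=50)
    @given(hnp.arrays(np.int64, hnp.array_shapes(min_dims=2, max_dims=2, max_side=12),
                      elements=st.integers(0, 2)))
    def test_argmax_roundtrip(self, lab):
        assert np.array_equal(dataio.one_hot(lab).argmax(axis=0), lab)


class TestManifest:
    def _write(self, tmp_path, rows):
        df = pd.DataFrame(rows, columns=dataio.MANIFEST_COLUMNS)
        path = tmp_path / "manifest.csv"
        dataio.write_manifest(df, path)
        return path, df

    def test_valid_pair(self, tmp_path):
        path, df = self._write(tmp_path, [("S1", "low", "a.png", "m.png"),
                                          ("S1", "high", "b.png", "m.png")])
        out = dataio.load_manifest(path)
        assert len(out) == 2

    def test_roundtrip_identity(self, tmp_path):
        rows = [(f"S{i}", e, f"S{i}_{e}.png", f"S{i}_m.png")
                for i in range(4) for e in ("low", "high")]
        path, df = self._write(tmp_path, rows)
        out = dataio.load_manifest(path)
        pd.testing.assert_frame_equal(out, df)

    def test_single_energy_rejected_unless_flagged(self, tmp_path):
        path, _ = self._write(tmp_path, [("S1", "low", "a.png", "m.png")])
        with pytest.raises(dataio.ManifestError, match="S1"):
            dataio.load_manifest(path)
        assert len(dataio.load_manifest(path, require_pairs=False)) == 1

    def test_study_scale_row_count(self, tmp_path):
        # 300 two-energy subjects -> 600 rows
        rows = [(f"S{i:03d}", e, "i.png", "m.png") for i in range(300) for e in ("low", "high")]
        path, _ = self._write(tmp_path, rows)
        assert len(dataio.load_manifest(path)) == 600
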