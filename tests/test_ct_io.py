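"""Slice/mask I/O, HU windowing, resizing, QC overlay and dataset splits."""

import numpy as np
import pytest

from rdaunet import ct_io
from rdaunet.ct_io import (CTSlice, WindowSpec, MaskSlice, SamplePair,
                           load_slice, apply_hu_window, resize_pair,
                           overlay_check, split_dataset, write_slice_png)
from rdaunet.errors import (FormatError, ContentError, PairingError,
                            ParameterError)
from .conftest import make_pair


def _write_dicom(path, pixels_stored, intercept=-1024.0, slope=1.0):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Rows, ds.Columns = pixels_stored.shape
    ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleIntercept = intercept
    ds.RescaleSlope = slope
    ds.PixelData = pixels_stored.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestLoading:
    def test_dicom_rescale_yields_hu(self, tmp_path):
        stored = np.full((8, 8), 500, dtype=np.uint16)
        stored[0, 0] = 1024  # intercept -1024 -> HU 0
        path = tmp_path / "s.dcm"
        _write_dicom(path, stored)
        ct = load_slice(path, format="dicom")
        assert ct.pixels[0, 0] == 0
        assert ct.pixels[1, 1] == 500 - 1024

    def test_png16_round_trip_is_pixel_identical(self, tmp_path, rng):
        hu = rng.integers(-1000, 1500, size=(16, 16)).astype(np.int32)
        ct = CTSlice(hu, slice_id="x")
        write_slice_png(ct, tmp_path / "x.png")
        back = load_slice(tmp_path / "x.png", format="png16")
        np.testing.assert_array_equal(back.pixels, hu)

    def test_truncated_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.png"
        bad.write_bytes(b"\x89PNG\r\n\x1a\n truncated")
        with pytest.raises(FormatError):
            load_slice(bad, format="png16")
        with pytest.raises(FormatError):
            load_slice(tmp_path / "missing.png")

    def test_rgb_png_is_rejected_as_content_error(self, tmp_path):
        from PIL import Image
        Image.new("RGB", (4, 4)).save(tmp_path / "rgb.png")
        with pytest.raises(ContentError):
            load_slice(tmp_path / "rgb.png", format="png16")


class TestWindowing:
    def test_endpoints_midpoint_and_saturation(self):
        w = WindowSpec(-160, 240)
        ct = CTSlice(np.array([[-160, 240], [40, 740]]))
        out = apply_hu_window(ct, w)
        np.testing.assert_allclose(out, [[0.0, 1.0], [0.5, 1.0]])

    def test_degenerate_window_rejected(self):
        with pytest.raises(ParameterError):
            WindowSpec(100, 100)

    def test_windowing_monotone_and_idempotent(self, rng):
        ct = CTSlice(rng.integers(-500, 1000, size=(10, 10)).astype(int))
        out = apply_hu_window(ct, WindowSpec(-160, 240))
        flat_hu = ct.pixels.ravel()
        flat = out.ravel()
        order = np.argsort(flat_hu)
        assert (np.diff(flat[order]) >= -1e-12).all()
        again = np.clip((out - 0.0) / 1.0, 0, 1)  # re-window with (0,1)
        np.testing.assert_array_equal(again, out)


class TestResize:
    def test_512_to_224_shapes_and_binary_mask(self, rng):
        img = rng.random((512, 512))
        mask = (rng.random((512, 512)) < 0.3).astype(np.uint8)
        out = resize_pair(make_pair(img, mask), 224)
        assert out.image.shape == (224, 224)
        assert out.mask.pixels.shape == (224, 224)
        assert set(np.unique(out.mask.pixels)) <= {0, 1}

    def test_identity_resize_keeps_pixels(self, rng):
        pair = make_pair(rng.random((224, 224)), np.zeros((224, 224), np.uint8))
        out = resize_pair(pair, 224)
        np.testing.assert_array_equal(out.image, pair.image)

    def test_constant_mask_preserved_and_round_trip_binary(self, rng):
        ones = np.ones((64, 64), dtype=np.uint8)
        out = resize_pair(make_pair(rng.random((64, 64)), ones), 224)
        assert (out.mask.pixels == 1).all()
        back = resize_pair(out, 64)
        assert set(np.unique(back.mask.pixels)) <= {0, 1}


class TestOverlay:
    def test_empty_mask_warns_and_reports_zero(self, rng):
        pair = make_pair(rng.random((16, 16)), np.zeros((16, 16), np.uint8))
        with pytest.warns(UserWarning):
            rep = overlay_check(pair)
        assert rep.empty_mask and rep.coverage == 0.0

    def test_bright_foreground_gives_full_coverage(self):
        img = np.full((16, 16), 0.9)
        mask = np.zeros((16, 16), np.uint8)
        mask[4:10, 4:10] = 1
        rep = overlay_check(make_pair(img, mask))
        assert rep.coverage == 1.0
        # contour painted red in the overlay
        assert (rep.overlay[4, 4] == (1.0, 0.0, 0.0)).all()

    def test_shape_mismatch_is_pairing_error(self):
        with pytest.raises(PairingError):
            SamplePair(np.zeros((8, 8)), MaskSlice(np.zeros((9, 9), np.uint8)))


class TestSplit:
    def test_eight_two_counts(self):
        ds = split_dataset(list(range(10)), ratio=0.8, seed=0)
        assert (len(ds.train), len(ds.val)) == (8, 2)

    def test_same_seed_same_membership(self):
        a = split_dataset(list(range(50)), 0.8, seed=3)
        b = split_dataset(list(range(50)), 0.8, seed=3)
        assert a.train == b.train and a.val == b.val

    def test_disjoint_union_preserved_for_various_seeds_and_ratios(self, rng):
        items = list(range(37))
        for seed in (0, 1, 99):
            for ratio in (0.5, 0.8, 0.33):
                ds = split_dataset(items, ratio, seed)
                assert sorted(ds.train + ds.val) == items
                assert len(ds.train) == int(np.floor(ratio * 37))

    def test_bad_ratio_rejected(self):
        with pytest.raises(ParameterError):
            split_dataset(list(range(4)), ratio=1.0, seed=0)


class TestManifests:
    def test_save_load_round_trip(self, tmp_path, organ_pairs):
        manifest = ct_io.save_pairs(organ_pairs[:3], tmp_path,
                                    split_labels=["train", "train", "val"])
        back = ct_io.load_pairs(manifest)
        assert len(back) == 3
        np.testing.assert_array_equal(back[0].mask.pixels,
                                      organ_pairs[0].mask.pixels)
        np.testing.assert_allclose(back[0].image, organ_pairs[0].image,
                                   atol=1.0 / 65535)
        only_train = ct_io.load_pairs(manifest, split="train")
        assert len(only_train) == 2
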