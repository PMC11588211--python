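"""Data model invariants and format round-trips."""

import numpy as np
import pandas as pd
import pytest

from sducl import (
    SpatialDataset,
    crop_patches,
    read_csv_pair,
    read_h5ad,
    read_visium,
    write_h5ad,
    write_fixture_visium,
)
from sducl.datasets import AlignmentError, FormatError


def _tiny_ds(n=4, g=3, with_image=False):
    kw = {}
    if with_image:
        kw = dict(
            image=np.zeros((50, 50, 3), dtype=np.uint8),
            pixel_coords=np.full((n, 2), 25.0),
            spot_diameter_px=10.0,
        )
    return SpatialDataset(
        counts=np.arange(n * g, dtype=float).reshape(n, g),
        coords=np.column_stack([np.arange(n), np.zeros(n)]).astype(float),
        spot_ids=[f"b{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
        **kw,
    )


class TestInvariants:
    def test_negative_counts_rejected(self):
        with pytest.raises(FormatError, match="negative"):
            SpatialDataset(
                counts=np.array([[-1.0]]), coords=np.zeros((1, 2)),
                spot_ids=["a"], gene_ids=["g"],
            )

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(FormatError, match="unique"):
            SpatialDataset(
                counts=np.ones((2, 1)), coords=np.zeros((2, 2)),
                spot_ids=["a", "a"], gene_ids=["g"],
            )

    def test_coord_count_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            SpatialDataset(
                counts=np.ones((3, 1)), coords=np.zeros((2, 2)),
                spot_ids=list("abc"), gene_ids=["g"],
            )

    def test_image_requires_pixel_coords(self):
        with pytest.raises(FormatError, match="pixel_coords"):
            SpatialDataset(
                counts=np.ones((1, 1)), coords=np.zeros((1, 2)),
                spot_ids=["a"], gene_ids=["g"],
                image=np.zeros((5, 5, 3), dtype=np.uint8),
            )


class TestVisium:
    @pytest.mark.parametrize("dialect", ["old", "new"])
    def test_write_read_round_trip(self, tmp_path, small_dataset, dialect):
        write_fixture_visium(small_dataset, tmp_path, dialect=dialect)
        ds = read_visium(tmp_path)
        assert ds.n_spots == small_dataset.n_spots
        # reader may reorder barcodes; align before comparing
        order = [ds.spot_ids.index(b) for b in small_dataset.spot_ids]
        np.testing.assert_array_equal(
            ds.counts[order], small_dataset.counts
        )
        np.testing.assert_allclose(ds.coords[order], small_dataset.coords)
        assert ds.image is not None

    def test_not_in_tissue_spots_dropped(self, tmp_path):
        ds = _tiny_ds(n=5)
        write_fixture_visium(ds, tmp_path)
        pos = pd.read_csv(tmp_path / "tissue_positions_list.csv", header=None)
        pos.iloc[2, 1] = 0  # flag one spot out of tissue
        pos.to_csv(tmp_path / "tissue_positions_list.csv", index=False, header=False)
        out = read_visium(tmp_path)
        assert out.n_spots == 4
        assert "b2" not in out.spot_ids

    def test_empty_directory_is_format_error(self, tmp_path):
        with pytest.raises(FormatError, match="matrix"):
            read_visium(tmp_path)

    def test_missing_positions_is_format_error(self, tmp_path):
        write_fixture_visium(_tiny_ds(), tmp_path)
        (tmp_path / "tissue_positions_list.csv").unlink()
        with pytest.raises(FormatError, match="positions"):
            read_visium(tmp_path)


class TestH5adAndCsv:
    def test_h5ad_round_trip_exact(self, tmp_path, small_dataset):
        p = tmp_path / "d.h5ad"
        write_h5ad(small_dataset, p)
        ds = read_h5ad(p)
        np.testing.assert_array_equal(ds.counts, small_dataset.counts)
        np.testing.assert_array_equal(ds.coords, small_dataset.coords)
        assert ds.spot_ids == small_dataset.spot_ids
        assert list(ds.labels) == list(small_dataset.labels)
        assert list(ds.labels.categories) == list(small_dataset.labels.categories)

    def test_h5ad_without_spatial_slot_rejected(self, tmp_path):
        import anndata as ad

        p = tmp_path / "bad.h5ad"
        ad.AnnData(X=np.ones((3, 2))).write_h5ad(p)
        with pytest.raises(FormatError, match="spatial"):
            read_h5ad(p)

    def test_csv_pair_reads_and_aligns(self, tmp_path):
        counts = pd.DataFrame(
            [[1, 2], [3, 4]], index=["s1", "s2"], columns=["gA", "gB"]
        )
        coords = pd.DataFrame(
            [[0.0, 0.0], [1.0, 1.0]], index=["s2", "s1"], columns=["x", "y"]
        )
        counts.to_csv(tmp_path / "c.csv")
        coords.to_csv(tmp_path / "xy.csv")
        ds = read_csv_pair(tmp_path / "c.csv", tmp_path / "xy.csv")
        assert ds.spot_ids == ["s1", "s2"]
        np.testing.assert_array_equal(ds.coords, [[1.0, 1.0], [0.0, 0.0]])

    def test_csv_pair_disjoint_keys_rejected(self, tmp_path):
        pd.DataFrame([[1]], index=["a"], columns=["g"]).to_csv(tmp_path / "c.csv")
        pd.DataFrame([[0, 0]], index=["z"], columns=["x", "y"]).to_csv(
            tmp_path / "xy.csv"
        )
        with pytest.raises(AlignmentError):
            read_csv_pair(tmp_path / "c.csv", tmp_path / "xy.csv")


class TestPatches:
    def _image_ds(self, pix, H=100, W=100):
        img = np.random.default_rng(0).integers(0, 255, (H, W, 3), dtype=np.uint8)
        n = len(pix)
        return SpatialDataset(
            counts=np.ones((n, 2)), coords=np.asarray(pix, dtype=float),
            spot_ids=[f"s{i}" for i in range(n)], gene_ids=["g1", "g2"],
            image=img, pixel_coords=np.asarray(pix, dtype=float),
            spot_diameter_px=32.0,
        )

    def test_interior_patch_is_direct_slice(self):
        ds = self._image_ds([(50, 50)])
        patch = crop_patches(ds, patch_px=32)[0]
        np.testing.assert_array_equal(patch, ds.image[34:66, 34:66])

    def test_corner_patch_clamped_to_bounds(self):
        ds = self._image_ds([(0, 0)])
        patch = crop_patches(ds, patch_px=32)[0]
        np.testing.assert_array_equal(patch, ds.image[0:32, 0:32])

    def test_stack_shape(self):
        ds = self._image_ds([(20, 20)] * 7)
        assert crop_patches(ds, patch_px=32).shape == (7, 32, 32, 3)

    def test_translation_consistency(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, (80, 80, 3), dtype=np.uint8)
        big = np.zeros((90, 90, 3), dtype=np.uint8)
        big[5:85, 5:85] = img
        ds1 = self._image_ds([(40, 40)])
        ds1.image = img
        ds2 = self._image_ds([(45, 45)])
        ds2.image = big
        np.testing.assert_array_equal(
            crop_patches(ds1, 16)[0], crop_patches(ds2, 16)[0]
        )

    def test_no_image_raises(self):
        with pytest.raises(ValueError, match="image"):
            crop_patches(_tiny_ds(), 8)

    def test_oversized_patch_raises(self):
        ds = self._image_ds([(25, 25)], H=40, W=40)
        with pytest.raises(ValueError, match="exceeds"):
            crop_patches(ds, patch_px=64)
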