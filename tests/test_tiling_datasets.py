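import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scopesr import (
    Crappifier,
    ImageStack,
    IntensityRange,
    SlideConfig,
    TiledDataset,
    TileIndex,
    split_by_tile,
    stitch_tiles,
    tile_image,
)


def _random_stack(rng, shape=(100, 100), axes="YX"):
    return ImageStack(rng.random(shape).astype(np.float32), axes)


class TestTileImage:
    def test_2x2_grid_no_overlap(self, rng):
        tiles = tile_image(_random_stack(rng), SlideConfig(50, 0))
        assert len(tiles) == 4
        assert {ti.tile_pos for ti, _ in tiles} == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_overlap_grid_count(self, rng):
        # stride 25 on extent 100: floor((100-50)/25)+1 = 3 per axis
        tiles = tile_image(_random_stack(rng), SlideConfig(50, 25))
        assert len(tiles) == 9

    def test_tile_equal_to_image(self, rng):
        stack = _random_stack(rng, (64, 64))
        tiles = tile_image(stack, SlideConfig(64, 0))
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0][1].data, stack.data)

    def test_frames_become_items(self, rng):
        stack = _random_stack(rng, (3, 100, 100), "TYX")
        tiles = tile_image(stack, SlideConfig(50, 0))
        assert len(tiles) == 12  # 4 tile positions x 3 frames
        frames = [ti.frame for ti, _ in tiles if ti.tile_pos == (0, 0)]
        assert sorted(frames) == [0, 1, 2]

    def test_pad_reflect_covers_remainder(self, rng):
        tiles = tile_image(_random_stack(rng, (70, 70)), SlideConfig(50, 0, "pad_reflect"))
        assert len(tiles) == 4

    def test_oversized_tile_drop_errors(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            tile_image(_random_stack(rng, (40, 40)), SlideConfig(64, 0))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            SlideConfig(32, 32)
        with pytest.raises(ValueError, match="boundary"):
            SlideConfig(32, 0, "wrap")


class TestSplitByTile:
    def _indices(self, n_tiles=10, n_frames=5):
        return [
            TileIndex("img", (r, 0), f) for r in range(n_tiles) for f in range(n_frames)
        ]

    def test_val_fraction_zero(self):
        train, val = split_by_tile(self._indices(), 0.0, 0)
        assert val == [] and len(train) == 50

    def test_tiles_kept_whole(self):
        indices = self._indices(10, 5)
        train, val = split_by_tile(indices, 0.2, 3)
        assert len(val) == 10  # 2 tiles x 5 frames
        assert set(train) | set(val) == set(indices)
        assert {ti.tile_key for ti in train} & {ti.tile_key for ti in val} == set()

    def test_deterministic(self):
        indices = self._indices()
        assert split_by_tile(indices, 0.3, 9) == split_by_tile(indices, 0.3, 9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), frac=st.floats(0.0, 1.0))
    def test_partition_property(self, seed, frac):
        """For any seed/fraction: disjoint at tile level, frames conserved."""
        indices = self._indices(7, 3)
        train, val = split_by_tile(indices, frac, seed)
        assert len(train) + len(val) == len(indices)
        assert {ti.tile_key for ti in train} & {ti.tile_key for ti in val} == set()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            split_by_tile(self._indices(), 1.5, 0)


class TestStitchTiles:
    @pytest.mark.parametrize("overlap", [0, 25])
    def test_roundtrip_exact(self, rng, overlap):
        stack = _random_stack(rng, (100, 100))
        cfg = SlideConfig(50, overlap)
        back = stitch_tiles(tile_image(stack, cfg), stack.shape, cfg)
        np.testing.assert_allclose(back.data, stack.data, atol=1e-6)

    def test_roundtrip_multiframe_pad_reflect(self, rng):
        stack = _random_stack(rng, (2, 70, 90), "TYX")
        cfg = SlideConfig(32, 8, "pad_reflect")
        back = stitch_tiles(tile_image(stack, cfg), stack.shape, cfg)
        np.testing.assert_allclose(back.data, stack.data, atol=1e-6)

    def test_missing_tiles_reported(self, rng):
        stack = _random_stack(rng)
        cfg = SlideConfig(50, 0)
        tiles = [t for t in tile_image(stack, cfg) if t[0].tile_pos != (1, 1)]
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            stitch_tiles(tiles, stack.shape, cfg)


class TestTiledDataset:
    def _hr_sources(self, rng, n=2):
        return {f"im{i}": _random_stack(rng, (64, 64)) for i in range(n)}

    def test_train_item_recrappified_per_epoch(self, rng):
        ds = TiledDataset(
            self._hr_sources(rng), SlideConfig(32, 0), "train_crappified",
            scale=2, crappifier=Crappifier("poisson", intensity=1.0, gain=200),
            intensity_range=IntensityRange(0.5, 1.5),
        )
        inp1, tgt1 = ds.get_item(0, epoch_seed=1)
        inp1b, tgt1b = ds.get_item(0, epoch_seed=1)
        inp2, tgt2 = ds.get_item(0, epoch_seed=2)
        np.testing.assert_array_equal(inp1.data, inp1b.data)  # same epoch: identical
        assert not np.array_equal(inp1.data, inp2.data)  # new epoch: new degradation
        np.testing.assert_array_equal(tgt1.data, tgt2.data)  # target never changes
        assert inp1.spatial_shape == (16, 16) and tgt1.spatial_shape == (32, 32)

    def test_predict_mode_has_no_target(self, rng):
        ds = TiledDataset(self._hr_sources(rng), SlideConfig(32, 0), "predict_lr_only")
        inp, tgt = ds.get_item(0)
        assert tgt is None

    def test_benchmark_mode_pairs_untouched(self, rng):
        hr = self._hr_sources(rng)
        lr = {k: _random_stack(rng, (32, 32)) for k in hr}
        ds = TiledDataset(hr, None, "benchmark_paired", lr_sources=lr)
        inp, tgt = ds.get_item(0)
        key = ds.indices[0].image_id
        np.testing.assert_array_equal(inp.data, lr[key].data)
        np.testing.assert_array_equal(tgt.data, hr[key].data)

    def test_benchmark_requires_matching_ids(self, rng):
        hr = self._hr_sources(rng)
        with pytest.raises(ValueError, match="identical image ids"):
            TiledDataset(hr, None, "benchmark_paired", lr_sources={"other": _random_stack(rng)})

    def test_length_and_subset(self, rng):
        ds = TiledDataset(
            self._hr_sources(rng, 3), SlideConfig(32, 0), "train_crappified",
            scale=2, crappifier=Crappifier("none"),
        )
        assert len(ds) == 12  # 3 images x 4 tiles
        train, val = split_by_tile(ds.indices, 0.25, 0)
        sub = ds.subset(val)
        assert len(sub) == 3
        with pytest.raises(IndexError):
            sub.get_item(99)

    def test_frame_window_input(self, rng):
        stack = _random_stack(rng, (4, 32, 32), "TYX")
        ds = TiledDataset(
            {"im": stack}, SlideConfig(32, 0), "train_crappified",
            scale=1, crappifier=Crappifier("none"), in_frame_window=3,
        )
        inp, tgt = ds.get_item(1)
        assert inp.shape == (3, 32, 32)  # window of frames in
        assert tgt.shape == (32, 32)  # single frame out
        np.testing.assert_array_equal(inp.data[1], tgt.data)  # center aligns with target
        # boundary frame: window reflects
        inp0, tgt0 = ds.get_item(0)
        np.testing.assert_array_equal(inp0.data[0], inp0.data[2])

    def test_train_mode_requires_crappifier(self, rng):
        with pytest.raises(ValueError, match="crappifier"):
            TiledDataset(self._hr_sources(rng), SlideConfig(32, 0), "train_crappified")
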