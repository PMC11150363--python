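"""Brain extraction, bias-field recovery, resizing and normalisation."""

import numpy as np
import pytest

from brainage import (
    PhantomParams,
    PreprocessConfig,
    VolumeImage,
    correct_bias,
    extract_brain,
    make_phantom,
    normalize_intensity,
    preprocess_pipeline,
    resize_volume,
)
from brainage.preprocess import ExtractionError
from brainage.synthetic import bias_field


def dice(a, b):
    return 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))


class TestExtractBrain:
    def test_supplied_mask_zeroes_background_and_shell(self, quiet_params):
        vol, regions = make_phantom(50, 0, quiet_params, seed=0)
        out = extract_brain(vol, mask=regions.brain)
        assert np.all(out.grid[regions.shell] == 0)
        assert np.all(out.grid[~regions.brain] == 0)
        np.testing.assert_array_equal(out.grid[regions.brain], vol.grid[regions.brain])

    def test_fallback_mask_close_to_ground_truth(self, quiet_params):
        vol, regions = make_phantom(50, 0, quiet_params, seed=0)
        out = extract_brain(vol)
        assert dice(out.mask, regions.brain) >= 0.90

    def test_all_zero_volume_raises_extraction_error(self):
        with pytest.raises(ExtractionError):
            extract_brain(VolumeImage(grid=np.zeros((16, 16, 8))))

    def test_shape_mismatch_rejected(self, quiet_params):
        vol, _ = make_phantom(50, 0, quiet_params, seed=0)
        with pytest.raises(ValueError):
            extract_brain(vol, mask=np.ones((4, 4, 4), bool))

    def test_tool_hook_takes_precedence_over_fallback(self, quiet_params):
        vol, regions = make_phantom(50, 0, quiet_params, seed=0)
        out = extract_brain(vol, tool_hook=lambda v: regions.brain)
        np.testing.assert_array_equal(out.mask, regions.brain)


class TestCorrectBias:
    def test_identity_field_nearly_untouched(self, quiet_params):
        vol, _ = make_phantom(50, 0, quiet_params, seed=0)
        out = correct_bias(vol, vol.mask, order=2)
        rel = np.abs(out.grid[vol.mask] - vol.grid[vol.mask]) / vol.grid[vol.mask]
        assert np.percentile(rel, 99) < 0.02

    def test_known_quadratic_field_recovered(self, quiet_params):
        clean, _ = make_phantom(50, 0, quiet_params, seed=0)
        rng = np.random.default_rng(7)
        field = bias_field(clean.shape, amplitude=0.3, rng=rng)
        biased = VolumeImage(grid=clean.grid * field, mask=clean.mask)
        out = correct_bias(biased, clean.mask, order=2)
        rel = np.abs(out.grid[clean.mask] - clean.grid[clean.mask]) / clean.grid[clean.mask]
        assert rel.max() <= 0.05

    def test_order_zero_is_global_rescale(self, quiet_params):
        vol, _ = make_phantom(50, 0, quiet_params, seed=0)
        rng = np.random.default_rng(3)
        field = bias_field(vol.shape, amplitude=0.2, rng=rng)
        biased = VolumeImage(grid=vol.grid * field, mask=vol.mask)
        out = correct_bias(biased, vol.mask, order=0)
        ratio = out.grid[vol.mask] / biased.grid[vol.mask]
        assert np.allclose(ratio, ratio.mean(), rtol=1e-9)

    def test_mean_intensity_preserved(self, quiet_params):
        vol, _ = make_phantom(50, 0, quiet_params, seed=0)
        rng = np.random.default_rng(5)
        biased = VolumeImage(grid=vol.grid * bias_field(vol.shape, 0.3, rng), mask=vol.mask)
        out = correct_bias(biased, vol.mask, order=2)
        assert np.isclose(out.grid[vol.mask].mean(), biased.grid[vol.mask].mean())

    def test_empty_mask_rejected(self, quiet_params):
        vol, _ = make_phantom(50, 0, quiet_params, seed=0)
        with pytest.raises(ValueError):
            correct_bias(vol, np.zeros(vol.shape, bool))


class TestResizeVolume:
    def test_target_shape_and_spacing(self):
        vol = VolumeImage(grid=np.random.default_rng(0).normal(size=(64, 64, 64)))
        out = resize_volume(vol, (16, 16, 8))
        assert out.shape == (16, 16, 8)
        assert out.spacing == (4.0, 4.0, 8.0)

    def test_constant_grid_stays_constant(self):
        vol = VolumeImage(grid=np.full((20, 12, 10), 7.0))
        out = resize_volume(vol, (7, 5, 3))
        np.testing.assert_allclose(out.grid, 7.0)

    def test_linear_ramp_matches_trilinear_oracle(self):
        """4x4x4 -> 2x2x2 against an independently coded trilinear interpolator."""
        x = np.arange(4, dtype=float)
        grid = x[:, None, None] + 2 * x[None, :, None] + 3 * x[None, None, :]
        out = resize_volume(VolumeImage(grid=grid), (2, 2, 2), anti_alias=False)

        def oracle(g, t):
            res = np.zeros(t)
            f = [s / tt for s, tt in zip(g.shape, t)]
            for i in np.ndindex(t):
                src = [min(max((ii + 0.5) * ff - 0.5, 0), s - 1)
                       for ii, ff, s in zip(i, f, g.shape)]
                lo = [int(np.floor(c)) for c in src]
                hi = [min(l + 1, s - 1) for l, s in zip(lo, g.shape)]
                w = [c - l for c, l in zip(src, lo)]
                acc = 0.0
                for dx in (0, 1):
                    for dy in (0, 1):
                        for dz in (0, 1):
                            cx = hi[0] if dx else lo[0]
                            cy = hi[1] if dy else lo[1]
                            cz = hi[2] if dz else lo[2]
                            wt = ((w[0] if dx else 1 - w[0])
                                  * (w[1] if dy else 1 - w[1])
                                  * (w[2] if dz else 1 - w[2]))
                            acc += wt * g[cx, cy, cz]
                res[i] = acc
            return res

        np.testing.assert_allclose(out.grid, oracle(grid, (2, 2, 2)), atol=1e-6)

    def test_mask_resized_nearest_stays_boolean(self, quiet_params):
        vol, _ = make_phantom(50, 0, quiet_params, seed=0)
        out = resize_volume(vol, (16, 16, 8))
        assert out.mask.dtype == bool and out.mask.any()

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            resize_volume(VolumeImage(grid=np.zeros((8, 8, 8))), (0, 4, 4))


class TestNormalizeIntensity:
    def test_zscore_within_mask(self, quiet_params):
        vol, _ = make_phantom(50, 0, quiet_params, seed=0)
        out = normalize_intensity(vol)
        inside = out.grid[vol.mask]
        assert abs(inside.mean()) < 1e-6
        assert abs(inside.std() - 1) < 1e-6
        assert np.all(out.grid[~vol.mask] == 0)

    def test_idempotent(self, quiet_params):
        vol, _ = make_phantom(50, 0, quiet_params, seed=0)
        once = normalize_intensity(vol)
        twice = normalize_intensity(once)
        np.testing.assert_allclose(twice.grid, once.grid, atol=1e-6)

    def test_constant_region_yields_zeros_with_warning(self, caplog):
        import logging

        vol = VolumeImage(grid=np.full((8, 8, 4), 5.0), mask=np.ones((8, 8, 4), bool))
        with caplog.at_level(logging.WARNING, logger="brainage"):
            out = normalize_intensity(vol)
        assert np.all(out.grid == 0)
        assert any("zero variance" in r.message for r in caplog.records)


class TestPipeline:
    def test_full_pipeline_contract(self, quiet_params):
        vol, regions = make_phantom(50, 1, quiet_params, seed=0)
        out = preprocess_pipeline(vol, PreprocessConfig(target_shape=(16, 16, 8)),
                                  mask=regions.brain)
        assert out.shape == (16, 16, 8)
        inside = out.grid[out.mask]
        assert abs(inside.mean()) < 1e-6 and abs(inside.std() - 1) < 1e-3

    def test_stage_toggle_matches_manual_composition(self, quiet_params):
        vol, regions = make_phantom(50, 1, quiet_params, seed=0)
        cfg = PreprocessConfig(do_bias=False, target_shape=(16, 16, 8))
        via_cfg = preprocess_pipeline(vol, cfg, mask=regions.brain)
        manual = normalize_intensity(
            resize_volume(extract_brain(vol, mask=regions.brain), (16, 16, 8))
        )
        np.testing.assert_allclose(via_cfg.grid, manual.grid)

    def test_bias_correction_improves_biased_phantom(self):
        """With-correction output is closer to the clean reference (in-mask L2)."""
        params = PhantomParams(noise_sd=0.0, bias_amplitude=0.0)
        clean, regions = make_phantom(50, 0, params, seed=0)
        rng = np.random.default_rng(11)
        field = bias_field(clean.shape, amplitude=0.4, rng=rng)
        biased = VolumeImage(grid=clean.grid * field)

        cfg_on = PreprocessConfig(target_shape=(16, 16, 8), do_bias=True)
        cfg_off = PreprocessConfig(target_shape=(16, 16, 8), do_bias=False)
        ref = preprocess_pipeline(clean, cfg_off, mask=regions.brain)
        with_corr = preprocess_pipeline(biased, cfg_on, mask=regions.brain)
        without = preprocess_pipeline(biased, cfg_off, mask=regions.brain)
        m = ref.mask
        err_on = np.linalg.norm(with_corr.grid[m] - ref.grid[m])
        err_off = np.linalg.norm(without.grid[m] - ref.grid[m])
        assert err_on < err_off

    def test_stage_errors_carry_stage_name(self):
        vol = VolumeImage(grid=np.zeros((16, 16, 8)))
        with pytest.raises(ExtractionError, match="extract_brain"):
            preprocess_pipeline(vol, PreprocessConfig())

    def test_pipeline_deterministic(self, quiet_params):
        vol, regions = make_phantom(50, 1, quiet_params, seed=0)
        a = preprocess_pipeline(vol, mask=regions.brain)
        b = preprocess_pipeline(vol, mask=regions.brain)
        np.testing.assert_array_equal(a.grid, b.grid)
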