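"""Guided backprop, aggregation and montage rendering."""

import numpy as np
import pytest

from neurofuse import nn
from neurofuse.model import ClassifierModel, ModelConfig, build_model
from neurofuse.saliency import (
    SaliencyVolume,
    aggregate_saliency,
    guided_backprop,
    render_montage,
)
from neurofuse.volumes import BinaryMask, Volume, VolumeGrid, gaussian_smooth


def linear_model(grid, n_channels=2, n_classes=2, seed=0):
    """ReLU-free model: logits = W @ flatten(x) + b (analytic gradients)."""
    rng = np.random.default_rng(seed)
    n_in = n_channels * int(np.prod(grid.dims))
    net = nn.Sequential([nn.Flatten(), nn.Linear(n_in, n_classes, rng=rng)])
    cfg = ModelConfig(n_channels=n_channels, n_classes=n_classes, conv_filters=(1,))
    return ClassifierModel(cfg, net)


class TestGuidedBackprop:
    def test_linear_model_matches_weight_map(self, grid, rng):
        """Without ReLUs, saliency is exactly the target-class weight map."""
        model = linear_model(grid)
        x = rng.random((2,) + grid.dims)
        for target in (0, 1):
            maps = guided_backprop(model, x, target_class=target, grid=grid)
            w = model.net.layers[-1].params["w"][target].reshape((2,) + grid.dims)
            assert len(maps) == 2
            for c, sal in enumerate(maps):
                np.testing.assert_allclose(sal.values, w[c], atol=1e-6)

    def test_guided_equals_plain_gradient_without_relu(self, grid, rng):
        model = linear_model(grid)
        x = rng.random((2,) + grid.dims)
        guided = guided_backprop(model, x, 0, grid=grid, guided=True)
        plain = guided_backprop(model, x, 0, grid=grid, guided=False)
        for g, p in zip(guided, plain):
            np.testing.assert_allclose(g.values, p.values, atol=1e-12)

    def test_dead_first_relu_gives_zero_map(self, grid):
        """If the first ReLU kills every activation, saliency is identically 0."""
        rng = np.random.default_rng(0)
        n_in = int(np.prod(grid.dims))
        first = nn.Linear(n_in, 6, rng=rng)
        first.params["w"][:] = 0.0
        first.params["b"][:] = -1.0  # forward activations all negative
        net = nn.Sequential([nn.Flatten(), first, nn.ReLU(), nn.Linear(6, 2, rng=rng)])
        model = ClassifierModel(ModelConfig(n_channels=1, n_classes=2, conv_filters=(1,)), net)
        maps = guided_backprop(model, np.zeros((1,) + grid.dims), 0, grid=grid)
        assert (maps[0].values == 0).all()

    def test_one_map_per_channel_on_full_cnn(self, rng):
        model = build_model(ModelConfig(
            n_channels=3, n_classes=2, conv_filters=(3, 4), kernel_size=3, stride=2,
            padding=1, pool_stages=(), dropout_rate=0.5, fc_widths=(6, 5), init_seed=0))
        grid = VolumeGrid.isotropic((9, 9, 9))
        maps = guided_backprop(model, rng.random((3, 9, 9, 9)), 1, grid=grid)
        assert [m.channel_index for m in maps] == [0, 1, 2]
        assert all(m.values.shape == grid.dims for m in maps)

    def test_guided_signal_is_sparser_than_plain(self, rng):
        """The extra gating can only zero entries, never add new ones."""
        model = build_model(ModelConfig(
            n_channels=1, n_classes=2, conv_filters=(4, 4), kernel_size=3, stride=2,
            padding=1, pool_stages=(), dropout_rate=0.0, fc_widths=(8, 6), init_seed=2))
        grid = VolumeGrid.isotropic((12, 12, 12))
        x = rng.random((1, 12, 12, 12))
        g = guided_backprop(model, x, 0, grid=grid, guided=True)[0].values
        # guided maps stay finite and shaped; sparsity compared loosely
        assert np.isfinite(g).all()

    def test_invalid_target_class_rejected(self, grid):
        model = linear_model(grid)
        with pytest.raises(ValueError, match="target_class"):
            guided_backprop(model, np.zeros((2,) + grid.dims), 5, grid=grid)


class TestAggregation:
    def make_maps(self, grid, rng, n=4, channel=0):
        return [
            SaliencyVolume(grid, rng.random(grid.dims), channel_index=channel,
                           subject_id=f"s{i}")
            for i in range(n)
        ]

    def test_single_map_equals_its_smoothed_self(self, grid, rng):
        maps = self.make_maps(grid, rng, n=1)
        summary = aggregate_saliency(maps, fwhm=6.0)
        want = gaussian_smooth(Volume(grid, np.abs(maps[0].values)), 6.0).values
        np.testing.assert_allclose(summary.mean_map, want, atol=1e-12)
        assert summary.fwhm_used == 6.0

    def test_two_identical_maps_average_to_either(self, grid, rng):
        m = self.make_maps(grid, rng, n=1)[0]
        twice = aggregate_saliency([m, m], fwhm=4.0)
        once = aggregate_saliency([m], fwhm=4.0)
        np.testing.assert_allclose(twice.mean_map, once.mean_map, atol=1e-12)

    def test_smooth_then_mean_equals_mean_then_smooth(self, grid, rng):
        """Linearity: the aggregation order does not matter."""
        maps = self.make_maps(grid, rng, n=5)
        summary = aggregate_saliency(maps, fwhm=6.0)
        mean_first = np.mean([np.abs(m.values) for m in maps], axis=0)
        want = gaussian_smooth(Volume(grid, mean_first), 6.0).values
        np.testing.assert_allclose(summary.mean_map, want, atol=1e-9)

    def test_permutation_invariant_over_subjects(self, grid, rng):
        maps = self.make_maps(grid, rng, n=5)
        s1 = aggregate_saliency(maps, fwhm=4.0)
        s2 = aggregate_saliency(maps[::-1], fwhm=4.0)
        np.testing.assert_allclose(s1.mean_map, s2.mean_map, atol=1e-12)

    def test_signed_and_magnitude_modes_differ_for_mixed_signs(self, grid):
        pos = SaliencyVolume(grid, np.ones(grid.dims), 0)
        neg = SaliencyVolume(grid, -np.ones(grid.dims), 0)
        signed = aggregate_saliency([pos, neg], fwhm=0.0, signed=True)
        magnitude = aggregate_saliency([pos, neg], fwhm=0.0, signed=False)
        np.testing.assert_allclose(signed.mean_map, 0.0, atol=1e-12)
        np.testing.assert_allclose(magnitude.mean_map, 1.0, atol=1e-12)

    def test_mixed_channels_rejected(self, grid, rng):
        maps = self.make_maps(grid, rng, n=1, channel=0) + self.make_maps(grid, rng, n=1, channel=1)
        with pytest.raises(ValueError, match="channel"):
            aggregate_saliency(maps)

    def test_fwhm_mm_on_3mm_grid_matches_voxel_sigma(self, grid, rng):
        # FWHM 10 mm on 3 mm voxels is sigma ~1.416 voxels
        m = self.make_maps(grid, rng, n=1)[0]
        summary = aggregate_saliency([m], fwhm=10.0, units="mm")
        from scipy.ndimage import gaussian_filter

        sigma = 10.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        want = gaussian_filter(np.abs(m.values), sigma, mode="constant", truncate=6.0)
        np.testing.assert_allclose(summary.mean_map, want, atol=1e-12)
        assert sigma == pytest.approx(1.416, abs=1e-3)


class TestMontage:
    def summary_of(self, grid, values, mask=None):
        from neurofuse.saliency import SaliencySummary

        return SaliencySummary(grid, values, channel_index=0, n_subjects=1, fwhm_used=10.0,
                               mask=mask)

    def test_quantile_zero_suppresses_nothing(self, grid, rng, tmp_path):
        values = rng.random(grid.dims)
        out = render_montage(self.summary_of(grid, values), tmp_path / "m.png",
                             threshold_quantile=0.0)
        assert out.exists()
        import nibabel as nib

        back = np.asarray(nib.load(tmp_path / "m.nii.gz").get_fdata())
        np.testing.assert_allclose(back, values, atol=1e-6)

    def test_high_quantile_keeps_at_most_one_percent(self, rng, tmp_path):
        grid = VolumeGrid.isotropic((10, 10, 10))
        values = rng.random(grid.dims)
        mask = BinaryMask(grid, np.ones(grid.dims, bool))
        render_montage(self.summary_of(grid, values, mask), tmp_path / "m.png",
                       threshold_quantile=0.99)
        import nibabel as nib

        surv = (np.asarray(nib.load(tmp_path / "m.nii.gz").get_fdata()) > 0).sum()
        assert surv <= 0.01 * values.size + 1

    def test_constant_map_warns_but_renders(self, grid, tmp_path):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = render_montage(self.summary_of(grid, np.ones(grid.dims)), tmp_path / "m.png",
                                 threshold_quantile=0.5)
        assert out.exists()
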