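"""Phantom generator: geometry contracts, noise model, dataset structure."""

import numpy as np
import pytest
from scipy import ndimage

from lumenmorph import (
    DatasetDesign,
    PhantomSpec,
    add_noise,
    brute_force_thickness,
    make_dataset,
    make_gfp_channel,
    make_phantom,
)
from lumenmorph.phantom import ConfigurationError, SizingError


def full_conn(ndim):
    return ndimage.generate_binary_structure(ndim, ndim)


class TestMakePhantom:
    def test_straight_tube_radius_field_is_uniform(self, straight_tube):
        _, truth = straight_tube
        assert np.all(truth.radius_field[truth.mask] == 1.0)
        assert np.all(truth.radius_field[~truth.mask] == 0.0)

    def test_bulkhead_positions_follow_spacing_contract(self):
        spec = PhantomSpec(spacing=(0.1, 0.1), tube_radius=1.0,
                           tube_length=20.0, bulkhead_spacing=2.0,
                           bulkhead_jitter=0.0)
        _, truth = make_phantom(spec)
        assert np.allclose(truth.bulkhead_positions,
                           [2, 4, 6, 8, 10, 12, 14, 16, 18])

    def test_jittered_spacing_keeps_mean_near_nominal(self):
        spec = PhantomSpec(spacing=(0.1, 0.1), tube_length=40.0,
                           bulkhead_spacing=2.0, bulkhead_jitter=0.1, seed=5)
        _, truth = make_phantom(spec)
        diffs = np.diff(truth.bulkhead_positions)
        assert abs(diffs.mean() - 2.0) < 3 * 0.1 * 2.0 / np.sqrt(len(diffs))

    def test_cyst_radius_field_and_no_bulkheads(self, cyst_8um):
        _, truth = cyst_8um
        centre = tuple(np.array(truth.mask.shape) // 2)
        assert truth.radius_field[centre] == 8.0
        assert truth.bulkhead_positions.size == 0
        assert truth.centerline.size == 0

    def test_mask_is_single_component_even_with_deep_bulkheads(self):
        spec = PhantomSpec(spacing=(0.1, 0.1), bulkhead_spacing=2.0,
                           bulkhead_depth=0.95)
        _, truth = make_phantom(spec)
        _, n = ndimage.label(truth.mask, structure=full_conn(2))
        assert n == 1

    def test_branched_tube_is_connected(self):
        spec = PhantomSpec(shape_kind="branched_tube", spacing=(0.2, 0.2),
                           branch_count=3, tube_length=20.0)
        _, truth = make_phantom(spec)
        _, n = ndimage.label(truth.mask, structure=full_conn(2))
        assert n == 1

    def test_object_too_large_names_the_axis(self):
        spec = PhantomSpec(spacing=(0.1, 0.1), tube_length=20.0,
                           image_size=(30, 100))
        with pytest.raises(SizingError, match="axis 1"):
            make_phantom(spec)

    def test_identical_spec_and_seed_give_identical_output(self):
        spec = PhantomSpec(spacing=(0.1, 0.1), bulkhead_jitter=0.2, seed=42)
        img1, t1 = make_phantom(spec)
        img2, t2 = make_phantom(spec)
        assert np.array_equal(img1.data, img2.data)
        assert np.array_equal(t1.bulkhead_positions, t2.bulkhead_positions)

    def test_3d_cyst_renders_a_ball(self):
        spec = PhantomSpec(shape_kind="cyst", spacing=(0.5, 0.5, 0.5),
                           cyst_radius=3.0)
        img, truth = make_phantom(spec)
        assert truth.mask.ndim == 3
        centre = tuple(np.array(truth.mask.shape) // 2)
        assert truth.mask[centre]

    @pytest.mark.parametrize("kind,param", [
        ("tube", 1.0), ("cyst", 4.0),
    ])
    def test_ground_truth_matches_brute_force_oracle(self, kind, param):
        """truth.radius_field equals the oracle radius within a pixel diagonal."""
        spec = PhantomSpec(
            shape_kind=kind, spacing=(0.25, 0.25), tube_radius=param,
            tube_length=8.0, cyst_radius=param, bulkhead_spacing=0.0,
        )
        _, truth = make_phantom(spec)
        oracle_r = brute_force_thickness(truth.mask, spec.spacing).values / 2
        diag = float(np.hypot(0.25, 0.25))
        assert np.abs(oracle_r[truth.mask]
                      - truth.radius_field[truth.mask]).max() <= diag


class TestAddNoise:
    def test_zero_noise_is_identity(self, straight_tube):
        img, _ = straight_tube
        spec = PhantomSpec(noise_gaussian_sd=0.0, noise_poisson_scale=0.0)
        assert add_noise(img, spec) is img

    def test_fixed_seed_is_deterministic(self, straight_tube):
        img, _ = straight_tube
        spec = PhantomSpec(noise_gaussian_sd=5.0, noise_poisson_scale=2.0,
                           seed=9)
        a = add_noise(img, spec)
        b = add_noise(img, spec)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, img.data)

    def test_poisson_preserves_mean_within_standard_error(self):
        from lumenmorph import RasterImage

        img = RasterImage(np.full((1, 100, 100), 100.0), {"actin": 0},
                          (1.0, 1.0))
        spec = PhantomSpec(noise_poisson_scale=1.0, seed=1)
        noisy = add_noise(img, spec)
        # Poisson(100) over 10^4 pixels: SE of the mean = 10/100 = 0.1
        assert abs(noisy.data.mean() - 100.0) < 3 * 0.1

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(noise_gaussian_sd=-1.0)


class TestGfpChannel:
    def _truths(self, n):
        out = []
        for i in range(n):
            spec = PhantomSpec(shape_kind="cyst", spacing=(0.5, 0.5),
                               cyst_radius=2.0, seed=i)
            out.append(make_phantom(spec)[1])
        return out

    def test_fraction_one_covers_every_object(self):
        truths = self._truths(3)
        chan, flags = make_gfp_channel(truths, 1.0, seed=0)
        assert all(flags)
        for t in truths:
            assert chan[t.mask].all()  # dilated mask covers the object

    def test_fraction_zero_gives_empty_channel(self):
        truths = self._truths(3)
        chan, flags = make_gfp_channel(truths, 0.0, seed=0)
        assert not chan.any() and not any(flags)

    def test_half_fraction_marks_rounded_count(self):
        truths = self._truths(10)
        _, flags = make_gfp_channel(truths, 0.5, seed=3)
        assert sum(flags) == 5  # round(10 * 0.5)


class TestMakeDataset:
    def test_replicate_structure_and_distinct_seeds(self):
        design = DatasetDesign(n_experiments=3, images_per_condition=4,
                               master_seed=0)
        ds = make_dataset(design)
        # 2 conditions x 3 experiments x 4 images
        assert len(ds.images) == 24
        seeds = [rec.seed for rec in ds.images]
        assert len(set(seeds)) == len(seeds)

    def test_same_master_seed_reproduces_manifest_and_pixels(self):
        design = DatasetDesign(n_experiments=1, images_per_condition=2,
                               master_seed=7)
        a = make_dataset(design)
        b = make_dataset(design)
        assert a.manifest().equals(b.manifest())
        for ra, rb in zip(a.images, b.images):
            assert np.array_equal(ra.image.data, rb.image.data)

    def test_mixture_counts_match_design_within_rounding(self):
        design = DatasetDesign(
            conditions={"control": {"tube": 1.0},
                        "knockdown": {"tube": 0.8, "cyst": 0.2}},
            n_experiments=2, images_per_condition=2, objects_per_image=5,
            master_seed=1,
        )
        mf = make_dataset(design).manifest()
        ko = mf[mf.condition == "knockdown"]
        per_image = ko.groupby(["experiment", "image"]).kind.value_counts()
        for (_, _), counts in per_image.groupby(level=[0, 1]):
            c = counts.droplevel([0, 1])
            assert c.get("cyst", 0) == 1 and c.get("tube", 0) == 4
        ctrl = mf[mf.condition == "control"]
        assert (ctrl.kind == "tube").all()

    def test_empty_design_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            DatasetDesign(conditions={})

    def test_truth_labels_partition_objects(self):
        design = DatasetDesign(n_experiments=1, images_per_condition=1,
                               master_seed=2)
        ds = make_dataset(design)
        for rec in ds.images:
            ids = np.unique(rec.truth_labels[rec.truth_labels > 0])
            assert len(ids) == len(rec.objects)
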