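"""Histogram statistics: weighting, two-level averaging, threshold fractions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lumenmorph import (
    RadiusHistogram,
    aggregate_image,
    average_histograms,
    fraction_above,
    make_bin_edges,
    object_histogram,
    object_weight,
)
from lumenmorph.histstats import EmptyImageError

EDGES = make_bin_edges(10.0, 0.25)


def hist_with_mass_at(radius_um, edges=EDGES, level="object"):
    """Unit-mass histogram concentrated in the bin containing radius_um."""
    density = np.zeros(len(edges) - 1)
    density[np.searchsorted(edges, radius_um, side="right") - 1] = 1.0
    return RadiusHistogram(edges, density, level=level)


class TestObjectHistogram:
    def test_uniform_radius_concentrates_in_one_bin(self):
        labels = np.ones((4, 4), dtype=np.int32)
        radius = np.full((4, 4), 1.0)
        h = object_histogram(radius, labels, 1, EDGES)
        assert h.density.sum() == pytest.approx(1.0, abs=1e-12)
        assert h.density[np.searchsorted(EDGES, 1.0)] == 1.0  # bin [1.0, 1.25)

    def test_two_radius_levels_split_mass_evenly(self):
        labels = np.ones((2, 4), dtype=np.int32)
        radius = np.array([[1.0, 1.0, 3.0, 3.0], [1.0, 1.0, 3.0, 3.0]])
        h = object_histogram(radius, labels, 1, EDGES)
        assert sorted(h.density[h.density > 0].tolist()) == [0.5, 0.5]

    def test_single_pixel_object_is_valid(self):
        labels = np.zeros((3, 3), dtype=np.int32)
        labels[1, 1] = 1
        h = object_histogram(np.full((3, 3), 0.5), labels, 1, EDGES)
        assert h.density.sum() == pytest.approx(1.0)

    def test_capped_values_fold_into_top_bin(self):
        labels = np.ones((2, 2), dtype=np.int32)
        radius = np.full((2, 2), 10.0)  # == top edge (capped map)
        h = object_histogram(radius, labels, 1, EDGES)
        assert h.density[-1] == 1.0

    def test_unknown_object_id_raises(self):
        with pytest.raises(KeyError):
            object_histogram(np.zeros((2, 2)), np.zeros((2, 2), np.int32),
                             3, EDGES)


@pytest.mark.parametrize("A,w", [(1, 1.0), (4, 8.0), (16, 64.0)])
def test_object_weight_is_a_to_three_halves(A, w):
    assert object_weight(A) == w


def test_object_weight_rejects_non_positive():
    with pytest.raises(ValueError):
        object_weight(0)


class TestAggregateImage:
    def test_single_object_passes_through(self):
        h = hist_with_mass_at(1.0)
        out = aggregate_image([h], [8.0])
        assert np.array_equal(out.density, h.density)
        assert out.level == "image"

    def test_identical_histograms_any_weights_unchanged(self):
        h = hist_with_mass_at(2.0)
        out = aggregate_image([h, h], [1.0, 99.0])
        assert np.allclose(out.density, h.density)

    def test_worked_example_four_and_sixteen_pixels(self):
        # A=4 -> w=8 with mass below 1 um; A=16 -> w=64 with mass above 7 um
        h1 = hist_with_mass_at(0.6)
        h2 = hist_with_mass_at(7.1)
        out = aggregate_image([h1, h2], [object_weight(4), object_weight(16)])
        lo = int(np.searchsorted(EDGES, 0.6, side="right")) - 1
        hi = int(np.searchsorted(EDGES, 7.1, side="right")) - 1
        assert out.density[lo] == pytest.approx(8 / 72)
        assert out.density[hi] == pytest.approx(64 / 72)
        assert out.density.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_objects_is_an_empty_image_sentinel(self):
        with pytest.raises(EmptyImageError):
            aggregate_image([], [])

    def test_equal_sized_objects_reduce_to_unweighted_mean(self):
        h1 = hist_with_mass_at(1.0)
        h2 = hist_with_mass_at(3.0)
        weighted = aggregate_image([h1, h2], [27.0, 27.0])
        unweighted = (h1.density + h2.density) / 2
        assert np.allclose(weighted.density, unweighted)


class TestAverageHistograms:
    def test_identical_images_give_zero_sem(self):
        h = hist_with_mass_at(1.0)
        study, exps = average_histograms([[h, h], [h, h]])
        assert np.array_equal(study.density, h.density)
        assert np.all(study.sem == 0.0)
        assert len(exps) == 2

    def test_two_experiment_means_and_sem(self):
        # per-experiment masses 0.2/0.8 and 0.4/0.6 in two bins
        e1 = RadiusHistogram(EDGES, np.r_[0.2, 0.8, np.zeros(38)])
        e2 = RadiusHistogram(EDGES, np.r_[0.4, 0.6, np.zeros(38)])
        study, _ = average_histograms([[e1], [e2]])
        assert study.density[0] == pytest.approx(0.3)
        # SD of {0.2, 0.4} is 0.1414...; SEM = SD/sqrt(2) = 0.1
        assert study.sem[0] == pytest.approx(0.1)

    def test_single_experiment_omits_sem(self):
        study, _ = average_histograms([[hist_with_mass_at(1.0)]])
        assert study.sem is None

    def test_unbalanced_design_weights_experiments_equally(self):
        # experiment A: 4 images at 1 um; B: 1 image at 3 um
        a = [hist_with_mass_at(1.0)] * 4
        b = [hist_with_mass_at(3.0)]
        study, _ = average_histograms([a, b])
        bin1 = np.searchsorted(EDGES, 1.0)
        bin3 = np.searchsorted(EDGES, 3.0)
        assert study.density[bin1] == pytest.approx(0.5)
        assert study.density[bin3] == pytest.approx(0.5)


class TestFractionAbove:
    def test_all_mass_below_threshold_is_zero(self):
        s = fraction_above([hist_with_mass_at(1.0, level="experiment")], 6.0)
        assert s.mean == 0.0

    def test_all_mass_above_threshold_is_hundred(self):
        s = fraction_above([hist_with_mass_at(8.0, level="experiment")], 6.0)
        assert s.mean == 100.0

    def test_worked_example_gives_88p9_percent(self):
        h1 = hist_with_mass_at(0.75)
        h2 = hist_with_mass_at(7.25)
        img = aggregate_image([h1, h2], [object_weight(4), object_weight(16)])
        s = fraction_above([img], 6.0)
        assert s.mean == pytest.approx(100 * 64 / 72, abs=1e-9)

    def test_object_mode_counts_objects_above(self):
        s = fraction_above(
            [hist_with_mass_at(1.0)], 6.0, mode="object",
            object_max_radii_by_experiment=[[1.0, 7.0, 8.0, 2.0]],
        )
        assert s.mean == pytest.approx(50.0)

    def test_misaligned_threshold_is_realigned_to_nearest_edge(self):
        h = hist_with_mass_at(6.1)  # bin [6.0, 6.25)
        s = fraction_above([h], 6.1)
        assert s.threshold == 6.1
        assert s.mean == 100.0  # realigned to edge 6.0, bin included

    def test_mean_and_sem_across_experiments(self):
        s = fraction_above(
            [hist_with_mass_at(7.0), hist_with_mass_at(1.0)], 6.0,
        )
        assert s.mean == pytest.approx(50.0)
        assert s.sem == pytest.approx(np.std([100, 0], ddof=1) / np.sqrt(2))


@given(st.lists(st.floats(0.01, 9.9), min_size=1, max_size=30),
       st.integers(0, 2**31 - 1))
def test_mass_conservation_through_all_levels(radii, seed):
    """Every histogram at every level sums to 1 within 1e-9."""
    rng = np.random.default_rng(seed)
    hists = [hist_with_mass_at(r) for r in radii]
    weights = rng.integers(1, 100, size=len(radii)).astype(float) ** 1.5
    img = aggregate_image(hists, weights)
    assert abs(img.density.sum() - 1.0) < 1e-9
    study, exps = average_histograms([[img], [img]])
    for h in (study, *exps):
        assert abs(h.density.sum() - 1.0) < 1e-9


@given(st.floats(0.5, 4.0))
def test_scale_equivariance_of_densities_and_fractions(c):
    """Scaling radii and edges by c leaves densities and fractions unchanged."""
    labels = np.ones((4, 4), dtype=np.int32)
    radius = np.linspace(0.5, 8.0, 16).reshape(4, 4)
    h1 = object_histogram(radius, labels, 1, EDGES)
    h2 = object_histogram(radius * c, labels, 1, EDGES * c)
    assert np.allclose(h1.density, h2.density)
    f1 = fraction_above([h1], 6.0)
    f2 = fraction_above([h2], 6.0 * c)
    assert f1.mean == pytest.approx(f2.mean)
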