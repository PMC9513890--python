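"""Phantom generator: determinism, geometry, and diameter statistics."""

import numpy as np
import pytest
from scipy import ndimage

from aneuseg.phantom import (
    PhantomSpec,
    PlacementError,
    desk_spec,
    generate_cohort,
    generate_phantom,
    sample_diameters,
)
from aneuseg.voi import CONNECTIVITY_26

SPEC = desk_spec(seed=11)


@pytest.fixture(scope="module")
def sample():
    return generate_phantom(SPEC)


def test_same_seed_is_voxel_identical(sample):
    again = generate_phantom(desk_spec(seed=11))
    assert np.array_equal(again.bundle.vessel.data, sample.bundle.vessel.data)
    assert np.array_equal(again.bundle.label.data, sample.bundle.label.data)


def test_different_seeds_differ(sample):
    other = generate_phantom(desk_spec(seed=12))
    assert not np.array_equal(other.bundle.vessel.data, sample.bundle.vessel.data)


def test_label_is_subset_of_bright_foreground(sample):
    """Aneurysm voxels must be bright: label intensities well above background."""
    v = sample.bundle.vessel.data
    lab = sample.bundle.label.data > 0
    fg_mean, _ = sample.spec.vessel_intensity
    bg_mean, _ = sample.spec.background_intensity
    assert v[lab].mean() > (fg_mean + bg_mean) / 2


def test_component_count_matches_requested():
    for n in (0, 1, 2):
        s = generate_phantom(desk_spec(seed=21, n_aneurysms=n))
        comp = ndimage.label(s.bundle.label.data, structure=CONNECTIVITY_26)[1]
        assert comp == n
        assert len(s.aneurysm_records) == n


def test_zero_aneurysms_empty_label():
    s = generate_phantom(desk_spec(seed=5, n_aneurysms=0))
    assert s.bundle.label.data.sum() == 0


def test_fixed_diameter_recovered_from_voxel_count():
    """Equivalent-sphere diameter of the label within 15% of the request."""
    spec = PhantomSpec(shape=(96, 96, 96), spacing=(0.5, 0.5, 0.5),
                       n_aneurysms=1, fixed_diameter_mm=6.0, seed=3)
    s = generate_phantom(spec)
    vol_mm3 = s.bundle.label.data.sum() * 0.5 ** 3
    d_eq = 2 * (3 * vol_mm3 / (4 * np.pi)) ** (1 / 3)
    assert abs(d_eq - 6.0) / 6.0 < 0.15


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(shape=(16, 64, 64))
    with pytest.raises(ValueError):
        PhantomSpec(n_vessels=0)
    with pytest.raises(ValueError):
        PhantomSpec(noise_sd=-1)


def test_diameter_sampler_respects_truncation_and_mean():
    rng = np.random.default_rng(0)
    d = sample_diameters(4000, PhantomSpec(), rng)
    assert d.min() >= 2.0 and d.max() <= 20.0
    # cohort rule: mean 5.468 mm; truncation shifts it slightly upward
    assert 4.7 <= d.mean() <= 6.1


class TestCohort:
    def test_five_samples_pairwise_distinct(self):
        cohort = generate_cohort(5, desk_spec(), seed=7)
        assert len(cohort) == 5
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.array_equal(
                    cohort[i].bundle.vessel.data, cohort[j].bundle.vessel.data
                )

    def test_cohort_is_reproducible(self):
        a = generate_cohort(3, desk_spec(), seed=9)
        b = generate_cohort(3, desk_spec(), seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.bundle.vessel.data, y.bundle.vessel.data)

    def test_recorded_diameters_match_sampling_rule_mean(self):
        """Monte-Carlo parameter recovery across a cohort of phantoms."""
        cohort = generate_cohort(60, desk_spec(), seed=13)
        diam = np.array([r[1] for s in cohort for r in s.aneurysm_records])
        assert len(diam) == 60
        se = 3.283 / np.sqrt(len(diam))
        assert abs(diam.mean() - 5.468) < 3 * se + 0.35  # truncation shift margin

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, desk_spec(), seed=1)

    def test_placement_error_carries_sample_index(self):
        tiny = PhantomSpec(shape=(32, 32, 32), spacing=(0.25, 0.25, 0.25),
                           fixed_diameter_mm=19.0)
        with pytest.raises(PlacementError, match="sample 0"):
            generate_cohort(1, tiny, seed=2)
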