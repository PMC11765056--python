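"""Standardization fit/apply and the body-preserving augmentations."""

import numpy as np
import pytest

from dosecast import (
    DomainError,
    FitError,
    PatientCase,
    PhantomConfig,
    VoxelGrid,
    allowed_shift_range,
    augment_dataset,
    fit_standardizer,
    flip_case,
    generate_cohort,
    standardize,
    translate_case,
)
from dosecast.dvh_metrics import dvh_criteria
from dosecast.preprocess import Standardizer


def _tiny_case(ct):
    """Bypass grid minima to hold an arbitrary CT volume for fitting tests."""
    case = PatientCase.__new__(PatientCase)
    case.ct = np.asarray(ct, dtype=np.float64)
    return case


def test_fit_population_moments():
    """CT {0,0,6} pools to mu=2 and population sd sqrt(8)=2.828..."""
    s = fit_standardizer([_tiny_case([0.0, 0.0, 6.0])])
    assert s.mu == pytest.approx(2.0)
    assert s.sigma == pytest.approx(np.sqrt(8.0))
    np.testing.assert_allclose(
        standardize(np.array([0.0, 0.0, 6.0]), s),
        [-0.7071067, -0.7071067, 1.4142135], atol=1e-6)


def test_fit_rejects_constant_and_empty():
    with pytest.raises(FitError):
        fit_standardizer([_tiny_case([5.0, 5.0, 5.0])])
    with pytest.raises(DomainError):
        fit_standardizer([])


def test_standardize_maps_mu_to_zero_and_mu_plus_sigma_to_one():
    s = Standardizer(mu=10.0, sigma=4.0)
    assert standardize(np.array([10.0]), s)[0] == 0.0
    assert standardize(np.array([14.0]), s)[0] == 1.0


def test_fit_then_standardize_gives_unit_moments(full_case):
    s = fit_standardizer([full_case])
    z = standardize(full_case.ct, s)
    assert abs(z.mean()) < 1e-6
    assert abs(z.std() - 1.0) < 1e-6


def test_standardizer_is_affine_equivariant(full_case):
    """Refitting on a*x+b gives the same z-scores as the original fit."""
    s = fit_standardizer([full_case])
    scaled = _tiny_case(2.0 * full_case.ct.astype(np.float64) + 100.0)
    s2 = fit_standardizer([scaled])
    np.testing.assert_allclose(standardize(scaled.ct, s2),
                               standardize(full_case.ct, s), atol=1e-9)


def test_standardizer_text_round_trip(tmp_path):
    s = Standardizer(mu=919.39, sigma=396.02)
    s.save(tmp_path / "standardizer.txt")
    back = Standardizer.load(tmp_path / "standardizer.txt")
    assert (back.mu, back.sigma) == (s.mu, s.sigma)


def test_flip_empty_axes_is_identity(full_case):
    same = flip_case(full_case, ())
    np.testing.assert_array_equal(same.ct, full_case.ct)


def test_flip_moves_voxels_and_is_involutive(full_case):
    f = flip_case(full_case, {0})
    n = full_case.grid.shape[0]
    assert f.ct[n - 1 - 3, 5, 7] == full_case.ct[3, 5, 7]
    ff = flip_case(f, {0})
    np.testing.assert_array_equal(ff.ct, full_case.ct)
    np.testing.assert_array_equal(ff.reference_dose, full_case.reference_dose)


def test_flip_rejects_bad_axis(full_case):
    with pytest.raises(DomainError):
        flip_case(full_case, {3})


def test_flip_preserves_dvh_criteria(full_case):
    """DVH criteria are permutation-invariant, so any flip leaves them fixed."""
    flipped = flip_case(full_case, {0, 2})
    a = dvh_criteria(full_case.reference_dose, full_case.masks)
    b = dvh_criteria(flipped.reference_dose, flipped.masks)
    np.testing.assert_allclose(a.values(), b.values(), atol=1e-9)
    assert a.labels() == b.labels()


@pytest.fixture()
def box_case(full_case):
    """A case whose body is a box spanning 10..20 along axis 0 (extent 32)."""
    case = full_case.copy()
    case.ct[:] = 0
    case.ct[10:21, 8:18, 12:22] = 1000.0
    case.possible_dose_mask = (case.ct > 0).astype(np.uint8)
    mask = np.zeros(case.grid.shape, dtype=np.uint8)
    mask[12:15, 10:13, 14:17] = 1
    case.masks = {"Larynx": mask}
    case.reference_dose = None
    return case


def test_allowed_shift_range_bounding_box_arithmetic(box_case):
    """Body box 10..20 on extent 32 allows shifts -10 .. +11 inclusive."""
    ranges = allowed_shift_range(box_case)
    assert ranges[0] == (-10, 11)
    assert ranges[1] == (-8, 14)
    assert ranges[2] == (-12, 10)


def test_phantom_shift_range_matches_its_bounding_box(full_case):
    body = full_case.possible_dose_mask
    for axis, (lo_shift, hi_shift) in enumerate(allowed_shift_range(full_case)):
        proj = np.any(body, axis=tuple(a for a in range(3) if a != axis))
        nz = np.flatnonzero(proj)
        assert lo_shift == -nz[0]
        assert hi_shift == full_case.grid.shape[axis] - 1 - nz[-1]
        # centered phantom body: symmetric range up to one voxel
        assert abs(abs(lo_shift) - abs(hi_shift)) <= 1


def test_translate_zero_is_identity_and_conserves_masks(box_case):
    same = translate_case(box_case, (0, 0, 0))
    np.testing.assert_array_equal(same.ct, box_case.ct)
    moved = translate_case(box_case, (11, -8, 10))
    assert moved.masks["Larynx"].sum() == box_case.masks["Larynx"].sum()
    assert moved.possible_dose_mask.sum() == box_case.possible_dose_mask.sum()


def test_translate_inverse(box_case):
    moved = translate_case(box_case, (2, -1, 3))
    back = translate_case(moved, (-2, 1, -3))
    np.testing.assert_array_equal(back.ct, box_case.ct)
    np.testing.assert_array_equal(back.masks["Larynx"], box_case.masks["Larynx"])


def test_translate_out_of_range_raises_not_crops(box_case):
    with pytest.raises(DomainError):
        translate_case(box_case, (12, 0, 0))  # body box would leave the grid
    with pytest.raises(DomainError):
        translate_case(box_case, (0, 0, -13))


def test_augment_counts(grid32):
    cfg = PhantomConfig(grid=grid32, seed=1, missing_structure_rate=0.0)
    assert augment_dataset([], seed=0) == []
    cohort = generate_cohort(cfg, 5)
    out = augment_dataset(cohort, seed=9)
    assert len(out) == 20
    assert len({c.id for c in out}) == 20
    # deterministic given the seed
    out2 = augment_dataset(cohort, seed=9)
    for a, b in zip(out, out2):
        np.testing.assert_array_equal(a.ct, b.ct)
    # every variant conserves structure voxel counts
    for i, case in enumerate(cohort):
        for variant in out[4 * i:4 * i + 4]:
            for name in case.masks:
                assert variant.masks[name].sum() == case.masks[name].sum()
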