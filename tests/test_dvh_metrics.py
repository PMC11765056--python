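"""DVH machinery against brute-force oracles and symmetry properties."""

import numpy as np
import pytest

from dosecast import (
    DomainError,
    VoxelGrid,
    cohort_dvh_score,
    dose_at_volume,
    dvh_criteria,
    dvh_curve,
    dvh_score,
    dvh_values,
)
from dosecast.dvh_metrics import DVHValues


def brute_force_percentile(values, p):
    """Independent sort-and-interpolate oracle at fractional rank p/100*(N-1)."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    r = p / 100.0 * (len(v) - 1)
    lo, hi = int(np.floor(r)), int(np.ceil(r))
    w = r - lo
    return v[lo] * (1 - w) + v[hi] * w


@pytest.mark.parametrize(
    "values,k,expected",
    [
        (np.full(17, 50.0), 30, 50.0),          # uniform structure
        (np.arange(101.0), 1, 99.0),            # 0..100, D1 = 99th pct
        (np.array([10.0, 20.0, 30.0, 40.0]), 50, 25.0),  # rank 1.5
    ],
)
def test_dose_at_volume_examples(values, k, expected):
    assert dose_at_volume(values, k) == pytest.approx(expected, abs=1e-12)


def test_dose_at_volume_validates():
    with pytest.raises(DomainError):
        dose_at_volume(np.array([]), 50)
    with pytest.raises(DomainError):
        dose_at_volume(np.array([1.0]), 0)
    with pytest.raises(DomainError):
        dose_at_volume(np.array([1.0]), 100)


def test_percentiles_match_brute_force_oracle(rng):
    """200 random 6^3 structures: every D_k equals the oracle to 1e-9."""
    for _ in range(200):
        n = int(rng.integers(1, 217))
        vals = rng.uniform(0, 70, size=n)
        for k in (1, 5, 50, 95, 99):
            assert dose_at_volume(vals, k) == pytest.approx(
                brute_force_percentile(vals, 100 - k), abs=1e-9)


def test_criteria_cardinality(full_case):
    dose = full_case.reference_dose
    assert dvh_criteria(dose, full_case.masks).n == 990
    masks = dict(full_case.masks)
    masks.pop("Esophagus")
    assert dvh_criteria(dose, masks).n == 891


def test_criteria_nonincreasing_in_k(full_case):
    crit = dvh_criteria(full_case.reference_dose, full_case.masks)
    values = crit.values().reshape(10, 99)
    assert np.all(np.diff(values, axis=1) <= 1e-12)


def test_uniform_structure_has_constant_criteria(grid16):
    dose = np.full(grid16.shape, 30.0)
    mask = np.zeros(grid16.shape, dtype=np.uint8)
    mask[4:8, 4:8, 4:8] = 1
    crit = dvh_criteria(dose, {"Larynx": mask})
    assert crit.n == 99
    assert np.allclose(crit.values(), 30.0)


def test_present_but_empty_mask_is_an_error(grid16):
    dose = np.zeros(grid16.shape)
    with pytest.raises(DomainError):
        dvh_criteria(dose, {"Larynx": np.zeros(grid16.shape, dtype=np.uint8)})


def test_values_vector_length_and_contents(full_case):
    vals = dvh_values(full_case.reference_dose, full_case.masks, full_case.grid)
    assert len(vals.entries) == 23
    metrics = {(s, m) for (s, m, _) in vals.entries}
    assert ("Brainstem", "Dmean") in metrics and ("PTV70", "D95") in metrics


def test_uniform_oar_dmean_equals_d01cc(grid16):
    dose = np.full(grid16.shape, 60.0)
    mask = np.zeros(grid16.shape, dtype=np.uint8)
    mask[2:10, 2:10, 2:10] = 1
    vals = dvh_values(dose, {"Brainstem": mask}, grid16)
    d = dict(((s, m), v) for (s, m, v) in vals.entries)
    assert d[("Brainstem", "Dmean")] == pytest.approx(60.0)
    assert d[("Brainstem", "D0.1cc")] == pytest.approx(60.0)


def test_d01cc_order_statistic():
    """100 voxels of 1..100 Gy at 0.05 cc each: m=2, D0.1cc = 99 Gy."""
    grid = VoxelGrid((10, 10, 8), spacing=(5.0, 5.0, 2.0))  # 0.05 cc voxels
    dose = np.zeros(grid.shape)
    mask = np.zeros(grid.shape, dtype=np.uint8)
    mask[0, :, :] = 1
    mask[1, :2, :] = 1  # 96 voxels... fill exactly 100
    sel = np.argwhere(mask)
    assert len(sel) == 96
    mask[1, 2, :4] = 1  # now 100 voxels
    sel = np.argwhere(mask)
    dose[tuple(sel.T)] = np.arange(1.0, 101.0)
    vals = dvh_values(dose, {"Larynx": mask}, grid)
    d = dict(((s, m), v) for (s, m, v) in vals.entries)
    assert d[("Larynx", "D0.1cc")] == pytest.approx(99.0)


def test_dvh_score_mean_absolute_difference():
    a = DVHValues(entries=(("Brainstem", "Dmean", 1.0),
                           ("Brainstem", "D0.1cc", 2.0),
                           ("PTV70", "D95", 3.0)))
    b = DVHValues(entries=(("Brainstem", "Dmean", 2.0),
                           ("Brainstem", "D0.1cc", 2.0),
                           ("PTV70", "D95", 5.0)))
    assert dvh_score(a, a) == 0.0
    assert dvh_score(a, b) == pytest.approx(1.0)
    assert dvh_score(b, a) == pytest.approx(1.0)
    assert dvh_score(a, b, strict_sum=True) == pytest.approx(3.0)
    assert cohort_dvh_score([1.0, 3.0]) == pytest.approx(2.0)


def test_dvh_score_rejects_mismatched_labels():
    a = DVHValues(entries=(("Brainstem", "Dmean", 1.0),))
    b = DVHValues(entries=(("Larynx", "Dmean", 1.0),))
    with pytest.raises(DomainError):
        dvh_score(a, b)


def test_dvh_curve_examples(grid16):
    mask = np.zeros(grid16.shape, dtype=np.uint8)
    mask[:4] = 1
    uniform = np.full(grid16.shape, 40.0)
    edges = np.array([0.0, 20.0, 40.0, 60.0])
    np.testing.assert_allclose(dvh_curve(uniform, mask, edges), [1, 1, 1, 0])
    half = np.where(np.arange(16)[:, None, None] % 2 == 0, 20.0, 60.0) \
        * np.ones(grid16.shape)
    frac = dvh_curve(half, mask, np.array([0.0, 40.0]))
    assert frac[0] == 1.0
    assert frac[1] == pytest.approx(0.5)
    curve = dvh_curve(half, mask, np.arange(0.0, 70.0, 5.0))
    assert np.all(np.diff(curve) <= 0)


def test_joint_permutation_invariance(full_case, rng):
    """Jointly permuting dose and masks leaves criteria and values unchanged."""
    dose = full_case.reference_dose
    perm = rng.permutation(dose.size)
    dose_p = dose.reshape(-1)[perm].reshape(dose.shape)
    masks_p = {k: v.reshape(-1)[perm].reshape(v.shape)
               for k, v in full_case.masks.items()}
    a = dvh_criteria(dose, full_case.masks)
    b = dvh_criteria(dose_p, masks_p)
    np.testing.assert_allclose(a.values(), b.values(), atol=1e-9)
    va = dvh_values(dose, full_case.masks, full_case.grid)
    vb = dvh_values(dose_p, masks_p, full_case.grid)
    np.testing.assert_allclose(va.values(), vb.values(), atol=1e-9)


def test_uniform_shift_moves_every_metric_by_c(full_case):
    """+c Gy inside a structure shifts its percentiles and Dmean by exactly c."""
    c = 2.5
    dose = full_case.reference_dose.astype(np.float64)
    shifted = dose.copy()
    for m in full_case.masks.values():
        shifted[m > 0] += c
    a = dvh_criteria(dose, full_case.masks)
    b = dvh_criteria(shifted, full_case.masks)
    np.testing.assert_allclose(b.values() - a.values(), c, atol=1e-9)
    va = dvh_values(dose, full_case.masks, full_case.grid)
    vb = dvh_values(shifted, full_case.masks, full_case.grid)
    np.testing.assert_allclose(vb.values() - va.values(), c, atol=1e-9)
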