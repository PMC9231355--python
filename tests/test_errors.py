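import numpy as np
import pytest
from scipy import ndimage

from dosestab import (
    ErrorModel,
    ProtocolSpec,
    ShiftSchedule,
    accumulate_error_dose,
    run_error_protocol,
    sample_shift_schedule,
    translate_dose,
)


def test_schedule_length_and_bound():
    model = ErrorModel()
    sched = sample_shift_schedule(30, model, seed=1)
    assert len(sched) == 30
    assert np.max(np.abs(sched.shifts)) <= model.bound_mm
    with pytest.raises(ValueError):
        sample_shift_schedule(0, model, seed=1)


def test_large_sample_statistics():
    model = ErrorModel()
    sched = sample_shift_schedule(40000, model, seed=123)
    comp = sched.shifts.ravel()
    assert comp.size >= 1e5
    assert np.max(np.abs(comp)) <= 3.0
    se = comp.std(ddof=1) / np.sqrt(comp.size)
    assert abs(comp.mean()) <= 3 * se
    # clipping piles mass exactly at the cap
    assert np.any(np.abs(comp) == 3.0)


def test_rejection_sampling_stays_within_bound_without_atoms():
    model = ErrorModel(truncation="reject")
    sched = sample_shift_schedule(5000, model, seed=5)
    comp = sched.shifts.ravel()
    assert np.max(np.abs(comp)) <= 3.0
    assert not np.any(np.abs(comp) == 3.0)


def test_translate_identity_and_bound(default_patient):
    grid, _ = default_patient
    out = translate_dose(grid, (0.0, 0.0, 0.0))
    assert np.array_equal(out.values, grid.values)
    with pytest.raises(ValueError, match="bound"):
        translate_dose(grid, (4.0, 0.0, 0.0))


def test_translate_one_voxel_equals_index_shift(default_patient):
    grid, _ = default_patient
    out = translate_dose(grid, (grid.spacing[0], 0.0, 0.0))
    assert np.allclose(out.values[1:], grid.values[:-1], atol=1e-12)
    assert np.allclose(out.values[0], 0.0)


def test_translation_conserves_integral_dose(default_patient):
    grid, _ = default_patient
    total = grid.values.sum()
    for shift in [(3, -3, 3), (1.7, -2.2, 0.4), (-2.9, 0.1, 2.3)]:
        out = translate_dose(grid, shift)
        assert abs(out.values.sum() - total) / total <= 1e-6


def test_accumulate_zero_and_single_schedules(default_patient):
    grid, _ = default_patient
    zero = ShiftSchedule(np.zeros((5, 3)))
    assert np.allclose(accumulate_error_dose(grid, zero).values, grid.values)
    one = ShiftSchedule(np.array([[1.3, -2.0, 0.7]]))
    direct = translate_dose(grid, (1.3, -2.0, 0.7))
    assert np.allclose(accumulate_error_dose(grid, one).values, direct.values)


def test_accumulation_converges_to_kernel_convolution(default_patient):
    """With many fractions the blurred dose approaches the planned dose
    convolved with the clipped-Gaussian displacement kernel."""
    grid, _ = default_patient
    model = ErrorModel()
    # empirical displacement kernel from a large independent sample,
    # splatted with trilinear weights onto the voxel grid
    ref = sample_shift_schedule(100_000, model, seed=999).shifts
    reach = int(np.ceil(model.bound_mm / min(grid.spacing))) + 1
    size = 2 * reach + 1
    kernel = np.zeros((size, size, size))
    vox = ref / np.asarray(grid.spacing)
    base = np.floor(vox).astype(int)
    frac = vox - base
    for corner in np.ndindex(2, 2, 2):
        w = np.prod(
            np.where(np.asarray(corner), frac, 1.0 - frac), axis=1
        )
        idx = base + np.asarray(corner) + reach
        np.add.at(kernel, tuple(idx.T), w)
    kernel /= kernel.sum()
    expected = ndimage.convolve(grid.values, kernel, mode="constant")

    scale = grid.values.max()
    rms = []
    for n in (50, 500, 2000):
        acc = accumulate_error_dose(grid, sample_shift_schedule(n, model, seed=4))
        rms.append(np.sqrt(np.mean((acc.values - expected) ** 2)) / scale)
    assert rms[0] > rms[1] > rms[2]
    assert rms[2] < 5e-3


def test_protocol_census_and_schedule_sharing(default_patient):
    grid, _ = default_patient
    small = ProtocolSpec(fraction_groups=(2, 5), replicates=3, base_seed=9)
    doses = run_error_protocol(grid, small, ErrorModel())
    assert len(doses) == 2 * 3 + 1
    assert "original" in doses
    # schedules depend only on (base_seed, group, replicate) when shared
    from dosestab.errors import schedule_seed

    s1 = sample_shift_schedule(5, ErrorModel(), schedule_seed(9, 5, 2, None))
    s2 = sample_shift_schedule(5, ErrorModel(), schedule_seed(9, 5, 2, None))
    assert np.array_equal(s1.shifts, s2.shifts)
    other_patient = run_error_protocol(grid, small, ErrorModel(), patient=3)
    for key in doses:
        assert np.array_equal(doses[key].values, other_patient[key].values)


def test_zero_error_limit(default_patient):
    grid, _ = default_patient
    model = ErrorModel(sd=(0.0, 0.0, 0.0))
    doses = run_error_protocol(
        grid, ProtocolSpec(fraction_groups=(2, 10), replicates=2), model
    )
    for key, dose in doses.items():
        # summing n identical volumes and dividing by n is float-exact only
        # for powers of two, hence the tight tolerance instead of equality
        assert np.allclose(dose.values, grid.values, rtol=1e-13, atol=1e-12), key


def test_replicate_variance_decreases_with_fraction_count(default_patient):
    """More fractions average the error out: across-replicate voxel variance
    inside the PTV shrinks as the fraction count grows."""
    grid, masks = default_patient
    ptv = masks["PTV"].values
    protocol = ProtocolSpec(fraction_groups=(2, 10, 20, 30), replicates=20, base_seed=2)
    doses = run_error_protocol(grid, protocol, ErrorModel())
    var_by_group = []
    for n in protocol.fraction_groups:
        stack = np.stack([doses[(n, r)].values[ptv] for r in range(20)])
        var_by_group.append(stack.var(axis=0).mean())
    assert var_by_group == sorted(var_by_group, reverse=True)
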