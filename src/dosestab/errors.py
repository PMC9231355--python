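"""Random interfractional setup error: shift sampling and dose accumulation.

Per-fraction isocenter displacements are drawn from a truncated Gaussian
(zero mean, 1.2 mm SD per axis, capped at +/-3 mm per axis by default).  The
planned dose grid is translated rigidly by each per-fraction shift and the
per-fraction doses are averaged, so that the error-free accumulated dose
equals the planned one ("same total dose" across fraction schemes).  The
rigid translation of a static dose cloud is the standard approximation for
random setup error; it replaces a per-fraction dose recalculation.

Seeds for the (fraction-group, replicate) schedules are derived from the
protocol base seed only, so the same schedules are reused for every patient
when schedule sharing is on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as _ndi_shift

from .grids import DoseGrid


@dataclass
class ErrorModel:
    """Truncated-Gaussian per-fraction isocenter shift model (mm)."""

    mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sd: tuple[float, float, float] = (1.2, 1.2, 1.2)
    bound_mm: float = 3.0
    truncation: str = "clip"  # "clip" caps realized shifts; "reject" resamples

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd):
            raise ValueError("sd components must be >= 0")
        if self.bound_mm <= 0:
            raise ValueError("bound must be > 0")
        if self.truncation not in ("clip", "reject"):
            raise ValueError(f"unknown truncation mode {self.truncation!r}")


@dataclass
class ShiftSchedule:
    """Ordered per-fraction isocenter displacements (mm), one 3-vector per fraction."""

    shifts: np.ndarray  # (n_fractions, 3)

    def __post_init__(self) -> None:
        self.shifts = np.atleast_2d(np.asarray(self.shifts, dtype=np.float64))
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 3:
            raise ValueError("shifts must be an (n, 3) array")
        if self.shifts.shape[0] < 1:
            raise ValueError("a schedule needs at least one fraction")

    @property
    def n_fractions(self) -> int:
        return self.shifts.shape[0]

    def __len__(self) -> int:
        return self.n_fractions


@dataclass
class ProtocolSpec:
    """The replicate protocol: fraction-number groups x error replicates."""

    fraction_groups: tuple[int, ...] = (2, 10, 20, 30)
    replicates: int = 20
    share_schedules_across_patients: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for a sample SD")
        if any(n < 1 for n in self.fraction_groups):
            raise ValueError("fraction counts must be >= 1")


def sample_shift_schedule(
    n_fractions: int, model: ErrorModel, seed
) -> ShiftSchedule:
    """Draw one per-fraction shift schedule from the error model.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``/Generator.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    rng = np.random.default_rng(seed)
    mean = np.asarray(model.mean)
    sd = np.asarray(model.sd)
    if model.truncation == "clip":
        raw = rng.normal(mean, sd, size=(n_fractions, 3))
        shifts = np.clip(raw, -model.bound_mm, model.bound_mm)
    else:
        shifts = np.empty((n_fractions, 3))
        for i in range(n_fractions):
            while True:
                v = rng.normal(mean, sd)
                if np.all(np.abs(v) <= model.bound_mm):
                    shifts[i] = v
                    break
    return ShiftSchedule(shifts)


def translate_dose(grid: DoseGrid, shift_mm, bound_mm: float | None = 3.0) -> DoseGrid:
    """Rigidly translate a dose grid by a displacement in mm.

    Trilinear interpolation; voxels translated in from outside the grid are
    filled with 0 Gy.  A warning is issued when the translation loses a
    non-negligible amount of integral dose over the boundary.
    """
    shift_mm = np.asarray(shift_mm, dtype=np.float64)
    if shift_mm.shape != (3,):
        raise ValueError("shift must be a 3-vector (mm)")
    if bound_mm is not None and np.any(np.abs(shift_mm) > bound_mm + 1e-9):
        raise ValueError(
            f"shift {shift_mm.tolist()} mm exceeds the protocol bound of {bound_mm} mm"
        )
    shift_vox = shift_mm / np.asarray(grid.spacing)
    out = _ndi_shift(grid.values, shift=shift_vox, order=1, mode="constant", cval=0.0)
    np.maximum(out, 0.0, out=out)
    total_in = grid.values.sum()
    if total_in > 0:
        lost = (total_in - out.sum()) / total_in
        if lost > 1e-6:
            warnings.warn(
                f"translation by {shift_mm.tolist()} mm lost {lost:.2e} of the "
                "integral dose over the grid boundary",
                stacklevel=2,
            )
    return grid.copy_with(out)


def accumulate_error_dose(d_ori: DoseGrid, schedule: ShiftSchedule,
                          bound_mm: float | None = 3.0) -> DoseGrid:
    """Accumulate the error-blurred dose over one fraction schedule.

    Each of the n fractions delivers 1/n of the planned dose, displaced by
    that fraction's shift; the result is the per-voxel mean of the shifted
    planned dose.
    """
    n = schedule.n_fractions
    acc = np.zeros_like(d_ori.values)
    for s in schedule.shifts:
        acc += translate_dose(d_ori, s, bound_mm=bound_mm).values
    return d_ori.copy_with(acc / n)


def schedule_seed(base_seed: int, n_fractions: int, replicate: int,
                  patient: int | None = None) -> np.random.SeedSequence:
    """Deterministic seed for one (fraction-group, replicate) schedule.

    Patient identity is folded in only when schedules are NOT shared across
    patients.
    """
    key = [int(base_seed), 7001, int(n_fractions), int(replicate)]
    if patient is not None:
        key.append(10000 + int(patient))
    return np.random.SeedSequence(key)


def run_error_protocol(
    d_ori: DoseGrid,
    protocol: ProtocolSpec | None = None,
    model: ErrorModel | None = None,
    patient: int | None = None,
) -> dict:
    """Produce the full error-dose ensemble for one patient.

    Returns a dict with the pass-through planned dose under the key
    ``"original"`` and one accumulated error dose per (fraction-group,
    replicate) pair under ``(n, r)`` keys — 81 volumes with the default
    4-group x 20-replicate protocol.
    """
    protocol = protocol if protocol is not None else ProtocolSpec()
    model = model if model is not None else ErrorModel()
    pat = None if protocol.share_schedules_across_patients else patient
    out: dict = {"original": d_ori}
    for n in protocol.fraction_groups:
        for r in range(protocol.replicates):
            sched = sample_shift_schedule(
                n, model, schedule_seed(protocol.base_seed, n, r, pat)
            )
            out[(n, r)] = accumulate_error_dose(d_ori, sched, bound_mm=model.bound_mm)
    return out
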