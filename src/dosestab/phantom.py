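"""Synthetic virtual patients: conformal lung-plan dose grids with four ROIs.

Each phantom emulates the qualitative structure of a curative-intent
IMRT/VMAT lung plan: a spherical/ellipsoidal gross tumor volume (GTV) inside
a margin-expanded planning target volume (PTV) that receives close to the
prescription dose, a steep logistic penumbra falling off outside the PTV,
an adjacent heart sitting in the intermediate-dose shoulder, and large
surrounding lungs that are mostly low-dose.  Spatially correlated Gaussian
heterogeneity is superimposed so that the discretized dose image has enough
distinct gray levels for texture matrices to be non-degenerate.

The whole dose field is multiplied by a window that is exactly zero in a
shell next to the grid boundary, so that rigid sub-voxel translations of a
few millimetres conserve the integral dose to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import DoseGrid, RoiMask

DOSE_MAX_GY = 70.0


@dataclass
class PhantomSettings:
    """Geometry and dose parameters of one virtual patient.

    Defaults target a 64^3 grid at 2.5 mm isotropic spacing with a 60 Gy
    prescription; the heterogeneity amplitude plus prescription must stay
    within the 0--70 Gy range used for discretization.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    prescription_gy: float = 60.0
    gtv_radius_mm: float = 14.0
    gtv_axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ptv_margin_mm: float = 6.0
    penumbra_width_mm: float = 6.0
    bath_fraction: float = 0.35  # share of prescription in the wide dose bath
    bath_width_mm: float = 28.0  # 80%-20% falloff width of the bath component
    bath_offset_mm: float = 20.0  # bath half-dose point, mm outside the PTV
    heterogeneity_gy: float = 2.0
    heterogeneity_length_mm: float = 7.5
    target_center_mm: tuple[float, float, float] | None = None  # None -> grid center
    heart_gap_mm: float = 0.0
    heart_semiaxes_mm: tuple[float, float, float] = (14.0, 18.0, 18.0)
    boundary_clear_mm: float = 10.0
    boundary_ramp_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prescription_gy + self.heterogeneity_gy > DOSE_MAX_GY:
            raise ValueError(
                "prescription plus heterogeneity amplitude exceeds the "
                f"{DOSE_MAX_GY} Gy discretization range"
            )
        if any(n < 16 for n in self.shape):
            raise ValueError("grid must be at least 16 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


def _physical_coords(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_distance(coords, center, semiaxes):
    """Normalized ellipsoid coordinate: <1 inside, 1 on surface."""
    q = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semiaxes))
    return np.sqrt(q)


def _boundary_window(shape, spacing, clear_mm, ramp_mm):
    """Smooth window equal to 0 within clear_mm of any face, 1 in the interior."""
    w = np.ones(shape)
    for ax, (n, s) in enumerate(zip(shape, spacing)):
        d = np.minimum(np.arange(n), n - 1 - np.arange(n)) * s
        t = np.clip((d - clear_mm) / max(ramp_mm, 1e-9), 0.0, 1.0)
        prof = t * t * (3 - 2 * t)  # smoothstep
        sl = [None] * 3
        sl[ax] = slice(None)
        w = w * prof[tuple(sl)]
    return w


def _correlated_noise(rng, shape, spacing, amplitude_gy, length_mm):
    sigma_vox = [length_mm / s for s in spacing]
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=sigma_vox, mode="constant")
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return smooth * (amplitude_gy / sd)


def generate_patient(settings: PhantomSettings) -> tuple[DoseGrid, dict[str, RoiMask]]:
    """Build one virtual patient: a dose grid plus GTV/PTV/Heart/Lung masks.

    The GTV is an ellipsoid; the PTV is the GTV expanded by a uniform margin.
    Dose = prescription x logistic falloff of the distance outside the PTV
    surface, plus correlated heterogeneity, clamped to [0, 70] Gy and
    windowed to zero near the grid boundary.  Deterministic given the seed.
    """
    st = settings
    rng = np.random.default_rng(st.seed)
    extent = [n * s for n, s in zip(st.shape, st.spacing)]
    center = (
        tuple(e / 2 for e in extent)
        if st.target_center_mm is None
        else tuple(st.target_center_mm)
    )
    gtv_semi = tuple(st.gtv_radius_mm * r for r in st.gtv_axis_ratios)
    ptv_semi = tuple(a + st.ptv_margin_mm for a in gtv_semi)

    margin_needed = 3.0 + st.penumbra_width_mm + st.boundary_clear_mm + st.boundary_ramp_mm
    for c, a, e in zip(center, ptv_semi, extent):
        if c - a < margin_needed or e - c - a < margin_needed:
            raise ValueError(
                "target too close to the grid boundary: need "
                f"{margin_needed:.1f} mm clearance beyond the PTV surface"
            )

    coords = _physical_coords(st.shape, st.spacing)
    q_gtv = _ellipsoid_distance(coords, center, gtv_semi)
    q_ptv = _ellipsoid_distance(coords, center, ptv_semi)
    gtv = q_gtv <= 1.0
    ptv = q_ptv <= 1.0

    # Signed mm distance outside the PTV surface (approximate, radial).
    mean_ptv_axis = float(np.mean(ptv_semi))
    dist_out = (q_ptv - 1.0) * mean_ptv_axis
    # Conformal core with a steep penumbra plus a wide low-dose bath that
    # emulates beam-path and scatter dose around the target.
    k = st.penumbra_width_mm / (2.0 * np.log(4.0))  # 80%-20% falloff width
    k_bath = st.bath_width_mm / (2.0 * np.log(4.0))
    core = (1.0 - st.bath_fraction) / (1.0 + np.exp(dist_out / k))
    bath = st.bath_fraction / (
        1.0 + np.exp((dist_out - st.bath_offset_mm) / k_bath)
    )
    base = st.prescription_gy * (core + bath)

    noise = _correlated_noise(
        rng, st.shape, st.spacing, st.heterogeneity_gy, st.heterogeneity_length_mm
    )
    dose = np.clip(base + noise, 0.0, DOSE_MAX_GY)
    dose *= _boundary_window(st.shape, st.spacing, st.boundary_clear_mm, st.boundary_ramp_mm)

    # Heart: ellipsoid abutting the PTV on the +x side, in the dose shoulder.
    heart_center = (
        center[0] + ptv_semi[0] + st.heart_gap_mm + st.heart_semiaxes_mm[0],
        center[1],
        center[2],
    )
    heart = _ellipsoid_distance(coords, heart_center, st.heart_semiaxes_mm) <= 1.0
    heart &= ~gtv

    # Lungs: two large lateral ellipsoids (target sits inside one), minus GTV.
    lung_semi = (
        0.30 * extent[0],
        0.32 * extent[1],
        0.38 * extent[2],
    )
    left_center = (center[0] - 0.04 * extent[0], center[1], center[2])
    right_center = (
        heart_center[0] + st.heart_semiaxes_mm[0] + 0.12 * extent[0],
        center[1],
        center[2],
    )
    lung = (
        (_ellipsoid_distance(coords, left_center, lung_semi) <= 1.0)
        | (_ellipsoid_distance(coords, right_center, lung_semi) <= 1.0)
    )
    lung &= ~gtv
    lung &= ~heart
    # keep the lung inside the region where the boundary window is 1
    lung &= _boundary_window(st.shape, st.spacing, st.boundary_clear_mm, st.boundary_ramp_mm) > 0.999

    grid = DoseGrid(dose, st.spacing)
    masks = {
        "GTV": RoiMask(gtv, "GTV", st.spacing),
        "PTV": RoiMask(ptv, "PTV", st.spacing),
        "Heart": RoiMask(heart, "Heart", st.spacing),
        "Lung": RoiMask(lung, "Lung", st.spacing),
    }
    return grid, masks


def generate_cohort(
    n_patients: int,
    base_seed: int = 0,
    settings: PhantomSettings | None = None,
) -> list[tuple[DoseGrid, dict[str, RoiMask]]]:
    """Generate a cohort of virtual patients with per-patient geometry jitter.

    Tumor size, axis ratios, penumbra and heart placement are jittered from
    the template so that feature values differ between patients (a non-zero
    between-subject variance is required for the intraclass correlation to
    be well defined).  Fully deterministic given (n_patients, base_seed).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    template = settings if settings is not None else PhantomSettings()
    cohort = []
    for p in range(n_patients):
        ss = np.random.SeedSequence([int(base_seed), 1000 + p])
        rng = np.random.default_rng(ss)
        extent = [n * s for n, s in zip(template.shape, template.spacing)]
        center = tuple(
            e / 2 + rng.uniform(-4.0, 4.0) for e in extent
        )
        st = replace(
            template,
            gtv_radius_mm=template.gtv_radius_mm * rng.uniform(0.8, 1.25),
            gtv_axis_ratios=tuple(rng.uniform(0.85, 1.15, size=3)),
            penumbra_width_mm=template.penumbra_width_mm * rng.uniform(0.85, 1.15),
            heterogeneity_gy=template.heterogeneity_gy * rng.uniform(0.8, 1.2),
            heterogeneity_length_mm=template.heterogeneity_length_mm * rng.uniform(0.85, 1.2),
            heart_gap_mm=template.heart_gap_mm * rng.uniform(0.8, 1.3),
            target_center_mm=center,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        cohort.append(generate_patient(st))
    return cohort
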