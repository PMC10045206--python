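"""Synthetic straightened-vessel CT phantoms with known vulnerability labels.

Each phantom vessel is a stack of axial slices containing, from the
centre outwards: a contrast-bright lumen disc (~400 HU), a soft-tissue
wall annulus (~50 HU), and a surrounding adipose field drawn as
spatially correlated Gaussian noise in the fat attenuation range.
Scattered bright "speck" voxels (> -30 HU) are sprinkled through the fat
so that the HU-window rule of the segmentation step is actually
exercised.  The vessel radius varies smoothly along the stack so the
per-slice diameter is non-trivial.

Two class-conditional effects can be injected for positive vessels:

* a mean-attenuation shift of the adipose field (``fat_mean_shift_hu``),
  emulating inflammation-related attenuation increase, and
* a change of the spatial correlation length of the adipose texture
  (``texture_corr_len_pos`` vs ``texture_corr_len_neg``), giving texture
  families a signal independent of the mean shift.

Wall masks are produced noiselessly (exact geometry), so segmentation
behaviour downstream is fully deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import VesselLabel, VesselVolume, WallSegmentation
from .segmentation import vessel_diameter

logger = logging.getLogger(__name__)

LUMEN_HU = 400.0
WALL_HU = 50.0
SPECK_MEAN_HU = 30.0
SPECK_SD_HU = 20.0
HU_CLIP = (-500.0, 600.0)


@dataclass
class PhantomConfig:
    """Cohort-level phantom parameters.

    The defaults describe the reference study conditions used throughout
    the test-suite: 30 vessels, ~47% positive prevalence, a 15 HU
    class-conditional adipose mean shift and a doubled texture
    correlation length for positives.
    """

    n_vessels: int = 30
    slices_per_vessel: int = 24
    slice_shape: tuple[int, int] = (48, 48)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    lumen_radius_mm: float = 1.5
    wall_thickness_mm: float = 0.75
    fat_mean_hu_neg: float = -80.0
    fat_mean_shift_hu: float = 15.0
    texture_corr_len_neg: float = 0.6  # mm
    texture_corr_len_pos: float = 1.2  # mm
    fat_sd_hu: float = 15.0
    prevalence: float = 0.47
    speck_fraction: float = 0.05
    loi_fraction: float = 0.2
    radius_modulation: float = 0.1  # relative amplitude of along-vessel taper
    effect_target: str = "tcfa"  # label channel that drives the injected effects
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels <= 0 or self.slices_per_vessel <= 0:
            raise ValueError("n_vessels and slices_per_vessel must be positive")
        if not (-190.0 < self.fat_mean_hu_neg < -30.0):
            raise ValueError("fat_mean_hu_neg must lie inside the fat window (-190, -30)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if min(self.lumen_radius_mm, self.wall_thickness_mm) <= 0:
            raise ValueError("lumen radius and wall thickness must be positive")
        if min(self.texture_corr_len_neg, self.texture_corr_len_pos) <= 0:
            raise ValueError("texture correlation lengths must be positive")
        if self.fat_sd_hu <= 0:
            raise ValueError("fat_sd_hu must be positive")
        if self.effect_target not in ("tcfa", "mc", "tcfa_mc"):
            raise ValueError("effect_target must be tcfa, mc or tcfa_mc")


def _check_geometry(config: PhantomConfig) -> None:
    """Fail loudly if the wall + annulus cannot fit in the slice."""
    outer_mm = (1.0 + config.radius_modulation) * (
        config.lumen_radius_mm + config.wall_thickness_mm
    )
    # the PCAT annulus extends one vessel diameter beyond the wall
    reach_mm = outer_mm + 2.0 * outer_mm
    for name, n_pix, d_mm in (
        ("row", config.slice_shape[0], config.spacing_mm[1]),
        ("col", config.slice_shape[1], config.spacing_mm[2]),
    ):
        half_extent = n_pix * d_mm / 2.0
        if reach_mm > half_extent:
            raise ValueError(
                f"vessel geometry exceeds slice extent along {name}: "
                f"needs {reach_mm:.1f} mm but half-extent is {half_extent:.1f} mm"
            )


def _correlated_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    corr_len_px: float,
    sd: float,
) -> np.ndarray:
    """Zero-mean Gaussian field with in-plane correlation length ``corr_len_px``.

    Smoothing is in-plane only (each axial slice is textured
    independently along z, matching per-slice 2-D analysis), then the
    field is renormalised to exactly zero mean and the requested SD.
    """
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=(0.0, corr_len_px, corr_len_px))
    smooth -= smooth.mean()
    smooth *= sd / smooth.std()
    return smooth


def generate_vessel(
    config: PhantomConfig, label: VesselLabel, seed: int
) -> tuple[VesselVolume, WallSegmentation]:
    """Generate one straightened phantom vessel and its exact wall masks."""
    _check_geometry(config)
    rng = np.random.default_rng(seed)
    n, (ny, nx) = config.slices_per_vessel, config.slice_shape
    dz, dy, dx = config.spacing_mm

    positive = label.value(config.effect_target)
    fat_mean = config.fat_mean_hu_neg + (config.fat_mean_shift_hu if positive else 0.0)
    corr_len_mm = config.texture_corr_len_pos if positive else config.texture_corr_len_neg
    corr_len_px = corr_len_mm / dx

    fat = fat_mean + _correlated_field(rng, (n, ny, nx), corr_len_px, config.fat_sd_hu)

    # smooth along-vessel radius modulation so the diameter varies per slice
    phase = rng.uniform(0.0, 2.0 * np.pi)
    z = np.arange(n)
    radius_factor = 1.0 + config.radius_modulation * np.sin(
        2.0 * np.pi * z / max(n, 1) + phase
    )

    yy, xx = np.meshgrid(
        (np.arange(ny) - (ny - 1) / 2.0) * dy,
        (np.arange(nx) - (nx - 1) / 2.0) * dx,
        indexing="ij",
    )
    r_mm = np.hypot(yy, xx)

    lumen = np.zeros((n, ny, nx), dtype=bool)
    outer = np.zeros((n, ny, nx), dtype=bool)
    voxels = fat
    for i in range(n):
        r_lumen = config.lumen_radius_mm * radius_factor[i]
        r_outer = (config.lumen_radius_mm + config.wall_thickness_mm) * radius_factor[i]
        lumen[i] = r_mm <= r_lumen
        outer[i] = r_mm <= r_outer

    # scattered non-fat specks in the background so the HU filter has work to do
    speck = rng.random((n, ny, nx)) < config.speck_fraction
    speck &= ~outer
    voxels[speck] = SPECK_MEAN_HU + SPECK_SD_HU * rng.standard_normal(int(speck.sum()))

    wall_ring = outer & ~lumen
    voxels[wall_ring] = WALL_HU + 10.0 * rng.standard_normal(int(wall_ring.sum()))
    voxels[lumen] = LUMEN_HU + 20.0 * rng.standard_normal(int(lumen.sum()))

    voxels = np.clip(voxels, *HU_CLIP)
    voxels[lumen] = np.maximum(voxels[lumen], 0.0)  # lumen stays contrast-bright

    loi_len = max(1, int(round(config.loi_fraction * n)))
    a = (n - loi_len) // 2
    volume = VesselVolume(
        voxels=voxels,
        spacing_mm=config.spacing_mm,
        loi_range=(a, a + loi_len),
        vessel_range=(0, n),
        vessel_id=f"phantom-{seed}",
    )
    diameters = np.array(
        [vessel_diameter(outer[i], (dy, dx)) for i in range(n)], dtype=float
    )
    walls = WallSegmentation(
        lumen_masks=lumen, outer_wall_masks=outer, diameter_mm=diameters
    )
    return volume, walls


def generate_cohort(
    config: PhantomConfig,
) -> tuple[list[tuple[VesselVolume, WallSegmentation]], list[VesselLabel]]:
    """Generate ``config.n_vessels`` labelled vessels.

    Labels: TCFA and MC are drawn as independent Bernoulli(prevalence)
    variables; the combined label is their conjunction.  Per-vessel
    generation seeds are derived deterministically from ``rng_seed``.
    """
    if config.n_vessels < 6:
        raise ValueError(
            "need at least 6 vessels to stratify three folds with both classes"
        )
    rng = np.random.default_rng(config.rng_seed)
    tcfa = rng.random(config.n_vessels) < config.prevalence
    mc = rng.random(config.n_vessels) < config.prevalence
    labels = [VesselLabel(tcfa=bool(t), mc=bool(m)) for t, m in zip(tcfa, mc)]

    driving = np.array([lab.value(config.effect_target) for lab in labels])
    n_pos = int(driving.sum())
    if n_pos in (0, config.n_vessels):
        logger.warning(
            "single-class cohort for target %s (%d/%d positive): cannot be stratified",
            config.effect_target,
            n_pos,
            config.n_vessels,
        )
    logger.info(
        "cohort of %d vessels: %d tcfa, %d mc, %d tcfa+mc",
        config.n_vessels,
        int(tcfa.sum()),
        int(mc.sum()),
        int((tcfa & mc).sum()),
    )

    seeds = rng.integers(0, 2**31 - 1, size=config.n_vessels)
    vessels = [
        generate_vessel(config, labels[i], int(seeds[i]))
        for i in range(config.n_vessels)
    ]
    return vessels, labels
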