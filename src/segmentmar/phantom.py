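"""Synthetic short-axis T2-weighted phantom with known MaR ground truth.

The phantom emulates the statistical structure the segmentation algorithm
assumes, not MR physics: an annular LV myocardium on every slice, two
Gaussian intensity populations (normal myocardium and a brighter edematous
wedge confined to one artery's territory and transmural by construction),
per-slice multiplicative intensity drift, and optionally focal bright/dark
artifacts and a hypo-intense microvascular-obstruction (MVO) core inside
the wedge.  The MVO core belongs to the ground-truth MaR.

Everything is deterministic given the spec's seed, which makes the phantom
usable both as a test fixture factory and as a cohort simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .geometry import (
    N_SECTORS,
    Orientation,
    SECTOR_WIDTH,
    ShortAxisStack,
    load_extent_model,
)

logger = logging.getLogger("segmentmar")


@dataclass
class Artifact:
    """A focal disc artifact painted into the myocardium.

    ``angle`` locates the disc centre at mid-wall in the RV-insertion-
    anchored frame (radians, counterclockwise); ``intensity`` is the mean
    painted value (bright or dark), with noise SD ``noise_sd``.
    """

    slice_index: int
    angle: float
    intensity: float
    radius_px: float = 3.0
    noise_sd: float = 2.0


@dataclass
class MvoSpec:
    """Hypo-intense core centred inside the wedge (angularly and radially)."""

    angular_fraction: float = 0.4
    radial_fraction: float = 0.5
    mu: float = 25.0
    sigma: float = 5.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Geometry defaults follow a typical T2-STIR short-axis acquisition
    (1.5 mm in-plane, 8 mm slices with 2 mm gap, 9 slices base to apex).
    The wedge is an angular interval in sector units, centred at
    ``wedge_center_sector`` with a width interpolated linearly from base to
    apex; the defaults give a 6-of-24-sector transmural LAD wedge aligned
    to sector boundaries (25% of LVM).  Intensity defaults put the two
    populations ~6 SD apart, a cleanly separable T2-STIR appearance.
    """

    n_slices: int = 9
    image_size: tuple[int, int] = (128, 128)
    endo_radius_mm: float = 22.0
    epi_radius_mm: float = 32.0
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    slice_thickness: float = 8.0
    slice_gap: float = 2.0
    artery: str = "LAD"
    rv_insertion_angle: float = 1.25 * np.pi
    wedge_center_sector: float = 15.0
    wedge_width_base: float = 6.0
    wedge_width_apex: float = 6.0
    mu_normal: float = 60.0
    mu_mar: float = 120.0
    sigma_normal: float = 8.0
    sigma_mar: float = 10.0
    slice_gain: Sequence[float] | None = None
    slice_gain_range: tuple[float, float] = (0.85, 1.15)
    background_mu: float = 5.0
    background_sigma: float = 2.0
    artifacts: list[Artifact] = field(default_factory=list)
    mvo: MvoSpec | None = None
    outflow_slices: dict[int, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def wedge_width(self, slice_index: int) -> float:
        if self.n_slices == 1:
            return self.wedge_width_base
        t = slice_index / (self.n_slices - 1)
        return (1 - t) * self.wedge_width_base + t * self.wedge_width_apex

    def wedge_interval(self, slice_index: int) -> tuple[float, float]:
        """(start, end) of the wedge arc in sector units, anchored frame."""
        w = self.wedge_width(slice_index)
        return (self.wedge_center_sector - w / 2.0,
                self.wedge_center_sector + w / 2.0)

    def validate(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if not 0 < self.endo_radius_mm < self.epi_radius_mm:
            raise ValueError("need 0 < endo_radius_mm < epi_radius_mm")
        if self.mu_mar <= self.mu_normal:
            raise ValueError("mu_mar must exceed mu_normal (hyperenhancement)")
        if self.sigma_normal < 0 or self.sigma_mar < 0:
            raise ValueError("population SDs must be >= 0")
        if min(self.wedge_width_base, self.wedge_width_apex) < 0 or \
                max(self.wedge_width_base, self.wedge_width_apex) > N_SECTORS:
            raise ValueError(f"wedge widths must lie in [0, {N_SECTORS}]")
        model = load_extent_model(self.artery)
        for s in range(self.n_slices):
            w = self.wedge_width(s)
            if w <= 0:
                continue
            start, end = self.wedge_interval(s)
            ring = (9 * s) // self.n_slices
            cells = np.arange(int(np.floor(start)), int(np.ceil(end))) % N_SECTORS
            outside = [int(k) for k in cells if not model.maximal[ring, k]]
            if outside:
                raise ValueError(
                    f"wedge sectors {outside} on slice {s} (ring {ring}) lie "
                    f"outside the {self.artery} maximal extent model"
                )


@dataclass
class PhantomTruth:
    """A generated phantom subject with its ground-truth MaR mask."""

    stack: ShortAxisStack
    orient: Orientation
    mar_truth: np.ndarray
    spec: PhantomSpec

    @property
    def truth_percent_lvm(self) -> float:
        return 100.0 * float(self.mar_truth.sum()) / float(self.stack.myo_mask.sum())


def _in_arc(sector_coord: np.ndarray, start: float, width: float) -> np.ndarray:
    return (sector_coord - start) % N_SECTORS < width


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate one synthetic subject; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, (n_rows, n_cols) = spec.n_slices, spec.image_size
    ps_r, ps_c = spec.pixel_spacing
    cr, cc = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0

    rr, col = np.indices((n_rows, n_cols), dtype=float)
    dist_mm = np.hypot((rr - cr) * ps_r, (col - cc) * ps_c)
    annulus = (dist_mm >= spec.endo_radius_mm) & (dist_mm <= spec.epi_radius_mm)
    theta = np.mod(np.arctan2(-(rr - cr), col - cc), 2 * np.pi)
    sector_coord = np.mod(theta - spec.rv_insertion_angle, 2 * np.pi) / SECTOR_WIDTH

    if spec.slice_gain is not None:
        gains = np.asarray(spec.slice_gain, dtype=float)
        if gains.shape != (n,):
            raise ValueError("slice_gain must have one factor per slice")
    else:
        gains = rng.uniform(*spec.slice_gain_range, size=n)

    image = rng.normal(spec.background_mu, spec.background_sigma, (n, n_rows, n_cols))
    myo_mask = np.broadcast_to(annulus, (n, n_rows, n_cols)).copy()
    mar_truth = np.zeros((n, n_rows, n_cols), dtype=bool)

    wall = spec.epi_radius_mm - spec.endo_radius_mm
    for s in range(n):
        image[s][annulus] = rng.normal(spec.mu_normal, spec.sigma_normal,
                                       int(annulus.sum()))
        w = spec.wedge_width(s)
        if w > 0:
            start, _ = spec.wedge_interval(s)
            wedge = annulus & _in_arc(sector_coord, start, w)
            image[s][wedge] = rng.normal(spec.mu_mar, spec.sigma_mar,
                                         int(wedge.sum()))
            mar_truth[s] = wedge
            if spec.mvo is not None:
                core_w = w * spec.mvo.angular_fraction
                core_start = spec.wedge_center_sector - core_w / 2.0
                pad = wall * (1.0 - spec.mvo.radial_fraction) / 2.0
                core = (
                    annulus
                    & _in_arc(sector_coord, core_start, core_w)
                    & (dist_mm >= spec.endo_radius_mm + pad)
                    & (dist_mm <= spec.epi_radius_mm - pad)
                )
                image[s][core] = rng.normal(spec.mvo.mu, spec.mvo.sigma,
                                            int(core.sum()))
        image[s] *= gains[s]

    # artifacts are painted last, at absolute intensity (not scaled by gain)
    for art in spec.artifacts:
        if not 0 <= art.slice_index < n:
            raise ValueError(f"artifact slice {art.slice_index} out of range")
        disp = spec.rv_insertion_angle + art.angle
        r_mid_mm = (spec.endo_radius_mm + spec.epi_radius_mm) / 2.0
        a_r = cr - np.sin(disp) * r_mid_mm / ps_r
        a_c = cc + np.cos(disp) * r_mid_mm / ps_c
        disc = np.hypot(rr - a_r, col - a_c) <= art.radius_px
        disc &= annulus
        image[art.slice_index][disc] = rng.normal(art.intensity, art.noise_sd,
                                                  int(disc.sum()))

    stack = ShortAxisStack(
        image=image, myo_mask=myo_mask,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness, slice_gap=spec.slice_gap,
    )
    orient = Orientation(rv_insertion_angle=spec.rv_insertion_angle,
                         outflow_slices=dict(spec.outflow_slices))
    return PhantomTruth(stack=stack, orient=orient, mar_truth=mar_truth, spec=spec)


def default_cohort_spec(rng: np.random.Generator, base: PhantomSpec) -> PhantomSpec:
    """Subject-level variation for cohort simulation.

    The wedge fraction of LVM is uniform on [15, 50]% (width 3.6-12 sectors,
    centred so the arc stays inside the LAD maximal territory on every
    ring); slice gains are redrawn per subject via the subject seed.
    """
    frac = rng.uniform(0.15, 0.50)
    width = frac * N_SECTORS
    return replace(
        base,
        wedge_center_sector=16.0,
        wedge_width_base=width,
        wedge_width_apex=width,
        slice_gain=None,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_subjects: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    spec_distribution: Callable[[np.random.Generator, PhantomSpec], PhantomSpec]
        | None = None,
) -> list[PhantomTruth]:
    """Generate ``n_subjects`` phantoms with subject-level variation.

    Reproducible per ``seed``; ``spec_distribution`` maps (rng, base spec)
    to each subject's spec and defaults to :func:`default_cohort_spec`.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    base = base_spec or PhantomSpec()
    draw = spec_distribution or default_cohort_spec
    return [generate_phantom(draw(rng, base)) for _ in range(n_subjects)]
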