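"""Short-axis geometry: sector/ring coordinates and coronary extent models.

The left-ventricular myocardium of each short-axis slice is divided into 24
angular sectors anchored at the inferior right-ventricular insertion point,
and the slice stack is mapped onto the 9 rings (3 basal, 3 mid-ventricular,
3 apical) of an extended AHA bulls-eye.  Coronary perfusion territories are
expressed in this 9x24 grid as a *normal* (typical) and a *maximal*
(anatomically possible) extent model per culprit artery.

Conventions
-----------
* Arrays are indexed (slice, row, col); slice 0 is the most basal.
* Angles are measured counterclockwise in the standard short-axis display,
  i.e. ``theta = atan2(-(row - cr), col - cc)`` so that "up" on screen is
  +90 degrees.  Sector 0 starts at the RV insertion angle and sector index
  increases counterclockwise; each sector spans 2*pi/24.
* Ring index runs 0 (most basal) .. 8 (most apical); a stack of n slices maps
  slice i to ring floor(9*i/n).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("segmentmar")

N_SECTORS = 24
N_RINGS = 9
SECTOR_WIDTH = 2.0 * np.pi / N_SECTORS

ARTERIES = ("LAD", "LCx", "RCA", "LM")
#: arteries whose MaR sits on the anterior side of the outflow tract
ANTERIOR_ARTERIES = ("LAD", "LM")


class GeometryError(ValueError):
    """Raised for inconsistent stacks, orientations or extent models."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ShortAxisStack:
    """A short-axis image volume with its myocardial mask and geometry.

    Parameters
    ----------
    image : ndarray, shape (n_slices, n_rows, n_cols)
        Scalar signal intensities, arbitrary units.
    myo_mask : ndarray of bool, same shape
        True on LV myocardium (endo/epi delineation, papillaries excluded).
    pixel_spacing : (float, float)
        In-plane spacing in mm (row, col).
    slice_thickness : float
        Slice thickness in mm.
    slice_gap : float
        Gap between slices in mm (>= 0).
    slice_order : str
        Tag asserting the stack direction; only ``"base-to-apex"`` is
        accepted (index 0 = most basal slice).
    """

    image: np.ndarray
    myo_mask: np.ndarray
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    slice_thickness: float = 8.0
    slice_gap: float = 2.0
    slice_order: str = "base-to-apex"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.myo_mask = np.asarray(self.myo_mask, dtype=bool)
        if self.image.ndim != 3:
            raise GeometryError(f"image must be 3-D, got shape {self.image.shape}")
        if self.image.shape != self.myo_mask.shape:
            raise GeometryError(
                f"image shape {self.image.shape} != mask shape {self.myo_mask.shape}"
            )
        ps = tuple(float(p) for p in np.atleast_1d(self.pixel_spacing))
        if len(ps) == 1:
            ps = (ps[0], ps[0])
        self.pixel_spacing = ps
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0:
            raise GeometryError("pixel_spacing and slice_thickness must be > 0")
        if self.slice_gap < 0:
            raise GeometryError("slice_gap must be >= 0")
        if self.slice_order != "base-to-apex":
            raise GeometryError(
                f"unsupported slice_order {self.slice_order!r}; reorder to base-to-apex"
            )

    @property
    def n_slices(self) -> int:
        return self.image.shape[0]

    @property
    def slice_spacing(self) -> float:
        """Centre-to-centre slice distance in mm (thickness + gap)."""
        return self.slice_thickness + self.slice_gap

    @property
    def voxel_volume(self) -> float:
        """Volume per myocardial pixel in mm^3, using contiguous-coverage spacing."""
        return self.pixel_spacing[0] * self.pixel_spacing[1] * self.slice_spacing


@dataclass
class Orientation:
    """User-supplied heart orientation.

    ``rv_insertion_angle`` is the display-counterclockwise angle (radians, in
    [0, 2*pi)) from the per-slice LV centroid towards the inferior RV
    insertion point; a scalar applies to every slice.  ``outflow_slices``
    maps basal slice indices containing the outflow tract to the angular
    interval (start, stop), measured in the RV-insertion-anchored frame, that
    lies on the anterior side of the outflow tract.
    """

    rv_insertion_angle: float | Sequence[float]
    outflow_slices: Mapping[int, tuple[float, float]] = field(default_factory=dict)

    def angle_for_slice(self, slice_index: int) -> float:
        a = np.atleast_1d(np.asarray(self.rv_insertion_angle, dtype=float))
        val = float(a[0]) if a.size == 1 else float(a[slice_index])
        return val % (2.0 * np.pi)


@dataclass
class SectorGrid:
    """Per-pixel sector labels and per-slice ring assignment.

    ``sector_of_pixel`` holds an integer 0..23 on myocardial pixels and -1
    elsewhere.  ``empty_slices`` lists slices with no usable myocardium
    (zero or a single pixel); they carry no sectors.
    """

    sector_of_pixel: np.ndarray
    ring_of_slice: np.ndarray
    centroid: np.ndarray           # (n_slices, 2) row/col, NaN where empty
    empty_slices: frozenset[int]

    @property
    def n_slices(self) -> int:
        return self.sector_of_pixel.shape[0]

    def sector_mask(self, slice_index: int, sector: int) -> np.ndarray:
        return self.sector_of_pixel[slice_index] == sector

    def slice_sectors(self, slice_index: int) -> np.ndarray:
        """Sector label of each myocardial pixel of the slice, row-major order."""
        labels = self.sector_of_pixel[slice_index]
        return labels[labels >= 0]


@dataclass
class ExtentModel:
    """Normal and maximal perfusion-territory masks for one culprit artery.

    Both matrices are (9 rings x 24 sectors) booleans on the extended AHA
    bulls-eye; ``normal`` must be a subset of ``maximal``.
    """

    artery: str
    normal: np.ndarray
    maximal: np.ndarray

    def __post_init__(self) -> None:
        if self.artery not in ARTERIES:
            raise GeometryError(
                f"unknown artery {self.artery!r}; expected one of {ARTERIES}"
            )
        self.normal = _as_model_matrix(self.normal, "normal")
        self.maximal = _as_model_matrix(self.maximal, "maximal")
        if np.any(self.normal & ~self.maximal):
            raise GeometryError(
                f"{self.artery}: normal extent is not a subset of maximal extent"
            )
        if self.artery != "LM":
            for r in range(N_RINGS):
                for name, mat in (("maximal", self.maximal), ("normal", self.normal)):
                    if mat[r].any() and row_to_arc(mat[r]) is None:
                        raise GeometryError(
                            f"{self.artery} {name} ring {r} is not a single "
                            "contiguous circular arc"
                        )


def _as_model_matrix(mat, name: str) -> np.ndarray:
    mat = np.asarray(mat)
    if mat.shape != (N_RINGS, N_SECTORS):
        raise GeometryError(
            f"{name} matrix must be {N_RINGS}x{N_SECTORS}, got {mat.shape}"
        )
    if not np.isin(mat, (0, 1)).all():
        raise GeometryError(f"{name} matrix entries must be 0/1")
    return mat.astype(bool)


# ---------------------------------------------------------------------------
# arc helpers (circular sector arithmetic on 24 sectors)
# ---------------------------------------------------------------------------

def arc_to_row(start: int, length: int) -> np.ndarray:
    """Boolean 24-vector covering ``length`` sectors from ``start`` (circular)."""
    if not 0 <= length <= N_SECTORS:
        raise GeometryError(f"arc length {length} outside [0, {N_SECTORS}]")
    row = np.zeros(N_SECTORS, dtype=bool)
    idx = (int(start) + np.arange(int(length))) % N_SECTORS
    row[idx] = True
    return row


def row_to_arc(row: np.ndarray) -> tuple[int, int] | None:
    """Inverse of :func:`arc_to_row`.

    Returns ``(start, length)`` if the true sectors of ``row`` form one
    contiguous circular arc (full circle reported as ``(0, 24)``), else None.
    Empty rows return ``(0, 0)``.
    """
    row = np.asarray(row, dtype=bool)
    n = int(row.sum())
    if n == 0:
        return (0, 0)
    if n == N_SECTORS:
        return (0, N_SECTORS)
    # a contiguous circular arc has exactly one False->True transition
    trans = np.flatnonzero(~row & np.roll(row, -1))  # row[i] False, row[i+1] True
    if trans.size != 1:
        return None
    start = int((trans[0] + 1) % N_SECTORS)
    if not arc_to_row(start, n).tolist() == row.tolist():
        return None
    return (start, n)


# ---------------------------------------------------------------------------
# sector grid
# ---------------------------------------------------------------------------

def pixel_angles(shape: tuple[int, int], centroid: tuple[float, float]) -> np.ndarray:
    """Display-counterclockwise angle of each pixel about ``centroid``, in [0, 2pi)."""
    rr, cc = np.indices(shape, dtype=float)
    theta = np.arctan2(-(rr - centroid[0]), cc - centroid[1])
    return np.mod(theta, 2.0 * np.pi)


def sector_of_angle(theta: np.ndarray, rv_angle: float) -> np.ndarray:
    """Sector index 0..23 of angles ``theta`` with sector 0 starting at ``rv_angle``."""
    rel = np.mod(np.asarray(theta, dtype=float) - rv_angle, 2.0 * np.pi)
    return np.minimum((rel / SECTOR_WIDTH).astype(int), N_SECTORS - 1)


def compute_sector_grid(stack: ShortAxisStack, orient: Orientation) -> SectorGrid:
    """Assign every myocardial pixel to one of 24 sectors and each slice to a ring.

    The per-slice sector origin is the centre of mass of the myocardial mask;
    sector 0 starts at the RV insertion angle and indices increase
    counterclockwise.  Slices with fewer than two myocardial pixels are
    flagged empty and excluded with a warning; a stack with no usable slice
    is an error.
    """
    n = stack.n_slices
    sector_of_pixel = np.full(stack.image.shape, -1, dtype=np.int8)
    centroid = np.full((n, 2), np.nan)
    empty: set[int] = set()

    for s in range(n):
        mask = stack.myo_mask[s]
        npix = int(mask.sum())
        if npix < 2:
            empty.add(s)
            if npix == 1:
                warnings.warn(
                    f"slice {s}: degenerate single-pixel myocardium, excluded",
                    stacklevel=2,
                )
            continue
        rows, cols = np.nonzero(mask)
        cr, cc = float(rows.mean()), float(cols.mean())
        centroid[s] = (cr, cc)
        theta = np.arctan2(-(rows - cr), cols - cc) % (2.0 * np.pi)
        sector_of_pixel[s, rows, cols] = sector_of_angle(theta, orient.angle_for_slice(s))

    if len(empty) == n:
        raise GeometryError("no slice contains usable myocardium")

    ring_of_slice = (N_RINGS * np.arange(n)) // n
    return SectorGrid(
        sector_of_pixel=sector_of_pixel,
        ring_of_slice=ring_of_slice.astype(int),
        centroid=centroid,
        empty_slices=frozenset(empty),
    )


# ---------------------------------------------------------------------------
# extent models
# ---------------------------------------------------------------------------

def _default_model_specs() -> dict:
    ref = resources.files("segmentmar").joinpath("data/extent_models.json")
    return json.loads(ref.read_text())


def _model_from_arcs(artery: str, spec: Mapping) -> ExtentModel:
    mats = {}
    for name in ("normal", "maximal"):
        arcs = spec[name]
        if len(arcs) != N_RINGS:
            raise GeometryError(f"{artery} {name}: expected {N_RINGS} ring arcs")
        mats[name] = np.stack([arc_to_row(int(a[0]), int(a[1])) for a in arcs])
    return ExtentModel(artery=artery, normal=mats["normal"], maximal=mats["maximal"])


def load_extent_model(artery: str, source: str | None = None) -> ExtentModel:
    """Load the extent model for ``artery`` from ``source`` or the packaged defaults.

    ``source`` may be a path to a JSON file either in matrix form
    ``{"artery": ..., "normal": 9x24, "maximal": 9x24}`` or in the packaged
    parametric arc form (per artery, per ring ``[start_sector, arc_length]``).
    The LM model is assembled as the element-wise union of the LAD, LCx and
    RCA models whenever it is not given explicitly.
    """
    if artery not in ARTERIES:
        raise GeometryError(f"unknown artery {artery!r}; expected one of {ARTERIES}")

    if source is None:
        specs = _default_model_specs()
    else:
        with open(source) as fh:
            loaded = json.load(fh)
        if "normal" in loaded and "maximal" in loaded:  # single-model matrix file
            file_artery = loaded.get("artery", artery)
            if file_artery != artery:
                raise GeometryError(
                    f"model file is for {file_artery!r}, requested {artery!r}"
                )
            return ExtentModel(
                artery=artery,
                normal=np.asarray(loaded["normal"]),
                maximal=np.asarray(loaded["maximal"]),
            )
        specs = loaded

    if artery in specs:
        spec = specs[artery]
        if "normal" in spec and len(np.asarray(spec["normal"]).shape) == 2 and \
                np.asarray(spec["normal"]).shape[1] == N_SECTORS:
            return ExtentModel(
                artery=artery,
                normal=np.asarray(spec["normal"]),
                maximal=np.asarray(spec["maximal"]),
            )
        return _model_from_arcs(artery, spec)

    if artery == "LM":
        parts = [load_extent_model(a, source) for a in ("LAD", "LCx", "RCA")]
        return ExtentModel(
            artery="LM",
            normal=np.logical_or.reduce([p.normal for p in parts]),
            maximal=np.logical_or.reduce([p.maximal for p in parts]),
        )
    raise GeometryError(f"no model for artery {artery!r} in source")


def remote_mask(stack: ShortAxisStack, grid: SectorGrid, model: ExtentModel) -> np.ndarray:
    """Myocardium outside the culprit artery's maximal extent model.

    A pixel is remote iff it is myocardial and its (ring, sector) cell is 0
    in the maximal extent matrix.  Slices entirely inside the maximal model
    yield an empty remote mask on that slice; callers relying on remote
    statistics must handle that case.
    """
    out = np.zeros_like(stack.myo_mask)
    for s in range(stack.n_slices):
        if s in grid.empty_slices:
            continue
        ring = int(grid.ring_of_slice[s])
        remote_sectors = ~model.maximal[ring]            # (24,) bool
        labels = grid.sector_of_pixel[s]
        out[s] = (labels >= 0) & remote_sectors[np.clip(labels, 0, N_SECTORS - 1)]
    return out
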