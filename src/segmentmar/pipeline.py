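"""MaR segmentation pipeline: from per-slice intensity fits to a pixel mask.

The pipeline turns the per-slice two-Gaussian fits into a transmural,
territory-constrained segmentation of myocardium at risk:

1. map each pixel's intensity to a MaR probability and average it over the
   24 angular sectors of each slice;
2. collect sectors with probability > 0.5 that lie inside the culprit
   artery's maximal extent model (and on the correct side of the outflow
   tract) into connected regions on the cylindrical (slice, sector) grid,
   with circumferential wrap-around;
3. score every candidate region by summing MaR probability inside it and
   normal probability (1 - p) outside, and keep the best;
4. smooth the region's two angular edges across slices by certainty-weighted
   normalized averaging;
5. rasterize the sector region back to a pixel mask — every pixel of a
   member sector is labelled, which enforces transmurality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .geometry import (
    ANTERIOR_ARTERIES,
    ExtentModel,
    N_SECTORS,
    Orientation,
    SECTOR_WIDTH,
    SectorGrid,
    ShortAxisStack,
    load_extent_model,
    row_to_arc,
)
from .intensity import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    MIN_PIXELS_FOR_EM,
    SliceIntensityModel,
    fit_em,
    initialize_from_priors,
    mar_probability,
    percentile_split_init,
)

logger = logging.getLogger("segmentmar")

#: probability threshold separating MaR from normal sectors
PROBABILITY_THRESHOLD = 0.5
#: normalized-averaging kernel: Gaussian, SD in slices, truncated half-width
KERNEL_SD_SLICES = 1.5
KERNEL_HALF_WIDTH = 3
#: certainty (b): SD of the inter-slice edge-step Gaussian, in sectors
EDGE_STEP_SD = 2.0
#: expected arc-width drift per slice towards the apex, in sectors
WIDTH_DRIFT = {"LAD": 2.0, "LM": 2.0, "RCA": -1.0, "LCx": -1.0}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SectorProbabilityMap:
    """Mean MaR probability per (slice, sector); ``valid`` marks sectors with
    at least one myocardial pixel on a modelled slice."""

    values: np.ndarray   # (n_slices, 24) float, NaN where invalid
    valid: np.ndarray    # (n_slices, 24) bool

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]


@dataclass
class MarRegion:
    """A connected set of (slice, sector) cells with its score and boundary.

    ``boundary`` maps each slice of the region to the continuous angular
    edges ``(start, end)`` of its arc, in sector units; the values are
    unwrapped across slices (they may leave [0, 24)) so that edge
    trajectories are smooth, and ``end - start`` is the arc width.
    """

    member_sectors: frozenset[tuple[int, int]]
    score: float = float("nan")
    boundary: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def slices(self) -> list[int]:
        return sorted({s for s, _ in self.member_sectors})

    def members_of_slice(self, s: int) -> set[int]:
        return {k for sl, k in self.member_sectors if sl == s}


@dataclass
class MarSegmentation:
    """Final segmentation: pixel mask, selected sector region and MaR burden."""

    pixel_mask: np.ndarray
    sector_region: MarRegion | None
    mar_percent_lvm: float
    per_step: dict | None = None


@dataclass
class SegmentOptions:
    """Pipeline switches, mainly for step-ablation experiments.

    Disabling ``transmural_sectors`` stops after the pixel-wise probability
    threshold; disabling ``regional_criteria`` keeps every supra-threshold
    sector without territory/connectivity constraints (interpolation is then
    skipped, as there is no single region to smooth).
    """

    apriori_init: bool = True
    transmural_sectors: bool = True
    regional_criteria: bool = True
    interpolation: bool = True
    store_intermediates: bool = False
    extent_source: str | None = None
    em_tol: float = DEFAULT_TOL
    em_max_iter: int = DEFAULT_MAX_ITER


# ---------------------------------------------------------------------------
# steps 2-4: fits, pixel probabilities, sector probabilities
# ---------------------------------------------------------------------------

def fit_all_slices(
    stack: ShortAxisStack,
    grid: SectorGrid,
    model: ExtentModel,
    apriori_init: bool = True,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> dict[int, SliceIntensityModel]:
    """EM-fit every usable slice; slices with too few pixels are skipped."""
    fits: dict[int, SliceIntensityModel] = {}
    for s in range(stack.n_slices):
        if s in grid.empty_slices:
            continue
        values = stack.image[s][stack.myo_mask[s]]
        if values.size < MIN_PIXELS_FOR_EM:
            logger.warning("slice %d: %d myocardial pixels < %d, left unmodeled",
                           s, values.size, MIN_PIXELS_FOR_EM)
            continue
        if apriori_init:
            init = initialize_from_priors(stack, grid, model, s)
        else:
            init = percentile_split_init(values)
        fits[s] = fit_em(values, init, tol=tol, max_iter=max_iter)
    return fits


def pixelwise_probability(
    stack: ShortAxisStack,
    grid: SectorGrid,
    fits: Mapping[int, SliceIntensityModel],
) -> np.ndarray:
    """Per-pixel MaR probability volume; NaN outside myocardium or on
    unmodeled slices."""
    p = np.full(stack.image.shape, np.nan)
    for s, fit in fits.items():
        myo = stack.myo_mask[s]
        p[s][myo] = mar_probability(stack.image[s][myo], fit)
    return p


def sector_probabilities(
    stack: ShortAxisStack,
    grid: SectorGrid,
    fits: Mapping[int, SliceIntensityModel],
) -> SectorProbabilityMap:
    """Average the pixel-wise MaR probability over the 24 sectors of each slice."""
    p3d = pixelwise_probability(stack, grid, fits)
    return sector_probabilities_from_pixels(grid, p3d, fits)


def sector_probabilities_from_pixels(
    grid: SectorGrid,
    p3d: np.ndarray,
    fits: Mapping[int, SliceIntensityModel],
) -> SectorProbabilityMap:
    n = grid.n_slices
    values = np.full((n, N_SECTORS), np.nan)
    valid = np.zeros((n, N_SECTORS), dtype=bool)
    for s in fits:
        labels = grid.sector_of_pixel[s]
        myo = labels >= 0
        lab = labels[myo]
        prob = p3d[s][myo]
        counts = np.bincount(lab, minlength=N_SECTORS)
        sums = np.bincount(lab, weights=prob, minlength=N_SECTORS)
        has = counts > 0
        values[s, has] = sums[has] / counts[has]
        valid[s] = has
    return SectorProbabilityMap(values=values, valid=valid)


# ---------------------------------------------------------------------------
# step 5: regional criteria, connected regions, scoring, selection
# ---------------------------------------------------------------------------

def _sector_angles() -> np.ndarray:
    """Centre angle of each sector in the RV-insertion-anchored frame."""
    return (np.arange(N_SECTORS) + 0.5) * SECTOR_WIDTH


def _in_circular_interval(angle: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    a0, a1 = interval
    span = (a1 - a0) % (2.0 * np.pi)
    return (angle - a0) % (2.0 * np.pi) < span


def allowed_cells(
    grid: SectorGrid,
    model: ExtentModel,
    orient: Orientation,
    artery: str,
) -> np.ndarray:
    """(slice, sector) cells admissible for MaR under the regional criteria:
    inside the maximal extent model and, on outflow-tract slices, on the
    anterior side for LAD/LM or the inferior (non-anterior) side for
    RCA/LCx."""
    n = grid.n_slices
    allowed = np.zeros((n, N_SECTORS), dtype=bool)
    centre = _sector_angles()
    for s in range(n):
        row = model.maximal[int(grid.ring_of_slice[s])].copy()
        if s in orient.outflow_slices:
            anterior = _in_circular_interval(centre, orient.outflow_slices[s])
            row &= anterior if artery in ANTERIOR_ARTERIES else ~anterior
        allowed[s] = row
    return allowed


def connected_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Connected components of a boolean (slice, sector) grid under the
    4-neighbourhood with circumferential wrap-around (sector 23 <-> 0)."""
    mask = np.asarray(mask, dtype=bool)
    n_slices = mask.shape[0]
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int]]] = []
    for s0 in range(n_slices):
        for k0 in range(N_SECTORS):
            if not mask[s0, k0] or seen[s0, k0]:
                continue
            comp: set[tuple[int, int]] = set()
            stack_ = [(s0, k0)]
            seen[s0, k0] = True
            while stack_:
                s, k = stack_.pop()
                comp.add((s, k))
                for ds, dk in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ns, nk = s + ds, (k + dk) % N_SECTORS
                    if 0 <= ns < n_slices and mask[ns, nk] and not seen[ns, nk]:
                        seen[ns, nk] = True
                        stack_.append((ns, nk))
            comps.append(comp)
    return comps


def find_candidate_regions(
    probmap: SectorProbabilityMap,
    model: ExtentModel,
    orient: Orientation,
    artery: str,
    grid: SectorGrid,
) -> list[MarRegion]:
    """Connected regions of supra-threshold sectors satisfying the regional
    a-priori criteria.  An empty list means the stack shows no MaR."""
    supra = probmap.valid & (np.nan_to_num(probmap.values, nan=0.0) > PROBABILITY_THRESHOLD)
    eligible = supra & allowed_cells(grid, model, orient, artery)
    comps = connected_components(eligible)
    regions = [MarRegion(member_sectors=frozenset(c)) for c in comps]
    for r in regions:
        r.boundary = _boundary_from_members(r)
    return regions


def score_region(
    region: MarRegion,
    stack: ShortAxisStack,
    grid: SectorGrid,
    fits: Mapping[int, SliceIntensityModel],
) -> float:
    """Region score: sum of p over pixels inside the region's sectors plus
    sum of (1 - p) over all other modelled myocardial pixels."""
    p3d = pixelwise_probability(stack, grid, fits)
    return score_region_from_pixels(region, grid, p3d)


def score_region_from_pixels(
    region: MarRegion, grid: SectorGrid, p3d: np.ndarray
) -> float:
    score = 0.0
    members_by_slice = {s: region.members_of_slice(s) for s in range(grid.n_slices)}
    for s in range(grid.n_slices):
        labels = grid.sector_of_pixel[s]
        myo = labels >= 0
        prob = p3d[s][myo]
        ok = np.isfinite(prob)
        if not ok.any():
            continue
        lab = labels[myo]
        inside = np.isin(lab, sorted(members_by_slice[s])) if members_by_slice[s] else \
            np.zeros_like(lab, dtype=bool)
        score += float(prob[ok & inside].sum())
        score += float((1.0 - prob[ok & ~inside]).sum())
    return score


def select_region(
    candidates: Sequence[MarRegion], scores: Sequence[float]
) -> MarRegion | None:
    """Highest-scoring region; ties broken by larger member count, then by
    lowest (slice, sector) lexicographic member.  None for no candidates."""
    if not candidates:
        return None
    keyed = [
        (float(sc), len(r.member_sectors), tuple(-x for x in min(r.member_sectors)))
        for r, sc in zip(candidates, scores)
    ]
    best = max(range(len(candidates)), key=lambda i: keyed[i])
    region = candidates[best]
    return replace(region, score=float(scores[best]))


# ---------------------------------------------------------------------------
# step 6: normalized-averaging boundary interpolation
# ---------------------------------------------------------------------------

def normalized_average(
    values: np.ndarray,
    certainties: np.ndarray,
    sd: float = KERNEL_SD_SLICES,
    half_width: int = KERNEL_HALF_WIDTH,
) -> np.ndarray:
    """Certainty-weighted smoothing of a 1-D signal.

    ``out[i] = sum_k w(k) c[i+k] v[i+k] / sum_k w(k) c[i+k]`` with a Gaussian
    kernel ``w`` truncated at ``half_width`` samples each side.  Positions
    whose kernel support carries zero total certainty are left unchanged.
    Constant signals under uniform positive certainty are reproduced to
    machine precision, since the weights then cancel exactly.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(certainties, dtype=float)
    if v.shape != c.shape or v.ndim != 1:
        raise ValueError("values and certainties must be equal-length 1-D arrays")
    if np.any(c < 0):
        raise ValueError("certainties must be non-negative")
    n = v.size
    out = v.copy()
    offsets = np.arange(-half_width, half_width + 1)
    w = np.exp(-0.5 * (offsets / sd) ** 2)
    for i in range(n):
        # accumulate certainty-weighted deviations from the centre sample so
        # that a constant signal is reproduced exactly
        num = 0.0
        den = 0.0
        for off, wk in zip(offsets, w):
            j = i + off
            if 0 <= j < n:
                num += wk * c[j] * (v[j] - v[i])
                den += wk * c[j]
        if den > 0.0:
            out[i] = v[i] + num / den
    return out


def _covering_arc(sectors: set[int]) -> tuple[float, float]:
    """Minimal circular arc (start, end) in sector units covering ``sectors``."""
    if len(sectors) == N_SECTORS:
        return (0.0, float(N_SECTORS))
    srt = sorted(sectors)
    m = len(srt)
    gaps = [(srt[(i + 1) % m] - srt[i]) % N_SECTORS for i in range(m)]
    j = int(np.argmax(gaps))
    start = srt[(j + 1) % m]
    width = N_SECTORS - gaps[j] + 1
    return (float(start), float(start + width))


def _boundary_from_members(region: MarRegion) -> dict[int, tuple[float, float]]:
    """Per-slice covering arcs, unwrapped across slices so edges are smooth."""
    boundary: dict[int, tuple[float, float]] = {}
    prev_start: float | None = None
    for s in region.slices:
        start, end = _covering_arc(region.members_of_slice(s))
        width = end - start
        if prev_start is not None:
            start += N_SECTORS * round((prev_start - start) / N_SECTORS)
        boundary[s] = (start, start + width)
        prev_start = start
    return boundary


def _unwrapped_model_arcs(
    model_row: np.ndarray, anchor: float
) -> tuple[float, float] | None:
    """(start, end) of the arc of ``model_row`` unwrapped so start <= anchor
    lies in the same winding as ``anchor``; None for a full or empty row."""
    arc = row_to_arc(model_row)
    if arc is None:
        # non-contiguous row (possible for LM): use the covering arc
        arc = tuple(int(x) for x in _covering_arc(set(np.flatnonzero(model_row))))
        arc = (arc[0], (arc[1] - arc[0]))
    start, width = arc
    if width in (0, N_SECTORS):
        return None
    d = (anchor - start) % N_SECTORS
    start_u = anchor - d
    return (start_u, start_u + width)


def edge_certainties(
    region: MarRegion,
    model: ExtentModel,
    probmap: SectorProbabilityMap,
    grid: SectorGrid,
    artery: str,
) -> dict[int, tuple[float, float]]:
    """Per-slice certainty of the region's two edges, as the product of

    a) closeness to the maximal extent model — linear from 1 at the normal-
       extent edge to 0 at the maximal-extent edge;
    b) agreement of the inter-slice edge step with the expected drift of the
       territory (arc width growing 2 sectors/slice towards the apex for
       LAD/LM, shrinking 1 sector/slice for RCA/LCx), via a Gaussian with SD
       2 sectors, the width drift split evenly across the two edges;
    c) the MaR probability of the sector just inside the edge.
    """
    slices = region.slices
    drift = WIDTH_DRIFT[artery]
    exp_start_step, exp_end_step = -drift / 2.0, drift / 2.0
    starts = np.array([region.boundary[s][0] for s in slices])
    ends = np.array([region.boundary[s][1] for s in slices])

    out: dict[int, tuple[float, float]] = {}
    for i, s in enumerate(slices):
        ring = int(grid.ring_of_slice[s])
        start_s, end_s = starts[i], ends[i]

        # a) distance to the maximal extent arc
        max_arc = _unwrapped_model_arcs(model.maximal[ring], start_s)
        ca_start = ca_end = 1.0
        if max_arc is not None:
            m_start, m_end = max_arc
            nrm_arc = _unwrapped_model_arcs(model.normal[ring], start_s)
            if nrm_arc is not None:
                n_start, n_end = nrm_arc
                if n_start > m_start:
                    ca_start = float(np.clip((start_s - m_start) / (n_start - m_start), 0, 1))
                if m_end > n_end:
                    ca_end = float(np.clip((m_end - end_s) / (m_end - n_end), 0, 1))

        # b) inter-slice edge step vs expected territory drift
        if len(slices) > 1:
            j = i if i + 1 < len(slices) else i - 1
            obs_start = starts[j + 1] - starts[j]
            obs_end = ends[j + 1] - ends[j]
            cb_start = float(np.exp(-0.5 * ((obs_start - exp_start_step) / EDGE_STEP_SD) ** 2))
            cb_end = float(np.exp(-0.5 * ((obs_end - exp_end_step) / EDGE_STEP_SD) ** 2))
        else:
            cb_start = cb_end = 1.0

        # c) MaR probability of the edge sectors
        k_start = int(np.floor(start_s)) % N_SECTORS
        k_end = int(np.ceil(end_s) - 1) % N_SECTORS
        cc_start = float(probmap.values[s, k_start]) if probmap.valid[s, k_start] else 0.5
        cc_end = float(probmap.values[s, k_end]) if probmap.valid[s, k_end] else 0.5

        out[s] = (ca_start * cb_start * cc_start, ca_end * cb_end * cc_end)
    return out


def interpolate_boundary(
    region: MarRegion,
    model: ExtentModel,
    probmap: SectorProbabilityMap,
    grid: SectorGrid,
    artery: str,
    allowed: np.ndarray | None = None,
) -> MarRegion:
    """Smooth the region's angular edges across slices by normalized averaging.

    Each edge trajectory is smoothed with a Gaussian kernel (SD 1.5 slices,
    truncated 3 slices each side) weighted by the per-edge certainties of
    :func:`edge_certainties`; smoothed edges are clipped to the maximal
    extent arc and the member set is rebuilt from the rounded edges.
    Single-slice regions are returned unchanged.
    """
    slices = region.slices
    if len(slices) <= 1:
        return region
    if not region.boundary:
        region = replace(region, boundary=_boundary_from_members(region))

    cert = edge_certainties(region, model, probmap, grid, artery)
    starts = np.array([region.boundary[s][0] for s in slices])
    ends = np.array([region.boundary[s][1] for s in slices])
    c_start = np.array([cert[s][0] for s in slices])
    c_end = np.array([cert[s][1] for s in slices])

    new_starts = normalized_average(starts, c_start)
    new_ends = normalized_average(ends, c_end)

    members: set[tuple[int, int]] = set()
    boundary: dict[int, tuple[float, float]] = {}
    for i, s in enumerate(slices):
        ring = int(grid.ring_of_slice[s])
        lo, hi = new_starts[i], new_ends[i]
        max_arc = _unwrapped_model_arcs(model.maximal[ring], starts[i])
        if max_arc is not None:
            lo = float(np.clip(lo, max_arc[0], max_arc[1]))
            hi = float(np.clip(hi, max_arc[0], max_arc[1]))
        hi = min(hi, lo + N_SECTORS)
        boundary[s] = (lo, hi)
        a, b = int(round(lo)), int(round(hi))
        for k in range(a, b):
            cell = (s, k % N_SECTORS)
            if allowed is None or allowed[cell[0], cell[1]]:
                members.add(cell)

    if not members:
        logger.warning("interpolation removed every sector; keeping original region")
        return region
    comps = connected_components(_cells_to_mask(members, grid.n_slices))
    comps.sort(key=lambda c: (len(c), tuple(-x for x in min(c))), reverse=True)
    members = comps[0]
    return MarRegion(member_sectors=frozenset(members), score=region.score,
                     boundary=boundary)


def _cells_to_mask(cells: set[tuple[int, int]], n_slices: int) -> np.ndarray:
    mask = np.zeros((n_slices, N_SECTORS), dtype=bool)
    for s, k in cells:
        mask[s, k] = True
    return mask


# ---------------------------------------------------------------------------
# step 7: rasterization and the full pipeline
# ---------------------------------------------------------------------------

def rasterize(
    region: MarRegion | None,
    grid: SectorGrid,
    stack: ShortAxisStack,
) -> MarSegmentation:
    """Label every pixel of each member sector as MaR (transmural labelling)."""
    from .metrics import mar_percent_lvm

    mask = np.zeros_like(stack.myo_mask)
    if region is not None:
        for s in region.slices:
            members = sorted(region.members_of_slice(s))
            labels = grid.sector_of_pixel[s]
            mask[s] = np.isin(labels, members) & (labels >= 0)
    percent = mar_percent_lvm(mask, stack.myo_mask, stack) if stack.myo_mask.any() else 0.0
    return MarSegmentation(pixel_mask=mask, sector_region=region,
                           mar_percent_lvm=percent)


def _check_final_region(region: MarRegion, allowed: np.ndarray) -> None:
    """Post-hoc assertion of the regional criteria on the final region."""
    bad = [cell for cell in region.member_sectors if not allowed[cell[0], cell[1]]]
    if bad:
        logger.error("final region violates regional criteria at cells %s", bad[:5])
    comps = connected_components(_cells_to_mask(region.member_sectors,
                                                int(allowed.shape[0])))
    if len(comps) != 1:
        logger.error("final region is not a single connected component (%d parts)",
                     len(comps))


def run_segment_mar(
    stack: ShortAxisStack,
    orient: Orientation,
    artery: str,
    options: SegmentOptions | None = None,
) -> MarSegmentation:
    """Run the full semi-automatic MaR segmentation.

    ``options`` can disable the a-priori initialisation, the transmural
    sector averaging, the regional criteria or the boundary interpolation to
    reproduce step-ablation experiments; intermediates are kept on the
    result when ``store_intermediates`` is set.  An empty final MaR region
    is a valid outcome, not an error.
    """
    opts = options or SegmentOptions()
    from .geometry import compute_sector_grid

    grid = compute_sector_grid(stack, orient)
    model = load_extent_model(artery, opts.extent_source)
    fits = fit_all_slices(stack, grid, model, apriori_init=opts.apriori_init,
                          tol=opts.em_tol, max_iter=opts.em_max_iter)
    if not fits:
        raise ValueError("no slice could be modelled")
    p3d = pixelwise_probability(stack, grid, fits)
    per_step: dict = {"fits": fits, "grid": grid, "model": model} \
        if opts.store_intermediates else {}

    if not opts.transmural_sectors:
        mask = np.zeros_like(stack.myo_mask)
        finite = np.isfinite(p3d)
        mask[finite] = p3d[finite] > PROBABILITY_THRESHOLD
        from .metrics import mar_percent_lvm
        seg = MarSegmentation(
            pixel_mask=mask, sector_region=None,
            mar_percent_lvm=mar_percent_lvm(mask, stack.myo_mask, stack),
            per_step=per_step or None,
        )
        return seg

    probmap = sector_probabilities_from_pixels(grid, p3d, fits)
    if opts.store_intermediates:
        per_step["probability_map"] = probmap

    if not opts.regional_criteria:
        supra = probmap.valid & (np.nan_to_num(probmap.values, nan=0.0)
                                 > PROBABILITY_THRESHOLD)
        cells = frozenset(map(tuple, np.argwhere(supra)))
        region = MarRegion(member_sectors=cells) if cells else None
        seg = rasterize(region, grid, stack)
        seg.per_step = per_step or None
        return seg

    candidates = find_candidate_regions(probmap, model, orient, artery, grid)
    if opts.store_intermediates:
        per_step["candidates"] = candidates
    if not candidates:
        logger.info("no sector exceeds probability %.2f inside the territory; "
                    "MaR is empty", PROBABILITY_THRESHOLD)
        seg = rasterize(None, grid, stack)
        seg.per_step = per_step or None
        return seg

    scores = [score_region_from_pixels(r, grid, p3d) for r in candidates]
    region = select_region(candidates, scores)
    if opts.store_intermediates:
        per_step["selected_region"] = region

    allowed = allowed_cells(grid, model, orient, artery)
    if opts.interpolation:
        region = interpolate_boundary(region, model, probmap, grid, artery,
                                      allowed=allowed)
    _check_final_region(region, allowed)
    seg = rasterize(region, grid, stack)
    seg.per_step = per_step or None
    return seg
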