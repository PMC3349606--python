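"""Slice-by-slice threshold comparator methods: 2SD-from-remote, FWHM, Otsu.

All three methods share the myocardial delineation with the main pipeline,
and 2SD/FWHM share its remote-region definition (myocardium outside the
culprit artery's maximal extent model).  Thresholds are computed and applied
per slice, because T2-weighted signal intensity drifts between slices;
pixels with intensity >= threshold are labelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import ShortAxisStack

logger = logging.getLogger("segmentmar")

OTSU_BINS = 256


@dataclass
class ThresholdResult:
    """Per-slice thresholds and the resulting pixel mask for one method.

    ``per_slice_threshold`` is NaN on slices the method had to skip (empty
    remote region, or a constant slice for Otsu); those slices contribute no
    labelled pixels.
    """

    per_slice_threshold: np.ndarray
    pixel_mask: np.ndarray
    method: str


def _apply_per_slice(stack: ShortAxisStack, thresholds: np.ndarray, method: str
                     ) -> ThresholdResult:
    mask = np.zeros_like(stack.myo_mask)
    for s, thr in enumerate(thresholds):
        if np.isfinite(thr):
            mask[s] = stack.myo_mask[s] & (stack.image[s] >= thr)
    return ThresholdResult(per_slice_threshold=thresholds, pixel_mask=mask,
                           method=method)


def threshold_2sd(stack: ShortAxisStack, remote: np.ndarray) -> ThresholdResult:
    """Threshold = mean + 2 SD of the intensity within the remote region.

    Slices with an empty remote region (territory covering the whole ring)
    are excluded with a warning.
    """
    thr = np.full(stack.n_slices, np.nan)
    for s in range(stack.n_slices):
        values = stack.image[s][remote[s]]
        if values.size == 0:
            logger.warning("2SD: slice %d has no remote myocardium, skipped", s)
            continue
        thr[s] = float(values.mean() + 2.0 * values.std(ddof=0))
    return _apply_per_slice(stack, thr, "2SD")


def threshold_fwhm(stack: ShortAxisStack, remote: np.ndarray) -> ThresholdResult:
    """Threshold = midway between the remote mean and the myocardial maximum.

    Both statistics are per slice.  Sensitive by construction to single
    bright artifacts, which pull the myocardial maximum (and hence the
    threshold) upwards.
    """
    thr = np.full(stack.n_slices, np.nan)
    for s in range(stack.n_slices):
        rem = stack.image[s][remote[s]]
        myo = stack.image[s][stack.myo_mask[s]]
        if rem.size == 0 or myo.size == 0:
            logger.warning("FWHM: slice %d lacks remote or myocardium, skipped", s)
            continue
        thr[s] = float((rem.mean() + myo.max()) / 2.0)
    return _apply_per_slice(stack, thr, "FWHM")


def otsu_threshold_from_histogram(hist: np.ndarray, edges: np.ndarray) -> tuple[int, float]:
    """Otsu's threshold on a histogram: the bin boundary minimising the
    weighted within-class intensity variance (equivalently maximising the
    between-class variance).

    Returns ``(split_index, threshold_value)`` where the lower class is bins
    ``[0, split)`` and the threshold value is ``edges[split]``.
    """
    hist = np.asarray(hist, dtype=float)
    centers = (np.asarray(edges[:-1]) + np.asarray(edges[1:])) / 2.0
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty histogram")

    w0 = np.cumsum(hist)[:-1]                    # mass below each interior edge
    w1 = total - w0
    cum_m = np.cumsum(hist * centers)
    m0 = cum_m[:-1]
    m1 = cum_m[-1] - m0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ValueError("histogram has a single occupied bin")
    mu0 = np.where(valid, m0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, m1 / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    split = int(np.argmax(between)) + 1
    return split, float(edges[split])


def threshold_otsu(stack: ShortAxisStack, nbins: int = OTSU_BINS) -> ThresholdResult:
    """Per-slice Otsu threshold on the myocardial intensity histogram.

    Uses ``nbins`` uniform bins over the slice's myocardial intensity range.
    Needs no remote region, but assumes both populations are present on
    every slice — on a slice of pure normal myocardium it still splits the
    noise and labels spurious pixels.  Constant slices are skipped with a
    warning.
    """
    thr = np.full(stack.n_slices, np.nan)
    for s in range(stack.n_slices):
        values = stack.image[s][stack.myo_mask[s]]
        if values.size == 0 or np.ptp(values) == 0:
            logger.warning("Otsu: slice %d constant or empty, skipped", s)
            continue
        hist, edges = np.histogram(values, bins=nbins)
        _, thr[s] = otsu_threshold_from_histogram(hist, edges)
    return _apply_per_slice(stack, thr, "Otsu")
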