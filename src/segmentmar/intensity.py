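"""Per-slice two-Gaussian intensity modelling of normal myocardium and MaR.

Each short-axis slice is modelled as a two-component Gaussian mixture: a
bright population (edematous myocardium at risk) and a darker one (normal
myocardium).  Because T2-weighted signal varies between slices, every slice
is fitted independently.  The fit is a standard EM refinement of an initial
estimate; with a-priori initialisation the MaR component starts from the
intensities inside the culprit artery's *normal* extent model and the normal
component from the intensities outside its *maximal* extent model.

The MaR probability of an intensity x is the weight-free density ratio

    p(x) = G(x; mu_mar, sigma_mar) / [G(x; mu_mar, sigma_mar)
                                      + G(x; mu_normal, sigma_normal)]

so p in [0, 1] and p > 0.5 marks intensities more likely to be MaR.  Mixture
weights are estimated inside EM (any standard EM carries them) but are
deliberately excluded from this ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit, logsumexp

from .geometry import ExtentModel, SectorGrid, ShortAxisStack

logger = logging.getLogger("segmentmar")

#: relative log-likelihood convergence threshold
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200
#: sigma floor, as a fraction of the slice intensity range
SIGMA_FLOOR_FRACTION = 1e-3
MIN_PIXELS_FOR_EM = 10


@dataclass
class SliceIntensityModel:
    """Two-Gaussian intensity model of one slice.

    ``mu_mar``/``sigma_mar`` describe the hyperintense (MaR) component,
    ``mu_normal``/``sigma_normal`` the normal-myocardium component and
    ``weight_mar`` the mixture proportion of the MaR component.
    """

    mu_mar: float
    sigma_mar: float
    mu_normal: float
    sigma_normal: float
    weight_mar: float = 0.5
    converged: bool = False
    n_iter: int = 0
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma_mar <= 0 or self.sigma_normal <= 0:
            raise ValueError("component standard deviations must be > 0")
        if not 0.0 <= self.weight_mar <= 1.0:
            raise ValueError("weight_mar must lie in [0, 1]")

    def to_dict(self) -> dict:
        """JSON-serialisable record of the fit, for audit/debug output."""
        d = asdict(self)
        return {k: (bool(v) if k == "converged" else v) for k, v in d.items()}


def _sample_stats(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1))


def percentile_split_init(intensities: np.ndarray) -> SliceIntensityModel:
    """Prior-free initialisation from the upper and lower intensity quartiles.

    Used when no a-priori territory information is available (ablation runs)
    or when an initialisation region is empty, e.g. an LM territory covering
    an entire ring so that no remote myocardium exists on the slice.
    """
    x = np.asarray(intensities, dtype=float)
    q25, q75 = np.percentile(x, [25, 75])
    hi, lo = x[x >= q75], x[x <= q25]
    mu_mar, sd_mar = _sample_stats(hi)
    mu_nrm, sd_nrm = _sample_stats(lo)
    floor = _sigma_floor(x)
    return SliceIntensityModel(
        mu_mar=mu_mar,
        sigma_mar=max(sd_mar, floor),
        mu_normal=mu_nrm,
        sigma_normal=max(sd_nrm, floor),
        weight_mar=0.25,
    )


def initialize_from_priors(
    stack: ShortAxisStack,
    grid: SectorGrid,
    model: ExtentModel,
    slice_index: int,
) -> SliceIntensityModel:
    """A-priori initial estimate for one slice from the territory model.

    The MaR component is initialised from the intensities inside the
    *normal* extent model of the culprit artery and the normal component
    from the intensities outside its *maximal* extent model; the mixture
    weight starts at the myocardial fraction of the normal-extent region.
    Falls back to :func:`percentile_split_init` (with a logged warning) when
    either region has fewer than two pixels.
    """
    labels = grid.sector_of_pixel[slice_index]
    myo = labels >= 0
    if not myo.any():
        raise ValueError(f"slice {slice_index} has no myocardial pixels")
    values = stack.image[slice_index]
    ring = int(grid.ring_of_slice[slice_index])
    sec = np.clip(labels, 0, None)
    in_normal = myo & model.normal[ring][sec]
    outside_maximal = myo & ~model.maximal[ring][sec]

    if in_normal.sum() < 2 or outside_maximal.sum() < 2:
        logger.warning(
            "slice %d: empty a-priori initialisation region for %s "
            "(inside-normal n=%d, remote n=%d); falling back to percentile split",
            slice_index, model.artery, int(in_normal.sum()), int(outside_maximal.sum()),
        )
        return percentile_split_init(values[myo])

    mu_mar, sd_mar = _sample_stats(values[in_normal])
    mu_nrm, sd_nrm = _sample_stats(values[outside_maximal])
    floor = _sigma_floor(values[myo])
    return SliceIntensityModel(
        mu_mar=mu_mar,
        sigma_mar=max(sd_mar, floor),
        mu_normal=mu_nrm,
        sigma_normal=max(sd_nrm, floor),
        weight_mar=float(in_normal.sum() / myo.sum()),
    )


def _sigma_floor(intensities: np.ndarray) -> float:
    rng = float(np.ptp(intensities))
    if rng > 0:
        return SIGMA_FLOOR_FRACTION * rng
    scale = max(1.0, abs(float(np.mean(intensities))))
    return SIGMA_FLOOR_FRACTION * scale


def _log_gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def fit_em(
    intensities: np.ndarray,
    init: SliceIntensityModel,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SliceIntensityModel:
    """Refine ``init`` by two-component Gaussian-mixture EM on one slice.

    Standard EM: E-step responsibilities from the weighted component
    densities, M-step weighted mean/SD/weight updates, iterated until the
    relative log-likelihood change falls below ``tol`` or ``max_iter`` is
    reached.  Components stay labelled (index 0 = the component initialised
    as MaR); if the labels end up swapped (mu_mar < mu_normal) they are
    relabelled so MaR is the brighter component, with a log message.

    Raises ValueError for fewer than ``MIN_PIXELS_FOR_EM`` pixels — callers
    mark such slices unmodeled.  Collapsing components are clamped to a
    sigma floor and flagged non-converged.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < MIN_PIXELS_FOR_EM:
        raise ValueError(
            f"EM needs >= {MIN_PIXELS_FOR_EM} myocardial pixels, got {x.size}"
        )
    floor = _sigma_floor(x)

    mu = np.array([init.mu_mar, init.mu_normal], dtype=float)
    sigma = np.maximum([init.sigma_mar, init.sigma_normal], floor).astype(float)
    w = np.clip([init.weight_mar, 1.0 - init.weight_mar], 1e-6, 1.0)
    w = w / w.sum()

    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    clamped = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_joint = np.stack(
            [np.log(w[k]) + _log_gauss(x, mu[k], sigma[k]) for k in range(2)]
        )
        log_norm = logsumexp(log_joint, axis=0)
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm)

        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (resp @ x) / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        sigma = np.sqrt(var)
        if np.any(sigma < floor):
            sigma = np.maximum(sigma, floor)
            clamped = True
        w = nk / x.size

        if np.isfinite(prev_ll):
            denom = max(abs(prev_ll), 1.0)
            if abs(ll - prev_ll) / denom < tol:
                converged = True
                break
        prev_ll = ll

    if clamped:
        converged = False

    mu_mar, mu_nrm = float(mu[0]), float(mu[1])
    sd_mar, sd_nrm = float(sigma[0]), float(sigma[1])
    w_mar = float(w[0])
    if mu_mar < mu_nrm:
        logger.info(
            "EM components swapped (mu_mar %.3g < mu_normal %.3g); relabelling "
            "so MaR is the brighter component", mu_mar, mu_nrm,
        )
        mu_mar, mu_nrm = mu_nrm, mu_mar
        sd_mar, sd_nrm = sd_nrm, sd_mar
        w_mar = 1.0 - w_mar

    return SliceIntensityModel(
        mu_mar=mu_mar,
        sigma_mar=sd_mar,
        mu_normal=mu_nrm,
        sigma_normal=sd_nrm,
        weight_mar=w_mar,
        converged=converged,
        n_iter=it,
        log_likelihood=ll,
    )


def em_log_likelihood(intensities: np.ndarray, fit: SliceIntensityModel) -> float:
    """Mixture log-likelihood of ``intensities`` under ``fit`` (for diagnostics)."""
    x = np.asarray(intensities, dtype=float).ravel()
    log_joint = np.stack(
        [
            np.log(max(fit.weight_mar, 1e-300)) + _log_gauss(x, fit.mu_mar, fit.sigma_mar),
            np.log(max(1.0 - fit.weight_mar, 1e-300))
            + _log_gauss(x, fit.mu_normal, fit.sigma_normal),
        ]
    )
    return float(logsumexp(log_joint, axis=0).sum())


def mar_probability(intensity, fit: SliceIntensityModel):
    """MaR probability of an intensity: the weight-free Gaussian density ratio.

    Computed via log densities so that it is numerically stable arbitrarily
    far into the tails.  Returns a scalar for scalar input, else an ndarray,
    always in [0, 1].
    """
    x = np.asarray(intensity, dtype=float)
    log_mar = _log_gauss(x, fit.mu_mar, fit.sigma_mar)
    log_nrm = _log_gauss(x, fit.mu_normal, fit.sigma_normal)
    p = expit(log_mar - log_nrm)
    if np.ndim(intensity) == 0:
        return float(p)
    return p
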