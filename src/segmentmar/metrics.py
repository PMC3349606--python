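"""Agreement statistics: MaR burden, Dice overlap, Bland-Altman, regression.

Quantitative agreement between two segmentation methods is summarised the
way segmentation-validation studies conventionally do: per-subject MaR as a
percentage of left-ventricular mass (LVM), Bland-Altman bias (mean +/- SD of
method minus reference), a paired t-test, ordinary least-squares regression
(r and p), and the Dice similarity coefficient per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .geometry import ShortAxisStack

logger = logging.getLogger("segmentmar")


@dataclass
class AgreementReport:
    """Cohort-level agreement of a method against a reference.

    ``bias_*`` are in % of LVM with the fixed sign convention method minus
    reference (an underestimating method has negative bias).
    """

    bias_mean: float
    bias_sd: float
    t_p_value: float
    r_value: float
    r_p_value: float
    dsc_mean: float
    dsc_sd: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def mar_percent_lvm(mar_mask: np.ndarray, myo_mask: np.ndarray,
                    stack: ShortAxisStack | None = None) -> float:
    """MaR volume as a percentage of left-ventricular mass.

    Volumes are pixel count x pixel area x (slice thickness + gap); since
    every voxel has the same volume and density, the geometry cancels in the
    ratio, but ``stack`` is accepted for interface symmetry with callers
    that report absolute volumes.
    """
    mar_mask = np.asarray(mar_mask, dtype=bool)
    myo_mask = np.asarray(myo_mask, dtype=bool)
    if mar_mask.shape != myo_mask.shape:
        raise ValueError("mask shapes differ")
    n_myo = int(myo_mask.sum())
    if n_myo == 0:
        raise ValueError("empty myocardium: LVM is zero")
    if np.any(mar_mask & ~myo_mask):
        raise ValueError("MaR mask extends outside the myocardium")
    return 100.0 * float(mar_mask.sum()) / n_myo


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    1 for perfect overlap, 0 for disjoint regions.  When both masks are
    empty the coefficient is defined here as 1 (perfect agreement that
    there is no MaR) and the case is logged.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.info("dice: both masks empty; returning 1.0 by convention")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def agreement(
    method_percent: np.ndarray,
    reference_percent: np.ndarray,
    dsc: np.ndarray | None = None,
) -> AgreementReport:
    """Cohort agreement statistics of paired per-subject MaR percentages.

    ``method_percent`` and ``reference_percent`` are paired per-subject MaR
    in % of LVM; ``dsc`` the optional per-subject Dice coefficients.  Bias
    is method minus reference; the t-test is two-sided and paired; r/p come
    from ordinary least-squares regression of method on reference.
    """
    m = np.asarray(method_percent, dtype=float)
    r = np.asarray(reference_percent, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("method and reference must be equal-length 1-D arrays")
    n = m.size
    if n < 2:
        raise ValueError("agreement statistics need n >= 2 paired subjects")

    diff = m - r
    bias_mean = float(diff.mean())
    bias_sd = float(diff.std(ddof=1))

    if np.allclose(diff, diff[0]):
        # zero-variance differences: t-test undefined, p reported as 1 for
        # identical pairs by convention
        t_p = 1.0 if np.allclose(diff, 0.0) else 0.0
    else:
        t_p = float(stats.ttest_rel(m, r).pvalue)

    if np.ptp(r) == 0 or np.ptp(m) == 0:
        r_value, r_p = float("nan"), float("nan")
    else:
        reg = stats.linregress(r, m)
        r_value, r_p = float(reg.rvalue), float(reg.pvalue)
        if np.allclose(m, r):
            r_value, r_p = 1.0, 0.0

    if dsc is not None:
        d = np.asarray(dsc, dtype=float)
        if d.shape != m.shape:
            raise ValueError("dsc must pair with the percent arrays")
        dsc_mean, dsc_sd = float(d.mean()), float(d.std(ddof=1))
    else:
        dsc_mean = dsc_sd = float("nan")

    return AgreementReport(
        bias_mean=bias_mean, bias_sd=bias_sd, t_p_value=t_p,
        r_value=r_value, r_p_value=r_p,
        dsc_mean=dsc_mean, dsc_sd=dsc_sd, n=n,
    )
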