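"""Evaluation statistics: ROI summaries, repeatability, and SNR.

Conventions (recorded here because they matter for reproducing numbers):
ROI standard deviations are population SDs (ddof=0); Bland-Altman limits
of agreement use the sample SD (ddof=1) of the paired differences; the
intraclass correlation uses a one-way decomposition in which the
within-subject variance is estimated from test-retest differences
(sigma_w^2 = mean(d_i^2)/2) and the between-subject variance from the
variance of subject means with the within-subject share removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROIStat",
    "ICCResult",
    "BlandAltman",
    "roi_stats",
    "icc",
    "bland_altman",
    "paired_ttest",
    "snr_estimate",
]


@dataclass(frozen=True)
class ROIStat:
    label: str
    n_voxels: int
    mean: float
    sd: float


@dataclass(frozen=True)
class ICCResult:
    """ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2), clamped to [0, 1]."""

    sigma_b_sq: float
    sigma_w_sq: float

    @property
    def icc(self) -> float:
        denom = self.sigma_b_sq + self.sigma_w_sq
        if denom == 0:
            return 0.0
        return float(np.clip(self.sigma_b_sq / denom, 0.0, 1.0))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    n: int


def roi_stats(volume: np.ndarray, roi_mask: np.ndarray, label: str = "roi") -> ROIStat:
    """Mean and population SD of a parameter map over a region of interest."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if volume.shape != roi_mask.shape:
        raise ValueError("volume and mask shapes differ")
    vals = np.asarray(volume)[roi_mask]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    return ROIStat(
        label=label,
        n_voxels=int(vals.size),
        mean=float(np.mean(vals)),
        sd=float(np.std(vals)),  # population SD
    )


def icc(scan1, scan2) -> ICCResult:
    """Test-retest intraclass correlation from paired per-subject values.

    One-way random-effects reading: each scan value is subject effect plus
    measurement error; sigma_w^2 comes from the paired differences, and the
    subject-mean variance is corrected for its error share (floored at 0).
    """
    x = np.asarray(scan1, dtype=float)
    y = np.asarray(scan2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scan1/scan2 must be equal-length 1-D arrays")
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    d = x - y
    sigma_w = float(np.mean(d**2) / 2.0)
    means = (x + y) / 2.0
    sigma_b = float(max(np.var(means, ddof=1) - sigma_w / 2.0, 0.0))
    return ICCResult(sigma_b_sq=sigma_b, sigma_w_sq=sigma_w)


def bland_altman(x, y) -> BlandAltman:
    """Agreement between paired measurements: bias and 95% limits
    (bias +/- 1.96 * sample SD of the differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x/y must be equal-length 1-D arrays")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=x.size
    )


def paired_ttest(x, y):
    """Paired two-tailed Student t-test; returns ``(t, df, p)``.

    The statistic is mean(d) / (sd(d)/sqrt(n)) with df = n-1 and the
    two-tailed p from the t-distribution survival function.  A zero
    difference variance is an error, not p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x/y must be equal-length 1-D arrays")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


def snr_estimate(image, signal_roi, noise_roi, rayleigh_correction: bool = False) -> float:
    """SNR of a magnitude image: mean over the signal ROI divided by the SD
    over a background noise ROI.

    With ``rayleigh_correction`` the background SD is converted to the
    underlying Gaussian component SD (divides by sqrt(2 - pi/2)), since
    magnitude background noise is Rayleigh-distributed; the plain estimator
    matches common practice and is the default.
    """
    image = np.asarray(image)
    s = image[np.asarray(signal_roi, dtype=bool)]
    nvals = image[np.asarray(noise_roi, dtype=bool)]
    if s.size == 0 or nvals.size == 0:
        raise ValueError("both ROIs must be nonempty")
    sd = float(np.std(nvals))
    if sd == 0:
        raise ValueError("noise ROI has zero SD")
    if rayleigh_correction:
        sd = sd / np.sqrt(2.0 - np.pi / 2.0)
    return float(np.mean(s) / sd)
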