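"""Agreement and reproducibility statistics for validation studies.

Two measurement series of the same spines (e.g. automatic vs. manual
volumes) are compared by Pearson correlation and a Bland–Altman analysis:
mean difference mu, standard deviation sigma of the differences, and the
fraction of spines whose difference falls within mu +/- 1.5 sigma.
Multi-rater reproducibility is summarised per spine as the standard
deviation across raters relative to the across-rater mean, in percent, and
reported as the population mean of that percentage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import ValidationError


@dataclass(frozen=True)
class AgreementResult:
    pearson_r: float          # nan when a series has zero variance
    zero_variance: bool
    mean_diff: float
    sd_diff: float
    frac_within_band: float
    band_sd: float = 1.5


@dataclass(frozen=True)
class ReproducibilityResult:
    percent_sd: float                 # mean over spines of 100 * sd / mean
    per_spine_percent_sd: np.ndarray
    n_excluded_zero_mean: int


def agreement_stats(a, b, band_sd: float = 1.5) -> AgreementResult:
    """Pearson r and Bland–Altman summary of two paired series."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("agreement_stats requires two 1-D series of equal length")
    if a.size < 3:
        raise ValidationError("agreement_stats requires at least 3 paired values")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("agreement_stats does not accept missing values")
    zero_var = bool(np.ptp(a) == 0 or np.ptp(b) == 0)
    if zero_var:
        warnings.warn("agreement_stats: a series has zero variance; r undefined", stacklevel=2)
        r = math.nan
    else:
        r = float(sstats.pearsonr(a, b).statistic)
    diff = a - b
    mu = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0:
        frac = 1.0
    else:
        frac = float(np.mean(np.abs(diff - mu) <= band_sd * sd))
    return AgreementResult(pearson_r=r, zero_variance=zero_var, mean_diff=mu,
                           sd_diff=sd, frac_within_band=frac, band_sd=band_sd)


def reproducibility_stats(ratings) -> ReproducibilityResult:
    """Percent standard deviation across raters, averaged over spines.

    ``ratings`` is a (n_raters, n_spines) matrix of one feature; spines with
    zero across-rater mean are excluded with a warning.
    """
    m = np.asarray(ratings, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValidationError("reproducibility_stats requires a (raters >= 2, spines) matrix")
    if np.isnan(m).any():
        raise ValidationError("reproducibility_stats requires a complete matrix")
    means = m.mean(axis=0)
    keep = means != 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"reproducibility_stats: excluding {n_excluded} spine(s) with zero mean",
                      stacklevel=2)
    if not keep.any():
        raise ValidationError("all spines have zero mean; percent SD undefined")
    sds = m[:, keep].std(axis=0, ddof=1)
    pct = 100.0 * sds / means[keep]
    return ReproducibilityResult(percent_sd=float(pct.mean()),
                                 per_spine_percent_sd=pct,
                                 n_excluded_zero_mean=n_excluded)
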