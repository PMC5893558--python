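"""Genomic-control inflation estimation and correction.

Population stratification and other confounding inflate association
chi-squares genome-wide. The classic genomic-control estimator compares the
median observed Wald chi-square (Z^2) to the null chi-square(1 df) median;
Z-scores are then deflated by sqrt(lambda). The estimator here is the
median-based one applied to all analysis SNPs by default, with an optional
control-subset mask (e.g. a user-supplied intergenic SNP list).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 df, computed not transcribed.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

MIN_SNPS_RELIABLE = 1000


@dataclass
class InflationEstimate:
    lambda_gc: float
    n_snps_used: int
    subset_label: str = "all"
    warning: str | None = None


def estimate_lambda(z, subset_mask=None) -> InflationEstimate:
    """Median-based genomic-control lambda from signed Z-scores.

    lambda_gc = median(z^2) / median(chi-square(1)). Sign-flip invariant by
    construction. A warning is attached when fewer than 1000 SNPs inform
    the median.
    """
    z = np.asarray(z, dtype=float)
    label = "all"
    if subset_mask is not None:
        z = z[np.asarray(subset_mask, dtype=bool)]
        label = "control-subset"
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no finite Z-scores to estimate lambda from")
    lam = float(np.median(z**2) / CHI2_1_MEDIAN)
    warning = None
    if z.size < MIN_SNPS_RELIABLE:
        warning = f"lambda estimated from only {z.size} SNPs (< {MIN_SNPS_RELIABLE})"
        logger.warning(warning)
    return InflationEstimate(lambda_gc=lam, n_snps_used=int(z.size),
                             subset_label=label, warning=warning)


def apply_gc(z, lambda_gc: float):
    """Deflate Z-scores by sqrt(max(lambda, 1)); never amplifies signal."""
    if lambda_gc <= 0:
        raise ValueError("lambda_gc must be > 0")
    return np.asarray(z, dtype=float) / np.sqrt(max(lambda_gc, 1.0))


def correct_panel(panel, subset_mask=None):
    """Estimate and apply GC per trait on a HarmonizedPanel, in place.

    Returns the list of InflationEstimate, one per trait. p-values are
    recomputed from the corrected Z.
    """
    from .sumstats import p_from_z

    estimates = []
    for k in range(panel.z.shape[1]):
        est = estimate_lambda(panel.z[:, k], subset_mask)
        panel.z[:, k] = apply_gc(panel.z[:, k], est.lambda_gc)
        panel.p[:, k] = p_from_z(panel.z[:, k])
        estimates.append(est)
        logger.info("trait %s: lambda_gc = %.4f (n=%d, %s)", panel.trait_names[k],
                    est.lambda_gc, est.n_snps_used, est.subset_label)
    panel.log["lambda_gc"] = [e.lambda_gc for e in estimates]
    return estimates
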