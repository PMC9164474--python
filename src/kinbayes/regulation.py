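"""Identification of significantly regulated phosphosites.

A site counts as regulated when, at one or more time points, both (a) a
two-sided one-sample Student t-test of its replicate log2 ratios against
zero gives p below ``alpha_p`` and (b) the absolute mean log2 ratio lies
outside an empirical 95% range.  The range half-width is taken as
``ci_multiplier`` times the largest per-time-point standard deviation of
the mean log2 ratios across all quantified sites (an empirical-Bayes
style pooled noise estimate).  With both criteria at level 0.05 the
expected false discovery rate is their product, 0.0025, and no further
multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import TIMES, PhosphoSite

logger = logging.getLogger("kinbayes")


class InsufficientDataError(ValueError):
    """Too few observations to compute the statistic."""


@dataclass(frozen=True)
class SignificanceConfig:
    """Thresholds for the dual significance criteria.

    alpha_p
        Per-time-point p-value threshold (default 0.05).
    ci_multiplier
        SD multiplier defining the confidence range; 2 by default so the
        printed half-width 2 x 0.148 rounds to 0.30.
    use_max_sd
        Use the largest per-time-point SD for one global range (default),
        rather than a per-time range.
    """

    alpha_p: float = 0.05
    ci_multiplier: float = 2.0
    use_max_sd: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_p < 1.0:
            raise ValueError(f"alpha_p must be in (0, 1), got {self.alpha_p}")
        if self.ci_multiplier <= 0:
            raise ValueError("ci_multiplier must be > 0")


@dataclass(frozen=True)
class RegulationReport:
    per_time_sd: tuple[float, ...]
    half_width: float
    fdr_estimate: float
    regulated_ids: tuple[str, ...]
    config: SignificanceConfig = field(default_factory=SignificanceConfig)


def per_timepoint_sd(sites: list[PhosphoSite]) -> np.ndarray:
    """Sample SD of the mean log2 ratio across sites, one value per time."""
    if len(sites) < 2:
        raise InsufficientDataError("need >= 2 sites to estimate per-time SDs")
    ratios = np.array([s.timecourse.log2_ratio for s in sites], dtype=float)
    return ratios.std(axis=0, ddof=1)


def confidence_half_width(sds, config: SignificanceConfig | None = None) -> float:
    """Half-width of the empirical range: multiplier x max SD, rounded to 2 dp."""
    config = config or SignificanceConfig()
    sds = np.asarray(sds, dtype=float)
    if sds.size == 0:
        raise ValueError("empty SD vector")
    if (sds < 0).any():
        raise ValueError("SDs must be non-negative")
    scale = sds.max() if config.use_max_sd else sds
    return float(np.round(config.ci_multiplier * scale, 2))


def site_p_value(replicate_ratios) -> float:
    """Two-sided one-sample t-test of replicate log2 ratios against 0."""
    reps = np.asarray(replicate_ratios, dtype=float)
    if reps.size < 2:
        raise InsufficientDataError("need >= 2 replicates for a p-value")
    if np.ptp(reps) == 0.0:
        if reps[0] == 0.0:
            return 1.0
        warnings.warn("zero replicate variance with nonzero mean; p = 0")
        return 0.0
    return float(stats.ttest_1samp(reps, 0.0).pvalue)


def p_value_matrix(sites: list[PhosphoSite]) -> np.ndarray:
    """(n_sites, n_times) matrix of one-sample t-test p-values, vectorized."""
    reps = np.array([s.timecourse.replicate_ratios for s in sites], dtype=float)
    n = reps.shape[2]
    mean = reps.mean(axis=2)
    sd = reps.std(axis=2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # degenerate replicates: zero variance -> p is nan; resolve per the scalar rule
    degenerate = sd == 0.0
    p[degenerate & (mean == 0.0)] = 1.0
    p[degenerate & (mean != 0.0)] = 0.0
    return p


def dual_criteria_filter(
    sites: list[PhosphoSite],
    half_width: float,
    config: SignificanceConfig | None = None,
) -> list[str]:
    """Site ids where, at >= 1 time point, p < alpha_p AND |mean ratio| > half-width."""
    config = config or SignificanceConfig()
    if not sites:
        return []
    ratios = np.array([s.timecourse.log2_ratio for s in sites], dtype=float)
    p = p_value_matrix(sites)
    hit = (p < config.alpha_p) & (np.abs(ratios) > half_width)
    return [s.site_id for s, h in zip(sites, hit.any(axis=1)) if h]


def fdr_product(alpha_p: float, alpha_range: float) -> float:
    """Expected FDR of the dual criteria: the product of the two levels."""
    return alpha_p * alpha_range


def regulation_report(
    sites: list[PhosphoSite], config: SignificanceConfig | None = None
) -> RegulationReport:
    """Run the full filter: pooled SDs, half-width, dual criteria, FDR."""
    config = config or SignificanceConfig()
    sds = per_timepoint_sd(sites)
    half = confidence_half_width(sds, config)
    regulated = dual_criteria_filter(sites, half, config)
    alpha_range = 0.05  # a 95% range excludes 5% of null sites by construction
    logger.info(
        "regulation filter: SDs=%s half_width=%.2f alpha_p=%g -> %d regulated",
        np.round(sds, 4).tolist(), half, config.alpha_p, len(regulated),
    )
    return RegulationReport(
        per_time_sd=tuple(float(x) for x in sds),
        half_width=half,
        fdr_estimate=fdr_product(config.alpha_p, alpha_range),
        regulated_ids=tuple(regulated),
        config=config,
    )


def mark_regulated(
    sites: list[PhosphoSite], report: RegulationReport
) -> list[PhosphoSite]:
    """Return sites with the ``regulated`` flag set from a report."""
    from dataclasses import replace

    reg = set(report.regulated_ids)
    return [replace(s, regulated=s.site_id in reg) for s in sites]
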