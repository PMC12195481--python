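"""Tissue-enriched ion detection and background-pixel removal.

For every ion the intensities of the tissue-region pixels are compared
against the background-region pixels with a one-sided Wilcoxon rank-sum
test (tissue > background) and a mean-based fold change.  Ions with
fold change > 1 and p < 0.05 (defaults) are tissue-enriched; the
percentage of such ions is the third quality metric.  The per-pixel total
intensity over the enriched subset then drives a threshold segmentation:
pixels whose total falls below the threshold are background and removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import ConfigError, DegenerateInputError, EmptyResultError, ValidationError
from .peaktable import PeakTable
from .regions import Region

#: Exact enumeration is used (tie-free samples) up to this combined size.
EXACT_LIMIT = 16


@dataclass
class RankSumResult:
    u: float
    p: float
    method: str  # "exact" | "normal"


@dataclass
class EnrichmentTable:
    """Per-ion fold change / p-value / enriched flag plus the summary rate."""

    table: pd.DataFrame  # columns: mz, fold_change, p_value, u, enriched
    alpha: float
    fc_min: float
    pseudocount: float

    @property
    def enriched_percent(self) -> float:
        if len(self.table) == 0:
            return 0.0
        return 100.0 * float(self.table["enriched"].mean())


@dataclass
class SegmentationResult:
    threshold: float
    totals: np.ndarray
    keep: np.ndarray  # boolean, aligned with the input table's pixels

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())


@dataclass
class SuggestedThreshold:
    value: float
    quantiles: dict


# ---------------------------------------------------------------------------


def rank_sum_test(
    a, b, alternative: str = "greater", mode: str = "auto"
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test of ``a`` against ``b``.

    ``mode='auto'`` uses the exact null distribution when the combined
    sample size is at most 16 and there are no ties, and otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.  Returns the U statistic of ``a`` and the p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("rank_sum_test requires non-empty samples")
    if alternative not in ("greater", "two-sided"):
        raise ConfigError(f"unsupported alternative {alternative!r}")
    if mode == "auto":
        pooled = np.concatenate([a, b])
        tie_free = len(np.unique(pooled)) == pooled.size
        method = "exact" if (a.size + b.size <= EXACT_LIMIT and tie_free) else "normal"
    elif mode in ("exact", "normal"):
        method = mode
    else:
        raise ConfigError(f"unsupported mode {mode!r}")
    res = stats.mannwhitneyu(
        a,
        b,
        alternative=alternative,
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(float(res.statistic), float(res.pvalue), method)


def ion_enrichment(
    pt: PeakTable,
    tissue: Region,
    background: Region,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    mode: str = "auto",
    bh: bool = False,
) -> EnrichmentTable:
    """Per-ion tissue-vs-background enrichment on the original table.

    fold_change = (mean tissue + eps) / (mean background + eps) with eps
    equal to half the smallest positive intensity in the table (guards the
    all-zero-background case); p is the one-sided rank-sum p-value.  An ion
    is enriched when fold_change > fc_min (strict) and p < alpha (strict).
    With ``bh=True`` p-values are Benjamini-Hochberg adjusted first.
    """
    if tissue.pixels & background.pixels:
        raise ConfigError("tissue and background regions overlap")
    ti = tissue.indices(pt)
    bi = background.indices(pt)
    pos = pt.intensity[pt.intensity > 0]
    eps = float(pos.min()) / 2.0 if pos.size else 1e-12

    t_mat = pt.intensity[ti]
    b_mat = pt.intensity[bi]
    fc = (t_mat.mean(axis=0) + eps) / (b_mat.mean(axis=0) + eps)

    large = len(ti) + len(bi) > EXACT_LIMIT
    if large and mode == "auto":
        # single vectorized asymptotic pass (tie-corrected, continuity-corrected)
        res = stats.mannwhitneyu(
            t_mat, b_mat, alternative="greater", method="asymptotic",
            use_continuity=True, axis=0,
        )
        u = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        u = np.empty(pt.n_ions)
        p = np.empty(pt.n_ions)
        for j in range(pt.n_ions):
            r = rank_sum_test(t_mat[:, j], b_mat[:, j], "greater", mode)
            u[j], p[j] = r.u, r.p
    p_eff = stats.false_discovery_control(p) if bh else p
    enriched = (fc > fc_min) & (p_eff < alpha)
    table = pd.DataFrame(
        {"mz": pt.mz, "fold_change": fc, "p_value": p_eff, "u": u, "enriched": enriched}
    )
    return EnrichmentTable(table, alpha, fc_min, eps)


def pixel_total_intensity(pt: PeakTable, ions) -> np.ndarray:
    """Per-pixel total intensity over an ion subset (boolean mask or indices)."""
    ions = np.asarray(ions)
    if ions.dtype == bool:
        if len(ions) != pt.n_ions:
            raise ConfigError("ion mask length mismatch")
        idx = np.flatnonzero(ions)
    else:
        idx = ions.astype(np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= pt.n_ions):
            raise ConfigError("ion index out of range")
    if idx.size == 0:
        raise ConfigError("ion subset must be non-empty")
    return pt.intensity[:, idx].sum(axis=1)


def remove_background_pixels(
    pt: PeakTable, totals: np.ndarray, threshold: float
) -> tuple[PeakTable, SegmentationResult]:
    """Keep pixels with total intensity >= threshold (boundary kept).

    Returns the restricted table plus a result recording the full keep
    mask, so removed pixels can be flagged (not dropped) in the per-pixel
    result table.
    """
    totals = np.asarray(totals, dtype=float)
    if len(totals) != pt.n_pixels:
        raise ValidationError("totals not aligned with the peak table")
    keep = totals >= threshold
    if not keep.any():
        raise EmptyResultError(
            f"threshold {threshold} removes all {pt.n_pixels} pixels"
        )
    out = pt.subset_pixels(keep, note=f"background pixels removed (threshold={threshold})")
    return out, SegmentationResult(float(threshold), totals, keep)


def suggest_threshold(totals: np.ndarray) -> SuggestedThreshold:
    """Advisory segmentation threshold: Otsu on log10(total + 1).

    The intended use is visual: the between-class-variance optimum on the
    log scale usually lands in the valley between the background and tissue
    modes; quantiles are reported alongside for context.
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size < 2 or np.ptp(totals) == 0:
        raise DegenerateInputError("totals are constant; no threshold can separate them")
    logt = np.log10(totals + 1.0)
    t = float(threshold_otsu(logt, nbins=512))
    value = float(10.0**t - 1.0)
    qs = {f"q{int(q * 100)}": float(np.quantile(totals, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)}
    return SuggestedThreshold(value, qs)
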