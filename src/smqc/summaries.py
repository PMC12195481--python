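"""Intensity and missing-value distribution summaries.

Per-pixel: median intensity over ions, total intensity, and the missing
pixel ratio (fraction of ions undetected at that pixel).  Per-ion: median
intensity over pixels, the missing ion ratio (fraction of pixels where the
ion is undetected), and a histogram of log10(median + 1) (MSI intensities
span decades).  "Undetected" means intensity <= 0, matching the reader's
NA-to-0 convention.

These two views obey an exact double-counting identity: the mean missing
pixel ratio, the mean missing ion ratio and the overall zero fraction of
the matrix are all the same number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .peaktable import PeakTable

DEFAULT_BINS = 50


@dataclass
class IonSummary:
    table: pd.DataFrame  # mz, median_intensity, missing_ion_ratio
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    log_scale: bool


def pixel_summaries(pt: PeakTable) -> pd.DataFrame:
    """Per-pixel median, total intensity and missing ratio."""
    if pt.n_pixels == 0 or pt.n_ions == 0:
        raise ConfigError("cannot summarize an empty peak table")
    return pd.DataFrame(
        {
            "x": pt.coords[:, 0],
            "y": pt.coords[:, 1],
            "median_intensity": np.median(pt.intensity, axis=1),
            "total_intensity": pt.intensity.sum(axis=1),
            "missing_pixel_ratio": (pt.intensity <= 0).mean(axis=1),
        }
    )


def ion_summaries(
    pt: PeakTable, bins: int = DEFAULT_BINS, log_scale: bool = True
) -> IonSummary:
    """Per-ion median and missing ratio plus a median-intensity histogram.

    Histogram: ``bins`` equal-width bins over the observed range of
    log10(median + 1) (or of the raw medians with ``log_scale=False``);
    counts always sum to the number of ions.
    """
    if pt.n_pixels == 0 or pt.n_ions == 0:
        raise ConfigError("cannot summarize an empty peak table")
    med = np.median(pt.intensity, axis=0)
    table = pd.DataFrame(
        {
            "mz": pt.mz,
            "median_intensity": med,
            "missing_ion_ratio": (pt.intensity <= 0).mean(axis=0),
        }
    )
    vals = np.log10(med + 1.0) if log_scale else med
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:  # all medians identical: a single degenerate bin still counts everything
        hi = lo + 1.0
    counts, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    return IonSummary(table, counts, edges, log_scale)


def missingness_identity(pt: PeakTable) -> dict:
    """The three equivalent missingness rates (used as a QC self-check).

    Computed from integer zero counts so the double-counting identity is
    bit-exact, not merely exact up to float summation order.
    """
    zero = pt.intensity <= 0
    cells = zero.size
    return {
        "mean_missing_pixel_ratio": int(zero.sum(axis=1).sum()) / cells,
        "mean_missing_ion_ratio": int(zero.sum(axis=0).sum()) / cells,
        "overall_zero_fraction": int(zero.sum()) / cells,
    }
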