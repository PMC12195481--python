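"""Noise-ion scoring by a quadrat test of complete spatial randomness.

A noise ion is one whose spatial pattern is indistinguishable from points
scattered uniformly at random over the retained pixels.  Each ion's
intensity image is first reduced to a point pattern (by default the top
half of its detected pixels by intensity: pure detection patterns
saturate when an ion is detected almost everywhere, destroying
discrimination, while intensity-rank selection preserves it).  The
support bounding box is divided into a grid of quadrats; observed point
counts are compared to CSR expectations proportional to the number of
support pixels per quadrat (so non-rectangular tissue masks are handled
without bias) with an upper-tail chi-square test.  The noise score is
-log10(p), computed in log space: structured ions can reach scores near
90, i.e. p ~ 1e-90, far below double-precision underflow.

Low scores mean "consistent with CSR", i.e. noise.  Ions scoring below
the threshold (default 60) -- or with too few points for the chi-square
to be reliable -- are flagged and removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import ConfigError, DegenerateInputError, EmptyResultError, ValidationError
from .peaktable import PeakTable

LN10 = math.log(10.0)


def chi2_log_survival(x: float, df: int) -> float:
    """log of the upper-tail chi-square probability, safe far past underflow.

    scipy's ``chi2.logsf`` returns -inf once the survival probability drops
    below the double-precision floor (~1e-308, a noise score of ~308).  In
    that regime the asymptotic expansion of the upper incomplete gamma
    function Q(a, t) ~ t^(a-1) e^-t / Gamma(a) * sum_j (a-1)...(a-j) / t^j
    (a = df/2, t = x/2) is accurate to machine precision.
    """
    lp = float(stats.chi2.logsf(x, df))
    if np.isfinite(lp):
        return lp
    a, t = df / 2.0, x / 2.0
    series = term = 1.0
    for j in range(1, 30):
        term *= (a - j) / t
        series += term
        if abs(term) < 1e-17 * series:
            break
    return (a - 1.0) * math.log(t) - t - math.lgamma(a) + math.log(series)

#: Default score threshold below which an ion is classified as noise.
DEFAULT_NOISE_THRESHOLD = 60.0
#: Chi-square on fewer points than this is unreliable; such ions are
#: auto-flagged as noise via the sparsity flag.
DEFAULT_MIN_POINTS = 20
DEFAULT_GRID = (5, 5)


@dataclass
class PointPattern:
    points: np.ndarray  # (k, 2) int coordinates, subset of support
    support: np.ndarray  # (n, 2) int coordinates of all retained pixels
    mode: str
    fraction: float


@dataclass
class QuadratResult:
    chi2: float
    df: int
    log_p: float  # natural-log upper-tail p (<= 0)
    noise_score: float  # -log10(p), >= 0, finite
    n_points: int
    n_quadrats_used: int


@dataclass
class NoiseTable:
    """Per-ion quadrat results with the noise classification."""

    table: pd.DataFrame  # mz, n_points, chi2, df, log_p, noise_score, sparse, is_noise
    threshold: float
    min_points: int
    grid: tuple
    mode: str
    fraction: float

    @property
    def noise_percent(self) -> float:
        if len(self.table) == 0:
            return 0.0
        return 100.0 * float(self.table["is_noise"].mean())


# ---------------------------------------------------------------------------


def ion_point_pattern(
    pt: PeakTable, ion: int, mode: str = "top_fraction", fraction: float = 0.5
) -> PointPattern:
    """Reduce one ion's image to a point pattern over the retained pixels.

    ``detected``: all pixels with intensity > 0.  ``top_fraction``: the
    ceil(f * k) highest-intensity detected pixels (k = detected count);
    ties at the cutoff break by pixel order for determinism.
    """
    if not (0 < fraction <= 1):
        raise ConfigError("fraction must be in (0, 1]")
    if not (0 <= ion < pt.n_ions):
        raise ConfigError(f"ion index {ion} out of range")
    v = pt.intensity[:, ion]
    det = np.flatnonzero(v > 0)
    if mode == "detected" or (mode == "top_fraction" and fraction == 1.0):
        sel = det
    elif mode == "top_fraction":
        k = int(math.ceil(fraction * det.size))
        # stable sort on (-intensity, pixel order): deterministic tie-break
        order = det[np.argsort(-v[det], kind="stable")]
        sel = np.sort(order[:k])
    else:
        raise ConfigError(f"unknown point-pattern mode {mode!r}")
    return PointPattern(pt.coords[sel], pt.coords, mode, float(fraction))


def _quadrat_ids(coords: np.ndarray, bbox, grid) -> np.ndarray:
    """Assign each coordinate to a quadrat of an nx x ny grid over bbox."""
    (xmin, xmax, ymin, ymax) = bbox
    nx, ny = grid
    # right-closed last bin: clip so the max edge belongs to the last quadrat
    gx = np.clip(((coords[:, 0] - xmin) * nx / max(xmax - xmin, 1e-12)).astype(int), 0, nx - 1)
    gy = np.clip(((coords[:, 1] - ymin) * ny / max(ymax - ymin, 1e-12)).astype(int), 0, ny - 1)
    return gy * nx + gx


def quadrat_csr_test(pp: PointPattern, grid: tuple = DEFAULT_GRID) -> QuadratResult:
    """Upper-tail chi-square quadrat test of CSR for one point pattern.

    The support bounding box is split into ``grid`` equal rectangles;
    quadrats containing no support pixel are dropped.  Expected counts are
    n_points * (support pixels in quadrat) / (total support pixels);
    df = (#used quadrats) - 1; the upper-tail log survival probability is
    evaluated in log space and converted to the base-10 noise score.
    """
    nx, ny = grid
    if nx < 2 or ny < 2:
        raise ConfigError("quadrat grid must be at least 2x2")
    support = pp.support
    if len(support) == 0:
        raise DegenerateInputError("empty support")
    xmin, ymin = support.min(axis=0)
    xmax, ymax = support.max(axis=0)
    # half-pixel margin so pixel centers on the bbox edge bin cleanly
    bbox = (xmin - 0.5, xmax + 0.5, ymin - 0.5, ymax + 0.5)
    sup_ids = _quadrat_ids(support, bbox, grid)
    sup_counts = np.bincount(sup_ids, minlength=nx * ny)
    used = sup_counts > 0
    if used.sum() < 2:
        raise DegenerateInputError("fewer than 2 quadrats contain support pixels")
    n = len(pp.points)
    obs = np.bincount(_quadrat_ids(pp.points, bbox, grid), minlength=nx * ny) if n else np.zeros(nx * ny)
    exp = n * sup_counts / sup_counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(used, (obs - exp) ** 2 / np.where(used, exp, 1.0), 0.0)
    chi2 = float(terms[used].sum()) if n else 0.0
    df = int(used.sum()) - 1
    log_p = chi2_log_survival(chi2, df) if n else 0.0
    return QuadratResult(chi2, df, min(log_p, 0.0), max(-log_p / LN10, 0.0), n, int(used.sum()))


def score_all_ions(
    pt: PeakTable,
    mode: str = "top_fraction",
    fraction: float = 0.5,
    grid: tuple = DEFAULT_GRID,
    min_points: int = DEFAULT_MIN_POINTS,
    threshold: float = DEFAULT_NOISE_THRESHOLD,
) -> NoiseTable:
    """Quadrat-test every ion of a (background-pixel-filtered) table.

    Ions with fewer than ``min_points`` detections get noise_score 0 and
    the sparsity flag; an ion is noise when its score is below the
    threshold or it is sparsity-flagged.
    """
    if pt.n_ions == 0 or pt.n_pixels == 0:
        raise ConfigError("cannot score an empty peak table")
    rows = []
    for j in range(pt.n_ions):
        pp = ion_point_pattern(pt, j, mode=mode, fraction=fraction)
        if len(pp.points) < min_points:
            rows.append((pt.mz[j], len(pp.points), 0.0, 0, 0.0, 0.0, True))
            continue
        qr = quadrat_csr_test(pp, grid=grid)
        rows.append((pt.mz[j], qr.n_points, qr.chi2, qr.df, qr.log_p, qr.noise_score, False))
    df = pd.DataFrame(
        rows, columns=["mz", "n_points", "chi2", "df", "log_p", "noise_score", "sparse"]
    )
    df["is_noise"] = (df["noise_score"] < threshold) | df["sparse"]
    return NoiseTable(df, float(threshold), int(min_points), tuple(grid), mode, float(fraction))


def filter_noise_ions(
    pt: PeakTable, nt: NoiseTable, threshold: float | None = None
) -> PeakTable:
    """Retain ions with noise_score >= threshold (boundary retained) and
    no sparsity flag."""
    if len(nt.table) != pt.n_ions or not np.array_equal(nt.table["mz"].to_numpy(), pt.mz):
        raise ValidationError("noise table not aligned with the peak table")
    if threshold is None:
        threshold = nt.threshold
    keep = (nt.table["noise_score"].to_numpy() >= threshold) & ~nt.table["sparse"].to_numpy()
    if not keep.any():
        raise EmptyResultError(f"noise threshold {threshold} removes all ions")
    return pt.subset_ions(keep, note=f"noise ions removed (threshold={threshold})")


def suggest_noise_threshold(nt: NoiseTable) -> float:
    """Data-driven threshold between the noise and structured score modes.

    Scripted stand-in for visual borderline-ion tuning: Otsu's
    between-class-variance optimum on log10(score + 1) of the non-sparse
    ions.  With a clearly bimodal score distribution this lands in the
    valley between CSR-like and structured ions.
    """
    scores = nt.table.loc[~nt.table["sparse"], "noise_score"].to_numpy()
    if scores.size < 2 or np.ptp(scores) == 0:
        raise DegenerateInputError("score distribution is degenerate; cannot tune")
    t = threshold_otsu(np.log10(scores + 1.0), nbins=512)
    return float(10.0**t - 1.0)


def borderline_ions(
    nt: NoiseTable,
    threshold: float,
    window: float,
    pt: PeakTable | None = None,
    outdir: str | Path | None = None,
) -> list:
    """Ions with |noise_score - threshold| <= window, sorted by score.

    When a table and output directory are given, each borderline ion's
    intensity image is exported as a PNG for visual threshold refinement.
    Returns the list of ion indices (into ``nt``/``pt``).
    """
    if window <= 0:
        raise ConfigError("window must be positive")
    scores = nt.table["noise_score"].to_numpy()
    idx = np.flatnonzero(np.abs(scores - threshold) <= window)
    idx = idx[np.argsort(scores[idx], kind="stable")]
    if pt is not None and outdir is not None:
        from .render import render_ion_image

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for j in idx:
            render_ion_image(
                pt, int(j), outdir / f"borderline_mz{pt.mz[j]:.4f}_score{scores[j]:.1f}.png"
            )
    return [int(j) for j in idx]
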