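"""Programmatic region delineation and background-consistency metrics.

Replaces the interactive lasso of a GUI workflow: tissue and background
regions are defined either by polygons (rasterized onto the pixel grid,
boundary-inclusive) or by explicit pixel lists, loaded from a small JSON
schema.  Per-region representative spectra are per-ion medians; background
consistency is the pairwise Pearson correlation of those median spectra,
summarized by the minimum off-diagonal coefficient (flagged consistent
above 0.9, the conventional stability cutoff for background acquisition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import (
    ConfigError,
    EmptyRegionError,
    GeometryError,
    UndefinedCorrelationError,
    ValidationError,
)
from .peaktable import PeakTable

ROLES = ("tissue", "background")

#: Background regions whose pairwise correlation stays above this are
#: considered mutually consistent (stable acquisition).
CONSISTENCY_CUTOFF = 0.9


@dataclass(frozen=True)
class Region:
    """A named set of pixels tagged tissue or background."""

    name: str
    role: str
    pixels: frozenset

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigError(f"region role must be one of {ROLES}, got {self.role!r}")
        if not self.pixels:
            raise EmptyRegionError(f"region {self.name!r} has no pixels")

    def indices(self, pt: PeakTable) -> np.ndarray:
        """Row indices of this region's pixels in the peak table."""
        idx = pt.pixel_index()
        try:
            rows = [idx[p] for p in sorted(self.pixels)]
        except KeyError as e:
            raise ValidationError(
                f"region {self.name!r} pixel {e.args[0]} not in peak table"
            ) from None
        return np.asarray(rows, dtype=np.int64)


@dataclass
class RegionSet:
    """Pairwise-disjoint named regions."""

    regions: list = field(default_factory=list)

    def __post_init__(self):
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ConfigError("region names must be unique")
        seen: set = set()
        for r in self.regions:
            if seen & r.pixels:
                raise ConfigError(f"region {r.name!r} overlaps another region")
            seen |= r.pixels

    def tissue(self) -> list:
        return [r for r in self.regions if r.role == "tissue"]

    def background(self) -> list:
        return [r for r in self.regions if r.role == "background"]

    def __iter__(self):
        return iter(self.regions)

    def __len__(self):
        return len(self.regions)


@dataclass
class RegionSpectrum:
    """Per-ion median intensity over one region's pixels."""

    name: str
    values: np.ndarray


@dataclass
class CorrelationMatrix:
    names: list
    matrix: np.ndarray
    min_offdiag: float
    consistent: bool


# ---------------------------------------------------------------------------


def region_from_polygon(
    vertices: Sequence[Sequence[float]], name: str, role: str, pt: PeakTable
) -> Region:
    """Region of all table pixels whose centers fall inside the polygon.

    Boundary points count as inside.  The polygon may be non-convex;
    self-intersecting polygons are rejected.  For simple polygons the
    containment rule is equivalent to the even-odd rule.
    """
    verts = [(float(x), float(y)) for x, y in vertices]
    if len(verts) < 3:
        raise GeometryError(f"polygon for {name!r} needs >= 3 vertices")
    poly = shapely.Polygon(verts)
    if not poly.is_valid:
        raise GeometryError(f"polygon for {name!r} is self-intersecting or degenerate")
    pts = shapely.points(pt.coords[:, 0].astype(float), pt.coords[:, 1].astype(float))
    inside = shapely.covers(poly, pts)
    if not inside.any():
        raise EmptyRegionError(f"polygon for {name!r} encloses no table pixel")
    pixels = frozenset(map(tuple, pt.coords[inside]))
    return Region(name, role, pixels)


def region_from_pixels(
    pixels: Sequence[Sequence[int]], name: str, role: str, pt: PeakTable
) -> Region:
    table = {tuple(c) for c in pt.coords}
    px = {(int(x), int(y)) for x, y in pixels}
    missing = px - table
    if missing:
        raise ValidationError(
            f"region {name!r} references pixels absent from the table: "
            f"{sorted(missing)[:5]}"
        )
    if not px:
        raise EmptyRegionError(f"region {name!r} has no pixels")
    return Region(name, role, frozenset(px))


def load_regions(source: str | Path | list | dict, pt: PeakTable) -> RegionSet:
    """Load a RegionSet from a regions.json file or equivalent object.

    Schema: a list of ``{"name", "role", "polygon": [[x,y],...]}`` or
    ``{"name", "role", "pixels": [[x,y],...]}`` entries.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            spec = json.load(fh)
    else:
        spec = source
    if isinstance(spec, dict) and "regions" in spec:
        spec = spec["regions"]
    if not isinstance(spec, list):
        raise ConfigError("regions file must be a list of region objects")
    regions = []
    for i, entry in enumerate(spec):
        if not isinstance(entry, dict):
            raise ConfigError(f"region entry {i} is not an object")
        unknown = set(entry) - {"name", "role", "polygon", "pixels"}
        if unknown:
            raise ConfigError(f"region entry {i}: unknown keys {sorted(unknown)}")
        try:
            name, role = entry["name"], entry["role"]
        except KeyError as e:
            raise ConfigError(f"region entry {i}: missing key {e.args[0]!r}") from None
        if ("polygon" in entry) == ("pixels" in entry):
            raise ConfigError(
                f"region {name!r}: exactly one of 'polygon'/'pixels' required"
            )
        if "polygon" in entry:
            regions.append(region_from_polygon(entry["polygon"], name, role, pt))
        else:
            regions.append(region_from_pixels(entry["pixels"], name, role, pt))
    return RegionSet(regions)


# ---------------------------------------------------------------------------


def region_spectrum(pt: PeakTable, region: Region) -> RegionSpectrum:
    """Per-ion median intensity over the region's pixels.

    Even-sized samples use the mean of the two central order statistics.
    """
    rows = region.indices(pt)
    return RegionSpectrum(region.name, np.median(pt.intensity[rows], axis=0))


def background_consistency(
    spectra: Sequence[RegionSpectrum], log10: bool = False
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of background median spectra.

    Summary statistic: the minimum off-diagonal coefficient (the strictest
    reading of "consistently high"); flagged consistent when it exceeds 0.9.
    With ``log10=True`` spectra are transformed as log10(v + 1) first.
    """
    if len(spectra) < 2:
        raise ConfigError("background consistency needs >= 2 background spectra")
    n = len(spectra[0].values)
    mat = np.empty((len(spectra), n))
    for i, sp in enumerate(spectra):
        if len(sp.values) != n:
            raise ValidationError("spectra are not aligned to one m/z axis")
        v = np.log10(sp.values + 1.0) if log10 else sp.values
        if np.ptp(v) == 0:
            raise UndefinedCorrelationError(
                f"spectrum {sp.name!r} has zero variance; correlation undefined"
            )
        mat[i] = v
    corr = np.corrcoef(mat)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    off = corr[~np.eye(len(spectra), dtype=bool)]
    mn = float(off.min())
    return CorrelationMatrix(
        [sp.name for sp in spectra], corr, mn, mn > CONSISTENCY_CUTOFF
    )


def cluster_background_spectra(
    cm: CorrelationMatrix, cut_distance: float | None = None
) -> tuple[np.ndarray, dict]:
    """Agglomerative clustering of background spectra on distance 1 - r.

    Average linkage; regions are ordered by name before linkage so ties
    break deterministically.  Flat labels come from a distance cut
    (default: half the maximum merge height).
    """
    if len(cm.names) < 2:
        raise ConfigError("clustering needs >= 2 regions")
    order = np.argsort(cm.names, kind="stable")
    names = [cm.names[i] for i in order]
    dist = 1.0 - cm.matrix[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(0.0, (dist + dist.T) / 2.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if cut_distance is None:
        cut_distance = float(Z[:, 2].max()) / 2.0 if len(Z) else 0.0
    flat = hierarchy.fcluster(Z, t=cut_distance, criterion="distance")
    labels = {name: int(lbl) for name, lbl in zip(names, flat)}
    return Z, labels
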