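"""The peak-table container and its CSV/TSV readers and writers.

A peak table is the single interchange object of the pipeline: a dense
pixel x ion intensity matrix.  The first two columns of the on-disk format
are the integer X and Y pixel coordinates; every remaining column header is
the m/z value of one ion, and each cell holds the (non-negative) intensity
of that ion at that pixel.  Missing cells are canonicalized to 0 on read:
peak tables conflate non-detection with zero, and every downstream
missingness metric treats intensity <= 0 as "undetected".
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ValidationError

logger = logging.getLogger("smqc")

#: Column order of the per-ion result table.
PEAK_INFO_COLUMNS = [
    "mz",
    "median_intensity",
    "missing_ion_ratio",
    "noise_score",
    "is_noise",
    "enriched",
    "fold_change",
    "p_value",
    "isotope_status",
    "adduct_labels",
]

#: Column order of the per-pixel result table.
PIXEL_INFO_COLUMNS = [
    "x",
    "y",
    "total_intensity",
    "median_intensity",
    "missing_pixel_ratio",
    "kept",
]


@dataclass
class PeakTable:
    """Dense pixel x ion intensity matrix with coordinates and an m/z axis.

    Parameters
    ----------
    coords:
        Integer array of shape ``(n_pixels, 2)`` holding (x, y) grid
        coordinates.  Coordinates must be unique.
    mz:
        Float array of shape ``(n_ions,)``, strictly increasing.
    intensity:
        Float array of shape ``(n_pixels, n_ions)``, all entries >= 0.
    metadata:
        Free-form provenance (source file, NA count, processing history).
    """

    coords: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must have shape (n_pixels, 2)")
        if self.intensity.shape != (len(self.coords), len(self.mz)):
            raise ValidationError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{len(self.coords)} pixels x {len(self.mz)} ions"
            )
        uniq = {tuple(c) for c in self.coords}
        if len(uniq) != len(self.coords):
            raise ValidationError("duplicate pixel coordinates")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValidationError("m/z values must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("non-finite intensity")
        if np.any(self.intensity < 0):
            r, c = np.argwhere(self.intensity < 0)[0]
            raise ValidationError(f"negative intensity at pixel row {r}, ion column {c}")

    # -- basic accessors -----------------------------------------------
    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def n_ions(self) -> int:
        return len(self.mz)

    def pixel_index(self) -> dict:
        """Map (x, y) tuple -> row index."""
        return {tuple(c): i for i, c in enumerate(self.coords)}

    def copy(self) -> "PeakTable":
        return PeakTable(
            self.coords.copy(), self.mz.copy(), self.intensity.copy(), dict(self.metadata)
        )

    # -- subsetting ----------------------------------------------------
    def subset_pixels(self, keep: np.ndarray, note: str | None = None) -> "PeakTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            if len(keep) != self.n_pixels:
                raise ValidationError("pixel mask length mismatch")
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        meta = dict(self.metadata)
        if note:
            meta.setdefault("history", []).append(note)
        return PeakTable(self.coords[idx], self.mz, self.intensity[idx], meta)

    def subset_ions(self, keep: np.ndarray, note: str | None = None) -> "PeakTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            if len(keep) != self.n_ions:
                raise ValidationError("ion mask length mismatch")
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        meta = dict(self.metadata)
        if note:
            meta.setdefault("history", []).append(note)
        return PeakTable(self.coords, self.mz[idx], self.intensity[:, idx], meta)

    # -- imaging helpers ----------------------------------------------
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) of the bounding grid of the coordinates."""
        if self.n_pixels == 0:
            return (0, 0)
        xmin, ymin = self.coords.min(axis=0)
        xmax, ymax = self.coords.max(axis=0)
        return (int(ymax - ymin + 1), int(xmax - xmin + 1))

    def rasterize(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Place a per-pixel vector onto the bounding 2-D grid (row = y)."""
        values = np.asarray(values, dtype=float)
        if len(values) != self.n_pixels:
            raise ValidationError("per-pixel vector length mismatch")
        h, w = self.grid_shape()
        img = np.full((h, w), fill, dtype=float)
        xmin, ymin = self.coords.min(axis=0)
        img[self.coords[:, 1] - ymin, self.coords[:, 0] - xmin] = values
        return img

    def ion_image(self, ion: int, fill: float = np.nan) -> np.ndarray:
        return self.rasterize(self.intensity[:, ion], fill=fill)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _detect_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _canonical_coords(raw: np.ndarray) -> tuple[np.ndarray, dict | None]:
    """Return integer grid coordinates; non-integer axes are rank-mapped."""
    if np.allclose(raw, np.round(raw)):
        return np.round(raw).astype(np.int64), None
    mapping: dict = {}
    out = np.empty_like(raw, dtype=np.int64)
    for axis, name in enumerate("xy"):
        vals = raw[:, axis]
        uniq = np.unique(vals)
        ranks = {v: i for i, v in enumerate(uniq)}
        out[:, axis] = [ranks[v] for v in vals]
        mapping[name] = {float(v): i for v, i in ranks.items()}
    return out, mapping


def read_peak_table(path: str | Path, sep: str | None = None) -> PeakTable:
    """Read and validate a peak-table CSV/TSV.

    The header must name the first two columns as coordinates (``x``/``y``,
    case-insensitive); every remaining header must parse as a numeric m/z.
    NA/empty cells become 0 (the count is logged and recorded in metadata);
    columns are returned sorted by ascending m/z with the original order
    recorded in metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = sep or _detect_sep(path)
    # raw header read: pandas mangles duplicate column names, and m/z
    # identity must come from the exact decimal literals in the file
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None or len(header) < 2:
        raise FormatError("peak table needs at least the two coordinate columns")
    df = pd.read_csv(path, sep=sep, header=0, skip_blank_lines=True)
    c0, c1 = (str(c).strip().lower() for c in header[:2])
    if c0 != "x" or c1 != "y":
        raise FormatError(
            f"first two columns must be x,y coordinates; got {header[:2]!r}"
        )
    mz = []
    for col in header[2:]:
        try:
            mz.append(float(str(col)))
        except ValueError:
            raise FormatError(f"m/z column header {col!r} is not numeric") from None
    mz = np.asarray(mz, dtype=float)
    if len(np.unique(mz)) != len(mz):
        dupes = sorted({v for v in mz if np.sum(mz == v) > 1})
        raise ValidationError(f"duplicate m/z columns: {dupes}")

    inten = df.iloc[:, 2:].to_numpy(dtype=float)
    na_count = int(np.isnan(inten).sum())
    if na_count:
        logger.info("read_peak_table: canonicalized %d NA cells to 0", na_count)
        inten = np.nan_to_num(inten, nan=0.0)
    if np.any(inten < 0):
        r, c = np.argwhere(inten < 0)[0]
        raise ValidationError(
            f"negative intensity at data row {r}, column {header[2 + c]!r}"
        )

    raw_coords = df.iloc[:, :2].to_numpy(dtype=float)
    if np.isnan(raw_coords).any():
        raise ValidationError("missing coordinate value")
    coords, mapping = _canonical_coords(raw_coords)
    uniq = {tuple(c) for c in coords}
    if len(uniq) != len(coords):
        seen: set = set()
        for c in map(tuple, coords):
            if c in seen:
                raise ValidationError(f"duplicate coordinate pair {c}")
            seen.add(c)

    order = np.argsort(mz, kind="stable")
    meta = {
        "source": str(path),
        "na_count": na_count,
        "original_mz_order": [float(m) for m in mz],
    }
    if mapping is not None:
        logger.info("read_peak_table: non-integer coordinates mapped to ranks")
        meta["coordinate_mapping"] = mapping
    return PeakTable(coords, mz[order], inten[:, order], meta)


def write_peak_table(
    pt: PeakTable,
    path: str | Path,
    mz_decimals: int = 6,
    intensity_decimals: int = 6,
) -> Path:
    """Write a peak table as CSV/TSV with deterministic number formatting.

    m/z headers are fixed to ``mz_decimals`` decimal places and intensities
    to ``intensity_decimals``; reading the file back reproduces the table up
    to that formatting.
    """
    path = Path(path)
    sep = _detect_sep(path)
    cols = ["x", "y"] + [f"{m:.{mz_decimals}f}" for m in pt.mz]
    df = pd.DataFrame(
        np.column_stack([pt.coords.astype(float), pt.intensity]), columns=cols
    )
    df["x"] = df["x"].astype(np.int64)
    df["y"] = df["y"].astype(np.int64)
    df.to_csv(path, sep=sep, index=False, float_format=f"%.{intensity_decimals}f")
    return path


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def build_peak_info(
    pt: PeakTable,
    enrichment: pd.DataFrame | None = None,
    noise: pd.DataFrame | None = None,
    isotope_status: Sequence[str] | None = None,
    adduct_labels: Sequence[Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Assemble the per-ion result table for the *input* table.

    Every ion of the input appears exactly once; ions removed by a later
    stage carry flags (``is_noise``) rather than vanishing.  ``enrichment``
    and ``noise`` frames are joined on m/z so they may describe subsets.
    """
    med = np.median(pt.intensity, axis=0) if pt.n_pixels else np.zeros(pt.n_ions)
    missing = (
        (pt.intensity <= 0).mean(axis=0) if pt.n_pixels else np.ones(pt.n_ions)
    )
    out = pd.DataFrame(
        {
            "mz": pt.mz,
            "median_intensity": med,
            "missing_ion_ratio": missing,
            "noise_score": np.nan,
            "is_noise": False,
            "enriched": False,
            "fold_change": np.nan,
            "p_value": np.nan,
            "isotope_status": "unknown",
            "adduct_labels": "",
        }
    )
    if enrichment is not None:
        m = out["mz"].isin(enrichment["mz"])
        e = enrichment.set_index("mz")
        out.loc[m, "fold_change"] = e.loc[out.loc[m, "mz"], "fold_change"].to_numpy()
        out.loc[m, "p_value"] = e.loc[out.loc[m, "mz"], "p_value"].to_numpy()
        out.loc[m, "enriched"] = e.loc[out.loc[m, "mz"], "enriched"].to_numpy()
    if noise is not None:
        m = out["mz"].isin(noise["mz"])
        nz = noise.set_index("mz")
        out.loc[m, "noise_score"] = nz.loc[out.loc[m, "mz"], "noise_score"].to_numpy()
        out.loc[m, "is_noise"] = nz.loc[out.loc[m, "mz"], "is_noise"].to_numpy()
    if isotope_status is not None:
        if len(isotope_status) != len(out):
            raise ConsistencyError("isotope_status length mismatch")
        out["isotope_status"] = list(isotope_status)
    if adduct_labels is not None:
        if len(adduct_labels) != len(out):
            raise ConsistencyError("adduct_labels length mismatch")
        out["adduct_labels"] = [";".join(lbls) for lbls in adduct_labels]
    return out[PEAK_INFO_COLUMNS]


def build_pixel_info(pt: PeakTable, kept: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble the per-pixel result table for the *input* table."""
    if kept is None:
        kept = np.ones(pt.n_pixels, dtype=bool)
    kept = np.asarray(kept, dtype=bool)
    if len(kept) != pt.n_pixels:
        raise ConsistencyError("kept mask length mismatch")
    out = pd.DataFrame(
        {
            "x": pt.coords[:, 0],
            "y": pt.coords[:, 1],
            "total_intensity": pt.intensity.sum(axis=1),
            "median_intensity": np.median(pt.intensity, axis=1)
            if pt.n_ions
            else np.zeros(pt.n_pixels),
            "missing_pixel_ratio": (pt.intensity <= 0).mean(axis=1)
            if pt.n_ions
            else np.ones(pt.n_pixels),
            "kept": kept,
        }
    )
    return out[PIXEL_INFO_COLUMNS]


def write_result_tables(
    peak_info: pd.DataFrame,
    pixel_info: pd.DataFrame,
    outdir: str | Path,
    expect_n_ions: int | None = None,
    expect_n_pixels: int | None = None,
) -> tuple[Path, Path]:
    """Write ``peak_info.csv`` and ``pixel_info.csv`` with fixed column order."""
    if expect_n_ions is not None and len(peak_info) != expect_n_ions:
        raise ConsistencyError(
            f"peak_info has {len(peak_info)} rows, expected {expect_n_ions}"
        )
    if expect_n_pixels is not None and len(pixel_info) != expect_n_pixels:
        raise ConsistencyError(
            f"pixel_info has {len(pixel_info)} rows, expected {expect_n_pixels}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ppath = outdir / "peak_info.csv"
    xpath = outdir / "pixel_info.csv"
    peak_info[PEAK_INFO_COLUMNS].to_csv(ppath, index=False, float_format="%.6g")
    pixel_info[PIXEL_INFO_COLUMNS].to_csv(xpath, index=False, float_format="%.6g")
    return ppath, xpath
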