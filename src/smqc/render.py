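"""PNG exports of pixel maps (spatial images on the coordinate lattice).

Rendering is deliberately simple and deterministic: the per-pixel vector
is rasterized onto the bounding grid, clipped at a documented upper
percentile (default 99, so one hot pixel cannot wash out the colormap),
min-max scaled and written through matplotlib's viridis colormap.  Pixels
absent from the table render as black.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .errors import ConfigError  # noqa: E402
from .peaktable import PeakTable  # noqa: E402

DEFAULT_CLIP_PERCENTILE = 99.0


def _scaled(img: np.ndarray, clip_percentile: float) -> np.ndarray:
    vals = img[np.isfinite(img)]
    filled = np.nan_to_num(img, nan=0.0)
    if vals.size == 0:
        return np.zeros_like(filled)
    vmax = float(np.percentile(vals, clip_percentile))
    if vmax <= 0:
        return np.zeros_like(filled)
    return np.clip(filled / vmax, 0.0, 1.0)


def render_map(
    pt: PeakTable,
    values: np.ndarray,
    path: str | Path,
    clip_percentile: float = DEFAULT_CLIP_PERCENTILE,
) -> Path:
    """Render a per-pixel vector as a PNG on the coordinate lattice."""
    img = pt.rasterize(values, fill=np.nan)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    plt.imsave(path, _scaled(img, clip_percentile), cmap="viridis", vmin=0.0, vmax=1.0)
    return path


def render_ion_image(
    pt: PeakTable, ion: int, path: str | Path,
    clip_percentile: float = DEFAULT_CLIP_PERCENTILE,
) -> Path:
    return render_map(pt, pt.intensity[:, ion], path, clip_percentile)


def render_images(
    pt: PeakTable,
    which: str,
    outdir: str | Path,
    clip_percentile: float = DEFAULT_CLIP_PERCENTILE,
) -> Path:
    """Render one selection: ``total``, ``median``, ``missing`` or ``ion:<mz>``."""
    outdir = Path(outdir)
    if which == "total":
        return render_map(pt, pt.intensity.sum(axis=1), outdir / "total_intensity.png",
                          clip_percentile)
    if which == "median":
        return render_map(pt, np.median(pt.intensity, axis=1),
                          outdir / "median_intensity.png", clip_percentile)
    if which == "missing":
        return render_map(pt, (pt.intensity <= 0).mean(axis=1),
                          outdir / "missing_pixel_ratio.png", clip_percentile)
    if which.startswith("ion:"):
        try:
            target = float(which[4:])
        except ValueError:
            raise ConfigError(f"bad ion selector {which!r}") from None
        hits = np.flatnonzero(np.isclose(pt.mz, target, rtol=0, atol=5e-5))
        if hits.size == 0:
            raise ConfigError(f"no ion with m/z {target} in the table")
        return render_ion_image(pt, int(hits[0]), outdir / f"ion_{target:.4f}.png",
                                clip_percentile)
    raise ConfigError(f"unknown image selector {which!r}")
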