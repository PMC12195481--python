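"""Synthetic peak tables with planted ground truth.

The generator emulates the statistical structure every pipeline stage
assumes, at a desk scale that keeps the full workflow testable offline:

* a rectangular pixel grid with an elliptical tissue mask and two nested
  sub-regions (an inner ellipse covering ~half the tissue and the
  surrounding annulus);
* *structured* ions: log-normal intensities, elevated inside the tissue
  so that the population tissue/background mean ratio equals the
  configured effect size exactly, with the elevation concentrated in one
  of the two sub-regions (so their spatial pattern is strongly
  non-random within the tissue);
* *noise* ions: Bernoulli detection uniformly over all pixels, log-normal
  intensity where detected -- complete spatial randomness by construction;
* *background/solvent* ions: present everywhere, on and off tissue alike;
* *isotope companions*: a partner ion's image scaled by the isotope
  intensity ratio with multiplicative noise, at m/z = partner + 1.0035 Da
  (jittered within half the ppm tolerance so planted pairs always pass the
  mass gate); plus spacing-correct *decoy* pairs whose two members live in
  opposite sub-regions, so their images are uncorrelated and must be
  rejected by the correlation gate;
* *adduct companions*: analogous, at the default positive-mode offset
  differences;
* dropout applied last, emulating sporadic non-detection.

Random m/z positions are rejection-sampled away from every isotopic and
adduct mass difference so that the only candidate pairs are the planted
ones, making planted-truth recovery tests exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import POSITIVE_ADDUCTS, NEGATIVE_ADDUCTS
from .errors import ConfigError
from .peaktable import PeakTable, write_peak_table


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset (defaults = demo config)."""

    width: int = 60
    height: int = 60
    n_structured: int = 100
    n_noise: int = 100
    n_background_ions: int = 10
    #: tissue/background population mean intensity ratio of structured ions
    effect: float = 2.0
    #: multiplier of the structured baseline OUTSIDE the assigned sub-region
    #: (kept slightly above 1 so one-sided enrichment holds tissue-wide)
    structure_low: float = 1.1
    n_isotope: int = 20
    iso_ratio: float = 0.2
    #: sd of the multiplicative log-normal noise on companion images
    companion_noise: float = 0.15
    n_isotope_decoys: int = 20  # number of decoy PAIRS (uses 2 structured ions each)
    n_adduct: int = 15
    adduct_ratio: float = 0.5
    dropout: float = 0.05
    #: "censor": zero each ion's lowest `dropout` quantile of positive values
    #: (detection-limit style, the default); "random": zero cells uniformly
    dropout_mode: str = "censor"
    #: per-ion log-mean drawn uniformly over [log(mu_low), log(mu_high)]
    mu_low: float = 1e3
    mu_high: float = 1e5
    #: within-ion pixel-to-pixel log-normal sigma (natural log)
    sigma: float = 0.2
    #: detection probability of noise ions; kept small so a noise ion's
    #: point pattern is a sparse subsample of the lattice (a dense
    #: subsample is under-dispersed relative to CSR and would make the
    #: planted quadrat p-values non-uniform)
    noise_detect_prob: float = 0.05
    mz_min: float = 100.0
    mz_max: float = 900.0
    iso_spacing: float = 1.0035
    ppm_tol: float = 5.0
    adduct_mode: str = "positive"
    seed: int = 7

    def __post_init__(self):
        if self.width < 10 or self.height < 10:
            raise ConfigError("grid must be at least 10x10")
        if not (0 <= self.dropout < 1):
            raise ConfigError("dropout must be in [0, 1)")
        for name in ("n_structured", "n_noise", "n_background_ions", "n_isotope",
                     "n_isotope_decoys", "n_adduct"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_isotope + 2 * self.n_isotope_decoys + self.n_adduct > self.n_structured:
            raise ConfigError("more companions/decoys than structured parent ions")


@dataclass
class Truth:
    """Planted ground truth for one generated dataset."""

    ions: pd.DataFrame  # mz, ion_class, subregion, partner_mz, delta, label
    pixels: pd.DataFrame  # x, y, tissue
    regions: list = field(default_factory=list)  # regions.json-style entries


# ---------------------------------------------------------------------------


def _ellipse_mask(coords, cx, cy, a, b):
    return ((coords[:, 0] - cx) / a) ** 2 + ((coords[:, 1] - cy) / b) ** 2 <= 1.0


def _ellipse_polygon(cx, cy, a, b, n=64):
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return [[float(cx + a * math.cos(t)), float(cy + b * math.sin(t))] for t in th]


_FORBIDDEN_MARGIN = 0.02  # Da; keep random m/z gaps away from annotatable deltas


def _forbidden_deltas(cfg: SynthConfig) -> np.ndarray:
    adducts = POSITIVE_ADDUCTS if cfg.adduct_mode == "positive" else NEGATIVE_ADDUCTS
    deltas = {k * cfg.iso_spacing for k in (1, 2, 3)}
    offs = [o for _, o in adducts]
    deltas |= {abs(ob - oa) for oa in offs for ob in offs if ob != oa}
    return np.array(sorted(deltas))


def _place_random_mz(rng, n, cfg, placed=None):
    """Rejection-sample m/z values whose pairwise gaps avoid all target deltas.

    Mutates ``placed`` (the shared list of occupied m/z positions) in place.
    """
    forbidden = _forbidden_deltas(cfg)
    placed = placed if placed is not None else []
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200 * n + 1000:
            raise ConfigError("could not place m/z values; range too crowded")
        m = float(rng.uniform(cfg.mz_min, cfg.mz_max))
        if not _mz_ok(m, placed, forbidden):
            continue
        placed.append(m)
        out.append(m)
    return out


def _mz_ok(m, placed, forbidden):
    if not placed:
        return True
    gaps = np.abs(np.asarray(placed) - m)
    if gaps.min() < 0.1:
        return False
    return np.min(np.abs(gaps[:, None] - forbidden[None, :])) >= _FORBIDDEN_MARGIN


def _place_pair(rng, delta, placed, cfg):
    """Place a lighter/heavier m/z pair separated by ``delta`` (jittered
    within half the ppm window at the heavier member).

    Both members must clear the minimum-gap and forbidden-delta rules
    against every previously placed ion; the pair-internal gap is the
    planted relation and is exempt.  Retries the whole pair jointly.
    """
    forbidden = _forbidden_deltas(cfg)
    for _ in range(2000):
        m = float(rng.uniform(cfg.mz_min, cfg.mz_max - abs(delta) - 1.0))
        if not _mz_ok(m, placed, forbidden):
            continue
        jit = rng.uniform(-0.5, 0.5) * (cfg.ppm_tol * (m + delta) / 1e6)
        m2 = m + delta + jit
        if not _mz_ok(m2, placed, forbidden):
            continue
        placed.extend([m, m2])
        return m, m2
    raise ConfigError("could not place an m/z pair; range too crowded")


def generate_dataset(cfg: SynthConfig | None = None) -> tuple[PeakTable, Truth]:
    """Generate a peak table, its planted truth and region definitions.

    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.width, cfg.height

    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.int64)
    n_px = len(coords)

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a, b = 0.40 * w, 0.35 * h
    tissue = _ellipse_mask(coords, cx, cy, a, b)
    inner = _ellipse_mask(coords, cx, cy, a / math.sqrt(2), b / math.sqrt(2))
    sub_a = tissue & inner
    sub_b = tissue & ~inner
    n_tissue = int(tissue.sum())
    if n_tissue == 0 or sub_a.sum() == 0 or sub_b.sum() == 0:
        raise ConfigError("tissue mask degenerate for this grid size")

    # ---- structured ion roles ------------------------------------------
    ns = cfg.n_structured
    # structured ions 0..2K-1 form the K decoy pairs, then isotope partners,
    # then adduct partners; the remainder are free-standing structured ions
    iso_partners = list(range(2 * cfg.n_isotope_decoys, 2 * cfg.n_isotope_decoys + cfg.n_isotope))
    add_partners = list(
        range(2 * cfg.n_isotope_decoys + cfg.n_isotope,
              2 * cfg.n_isotope_decoys + cfg.n_isotope + cfg.n_adduct)
    )
    # sub-region assignment: alternate, so decoy pairs (2k, 2k+1) straddle A/B
    assigned_a = np.array([i % 2 == 0 for i in range(ns)])

    # ---- m/z placement -------------------------------------------------
    adducts = POSITIVE_ADDUCTS if cfg.adduct_mode == "positive" else NEGATIVE_ADDUCTS
    base_label, base_off = adducts[0]  # lighter member interpreted as this form
    partner_forms = [a_ for a_ in adducts[1:4]]  # cycle through a few heavier forms

    placed: list = []
    struct_mz = [0.0] * ns
    # decoy heavier member sits at the isotope spacing above its partner;
    # pairs are placed jointly so both members clear the forbidden-delta rules
    for k in range(cfg.n_isotope_decoys):
        struct_mz[2 * k], struct_mz[2 * k + 1] = _place_pair(
            rng, cfg.iso_spacing, placed, cfg
        )
    iso_mz = []
    for p in iso_partners:
        struct_mz[p], mz_c = _place_pair(rng, cfg.iso_spacing, placed, cfg)
        iso_mz.append(mz_c)
    add_mz = []
    for n_, p in enumerate(add_partners):
        _, off = partner_forms[n_ % len(partner_forms)]
        struct_mz[p], mz_c = _place_pair(rng, off - base_off, placed, cfg)
        add_mz.append(mz_c)
    free = [i for i in range(ns) if struct_mz[i] == 0.0]
    for i, m in zip(free, _place_random_mz(rng, len(free), cfg, placed)):
        struct_mz[i] = m
    noise_mz = _place_random_mz(rng, cfg.n_noise, cfg, placed)
    solvent_mz = _place_random_mz(rng, cfg.n_background_ions, cfg, placed)

    # ---- images --------------------------------------------------------
    cols: list = []  # (mz, image, class, subregion, partner_mz, delta, label)

    f_a = sub_a.sum() / n_tissue
    f_b = sub_b.sum() / n_tissue
    mus = rng.uniform(math.log(cfg.mu_low), math.log(cfg.mu_high), size=ns)
    struct_imgs = []
    for i in range(ns):
        sub = sub_a if assigned_a[i] else sub_b
        f = f_a if assigned_a[i] else f_b
        lo = cfg.structure_low
        hi = (cfg.effect - lo * (1 - f)) / f
        if hi <= lo:
            raise ConfigError("effect too small for the configured structure_low")
        mult = np.ones(n_px)
        mult[tissue] = lo
        mult[sub] = hi
        img = np.exp(mus[i] + cfg.sigma * rng.standard_normal(n_px)) * mult
        struct_imgs.append(img)
        cols.append(
            [struct_mz[i], img, "structured", "A" if assigned_a[i] else "B",
             np.nan, np.nan, ""]
        )
    # decoy bookkeeping: the heavier member of each decoy pair records its partner
    for k in range(cfg.n_isotope_decoys):
        i, j = 2 * k, 2 * k + 1
        cols[j][2] = "structured"  # decoys stay structured ions
        cols[j][4] = struct_mz[i]
        cols[j][5] = struct_mz[j] - struct_mz[i]
        cols[j][6] = "decoy"

    for i in range(cfg.n_noise):
        detected = rng.random(n_px) < cfg.noise_detect_prob
        mu = rng.uniform(math.log(cfg.mu_low), math.log(cfg.mu_high))
        img = np.where(detected, np.exp(mu + cfg.sigma * rng.standard_normal(n_px)), 0.0)
        cols.append([noise_mz[i], img, "noise", "", np.nan, np.nan, ""])

    for i in range(cfg.n_background_ions):
        mu = rng.uniform(math.log(cfg.mu_low), math.log(cfg.mu_high))
        img = np.exp(mu + cfg.sigma * rng.standard_normal(n_px))
        cols.append([solvent_mz[i], img, "background_solvent", "", np.nan, np.nan, ""])

    for n_, p in enumerate(iso_partners):
        mz_c = iso_mz[n_]
        img = (
            cfg.iso_ratio
            * struct_imgs[p]
            * np.exp(cfg.companion_noise * rng.standard_normal(n_px))
        )
        cols.append(
            [mz_c, img, "isotope_companion", "A" if assigned_a[p] else "B",
             struct_mz[p], mz_c - struct_mz[p], "M+1"]
        )

    for n_, p in enumerate(add_partners):
        lbl, off = partner_forms[n_ % len(partner_forms)]
        mz_c = add_mz[n_]
        img = (
            cfg.adduct_ratio
            * struct_imgs[p]
            * np.exp(cfg.companion_noise * rng.standard_normal(n_px))
        )
        cols.append(
            [mz_c, img, "adduct_companion", "A" if assigned_a[p] else "B",
             struct_mz[p], mz_c - struct_mz[p], f"{base_label}/{lbl}"]
        )

    if not cols:
        raise ConfigError("configuration generates no ions")

    mz_all = np.array([c[0] for c in cols])
    order = np.argsort(mz_all, kind="stable")
    intensity = np.column_stack([cols[i][1] for i in order])
    if cfg.dropout > 0:
        if cfg.dropout_mode == "censor":
            # detection-limit non-detection: each ion loses its weakest pixels
            for j in range(intensity.shape[1]):
                col = intensity[:, j]
                pos = col > 0
                if pos.any():
                    col[col < np.quantile(col[pos], cfg.dropout)] = 0.0
        elif cfg.dropout_mode == "random":
            intensity = np.where(rng.random(intensity.shape) < cfg.dropout, 0.0, intensity)
        else:
            raise ConfigError(f"unknown dropout_mode {cfg.dropout_mode!r}")

    pt = PeakTable(
        coords,
        mz_all[order],
        intensity,
        {"source": "smqc.synthetic", "seed": cfg.seed, "config": asdict(cfg)},
    )

    ions = pd.DataFrame(
        {
            "mz": mz_all[order],
            "ion_class": [cols[i][2] for i in order],
            "subregion": [cols[i][3] for i in order],
            "partner_mz": [cols[i][4] for i in order],
            "delta": [cols[i][5] for i in order],
            "label": [cols[i][6] for i in order],
        }
    )
    pixels = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "tissue": tissue}
    )

    # ---- region definitions (one tissue, three background corners) -----
    m = max(3, min(w, h) // 8)
    regions = [
        {
            "name": "tissue",
            "role": "tissue",
            "polygon": _ellipse_polygon(cx, cy, 0.85 * a, 0.85 * b),
        },
        {"name": "bg1", "role": "background",
         "polygon": [[0, 0], [m, 0], [m, m], [0, m]]},
        {"name": "bg2", "role": "background",
         "polygon": [[w - 1 - m, 0], [w - 1, 0], [w - 1, m], [w - 1 - m, m]]},
        {"name": "bg3", "role": "background",
         "polygon": [[0, h - 1 - m], [m, h - 1 - m], [m, h - 1], [0, h - 1]]},
    ]
    return pt, Truth(ions, pixels, regions)


def write_dataset(cfg: SynthConfig, outdir: str | Path) -> dict:
    """Generate and write peak_table.csv, regions.json and the truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pt, truth = generate_dataset(cfg)
    paths = {
        "peak_table": write_peak_table(pt, outdir / "peak_table.csv"),
        "regions": outdir / "regions.json",
        "truth_ions": outdir / "truth_ions.csv",
        "truth_pixels": outdir / "truth_pixels.csv",
    }
    with open(paths["regions"], "w") as fh:
        json.dump(truth.regions, fh, indent=1)
    truth.ions.to_csv(paths["truth_ions"], index=False, float_format="%.6f")
    truth.pixels.to_csv(paths["truth_pixels"], index=False)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# hand-sized worked fixture
# ---------------------------------------------------------------------------


def worked_micro_fixture() -> tuple[PeakTable, dict]:
    """A 4x4-pixel, 6-ion table with hand-computable expected values.

    Ions: 100.0 with an exact M+1 companion at 101.0035 (image scaled by
    0.2, correlation exactly 1); 150.0 with an exact adduct companion at
    171.981942 ((M+Na)-(M+H), image scaled by 0.5); an ion with half its
    pixels missing; and a constant ion (zero variance).  The expected
    dictionary records hand-computed values used by the doc-tests.
    """
    coords = np.array([(x, y) for y in range(4) for x in range(4)])
    base = np.arange(1.0, 17.0)  # pixel (0,0) -> 1, ..., (3,3) -> 16
    ion0 = base
    ion1 = 0.2 * base
    ion2 = base[::-1].copy()
    ion3 = 0.5 * base[::-1]
    ion4 = np.array([0.0] * 8 + [5.0] * 8)  # missing in the first 8 pixels
    ion5 = np.full(16, 3.0)  # constant: zero variance
    mz = np.array([100.0, 101.0035, 150.0, 171.981942, 200.0, 250.0])
    intensity = np.column_stack([ion0, ion1, ion2, ion3, ion4, ion5])
    pt = PeakTable(coords, mz, intensity, {"source": "worked_micro_fixture"})
    expected = {
        # pixel (0,0) row: [1, 0.2, 16, 8, 0, 3] -> one zero of six ions
        "missing_pixel_ratio_0_0": 1.0 / 6.0,
        # median of [1, 0.2, 16, 8, 0, 3] = mean(1, 3) = 2
        "median_intensity_0_0": 2.0,
        "total_intensity_0_0": 1 + 0.2 + 16 + 8 + 0 + 3,
        # ion4 is zero at 8 of 16 pixels
        "missing_ion_ratio_mz200": 0.5,
        # ion0 median over 16 pixels = mean(8, 9) = 8.5
        "median_intensity_mz100": 8.5,
        "n_isotope_pairs": 1,
        "n_adduct_pairs": 1,
        "isotope_pair": (100.0, 101.0035),
        "adduct_pair": (150.0, 171.981942),
        "adduct_labels": ("M+H", "M+Na"),
    }
    return pt, expected
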