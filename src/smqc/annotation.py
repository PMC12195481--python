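"""Isotopologue and adduct annotation by mass spacing plus co-localization.

Isotopologue pairs: two ions whose m/z difference matches k times the
M+1 isotopic spacing (default 1.0035 Da; the physically precise 13C
spacing 1.003355 is available as ``C13_SPACING``) within a ppm tolerance
anchored at the heavier member, and whose intensity images correlate
across the retained pixels above ``corr_min``.  Confirmed heavier members
are flagged as isotope peaks and excluded from the adduct search.

Adduct pairs: two monoisotopic ions whose m/z difference matches the
difference of two adduct mass offsets from a configurable list (e.g.
(M+Na) - (M+H) = 21.981942 Da), again gated by spatial correlation.
Several default positive- and negative-mode offsets share differences
(e.g. Na-H equals (2Na-H)-Na exactly), so each unordered ion pair is
recorded once with the smallest-ppm-error interpretation, ties broken by
adduct list order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .peaktable import PeakTable

#: M+1 spacing default (Da); the 13C value is available as a preset.
DEFAULT_ISO_SPACING = 1.0035
C13_SPACING = 1.003355

#: (label, mass offset in Da) lists for the two ionization modes.
POSITIVE_ADDUCTS = [
    ("M+H", 1.007276),
    ("M+NH4", 18.033823),
    ("M+Na", 22.989218),
    ("M+K", 38.963158),
    ("M+H-H2O", -17.003289),
    ("M+2Na-H", 44.971160),
    ("M+ACN+H", 42.033823),
]
NEGATIVE_ADDUCTS = [
    ("M-H", -1.007276),
    ("M+Cl", 34.969402),
    ("M+FA-H", 44.998201),
    ("M-H2O-H", -19.017841),
    ("M+Na-2H", 20.974666),
    ("M+K-2H", 36.948606),
    ("M+HAc-H", 59.013851),
]


@dataclass
class IsotopeConfig:
    iso_spacing: float = DEFAULT_ISO_SPACING
    max_order: int = 1
    ppm_tol: float = 5.0
    corr_min: float = 0.7

    def __post_init__(self):
        if self.ppm_tol <= 0:
            raise ConfigError("ppm_tol must be positive")
        if not (-1 <= self.corr_min <= 1):
            raise ConfigError("corr_min must be in [-1, 1]")
        if self.max_order < 1:
            raise ConfigError("max_order must be >= 1")


@dataclass
class AdductConfig:
    mode: str = "positive"
    adducts: list | None = None
    ppm_tol: float = 5.0
    corr_min: float = 0.7

    def __post_init__(self):
        if self.mode not in ("positive", "negative"):
            raise ConfigError("adduct mode must be 'positive' or 'negative'")
        if self.adducts is None:
            self.adducts = list(POSITIVE_ADDUCTS if self.mode == "positive" else NEGATIVE_ADDUCTS)
        labels = [a[0] for a in self.adducts]
        offsets = [float(a[1]) for a in self.adducts]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate adduct labels")
        if len(set(offsets)) != len(offsets):
            raise ConfigError("duplicate adduct mass offsets")
        if not self.adducts:
            raise ConfigError("adduct list must be non-empty")
        if self.ppm_tol <= 0:
            raise ConfigError("ppm_tol must be positive")
        if not (-1 <= self.corr_min <= 1):
            raise ConfigError("corr_min must be in [-1, 1]")


@dataclass
class PairRecord:
    lighter: int  # ion column index
    heavier: int
    kind: str  # "isotope" | "adduct"
    observed_delta: float
    theoretical_delta: float
    ppm_error: float
    correlation: float
    label_lighter: str  # "M" / adduct label of the lighter member
    label_heavier: str  # "M+1" (order k) / adduct label of the heavier member


@dataclass
class AnnotationLedger:
    """Confirmed pair records plus per-ion labels and the summary rates."""

    n_ions: int
    mz: np.ndarray
    pairs: list = field(default_factory=list)
    # per-ion list of (anchor index, ppm error), smallest ppm first
    isotope_anchors: dict = field(default_factory=dict)
    adduct_labels: dict = field(default_factory=dict)

    def isotope_flagged(self) -> np.ndarray:
        mask = np.zeros(self.n_ions, dtype=bool)
        mask[list(self.isotope_anchors)] = True
        return mask

    def isotope_status(self) -> list:
        """Per-ion status strings: 'monoisotopic' or 'isotope-of:<mz>'."""
        out = []
        for j in range(self.n_ions):
            anchors = self.isotope_anchors.get(j)
            if not anchors:
                out.append("monoisotopic")
            else:
                out.append(
                    "isotope-of:" + ";".join(f"{self.mz[a]:.4f}" for a, _ in anchors)
                )
        return out

    def adduct_label_lists(self) -> list:
        return [sorted(self.adduct_labels.get(j, [])) for j in range(self.n_ions)]

    def qvp7(self) -> float:
        """Percent of ions flagged as isotope peaks."""
        if self.n_ions == 0:
            return 0.0
        return 100.0 * float(self.isotope_flagged().mean())

    def qvp8(self) -> float:
        """Percent of monoisotopic ions in >= 1 confirmed adduct pair."""
        mono = ~self.isotope_flagged()
        if mono.sum() == 0:
            return 0.0
        in_pair = np.zeros(self.n_ions, dtype=bool)
        for pr in self.pairs:
            if pr.kind == "adduct":
                in_pair[pr.lighter] = in_pair[pr.heavier] = True
        return 100.0 * float(in_pair[mono].sum() / mono.sum())

    def label_frequencies(self) -> dict:
        freq: dict = {}
        for pr in self.pairs:
            if pr.kind != "adduct":
                continue
            for lbl in (pr.label_lighter, pr.label_heavier):
                freq[lbl] = freq.get(lbl, 0) + 1
        return dict(sorted(freq.items()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lighter_mz": self.mz[pr.lighter],
                "heavier_mz": self.mz[pr.heavier],
                "kind": pr.kind,
                "observed_delta": pr.observed_delta,
                "theoretical_delta": pr.theoretical_delta,
                "ppm_error": pr.ppm_error,
                "correlation": pr.correlation,
                "label_lighter": pr.label_lighter,
                "label_heavier": pr.label_heavier,
            }
            for pr in self.pairs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "lighter_mz", "heavier_mz", "kind", "observed_delta",
                "theoretical_delta", "ppm_error", "correlation",
                "label_lighter", "label_heavier",
            ],
        )


# ---------------------------------------------------------------------------


def spatial_correlation(pt: PeakTable, i: int, j: int) -> float | None:
    """Pearson correlation of two ion images over all retained pixels.

    Returns None (undefined-correlation sentinel) when either image has
    zero variance; callers reject such pairs.
    """
    if i == j:
        raise ConfigError("spatial correlation needs two distinct ions")
    a = pt.intensity[:, i]
    b = pt.intensity[:, j]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def _ppm_window(mz_heavier: float, ppm_tol: float) -> float:
    return ppm_tol * mz_heavier / 1e6


def find_isotope_pairs(pt: PeakTable, cfg: IsotopeConfig | None = None) -> AnnotationLedger:
    """Identify confirmed isotopologue pairs on a noise-filtered table.

    Anchors are swept in ascending m/z; an ion already confirmed as an
    isotope peak cannot serve as a monoisotopic anchor.  For each order
    k <= max_order, heavier candidates within the ppm window (anchored at
    the heavier m/z) around k * iso_spacing are confirmed when the spatial
    correlation reaches corr_min.  A heavier ion may match several
    anchors; all pairs are recorded and its status lists anchors by
    increasing ppm error.
    """
    cfg = cfg or IsotopeConfig()
    mz = pt.mz
    if np.any(np.diff(mz) <= 0):
        raise ValidationError("peak table m/z axis must be sorted ascending")
    ledger = AnnotationLedger(pt.n_ions, mz)
    for i in range(pt.n_ions):
        if i in ledger.isotope_anchors:
            continue  # isotope peaks are not anchors
        for k in range(1, cfg.max_order + 1):
            target = mz[i] + k * cfg.iso_spacing
            # widest possible window at this target m/z
            tol_hi = _ppm_window(target + 1.0, cfg.ppm_tol)
            lo = np.searchsorted(mz, target - tol_hi, side="left")
            hi = np.searchsorted(mz, target + tol_hi, side="right")
            for j in range(lo, hi):
                if j == i:
                    continue
                delta = mz[j] - mz[i]
                err = delta - k * cfg.iso_spacing
                if abs(err) > _ppm_window(mz[j], cfg.ppm_tol):
                    continue
                r = spatial_correlation(pt, i, j)
                if r is None or r < cfg.corr_min:
                    continue
                ppm = err / mz[j] * 1e6
                ledger.pairs.append(
                    PairRecord(i, j, "isotope", delta, k * cfg.iso_spacing, ppm,
                               r, "M", f"M+{k}")
                )
                ledger.isotope_anchors.setdefault(j, []).append((i, ppm))
    for j, anchors in ledger.isotope_anchors.items():
        anchors.sort(key=lambda t: (abs(t[1]), t[0]))
    return ledger


def find_adduct_pairs(
    pt: PeakTable, cfg: AdductConfig | None = None, ledger: AnnotationLedger | None = None
) -> AnnotationLedger:
    """Identify confirmed adduct pairs among monoisotopic ions.

    For each unordered ion pair (lighter, heavier) the observed m/z
    difference is matched against every positive difference of two adduct
    offsets; matches within the ppm tolerance (anchored at the heavier
    m/z) are gated by spatial correlation.  Each ion pair is recorded at
    most once, under its smallest-|ppm| interpretation.
    """
    cfg = cfg or AdductConfig()
    if ledger is None:
        ledger = AnnotationLedger(pt.n_ions, pt.mz)
    mz = pt.mz
    iso = ledger.isotope_flagged()
    mono = np.flatnonzero(~iso)
    # ordered adduct pairs (a, b) with offset_b > offset_a; different pairs
    # can give the numerically identical difference (e.g. Na-H == (2Na-H)-Na),
    # so near-equal deltas are merged keeping the earliest list-order pair
    raw = []
    for la, oa in cfg.adducts:
        for lb, ob in cfg.adducts:
            if ob > oa:
                raw.append((ob - oa, len(raw), la, lb))
    raw.sort(key=lambda t: (t[0], t[1]))
    deltas = []
    i0 = 0
    while i0 < len(raw):
        i1 = i0 + 1
        while i1 < len(raw) and raw[i1][0] - raw[i0][0] < 1e-9:
            i1 += 1
        d, _, la, lb = min(raw[i0:i1], key=lambda t: t[1])
        deltas.append((d, la, lb))
        i0 = i1
    dvals = np.array([d[0] for d in deltas])
    max_delta = dvals[-1] if len(dvals) else 0.0

    corr_cache: dict = {}

    def corr(i, j):
        if (i, j) not in corr_cache:
            corr_cache[(i, j)] = spatial_correlation(pt, i, j)
        return corr_cache[(i, j)]

    mono_mz = mz[mono]
    for a_pos, i in enumerate(mono):
        hi = np.searchsorted(mono_mz, mz[i] + max_delta + 0.1, side="right")
        for b_pos in range(a_pos + 1, hi):
            j = mono[b_pos]
            obs = mz[j] - mz[i]
            tol = _ppm_window(mz[j], cfg.ppm_tol)
            best = None  # (|ppm|, list position, record fields)
            lo_d = np.searchsorted(dvals, obs - tol, side="left")
            hi_d = np.searchsorted(dvals, obs + tol, side="right")
            for pos in range(lo_d, hi_d):
                target, la, lb = deltas[pos]
                ppm = (obs - target) / mz[j] * 1e6
                key = (abs(ppm), pos)
                if best is None or key < best[0]:
                    best = (key, (target, la, lb, ppm))
            if best is None:
                continue
            r = corr(i, j)
            if r is None or r < cfg.corr_min:
                continue
            target, la, lb, ppm = best[1]
            ledger.pairs.append(
                PairRecord(int(i), int(j), "adduct", obs, target, ppm, r, la, lb)
            )
            ledger.adduct_labels.setdefault(int(i), set()).add(la)
            ledger.adduct_labels.setdefault(int(j), set()).add(lb)
    return ledger


def annotate(
    pt: PeakTable,
    iso_cfg: IsotopeConfig | None = None,
    adduct_cfg: AdductConfig | None = None,
) -> AnnotationLedger:
    """Full annotation pass: isotopologues first, then adducts on the
    monoisotopic remainder."""
    ledger = find_isotope_pairs(pt, iso_cfg)
    return find_adduct_pairs(pt, adduct_cfg, ledger)
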