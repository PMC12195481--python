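"""End-to-end QC pipeline: regions -> enrichment -> pixel removal ->
noise filtering -> summaries -> annotation -> result tables.

The stage order is fixed: each quality metric assumes the filtering state
left by the previous stages (the adduct search, for instance, runs after
non-monoisotopic peaks are flagged, and noise scoring runs on the
background-pixel-filtered table).  Every stage logs its parameters and
input/output dimensions; a failing stage aborts with a stage-named error
and leaves the outputs of prior stages intact.

All quality numbers live in the machine-readable ``qc_report.json``
(stable key order, deterministic for a fixed input and configuration);
stage wall-clock timings go to a separate ``timings.json`` so reports are
byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotation as ann
from . import noise as noisemod
from . import regions as regmod
from . import segmentation as segmod
from . import summaries as summod
from .errors import ConfigError, SmqcError, StageError
from .peaktable import (
    PeakTable,
    build_peak_info,
    build_pixel_info,
    read_peak_table,
    write_peak_table,
    write_result_tables,
)

logger = logging.getLogger("smqc")


@dataclass
class PipelineConfig:
    """All pipeline parameters with their documented defaults."""

    # enrichment (tissue vs background)
    alpha: float = 0.05
    fc_min: float = 1.0
    bh: bool = False
    # background-pixel removal; None -> Otsu suggestion on the totals
    intensity_threshold: float | None = None
    # noise scoring
    noise_mode: str = "top_fraction"
    noise_fraction: float = 0.5
    noise_grid: tuple = (5, 5)
    min_points: int = noisemod.DEFAULT_MIN_POINTS
    noise_threshold: float = noisemod.DEFAULT_NOISE_THRESHOLD
    borderline_window: float = 5.0
    # annotation
    iso_spacing: float = ann.DEFAULT_ISO_SPACING
    max_order: int = 1
    ppm_tol: float = 5.0
    corr_min: float = 0.7
    adduct_mode: str = "positive"
    adducts: list | None = None
    # QVP2 options
    log10_background: bool = False
    cluster_cut: float | None = None
    # stage toggles / misc
    do_annotation: bool = True
    do_images: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.noise_grid, (list, tuple)):
            cfg.noise_grid = tuple(int(g) for g in cfg.noise_grid)
        else:
            raise ConfigError("noise_grid must be a pair [nx, ny]")
        if cfg.adducts is not None:
            cfg.adducts = [(str(l), float(o)) for l, o in cfg.adducts]
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_grid"] = list(self.noise_grid)
        if d["adducts"] is not None:
            d["adducts"] = [[l, o] for l, o in d["adducts"]]
        return d


@dataclass
class PipelineResult:
    report: dict
    processed: PeakTable
    timings: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)


def _stage(name, timings, fn, *args, **kwargs):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        out = fn(*args, **kwargs)
    except SmqcError as e:
        raise StageError(name, str(e)) from e
    timings[name] = time.perf_counter() - t0
    return out


def run_pipeline(
    table: PeakTable | str | Path,
    regions: regmod.RegionSet | str | Path | list,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full QC workflow and (optionally) write all output files."""
    cfg = config or PipelineConfig()
    timings: dict = {}
    files: dict = {}
    report: dict = {"parameters": cfg.to_dict()}

    if not isinstance(table, PeakTable):
        table = _stage("read", timings, read_peak_table, table)
    pt0 = table
    if not isinstance(regions, regmod.RegionSet):
        regions = _stage("regions", timings, regmod.load_regions, regions, pt0)
    tis = regions.tissue()
    bgs = regions.background()
    if len(tis) != 1:
        raise StageError("regions", f"exactly one tissue region required, got {len(tis)}")
    if len(bgs) < 1:
        raise StageError("regions", "at least one background region required")
    tissue = tis[0]

    # ---- QVP1: per-region median spectra -------------------------------
    spectra = _stage(
        "qvp1", timings,
        lambda: [regmod.region_spectrum(pt0, r) for r in regions],
    )
    report["qvp1"] = {
        "regions": [
            {"name": r.name, "role": r.role, "n_pixels": len(r.pixels)} for r in regions
        ]
    }

    # ---- QVP2: background consistency + sub-clustering ------------------
    bg_spectra = [s for s, r in zip(spectra, regions) if r.role == "background"]
    if len(bg_spectra) >= 2:
        cm = _stage("qvp2", timings, regmod.background_consistency,
                    bg_spectra, cfg.log10_background)
        Z, labels = regmod.cluster_background_spectra(cm, cfg.cluster_cut)
        report["qvp2"] = {
            "min_background_correlation": round(cm.min_offdiag, 6),
            "consistent": bool(cm.consistent),
            "cluster_labels": labels,
            "n_clusters": len(set(labels.values())),
        }
    else:
        report["qvp2"] = None

    # ---- QVP3: tissue-enriched ions on the original table ---------------
    if len(bgs) > 1:
        bg_pixels = frozenset().union(*[r.pixels for r in bgs])
        bg_all = regmod.Region("background_all", "background", bg_pixels)
    else:
        bg_all = bgs[0]
    enr = _stage("qvp3", timings, segmod.ion_enrichment, pt0, tissue, bg_all,
                 cfg.alpha, cfg.fc_min, "auto", cfg.bh)
    report["qvp3"] = {
        "enriched_percent": round(enr.enriched_percent, 4),
        "n_enriched": int(enr.table["enriched"].sum()),
        "alpha": cfg.alpha,
        "fc_min": cfg.fc_min,
    }

    # ---- Process 2: background-pixel removal ----------------------------
    def _process2():
        mask = enr.table["enriched"].to_numpy()
        if not mask.any():  # fall back to all ions so segmentation stays defined
            mask = np.ones(pt0.n_ions, dtype=bool)
        totals = segmod.pixel_total_intensity(pt0, mask)
        if cfg.intensity_threshold is None:
            thr = segmod.suggest_threshold(totals).value
            source = "otsu"
        else:
            thr, source = float(cfg.intensity_threshold), "user"
        pt1, seg = segmod.remove_background_pixels(pt0, totals, thr)
        return pt1, seg, source

    pt1, seg, thr_source = _stage("process2", timings, _process2)
    report["process2"] = {
        "threshold": round(seg.threshold, 6),
        "threshold_source": thr_source,
        "n_kept": seg.n_kept,
        "n_removed": seg.n_removed,
    }

    # ---- QVP4 / Process 3: noise scoring and ion removal -----------------
    nt = _stage("qvp4", timings, noisemod.score_all_ions, pt1,
                cfg.noise_mode, cfg.noise_fraction, cfg.noise_grid,
                cfg.min_points, cfg.noise_threshold)
    report["qvp4"] = {
        "noise_percent": round(nt.noise_percent, 4),
        "threshold": nt.threshold,
        "mode": nt.mode,
        "fraction": nt.fraction,
        "grid": list(nt.grid),
        "min_points": nt.min_points,
        "n_sparse": int(nt.table["sparse"].sum()),
    }
    pt2 = _stage("process3", timings, noisemod.filter_noise_ions, pt1, nt)
    report["process3"] = {
        "n_ions_kept": pt2.n_ions,
        "n_ions_removed": pt1.n_ions - pt2.n_ions,
    }

    # ---- QVP5/6: intensity and missingness summaries ---------------------
    psum = _stage("qvp5", timings, summod.pixel_summaries, pt2)
    isum = _stage("qvp5_ions", timings, summod.ion_summaries, pt2)
    report["qvp5"] = {
        "median_pixel_total": round(float(np.median(psum["total_intensity"])), 4),
        "median_ion_median": round(float(np.median(isum.table["median_intensity"])), 4),
    }
    ident = summod.missingness_identity(pt2)
    report["qvp6"] = {k: round(v, 6) for k, v in ident.items()}

    # ---- QVP7/8: isotope and adduct annotation ---------------------------
    if cfg.do_annotation:
        iso_cfg = ann.IsotopeConfig(cfg.iso_spacing, cfg.max_order, cfg.ppm_tol,
                                    cfg.corr_min)
        add_cfg = ann.AdductConfig(cfg.adduct_mode, cfg.adducts, cfg.ppm_tol,
                                   cfg.corr_min)
        ledger = _stage("qvp7", timings, ann.find_isotope_pairs, pt2, iso_cfg)
        ledger = _stage("qvp8", timings, ann.find_adduct_pairs, pt2, add_cfg, ledger)
        n_iso_pairs = sum(1 for p in ledger.pairs if p.kind == "isotope")
        n_add_pairs = sum(1 for p in ledger.pairs if p.kind == "adduct")
        report["qvp7"] = {
            "isotope_percent": round(ledger.qvp7(), 4),
            "n_isotope_ions": int(ledger.isotope_flagged().sum()),
            "n_pairs": n_iso_pairs,
            "iso_spacing": cfg.iso_spacing,
            "ppm_tol": cfg.ppm_tol,
            "corr_min": cfg.corr_min,
        }
        report["qvp8"] = {
            "adduct_percent": round(ledger.qvp8(), 4),
            "n_monoisotopic": int((~ledger.isotope_flagged()).sum()),
            "n_pairs": n_add_pairs,
            "label_frequencies": ledger.label_frequencies(),
            "mode": cfg.adduct_mode,
        }
    else:
        ledger = None
        report["qvp7"] = None
        report["qvp8"] = None

    # ---- result tables and outputs --------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files["processed_peak_table"] = str(
            write_peak_table(pt2, outdir / "processed_peak_table.csv")
        )
        enr.table.to_csv(outdir / "enrichment.csv", index=False, float_format="%.6g")
        nt.table.to_csv(outdir / "noise_scores.csv", index=False, float_format="%.6g")
        files["enrichment"] = str(outdir / "enrichment.csv")
        files["noise_scores"] = str(outdir / "noise_scores.csv")

        # map annotation (computed on the filtered table) back to input ions
        iso_status = None
        adduct_lists = None
        if ledger is not None:
            status_by_mz = dict(zip(pt2.mz, ledger.isotope_status()))
            labels_by_mz = dict(zip(pt2.mz, ledger.adduct_label_lists()))
            iso_status = [status_by_mz.get(m, "unknown") for m in pt0.mz]
            adduct_lists = [labels_by_mz.get(m, []) for m in pt0.mz]
            ledger.to_frame().to_csv(
                outdir / "annotation_ledger.csv", index=False, float_format="%.8g"
            )
            files["annotation_ledger"] = str(outdir / "annotation_ledger.csv")
        peak_info = build_peak_info(pt0, enr.table, nt.table, iso_status, adduct_lists)
        pixel_info = build_pixel_info(pt0, seg.keep)
        p1, p2paths = write_result_tables(
            peak_info, pixel_info, outdir,
            expect_n_ions=pt0.n_ions, expect_n_pixels=pt0.n_pixels,
        )
        files["peak_info"], files["pixel_info"] = str(p1), str(p2paths)

        if cfg.do_images:
            from . import render

            for which in ("total", "median", "missing"):
                render.render_images(pt2, which, outdir / "images")
            files["images"] = str(outdir / "images")
        if cfg.borderline_window > 0:
            idx = noisemod.borderline_ions(
                nt, nt.threshold, cfg.borderline_window,
                pt1 if cfg.do_images else None,
                (outdir / "borderline") if cfg.do_images else None,
            )
            report["qvp4"]["n_borderline"] = len(idx)

        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        with open(outdir / "timings.json", "w") as fh:
            json.dump({k: round(v, 4) for k, v in timings.items()}, fh, indent=1)
        files["qc_report"] = str(outdir / "qc_report.json")
    elif cfg.borderline_window > 0:
        idx = noisemod.borderline_ions(nt, nt.threshold, cfg.borderline_window)
        report["qvp4"]["n_borderline"] = len(idx)

    return PipelineResult(report, pt2, timings, files)
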