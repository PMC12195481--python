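import numpy as np
import pytest

from smqc.pipeline import PipelineConfig, run_pipeline
from smqc.regions import Region, load_regions
from smqc.segmentation import ion_enrichment, pixel_total_intensity, remove_background_pixels, suggest_threshold
from smqc.synthetic import SynthConfig, generate_dataset, worked_micro_fixture


@pytest.fixture(scope="session")
def micro():
    """Hand-sized 4x4-pixel, 6-ion table with hand-computed expected values."""
    return worked_micro_fixture()


@pytest.fixture(scope="session")
def demo():
    """The default demo dataset with planted ground truth (seed 7)."""
    pt, truth = generate_dataset(SynthConfig())
    return pt, truth


@pytest.fixture(scope="session")
def demo_filtered(demo):
    """Demo dataset after enrichment + background-pixel removal (Process 2)."""
    pt, truth = demo
    rs = load_regions(truth.regions, pt)
    bg = Region(
        "background_all",
        "background",
        frozenset().union(*[r.pixels for r in rs.background()]),
    )
    enr = ion_enrichment(pt, rs.tissue()[0], bg)
    totals = pixel_total_intensity(pt, enr.table["enriched"].to_numpy())
    thr = suggest_threshold(totals).value
    pt1, seg = remove_background_pixels(pt, totals, thr)
    return pt1, truth, enr, seg


@pytest.fixture(scope="session")
def demo_run(demo, tmp_path_factory):
    """Full pipeline run on the demo dataset, with all files written."""
    pt, truth = demo
    outdir = tmp_path_factory.mktemp("demo_run")
    res = run_pipeline(pt, truth.regions, PipelineConfig(), outdir)
    return res, truth, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
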