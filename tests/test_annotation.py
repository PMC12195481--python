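import numpy as np
import pytest

from smqc.annotation import (
    AdductConfig,
    IsotopeConfig,
    POSITIVE_ADDUCTS,
    annotate,
    find_adduct_pairs,
    find_isotope_pairs,
    spatial_correlation,
)
from smqc.errors import ConfigError
from smqc.peaktable import PeakTable


def table(mz, images):
    n = len(images[0])
    side = int(np.ceil(np.sqrt(n)))
    coords = np.array([(i % side, i // side) for i in range(n)])
    return PeakTable(coords, np.asarray(mz, dtype=float), np.column_stack(images))


def brute_force_ledger(pt, iso_cfg, add_cfg):
    """Independent all-pairs reimplementation of the annotation contract."""
    mz = pt.mz
    n = pt.n_ions
    iso_flag = set()
    iso_pairs = []
    for i in range(n):  # ascending m/z sweep
        if i in iso_flag:
            continue
        for j in range(n):
            if mz[j] <= mz[i]:
                continue
            for k in range(1, iso_cfg.max_order + 1):
                err = (mz[j] - mz[i]) - k * iso_cfg.iso_spacing
                if abs(err) > iso_cfg.ppm_tol * mz[j] / 1e6:
                    continue
                r = spatial_correlation(pt, i, j)
                if r is None or r < iso_cfg.corr_min:
                    continue
                iso_pairs.append((i, j))
                iso_flag.add(j)
    deltas = {}
    for pa, (la, oa) in enumerate(add_cfg.adducts):
        for pb, (lb, ob) in enumerate(add_cfg.adducts):
            if ob > oa:
                key = round(ob - oa, 9)
                deltas.setdefault(key, (ob - oa, la, lb))
    adduct_pairs = []
    mono = [i for i in range(n) if i not in iso_flag]
    for ai, i in enumerate(mono):
        for j in mono[ai + 1:]:
            lo, hi = (i, j) if mz[i] < mz[j] else (j, i)
            obs = mz[hi] - mz[lo]
            tol = add_cfg.ppm_tol * mz[hi] / 1e6
            cands = [(abs(obs - d), la, lb) for d, la, lb in deltas.values()
                     if abs(obs - d) <= tol]
            if not cands:
                continue
            r = spatial_correlation(pt, lo, hi)
            if r is None or r < add_cfg.corr_min:
                continue
            _, la, lb = min(cands)
            adduct_pairs.append((lo, hi, la, lb))
    return sorted(iso_pairs), sorted(adduct_pairs)


class TestSpatialCorrelation:
    def test_scaled_image_gives_unit_correlation(self, rng):
        img = rng.random(16)
        pt = table([100.0, 200.0], [img, 0.1 * img])
        assert spatial_correlation(pt, 0, 1) == pytest.approx(1.0)

    def test_constant_image_rejected_with_sentinel(self, rng):
        pt = table([100.0, 200.0], [rng.random(16), np.full(16, 3.0)])
        assert spatial_correlation(pt, 0, 1) is None

    def test_matches_direct_formula(self, rng):
        a, b = rng.random(25), rng.random(25)
        pt = table([100.0, 200.0], [a, b])
        expect = float(
            ((a - a.mean()) * (b - b.mean())).sum()
            / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        assert spatial_correlation(pt, 0, 1) == pytest.approx(expect, abs=1e-12)


class TestIsotopePairs:
    def test_exact_spacing_confirmed(self, rng):
        img = rng.random(16) + 0.5
        pt = table([100.0, 101.0035], [img, 0.2 * img])
        led = find_isotope_pairs(pt)
        assert len(led.pairs) == 1
        assert led.isotope_status() == ["monoisotopic", "isotope-of:100.0000"]
        assert led.qvp7() == pytest.approx(50.0)

    def test_off_spacing_never_candidate(self, rng):
        img = rng.random(16) + 0.5
        pt = table([100.0, 100.5], [img, img.copy()])
        led = find_isotope_pairs(pt, IsotopeConfig(ppm_tol=1000.0))
        assert led.pairs == []

    def test_uncorrelated_pair_at_spacing_rejected(self, rng):
        pt = table([100.0, 101.0035], [rng.random(100), rng.random(100)])
        assert find_isotope_pairs(pt).pairs == []

    def test_isotope_peak_cannot_anchor_the_next_order(self, rng):
        # chain M, M+1, M+2: with max_order=1 the middle ion is flagged as an
        # isotope and must not anchor the third
        img = rng.random(16) + 0.5
        pt = table([100.0, 101.0035, 102.0070],
                   [img, 0.2 * img, 0.04 * img])
        led = find_isotope_pairs(pt)
        assert [(p.lighter, p.heavier) for p in led.pairs] == [(0, 1)]


class TestAdductPairs:
    def test_proton_sodium_pair_confirmed(self, rng):
        img = rng.random(16) + 0.5
        pt = table([150.0, 171.981944], [img, 0.5 * img])
        led = find_adduct_pairs(pt)
        assert len(led.pairs) == 1
        pr = led.pairs[0]
        assert (pr.label_lighter, pr.label_heavier) == ("M+H", "M+Na")
        assert abs(pr.ppm_error) <= 5.0

    def test_single_ion_table_empty_ledger(self, rng):
        pt = table([150.0], [rng.random(16)])
        led = find_adduct_pairs(pt)
        assert led.pairs == [] and led.qvp8() == 0.0

    def test_isotope_flagged_ions_excluded(self, rng):
        # the heavier ion is first confirmed as an isotope; a would-be adduct
        # partner of it must be ignored
        img = rng.random(16) + 0.5
        # 122.985442 sits exactly Na-H above the isotope peak at 101.0035
        pt = table([100.0, 101.0035, 122.985442], [img, 0.2 * img, 0.3 * img])
        led = annotate(pt)
        assert all(p.kind == "isotope" or 1 not in (p.lighter, p.heavier)
                   for p in led.pairs)
        assert not any(p.kind == "adduct" for p in led.pairs)

    def test_duplicate_offsets_rejected(self):
        with pytest.raises(ConfigError):
            AdductConfig(adducts=[("A", 1.0), ("B", 1.0)])

    def test_degenerate_deltas_resolve_by_list_order(self, rng):
        # (M+Na)-(M+H) and (M+2Na-H)-(M+Na) are the same mass difference;
        # the earlier list-order interpretation must win
        img = rng.random(16) + 0.5
        pt = table([150.0, 150.0 + (22.989218 - 1.007276)], [img, 0.5 * img])
        led = find_adduct_pairs(pt)
        assert (led.pairs[0].label_lighter, led.pairs[0].label_heavier) == ("M+H", "M+Na")


class TestLedgerInvariants:
    def test_matches_brute_force_oracle_on_demo(self, demo_filtered):
        from smqc.noise import filter_noise_ions, score_all_ions

        pt1, _, _, _ = demo_filtered
        pt2 = filter_noise_ions(pt1, score_all_ions(pt1))
        assert pt2.n_ions <= 200
        iso_cfg, add_cfg = IsotopeConfig(), AdductConfig()
        led = annotate(pt2, iso_cfg, add_cfg)
        iso_got = sorted((p.lighter, p.heavier) for p in led.pairs if p.kind == "isotope")
        add_got = sorted((p.lighter, p.heavier, p.label_lighter, p.label_heavier)
                         for p in led.pairs if p.kind == "adduct")
        iso_exp, add_exp = brute_force_ledger(pt2, iso_cfg, add_cfg)
        assert iso_got == iso_exp
        assert add_got == add_exp

    def test_every_confirmed_pair_satisfies_its_own_invariants(self, demo_filtered):
        from smqc.noise import filter_noise_ions, score_all_ions

        pt1, _, _, _ = demo_filtered
        pt2 = filter_noise_ions(pt1, score_all_ions(pt1))
        led = annotate(pt2)
        iso_flag = led.isotope_flagged()
        for p in led.pairs:
            assert pt2.mz[p.heavier] > pt2.mz[p.lighter]
            assert abs(p.ppm_error) <= 5.0
            assert p.correlation >= 0.7
            if p.kind == "adduct":
                assert not iso_flag[p.lighter] and not iso_flag[p.heavier]

    def test_rates_invariant_under_global_rescaling(self, rng):
        img = rng.random(36) + 0.5
        other = rng.random(36) + 0.5
        pt = table([100.0, 101.0035, 150.0, 171.981942],
                   [img, 0.2 * img, other, 0.5 * other])
        led1 = annotate(pt)
        pt2 = PeakTable(pt.coords, pt.mz, 42.0 * pt.intensity)
        led2 = annotate(pt2)
        assert led1.qvp7() == led2.qvp7()
        assert led1.qvp8() == led2.qvp8()

    def test_planted_recovery_and_decoy_rejection(self, demo_filtered):
        from smqc.noise import filter_noise_ions, score_all_ions

        pt1, truth, _, _ = demo_filtered
        pt2 = filter_noise_ions(pt1, score_all_ions(pt1))
        led = annotate(pt2)
        confirmed = {(round(pt2.mz[p.lighter], 4), round(pt2.mz[p.heavier], 4))
                     for p in led.pairs if p.kind == "isotope"}
        iso = truth.ions[truth.ions.ion_class == "isotope_companion"]
        recovered = sum((round(r.partner_mz, 4), round(r.mz, 4)) in confirmed
                        for _, r in iso.iterrows())
        decoys = truth.ions[truth.ions.label == "decoy"]
        decoys_confirmed = sum((round(r.partner_mz, 4), round(r.mz, 4)) in confirmed
                               for _, r in decoys.iterrows())
        assert recovered >= 0.95 * len(iso)
        assert decoys_confirmed <= 0.05 * len(decoys)

    def test_planted_adduct_labels_match_truth(self, demo_filtered):
        from smqc.noise import filter_noise_ions, score_all_ions

        pt1, truth, _, _ = demo_filtered
        pt2 = filter_noise_ions(pt1, score_all_ions(pt1))
        led = annotate(pt2)
        n_add = int((truth.ions.ion_class == "adduct_companion").sum())
        freq = led.label_frequencies()
        assert freq.get("M+H", 0) == n_add
        assert sum(freq.values()) == 2 * n_add
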