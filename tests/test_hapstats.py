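import numpy as np
import pandas as pd
import pytest

from conftest import make_panel
from sweepscan.hapstats import (
    UndefinedEHH,
    _chrom_spans,
    _ihh_site,
    ehh,
    ihh,
    ihs_raw,
    ihs_scan,
    standardize_ihs,
    standardize_xpehh,
    xpehh_scan,
)


class TestEHH:
    def test_identical_haplotypes_keep_ehh_one(self):
        haps = np.tile(np.array([0, 1, 0, 1, 1]), (4, 1))
        prof = ehh(make_panel(haps), focal=2)
        assert np.all(prof.ehh_values == 1.0)

    def test_all_distinct_haplotypes_drop_to_zero(self):
        haps = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]])
        prof = ehh(make_panel(haps), focal=2)
        # after one site leftward the four haplotypes split into two pairs,
        # after two they are all distinct
        left = prof.ehh_values[prof.distances_cM < 0]
        assert left[0] == 0.0 and left[1] == pytest.approx(2 / 6)

    def test_counts_two_one_one(self):
        # two sites right of the focal: extended haplotypes 00,00,01,10
        haps = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1], [0, 1, 0]])
        prof = ehh(make_panel(haps), focal=0)
        at = prof.ehh_values[prof.distances_cM > 0]
        assert at[1] == pytest.approx(1 / 6)

    def test_class_below_two_is_undefined(self):
        with pytest.raises(UndefinedEHH):
            ehh(make_panel(np.zeros((2, 3))), focal=0, rows=np.array([0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_profiles_non_increasing_outward(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(12, 40)).astype(np.uint8)
        panel = make_panel(haps, pos=np.sort(
            rng.choice(100_000, size=40, replace=False)))
        for focal in (0, 20, 39):
            prof = ehh(panel, focal)
            for direction in (-1, 1):
                _, e, _ = prof.side(direction)
                assert np.all(np.diff(e) <= 1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(10, 30)).astype(np.uint8)
        panel = make_panel(haps)
        shuffled = make_panel(haps[rng.permutation(10)])
        p1 = ehh(panel, 15)
        p2 = ehh(shuffled, 15)
        np.testing.assert_allclose(p1.ehh_values, p2.ehh_values)


class TestIHH:
    def test_rectangle_integral(self):
        # EHH == 1 over 0.05 cM on each side, then a sub-cutoff split
        pos = np.array([0, 50_000, 100_000, 150_000, 200_000])
        haps = np.zeros((4, 5), np.uint8)
        haps[:, 0] = [0, 0, 1, 1]   # {2,2}: EHH 1/3 at the ends
        haps[:, 4] = [0, 0, 1, 1]
        prof = ehh(make_panel(haps, pos=pos), focal=2)
        val = ihh(prof, cutoff=0.4, max_gap_bp=300_000,
                  gap_scale_bp=100_000)  # spacing below the gap penalty
        assert val == pytest.approx(0.1, abs=1e-15)

    def test_flat_profile_known_area(self):
        pos = np.arange(11) * 10_000
        haps = np.tile(np.array([0, 1]), (6, 1)).T  # two identical classes
        haps = np.zeros((4, 11), np.uint8)
        prof = ehh(make_panel(haps, pos=pos), focal=5)
        # identical haplotypes: EHH 1 everywhere -> never decays -> unscored
        assert np.isnan(ihh(prof))

    def test_excludes_sub_cutoff_tail(self):
        pos = np.array([0, 10_000, 20_000, 30_000])
        haps = np.array([[0, 0, 0, 0],
                         [0, 0, 0, 0],
                         [1, 0, 0, 1],
                         [1, 0, 0, 1]], dtype=np.uint8)
        prof = ehh(make_panel(haps, pos=pos), focal=1)
        # cutoff 0.4: left side EHH 1/3 immediately (excluded, side decayed);
        # right side one full trapezoid then EHH 1/3 -> tail excluded
        got = ihh(prof, cutoff=0.4)
        assert got == pytest.approx(0.01, abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numerical_integration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = 30
        pos = np.sort(rng.choice(300_000, size=n_sites, replace=False))
        haps = rng.integers(0, 2, size=(8, n_sites)).astype(np.uint8)
        panel = make_panel(haps, pos=pos)
        prof = ehh(panel, 15)
        got = ihh(prof, cutoff=0.05, max_gap_bp=10**9, gap_scale_bp=10**9)
        want = 0.0
        for direction in (-1, 1):
            d, e, _ = prof.side(direction)
            stop = len(e)
            for k in range(1, len(e)):
                if e[k] < 0.05:
                    stop = k
                    break
            if stop == len(e):
                want = float("nan")
                break
            want += np.trapezoid(e[:stop], d[:stop])
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)

    def test_fast_path_matches_reference(self, sweep_study):
        panel, _, _ = sweep_study
        sub = panel.for_population("POP1")
        derived, _ = sub.derived_haplotypes()
        from sweepscan.variant_io import HaplotypePanel
        dp = HaplotypePanel(sites=sub.sites, haplotypes=derived,
                            samples=sub.samples, popmap=sub.popmap)
        spans = _chrom_spans(sub.sites)
        cm, pos = sub.map_cM, sub.positions
        for j in (10, 400, 2000, 2525, 4000):
            rows = np.flatnonzero(derived[:, j] == 1)
            if len(rows) < 2:
                continue
            ref = ihh(ehh(dp, j, rows))
            lo, hi = spans[j]
            fast = _ihh_site(derived, rows, j, lo, hi, cm, pos,
                             0.05, 200_000, 20_000)
            if np.isnan(ref):
                assert np.isnan(fast)
            else:
                assert fast == pytest.approx(ref, abs=1e-12)


class TestIHS:
    def test_mirror_symmetry_gives_zero(self):
        # ancestral and derived classes with identical extension structure
        rng = np.random.default_rng(2)
        block = rng.integers(0, 2, size=(4, 21)).astype(np.uint8)
        haps = np.vstack([block, block])
        haps[:4, 10] = 0   # ancestral class
        haps[4:, 10] = 1   # derived class, same flanking haplotypes
        panel = make_panel(haps)
        score = ihs_raw(panel, focal=10)
        assert score.raw == pytest.approx(0.0, abs=1e-12)

    def test_sweep_makes_ihs_strongly_negative(self, sweep_study):
        panel, _, truth = sweep_study
        tw = truth.sweep_windows.iloc[0]
        scores = standardize_ihs(ihs_scan(panel, "POP1"))
        near = scores[(scores.pos >= tw.start - 50_000)
                      & (scores.pos < tw.end + 50_000)]
        # hitchhiked sites score strongly in |iHS| (sign depends on
        # whether the core carries the derived or ancestral allele)
        assert near["std"].abs().mean() > 2 * scores["std"].abs().mean()
        swept = near[near.derived_freq > 0.9]
        assert swept["raw"].mean() < -1.0

    def test_log_ratio_arithmetic(self):
        assert np.log(0.2 / 0.1) == pytest.approx(0.6931, abs=1e-4)

    def test_maf_floor_excludes_rare_sites(self):
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, size=(20, 50)).astype(np.uint8)
        haps[:, 25] = 0
        haps[0, 25] = 1  # derived frequency 0.05 > floor only if >= 0.05
        panel = make_panel(haps)
        scores = ihs_scan(panel, maf_floor=0.10)
        assert 25 not in set(scores["site"])


class TestStandardize:
    def test_bins_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"site": np.arange(2000),
                           "chrom": "chr1", "pos": np.arange(2000),
                           "derived_freq": rng.uniform(0.05, 0.95, 2000),
                           "raw": rng.normal(size=2000)})
        out = standardize_ihs(df, n_bins=10)
        bins = np.clip(np.digitize(out["derived_freq"],
                                   np.linspace(0, 1, 11)) - 1, 0, 9)
        for b in np.unique(bins):
            vals = out.loc[bins == b, "std"]
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
            assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_bin_flagged_nan(self):
        df = pd.DataFrame({"site": [0, 1], "chrom": "chr1", "pos": [0, 1],
                           "derived_freq": [0.5, 0.5], "raw": [1.0, 1.0]})
        out = standardize_ihs(df)
        assert out["std"].isna().all()

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"site": np.arange(500),
                           "chrom": "chr1", "pos": np.arange(500),
                           "derived_freq": rng.uniform(0, 1, 500),
                           "raw": rng.normal(size=500)})
        a = standardize_ihs(df).set_index("site")["std"]
        b = standardize_ihs(df.sample(frac=1, random_state=0)) \
            .set_index("site")["std"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


class TestXPEHH:
    def test_identical_panels_give_zero(self):
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, size=(8, 60)).astype(np.uint8)
        both = np.vstack([haps, haps])
        panel = make_panel(both, popmap=["A"] * 4 + ["B"] * 4)
        scores = xpehh_scan(panel, "A", "B")
        assert len(scores) > 0
        np.testing.assert_allclose(scores["raw"], 0.0, atol=1e-12)

    def test_label_swap_antisymmetry(self, sweep_study):
        panel, _, _ = sweep_study
        small = panel  # full panel; scan is fast
        ab = xpehh_scan(small, "POP1", "POP2").set_index("site")["raw"]
        ba = xpehh_scan(small, "POP2", "POP1").set_index("site")["raw"]
        common = ab.index.intersection(ba.index)
        assert len(common) > 1000
        np.testing.assert_allclose(ab[common], -ba[common], atol=1e-12)

    def test_sweep_in_a_gives_positive_scores(self, sweep_study):
        panel, _, truth = sweep_study
        tw = truth.sweep_windows.iloc[0]
        scores = standardize_xpehh(xpehh_scan(panel, "POP1", "POP2"))
        near = scores[(scores.pos >= tw.start) & (scores.pos < tw.end)]
        assert near["raw"].mean() > 1.0

    def test_genomewide_standardization(self):
        df = pd.DataFrame({"site": range(4), "chrom": "chr1",
                           "pos": range(4), "derived_freq": 0.5,
                           "raw": [1.0, 2.0, 3.0, 4.0]})
        out = standardize_xpehh(df)
        assert out["std"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["std"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
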