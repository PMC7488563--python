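import numpy as np
import pandas as pd
import pytest

from conftest import make_gm
from sweepscan.roh import (
    ROHParams,
    _letters_from_sig,
    compare_groups,
    detect_roh,
    froh,
    froh_summary,
    roh_hotspots,
)
from sweepscan.simulate import RohSpec, SimConfig, simulate
from sweepscan.variant_io import MISSING


def roh_oracle(calls, pos, params):
    """Exhaustive scanning-window oracle for one sample on one chromosome."""
    S = len(pos)
    W = params.window_snps
    if S < W:
        return []
    het = calls == 1
    mis = calls == MISSING
    hits = []
    for start in range(S - W + 1):
        h = het[start:start + W].sum()
        m = mis[start:start + W].sum()
        hits.append(h <= params.max_het_per_window
                    and m <= params.max_missing_per_window)
    state = []
    for i in range(S):
        covering = [hits[w] for w in range(max(0, i - W + 1),
                                           min(i, S - W) + 1)]
        state.append(sum(covering) / len(covering) >= params.hit_proportion)
    runs = []
    i = 0
    while i < S:
        if state[i]:
            j = i
            while j + 1 < S and state[j + 1]:
                j += 1
            length = pos[j] - pos[i] + 1
            if length >= params.min_length_bp \
                    and j - i + 1 >= params.min_snps_in_run:
                runs.append((int(pos[i]), int(pos[j]) + 1))
            i = j + 1
        else:
            i += 1
    return runs


def random_roh_instance(rng, n_snps):
    """Genotypes with a few long homozygous tracts on a noisy background."""
    pos = np.sort(rng.choice(n_snps * 1000, size=n_snps, replace=False))
    calls = rng.choice([0, 1, 2], size=n_snps, p=[0.35, 0.4, 0.25])
    calls[rng.random(n_snps) < 0.02] = MISSING
    for _ in range(rng.integers(0, 4)):
        a = int(rng.integers(0, max(n_snps - 700, 1)))
        b = min(a + int(rng.integers(100, 700)), n_snps)
        calls[a:b] = rng.choice([0, 2], size=b - a)
        stray = rng.random(b - a) < 0.01
        calls[a:b][stray] = 1
    return calls.astype(np.int8), pos


class TestDetectRoh:
    def test_homozygous_megabase_tract_found(self):
        rng = np.random.default_rng(0)
        n = 1500
        pos = np.arange(n) * 1000
        calls = rng.choice([0, 1, 2], size=n, p=[0.3, 0.5, 0.2])
        calls[200:1201] = 0  # 1 Mb perfectly homozygous
        gm = make_gm(calls[None, :], pos=pos)
        segs = detect_roh(gm)
        assert len(segs) == 1
        seg = segs.iloc[0]
        assert seg.start <= 250_000 and seg.end >= 1_150_000
        assert seg.length_bp >= 900_000

    def test_fully_heterozygous_has_no_runs(self):
        gm = make_gm(np.ones((1, 500), np.int8), pos=np.arange(500) * 1000)
        assert len(detect_roh(gm)) == 0

    def test_short_tract_rejected_by_length_floor(self):
        rng = np.random.default_rng(1)
        n = 1000
        pos = np.arange(n) * 1000
        calls = rng.choice([1, 1, 0, 2], size=n)
        calls[300:701] = 2  # 400 kb tract
        gm = make_gm(calls[None, :].astype(np.int8), pos=pos)
        segs = detect_roh(gm)
        assert not ((segs["start"] >= 250_000) & (segs["end"] <= 750_000)
                    & (segs["length_bp"] >= 500_000)).any()
        assert len(segs) == 0

    def test_short_chromosome_skipped(self):
        gm = make_gm(np.zeros((1, 10), np.int8))
        assert len(detect_roh(gm)) == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 1200))
        calls, pos = random_roh_instance(rng, n)
        params = ROHParams()
        gm = make_gm(calls[None, :], pos=pos)
        got = [(int(r.start), int(r.end))
               for r in detect_roh(gm, params).itertuples()]
        want = roh_oracle(calls, pos, params)
        assert got == want


class TestFroh:
    def test_arithmetic(self):
        segs = pd.DataFrame([{"sample": "S1", "chrom": "chr1", "start": 0,
                              "end": 251_140_000, "n_snps": 10,
                              "length_bp": 251_140_000}])
        table = froh(segs, ["S1", "S2"])
        assert table.set_index("sample").loc["S1", "froh"] == pytest.approx(0.1)
        assert table.set_index("sample").loc["S2", "froh"] == 0.0

    @pytest.mark.parametrize("target", [0.05, 0.15])
    def test_recovers_injected_autozygosity(self, target):
        # genome long enough that a single borderline-500-kb tract cannot
        # dominate the autozygous total
        cfg = SimConfig(n_pops=1, n_per_pop=4, chrom_lengths=[50_000_000],
                        seed=21, roh_specs=[RohSpec("POP1", target)])
        _, gm, truth = simulate(cfg)
        table = froh(detect_roh(gm), gm.samples, l_gen_bp=50_000_000)
        assert np.all(np.abs(table["froh"] - target) <= 0.02)


class TestFrohSummary:
    def test_constant_values(self):
        table = pd.DataFrame({"sample": ["a", "b", "c"],
                              "s_roh_bp": 0, "froh": 0.1})
        out = froh_summary(table, {"a": "P", "b": "P", "c": "P"})
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(0.1)
        assert row["cv_pct"] == pytest.approx(0.0)

    def test_median_of_two(self):
        table = pd.DataFrame({"sample": ["a", "b"], "s_roh_bp": 0,
                              "froh": [0.0, 0.2]})
        out = froh_summary(table, {"a": "P", "b": "P"})
        assert out.iloc[0]["mean"] == pytest.approx(0.1)
        assert out.iloc[0]["median"] == pytest.approx(0.1)

    def test_invariant_under_sample_order(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"sample": [f"s{i}" for i in range(8)],
                              "s_roh_bp": 0, "froh": rng.random(8)})
        pm = {f"s{i}": "AB"[i % 2] for i in range(8)}
        a = froh_summary(table, pm).set_index("pop")
        b = froh_summary(table.iloc[::-1].reset_index(drop=True),
                         pm).set_index("pop")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestCompareGroups:
    def make_table(self, means, n=8, sd=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows, pm = [], {}
        for g, mu in means.items():
            for i in range(n):
                s = f"{g}{i}"
                rows.append({"sample": s, "s_roh_bp": 0,
                             "froh": rng.normal(mu, sd)})
                pm[s] = g
        return pd.DataFrame(rows), pm

    def test_identical_distributions_share_letter(self):
        table, pm = self.make_table({"A": 0.1, "B": 0.1}, seed=3)
        out = compare_groups(table, pm).set_index("pop")
        assert out.loc["A", "letter"] == out.loc["B", "letter"]

    def test_large_shift_gets_distinct_letters(self):
        table, pm = self.make_table({"A": 0.05, "B": 0.15, "C": 0.05}, seed=4)
        out = compare_groups(table, pm).set_index("pop")
        assert set(out.loc["B", "letter"]).isdisjoint(out.loc["A", "letter"])
        assert set(out.loc["A", "letter"]) & set(out.loc["C", "letter"])

    def test_identical_data_single_letter(self):
        table, pm = self.make_table({"A": 0.1, "B": 0.1}, sd=0.0)
        out = compare_groups(table, pm)
        assert set(out["letter"]) == {"a"}

    def test_type_one_error_control(self):
        shared = 0
        for seed in range(20):
            table, pm = self.make_table({"A": 0.1, "B": 0.1}, seed=100 + seed)
            out = compare_groups(table, pm).set_index("pop")
            shared += bool(set(out.loc["A", "letter"])
                           & set(out.loc["B", "letter"]))
        assert shared >= 18  # alpha = 0.05 pairwise

    def test_letter_display_handles_chains(self):
        # A~B and B~C not significant but A-C significant: B bridges
        letters = _letters_from_sig(["A", "B", "C"],
                                    {frozenset(("A", "C"))})
        assert set(letters["B"]) & set(letters["A"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])


def hotspot_oracle(segments, popmap, share_fraction):
    """Per-basepair counting oracle on small coordinates."""
    out = []
    pops = sorted(set(popmap.values()))
    for pop in pops:
        n = sum(1 for p in popmap.values() if p == pop)
        segs = segments[segments["sample"].map(popmap) == pop]
        for chrom in sorted(set(segs["chrom"])):
            cs = segs[segs["chrom"] == chrom]
            limit = int(cs["end"].max())
            cover = np.zeros(limit + 1)
            for sample in set(cs["sample"]):
                mask = np.zeros(limit + 1, bool)
                for _, r in cs[cs["sample"] == sample].iterrows():
                    mask[r["start"]:r["end"]] = True
                cover += mask
            hot = cover > share_fraction * n
            i = 0
            while i <= limit:
                if hot[i]:
                    j = i
                    while j + 1 <= limit and hot[j + 1]:
                        j += 1
                    out.append((pop, chrom, i, j + 1))
                    i = j + 1
                else:
                    i += 1
    return out


class TestHotspots:
    def segs(self, spans, pop="P"):
        return pd.DataFrame([{"sample": s, "chrom": "chr1",
                              "start": a, "end": b, "n_snps": 1,
                              "length_bp": b - a}
                             for s, a, b in spans])

    def test_strict_majority_required(self):
        pm = {f"s{i}": "P" for i in range(12)}
        seven = self.segs([(f"s{i}", 100, 200) for i in range(7)])
        six = self.segs([(f"s{i}", 100, 200) for i in range(6)])
        assert len(roh_hotspots(seven, pm)) == 1
        assert len(roh_hotspots(six, pm)) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pm = {f"s{i}": "AB"[i % 2] for i in range(8)}
        rows = []
        for s in pm:
            for _ in range(rng.integers(1, 5)):
                a = int(rng.integers(0, 900))
                b = a + int(rng.integers(10, 300))
                rows.append((s, a, b))
        segments = self.segs(rows)
        got = [(r.pop, r.chrom, r.start, r.end)
               for r in roh_hotspots(segments, pm).itertuples()]
        want = hotspot_oracle(segments, pm, 0.5)
        assert sorted(got) == sorted(want)

    def test_monotone_in_share_fraction(self):
        rng = np.random.default_rng(9)
        pm = {f"s{i}": "P" for i in range(10)}
        rows = [(f"s{i}", int(rng.integers(0, 500)),
                 int(rng.integers(500, 1000))) for i in range(10)
                for _ in range(2)]
        segments = self.segs(rows)
        lo = roh_hotspots(segments, pm, share_fraction=0.3)
        hi = roh_hotspots(segments, pm, share_fraction=0.7)
        total = lambda df: (df["end"] - df["start"]).sum()
        assert total(hi) <= total(lo)
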