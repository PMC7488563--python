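"""Runs of homozygosity: PLINK-style detection, F_ROH, Tukey groups, hotspots.

Detection reimplements PLINK v1.90's scanning-window algorithm: 50-SNP
windows slide one SNP at a time; a window is a "hit" when it contains
at most 3 heterozygous and at most 3 missing calls; a SNP is in
homozygous state when the fraction of complete windows covering it that
are hits reaches the hit proportion (0.05). Maximal stretches of such
SNPs become candidate runs, kept when spanning >= 500 kb and >= 50
SNPs. PLINK's density and inter-SNP-gap sub-thresholds default to
unlimited here.

F_ROH = S_ROH / L_GEN per individual (total ROH length over the SNP-
covered autosome length; the cattle UMD 3.1 value 2511.4 Mb is the
default L_GEN and should be overridden by the actual genome length for
other data). Hotspots are maximal intervals covered by ROH in strictly
more than ``share_fraction`` of a population's samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

L_GEN_DEFAULT = 2_511_400_000  # bp


@dataclass
class ROHParams:
    window_snps: int = 50
    min_length_bp: int = 500_000
    max_het_per_window: int = 3
    max_missing_per_window: int = 3
    hit_proportion: float = 0.05
    min_snps_in_run: int = 50

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0 or self.window_snps <= 0:
            raise ValueError("window_snps and min_length_bp must be positive")


def _homozygous_state(het: np.ndarray, mis: np.ndarray,
                      params: ROHParams) -> np.ndarray:
    """Per-SNP in-run state for one sample on one chromosome."""
    S = len(het)
    W = params.window_snps
    if S < W:
        return np.zeros(S, dtype=bool)
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(S - W + 1)
    hit = ((ch[starts + W] - ch[starts] <= params.max_het_per_window)
           & (cm[starts + W] - cm[starts] <= params.max_missing_per_window))
    hh = np.concatenate([[0], np.cumsum(hit)])
    i = np.arange(S)
    first = np.maximum(0, i - W + 1)
    last = np.minimum(i, S - W)
    n_windows = last - first + 1
    n_hits = hh[last + 1] - hh[first]
    return n_hits / n_windows >= params.hit_proportion


def _runs_from_state(state: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [i, j] index stretches of True."""
    runs = []
    i = 0
    S = len(state)
    while i < S:
        if state[i]:
            j = i
            while j + 1 < S and state[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def detect_roh(gm: GenotypeMatrix, params: ROHParams | None = None,
               ) -> pd.DataFrame:
    """PLINK-style ROH segments for every sample.

    Returns sample/chrom/start/end (bp, half-open)/n_snps/length_bp.
    Chromosomes with fewer SNPs than the window are skipped.
    """
    params = params or ROHParams()
    sites = gm.sites
    chrom_arr = sites["chrom"].to_numpy(object)
    pos_arr = sites["pos"].to_numpy(np.int64)
    rows = []
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        if len(idx) < params.window_snps:
            log.warning("chromosome %s has %d < %d SNPs; skipped",
                        chrom, len(idx), params.window_snps)
            continue
        pos = pos_arr[idx]
        calls = gm.calls[:, idx]
        for si, sample in enumerate(gm.samples):
            het = calls[si] == 1
            mis = calls[si] == MISSING
            state = _homozygous_state(het, mis, params)
            for i, j in _runs_from_state(state):
                length = int(pos[j] - pos[i] + 1)
                n_snps = j - i + 1
                if length >= params.min_length_bp \
                        and n_snps >= params.min_snps_in_run:
                    rows.append({"sample": sample, "chrom": chrom,
                                 "start": int(pos[i]), "end": int(pos[j]) + 1,
                                 "n_snps": n_snps, "length_bp": length})
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "n_snps", "length_bp"])


def froh(segments: pd.DataFrame, samples: list[str],
         l_gen_bp: int = L_GEN_DEFAULT) -> pd.DataFrame:
    """Per-sample S_ROH and F_ROH = S_ROH / L_GEN (samples without
    segments get 0)."""
    s_roh = segments.groupby("sample")["length_bp"].sum() if len(segments) \
        else pd.Series(dtype=float)
    rows = [{"sample": s, "s_roh_bp": int(s_roh.get(s, 0)),
             "froh": float(s_roh.get(s, 0)) / l_gen_bp} for s in samples]
    out = pd.DataFrame(rows)
    out.attrs["l_gen_bp"] = l_gen_bp
    return out


def froh_summary(table: pd.DataFrame, popmap: dict[str, str]) -> pd.DataFrame:
    """Per-population mean/median/min/max/CV% of F_ROH."""
    df = table.copy()
    df["pop"] = df["sample"].map(popmap)
    rows = []
    for pop, grp in df.groupby("pop", sort=False):
        v = grp["froh"]
        mean = v.mean()
        cv = 100 * v.std(ddof=1) / mean if mean > 0 and len(v) > 1 else np.nan
        rows.append({"pop": pop, "n": len(v), "mean": mean,
                     "median": v.median(), "min": v.min(), "max": v.max(),
                     "cv_pct": cv})
    return pd.DataFrame(rows)


def _letters_from_sig(groups: list[str],
                      sig: set[frozenset]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Start from one letter covering all groups; every significant pair
    splits each letter set containing both; subsets are absorbed.
    Groups sharing a letter are not significantly different.
    """
    cliques: list[set[str]] = [set(groups)]
    for pair in sig:
        i, j = tuple(pair)
        nxt: list[set[str]] = []
        for cl in cliques:
            if i in cl and j in cl:
                nxt.extend([cl - {i}, cl - {j}])
            else:
                nxt.append(cl)
        uniq: list[set[str]] = []
        for cl in nxt:
            if cl and cl not in uniq:
                uniq.append(cl)
        cliques = [c for c in uniq if not any(c < d for d in uniq)]
    letters = {g: "" for g in groups}
    for k, cl in enumerate(cliques):
        for g in groups:
            if g in cl:
                letters[g] += chr(ord("a") + k)
    return letters


def compare_groups(table: pd.DataFrame, popmap: dict[str, str],
                   alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD on F_ROH with a compact letter display.

    Populations sharing a letter are not significantly different at
    ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table.copy()
    df["pop"] = df["sample"].map(popmap)
    groups = list(dict.fromkeys(df["pop"]))
    if len(groups) < 2 or (df.groupby("pop").size() < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if df["froh"].var(ddof=0) == 0:
        letters = {g: "a" for g in groups}
        return pd.DataFrame([{"pop": g, "letter": letters[g]} for g in groups])
    tk = pairwise_tukeyhsd(df["froh"].to_numpy(), df["pop"].to_numpy(),
                           alpha=alpha)
    res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    sig = {frozenset((r["group1"], r["group2"]))
           for _, r in res.iterrows() if r["reject"]}
    letters = _letters_from_sig(groups, sig)
    out = pd.DataFrame([{"pop": g, "letter": letters[g]} for g in groups])
    out.attrs["tukey"] = res
    return out


def roh_hotspots(segments: pd.DataFrame, popmap: dict[str, str],
                 share_fraction: float = 0.5) -> pd.DataFrame:
    """Per-population intervals covered by ROH in > share_fraction of samples.

    Strict majority: an interval covered by exactly half the samples is
    not a hotspot. Returns pop/chrom/start/end (half-open, maximal).
    """
    pop_sizes: dict[str, int] = {}
    for s, p in popmap.items():
        pop_sizes[p] = pop_sizes.get(p, 0) + 1
    rows = []
    if len(segments):
        segments = segments.copy()
        segments["pop"] = segments["sample"].map(popmap)
    for pop, n in pop_sizes.items():
        segs = segments[segments["pop"] == pop] if len(segments) else segments
        if len(segs) == 0:
            continue
        need = share_fraction * n
        for chrom, grp in segs.groupby("chrom"):
            events = []
            # overlapping segments of one sample count once
            for _, sample_grp in grp.groupby("sample"):
                iv = sorted(zip(sample_grp["start"], sample_grp["end"]))
                cs, ce = iv[0]
                merged = []
                for s0, e0 in iv[1:]:
                    if s0 <= ce:
                        ce = max(ce, e0)
                    else:
                        merged.append((cs, ce))
                        cs, ce = s0, e0
                merged.append((cs, ce))
                for s0, e0 in merged:
                    events.append((s0, 1))
                    events.append((e0, -1))
            events.sort()
            depth = 0
            open_at = None
            for x, d in events:
                new = depth + d
                if depth <= need < new and open_at is None:
                    open_at = x
                if new <= need and open_at is not None:
                    if x > open_at:
                        rows.append({"pop": pop, "chrom": chrom,
                                     "start": int(open_at), "end": int(x)})
                    open_at = None
                depth = new
    out = pd.DataFrame(rows, columns=["pop", "chrom", "start", "end"])
    # coalesce touching intervals produced by coincident event points
    merged_rows = []
    for (pop, chrom), grp in out.groupby(["pop", "chrom"], sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, r in grp.iterrows():
            if cur is not None and r["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], r["end"])
            else:
                if cur is not None:
                    merged_rows.append(cur)
                cur = {"pop": pop, "chrom": chrom,
                       "start": r["start"], "end": r["end"]}
        if cur is not None:
            merged_rows.append(cur)
    return pd.DataFrame(merged_rows, columns=["pop", "chrom", "start", "end"])
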