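"""Extended-haplotype-homozygosity statistics: EHH, iHH, iHS, XP-EHH.

EHH at offset d from a focal site, within a class of n haplotypes, is
the probability that two distinct haplotypes drawn from the class are
identical over the whole span focal..d:

    EHH(d) = sum_h C(c_h, 2) / C(n, 2)

over the distinct extended haplotypes h with multiplicities c_h. iHH
integrates EHH over genetic distance (trapezoids) outward in both
directions, truncated at an EHH cutoff, with long physical gaps
down-weighted and very long gaps truncating — the selscan v1.2.0a
default behaviour (cutoff 0.05, gap scale 20 kb, max gap 200 kb,
MAF floor 0.05, 100 frequency bins for iHS normalization).

iHS_raw = ln(iHH_ancestral / iHH_derived); XP-EHH_raw = ln(iHH_A /
iHH_B) using all haplotypes of each population. iHS is standardized
within derived-allele-frequency bins, XP-EHH genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import HaplotypePanel

EHH_CUTOFF = 0.05
MAF_FLOOR = 0.05
GAP_SCALE_BP = 20_000
MAX_GAP_BP = 200_000
N_BINS = 100


@dataclass
class EHHProfile:
    """One-directional-merged EHH curve around a focal site.

    distances_cM are signed offsets (negative = left); ehh_values align
    with them; the focal site itself appears with offset 0 and EHH 1.
    """

    focal_site: int
    distances_cM: np.ndarray
    ehh_values: np.ndarray
    positions_bp: np.ndarray
    group: str

    def side(self, direction: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(|distance|, ehh, |pos offset|) walking outward; direction ±1."""
        if direction > 0:
            m = self.distances_cM >= 0
            order = np.argsort(self.distances_cM[m])
        else:
            m = self.distances_cM <= 0
            order = np.argsort(-self.distances_cM[m])
        return (np.abs(self.distances_cM[m][order]),
                self.ehh_values[m][order],
                np.abs(self.positions_bp[m][order]))


class UndefinedEHH(ValueError):
    """EHH requested for a haplotype class of size < 2."""


def _ehh_walk(haps: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """EHH at each successive site in ``cols`` (outward order), plus leading 1."""
    n = haps.shape[0]
    pairs = n * (n - 1) / 2
    ehh = np.empty(len(cols) + 1)
    ehh[0] = 1.0
    group = np.zeros(n, dtype=np.int64)
    for k, c in enumerate(cols):
        key = group * 2 + haps[:, c]
        _, group, counts = np.unique(key, return_inverse=True,
                                     return_counts=True)
        ehh[k + 1] = (counts * (counts - 1)).sum() / 2 / pairs
    return ehh


def ehh(panel: HaplotypePanel, focal: int, rows: np.ndarray | None = None,
        group: str = "all") -> EHHProfile:
    """Full EHH profile (both directions) for the given haplotype rows."""
    haps = panel.haplotypes if rows is None else panel.haplotypes[rows]
    if haps.shape[0] < 2:
        raise UndefinedEHH(f"class '{group}' has {haps.shape[0]} haplotypes")
    cm = panel.map_cM
    pos = panel.positions
    chrom = panel.sites["chrom"].to_numpy(object)
    on = np.flatnonzero(chrom == chrom[focal])
    right = on[on > focal]
    left = on[on < focal][::-1]
    ehh_r = _ehh_walk(haps, right)
    ehh_l = _ehh_walk(haps, left)
    d = np.concatenate([-(cm[focal] - cm[left][::-1]), [0.0],
                        cm[right] - cm[focal]])
    e = np.concatenate([ehh_l[1:][::-1], [1.0], ehh_r[1:]])
    p = np.concatenate([-(pos[focal] - pos[left][::-1]).astype(float), [0.0],
                        (pos[right] - pos[focal]).astype(float)])
    return EHHProfile(focal_site=focal, distances_cM=d, ehh_values=e,
                      positions_bp=p, group=group)


def ihh(profile: EHHProfile, cutoff: float = EHH_CUTOFF,
        max_gap_bp: int = MAX_GAP_BP, gap_scale_bp: int = GAP_SCALE_BP,
        ) -> float:
    """Integrated EHH (cM), both sides; NaN if a side never decays below cutoff.

    Trapezoids are taken between consecutive profile points while EHH
    stays >= cutoff; the sub-cutoff tail is excluded. A physical gap g
    between consecutive sites scales its trapezoid by gap_scale_bp/g
    when g > gap_scale_bp and truncates the side when g > max_gap_bp.
    """
    total = 0.0
    for direction in (-1, 1):
        dist, e, pos = profile.side(direction)
        decayed = False
        for k in range(1, len(e)):
            if e[k] < cutoff:
                decayed = True
                break
            gap = pos[k] - pos[k - 1]
            if gap > max_gap_bp:
                decayed = True  # selscan: oversized gap ends the integral
                break
            w = gap_scale_bp / gap if gap > gap_scale_bp else 1.0
            total += w * (e[k] + e[k - 1]) / 2 * (dist[k] - dist[k - 1])
        if not decayed:
            return float("nan")  # hit chromosome end above cutoff: unscored
    return total


def _ihh_side(haps: np.ndarray, cols, cm: np.ndarray,
              pos: np.ndarray, focal: int, cutoff: float, max_gap_bp: int,
              gap_scale_bp: int) -> float:
    """One-sided iHH by incremental outward walk; NaN if never decayed.

    Equivalent to ihh(ehh(...)) restricted to one side, but stops as
    soon as EHH drops below the cutoff — the hot path for whole-panel
    scans.
    """
    n = haps.shape[0]
    pairs = n * (n - 1) / 2
    group = np.zeros(n, dtype=np.int64)
    prev_e, prev_d, prev_p = 1.0, 0.0, pos[focal]
    total = 0.0
    for c in cols:
        key = group * 2 + haps[:, c]
        _, group, counts = np.unique(key, return_inverse=True,
                                     return_counts=True)
        e = (counts * (counts - 1)).sum() / 2 / pairs
        gap = abs(int(pos[c]) - int(prev_p))
        if e < cutoff or gap > max_gap_bp:
            return total
        d = abs(cm[c] - cm[focal])
        w = gap_scale_bp / gap if gap > gap_scale_bp else 1.0
        total += w * (e + prev_e) / 2 * (d - prev_d)
        prev_e, prev_d, prev_p = e, d, pos[c]
        if e == 0.0:
            return total
    return float("nan")


try:  # jitted EHH walk: same arithmetic as _ihh_side, ~50x faster
    from numba import njit

    @njit(cache=False)
    def _ihh_side_nb(haps, rows, start, stop, step, cm, pos, focal,
                     cutoff, max_gap_bp, gap_scale_bp):  # pragma: no cover
        n = rows.shape[0]
        pairs = n * (n - 1) / 2.0
        group = np.zeros(n, np.int64)
        n_groups = 1
        newid = np.empty(2 * n + 2, np.int64)
        prev_e, prev_d = 1.0, 0.0
        prev_p = pos[focal]
        total = 0.0
        for c in range(start, stop, step):
            for k in range(2 * n_groups):
                newid[k] = -1
            ng = 0
            for i in range(n):
                key = group[i] * 2 + haps[rows[i], c]
                if newid[key] == -1:
                    newid[key] = ng
                    ng += 1
                group[i] = newid[key]
            n_groups = ng
            ssum = 0.0
            counts = np.zeros(ng, np.int64)
            for i in range(n):
                counts[group[i]] += 1
            for g in range(ng):
                ssum += counts[g] * (counts[g] - 1)
            e = ssum / 2.0 / pairs
            gap = pos[c] - prev_p
            if gap < 0:
                gap = -gap
            if e < cutoff or gap > max_gap_bp:
                return total
            d = cm[c] - cm[focal]
            if d < 0:
                d = -d
            w = gap_scale_bp / gap if gap > gap_scale_bp else 1.0
            total += w * (e + prev_e) / 2.0 * (d - prev_d)
            prev_e, prev_d, prev_p = e, d, pos[c]
            if e == 0.0:
                return total
        return np.nan

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _ihh_site(haps: np.ndarray, rows, focal: int, lo: int, hi: int,
              cm: np.ndarray, pos: np.ndarray, cutoff: float,
              max_gap_bp: int, gap_scale_bp: int) -> float:
    """Two-sided iHH; lo/hi bound the focal chromosome's site indices."""
    if rows is None:
        rows = np.arange(haps.shape[0])
    if _HAVE_NUMBA:
        if not haps.flags.c_contiguous:
            haps = np.ascontiguousarray(haps)
        rows = np.asarray(rows, np.int64)
        a = _ihh_side_nb(haps, rows, focal + 1, hi + 1, 1, cm, pos,
                         focal, cutoff, max_gap_bp, gap_scale_bp)
        b = _ihh_side_nb(haps, rows, focal - 1, lo - 1, -1, cm, pos,
                         focal, cutoff, max_gap_bp, gap_scale_bp)
        return a + b
    sub = haps[rows]
    a = _ihh_side(sub, range(focal + 1, hi + 1), cm, pos, focal, cutoff,
                  max_gap_bp, gap_scale_bp)
    b = _ihh_side(sub, range(focal - 1, lo - 1, -1), cm, pos, focal, cutoff,
                  max_gap_bp, gap_scale_bp)
    return a + b


def _chrom_spans(sites: pd.DataFrame) -> list[tuple[int, int]]:
    """Per-site (first, last) site index of the site's chromosome."""
    chrom = sites["chrom"].to_numpy(object)
    spans = {}
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        spans[c] = (int(idx[0]), int(idx[-1]))
    return [spans[c] for c in chrom]


@dataclass
class SiteScore:
    site: int
    raw: float
    std: float
    derived_freq: float


def _scan_frame(panel: HaplotypePanel, records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records,
                      columns=["site", "chrom", "pos", "derived_freq", "raw"])
    return df


def ihs_scan(panel: HaplotypePanel, pop: str | None = None,
             maf_floor: float = MAF_FLOOR, cutoff: float = EHH_CUTOFF,
             max_gap_bp: int = MAX_GAP_BP, gap_scale_bp: int = GAP_SCALE_BP,
             ) -> pd.DataFrame:
    """Unstandardized iHS per site: ln(iHH_ancestral / iHH_derived).

    Sites are polarized by the ancestral column where known and by the
    REF-as-ancestral fallback otherwise. Sites with minor derived-class
    frequency below ``maf_floor``, an unscored side, or a zero iHH are
    skipped.
    """
    sub = panel if pop is None else panel.for_population(pop)
    derived, _ = sub.derived_haplotypes()
    freqs = derived.mean(axis=0)
    cm, positions = sub.map_cM, sub.positions
    spans = _chrom_spans(sub.sites)
    records = []
    chroms = sub.sites["chrom"].to_numpy(object)
    for j in range(derived.shape[1]):
        f = freqs[j]
        if min(f, 1 - f) < maf_floor:
            continue
        der_rows = np.flatnonzero(derived[:, j] == 1)
        anc_rows = np.flatnonzero(derived[:, j] == 0)
        if len(der_rows) < 2 or len(anc_rows) < 2:
            continue
        lo, hi = spans[j]
        ihh_d = _ihh_site(derived, der_rows, j, lo, hi, cm, positions,
                          cutoff, max_gap_bp, gap_scale_bp)
        ihh_a = _ihh_site(derived, anc_rows, j, lo, hi, cm, positions,
                          cutoff, max_gap_bp, gap_scale_bp)
        if not (np.isfinite(ihh_a) and np.isfinite(ihh_d)) \
                or ihh_a <= 0 or ihh_d <= 0:
            continue
        records.append({"site": j, "chrom": chroms[j], "pos": positions[j],
                        "derived_freq": f, "raw": np.log(ihh_a / ihh_d)})
    return _scan_frame(sub, records)


def ihs_raw(panel: HaplotypePanel, focal: int, pop: str | None = None,
            **kw) -> SiteScore:
    """iHS at a single site (convenience over ihs_scan internals)."""
    sub = panel if pop is None else panel.for_population(pop)
    derived, _ = sub.derived_haplotypes()
    dpanel = HaplotypePanel(sites=sub.sites, haplotypes=derived,
                            samples=sub.samples, popmap=sub.popmap)
    der_rows = np.flatnonzero(derived[:, focal] == 1)
    anc_rows = np.flatnonzero(derived[:, focal] == 0)
    ihh_d = ihh(ehh(dpanel, focal, der_rows, "derived"), **kw)
    ihh_a = ihh(ehh(dpanel, focal, anc_rows, "ancestral"), **kw)
    raw = np.log(ihh_a / ihh_d)
    return SiteScore(site=focal, raw=float(raw), std=float("nan"),
                     derived_freq=float(derived[:, focal].mean()))


def standardize_ihs(scores: pd.DataFrame, n_bins: int = N_BINS) -> pd.DataFrame:
    """Standardize raw scores within equal-width derived-frequency bins.

    Adds ``std`` = (raw - bin mean) / bin sd; sites in singleton or
    zero-variance bins get NaN.
    """
    out = scores.copy()
    edges = np.linspace(0, 1, n_bins + 1)
    bins = np.clip(np.digitize(out["derived_freq"], edges) - 1, 0, n_bins - 1)
    out["std"] = np.nan
    for b in np.unique(bins):
        m = bins == b
        vals = out.loc[m, "raw"]
        if len(vals) < 2:
            continue
        sd = vals.std(ddof=0)
        if sd == 0:
            continue
        out.loc[m, "std"] = (vals - vals.mean()) / sd
    return out


def xpehh_scan(panel: HaplotypePanel, pop_a: str, pop_b: str,
               cutoff: float = EHH_CUTOFF, max_gap_bp: int = MAX_GAP_BP,
               gap_scale_bp: int = GAP_SCALE_BP) -> pd.DataFrame:
    """Unstandardized XP-EHH per site: ln(iHH_A / iHH_B), all haplotypes.

    Sites must segregate in the pooled pair; unscored in either
    population -> skipped.
    """
    sub_a = panel.for_population(pop_a)
    sub_b = panel.for_population(pop_b)
    pooled_freq = (sub_a.haplotypes.sum(0) + sub_b.haplotypes.sum(0)) / (
        sub_a.n_haplotypes + sub_b.n_haplotypes)
    cm, positions = panel.map_cM, panel.positions
    spans = _chrom_spans(panel.sites)
    records = []
    chroms = panel.sites["chrom"].to_numpy(object)
    for j in range(panel.haplotypes.shape[1]):
        if pooled_freq[j] in (0.0, 1.0):
            continue
        lo, hi = spans[j]
        ihh_a = _ihh_site(sub_a.haplotypes, None, j, lo, hi, cm,
                          positions, cutoff, max_gap_bp, gap_scale_bp)
        ihh_b = _ihh_site(sub_b.haplotypes, None, j, lo, hi, cm,
                          positions, cutoff, max_gap_bp, gap_scale_bp)
        if not (np.isfinite(ihh_a) and np.isfinite(ihh_b)) \
                or ihh_a <= 0 or ihh_b <= 0:
            continue
        records.append({"site": j, "chrom": chroms[j], "pos": positions[j],
                        "derived_freq": pooled_freq[j],
                        "raw": np.log(ihh_a / ihh_b)})
    return _scan_frame(panel, records)


def standardize_xpehh(scores: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide single-bin standardization (selscan norm --xpehh)."""
    out = scores.copy()
    sd = out["raw"].std(ddof=0)
    out["std"] = np.nan if sd == 0 else (out["raw"] - out["raw"].mean()) / sd
    return out
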