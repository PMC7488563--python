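"""Allele-frequency statistics: per-site F_ST and a CLR sweep scan.

F_ST follows the heterozygosity-partition form

    F_ST = ( pbar(1-pbar) - sum_i c_i p_i (1-p_i) ) / ( pbar(1-pbar) )

with p_i the allele frequency in population i, c_i = n_i / sum_j n_j
the relative (non-missing) chromosome sample size, and
pbar = sum_i c_i p_i. Concavity of x(1-x) keeps the value in [0, 1];
sites monomorphic in the pool are undefined and excluded downstream.

The CLR scan is a SweepFinder-style composite likelihood ratio against
the genome-wide background site-frequency spectrum. At a test position
x with sweep intensity alpha, a site at recombination distance d
(Morgans; 1 Mb = 1 cM map) escapes the sweep with probability
p_e = 1 - exp(-alpha d). Its derived-count likelihood mixes the
background SFS (escaped) with a sweep-forced spectrum concentrating
mass on counts n-1 and 1 (hitchhiked lineages carry the swept
haplotype's allele; a single escaped lineage carries the other).
CLR(x) = 2 (max_alpha log CL - log CL_background), maximized over a
log-spaced alpha grid with the background-only model always included,
so CLR >= 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix, HaplotypePanel


@dataclass
class AlleleFreqTable:
    """Per-site per-population ALT frequencies with missing-aware counts."""

    chrom: np.ndarray
    pos: np.ndarray
    pops: list[str]
    p: np.ndarray        # (n_pops, n_sites) ALT frequency; NaN when no calls
    n: np.ndarray        # (n_pops, n_sites) non-missing allele counts

    def weights(self) -> np.ndarray:
        """c_i = n_i / sum_j n_j per site (NaN-safe)."""
        tot = self.n.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.n / tot, np.nan)

    def pooled(self) -> np.ndarray:
        c = self.weights()
        return np.nansum(c * self.p, axis=0)


def allele_frequencies(gm: GenotypeMatrix,
                       pops: list[str] | None = None) -> AlleleFreqTable:
    """ALT-allele frequency and allele count per population per site."""
    pops = pops or gm.populations
    n_sites = gm.n_sites
    p = np.full((len(pops), n_sites), np.nan)
    n = np.zeros((len(pops), n_sites))
    for k, pop in enumerate(pops):
        calls = gm.calls[gm.sample_indices(pop)]
        ok = calls != MISSING
        cnt = 2 * ok.sum(axis=0)
        alt = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(cnt > 0, alt / np.maximum(cnt, 1), np.nan)
        n[k] = cnt
    return AlleleFreqTable(chrom=gm.sites["chrom"].to_numpy(object),
                           pos=gm.sites["pos"].to_numpy(np.int64),
                           pops=pops, p=p, n=n)


def fst_sites(freqs: AlleleFreqTable) -> np.ndarray:
    """Per-site F_ST across all populations in the table; NaN where undefined."""
    c = freqs.weights()
    p = freqs.p
    pbar = np.nansum(c * p, axis=0)
    denom = pbar * (1 - pbar)
    within = np.nansum(c * p * (1 - p), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, (denom - within) / denom, np.nan)
    # a population with zero calls at a site leaves the site undefined
    fst = np.where(np.any(freqs.n == 0, axis=0), np.nan, fst)
    return fst


def fst_site(p: np.ndarray, c: np.ndarray) -> float:
    """F_ST for one site from frequencies p_i and weights c_i."""
    p = np.asarray(p, float)
    c = np.asarray(c, float)
    pbar = float((c * p).sum())
    denom = pbar * (1 - pbar)
    if denom <= 0:
        return float("nan")
    return float((denom - (c * p * (1 - p)).sum()) / denom)


def fst_scan(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Pairwise per-site F_ST between two populations as a tidy frame."""
    freqs = allele_frequencies(gm, [pop_a, pop_b])
    return pd.DataFrame({"chrom": freqs.chrom, "pos": freqs.pos,
                         "fst": fst_sites(freqs)})


@dataclass
class BackgroundSFS:
    """Unfolded background SFS over derived counts 1..n-1."""

    n: int
    prob: np.ndarray  # length n-1, index k-1 holds P(count = k)

    def __post_init__(self) -> None:
        if len(self.prob) != self.n - 1:
            raise ValueError("prob must cover counts 1..n-1")
        if not np.isclose(self.prob.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")


def background_sfs(panel: HaplotypePanel, pop: str | None = None,
                   ) -> tuple[BackgroundSFS, np.ndarray]:
    """Background SFS from polarized segregating sites of one population.

    Returns the SFS and the per-site derived counts (NaN at unusable
    sites: unpolarized, monomorphic).
    """
    sub = panel if pop is None else panel.for_population(pop)
    derived, polarized = sub.derived_haplotypes()
    n = derived.shape[0]
    counts = derived.sum(axis=0).astype(float)
    usable = polarized & (counts >= 1) & (counts <= n - 1)
    if not usable.any():
        raise ValueError("no polarized segregating sites")
    hist = np.bincount(counts[usable].astype(int), minlength=n)[1:n]
    sfs = BackgroundSFS(n=n, prob=hist / hist.sum())
    counts[~usable] = np.nan
    return sfs, counts


@dataclass
class CLRModel:
    """Sweep-intensity grid and scan geometry.

    The default alpha grid spans sweeps whose escape probability reaches
    1/2 between ~1 kb and ~10 Mb (on the 1 Mb = 1 cM map); sites beyond
    ``max_dist_bp`` of a test position contribute ~background to both
    hypotheses and are skipped.
    """

    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(np.log(2) / 0.1,
                                             np.log(2) / 1e-5, 40))
    window_bp: int = 50_000
    max_dist_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if np.any(self.alpha_grid <= 0) or np.any(np.diff(self.alpha_grid) <= 0):
            raise ValueError("alpha_grid must be positive and increasing")


def clr_scan(panel: HaplotypePanel, sfs: BackgroundSFS,
             counts: np.ndarray | None = None,
             model: CLRModel | None = None,
             pop: str | None = None) -> pd.DataFrame:
    """CLR at each 50-kb window centre.

    ``counts`` are per-site derived counts aligned to the panel's sites
    (from background_sfs); recomputed when omitted. Positions with no
    usable site within reach emit CLR = 0 with ``empty`` flagged.
    """
    sub = panel if pop is None else panel.for_population(pop)
    model = model or CLRModel()
    if counts is None:
        _, counts = background_sfs(sub)
    n = sfs.n
    bg = np.concatenate([[np.nan], sfs.prob, [np.nan]])  # index by count
    w_high = float(np.sum(sfs.prob * np.arange(1, n) / n))
    forced = np.zeros(n + 1)
    forced[n - 1] = w_high
    forced[1] = 1 - w_high

    pos_all = sub.positions
    chrom_all = sub.sites["chrom"].to_numpy(object)
    rows = []
    alphas = model.alpha_grid[:, None]
    for chrom in pd.unique(chrom_all):
        on = np.flatnonzero(chrom_all == chrom)
        ok = on[np.isfinite(counts[on])]
        pos = pos_all[ok]
        k = counts[ok].astype(int)
        last = pos_all[on].max()
        centres = np.arange(model.window_bp // 2, last + 1, model.window_bp)
        for x in centres:
            near = (pos >= x - model.max_dist_bp) & (pos <= x + model.max_dist_bp)
            if not near.any():
                rows.append({"chrom": chrom, "pos": int(x), "clr": 0.0,
                             "alpha": np.nan, "empty": True})
                continue
            d = np.abs(pos[near] - x) / 1e8  # bp -> Morgans via 1 Mb = 1 cM
            kj = k[near]
            p_esc = np.clip(1 - np.exp(-alphas * d[None, :]), 1e-12, 1.0)
            lik = p_esc * bg[kj][None, :] + (1 - p_esc) * forced[kj][None, :]
            ll = np.log(np.maximum(lik, 1e-300)).sum(axis=1)
            ll0 = np.log(bg[kj]).sum()
            best = int(np.argmax(ll))
            clr = max(0.0, 2 * (ll[best] - ll0))
            rows.append({"chrom": chrom, "pos": int(x), "clr": float(clr),
                         "alpha": float(model.alpha_grid[best]),
                         "empty": False})
    return pd.DataFrame(rows, columns=["chrom", "pos", "clr", "alpha", "empty"])
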