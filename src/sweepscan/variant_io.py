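"""Genotype/haplotype containers, VCF I/O and the hard-filter scheme.

Internal coordinates are 0-based half-open; VCF is converted at the
boundary (VCF POS is 1-based). Genotypes count ALT alleles (0/1/2) with
-1 for missing. Haplotypes are coded 1 = ALT; polarization to
ancestral/derived happens via the per-site ``ancestral`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

#: caller annotation columns subject to two-sided quantile filtering
RANKSUM_COLS = ("BaseQRankSum", "MQRankSum", "ReadPosRankSum", "DP")
ANNOTATION_COLS = ("FS", "MQ") + RANKSUM_COLS

SITE_COLS = ["chrom", "pos", "ref", "alt", "ancestral"]


class PopmapError(ValueError):
    """A sample in the VCF has no population assignment."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for samples x biallelic SNP sites.

    ``sites`` holds chrom/pos/ref/alt/ancestral plus any caller
    annotation columns; ``calls`` is an int8 array (n_samples, n_sites)
    of ALT-allele counts with -1 = missing.
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    popmap: dict[str, str]

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        missing_pop = [s for s in self.samples if s not in self.popmap]
        if missing_pop:
            raise PopmapError(f"samples without population: {missing_pop}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.popmap[s], None)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.popmap[s] == pop],
            dtype=int,
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            calls=self.calls[:, index],
            popmap=dict(self.popmap),
        )

    def for_population(self, pop: str) -> "GenotypeMatrix":
        idx = self.sample_indices(pop)
        return GenotypeMatrix(
            sites=self.sites,
            samples=[self.samples[i] for i in idx],
            calls=self.calls[idx],
            popmap=dict(self.popmap),
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (2n x sites); rows 2i, 2i+1 belong to sample i.

    ``map_cM`` follows the physical map unless a ``cM`` column is present
    in ``sites``: 1 Mb = 1 cM.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    samples: list[str]
    popmap: dict[str, str]
    phased: bool = True

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype count must be 2 x sample count")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("haplotype width inconsistent with sites")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def map_cM(self) -> np.ndarray:
        if "cM" in self.sites.columns:
            return self.sites["cM"].to_numpy(float)
        return self.sites["pos"].to_numpy(float) / 1e6

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy(np.int64)

    def haplotype_indices(self, pop: str) -> np.ndarray:
        rows = []
        for i, s in enumerate(self.samples):
            if self.popmap[s] == pop:
                rows.extend((2 * i, 2 * i + 1))
        return np.array(rows, dtype=int)

    def for_population(self, pop: str) -> "HaplotypePanel":
        rows = self.haplotype_indices(pop)
        return HaplotypePanel(
            sites=self.sites,
            haplotypes=self.haplotypes[rows],
            samples=[s for s in self.samples if self.popmap[s] == pop],
            popmap=dict(self.popmap),
            phased=self.phased,
        )

    def derived_haplotypes(self) -> tuple[np.ndarray, np.ndarray]:
        """Polarized copy (1 = derived) and the polarized-site mask.

        Sites whose ancestral allele is unknown keep the 1 = ALT coding
        (REF-as-ancestral fallback) and are flagged False in the mask.
        """
        anc = self.sites["ancestral"].to_numpy(object)
        ref = self.sites["ref"].to_numpy(object)
        alt = self.sites["alt"].to_numpy(object)
        polarized = (anc == ref) | (anc == alt)
        flip = anc == alt
        out = self.haplotypes.copy()
        out[:, flip] = 1 - out[:, flip]
        return out, polarized

    def to_genotypes(self) -> GenotypeMatrix:
        h = self.haplotypes
        calls = (h[0::2].astype(np.int8) + h[1::2].astype(np.int8))
        return GenotypeMatrix(
            sites=self.sites, samples=list(self.samples), calls=calls,
            popmap=dict(self.popmap),
        )


@dataclass
class FilterConfig:
    """Quantile-based hard-filter configuration.

    Thresholds are realized as empirical quantiles of the data at hand:
    FS drops the upper ``1 - fs_upper_q`` tail; each rank-sum statistic
    and DP drop ``ranksum_tail_q`` from both tails; MQ uses a fixed
    floor (strictly-below removed).
    """

    fs_upper_q: float = 0.95
    ranksum_tail_q: float = 0.025
    mq_min: float = 30.0
    cluster_max_snps: int = 5
    cluster_window_bp: int = 20

    def __post_init__(self) -> None:
        if not (0.5 < self.fs_upper_q < 1):
            raise ValueError("fs_upper_q must lie in (0.5, 1)")
        if not (0 < self.ranksum_tail_q < 0.5):
            raise ValueError("ranksum_tail_q must lie in (0, 0.5)")
        if self.cluster_window_bp <= 0:
            raise ValueError("cluster_window_bp must be positive")


@dataclass
class FilterReport:
    """Per-filter realized thresholds and removal counts."""

    rows: list[dict] = field(default_factory=list)

    def add(self, name: str, threshold, removed: int, note: str = "") -> None:
        self.rows.append(
            {"filter": name, "threshold": threshold, "removed": removed,
             "note": note}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["filter", "threshold", "removed", "note"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_popmap(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["pop"]))


def write_popmap(popmap: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.items():
            fh.write(f"{s}\t{p}\n")


def _is_snp(ref: str, alts: tuple[str, ...]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref != alts[0]
        and ref in "ACGT"
        and alts[0] in "ACGT"
    )


def read_vcf(path, popmap_path=None, popmap: dict[str, str] | None = None,
             ancestral: dict[tuple[str, int], str] | None = None,
             ) -> tuple[GenotypeMatrix, HaplotypePanel | None]:
    """Read a VCF into a GenotypeMatrix (+ HaplotypePanel when fully phased).

    Multi-allelic sites and indels are dropped (counts logged). INFO
    fields FS/MQ/rank-sums/DP become annotation columns where present.
    ``ancestral`` optionally maps (chrom, 1-based pos) -> ancestral base;
    the VCF INFO field ``AA`` is honoured otherwise.
    """
    from cyvcf2 import VCF

    if popmap is None:
        if popmap_path is None:
            raise ValueError("either popmap_path or popmap is required")
        popmap = read_popmap(popmap_path)

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing_pop = [s for s in samples if s not in popmap]
    if missing_pop:
        raise PopmapError(f"popmap lacks entries for samples: {missing_pop}")

    rows, call_rows, hap_rows = [], [], []
    n_multi = n_indel = 0
    all_phased = True
    last_key: tuple[str, int] | None = None
    for v in vcf:
        alts = tuple(v.ALT)
        if len(alts) > 1:
            n_multi += 1
            continue
        if not _is_snp(v.REF, alts):
            n_indel += 1
            continue
        key = (v.CHROM, v.POS)
        if last_key is not None and key[0] == last_key[0] and key[1] <= last_key[1]:
            raise ValueError(f"VCF not position-sorted at {key[0]}:{key[1]}")
        last_key = key
        anc = None
        if ancestral is not None:
            anc = ancestral.get((v.CHROM, v.POS))
        if anc is None:
            aa = v.INFO.get("AA")
            anc = aa if isinstance(aa, str) else None
        row = {"chrom": v.CHROM, "pos": v.POS - 1, "ref": v.REF,
               "alt": alts[0], "ancestral": anc}
        for k in ANNOTATION_COLS:
            val = v.INFO.get(k)
            if val is not None:
                row[k] = float(val)
        rows.append(row)
        gt = np.asarray(v.genotype.array())
        a, b = gt[:, 0], gt[:, 1]
        calls = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        call_rows.append(calls)
        phased_here = bool(np.all(gt[:, 2] > 0)) and not np.any((a < 0) | (b < 0))
        all_phased = all_phased and phased_here
        hap_rows.append(np.column_stack([a, b]).reshape(-1))

    if n_multi or n_indel:
        log.info("read_vcf: dropped %d multi-allelic and %d indel records",
                 n_multi, n_indel)
    sites = pd.DataFrame(rows)
    for c in SITE_COLS:
        if c not in sites.columns:
            sites[c] = pd.Series(dtype=object)
    calls = (np.array(call_rows, dtype=np.int8).T if call_rows
             else np.zeros((len(samples), 0), np.int8))
    gm = GenotypeMatrix(sites=sites, samples=samples, calls=calls,
                        popmap=popmap)
    panel = None
    if all_phased and call_rows:
        haps = np.array(hap_rows, dtype=np.uint8).T
        panel = HaplotypePanel(sites=sites, haplotypes=haps, samples=samples,
                               popmap=popmap, phased=True)
    return gm, panel


def write_vcf(obj: GenotypeMatrix | HaplotypePanel, path) -> None:
    """Write an uncompressed VCF 4.2; phased ``a|b`` for panels, ``a/b`` else."""
    panel = obj if isinstance(obj, HaplotypePanel) else None
    gm = panel.to_genotypes() if panel is not None else obj
    sites = gm.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        for k in ANNOTATION_COLS:
            if k in sites.columns:
                fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sites["chrom"].unique():
            ln = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 2
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        anns = [k for k in ANNOTATION_COLS if k in sites.columns]
        for j in range(gm.n_sites):
            row = sites.iloc[j]
            info = []
            if isinstance(row["ancestral"], str):
                info.append(f"AA={row['ancestral']}")
            for k in anns:
                v = row[k]
                if pd.notna(v):
                    info.append(f"{k}={v:g}")
            if panel is not None:
                h = panel.haplotypes[:, j]
                gts = [f"{h[2*i]}|{h[2*i+1]}" for i in range(len(gm.samples))]
            else:
                enc = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [enc[int(c)] for c in gm.calls[:, j]]
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t.\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t{';'.join(info) or '.'}\tGT\t"
                + "\t".join(gts) + "\n"
            )


def apply_hard_filters(gm: GenotypeMatrix, cfg: FilterConfig | None = None,
                       thresholds: dict | None = None,
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Outlier-quantile hard filtering on caller annotation columns.

    Thresholds are empirical quantiles of the input unless ``thresholds``
    (a prior report's realized cut-offs) is supplied — passing them back
    makes the operation idempotent. Removal is strict: a site is dropped
    when its statistic is strictly beyond the cut. Sites lacking an
    annotation are exempt from that filter.
    """
    cfg = cfg or FilterConfig()
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport()
    keep = np.ones(gm.n_sites, dtype=bool)
    thresholds = dict(thresholds or {})

    def col(name: str) -> np.ndarray | None:
        if name not in gm.sites.columns:
            return None
        return gm.sites[name].to_numpy(float)

    fs = col("FS")
    if fs is None or np.all(np.isnan(fs)):
        report.add("FS", None, 0, "column absent or all-missing; skipped")
    else:
        hi = thresholds.get("FS", float(np.nanquantile(fs, cfg.fs_upper_q)))
        thresholds["FS"] = hi
        bad = np.nan_to_num(fs, nan=-np.inf) > hi
        report.add("FS", hi, int((bad & keep).sum()))
        keep &= ~bad

    for name in RANKSUM_COLS:
        x = col(name)
        if x is None or np.all(np.isnan(x)):
            report.add(name, None, 0, "column absent or all-missing; skipped")
            continue
        lo, hi = thresholds.get(name) or (
            float(np.nanquantile(x, cfg.ranksum_tail_q)),
            float(np.nanquantile(x, 1 - cfg.ranksum_tail_q)),
        )
        thresholds[name] = (lo, hi)
        with np.errstate(invalid="ignore"):
            bad = (x < lo) | (x > hi)
        bad &= ~np.isnan(x)
        report.add(name, (lo, hi), int((bad & keep).sum()))
        keep &= ~bad

    mq = col("MQ")
    if mq is None or np.all(np.isnan(mq)):
        report.add("MQ", None, 0, "column absent or all-missing; skipped")
    else:
        bad = np.nan_to_num(mq, nan=np.inf) < cfg.mq_min
        report.add("MQ", cfg.mq_min, int((bad & keep).sum()))
        keep &= ~bad

    out = gm.take_sites(np.flatnonzero(keep))
    report.thresholds = thresholds  # realized cuts, reusable for idempotence
    return out, report


def clustered_snp_mask(pos: np.ndarray, max_snps: int = 5,
                       window_bp: int = 20) -> np.ndarray:
    """True for every SNP inside some ``window_bp`` span with > max_snps SNPs.

    A span of ``window_bp`` holds positions p..p+window_bp-1 inclusive.
    """
    n = len(pos)
    bad = np.zeros(n, dtype=bool)
    # right[i]: last index within the window starting at pos[i]
    right = np.searchsorted(pos, pos + window_bp, side="left") - 1
    for i in range(n):
        if right[i] - i + 1 > max_snps:
            bad[i:right[i] + 1] = True
    return bad


def filter_clustered_snps(gm: GenotypeMatrix, max_snps: int = 5,
                          window_bp: int = 20) -> GenotypeMatrix:
    """Remove SNP clusters: any SNP in a ``window_bp`` span of > max_snps SNPs."""
    keep = np.ones(gm.n_sites, dtype=bool)
    sites = gm.sites
    for chrom in sites["chrom"].unique():
        idx = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        pos = sites["pos"].to_numpy(np.int64)[idx]
        bad = clustered_snp_mask(pos, max_snps, window_bp)
        keep[idx[bad]] = False
    return gm.take_sites(np.flatnonzero(keep))


def genotype_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype columns, missing-aware."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0  # monomorphic: correlation undefined, treated as 0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.1, window_snps: int = 50,
             step: int = 5) -> np.ndarray:
    """Greedy LD pruning; returns retained site indices.

    Within each ``window_snps`` window (advancing by ``step``), any pair
    with genotype r² > ``r2_max`` loses its later-positioned member.
    """
    sites = gm.sites
    keep = np.ones(gm.n_sites, dtype=bool)
    for chrom in sites["chrom"].unique():
        idx = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        start = 0
        while start < len(idx):
            window = [j for j in idx[start:start + window_snps] if keep[j]]
            changed = True
            while changed:
                changed = False
                for ai in range(len(window)):
                    for bi in range(ai + 1, len(window)):
                        a, b = window[ai], window[bi]
                        if genotype_r2(gm.calls[:, a], gm.calls[:, b]) > r2_max:
                            keep[b] = False  # later-positioned SNP removed
                            window.pop(bi)
                            changed = True
                            break
                    if changed:
                        break
            if start + window_snps >= len(idx):
                break
            start += step
    return np.flatnonzero(keep)
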