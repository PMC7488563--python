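"""End-to-end orchestration: within/cross sweep scans, ROH, structure.

``run_within`` composes per-population CLR and |iHS| columns into one
within-population DCMS; ``run_cross`` composes per-pair F_ST and
|XP-EHH| columns into one cross-population DCMS; ``run_roh`` produces
F_ROH, hotspots, and the hotspot x sweep intersection. Each run is
deterministic given its inputs and records a manifest of parameters.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import dcms as dcms_mod
from . import hapstats, regions, roh as roh_mod, sfs, structure
from .simulate import SimConfig, simulate
from .variant_io import GenotypeMatrix, HaplotypePanel

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    window_bp: int = 50_000
    top_fraction: float = 0.01
    roh_params: roh_mod.ROHParams = field(default_factory=roh_mod.ROHParams)
    l_gen_bp: int | None = None   # None: inferred from the data span
    use_clr: bool = True
    use_ihs: bool = True
    use_fst: bool = True
    use_xpehh: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction < 1):
            raise ValueError("top_fraction must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class ScanRun:
    """Result bundle of a within- or cross-population DCMS run."""

    window_table: pd.DataFrame
    dcms: dcms_mod.DCMSResult
    regions: pd.DataFrame
    manifest: dict


def _manifest(cfg: RunConfig, mode: str, columns: list[str]) -> dict:
    payload = {"mode": mode, "columns": columns,
               "window_bp": cfg.window_bp, "top_fraction": cfg.top_fraction,
               "tail": "upper one-sided for every column", "seed": cfg.seed}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
    return payload


def run_within(panel: HaplotypePanel, cfg: RunConfig | None = None) -> ScanRun:
    """Per-population {CLR, |iHS|} columns -> one within-population DCMS."""
    cfg = cfg or RunConfig()
    pops = panel.to_genotypes().populations
    columns: dict[str, pd.DataFrame] = {}
    for pop in pops:
        sub = panel.for_population(pop)
        if cfg.use_clr:
            bg, counts = sfs.background_sfs(sub)
            clr = sfs.clr_scan(sub, bg, counts,
                               sfs.CLRModel(window_bp=cfg.window_bp))
            clr = clr.rename(columns={"clr": "value"})
            clr["start"] = dcms_mod.window_index(clr["pos"].to_numpy(),
                                                 cfg.window_bp) * cfg.window_bp
            clr["end"] = clr["start"] + cfg.window_bp
            clr["support"] = 1
            columns[f"clr_{pop}"] = clr[["chrom", "start", "end", "value",
                                         "support"]]
        if cfg.use_ihs:
            scores = hapstats.standardize_ihs(hapstats.ihs_scan(sub))
            columns[f"ihs_{pop}"] = dcms_mod.window_average(
                scores.dropna(subset=["std"]), "std", cfg.window_bp,
                absolute=True)
    table = dcms_mod.build_window_table(columns, cfg.window_bp)
    result = dcms_mod.dcms_score(table, list(columns))
    result = dcms_mod.select_top(result, cfg.top_fraction)
    regs = dcms_mod.merge_regions(result, source="within")
    return ScanRun(window_table=table, dcms=result, regions=regs,
                   manifest=_manifest(cfg, "within", list(columns)))


def run_cross(panel: HaplotypePanel, cfg: RunConfig | None = None) -> ScanRun:
    """Per-pair {F_ST, |XP-EHH|} columns -> one cross-population DCMS."""
    cfg = cfg or RunConfig()
    gm = panel.to_genotypes()
    pops = gm.populations
    columns: dict[str, pd.DataFrame] = {}
    for a, b in itertools.combinations(pops, 2):
        tag = f"{a}_{b}"
        if cfg.use_fst:
            per_site = sfs.fst_scan(gm, a, b)
            columns[f"fst_{tag}"] = dcms_mod.window_average(
                per_site, "fst", cfg.window_bp)
        if cfg.use_xpehh:
            scores = hapstats.standardize_xpehh(
                hapstats.xpehh_scan(panel, a, b))
            columns[f"xpehh_{tag}"] = dcms_mod.window_average(
                scores.dropna(subset=["std"]), "std", cfg.window_bp,
                absolute=True)
    table = dcms_mod.build_window_table(columns, cfg.window_bp)
    result = dcms_mod.dcms_score(table, list(columns))
    result = dcms_mod.select_top(result, cfg.top_fraction)
    regs = dcms_mod.merge_regions(result, source="cross")
    return ScanRun(window_table=table, dcms=result, regions=regs,
                   manifest=_manifest(cfg, "cross", list(columns)))


@dataclass
class RohRun:
    segments: pd.DataFrame
    froh: pd.DataFrame
    summary: pd.DataFrame
    hotspots: pd.DataFrame
    intersections: pd.DataFrame | None
    manifest: dict


def run_roh(gm: GenotypeMatrix, cfg: RunConfig | None = None,
            sweep_regions: pd.DataFrame | None = None) -> RohRun:
    """ROH -> F_ROH -> per-population summary -> hotspots (-> x sweeps)."""
    cfg = cfg or RunConfig()
    segments = roh_mod.detect_roh(gm, cfg.roh_params)
    l_gen = cfg.l_gen_bp
    if l_gen is None:
        span = gm.sites.groupby("chrom")["pos"].agg(["min", "max"])
        l_gen = int((span["max"] - span["min"] + 1).sum())
    table = roh_mod.froh(segments, gm.samples, l_gen)
    summary = roh_mod.froh_summary(table, gm.popmap)
    hotspots = roh_mod.roh_hotspots(segments, {s: gm.popmap[s]
                                               for s in gm.samples})
    inter = None
    if sweep_regions is not None:
        inter = regions.intersect_sweeps_hotspots(sweep_regions, hotspots)
    manifest = {"l_gen_bp": l_gen, "roh_params": asdict(cfg.roh_params)}
    return RohRun(segments=segments, froh=table, summary=summary,
                  hotspots=hotspots, intersections=inter, manifest=manifest)


def demo(out_dir: str | Path, seed: int = 0,
         n_chroms: int = 2, chrom_bp: int = 5_000_000) -> dict:
    """Small end-to-end run on simulated data; writes all stage outputs.

    Simulates two populations with one sweep (in POP1) and elevated
    autozygosity in POP2, runs the within and cross scans, ROH and
    structure stages, and writes TSV/BED/JSON artifacts into out_dir.
    """
    from .simulate import RohSpec, SweepSpec

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(
        n_pops=2, n_per_pop=24,
        chrom_lengths=[chrom_bp] * n_chroms,
        fst_target=0.05, seed=seed,
        sweep_specs=[SweepSpec("POP1", "chr1", chrom_bp // 2)],
        roh_specs=[RohSpec("POP2", target_fraction=0.10)],
    )
    panel, gm, truth = simulate(cfg)
    rcfg = RunConfig(seed=seed)
    within = run_within(panel, rcfg)
    cross = run_cross(panel, rcfg)
    sweeps = pd.concat([within.regions, cross.regions], ignore_index=True)
    rohrun = run_roh(gm, rcfg, sweep_regions=sweeps)
    pc = structure.pca(gm)
    am = structure.amova(gm, n_perm=200, seed=seed)

    within.window_table.to_csv(out / "within_windows.tsv", sep="\t",
                               index=False)
    within.dcms.table.to_csv(out / "within_dcms.tsv", sep="\t", index=False)
    regions.write_bed(within.regions.assign(
        name=lambda d: "within_" + d.index.astype(str)),
        out / "within_regions.bed")
    cross.dcms.table.to_csv(out / "cross_dcms.tsv", sep="\t", index=False)
    regions.write_bed(cross.regions.assign(
        name=lambda d: "cross_" + d.index.astype(str)),
        out / "cross_regions.bed")
    dcms_mod.plot_manhattan(within.dcms, out / "within_manhattan.png",
                            "within-population DCMS")
    dcms_mod.plot_manhattan(cross.dcms, out / "cross_manhattan.png",
                            "cross-population DCMS")
    rohrun.segments.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    rohrun.froh.to_csv(out / "froh.tsv", sep="\t", index=False)
    rohrun.summary.to_csv(out / "froh_summary.tsv", sep="\t", index=False)
    rohrun.hotspots.to_csv(out / "roh_hotspots.tsv", sep="\t", index=False)
    if rohrun.intersections is not None:
        rohrun.intersections.to_csv(out / "sweep_x_hotspot.tsv", sep="\t",
                                    index=False)
    summary = {
        "seed": seed,
        "n_sites": int(gm.n_sites),
        "n_within_regions": int(len(within.regions)),
        "n_cross_regions": int(len(cross.regions)),
        "truth_sweep_window": truth.sweep_windows.iloc[0][
            ["chrom", "start", "end"]].to_dict(),
        "froh_mean_pop2": float(
            rohrun.summary.set_index("pop").loc["POP2", "mean"]),
        "pca_var12_pct": float(100 * pc.variance_explained[:2].sum()),
        "amova_phi_st": float(am.phi_st),
        "amova_p": float(am.p_value),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump({**summary, "within": within.manifest,
                   "cross": cross.manifest, "roh": rohrun.manifest}, fh,
                  indent=2)
    return summary
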