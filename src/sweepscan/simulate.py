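"""Synthetic multi-population phased genotypes with known ground truth.

The generator emulates a small re-sequencing study design: a handful of
populations of ~12-25 diploids genotyped at biallelic SNPs on one or
more chromosomes with a uniform 1 Mb = 1 cM map. Population divergence
follows the Balding-Nichols model: each site draws an ancestral allele
frequency p, and each population draws its own frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F), giving E[F_ST] ~ F. The baseline is
linkage equilibrium; haplotype structure enters only through injected
sweeps (a shared long core haplotype plus a frequency lift at the
focal site) and injected autozygous tracts, which is exactly the pair
of signals the downstream scan statistics respond to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, HaplotypePanel

BASES = np.array(list("ACGT"))


@dataclass
class SweepSpec:
    """A hard sweep: frequency lift + shared core haplotype.

    core_halflength_bp is the mean one-sided extent of the copied core;
    each carrier haplotype draws its own geometric extent per side.
    """

    population: str
    chrom: str
    position: int
    final_derived_freq: float = 0.95
    core_halflength_bp: int = 200_000

    def __post_init__(self) -> None:
        if not (0 <= self.final_derived_freq <= 1):
            raise ValueError("final_derived_freq must lie in [0, 1]")


@dataclass
class RohSpec:
    """Per-individual autozygosity target for one population.

    Tract lengths are min_tract_bp plus an exponential remainder (mean
    tract_mean_bp overall); the floor matches the 500-kb minimum of the
    ROH definition so every ground-truth tract is in principle
    detectable.
    """

    population: str
    target_fraction: float = 0.10
    tract_mean_bp: int = 2_000_000
    min_tract_bp: int = 500_000

    def __post_init__(self) -> None:
        if not (0 <= self.target_fraction < 1):
            raise ValueError("target_fraction must lie in [0, 1)")
        if self.tract_mean_bp < self.min_tract_bp:
            raise ValueError("tract_mean_bp must be >= min_tract_bp")


@dataclass
class SimConfig:
    n_pops: int = 2
    n_per_pop: int = 24
    chrom_lengths: list[int] = field(default_factory=lambda: [10_000_000])
    snp_density: float = 1 / 1000
    fst_target: float = 0.05
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    roh_specs: list[RohSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fst_target < 1):
            raise ValueError("fst_target must lie in (0, 1)")

    @property
    def pop_names(self) -> list[str]:
        return [f"POP{i + 1}" for i in range(self.n_pops)]

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths))


@dataclass
class Truth:
    """Ground truth carried alongside simulated data."""

    sweep_windows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["population", "chrom", "start", "end", "position"]))
    autozygous_tracts: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample", "chrom", "start", "end"]))


def _simulate_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c, length in enumerate(cfg.chrom_lengths):
        n = int(round(length * cfg.snp_density))
        pos = np.sort(rng.choice(length, size=n, replace=False))
        chrom = f"chr{c + 1}"
        for p in pos:
            rows.append((chrom, int(p)))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    n = len(df)
    anc_idx = rng.integers(0, 4, n)
    der_off = rng.integers(1, 4, n)
    anc = BASES[anc_idx]
    der = BASES[(anc_idx + der_off) % 4]
    # ~30% of sites list the derived base as REF so polarization is exercised
    derived_is_ref = rng.random(n) < 0.3
    df["ref"] = np.where(derived_is_ref, der, anc)
    df["alt"] = np.where(derived_is_ref, anc, der)
    df["ancestral"] = anc
    return df


def simulate_neutral(cfg: SimConfig,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[HaplotypePanel, GenotypeMatrix, Truth]:
    """Balding-Nichols neutral baseline: per-site independent haplotypes.

    Deterministic under cfg.seed (or an explicit generator).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sites = _simulate_sites(cfg, rng)
    n_sites = len(sites)
    p_anc = rng.uniform(0.05, 0.95, n_sites)
    F = cfg.fst_target
    a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F

    samples, popmap, hap_blocks = [], {}, []
    for pop in cfg.pop_names:
        p_pop = rng.beta(a, b)
        haps = (rng.random((2 * cfg.n_per_pop, n_sites)) < p_pop).astype(np.uint8)
        hap_blocks.append(haps)
        for i in range(cfg.n_per_pop):
            s = f"{pop}_{i + 1:02d}"
            samples.append(s)
            popmap[s] = pop

    derived = np.vstack(hap_blocks)
    # haplotypes are coded 1 = ALT; flip where the derived base is REF
    flip = (sites["ancestral"] == sites["alt"]).to_numpy()
    haps = derived.copy()
    haps[:, flip] = 1 - haps[:, flip]
    panel = HaplotypePanel(sites=sites, haplotypes=haps, samples=samples,
                           popmap=popmap, phased=True)
    return panel, panel.to_genotypes(), Truth()


def inject_sweep(panel: HaplotypePanel, spec: SweepSpec,
                 rng: np.random.Generator,
                 window_bp: int = 50_000) -> tuple[HaplotypePanel, Truth]:
    """Inject a hard sweep into one population of the panel (in place).

    The favoured allele is the derived allele at the SNP nearest
    spec.position. Its frequency in the target population is lifted to
    final_derived_freq by recruiting random non-carriers; then one
    carrier haplotype is chosen as the core and copied over every
    carrier across a geometric-length interval around the focal site
    (mean core_halflength_bp per side, memoryless like recombination
    breakpoints).
    """
    sites = panel.sites
    on_chrom = np.flatnonzero((sites["chrom"] == spec.chrom).to_numpy())
    if len(on_chrom) == 0:
        raise ValueError(f"no sites on {spec.chrom}")
    pos = sites["pos"].to_numpy(np.int64)
    focal = on_chrom[np.argmin(np.abs(pos[on_chrom] - spec.position))]
    rows = panel.haplotype_indices(spec.population)
    derived, _ = panel.derived_haplotypes()
    flip_focal = sites["ancestral"].iloc[focal] == sites["alt"].iloc[focal]

    carriers = rows[derived[rows, focal] == 1]
    non = rows[derived[rows, focal] == 0]
    if len(carriers) == 0 and len(non) == len(rows):
        # monomorphic-ancestral focal site: seed one carrier
        if spec.final_derived_freq == 0:
            raise ValueError("focal site monomorphic and no lift requested")
        seed_row = rng.choice(non)
        panel.haplotypes[seed_row, focal] ^= 1
        carriers = np.array([seed_row])
        non = non[non != seed_row]

    target_n = int(round(spec.final_derived_freq * len(rows)))
    n_new = target_n - len(carriers)
    if n_new > 0:
        recruits = rng.choice(non, size=min(n_new, len(non)), replace=False)
        alt_val = 0 if flip_focal else 1  # derived coded back to ALT space
        panel.haplotypes[recruits, focal] = alt_val
        carriers = np.concatenate([carriers, recruits])

    if spec.core_halflength_bp > 0 and len(carriers) > 1:
        core_row = rng.choice(carriers)
        core = panel.haplotypes[core_row].copy()
        chrom_pos = pos[on_chrom]
        focal_pos = pos[focal]
        for row in carriers:
            if row == core_row:
                continue
            left = rng.geometric(1.0 / max(spec.core_halflength_bp, 1))
            right = rng.geometric(1.0 / max(spec.core_halflength_bp, 1))
            sel = on_chrom[(chrom_pos >= focal_pos - left)
                           & (chrom_pos <= focal_pos + right)]
            panel.haplotypes[row, sel] = core[sel]

    start = (int(pos[focal]) // window_bp) * window_bp
    truth = Truth(sweep_windows=pd.DataFrame(
        [{"population": spec.population, "chrom": spec.chrom,
          "start": start, "end": start + window_bp,
          "position": int(pos[focal])}]))
    return panel, truth


def inject_autozygosity(panel: HaplotypePanel, spec: RohSpec,
                        rng: np.random.Generator,
                        chrom_lengths: dict[str, int],
                        max_retries: int = 1000) -> tuple[HaplotypePanel, Truth]:
    """Overwrite haplotype 2 with haplotype 1 inside random tracts.

    Tracts are exponential-length (mean tract_mean_bp), non-overlapping
    per individual, placed until the total length reaches
    target_fraction of the genome (within half a mean tract).
    """
    genome = sum(chrom_lengths.values())
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], float)
    weights /= weights.sum()
    pos = panel.sites["pos"].to_numpy(np.int64)
    site_chrom = panel.sites["chrom"].to_numpy(object)
    rows_truth = []
    target_bp = spec.target_fraction * genome
    for i, s in enumerate(panel.samples):
        if panel.popmap[s] != spec.population:
            continue
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        total = 0
        tries = 0
        min_tract = min(spec.min_tract_bp, max(int(target_bp), 1))
        while target_bp - total >= min_tract:
            tries += 1
            if tries > max_retries:
                raise RuntimeError(
                    f"could not place autozygous tracts for {s} "
                    f"(target {spec.target_fraction})")
            c = chroms[rng.choice(len(chroms), p=weights)]
            length = min_tract + int(rng.exponential(
                max(spec.tract_mean_bp - min_tract, 1)))
            # last tract is clipped so the total lands on the target
            length = min(length, chrom_lengths[c], int(target_bp - total))
            if length <= 0:
                break
            start = int(rng.integers(0, chrom_lengths[c] - length + 1))
            end = start + length
            if any(start < e and s0 < end for s0, e in placed[c]):
                continue
            placed[c].append((start, end))
            sel = np.flatnonzero((site_chrom == c) & (pos >= start) & (pos < end))
            panel.haplotypes[2 * i + 1, sel] = panel.haplotypes[2 * i, sel]
            total += length
            rows_truth.append({"sample": s, "chrom": c,
                               "start": start, "end": end})
    truth = Truth(autozygous_tracts=pd.DataFrame(
        rows_truth, columns=["sample", "chrom", "start", "end"]))
    return panel, truth


def simulate_annotation_table(n_sites: int, seed: int | np.random.Generator = 0,
                              ) -> pd.DataFrame:
    """Synthetic caller-annotation columns with realistic shapes.

    FS heavy-tailed positive (lognormal), rank sums ~normal, DP
    overdispersed (negative binomial), MQ a high-quality bulk with a
    low-quality tail.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fs = rng.lognormal(mean=0.5, sigma=1.0, size=n_sites)
    out = pd.DataFrame({
        "FS": fs,
        "BaseQRankSum": rng.normal(0, 1, n_sites),
        "MQRankSum": rng.normal(0, 0.8, n_sites),
        "ReadPosRankSum": rng.normal(0, 0.9, n_sites),
        "DP": rng.negative_binomial(12, 12 / (12 + 500), n_sites).astype(float),
        "MQ": np.where(rng.random(n_sites) < 0.05,
                       rng.normal(22, 5, n_sites),
                       rng.normal(55, 3, n_sites)),
    })
    return out


def simulate(cfg: SimConfig) -> tuple[HaplotypePanel, GenotypeMatrix, Truth]:
    """Full generator: neutral baseline + configured sweeps and tracts."""
    rng = np.random.default_rng(cfg.seed)
    panel, _, truth = simulate_neutral(cfg, rng)
    sweep_frames, tract_frames = [], []
    for spec in cfg.sweep_specs:
        panel, t = inject_sweep(panel, spec, rng)
        sweep_frames.append(t.sweep_windows)
    chrom_lengths = {f"chr{i + 1}": ln
                     for i, ln in enumerate(cfg.chrom_lengths)}
    for spec in cfg.roh_specs:
        panel, t = inject_autozygosity(panel, spec, rng, chrom_lengths)
        tract_frames.append(t.autozygous_tracts)
    if sweep_frames:
        truth.sweep_windows = pd.concat(sweep_frames, ignore_index=True)
    if tract_frames:
        truth.autozygous_tracts = pd.concat(tract_frames, ignore_index=True)
    return panel, panel.to_genotypes(), truth
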