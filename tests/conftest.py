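import numpy as np
import pandas as pd
import pytest

from sweepscan.variant_io import GenotypeMatrix, HaplotypePanel


def make_sites(pos, chrom="chr1", ref="A", alt="G", ancestral=None,
               **extra) -> pd.DataFrame:
    n = len(pos)
    df = pd.DataFrame({
        "chrom": [chrom] * n if isinstance(chrom, str) else list(chrom),
        "pos": list(pos),
        "ref": [ref] * n if isinstance(ref, str) else list(ref),
        "alt": [alt] * n if isinstance(alt, str) else list(alt),
    })
    if ancestral is None:
        df["ancestral"] = df["ref"]
    else:
        df["ancestral"] = ([ancestral] * n if isinstance(ancestral, str)
                           else list(ancestral))
    for k, v in extra.items():
        df[k] = v
    return df


def make_gm(calls, pos=None, popmap=None, **kw) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if pos is None:
        pos = np.arange(n_sites) * 1000
    samples = [f"S{i+1}" for i in range(n_samples)]
    if popmap is None:
        popmap = {s: "POP1" for s in samples}
    else:
        popmap = dict(zip(samples, popmap))
    return GenotypeMatrix(sites=make_sites(pos, **kw), samples=samples,
                          calls=calls, popmap=popmap)


def make_panel(haps, pos=None, popmap=None, **kw) -> HaplotypePanel:
    haps = np.asarray(haps, dtype=np.uint8)
    n_hap, n_sites = haps.shape
    assert n_hap % 2 == 0
    if pos is None:
        pos = np.arange(n_sites) * 1000
    samples = [f"S{i+1}" for i in range(n_hap // 2)]
    if popmap is None:
        popmap = {s: "POP1" for s in samples}
    else:
        popmap = dict(zip(samples, popmap))
    return HaplotypePanel(sites=make_sites(pos, **kw), haplotypes=haps,
                          samples=samples, popmap=popmap)


@pytest.fixture(scope="session")
def sweep_study():
    """One sweep simulation reused across haplotype-statistic tests."""
    from sweepscan.simulate import SimConfig, SweepSpec, simulate

    cfg = SimConfig(n_pops=2, n_per_pop=24, chrom_lengths=[5_000_000],
                    fst_target=0.05, seed=17,
                    sweep_specs=[SweepSpec("POP1", "chr1", 2_525_000)])
    panel, gm, truth = simulate(cfg)
    return panel, gm, truth
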