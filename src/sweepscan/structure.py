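"""Population-structure diagnostics: genotype PCA and one-level AMOVA.

PCA centers each site by its mean call and (optionally) scales by
sqrt(p(1-p)) with p the ALT frequency; missing calls are mean-imputed
per site; components come from the eigendecomposition of the sample
covariance, ordered by eigenvalue.

AMOVA partitions pairwise squared Euclidean distances over raw 0/1/2
genotype vectors into among- and within-population variance components
(Excoffier's sums-of-squares framework), yielding
Phi_ST = sigma2_among / (sigma2_among + sigma2_within). Significance is
a permutation test over random reassignments of samples to populations
of fixed sizes, with the add-one estimator so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variant_io import MISSING, GenotypeMatrix


@dataclass
class PCAResult:
    coordinates: np.ndarray        # samples x components
    variance_explained: np.ndarray


@dataclass
class AMOVAResult:
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    ss_among: float
    ss_within: float


def _imputed_dosage(gm: GenotypeMatrix) -> np.ndarray:
    x = gm.calls.astype(float)
    x[x == MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = mean[idx[1]]
    return x


def pca(gm: GenotypeMatrix, sites: np.ndarray | None = None,
        scale: bool = True, n_components: int | None = None) -> PCAResult:
    """Genotype PCA; monomorphic sites dropped, missing mean-imputed."""
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    x = _imputed_dosage(gm)
    if sites is not None:
        x = x[:, sites]
    mean = x.mean(axis=0)
    poly = x.std(axis=0) > 0
    x = x[:, poly] - mean[poly]
    if scale:
        p = mean[poly] / 2
        x = x / np.sqrt(p * (1 - p))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    ev = s ** 2
    total = ev.sum()
    k = n_components or len(ev)
    return PCAResult(coordinates=u[:, :k] * s[:k],
                     variance_explained=ev[:k] / total)


def _squared_euclidean(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distance over genotype vectors.

    With missing calls, each pair uses its complete sites rescaled to
    the full site count (pairwise-complete convention).
    """
    x = gm.calls.astype(float)
    x[x == MISSING] = np.nan
    n = gm.n_samples
    d2 = np.zeros((n, n))
    if not np.isnan(x).any():
        g = x @ x.T
        sq = np.diag(g)
        d2 = sq[:, None] + sq[None, :] - 2 * g
        return np.maximum(d2, 0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(x[i]) & ~np.isnan(x[j])
            diff = x[i, ok] - x[j, ok]
            d2[i, j] = d2[j, i] = (diff ** 2).sum() * x.shape[1] / ok.sum()
    return d2


def _phi_from_labels(d2: np.ndarray, labels: np.ndarray,
                     ) -> tuple[float, float, float, float, float]:
    """(phi, sigma2_a, sigma2_w, SS_a, SS_w) for one labelling."""
    N = len(labels)
    groups = np.unique(labels)
    k = len(groups)
    ss_total = d2.sum() / (2 * N)
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = labels == g
        n_g = int(idx.sum())
        sizes.append(n_g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * n_g)
    ss_among = ss_total - ss_within
    df_a, df_w = k - 1, N - k
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w
    sizes = np.array(sizes)
    n0 = (N - (sizes ** 2).sum() / N) / df_a
    sigma2_w = ms_w
    sigma2_a = (ms_a - ms_w) / n0
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom > 0 else float("nan")
    return phi, sigma2_a, sigma2_w, ss_among, ss_within


def amova(gm: GenotypeMatrix, n_perm: int = 1000,
          seed: int | np.random.Generator = 0) -> AMOVAResult:
    """One-level AMOVA with permutation significance.

    p = (1 + #{permuted Phi >= observed}) / (1 + n_perm).
    """
    labels = np.array([gm.popmap[s] for s in gm.samples])
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need >= 2 populations")
    if (counts < 2).any():
        raise ValueError("every population needs >= 2 samples")
    d2 = _squared_euclidean(gm)
    if d2.max() == 0:
        raise ValueError("zero total variance: all samples identical")
    phi, s2a, s2w, ss_a, ss_w = _phi_from_labels(d2, labels)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        p_phi = _phi_from_labels(d2, perm)[0]
        if p_phi >= phi:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return AMOVAResult(sigma2_among=s2a, sigma2_within=s2w, phi_st=phi,
                       p_value=p, n_permutations=n_perm,
                       ss_among=ss_a, ss_within=ss_w)
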