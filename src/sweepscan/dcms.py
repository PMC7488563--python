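"""Windowing, skew-normal empirical p-values, DCMS scores, region calling.

Per-site statistics are averaged in non-overlapping 50-kb windows
(|iHS| and |XP-EHH| are absolute-valued before averaging; CLR arrives
already on window centres). Each window column gets an upper-tail
empirical p-value from a maximum-likelihood three-parameter skew-normal
fit, and the de-correlated composite of multiple signals (DCMS) is

    DCMS_i = sum_s w_s * (-log10 p_{s,i}),   w_s = 1 / sum_t |r_{s,t}|

with r the Pearson correlation matrix of the -log10 p columns
(diagonal included). Sweep regions are the top 1% of windows by DCMS,
merged over bookended windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

WINDOW_BP = 50_000


def window_index(pos: np.ndarray, window_bp: int = WINDOW_BP) -> np.ndarray:
    return (np.asarray(pos) // window_bp).astype(np.int64)


def window_average(scores: pd.DataFrame, value_col: str,
                   window_bp: int = WINDOW_BP, absolute: bool = False,
                   ) -> pd.DataFrame:
    """Mean of a per-site statistic per 50-kb window.

    Returns chrom/start/end/value/support; NaN input values are excluded
    from both mean and support. ``absolute`` applies |.| before
    averaging (iHS, XP-EHH).
    """
    df = scores[["chrom", "pos", value_col]].copy()
    if absolute:
        df[value_col] = df[value_col].abs()
    df = df.dropna(subset=[value_col])
    df["start"] = window_index(df["pos"].to_numpy(), window_bp) * window_bp
    g = df.groupby(["chrom", "start"], sort=True)[value_col]
    out = g.agg(value="mean", support="size").reset_index()
    out["end"] = out["start"] + window_bp
    return out[["chrom", "start", "end", "value", "support"]]


def build_window_table(columns: dict[str, pd.DataFrame],
                       window_bp: int = WINDOW_BP) -> pd.DataFrame:
    """Outer-join window_average frames into one windows x statistics table."""
    merged: pd.DataFrame | None = None
    for name, frame in columns.items():
        f = frame.rename(columns={"value": name,
                                  "support": f"support_{name}"})
        merged = f if merged is None else merged.merge(
            f, on=["chrom", "start", "end"], how="outer")
    assert merged is not None, "no columns supplied"
    return merged.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class SkewNormalFit:
    """MLE skew-normal parameters for one statistic column."""

    shape: float      # alpha
    location: float   # xi
    scale: float      # omega
    converged: bool

    def sf(self, x: np.ndarray) -> np.ndarray:
        return stats.skewnorm.sf(x, self.shape, loc=self.location,
                                 scale=self.scale)


def _moment_start(x: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments skew-normal start values (skewness clipped to valid)."""
    g1 = float(np.clip(stats.skew(x), -0.92, 0.92))
    r = np.sign(g1) * (2 * np.abs(g1) / (4 - np.pi)) ** (1 / 3)
    delta = np.clip(r / np.sqrt(1 + r ** 2) * np.sqrt(np.pi / 2), -0.995, 0.995)
    alpha = delta / np.sqrt(1 - delta ** 2)
    omega = float(x.std() / np.sqrt(1 - 2 * delta ** 2 / np.pi))
    xi = float(x.mean() - omega * delta * np.sqrt(2 / np.pi))
    return float(alpha), xi, omega


def fit_skew_normal(values, min_windows: int = 50) -> SkewNormalFit:
    """Three-parameter skew-normal MLE with method-of-moments start.

    Falls back to the moment estimates (converged=False) if the MLE
    errors out or degenerates.
    """
    x = np.asarray(pd.Series(values).dropna(), float)
    if len(x) < min_windows:
        raise ValueError(f"need >= {min_windows} windows, got {len(x)}")
    if x.std() == 0:
        raise ValueError("zero variance")
    a0, xi0, om0 = _moment_start(x)
    # the likelihood is flat in alpha near 0, so a single start can
    # stall; run from the moment start and a normal (alpha=0) start and
    # keep the higher-likelihood solution
    starts = [(a0, xi0, om0), (0.0, float(x.mean()), float(x.std()))]
    best, best_ll = None, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a_s, xi_s, om_s in starts:
            try:
                a, loc, scale = stats.skewnorm.fit(x, a_s, loc=xi_s,
                                                   scale=om_s)
            except Exception:
                continue
            if not (np.isfinite([a, loc, scale]).all() and scale > 0):
                continue
            ll = stats.skewnorm.logpdf(x, a, loc, scale).sum()
            if ll > best_ll:
                best, best_ll = (a, loc, scale), ll
    if best is None:
        log.warning("skew-normal MLE failed; moment estimates used")
        return SkewNormalFit(shape=a0, location=xi0, scale=om0,
                             converged=False)
    return SkewNormalFit(shape=float(best[0]), location=float(best[1]),
                         scale=float(best[2]), converged=True)


def empirical_pvalues(fit: SkewNormalFit, values) -> np.ndarray:
    """Upper-tail p per window (large = sweep-like); floored above zero."""
    x = np.asarray(values, float)
    p = fit.sf(x)
    tiny = np.finfo(float).tiny
    with np.errstate(invalid="ignore"):
        p = np.where(np.isnan(x), np.nan, np.clip(p, tiny, 1.0))
    return p


@dataclass
class DCMSResult:
    """Window table + per-column p-values + weights + DCMS scores."""

    table: pd.DataFrame           # windows with p_<col> and dcms columns
    weights: pd.Series            # per statistic column
    fits: dict[str, SkewNormalFit]
    threshold: float | None = None

    @property
    def scores(self) -> pd.Series:
        return self.table["dcms"]


def dcms_from_pvalues(pvals: pd.DataFrame,
                      corr_method: str = "pearson",
                      ) -> tuple[np.ndarray, pd.Series]:
    """DCMS scores and de-correlation weights from a p-value table.

    Weights: w_s = 1 / sum_t |corr(-log10 p_s, -log10 p_t)| with the
    diagonal included. Rows missing some columns use the available ones
    with the weight total renormalized.
    """
    neglog = -np.log10(pvals.astype(float))
    r = neglog.corr(method=corr_method, min_periods=2).abs()
    w = 1.0 / r.sum(axis=1)
    mat = neglog.to_numpy()
    wv = w.to_numpy()
    have = ~np.isnan(mat)
    wsum = (have * wv).sum(axis=1)
    full = wv.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        dcms = np.where(have, mat, 0.0) @ wv * (full / wsum)
    dcms[wsum == 0] = np.nan
    return dcms, w


def dcms_score(window_table: pd.DataFrame, stat_cols: list[str],
               fits: dict[str, SkewNormalFit] | None = None,
               corr_method: str = "pearson") -> DCMSResult:
    """Compute p-values, de-correlation weights and the DCMS per window.

    Constant columns are dropped with a warning. Windows missing some
    columns use the available ones with weights renormalized (flagged
    in ``partial``).
    """
    table = window_table.copy()
    usable = []
    for c in stat_cols:
        vals = table[c]
        if vals.dropna().nunique() <= 1:
            log.warning("DCMS column %s is constant; dropped", c)
            continue
        usable.append(c)
    if not usable:
        raise ValueError("no usable statistic columns")
    fits = fits or {c: fit_skew_normal(table[c]) for c in usable}
    pvals = pd.DataFrame(index=table.index)
    for c in usable:
        p = empirical_pvalues(fits[c], table[c].to_numpy())
        table[f"p_{c}"] = p
        pvals[c] = p
    dcms, w = dcms_from_pvalues(pvals, corr_method)
    table["dcms"] = dcms
    table["partial"] = (~pvals.isna()).sum(axis=1) < len(usable)
    return DCMSResult(table=table, weights=w, fits=fits)


def select_top(result: DCMSResult, fraction: float = 0.01) -> DCMSResult:
    """Flag the top ``fraction`` of windows by DCMS.

    k = floor(fraction * n_scored); ties at the cutoff resolve by
    genomic order (earlier window kept), with a warning.
    """
    table = result.table
    scored = table["dcms"].notna()
    n = int(scored.sum())
    k = int(np.floor(fraction * n))
    table["selected"] = False
    if k > 0:
        sub = table.loc[scored].sort_values(
            ["dcms"], ascending=False, kind="stable")
        # stable sort on descending score preserves genomic order inside ties
        cut = sub.iloc[:k]
        if len(sub) > k and sub.iloc[k]["dcms"] == cut.iloc[-1]["dcms"]:
            log.warning("DCMS ties at the top-%g cutoff broken by genomic order",
                        fraction)
        table.loc[cut.index, "selected"] = True
    result.threshold = (float(table.loc[table["selected"], "dcms"].min())
                        if k > 0 else None)
    return result


def plot_manhattan(result: DCMSResult, path, title: str = "DCMS") -> None:
    """Manhattan-style plot of DCMS scores with the top-fraction cutoff."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(table.groupby("chrom", sort=False)):
        x = (grp["start"] + grp["end"]) / 2 + offset
        ax.scatter(x, grp["dcms"], s=6,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        sel = grp["selected"] if "selected" in grp else None
        if sel is not None and sel.any():
            ax.scatter(x[sel], grp.loc[sel, "dcms"], s=14, color="crimson")
        ticks.append(offset + (grp["start"].min() + grp["end"].max()) / 2)
        labels.append(str(chrom))
        offset += grp["end"].max()
    if result.threshold is not None:
        ax.axhline(result.threshold, ls="--", lw=0.8, color="grey")
    ax.set_xticks(ticks, labels)
    ax.set_ylabel("DCMS")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def merge_regions(result: DCMSResult, source: str = "within") -> pd.DataFrame:
    """Merge bookended selected windows into sweep regions.

    Returns chrom/start/end/peak_dcms/n_windows/source, sorted and
    non-overlapping; idempotent by construction.
    """
    sel = result.table.loc[result.table["selected"],
                           ["chrom", "start", "end", "dcms"]]
    sel = sel.sort_values(["chrom", "start"])
    rows = []
    cur = None
    for _, w in sel.iterrows():
        if cur is not None and w["chrom"] == cur["chrom"] \
                and w["start"] == cur["end"]:
            cur["end"] = w["end"]
            cur["peak_dcms"] = max(cur["peak_dcms"], w["dcms"])
            cur["n_windows"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": w["chrom"], "start": int(w["start"]),
                   "end": int(w["end"]), "peak_dcms": float(w["dcms"]),
                   "n_windows": 1}
    if cur is not None:
        rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_dcms",
                                      "n_windows"])
    out["source"] = source
    return out
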