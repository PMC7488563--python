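"""Interval algebra: BED/TSV feature tables, overlap, nearest, intersection.

All intervals are internally 0-based half-open; BED input is taken
as-is, TSV input declared 1-based closed is converted at the boundary.
Overlaps are computed per chromosome with a sorted sweep
(searchsorted), so adjacency at a shared boundary is NOT an overlap.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FEATURE_COLS = ["chrom", "start", "end", "name", "source"]


def make_features(df: pd.DataFrame, source: str = "feature") -> pd.DataFrame:
    """Normalize an interval frame into a sorted feature table."""
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = [f"{source}_{i}" for i in range(len(out))]
    if "source" not in out.columns:
        out["source"] = source
    bad = out["end"] <= out["start"]
    if bad.any():
        log.warning("rejected %d records with end <= start", int(bad.sum()))
        out = out[~bad]
    out = out.sort_values(["chrom", "start", "end"], kind="stable")
    return out[FEATURE_COLS + [c for c in out.columns
                               if c not in FEATURE_COLS]].reset_index(drop=True)


def read_features(path, fmt: str = "bed", source: str = "feature",
                  ) -> pd.DataFrame:
    """Read BED (0-based half-open) or TSV with 1-based closed coordinates.

    The TSV must have columns chrom/start/end and optionally name.
    """
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3],
                         names=["chrom", "start", "end", "name"],
                         dtype={0: str})
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        df["start"] = df["start"] - 1  # 1-based closed -> 0-based half-open
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return make_features(df, source=source)


def write_bed(features: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"]
            if c in features.columns]
    features[cols].to_csv(path, sep="\t", header=False, index=False)


def overlap(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
    """All query/subject pairs with >= 1 bp overlap.

    Columns: query/subject identifiers, coordinates and overlap_bp.
    """
    rows = []
    for chrom, q in query.groupby("chrom", sort=False):
        s = subject[subject["chrom"] == chrom]
        if len(s) == 0:
            continue
        s = s.sort_values("start", kind="stable")
        s_start = s["start"].to_numpy()
        s_end = s["end"].to_numpy()
        for _, qr in q.iterrows():
            # candidates: subject.start < q.end and subject.end > q.start
            hi = np.searchsorted(s_start, qr["end"], side="left")
            cand = np.arange(hi)
            cand = cand[s_end[cand] > qr["start"]]
            for ci in cand:
                sr = s.iloc[ci]
                ov = min(qr["end"], sr["end"]) - max(qr["start"], sr["start"])
                rows.append({
                    "chrom": chrom,
                    "q_start": int(qr["start"]), "q_end": int(qr["end"]),
                    "q_name": qr.get("name"),
                    "s_start": int(sr["start"]), "s_end": int(sr["end"]),
                    "s_name": sr.get("name"), "overlap_bp": int(ov),
                })
    return pd.DataFrame(rows, columns=["chrom", "q_start", "q_end", "q_name",
                                       "s_start", "s_end", "s_name",
                                       "overlap_bp"])


def nearest(query: pd.DataFrame, subject: pd.DataFrame,
            max_distance_bp: int | None = None) -> pd.DataFrame:
    """Nearest same-chromosome subject for queries without any overlap.

    Distance is the gap in bp (0 would mean overlap, which routes
    through overlap()); queries with no subject on their chromosome or
    beyond max_distance_bp are omitted (logged).
    """
    hits = overlap(query, subject)
    overlapping = set(zip(hits["chrom"], hits["q_start"], hits["q_end"]))
    rows = []
    for chrom, q in query.groupby("chrom", sort=False):
        s = subject[subject["chrom"] == chrom]
        if len(s) == 0:
            log.info("no subject features on %s; %d queries skipped",
                     chrom, len(q))
            continue
        s_start = s["start"].to_numpy()
        s_end = s["end"].to_numpy()
        for _, qr in q.iterrows():
            if (chrom, qr["start"], qr["end"]) in overlapping:
                continue
            gap_left = qr["start"] - s_end       # >= 0 where subject left
            gap_right = s_start - qr["end"]      # >= 0 where subject right
            gaps = np.maximum(gap_left, gap_right)
            best = int(np.argmin(gaps))
            dist = int(gaps[best])
            if max_distance_bp is not None and dist > max_distance_bp:
                continue
            sr = s.iloc[best]
            rows.append({"chrom": chrom, "q_start": int(qr["start"]),
                         "q_end": int(qr["end"]), "q_name": qr.get("name"),
                         "s_start": int(sr["start"]), "s_end": int(sr["end"]),
                         "s_name": sr.get("name"), "distance_bp": dist})
    return pd.DataFrame(rows, columns=["chrom", "q_start", "q_end", "q_name",
                                       "s_start", "s_end", "s_name",
                                       "distance_bp"])


def intersect_sweeps_hotspots(sweeps: pd.DataFrame,
                              hotspots: pd.DataFrame) -> pd.DataFrame:
    """Shared intervals between sweep regions and per-population ROH hotspots.

    Returns chrom/start/end of each intersection with the sweep source
    (within|cross) and the hotspot's population.
    """
    sw = sweeps.copy()
    if "name" not in sw.columns:
        sw["name"] = [f"sweep_{i}" for i in range(len(sw))]
    hs = hotspots.copy()
    hs["name"] = hs.get("pop", pd.Series(["hotspot"] * len(hs)))
    hits = overlap(sw, hs)
    rows = []
    for _, h in hits.iterrows():
        rows.append({
            "chrom": h["chrom"],
            "start": int(max(h["q_start"], h["s_start"])),
            "end": int(min(h["q_end"], h["s_end"])),
            "sweep_source": sweeps.get("source", pd.Series(dtype=object)).iloc[0]
            if "source" in sweeps.columns and len(sweeps) else None,
            "population": h["s_name"],
        })
    out = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                      "sweep_source", "population"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def region_label(chrom: str, start: int, end: int) -> str:
    """Human-readable 1-based inclusive label, e.g. chr4:101600001-101650000."""
    return f"{chrom}:{start + 1}-{end}"
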