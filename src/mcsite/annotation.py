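"""Chromatin annotation of target sites.

Computes weighted methylation levels over a 100-bp non-overlapping genome
tiling and classifies each window into one of five methylation domains
(RdDM, heterochromatin, CG-only, unmethylated, intermediate); calls sites
open/closed by ATAC-peak overlap; aggregates feature-track signal over a
1-kb window centred on each target; and min-max-normalizes features to
[0, 1] for cross-feature comparison.

Weighted methylation for one context in a region is
``sum(methylated read counts) / sum(total read counts)`` over every
cytosine of that context in the region, both strands combined. Levels are
undefined (NaN) where a context has no covered cytosine.
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

DOMAIN_LABELS = ("RdDM", "heterochromatin", "CG-only", "unmethylated", "intermediate")

WINDOW_COLUMNS = [
    "chrom", "start", "end", "mCG", "mCHG", "mCHH", "n_CG", "n_CHG", "n_CHH",
]


def window_methylation(
    calls: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 100,
) -> pd.DataFrame:
    """Weighted per-context methylation over a non-overlapping tiling.

    Returns one row per window that has at least one call, with levels NaN
    in contexts with zero coverage and per-context informative-cytosine
    counts. Calls outside the stated chromosome lengths fail.
    """
    if calls.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    bad = calls[~calls["chrom"].isin(chrom_lengths)]
    if not bad.empty:
        raise ValueError(f"calls on unknown chromosome {bad['chrom'].iloc[0]!r}")
    for chrom, group in calls.groupby("chrom"):
        if (group["pos0"] >= chrom_lengths[chrom]).any() or (group["pos0"] < 0).any():
            raise ValueError(f"call positioned outside chromosome {chrom}")

    df = calls.copy()
    df["win"] = df["pos0"] // window
    rows = []
    for (chrom, win), group in df.groupby(["chrom", "win"], sort=True):
        start = int(win) * window
        end = min(start + window, chrom_lengths[chrom])
        row = {"chrom": chrom, "start": start, "end": end}
        for ctx in ("CG", "CHG", "CHH"):
            sub = group[group["context"] == ctx]
            total = int(sub["total_count"].sum())
            row[f"n_{ctx}"] = len(sub)
            row[f"m{ctx}"] = float(sub["mc_count"].sum() / total) if total > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def classify_domain(mcg: float, mchg: float, mchh: float) -> str:
    """Assign one methylation-domain label from the three context levels.

    Precedence resolves overlapping rules: a fully unmethylated window
    (all levels < 10%) first; then RdDM, which is defined by substantial
    CHH methylation (>= 15%); then heterochromatin (mCG and mCHG both
    > 40%); then CG-only (mCG > 40% with mCHG and mCHH both < 10%);
    everything else with data is intermediate.
    """
    for name, level in (("mCG", mcg), ("mCHG", mchg), ("mCHH", mchh)):
        if level is None or (isinstance(level, float) and np.isnan(level)):
            raise ValueError(f"{name} undefined; exclude or flag the window before classifying")
    if mcg < 0.10 and mchg < 0.10 and mchh < 0.10:
        return "unmethylated"
    if mchh >= 0.15:
        return "RdDM"
    if mcg > 0.40 and mchg > 0.40:
        return "heterochromatin"
    if mcg > 0.40 and mchg < 0.10 and mchh < 0.10:
        return "CG-only"
    return "intermediate"


def classify_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Add a ``domain`` column; windows missing any context get "no data"."""
    out = windows.copy()
    labels = []
    for _, row in out.iterrows():
        levels = (row["mCG"], row["mCHG"], row["mCHH"])
        if any(pd.isna(v) for v in levels):
            labels.append("no data")
        else:
            labels.append(classify_domain(*levels))
    out["domain"] = labels
    return out


def call_accessibility(
    site: Tuple[str, int, int], peaks: pd.DataFrame
) -> str:
    """"open" iff any peak interval overlaps the site by >= 1 bp."""
    chrom, start, end = site
    sel = peaks[peaks["chrom"] == chrom]
    overlap = (sel["start"] < end) & (sel["end"] > start)
    return "open" if bool(overlap.any()) else "closed"


def feature_window_means(
    sites: pd.DataFrame,
    tracks: Dict[str, pd.DataFrame],
    chrom_lengths: Mapping[str, int] | None = None,
    half_width: int = 500,
) -> pd.DataFrame:
    """Coverage-weighted mean signal over a 1-kb window around each site.

    ``sites`` needs columns site_id, chrom, start, end; the window is
    [center - half_width, center + half_width) with center the floor
    midpoint of the 23-mer interval. Intervals partially overlapping the
    window contribute pro rata; uncovered positions count as signal 0.
    Windows running off a chromosome end are truncated with a warning.
    """
    trees: Dict[str, Dict[str, IntervalTree]] = {}
    for feature, track in tracks.items():
        by_chrom: Dict[str, IntervalTree] = {}
        for chrom, group in track.groupby("chrom"):
            tree = IntervalTree()
            for _, row in group.iterrows():
                tree.addi(int(row["start"]), int(row["end"]), float(row["value"]))
            by_chrom[chrom] = tree
        trees[feature] = by_chrom

    rows = []
    for _, site in sites.iterrows():
        center = (int(site["start"]) + int(site["end"])) // 2
        lo, hi = center - half_width, center + half_width
        if lo < 0 or (chrom_lengths is not None and hi > chrom_lengths[site["chrom"]]):
            warnings.warn(
                f"feature window for {site['site_id']} truncated at chromosome bounds",
                stacklevel=2,
            )
            lo = max(lo, 0)
            if chrom_lengths is not None:
                hi = min(hi, chrom_lengths[site["chrom"]])
        span = hi - lo
        row = {"site_id": site["site_id"]}
        for feature, by_chrom in trees.items():
            tree = by_chrom.get(site["chrom"])
            weighted = 0.0
            if tree is not None:
                for iv in tree.overlap(lo, hi):
                    weighted += iv.data * (min(iv.end, hi) - max(iv.begin, lo))
            row[feature] = weighted / span if span > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")


def per_base_methylation(
    site: Tuple[str, int, int], calls: pd.DataFrame
) -> np.ndarray:
    """Weighted methylation per position of the 23-mer, on a 0-100 scale.

    Positions with no cytosine call on either strand are NaN.
    """
    chrom, start, end = site
    sel = calls[(calls["chrom"] == chrom) & (calls["pos0"] >= start) & (calls["pos0"] < end)]
    out = np.full(end - start, np.nan)
    for pos, group in sel.groupby("pos0"):
        total = group["total_count"].sum()
        if total > 0:
            out[int(pos) - start] = 100.0 * group["mc_count"].sum() / total
    return out


def normalize_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each feature column to [0, 1].

    Column max maps to 1 and min to 0; a constant column maps to all 0
    with a warning. Requires at least two sites.
    """
    if raw.empty:
        raise ValueError("cannot normalize an empty feature matrix")
    if len(raw) < 2:
        raise ValueError("feature normalization needs at least two sites")
    out = raw.copy().astype(float)
    for col in out.columns:
        lo, hi = out[col].min(), out[col].max()
        if hi > lo:
            out[col] = (out[col] - lo) / (hi - lo)
        else:
            warnings.warn(f"feature {col!r} is constant; normalized to 0", stacklevel=2)
            out[col] = 0.0
    return out


def site_domain(
    site: Tuple[str, int, int, str],
    classified_windows: pd.DataFrame,
    protospacer_offset: int = 0,
    window: int = 100,
) -> str:
    """Methylation domain of the tiling window containing the site's cut.

    The cut lies between protospacer positions 17 and 18; on the forward
    strand that is 17 bases from the interval start, on the reverse strand
    17 bases from the interval end.
    """
    chrom, start, end, strand = site
    cut = start + 17 if strand == "+" else end - 18
    win_start = (cut // window) * window
    sel = classified_windows[
        (classified_windows["chrom"] == chrom) & (classified_windows["start"] == win_start)
    ]
    if sel.empty:
        return "no data"
    return str(sel["domain"].iloc[0])
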