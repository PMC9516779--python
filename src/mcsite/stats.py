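"""Association statistics for editing efficiency and chromatin features.

Groups sites within a family into high/moderate/low (H/M/L) mutagenesis
levels via one-way ANOVA plus Tukey HSD homogeneous subsets; correlates
efficiency or insertion rate with chromatin features by Spearman rank
correlation; clusters normalized features hierarchically (average linkage,
Euclidean distance); and compares treatment conditions per site with the
two-sided Mann-Whitney U test and Kruskal-Wallis across families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class CorrelationResult:
    feature: str
    response: str
    n: int
    r: float
    p: float
    flagged: bool = False


@dataclass
class ClusterLayout:
    feature_linkage: np.ndarray
    site_linkage: np.ndarray
    feature_order: List[str]
    site_order: List[str]
    matrix: pd.DataFrame  # reordered

    def to_dict(self) -> dict:
        return {
            "feature_order": self.feature_order,
            "site_order": self.site_order,
            "feature_merges": self.feature_linkage[:, :2].astype(int).tolist(),
            "site_merges": self.site_linkage[:, :2].astype(int).tolist(),
        }


def assign_groups(table: pd.DataFrame, alpha: float = 0.05) -> Dict[str, str]:
    """Label each site H, M or L by replicate-level editing frequency.

    ``table`` has columns ``site_id`` and ``value`` with >= 2 replicates
    per site (>= 3 sites). One-way ANOVA establishes overall separation;
    Tukey HSD pairwise tests at ``alpha`` drive a sweep over sites sorted
    by descending mean that merges consecutive sites into homogeneous
    subsets (no within-subset pair significant). Subsets map to labels:
    one subset -> all M; two -> H and L; three -> H, M, L; more than three
    -> first H, last L, middle all M.
    """
    groups = {site: g["value"].to_numpy(float) for site, g in table.groupby("site_id")}
    if len(groups) < 3:
        raise ValueError("grouping needs at least three sites")
    for site, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"site {site} has fewer than 2 replicates")

    sites = sorted(groups, key=lambda s: groups[s].mean(), reverse=True)
    samples = [groups[s] for s in sites]

    pooled = np.concatenate(samples)
    if np.allclose(pooled, pooled[0]):
        return {s: "M" for s in sites}

    tukey = sps.tukey_hsd(*samples)
    pvals = tukey.pvalue

    def homogeneous(i: int, j: int) -> bool:
        # every pair within sites[i..j] non-significant
        return all(
            pvals[a][b] >= alpha for a in range(i, j + 1) for b in range(a + 1, j + 1)
        )

    subsets: List[List[str]] = []
    i = 0
    while i < len(sites):
        j = i
        while j + 1 < len(sites) and homogeneous(i, j + 1):
            j += 1
        subsets.append(sites[i : j + 1])
        i = j + 1

    if len(subsets) == 1:
        labels = ["M"]
    elif len(subsets) == 2:
        labels = ["H", "L"]
    else:
        labels = ["H"] + ["M"] * (len(subsets) - 2) + ["L"]
    return {site: label for subset, label in zip(subsets, labels) for site in subset}


def correlate(
    features: pd.DataFrame,
    response: pd.Series,
    response_name: str = "efficiency",
) -> List[CorrelationResult]:
    """Spearman rank correlation of each feature column with the response.

    ``features`` rows and ``response`` entries are matched by index (one
    observation per row; replicate- or site-level depending on the caller).
    Ties get average ranks; P-values are two-sided via the t
    approximation. Constant responses or features are flagged with NaN R.
    """
    idx = features.index.intersection(response.index)
    if len(idx) < 5:
        raise ValueError("correlation needs at least 5 observations")
    y = response.loc[idx].to_numpy(float)
    results = []
    for feature in features.columns:
        x = features.loc[idx, feature].to_numpy(float)
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            results.append(CorrelationResult(feature, response_name, len(idx), np.nan, np.nan, True))
            continue
        r, p = sps.spearmanr(x, y)
        results.append(CorrelationResult(feature, response_name, len(idx), float(r), float(p)))
    return results


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"feature": r.feature, "response": r.response, "n": r.n,
             "R": r.r, "P": r.p, "flagged": r.flagged}
            for r in results
        ]
    )
    # raw P-values are what the analysis reports; a BH column is added for
    # transparency only
    ok = df["P"].notna()
    df["q_BH"] = np.nan
    if ok.any():
        p = df.loc[ok, "P"].to_numpy(float)
        order = np.argsort(p)
        m = len(p)
        q = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            k = order[rank_idx]
            prev = min(prev, p[k] * m / (rank_idx + 1))
            q[k] = prev
        df.loc[ok, "q_BH"] = q
    return df


def cluster_features(matrix: pd.DataFrame) -> ClusterLayout:
    """Average-linkage Euclidean clustering of features and sites.

    ``matrix`` is sites x normalized features. Missing values are imputed
    with the column mean (with a warning from pandas semantics avoided by
    explicit fill). Tie-breaking follows scipy's deterministic ordering,
    so identical inputs give identical layouts.
    """
    m = matrix.copy().astype(float)
    if m.isna().any().any():
        import warnings

        warnings.warn("imputing missing feature values with column means", stacklevel=2)
        m = m.fillna(m.mean())
    if m.shape[1] == 1:
        feat_link = np.empty((0, 4))
        feat_order = list(m.columns)
    else:
        feat_link = hierarchy.linkage(pdist(m.T.to_numpy()), method="average")
        feat_order = [m.columns[i] for i in hierarchy.leaves_list(feat_link)]
    if m.shape[0] == 1:
        site_link = np.empty((0, 4))
        site_order = list(m.index)
    else:
        site_link = hierarchy.linkage(pdist(m.to_numpy()), method="average")
        site_order = [m.index[i] for i in hierarchy.leaves_list(site_link)]
    return ClusterLayout(
        feature_linkage=feat_link,
        site_linkage=site_link,
        feature_order=list(feat_order),
        site_order=list(site_order),
        matrix=m.loc[site_order, feat_order],
    )


def compare_conditions(
    a: pd.DataFrame, b: pd.DataFrame
) -> pd.DataFrame:
    """Per-site two-sided Mann-Whitney U test between two conditions.

    Both frames have columns ``site_id`` and ``value`` with >= 3
    replicates per site. Returns one row per shared site with the U
    statistic, P (exact for small samples without ties, normal
    approximation with tie correction otherwise - scipy's default), and
    the fold change mean(B) / mean(A).
    """
    rows = []
    sites = sorted(set(a["site_id"]) & set(b["site_id"]))
    for site in sites:
        xa = a.loc[a["site_id"] == site, "value"].to_numpy(float)
        xb = b.loc[b["site_id"] == site, "value"].to_numpy(float)
        if len(xa) < 3 or len(xb) < 3:
            raise ValueError(f"site {site}: need >= 3 replicates per condition")
        pooled = np.concatenate([xa, xb])
        if np.allclose(pooled, pooled[0]):
            u, p = len(xa) * len(xb) / 2.0, 1.0
        else:
            u, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        fold = xb.mean() / xa.mean() if xa.mean() > 0 else np.nan
        rows.append({"site_id": site, "U": float(u), "P": float(p), "fold_change": float(fold)})
    return pd.DataFrame(rows)


def kruskal_wallis(groups: Dict[str, Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H and P across >= 2 groups of >= 2 observations."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = []
    for name, vals in groups.items():
        vals = np.asarray(vals, float)
        if len(vals) < 2:
            raise ValueError(f"group {name} has fewer than 2 observations")
        arrays.append(vals)
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def anova_p(table: pd.DataFrame) -> float:
    """One-way ANOVA P across sites (columns site_id, value)."""
    samples = [g["value"].to_numpy(float) for _, g in table.groupby("site_id")]
    return float(sps.f_oneway(*samples).pvalue)
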