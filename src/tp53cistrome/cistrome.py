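"""Cross-experiment ChIP coverage: tiers, clustering and meta-ranking.

TP53 binding strength is highly reproducible across cell types and
treatments: summarising ChIP-seq coverage of candidate sites over many
experiments separates shared strong, shared weak and shared unbound
tiers, while indirect peaks are private to single experiments.  This
module builds the sites x experiments coverage matrix from bedGraph
tracks (site midpoint +/- flank), partitions sites into tiers by seeded
k-means on log1p coverage, aggregates per-experiment coverage ranks into
a meta-ranking (mean rank / Borda, invariant to monotone transforms of
coverage), and quantifies peak-set overlap consistency for direct vs
indirect subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.cluster import KMeans

TIER_NAMES = ("strong", "weak", "unbound")


@dataclass
class ClusterResult:
    labels: pd.Series            # site_id -> tier name
    cluster_means: pd.DataFrame  # tier x experiment mean coverage
    k: int
    degenerate: bool = False


def coverage_matrix(sites: pd.DataFrame, tracks: dict[str, pd.DataFrame],
                    flank: int = 2000) -> pd.DataFrame:
    """Sum per-base coverage over [midpoint - flank, midpoint + flank).

    ``tracks`` maps experiment name to a bedGraph frame; bases not covered
    by any interval count 0, and a site on a chromosome absent from a
    track contributes 0 with a warning.
    """
    mids = ((sites["start"] + sites["end"]) // 2).to_numpy()
    site_ids = sites["name"].tolist()
    data = {}
    for exp in sorted(tracks):
        track = tracks[exp]
        trees: dict[str, IntervalTree] = {}
        for _, r in track.iterrows():
            if r["end"] > r["start"]:
                trees.setdefault(r["chrom"], IntervalTree()).addi(
                    int(r["start"]), int(r["end"]), float(r["value"]))
        col = np.zeros(len(sites))
        n_missing = 0
        for i, (chrom, mid) in enumerate(zip(sites["chrom"], mids)):
            lo, hi = mid - flank, mid + flank
            tree = trees.get(chrom)
            if tree is None:
                n_missing += 1
                continue
            total = 0.0
            for iv in tree.overlap(lo, hi):
                total += iv.data * (min(iv.end, hi) - max(iv.begin, lo))
            col[i] = total
        if n_missing:
            warnings.warn(f"{exp}: {n_missing} sites on chromosomes absent "
                          "from the track scored 0")
        data[exp] = col
    return pd.DataFrame(data, index=pd.Index(site_ids, name="site_id"))


def cluster_sites(matrix: pd.DataFrame, k: int = 3, seed: int = 0,
                  n_restarts: int = 10) -> ClusterResult:
    """Seeded k-means on log1p coverage; clusters relabelled by mean.

    Clusters are renamed strong > weak > unbound (for k = 3; ``tier_i``
    otherwise) by descending mean coverage, so labels do not depend on
    k-means initialisation order.  A constant matrix cannot support k
    clusters and returns a single label with ``degenerate=True``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(matrix) < k:
        raise ValueError("fewer sites than clusters")
    X = np.log1p(matrix.to_numpy(dtype=float))
    if np.unique(X, axis=0).shape[0] < k:
        labels = pd.Series("unbound", index=matrix.index, name="tier")
        means = pd.DataFrame([matrix.mean()], index=["unbound"])
        return ClusterResult(labels, means, k=1, degenerate=True)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    raw = pd.Series(km.labels_, index=matrix.index)
    order = (matrix.groupby(raw.values).mean().mean(axis=1)
             .sort_values(ascending=False).index)
    names = list(TIER_NAMES) if k == 3 else [f"tier_{i+1}" for i in range(k)]
    rename = {cluster: names[rank] for rank, cluster in enumerate(order)}
    labels = raw.map(rename).rename("tier")
    means = matrix.groupby(labels.values).mean().loc[names]
    return ClusterResult(labels, means, k=k)


def aggregate_ranks(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-rank (Borda) aggregation of per-experiment coverage ranks.

    Within each experiment sites are ranked by descending coverage with
    average ranks for ties; the aggregate is the mean rank across
    experiments and the final ``meta_rank`` (1 = strongest) orders by
    aggregate, breaking ties by site id, giving a permutation of 1..n.
    """
    if matrix.shape[1] < 1:
        raise ValueError("at least one experiment required")
    ranks = pd.DataFrame(
        {exp: stats.rankdata(-matrix[exp].to_numpy(), method="average")
         for exp in matrix.columns}, index=matrix.index)
    out = ranks.add_prefix("rank_")
    out["mean_rank"] = ranks.mean(axis=1)
    key = pd.DataFrame({"mean_rank": out["mean_rank"],
                        "site": out.index.astype(str)}, index=out.index)
    order = key.sort_values(["mean_rank", "site"]).index
    out["meta_rank"] = 0
    out.loc[order, "meta_rank"] = np.arange(1, len(out) + 1)
    return out


def overlap_consistency(peak_sets: dict[str, pd.DataFrame],
                        reference: pd.DataFrame,
                        label_column: str = "label") -> pd.DataFrame:
    """Percent of labelled reference peaks overlapped (>=1 bp) by each set."""
    if reference.empty:
        raise ValueError("empty reference peak set")
    labels = (reference[label_column] if label_column in reference.columns
              else pd.Series("all", index=reference.index))
    rows = []
    for name in sorted(peak_sets):
        trees: dict[str, IntervalTree] = {}
        for _, r in peak_sets[name].iterrows():
            if r["end"] > r["start"]:
                trees.setdefault(r["chrom"], IntervalTree()).addi(
                    int(r["start"]), int(r["end"]))
        hit = [bool(trees.get(r["chrom"], IntervalTree())
                    .overlap(r["start"], r["end"]))
               for _, r in reference.iterrows()]
        hit = pd.Series(hit, index=reference.index)
        for label, sub in hit.groupby(labels.values):
            rows.append((name, str(label), 100.0 * sub.mean(), int(len(sub))))
    return pd.DataFrame(rows, columns=["peak_set", "label", "pct_overlap", "n"])


def rank_functional_correlation(meta: pd.DataFrame,
                                site_scores: pd.DataFrame | pd.Series,
                                window: int = 50) -> dict:
    """Monotone association between the meta-ranking and auxiliary scores.

    Returns per-score Spearman rho/P against ``meta_rank`` and the
    sliding-window mean of each score along the ranking (strongest first).
    """
    if isinstance(site_scores, pd.Series):
        site_scores = site_scores.to_frame()
    if not meta.index.equals(site_scores.index):
        if set(meta.index) != set(site_scores.index):
            raise ValueError("site ids of meta-ranking and scores differ")
        site_scores = site_scores.loc[meta.index]
    order = meta["meta_rank"].sort_values().index
    report = {}
    for col in site_scores.columns:
        vals = site_scores[col]
        rho, p = stats.spearmanr(meta["meta_rank"], vals)
        smoothed = (vals.loc[order].rolling(window, min_periods=1,
                                            center=True).mean())
        report[col] = {"spearman_rho": float(rho), "p_value": float(p),
                       "smoothed": smoothed}
    return report
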