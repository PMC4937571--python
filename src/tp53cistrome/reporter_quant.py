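"""Enhancer activity quantification from barcoded reporter counts.

The pipeline turns long-read barcode-region coupling evidence and
barcode x sample count tables into per-region activity calls:

1. ``build_coupling_dictionary`` resolves each barcode to a single region
   by a majority rule with support and purity filters.
2. ``normalize_counts`` scales cDNA counts to CPM and divides by the
   plasmid (input library) CPM of the same barcode, so expression is
   normalised both by sequencing depth and by plasmid abundance.
3. ``call_activity`` tests p53-high vs p53-off log expression per region
   (Welch t across barcode x replicate observations), adjusts with
   Benjamini-Hochberg, and classifies regions as positive / down /
   grayzone / negative using fold-change and significance thresholds.
4. ``collapse_to_peaks`` lifts region calls onto ChIP-seq peaks and
   ``compare_assays`` cross-tabulates two assays (e.g. captured-fragment
   reporter vs STARR-seq) over shared peaks.

A region is "positive" iff adjusted P < 0.05 and log2FC >= 1.5 (and
"down" for log2FC <= -1.5); the grayzone holds significant-but-small and
large-but-nonsignificant responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

CLASSES = ("positive", "down", "grayzone", "negative", "low_coverage")


@dataclass
class Thresholds:
    fdr: float = 0.05
    lfc: float = 1.5
    lfc_gray: float = 0.5
    min_barcodes: int = 1
    center_lfc: bool = True  # remove library-composition shift (median lfc)
    var_mode: str = "pooled"  # "pooled" (moderated, shared dispersion) | "welch"


def build_coupling_dictionary(coupling_reads: pd.DataFrame,
                              min_support: int = 3,
                              purity: float = 0.9) -> pd.DataFrame:
    """Resolve barcodes to regions by majority vote.

    A barcode is retained (status ``unique``) iff its total read support is
    >= ``min_support`` and the majority region holds >= ``purity`` of the
    reads; otherwise it is flagged ``low_support`` or ``ambiguous`` and
    excluded from quantification downstream.
    """
    if coupling_reads.empty:
        warnings.warn("empty coupling input: returning empty dictionary")
        return pd.DataFrame(columns=["barcode", "region_id", "support",
                                     "purity", "status"])
    grouped = (coupling_reads.groupby(["barcode", "region_id"])["n_reads"]
               .sum().reset_index())
    rows = []
    for barcode, sub in grouped.groupby("barcode"):
        total = int(sub["n_reads"].sum())
        best = sub.sort_values(["n_reads", "region_id"],
                               ascending=[False, True]).iloc[0]
        frac = best["n_reads"] / total
        if total < min_support:
            status = "low_support"
        elif frac < purity:
            status = "ambiguous"
        else:
            status = "unique"
        rows.append((barcode, best["region_id"], total, frac, status))
    return pd.DataFrame(rows, columns=["barcode", "region_id", "support",
                                       "purity", "status"])


def normalize_counts(counts: pd.DataFrame,
                     samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """cDNA expression normalised by depth and plasmid abundance.

    Counts get pseudocount 1, are scaled to counts-per-million of the raw
    library size, and each cDNA CPM is divided by the unit's mean plasmid
    CPM.  Returns (normalised cDNA table, low_coverage flags) where a unit
    with zero plasmid counts in every plasmid sample is flagged.
    """
    plasmid_ids = samples.loc[samples["material"].str.lower() == "plasmid",
                              "sample_id"].tolist()
    if not plasmid_ids:
        raise ValueError("sample sheet contains no plasmid sample")
    missing = [s for s in samples["sample_id"] if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from count table: {missing}")
    libsize = counts.sum(axis=0).astype(float)
    cpm = (counts + 1).div(libsize, axis=1) * 1e6
    plasmid_ref = cpm[plasmid_ids].mean(axis=1)
    low_coverage = counts[plasmid_ids].sum(axis=1) == 0
    cdna_ids = samples.loc[samples["material"].str.lower() != "plasmid",
                           "sample_id"].tolist()
    normalized = cpm[cdna_ids].div(plasmid_ref, axis=0)
    return normalized, low_coverage


def replicate_qc(normalized: pd.DataFrame, samples: pd.DataFrame,
                 r2_threshold: float = 0.8) -> pd.DataFrame:
    """Squared Pearson correlation of log expression per replicate pair.

    Also reports fold-change reproducibility (per-replicate high/off log
    ratios) when both conditions have matching replicates.  With fewer
    than two replicates everywhere the result is empty (not an error).
    """
    logged = np.log2(normalized)
    cdna = samples[samples["material"].str.lower() != "plasmid"]

    def _r2(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    rows = []
    for condition, sub in cdna.groupby("condition"):
        ids = sub.sort_values("replicate")["sample_id"].tolist()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r2 = _r2(logged[ids[i]], logged[ids[j]])
                rows.append((str(condition), ids[i], ids[j], r2,
                             r2 < r2_threshold))
    by_rep = {(c, r): s for c, r, s in
              zip(cdna["condition"], cdna["replicate"], cdna["sample_id"])}
    reps = sorted({r for c, r in by_rep if ("p53_high", r) in by_rep
                   and ("p53_off", r) in by_rep})
    fc = {r: logged[by_rep[("p53_high", r)]] - logged[by_rep[("p53_off", r)]]
          for r in reps}
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            r2 = _r2(fc[reps[i]], fc[reps[j]])
            rows.append(("fold_change", str(reps[i]), str(reps[j]), r2,
                         r2 < r2_threshold))
    return pd.DataFrame(rows, columns=["condition", "a", "b", "r2", "flagged"])


def _classify(lfc: float, padj: float, th: Thresholds) -> str:
    significant = padj < th.fdr
    if significant and lfc >= th.lfc:
        return "positive"
    if significant and lfc <= -th.lfc:
        return "down"
    if (significant and th.lfc_gray <= abs(lfc) < th.lfc) \
            or (abs(lfc) >= th.lfc and not significant):
        return "grayzone"
    return "negative"


def call_activity(normalized: pd.DataFrame, couplings: pd.DataFrame | None,
                  samples: pd.DataFrame,
                  thresholds: Thresholds | None = None,
                  low_coverage: pd.Series | None = None) -> pd.DataFrame:
    """Per-region activity calls from normalised barcode expression.

    log2FC is the difference of mean log2 expression (p53-high minus
    p53-off) over barcode x replicate observations; the P value comes from
    a two-sided unequal-variance (Welch) test on the same values, adjusted
    across regions with Benjamini-Hochberg.  In STARR-seq mode pass
    ``couplings=None`` and the table rows are treated as regions directly.
    """
    th = thresholds or Thresholds()
    high_ids = samples.loc[samples["condition"] == "p53_high", "sample_id"]
    off_ids = samples.loc[samples["condition"] == "p53_off", "sample_id"]
    high_ids = [s for s in high_ids if s in normalized.columns]
    off_ids = [s for s in off_ids if s in normalized.columns]
    if not high_ids or not off_ids:
        raise ValueError("need both p53_high and p53_off samples")

    if couplings is None:
        unit_region = pd.Series(normalized.index, index=normalized.index)
    else:
        retained = couplings[couplings["status"] == "unique"]
        unit_region = retained.set_index("barcode")["region_id"]
    if low_coverage is None:
        low_coverage = pd.Series(False, index=normalized.index)

    logged = np.log2(normalized)
    obs = []
    for region, units in unit_region.groupby(unit_region.values):
        idx = [u for u in units.index if u in logged.index
               and not low_coverage.get(u, False)]
        n_bc = len(idx)
        if n_bc < th.min_barcodes or n_bc == 0:
            obs.append((region, None, None, np.nan, n_bc))
            continue
        high = logged.loc[idx, high_ids].to_numpy().ravel()
        off = logged.loc[idx, off_ids].to_numpy().ravel()
        base_mean = float(normalized.loc[idx, high_ids + off_ids]
                          .to_numpy().mean())
        obs.append((region, high, off, base_mean, n_bc))

    # Library-composition offset: with CPM scaling, strongly induced units
    # inflate the p53-high library total and shift every raw fold change.
    # The median raw lfc (the unresponsive bulk) estimates that offset.
    raw_lfcs = [h.mean() - o.mean() for _, h, o, _, _ in obs if h is not None]
    shift = float(np.median(raw_lfcs)) if (th.center_lfc and raw_lfcs) else 0.0

    # NB counts share one dispersion, so log-scale noise is near-homoscedastic
    # across regions: pool the within-group residual variance over all regions
    # to stabilise the test when a region has few barcodes (var_mode="pooled").
    ss, df_pooled = 0.0, 0
    for _, high, off, _, _ in obs:
        if high is None:
            continue
        for arr in (high, off):
            if arr.size >= 2:
                ss += float(((arr - arr.mean()) ** 2).sum())
                df_pooled += arr.size - 1
    pooled_var = ss / df_pooled if df_pooled > 0 else np.nan

    rows = []
    for region, high, off, base_mean, n_bc in obs:
        if high is None:
            rows.append((region, np.nan, np.nan, np.nan, n_bc, "low_coverage"))
            continue
        off_adj = off + shift
        lfc = float(high.mean() - off_adj.mean())
        if high.size < 1 or off.size < 1:
            p = np.nan
        elif th.var_mode == "pooled" and df_pooled > 0 and pooled_var > 0:
            se = np.sqrt(pooled_var * (1.0 / high.size + 1.0 / off.size))
            p = float(2 * stats.t.sf(abs(lfc) / se, df_pooled))
        elif high.size < 2 or off.size < 2 \
                or (np.ptp(high) == 0 and np.ptp(off) == 0):
            p = 1.0 if lfc == 0 else np.nan
        else:
            p = float(stats.ttest_ind(high, off_adj, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append((region, base_mean, lfc, p, n_bc, None))
    calls = pd.DataFrame(rows, columns=["region_id", "base_mean", "log2FC",
                                        "p_value", "n_barcodes", "class"])
    testable = calls["class"].isna() & calls["p_value"].notna()
    padj = pd.Series(np.nan, index=calls.index)
    if testable.any():
        padj[testable] = multipletests(calls.loc[testable, "p_value"],
                                       method="fdr_bh")[1]
    calls["p_adj"] = padj
    for i in calls.index[testable]:
        calls.loc[i, "class"] = _classify(calls.loc[i, "log2FC"],
                                          calls.loc[i, "p_adj"], th)
    calls.loc[calls["class"].isna(), "class"] = "low_coverage"
    return calls.sort_values("region_id").reset_index(drop=True)


def collapse_to_peaks(region_calls: pd.DataFrame, regions_bed: pd.DataFrame,
                      peaks_bed: pd.DataFrame,
                      min_overlap_fraction: float = 0.60) -> pd.DataFrame:
    """Lift region-level calls onto peaks.

    A peak is covered iff at least one retained (non-low_coverage) region
    overlaps >= ``min_overlap_fraction`` of the peak; the peak inherits the
    class of the best-supported overlapping region (most barcodes, ties
    broken by larger |log2FC|).
    """
    calls = region_calls.set_index("region_id")
    trees: dict[str, IntervalTree] = {}
    for _, r in regions_bed.iterrows():
        if r["end"] > r["start"]:
            trees.setdefault(r["chrom"], IntervalTree()).addi(
                r["start"], r["end"], r["name"])
    rows = []
    for _, pk in peaks_bed.iterrows():
        length = pk["end"] - pk["start"]
        candidates = []
        for iv in trees.get(pk["chrom"], IntervalTree()).overlap(
                pk["start"], pk["end"]):
            rid = iv.data
            if rid not in calls.index:
                continue
            call = calls.loc[rid]
            if call["class"] == "low_coverage":
                continue
            overlap = min(iv.end, pk["end"]) - max(iv.begin, pk["start"])
            if length > 0 and overlap / length >= min_overlap_fraction:
                candidates.append((call["n_barcodes"], abs(call["log2FC"]),
                                   rid, call["class"]))
        if candidates:
            candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
            n_bc, _, rid, cls = candidates[0]
            rows.append((pk["name"], True, rid, cls, int(n_bc)))
        else:
            rows.append((pk["name"], False, None, "not_covered", 0))
    return pd.DataFrame(rows, columns=["peak_id", "covered", "region_id",
                                       "class", "n_barcodes"])


def compare_assays(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Concordance of two assays over shared peaks.

    Returns the class cross-tabulation, the percentage of A-positives that
    are positive-or-grayzone in B, and a chi-square test on the table.
    """
    a = calls_a.set_index("peak_id")["class"]
    b = calls_b.set_index("peak_id")["class"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared peaks between call sets")
    table = pd.crosstab(a.loc[shared], b.loc[shared])
    a_pos = shared[a.loc[shared] == "positive"]
    if len(a_pos):
        concordant = (b.loc[a_pos].isin(["positive", "grayzone"])).sum()
        pct = 100.0 * concordant / len(a_pos)
    else:
        pct = np.nan
    trimmed = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if trimmed.shape[0] > 1 and trimmed.shape[1] > 1:
        chi2, p, _, _ = stats.chi2_contingency(trimmed)
    else:
        chi2, p = np.nan, np.nan
    return {"table": table, "pct_a_pos_concordant": pct,
            "chi2": chi2, "chi2_p": p, "n_shared": int(len(shared))}
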