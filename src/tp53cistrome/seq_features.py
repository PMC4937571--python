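"""Flanking-sequence diagnostics around binding sites.

Bound TP53 sites sit in a characteristic sequence context: elevated
conservation at the site, depletion of the stiff AA/TT/AT/TA
dinucleotides ~100 bp to either side (a nucleosome-positioning
signature), and distinctive helical-twist / propeller-twist shape
profiles.  These functions compute per-offset profiles relative to the
site midpoint (offset 0) for groups of sites: dinucleotide composition,
G+C content, conservation-track means, and pentamer-lookup DNA shape.

All profiles are returned long-format: (group, feature, offset, mean, n).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .motif_model import reverse_complement

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


def _center(seq: str, window: int) -> str | None:
    if len(seq) < window:
        return None
    lo = (len(seq) - window) // 2
    return seq[lo:lo + window].upper()


def _offsets(window: int, span: int) -> np.ndarray:
    # offset k spans [k, k + span) relative to the midpoint at window//2
    return np.arange(-window // 2, window // 2 - span + 1)


def dinucleotide_profile(seqs, window: int, group: str = "all") -> pd.DataFrame:
    """Per-offset frequency of each of the 16 dinucleotides.

    The dinucleotide at offset k spans [k, k+2) relative to the site
    midpoint.  N-containing dinucleotides are excluded from the
    denominator; sequences shorter than ``window`` are skipped (the
    returned frame's ``n`` column counts the sequences used per offset).
    """
    if window % 2:
        raise ValueError("window must be even")
    centered = [c for c in (_center(s, window) for s in seqs) if c is not None]
    offsets = _offsets(window, 2)
    counts = np.zeros((len(offsets), 16), dtype=float)
    totals = np.zeros(len(offsets), dtype=float)
    index = {d: i for i, d in enumerate(DINUCLEOTIDES)}
    for seq in centered:
        for j in range(len(offsets)):
            din = seq[j:j + 2]
            i = index.get(din)
            if i is not None:
                counts[j, i] += 1
                totals[j] += 1
    rows = []
    for j, off in enumerate(offsets):
        denom = totals[j] if totals[j] > 0 else np.nan
        for d in DINUCLEOTIDES:
            rows.append((group, d, int(off), counts[j, index[d]] / denom,
                         int(totals[j])))
    return pd.DataFrame(rows, columns=["group", "feature", "offset", "mean", "n"])


def gc_profile(seqs, window: int, smoothing_bp: int = 0,
               group: str = "all") -> pd.DataFrame:
    """Per-offset G+C fraction, optionally boxcar-smoothed."""
    if window % 2:
        raise ValueError("window must be even")
    centered = [c for c in (_center(s, window) for s in seqs) if c is not None]
    offsets = _offsets(window, 1)
    gc = np.zeros(len(offsets))
    n = np.zeros(len(offsets))
    for seq in centered:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
        gc += np.where(is_acgt, is_gc, 0)
        n += is_acgt
    with np.errstate(invalid="ignore"):
        frac = gc / n
    if smoothing_bp > 1:
        frac = (pd.Series(frac).rolling(smoothing_bp, min_periods=1,
                                        center=True).mean().to_numpy())
    return pd.DataFrame({"group": group, "feature": "GC", "offset": offsets,
                         "mean": frac, "n": n.astype(int)})


def conservation_profile(sites: pd.DataFrame, track: pd.DataFrame,
                         window: int, missing: str = "zero",
                         group: str = "all") -> pd.DataFrame:
    """Mean per-offset conservation score around site midpoints.

    ``track`` is a bedGraph frame; per-base values are read over
    [midpoint - window/2, midpoint + window/2).  ``missing`` handles bases
    with no track interval: "zero" scores them 0, "skip" drops them from
    the mean.  Raises if no site has any coverage.
    """
    if window % 2:
        raise ValueError("window must be even")
    half = window // 2
    per_chrom: dict[str, pd.DataFrame] = {
        str(c): t.sort_values("start") for c, t in track.groupby("chrom")}
    sums = np.zeros(window)
    counts = np.zeros(window)
    any_chrom_present = False
    for _, site in sites.iterrows():
        mid = (int(site["start"]) + int(site["end"])) // 2
        values = np.full(window, np.nan)
        sub = per_chrom.get(str(site["chrom"]))
        if sub is not None:
            any_chrom_present = True
            lo, hi = mid - half, mid + half
            for _, iv in sub.iterrows():
                a, b = max(int(iv["start"]), lo), min(int(iv["end"]), hi)
                if b > a:
                    values[a - lo:b - lo] = iv["value"]
            if missing == "zero":
                values = np.nan_to_num(values, nan=0.0)
        ok = ~np.isnan(values)
        sums[ok] += values[ok]
        counts[ok] += 1
    if not any_chrom_present:
        raise ValueError("no site is covered by the score track")
    with np.errstate(invalid="ignore"):
        mean = sums / counts
    return pd.DataFrame({"group": group, "feature": "conservation",
                         "offset": np.arange(-half, half), "mean": mean,
                         "n": counts.astype(int)})


def symmetrize_pentamer_table(table: dict[str, float]) -> dict[str, float]:
    """Extend a pentamer table so each reverse complement maps equally."""
    out = dict(table)
    for penta, val in table.items():
        out.setdefault(reverse_complement(penta), val)
    return out


def shape_profile(seqs, pentamer_table: dict[str, float], feature: str,
                  window: int, group: str = "all") -> pd.DataFrame:
    """Per-offset DNA shape value by centred-pentamer lookup.

    The value at offset k is the table entry for the pentamer centred on
    k, averaged across sequences; the outermost 2 bp on each side have no
    centred pentamer and are trimmed.  The table must be
    strand-symmetrized (see :func:`symmetrize_pentamer_table`); a pentamer
    absent from it raises an error naming it.
    """
    if window % 2:
        raise ValueError("window must be even")
    centered = [c for c in (_center(s, window) for s in seqs) if c is not None]
    offsets = _offsets(window, 1)[2:-2]
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets))
    for seq in centered:
        for j, _ in enumerate(offsets):
            penta = seq[j:j + 5]
            if "N" in penta:
                continue
            if penta not in pentamer_table:
                raise KeyError(f"pentamer {penta!r} absent from shape table")
            sums[j] += pentamer_table[penta]
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        mean = sums / counts
    return pd.DataFrame({"group": group, "feature": feature, "offset": offsets,
                         "mean": mean, "n": counts.astype(int)})


def grouped_profiles(groups: dict[str, list[str]], window: int,
                     kind: str = "dinucleotide", **kwargs) -> pd.DataFrame:
    """Apply a profile function per group and concatenate long-format."""
    fn = {"dinucleotide": dinucleotide_profile, "gc": gc_profile,
          "shape": shape_profile}[kind]
    frames = [fn(seqs, window=window, group=g, **kwargs)
              for g, seqs in groups.items()]
    return pd.concat(frames, ignore_index=True)
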