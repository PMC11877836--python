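"""Genomic-interval primitives used across callers and annotation.

All intervals are 0-based half-open ``[start, end)``.  Inputs are plain
pandas DataFrames with at least ``chrom``, ``start`` and ``end`` columns;
helpers return DataFrames in the same convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_within_gap(df: pd.DataFrame, gap: int) -> pd.DataFrame:
    """Greedy left-to-right merge of intervals whose gap is <= `gap`.

    The gap between consecutive intervals is ``next.start - cur.end``; a
    negative gap (overlap) always merges.  Returns merged intervals with an
    ``n_merged`` column counting constituent input intervals.
    """
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_merged"])
    df = sort_intervals(df)
    out = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is not None and row.chrom == cur[0] and row.start - cur[2] <= gap:
            cur[2] = max(cur[2], row.end)
            cur[3] += 1
        else:
            if cur is not None:
                out.append(tuple(cur))
            cur = [row.chrom, row.start, row.end, 1]
    out.append(tuple(cur))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_merged"])


def _per_chrom(df: pd.DataFrame):
    for chrom, sub in df.groupby("chrom", sort=True, observed=True):
        yield chrom, sub


def overlap_pairs(a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1) -> pd.DataFrame:
    """All (a_index, b_index) pairs overlapping by at least `min_overlap` bp."""
    hits = []
    b_by_chrom = {c: s for c, s in _per_chrom(b)}
    for chrom, sa in _per_chrom(a):
        sb = b_by_chrom.get(chrom)
        if sb is None:
            continue
        bs = sb["start"].to_numpy()
        be = sb["end"].to_numpy()
        order = np.argsort(bs, kind="mergesort")
        bs_s, be_s = bs[order], be[order]
        bidx = sb.index.to_numpy()[order]
        # prefix max of ends lets us bound the leftmost candidate
        for ai, a_start, a_end in zip(sa.index, sa["start"], sa["end"]):
            j_hi = np.searchsorted(bs_s, a_end - min_overlap, side="right")
            for j in range(j_hi):
                ov = min(a_end, be_s[j]) - max(a_start, bs_s[j])
                if ov >= min_overlap:
                    hits.append((ai, bidx[j]))
    return pd.DataFrame(hits, columns=["a_index", "b_index"])


def set_overlap_counts(a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1) -> dict:
    """Interval-set overlap summary for Venn-style comparisons.

    Returns a dict with the number of a-intervals hitting no b interval
    (``n_a_only``), the converse (``n_b_only``), the per-set hit counts, and
    the symmetric count of overlapping (a, b) pairs (``n_shared``).
    """
    pairs = overlap_pairs(a, b, min_overlap=min_overlap)
    a_hit = pairs["a_index"].nunique()
    b_hit = pairs["b_index"].nunique()
    return {
        "n_a_only": len(a) - a_hit,
        "n_b_only": len(b) - b_hit,
        "n_a_shared": a_hit,
        "n_b_shared": b_hit,
        "n_shared": len(pairs),
    }


def nearest_gap(loci: pd.DataFrame, features: pd.DataFrame) -> pd.Series:
    """Minimal edge-to-edge gap from each locus to any feature.

    Overlapping intervals (sharing at least one base) give a gap of 0 and
    are additionally marked by :func:`proximity gaps < 0`; here overlap is
    encoded as -1 so callers can distinguish touch (gap 0, no shared base)
    from true overlap.  Loci on chromosomes with no feature get +inf.
    """
    gaps = pd.Series(np.inf, index=loci.index, dtype=float)
    f_by_chrom = {c: s for c, s in _per_chrom(features)}
    for chrom, sub in _per_chrom(loci):
        fs = f_by_chrom.get(chrom)
        if fs is None:
            continue
        starts = fs["start"].to_numpy()
        ends = fs["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts_s = starts[order]
        ends_pref = np.maximum.accumulate(ends[order])
        for li, l_start, l_end in zip(sub.index, sub["start"], sub["end"]):
            i = np.searchsorted(starts_s, l_end, side="left")
            best = np.inf
            if i < len(starts_s):
                best = starts_s[i] - l_end  # nearest feature to the right
            if i > 0:
                left_end = ends_pref[i - 1]
                if left_end > l_start:
                    best = -1.0  # shares at least one base
                else:
                    best = min(best, l_start - left_end)
            gaps.loc[li] = best
    return gaps


def interval_recovery(called: pd.DataFrame, truth: pd.DataFrame, min_overlap: int = 1) -> dict:
    """Precision/recall of called intervals against planted truth intervals."""
    if len(called) == 0:
        return {"precision": float("nan") if len(truth) else 1.0,
                "recall": 0.0 if len(truth) else 1.0,
                "n_called": 0, "n_truth": len(truth)}
    counts = set_overlap_counts(called, truth, min_overlap=min_overlap)
    precision = counts["n_a_shared"] / len(called)
    recall = counts["n_b_shared"] / len(truth) if len(truth) else 1.0
    return {"precision": precision, "recall": recall,
            "n_called": len(called), "n_truth": len(truth)}
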