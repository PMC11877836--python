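"""Windowed methylation quantification and end-anchored metaprofiles.

All pooled quantities are coverage-weighted: the fraction reported for a
window, interval or metaprofile bin is sum(meth) / sum(total) over the
contributing cytosines, not a mean of per-cytosine fractions.  Windows and
intervals are 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from slmkit.io import CONTEXTS


def window_methylation(methylome: pd.DataFrame, window: int = 50,
                       contexts=CONTEXTS, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Pool counts into fixed-width genomic windows per context.

    Every cytosine is assigned to exactly one window by
    ``floor((pos - 1) / window)``.  Windows containing at least one record
    of a context appear in the output even when their pooled total is zero
    (fraction is NaN there, flagged by the ``covered`` column).

    Returns columns: chrom, start, end, context, n_sites, meth, total,
    fraction, covered.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sub = methylome[methylome["context"].isin(contexts)]
    pos0 = sub["pos"] - 1
    win = pos0 // window
    grouped = sub.groupby([sub["chrom"], win, sub["context"]], observed=True)
    agg = grouped.agg(n_sites=("meth", "size"), meth=("meth", "sum"),
                      total=("total", "sum"))
    agg.index.names = ["chrom", "win", "context"]
    out = agg.reset_index()
    out["start"] = out["win"] * window
    out["end"] = out["start"] + window
    if chrom_sizes is not None:
        out["end"] = np.minimum(out["end"],
                                out["chrom"].map(chrom_sizes).fillna(np.inf))
        out["end"] = out["end"].astype(np.int64)
    out["covered"] = out["total"] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fraction"] = np.where(out["covered"], out["meth"] / out["total"], np.nan)
    cols = ["chrom", "start", "end", "context", "n_sites", "meth", "total",
            "fraction", "covered"]
    return out[cols].sort_values(["chrom", "start", "context"],
                                 kind="mergesort").reset_index(drop=True)


def interval_quantify(methylome: pd.DataFrame, intervals: pd.DataFrame,
                      contexts=CONTEXTS, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Pool methylation counts over arbitrary intervals per context.

    `intervals` needs chrom/start/end columns; its index is preserved as
    ``interval`` in the output.  Returns one row per interval x context
    with n_sites (records), n_covered (total > 0), meth, total, fraction.
    """
    if chrom_sizes is not None:
        for row in intervals.itertuples():
            limit = chrom_sizes.get(row.chrom)
            if limit is not None and row.end > limit:
                raise ValueError(
                    f"interval {row.chrom}:{row.start}-{row.end} beyond chromosome end {limit}")
    rows = []
    for ctx in contexts:
        sub = methylome[methylome["context"] == ctx]
        by_chrom = {c: s for c, s in sub.groupby("chrom", observed=True)}
        for chrom, s in by_chrom.items():
            by_chrom[chrom] = (
                s["pos"].to_numpy() - 1,
                np.concatenate([[0], np.cumsum(s["meth"].to_numpy())]),
                np.concatenate([[0], np.cumsum(s["total"].to_numpy())]),
                np.concatenate([[0], np.cumsum((s["total"].to_numpy() > 0).astype(np.int64))]),
            )
        for row in intervals.itertuples():
            entry = by_chrom.get(row.chrom)
            if entry is None:
                rows.append((row.Index, ctx, 0, 0, 0, 0))
                continue
            pos0, cm, ct, cc = entry
            i0 = np.searchsorted(pos0, row.start, side="left")
            i1 = np.searchsorted(pos0, row.end, side="left")
            rows.append((row.Index, ctx, i1 - i0, cc[i1] - cc[i0],
                         cm[i1] - cm[i0], ct[i1] - ct[i0]))
    out = pd.DataFrame(rows, columns=["interval", "context", "n_sites",
                                      "n_covered", "meth", "total"])
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fraction"] = np.where(out["total"] > 0, out["meth"] / out["total"], np.nan)
    return out


def substantial_mask(quantified: pd.DataFrame, min_covered: int = 4) -> pd.Series:
    """Intervals with at least `min_covered` covered cytosines of every context.

    Operationalises the "substantial methylation" filter behind windowed
    box plots; apply per sample group and AND the masks across groups.
    """
    ok = quantified.groupby("interval", observed=True)["n_covered"].min() >= min_covered
    return ok


def _anchor_rel(pos0: np.ndarray, start: int, end: int, strand: str, anchor: str) -> np.ndarray:
    """Signed distance of positions from a feature anchor.

    Positive = into the feature, negative = outside (upstream of the 5'
    anchor or downstream of the 3' anchor), in biological orientation.
    """
    if anchor == "5prime":
        return pos0 - start if strand == "+" else (end - 1) - pos0
    if anchor == "3prime":
        return (end - 1) - pos0 if strand == "+" else pos0 - start
    raise ValueError("anchor must be '5prime' or '3prime'")


def ends_metaprofile(methylome: pd.DataFrame, features: pd.DataFrame,
                     anchor: str = "5prime", bin_width: int = 100,
                     span: int = 3000, contexts=CONTEXTS) -> pd.DataFrame:
    """End-anchored average methylation profile over a feature set.

    Bins of `bin_width` bp cover [-span, +span) around the anchor; negative
    bins are outside the feature.  To avoid short features skewing the
    inside of the profile, a feature contributes to the inside bin covering
    distances [d, d + bin_width) only when its length is at least
    d + bin_width (it fully spans the bin); its positions beyond that are
    excluded.  Bin values are coverage-weighted pooled fractions.

    Returns: bin (index, bin 0 starts at the anchor), rel_start, context,
    meth, total, fraction, n_features.
    """
    if len(features) == 0:
        raise ValueError("ends_metaprofile needs a non-empty feature set")
    if span % bin_width != 0:
        raise ValueError("span must be a multiple of bin_width")
    n_bins_side = span // bin_width
    bins = np.arange(-n_bins_side, n_bins_side)

    sub = methylome[methylome["context"].isin(contexts)]
    by_chrom = {}
    for chrom, s in sub.groupby("chrom", observed=True):
        by_chrom[chrom] = (s["pos"].to_numpy() - 1, s["context"].to_numpy(),
                           s["meth"].to_numpy(), s["total"].to_numpy())

    acc = {(b, ctx): [0, 0] for b in bins for ctx in contexts}
    lengths = (features["end"] - features["start"]).to_numpy()
    for row, length in zip(features.itertuples(), lengths):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        pos0, ctx_arr, meth, total = entry
        lo = np.searchsorted(pos0, row.start - span)
        hi = np.searchsorted(pos0, row.end + span)
        sl = slice(lo, hi)
        rel = _anchor_rel(pos0[sl], row.start, row.end, row.strand, anchor)
        # inside: within the feature, truncated to fully-spanned bins
        max_inside = bin_width * (length // bin_width)
        keep = (rel >= -span) & (rel < min(span, max_inside))
        keep &= ~((rel >= 0) & (rel >= length))
        b = np.floor_divide(rel[keep], bin_width)
        for bb, cc, mm, tt in zip(b, ctx_arr[sl][keep], meth[sl][keep], total[sl][keep]):
            slot = acc[(bb, cc)]
            slot[0] += mm
            slot[1] += tt

    n_feat = {}
    for b in bins:
        if b < 0:
            n_feat[b] = len(features)
        else:
            n_feat[b] = int((lengths >= (b + 1) * bin_width).sum())

    rows = []
    for b in bins:
        for ctx in contexts:
            m, t = acc[(b, ctx)]
            frac = m / t if t > 0 else np.nan
            rows.append((b, b * bin_width, ctx, m, t, frac, n_feat[b]))
    return pd.DataFrame(rows, columns=["bin", "rel_start", "context", "meth",
                                       "total", "fraction", "n_features"])


def flank_profile(methylome: pd.DataFrame, features: pd.DataFrame,
                  flank: int = 200, body_bins: int = 10, flank_bin: int = 50,
                  contexts=CONTEXTS) -> pd.DataFrame:
    """Scaled-body-plus-flank methylation profile (TE-style metaplot).

    The feature body is rescaled to `body_bins` equal-occupancy bins (a
    cytosine at relative position r in [0, 1) lands in bin floor(r *
    body_bins), so features shorter than `body_bins` bp contribute
    proportionally rather than being dropped); flanks use fixed
    `flank_bin`-bp bins in biological orientation.  Bin labels: negative =
    upstream flank, 0..body_bins-1 = body, >= body_bins = downstream flank.
    """
    if len(features) == 0:
        raise ValueError("flank_profile needs a non-empty feature set")
    if flank < 0 or body_bins < 1:
        raise ValueError("flank must be >= 0 and body_bins >= 1")
    n_flank_bins = -(-flank // flank_bin) if flank else 0
    up_bins = np.arange(-n_flank_bins, 0)
    body = np.arange(body_bins)
    down_bins = np.arange(body_bins, body_bins + n_flank_bins)
    all_bins = np.concatenate([up_bins, body, down_bins])

    sub = methylome[methylome["context"].isin(contexts)]
    by_chrom = {}
    for chrom, s in sub.groupby("chrom", observed=True):
        by_chrom[chrom] = (s["pos"].to_numpy() - 1, s["context"].to_numpy(),
                           s["meth"].to_numpy(), s["total"].to_numpy())

    acc = {(b, ctx): [0, 0] for b in all_bins for ctx in contexts}
    for row in features.itertuples():
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        pos0, ctx_arr, meth, total = entry
        length = row.end - row.start
        lo = np.searchsorted(pos0, row.start - flank)
        hi = np.searchsorted(pos0, row.end + flank)
        for p, cc, mm, tt in zip(pos0[lo:hi], ctx_arr[lo:hi], meth[lo:hi], total[lo:hi]):
            if row.start <= p < row.end:  # body
                r = (p - row.start) / length if row.strand == "+" else \
                    (row.end - 1 - p) / length
                b = min(int(r * body_bins), body_bins - 1)
            else:
                if p < row.start:
                    dist = row.start - p  # bases upstream in + orientation
                    upstream = row.strand == "+"
                else:
                    dist = p - (row.end - 1)
                    upstream = row.strand == "-"
                if upstream:
                    b = -((dist + flank_bin - 1) // flank_bin)  # -ceil(dist/flank_bin)
                else:
                    b = body_bins + (dist - 1) // flank_bin
            slot = acc.get((b, cc))
            if slot is not None:
                slot[0] += mm
                slot[1] += tt

    rows = []
    for b in all_bins:
        segment = "body" if 0 <= b < body_bins else ("upstream" if b < 0 else "downstream")
        for ctx in contexts:
            m, t = acc[(b, ctx)]
            frac = m / t if t > 0 else np.nan
            rows.append((int(b), segment, ctx, m, t, frac, len(features)))
    return pd.DataFrame(rows, columns=["bin", "segment", "context", "meth",
                                       "total", "fraction", "n_features"])
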