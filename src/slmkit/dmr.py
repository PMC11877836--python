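"""Sliding-window DMR calling between two conditions.

Re-implements a windowed differential-methylation screen of the kind used
to define RdDM-target loci from an rdr2-mutant versus wild-type CHH
comparison: per-window Fisher's exact tests on pooled counts with
Benjamini-Hochberg correction, a minimum number of effective cytosines per
window, and a minimum percent methylation difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from slmkit.io import coverage_filter
from slmkit.stats import bh_qvalues, fisher_exact_two_sided


@dataclass
class DmrParams:
    """Windowed DMR screen thresholds (CHH defaults as printed)."""

    window: int = 50
    step: int = 50
    min_cov: int = 5          # per-cytosine coverage for an effective site
    min_cytosines: int = 10   # effective sites per retained window
    q_max: float = 0.005
    min_diff: float = 10.0    # percent methylation difference, strict
    context: str = "CHH"

    def __post_init__(self):
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if min(self.window, self.step, self.min_cov, self.min_cytosines) < 0 or \
                min(self.q_max, self.min_diff) < 0:
            raise ValueError("all thresholds must be >= 0")


def call_dmrs(cond_a: pd.DataFrame, cond_b: pd.DataFrame,
              params: DmrParams | None = None) -> pd.DataFrame:
    """Call DMRs of `params.context` between two methylomes.

    Effective sites are cytosines of the context covered by at least
    `min_cov` reads in *both* conditions.  Windows (width `window`, step
    `step`) with at least `min_cytosines` effective sites are tested with a
    two-sided Fisher's exact test on pooled counts; q-values are BH over
    retained windows.  A window is a DMR iff q < q_max and
    |fraction_a - fraction_b| * 100 > min_diff.  Direction is relative to
    condition a: "hyper" where a exceeds b.

    With step < window the scan produces overlapping windows; runs of
    overlapping called windows are collapsed to the lowest-q window.

    Returns a locus table: chrom, start, end, n_cytosines, frac_a, frac_b,
    diff (signed, a - b), p, q, direction, label ("DMR").
    """
    params = params or DmrParams()
    a = coverage_filter(cond_a[cond_a["context"] == params.context], params.min_cov)
    b = coverage_filter(cond_b[cond_b["context"] == params.context], params.min_cov)
    joined = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    if len(joined) == 0:
        warnings.warn("no effective sites shared by both conditions; no DMRs")
        return _empty()

    window_frames = []
    pos0 = joined["pos"].to_numpy() - 1
    for offset in range(0, params.window, params.step):
        win = (pos0 - offset) // params.window
        in_scan = pos0 >= offset  # sites left of the first offset window are covered by offset 0
        g = joined[in_scan].groupby(
            [joined["chrom"][in_scan], win[in_scan]], observed=True)
        agg = g.agg(n_cytosines=("pos", "size"),
                    meth_a=("meth_a", "sum"), total_a=("total_a", "sum"),
                    meth_b=("meth_b", "sum"), total_b=("total_b", "sum"))
        agg.index.names = ["chrom", "win"]
        agg = agg.reset_index()
        agg["start"] = agg["win"] * params.window + offset
        agg["end"] = agg["start"] + params.window
        window_frames.append(agg.drop(columns="win"))
    windows = pd.concat(window_frames, ignore_index=True)
    windows = windows[windows["n_cytosines"] >= params.min_cytosines].reset_index(drop=True)
    if len(windows) == 0:
        warnings.warn("no windows reach the effective-cytosine minimum; no DMRs")
        return _empty()

    windows["p"] = fisher_exact_two_sided(
        windows["meth_a"].to_numpy(),
        (windows["total_a"] - windows["meth_a"]).to_numpy(),
        windows["meth_b"].to_numpy(),
        (windows["total_b"] - windows["meth_b"]).to_numpy())
    windows["q"] = bh_qvalues(windows["p"].to_numpy())
    windows["frac_a"] = windows["meth_a"] / windows["total_a"]
    windows["frac_b"] = windows["meth_b"] / windows["total_b"]
    windows["diff"] = windows["frac_a"] - windows["frac_b"]

    called = windows[(windows["q"] < params.q_max) &
                     (windows["diff"].abs() * 100 > params.min_diff)].copy()
    called = called.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    if params.step < params.window and len(called) > 1:
        called = _dedup_overlapping(called)

    called["direction"] = np.where(called["diff"] > 0, "hyper", "hypo")
    called["label"] = "DMR"
    cols = ["chrom", "start", "end", "n_cytosines", "frac_a", "frac_b",
            "diff", "p", "q", "direction", "label"]
    return called[cols]


def _dedup_overlapping(called: pd.DataFrame) -> pd.DataFrame:
    """Keep the lowest-q window per run of overlapping called windows."""
    keep_rows = []
    run = [called.iloc[0]]
    for _, row in called.iloc[1:].iterrows():
        last = run[-1]
        if row["chrom"] == last["chrom"] and row["start"] < last["end"]:
            run.append(row)
        else:
            keep_rows.append(min(run, key=lambda r: (r["q"], r["start"])))
            run = [row]
    keep_rows.append(min(run, key=lambda r: (r["q"], r["start"])))
    return pd.DataFrame(keep_rows).reset_index(drop=True)


def _empty() -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_cytosines", "frac_a", "frac_b",
            "diff", "p", "q", "direction", "label"]
    return pd.DataFrame(columns=cols)


MAPPING_COLUMNS = ["src_chrom", "src_start", "src_end",
                   "tgt_chrom", "tgt_start", "tgt_end"]


def homolog_transfer(loci: pd.DataFrame, mapping: pd.DataFrame):
    """Lift loci through a table of source-to-target homologous intervals.

    `mapping` carries at least the six interval columns (plus optional
    ``identity`` and ``evalue`` from the upstream homology search).  For a
    locus overlapping several source intervals the best mapping wins:
    lowest e-value, then highest identity, then longest source interval;
    remaining ties keep the first row and are logged.  The locus is lifted
    by offset within the source interval, scaled when source and target
    lengths differ, and clipped to the target interval.

    Returns (mapped, unmapped): mapped loci in target coordinates with the
    original interval recorded, and the loci with no overlapping mapping.
    """
    for col in MAPPING_COLUMNS:
        if col not in mapping.columns:
            raise ValueError(f"mapping table lacks column {col!r}")
    mapping = mapping.copy()
    if "evalue" not in mapping.columns:
        mapping["evalue"] = 0.0
    if "identity" not in mapping.columns:
        mapping["identity"] = 100.0

    mapped_rows, unmapped_rows = [], []
    for idx, locus in loci.iterrows():
        cand = mapping[(mapping["src_chrom"] == locus["chrom"]) &
                       (mapping["src_start"] < locus["end"]) &
                       (mapping["src_end"] > locus["start"])]
        if len(cand) == 0:
            unmapped_rows.append(locus)
            continue
        src_len = cand["src_end"] - cand["src_start"]
        cand = cand.assign(_len=src_len).sort_values(
            by=["evalue", "identity", "_len"],
            ascending=[True, False, False], kind="mergesort")
        best = cand.iloc[0]
        scale = (best["tgt_end"] - best["tgt_start"]) / max(best["src_end"] - best["src_start"], 1)
        new_start = int(best["tgt_start"] + round((locus["start"] - best["src_start"]) * scale))
        new_end = int(best["tgt_start"] + round((locus["end"] - best["src_start"]) * scale))
        new_start = int(np.clip(new_start, best["tgt_start"], best["tgt_end"] - 1))
        new_end = int(np.clip(new_end, new_start + 1, best["tgt_end"]))
        row = locus.copy()
        row["src_chrom"], row["src_start"], row["src_end"] = \
            locus["chrom"], locus["start"], locus["end"]
        row["chrom"], row["start"], row["end"] = best["tgt_chrom"], new_start, new_end
        mapped_rows.append(row)
    mapped = pd.DataFrame(mapped_rows).reset_index(drop=True) if mapped_rows else \
        pd.DataFrame(columns=list(loci.columns) + ["src_chrom", "src_start", "src_end"])
    unmapped = pd.DataFrame(unmapped_rows).reset_index(drop=True) if unmapped_rows else \
        pd.DataFrame(columns=loci.columns)
    return mapped, unmapped
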