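"""Calling of sex-cell hypermethylated loci (SLM-like / canonical SLH-like).

The procedure compares fractional methylation in fixed 50-bp windows
between the average of the male sex cell types (meiocyte, microspore,
pollen) and a somatic reference (leaf):

1.  *Screen*: keep windows with per-context differences
    diff_CG > 0, diff_CHG > 0, diff_CHH > 0 and
    diff_CG + diff_CHG + diff_CHH > 0.2, where diff_X is the unweighted
    mean of sex-cell window fractions minus the somatic fraction.
2.  *Merge*: candidate windows within 100 bp of each other are merged;
    merged loci shorter than 100 bp are discarded.
3.  *Test*: total methylation (all contexts, sex groups pooled) against
    the somatic counts with a two-sided Fisher's exact test, p < 0.001.
4.  *Consistency*: every sex cell type individually must be more
    methylated than the somatic reference over the locus.
5.  *Classify*: loci with somatic CHH < 0.05 and CHG < 0.1 (low somatic
    RdDM activity) are SLM-like; the rest are canonical SLH-like.

All inequalities are strict; boundary values fall on the non-passing /
non-SLM side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from slmkit.io import CONTEXTS
from slmkit.intervals import merge_within_gap
from slmkit.profiles import interval_quantify, window_methylation
from slmkit.stats import fisher_exact_two_sided

log = logging.getLogger("slmkit.slm")

SLM_LIKE = "SLM_like"
SLH_LIKE = "canonical_SLH_like"


@dataclass
class SlmParams:
    """Thresholds of the locus-calling procedure (defaults as printed)."""

    window: int = 50
    merge_gap: int = 100          # "within 100 bp", inclusive
    min_len: int = 100            # merged locus must cover >= 100 bp
    sum_diff_min: float = 0.2
    p_max: float = 0.001
    leaf_chh_max: float = 0.05
    leaf_chg_max: float = 0.1
    contexts: tuple = CONTEXTS

    def __post_init__(self):
        if min(self.window, self.merge_gap, self.min_len) < 0 or \
                min(self.sum_diff_min, self.p_max, self.leaf_chh_max, self.leaf_chg_max) < 0:
            raise ValueError("all thresholds must be >= 0")
        if self.sum_diff_min > 3:
            raise ValueError("sum of three per-context differences cannot exceed 3")


def _group_window_frames(group_methylomes: dict, params: SlmParams,
                         chrom_sizes=None) -> dict:
    return {name: window_methylation(m, window=params.window,
                                     contexts=params.contexts,
                                     chrom_sizes=chrom_sizes)
            for name, m in group_methylomes.items()}


def screen_windows(group_windows: dict, sex_groups, somatic_group: str,
                   params: SlmParams | None = None) -> pd.DataFrame:
    """Windows hypermethylated in the sex-cell average relative to soma.

    `group_windows` maps group name to a :func:`window_methylation` frame.
    Windows lacking coverage in any group for any context are excluded
    (they cannot support all three per-context differences).  Returns the
    passing windows with their per-context differences.
    """
    params = params or SlmParams()
    if len(sex_groups) < 1:
        raise ValueError("need at least one sex group")
    if somatic_group in sex_groups:
        raise ValueError("somatic group cannot also be a sex group")

    frames = []
    for name in list(sex_groups) + [somatic_group]:
        w = group_windows[name]
        w = w[w["covered"]]
        piv = w.pivot_table(index=["chrom", "start", "end"], columns="context",
                            values="fraction", observed=True)
        piv.columns = [f"{name}:{c}" for c in piv.columns]
        # a group may lack a context altogether; such windows must drop out
        piv = piv.reindex(columns=[f"{name}:{c}" for c in params.contexts])
        frames.append(piv)
    joined = pd.concat(frames, axis=1, join="inner").dropna()
    if len(joined) == 0:
        warnings.warn("no windows covered in all groups; empty screen result")
        return pd.DataFrame(columns=["chrom", "start", "end",
                                     "diff_CG", "diff_CHG", "diff_CHH"])

    for ctx in params.contexts:
        sex_mean = joined[[f"{g}:{ctx}" for g in sex_groups]].mean(axis=1)
        joined[f"diff_{ctx}"] = sex_mean - joined[f"{somatic_group}:{ctx}"]

    diff_cols = [f"diff_{c}" for c in params.contexts]
    passing = (joined[diff_cols] > 0).all(axis=1) & \
        (joined[diff_cols].sum(axis=1) > params.sum_diff_min)
    out = joined.loc[passing, diff_cols].reset_index()
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def merge_candidates(windows: pd.DataFrame, params: SlmParams | None = None) -> pd.DataFrame:
    """Merge candidate windows within `merge_gap` bp; drop short loci."""
    params = params or SlmParams()
    merged = merge_within_gap(windows[["chrom", "start", "end"]], gap=params.merge_gap)
    merged = merged[(merged["end"] - merged["start"]) >= params.min_len]
    return merged.rename(columns={"n_merged": "n_windows"}).reset_index(drop=True)


def _pool(quant: pd.DataFrame) -> pd.DataFrame:
    """All-context (meth, total) per interval from an interval_quantify frame."""
    return quant.groupby("interval", observed=True)[["meth", "total"]].sum()


def fisher_screen(loci_counts_sex: pd.DataFrame, loci_counts_somatic: pd.DataFrame) -> np.ndarray:
    """Two-sided Fisher p per locus on pooled total methylation.

    Inputs are aligned frames with meth/total columns: sex counts pooled
    over all sex groups and contexts versus somatic counts.
    """
    return fisher_exact_two_sided(
        loci_counts_sex["meth"].to_numpy(),
        (loci_counts_sex["total"] - loci_counts_sex["meth"]).to_numpy(),
        loci_counts_somatic["meth"].to_numpy(),
        (loci_counts_somatic["total"] - loci_counts_somatic["meth"]).to_numpy(),
    )


def consistency_filter(per_group_pooled: dict, somatic_group: str,
                       sex_groups) -> pd.Series:
    """True where every sex group is strictly more methylated than soma.

    `per_group_pooled` maps group -> frame indexed by locus with pooled
    all-context meth/total.  A sex group with zero total over a locus
    cannot assert "higher" and fails the filter.
    """
    som = per_group_pooled[somatic_group]
    with np.errstate(invalid="ignore", divide="ignore"):
        som_frac = np.where(som["total"] > 0, som["meth"] / som["total"], np.nan)
    ok = pd.Series(True, index=som.index)
    for g in sex_groups:
        gp = per_group_pooled[g]
        has = gp["total"] > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(has, gp["meth"] / gp["total"], np.nan)
        ok &= has & pd.Series(frac > som_frac, index=gp.index)
    return ok


def classify_locus(leaf_chh: float, leaf_chg: float,
                   params: SlmParams | None = None) -> str:
    """SLM-like iff somatic CHH and CHG are both below their caps.

    Somatic fractions that cannot be computed (no covered cytosines of the
    context) cannot establish "lower than" and classify as canonical
    SLH-like.
    """
    params = params or SlmParams()
    if np.isnan(leaf_chh) or np.isnan(leaf_chg):
        return SLH_LIKE
    if leaf_chh < params.leaf_chh_max and leaf_chg < params.leaf_chg_max:
        return SLM_LIKE
    return SLH_LIKE


def call_slm(group_methylomes: dict, sex_groups, somatic_group: str,
             params: SlmParams | None = None, chrom_sizes: dict | None = None):
    """Full locus-calling pipeline: screen, merge, test, filter, classify.

    Parameters
    ----------
    group_methylomes
        {group name: merged, coverage-filtered methylome table}.
    sex_groups, somatic_group
        Names of the sex cell types and of the somatic reference; all must
        be keys of `group_methylomes`.

    Returns
    -------
    (loci, summary)
        `loci` has one row per retained locus with interval, per-context
        differences, per-group per-context fractions, Fisher p and label.
        `summary` reports n_total, n_SLM_like, n_SLH_like and mean length.
    """
    params = params or SlmParams()
    windows = _group_window_frames(group_methylomes, params, chrom_sizes)
    cand = screen_windows(windows, sex_groups, somatic_group, params)
    log.info("screen: %d candidate windows", len(cand))
    merged = merge_candidates(cand, params)
    log.info("merge: %d candidate loci (>= %d bp)", len(merged), params.min_len)

    if len(merged) == 0:
        empty = _empty_loci(params)
        return empty, _summary(empty)

    quant = {g: interval_quantify(m, merged, contexts=params.contexts)
             for g, m in group_methylomes.items()}
    pooled = {g: _pool(q) for g, q in quant.items()}
    sex_pool = sum(pooled[g] for g in sex_groups)

    merged = merged.copy()
    merged["fisher_p"] = fisher_screen(sex_pool, pooled[somatic_group])
    keep = merged["fisher_p"] < params.p_max
    keep &= consistency_filter(pooled, somatic_group, sex_groups).to_numpy()

    loci = merged[keep].reset_index(drop=True)
    idx = merged.index[keep]

    # locus-level per-group per-context fractions and differences
    ctx_frac = {}
    for g, q in quant.items():
        piv = q.pivot_table(index="interval", columns="context",
                            values="fraction", observed=True)
        ctx_frac[g] = piv.reindex(idx)
        for ctx in params.contexts:
            loci[f"frac_{g}_{ctx}"] = ctx_frac[g][ctx].to_numpy()
    for ctx in params.contexts:
        sex_mean = np.mean([ctx_frac[g][ctx].to_numpy() for g in sex_groups], axis=0)
        loci[f"diff_{ctx}"] = sex_mean - ctx_frac[somatic_group][ctx].to_numpy()

    loci["label"] = [
        classify_locus(chh, chg, params)
        for chh, chg in zip(loci[f"frac_{somatic_group}_CHH"],
                            loci[f"frac_{somatic_group}_CHG"])
    ]
    loci["length"] = loci["end"] - loci["start"]
    return loci, _summary(loci)


def _empty_loci(params: SlmParams) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_windows", "fisher_p", "label", "length"]
    return pd.DataFrame(columns=cols)


def _summary(loci: pd.DataFrame) -> dict:
    n = len(loci)
    return {
        "n_total": n,
        "n_SLM_like": int((loci["label"] == SLM_LIKE).sum()) if n else 0,
        "n_SLH_like": int((loci["label"] == SLH_LIKE).sum()) if n else 0,
        "mean_length": float(loci["length"].mean()) if n else float("nan"),
    }


def write_loci(loci: pd.DataFrame, bed_path=None, tsv_path=None) -> None:
    """Write called loci as BED6 (name=label, score=-log10 p) and/or TSV."""
    if bed_path is not None:
        with np.errstate(divide="ignore"):
            score = -np.log10(np.maximum(loci["fisher_p"].to_numpy(dtype=float), 1e-300))
        bed = pd.DataFrame({
            "chrom": loci["chrom"], "start": loci["start"], "end": loci["end"],
            "name": loci["label"], "score": np.round(score, 3), "strand": ".",
        })
        bed.to_csv(bed_path, sep="\t", header=False, index=False)
    if tsv_path is not None:
        loci.to_csv(tsv_path, sep="\t", index=False)
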