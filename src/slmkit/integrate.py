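"""Intersection of locus-targeted genes with differential-expression calls.

The package consumes an externally fitted differential-expression table
(gene, contrast, log2fc, pvalue) and applies the direction thresholds
here, so that downstream set algebra is reproducible: a gene is "up" in a
contrast iff p < p_max and log2fc >= lfc_min, "down" iff p < p_max and
log2fc <= -lfc_min, else "ns".  Note the fold-change bound is inclusive
while the p bound is strict.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import pandas as pd

UP, DOWN, NS = "up", "down", "ns"


def deg_classify(table: pd.DataFrame, p_max: float = 0.05,
                 lfc_min: float = 1.0) -> pd.DataFrame:
    """Add a three-way `direction` column per (gene, contrast) row.

    Rows with missing p or log2fc are flagged "ns" with a warning.
    """
    out = table.copy()
    missing = out["pvalue"].isna() | out["log2fc"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} rows lack p or log2fc; flagged ns")
    direction = pd.Series(NS, index=out.index)
    sig = (out["pvalue"] < p_max) & ~missing
    direction[sig & (out["log2fc"] >= lfc_min)] = UP
    direction[sig & (out["log2fc"] <= -lfc_min)] = DOWN
    out["direction"] = direction
    return out


def slm_deg_overlap(deg: pd.DataFrame, slm_genes) -> dict:
    """Overlap of locus-targeted genes with up/down calls per contrast.

    `deg` must carry gene, contrast and direction columns (see
    :func:`deg_classify`).  Returns per-contrast counts plus the union
    summary: how many targeted genes are differentially expressed in at
    least one contrast, with the denominator reported explicitly.
    """
    slm_genes = set(slm_genes)
    if not slm_genes:
        return {"contrasts": {}, "n_slm_genes": 0, "n_union_up": 0,
                "n_union_down": 0, "n_union_deg": 0, "union_fraction": float("nan")}
    universe = set(deg["gene"])
    if slm_genes and universe and not (slm_genes & universe):
        warnings.warn("locus-targeted gene ids share nothing with the DEG "
                      "table; check id spaces")
    per_contrast = {}
    union_up, union_down = set(), set()
    for contrast, sub in deg.groupby("contrast", observed=True):
        up = set(sub.loc[sub["direction"] == UP, "gene"])
        down = set(sub.loc[sub["direction"] == DOWN, "gene"])
        union_up |= up & slm_genes
        union_down |= down & slm_genes
        per_contrast[contrast] = {
            "n_up_slm": len(up & slm_genes),
            "n_down_slm": len(down & slm_genes),
            "n_up_total": len(up),
            "n_down_total": len(down),
        }
    union_deg = union_up | union_down
    return {
        "contrasts": per_contrast,
        "n_slm_genes": len(slm_genes),
        "n_union_up": len(union_up),
        "n_union_down": len(union_down),
        "n_union_deg": len(union_deg),
        "union_fraction": len(union_deg) / len(slm_genes),
    }


def venn_counts(sets: dict) -> dict:
    """Exclusive-region cardinalities for 2 or 3 named sets.

    Keys of the result are '&'-joined sorted name combinations; each count
    is the number of elements in exactly that combination of sets.  Region
    counts sum to the size of the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_counts supports exactly 2 or 3 sets")
    result = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set.union(set(), *(set(sets[n]) for n in names if n not in combo))
            result["&".join(sorted(combo))] = len(inside - outside)
    return result
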