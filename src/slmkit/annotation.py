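"""Relating called loci to gene/TE annotation.

Feature tables are DataFrames with columns: id, chrom, start, end (0-based
half-open), strand, kind ("gene" or "TE"), superfamily (TEs; empty for
genes).  Distances are unstranded gaps between closest interval edges;
"within N bp" is inclusive at exactly N.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from slmkit.intervals import nearest_gap, overlap_pairs, set_overlap_counts

FEATURE_KINDS = ("gene", "TE")

PROXIMITY_CLASSES = ("overlapping", "within_near", "beyond_near")


def proximity_classify(loci: pd.DataFrame, features: pd.DataFrame,
                       near: int = 500) -> pd.DataFrame:
    """Classify each locus by distance to the nearest gene and nearest TE.

    Classes: ``overlapping`` (shares >= 1 base), ``within_near`` (gap of
    0..`near` bp without a shared base) and ``beyond_near``.  Gene and TE
    classes are computed independently, so a locus near both counts in
    both per-kind summaries.
    """
    out = pd.DataFrame(index=loci.index)
    for kind in FEATURE_KINDS:
        feats = features[features["kind"] == kind]
        if len(feats) == 0:
            out[kind] = "beyond_near"
            continue
        gap = nearest_gap(loci, feats)
        cls = np.where(gap < 0, "overlapping",
                       np.where(gap <= near, "within_near", "beyond_near"))
        out[kind] = cls
    return out


def proximity_percentages(classes: pd.DataFrame) -> dict:
    """Per-kind percentage of loci in each proximity class (pie-chart data)."""
    result = {}
    n = len(classes)
    for kind in classes.columns:
        counts = classes[kind].value_counts()
        result[kind] = {c: 100.0 * counts.get(c, 0) / n if n else float("nan")
                        for c in PROXIMITY_CLASSES}
    return result


def target_genes(loci: pd.DataFrame, features: pd.DataFrame,
                 near: int = 500) -> pd.DataFrame:
    """Genes overlapping or within `near` bp of each locus.

    Returns one row per (locus, gene) pair with the locus index, gene id
    and gap (-1 for overlap).  A locus may target several genes; the
    deduplicated gene universe is ``result["gene_id"].unique()``.
    """
    genes = features[features["kind"] == "gene"]
    if len(genes) == 0 or len(loci) == 0:
        return pd.DataFrame(columns=["locus", "gene_id", "gap"])
    # widen loci by `near` on both sides, then compute exact gaps pairwise
    widened = loci[["chrom", "start", "end"]].copy()
    widened["start"] = (widened["start"] - near).clip(lower=0)
    widened["end"] = widened["end"] + near
    pairs = overlap_pairs(widened, genes[["chrom", "start", "end"]])
    rows = []
    for a_idx, b_idx in pairs.itertuples(index=False):
        locus = loci.loc[a_idx]
        gene = genes.loc[b_idx]
        if gene["start"] < locus["end"] and locus["start"] < gene["end"]:
            gap = -1
        elif gene["start"] >= locus["end"]:
            gap = gene["start"] - locus["end"]
        else:
            gap = locus["start"] - gene["end"]
        if gap <= near:
            rows.append((a_idx, gene["id"], gap))
    return pd.DataFrame(rows, columns=["locus", "gene_id", "gap"])


def locus_set_overlap(set_a: pd.DataFrame, set_b: pd.DataFrame,
                      min_overlap: int = 1) -> dict:
    """Overlap summary between two locus sets (see intervals.set_overlap_counts)."""
    return set_overlap_counts(set_a, set_b, min_overlap=min_overlap)


# --- annotation file formats -------------------------------------------------

_GFF_COLS = ["chrom", "source", "type", "start", "end", "score", "strand",
             "frame", "attributes"]


def read_gff3(path, te_types=("transposable_element",), gene_types=("gene",)) -> pd.DataFrame:
    """Read a GFF3 file into a feature table (1-based closed to 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=_GFF_COLS)
    df = df[df["type"].isin(set(te_types) | set(gene_types))].reset_index(drop=True)

    def attr(s, key):
        m = re.search(rf"{key}=([^;]+)", s)
        return m.group(1) if m else ""

    out = pd.DataFrame({
        "id": [attr(s, "ID") for s in df["attributes"]],
        "chrom": df["chrom"],
        "start": df["start"] - 1,
        "end": df["end"],
        "strand": df["strand"],
        "kind": np.where(df["type"].isin(gene_types), "gene", "TE"),
        "superfamily": [attr(s, "superfamily") for s in df["attributes"]],
    })
    out["length"] = out["end"] - out["start"]
    return out


def write_gff3(features: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            ftype = "gene" if row.kind == "gene" else "transposable_element"
            attrs = f"ID={row.id}"
            if getattr(row, "superfamily", ""):
                attrs += f";superfamily={row.superfamily}"
            fh.write("\t".join(map(str, [row.chrom, "slmkit", ftype,
                                         row.start + 1, row.end, ".",
                                         row.strand, ".", attrs])) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame (0-based half-open, as on disk)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    out = df[["chrom", "start", "end"]].copy()
    if name_col is not None and name_col in df.columns:
        out["name"] = df[name_col]
    out.to_csv(path, sep="\t", header=False, index=False)
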