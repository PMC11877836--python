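"""Reading, validation, filtering and merging of per-cytosine methylation calls.

The canonical in-memory methylome is a pandas DataFrame with columns

    chrom   str    chromosome name
    pos     int    1-based cytosine position (as in CX reports)
    strand  str    '+' or '-'
    context str    'CG', 'CHG' or 'CHH'
    meth    int    methylated read count
    total   int    total (informative) read count, total >= meth

sorted by (chrom, pos, strand).  Fractional methylation at a cytosine is
``meth / total``.  Two on-disk dialects are supported:

``cx``
    Bismark-style CX report: chrom, pos (1-based), strand,
    count_methylated, count_unmethylated, context, trinucleotide.
    Rows with context ``Unknown`` (chromosome-end cytosines lacking two
    downstream bases) are dropped on read.

``bedgraph_cov``
    Extended bedGraph: chrom, start (0-based), end, fraction in [0,1],
    count_methylated, count_total, strand, context.

Coordinates are 1-based inclusive in CX files and 0-based half-open in all
BED-style interfaces; internal window arithmetic uses 0-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

_CX_COLS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide"]
_BG_COLS = ["chrom", "start", "end", "fraction", "meth", "total", "strand", "context"]

METHYLOME_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]


@dataclass
class SampleGroup:
    """A named cell type with one or more replicate methylome tables."""

    name: str
    replicate_tables: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.replicate_tables) < 1:
            raise ValueError(f"sample group {self.name!r} needs >=1 replicate")


def _fail(path, lineno, message):
    raise ValueError(f"{path}: line {lineno}: {message}")


def read_cx_report(path, dialect: str = "cx") -> pd.DataFrame:
    """Parse a per-cytosine call file into the canonical methylome table.

    Malformed lines are rejected with their (1-based) line number; the
    first offending line is reported.  Output is sorted by
    (chrom, pos, strand) and duplicate positions are an error.
    """
    if dialect == "cx":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=_CX_COLS, dtype=str)
        return _finalize_cx(df, path)
    if dialect == "bedgraph_cov":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=_BG_COLS, dtype=str)
        return _finalize_bedgraph(df, path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'cx' or 'bedgraph_cov'")


def _first_bad(mask: pd.Series) -> int:
    """1-based file line number of the first True entry."""
    return int(mask.idxmax()) + 1


def _finalize_cx(df: pd.DataFrame, path) -> pd.DataFrame:
    for col in ("meth", "unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        if bad.any():
            _fail(path, _first_bad(bad), f"non-integer or negative {col} count")
        df[col] = vals.astype(np.int64)
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos < 1) | (pos % 1 != 0)
    if bad.any():
        _fail(path, _first_bad(bad), "position must be an integer >= 1")
    df["pos"] = pos.astype(np.int64)

    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        _fail(path, _first_bad(bad), f"bad strand {df['strand'][bad].iloc[0]!r}")
    known = df["context"].isin(CONTEXTS)
    unknown = df["context"] == "Unknown"
    bad = ~(known | unknown)
    if bad.any():
        _fail(path, _first_bad(bad), f"unknown context token {df['context'][bad].iloc[0]!r}")

    out = df.loc[known, ["chrom", "pos", "strand", "context", "meth"]].copy()
    out["total"] = df.loc[known, "meth"] + df.loc[known, "unmeth"]
    return _sort_and_check(out, path)


def _finalize_bedgraph(df: pd.DataFrame, path) -> pd.DataFrame:
    for col in ("start", "end", "meth", "total"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        if bad.any():
            _fail(path, _first_bad(bad), f"non-integer or negative {col}")
        df[col] = vals.astype(np.int64)
    bad = df["meth"] > df["total"]
    if bad.any():
        _fail(path, _first_bad(bad), "count_methylated exceeds count_total")
    frac = pd.to_numeric(df["fraction"], errors="coerce")
    bad = frac.isna() | (frac < 0) | (frac > 1)
    if bad.any():
        _fail(path, _first_bad(bad), "fraction must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        implied = np.where(df["total"] > 0, df["meth"] / df["total"].replace(0, 1), 0.0)
    bad = (df["total"] > 0) & (np.abs(frac - implied) > 1e-6)
    if bad.any():
        _fail(path, _first_bad(bad), "fraction inconsistent with counts")
    bad = df["end"] != df["start"] + 1
    if bad.any():
        _fail(path, _first_bad(bad), "per-cytosine record must span one base")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        _fail(path, _first_bad(bad), f"bad strand {df['strand'][bad].iloc[0]!r}")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        _fail(path, _first_bad(bad), f"unknown context token {df['context'][bad].iloc[0]!r}")

    out = df[["chrom", "strand", "context", "meth", "total"]].copy()
    out["pos"] = df["start"] + 1  # to 1-based
    return _sort_and_check(out[METHYLOME_COLUMNS], path)


def _sort_and_check(df: pd.DataFrame, path) -> pd.DataFrame:
    df = df[METHYLOME_COLUMNS].sort_values(
        ["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(["chrom", "pos", "strand"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record at {row.chrom}:{row.pos}({row.strand})")
    return df


def write_cx_report(table: pd.DataFrame, path) -> None:
    """Write the canonical methylome table as a CX report (round-trips with
    :func:`read_cx_report`).  The trinucleotide column repeats the context."""
    out = pd.DataFrame({
        "chrom": table["chrom"],
        "pos": table["pos"],
        "strand": table["strand"],
        "meth": table["meth"],
        "unmeth": table["total"] - table["meth"],
        "context": table["context"],
        "trinucleotide": table["context"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def merge_replicates(group) -> pd.DataFrame:
    """Sum counts across replicates per (chrom, pos, strand).

    Accepts a :class:`SampleGroup` or a plain list of methylome tables.
    Contexts must agree wherever replicates share a position.
    """
    tables = group.replicate_tables if isinstance(group, SampleGroup) else list(group)
    if len(tables) == 0:
        raise ValueError("need at least one replicate to merge")
    if len(tables) == 1:
        return tables[0].reset_index(drop=True)
    cat = pd.concat(tables, ignore_index=True)
    grouped = cat.groupby(["chrom", "pos", "strand"], sort=True, observed=True)
    ctx_n = grouped["context"].nunique()
    if (ctx_n > 1).any():
        key = ctx_n[ctx_n > 1].index[0]
        raise ValueError(f"context disagreement across replicates at {key}")
    merged = grouped.agg(context=("context", "first"),
                         meth=("meth", "sum"),
                         total=("total", "sum")).reset_index()
    return merged[METHYLOME_COLUMNS]


def coverage_filter(table: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Retain cytosines with ``total >= min_reads`` informative reads.

    The default of 5 is the single coverage knob used throughout the
    pipeline; both the ">5" and ">=5" readings of typical methods wording
    are reachable by passing 6 or 5.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return table[table["total"] >= min_reads].reset_index(drop=True)


def replicate_correlation(group, window: int = 1000) -> pd.DataFrame:
    """Pairwise Pearson correlation of windowed fractional methylation.

    Counts are pooled over all contexts into `window`-bp windows per
    replicate; for each replicate pair only windows covered (total > 0) in
    both members enter the correlation.  Returns a symmetric DataFrame with
    unit diagonal, indexed by replicate number.
    """
    tables = group.replicate_tables if isinstance(group, SampleGroup) else list(group)
    if len(tables) < 2:
        raise ValueError("replicate correlation needs >= 2 replicates")

    fracs = []
    for t in tables:
        win = (t["pos"] - 1) // window
        g = t.groupby([t["chrom"], win], observed=True)[["meth", "total"]].sum()
        g = g[g["total"] > 0]
        fracs.append(g["meth"] / g["total"])

    n = len(fracs)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            joined = pd.concat([fracs[i], fracs[j]], axis=1, join="inner")
            if len(joined) < 2:
                r = np.nan
            else:
                r = joined.corr().iloc[0, 1]
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat,
                        index=range(n), columns=range(n))


def load_sample_groups(samples: dict, dialect: str = "cx",
                       min_reads: int = 5) -> dict:
    """Read, merge and coverage-filter a {group: [paths]} mapping.

    Returns {group: methylome DataFrame}; the order of `samples` is kept.
    """
    out = {}
    for name, paths in samples.items():
        tables = [read_cx_report(p, dialect=dialect) for p in paths]
        merged = merge_replicates(SampleGroup(name, tables))
        out[name] = coverage_filter(merged, min_reads=min_reads)
    return out
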