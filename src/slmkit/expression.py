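"""TPM computation, TE activity classification and expression clustering.

Abundance follows the standard transcripts-per-million definition,
TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j) per sample, after removing
an exclusion set (e.g. rRNA ids) from the matrix.  Activity of a TE is
decided from its TPM across cell types; active TEs are partitioned by
k-means on per-feature z-scored TPM, with clusters renumbered
deterministically by the cell type at which each centroid peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans

ACTIVE, INACTIVE, INTERMEDIATE = "active", "inactive", "intermediate"

# renumbering priority: the cell type whose peak defines cluster 1, 2, ...
DEFAULT_PEAK_ORDER = ("meiocyte", "microspore", "leaf", "pollen")


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance container (counts, TPM, z-scores)."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    lengths: pd.Series

    def zscores(self) -> pd.DataFrame:
        """Per-feature z-scores of TPM across samples (rows with zero
        spread are set to zeros with a warning)."""
        mean = self.tpm.mean(axis=1)
        sd = self.tpm.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            warnings.warn(f"{int(flat.sum())} features have zero expression "
                          "spread; their z-scores are set to 0")
        sd = sd.replace(0, 1.0)
        z = self.tpm.sub(mean, axis=0).div(sd, axis=0)
        z[flat] = 0.0
        return z


def percent(part: float, whole: float) -> float:
    """Percentage of `part` in `whole` (NaN when the denominator is zero)."""
    return 100.0 * part / whole if whole else float("nan")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series,
                exclude=()) -> ExpressionMatrix:
    """Length-normalise raw counts to TPM after removing excluded features.

    `counts` is features x samples; `lengths` gives feature lengths in bp.
    Unknown ids in `exclude` produce a warning, not an error.  A sample
    with zero total counts yields an all-zero TPM column with a warning.
    """
    exclude = set(exclude)
    unknown = exclude - set(counts.index)
    if unknown:
        warnings.warn(f"{len(unknown)} exclusion ids not in the count matrix")
    keep = [i for i in counts.index if i not in exclude]
    counts = counts.loc[keep]
    lengths = lengths.loc[keep]
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")

    rpk = counts.div(lengths / 1000.0, axis=0)
    denom = rpk.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        warnings.warn(f"samples with zero counts: {list(denom.index[zero_cols])}")
    denom = denom.replace(0, 1.0)
    tpm = rpk.div(denom, axis=1) * 1e6
    return ExpressionMatrix(counts=counts, tpm=tpm, lengths=lengths)


def classify_activity(matrix: ExpressionMatrix, te_ids=None,
                      active_min: float = 10.0,
                      inactive_max: float = 0.001) -> pd.DataFrame:
    """Three-way activity call per TE from its TPM across samples.

    active: TPM > `active_min` in at least one sample; inactive: TPM <
    `inactive_max` in all samples; otherwise intermediate (excluded from
    both downstream sets).  Returns id-indexed frame with status, max_tpm.
    """
    tpm = matrix.tpm if te_ids is None else matrix.tpm.loc[list(te_ids)]
    max_tpm = tpm.max(axis=1)
    status = np.where(max_tpm > active_min, ACTIVE,
                      np.where(max_tpm < inactive_max, INACTIVE, INTERMEDIATE))
    return pd.DataFrame({"status": status, "max_tpm": max_tpm}, index=tpm.index)


def cluster_active(matrix: ExpressionMatrix, active_ids, k: int = 4,
                   seed: int = 0, peak_order=DEFAULT_PEAK_ORDER,
                   superfamilies: pd.Series | None = None):
    """K-means partition of active TEs on per-feature z-scored TPM.

    Cluster numbers are not the arbitrary k-means labels: clusters are
    renumbered 1..k by the sample at which their centroid peaks, following
    `peak_order` for samples named there (ties broken by descending peak
    height) and column order for the rest.  This makes the labelling a
    pure function of the fitted centroids, so reruns with the same seed
    reproduce identical output.

    Returns (labels, summaries): labels is an id-indexed Series of cluster
    numbers; summaries is a per-cluster DataFrame with n, pct_of_active,
    peak sample and (if `superfamilies` is given) composition columns.
    """
    active_ids = list(active_ids)
    if len(active_ids) < k:
        raise ValueError(f"need >= k={k} active features to cluster")
    sub = ExpressionMatrix(counts=matrix.counts.loc[active_ids],
                           tpm=matrix.tpm.loc[active_ids],
                           lengths=matrix.lengths.loc[active_ids])
    z = sub.zscores()
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(z.to_numpy())

    columns = list(z.columns)
    order_key = {}
    ordered_cols = [c for c in peak_order if c in columns] + \
        [c for c in columns if c not in peak_order]
    for raw_label in range(k):
        centroid = km.cluster_centers_[raw_label]
        peak_idx = int(np.argmax(centroid))
        peak_col = columns[peak_idx]
        order_key[raw_label] = (ordered_cols.index(peak_col), -centroid[peak_idx])
    renumber = {raw: i + 1 for i, raw in
                enumerate(sorted(range(k), key=lambda r: order_key[r]))}
    labels = pd.Series([renumber[r] for r in raw], index=z.index, name="cluster")

    rows = []
    for cl in range(1, k + 1):
        members = labels.index[labels == cl]
        raw_label = [r for r, new in renumber.items() if new == cl][0]
        peak_col = columns[int(np.argmax(km.cluster_centers_[raw_label]))]
        row = {"cluster": cl, "n": len(members),
               "pct_of_active": percent(len(members), len(active_ids)),
               "peak": peak_col}
        if superfamilies is not None:
            comp = superfamilies.loc[members].value_counts()
            for fam, cnt in comp.items():
                row[f"n_{fam}"] = int(cnt)
        rows.append(row)
    summaries = pd.DataFrame(rows).set_index("cluster")
    return labels, summaries


def length_composition(calls: pd.DataFrame, lengths: pd.Series,
                       breaks=(2000,)) -> dict:
    """Length-bin fractions per activity status plus an active-vs-inactive test.

    `calls` is the classify_activity output; `breaks` are bin edges in bp
    (bins: [0, b1), [b1, b2), ..., [bk, inf)).  The comparison of active
    and inactive lengths uses a two-sided Wilcoxon rank-sum test.  Empty
    status classes are flagged with NaN fractions.
    """
    breaks = sorted(breaks)
    edges = [0] + list(breaks) + [np.inf]
    bin_labels = [f"<{b}" for b in breaks] + [f">={breaks[-1]}"]
    result = {"bins": bin_labels, "fractions": {}}
    for status in (ACTIVE, INACTIVE, INTERMEDIATE):
        ids = calls.index[calls["status"] == status]
        if len(ids) == 0:
            result["fractions"][status] = [float("nan")] * len(bin_labels)
            continue
        hist, _ = np.histogram(lengths.loc[ids], bins=edges)
        result["fractions"][status] = list(hist / len(ids))
    act = lengths.loc[calls.index[calls["status"] == ACTIVE]]
    inact = lengths.loc[calls.index[calls["status"] == INACTIVE]]
    if len(act) and len(inact):
        stat, p = mannwhitneyu(act, inact, alternative="two-sided")
        result["ranksum_p"] = float(p)
    else:
        result["ranksum_p"] = float("nan")
    return result
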