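"""Time-course expression transforms, K-means clustering, heatmap.

Supported transforms: TPM, log2(TPM+1), per-row log2 fold-change against a
baseline time point, and per-row Z-scores of either log measure.  Rows are
clustered by seeded K-means and ordered within each cluster by
complete-linkage hierarchical clustering (Euclidean distance); columns may
also be hierarchically clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

PSEUDOCOUNT = 1.0

TRANSFORMS = (
    "raw_counts",
    "tpm",
    "log_tpm",
    "log_fc",
    "zscore(log_tpm)",
    "zscore(log_fc)",
)


@dataclass
class ExpressionMatrix:
    """Transcripts x time-points values with transform provenance."""

    values: pd.DataFrame  # rows = transcripts, columns = time points
    transform: str = "raw_counts"
    baseline: str | None = None

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.transform == "log_fc" and self.baseline is None:
            raise ValueError("log_fc matrix requires a baseline column")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterAssignment:
    """K-means labels (1..k) plus row/column display orders.

    ``row_order`` groups rows contiguously by cluster label.
    """

    labels: pd.Series  # row_id -> cluster label
    row_order: list[str]
    col_order: list[str]

    def __post_init__(self) -> None:
        seen = [self.labels[r] for r in self.row_order]
        blocks = [lab for i, lab in enumerate(seen) if i == 0 or lab != seen[i - 1]]
        if len(blocks) != len(set(blocks)):
            raise ValueError("row_order does not group clusters contiguously")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million from a counts matrix and transcript lengths (bp).

    Per column: rate_i = count_i / length_i(kb); TPM_i = rate_i / sum(rate)
    * 1e6.  All-zero columns stay all-zero.
    """
    missing = set(counts.index) - set(lengths.index)
    if missing:
        raise KeyError(f"lengths missing for transcripts: {sorted(missing)[:5]}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    length_kb = lengths.reindex(counts.index).astype(float) / 1000.0
    if (length_kb <= 0).any():
        raise ValueError("transcript lengths must be positive")
    rate = counts.div(length_kb, axis=0)
    totals = rate.sum(axis=0)
    tpm = rate.div(totals.where(totals > 0, 1.0), axis=1) * 1e6
    return ExpressionMatrix(values=tpm, transform="tpm")


def transform(matrix: ExpressionMatrix, mode: str, baseline: str | None = None) -> ExpressionMatrix:
    """Apply one of {log_tpm, log_fc, zscore} to a matrix.

    log_tpm = log2(TPM + 1); log_fc = log2((TPM + 1) / (TPM_baseline + 1))
    per row; zscore = per-row (x - mean) / sd across columns, with sd-0 rows
    mapped to all zeros.  ``zscore`` applies to a log-scale matrix and tags
    the result zscore(log_tpm) or zscore(log_fc).
    """
    v = matrix.values
    if mode == "log_tpm":
        if matrix.transform != "tpm":
            raise ValueError(f"log_tpm requires a tpm matrix, got {matrix.transform}")
        return ExpressionMatrix(np.log2(v + PSEUDOCOUNT), "log_tpm")
    if mode == "log_fc":
        if matrix.transform != "tpm":
            raise ValueError(f"log_fc requires a tpm matrix, got {matrix.transform}")
        if baseline is None or baseline not in v.columns:
            raise ValueError(f"log_fc requires a baseline column; got {baseline!r}")
        shifted = v + PSEUDOCOUNT
        fc = np.log2(shifted.div(shifted[baseline], axis=0))
        return ExpressionMatrix(fc, "log_fc", baseline=baseline)
    if mode == "zscore":
        if matrix.transform not in ("log_tpm", "log_fc"):
            raise ValueError(f"zscore applies to log matrices, got {matrix.transform}")
        mean = v.mean(axis=1)
        sd = v.std(axis=1, ddof=0)
        z = v.sub(mean, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
        z[sd == 0] = 0.0
        return ExpressionMatrix(z, f"zscore({matrix.transform})", baseline=matrix.baseline)
    raise ValueError(f"unknown transform mode {mode!r}")


def read_expression_table(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV with transcript ids in the first column and numeric
    time-point columns."""
    if sep is None:
        sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.astype(float)


def collapse_replicates(df: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    """Mean-collapse replicate columns into one column per group label."""
    if len(groups) != df.shape[1]:
        raise ValueError("one group label per column required")
    return df.T.groupby(pd.Index(groups, name=None), sort=False).mean().T


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def kmeans_rows(matrix: ExpressionMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """Seeded K-means over rows (k-means++, n_init=10, best inertia).

    Labels are relabeled 1..k by descending cluster size, ties broken by
    the first row index in the cluster, so the labeling is deterministic
    for a given seed.  Rows are then ordered within each cluster by
    complete-linkage hierarchical clustering.
    """
    n = matrix.values.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    X = matrix.values.to_numpy()
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    raw = km.labels_

    order_key = []
    for lab in range(k):
        idx = np.flatnonzero(raw == lab)
        order_key.append((-len(idx), int(idx[0]) if len(idx) else n, lab))
    relabel = {lab: rank + 1 for rank, (_, _, lab) in enumerate(sorted(order_key))}
    labels = pd.Series(
        [relabel[l] for l in raw], index=matrix.values.index, name="cluster"
    )
    grouped = sorted(matrix.values.index, key=lambda r: labels[r])
    assignment = ClusterAssignment(
        labels=labels, row_order=grouped, col_order=list(matrix.values.columns)
    )
    assignment.row_order = order_within_clusters(matrix, assignment)
    return assignment


def order_within_clusters(matrix: ExpressionMatrix, assignment: ClusterAssignment) -> list[str]:
    """Row order: clusters in label order, rows within each cluster in
    complete-linkage (Euclidean) dendrogram leaf order."""
    order: list[str] = []
    labels = assignment.labels
    for lab in sorted(labels.unique()):
        ids = [r for r in matrix.values.index if labels[r] == lab]
        if len(ids) <= 2:
            order.extend(ids)
            continue
        sub = matrix.values.loc[ids].to_numpy()
        Z = linkage(sub, method="complete", metric="euclidean")
        order.extend(ids[i] for i in leaves_list(Z))
    return order


def cluster_columns(matrix: ExpressionMatrix) -> list[str]:
    """Column order from complete-linkage (Euclidean) clustering of samples."""
    cols = list(matrix.values.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 columns to cluster samples")
    if len(cols) == 2:
        return cols
    Z = linkage(matrix.values.to_numpy().T, method="complete", metric="euclidean")
    return [cols[i] for i in leaves_list(Z)]


def kmeans_inertia(matrix: ExpressionMatrix, k: int, seed: int = 0) -> float:
    """Within-cluster sum of squares at the best of 10 k-means++ starts."""
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(matrix.values.to_numpy())
    return float(km.inertia_)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_heatmap(
    matrix: ExpressionMatrix,
    assignment: ClusterAssignment,
    out_path: str,
    width: float = 6.0,
    height: float = 8.0,
) -> str:
    """Render the clustered heatmap to PNG/PDF with cluster bands.

    Purely presentational; the figure is deterministic for fixed inputs
    (no timestamps are embedded in the PNG).
    """
    if matrix.values.size == 0:
        raise ValueError("cannot render an empty matrix")
    data = matrix.values.loc[assignment.row_order, assignment.col_order]
    labels = assignment.labels.loc[assignment.row_order]

    fig, (ax_band, ax) = plt.subplots(
        1, 2, figsize=(width, height), gridspec_kw={"width_ratios": [0.04, 1], "wspace": 0.02}
    )
    ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax_band.imshow(
        labels.to_numpy().reshape(-1, 1), aspect="auto", cmap="tab10",
        interpolation="nearest", vmin=1, vmax=10,
    )
    ax_band.set_xticks([])
    ax_band.set_yticks([])
    ax_band.set_ylabel("cluster", fontsize=7)
    for boundary in np.flatnonzero(np.diff(labels.to_numpy())) + 1:
        ax.axhline(boundary - 0.5, color="black", linewidth=0.6)
    fig.savefig(out_path, dpi=150, metadata={"Software": "peaklink"})
    plt.close(fig)
    return out_path
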