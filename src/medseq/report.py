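"""Normalisation, sample clustering and summary exports.

Counts are normalised to reads per million (RPM) of each sample's total
filtered reads, Z-scored per row, and samples are clustered by complete
linkage under the cityblock (L1) metric — the configuration used for the
published heatmaps.  Plot rendering is out of scope; exports are
heatmap-ready TSV/JSON bundles.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import pdist

from .dmr import DMR
from .matrix import SiteCountMatrix

logger = logging.getLogger(__name__)


def rpm_normalize(counts, totals: dict[str, int] | None = None) -> pd.DataFrame:
    """Reads-per-million: ``1e6 * count / sample_total``.

    Accepts a :class:`SiteCountMatrix` (totals taken from it) or a DataFrame
    with one column per sample plus a ``totals`` dict.  Zero totals are an
    error naming the sample.
    """
    if isinstance(counts, SiteCountMatrix):
        df = pd.DataFrame(counts.counts, columns=counts.samples, index=counts.site_ids)
        totals = counts.totals
    else:
        if totals is None:
            raise ValueError("totals required when counts is a plain frame")
        df = counts.copy()
    for s in df.columns:
        if totals[s] <= 0:
            raise ValueError(f"sample {s!r} has zero total read count")
    return df * (1e6 / pd.Series(totals)[df.columns])


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row Z-scores with population SD; zero-variance rows dropped with a warning."""
    if matrix.shape[1] < 2:
        raise ValueError("Z-scoring needs at least two columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)       # population SD (ddof=0)
    keep = sd[:, 0] > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance rows before Z-scoring", (~keep).sum())
    z = (values[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples (columns)."""

    linkage: np.ndarray          # scipy linkage matrix (merges, heights, sizes)
    labels: list[str]            # column names in input order
    leaf_order: list[str]        # dendrogram leaf order
    cophenetic: np.ndarray       # condensed cophenetic distance matrix

    def cut(self, k: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        assignment = fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))


def hierarchical_cluster(
    matrix: pd.DataFrame,
    method: str = "complete",
    metric: str = "cityblock",
) -> ClusterResult:
    """Complete-linkage cityblock clustering of samples over the matrix rows."""
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    values = matrix.to_numpy(dtype=float).T          # observations = samples
    if np.isnan(values).any():
        raise ValueError("matrix contains NaN values")
    Z = linkage(values, method=method, metric=metric)
    order = [matrix.columns[i] for i in leaves_list(Z)]
    coph = cophenet(Z, pdist(values, metric=metric))[1]
    return ClusterResult(
        linkage=Z,
        labels=list(matrix.columns),
        leaf_order=order,
        cophenetic=coph,
    )


def dmr_sample_matrix(dmrs: list[DMR], matrix: SiteCountMatrix) -> pd.DataFrame:
    """Per-DMR, per-sample counts (sum of member-site counts); rows labelled by locus."""
    rows = []
    index = []
    for d in dmrs:
        rows.append(matrix.counts[d.site_ids, :].sum(axis=0))
        index.append(f"{d.chrom}:{d.start}-{d.end}")
    return pd.DataFrame(rows, index=index, columns=matrix.samples)


def chromosome_distribution(dmrs: list[DMR], by: str = "contrast") -> pd.DataFrame:
    """Per-group counts and percentages of DMRs per chromosome.

    Percentages sum to 100 within each group.  Empty input yields an empty frame.
    """
    if not dmrs:
        return pd.DataFrame(columns=["group", "chrom", "count", "percent"])
    df = pd.DataFrame({
        "group": [getattr(d, by, "") or "all" for d in dmrs],
        "chrom": [d.chrom for d in dmrs],
    })
    out = df.groupby(["group", "chrom"]).size().rename("count").reset_index()
    totals = out.groupby("group")["count"].transform("sum")
    out["percent"] = 100.0 * out["count"] / totals
    return out


def export_heatmap_data(
    matrix: pd.DataFrame,
    clusters: ClusterResult,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the Z-matrix (TSV) and cluster bundle (JSON); lossless round trip.

    The JSON bundle holds the linkage table, the sample labels, the leaf
    order, and the row order of the TSV.
    """
    out_prefix = Path(out_prefix)
    if list(matrix.columns) != clusters.labels:
        raise ValueError("matrix columns and cluster labels disagree")
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")
    matrix.to_csv(tsv_path, sep="\t", index=True, index_label="row_id", float_format="%.17g")
    bundle = {
        "schema": "medseq-heatmap-v1",
        "samples": clusters.labels,
        "leaf_order": clusters.leaf_order,
        "row_order": [str(i) for i in matrix.index],
        "linkage": clusters.linkage.tolist(),
    }
    json_path.write_text(json.dumps(bundle, indent=2) + "\n")
    return tsv_path, json_path


def load_heatmap_data(out_prefix: str | Path) -> tuple[pd.DataFrame, dict]:
    out_prefix = Path(out_prefix)
    matrix = pd.read_csv(out_prefix.with_suffix(".tsv"), sep="\t", index_col="row_id",
                         float_precision="round_trip")
    bundle = json.loads(out_prefix.with_suffix(".json").read_text())
    return matrix, bundle
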