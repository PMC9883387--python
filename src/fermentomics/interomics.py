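"""Interomic correlation of microbiota and volatilome datasets.

Spearman rank correlations between taxon abundances and VOC quantifications
over matched samples, clustered by complete-linkage agglomeration on
1 - Pearson correlation between correlation profiles — the machine form of a
two-way joined correlation heatmap with dendrograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .stat_tests import spearman
from .volatilome import VOCTable

__all__ = [
    "CorrelationMatrix",
    "correlate_omics",
    "cluster_correlations",
    "export_heatmap",
    "load_heatmap",
]

_MATCH_COLS = ["treatment", "time_h", "bio_rep"]


@dataclass
class CorrelationMatrix:
    """Taxon x VOC Spearman correlations with optional cluster structure."""

    rho: pd.DataFrame
    p: pd.DataFrame
    alpha: float = 0.05
    row_order: list[str] | None = None
    col_order: list[str] | None = None
    row_clusters: dict[str, int] | None = None
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None
    quarantined_rows: list[str] = field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha


def correlate_omics(
    taxa: pd.DataFrame,
    vocs: VOCTable | pd.DataFrame,
    treatment: str | None = "HBPA",
    alpha: float = 0.05,
    mean_center_inputs: bool = True,
) -> CorrelationMatrix:
    """Spearman rho and two-sided p for every (taxon, VOC) pair.

    Samples are matched on (treatment, time, biological replicate); technical
    replicates on the VOC side are averaged first.  By default only the HBPA
    arm is used (``treatment=None`` widens to all arms).  Both datasets are
    mean-centered beforehand — pure bookkeeping for a rank statistic, kept to
    mirror the convention of correlating two normalized datasets.
    """
    voc_df = vocs.data if isinstance(vocs, VOCTable) else vocs
    taxa_df = taxa
    if treatment is not None:
        taxa_df = taxa_df[taxa_df["treatment"] == treatment]
        voc_df = voc_df[voc_df["treatment"] == treatment]
    from .config import META_COLS
    taxon_cols = [c for c in taxa_df.columns if c not in META_COLS]
    voc_cols = [c for c in voc_df.columns if c not in META_COLS]
    t = taxa_df.groupby(_MATCH_COLS, as_index=True)[taxon_cols].mean()
    v = voc_df.groupby(_MATCH_COLS, as_index=True)[voc_cols].mean()
    shared = t.index.intersection(v.index)
    if len(shared) == 0:
        raise ValueError("no overlapping samples between the two datasets")
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} matched samples; need at least 3")
    t = t.loc[shared]
    v = v.loc[shared]
    if mean_center_inputs:
        t = t - t.mean(axis=0)
        v = v - v.mean(axis=0)
    rho = pd.DataFrame(index=taxon_cols, columns=voc_cols, dtype=float)
    pval = pd.DataFrame(index=taxon_cols, columns=voc_cols, dtype=float)
    for taxon in taxon_cols:
        x = t[taxon].to_numpy()
        for voc in voc_cols:
            r, p = spearman(x, v[voc].to_numpy())
            rho.loc[taxon, voc] = r
            pval.loc[taxon, voc] = p
    return CorrelationMatrix(rho=rho, p=pval, alpha=alpha)


def _profile_linkage(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Complete linkage on 1 - Pearson correlation between profile rows."""
    keep = profiles.index[profiles.std(axis=1) > 0].tolist()
    dropped = [i for i in profiles.index if i not in keep]
    if dropped:
        warnings.warn(f"constant profiles quarantined from clustering: {dropped}", stacklevel=3)
    sub = profiles.loc[keep]
    corr = np.corrcoef(sub.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    return z, keep, pd.DataFrame(dist, index=keep, columns=keep)


def cluster_correlations(
    matrix: CorrelationMatrix,
    k_hint: int | None = None,
    cluster_columns: bool = True,
) -> CorrelationMatrix:
    """Order and cluster the correlation matrix.

    Rows (taxa) are clustered on their correlation profiles across VOCs with
    complete linkage; columns optionally likewise ("two-way joining").  The
    number of row clusters is ``k_hint`` if given, otherwise chosen at the
    largest gap between successive merge heights.  Constant profiles are
    quarantined with a warning.  Leaf order is deterministic for a given
    input ordering.
    """
    if matrix.rho.shape[0] < 3:
        raise ValueError("need at least 3 rows to cluster")
    z_rows, row_ids, _ = _profile_linkage(matrix.rho)
    if k_hint is None:
        # natural cut: largest smoothed relative jump between merge heights
        heights = z_rows[:, 2]
        h_max = float(heights.max())
        if h_max <= 0 or len(heights) < 2:
            k = 1
        else:
            delta = 0.05 * h_max
            ratios = (heights[1:] + delta) / (heights[:-1] + delta)
            k = len(row_ids) - int(np.argmax(ratios) + 1)
            k = max(k, 1)
    else:
        k = k_hint
    labels = fcluster(z_rows, t=k, criterion="maxclust")
    row_order = [row_ids[i] for i in leaves_list(z_rows)]
    result = CorrelationMatrix(
        rho=matrix.rho,
        p=matrix.p,
        alpha=matrix.alpha,
        row_order=row_order + [r for r in matrix.rho.index if r not in row_ids],
        row_clusters=dict(zip(row_ids, (int(l) for l in labels))),
        row_linkage=z_rows,
        quarantined_rows=[r for r in matrix.rho.index if r not in row_ids],
    )
    if cluster_columns:
        z_cols, col_ids, _ = _profile_linkage(matrix.rho.T)
        result.col_linkage = z_cols
        result.col_order = [col_ids[i] for i in leaves_list(z_cols)] + [
            c for c in matrix.rho.columns if c not in col_ids
        ]
    else:
        result.col_order = list(matrix.rho.columns)
    return result


def export_heatmap(matrix: CorrelationMatrix, path: str | Path) -> tuple[Path, Path]:
    """Write plot-ready TSVs: a long table and the cluster-ordered matrix.

    ``<path>_long.tsv`` holds (taxon, voc, rho, p, significant) plus the
    dendrogram positions; ``<path>_matrix.tsv`` is the reordered wide rho
    matrix.  The long table round-trips losslessly via :func:`load_heatmap`.
    """
    path = Path(path)
    row_order = matrix.row_order or list(matrix.rho.index)
    col_order = matrix.col_order or list(matrix.rho.columns)
    long_rows = []
    for taxon in row_order:
        for voc in col_order:
            long_rows.append({
                "taxon": taxon,
                "voc": voc,
                "rho": matrix.rho.loc[taxon, voc],
                "p": matrix.p.loc[taxon, voc],
                "significant": bool(matrix.p.loc[taxon, voc] < matrix.alpha),
                "row_pos": row_order.index(taxon),
                "col_pos": col_order.index(voc),
                "row_cluster": (matrix.row_clusters or {}).get(taxon, 0),
            })
    long_path = path.with_name(path.name + "_long.tsv")
    matrix_path = path.with_name(path.name + "_matrix.tsv")
    pd.DataFrame(long_rows).to_csv(long_path, sep="\t", index=False)
    matrix.rho.loc[row_order, col_order].to_csv(matrix_path, sep="\t", index_label="taxon")
    return long_path, matrix_path


def load_heatmap(long_path: str | Path, alpha: float = 0.05) -> CorrelationMatrix:
    """Re-import a long-format export written by :func:`export_heatmap`."""
    df = pd.read_csv(long_path, sep="\t")
    rho = df.pivot(index="taxon", columns="voc", values="rho")
    p = df.pivot(index="taxon", columns="voc", values="p")
    row_order = df.sort_values("row_pos")["taxon"].drop_duplicates().tolist()
    col_order = df.sort_values("col_pos")["voc"].drop_duplicates().tolist()
    rho = rho.loc[row_order, col_order]
    p = p.loc[row_order, col_order]
    clusters = df.drop_duplicates("taxon").set_index("taxon")["row_cluster"].to_dict()
    return CorrelationMatrix(
        rho=rho, p=p, alpha=alpha, row_order=row_order, col_order=col_order,
        row_clusters={k: int(v) for k, v in clusters.items()},
    )
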