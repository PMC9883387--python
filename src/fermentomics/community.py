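"""Community composition metrics.

Relative abundances, the Firmicutes/Bacteroidetes eubiosis ratio, baseline-
referenced Log2 fold changes with post-hoc letters, alpha diversity (observed
richness, Chao1, Shannon, Simpson, Good's coverage), and beta diversity
(Bray-Curtis, unweighted UniFrac) with principal-coordinate ordination.

Tables are pandas DataFrames whose first columns are the sample metadata
(``sample_id, treatment, time_h, bio_rep, tech_rep``) and whose remaining
columns are taxa.  Relative abundances are percentages summing to 100 per
sample; count tables are non-negative integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .config import META_COLS
from .stat_tests import one_way_anova, tukey_cld

__all__ = [
    "split_meta",
    "relative_abundance",
    "aggregate_by_rank",
    "fb_ratio",
    "log2_fold_change",
    "alpha_diversity",
    "bray_curtis",
    "unweighted_unifrac",
    "pcoa",
    "OrdinationResult",
]

ALPHA_METRICS = ("observed_otus", "chao1", "shannon", "simpson", "goods_coverage", "goods_rarity")


def split_meta(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a typed table into (metadata, feature) blocks."""
    meta_cols = [c for c in META_COLS if c in table.columns]
    features = table.drop(columns=meta_cols)
    return table[meta_cols], features


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert an OTU count table to percentages summing to 100 per sample."""
    meta, values = split_meta(counts)
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.loc[totals <= 0, "sample_id"].tolist() if "sample_id" in counts else list(totals.index[totals <= 0])
        raise ValueError(f"all-zero sample rows: {bad}")
    rel = values.div(totals, axis=0) * 100.0
    return pd.concat([meta, rel], axis=1)


def aggregate_by_rank(table: pd.DataFrame, taxonomy: dict[str, str]) -> pd.DataFrame:
    """Sum taxon columns into the higher rank given by ``taxonomy`` (taxon -> group)."""
    meta, values = split_meta(table)
    missing = set(values.columns) - set(taxonomy)
    if missing:
        raise KeyError(f"taxa without a rank annotation: {sorted(missing)}")
    grouped = values.T.groupby(values.columns.map(taxonomy)).sum().T
    return pd.concat([meta, grouped], axis=1)


def fb_ratio(
    table: pd.DataFrame,
    taxonomy: dict[str, str] | None = None,
    dysbiosis_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-sample Firmicutes/Bacteroidetes ratio with a dysbiosis flag.

    Values above the threshold (default 2) are conventionally read as
    dysbiosis.  If ``taxonomy`` is given, taxa are first aggregated to phyla;
    otherwise the table must already carry ``Firmicutes`` and ``Bacteroidetes``
    columns.  A zero Bacteroidetes abundance yields a NaN ratio flagged as
    undefined rather than infinity.
    """
    phyla = aggregate_by_rank(table, taxonomy) if taxonomy else table
    for col in ("Firmicutes", "Bacteroidetes"):
        if col not in phyla.columns:
            raise KeyError(f"phylum column {col!r} missing; pass a taxonomy mapping")
    meta, _ = split_meta(phyla)
    firm = phyla["Firmicutes"].to_numpy(dtype=float)
    bact = phyla["Bacteroidetes"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bact > 0, firm / np.where(bact > 0, bact, 1.0), np.nan)
    out = meta.copy()
    out["fb_ratio"] = ratio
    out["dysbiosis"] = ratio > dysbiosis_threshold
    out["undefined"] = bact <= 0
    return out


def log2_fold_change(
    endpoint: pd.DataFrame,
    baseline: pd.DataFrame,
    floor: float = 0.001,
    treatment_col: str = "treatment",
    alpha: float = 0.05,
    letters: bool = True,
) -> pd.DataFrame:
    """Baseline-referenced Log2 fold changes per taxon and treatment.

    The baseline reference is the pooled mean of all baseline samples; the
    endpoint value per treatment is the pooled mean of its replicates.
    Abundances below ``floor`` (the 0.001% detection cutoff) are substituted
    by the floor so fold changes stay finite.  A one-way ANOVA across the
    groups {baseline, treatments} on raw per-sample abundances provides the
    p-value, and Tukey HSD letters mark which groups differ.

    Returns one row per taxon: baseline_mean, baseline_sd,
    ``log2fc_<treatment>`` columns, anova_p, and ``letters_<group>`` columns.
    """
    _, base_vals = split_meta(baseline)
    meta_end, end_vals = split_meta(endpoint)
    missing = set(end_vals.columns) - set(base_vals.columns)
    if missing:
        raise KeyError(f"taxa absent from baseline: {sorted(missing)}")
    treatments = list(dict.fromkeys(meta_end[treatment_col]))
    records = []
    for taxon in end_vals.columns:
        base = base_vals[taxon].to_numpy(dtype=float)
        base_mean = float(base.mean())
        rec = {
            "taxon": taxon,
            "baseline_mean": base_mean,
            "baseline_sd": float(base.std(ddof=1)) if base.size > 1 else 0.0,
        }
        groups = {"baseline": base}
        for trt in treatments:
            vals = end_vals.loc[meta_end[treatment_col] == trt, taxon].to_numpy(dtype=float)
            groups[trt] = vals
            rec[f"log2fc_{trt}"] = float(
                np.log2(max(vals.mean(), floor) / max(base_mean, floor))
            )
        f, p = one_way_anova(groups)
        rec["anova_p"] = p
        if letters:
            if np.isfinite(p) and all(len(v) > 1 for v in groups.values()):
                cld = tukey_cld(groups, alpha=alpha).letters
            else:
                cld = {g: "" for g in groups}
            for g, letter in cld.items():
                rec[f"letters_{g}"] = letter
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _alpha_one(counts: np.ndarray, metric: str, base: float | None) -> float:
    counts = counts[counts > 0]
    n = counts.sum()
    if metric == "observed_otus":
        return float(counts.size)
    if metric == "chao1":
        s_obs = counts.size
        f1 = int((counts == 1).sum())
        f2 = int((counts == 2).sum())
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    p = counts / n
    if metric == "shannon":
        h = float(-(p * np.log(p)).sum())
        return h / np.log(base) if base else h
    if metric == "simpson":
        return float(1.0 - (p**2).sum())
    if metric == "dominance":
        return float((p**2).sum())
    f1 = int((counts == 1).sum())
    if metric == "goods_coverage":
        return float(1.0 - f1 / n)
    if metric == "goods_rarity":
        return float(f1 / n)
    raise ValueError(f"unknown alpha metric {metric!r}")


def alpha_diversity(counts: pd.DataFrame, metric: str, log_base: float | None = None) -> pd.Series:
    """Per-sample alpha diversity.

    Metrics: ``observed_otus``; ``chao1`` (bias-corrected,
    S_obs + F1(F1-1)/(2(F2+1))); ``shannon`` (natural log by default,
    ``log_base`` overrides); ``simpson`` (1 - sum p_i^2, the probability two
    draws differ; ``dominance`` exposes the raw sum); ``goods_coverage``
    (1 - F1/N) and ``goods_rarity`` (F1/N, the complement, exposed because the
    singleton fraction is sometimes reported as a "rarity" index).

    Count-based metrics (chao1, goods_*) require integer counts.
    """
    meta, values = split_meta(counts)
    arr = values.to_numpy()
    if metric in ("chao1", "goods_coverage", "goods_rarity"):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{metric} requires integer counts")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=1) <= 0).any():
        raise ValueError("every sample needs a positive total count")
    out = np.array([_alpha_one(row.astype(float), metric, log_base) for row in arr])
    index = meta["sample_id"] if "sample_id" in meta else values.index
    return pd.Series(out, index=index, name=metric)


# ---------------------------------------------------------------------------
# Beta diversity and ordination
# ---------------------------------------------------------------------------

def _ids(table: pd.DataFrame) -> list[str]:
    if "sample_id" in table.columns:
        return [str(s) for s in table["sample_id"]]
    return [str(i) for i in table.index]


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix: d = 1 - 2*sum(min)/(sum A + sum B)."""
    _, values = split_meta(table)
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    arr = values.to_numpy(dtype=float)
    if (arr.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample rows make Bray-Curtis undefined")
    return DistanceMatrix(squareform(pdist(arr, metric="braycurtis")), ids=_ids(table))


def unweighted_unifrac(table: pd.DataFrame, tree: TreeNode | str) -> DistanceMatrix:
    """Unweighted (presence/absence) UniFrac distance matrix.

    The distance between two samples is the branch length unique to either,
    divided by the total branch length leading to taxa present in their
    union.  Every taxon column must be a leaf of the (rooted) tree; branch
    lengths are required.
    """
    if isinstance(tree, (str, bytes)) or hasattr(tree, "read"):
        tree = TreeNode.read(tree)
    _, values = split_meta(table)
    leaves = {t.name for t in tree.tips()}
    missing = set(values.columns) - leaves
    if missing:
        raise KeyError(f"taxa missing from tree: {sorted(missing)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has a branch without a length; UniFrac needs branch lengths")
    presence = (values.to_numpy(dtype=float) > 0).astype(int)
    return beta_diversity(
        "unweighted_unifrac",
        presence,
        ids=_ids(table),
        taxa=list(values.columns),
        tree=tree,
    )


@dataclass
class OrdinationResult:
    """Sample coordinates and per-axis explained-variance fractions."""

    coordinates: pd.DataFrame  # samples x axes
    proportion_explained: np.ndarray
    eigenvalues: np.ndarray


def pcoa(distance: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Eigen-decomposition of the double-centered squared-distance matrix;
    axes with negative eigenvalues are reported but never returned as
    coordinates.  Requesting more axes than there are positive eigenvalues
    returns the available ones with a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(distance, method="eigh")
    eigvals = res.eigvals.to_numpy()
    n_pos = int((eigvals > 1e-10).sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; returning {n_pos}",
            stacklevel=2,
        )
    k = max(min(n_axes, n_pos), 0)
    coords = res.samples.iloc[:, :k].copy()
    coords.index = list(distance.ids)
    if k == 0:
        # fully degenerate (all samples identical): a single zero axis
        coords = pd.DataFrame(
            np.zeros((len(distance.ids), 1)), index=list(distance.ids), columns=["PC1"]
        )
        return OrdinationResult(coords, np.zeros(1), eigvals)
    return OrdinationResult(
        coords, res.proportion_explained.to_numpy()[:k], eigvals
    )
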