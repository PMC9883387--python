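"""Volatilome (SPME GC-MS VOC table) analysis chain.

Order of operations, enforced through provenance tags:

1. ``censor_lod`` — floor values below the limit of detection and flag them
   (LOD 0.01 mg/kg, LOQ 0.03 mg/kg for absolutely quantified metabolites).
2. ``significant_vocs`` — keep compounds with a one-way ANOVA p < 0.05
   across the fermentation cases.
3. ``mean_center`` — per-compound mean centering over the whole dataset.
4. ``supernormalize_by_class`` — split by chemical class and re-center each
   class independently, so less volatile classes are not swamped.
5. ``baseline_shift`` — subtract the baseline mean per compound and attach
   Tukey HSD letters comparing treatments.
6. ``pca_vocs`` / ``descriptor_assignment`` — per-class PCA and two-factor
   ("matrix" x time) descriptor attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import META_COLS, VOC_CLASSES
from .stat_tests import one_way_anova, tukey_cld, two_factor_attribution

__all__ = [
    "VOCTable",
    "censor_lod",
    "significant_vocs",
    "mean_center",
    "supernormalize_by_class",
    "baseline_shift",
    "pca_vocs",
    "descriptor_assignment",
    "area_ratio_to_mgkg",
]

PROVENANCES = ("raw", "centered", "supernormalized", "baseline_shift")


@dataclass
class VOCTable:
    """A compound x sample quantification table with class annotations.

    ``data`` holds metadata columns first, then one column per compound
    (mg/kg for raw tables, unitless after normalization).  ``classes`` maps
    each compound to its chemical class.  ``censored``/``semi_quant`` are
    boolean frames aligned with the compound columns.
    """

    data: pd.DataFrame
    classes: Mapping[str, str]
    provenance: str = "raw"
    censored: pd.DataFrame | None = None
    semi_quant: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        unknown = set(self.compounds) - set(self.classes)
        if unknown:
            raise KeyError(f"compounds without a chemical-class annotation: {sorted(unknown)}")
        bad = {c: cls for c, cls in self.classes.items() if cls not in VOC_CLASSES}
        if bad:
            raise ValueError(f"unknown chemical classes: {bad}")

    @property
    def meta(self) -> pd.DataFrame:
        return self.data[[c for c in META_COLS if c in self.data.columns]]

    @property
    def compounds(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLS]

    @property
    def values(self) -> pd.DataFrame:
        return self.data[self.compounds]

    def with_values(self, values: pd.DataFrame, provenance: str) -> "VOCTable":
        data = pd.concat([self.meta.reset_index(drop=True),
                          values.reset_index(drop=True)], axis=1)
        return replace(self, data=data, provenance=provenance)


def censor_lod(table: VOCTable, lod: float = 0.01, loq: float = 0.03) -> VOCTable:
    """Apply detection/quantification limits.

    Values below ``lod`` are stored at the LOD floor and flagged censored;
    values in ``[lod, loq)`` keep their value but are flagged
    semi-quantitative.  Negative inputs are rejected.
    """
    vals = table.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("negative VOC quantification")
    censored = vals < lod
    semi = (vals >= lod) & (vals < loq)
    floored = vals.mask(censored, lod)
    out = table.with_values(floored, provenance="raw")
    out.censored = censored.reset_index(drop=True)
    out.semi_quant = semi.reset_index(drop=True)
    return out


def significant_vocs(
    table: VOCTable,
    alpha: float = 0.05,
    group_cols: Sequence[str] = ("treatment", "time_h"),
    correct: str | None = None,
) -> tuple[VOCTable, pd.DataFrame]:
    """Keep compounds whose across-case one-way ANOVA p-value is below alpha.

    Cases are the ``(treatment, time)`` combinations.  Compounds constant over
    all samples are dropped (undefined F).  ``correct='fdr_bh'`` applies a
    Benjamini-Hochberg correction before thresholding (off by default: raw
    p-values are thresholded, matching common practice in this assay).

    Returns the filtered table and a per-compound report
    (compound, p, kept, reason).
    """
    meta = table.meta
    labels = meta[list(group_cols)].astype(str).agg("|".join, axis=1)
    if labels.nunique() < 2:
        raise ValueError("need at least two cases for the significance screen")
    report = []
    pvals: dict[str, float] = {}
    for compound in table.compounds:
        series = table.data[compound].astype(float)
        if series.nunique() <= 1:
            report.append({"compound": compound, "p": np.nan, "kept": False,
                           "reason": "constant across all samples"})
            continue
        groups = {lab: series[labels == lab].to_numpy() for lab in labels.unique()}
        _, p = one_way_anova(groups)
        pvals[compound] = p
    if correct == "fdr_bh" and pvals:
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(list(pvals.values()), method="fdr_bh")[1]
        pvals = dict(zip(pvals, adj))
    for compound, p in pvals.items():
        kept = bool(p < alpha)
        report.append({"compound": compound, "p": p, "kept": kept,
                       "reason": "" if kept else f"ANOVA p >= {alpha}"})
    report_df = pd.DataFrame(report)
    keep = [r["compound"] for r in report if r["kept"]]
    filtered = table.with_values(table.values[keep], provenance=table.provenance)
    filtered.classes = {c: table.classes[c] for c in keep}
    return filtered, report_df


def mean_center(table: VOCTable, provenance: str = "centered") -> VOCTable:
    """Center each compound to zero mean over the whole dataset."""
    if len(table.data) < 2:
        raise ValueError("cannot center a single-sample dataset")
    vals = table.values.astype(float)
    return table.with_values(vals - vals.mean(axis=0), provenance=provenance)


def supernormalize_by_class(table: VOCTable, scale: bool = False) -> dict[str, VOCTable]:
    """Split by chemical class and re-center each class table independently.

    With ``scale=True`` compounds are additionally brought to unit variance.
    Returns a mapping chemical class -> normalized VOCTable.
    """
    out: dict[str, VOCTable] = {}
    for cls in dict.fromkeys(table.classes[c] for c in table.compounds):
        members = [c for c in table.compounds if table.classes[c] == cls]
        sub = table.with_values(table.values[members].astype(float), provenance=table.provenance)
        sub.classes = {c: cls for c in members}
        sub = mean_center(sub, provenance="supernormalized")
        if scale:
            vals = sub.values
            sd = vals.std(axis=0, ddof=0).replace(0.0, 1.0)
            sub = sub.with_values(vals / sd, provenance="supernormalized")
            sub.classes = {c: cls for c in members}
        out[cls] = sub
    return out


def baseline_shift(table: VOCTable, alpha: float = 0.05) -> pd.DataFrame:
    """Subtract the baseline mean per compound and compare treatments.

    Requires a normalized table (provenance ``centered`` or
    ``supernormalized``); the baseline reference is the mean over all
    baseline (0 h) samples.  Returns a tidy frame with one row per
    (compound, treatment, time): mean shift, SD, n and Tukey HSD letters
    comparing treatments within that time point.
    """
    if table.provenance not in ("centered", "supernormalized"):
        raise ValueError(
            f"baseline_shift needs a normalized table, got provenance {table.provenance!r}"
        )
    meta = table.meta
    is_bl = meta["time_h"] == 0
    if not is_bl.any():
        raise ValueError("no baseline (time_h == 0) samples in table")
    rows = []
    for compound in table.compounds:
        series = table.data[compound].astype(float)
        bl_mean = float(series[is_bl].mean())
        shift = series - bl_mean
        for time in sorted(meta["time_h"].unique()):
            at_t = meta["time_h"] == time
            groups = {
                trt: shift[at_t & (meta["treatment"] == trt)].to_numpy()
                for trt in dict.fromkeys(meta.loc[at_t, "treatment"])
            }
            usable = {k: v for k, v in groups.items() if v.size > 1}
            if len(usable) >= 2 and any(np.ptp(v) > 0 for v in usable.values()):
                letters = tukey_cld(usable, alpha=alpha).letters
            else:
                letters = {}
            for trt, vals in groups.items():
                rows.append({
                    "compound": compound,
                    "treatment": trt,
                    "time_h": time,
                    "shift": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n": int(vals.size),
                    "letters": letters.get(trt, ""),
                })
    return pd.DataFrame(rows)


@dataclass
class VOCPCA:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # compounds x components
    proportion_explained: np.ndarray


def pca_vocs(table: VOCTable, n_components: int | None = None) -> VOCPCA:
    """PCA (via SVD) of a normalized VOC table: case scores plus loadings."""
    if table.provenance == "raw":
        raise ValueError("pca_vocs needs a normalized (centered/supernormalized) table")
    vals = table.values.astype(float)
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 compounds")
    if np.allclose(vals.to_numpy(), 0) or np.allclose(vals.std(axis=0), 0):
        raise ValueError("rank-0 matrix: no variance to decompose")
    k = n_components or min(vals.shape) - 1
    k = min(k, min(vals.shape))
    model = PCA(n_components=k, svd_solver="full", random_state=0)
    scores = model.fit_transform(vals.to_numpy())
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    ids = table.meta["sample_id"] if "sample_id" in table.meta else vals.index
    return VOCPCA(
        scores=pd.DataFrame(scores, index=list(ids), columns=cols),
        loadings=pd.DataFrame(model.components_.T, index=vals.columns, columns=cols),
        proportion_explained=model.explained_variance_ratio_,
    )


def descriptor_assignment(
    table: VOCTable,
    matrix_col: str = "treatment",
    time_col: str = "time_h",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Label each compound with the factor level it describes.

    Runs the two-factor (matrix x time) attribution; a compound significant
    for a factor at ``alpha`` becomes a descriptor of that factor's
    highest-mean level (lexicographic tie-break, flagged).  Non-significant
    compounds are labeled ``none``.
    """
    attribution = two_factor_attribution(
        table.data, table.compounds, matrix_col=matrix_col, time_col=time_col, alpha=alpha
    )
    return attribution


def area_ratio_to_mgkg(area_ratio: float | np.ndarray, istd_mg_per_l: float = 4.0) -> np.ndarray:
    """Convert analyte/internal-standard peak-area ratios to mg/kg.

    Single-point internal-standard quantification at the stated spike
    concentration (default 4 mg/L of 4-methyl-2-pentanol), assuming unit
    matrix density so mg/L and mg/kg coincide.
    """
    return np.asarray(area_ratio, dtype=float) * istd_mg_per_l
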