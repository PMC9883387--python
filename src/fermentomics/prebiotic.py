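"""qPCR Prebiotic Index (qPI).

The index scores a fermentation sample from qPCR quantifications
(Log10 cells/mL) of four bacterial groups relative to total Eubacteria:

    qPI = Bifidobacteriaceae/Eubacteria - Enterobacteriaceae/Eubacteria
        + Lactobacillales/Eubacteria   - ClostridiumGroupI/Eubacteria

Beneficial groups (Bifidobacteriaceae, Lactobacillales) add, detrimental
groups (Enterobacteriaceae, Clostridium cluster I) subtract.  The ratios are
taken on the Log10 quantities exactly as defined for the index — not on
linear cell counts.  Values below the detection floor (default Log10 = 2, a
typical qPCR limit of quantification) are substituted by the floor and
flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QPI_TARGETS
from .stat_tests import one_way_anova, tukey_cld

__all__ = ["qpi", "qpi_timecourse", "QPIResult"]

_BENEFICIAL = ("Bifidobacteriaceae", "Lactobacillales")
_DETRIMENTAL = ("Enterobacteriaceae", "ClostridiumGroupI")


def qpi(table: pd.DataFrame | pd.Series, detection_floor: float = 2.0) -> pd.Series | float:
    """Compute the qPI for one record or per row of a quantification table.

    Any target below ``detection_floor`` is replaced by the floor.  A row
    whose Eubacteria value is missing or at/below the floor has an undefined
    index and yields NaN (flagged by a warning rather than silently).
    """
    single = isinstance(table, pd.Series)
    df = table.to_frame().T if single else table
    missing = set(QPI_TARGETS) - set(df.columns)
    if missing:
        raise KeyError(f"qPCR table missing target columns: {sorted(missing)}")
    vals = df[list(QPI_TARGETS)].astype(float).clip(lower=detection_floor)
    eub = vals["Eubacteria"]
    undefined = df["Eubacteria"].astype(float) <= detection_floor
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} row(s) with Eubacteria at or below the "
            f"detection floor: qPI undefined (NaN)",
            stacklevel=2,
        )
    out = (
        vals["Bifidobacteriaceae"] / eub
        - vals["Enterobacteriaceae"] / eub
        + vals["Lactobacillales"] / eub
        - vals["ClostridiumGroupI"] / eub
    )
    out = out.mask(undefined)
    out.name = "qpi"
    return float(out.iloc[0]) if single else out


@dataclass
class QPIResult:
    """Per-(treatment, time) qPI summary with post-hoc letters."""

    summary: pd.DataFrame      # treatment, time_h, mean, sd, n, letters
    replicate_values: pd.Series
    anova_f: float
    anova_p: float
    best_cell: tuple[str, float]
    worst_cell: tuple[str, float]


def qpi_timecourse(
    table: pd.DataFrame, detection_floor: float = 2.0, alpha: float = 0.05
) -> QPIResult:
    """qPI over the fermentation time course with group comparison.

    Replicate qPI values are summarized per (treatment, time) cell; a one-way
    ANOVA across cells is followed by Tukey HSD letters.  Cells with fewer
    than 2 replicates are excluded from the comparison with a warning.
    """
    values = qpi(table, detection_floor=detection_floor)
    meta = table[["treatment", "time_h"]]
    cells: dict[tuple[str, float], np.ndarray] = {}
    for (trt, time), idx in meta.groupby(["treatment", "time_h"], sort=True).groups.items():
        cells[(str(trt), float(time))] = values.loc[idx].dropna().to_numpy()
    usable = {k: v for k, v in cells.items() if v.size >= 2}
    skipped = sorted(set(cells) - set(usable))
    if skipped:
        warnings.warn(f"cells excluded from ANOVA (<2 replicates): {skipped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least 2 (treatment, time) cells with replicates")
    labels = {f"{trt}@{time:g}h": v for (trt, time), v in usable.items()}
    f, p = one_way_anova(labels)
    letters = tukey_cld(labels, alpha=alpha).letters if np.isfinite(p) else {}
    rows = []
    for (trt, time), v in cells.items():
        rows.append({
            "treatment": trt,
            "time_h": time,
            "mean": float(v.mean()) if v.size else np.nan,
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size),
            "letters": letters.get(f"{trt}@{time:g}h", ""),
        })
    summary = pd.DataFrame(rows)
    means = {k: v.mean() for k, v in usable.items()}
    best = max(means, key=lambda k: (means[k], k))
    worst = min(means, key=lambda k: (means[k], k))
    return QPIResult(
        summary=summary,
        replicate_values=values,
        anova_f=f,
        anova_p=p,
        best_cell=best,
        worst_cell=worst,
    )
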