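"""Synthetic fermentation time-course generator.

Emulates the statistical structure of a 24 h in vitro colonic fermentation
screen: a baseline community with per-taxon means and SDs, treatment-specific
Log2 fold-change trajectories with multiplicative replicate noise, qPCR
counts (Log10 cells/mL) for the five prebiotic-index targets, and LOD-censored
VOC production/decay curves per chemical class.

Design notes
------------
* Taxon effects interpolate log-linearly in time: the expected abundance of
  taxon *i* at time *t* is ``baseline_i * 2^(effect_i * t / 24)``.
* Remainder taxa (``config.remainder_taxa``) absorb the compositional budget
  so each sample sums to exactly 100%; at zero noise the configured effects
  are therefore recovered exactly by downstream fold-change analysis.
* Replicate noise is log-normal multiplicative with unit mean,
  CV-parameterized, applied before the final renormalization; this keeps
  abundances positive and compositional.
* All randomness flows from ``config.seed`` through independent named
  streams, so identical configs yield identical datasets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import QPI_TARGETS, SimulationConfig
from .volatilome import VOCTable, censor_lod

__all__ = [
    "generate_community_timecourse",
    "generate_qpcr_timecourse",
    "generate_voc_timecourse",
]

# fixed sub-stream ids so the three tables are independently reproducible
_STREAM = {"taxa": 1, "qpcr": 2, "voc": 3}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.seed % (2**31)])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _meta_row(treatment: str, time_h: float, bio: int, tech: int) -> dict:
    return {
        "sample_id": f"{treatment}_t{time_h:g}_b{bio}_r{tech}",
        "treatment": treatment,
        "time_h": float(time_h),
        "bio_rep": int(bio),
        "tech_rep": int(tech),
    }


def generate_community_timecourse(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (relative-abundance %, integer OTU count) tables.

    One sequencing sample per (treatment, time, biological replicate);
    rows sum to 100% (closure enforced by the remainder taxa plus a final
    renormalization under noise).  Counts are multinomial draws of
    ``config.sequencing_depth`` reads from each sample's composition —
    deterministic scaling-and-rounding when ``noise_cv`` is zero, so the
    noise-free count table is exactly proportional to the abundances.
    """
    taxa = list(config.baseline_profile)
    base = np.array([config.baseline_profile[t][0] for t in taxa])
    effects = {
        trt: np.array([config.effect_matrix.get(t, {}).get(trt, 0.0) for t in taxa])
        for trt in config.treatments
    }
    remainder = np.array([t in set(config.remainder_taxa) for t in taxa])
    if remainder.any() and not np.all(base[remainder] > 0):
        raise ValueError("remainder taxa need positive baseline abundance")
    rng = _rng(config, "taxa")
    horizon = max(config.time_points)
    rows, meta_rows = [], []
    for trt in config.treatments:
        for time in config.time_points:
            frac = time / horizon if horizon else 0.0
            mean = base * np.power(2.0, effects[trt] * frac)
            if remainder.any():
                budget = 100.0 - mean[~remainder].sum()
                if budget < 0:
                    raise ValueError(
                        f"effects exceed the compositional budget for {trt} at {time} h"
                    )
                mean[remainder] = base[remainder] / base[remainder].sum() * budget
            for bio in range(1, config.n_bio_reps + 1):
                sample = mean * _lognormal_factor(rng, config.noise_cv, mean.shape)
                sample = sample / sample.sum() * 100.0
                rows.append(sample)
                meta_rows.append(_meta_row(trt, time, bio, 1))
    meta = pd.DataFrame(meta_rows)
    abund = pd.concat([meta, pd.DataFrame(rows, columns=taxa)], axis=1)
    fractions = np.asarray(rows) / 100.0
    if config.noise_cv == 0:
        counts_vals = np.rint(fractions * config.sequencing_depth).astype(np.int64)
    else:
        counts_vals = np.vstack([
            rng.multinomial(config.sequencing_depth, p / p.sum()) for p in fractions
        ]).astype(np.int64)
    counts = pd.concat([meta.copy(), pd.DataFrame(counts_vals, columns=taxa)], axis=1)
    return abund, counts


def generate_qpcr_timecourse(config: SimulationConfig) -> pd.DataFrame:
    """Generate the qPCR quantification table (Log10 cells/mL).

    Columns are exactly the five prebiotic-index targets; rows are
    (treatment, time, biological replicate, technical replicate) — the
    default design yields sextuplicate values per cell (3 technical x 2
    experimental).  Gaussian noise (``qpcr_noise_sd``, Log10 scale) is added
    per replicate; subgroup values are capped at the Eubacteria total of
    their own row, preserving the nestedness invariant.
    """
    missing = set(QPI_TARGETS) - set(config.qpcr_baseline)
    if missing:
        raise ValueError(f"qPCR baseline missing targets: {sorted(missing)}")
    rng = _rng(config, "qpcr")
    rows, meta_rows = [], []
    targets = list(QPI_TARGETS)
    for trt in config.treatments:
        shifts = config.qpcr_effects.get(trt, {})
        for time in config.time_points:
            mean = np.array([
                config.qpcr_baseline[tg] + shifts.get(tg, {}).get(time, 0.0)
                for tg in targets
            ])
            for bio in range(1, config.n_bio_reps + 1):
                for tech in range(1, config.n_tech_reps_qpcr + 1):
                    vals = mean + rng.normal(0.0, config.qpcr_noise_sd, size=mean.shape)
                    eub = vals[targets.index("Eubacteria")]
                    vals = np.minimum(vals, eub)
                    rows.append(vals)
                    meta_rows.append(_meta_row(trt, time, bio, tech))
    meta = pd.DataFrame(meta_rows)
    return pd.concat([meta, pd.DataFrame(rows, columns=targets)], axis=1)


def generate_voc_timecourse(config: SimulationConfig) -> VOCTable:
    """Generate the VOC quantification table (mg/kg) with LOD censoring.

    Each compound follows a saturating first-order curve
    ``baseline + A * (1 - exp(-k t))`` per treatment (A < 0 models decay,
    clipped at zero), times unit-mean log-normal noise; treatments without a
    kinetic entry for a compound follow the zero-production parameterization,
    which is how the blank control is expressed.  Values below the absolute
    LOD are floored there and flagged censored.
    """
    compounds = list(config.voc_compounds)
    rng = _rng(config, "voc")
    base = np.array([config.voc_baseline[c] for c in compounds])
    rows, meta_rows = [], []
    for trt in config.treatments:
        kin = config.voc_kinetics.get(trt, {})
        amp = np.array([kin.get(c, (0.0, 0.0))[0] for c in compounds])
        rate = np.array([kin.get(c, (0.0, 0.0))[1] for c in compounds])
        for time in config.time_points:
            mean = np.clip(base + amp * (1.0 - np.exp(-rate * time)), 0.0, None)
            for bio in range(1, config.n_bio_reps + 1):
                for tech in range(1, config.n_tech_reps_voc + 1):
                    vals = mean * _lognormal_factor(rng, config.voc_noise_cv, mean.shape)
                    rows.append(vals)
                    meta_rows.append(_meta_row(trt, time, bio, tech))
    meta = pd.DataFrame(meta_rows)
    data = pd.concat([meta, pd.DataFrame(rows, columns=compounds)], axis=1)
    table = VOCTable(data=data, classes=dict(config.voc_compounds), provenance="raw")
    return censor_lod(table, lod=config.lod_absolute, loq=config.loq_absolute)
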