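"""End-to-end orchestration: QC, diversity, fold changes, qPI, volatilome,
interomics — from on-disk tables or the synthetic generator — into a
reproducible result bundle on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, interomics as interomics_mod, io as io_mod, volatilome as voc_mod
from .config import META_COLS, SimulationConfig
from .prebiotic import qpi_timecourse
from .simulate import (
    generate_community_timecourse,
    generate_qpcr_timecourse,
    generate_voc_timecourse,
)
from .stat_tests import one_way_anova

__all__ = ["PipelineConfig", "QCReport", "qc_report", "run_pipeline"]

log = logging.getLogger("fermentomics")

ARCHAEAL_PHYLA = {"Euryarchaeota", "Crenarchaeota", "Archaea", "Thaumarchaeota"}


@dataclass
class PipelineConfig:
    """Pipeline inputs and thresholds.

    Exactly one of synthetic mode (``synthetic``) or file inputs
    (``taxa_path``/``counts_path``/``qpcr_path``/``voc_path``) must be active.
    """

    out_dir: str | Path = "results"
    seed: int = 0
    synthetic: SimulationConfig | None = None
    taxa_path: str | None = None
    counts_path: str | None = None
    qpcr_path: str | None = None
    voc_path: str | None = None
    voc_classes_path: str | None = None
    tree_path: str | None = None
    taxonomy_path: str | None = None
    alpha: float = 0.05
    manova_alpha: float = 0.01
    otu_cutoff: float = 0.001
    fb_dysbiosis: float = 2.0
    lod: float = 0.01
    loq: float = 0.03
    qpi_detection_floor: float = 2.0
    interomics_treatment: str | None = "HBPA"

    def __post_init__(self) -> None:
        file_mode = any([self.taxa_path, self.counts_path, self.qpcr_path, self.voc_path])
        if file_mode == (self.synthetic is not None):
            raise ValueError("exactly one of synthetic mode or input paths must be set")
        for name in ("alpha", "manova_alpha", "otu_cutoff", "fb_dysbiosis", "lod", "loq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data = dict(data or {})
        if "synthetic" in data and data["synthetic"] is not None:
            syn = dict(data["synthetic"])
            syn.setdefault("seed", data.get("seed", 0))
            data["synthetic"] = SimulationConfig.from_dict(syn)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(bad)}")
        return cls(**data)


@dataclass
class QCReport:
    """Quality-control checklist; every item resolves to pass/fail/not_evaluable."""

    items: pd.DataFrame  # item, status, detail
    fb_table: pd.DataFrame

    def status(self, item: str) -> str:
        return str(self.items.set_index("item").loc[item, "status"])


def qc_report(
    taxa: pd.DataFrame,
    counts: pd.DataFrame,
    taxonomy: dict[str, str] | None = None,
    fb_threshold: float = 2.0,
    alpha: float = 0.05,
) -> QCReport:
    """Protocol-validation checks on baseline vs endpoint communities.

    (i) the Firmicutes/Bacteroidetes ratio stays at or below the dysbiosis
    threshold in every vessel; (ii) archaeal taxa detected at baseline are
    retained at the endpoint; (iii) Good's coverage is stable over time
    (ANOVA p > alpha); (iv) observed-OTU richness is reported per sample.
    """
    times = sorted(taxa["time_h"].unique())
    if len(times) < 2:
        raise ValueError("QC needs baseline and endpoint samples")
    t0, t_end = times[0], times[-1]
    items = []

    # (i) F/B eubiosis per vessel
    if taxonomy:
        fb = community.fb_ratio(taxa, taxonomy=taxonomy, dysbiosis_threshold=fb_threshold)
        ends = fb[fb["time_h"].isin([t0, t_end])]
        # one ratio per fermentation case, as conventionally reported
        cell_means = ends.groupby(["treatment", "time_h"])["fb_ratio"].mean()
        bad = cell_means[cell_means.isna() | (cell_means > fb_threshold)]
        items.append({
            "item": "fb_ratio",
            "status": "fail" if len(bad) else "pass",
            "detail": f"{len(bad)}/{len(cell_means)} baseline/endpoint cases above {fb_threshold}",
        })
    else:
        fb = pd.DataFrame()
        items.append({"item": "fb_ratio", "status": "not_evaluable",
                      "detail": "no taxonomy mapping supplied"})

    # (ii) archaea retained from baseline to endpoint
    feature_cols = [c for c in taxa.columns if c not in META_COLS]
    if taxonomy:
        archaea = [c for c in feature_cols if taxonomy.get(c) in ARCHAEAL_PHYLA]
    else:
        archaea = [c for c in feature_cols if "Archaea" in c or "Methano" in c]
    if archaea:
        at_bl = taxa.loc[taxa["time_h"] == t0, archaea].sum(axis=1) > 0
        at_end = taxa.loc[taxa["time_h"] == t_end, archaea].sum(axis=1) > 0
        retained = bool(at_bl.all() and at_end.all())
        items.append({
            "item": "archaea_retention",
            "status": "pass" if retained else "fail",
            "detail": f"{len(archaea)} archaeal taxa tracked",
        })
    else:
        items.append({"item": "archaea_retention", "status": "not_evaluable",
                      "detail": "no archaeal taxa in table"})

    # (iii) Good's coverage stability, baseline vs endpoint
    coverage = community.alpha_diversity(counts, "goods_coverage")
    groups = {
        f"t{t:g}": coverage[(counts["time_h"] == t).to_numpy()].to_numpy()
        for t in (t0, t_end)
    }
    usable = {k: v for k, v in groups.items() if v.size >= 2}
    if len(usable) >= 2:
        _, p = one_way_anova(usable)
        stable = bool(np.isnan(p) or p > alpha)
        items.append({
            "item": "goods_coverage_stability",
            "status": "pass" if stable else "fail",
            "detail": f"ANOVA p = {p:.4g}",
        })
    else:
        items.append({"item": "goods_coverage_stability", "status": "not_evaluable",
                      "detail": "insufficient replication"})

    # (iv) observed OTU richness (informational, always evaluable)
    richness = community.alpha_diversity(counts, "observed_otus")
    items.append({
        "item": "observed_otus",
        "status": "pass",
        "detail": f"median {richness.median():.0f} OTUs per sample",
    })
    return QCReport(items=pd.DataFrame(items), fb_table=fb)


def _manifest(config: PipelineConfig, stage_counts: dict[str, str]) -> dict:
    as_dict = dataclasses.asdict(config)
    as_dict.pop("out_dir")  # the hash identifies the analysis, not its location
    blob = json.dumps(as_dict, sort_keys=True, default=str)
    from . import __version__
    return {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "stages": stage_counts,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write the result bundle.

    Outputs (TSV/JSON under ``config.out_dir``): QC report, alpha-diversity
    table, Bray-Curtis (and UniFrac, if a tree is given) distances with PCoA
    coordinates, the baseline-referenced fold-change table, the qPI time
    course, VOC baseline-shift tables, per-class PCA scores/loadings with
    descriptor attribution, and the interomic correlation exports, plus a
    run manifest.  Identical config and seed produce identical bundles.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}

    # ---- inputs ----------------------------------------------------------
    if config.synthetic is not None:
        sim = dataclasses.replace(config.synthetic, seed=config.seed)
        taxa, counts = generate_community_timecourse(sim)
        qpcr = generate_qpcr_timecourse(sim)
        voc = generate_voc_timecourse(sim)
        taxonomy = dict(sim.taxonomy)
        io_mod.write_table(taxa, out / "input_taxa.tsv")
        io_mod.write_table(counts, out / "input_counts.tsv")
        io_mod.write_table(qpcr, out / "input_qpcr.tsv")
        io_mod.write_voc_table(voc, out / "input_voc.tsv", out / "input_voc_classes.tsv")
    else:
        taxa = io_mod.read_table(config.taxa_path, "taxon") if config.taxa_path else None
        counts = io_mod.read_table(config.counts_path, "taxon") if config.counts_path else None
        if taxa is None and counts is not None:
            taxa = community.relative_abundance(counts)
        qpcr = io_mod.read_qpcr_table(config.qpcr_path) if config.qpcr_path else None
        voc = (
            io_mod.read_voc_table(config.voc_path, config.voc_classes_path)
            if config.voc_path else None
        )
        if voc is not None:
            voc = voc_mod.censor_lod(voc, lod=config.lod, loq=config.loq)
        taxonomy = None
        if config.taxonomy_path:
            ann = pd.read_csv(config.taxonomy_path, sep="\t")
            taxonomy = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    tree = io_mod.read_tree(config.tree_path) if config.tree_path else None

    # ---- microbiota ------------------------------------------------------
    if taxa is not None and counts is not None:
        report = qc_report(taxa, counts, taxonomy=taxonomy,
                           fb_threshold=config.fb_dysbiosis, alpha=config.alpha)
        report.items.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        if not report.fb_table.empty:
            report.fb_table.to_csv(out / "fb_ratio.tsv", sep="\t", index=False)
        stages["qc"] = "; ".join(
            f"{r.item}={r.status}" for r in report.items.itertuples()
        )

        alphas = {
            m: community.alpha_diversity(counts, m)
            for m in ("observed_otus", "chao1", "shannon", "simpson", "goods_coverage")
        }
        alpha_df = pd.concat(alphas, axis=1)
        alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")

        bc = community.bray_curtis(taxa)
        bc.to_data_frame().to_csv(out / "bray_curtis.tsv", sep="\t", index_label="sample_id")
        ord_bc = community.pcoa(bc, n_axes=2)
        ord_bc.coordinates.to_csv(out / "pcoa_bray_curtis.tsv", sep="\t",
                                  index_label="sample_id")
        if tree is not None:
            uf = community.unweighted_unifrac(counts, tree)
            uf.to_data_frame().to_csv(out / "unifrac.tsv", sep="\t", index_label="sample_id")
            community.pcoa(uf, n_axes=2).coordinates.to_csv(
                out / "pcoa_unifrac.tsv", sep="\t", index_label="sample_id"
            )

        times = sorted(taxa["time_h"].unique())
        baseline = taxa[taxa["time_h"] == times[0]]
        endpoint = taxa[taxa["time_h"] == times[-1]]
        fold = community.log2_fold_change(
            endpoint, baseline, floor=config.otu_cutoff, alpha=config.alpha
        )
        fold.to_csv(out / "fold_change.tsv", sep="\t", index=False)
        stages["fold_change"] = f"{len(fold)} taxa"

    # ---- prebiotic index -------------------------------------------------
    if qpcr is not None:
        result = qpi_timecourse(qpcr, detection_floor=config.qpi_detection_floor,
                                alpha=config.alpha)
        result.summary.to_csv(out / "qpi.tsv", sep="\t", index=False)
        stages["qpi"] = (
            f"best={result.best_cell[0]}@{result.best_cell[1]:g}h "
            f"worst={result.worst_cell[0]}@{result.worst_cell[1]:g}h"
        )

    # ---- volatilome ------------------------------------------------------
    if voc is not None:
        kept, screen = voc_mod.significant_vocs(voc, alpha=config.alpha)
        screen.to_csv(out / "voc_screen.tsv", sep="\t", index=False)
        stages["significant_vocs"] = f"{len(kept.compounds)}/{len(voc.compounds)} kept"
        log.info("significant VOCs: %s", stages["significant_vocs"])
        if len(kept.compounds) >= 2:
            centered = voc_mod.mean_center(kept)
            shifts = voc_mod.baseline_shift(centered, alpha=config.alpha)
            shifts.to_csv(out / "voc_shifts.tsv", sep="\t", index=False)
            per_class = voc_mod.supernormalize_by_class(kept)
            desc_frames = []
            for cls, sub in sorted(per_class.items()):
                if len(sub.compounds) >= 2:
                    p = voc_mod.pca_vocs(sub)
                    p.scores.to_csv(out / f"pca_{cls}_scores.tsv", sep="\t",
                                    index_label="sample_id")
                    p.loadings.to_csv(out / f"pca_{cls}_loadings.tsv", sep="\t",
                                      index_label="compound")
                attribution = voc_mod.descriptor_assignment(sub, alpha=config.manova_alpha)
                attribution.insert(0, "chemical_class", cls)
                desc_frames.append(attribution)
            if desc_frames:
                pd.concat(desc_frames, ignore_index=True).to_csv(
                    out / "voc_descriptors.tsv", sep="\t", index=False
                )

    # ---- interomics ------------------------------------------------------
    if taxa is not None and voc is not None:
        try:
            cm = interomics_mod.correlate_omics(
                taxa, voc, treatment=config.interomics_treatment, alpha=config.alpha
            )
            cm = interomics_mod.cluster_correlations(cm)
            interomics_mod.export_heatmap(cm, out / "interomics")
            stages["interomics"] = f"{cm.rho.shape[0]}x{cm.rho.shape[1]} pairs"
        except ValueError as err:
            stages["interomics"] = f"skipped ({err})"

    manifest = _manifest(config, stages)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
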