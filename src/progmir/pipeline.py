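"""Configuration-driven orchestration of the full progression workflow.

Stages: z-normalization and outlier QC -> per-dataset moderated
differential expression for every contrast -> cross-dataset
meta-signatures and their CP/PDAC intersection -> progressive gene
filtering and SOM partitioning -> counter-regulation pairing -> GSEA of
the retained miRNAs' target sets along the mRNA ranking (plus optional
ORA against a user GMT) -> expression-stratified survival analysis.
Every stage writes a TSV table; the whole run is deterministic under the
configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexp, enrichment, integrate, preprocess
from . import io as pio
from . import survival as surv
from .diffexp import DECallConfig
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

MIRNA_CONTRASTS = (("HC", "CP"), ("HC", "PDAC"))
MRNA_CONTRASTS = (("HC", "CP"), ("HC", "PDAC"), ("HC", "MPDAC"))


@dataclass
class DatasetSpec:
    expression: str
    annotations: str
    omic: str            # "mirna" | "mrna"
    dataset_id: str = ""
    compartment: str = ""


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run; defaults are the study's
    printed cutoffs (miRNA raw p<0.05; mRNA adj p<0.05 & |FC|>=1.5;
    >=2 of 3 datasets; progressive logFC>1.5; 1000 permutations)."""

    datasets: list = field(default_factory=list)
    interactions: str | None = None
    gene_sets: str | None = None
    survival: str | None = None
    mirna_p: float = 0.05
    mrna_p_adj: float = 0.05
    mrna_fc: float = diffexp.FC_15_LOG2
    progressive_logfc: float = 1.5
    min_datasets: int = 2
    gsea_nperm: int = 1000
    gsea_min_size: int = 5
    ora_fdr: float = 0.05
    stage_order: tuple = ("HC", "CP", "PDAC")
    outlier_frac: float = 0.10
    som_grid: tuple = (2, 2)
    som_iter: int = 200
    survival_rule: str = "quartile_75_vs_rest"
    n_signature_genes: int = 15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = [DatasetSpec(**d) for d in raw.pop("datasets", [])]
        cfg = cls(datasets=datasets, **raw)
        for spec in cfg.datasets:
            for p in (spec.expression, spec.annotations):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        return cfg

    def fingerprint(self) -> str:
        blob = json.dumps({k: str(v) for k, v in vars(self).items()},
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    tables: dict
    seed: int
    fingerprint: str
    out_dir: str | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables.items():
            if isinstance(tab, pd.DataFrame):
                tab.to_csv(out / f"{name}.tsv", sep="\t")
        pio.write_json({"seed": self.seed, "fingerprint": self.fingerprint,
                        "tables": sorted(self.tables)}, out / "report.json")
        self.out_dir = str(out)


def _load_inputs(config: PipelineConfig):
    mirna_studies, mrna_study = [], None
    for spec in config.datasets:
        study = pio.read_expression_tsv(spec.expression, spec.annotations,
                                        dataset_id=spec.dataset_id)
        if spec.omic == "mirna":
            mirna_studies.append(study)
        elif spec.omic == "mrna":
            mrna_study = study
        else:
            raise ValueError(f"unknown omic {spec.omic!r}")
    interactions = (pio.read_interactions_tsv(config.interactions)
                    if config.interactions else None)
    gene_sets = pio.read_gmt(config.gene_sets) if config.gene_sets else None
    survival_tab = (pio.read_survival_tsv(config.survival)
                    if config.survival else None)
    return mirna_studies, mrna_study, interactions, gene_sets, survival_tab


def run_pipeline(config: PipelineConfig, out_dir=None,
                 mirna_studies=None, mrna_study=None, interactions=None,
                 gene_sets=None, survival_table=None) -> RunReport:
    """Execute the full workflow; inputs may be paths (via config) or
    in-memory objects (keyword arguments take precedence)."""
    if mirna_studies is None and config.datasets:
        mirna_studies, mrna_study, interactions, gene_sets, survival_table = \
            _load_inputs(config)
    if not mirna_studies or mrna_study is None:
        raise ValueError("pipeline needs >= 1 miRNA study and an mRNA study")

    tables: dict[str, pd.DataFrame] = {}
    mirna_cfg = DECallConfig(p_threshold=config.mirna_p)
    mrna_cfg = DECallConfig(p_threshold=config.mrna_p_adj,
                            fc_threshold=config.mrna_fc, use_adjusted=True)

    # --- preprocess -------------------------------------------------------
    def qc(study: ExpressionStudy) -> ExpressionStudy:
        z = preprocess.z_normalize(study)
        res = preprocess.detect_outliers(z, config.outlier_frac)
        if res.reject_study:
            logger.warning("pipeline: study %s fails QC (%d outliers)",
                           study.dataset_id, len(res.flagged))
        if res.flagged:
            keep = [s for s in z.sample_ids if s not in set(res.flagged)]
            z = z.subset_samples(keep)
            logger.info("pipeline: dropped %d outlier sample(s) from %s",
                        len(res.flagged), study.dataset_id)
        return z

    mirna_z = [qc(s) for s in mirna_studies]
    mrna_z = qc(mrna_study)

    # --- differential expression -----------------------------------------
    mirna_de: dict[str, dict[str, pd.DataFrame]] = {}
    de_counts = []
    for a, b in MIRNA_CONTRASTS:
        contrast = f"{a}_vs_{b}"
        mirna_de[contrast] = {}
        for study in mirna_z:
            de = diffexp.moderate(diffexp.fit_contrast(study, a, b))
            mirna_de[contrast][study.dataset_id] = de
            n_called = len(diffexp.call_de(de, mirna_cfg))
            de_counts.append(("mirna", study.dataset_id, contrast, n_called))
            logger.info("DE %s %s: %d/%d miRNAs called", study.dataset_id,
                        contrast, n_called, len(de))
    mrna_de: dict[str, pd.DataFrame] = {}
    for a, b in MRNA_CONTRASTS:
        if b not in set(mrna_z.groups):
            continue
        contrast = f"{a}_vs_{b}"
        de = diffexp.moderate(diffexp.fit_contrast(mrna_z, a, b))
        mrna_de[contrast] = de
        n_called = len(diffexp.call_de(de, mrna_cfg))
        de_counts.append(("mrna", mrna_z.dataset_id, contrast, n_called))
        logger.info("DE mRNA %s: %d/%d genes called", contrast, n_called, len(de))
    tables["de_counts"] = pd.DataFrame(
        de_counts, columns=["omic", "dataset", "contrast", "n_called"]
    ).set_index(["omic", "dataset", "contrast"])

    # --- meta-signatures and intersection --------------------------------
    metas = {}
    for contrast, de_sets in mirna_de.items():
        meta = integrate.meta_signature(de_sets, config.min_datasets, mirna_cfg)
        metas[contrast] = meta
        tables[f"meta_signature_{contrast}"] = meta
        logger.info("meta-signature %s: %d miRNAs retained", contrast, len(meta))
    common = integrate.cross_contrast_intersection(metas["HC_vs_CP"],
                                                   metas["HC_vs_PDAC"])
    tables["meta_signature_common"] = common
    logger.info("CP/PDAC-common meta-signature: %d miRNAs", len(common))

    # --- progressive genes and SOM ---------------------------------------
    up, down = integrate.progressive_filter(mrna_z, tuple(config.stage_order),
                                            config.progressive_logfc)
    tables["progressive_genes"] = pd.DataFrame(
        [(g, "up") for g in up] + [(g, "down") for g in down],
        columns=["gene_id", "direction"]).set_index("gene_id")
    logger.info("progressive genes: %d up, %d down", len(up), len(down))
    som = integrate.som_cluster(mrna_z, grid_shape=tuple(config.som_grid),
                                n_iter=config.som_iter, seed=config.seed)
    tables["som_assignment"] = pd.DataFrame({
        "sample": list(som.assignment),
        "node": [som.assignment[s] for s in som.assignment],
    }).set_index("sample")

    # --- counter-regulation ----------------------------------------------
    counterreg = {}
    if interactions is not None:
        for contrast in mrna_de:
            if contrast not in metas:
                continue
            meta_common = metas[contrast].loc[
                metas[contrast].index.intersection(common.index)].copy()
            meta_common.attrs.update(metas[contrast].attrs)
            res = integrate.counter_regulation(meta_common, mrna_de[contrast],
                                               interactions, contrast, mrna_cfg)
            counterreg[contrast] = res
            tables[f"counter_regulation_{contrast}"] = res.pairs.set_index(
                ["mirna_id", "gene_id"])
            logger.info("counter-regulation %s: %d pairs / %d miRNAs", contrast,
                        len(res.pairs), res.targets_per_mirna.index.nunique())

    # --- enrichment -------------------------------------------------------
    if interactions is not None and len(common):
        target_sets = {
            f"targets_{m}": set(interactions.loc[interactions["mirna_id"] == m,
                                                 "gene_id"])
            for m in common.index
        }
        gsea_rows = []
        for contrast, de in sorted(mrna_de.items()):
            ranked = enrichment.rank_by_statistic(de)
            results = enrichment.gsea(ranked, target_sets,
                                      n_perm=config.gsea_nperm,
                                      min_size=config.gsea_min_size,
                                      seed=config.seed)
            for r in results:
                gsea_rows.append((r.set_id.removeprefix("targets_"), contrast,
                                  r.es, r.nominal_p, r.n_genes_in_set_and_list,
                                  r.leading_edge_size))
        tables["gsea_mirna_targets"] = pd.DataFrame(
            gsea_rows, columns=["mirna_id", "contrast", "es", "nominal_p",
                                "n_in_list", "n_enriched"]
        ).set_index(["mirna_id", "contrast"])
        tables["mirna_ranking"] = _rank_mirnas(tables["gsea_mirna_targets"],
                                               counterreg)

    if gene_sets is not None and counterreg:
        last_contrast = sorted(counterreg)[-1]
        query = set(counterreg[last_contrast].pairs["gene_id"])
        universe = set(mrna_z.feature_ids)
        if query:
            ora = enrichment.ora_collection(query & universe, gene_sets, universe)
            tables["ora"] = ora

    # --- survival ---------------------------------------------------------
    if survival_table is not None and counterreg:
        tables.update(_survival_stage(config, mrna_z, counterreg, survival_table))

    report = RunReport(tables=tables, seed=config.seed,
                       fingerprint=config.fingerprint())
    if out_dir is not None:
        report.write(out_dir)
    return report


def _rank_mirnas(gsea_table: pd.DataFrame, counterreg: dict) -> pd.DataFrame:
    """Rank retained miRNAs by PDAC GSEA significance then target growth.

    Emulates the hub-selection logic: the dominant regulator is the one
    whose target set is most significantly enriched in the carcinoma
    contrast and gains the most counter-regulated targets from CP on.
    """
    rows = []
    pdac = "HC_vs_PDAC"
    cp = "HC_vs_CP"
    mirnas = sorted({m for m, _ in gsea_table.index})
    for m in mirnas:
        try:
            p = gsea_table.loc[(m, pdac), "nominal_p"]
            es = gsea_table.loc[(m, pdac), "es"]
        except KeyError:
            p, es = 1.0, 0.0
        n_cp = counterreg[cp].targets_per_mirna.get(m, 0) if cp in counterreg else 0
        n_pdac = (counterreg[pdac].targets_per_mirna.get(m, 0)
                  if pdac in counterreg else 0)
        rows.append((m, float(p), float(es), abs(float(es)), int(n_cp),
                     int(n_pdac), int(n_pdac) - int(n_cp)))
    out = pd.DataFrame(rows, columns=["mirna_id", "gsea_p_pdac", "es_pdac",
                                      "abs_es_pdac", "targets_cp",
                                      "targets_pdac", "target_growth"])
    # permutation p saturates at its floor for every strong set, so ties
    # break on the enrichment magnitude before target growth
    out = out.sort_values(["gsea_p_pdac", "abs_es_pdac", "target_growth",
                           "mirna_id"],
                          ascending=[True, False, False, True])
    return out.reset_index(drop=True).set_index("mirna_id")


def _survival_stage(config, mrna_z, counterreg, survival_table) -> dict:
    last_contrast = sorted(counterreg)[-1]
    pairs = counterreg[last_contrast].pairs
    genes = (pairs.assign(abs_lfc=pairs["gene_logfc"].abs())
             .sort_values(["abs_lfc", "gene_id"], ascending=[False, True])
             ["gene_id"].drop_duplicates()
             .head(config.n_signature_genes).tolist())
    out = {}
    common = survival_table.index.intersection(mrna_z.values.columns)
    surv_tab = survival_table.loc[common]
    rows = []
    for g in genes:
        expr = mrna_z.values.loc[g, common]
        try:
            res = surv.survival_by_stratum(surv_tab, expr, config.survival_rule)
        except ValueError:
            continue
        rows.append((g, config.survival_rule, res["cox"].hr, res["cox"].beta,
                     res["cox"].p_wald, res["cox"].lr_p, res["logrank_p"],
                     res["n_high"], res["n_low"]))
    out["survival_per_gene"] = pd.DataFrame(
        rows, columns=["feature", "rule", "hr", "beta", "p_wald", "lr_p",
                       "logrank_p", "n_high", "n_low"]).set_index("feature")
    if genes:
        score = surv.combined_signature(mrna_z.values[common], genes)
        res = surv.survival_by_stratum(surv_tab, score, "median")
        out["survival_combined"] = pd.DataFrame([
            ("combined_signature", "median", res["cox"].hr, res["cox"].beta,
             res["cox"].p_wald, res["cox"].lr_p, res["logrank_p"],
             res["n_high"], res["n_low"], len(genes))],
            columns=["feature", "rule", "hr", "beta", "p_wald", "lr_p",
                     "logrank_p", "n_high", "n_low", "n_genes"]
        ).set_index("feature")
    return out
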