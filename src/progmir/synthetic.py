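"""Synthetic multi-dataset cohorts with planted counter-regulated modules.

The generator emulates the structure of a multi-study pancreatic-disease
meta-analysis: several miRNA datasets (tissue and blood) with healthy
(HC), chronic-pancreatitis (CP) and carcinoma (PDAC) groups, plus one
mRNA dataset that adds a metastatic (MPDAC) group.  A handful of miRNA
"modules" are planted: each module's miRNA is shifted *down* in diseased
groups by a stage schedule that grows with disease severity, while its
target genes are shifted *up* by the same schedule (counter-regulation).
Unplanted features are stage-independent noise.  Every planted pair is
recorded in an emitted interaction table alongside uniformly sampled
decoy pairs among null features, and a subset of planted target genes
drives survival through a proportional-hazards model — so every
downstream stage of the pipeline has ground truth to be scored against.

Base expression is i.i.d. Gaussian per feature with feature-specific
mean and spread; planted effects are additive mean shifts expressed in
z-units of the nominal noise level, and each dataset receives its own
location/scale perturbation before emission (undone by z-normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as pio
from .study import ExpressionStudy

_STAGES = ("HC", "CP", "PDAC", "MPDAC")


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic cohort.

    ``effect_schedule`` maps diseased stage to the planted mean shift in
    z-units of ``noise_sd``; it must be strictly increasing with stage.
    ``hub_boost`` makes module 0 the "hub": more targets and a steeper
    schedule, emulating a dominant regulator.
    """

    n_mirna_datasets: int = 3
    n_genes: int = 2000
    n_mirnas: int = 300
    group_sizes: dict = field(default_factory=lambda: {g: 20 for g in _STAGES})
    n_modules: int = 5
    targets_per_mirna: int = 40
    effect_schedule: dict = field(
        default_factory=lambda: {"CP": 1.0, "PDAC": 2.0, "MPDAC": 3.0}
    )
    noise_sd: float = 1.0
    dataset_shift: list = field(
        default_factory=lambda: [(0.0, 1.0), (0.5, 1.2), (-0.5, 0.9)]
    )
    hazard_beta: float = 0.8
    n_survival_genes: int = 15
    censor_rate: float = 0.2
    decoy_factor: int = 5
    hub_boost: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna_datasets", "n_genes", "n_mirnas", "n_modules",
                     "targets_per_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs >= 2 samples")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        # hub module may take extra targets
        hub_targets = int(round(self.targets_per_mirna * self.hub_boost))
        need = hub_targets + (self.n_modules - 1) * self.targets_per_mirna
        if need > self.n_genes:
            raise ValueError("targets_per_mirna x n_modules exceeds n_genes")
        if self.n_modules > self.n_mirnas:
            raise ValueError("n_modules exceeds n_mirnas")
        sched = [self.effect_schedule.get(s) for s in _STAGES[1:]
                 if s in self.effect_schedule]
        if any(b < a for a, b in zip(sched, sched[1:])):
            raise ValueError("effect_schedule must be non-decreasing with stage")


@dataclass
class PlantedModule:
    mirna_id: str
    target_gene_ids: list
    direction: str  # direction of the miRNA shift in disease
    effect_schedule: dict


@dataclass
class SyntheticTruth:
    """Ground truth of the planted signal, for scoring recovery."""

    modules: list
    survival_genes: list  # (gene_id, hazard_beta)
    null_mirna_ids: list
    null_gene_ids: list

    @property
    def planted_mirna_ids(self) -> list:
        return [m.mirna_id for m in self.modules]

    @property
    def planted_gene_ids(self) -> list:
        return [g for m in self.modules for g in m.target_gene_ids]

    @property
    def planted_pairs(self) -> set:
        return {(m.mirna_id, g) for m in self.modules for g in m.target_gene_ids}

    @property
    def hub_module(self) -> PlantedModule:
        """The module with the most targets and steepest schedule."""
        return max(self.modules,
                   key=lambda m: (len(m.target_gene_ids),
                                  max(m.effect_schedule.values())))

    def to_dict(self) -> dict:
        return {
            "modules": [
                {"mirna_id": m.mirna_id,
                 "target_gene_ids": list(m.target_gene_ids),
                 "direction": m.direction,
                 "effect_schedule": dict(m.effect_schedule)}
                for m in self.modules
            ],
            "survival_genes": [[g, b] for g, b in self.survival_genes],
            "null_mirna_ids": list(self.null_mirna_ids),
            "null_gene_ids": list(self.null_gene_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            modules=[PlantedModule(m["mirna_id"], list(m["target_gene_ids"]),
                                   m["direction"], dict(m["effect_schedule"]))
                     for m in d["modules"]],
            survival_genes=[(g, float(b)) for g, b in d["survival_genes"]],
            null_mirna_ids=list(d["null_mirna_ids"]),
            null_gene_ids=list(d["null_gene_ids"]),
        )


def _simulate_matrix(rng, feature_ids, groups_per_sample, planted_shift,
                     noise_sd, loc, scale, sample_prefix):
    """One dataset matrix: feature-specific baselines + planted group shifts."""
    n_feat = len(feature_ids)
    n_samp = len(groups_per_sample)
    base_mean = rng.normal(7.0, 1.0, size=n_feat)
    feat_sd = noise_sd * rng.uniform(0.9, 1.1, size=n_feat)
    vals = base_mean[:, None] + feat_sd[:, None] * rng.standard_normal((n_feat, n_samp))
    for f_idx, shifts in planted_shift.items():
        for s_idx, group in enumerate(groups_per_sample):
            vals[f_idx, s_idx] += shifts.get(group, 0.0)
    vals = vals * scale + loc
    sample_ids = [f"{sample_prefix}_S{j:03d}" for j in range(n_samp)]
    return pd.DataFrame(vals, index=feature_ids, columns=sample_ids)


def generate_cohort(config: SimConfig):
    """Generate the full synthetic cohort.

    Returns
    -------
    (studies, interactions, truth)
        ``studies`` is a list of :class:`ExpressionStudy`:
        ``config.n_mirna_datasets`` miRNA studies (the first one "tissue",
        the rest "blood") with groups HC/CP/PDAC, followed by one mRNA
        tissue study with groups HC/CP/PDAC/MPDAC. ``interactions`` is the
        emitted miRNA->gene table (planted pairs + decoys); ``truth`` the
        planted ground truth.
    """
    root = np.random.SeedSequence(config.seed)
    # fixed fan-out: design, per-dataset streams, interactions
    streams = root.spawn(2 + config.n_mirna_datasets + 1)
    design_rng = np.random.default_rng(streams[0])
    inter_rng = np.random.default_rng(streams[1])

    mirna_ids = [f"miR-{i:04d}" for i in range(config.n_mirnas)]
    gene_ids = [f"GENE{i:05d}" for i in range(config.n_genes)]

    planted_mirnas = list(design_rng.choice(mirna_ids, size=config.n_modules,
                                            replace=False))
    hub_targets = int(round(config.targets_per_mirna * config.hub_boost))
    sizes = [hub_targets] + [config.targets_per_mirna] * (config.n_modules - 1)
    gene_pool = list(design_rng.permutation(gene_ids))
    modules, pos = [], 0
    for k, (mid, sz) in enumerate(zip(planted_mirnas, sizes)):
        targets = sorted(gene_pool[pos:pos + sz])
        pos += sz
        boost = config.hub_boost if k == 0 else 1.0
        sched = {s: v * boost for s, v in config.effect_schedule.items()}
        modules.append(PlantedModule(mid, targets, "down", sched))

    planted_gene_set = {g for m in modules for g in m.target_gene_ids}
    null_genes = sorted(set(gene_ids) - planted_gene_set)
    null_mirnas = sorted(set(mirna_ids) - set(planted_mirnas))

    surv_pool = sorted(modules[0].target_gene_ids)
    n_surv = min(config.n_survival_genes, len(surv_pool))
    # the hazard budget is shared across the signature genes so the joint
    # linear predictor stays on a clinically plausible scale
    per_gene_beta = config.hazard_beta / n_surv
    surv_genes = [(g, per_gene_beta)
                  for g in design_rng.choice(surv_pool, size=n_surv, replace=False)]
    surv_genes.sort()

    truth = SyntheticTruth(modules=modules, survival_genes=surv_genes,
                           null_mirna_ids=null_mirnas, null_gene_ids=null_genes)

    mirna_index = {m: i for i, m in enumerate(mirna_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    studies = []
    mirna_groups = [g for g in ("HC", "CP", "PDAC") if g in config.group_sizes]
    mirna_group_vec = [g for g in mirna_groups for _ in range(config.group_sizes[g])]
    for d in range(config.n_mirna_datasets):
        loc, scale = config.dataset_shift[d % len(config.dataset_shift)]
        rng = np.random.default_rng(streams[2 + d])
        planted_shift = {
            mirna_index[m.mirna_id]: {s: -v * config.noise_sd
                                      for s, v in m.effect_schedule.items()}
            for m in modules
        }
        ds_id = f"mirna_{d + 1}"
        values = _simulate_matrix(rng, mirna_ids, mirna_group_vec, planted_shift,
                                  config.noise_sd, loc, scale, ds_id)
        ann = pd.DataFrame({
            "group": mirna_group_vec,
            "dataset_id": ds_id,
            "compartment": "tissue" if d == 0 else "blood",
        }, index=values.columns)
        studies.append(ExpressionStudy(values=values, annotations=ann,
                                       dataset_id=ds_id))

    mrna_groups = [g for g in _STAGES if g in config.group_sizes]
    mrna_group_vec = [g for g in mrna_groups for _ in range(config.group_sizes[g])]
    rng = np.random.default_rng(streams[2 + config.n_mirna_datasets])
    planted_shift = {}
    for m in modules:
        for g in m.target_gene_ids:
            planted_shift[gene_index[g]] = {s: +v * config.noise_sd
                                            for s, v in m.effect_schedule.items()}
    values = _simulate_matrix(rng, gene_ids, mrna_group_vec, planted_shift,
                              config.noise_sd, 0.0, 1.0, "mrna")
    ann = pd.DataFrame({"group": mrna_group_vec, "dataset_id": "mrna",
                        "compartment": "tissue"}, index=values.columns)
    studies.append(ExpressionStudy(values=values, annotations=ann,
                                   dataset_id="mrna"))

    interactions = _build_interactions(inter_rng, truth, config)
    return studies, interactions, truth


def _build_interactions(rng, truth: SyntheticTruth, config: SimConfig) -> pd.DataFrame:
    """Planted pairs plus ``decoy_factor`` x as many decoys among nulls."""
    sources = ("mirtarbase", "msigdb")
    rows = [
        (m.mirna_id, g, sources[int(rng.integers(len(sources)))])
        for m in truth.modules for g in m.target_gene_ids
    ]
    n_decoy = config.decoy_factor * len(rows)
    seen = set()
    null_m = np.asarray(truth.null_mirna_ids)
    null_g = np.asarray(truth.null_gene_ids)
    while len(seen) < n_decoy:
        draw_m = null_m[rng.integers(len(null_m), size=n_decoy)]
        draw_g = null_g[rng.integers(len(null_g), size=n_decoy)]
        for mm, gg in zip(draw_m, draw_g):
            if (mm, gg) not in seen:
                seen.add((mm, gg))
                if len(seen) == n_decoy:
                    break
    rows += [(mm, gg, sources[int(rng.integers(len(sources)))])
             for mm, gg in sorted(seen)]
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source_tag"])


def simulate_ph_times(linear_predictor, censor_rate, rng,
                      baseline_median: float = 24.0) -> pd.DataFrame:
    """Draw survival data from an exponential proportional-hazards model.

    Event times follow ``T ~ Exp(rate = lambda0 * exp(eta))`` with
    ``lambda0`` set so the baseline median is ``baseline_median``.
    Censoring is an independent ``Uniform(0, tau)`` time with ``tau``
    calibrated so the expected censored fraction equals ``censor_rate``.
    """
    eta = np.asarray(linear_predictor, dtype=float)
    lam0 = np.log(2.0) / baseline_median
    rates = lam0 * np.exp(eta - eta.mean())
    times = rng.exponential(1.0 / rates)
    if censor_rate <= 0:
        return pd.DataFrame({"time": times, "event": np.ones(len(times), dtype=int)})

    def expected_censored(tau):
        # P(T > C) for C ~ U(0, tau), T ~ Exp(rate): (1 - exp(-r tau)) / (r tau)
        x = rates * tau
        return float(np.mean(-np.expm1(-x) / x)) - censor_rate

    lo, hi = 1e-12, 1.0
    while expected_censored(hi) > 0 and hi < 1e15:
        hi *= 10.0
    tau = brentq(expected_censored, lo, hi)
    cens = rng.uniform(0.0, tau, size=len(times))
    event = (times <= cens).astype(int)
    obs = np.minimum(times, cens)
    return pd.DataFrame({"time": obs, "event": event})


def generate_survival(study: ExpressionStudy, truth: SyntheticTruth,
                      config: SimConfig) -> pd.DataFrame:
    """Survival table linked to planted gene expression by a PH model."""
    if not truth.survival_genes:
        raise ValueError("truth has no survival genes")
    missing = [g for g, _ in truth.survival_genes if g not in study.values.index]
    if missing:
        raise ValueError(f"study lacks survival genes: {missing[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(100)[-1])
    eta = np.zeros(len(study.sample_ids))
    for g, beta in truth.survival_genes:
        expr = study.values.loc[g].to_numpy(dtype=float)
        eta += beta * (expr - expr.mean())
    tab = simulate_ph_times(eta, config.censor_rate, rng)
    tab.index = pd.Index(study.sample_ids, name="sample")
    return tab


def write_fixtures(studies, interactions, truth, directory,
                   survival: pd.DataFrame | None = None) -> dict:
    """Write the cohort as plain-text fixtures; returns a file manifest."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"expression": [], "annotations": []}
    for study in studies:
        expr = directory / f"{study.dataset_id}_expression.tsv"
        ann = directory / f"{study.dataset_id}_annotations.tsv"
        pio.write_expression_tsv(study, expr)
        pio.write_annotations_tsv(study.annotations, ann)
        manifest["expression"].append(str(expr))
        manifest["annotations"].append(str(ann))
    inter_path = directory / "interactions.tsv"
    pio.write_interactions_tsv(interactions, inter_path)
    manifest["interactions"] = str(inter_path)
    gmt_path = directory / "planted_targets.gmt"
    pio.write_gmt({f"targets_{m.mirna_id}": set(m.target_gene_ids)
                   for m in truth.modules},
                  gmt_path,
                  descriptions={f"targets_{m.mirna_id}": f"planted targets of {m.mirna_id}"
                                for m in truth.modules})
    manifest["gene_sets"] = str(gmt_path)
    truth_path = directory / "truth.json"
    pio.write_json(truth.to_dict(), truth_path)
    manifest["truth"] = str(truth_path)
    if survival is not None:
        surv_path = directory / "survival.tsv"
        pio.write_survival_tsv(survival, surv_path)
        manifest["survival"] = str(surv_path)
    manifest_path = directory / "manifest.json"
    pio.write_json(manifest, manifest_path)
    return manifest
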