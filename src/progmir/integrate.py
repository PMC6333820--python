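"""Cross-dataset integration: meta-signatures, progressive genes, SOM,
and miRNA–mRNA counter-regulation.

The meta-signature retains features that are called differentially
expressed with a consistent direction in at least ``min_datasets`` of
the analyzed datasets for a given contrast; intersecting the CP and PDAC
meta-signatures yields the features consistently dysregulated across the
whole disease progression.  Progressive genes change strictly
monotonically along the stage order with a terminal log fold change
above a threshold.  Counter-regulation pairs a meta-significant miRNA
with a differentially expressed target gene of opposite direction,
restricted to a validated interaction table.  A Kohonen self-organizing
map partitions samples by expression profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import DECallConfig, call_de
from .study import ExpressionStudy


# ---------------------------------------------------------------------------
# meta-signature

def meta_signature(de_sets: dict[str, pd.DataFrame], min_datasets: int,
                   call_config: DECallConfig | None = None,
                   require_direction_consistency: bool = True) -> pd.DataFrame:
    """Direction-consistent cross-dataset intersection of DE calls.

    Parameters
    ----------
    de_sets
        ``dataset_id -> DE result table`` for one contrast.
    min_datasets
        Minimum number of datasets in which a feature must be called.
    call_config
        Per-dataset calling rule (default: the miRNA rule, raw p < 0.05).

    Returns
    -------
    DataFrame indexed by feature with per-dataset ``<ds>_logfc``/``<ds>_p``/
    ``<ds>_called`` columns plus ``n_called``, ``direction`` (``up``/
    ``down``/``inconsistent``) and ``mean_logfc`` (over calling datasets),
    restricted to retained features.
    """
    if len(de_sets) < 1:
        raise ValueError("need at least one dataset")
    cfg = call_config or DECallConfig.mirna()
    ds_ids = sorted(de_sets)
    namespaces = [set(de_sets[d].index) for d in ds_ids]
    shared = set.intersection(*namespaces)
    if len(ds_ids) > 1 and not shared:
        raise ValueError("datasets share no features (disjoint namespaces)")
    contrasts = {de_sets[d].attrs.get("contrast") for d in ds_ids}
    if len(contrasts) > 1:
        raise ValueError(f"mixed contrasts in meta-analysis: {sorted(map(str, contrasts))}")

    calls = {d: dict(call_de(de_sets[d], cfg)) for d in ds_ids}
    all_features = sorted(set.union(*namespaces))
    cols: dict[str, list] = {}
    for d in ds_ids:
        tab = de_sets[d]
        cols[f"{d}_logfc"] = [tab["logfc"].get(f, np.nan) for f in all_features]
        p_col = "p_adj" if cfg.use_adjusted else "p_raw"
        cols[f"{d}_p"] = [tab[p_col].get(f, np.nan) for f in all_features]
        cols[f"{d}_called"] = [f in calls[d] for f in all_features]
    out = pd.DataFrame(cols, index=pd.Index(all_features, name="feature"))

    n_called, direction, mean_logfc = [], [], []
    for f in all_features:
        dirs = [calls[d][f] for d in ds_ids if f in calls[d]]
        lfcs = [de_sets[d]["logfc"].get(f) for d in ds_ids if f in calls[d]]
        n_called.append(len(dirs))
        if not dirs:
            direction.append("inconsistent")  # never retained anyway
        elif len(set(dirs)) == 1:
            direction.append(dirs[0])
        else:
            direction.append("inconsistent")
        mean_logfc.append(float(np.mean(lfcs)) if lfcs else np.nan)
    out["n_called"] = n_called
    out["direction"] = direction
    out["mean_logfc"] = mean_logfc

    keep = out["n_called"] >= min_datasets
    if require_direction_consistency:
        keep &= out["direction"] != "inconsistent"
    out = out[keep].copy()
    out.attrs["contrast"] = next(iter(contrasts)) if contrasts else None
    out.attrs["min_datasets"] = min_datasets
    return out


def cross_contrast_intersection(meta_a: pd.DataFrame,
                                meta_b: pd.DataFrame) -> pd.DataFrame:
    """Features meta-significant in both contrasts with the same direction.

    Reproduces the "common across CP and PDAC" logic: the returned table
    holds one row per feature with each contrast's direction and mean
    logFC.
    """
    common = meta_a.index.intersection(meta_b.index)
    rows = []
    for f in common:
        da, db = meta_a.loc[f, "direction"], meta_b.loc[f, "direction"]
        if da == db and da != "inconsistent":
            rows.append((f, da, meta_a.loc[f, "mean_logfc"],
                         meta_b.loc[f, "mean_logfc"]))
    ca = meta_a.attrs.get("contrast") or "a"
    cb = meta_b.attrs.get("contrast") or "b"
    out = pd.DataFrame(rows, columns=["feature", "direction",
                                      f"mean_logfc_{ca}", f"mean_logfc_{cb}"])
    return out.set_index("feature")


# ---------------------------------------------------------------------------
# progressive filter

def progressive_filter(study: ExpressionStudy,
                       stage_order: tuple[str, ...] = ("HC", "CP", "PDAC"),
                       logfc_min: float = 1.5,
                       use_median: bool = False) -> tuple[list[str], list[str]]:
    """Split features into progressive-up / progressive-down lists.

    A feature is progressive-up when its per-group location (mean, or
    median with ``use_median``) increases strictly along ``stage_order``
    and the terminal change (last vs first stage) exceeds ``logfc_min``;
    progressive-down is symmetric. The two lists are disjoint.
    """
    present = set(study.groups)
    missing = [s for s in stage_order if s not in present]
    if missing:
        raise ValueError(f"stages absent from annotations: {missing}")
    locs = {}
    for g in stage_order:
        cols = study.samples_in_group(g)
        block = study.values[cols]
        locs[g] = block.median(axis=1) if use_median else block.mean(axis=1)
    loc = pd.DataFrame(locs)[list(stage_order)]
    diffs = loc.diff(axis=1).iloc[:, 1:]
    terminal = loc[stage_order[-1]] - loc[stage_order[0]]
    up = (diffs.gt(0).all(axis=1)) & (terminal > logfc_min)
    down = (diffs.lt(0).all(axis=1)) & (terminal < -logfc_min)
    return list(loc.index[up]), list(loc.index[down])


# ---------------------------------------------------------------------------
# self-organizing map

@dataclass
class SomGrid:
    """A fitted SOM over samples (samples are the data points)."""

    grid_shape: tuple[int, int]
    prototypes: np.ndarray            # nodes x features
    assignment: dict                  # sample_id -> flat node index
    quantization_error: float
    qe_history: list = field(default_factory=list)

    def node_coords(self, node: int) -> tuple[int, int]:
        return divmod(node, self.grid_shape[1])


def _grid_positions(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    return np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)


def som_cluster(study: ExpressionStudy, grid_shape: tuple[int, int] = (2, 2),
                n_iter: int = 500,
                learning_rate_schedule: tuple[float, float] = (0.5, 0.01),
                radius_schedule: tuple[float, float] | None = None,
                seed: int = 0, mode: str = "batch") -> SomGrid:
    """Kohonen SOM partitioning of samples by expression profile.

    ``mode='batch'`` recomputes every prototype each epoch as the
    neighborhood-weighted mean of the samples (no learning rate);
    ``mode='online'`` applies per-sample updates with a decaying rate.
    Both use a Gaussian neighborhood whose radius decays linearly along
    ``radius_schedule`` (default: half the larger grid dimension down to
    0.1). Deterministic under ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    x = study.matrix().T  # samples x features
    n_samples = x.shape[0]
    n_nodes = grid_shape[0] * grid_shape[1]
    if n_nodes > n_samples:
        import logging
        logging.getLogger(__name__).warning(
            "SOM grid has more nodes (%d) than samples (%d)", n_nodes, n_samples)
    if radius_schedule is None:
        radius_schedule = (max(max(grid_shape) / 2.0, 0.5), 0.1)
    pos = _grid_positions(grid_shape)
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)  # nodes x nodes
    rng = np.random.default_rng(seed)
    proto = x[rng.integers(n_samples, size=n_nodes)] + 1e-6 * rng.standard_normal(
        (n_nodes, x.shape[1]))

    def bmu_of(data, protos):
        d2 = ((data[:, None, :] - protos[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1), d2

    qe_history = []
    for it in range(n_iter):
        frac = it / max(n_iter - 1, 1)
        sigma = radius_schedule[0] + frac * (radius_schedule[1] - radius_schedule[0])
        if mode == "batch":
            bmu, d2 = bmu_of(x, proto)
            qe_history.append(float(np.sqrt(d2[np.arange(n_samples), bmu]).mean()))
            h = np.exp(-grid_d2[:, bmu] / (2.0 * sigma ** 2))  # nodes x samples
            weights = h.sum(axis=1)
            new = h @ x
            nonempty = weights > 1e-12
            proto[nonempty] = new[nonempty] / weights[nonempty, None]
        elif mode == "online":
            lr = learning_rate_schedule[0] + frac * (
                learning_rate_schedule[1] - learning_rate_schedule[0])
            s = int(rng.integers(n_samples))
            d2 = ((proto - x[s]) ** 2).sum(-1)
            bmu_s = int(d2.argmin())
            h = np.exp(-grid_d2[:, bmu_s] / (2.0 * sigma ** 2))
            proto += lr * h[:, None] * (x[s] - proto)
        else:
            raise ValueError(f"unknown mode {mode!r}")

    bmu, d2 = bmu_of(x, proto)
    qe = float(np.sqrt(d2[np.arange(n_samples), bmu]).mean())
    qe_history.append(qe)
    assignment = {sid: int(b) for sid, b in zip(study.sample_ids, bmu)}
    return SomGrid(grid_shape=grid_shape, prototypes=proto,
                   assignment=assignment, quantization_error=qe,
                   qe_history=qe_history)


# ---------------------------------------------------------------------------
# counter-regulation

@dataclass
class CounterRegResult:
    """Counter-regulated pairs plus biplot-ready and per-miRNA summaries."""

    pairs: pd.DataFrame        # mirna_id, gene_id, mirna_logfc, gene_logfc, ...
    biplot: pd.DataFrame       # gene, mirna, gene_logfc, mirna_logfc
    targets_per_mirna: pd.Series
    contrast: str


def counter_regulation(mirna_meta: pd.DataFrame, gene_de: pd.DataFrame,
                       interactions: pd.DataFrame, contrast: str,
                       gene_call_config: DECallConfig | None = None) -> CounterRegResult:
    """Pair meta-significant miRNAs with opposite-direction DE target genes.

    A pair is emitted when it appears in the validated interaction table,
    the miRNA is in the meta-signature, the gene passes the mRNA calling
    rule, and the two fold changes have opposite signs.
    """
    if interactions.empty:
        raise ValueError("interaction table is empty")
    meta_contrast = mirna_meta.attrs.get("contrast")
    gene_contrast = gene_de.attrs.get("contrast")
    for name, got in (("miRNA meta-signature", meta_contrast),
                      ("gene DE table", gene_contrast)):
        if got is not None and got != contrast:
            raise ValueError(f"{name} is for contrast {got!r}, not {contrast!r}")
    cfg = gene_call_config or DECallConfig.mrna()
    gene_calls = dict(call_de(gene_de, cfg))

    rows = []
    for rec in interactions.itertuples(index=False):
        m, g = rec.mirna_id, rec.gene_id
        if m not in mirna_meta.index or g not in gene_calls:
            continue
        m_lfc = float(mirna_meta.loc[m, "mean_logfc"])
        g_lfc = float(gene_de.loc[g, "logfc"])
        if np.sign(m_lfc) == np.sign(g_lfc) or m_lfc == 0 or g_lfc == 0:
            continue
        rows.append((m, g, m_lfc, g_lfc, contrast,
                     getattr(rec, "source_tag", "unknown")))
    pairs = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "mirna_logfc",
                                        "gene_logfc", "contrast", "source_tag"])
    pairs = pairs.sort_values(["mirna_id", "gene_id"]).reset_index(drop=True)
    biplot = pairs[["gene_id", "mirna_id", "gene_logfc", "mirna_logfc"]].copy()
    counts = pairs.groupby("mirna_id").size().sort_values(ascending=False) \
        if len(pairs) else pd.Series(dtype=int)
    counts.name = "n_targets"
    return CounterRegResult(pairs=pairs, biplot=biplot,
                            targets_per_mirna=counts, contrast=contrast)
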