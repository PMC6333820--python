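"""Gene-set enrichment: weighted-KS GSEA with a permutation null, and
hypergeometric over-representation analysis.

The enrichment score (ES) of a gene set along a ranked list is the
signed extremum of a running sum that increments at set members ("hits")
by their weighted ranking metric and decrements at non-members by a
constant.  Significance is assessed against a permutation null: under
``gene_set`` mode the set labels are re-drawn uniformly along the list
(equivalently, random hit positions); under ``phenotype`` mode the
sample labels of the originating study are shuffled and the ranking
metric recomputed.  The nominal p-value is add-one, computed within the
same-signed portion of the null so that null sets yield uniform p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .study import ExpressionStudy


def make_ranked_list(gene_ids, scores) -> pd.Series:
    """Build a ranked list (scores sorted non-increasing, unique ids)."""
    s = pd.Series(np.asarray(scores, dtype=float), index=list(gene_ids))
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in ranked list: {dup!r}")
    return s.sort_values(ascending=False, kind="stable")


def rank_by_statistic(de_results: pd.DataFrame, column: str = "t_moderated") -> pd.Series:
    """Ranked list from a DE table (default metric: moderated t)."""
    if column not in de_results.columns:
        column = "t_ordinary"
    return make_ranked_list(de_results.index, de_results[column].to_numpy())


def _validate_ranked(ranked: pd.Series) -> None:
    arr = ranked.to_numpy()
    if np.any(np.diff(arr) > 1e-12):
        raise ValueError("ranked-list scores must be sorted non-increasing")
    if ranked.index.duplicated().any():
        raise ValueError("ranked-list ids must be unique")


def gsea_es(ranked: pd.Series, gene_set, weight_exponent: float = 1.0):
    """Enrichment score and full running sum of one gene set.

    Hits increment by ``|score|^w / sum_hits |score|^w``; misses decrement
    by ``1/(N - N_hits)``.  ES is the extremum of the running sum (the
    positive maximum if it is at least as large in magnitude as the
    negative minimum, else the minimum).
    """
    _validate_ranked(ranked)
    n = len(ranked)
    hit = ranked.index.isin(set(gene_set))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")
    absw = np.abs(ranked.to_numpy()) ** weight_exponent
    denom = absw[hit].sum()
    steps = np.where(hit, (absw / denom) if denom > 0 else (1.0 / n_hit),
                     -1.0 / (n - n_hit))
    if denom <= 0:
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    max_dev, min_dev = running.max(), running.min()
    es = float(max_dev if max_dev >= -min_dev else min_dev)
    return es, running


def leading_edge_size(ranked: pd.Series, gene_set, weight_exponent: float = 1.0) -> int:
    """Number of set members at or before the running-sum extremum
    (positive ES), or at or after it (negative ES)."""
    es, running = gsea_es(ranked, gene_set, weight_exponent)
    hit = ranked.index.isin(set(gene_set))
    if es >= 0:
        peak = int(np.argmax(running))
        return int(hit[: peak + 1].sum())
    trough = int(np.argmin(running))
    return int(hit[trough:].sum())


def _es_from_positions(positions: np.ndarray, absw: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many permutations given sorted hit positions.

    ``positions`` is (n_perm, k), 0-based, sorted ascending per row.  The
    running sum is piecewise linear between hits, so its extrema occur
    just before or just after hits; both candidates are evaluated in
    closed form.
    """
    n_perm, k = positions.shape
    w = absw[positions]
    tot = w.sum(axis=1)
    cum = np.cumsum(w, axis=1)
    uniform = tot <= 0
    if uniform.any():
        cum[uniform] = np.arange(1, k + 1)[None, :]
        tot[uniform] = k
    cum = cum / tot[:, None]
    jj = np.arange(1, k + 1)[None, :]
    miss_den = n - k
    after = cum - (positions + 1 - jj) / miss_den
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) \
        - (positions - jj + 1) / miss_den
    max_dev = after.max(axis=1)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


@dataclass
class GseaResult:
    set_id: str
    es: float
    nominal_p: float
    n_genes_in_set_and_list: int
    leading_edge_size: int
    n_permutations: int


def _nominal_p(es: float, null_es: np.ndarray) -> float:
    """Add-one permutation p within the same-signed null tail."""
    if es >= 0:
        same = null_es >= 0
    else:
        same = null_es < 0
    count = int((same & (np.abs(null_es) >= abs(es))).sum())
    return (1 + count) / (1 + int(same.sum()))


def gsea(ranked: pd.Series, sets: dict[str, set], n_perm: int = 1000,
         perm_mode: str = "gene_set", seed: int = 0, min_size: int = 5,
         weight_exponent: float = 1.0,
         study: ExpressionStudy | None = None,
         group_a: str | None = None, group_b: str | None = None) -> list[GseaResult]:
    """GSEA over a GMT collection with permutation nominal p-values.

    Sets with fewer than ``min_size`` members in the list are skipped.
    ``phenotype`` mode requires the originating ``study`` and the two
    group labels whose t-statistic produced the ranking.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    _validate_ranked(ranked)
    n = len(ranked)
    rng = np.random.default_rng(seed)
    absw = np.abs(ranked.to_numpy()) ** weight_exponent

    perm_rankings = None
    if perm_mode == "phenotype":
        if study is None or group_a is None or group_b is None:
            raise ValueError("phenotype mode needs study, group_a and group_b")
        if set(study.feature_ids) != set(ranked.index):
            raise ValueError("phenotype mode: ranked list must cover exactly "
                             "the study's features")
        perm_rankings = _phenotype_permutation_positions(
            study, group_a, group_b, n_perm, rng)
    elif perm_mode != "gene_set":
        raise ValueError(f"unknown perm_mode {perm_mode!r}")

    results = []
    for set_id in sorted(sets):
        members = set(sets[set_id])
        hit = ranked.index.isin(members)
        k = int(hit.sum())
        if k < min_size or k == n:
            continue
        es, _ = gsea_es(ranked, members, weight_exponent)
        if perm_mode == "gene_set":
            u = rng.random((n_perm, n))
            positions = np.sort(np.argpartition(u, k, axis=1)[:, :k], axis=1)
            null_es = _es_from_positions(positions, absw, n)
        else:
            perm_ids, perm_absw, feature_index = perm_rankings
            # membership mask in the study's feature order, then mapped
            # through each permutation's rank ordering
            is_member = feature_index.isin(members)
            hits_mask = is_member[perm_ids]  # (n_perm, n)
            positions = np.sort(
                np.where(hits_mask, np.arange(n)[None, :], n), axis=1
            )[:, :k]
            null_es = np.array([
                _es_from_positions(positions[i:i + 1],
                                   perm_absw[i] ** weight_exponent, n)[0]
                for i in range(n_perm)
            ])
        p = _nominal_p(es, null_es)
        results.append(GseaResult(
            set_id=set_id, es=es, nominal_p=p,
            n_genes_in_set_and_list=k,
            leading_edge_size=leading_edge_size(ranked, members, weight_exponent),
            n_permutations=n_perm,
        ))
    return results


def _phenotype_permutation_positions(study: ExpressionStudy, group_a: str,
                                     group_b: str, n_perm: int, rng):
    """Permute sample labels and recompute the t-ranking for each draw."""
    cols_a = study.samples_in_group(group_a)
    cols_b = study.samples_in_group(group_b)
    x = study.values[cols_a + cols_b].to_numpy(dtype=float)
    na = len(cols_a)
    n_feat = x.shape[0]
    perm_ids = np.empty((n_perm, n_feat), dtype=np.int32)
    perm_absw = np.empty((n_perm, n_feat))
    for i in range(n_perm):
        order = rng.permutation(x.shape[1])
        xa, xb = x[:, order[:na]], x[:, order[na:]]
        d = xa.shape[1] + xb.shape[1] - 2
        s2 = (((xa - xa.mean(1, keepdims=True)) ** 2).sum(1)
              + ((xb - xb.mean(1, keepdims=True)) ** 2).sum(1)) / d
        se = np.sqrt(s2 * (1.0 / na + 1.0 / xb.shape[1]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, (xb.mean(1) - xa.mean(1)) / se, 0.0)
        order_rank = np.argsort(-t, kind="stable")
        perm_ids[i] = order_rank
        perm_absw[i] = np.abs(t[order_rank])
    return perm_ids, perm_absw, study.values.index


# ---------------------------------------------------------------------------
# over-representation analysis

@dataclass
class OraResult:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_raw: float
    p_adj: float = float("nan")


def ora_hypergeom(query: set, gene_set: set, universe: set,
                  set_id: str = "") -> OraResult:
    """Upper-tail hypergeometric over-representation p of one set."""
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    if not query <= set(universe):
        raise ValueError("query must be a subset of the universe")
    eff_set = set(gene_set) & set(universe)
    overlap = len(query & eff_set)
    m, n_set, n_query = len(universe), len(eff_set), len(query)
    p = float(stats.hypergeom.sf(overlap - 1, m, n_set, n_query))
    return OraResult(set_id=set_id, overlap=overlap, set_size=n_set,
                     query_size=n_query, universe_size=m, p_raw=min(p, 1.0))


def ora_collection(query: set, sets: dict[str, set], universe: set) -> pd.DataFrame:
    """ORA over a GMT collection with BH adjustment across sets."""
    from .diffexp import bh_adjust

    rows = [ora_hypergeom(query, sets[sid], universe, set_id=sid)
            for sid in sorted(sets)]
    out = pd.DataFrame([vars(r) for r in rows]).set_index("set_id")
    if len(out):
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out
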