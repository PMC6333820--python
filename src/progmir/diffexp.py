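"""Per-dataset differential expression with empirical-Bayes moderation.

Each feature is tested between a disease group and the reference group
with a two-sample linear model (difference of group means, pooled
variance).  Variances are then moderated across the feature ensemble:
a scaled inverse-chi-square prior (d0, s0^2) is estimated from the
observed log sample variances by method of moments, and each feature's
posterior variance

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d)

replaces the raw one in the t-statistic, which gains d0 extra degrees of
freedom.  This is the standard moderated-t construction for small-sample
microarray designs.

Calling conventions follow the two omics' rules: miRNAs are called at
raw p < 0.05; mRNAs need both adjusted p < 0.05 and an absolute fold
change of at least 1.5.  On z-normalized data a linear ratio is
ill-defined, so the fold-change gate defaults to |logFC| >= log2(1.5);
the threshold is a plain number and callers may set it to any cut
(including 0 to disable the gate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .study import ExpressionStudy

#: |logFC| equivalent of a 1.5-fold linear change.
FC_15_LOG2 = math.log2(1.5)


@dataclass
class DECallConfig:
    """Thresholds for calling a feature differentially expressed."""

    p_threshold: float = 0.05
    fc_threshold: float = 0.0
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be >= 0")

    @classmethod
    def mirna(cls) -> "DECallConfig":
        """Raw p < 0.05, no fold-change gate."""
        return cls(p_threshold=0.05, fc_threshold=0.0, use_adjusted=False)

    @classmethod
    def mrna(cls) -> "DECallConfig":
        """Adjusted p < 0.05 and |logFC| >= log2(1.5)."""
        return cls(p_threshold=0.05, fc_threshold=FC_15_LOG2, use_adjusted=True)


def fit_contrast(study: ExpressionStudy, group_a: str, group_b: str) -> pd.DataFrame:
    """Two-group ordinary statistics per feature; ``logfc = mean_b - mean_a``.

    Returns a DataFrame indexed by feature with columns ``logfc``,
    ``mean_a``, ``mean_b``, ``s2``, ``t_ordinary``, ``p_ordinary``,
    ``p_raw`` (= ordinary p until :func:`moderate` is applied) and
    ``direction``. Contrast metadata lives in ``.attrs``.
    """
    cols_a = study.samples_in_group(group_a)
    cols_b = study.samples_in_group(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"both groups need >= 2 samples "
                         f"({group_a}: {len(cols_a)}, {group_b}: {len(cols_b)})")
    xa = study.values[cols_a].to_numpy(dtype=float)
    xb = study.values[cols_b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    logfc = mean_b - mean_a
    ssa = ((xa - mean_a[:, None]) ** 2).sum(axis=1)
    ssb = ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = (ssa + ssb) / df
    se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame({
        "logfc": logfc, "mean_a": mean_a, "mean_b": mean_b, "s2": s2,
        "t_ordinary": t, "p_ordinary": p, "p_raw": p,
        "direction": np.where(logfc >= 0, "up", "down"),
    }, index=study.values.index.copy())
    out.attrs.update({"group_a": group_a, "group_b": group_b,
                      "n_a": na, "n_b": nb, "df_resid": df,
                      "contrast": f"{group_a}_vs_{group_b}",
                      "dataset_id": study.dataset_id, "moderated": False})
    return out


def trigamma_inverse(target: float, max_iter: int = 50, tol: float = 1e-8) -> float:
    """Solve ``trigamma(y) = target`` for y > 0 (Newton on the inverse)."""
    if target <= 0:
        return math.inf
    if target > 1e7:
        return 1.0 / math.sqrt(target)
    y = 0.5 + 1.0 / target
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / target) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < tol:
            break
    return y


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior df d0, prior variance s0^2).

    Works on the log sample variances: their mean and excess spread over
    the chi-square sampling noise identify the prior's scale and df.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all features have zero variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        log_s0 = emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    else:
        d0 = math.inf
        log_s0 = emean
    return d0, math.exp(log_s0)


def moderate(results: pd.DataFrame, prior_df: float | None = None,
             prior_var: float | None = None) -> pd.DataFrame:
    """Fill moderated statistics; updates ``p_raw`` and adds BH ``p_adj``.

    ``prior_df``/``prior_var`` override the estimated hyperparameters
    (``prior_df=0`` disables the prior and reproduces the ordinary t
    exactly; ``inf`` shrinks fully to the prior variance).
    """
    if len(results) < 10 and (prior_df is None or prior_var is None):
        raise ValueError("moderation needs >= 10 features to estimate the prior")
    df = float(results.attrs["df_resid"])
    na, nb = results.attrs["n_a"], results.attrs["n_b"]
    s2 = results["s2"].to_numpy(dtype=float)
    if prior_df is None or prior_var is None:
        d0_est, s0_est = estimate_prior(s2, df)
    else:
        d0_est = s0_est = None
    d0 = float(prior_df) if prior_df is not None else d0_est
    s0_2 = float(prior_var) if prior_var is not None else s0_est
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    logfc = results["logfc"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, logfc / se, 0.0)
    p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = results.copy()
    out["s2_post"] = s2_post
    out["t_moderated"] = t_mod
    out["df_total"] = df_total
    out["p_raw"] = p_mod
    out["p_adj"] = bh_adjust(p_mod)
    out.attrs.update(results.attrs)
    out.attrs.update({"moderated": True, "d0": d0, "s0_2": s0_2})
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, config: DECallConfig) -> set[tuple[str, str]]:
    """Features passing the configured thresholds, with their direction."""
    if config.use_adjusted:
        if "p_adj" not in results.columns:
            raise ValueError("use_adjusted requires moderated results with p_adj")
        p = results["p_adj"]
    else:
        p = results["p_raw"]
    mask = (p < config.p_threshold) & (results["logfc"].abs() >= config.fc_threshold)
    if config.fc_threshold == 0:
        mask = p < config.p_threshold
    return {(f, d) for f, d in zip(results.index[mask], results["direction"][mask])}
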