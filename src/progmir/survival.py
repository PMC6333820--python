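"""Expression-stratified survival analysis.

Samples are split into high/low expression strata by rank-based rules
(median, 75th percentile vs rest, or upper vs lower quartile), compared
with Kaplan–Meier curves and the log-rank test, and modelled with a
univariate Cox proportional-hazards fit (Newton–Raphson on the partial
likelihood, Breslow tie handling).  Multi-gene signatures are aggregated
as the mean of per-gene z-scores.  A Wilcoxon rank-sum comparison covers
group-wise validation of marker levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STRATIFY_RULES = ("median", "quartile_75_vs_rest", "upper_vs_lower_quartile")


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    if (table["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(np.unique(table["event"])) <= {0, 1}:
        raise ValueError("event must be 0 or 1")
    return table


def stratify_by_expression(expr: pd.Series, rule: str = "quartile_75_vs_rest") -> pd.Series:
    """Assign each sample to ``high``, ``low`` or ``excluded`` by rank.

    Rank-based (invariant under monotone transforms); ties are broken by
    stable sample order.  ``median``: lower half low, upper half high;
    ``quartile_75_vs_rest``: top quarter high, rest low;
    ``upper_vs_lower_quartile``: top quarter high, bottom quarter low,
    middle excluded.
    """
    if rule not in STRATIFY_RULES:
        raise ValueError(f"unknown rule {rule!r}")
    n = len(expr)
    if n < 4:
        raise ValueError("stratification needs >= 4 samples")
    vals = expr.to_numpy(dtype=float)
    if np.allclose(vals, vals[0]):
        raise ValueError("constant expression: split undefined")
    order = np.argsort(vals, kind="stable")  # ascending
    labels = np.empty(n, dtype=object)
    quarter = n // 4
    if rule == "median":
        n_low = n // 2
        labels[order[:n_low]] = "low"
        labels[order[n_low:]] = "high"
    elif rule == "quartile_75_vs_rest":
        n_high = max(1, quarter)
        labels[order[:-n_high]] = "low"
        labels[order[-n_high:]] = "high"
    else:  # upper_vs_lower_quartile
        q = max(1, quarter)
        labels[:] = "excluded"
        labels[order[:q]] = "low"
        labels[order[-q:]] = "high"
    return pd.Series(labels, index=expr.index)


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


def km_estimate(table: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier product-limit estimator ``S(t) = prod(1 - d_i/n_i)``."""
    if len(table) < 1:
        raise ValueError("empty survival table")
    _check_table(table)
    times = table["time"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    ev_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in ev_times])
    d = np.array([((times == t) & (events == 1)).sum() for t in ev_times])
    surv = np.cumprod(1.0 - d / at_risk) if len(ev_times) else np.array([])
    return KMCurve(event_times=ev_times, at_risk=at_risk, events=d, survival=surv)


def logrank_test(table_a: pd.DataFrame, table_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test: ``chi2 = (sum(O - E))^2 / sum(V)``.

    O/E/V are accumulated over the distinct event times of the pooled
    sample with the hypergeometric variance.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both groups must be nonempty")
    for t in (table_a, table_b):
        _check_table(t)
    ta, ea = table_a["time"].to_numpy(float), table_a["event"].to_numpy(int)
    tb, eb = table_b["time"].to_numpy(float), table_b["event"].to_numpy(int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    ev_times = np.unique(all_times[all_events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in ev_times:
        n1 = (ta >= t).sum()
        n0 = (tb >= t).sum()
        n = n1 + n0
        d1 = ((ta == t) & (ea == 1)).sum()
        d = ((all_times == t) & (all_events == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n0 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


@dataclass
class CoxFit:
    beta: float
    hr: float
    se: float
    z: float
    p_wald: float
    loglik_null: float
    loglik_fit: float
    lr_stat: float
    lr_p: float
    n: int
    n_events: int
    converged: bool = True


def _cox_derivatives(beta: float, times, events, x):
    """Breslow partial log-likelihood, score and information at ``beta``."""
    eta = beta * x
    # cap to keep exp finite during wild Newton steps
    w = np.exp(np.clip(eta, -500, 500))
    ev_times = np.unique(times[events == 1])
    ll = score = info = 0.0
    for t in ev_times:
        at_risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        s0 = w[at_risk].sum()
        s1 = (w[at_risk] * x[at_risk]).sum()
        s2 = (w[at_risk] * x[at_risk] ** 2).sum()
        ll += beta * x[dead].sum() - d * np.log(s0)
        score += x[dead].sum() - d * s1 / s0
        info += d * (s2 / s0 - (s1 / s0) ** 2)
    return ll, score, info


def cox_score_test(table: pd.DataFrame, covariate: pd.Series) -> float:
    """Score (Rao) chi-square of the Cox model at beta = 0."""
    times = table["time"].to_numpy(float)
    events = table["event"].to_numpy(int)
    x = covariate.loc[table.index].to_numpy(float)
    _, score, info = _cox_derivatives(0.0, times, events, x)
    return float(score ** 2 / info)


def cox_univariate(table: pd.DataFrame, covariate: pd.Series,
                   tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Univariate Cox PH fit by Newton–Raphson with Breslow ties."""
    _check_table(table)
    times = table["time"].to_numpy(float)
    events = table["event"].to_numpy(int)
    x = covariate.loc[table.index].to_numpy(float)
    if events.sum() < 2:
        raise ValueError("need >= 2 events")
    if np.allclose(x, x[0]):
        raise ValueError("covariate is constant")

    ll0, _, _ = _cox_derivatives(0.0, times, events, x)
    beta, ll = 0.0, ll0
    converged = False
    for _ in range(max_iter):
        ll, score, info = _cox_derivatives(beta, times, events, x)
        if info <= 0:
            break
        step = score / info
        # step-halving keeps the likelihood ascending
        new_beta = beta + step
        new_ll = _cox_derivatives(new_beta, times, events, x)[0]
        halvings = 0
        while new_ll < ll and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll = _cox_derivatives(new_beta, times, events, x)[0]
            halvings += 1
        beta = new_beta
        if abs(step) < tol:
            converged = True
            break
    if not converged or abs(beta) > 15:
        logger.warning("Cox fit did not converge cleanly (beta=%.3g); "
                       "possible monotone likelihood", beta)
        converged = converged and abs(beta) <= 15
    ll_fit, _, info = _cox_derivatives(beta, times, events, x)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    lr = max(2.0 * (ll_fit - ll0), 0.0)
    return CoxFit(beta=float(beta), hr=float(np.exp(beta)), se=se, z=float(z),
                  p_wald=float(2.0 * stats.norm.sf(abs(z))),
                  loglik_null=float(ll0), loglik_fit=float(ll_fit),
                  lr_stat=float(lr), lr_p=float(stats.chi2.sf(lr, 1)),
                  n=len(times), n_events=int(events.sum()), converged=converged)


def combined_signature(expr_matrix: pd.DataFrame, gene_ids) -> pd.Series:
    """Additive multi-gene score: mean of per-gene z-scores per sample."""
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene list")
    missing = [g for g in gene_ids if g not in expr_matrix.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    block = expr_matrix.loc[gene_ids]
    z = block.sub(block.mean(axis=1), axis=0).div(block.std(axis=1, ddof=1), axis=0)
    return z.mean(axis=0)


def wilcoxon_validation(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum (Mann–Whitney) comparisons.

    Exact p for small tie-free samples (both n < 25); otherwise the
    normal approximation with tie correction (no continuity correction,
    so identical groups give p = 1).
    """
    for label, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 values")
    labels = sorted(groups)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            a = np.asarray(groups[la], dtype=float)
            b = np.asarray(groups[lb], dtype=float)
            has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            if not has_ties and max(len(a), len(b)) < 25:
                res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact")
            else:
                res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic", use_continuity=False)
            rows.append((la, lb, float(res.pvalue)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "p"])


def survival_by_stratum(table: pd.DataFrame, expr: pd.Series,
                        rule: str = "quartile_75_vs_rest") -> dict:
    """KM + log-rank + Cox for one marker under one stratification rule.

    The Cox covariate is the high-group indicator (reference level: low),
    so HR > 1 means the high-expression stratum has the higher hazard.
    """
    common = table.index.intersection(expr.index)
    table = table.loc[common]
    strata = stratify_by_expression(expr.loc[common], rule)
    high = table[strata == "high"]
    low = table[strata == "low"]
    chi2, logrank_p = logrank_test(high, low)
    used = table[strata != "excluded"]
    indicator = (strata[strata != "excluded"] == "high").astype(float)
    cox = cox_univariate(used, indicator)
    return {
        "rule": rule, "reference": "low",
        "n_high": int(len(high)), "n_low": int(len(low)),
        "km_high": km_estimate(high), "km_low": km_estimate(low),
        "logrank_chi2": chi2, "logrank_p": logrank_p, "cox": cox,
    }
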