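"""Group statistics for freezing-time and regional-expression data.

The resampling scheme follows the bootstrap-null recipe: every resample
draws N subjects with replacement from the *pooled* sample and assigns
them positionally to the original group slots, which breaks the
group-outcome link and yields a null distribution of the statistic. The
p-value is the fraction of resampled statistics exceeding the empirical
one (strictly greater by default; an add-one small-sample correction is
switchable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BehaviorTable, ExpressionMatrix

__all__ = [
    "StatResult",
    "oneway_F",
    "f_statistic",
    "welch_t",
    "bootstrap_p",
    "pairwise_t_bootstrap",
    "regionwise_expression_test",
    "ks_two_sample",
    "cohens_d",
    "bootstrap_ci_mean",
]


@dataclass
class StatResult:
    """One test: statistic name and value, resampled p, correction applied."""

    name: str
    value: float
    p: float | None = None
    p_corrected: float | None = None
    correction: str | None = None
    groups: tuple[str, ...] = ()
    n_resamples: int | None = None
    rng_seed: int | None = None


def _group_arrays(table: BehaviorTable) -> tuple[list[str], list[np.ndarray]]:
    labels = list(dict.fromkeys(table.df["group"]))
    return labels, [table.sample(g) for g in labels]


def oneway_F(table: BehaviorTable) -> float:
    """Classical one-way ANOVA F = MS_between / MS_within over the groups."""
    _, samples = _group_arrays(table)
    if len(samples) < 2:
        raise ValueError("at least two groups required")
    return f_statistic(samples)


def f_statistic(samples: list[np.ndarray]) -> float:
    """One-way ANOVA F from a list of per-group samples."""
    ns = np.array([len(s) for s in samples])
    means = np.array([s.mean() for s in samples])
    grand = np.concatenate(samples).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    df_between = len(samples) - 1
    df_within = int(ns.sum()) - len(samples)
    if df_within <= 0:
        raise ValueError("not enough observations for within-group variance")
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise ValueError("zero within-group variance; F undefined")
    return (ss_between / df_between) / ms_within


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch's unequal-variance t statistic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / len(a) + vb / len(b))
    if denom == 0:
        raise ValueError("zero variance in both samples; t undefined")
    return float((a.mean() - b.mean()) / denom)


def bootstrap_p(
    statistic_fn,
    samples: list[np.ndarray],
    n_resamples: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    add_one: bool = False,
) -> tuple[float, float]:
    """Pooled-bootstrap null p-value for an arbitrary group statistic.

    ``statistic_fn`` maps a list of per-group samples to a scalar. Returns
    (empirical statistic, p). Statistics are compared on their magnitude so
    that sign-carrying statistics (t) are treated two-sided.
    """
    import warnings

    if n_resamples < 100:
        warnings.warn("fewer than 100 resamples gives an unstable p-value")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    empirical = statistic_fn(samples)
    pooled = np.concatenate(samples)
    sizes = [len(s) for s in samples]
    edges = np.cumsum([0] + sizes)
    exceed = 0
    for _ in range(n_resamples):
        draw = pooled[rng.integers(0, len(pooled), size=len(pooled))]
        resampled = [draw[edges[i] : edges[i + 1]] for i in range(len(sizes))]
        try:
            stat = statistic_fn(resampled)
        except ValueError:
            continue  # degenerate resample (zero variance); contributes no exceedance
        if abs(stat) > abs(empirical):
            exceed += 1
    p = (exceed + 1) / (n_resamples + 1) if add_one else exceed / n_resamples
    return float(empirical), float(min(p, 1.0))


def pairwise_t_bootstrap(
    table: BehaviorTable,
    comparisons: list[tuple[str, str]],
    n_resamples: int = 10_000,
    rng_seed: int = 0,
    correction: str = "bonferroni",
) -> list[StatResult]:
    """Welch t per pair with pooled-bootstrap p, corrected for the number of
    concomitant comparisons (corrected p = min(1, raw * k))."""
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported here")
    k = len(comparisons)
    rng = np.random.default_rng(rng_seed)
    results = []
    for ga, gb in comparisons:
        a, b = table.sample(ga), table.sample(gb)
        t_emp, p_raw = bootstrap_p(
            lambda s: welch_t(s[0], s[1]), [a, b], n_resamples, rng
        )
        results.append(
            StatResult(
                name="t",
                value=t_emp,
                p=p_raw,
                p_corrected=min(1.0, p_raw * k),
                correction=f"bonferroni(k={k})",
                groups=(ga, gb),
                n_resamples=n_resamples,
                rng_seed=rng_seed,
            )
        )
    return results


def regionwise_expression_test(
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    n_resamples: int = 10_000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap Welch-t per common region, Benjamini-Hochberg corrected.

    Returns one row per region with t, raw p and FDR-corrected p.
    """
    common = [r for r in exprA.regions if r in set(exprB.regions)]
    if not common:
        raise ValueError("no common regions")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for region in common:
        a = exprA.data[region].to_numpy()
        b = exprB.data[region].to_numpy()
        t_emp, p_raw = bootstrap_p(
            lambda s: welch_t(s[0], s[1]), [a, b], n_resamples, rng
        )
        rows.append({"region": region, "t": t_emp, "p": p_raw})
    df = pd.DataFrame(rows)
    if len(df) == 1:
        df["p_fdr"] = df["p"]
    else:
        df["p_fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS: maximum ECDF gap D and its asymptotic p-value."""
    res = stats.ks_2samp(np.asarray(a, float), np.asarray(b, float), method="asymp")
    return float(res.statistic), float(res.pvalue)


def cohens_d(a: np.ndarray, b: np.ndarray, signed: bool = False) -> float:
    """Cohen's d with the pooled (n-1)-weighted standard deviation.

    Reported as a magnitude by default; ``signed=True`` keeps the sign of
    mean(a) - mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation; d undefined")
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    return float(d if signed else abs(d))


def bootstrap_ci_mean(
    sample: np.ndarray,
    n_resamples: int = 10_000,
    level: float = 0.95,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the sample mean (within-sample resampling)."""
    sample = np.asarray(sample, dtype=float)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    draws = sample[rng.integers(0, len(sample), size=(n_resamples, len(sample)))]
    means = draws.mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
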