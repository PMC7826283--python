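"""Expression filtering, simplified fold-change estimation, the
translation-efficiency T-statistic with FDR correction, and Fisher
odds-ratio overlap of target genes with differentially expressed genes.

The T-statistic is
``T = |log2FC_ribo - log2FC_rna| / sqrt(SE_ribo^2 + SE_rna^2)`` with a
two-tailed standard-normal p-value and Benjamini-Hochberg correction. The
fold-change estimator is a documented simplified stand-in for a GLM
fitter: median-of-ratios size factors, pseudo-counted log2 ratio of group
means, and a delta-method SE from a moment estimate of the common
negative-binomial dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def filter_expressed(count_matrix: pd.DataFrame, cpm_threshold: float = 1.0) -> pd.DataFrame:
    """Keep genes with mean counts-per-million >= threshold across samples."""
    lib = count_matrix.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    cpm = count_matrix * 1e6 / lib
    return count_matrix.loc[cpm.mean(axis=1) >= cpm_threshold]


def estimate_dispersion(normed: pd.DataFrame, groups: Sequence[Sequence[str]]) -> float:
    """Moment estimate of a common NB dispersion.

    Pools within-group mean/variance pairs over all genes and solves
    ``E[var] = mu + alpha*mu^2`` by regression through the origin:
    ``alpha = sum(var - mu) / sum(mu^2)``, floored at 0. The ratio of sums
    keeps the estimator unbiased at small replicate counts, where a
    per-gene median would be biased low.
    """
    num = den = 0.0
    for cols in groups:
        sub = normed[list(cols)]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        num += float((var[ok] - mu[ok]).sum())
        den += float((mu[ok] ** 2).sum())
    return max(0.0, num / den) if den > 0 else 0.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (robust to asymmetric differential
    expression, unlike plain library totals). Falls back to relative
    library totals when no gene has positive counts in every sample."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        lib = counts.sum(axis=0)
        return lib / lib.mean()
    log_geo_mean = np.log(positive).mean(axis=1)
    sf = np.exp(np.log(positive).sub(log_geo_mean, axis=0).median(axis=0))
    return sf / sf.mean()


def estimate_fc(
    counts: pd.DataFrame,
    group_labels: Dict[str, str],
    treatment: str = "ko",
    control: str = "ctrl",
    pseudocount: float = 0.5,
    min_se: float = 1e-6,
) -> pd.DataFrame:
    """Per-gene log2 fold change (treatment over control) with a
    delta-method standard error.

    Counts are normalized by median-of-ratios size factors; ``log2fc =
    log2((mu_t + pc) / (mu_c + pc))`` on group means of normalized counts.
    The SE uses ``var(mean) = (mu + alpha*mu^2)/n`` per group with a
    common dispersion alpha estimated from replicate moments, propagated
    through the log: ``SE = sqrt(sum_g var(mean_g)/(mu_g+pc)^2) / ln 2``.
    Returns a frame with columns log2fc, se.
    """
    t_cols = [c for c, g in group_labels.items() if g == treatment]
    c_cols = [c for c, g in group_labels.items() if g == control]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    lib = counts.sum(axis=0)
    if (lib[t_cols].sum() <= 0) or (lib[c_cols].sum() <= 0):
        raise ValueError("group with zero total counts")
    normed = counts / size_factors(counts)
    alpha = estimate_dispersion(normed, [t_cols, c_cols])

    mu_t = normed[t_cols].mean(axis=1)
    mu_c = normed[c_cols].mean(axis=1)
    log2fc = np.log2((mu_t + pseudocount) / (mu_c + pseudocount))
    var_t = (mu_t + alpha * mu_t**2) / len(t_cols)
    var_c = (mu_c + alpha * mu_c**2) / len(c_cols)
    se = np.sqrt(var_t / (mu_t + pseudocount) ** 2 + var_c / (mu_c + pseudocount) ** 2) / np.log(2)
    se = se.clip(lower=min_se)
    return pd.DataFrame({"log2fc": log2fc, "se": se}, index=counts.index)


def translation_efficiency_test(fc_ribo: pd.DataFrame, fc_rna: pd.DataFrame) -> pd.DataFrame:
    """T-statistic for differential translation efficiency.

    ``delta = log2fc_ribo - log2fc_rna``; ``t = |delta| / sqrt(se_ribo^2 +
    se_rna^2)``; two-tailed normal p; BH q over testable genes. Genes with
    no positive SE in either assay get NA and are excluded from BH.
    """
    genes = fc_ribo.index.intersection(fc_rna.index)
    ribo = fc_ribo.loc[genes]
    rna = fc_rna.loc[genes]
    delta = ribo["log2fc"] - rna["log2fc"]
    denom = np.sqrt(ribo["se"] ** 2 + rna["se"] ** 2)
    testable = denom > 0
    t = pd.Series(np.nan, index=genes)
    t[testable] = (delta[testable].abs() / denom[testable])
    p = pd.Series(np.nan, index=genes)
    p[testable] = 2 * stats.norm.sf(t[testable])
    q = pd.Series(np.nan, index=genes)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    return pd.DataFrame({"delta": delta, "t": t, "p": p, "q": q})


@dataclass
class OverlapResult:
    rpm_threshold: float
    direction: str
    table: Tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


def fisher_overlap(
    target: Set[str], de: Set[str], universe: Set[str], z: float = 1.959963984540054
) -> Tuple[Tuple[int, int, int, int], float, float, float, float]:
    """2x2 Fisher test of target membership vs DE membership.

    Sample OR = (a*d)/(b*c); CI = exp(log OR +/- z*sqrt(1/a+1/b+1/c+1/d));
    zero cells get a Haldane 0.5 correction for the OR and CI only; p is
    the exact (hypergeometric) two-sided Fisher p on the uncorrected table.
    """
    if not universe:
        raise ValueError("empty universe")
    a = len(target & de)
    b = len(target - de)
    c = len((universe - target) & de)
    d = len(universe - target - de)
    ta, tb, tc, td = (a, b, c, d)
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    odds = (a2 * d2) / (b2 * c2)
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    ci_low, ci_high = np.exp(np.log(odds) - z * se), np.exp(np.log(odds) + z * se)
    _, p = stats.fisher_exact([[ta, tb], [tc, td]], alternative="two-sided")
    return (ta, tb, tc, td), float(odds), float(ci_low), float(ci_high), float(p)


def overlap_odds_ratio(
    gene_rpm: Dict[str, float],
    up_genes: Set[str],
    down_genes: Set[str],
    universe: Set[str],
    rpm_thresholds: Sequence[float] = (0, 0.5, 1, 3, 5, 10, 50),
) -> pd.DataFrame:
    """Odds-ratio sweep: target sets at each RPM threshold (strict >)
    crossed with up- and down-regulated gene sets."""
    rows: List[OverlapResult] = []
    for thr in rpm_thresholds:
        target = {g for g, r in gene_rpm.items() if r > thr} & universe
        for direction, de in (("down", down_genes), ("up", up_genes)):
            table, odds, lo, hi, p = fisher_overlap(target, de & universe, universe)
            rows.append(OverlapResult(thr, direction, table, odds, lo, hi, p))
    return pd.DataFrame(
        {
            "rpm_threshold": [r.rpm_threshold for r in rows],
            "direction": [r.direction for r in rows],
            "a": [r.table[0] for r in rows],
            "b": [r.table[1] for r in rows],
            "c": [r.table[2] for r in rows],
            "d": [r.table[3] for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p": [r.p for r in rows],
        }
    )


def define_de_genes(
    results: Sequence[pd.DataFrame],
    alpha: float = 0.05,
    min_abs_lfc: float = 0.5,
) -> Tuple[Set[str], Set[str]]:
    """Up/down DE gene sets consistent across all provided result frames
    (columns log2fc, q): q < alpha and |log2fc| > min_abs_lfc in every
    frame, with a consistent sign."""
    up: Optional[Set[str]] = None
    down: Optional[Set[str]] = None
    for res in results:
        sig = res[(res["q"] < alpha) & (res["log2fc"].abs() > min_abs_lfc)]
        u = set(sig[sig["log2fc"] > 0].index)
        d = set(sig[sig["log2fc"] < 0].index)
        up = u if up is None else up & u
        down = d if down is None else down & d
    return up or set(), down or set()
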