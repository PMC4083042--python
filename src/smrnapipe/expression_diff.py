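"""Differential expression from a replicate log2 expression table, the
chromosomal-distribution chi-square test, and GO-category proportions.

The default per-gene test is an empirical-Bayes moderated t: per-gene
pooled variances are shrunk toward a common prior fitted by the
method of moments on log sample variances (the scaled-inverse-chi-square
hierarchy of Smyth 2004), which recovers most of the power lost to
3-replicate designs.  A plain Welch t-test is available with
``method="welch"``.  P-values are Benjamini-Hochberg adjusted and a gene
is called up/down when its q-value passes ``alpha`` and |log2 fold
change| passes ``min_lfc``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "call_degs",
    "chi_square_gof",
    "chrom_distribution_test",
    "go_proportions",
    "squeeze_variances",
    "ChromDistributionTest",
]


def chi_square_gof(observed, expected) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit: statistic, df = k - 1, and the upper-tail
    p-value from the chi-square survival function."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or (exp <= 0).any():
        raise ValueError("observed/expected must match and expectations be positive")
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = len(obs) - 1
    return statistic, df, float(stats.chi2.sf(statistic, df))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits the prior (d0, s0^2) of a scaled-inverse-chi-square hierarchy by
    matching moments of log(s2), then returns the posterior variances
    ``(d0*s0^2 + df*s2) / (d0 + df)`` together with (d0, s0^2).  d0 may be
    infinite when the sample variances are no more dispersed than
    chi-square sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.mean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    evar_excess = evar - float(special.polygamma(1, df / 2.0))
    if evar_excess > 0:
        d0 = 2.0 * _trigamma_inverse(evar_excess)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
        post = np.full_like(s2, s02)
    return post, d0, s02


def _split_design(matrix: pd.DataFrame, design: pd.DataFrame, mutant: str, wildtype: str):
    labels = design.set_index("sample")["genotype"]
    mut_cols = [c for c in matrix.columns if labels.get(c) == mutant]
    wt_cols = [c for c in matrix.columns if labels.get(c) == wildtype]
    if len(mut_cols) < 2 or len(wt_cols) < 2:
        raise ValueError("at least two replicates per genotype are required")
    return matrix[mut_cols].to_numpy(float), matrix[wt_cols].to_numpy(float)


def call_degs(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    min_lfc: float = 1.0,
    method: str = "moderated",
    mutant: str = "mut",
    wildtype: str = "wt",
    gene_chrom: dict | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between genotypes.

    ``matrix`` is genes x samples on the log2 scale (index = gene ids);
    ``design`` has columns ``sample`` and ``genotype``.  Returns a
    DataFrame with columns ``gene_id, chrom, mean_mut, mean_wt, log2fc,
    p_value, q_value, direction`` where direction is up/down/unchanged
    per the q-value and fold-change thresholds.
    """
    mut, wt = _split_design(matrix, design, mutant, wildtype)
    n1, n2 = mut.shape[1], wt.shape[1]
    mean_mut = mut.mean(axis=1)
    mean_wt = wt.mean(axis=1)
    lfc = mean_mut - mean_wt
    if method == "moderated":
        df_resid = n1 + n2 - 2
        s2 = (mut.var(axis=1, ddof=1) * (n1 - 1) + wt.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
        s2_post, d0, _ = squeeze_variances(s2, df_resid)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        df_total = df_resid + d0
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = lfc / se
        if np.isfinite(df_total):
            p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(tstat))
        p = np.where(se == 0, np.where(lfc == 0, 1.0, 0.0), p)
    elif method == "welch":
        res = stats.ttest_ind(mut, wt, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        # zero variance in both groups: p=1 for equal means, else 0
        degenerate = np.isnan(p)
        p = np.where(degenerate & (lfc == 0), 1.0, p)
        p = np.where(degenerate & (lfc != 0), 0.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    q = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    significant = (q <= alpha) & (np.abs(lfc) >= min_lfc)
    direction = np.where(significant, np.where(lfc > 0, "up", "down"), "unchanged")
    out = pd.DataFrame(
        {
            "gene_id": matrix.index,
            "chrom": [
                (gene_chrom or {}).get(g, "") for g in matrix.index
            ],
            "mean_mut": mean_mut,
            "mean_wt": mean_wt,
            "log2fc": lfc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    ).reset_index(drop=True)
    return out


@dataclass
class ChromDistributionTest:
    observed: dict
    expected: dict
    statistic: float
    df: int
    p_value: float
    excluded: list


def chrom_distribution_test(
    degs: pd.DataFrame, expressed_chrom: pd.Series | dict
) -> ChromDistributionTest:
    """Chi-square goodness of fit of DEG counts across chromosomes.

    The expected count on chromosome i is total_DEGs * (expressed genes on
    chromosome i / total expressed genes), so the null is that DEGs fall
    where expressed genes are.  Chromosomes with zero expectation are
    excluded with the degrees of freedom reduced accordingly.
    """
    expressed = pd.Series(expressed_chrom)
    de = degs[degs["direction"] != "unchanged"]
    total = len(de)
    if total == 0:
        raise ValueError("no differentially expressed genes to test")
    chrom_expressed = expressed.value_counts()
    observed_counts = de["chrom"].value_counts()
    chroms = sorted(chrom_expressed.index)
    observed, expected, excluded = {}, {}, []
    for chrom in chroms:
        exp = total * chrom_expressed[chrom] / len(expressed)
        obs = int(observed_counts.get(chrom, 0))
        if exp == 0:
            excluded.append(chrom)
            continue
        observed[chrom] = obs
        expected[chrom] = exp
    obs_arr = np.array(list(observed.values()), dtype=float)
    exp_arr = np.array(list(expected.values()), dtype=float)
    # renormalize so expectations sum to the observed total over kept chroms
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    statistic, df, p = chi_square_gof(obs_arr, exp_arr)
    return ChromDistributionTest(
        observed,
        dict(zip(observed.keys(), exp_arr)),
        statistic,
        df,
        p,
        excluded,
    )


def go_proportions(
    degs: pd.DataFrame, go_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-GO-category proportion of differentially expressed genes.

    ``go_table`` has columns ``gene_id`` and ``category`` (a gene may
    appear under several categories and counts once in each).  Only genes
    present in ``degs`` count as expressed; categories with no expressed
    genes are omitted.  Rows are ordered by the number of expressed genes
    in the category, descending.
    """
    expressed = set(degs["gene_id"])
    de = set(degs.loc[degs["direction"] != "unchanged", "gene_id"])
    table = go_table[go_table["gene_id"].isin(expressed)]
    rows = []
    for category, sub in table.groupby("category", sort=True):
        genes = set(sub["gene_id"])
        n_expr = len(genes)
        n_de = len(genes & de)
        rows.append(
            {
                "category": category,
                "n_de_in_category": n_de,
                "n_expressed_in_category": n_expr,
                "proportion": n_de / n_expr,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["category", "n_de_in_category", "n_expressed_in_category", "proportion"],
    )
    return out.sort_values(
        ["n_expressed_in_category", "category"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
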