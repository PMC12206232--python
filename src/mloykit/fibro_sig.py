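"""Functional signals associated with single-cell Y loss.

All expression-based operations share one normalisation: per-cell scaling
to a common library size followed by log1p (see
:func:`mloykit.sc_loy.normalize_log1p`).

Contents: LOY-vs-WT differential expression (rank-sum), binned-control
module scoring, per-lineage score tests, detection-based per-condition
gene tests (logistic likelihood ratio), hypergeometric over-representation
of gene sets, and the donor-level %LOY-vs-fibroblast-activation
regression.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .sc_loy import CellDataset, normalize_log1p

__all__ = [
    "dge_loy_vs_wt",
    "module_score",
    "score_group_test",
    "expression_condition_test",
    "ora",
    "loy_activation_regression",
    "ActivationRegression",
    "read_gmt",
    "write_gmt",
    "default_gene_sets",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list} (description dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def default_gene_sets() -> dict[str, list[str]]:
    """Illustrative TGF-signaling / fibroblast-activation sets shipped as
    editable fixtures; real analyses should supply curated GMT files."""
    path = importlib.resources.files("mloykit").joinpath("data/gene_sets.gmt")
    with importlib.resources.as_file(path) as p:
        return read_gmt(p)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    try:
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue
        )
    except ValueError:  # all-identical values etc.
        return 1.0


def dge_loy_vs_wt(
    dataset: CellDataset,
    calls: pd.DataFrame,
    group: Optional[pd.Series] = None,
    min_cells: int = 20,
    target_sum: float = 1e4,
    min_reads: int = 4000,
) -> pd.DataFrame:
    """Per-gene LOY-vs-WT differential expression within a cell subset.

    Cells must pass QC, have a defined LOY call and depth > ``min_reads``.
    The test is a two-sided rank-sum on normalised log1p expression; the
    fold change is ``log2((mean_loy + 1) / (mean_wt + 1))`` on the
    common-library-size scale (pseudocount 1); q-values are
    Benjamini-Hochberg over tested genes. MSY genes are flagged — they are
    LOY-defining and necessarily appear down-regulated.
    """
    mask = calls["is_loy"].notna() & (dataset.cells["depth"].values > min_reads)
    if group is not None:
        mask &= group.reindex(dataset.cells.index).fillna(False).astype(bool)
    idx = np.flatnonzero(mask.values)
    is_loy = calls["is_loy"][mask].astype(bool).values
    n_loy, n_wt = int(is_loy.sum()), int((~is_loy).sum())
    if n_loy < min_cells or n_wt < min_cells:
        raise ValueError(
            f"insufficient cells for DGE: {n_loy} LOY vs {n_wt} WT "
            f"(need >= {min_cells} each)"
        )
    norm = normalize_log1p(dataset.counts[:, idx], target_sum)
    loy_mat, wt_mat = norm[:, is_loy], norm[:, ~is_loy]
    # means on the linear common-size scale for fold changes
    mean_loy = np.expm1(loy_mat).mean(axis=1)
    mean_wt = np.expm1(wt_mat).mean(axis=1)
    log2fc = np.log2((mean_loy + 1.0) / (mean_wt + 1.0))
    pct_loy = (loy_mat > 0).mean(axis=1)
    pct_wt = (wt_mat > 0).mean(axis=1)

    pvals = np.ones(dataset.n_genes)
    expressed = (pct_loy > 0) | (pct_wt > 0)
    for g in np.flatnonzero(expressed):
        pvals[g] = _ranksum_p(loy_mat[g], wt_mat[g])
    out = pd.DataFrame(
        {
            "gene": dataset.genes.index,
            "log2fc": log2fc,
            "p_value": pvals,
            "pct_loy": pct_loy,
            "pct_wt": pct_wt,
            "is_msy": dataset.genes["is_msy"].values,
        }
    )
    out = out[expressed].reset_index(drop=True)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out.attrs["n_loy"] = n_loy
    out.attrs["n_wt"] = n_wt
    return out


# ---------------------------------------------------------------------------
# Module scores
# ---------------------------------------------------------------------------

def module_score(
    dataset: CellDataset,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    set_name: str = "module",
    target_sum: float = 1e4,
) -> pd.Series:
    """Binned-control module score per cell.

    Genes are ranked by average normalised expression and split into
    ``n_bins`` equal-size bins; for each set gene, ``n_ctrl`` control genes
    are sampled with replacement from its bin. The score is
    ``mean(set genes) - mean(pooled control genes)`` per cell, so adding a
    constant to every gene's normalised expression leaves it unchanged.
    Deterministic given ``seed``.
    """
    norm = normalize_log1p(dataset.counts, target_sum)
    gene_index = dataset.genes.index
    present = [g for g in gene_set if g in gene_index]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    avg = norm.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    # equal-size bins over the expression ranking
    bins[order] = np.floor(
        np.arange(len(avg)) * n_bins / len(avg)
    ).astype(int)
    rng = np.random.default_rng(seed)
    ctrl_rows: list[np.ndarray] = []
    set_rows = gene_index.get_indexer(present)
    for row in set_rows:
        pool = np.flatnonzero(bins == bins[row])
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_rows)
    score = norm[set_rows, :].mean(axis=0) - norm[ctrl, :].mean(axis=0)
    return pd.Series(score, index=dataset.cells.index, name=set_name)


def score_group_test(
    scores: pd.Series,
    calls: pd.DataFrame,
    grouping: pd.Series,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Two-sample t test of LOY vs WT module scores within each group.

    Student's t by default; Welch fallback when a group's pooled variance
    is degenerate (annotated). Adjusted p = min(1, p * n_groups) under
    Bonferroni.
    """
    df = pd.DataFrame(
        {"score": scores, "is_loy": calls["is_loy"], "group": grouping}
    ).dropna(subset=["is_loy", "group"])
    rows = []
    for group, sub in df.groupby("group", sort=True):
        loy = sub.loc[sub["is_loy"].astype(bool), "score"].values
        wt = sub.loc[~sub["is_loy"].astype(bool), "score"].values
        if len(loy) < 2 or len(wt) < 2:
            continue
        annotation = ""
        tstat, p = stats.ttest_ind(loy, wt, equal_var=True)
        if not np.isfinite(p):
            tstat, p = stats.ttest_ind(loy, wt, equal_var=False)
            annotation = "welch"
        rows.append(
            {
                "group": group,
                "n_loy": len(loy),
                "n_wt": len(wt),
                "mean_loy": float(np.mean(loy)),
                "mean_wt": float(np.mean(wt)),
                "t_stat": float(tstat),
                "p_value": float(p),
                "annotation": annotation,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if correction == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(out))
    elif correction == "fdr_bh":
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out


# ---------------------------------------------------------------------------
# Detection-based per-condition gene test
# ---------------------------------------------------------------------------

def expression_condition_test(
    dataset: CellDataset,
    calls: pd.DataFrame,
    gene: str,
    conditions: pd.Series,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-condition logistic model of gene detection on LOY status.

    Within each condition, detection (count > 0) is modeled as
    ``detected ~ 1 + is_loy`` and compared to the intercept-only model by
    likelihood ratio; the effect is the LOY odds ratio for detection.
    Quasi-separated fits fall back to an L2-penalised fit (annotated,
    Wald/LR statistics suppressed).
    """
    if gene not in dataset.genes.index:
        raise ValueError(f"gene {gene!r} not in matrix")
    row = dataset.genes.index.get_loc(gene)
    detected = np.asarray(dataset.counts[row, :].todense()).ravel() > 0
    df = pd.DataFrame(
        {
            "detected": detected,
            "is_loy": calls["is_loy"].values,
            "condition": conditions.values,
        },
        index=dataset.cells.index,
    ).dropna(subset=["is_loy"])
    levels = pd.unique(df["condition"].dropna())
    if len(levels) < 2:
        raise ValueError("need >= 2 conditions")
    rows = []
    for cond in sorted(map(str, levels)):
        sub = df[df["condition"].astype(str) == cond]
        y = sub["detected"].astype(float).values
        x = sub["is_loy"].astype(float).values
        if len(sub) < min_cells or len(np.unique(x)) < 2:
            continue
        X = sm.add_constant(x)
        annotation = ""
        try:
            full = sm.Logit(y, X).fit(disp=0, maxiter=200)
            null = sm.Logit(y, np.ones_like(y)).fit(disp=0, maxiter=200)
            lr = 2.0 * (full.llf - null.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            beta = float(full.params[1])
            if not np.isfinite(beta) or abs(beta) > 15:
                raise np.linalg.LinAlgError("separation")
        except Exception:
            full = sm.Logit(y, X).fit_regularized(
                alpha=1.0, L1_wt=0.0, disp=0, maxiter=500
            )
            beta = float(np.asarray(full.params)[1])
            lr, p = np.nan, np.nan
            annotation = "penalized"
        rows.append(
            {
                "condition": cond,
                "n_cells": len(sub),
                "odds_ratio": float(np.exp(beta)),
                "lr_stat": float(lr) if np.isfinite(lr) else np.nan,
                "p_value": p,
                "annotation": annotation,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora(
    query_genes: Sequence[str],
    gene_set_collection: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    Sets are intersected with the universe; the query must be a subset of
    the universe. p is the upper tail P(X >= overlap); q is BH across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= uni:
        raise ValueError("query genes must be contained in the universe")
    n_uni, n_query = len(uni), len(query)
    rows = []
    for name, genes in gene_set_collection.items():
        in_set = set(genes) & uni
        k = len(query & in_set)
        m = len(in_set)
        expected = n_query * m / n_uni if m else 0.0
        fold = (k / expected) if expected > 0 else 0.0
        p = (
            float(stats.hypergeom.sf(k - 1, n_uni, m, n_query))
            if m
            else 1.0
        )
        rows.append(
            {
                "set_name": name,
                "set_size": m,
                "overlap": k,
                "fold_enrichment": fold,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Donor-level regression
# ---------------------------------------------------------------------------

@dataclass
class ActivationRegression:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_donors: int
    slope_se: float


def loy_activation_regression(
    per_donor: pd.DataFrame,
    x_col: str = "percent_loy",
    y_col: str = "activation_score",
    weights: Optional[pd.Series] = None,
) -> ActivationRegression:
    """OLS of the donor mean fibroblast-activation score on %LOY leukocytes.

    Unweighted by default; pass per-donor weights (e.g. cell counts) to
    weight the fit.
    """
    df = per_donor[[x_col, y_col]].dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 donors")
    x = df[x_col].values.astype(float)
    y = df[y_col].values.astype(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in %LOY: slope undefined")
    if weights is None:
        res = stats.linregress(x, y)
        return ActivationRegression(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            p_value=float(res.pvalue),
            n_donors=len(df),
            slope_se=float(res.stderr),
        )
    w = weights.reindex(df.index).values.astype(float)
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    return ActivationRegression(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n_donors=len(df),
        slope_se=float(fit.bse[1]),
    )
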