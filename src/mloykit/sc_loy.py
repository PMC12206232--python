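"""Single-cell LOY calling and per-cell-type enrichment.

A cell is a *LOY cell* when it expresses no transcript from any gene in
the male-specific region of chromosome Y (MSY): the per-cell MSY transcript
sum is computed after quality control and ``is_loy`` is exactly
``msy_total == 0``. Cell types are assigned from marker genes (either per
cell or per externally supplied cluster), and LOY enrichment between
conditions is tested per cell type with Fisher's exact test.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CellDataset",
    "default_msy_genes",
    "normalize_log1p",
    "qc_filter_cells",
    "qc_filter_depth",
    "call_loy",
    "annotate_cell_types",
    "annotate_hierarchy",
    "loy_enrichment_by_type",
    "loy_fraction_summary",
    "MAJOR_MARKERS",
    "LEUKOCYTE_MARKERS",
    "MACROPHAGE_MARKERS",
    "p_to_stars",
]

# Marker panels used for hierarchical annotation: major cell classes,
# leukocyte sub-lineages, then macrophage polarization subtypes.
MAJOR_MARKERS: dict[str, list[str]] = {
    "leukocyte": ["PTPRC"],
    "endothelial": ["CDH5"],
    "epithelial": ["EPCAM"],
    "fibroblast": ["PDGFRA"],
    "smooth_muscle": ["ACTA2"],
}

LEUKOCYTE_MARKERS: dict[str, list[str]] = {
    "macrophage": ["CD68"],
    "monocyte": ["CSF1R"],
    "neutrophil": ["CSF3R"],
    "T_cell": ["CD3G"],
    "B_cell": ["CD79A"],
    "NK_cell": ["NCAM1"],
    "dendritic": ["CD80"],
}

# M1 and M2b share IL1B; M1 is resolved by MRC1-negativity (see
# annotate_hierarchy).
MACROPHAGE_MARKERS: dict[str, list[str]] = {
    "M1": ["IL1B"],
    "M2": ["MRC1"],
    "M2a": ["FN1", "TGM2"],
    "M2b": ["IL1B"],
    "M2c": ["MERTK"],
    "M2d": ["VEGFA"],
}

_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_stars(p: float) -> str:
    for cut, mark in _STAR_LEVELS:
        if p < cut:
            return mark
    return "ns"


def default_msy_genes() -> list[str]:
    """MSY gene symbols shipped with the package (human, overridable)."""
    text = (
        importlib.resources.files("mloykit")
        .joinpath("data/msy_genes.txt")
        .read_text()
    )
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


@dataclass
class CellDataset:
    """Genes x cells count matrix with per-gene flags and cell metadata.

    ``genes`` is indexed by gene id with boolean columns ``is_msy`` and
    ``is_mito``; ``cells`` is indexed by cell id and carries at least
    ``donor_id`` and ``condition`` plus the derived ``depth``,
    ``n_expressed_genes`` and ``mito_fraction`` columns (recomputed from
    the matrix by :meth:`refresh_metadata`).
    """

    counts: sparse.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"(n_genes={len(self.genes)}, n_cells={len(self.cells)})"
            )
        if (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("is_msy", "is_mito"):
            if col not in self.genes.columns:
                self.genes[col] = False
        self.refresh_metadata()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def refresh_metadata(self) -> None:
        """Recompute depth, expressed-gene counts and mito fraction."""
        depth = np.asarray(self.counts.sum(axis=0)).ravel()
        nnz = self.counts.getnnz(axis=0)
        mito = np.asarray(
            self.counts[self.genes["is_mito"].values, :].sum(axis=0)
        ).ravel()
        self.cells["depth"] = depth
        self.cells["n_expressed_genes"] = nnz
        with np.errstate(invalid="ignore", divide="ignore"):
            self.cells["mito_fraction"] = np.where(depth > 0, mito / np.maximum(depth, 1), 0.0)

    def set_msy(self, msy_genes: Sequence[str]) -> None:
        self.genes["is_msy"] = self.genes.index.isin(set(msy_genes))

    # -- IO -----------------------------------------------------------------

    @classmethod
    def from_mtx(
        cls,
        matrix_path,
        features_path,
        barcodes_path,
        cells_path=None,
        msy_genes: Optional[Sequence[str]] = None,
    ) -> "CellDataset":
        """Load a 10x-style MTX triplet (genes x cells orientation)."""
        counts = sparse.csr_matrix(mmread(str(matrix_path)))
        features = pd.read_csv(features_path, sep="\t", header=None)
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
        gene_ids = features.iloc[:, 0].astype(str)
        genes = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
        genes["is_mito"] = genes.index.str.upper().str.startswith("MT-")
        if cells_path is not None:
            cells = pd.read_csv(cells_path, index_col=0)
        else:
            cells = pd.DataFrame(index=barcodes.iloc[:, 0].astype(str))
        cells.index.name = "cell_id"
        ds = cls(counts=counts, genes=genes, cells=cells)
        ds.set_msy(msy_genes if msy_genes is not None else default_msy_genes())
        return ds

    @classmethod
    def from_dense(
        cls,
        frame: pd.DataFrame,
        cells: Optional[pd.DataFrame] = None,
        msy_genes: Optional[Sequence[str]] = None,
    ) -> "CellDataset":
        """Build from a dense genes-by-cells DataFrame."""
        genes = pd.DataFrame(index=frame.index.astype(str))
        genes.index.name = "gene"
        genes["is_mito"] = genes.index.str.upper().str.startswith("MT-")
        if cells is None:
            cells = pd.DataFrame(index=frame.columns.astype(str))
        cells.index.name = "cell_id"
        ds = cls(
            counts=sparse.csr_matrix(frame.values), genes=genes, cells=cells
        )
        ds.set_msy(msy_genes if msy_genes is not None else default_msy_genes())
        return ds

    def write_mtx(self, outdir) -> None:
        """Write matrix.mtx + features.tsv + barcodes.tsv + cells.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(self.counts))
        self.genes.index.to_series().to_csv(
            outdir / "features.tsv", sep="\t", header=False, index=False
        )
        self.cells.index.to_series().to_csv(
            outdir / "barcodes.tsv", sep="\t", header=False, index=False
        )
        self.cells.to_csv(outdir / "cells.csv")


def normalize_log1p(
    counts: sparse.spmatrix | np.ndarray, target_sum: float = 1e4
) -> np.ndarray:
    """Per-cell library-size normalisation to ``target_sum``, then log1p.

    Returns a dense genes x cells float array; the shared normalisation
    contract for annotation, DGE and module scoring.
    """
    dense = np.asarray(
        counts.todense() if sparse.issparse(counts) else counts, dtype=float
    )
    depth = dense.sum(axis=0)
    scale = np.divide(
        target_sum, depth, out=np.zeros_like(depth), where=depth > 0
    )
    return np.log1p(dense * scale[None, :])


def qc_filter_cells(
    dataset: CellDataset,
    mito_max: float = 0.10,
    genes_min: int = 800,
    genes_max: int = 3500,
) -> pd.DataFrame:
    """Per-cell QC: mito fraction <= mito_max and expressed genes within
    [genes_min, genes_max]. Returns ``qc_pass`` plus per-cell reasons."""
    mito = dataset.cells["mito_fraction"].values
    ngene = dataset.cells["n_expressed_genes"].values
    fail_mito = mito > mito_max
    fail_low = ngene < genes_min
    fail_high = ngene > genes_max
    reasons = []
    for fm, fl, fh in zip(fail_mito, fail_low, fail_high):
        r = []
        if fm:
            r.append("mito")
        if fl:
            r.append("few_genes")
        if fh:
            r.append("many_genes")
        reasons.append(",".join(r))
    return pd.DataFrame(
        {
            "qc_pass": ~(fail_mito | fail_low | fail_high),
            "qc_reasons": reasons,
        },
        index=dataset.cells.index,
    )


def qc_filter_depth(dataset: CellDataset, min_reads: int = 4000) -> pd.Series:
    """Inclusion flag for functional (expression) analyses: depth strictly
    greater than ``min_reads``. Kept separate from the clustering QC."""
    return pd.Series(
        dataset.cells["depth"].values > min_reads,
        index=dataset.cells.index,
        name="depth_pass",
    )


def call_loy(
    dataset: CellDataset, qc: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """LOY calls: ``is_loy`` iff the summed MSY transcript count is zero.

    ``is_loy`` is defined (non-null) only for qc-passing cells. Returns a
    frame with ``msy_total``, ``qc_pass`` and nullable-boolean ``is_loy``.
    """
    msy_mask = dataset.genes["is_msy"].values
    if not msy_mask.any():
        raise ValueError("MSY gene set is empty: configure is_msy flags")
    if qc is None:
        qc = qc_filter_cells(dataset)
    msy_total = np.asarray(dataset.counts[msy_mask, :].sum(axis=0)).ravel()
    out = pd.DataFrame(
        {
            "msy_total": msy_total.astype(int),
            "qc_pass": qc["qc_pass"].values,
        },
        index=dataset.cells.index,
    )
    is_loy = pd.array(msy_total == 0, dtype="boolean")
    is_loy[~qc["qc_pass"].values] = pd.NA
    out["is_loy"] = is_loy
    return out


def _marker_scores(
    norm: np.ndarray,
    gene_index: pd.Index,
    marker_table: Mapping[str, Sequence[str]],
    strict: bool = True,
) -> pd.DataFrame:
    """Mean normalised expression of each label's markers, per cell.

    Labels with no marker present raise (``strict``) or are dropped with a
    warning (hierarchical panels applied to partial gene sets).
    """
    import warnings

    scores = {}
    for label in sorted(marker_table):
        present = [g for g in marker_table[label] if g in gene_index]
        if not present:
            if strict:
                raise ValueError(f"no marker genes present for label {label!r}")
            warnings.warn(f"no marker genes present for label {label!r}; dropped")
            continue
        rows = gene_index.get_indexer(present)
        scores[label] = norm[rows, :].mean(axis=0)
    if not scores:
        raise ValueError("no label has any marker gene present")
    return pd.DataFrame(scores)


def annotate_cell_types(
    dataset: CellDataset,
    marker_table: Mapping[str, Sequence[str]],
    clusters: Optional[pd.Series] = None,
    target_sum: float = 1e4,
) -> pd.Series:
    """Assign each cell (or cluster) the label with maximal mean
    library-size-normalised log1p marker expression.

    Ties break lexicographically on the label for determinism. When
    ``clusters`` is given, scores are averaged within each cluster and the
    whole cluster receives one label.
    """
    norm = normalize_log1p(dataset.counts, target_sum)
    scores = _marker_scores(norm, dataset.genes.index, marker_table)
    scores.index = dataset.cells.index
    if clusters is not None:
        cluster_scores = scores.groupby(clusters.values).mean()
        cluster_label = cluster_scores.idxmax(axis=1)  # first max = lexicographic
        labels = pd.Series(clusters.values, index=dataset.cells.index).map(
            cluster_label
        )
    else:
        labels = scores.idxmax(axis=1)
    labels.name = "cell_type"
    return labels


def annotate_hierarchy(
    dataset: CellDataset,
    clusters: Optional[pd.Series] = None,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Hierarchical annotation: major type -> leukocyte lineage ->
    macrophage subtype, using the shipped marker panels.

    M1 and M2b share IL1B; cells scoring top for that shared marker are
    labeled M1 when MRC1 is undetected and M2b otherwise.
    """
    norm = normalize_log1p(dataset.counts, target_sum)
    gidx = dataset.genes.index
    major_scores = _marker_scores(norm, gidx, MAJOR_MARKERS, strict=False)
    major_scores.index = dataset.cells.index
    if clusters is not None:
        cl_scores = major_scores.groupby(clusters.values).mean()
        major = pd.Series(clusters.values, index=dataset.cells.index).map(
            cl_scores.idxmax(axis=1)
        )
    else:
        major = major_scores.idxmax(axis=1)
    out = pd.DataFrame({"major": major})
    out["lineage"] = pd.NA
    out["subtype"] = pd.NA

    leuk = major == "leukocyte"
    if leuk.any() and any(
        g in gidx for v in LEUKOCYTE_MARKERS.values() for g in v
    ):
        scores = _marker_scores(norm, gidx, LEUKOCYTE_MARKERS, strict=False)
        scores.index = dataset.cells.index
        out.loc[leuk, "lineage"] = scores.loc[leuk].idxmax(axis=1)

    macro = out["lineage"] == "macrophage"
    sub_table = {
        k: v
        for k, v in MACROPHAGE_MARKERS.items()
        if k != "M2b" and any(g in gidx for g in v)
    }
    if macro.any() and sub_table:
        scores = _marker_scores(norm, gidx, sub_table, strict=False)
        scores.index = dataset.cells.index
        sub = scores.loc[macro].idxmax(axis=1)
        if "MRC1" in gidx:
            mrc1 = norm[gidx.get_loc("MRC1"), :]
            mrc1 = pd.Series(mrc1, index=dataset.cells.index)
            il1b_top = sub == "M1"
            sub[il1b_top & (mrc1.loc[sub.index] > 0)] = "M2b"
        out.loc[macro, "subtype"] = sub

    finest = out["subtype"].copy()
    finest = finest.fillna(out["lineage"]).fillna(out["major"])
    out["label"] = finest
    return out


def loy_enrichment_by_type(
    calls: pd.DataFrame,
    labels: pd.Series,
    condition: pd.Series,
    case: str = "IPF",
    control: str = "control",
) -> pd.DataFrame:
    """Per-cell-type Fisher's exact test of LOY vs WT across conditions.

    2x2 table per type: rows LOY/WT, columns case/control. The odds ratio
    is the conditional maximum-likelihood estimate with an exact
    conditional 95% CI when all margins are positive; zero cells fall back
    to the Woolf interval around the Haldane-Anscombe-corrected sample OR
    (annotated). p-values are two-sided and reported unadjusted with star
    marks; a Benjamini-Hochberg column is included.
    """
    df = pd.DataFrame(
        {
            "is_loy": calls["is_loy"],
            "label": labels,
            "condition": condition,
        }
    ).dropna(subset=["is_loy", "label"])
    rows = []
    for cell_type, sub in df.groupby("label", sort=True):
        in_case = sub["condition"] == case
        in_ctrl = sub["condition"] == control
        if not in_case.any() or not in_ctrl.any():
            continue  # both conditions required
        loy = sub["is_loy"].astype(bool)
        a = int((loy & in_case).sum())  # LOY, case
        b = int((~loy & in_case).sum())  # WT, case
        c = int((loy & in_ctrl).sum())  # LOY, control
        d = int((~loy & in_ctrl).sum())  # WT, control
        table = np.array([[a, c], [b, d]])
        _, p = stats.fisher_exact(table, alternative="two-sided")
        annotation = ""
        if min(a, b, c, d) > 0:
            res = stats.contingency.odds_ratio(table, kind="conditional")
            or_est = float(res.statistic)
            ci = res.confidence_interval(0.95)
            ci_low, ci_high = float(ci.low), float(ci.high)
        else:
            # Haldane-Anscombe correction + Woolf interval
            a2, b2, c2, d2 = (v + 0.5 for v in (a, b, c, d))
            or_est = (a2 * d2) / (b2 * c2)
            se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
            z = stats.norm.ppf(0.975)
            ci_low = float(or_est * np.exp(-z * se))
            ci_high = float(or_est * np.exp(z * se))
            annotation = "haldane-anscombe"
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                or_est, ci_low, ci_high = np.nan, np.nan, np.nan
                annotation = "zero-margin"
        rows.append(
            {
                "cell_type": cell_type,
                "loy_case": a,
                "wt_case": b,
                "loy_control": c,
                "wt_control": d,
                "odds_ratio": or_est,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p_value": float(p),
                "significant_marks": p_to_stars(p),
                "annotation": annotation,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def loy_fraction_summary(
    calls: pd.DataFrame,
    labels: Optional[pd.Series] = None,
    grouping: Optional[pd.DataFrame | pd.Series] = None,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Percent LOY with exact (Clopper-Pearson) binomial CIs per group.

    ``grouping`` may be any combination of per-cell keys (donor, condition,
    lineage, ...); ``labels`` adds a cell-type key. Groups with no defined
    calls yield an annotated empty row.
    """
    df = pd.DataFrame({"is_loy": calls["is_loy"]})
    keys = []
    if labels is not None:
        df["cell_type"] = labels
        keys.append("cell_type")
    if grouping is not None:
        g = grouping.to_frame() if isinstance(grouping, pd.Series) else grouping
        for col in g.columns:
            df[col] = g[col].values
            keys.append(col)
    if not keys:
        df["_all"] = "all"
        keys = ["_all"]
    rows = []
    for key, sub in df.groupby(keys, sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        called = sub["is_loy"].dropna().astype(bool)
        n = int(len(called))
        k = int(called.sum())
        if n == 0:
            rows.append(
                dict(zip(keys, key))
                | {
                    "n_cells": 0,
                    "n_loy": 0,
                    "percent_loy": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "annotation": "no called cells",
                }
            )
            continue
        ci = stats.binomtest(k, n).proportion_ci(
            confidence_level=confidence, method="exact"
        )
        rows.append(
            dict(zip(keys, key))
            | {
                "n_cells": n,
                "n_loy": k,
                "percent_loy": 100.0 * k / n,
                "ci_low": 100.0 * ci.low,
                "ci_high": 100.0 * ci.high,
                "annotation": "",
            }
        )
    return pd.DataFrame(rows)
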