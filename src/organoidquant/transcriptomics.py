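"""Cell QC filtering, DE-table thresholding, and cross-dataset
directionality concordance.

The transcriptomic side of the phenotype analysis consumes gene-level
differential-expression tables produced elsewhere; this module supplies
the arithmetic around them: the four-rule single-cell QC filter, the
significance cutoff (adjusted p and |log2FC|), and the overlap /
sign-concordance report used to compare an organoid stress condition
against a patient-biopsy dataset.

Boundary behavior is deliberately asymmetric, following the stated
rules literally: QC keeps cells strictly *below* each threshold, while
the DE cutoffs are inclusive (padj <= alpha, |log2FC| >= lfc_min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CellQCThresholds",
    "ConcordanceReport",
    "qc_filter_cells",
    "filter_de",
    "overlap_concordance",
]


@dataclass
class CellQCThresholds:
    """Upper bounds of the four cell-QC rules (all strict).

    Defaults are the study-scale values: cells with UMI < 40,000,
    detected genes < 8,500, mitochondrial fraction < 10% and ribosomal
    fraction < 40% are kept.
    """

    max_umi: float = 40_000
    max_genes: int = 8_500
    max_mito_fraction: float = 0.10
    max_ribo_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.max_umi <= 0 or self.max_genes <= 0:
            raise ValueError("UMI and gene thresholds must be positive")
        for f in (self.max_mito_fraction, self.max_ribo_fraction):
            if not 0 < f <= 1:
                raise ValueError("fraction thresholds must be in (0, 1]")


def qc_filter_cells(
    counts: sparse.spmatrix | np.ndarray,
    gene_names: Sequence[str],
    thresholds: CellQCThresholds | None = None,
    mito_prefix: str = "MT-",
    ribo_prefixes: tuple[str, ...] = ("RPS", "RPL"),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the four QC rules to a cells-by-genes count matrix.

    A cell is kept iff **all** of: total counts < max_umi, detected
    genes < max_genes, mitochondrial count fraction < max_mito_fraction
    and ribosomal count fraction < max_ribo_fraction (strict
    inequalities).  Mitochondrial/ribosomal genes are identified by
    configurable name prefixes.

    Returns the boolean kept mask and a per-cell report with the four
    metrics and per-rule pass flags.
    """
    thresholds = thresholds or CellQCThresholds()
    X = counts.tocsr() if sparse.issparse(counts) else np.asarray(counts)
    n_cells, n_genes = X.shape
    if len(gene_names) != n_genes:
        raise ValueError("gene_names must cover all matrix columns")
    if (X.data if sparse.issparse(X) else X).min(initial=0) < 0:
        raise ValueError("count matrix contains negative counts")

    mito_mask = np.array([g.startswith(mito_prefix) for g in gene_names])
    ribo_mask = np.array([g.startswith(ribo_prefixes) for g in gene_names])

    if sparse.issparse(X):
        total = np.asarray(X.sum(axis=1)).ravel()
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        ribo = np.asarray(X[:, ribo_mask].sum(axis=1)).ravel()
    else:
        total = X.sum(axis=1)
        detected = (X > 0).sum(axis=1)
        mito = X[:, mito_mask].sum(axis=1)
        ribo = X[:, ribo_mask].sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        ribo_frac = np.where(total > 0, ribo / np.maximum(total, 1), 0.0)

    pass_umi = total < thresholds.max_umi
    pass_genes = detected < thresholds.max_genes
    pass_mito = mito_frac < thresholds.max_mito_fraction
    pass_ribo = ribo_frac < thresholds.max_ribo_fraction
    kept = pass_umi & pass_genes & pass_mito & pass_ribo

    report = pd.DataFrame(
        {
            "total_umi": total,
            "n_genes": detected,
            "mito_fraction": mito_frac,
            "ribo_fraction": ribo_frac,
            "pass_umi": pass_umi,
            "pass_genes": pass_genes,
            "pass_mito": pass_mito,
            "pass_ribo": pass_ribo,
            "kept": kept,
        }
    )
    return kept, report


def filter_de(
    table: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 0.8,
    gene_col: str = "gene",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> pd.DataFrame:
    """Keep rows with adjusted p <= ``alpha`` and |log2FC| >= ``lfc_min``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    if table.empty:
        return table.copy()
    if table[gene_col].duplicated().any():
        dupes = table[gene_col][table[gene_col].duplicated()].unique()[:5]
        raise ValueError(f"duplicate gene IDs in DE table: {list(dupes)}")
    padj = table[padj_col].to_numpy(dtype=float)
    if np.nanmin(padj) < 0 or np.nanmax(padj) > 1:
        raise ValueError("adjusted p values must lie in [0, 1]")
    keep = (padj <= alpha) & (table[lfc_col].abs().to_numpy() >= lfc_min)
    return table.loc[keep].reset_index(drop=True)


@dataclass
class ConcordanceReport:
    """Overlap and sign-concordance summary for two DE tables.

    Fractions of the overlap are reported alongside two overlap
    referents — relative to table A, table B, and the union of both
    significant gene sets — because the natural denominator of
    "fraction of all analyzed" is ambiguous.
    """

    n_a: int
    n_b: int
    n_overlap: int
    n_concordant: int
    n_up_both: int
    n_down_both: int
    n_discordant: int
    concordant_fraction: float
    up_both_fraction: float
    down_both_fraction: float
    overlap_fraction_of_a: float
    overlap_fraction_of_b: float
    overlap_fraction_of_union: float
    fractions_defined: bool
    genes: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "genes"}
        d["genes"] = {k: list(v) for k, v in self.genes.items()}
        return d


def overlap_concordance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    apply_filter: bool = False,
    alpha: float = 0.05,
    lfc_min: float = 0.8,
    gene_col: str = "gene",
    lfc_col: str = "log2fc",
) -> ConcordanceReport:
    """Gene-ID overlap of two DE tables with fold-change sign agreement.

    A shared gene is *concordant* when its log2FC signs agree in both
    tables; zero fold changes count as discordant (with a warning).
    With ``apply_filter`` the significance cutoffs are applied to both
    tables first.
    """
    if apply_filter:
        a = filter_de(a, alpha=alpha, lfc_min=lfc_min, gene_col=gene_col, lfc_col=lfc_col)
        b = filter_de(b, alpha=alpha, lfc_min=lfc_min, gene_col=gene_col, lfc_col=lfc_col)
    merged = a[[gene_col, lfc_col]].merge(
        b[[gene_col, lfc_col]], on=gene_col, suffixes=("_a", "_b")
    )
    n_a, n_b = len(a), len(b)
    n_overlap = len(merged)
    sa = np.sign(merged[f"{lfc_col}_a"].to_numpy())
    sb = np.sign(merged[f"{lfc_col}_b"].to_numpy())
    if n_overlap and ((sa == 0) | (sb == 0)).any():
        warnings.warn("zero log2FC among overlapping genes; counted as discordant")
    up_both = (sa > 0) & (sb > 0)
    down_both = (sa < 0) & (sb < 0)
    concordant = up_both | down_both
    union = len(set(a[gene_col]) | set(b[gene_col]))

    genes = {
        "up_in_both": sorted(merged.loc[up_both, gene_col]),
        "down_in_both": sorted(merged.loc[down_both, gene_col]),
        "discordant": sorted(merged.loc[~concordant, gene_col]),
        "overlap": sorted(merged[gene_col]),
    }
    defined = n_overlap > 0
    nan = float("nan")
    return ConcordanceReport(
        n_a=n_a,
        n_b=n_b,
        n_overlap=n_overlap,
        n_concordant=int(concordant.sum()),
        n_up_both=int(up_both.sum()),
        n_down_both=int(down_both.sum()),
        n_discordant=int(n_overlap - concordant.sum()),
        concordant_fraction=float(concordant.sum() / n_overlap) if defined else nan,
        up_both_fraction=float(up_both.sum() / n_overlap) if defined else nan,
        down_both_fraction=float(down_both.sum() / n_overlap) if defined else nan,
        overlap_fraction_of_a=n_overlap / n_a if n_a else nan,
        overlap_fraction_of_b=n_overlap / n_b if n_b else nan,
        overlap_fraction_of_union=n_overlap / union if union else nan,
        fractions_defined=defined,
        genes=genes,
    )
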