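"""Marker (signature) gene selection for cell-type deconvolution.

Signature genes are genes expressed by one or more of the characterized
cell types but at negligible levels in the uncharacterized (cancer) cells
and in non-hematopoietic background tissues.  The selection logic keeps a
gene for a cell type only when it is significantly overexpressed against
EVERY other cell type and EVERY background tissue, ranks survivors by
their worst-case fold change, and removes extreme-expression genes that
would otherwise dominate a least-squares fit.

Differential overexpression is assessed with a one-sided Wilcoxon
rank-sum test on TPM values with Benjamini-Hochberg correction across
genes — a distribution-free choice that needs no dispersion estimation
and is fully deterministic.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import InputError, Source, _sniff_sep


@dataclass
class SignatureSet:
    """Per-cell-type ordered marker gene lists."""

    markers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell_type, genes in self.markers.items():
            if len(set(genes)) != len(genes):
                raise InputError(f"duplicate markers for cell type {cell_type!r}")
            if not genes:
                raise InputError(f"cell type {cell_type!r} has no markers")

    @property
    def union(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.markers.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    @property
    def n_genes(self) -> int:
        return len(self.union)

    def validate_against(self, gene_universe) -> None:
        universe = set(gene_universe)
        for cell_type, genes in self.markers.items():
            missing = [g for g in genes if g not in universe]
            if missing:
                raise InputError(
                    f"markers for {cell_type!r} absent from reference: {missing[:10]}"
                )

    def write(self, path: str | Path) -> None:
        rows = [
            {"cell_type": ct, "gene": g}
            for ct, genes in self.markers.items()
            for g in genes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, source: Source) -> "SignatureSet":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        sep = _sniff_sep(text.splitlines()[0])
        df = pd.read_csv(_io.StringIO(text), sep=sep)
        if not {"cell_type", "gene"} <= set(df.columns):
            raise InputError("signature file needs 'cell_type' and 'gene' columns")
        markers: dict[str, list[str]] = {}
        for ct, sub in df.groupby("cell_type", sort=False):
            markers[str(ct)] = [str(g) for g in sub["gene"]]
        return cls(markers)


@dataclass
class DifferentialResult:
    """Per-gene one-sided overexpression statistics (target > other)."""

    table: pd.DataFrame  # columns: log2_fold_change, pvalue, padj

    @property
    def log2_fold_change(self) -> pd.Series:
        return self.table["log2_fold_change"]

    @property
    def pvalue(self) -> pd.Series:
        return self.table["pvalue"]

    @property
    def padj(self) -> pd.Series:
        return self.table["padj"]


def differential_overexpression_test(
    target: pd.DataFrame,
    other: pd.DataFrame,
    pseudocount: float = 1.0,
) -> DifferentialResult:
    """One-sided rank-sum test of target > other, per gene, BH-adjusted.

    ``target`` and ``other`` are genes x samples frames on the same gene
    index.  The fold change is ``(mean(target)+pc) / (mean(other)+pc)``
    reported on a log2 scale.
    """
    if pseudocount <= 0:
        raise InputError("pseudocount must be > 0")
    if target.shape[1] < 2 or other.shape[1] < 2:
        raise InputError("each group needs at least 2 samples")
    if not target.index.equals(other.index):
        other = other.reindex(target.index)
        if other.isna().any().any():
            raise InputError("gene universes of the two groups differ")
    res = stats.mannwhitneyu(
        target.to_numpy(dtype=float),
        other.to_numpy(dtype=float),
        alternative="greater",
        axis=1,
    )
    pvals = np.asarray(res.pvalue, dtype=float)
    log2fc = np.log2(
        (target.mean(axis=1).to_numpy() + pseudocount)
        / (other.mean(axis=1).to_numpy() + pseudocount)
    )
    padj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2_fold_change": log2fc, "pvalue": pvals, "padj": padj},
        index=target.index,
    )
    return DifferentialResult(table)


def _passes_all(
    target: pd.DataFrame,
    opponents: dict[str, pd.DataFrame],
    alpha: float,
    min_fold: float,
    pseudocount: float,
) -> pd.DataFrame:
    """Genes significant and >= min_fold against every opponent group.

    Returns a frame with the per-gene minimum log2 fold change over
    opponents, restricted to surviving genes.
    """
    keep = pd.Series(True, index=target.index)
    min_l2fc = pd.Series(np.inf, index=target.index)
    threshold = np.log2(min_fold)
    for frame in opponents.values():
        result = differential_overexpression_test(target, frame, pseudocount)
        keep &= (result.padj < alpha) & (result.log2_fold_change >= threshold)
        min_l2fc = np.minimum(min_l2fc, result.log2_fold_change)
    survivors = min_l2fc[keep]
    return survivors.sort_values(ascending=False).to_frame("min_log2_fold_change")


def select_signature_genes(
    groups: dict[str, pd.DataFrame],
    background: dict[str, pd.DataFrame] | None = None,
    alpha: float = 0.01,
    min_fold: float = 2.0,
    top_k: int = 50,
    expression_cap: float = 1000.0,
    pseudocount: float = 1.0,
) -> SignatureSet:
    """Select per-cell-type marker genes.

    For each cell type, keep genes significantly overexpressed
    (BH-adjusted p < ``alpha``) with fold change >= ``min_fold`` against
    every other cell type and every background tissue; rank by minimum
    fold change, truncate to ``top_k``, then drop genes whose maximum
    group-mean expression exceeds ``expression_cap`` TPM (extreme genes
    would dominate the weighted least-squares objective).
    """
    if len(groups) < 2:
        raise InputError("at least two cell types are required")
    background = background or {}
    markers: dict[str, list[str]] = {}
    group_means = pd.DataFrame({ct: df.mean(axis=1) for ct, df in groups.items()})
    for cell_type, target in groups.items():
        opponents = {ct: df for ct, df in groups.items() if ct != cell_type}
        opponents.update(background)
        ranked = _passes_all(target, opponents, alpha, min_fold, pseudocount)
        chosen = list(ranked.index[:top_k])
        max_expr = group_means.loc[chosen].max(axis=1)
        chosen = [g for g in chosen if max_expr[g] <= expression_cap]
        if not chosen:
            raise InputError(
                f"no marker genes survive for cell type {cell_type!r}; "
                "consider relaxing alpha/min_fold or raising expression_cap"
            )
        markers[cell_type] = chosen
    return SignatureSet(markers)


def build_shared_t_signature(
    cd4: pd.DataFrame,
    cd8: pd.DataFrame,
    others: dict[str, pd.DataFrame],
    alpha: float = 0.01,
    min_fold: float = 2.0,
    top_k: int = 50,
    expression_cap: float = 1000.0,
    pseudocount: float = 1.0,
    similarity_bound: float = 1.0,
) -> list[str]:
    """General T-cell markers shared by the CD4 and CD8 subsets.

    Pools the two T subsets, applies the standard selection against every
    non-T group, then keeps only genes with |log2 fold change| between CD4
    and CD8 below ``similarity_bound`` — markers of T cells as a lineage
    rather than of one subset.
    """
    pooled = pd.concat([cd4, cd8], axis=1)
    ranked = _passes_all(pooled, others, alpha, min_fold, pseudocount)
    chosen = list(ranked.index[:top_k])
    means = pd.concat(
        [pooled.mean(axis=1)] + [df.mean(axis=1) for df in others.values()], axis=1
    ).max(axis=1)
    chosen = [g for g in chosen if means[g] <= expression_cap]
    subset_l2fc = np.log2(
        (cd4.mean(axis=1) + pseudocount) / (cd8.mean(axis=1) + pseudocount)
    )
    return [g for g in chosen if abs(subset_l2fc[g]) <= similarity_bound]
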