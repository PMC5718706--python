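"""Expression matrices, TPM normalization and gene-universe alignment.

The central container is :class:`ExpressionMatrix`, a thin wrapper around a
genes x samples :class:`pandas.DataFrame` tagged with its unit (``"tpm"`` or
``"counts"``).  TPM (transcripts per million) is the working unit of the
whole package: every downstream derivation relies on each sample column
summing to 10^6, which is what makes the fitted mixture proportions sum
to one.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, TextIO, Union

import numpy as np
import pandas as pd

TPM_TOTAL = 1e6

Source = Union[str, Path, TextIO]


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples expression values.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with one column per sample.
    unit
        ``"tpm"`` or ``"counts"``.
    gene_lengths
        Optional per-gene lengths in kilobases; required only to convert
        raw counts to TPM.
    """

    data: pd.DataFrame
    unit: str = "tpm"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("tpm", "counts"):
            raise InputError(f"unknown unit tag {self.unit!r}; use 'tpm' or 'counts'")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene identifiers: {dups[:10]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample identifiers: {dups[:10]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise InputError("expression values must be finite")
        if (values < 0).any():
            raise InputError("expression values must be >= 0")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.data.index)

    # -- conveniences -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise InputError(f"genes absent from matrix: {missing[:10]}")
        lengths = None
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.loc[list(genes)]
        return ExpressionMatrix(self.data.loc[list(genes)], self.unit, lengths)


@dataclass
class GeneAlignmentReport:
    """How the bulk, reference and signature gene universes overlap."""

    shared_genes: list[str]
    dropped_signature_genes: dict[str, list[str]] = field(default_factory=dict)
    coverage_fraction: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"shared genes: {len(self.shared_genes)}"]
        for ct, frac in self.coverage_fraction.items():
            dropped = self.dropped_signature_genes.get(ct, [])
            lines.append(
                f"  {ct}: signature coverage {frac:.2%}"
                + (f" (dropped: {', '.join(dropped)})" if dropped else "")
            )
        return "\n".join(lines)


def _sniff_sep(sample_line: str) -> str:
    return "\t" if "\t" in sample_line else ","


def read_expression_table(
    source: Source,
    unit_tag: str = "tpm",
    *,
    gene_lengths: pd.Series | None = None,
    uppercase: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table (genes in first column, samples in header).

    TSV is the default; comma-separated files are detected automatically.
    Duplicate gene rows are collapsed by arithmetic mean; a duplicated
    sample identifier is an error.  A non-numeric body cell raises an
    :class:`InputError` naming its row and column.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    first_line = text.splitlines()[0] if text else ""
    sep = _sniff_sep(first_line)
    header = [tok.strip() for tok in first_line.rstrip("\n").split(sep)][1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise InputError(f"duplicate sample identifiers in header: {dups}")
    raw = pd.read_csv(_io.StringIO(text), sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    if uppercase:
        raw.index = raw.index.str.upper()
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise InputError(f"duplicate sample identifiers in header: {dups}")
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise InputError(
                f"non-numeric or missing value at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = converted
    if numeric.index.duplicated().any():
        numeric = numeric.groupby(level=0, sort=False).mean()
    if gene_lengths is not None and uppercase:
        gene_lengths = gene_lengths.copy()
        gene_lengths.index = gene_lengths.index.astype(str).str.upper()
    return ExpressionMatrix(numeric, unit_tag, gene_lengths)


def read_gene_lengths(source: Source) -> pd.Series:
    """Two-column table: gene identifier, length in kilobases."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    sep = _sniff_sep(text.splitlines()[0])
    df = pd.read_csv(_io.StringIO(text), sep=sep, index_col=0)
    series = df.iloc[:, 0].astype(float)
    if (series <= 0).any():
        bad = series.index[series <= 0].tolist()
        raise InputError(f"nonpositive gene lengths: {bad[:10]}")
    return series


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def tpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to TPM using per-gene lengths (kilobases).

    Per sample: ``tpm_i = 1e6 * (counts_i / l_i) / sum_k(counts_k / l_k)``.
    """
    if counts.unit != "counts":
        raise InputError("tpm_normalize expects a counts matrix")
    if counts.gene_lengths is None:
        raise InputError("gene lengths are required to TPM-normalize counts")
    lengths = counts.gene_lengths
    missing = lengths.index[lengths.isna()].tolist()
    if missing:
        raise InputError(f"genes without a length: {missing[:10]}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise InputError(f"nonpositive gene lengths: {bad[:10]}")
    rates = counts.data.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise InputError(f"all-zero samples cannot be normalized: {zero}")
    tpm = rates.div(totals, axis=1) * TPM_TOTAL
    return ExpressionMatrix(tpm, "tpm", counts.gene_lengths)


def rescale_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every sample column to sum exactly 10^6 (idempotent)."""
    totals = matrix.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise InputError(f"all-zero samples cannot be rescaled: {zero}")
    scaled = matrix.data.div(totals, axis=1) * TPM_TOTAL
    return ExpressionMatrix(scaled, "tpm", matrix.gene_lengths)


def align_genes(bulk: ExpressionMatrix, reference, signature) -> GeneAlignmentReport:
    """Report the shared gene universe and per-cell-type signature coverage.

    Matching is exact, case-sensitive string equality.  A cell type whose
    signature is entirely absent from the shared universe is a hard error:
    its proportion could not be constrained at all.
    """
    bulk_genes = set(bulk.gene_ids)
    ref_genes = set(reference.gene_ids)
    shared = [g for g in bulk.gene_ids if g in ref_genes]
    shared_set = bulk_genes & ref_genes
    dropped: dict[str, list[str]] = {}
    coverage: dict[str, float] = {}
    for cell_type, markers in signature.markers.items():
        lost = [g for g in markers if g not in shared_set]
        kept = len(markers) - len(lost)
        dropped[cell_type] = lost
        coverage[cell_type] = kept / len(markers) if markers else 0.0
        if markers and kept == 0:
            raise InputError(
                f"cell type {cell_type!r} retains no signature genes in the "
                "shared bulk/reference universe"
            )
    return GeneAlignmentReport(shared, dropped, coverage)
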