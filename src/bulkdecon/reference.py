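"""Reference expression profiles per cell type and per-cell mRNA contents.

A :class:`ReferenceProfileSet` holds, for each characterized cell type, the
expected TPM expression of every gene (``profile``) and a same-shaped
per-gene variability (``variability``) used to down-weight unreliable
signature genes during fitting.  Two constructions are provided:

* sorted-cell bulk replicates -> per-gene median and interquartile range,
  the robust choice for bulk RNA-seq of flow-sorted populations;
* labeled single cells -> per-gene mean and standard deviation, which
  tolerate the dropout-heavy, zero-inflated nature of single-cell data.

The :class:`MRnaContentTable` maps cell types to picograms of mRNA per
cell.  Lymphocytes and cancer cells carry a comparable mRNA mass, so the
default for those classes (and the uncharacterized fraction) is 0.4 pg.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, InputError, Source, _sniff_sep

#: pg of mRNA per cell for the lymphocyte-like class (B, NK, T and cancer
#: cells carry similar mRNA mass); used for both characterized defaults and
#: the uncharacterized fraction.
LYMPHOCYTE_MRNA_PG = 0.4

_LYMPHOCYTE_CLASS = {
    "bcell", "bcells", "b",
    "nkcell", "nkcells", "nk",
    "tcell", "tcells", "t",
    "cd4_tcell", "cd4_tcells", "cd4tcell", "cd4", "cd4_t",
    "cd8_tcell", "cd8_tcells", "cd8tcell", "cd8", "cd8_t",
    "treg", "thelper",
    "cancer", "cancercell", "cancercells", "tumor", "uncharacterized",
}


@dataclass
class ReferenceProfileSet:
    """Per-cell-type expected expression and variability (genes x types)."""

    profile: pd.DataFrame
    variability: pd.DataFrame
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.profile.shape != self.variability.shape:
            raise InputError("profile and variability must share shape")
        if not self.profile.index.equals(self.variability.index) or not (
            self.profile.columns.equals(self.variability.columns)
        ):
            raise InputError("profile and variability must share gene/type indexing")
        if self.profile.columns.duplicated().any():
            raise InputError("duplicate cell type names")
        if self.profile.shape[1] == 0:
            raise InputError("at least one cell type is required")
        for name, df in (("profile", self.profile), ("variability", self.variability)):
            arr = df.to_numpy(dtype=float)
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise InputError(f"{name} entries must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profile.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.profile.columns)

    def subset_genes(self, genes) -> "ReferenceProfileSet":
        genes = list(genes)
        return ReferenceProfileSet(
            self.profile.loc[genes], self.variability.loc[genes], self.provenance
        )

    def drop_cell_type(self, cell_type: str) -> "ReferenceProfileSet":
        if cell_type not in self.profile.columns:
            raise InputError(f"unknown cell type {cell_type!r}")
        return ReferenceProfileSet(
            self.profile.drop(columns=cell_type),
            self.variability.drop(columns=cell_type),
            self.provenance,
        )

    def write(self, profile_path: str | Path, variability_path: str | Path) -> None:
        self.profile.to_csv(profile_path, sep="\t", index_label="gene")
        self.variability.to_csv(variability_path, sep="\t", index_label="gene")

    @classmethod
    def read(
        cls,
        profile_path: str | Path,
        variability_path: str | Path,
        provenance: str = "user",
    ) -> "ReferenceProfileSet":
        profile = pd.read_csv(profile_path, sep="\t", index_col=0)
        variability = pd.read_csv(variability_path, sep="\t", index_col=0)
        return cls(profile, variability, provenance)


@dataclass
class MRnaContentTable:
    """Cell type -> picograms of mRNA per cell (r_j)."""

    entries: dict[str, float] = field(default_factory=dict)
    uncharacterized_value: float = LYMPHOCYTE_MRNA_PG
    fallback: float = LYMPHOCYTE_MRNA_PG

    def __post_init__(self) -> None:
        for name, value in self.entries.items():
            if not np.isfinite(value) or value <= 0:
                raise InputError(f"mRNA content for {name!r} must be > 0, got {value}")
        if not np.isfinite(self.uncharacterized_value) or self.uncharacterized_value <= 0:
            raise InputError("uncharacterized mRNA content must be > 0")

    def get(self, cell_type: str) -> float:
        if cell_type == "uncharacterized":
            return self.uncharacterized_value
        if cell_type in self.entries:
            return self.entries[cell_type]
        warnings.warn(
            f"no mRNA content for cell type {cell_type!r}; "
            f"using fallback {self.fallback} pg",
            stacklevel=2,
        )
        return self.fallback

    def write(self, path: str | Path) -> None:
        rows = dict(self.entries)
        rows["uncharacterized"] = self.uncharacterized_value
        pd.Series(rows, name="mrna_pg").to_csv(path, sep="\t", index_label="cell_type")

    @classmethod
    def read(cls, source: Source) -> "MRnaContentTable":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        sep = _sniff_sep(text.splitlines()[0])
        df = pd.read_csv(_io.StringIO(text), sep=sep, index_col=0)
        series = df.iloc[:, 0].astype(float)
        entries = series.to_dict()
        unch = entries.pop("uncharacterized", LYMPHOCYTE_MRNA_PG)
        return cls(entries, uncharacterized_value=float(unch))


def build_reference_sorted(
    samples: ExpressionMatrix,
    cell_labels: dict[str, str] | pd.Series,
) -> ReferenceProfileSet:
    """Build a reference from sorted-cell bulk replicates.

    Profile is the per-gene median of each cell type's samples; variability
    is the per-gene interquartile range (linear-interpolation quartiles).
    Requires at least two replicates per cell type.
    """
    if samples.unit != "tpm":
        raise InputError("reference construction expects TPM input")
    labels = pd.Series(cell_labels)
    missing = [s for s in samples.sample_ids if s not in labels.index]
    if missing:
        raise InputError(f"samples without a cell label: {missing[:10]}")
    labels = labels.loc[samples.sample_ids]
    profiles = {}
    variabilities = {}
    for cell_type, members in labels.groupby(labels).groups.items():
        cols = samples.data[list(members)]
        if cols.shape[1] < 2:
            raise InputError(
                f"cell type {cell_type!r} has {cols.shape[1]} sample(s); >= 2 required"
            )
        profiles[cell_type] = cols.median(axis=1)
        q3 = cols.quantile(0.75, axis=1)
        q1 = cols.quantile(0.25, axis=1)
        variabilities[cell_type] = q3 - q1
    order = sorted(profiles)
    return ReferenceProfileSet(
        pd.DataFrame({ct: profiles[ct] for ct in order}),
        pd.DataFrame({ct: variabilities[ct] for ct in order}),
        provenance="sorted_bulk",
    )


def build_reference_single_cell(
    cells: ExpressionMatrix,
    cell_labels: dict[str, str] | pd.Series,
    patient_labels: dict[str, str] | pd.Series,
    min_cells_per_type: int = 3,
    ddof: int = 1,
) -> ReferenceProfileSet:
    """Build a reference from labeled single cells of several patients.

    For each patient, cell types represented by at least
    ``min_cells_per_type`` cells are averaged per gene; the per-patient
    averages are then averaged across patients so that no single patient
    dominates the profile.  Variability is the per-gene standard deviation
    across all qualifying cells of a type (``ddof=1`` by default).
    Cell types below the threshold in every patient are excluded with a
    warning.
    """
    cell_labels = pd.Series(cell_labels).loc[cells.sample_ids]
    patient_labels = pd.Series(patient_labels).loc[cells.sample_ids]
    data = cells.data
    type_names = sorted(cell_labels.unique())
    profiles: dict[str, pd.Series] = {}
    variabilities: dict[str, pd.Series] = {}
    for cell_type in type_names:
        per_patient_means = []
        qualifying_cells: list[str] = []
        in_type = cell_labels == cell_type
        for patient in sorted(patient_labels.unique()):
            members = cell_labels.index[in_type & (patient_labels == patient)]
            if len(members) >= min_cells_per_type:
                per_patient_means.append(data[list(members)].mean(axis=1))
                qualifying_cells.extend(members)
        if not per_patient_means:
            warnings.warn(
                f"cell type {cell_type!r} has fewer than {min_cells_per_type} "
                "cells in every patient; excluded from the reference",
                stacklevel=2,
            )
            continue
        profiles[cell_type] = pd.concat(per_patient_means, axis=1).mean(axis=1)
        variabilities[cell_type] = data[qualifying_cells].std(axis=1, ddof=ddof)
    if not profiles:
        raise InputError("no cell type passed the minimum-cell threshold")
    return ReferenceProfileSet(
        pd.DataFrame(profiles),
        pd.DataFrame(variabilities),
        provenance="single_cell",
    )


def merge_cell_types(
    refset: ReferenceProfileSet, mapping: dict[str, str]
) -> ReferenceProfileSet:
    """Merge and/or rename reference columns.

    ``mapping`` sends existing cell type names to new names; old names that
    share a new name are merged by column mean (both profile and
    variability).  Renaming without merging is the single-member case.
    Mapping onto an existing, unmapped cell type name is a collision error.
    """
    for old in mapping:
        if old not in refset.profile.columns:
            raise InputError(f"unknown cell type {old!r} in mapping")
    untouched = [c for c in refset.cell_types if c not in mapping]
    for new in mapping.values():
        if new in untouched:
            raise InputError(
                f"mapping collides with existing unmapped cell type {new!r}"
            )
    new_profile: dict[str, pd.Series] = {}
    new_var: dict[str, pd.Series] = {}
    for col in untouched:
        new_profile[col] = refset.profile[col]
        new_var[col] = refset.variability[col]
    groups: dict[str, list[str]] = {}
    for old, new in mapping.items():
        groups.setdefault(new, []).append(old)
    for new, members in groups.items():
        new_profile[new] = refset.profile[members].mean(axis=1)
        new_var[new] = refset.variability[members].mean(axis=1)
    return ReferenceProfileSet(
        pd.DataFrame(new_profile), pd.DataFrame(new_var), refset.provenance
    )


def default_mrna_contents(
    cell_types, fallback: float = LYMPHOCYTE_MRNA_PG
) -> MRnaContentTable:
    """Default per-cell mRNA masses for the requested cell types.

    Lymphocyte-class types (B, NK, T subsets) and cancer cells get
    0.4 pg/cell; types outside that class get ``fallback`` with a warning,
    since their true content should be measured or supplied by the user.
    """
    entries: dict[str, float] = {}
    for cell_type in cell_types:
        key = cell_type.lower().replace(" ", "").replace("-", "_")
        if key in _LYMPHOCYTE_CLASS or key.replace("_", "") in _LYMPHOCYTE_CLASS:
            entries[cell_type] = LYMPHOCYTE_MRNA_PG
        else:
            warnings.warn(
                f"no measured mRNA content for {cell_type!r}; "
                f"assigning fallback {fallback} pg",
                stacklevel=2,
            )
            entries[cell_type] = fallback
    return MRnaContentTable(entries, uncharacterized_value=LYMPHOCYTE_MRNA_PG,
                            fallback=fallback)
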