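"""Synthetic reference profiles, cancer profiles, single-cell cohorts and bulk mixtures.

The generators emulate the statistical structure the estimator is designed
for: a handful of characterized cell types whose signature genes are
silent in an uncharacterized cancer component, mixtures assembled at the
mRNA level (cell fractions weighted by per-cell mRNA content), per-gene
multiplicative lognormal noise, and dropout-ridden single-cell cohorts
with per-patient composition ground truth.  Every generator is
deterministic under its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, InputError, TPM_TOTAL
from .reference import MRnaContentTable, ReferenceProfileSet
from .signatures import SignatureSet


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated mixture."""

    true_cell_fractions: pd.DataFrame  # samples x types (incl. cancer)
    true_mrna_fractions: pd.DataFrame  # same shape
    mrna_contents: MRnaContentTable | None
    noise_sigma: float
    leakage: float
    seed: int | None

    def __post_init__(self) -> None:
        for name, df in (
            ("true_cell_fractions", self.true_cell_fractions),
            ("true_mrna_fractions", self.true_mrna_fractions),
        ):
            arr = df.to_numpy(dtype=float)
            if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
                raise InputError(f"{name} entries must lie in [0, 1]")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise InputError(f"{name} rows must sum to 1")


def simulate_reference_profiles(
    n_genes: int,
    cell_types: list[str],
    markers_per_type: int = 5,
    seed: int | None = None,
    baseline_log_mean: float = np.log(50.0),
    baseline_log_sigma: float = 1.0,
    marker_log_mean: float = np.log(500.0),
    marker_log_sigma: float = 0.5,
    variability_cv: float = 0.3,
) -> tuple[ReferenceProfileSet, SignatureSet]:
    """Reference profiles with planted, perfectly type-specific markers.

    Non-marker genes share one lognormal baseline across all types;
    each cell type additionally expresses ``markers_per_type`` planted
    marker genes that every other type (and, by construction later, the
    cancer profile) leaves at zero.  Columns are rescaled to TPM and the
    variability matrix is drawn proportional to expression with lognormal
    scatter.
    """
    if n_genes < len(cell_types) * markers_per_type:
        raise InputError(
            f"need at least {len(cell_types) * markers_per_type} genes for "
            f"{len(cell_types)} types x {markers_per_type} markers"
        )
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    baseline = rng.lognormal(baseline_log_mean, baseline_log_sigma, size=n_genes)
    profile = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(cell_types))),
        index=genes,
        columns=cell_types,
    )
    markers: dict[str, list[str]] = {}
    cursor = 0
    for cell_type in cell_types:
        chosen = genes[cursor : cursor + markers_per_type]
        cursor += markers_per_type
        profile.loc[chosen, :] = 0.0
        profile.loc[chosen, cell_type] = rng.lognormal(
            marker_log_mean, marker_log_sigma, size=markers_per_type
        )
        markers[cell_type] = chosen
    profile = profile / profile.sum(axis=0) * TPM_TOTAL
    scatter = rng.lognormal(0.0, 0.2, size=profile.shape)
    variability = profile * variability_cv * scatter
    refset = ReferenceProfileSet(profile, variability, provenance="user")
    return refset, SignatureSet(markers)


def simulate_cancer_profile(
    refset: ReferenceProfileSet,
    signature: SignatureSet,
    leakage: float = 0.0,
    seed: int | None = None,
    log_mean: float = np.log(50.0),
    log_sigma: float = 1.0,
) -> pd.Series:
    """An uncharacterized-cell expression vector silent on signature genes.

    Non-signature genes get independent lognormal expression; signature
    genes are set to ``leakage`` TPM (0 = the identifying assumption holds
    exactly) before the final rescale to TPM.
    """
    rng = np.random.default_rng(seed)
    genes = refset.gene_ids
    values = pd.Series(rng.lognormal(log_mean, log_sigma, size=len(genes)),
                       index=genes)
    sig = [g for g in signature.union if g in values.index]
    values.loc[sig] = leakage
    total = values.sum()
    if total == 0:
        raise InputError("cancer profile is identically zero")
    return values / total * TPM_TOTAL


def simulate_bulk_mixture(
    profiles: pd.DataFrame,
    cell_fractions: pd.DataFrame | pd.Series,
    contents: MRnaContentTable | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    leakage: float = 0.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Mix cell-type expression vectors at known cell fractions.

    ``profiles`` is genes x types (including the uncharacterized/cancer
    column).  Mixing happens at the mRNA level: mRNA fractions are
    ``pbar_j ∝ p_j * r_j`` and the bulk is the pbar-weighted sum of TPM
    profiles, optionally perturbed per gene by multiplicative lognormal
    noise exp(N(0, sigma^2)) and rescaled back to TPM.
    """
    if isinstance(cell_fractions, pd.Series):
        cell_fractions = cell_fractions.to_frame().T
        cell_fractions.index = ["sample_0"]
    missing = [t for t in cell_fractions.columns if t not in profiles.columns]
    if missing:
        raise InputError(f"no profile for mixture component(s): {missing}")
    fractions = cell_fractions.to_numpy(dtype=float)
    if not np.allclose(fractions.sum(axis=1), 1.0, atol=1e-9):
        raise InputError("cell fractions must sum to 1 per sample")
    types = list(cell_fractions.columns)
    if contents is None:
        r = np.ones(len(types))
    else:
        r = np.array(
            [contents.get(t) if t in contents.entries or t == "uncharacterized"
             else contents.uncharacterized_value
             for t in types]
        )
    rng = np.random.default_rng(seed)
    mrna = fractions * r
    mrna = mrna / mrna.sum(axis=1, keepdims=True)
    P = profiles[types].to_numpy(dtype=float)  # genes x types, TPM columns
    bulk = P @ mrna.T  # genes x samples
    if noise_sigma > 0:
        bulk = bulk * rng.lognormal(0.0, noise_sigma, size=bulk.shape)
    totals = bulk.sum(axis=0)
    bulk = bulk / totals * TPM_TOTAL
    matrix = ExpressionMatrix(
        pd.DataFrame(bulk, index=profiles.index, columns=cell_fractions.index),
        "tpm",
    )
    truth = SyntheticTruth(
        true_cell_fractions=cell_fractions.astype(float),
        true_mrna_fractions=pd.DataFrame(
            mrna, index=cell_fractions.index, columns=types
        ),
        mrna_contents=contents,
        noise_sigma=noise_sigma,
        leakage=leakage,
        seed=seed,
    )
    return matrix, truth


def simulate_single_cell_cohort(
    n_patients: int,
    cells_per_type: tuple[int, int] | dict[str, tuple[int, int]],
    refset: ReferenceProfileSet,
    dropout_rate: float = 0.0,
    noise_sigma: float = 0.3,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.Series, pd.Series, dict[str, pd.Series]]:
    """Labeled single cells for several patients, with dropout.

    Each cell is its type's reference profile perturbed by per-gene
    multiplicative lognormal noise, zeroed independently with probability
    ``dropout_rate``, and rescaled to TPM.  Returns (cells, cell-type
    labels, patient labels, per-patient true cell-count fractions).
    """
    if not 0.0 <= dropout_rate <= 1.0:
        raise InputError("dropout_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    types = refset.cell_types
    if isinstance(cells_per_type, tuple):
        ranges = {t: cells_per_type for t in types}
    else:
        ranges = cells_per_type
    columns: dict[str, np.ndarray] = {}
    cell_labels: dict[str, str] = {}
    patient_labels: dict[str, str] = {}
    truth: dict[str, pd.Series] = {}
    profile = refset.profile
    for ip in range(n_patients):
        patient = f"patient_{ip}"
        counts: dict[str, int] = {}
        for cell_type in types:
            lo, hi = ranges[cell_type]
            n_cells = int(rng.integers(lo, hi + 1))
            counts[cell_type] = n_cells
            base = profile[cell_type].to_numpy(dtype=float)
            for ic in range(n_cells):
                cell = base.copy()
                if noise_sigma > 0:
                    cell = cell * rng.lognormal(0.0, noise_sigma, size=cell.size)
                if dropout_rate > 0:
                    cell = cell * (rng.random(cell.size) >= dropout_rate)
                total = cell.sum()
                if total > 0:
                    cell = cell / total * TPM_TOTAL
                name = f"{patient}_{cell_type}_{ic}"
                columns[name] = cell
                cell_labels[name] = cell_type
                patient_labels[name] = patient
        total_cells = sum(counts.values())
        if total_cells == 0:
            warnings.warn(f"{patient} has no cells", stacklevel=2)
            continue
        truth[patient] = pd.Series(
            {t: counts[t] / total_cells for t in types}, dtype=float
        )
    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=profile.index), "tpm"
    )
    if dropout_rate == 1.0:
        warnings.warn("dropout_rate=1 produced an all-zero cohort", stacklevel=2)
    return matrix, pd.Series(cell_labels), pd.Series(patient_labels), truth
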