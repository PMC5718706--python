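"""Accuracy metrics and the patient-level leave-one-out harness.

Predictions are scored against known fractions with pooled and
per-cell-type Pearson correlation and root mean squared error, the two
summary statistics conventional for benchmarking cell-fraction
deconvolution.  A correlation over a constant truth vector is undefined
and reported as such, never fabricated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolve import UNCHARACTERIZED, deconvolve
from .matrix import ExpressionMatrix, InputError, TPM_TOTAL
from .reference import MRnaContentTable, build_reference_single_cell
from .signatures import SignatureSet


def _metrics_row(pred: np.ndarray, truth: np.ndarray) -> dict:
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    if np.ptp(truth) == 0 or np.ptp(pred) == 0 or len(truth) < 3:
        return {"pearson_r": np.nan, "p_value": np.nan, "rmse": rmse,
                "n_points": len(truth), "undefined_r": True}
    r, p = stats.pearsonr(pred, truth)
    return {"pearson_r": float(r), "p_value": float(p), "rmse": rmse,
            "n_points": len(truth), "undefined_r": False}


def evaluate_predictions(
    predicted: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Pooled and per-cell-type Pearson R and RMSE.

    Both frames are samples x cell types with identical labels.  The
    pooled row ("all") flattens every (sample, type) pair; per-type rows
    follow.
    """
    if set(predicted.columns) != set(truth.columns) or set(predicted.index) != set(
        truth.index
    ):
        extra_c = sorted(set(predicted.columns) ^ set(truth.columns))
        extra_r = sorted(set(predicted.index) ^ set(truth.index))
        raise InputError(
            f"label mismatch between predictions and truth; "
            f"columns differing: {extra_c}, rows differing: {extra_r}"
        )
    truth = truth.loc[predicted.index, predicted.columns]
    rows = {
        "all": _metrics_row(
            predicted.to_numpy(dtype=float).ravel(),
            truth.to_numpy(dtype=float).ravel(),
        )
    }
    for cell_type in predicted.columns:
        rows[cell_type] = _metrics_row(
            predicted[cell_type].to_numpy(dtype=float),
            truth[cell_type].to_numpy(dtype=float),
        )
    table = pd.DataFrame(rows).T
    table.index.name = "scope"
    return table


def leave_one_out_eval(
    cells: ExpressionMatrix,
    cell_labels: pd.Series,
    patient_labels: pd.Series,
    contents: MRnaContentTable,
    signature: SignatureSet,
    min_cells_per_type: int = 3,
    uncharacterized_label: str | None = None,
    epsilon: float = 1e-9,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Patient-level leave-one-out deconvolution of single-cell cohorts.

    For each patient the reference is rebuilt from all OTHER patients'
    cells, the held-out patient's pseudo-bulk (per-gene mean over their
    cells) is deconvolved, and the result is compared to that patient's
    cell-count fractions.  ``uncharacterized_label``, when given, names
    the truth cell type (e.g. "cancer") matched against the estimator's
    uncharacterized output.  Returns (metrics, predictions, truth).
    """
    cell_labels = pd.Series(cell_labels).loc[cells.sample_ids]
    patient_labels = pd.Series(patient_labels).loc[cells.sample_ids]
    patients = sorted(patient_labels.unique())
    if len(patients) < 2:
        raise InputError("leave-one-out needs at least 2 patients")
    predictions: dict[str, pd.Series] = {}
    truths: dict[str, pd.Series] = {}
    for held_out in patients:
        keep = patient_labels != held_out
        train_cells = cells.data.loc[:, keep.to_numpy()]
        train_cell_labels = cell_labels[keep]
        train_patient_labels = patient_labels[keep]
        if uncharacterized_label is not None:
            is_ref = train_cell_labels != uncharacterized_label
            train_cells = train_cells.loc[:, is_ref.to_numpy()]
            train_patient_labels = train_patient_labels[is_ref]
            train_cell_labels = train_cell_labels[is_ref]
        refset = build_reference_single_cell(
            ExpressionMatrix(train_cells, "tpm"),
            train_cell_labels,
            train_patient_labels,
            min_cells_per_type=min_cells_per_type,
        )
        held_cells = cells.data.loc[:, (~keep).to_numpy()]
        pseudo_bulk = ExpressionMatrix(
            held_cells.mean(axis=1).to_frame(held_out), "tpm"
        )
        result = deconvolve(
            pseudo_bulk, refset, signature, contents, epsilon=epsilon
        )
        predictions[held_out] = result.cell_fractions.iloc[0]
        counts = cell_labels[~keep].value_counts()
        truth = (counts / counts.sum()).astype(float)
        if uncharacterized_label is not None and uncharacterized_label in truth:
            truth = truth.rename({uncharacterized_label: UNCHARACTERIZED})
        truths[held_out] = truth
    pred_df = pd.DataFrame(predictions).T.fillna(0.0)
    truth_df = pd.DataFrame(truths).T.reindex(columns=pred_df.columns).fillna(0.0)
    metrics = evaluate_predictions(pred_df, truth_df)
    return metrics, pred_df, truth_df
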