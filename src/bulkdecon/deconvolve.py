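"""Constrained weighted least-squares deconvolution with an uncharacterized fraction.

The bulk sample's TPM vector is modeled as a superposition of reference
cell-type profiles plus one uncharacterized component (chiefly cancer
cells) for which no profile is assumed.  Restricting the fit to signature
genes — genes the uncharacterized cells do not express — makes the model
identifiable without knowing the cancer transcriptome:

    minimize  sum_{i in S} w_i * (b_i - (C p)_i)^2
    subject to  p_j >= 0,  sum_j p_j <= 1

The per-gene weights favor signature genes with low variability in the
reference samples,

    u_i = sum_j C_ij / (V_ij + eps),    w_i = min(u_i, 100 * median(u)),

with the cap preventing a handful of near-constant genes from dominating
the objective.  The fitted p are mRNA proportions; the uncharacterized
share is 1 - sum(p), and dividing by per-cell mRNA contents r_j (then
renormalizing to sum 1) converts mRNA proportions into cell fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .matrix import (
    ExpressionMatrix,
    GeneAlignmentReport,
    InputError,
    TPM_TOTAL,
    align_genes,
)
from .reference import MRnaContentTable, ReferenceProfileSet
from .signatures import SignatureSet

WEIGHT_CAP_FACTOR = 100.0
UNCHARACTERIZED = "uncharacterized"


@dataclass
class GeneWeights:
    """Per-signature-gene regression weights."""

    u: pd.Series
    w: pd.Series
    epsilon: float

    @property
    def median_u(self) -> float:
        return float(np.median(self.u.to_numpy()))


@dataclass
class DeconvolutionResult:
    """Fitted proportions and diagnostics for a set of bulk samples.

    ``mrna_proportions`` are shares of total mRNA per cell type (plus the
    uncharacterized entry), summing to 1 per sample by construction.
    ``cell_fractions`` are the mRNA-content-renormalized cell-number
    fractions (``None`` when renormalization was skipped).
    """

    mrna_proportions: pd.DataFrame  # samples x (cell types + uncharacterized)
    cell_fractions: pd.DataFrame | None
    alpha: pd.Series | None  # per-sample renormalization constant
    diagnostics: pd.DataFrame
    alignment: GeneAlignmentReport | None = None
    weights: GeneWeights | None = None

    def write(self, directory: str | Path, prefix: str = "deconvolution") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.mrna_proportions.to_csv(
            directory / f"{prefix}_mrna_proportions.tsv", sep="\t",
            index_label="sample",
        )
        if self.cell_fractions is not None:
            self.cell_fractions.to_csv(
                directory / f"{prefix}_cell_fractions.tsv", sep="\t",
                index_label="sample",
            )
        self.diagnostics.to_csv(
            directory / f"{prefix}_diagnostics.tsv", sep="\t", index_label="sample"
        )


def compute_gene_weights(
    refset: ReferenceProfileSet, epsilon: float = 1e-9
) -> GeneWeights:
    """Weights for a reference already restricted to the signature genes."""
    if refset.profile.shape[0] == 0:
        raise InputError("empty signature restriction")
    profile = refset.profile.to_numpy(dtype=float)
    variability = refset.variability.to_numpy(dtype=float)
    u = (profile / (variability + epsilon)).sum(axis=1)
    cap = WEIGHT_CAP_FACTOR * np.median(u)
    w = np.minimum(u, cap)
    index = refset.profile.index
    return GeneWeights(pd.Series(u, index=index), pd.Series(w, index=index), epsilon)


def _polish_active_set(
    A: np.ndarray, y: np.ndarray, p: np.ndarray, a: np.ndarray,
    tol: float = 1e-9,
) -> np.ndarray | None:
    """Re-solve exactly on the active set identified by the solver.

    ``a`` is the coefficient vector of the budget constraint a'p <= 1.
    Returns the polished solution when it satisfies feasibility and the
    KKT sign conditions, else ``None``.
    """
    m = A.shape[1]
    free = p > tol
    sum_active = a @ p > 1 - tol
    polished = np.zeros(m)
    if not free.any():
        grad = 2 * A.T @ (A @ polished - y)
        return polished if (grad >= -1e-8 * max(1.0, abs(grad).max())).all() else None
    AF = A[:, free]
    aF = a[free]
    if sum_active:
        H = 2 * AF.T @ AF
        k = AF.shape[1]
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = H
        kkt[:k, k] = aF
        kkt[k, :k] = aF
        rhs = np.concatenate([2 * AF.T @ y, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            return None
        pF, mu = sol[:k], sol[k]
        if mu < -1e-8:
            return None
    else:
        pF, *_ = np.linalg.lstsq(AF, y, rcond=None)
        mu = 0.0
    if (pF < -1e-10).any():
        return None
    polished[free] = np.maximum(pF, 0.0)
    if a @ polished > 1 + 1e-10:
        return None
    grad = 2 * A.T @ (A @ polished - y)
    lam = grad + mu * a
    scale = max(1.0, np.abs(grad).max())
    if (lam[~free] < -1e-7 * scale).any():
        return None
    return polished


def _project_simplex_cap(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {p >= 0, sum(p) <= 1}."""
    clipped = np.maximum(v, 0.0)
    if clipped.sum() <= 1.0:
        return clipped
    # project onto the probability simplex (sort-based algorithm)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, len(v) + 1)
    rho = idx[u - css / idx > 0][-1]
    theta = css[rho - 1] / rho
    return np.maximum(v - theta, 0.0)


def _solve_pgd(
    A: np.ndarray, y: np.ndarray, max_iter: int = 50_000, tol: float = 1e-14
) -> np.ndarray:
    """Accelerated projected-gradient solver (cross-check fallback)."""
    H = A.T @ A
    g = A.T @ y
    L = 2 * np.linalg.eigvalsh(H)[-1] + 1e-12
    p = np.zeros(A.shape[1])
    z = p.copy()
    t = 1.0
    for _ in range(max_iter):
        grad = 2 * (H @ z - g)
        p_new = _project_simplex_cap(z - grad / L)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = p_new + ((t - 1) / t_new) * (p_new - p)
        if np.abs(p_new - p).max() < tol:
            p = p_new
            break
        p, t = p_new, t_new
    return p


def solve_constrained_wls(
    b_s: pd.Series | np.ndarray,
    C_s: pd.DataFrame | np.ndarray,
    weights: GeneWeights | np.ndarray | pd.Series,
    method: str = "slsqp",
    budget_coefficients: np.ndarray | None = None,
) -> tuple[pd.Series, dict]:
    """Minimize the weighted signature-gene residual over the capped simplex.

    Returns the mRNA proportions of the characterized cell types together
    with solver diagnostics.  The objective is convex, so the minimizer is
    unique whenever the weighted design has full column rank; the default
    path runs SLSQP and then polishes the identified active set by an
    exact equality-constrained solve, checking the KKT conditions.
    ``method="pgd"`` runs an accelerated projected-gradient solver instead
    (useful as an independent cross-check).

    ``budget_coefficients`` generalizes the sum constraint to
    ``a'p <= 1`` (default: all ones, i.e. proportions summing to at most
    one); the a-priori content-rescaled variant needs a = r.
    """
    if isinstance(weights, GeneWeights):
        w = weights.w.to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    b = np.asarray(b_s, dtype=float)
    if isinstance(C_s, pd.DataFrame):
        columns = list(C_s.columns)
        C = C_s.to_numpy(dtype=float)
    else:
        C = np.asarray(C_s, dtype=float)
        columns = [f"type_{j}" for j in range(C.shape[1])]
    if (w <= 0).any():
        raise InputError("weights must be positive")
    m = C.shape[1]
    a = np.ones(m) if budget_coefficients is None else np.asarray(
        budget_coefficients, dtype=float
    )
    if (a <= 0).any():
        raise InputError("budget coefficients must be positive")
    sw = np.sqrt(w)
    A = sw[:, None] * C
    y = sw * b
    cond = float(np.linalg.cond(A))
    if cond > 1e8:
        warnings.warn(
            f"weighted signature design is near rank-deficient (cond={cond:.3g}); "
            "proportions of collinear cell types are not identifiable",
            stacklevel=2,
        )

    # scale the problem to unit residual magnitude so the optimizer's
    # absolute tolerances are meaningful regardless of expression units
    scale = max(float(np.linalg.norm(y)), 1e-30)
    As, ys = A / scale, y / scale

    if method == "pgd":
        if budget_coefficients is not None:
            raise InputError("pgd supports only the unit budget constraint")
        p = _solve_pgd(As, ys)
        polished = _polish_active_set(As, ys, p, a)
        status = "pgd"
        if polished is not None:
            p, status = polished, "pgd+polish"
    elif method == "slsqp":
        H2 = 2 * As.T @ As
        g2 = 2 * As.T @ ys

        def objective(p):
            r = As @ p - ys
            return float(r @ r)

        def jac(p):
            return H2 @ p - g2

        x0 = np.full(m, 1.0 / (m + 1)) / a
        res = optimize.minimize(
            objective,
            x0,
            jac=jac,
            method="SLSQP",
            bounds=[(0.0, 1.0 / a[j]) for j in range(m)],
            constraints=[{"type": "ineq", "fun": lambda p: 1.0 - a @ p,
                          "jac": lambda p: -a}],
            options={"maxiter": 500, "ftol": 1e-16},
        )
        candidates: list[tuple[float, np.ndarray, str]] = []
        if res.success or res.status == 8:  # 8: stalled linesearch at optimum
            x = np.clip(res.x, 0.0, None)
            candidates.append((objective(x), x, "slsqp"))
            polished = _polish_active_set(As, ys, x, a)
            if polished is not None:
                candidates.append((objective(polished), polished, "slsqp+polish"))
        # the projected-gradient path is the safety net: certifiably
        # convergent for this convex problem, if slower
        if budget_coefficients is None and not any(
            name.endswith("polish") for _, _, name in candidates
        ):
            x = _solve_pgd(As, ys)
            candidates.append((objective(x), x, "pgd"))
            polished = _polish_active_set(As, ys, x, a)
            if polished is not None:
                candidates.append((objective(polished), polished, "pgd+polish"))
        if not candidates:
            raise InputError(f"constrained solver failed: {res.message}")
        _, p, status = min(candidates, key=lambda c: c[0])
    else:
        raise InputError(f"unknown solver method {method!r}")

    # tiny constraint violations from floating point are clipped, larger
    # ones indicate a solver failure and must surface
    if (p < -1e-9).any() or a @ p > 1 + 1e-9:
        raise InputError("solver returned an infeasible solution")
    p = np.clip(p, 0.0, None)
    if a @ p > 1.0:
        p = p / (a @ p)
    residual = float(np.linalg.norm(A @ p - y))
    diag = {
        "status": status,
        "weighted_residual_norm": residual,
        "condition_number": cond,
        "n_signature_genes": int(len(b)),
    }
    return pd.Series(p, index=columns), diag


def uncharacterized_fraction(p_star: pd.Series | np.ndarray) -> float:
    """Share of the mixture left for cells without a reference profile."""
    arr = np.asarray(p_star, dtype=float)
    if arr.size == 0:
        return 1.0
    if (arr < -1e-9).any():
        raise InputError("characterized proportions must be >= 0")
    total = arr.sum()
    if total > 1 + 1e-6:
        raise InputError(
            f"characterized proportions sum to {total}, exceeding 1"
        )
    return float(np.clip(1.0 - total, 0.0, 1.0))


def renormalize_by_mrna(
    pbar: pd.Series, contents: MRnaContentTable
) -> tuple[pd.Series, float]:
    """Convert mRNA proportions into cell fractions.

    ``p_j = alpha * pbar_j / r_j`` with alpha chosen so the fractions sum
    to one.  Returns (fractions, alpha).
    """
    r = np.array([contents.get(ct) for ct in pbar.index], dtype=float)
    if (r <= 0).any():
        raise InputError("mRNA contents must be positive")
    unnorm = pbar.to_numpy(dtype=float) / r
    total = unnorm.sum()
    if total == 0:
        raise InputError("all proportions are zero; cannot renormalize")
    alpha = 1.0 / total
    return pd.Series(unnorm * alpha, index=pbar.index), alpha


def _prepare(
    bulk: ExpressionMatrix,
    refset: ReferenceProfileSet,
    signature: SignatureSet,
    epsilon: float,
):
    """Shared-universe rescaling and signature restriction.

    Both the bulk columns and the reference columns are rescaled to sum
    10^6 over the SHARED gene universe before subsetting to the signature
    genes; a consistent normalization universe is what makes the fitted
    proportions sum to at most one.  Reference variability is rescaled by
    the same per-column factor (it is TPM-based).
    """
    report = align_genes(bulk, refset, signature)
    shared = report.shared_genes
    if not shared:
        raise InputError("bulk and reference share no genes")
    bulk_shared = bulk.data.loc[shared]
    bulk_totals = bulk_shared.sum(axis=0)
    zero = bulk_totals.index[bulk_totals == 0].tolist()
    if zero:
        warnings.warn(
            f"bulk samples with zero shared-gene expression skipped: {zero}",
            stacklevel=3,
        )
        bulk_shared = bulk_shared.drop(columns=zero)
        bulk_totals = bulk_totals.drop(index=zero)
        if bulk_shared.shape[1] == 0:
            raise InputError("every bulk sample has zero shared-gene expression")
    bulk_scaled = bulk_shared.div(bulk_totals, axis=1) * TPM_TOTAL

    ref_profile = refset.profile.loc[shared]
    ref_totals = ref_profile.sum(axis=0)
    if (ref_totals == 0).any():
        bad = ref_totals.index[ref_totals == 0].tolist()
        raise InputError(f"reference cell types with zero shared expression: {bad}")
    factors = TPM_TOTAL / ref_totals
    ref_profile = ref_profile.mul(factors, axis=1)
    ref_var = refset.variability.loc[shared].mul(factors, axis=1)

    shared_set = set(shared)
    sig_genes = [g for g in signature.union if g in shared_set]
    restricted = ReferenceProfileSet(
        ref_profile.loc[sig_genes], ref_var.loc[sig_genes], refset.provenance
    )
    weights = compute_gene_weights(restricted, epsilon)
    # signature genes with no expression in any characterized type carry
    # no information about the fit and would get zero weight; drop them
    dead = weights.w.index[weights.w <= 0].tolist()
    if dead:
        warnings.warn(
            f"{len(dead)} signature gene(s) have zero reference expression "
            f"and were dropped: {dead[:5]}{'...' if len(dead) > 5 else ''}",
            stacklevel=3,
        )
        sig_genes = [g for g in sig_genes if g not in set(dead)]
        if not sig_genes:
            raise InputError("no usable signature genes remain")
        restricted = restricted.subset_genes(sig_genes)
        weights = compute_gene_weights(restricted, epsilon)
    return report, bulk_scaled, restricted, sig_genes, weights


def deconvolve(
    bulk: ExpressionMatrix,
    refset: ReferenceProfileSet,
    signature: SignatureSet,
    contents: MRnaContentTable | None = None,
    *,
    skip_renormalization: bool = False,
    epsilon: float = 1e-9,
    solver: str = "slsqp",
) -> DeconvolutionResult:
    """Estimate cell-type mRNA proportions and cell fractions per bulk sample.

    Pipeline per sample: rescale bulk and reference over the shared gene
    universe, restrict to signature genes, compute variability weights,
    solve the constrained weighted least squares, assign the remainder to
    the uncharacterized fraction, and (unless skipped) renormalize by
    per-cell mRNA content.  Failures in one sample do not abort the rest.
    """
    if contents is None and not skip_renormalization:
        from .reference import default_mrna_contents

        contents = default_mrna_contents(refset.cell_types)
    report, bulk_scaled, restricted, sig_genes, weights = _prepare(
        bulk, refset, signature, epsilon
    )
    cell_types = restricted.cell_types
    out_cols = cell_types + [UNCHARACTERIZED]
    mrna_rows, frac_rows, alpha_rows, diag_rows = {}, {}, {}, {}
    for sample in bulk_scaled.columns:
        try:
            b_s = bulk_scaled.loc[sig_genes, sample] / TPM_TOTAL
            p_star, diag = solve_constrained_wls(
                b_s, restricted.profile / TPM_TOTAL, weights, method=solver
            )
            pm = uncharacterized_fraction(p_star)
            pbar = pd.concat([p_star, pd.Series({UNCHARACTERIZED: pm})])
            mrna_rows[sample] = pbar
            if not skip_renormalization:
                fractions, alpha = renormalize_by_mrna(pbar, contents)
                frac_rows[sample] = fractions
                alpha_rows[sample] = alpha
            diag_rows[sample] = diag
        except InputError as exc:  # isolate per-sample failures
            warnings.warn(f"sample {sample!r} failed: {exc}", stacklevel=2)
            diag_rows[sample] = {"status": f"failed: {exc}"}
    if not mrna_rows:
        raise InputError("deconvolution failed for every sample")
    mrna = pd.DataFrame(mrna_rows).T.reindex(columns=out_cols)
    fractions_df = pd.DataFrame(frac_rows).T.reindex(columns=out_cols) if frac_rows else None
    alpha_series = pd.Series(alpha_rows) if alpha_rows else None
    diagnostics = pd.DataFrame(diag_rows).T
    return DeconvolutionResult(
        mrna, fractions_df, alpha_series, diagnostics, report, weights
    )


def deconvolve_apriori_rescaled(
    bulk: ExpressionMatrix,
    refset: ReferenceProfileSet,
    signature: SignatureSet,
    contents: MRnaContentTable | None = None,
    *,
    epsilon: float = 1e-9,
    solver: str = "slsqp",
) -> DeconvolutionResult:
    """Variant that folds mRNA contents into the reference before fitting.

    Each reference column (profile and variability) is multiplied by its
    per-cell mRNA content r_j; the feasible set is mapped accordingly
    (coefficients q_j = pbar_j / r_j must satisfy sum_j q_j r_j <= 1), so
    the fitted coefficients are proportional to cell numbers directly and
    only a final sum-to-one normalization is applied — the a-posteriori
    mRNA division never happens.  In the noiseless limit this agrees with
    the standard two-step estimate.
    """
    if contents is None:
        from .reference import default_mrna_contents

        contents = default_mrna_contents(refset.cell_types)
    report, bulk_scaled, restricted, sig_genes, weights_std = _prepare(
        bulk, refset, signature, epsilon
    )
    cell_types = restricted.cell_types
    r = pd.Series({ct: contents.get(ct) for ct in cell_types})
    r_m = contents.get(UNCHARACTERIZED)
    r_vec = r.to_numpy(dtype=float)
    # fold contents into the (shared-universe-normalized) reference: the
    # design column for type j becomes r_j * C_j, so a fitted coefficient
    # q_j equals pbar_j / r_j and is proportional to the number of cells
    design = restricted.profile.mul(r, axis=1) / TPM_TOTAL
    weights = compute_gene_weights(
        ReferenceProfileSet(
            restricted.profile.mul(r, axis=1),
            restricted.variability.mul(r, axis=1),
            restricted.provenance,
        ),
        epsilon,
    )
    out_cols = cell_types + [UNCHARACTERIZED]
    frac_rows, mrna_rows, alpha_rows, diag_rows = {}, {}, {}, {}
    for sample in bulk_scaled.columns:
        try:
            b_s = bulk_scaled.loc[sig_genes, sample] / TPM_TOTAL
            # feasible set in q-space: q >= 0 and sum_j r_j q_j <= 1 (the
            # image of the mRNA-proportion simplex under q = pbar / r)
            q_star, diag = solve_constrained_wls(
                b_s, design, weights, method=solver, budget_coefficients=r_vec
            )
            pbar_star = q_star * r
            pm = uncharacterized_fraction(pbar_star)
            mrna_rows[sample] = pd.concat(
                [pbar_star, pd.Series({UNCHARACTERIZED: pm})]
            )
            q = pd.concat([q_star, pd.Series({UNCHARACTERIZED: pm / r_m})])
            fractions = q / q.sum()
            frac_rows[sample] = fractions
            alpha_rows[sample] = 1.0 / q.sum()
            diag_rows[sample] = diag
        except InputError as exc:
            warnings.warn(f"sample {sample!r} failed: {exc}", stacklevel=2)
            diag_rows[sample] = {"status": f"failed: {exc}"}
    if not frac_rows:
        raise InputError("deconvolution failed for every sample")
    mrna = pd.DataFrame(mrna_rows).T.reindex(columns=out_cols)
    fractions_df = pd.DataFrame(frac_rows).T.reindex(columns=out_cols)
    return DeconvolutionResult(
        mrna, fractions_df, pd.Series(alpha_rows), pd.DataFrame(diag_rows).T,
        report, weights,
    )
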