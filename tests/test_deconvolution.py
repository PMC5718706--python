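import numpy as np
import pandas as pd
import pytest

import bulkdecon as bd
from bulkdecon.matrix import TPM_TOTAL
from tests.conftest import grid_search_simplex, weighted_sse


def refset_from_arrays(profile_rows, variability_rows, types=None):
    profile = np.asarray(profile_rows, dtype=float)
    types = types or [f"t{j}" for j in range(profile.shape[1])]
    genes = [f"g{i}" for i in range(profile.shape[0])]
    return bd.ReferenceProfileSet(
        pd.DataFrame(profile, index=genes, columns=types),
        pd.DataFrame(np.asarray(variability_rows, dtype=float),
                     index=genes, columns=types),
    )


class TestGeneWeights:
    def test_direct_formula(self):
        ref = refset_from_arrays(
            [[10, 30], [5, 5], [1, 1]], np.ones((3, 2))
        )
        gw = bd.compute_gene_weights(ref, epsilon=0.0)
        np.testing.assert_allclose(gw.u, [40.0, 10.0, 2.0])
        # median u = 10, cap = 1000: no gene capped
        np.testing.assert_allclose(gw.w, [40.0, 10.0, 2.0])

    def test_cap_activates_for_vanishing_variability(self):
        ref = refset_from_arrays(
            [[10, 30], [5, 5], [1, 1]],
            [[1e-15, 1e-15], [1, 1], [1, 1]],
        )
        gw = bd.compute_gene_weights(ref, epsilon=0.0)
        assert gw.w.iloc[0] == pytest.approx(100.0 * gw.median_u)
        assert gw.w.iloc[0] < gw.u.iloc[0]

    def test_symmetry(self):
        ref = refset_from_arrays(np.full((4, 2), 7.0), np.full((4, 2), 2.0))
        gw = bd.compute_gene_weights(ref)
        assert gw.w.nunique() == 1

    def test_weight_monotone_in_variability(self):
        rng = np.random.default_rng(3)
        profile = rng.uniform(1, 100, size=(6, 3))
        var = rng.uniform(0.5, 5, size=(6, 3))
        base = bd.compute_gene_weights(refset_from_arrays(profile, var)).w
        bumped = var.copy()
        bumped[2, 1] *= 10
        after = bd.compute_gene_weights(refset_from_arrays(profile, bumped)).w
        assert after.iloc[2] <= base.iloc[2] + 1e-12


class TestSolveConstrainedWls:
    def test_diagonal_interior_optimum(self):
        C = pd.DataFrame([[100.0, 0.0], [0.0, 200.0]], columns=["a", "b"])
        p, diag = bd.solve_constrained_wls([30.0, 100.0], C, np.ones(2))
        np.testing.assert_allclose(p, [0.3, 0.5], atol=1e-10)

    def test_boundary_optimum_matches_kkt_analysis(self):
        # unconstrained optimum (0.8, 1.5) is infeasible; the constrained
        # minimizer derived by hand (and by brute-force grid) is (0, 1)
        C = np.array([[100.0, 0.0], [0.0, 200.0]])
        b = np.array([80.0, 300.0])
        w = np.ones(2)
        p, _ = bd.solve_constrained_wls(b, C, w)
        np.testing.assert_allclose(p, [0.0, 1.0], atol=1e-9)
        grid_p, grid_val = grid_search_simplex(b, C, w, step=1e-3)
        np.testing.assert_allclose(p, grid_p, atol=1e-3)

    def test_exact_model_member_recovered(self):
        rng = np.random.default_rng(8)
        C = rng.uniform(0, 100, size=(10, 2))
        b = C @ np.array([0.25, 0.25])
        p, diag = bd.solve_constrained_wls(b, C, np.ones(10))
        np.testing.assert_allclose(p, [0.25, 0.25], atol=1e-9)
        assert diag["weighted_residual_norm"] < 1e-9

    def test_agrees_with_projected_gradient(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            C = rng.uniform(0, 50, size=(8, 3))
            b = rng.uniform(0, 60, size=8)
            w = rng.uniform(0.5, 5, size=8)
            p_default, _ = bd.solve_constrained_wls(b, C, w)
            p_pgd, _ = bd.solve_constrained_wls(b, C, w, method="pgd")
            np.testing.assert_allclose(p_default, p_pgd, atol=1e-8)

    def test_rank_deficient_design_warns(self):
        C = np.array([[10.0, 10.0], [20.0, 20.0], [5.0, 5.0]])
        with pytest.warns(UserWarning, match="rank-deficient|identifiable"):
            bd.solve_constrained_wls(np.array([10.0, 20.0, 5.0]), C, np.ones(3))

    def test_grid_oracle_agreement_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            m = int(rng.integers(2, 4))
            C = rng.uniform(0, 100, size=(6, m))
            b = rng.uniform(0, 120, size=6)
            w = rng.uniform(0.1, 10, size=6)
            p, _ = bd.solve_constrained_wls(b, C, w)
            _, grid_val = grid_search_simplex(b, C, w, step=1e-2)
            solver_val = weighted_sse(b, C, w, np.asarray(p))
            assert solver_val <= grid_val + 1e-8 * (1 + grid_val)


class TestUncharacterizedFraction:
    def test_complement(self):
        assert bd.uncharacterized_fraction(np.array([0.2, 0.3])) == pytest.approx(0.5)

    def test_saturated(self):
        assert bd.uncharacterized_fraction(np.array([1.0])) == 0.0

    def test_empty_set_is_all_uncharacterized(self):
        assert bd.uncharacterized_fraction(np.array([])) == 1.0

    def test_overflow_is_error(self):
        with pytest.raises(bd.InputError, match="exceed"):
            bd.uncharacterized_fraction(np.array([0.8, 0.3]))


class TestRenormalizeByMrna:
    def test_equal_contents_identity(self):
        pbar = pd.Series({"a": 0.5, "b": 0.5})
        p, alpha = bd.renormalize_by_mrna(
            pbar, bd.MRnaContentTable({"a": 1.0, "b": 1.0})
        )
        np.testing.assert_allclose(p, [0.5, 0.5])
        assert alpha == pytest.approx(1.0)

    def test_hand_computed_example(self):
        pbar = pd.Series({"a": 0.5, "b": 0.3, "c": 0.2})
        contents = bd.MRnaContentTable({"a": 0.2, "b": 0.4, "c": 0.4})
        p, alpha = bd.renormalize_by_mrna(pbar, contents)
        np.testing.assert_allclose(p, [2 / 3, 0.2, 2 / 15], atol=1e-9)
        assert alpha == pytest.approx(1 / 3.75)

    def test_zero_stays_zero(self):
        pbar = pd.Series({"a": 0.0, "b": 1.0})
        p, _ = bd.renormalize_by_mrna(
            pbar, bd.MRnaContentTable({"a": 0.1, "b": 2.0})
        )
        assert p["a"] == 0.0


class TestDeconvolve:
    def test_noiseless_mixture_recovered(self, mixture_setup):
        refset, signature, profiles, contents = mixture_setup
        fractions = pd.DataFrame(
            [[0.2, 0.3, 0.1, 0.4]],
            columns=["Bcells", "Tcells", "NKcells", "cancer"], index=["s1"],
        )
        bulk, truth = bd.simulate_bulk_mixture(profiles, fractions, contents)
        result = bd.deconvolve(bulk, refset, signature, contents)
        expected = truth.true_mrna_fractions.rename(
            columns={"cancer": "uncharacterized"}
        )
        np.testing.assert_allclose(
            result.mrna_proportions.to_numpy(), expected.to_numpy(), atol=1e-6
        )

    def test_tpm_scale_invariance(self, mixture_setup):
        refset, signature, profiles, contents = mixture_setup
        fractions = pd.Series(
            {"Bcells": 0.25, "Tcells": 0.25, "NKcells": 0.2, "cancer": 0.3}
        )
        bulk, _ = bd.simulate_bulk_mixture(profiles, fractions, contents)
        scaled = bd.ExpressionMatrix(bulk.data * 7.0, "tpm")
        r1 = bd.deconvolve(bulk, refset, signature, contents)
        r2 = bd.deconvolve(scaled, refset, signature, contents)
        np.testing.assert_allclose(
            r1.mrna_proportions.to_numpy(), r2.mrna_proportions.to_numpy(),
            atol=1e-12,
        )

    def test_skip_renormalization_consistent_with_equal_contents(self, mixture_setup):
        refset, signature, profiles, contents = mixture_setup
        fractions = pd.Series(
            {"Bcells": 0.4, "Tcells": 0.2, "NKcells": 0.1, "cancer": 0.3}
        )
        bulk, _ = bd.simulate_bulk_mixture(profiles, fractions, contents)
        full = bd.deconvolve(bulk, refset, signature, contents)
        mrna_only = bd.deconvolve(bulk, refset, signature,
                                  skip_renormalization=True)
        assert mrna_only.cell_fractions is None
        np.testing.assert_allclose(
            full.cell_fractions.to_numpy(),
            mrna_only.mrna_proportions.to_numpy(),
            atol=1e-9,
        )

    def test_mrna_proportions_sum_to_one_and_bounded(self, mixture_setup):
        refset, signature, profiles, contents = mixture_setup
        rng = np.random.default_rng(21)
        raw = rng.dirichlet(np.ones(4), size=6)
        fractions = pd.DataFrame(
            raw, columns=["Bcells", "Tcells", "NKcells", "cancer"],
            index=[f"s{i}" for i in range(6)],
        )
        bulk, _ = bd.simulate_bulk_mixture(
            profiles, fractions, contents, noise_sigma=0.3, seed=22
        )
        result = bd.deconvolve(bulk, refset, signature, contents)
        sums = result.mrna_proportions.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        values = result.mrna_proportions.to_numpy()
        assert ((values >= 0) & (values <= 1)).all()

    def test_cancer_profile_independence(self, mixture_setup):
        # replacing the uncharacterized cells' non-signature expression must
        # not move the recovered proportions (the fit sees only S)
        refset, signature, profiles, contents = mixture_setup
        fractions = pd.Series(
            {"Bcells": 0.15, "Tcells": 0.35, "NKcells": 0.1, "cancer": 0.4}
        )
        other_cancer = bd.simulate_cancer_profile(refset, signature, seed=99)
        profiles2 = profiles.copy()
        profiles2["cancer"] = other_cancer
        bulk1, _ = bd.simulate_bulk_mixture(profiles, fractions, contents)
        bulk2, _ = bd.simulate_bulk_mixture(profiles2, fractions, contents)
        r1 = bd.deconvolve(bulk1, refset, signature, contents)
        r2 = bd.deconvolve(bulk2, refset, signature, contents)
        np.testing.assert_allclose(
            r1.mrna_proportions.to_numpy(), r2.mrna_proportions.to_numpy(),
            atol=1e-6,
        )

    def test_leave_one_type_out_robustness(self, mixture_setup):
        refset, signature, profiles, contents = mixture_setup
        fractions = pd.Series(
            {"Bcells": 0.3, "Tcells": 0.25, "NKcells": 0.05, "cancer": 0.4}
        )
        bulk, _ = bd.simulate_bulk_mixture(profiles, fractions, contents)
        reduced_ref = refset.drop_cell_type("NKcells")
        reduced_sig = bd.SignatureSet(
            {ct: g for ct, g in signature.markers.items() if ct != "NKcells"}
        )
        result = bd.deconvolve(bulk, reduced_ref, reduced_sig, contents)
        for cell_type in ("Bcells", "Tcells"):
            err = abs(result.cell_fractions.iloc[0][cell_type]
                      - fractions[cell_type])
            assert err < fractions["NKcells"]

    def test_per_sample_failure_isolated(self, mixture_setup):
        refset, signature, profiles, contents = mixture_setup
        fractions = pd.Series(
            {"Bcells": 0.25, "Tcells": 0.25, "NKcells": 0.25, "cancer": 0.25}
        )
        bulk, _ = bd.simulate_bulk_mixture(profiles, fractions, contents)
        broken = bulk.data.copy()
        broken["bad_sample"] = 0.0
        with pytest.warns(UserWarning, match="bad_sample"):
            result = bd.deconvolve(
                bd.ExpressionMatrix(broken, "tpm"), refset, signature, contents
            )
        assert "sample_0" in result.mrna_proportions.index
        assert "bad_sample" not in result.mrna_proportions.index


class TestAprioriRescaled:
    def test_equal_contents_matches_standard(self, mixture_setup):
        refset, signature, profiles, contents = mixture_setup
        fractions = pd.Series(
            {"Bcells": 0.3, "Tcells": 0.3, "NKcells": 0.1, "cancer": 0.3}
        )
        bulk, _ = bd.simulate_bulk_mixture(profiles, fractions, contents)
        standard = bd.deconvolve(bulk, refset, signature, contents)
        apriori = bd.deconvolve_apriori_rescaled(bulk, refset, signature, contents)
        np.testing.assert_allclose(
            standard.cell_fractions.to_numpy(),
            apriori.cell_fractions.to_numpy(),
            atol=1e-9,
        )

    def test_unequal_contents_noiseless_recovery(self, mixture_setup,
                                                 unequal_contents):
        refset, signature, profiles, _ = mixture_setup
        fractions = pd.Series(
            {"Bcells": 0.2, "Tcells": 0.35, "NKcells": 0.15, "cancer": 0.3}
        )
        bulk, _ = bd.simulate_bulk_mixture(profiles, fractions, unequal_contents)
        apriori = bd.deconvolve_apriori_rescaled(
            bulk, refset, signature, unequal_contents
        )
        recovered = apriori.cell_fractions.iloc[0]
        for cell_type in ("Bcells", "Tcells", "NKcells"):
            assert recovered[cell_type] == pytest.approx(
                fractions[cell_type], abs=1e-6
            )
        assert recovered["uncharacterized"] == pytest.approx(0.3, abs=1e-6)

    def test_modes_agree_in_noiseless_limit(self, mixture_setup, unequal_contents):
        refset, signature, profiles, _ = mixture_setup
        fractions = pd.Series(
            {"Bcells": 0.1, "Tcells": 0.4, "NKcells": 0.2, "cancer": 0.3}
        )
        bulk, _ = bd.simulate_bulk_mixture(profiles, fractions, unequal_contents)
        standard = bd.deconvolve(bulk, refset, signature, unequal_contents)
        apriori = bd.deconvolve_apriori_rescaled(
            bulk, refset, signature, unequal_contents
        )
        np.testing.assert_allclose(
            standard.cell_fractions.to_numpy(),
            apriori.cell_fractions.to_numpy(),
            atol=1e-6,
        )
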