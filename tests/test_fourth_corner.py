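import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fourthcorner as fc
from fourthcorner.matrices import ValidationError

from conftest import random_triple


def plain_pearson_oracle(R, L, Q, env_col=0, trait_col=0):
    """Pearson r on the individual-level table: each (site, species) cell
    contributes `count` identical rows.  Independent of the weighted path."""
    xs, ys = [], []
    counts = L.values.astype(int)
    for s, j in zip(*np.nonzero(counts)):
        xs += [R.values[s, env_col]] * counts[s, j]
        ys += [Q.values[j, trait_col]] * counts[s, j]
    return np.corrcoef(xs, ys)[0, 1]


class TestInflate:
    def test_two_equal_cells(self):
        R = fc.EnvMatrix(pd.DataFrame({"e": [0.0, 1.0]}, index=["a", "b"]))
        L = fc.AbundanceMatrix(pd.DataFrame([[2, 0], [0, 2]],
                                            index=["a", "b"], columns=["x", "y"]))
        Q = fc.TraitMatrix(pd.DataFrame({"t": [0.0, 1.0]}, index=["x", "y"]))
        infl = fc.inflate(R, L, Q)
        assert infl.n_rows == 2
        assert np.allclose(infl.weights, [0.5, 0.5])

    def test_one_row_per_nonzero_cell(self, one_species_per_site):
        infl = fc.inflate(*one_species_per_site)
        assert infl.n_rows == 5
        assert abs(infl.weights.sum() - 1.0) < 1e-12

    def test_unequal_weights(self):
        R = fc.EnvMatrix(pd.DataFrame({"e": [0.0, 1.0]}, index=["a", "b"]))
        L = fc.AbundanceMatrix(pd.DataFrame([[2, 1], [0, 1]],
                                            index=["a", "b"], columns=["x", "y"]))
        Q = fc.TraitMatrix(pd.DataFrame({"t": [0.0, 1.0]}, index=["x", "y"]))
        infl = fc.inflate(R, L, Q)
        assert infl.n_rows == 3
        assert np.allclose(sorted(infl.weights), [0.25, 0.25, 0.5])


class TestStatistic:
    def test_perfect_correlation(self, one_species_per_site):
        infl = fc.inflate(*one_species_per_site)
        assert fc.fourth_corner_stat(infl, 0, 0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_trait_errors(self):
        R = fc.EnvMatrix(pd.DataFrame({"e": [0.0, 1.0]}, index=["a", "b"]))
        L = fc.AbundanceMatrix(pd.DataFrame([[1, 1], [1, 1]],
                                            index=["a", "b"], columns=["x", "y"]))
        Q = fc.TraitMatrix(pd.DataFrame({"t": [2.0, 2.0]}, index=["x", "y"]))
        with pytest.raises(ValidationError, match="variance"):
            fc.fourth_corner_stat(fc.inflate(R, L, Q), 0, 0)

    def test_weighted_statistic_equals_occurrence_level_pearson(self):
        # L=[[2,1],[0,1]] expands to pairs (0,0),(0,0),(0,1),(1,1): r = 1/sqrt(3)
        R = fc.EnvMatrix(pd.DataFrame({"e": [0.0, 1.0]}, index=["a", "b"]))
        L = fc.AbundanceMatrix(pd.DataFrame([[2, 1], [0, 1]],
                                            index=["a", "b"], columns=["x", "y"]))
        Q = fc.TraitMatrix(pd.DataFrame({"t": [0.0, 1.0]}, index=["x", "y"]))
        r = fc.fourth_corner_stat(fc.inflate(R, L, Q), 0, 0)
        assert r == pytest.approx(0.5773502691896258, abs=1e-10)
        assert r == pytest.approx(plain_pearson_oracle(R, L, Q), abs=1e-10)


class TestFullMatrix:
    def test_output_dimensions(self):
        rng = np.random.default_rng(1)
        R, L, Q = random_triple(rng, 27, 30, n_env=16, n_traits=26)
        assert fc.full_stat_matrix(R, L, Q).shape == (26, 16)

    def test_duplicated_trait_gives_identical_rows(self, small_dataset):
        ds = small_dataset
        Q2 = fc.TraitMatrix(
            ds.Q.data.assign(dup=ds.Q.data.iloc[:, 0])
        )
        r = fc.full_stat_matrix(ds.R, ds.L, Q2)
        assert np.allclose(r.iloc[0], r.loc["dup"], atol=1e-12)

    def test_associativity_of_multiplication_orders(self):
        # (Q' W') R' vs Q' (W' R') on standardized, weight-normalized forms
        rng = np.random.default_rng(7)
        R, L, Q = random_triple(rng, 4, 3, n_env=2, n_traits=3)
        W = L.values / L.values.sum()
        a, b = W.sum(1), W.sum(0)
        E, T = R.values, Q.values
        ze = (E - a @ E) / np.sqrt(a @ (E - a @ E) ** 2)
        zq = (T - b @ T) / np.sqrt(b @ (T - b @ T) ** 2)
        left = (zq.T @ W.T) @ ze
        right = zq.T @ (W.T @ ze)
        assert np.allclose(left, right, atol=1e-10)
        assert np.allclose(left, fc.full_stat_matrix(R, L, Q).to_numpy(), atol=1e-10)

    def test_raw_counts_equal_relative_abundances(self, small_dataset):
        ds = small_dataset
        r_raw = fc.full_stat_matrix(ds.R, ds.L, ds.Q)
        r_rel = fc.full_stat_matrix(ds.R, fc.to_relative_abundance(ds.L), ds.Q)
        assert np.allclose(r_raw, r_rel, atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_affine_rescaling_invariance_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        R, L, Q = random_triple(rng, 5, 4, n_env=2, n_traits=2)
        r = fc.full_stat_matrix(R, L, Q).to_numpy()
        ok = np.isfinite(r)
        assert (np.abs(r[ok]) <= 1 + 1e-12).all()
        R2 = fc.EnvMatrix(R.data * 3.7 - 11.0)
        Q2 = fc.TraitMatrix(Q.data * -0.2 + 5.0)
        r2 = fc.full_stat_matrix(R2, L, Q2).to_numpy()
        assert np.allclose(np.abs(r[ok]), np.abs(r2[ok]), atol=1e-10)

    def test_oracle_equivalence_on_random_small_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            R, L, Q = random_triple(rng, 4, 4, n_env=1, n_traits=1)
            r = fc.full_stat_matrix(R, L, Q).iloc[0, 0]
            oracle = plain_pearson_oracle(R, L, Q)
            if np.isnan(r):
                assert not np.isfinite(oracle) or abs(oracle) > 0.999
            else:
                assert r == pytest.approx(oracle, abs=1e-10)


class TestPermuteL:
    def _L(self, rng):
        return fc.AbundanceMatrix(
            pd.DataFrame(rng.integers(0, 6, (4, 5)) + np.eye(4, 5, dtype=int),
                         index=list("abcd"), columns=list("vwxyz"))
        )

    @pytest.mark.parametrize("model", fc.MODELS)
    def test_entry_multiset_preserved(self, model):
        rng = np.random.default_rng(0)
        L = self._L(rng)
        perm = fc.permute_L(L, model, np.random.default_rng(1))
        assert sorted(perm.values.ravel()) == sorted(L.values.ravel())

    def test_model_II_preserves_row_vectors(self):
        rng = np.random.default_rng(2)
        L = self._L(rng)
        perm = fc.permute_L(L, "II", np.random.default_rng(3))
        rows = {tuple(r) for r in L.values}
        assert {tuple(r) for r in perm.values} == rows

    def test_model_IV_permutes_column_sums(self):
        rng = np.random.default_rng(4)
        L = self._L(rng)
        perm = fc.permute_L(L, "IV", np.random.default_rng(5))
        assert sorted(perm.values.sum(0)) == sorted(L.values.sum(0))

    def test_model_I_single_site_is_identity(self):
        L = fc.AbundanceMatrix(pd.DataFrame([[3, 1, 4]], index=["a"],
                                            columns=["x", "y", "z"]))
        perm = fc.permute_L(L, "I", np.random.default_rng(6))
        assert np.array_equal(perm.values, L.values)

    def test_unknown_model_errors(self):
        L = self._L(np.random.default_rng(7))
        with pytest.raises(ValueError, match="model"):
            fc.permute_L(L, "III", np.random.default_rng(0))

    def test_model_II_equivalent_to_shuffling_R_rows(self):
        """The full model-II permutation distribution of r is the same
        whether L rows or R rows are reshuffled."""
        rng = np.random.default_rng(8)
        R, L, Q = random_triple(rng, 4, 3, n_env=1, n_traits=1)
        from fourthcorner.fourth_corner import _corr_core

        def rset(shuffle_L):
            vals = []
            for p in itertools.permutations(range(L.shape[0])):
                p = list(p)
                if shuffle_L:
                    r = _corr_core(R.values, L.values[p, :], Q.values)
                else:
                    r = _corr_core(R.values[p, :], L.values, Q.values)
                vals.append(round(float(r[0, 0]), 10))
            return sorted(vals)

        assert rset(True) == rset(False)


class TestPermutationTest:
    def test_single_permutation_forces_half_or_one(self, small_dataset):
        ds = small_dataset
        res = fc.fourth_corner_test(ds.R, ds.L, ds.Q, model="I", n_perm=1, seed=0)
        assert set(np.unique(res.p.to_numpy())) <= {0.5, 1.0}

    def test_determinism_under_seed(self, small_dataset):
        ds = small_dataset
        a = fc.fourth_corner_test(ds.R, ds.L, ds.Q, model="II", n_perm=49, seed=9)
        b = fc.fourth_corner_test(ds.R, ds.L, ds.Q, model="II", n_perm=49, seed=9)
        pd.testing.assert_frame_equal(a.p, b.p)
        pd.testing.assert_frame_equal(a.r, b.r)

    def test_p_values_independent_of_other_traits_present(self, small_dataset):
        """Dropping trait columns must not change the remaining p-values:
        the null acts on L alone."""
        ds = small_dataset
        full = fc.fourth_corner_test(ds.R, ds.L, ds.Q, model="I", n_perm=99, seed=2)
        Q1 = fc.TraitMatrix(ds.Q.data.iloc[:, [0]])
        solo = fc.fourth_corner_test(ds.R, ds.L, Q1, model="I", n_perm=99, seed=2)
        pd.testing.assert_series_equal(full.p.iloc[0], solo.p.iloc[0])

    def test_sign_zero_iff_not_significant(self, small_dataset):
        ds = small_dataset
        res = fc.fourth_corner_test(ds.R, ds.L, ds.Q, model="I", n_perm=99, seed=3)
        sig = res.p.le(res.alpha).to_numpy()
        assert ((res.sign.to_numpy() != 0) == sig).all()

    def test_pairwise_deletion_matches_subset_analysis(self, small_dataset):
        """A trait missing for one species should be tested exactly as if
        that species' L column had been removed for that trait."""
        ds = small_dataset
        q = ds.Q.data.copy()
        q.iloc[0, 0] = np.nan
        res = fc.fourth_corner_test(ds.R, ds.L, fc.TraitMatrix(q),
                                    model="I", n_perm=99, seed=5)
        sub_L = fc.AbundanceMatrix(ds.L.data.iloc[:, 1:])
        sub_Q = fc.TraitMatrix(ds.Q.data.iloc[1:, [0]])
        sub = fc.fourth_corner_test(ds.R, sub_L, sub_Q, model="I", n_perm=99, seed=5)
        assert res.r.iloc[0, 0] == pytest.approx(sub.r.iloc[0, 0], abs=1e-12)
        assert res.p.iloc[0, 0] == pytest.approx(sub.p.iloc[0, 0], abs=1e-12)
        # remaining (complete) traits are unaffected by the deletion
        full = fc.fourth_corner_test(ds.R, ds.L, ds.Q, model="I", n_perm=99, seed=5)
        pd.testing.assert_series_equal(res.p.iloc[1], full.p.iloc[1])


class TestCounting:
    def _result(self, p, alpha=0.05):
        idx = [f"t{i}" for i in range(p.shape[0])]
        cols = [f"v{k}" for k in range(p.shape[1])]
        dfp = pd.DataFrame(p, index=idx, columns=cols)
        sign = pd.DataFrame(np.where(dfp <= alpha, 1, 0), index=idx, columns=cols)
        return fc.FourthCornerResult(model="I", r=dfp * 0 + 0.5, p=dfp, sign=sign,
                                     n_perm=99, alpha=alpha, seed=0)

    def test_all_insignificant(self):
        counts = fc.count_significances(self._result(np.ones((3, 2))))
        assert counts.total == 0 and (counts.per_variable == 0).all()

    def test_counts_add_up_to_total(self):
        rng = np.random.default_rng(12)
        counts = fc.count_significances(self._result(rng.uniform(size=(6, 4))))
        assert counts.total == counts.per_variable.sum()

    def test_nan_cells_excluded(self):
        p = np.array([[0.01, np.nan], [0.2, 0.01]])
        counts = fc.count_significances(self._result(p))
        assert counts.total == 2
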