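"""Pairwise logratios, total variance, and stepwise (SRDA) selection."""

import numpy as np
import pandas as pd
import pytest

import lymphocoda as lc
from lymphocoda.logratios import clr_matrix

from conftest import random_composition


class TestAllPairwiseLogratios:
    def test_pair_count_for_16_parts(self, small_composition):
        lrs = lc.all_pairwise_logratios(small_composition)
        assert lrs.n_pairs == 120
        assert lrs.values.shape[1] == 120

    def test_three_part_values(self):
        comp = lc.CompositionMatrix(
            proportions=pd.DataFrame([[0.5, 0.25, 0.25]], columns=["a", "b", "c"])
        )
        lrs = lc.all_pairwise_logratios(comp)
        assert lrs.values.iloc[0].tolist() == pytest.approx(
            [np.log(2), np.log(2), 0.0]
        )

    def test_equal_composition_row_is_zero(self):
        comp = lc.CompositionMatrix(
            proportions=pd.DataFrame([[0.25] * 4], columns=list("abcd"))
        )
        assert (lc.all_pairwise_logratios(comp).values.iloc[0] == 0).all()

    def test_nonpositive_entry_rejected(self):
        comp = lc.CompositionMatrix(
            proportions=pd.DataFrame([[0.0, 1.0]], columns=["a", "b"])
        )
        with pytest.raises(ValueError, match="replace_zeros"):
            lc.all_pairwise_logratios(comp)


class TestTotalVariance:
    def test_constant_composition_zero(self):
        comp = lc.CompositionMatrix(
            proportions=pd.DataFrame([[0.3, 0.7]] * 5, columns=["a", "b"])
        )
        assert lc.total_logratio_variance(comp) == pytest.approx(0.0)

    def test_two_subject_hand_value(self):
        # ln-ratio values {0, 1}: T = (1/D²)·Var = (1/4)·0.5 = 0.125
        c = 1.0 / (1.0 + np.e)
        comp = lc.CompositionMatrix(
            proportions=pd.DataFrame(
                [[0.5, 0.5], [np.e * c, c]], columns=["a", "b"]
            )
        )
        assert lc.total_logratio_variance(comp) == pytest.approx(0.125)

    def test_invariant_to_per_subject_scaling(self):
        comp = random_composition(50, 6, seed=0)
        t0 = lc.total_logratio_variance(comp)
        rng = np.random.default_rng(1)
        scaled = lc.CompositionMatrix(
            proportions=comp.proportions * rng.uniform(0.5, 8.0, size=(50, 1))
        )
        assert lc.total_logratio_variance(scaled) == pytest.approx(t0, rel=1e-12)

    def test_n_below_two_rejected(self):
        comp = random_composition(1, 4, seed=0)
        with pytest.raises(ValueError, match="n < 2"):
            lc.total_logratio_variance(comp)

    def test_equals_weighted_clr_trace(self, small_composition):
        # T with uniform weights is (1/D)·trace of the CLR covariance
        z = clr_matrix(small_composition)
        t_clr = np.var(z, axis=0, ddof=1).sum() / z.shape[1]
        assert lc.total_logratio_variance(small_composition) == pytest.approx(t_clr)


def brute_force_greedy(comp, weights_scale=True):
    """Independent SRDA oracle: explicit projection for every candidate.

    At each step, for every remaining pair, build the design of selected
    columns plus the candidate, project every centred CLR column onto it by
    lstsq, and measure explained variance directly.
    """
    x = comp.proportions.to_numpy()
    lx = np.log(x)
    Y = lx - lx.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=0, keepdims=True)
    denom = (Y**2).sum()
    D = Y.shape[1]
    pairs = [(i, j) for i in range(D) for j in range(D) if i < j]
    cols = {p: lx[:, p[0]] - lx[:, p[1]] for p in pairs}
    selected = []
    trace = []
    prev = 0.0
    for _ in range(D - 1):
        best, best_frac = None, -1.0
        for p in pairs:
            if p in selected:
                continue
            S = np.column_stack([cols[q] for q in selected + [p]])
            S = S - S.mean(axis=0, keepdims=True)
            fit, *_ = np.linalg.lstsq(S, Y, rcond=None)
            frac = ((S @ fit) ** 2).sum() / denom
            # same tolerance-aware lexicographic tie-break as the library:
            # distinct pairs can span identical subspaces
            if frac > best_frac + 1e-10:
                best, best_frac = p, frac
        selected.append(best)
        trace.append((best, best_frac - prev, best_frac))
        prev = best_frac
    return trace


class TestSrdaSelect:
    def test_three_parts_two_steps(self):
        comp = random_composition(30, 3, seed=2)
        tr = lc.srda_select(lc.all_pairwise_logratios(comp), target_fraction=1.0)
        assert len(tr.steps) == 2
        assert tr.steps["cumulative"].iloc[-1] == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_oracle(self):
        comp = random_composition(40, 5, seed=11)
        tr = lc.srda_select(lc.all_pairwise_logratios(comp), target_fraction=1.0)
        oracle = brute_force_greedy(comp)
        parts = list(comp.proportions.columns)
        for row, (pair, add, cum) in zip(tr.steps.itertuples(), oracle):
            assert row.pair == f"{parts[pair[0]]}/{parts[pair[1]]}"
            assert row.additional == pytest.approx(add, abs=1e-9)
            assert row.cumulative == pytest.approx(cum, abs=1e-9)

    def test_single_pair_fraction_matches_projection_oracle(self):
        # first-step gain equals the explicit one-column projection value
        comp = random_composition(60, 6, seed=3)
        tr = lc.srda_select(lc.all_pairwise_logratios(comp), max_steps=1)
        oracle = brute_force_greedy(comp)
        assert tr.steps["additional"].iloc[0] == pytest.approx(oracle[0][1], abs=1e-10)

    def test_cumulative_nondecreasing_and_exhaustive(self, small_composition):
        tr = lc.srda_select(lc.all_pairwise_logratios(small_composition), target_fraction=1.0)
        cum = tr.steps["cumulative"].to_numpy()
        assert (np.diff(cum) > -1e-12).all()
        assert len(tr.steps) == 15
        assert cum[-1] == pytest.approx(1.0, abs=1e-8)

    def test_target_fraction_stops_early(self, small_composition):
        tr = lc.srda_select(lc.all_pairwise_logratios(small_composition), target_fraction=0.5)
        assert tr.steps["cumulative"].iloc[-1] >= 0.5
        assert tr.steps["cumulative"].iloc[-2] < 0.5

    def test_no_stop_rule_rejected(self, small_composition):
        with pytest.raises(ValueError, match="target_fraction"):
            lc.srda_select(lc.all_pairwise_logratios(small_composition))

    def test_permutation_equivariance(self):
        comp = random_composition(40, 5, seed=13)
        perm = [3, 0, 4, 1, 2]
        permuted = lc.CompositionMatrix(
            proportions=comp.proportions.iloc[:, perm]
        )
        tr1 = lc.srda_select(lc.all_pairwise_logratios(comp), target_fraction=1.0)
        tr2 = lc.srda_select(lc.all_pairwise_logratios(permuted), target_fraction=1.0)
        # variance fractions are equivariant; pair labels need not be, since
        # distinct pairs can span the same subspace once one pair is chosen
        # (e.g. {a/b, a/c} vs {a/b, b/c}) and ties break lexicographically
        assert np.allclose(tr1.steps["additional"], tr2.steps["additional"], atol=1e-10)
        assert np.allclose(tr1.steps["cumulative"], tr2.steps["cumulative"], atol=1e-10)

    def test_invariant_to_per_subject_rescaling(self):
        comp = random_composition(40, 5, seed=17)
        rng = np.random.default_rng(4)
        scaled = lc.CompositionMatrix(
            proportions=comp.proportions * rng.uniform(0.1, 10.0, size=(40, 1))
        )
        tr1 = lc.srda_select(lc.all_pairwise_logratios(comp), target_fraction=1.0)
        tr2 = lc.srda_select(lc.all_pairwise_logratios(scaled), target_fraction=1.0)
        assert list(tr1.steps["pair"]) == list(tr2.steps["pair"])
        assert np.allclose(tr1.steps["cumulative"], tr2.steps["cumulative"], atol=1e-10)


class TestPairwiseCorrelations:
    def test_unit_diagonal_and_symmetry(self, small_composition):
        c = lc.pairwise_correlations(small_composition)
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c, c.T)

    def test_two_part_closure_forces_minus_one(self):
        comp = random_composition(30, 2, seed=5)
        c = lc.pairwise_correlations(comp)
        assert c.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_formula(self, small_composition):
        c = lc.pairwise_correlations(small_composition).to_numpy()
        x = small_composition.proportions.to_numpy()
        oracle = np.corrcoef(x, rowvar=False)
        assert np.abs(c - oracle).max() < 1e-12

    def test_zero_variance_column_flagged(self):
        df = pd.DataFrame({"a": [0.5, 0.5], "b": [0.25, 0.3], "c": [0.25, 0.2]})
        with pytest.raises(ValueError, match="zero-variance"):
            lc.pairwise_correlations(lc.CompositionMatrix(proportions=df))
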