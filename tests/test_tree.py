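"""Tree construction, validation, composition conversion, zero replacement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lymphocoda as lc
from lymphocoda.tree import MEASURED_NODES, build_tree


class TestBuildTree:
    def test_canonical_tree_shape(self, tree):
        assert len(tree.nodes) == 21
        assert len(tree.leaves) == 16
        assert tree.leaves == lc.LEAVES
        # four levels below the root at the deepest branch
        assert max(tree.depth(l) for l in tree.leaves) == 3
        # every internal node has exactly one derived complement child
        for node in tree.internal_nodes():
            derived = [c for c in tree.children(node) if tree.nodes[c].derived]
            assert len(derived) == 1

    def test_minimal_spec_gets_complement_child(self):
        t = build_tree([("T", "root"), ("B", "root")])
        assert set(t.children("root")) == {"T", "B", "LYMPO"}
        assert t.nodes["LYMPO"].derived

    def test_orphan_parent_rejected(self):
        # children referencing an omitted parent cannot reach the root
        broken = [m for m in MEASURED_NODES if m[0] != "TCD8"]
        with pytest.raises(ValueError, match="parent path"):
            build_tree(broken)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_tree(MEASURED_NODES + [("TCD4N", "TCD8")])


class TestDeriveOther:
    def test_complement_values(self, tree):
        panel = pd.DataFrame([{n: 0.0 for n, _ in MEASURED_NODES}])
        panel.loc[0, ["T", "B"]] = [60.0, 15.0]
        panel.loc[0, ["TCD4N", "TCD4CM", "TCD4EM", "TCD4TDEM"]] = [50.0, 30.0, 10.0, 10.0]
        ext = lc.derive_other(panel, tree)
        assert ext.loc[0, "LYMPO"] == pytest.approx(25.0)
        assert ext.loc[0, "TCD4O"] == pytest.approx(0.0)
        assert ext.loc[0, "BO"] == pytest.approx(100.0)

    def test_exact_partition_gives_zero_others(self, tree):
        panel = pd.DataFrame([{n: 0.0 for n, _ in MEASURED_NODES}])
        panel.loc[0, ["T", "B"]] = [70.0, 30.0]
        panel.loc[0, ["TCD4", "TCD8"]] = [60.0, 40.0]
        panel.loc[0, ["TCD4N", "TCD4CM", "TCD4EM", "TCD4TDEM"]] = [25.0] * 4
        panel.loc[0, ["TCD8N", "TCD8CM", "TCD8EM", "TCD8TDEM"]] = [25.0] * 4
        panel.loc[0, ["BN", "BMIgD-", "BMIgD+"]] = [50.0, 25.0, 25.0]
        ext = lc.derive_other(panel, tree)
        for other in ["LYMPO", "TO", "TCD4O", "TCD8O", "BO"]:
            assert ext.loc[0, other] == 0.0


class TestValidateSubjects:
    @pytest.fixture()
    def panel(self, small_cohort):
        return small_cohort.panel.copy()

    def test_oversum_excluded(self, panel, tree):
        panel.iloc[0, panel.columns.get_loc("TCD4N")] = 90.0
        panel.iloc[0, panel.columns.get_loc("TCD4CM")] = 13.0  # CD4 children > 100
        kept, log = lc.validate_subjects(panel, tree)
        assert panel.index[0] not in kept.index
        assert log.set_index("subject_id").loc[panel.index[0], "reason"] == "oversum"

    def test_missing_excluded(self, panel, tree):
        panel.iloc[1, panel.columns.get_loc("BN")] = np.nan
        kept, log = lc.validate_subjects(panel, tree)
        assert panel.index[1] not in kept.index
        assert log.set_index("subject_id").loc[panel.index[1], "reason"] == "missing"

    def test_valid_subjects_kept(self, panel, tree):
        kept, log = lc.validate_subjects(panel, tree)
        assert len(kept) == len(panel)
        assert log.empty

    def test_exactly_100_is_valid(self, tree):
        panel = pd.DataFrame([{n: 0.0 for n, _ in MEASURED_NODES}])
        panel.loc[0, ["T", "B"]] = [70.0, 30.0]
        kept, log = lc.validate_subjects(panel, tree)
        assert len(kept) == 1 and log.empty

    def test_relaxing_tolerance_never_excludes_more(self, panel, tree):
        panel.iloc[2, panel.columns.get_loc("BN")] = 99.9
        panel.iloc[2, panel.columns.get_loc("BMIgD-")] = 0.11
        counts = []
        for tol in [1e-9, 1e-3, 1.0]:
            _, log = lc.validate_subjects(panel, tree, tol=tol)
            counts.append(len(log))
        assert counts == sorted(counts, reverse=True)

    def test_all_excluded_raises(self, tree):
        panel = pd.DataFrame([{n: np.nan for n, _ in MEASURED_NODES}])
        with pytest.raises(ValueError, match="unusable"):
            lc.validate_subjects(panel, tree)


class TestToComposition:
    def test_path_product(self, tree):
        panel = pd.DataFrame([{n: 0.0 for n, _ in MEASURED_NODES}])
        panel.loc[0, "T"] = 70.0
        panel.loc[0, "TCD4"] = 60.0
        panel.loc[0, "TCD4N"] = 50.0
        comp = lc.to_composition(lc.derive_other(panel, tree), tree)
        assert comp.proportions.loc[0, "TCD4N"] == pytest.approx(0.7 * 0.6 * 0.5)

    def test_degenerate_all_b_naive(self, tree):
        panel = pd.DataFrame([{n: 0.0 for n, _ in MEASURED_NODES}])
        panel.loc[0, "B"] = 40.0
        panel.loc[0, "BN"] = 100.0
        comp = lc.to_composition(lc.derive_other(panel, tree), tree)
        assert comp.proportions.loc[0, "BN"] == pytest.approx(0.4)
        assert comp.proportions.loc[0, ["BMIgD-", "BMIgD+", "BO"]].sum() == 0.0

    def test_closure_on_many_random_subjects(self, tree):
        # 1000 random valid subjects; row sums must close to 1 and summing
        # leaves back up the tree must reproduce every internal node
        comp = lc.generate_compositions(1000, seed=7)
        panel = lc.decompose_to_panel(comp, tree)
        back = lc.to_composition(lc.derive_other(panel, tree), tree)
        sums = back.proportions.sum(axis=1).to_numpy()
        assert np.abs(sums - 1.0).max() < 1e-9
        # partition consistency for the T branch
        t_total = back.proportions[
            [l for l in lc.LEAVES if l.startswith("T") and l != "TO"] + ["TO"]
        ].sum(axis=1)
        assert np.allclose(t_total, panel["T"] / 100.0, atol=1e-9)


class TestReplaceZeros:
    def test_column_minimum_rule(self):
        df = pd.DataFrame({"a": [0.0, 0.07, 0.38], "b": [1.0, 0.93, 0.62]})
        comp = lc.CompositionMatrix(proportions=df)
        out = lc.replace_zeros(comp)
        assert out.proportions.loc[0, "a"] == pytest.approx(0.07)
        assert out.zero_replaced.loc[0, "a"]
        assert not out.zero_replaced.loc[1, "a"]

    def test_no_zeros_unchanged(self, small_composition):
        again = lc.replace_zeros(small_composition)
        pd.testing.assert_frame_equal(again.proportions, small_composition.proportions)

    def test_idempotent(self, small_cohort):
        kept, _ = lc.validate_subjects(small_cohort.panel)
        comp = lc.to_composition(lc.derive_other(kept))
        once = lc.replace_zeros(comp)
        twice = lc.replace_zeros(once)
        pd.testing.assert_frame_equal(once.proportions, twice.proportions)

    def test_two_zeros_same_replacement(self):
        df = pd.DataFrame({"a": [0.0, 0.0, 0.2, 0.4], "b": [1.0, 1.0, 0.8, 0.6]})
        out = lc.replace_zeros(lc.CompositionMatrix(proportions=df))
        assert (out.proportions.loc[[0, 1], "a"] == 0.2).all()

    def test_all_zero_column_rejected(self):
        df = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 1.0]})
        with pytest.raises(ValueError, match="entirely zero"):
            lc.replace_zeros(lc.CompositionMatrix(proportions=df))

    def test_renormalize_option_recloses(self, small_cohort):
        kept, _ = lc.validate_subjects(small_cohort.panel)
        comp = lc.to_composition(lc.derive_other(kept))
        out = lc.replace_zeros(comp, renormalize=True)
        assert np.allclose(out.proportions.sum(axis=1), 1.0, atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_roundtrip_panel_composition(seed):
    """decompose → derive_other → to_composition reproduces the composition."""
    comp = lc.generate_compositions(20, seed=seed)
    panel = lc.decompose_to_panel(comp)
    back = lc.to_composition(lc.derive_other(panel))
    assert np.abs(back.proportions.to_numpy() - comp.proportions.to_numpy()).max() < 1e-9
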