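"""Single-cell stage: binarization, age groups, merging, fractions,
increase flags, log-odds ratios and the Fisher exact test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import fisher_enumeration_p
from senesurf.sc import (
    SingleCellBinary,
    assign_age_groups,
    binarize,
    compute_lor,
    exclude_unbalanced_tissues,
    fisher_exact_p,
    flag_age_increase,
    fraction_positive,
    merge_datasets,
    overlap_flags,
)


def _mk(calls: np.ndarray, tissue, cell_type, age_group, genes=None,
        prefix="c") -> SingleCellBinary:
    n = len(calls)
    genes = genes or [f"g{j}" for j in range(calls.shape[1])]
    idx = pd.Index([f"{prefix}{i}" for i in range(n)], name="cell_id")
    obs = pd.DataFrame(
        {"tissue": tissue, "cell_type": cell_type, "age_group": age_group},
        index=idx,
    )
    return SingleCellBinary(pd.DataFrame(calls, index=idx, columns=genes,
                                         dtype=np.int8), obs)


class TestBinarize:
    def test_zero_column_stays_zero(self):
        counts = pd.DataFrame({"a": [0.0, 0, 0], "b": [1.0, 0, 2]},
                              index=pd.Index(["c0", "c1", "c2"], name="cell_id"))
        obs = pd.DataFrame({"tissue": "t", "cell_type": "ct", "age_group": "young"},
                           index=counts.index)
        data = binarize(counts, obs)
        assert data.calls["a"].sum() == 0
        assert list(data.calls["b"]) == [1, 0, 1]

    def test_fractional_counts_are_positive_calls(self):
        counts = pd.DataFrame({"a": [0.5]}, index=pd.Index(["c0"], name="cell_id"))
        obs = pd.DataFrame({"tissue": "t", "cell_type": "ct"}, index=counts.index)
        assert binarize(counts, obs).calls.iloc[0, 0] == 1

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.poisson(0.7, size=(20, 4)).astype(float))
        counts.index.name = "cell_id"
        obs = pd.DataFrame({"tissue": "t", "cell_type": "ct"}, index=counts.index)
        once = binarize(counts, obs).calls
        twice = binarize(once, obs).calls
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"a": [-1.0]}, index=pd.Index(["c0"], name="cell_id"))
        obs = pd.DataFrame({"tissue": "t", "cell_type": "ct"}, index=counts.index)
        with pytest.raises(ValueError):
            binarize(counts, obs)


class TestAgeGroups:
    def test_inclusive_bounds_and_gap(self):
        obs = pd.DataFrame(
            {"tissue": "t", "cell_type": "ct", "age_months": [3, 18, 12, 1, 24]},
            index=pd.Index([f"c{i}" for i in range(5)], name="cell_id"),
        )
        with pytest.warns(UserWarning, match="intermediate"):
            labeled = assign_age_groups(obs)
        groups = labeled["age_group"].to_dict()
        assert groups["c0"] == "young"  # exactly 3 months
        assert groups["c1"] == "old"  # exactly 18 months
        assert "c2" not in groups  # 12 months excluded
        assert groups["c3"] == "young" and groups["c4"] == "old"

    def test_prelabeled_cells_pass_through(self):
        obs = pd.DataFrame(
            {"tissue": "t", "cell_type": "ct", "age_group": ["young", "old"]},
            index=pd.Index(["a", "b"], name="cell_id"),
        )
        out = assign_age_groups(obs)
        assert list(out["age_group"]) == ["young", "old"]

    def test_unresolvable_cell_is_an_error(self):
        obs = pd.DataFrame({"tissue": "t", "cell_type": "ct"},
                           index=pd.Index(["a"], name="cell_id"))
        with pytest.raises(ValueError, match="neither"):
            assign_age_groups(obs)


class TestTissueExclusionAndMerge:
    def test_one_sided_tissue_removed(self):
        d_young = _mk(np.ones((4, 2)), "liver", "hep", "young", prefix="y")
        d_old = _mk(np.ones((4, 2)), "liver", "hep", "old", prefix="o")
        d_only_old = _mk(np.ones((3, 2)), "skin", "ker", "old", prefix="s")
        merged = merge_datasets(merge_datasets(d_young, d_old), d_only_old)
        with pytest.warns(UserWarning, match="skin"):
            kept = exclude_unbalanced_tissues(merged)
        assert set(kept.obs["tissue"]) == {"liver"}

    def test_balanced_data_identity(self):
        d_young = _mk(np.ones((4, 2)), "liver", "hep", "young", prefix="y")
        d_old = _mk(np.ones((4, 2)), "liver", "hep", "old", prefix="o")
        merged = merge_datasets(d_young, d_old)
        kept = exclude_unbalanced_tissues(merged)
        pd.testing.assert_frame_equal(kept.calls, merged.calls)

    def test_merge_bookkeeping_130_plus_25(self):
        """130 tissue-cell types over 11 tissues merged with 25 brain cell
        types gives 155 tissue-cell types over 12 tissues."""
        blocks1, blocks2 = [], []
        tissues = [f"tissue{i}" for i in range(11)]
        k = 0
        for u in range(130):
            t = tissues[u % 11]
            blocks1.append(_mk(np.ones((2, 2)), t, f"ct{u}", "young",
                               prefix=f"a{k}_"))
            k += 1
        for u in range(25):
            blocks2.append(_mk(np.ones((2, 2)), "brain", f"brainct{u}", "old",
                               prefix=f"b{k}_"))
            k += 1
        d1 = blocks1[0]
        for b in blocks1[1:]:
            d1 = merge_datasets(d1, b)
        d2 = blocks2[0]
        for b in blocks2[1:]:
            d2 = merge_datasets(d2, b)
        assert d1.n_units() == 130 and d1.n_tissues() == 11
        merged = merge_datasets(d1, d2)
        assert merged.n_units() == 155
        assert merged.n_tissues() == 12

    def test_duplicate_cell_ids_rejected(self):
        d = _mk(np.ones((3, 2)), "liver", "hep", "young")
        with pytest.raises(ValueError, match="duplicate"):
            merge_datasets(d, d)

    def test_merge_with_empty_is_identity(self):
        d = _mk(np.ones((3, 2)), "liver", "hep", "young")
        empty = _mk(np.ones((0, 2)), "x", "y", "young", prefix="e")
        merged = merge_datasets(d, empty)
        pd.testing.assert_frame_equal(merged.calls, d.calls)


class TestFractionsAndFlags:
    def test_three_of_eight(self):
        calls = np.zeros((8, 1))
        calls[:3, 0] = 1
        d = _mk(calls, "t", "ct", "young", genes=["g"])
        f = fraction_positive(d, "g")
        assert f.iloc[0]["fraction"] == pytest.approx(0.375)
        assert f.iloc[0]["n_positive"] == 3 and f.iloc[0]["n_total"] == 8

    def test_fraction_self_consistency(self):
        rng = np.random.default_rng(0)
        d = _mk((rng.random((50, 2)) < 0.3).astype(int), "t", "ct", "old")
        f = fraction_positive(d, "g0")
        assert (f["fraction"] == f["n_positive"] / f["n_total"]).all()

    def test_tie_is_not_an_increase(self):
        f = pd.DataFrame(
            {"tissue": ["t"] * 2, "cell_type": ["ct"] * 2,
             "age_group": ["young", "old"], "gene": "g",
             "fraction": [0.2, 0.2], "n_positive": [2, 2], "n_total": [10, 10]}
        )
        assert not flag_age_increase(f, "g").iloc[0]

    def test_zero_to_positive_is_an_increase(self):
        f = pd.DataFrame(
            {"tissue": ["t"] * 2, "cell_type": ["ct"] * 2,
             "age_group": ["young", "old"], "gene": "g",
             "fraction": [0.0, 0.05], "n_positive": [0, 5], "n_total": [100, 100]}
        )
        assert flag_age_increase(f, "g").iloc[0]

    def test_overlap_counts_31_of_50(self):
        units = pd.MultiIndex.from_tuples(
            [("t", f"ct{i}") for i in range(155)], names=["tissue", "cell_type"]
        )
        gene = pd.Series(False, index=units)
        ref = pd.Series(False, index=units)
        gene.iloc[:50] = True
        ref.iloc[19:109] = True  # 90 reference units; overlap = units 19..49 = 31
        out = overlap_flags(gene, ref)
        assert out["n_gene_flagged"] == 50
        assert out["n_reference_flagged"] == 90
        assert out["n_both"] == 31
        assert out["pct_of_gene_flagged"] == 62.0

    def test_identical_and_disjoint_flags(self):
        idx = pd.MultiIndex.from_tuples([("t", f"c{i}") for i in range(10)])
        a = pd.Series([True] * 5 + [False] * 5, index=idx)
        assert overlap_flags(a, a)["pct_of_gene_flagged"] == 100.0
        assert overlap_flags(a, ~a)["pct_of_gene_flagged"] == 0.0


class TestLor:
    def _unit(self, a, b, c, d):
        calls = np.array(
            [[1, 1]] * a + [[1, 0]] * b + [[0, 1]] * c + [[0, 0]] * d
        )
        return _mk(calls, "t", "ct", "old", genes=["g1", "g2"])

    def test_balanced_table_is_independent(self):
        rec = compute_lor(self._unit(10, 10, 10, 10), "g1", "g2", ("t", "ct"))
        assert rec["lor"] == pytest.approx(0.0)
        assert rec["p_value"] == pytest.approx(1.0)
        assert not rec["corrected"]

    def test_hand_computed_lor_and_enumerated_p(self):
        rec = compute_lor(self._unit(8, 2, 3, 7), "g1", "g2", ("t", "ct"))
        assert rec["lor"] == pytest.approx(math.log(56 / 6), abs=1e-12)
        assert rec["p_value"] == pytest.approx(fisher_enumeration_p(8, 2, 3, 7),
                                               abs=1e-12)

    def test_gene_swap_symmetry(self):
        d = self._unit(5, 9, 2, 14)
        r1 = compute_lor(d, "g1", "g2", ("t", "ct"))
        r2 = compute_lor(d, "g2", "g1", ("t", "ct"))
        assert r1["lor"] == pytest.approx(r2["lor"])
        assert r1["p_value"] == pytest.approx(r2["p_value"])

    def test_zero_cell_gets_haldane_correction(self):
        rec = compute_lor(self._unit(5, 0, 3, 7), "g1", "g2", ("t", "ct"))
        assert rec["corrected"]
        assert rec["lor"] == pytest.approx(
            math.log((5.5 * 7.5) / (0.5 * 3.5)), abs=1e-12
        )
        assert math.isfinite(rec["lor"])

    def test_flip_one_gene_negates_lor(self):
        d = self._unit(8, 2, 3, 7)
        flipped = SingleCellBinary(
            d.calls.assign(g2=1 - d.calls["g2"]), d.obs
        )
        r = compute_lor(d, "g1", "g2", ("t", "ct"))
        rf = compute_lor(flipped, "g1", "g2", ("t", "ct"))
        assert rf["lor"] == pytest.approx(-r["lor"], abs=1e-12)

    def test_log_base_option(self):
        rec2 = compute_lor(self._unit(8, 2, 3, 7), "g1", "g2", ("t", "ct"),
                           log_base=2.0)
        assert rec2["lor"] == pytest.approx(math.log2(56 / 6), abs=1e-12)


class TestFisher:
    def test_two_by_two_identity_table(self):
        # margins (1,1,1,1): both extreme tables equally probable, p = 1
        assert fisher_exact_p(1, 0, 0, 1) == pytest.approx(1.0)

    def test_crossed_table_from_enumeration(self):
        assert fisher_exact_p(0, 5, 5, 0) == pytest.approx(
            fisher_enumeration_p(0, 5, 5, 0), abs=1e-12
        )

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_exact_p(a, b, c, d) == pytest.approx(
            fisher_enumeration_p(a, b, c, d), abs=1e-12
        )

    def test_transpose_and_rowcol_swap_invariance(self):
        p = fisher_exact_p(7, 2, 1, 9)
        assert fisher_exact_p(7, 1, 2, 9) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_p(9, 1, 2, 7) == pytest.approx(p, abs=1e-12)

    def test_rejects_negative_or_fractional(self):
        with pytest.raises(ValueError):
            fisher_exact_p(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            fisher_exact_p(0.5, 0, 0, 1)


class TestParameterRecovery:
    @pytest.mark.parametrize("omega", [0.5, 1.0, 2.0, 4.0])
    def test_mean_lor_recovers_target(self, omega):
        from senesurf.simulate import ScSimConfig, generate_sc_dataset

        lors = []
        for seed in range(20):
            cfg = ScSimConfig(
                seed=seed, tissue_cell_types=(("t", "c"),),
                n_cells_young=5000, n_cells_old=5000,
                p_young=0.15, p_old=0.15, target_or=omega,
                candidate_genes=("PLXNA1",),
            )
            data, _ = generate_sc_dataset(cfg)
            lors.append(compute_lor(data, "PLXNA1", "CDKN2A", ("t", "c"))["lor"])
        assert abs(float(np.mean(lors)) - math.log(omega)) < 0.1
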