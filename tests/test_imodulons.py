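"""Basal transformation, matching, differential activity, DEO calls."""

import numpy as np
import pandas as pd
import pytest

from trn_adapt.errors import InvalidSpecError
from trn_adapt.imodulons import (
    BasalActivity,
    Decomposition,
    ExpressionMatrix,
    assign_direction,
    basal_transform,
    diff_expressed_operons,
    differential_activity,
    explained_variance,
    match_imodulons,
    member_genes,
)
from trn_adapt import synthetic as syn


def _toy_decomposition(n_genes=12, n_imod=3, n_samples=30, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    ims = [f"im{k}" for k in range(n_imod)]
    samples = [f"s{j}" for j in range(n_samples)]
    m = pd.DataFrame(rng.normal(size=(n_genes, n_imod)), index=genes, columns=ims)
    a = pd.DataFrame(rng.normal(size=(n_imod, n_samples)), index=ims, columns=samples)
    return Decomposition(M=m, A=a)


class TestMemberGenes:
    def test_all_zero_column_warns_and_is_empty(self):
        col = pd.Series(np.zeros(5), index=list("abcde"), name="im0")
        with pytest.warns(UserWarning):
            assert member_genes(col) == set()

    def test_dominant_weight_is_captured(self):
        rng = np.random.default_rng(0)
        weights = list(rng.normal(scale=0.05, size=30)) + [5.0]
        genes = [f"g{i}" for i in range(31)]
        col = pd.Series(weights, index=genes, name="im0")
        assert "g30" in member_genes(col)

    def test_matches_direct_threshold(self):
        rng = np.random.default_rng(1)
        col = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        w = col.abs()
        cutoff = w.mean() + 2 * w.std(ddof=0)
        assert member_genes(col) == set(w.index[w > cutoff])


class TestExplainedVariance:
    def test_exact_rank_one_reconstruction_gives_unity(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(8)]
        m = pd.DataFrame({"im0": rng.normal(size=8)}, index=genes)
        a = pd.DataFrame([rng.normal(size=20)], index=["im0"],
                         columns=[f"s{j}" for j in range(20)])
        d = Decomposition(M=m, A=a)
        x = ExpressionMatrix(values=d.reconstruct())
        assert explained_variance(x, d, "im0", genes) == pytest.approx(1.0)

    def test_zero_activity_explains_nothing(self):
        d = _toy_decomposition()
        x = ExpressionMatrix(values=d.reconstruct())
        d.A.loc["im1"] = 0.0
        assert explained_variance(x, d, "im1", list(x.genes)) == pytest.approx(0.0)

    def test_matches_manual_frobenius_computation(self):
        d = _toy_decomposition(seed=5)
        rng = np.random.default_rng(6)
        x_vals = d.reconstruct() + rng.normal(scale=0.5, size=(12, 30))
        x = ExpressionMatrix(values=x_vals)
        genes = list(x.genes)[:7]
        xg = x.values.loc[genes].to_numpy()
        xc = xg - xg.mean(axis=1, keepdims=True)
        recon = np.outer(d.M.loc[genes, "im0"], d.A.loc["im0"])
        rc = recon - recon.mean(axis=1, keepdims=True)
        expected = 1 - np.sum((xc - rc) ** 2) / np.sum(xc**2)
        assert explained_variance(x, d, "im0", genes) == pytest.approx(expected)

    def test_empty_gene_set_rejected(self):
        d = _toy_decomposition()
        x = ExpressionMatrix(values=d.reconstruct())
        with pytest.raises(InvalidSpecError):
            explained_variance(x, d, "im0", [])


class TestAssignDirection:
    def test_ko_at_high_end_means_positive(self):
        row = pd.Series([1.0, 2, 3, 4, 100.0], index=list("abcde"), name="im")
        assert assign_direction(row, ["a", "b", "c", "d"], ko_sample_ids=["e"]) == 1

    def test_ko_at_low_end_means_negative(self):
        row = pd.Series([-50.0, 2, 3, 4, 5], index=list("abcde"), name="im")
        assert assign_direction(row, list("bcde"), ko_sample_ids=["a"]) == -1

    def test_tie_resolves_negative_with_warning(self):
        row = pd.Series([1.0, 2.0, 3.0, 2.0], index=list("abcd"), name="im")
        with pytest.warns(UserWarning):
            assert assign_direction(row, ["a", "b", "c"], ko_sample_ids=["d"]) == -1

    def test_annotation_fallback_and_missing_sources(self):
        row = pd.Series([1.0, 2.0], index=["a", "b"], name="im")
        assert assign_direction(row, ["a"], annotated_direction=1) == 1
        with pytest.raises(InvalidSpecError):
            assign_direction(row, ["a"])


class TestBasalTransform:
    def test_constant_row_maps_to_zero(self):
        d = _toy_decomposition(n_imod=1)
        d.A.loc["im0"] = 7.5
        refs = list(d.A.columns)
        _, b = basal_transform(d, {"im0": -1}, refs)
        assert np.allclose(b.A_basal.loc["im0"], 0.0)

    def test_positive_direction_quantile_arithmetic(self):
        samples = [f"s{j}" for j in range(101)]
        a = pd.DataFrame([np.arange(101.0)], index=["im0"], columns=samples)
        m = pd.DataFrame({"im0": [1.0, 2.0]}, index=["g0", "g1"])
        d = Decomposition(M=m, A=a)
        d2, b = basal_transform(d, {"im0": 1}, samples)
        assert b.offsets["im0"] == pytest.approx(95.0)
        assert b.A_basal.loc["im0", "s100"] == pytest.approx(-5.0)
        assert b.A_basal.loc["im0", "s0"] == pytest.approx(95.0)
        assert np.allclose(d2.M["im0"], -m["im0"])  # sign flip recorded in M

    def test_missing_direction_rejected_and_few_references_warn(self):
        d = _toy_decomposition(n_imod=2)
        refs = list(d.A.columns)
        with pytest.raises(InvalidSpecError):
            basal_transform(d, {"im0": -1}, refs)
        with pytest.warns(UserWarning):
            basal_transform(d, {"im0": -1, "im1": 1}, refs[:5])

    def test_invertible_and_reference_tail_bounded(self):
        d = _toy_decomposition(n_genes=20, n_imod=4, n_samples=60, seed=9)
        refs = list(d.A.columns)[:40]
        directions = {"im0": 1, "im1": -1, "im2": 1, "im3": -1}
        _, b = basal_transform(d, directions, refs)
        back = b.invert()
        assert np.allclose(back.to_numpy(), d.A.to_numpy(), atol=1e-12)
        neg_frac = (b.A_basal[refs] < 0).mean(axis=1)
        assert (neg_frac <= 0.05 + 1 / len(refs)).all()

    def test_reconstruction_identity_holds_for_both_directions(self):
        # M'_k A'_k = M_k (A_k - offset) regardless of direction: the +1
        # branch negates both factors
        d = _toy_decomposition(n_imod=2, seed=3)
        refs = list(d.A.columns)
        d2, b = basal_transform(d, {"im0": 1, "im1": -1}, refs)
        for k in ("im0", "im1"):
            lhs = np.outer(d2.M[k], d2.A.loc[k])
            rhs = np.outer(d.M[k], d.A.loc[k] - b.offsets[k])
            assert np.allclose(lhs, rhs, atol=1e-12)

    def test_idempotent_after_direction_reassessment(self):
        # after the transform, high value = high activity and the reference
        # 5th percentile is exactly zero, so a second pass changes nothing
        study = syn.simulate_study(syn.archetype_spec(seed=2))
        d, x = study.decomposition, study.expression
        refs = x.reference_ids
        truth = study.ground_truth.true_directions
        d2, b1 = basal_transform(d, truth, refs)
        ko_col = x.samples["ko"]
        redirections = {}
        for im in d2.imodulons:
            reg = d2.regulator_of(im)
            ko_ids = list(x.samples.index[ko_col == reg])
            redirections[im] = assign_direction(d2.A.loc[im], refs,
                                                ko_sample_ids=ko_ids or None,
                                                annotated_direction=-1)
        d3, b2 = basal_transform(d2, redirections, refs)
        assert np.allclose(b2.A_basal.to_numpy(), b1.A_basal.to_numpy(), atol=1e-9)


class TestMatchImodulons:
    def test_permutation_recovered_exactly(self):
        d1 = _toy_decomposition(n_genes=15, n_imod=4, seed=12)
        perm = [2, 0, 3, 1]
        m2 = d1.M.iloc[:, perm].copy()
        m2.columns = [f"q{k}" for k in range(4)]
        a2 = d1.A.iloc[perm].copy()
        a2.index = m2.columns
        d2 = Decomposition(M=m2, A=a2)
        table, frac = match_imodulons(d1, d2)
        assert frac == 1.0
        mapping = dict(zip(table["imodulon_1"], table["imodulon_2"]))
        assert mapping == {d1.imodulons[p]: f"q{k}" for k, p in enumerate(perm)}
        assert np.allclose(table["r"].abs(), 1.0)

    def test_sign_flips_do_not_break_matching(self):
        d1 = _toy_decomposition(n_genes=15, n_imod=3, seed=13)
        m2 = -d1.M.copy()
        d2 = Decomposition(M=m2, A=-d1.A.copy())
        table, frac = match_imodulons(d1, d2)
        assert frac == 1.0
        assert np.allclose(table["r"], -1.0)

    def test_small_gene_overlap_rejected(self):
        d1 = _toy_decomposition(n_genes=5)
        with pytest.raises(InvalidSpecError):
            match_imodulons(d1, d1)


class TestDifferentialActivity:
    @staticmethod
    def _basal(values: np.ndarray) -> BasalActivity:
        a = pd.DataFrame(values, index=[f"im{i}" for i in range(values.shape[0])],
                         columns=[f"s{j}" for j in range(values.shape[1])])
        return BasalActivity(A_basal=a, directions={}, offsets={})

    def test_identical_groups_flag_nothing(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 12))
        vals[:, 6:] = vals[:, :6]
        b = self._basal(vals)
        res = differential_activity(b, [f"s{j}" for j in range(6)],
                                    [f"s{j}" for j in range(6, 12)],
                                    n_permutations=300, seed=1)
        assert not res["flagged"].any()

    def test_overlapping_groups_rejected(self):
        b = self._basal(np.zeros((2, 6)))
        with pytest.raises(InvalidSpecError):
            differential_activity(b, ["s0", "s1"], ["s1", "s2"])

    def test_large_shift_detected_with_high_power(self):
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            vals = rng.normal(scale=1.0, size=(5, 12))
            vals[2, 6:] += 10.0  # ten within-group sds
            b = self._basal(vals)
            res = differential_activity(b, [f"s{j}" for j in range(6)],
                                        [f"s{j}" for j in range(6, 12)],
                                        n_permutations=400, seed=seed)
            hits += bool(res.loc["im2", "flagged"])
        assert hits >= int(0.95 * n_rep)

    def test_null_flag_rate_within_fdr(self):
        flags = total = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            vals = rng.normal(size=(8, 12))
            b = self._basal(vals)
            res = differential_activity(b, [f"s{j}" for j in range(6)],
                                        [f"s{j}" for j in range(6, 12)],
                                        n_permutations=300, seed=seed)
            flags += int(res["flagged"].sum())
            total += len(res)
        assert flags / total <= 0.05


class TestDiffExpressedOperons:
    @staticmethod
    def _expression(shift_genes=(), shift=0.0, noise=0.1, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(9)]
        cols = [f"a{j}" for j in range(3)] + [f"b{j}" for j in range(3)]
        base = rng.normal(5.0, 1.0, size=(9, 1))
        vals = base + rng.normal(scale=noise, size=(9, 6))
        x = pd.DataFrame(vals, index=genes, columns=cols)
        for g in shift_genes:
            x.loc[g, ["a0", "a1", "a2"]] += shift
        return ExpressionMatrix(values=x)

    OPERONS = {f"g{i}": f"op{i // 3}" for i in range(9)}

    def test_identical_conditions_yield_no_calls(self):
        x = self._expression()
        x.values[["b0", "b1", "b2"]] = x.values[["a0", "a1", "a2"]].to_numpy()
        res = diff_expressed_operons(x, self.OPERONS, ["a0", "a1", "a2"],
                                     ["b0", "b1", "b2"])
        assert not res["de"].any()

    def test_shifted_operon_detected(self):
        x = self._expression(shift_genes=("g3", "g4", "g5"), shift=4.0)
        res = diff_expressed_operons(x, self.OPERONS, ["a0", "a1", "a2"],
                                     ["b0", "b1", "b2"])
        assert bool(res.loc["op1", "de"])
        assert not res.drop("op1")["de"].any()

    def test_operon_fold_change_is_mean_of_gene_fold_changes(self):
        x = self._expression(seed=4)
        res = diff_expressed_operons(x, self.OPERONS, ["a0", "a1", "a2"],
                                     ["b0", "b1", "b2"])
        genes = ["g0", "g1", "g2"]
        lfcs = [
            x.values.loc[g, ["a0", "a1", "a2"]].mean()
            - x.values.loc[g, ["b0", "b1", "b2"]].mean()
            for g in genes
        ]
        assert res.loc["op0", "log2fc"] == pytest.approx(np.mean(lfcs))

    def test_unmeasured_operon_skipped_with_warning(self):
        x = self._expression()
        operons = dict(self.OPERONS, ghost="op_ghost")
        with pytest.warns(UserWarning):
            res = diff_expressed_operons(x, operons, ["a0", "a1", "a2"],
                                         ["b0", "b1", "b2"])
        assert "op_ghost" not in res.index
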