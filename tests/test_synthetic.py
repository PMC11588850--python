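"""Ground-truth structure and determinism of the synthetic-study generators."""

import numpy as np
import pandas as pd
import pytest

from trn_adapt.errors import InvalidSpecError
from trn_adapt import synthetic as syn


class TestSpecValidation:
    def test_zero_tfs_rejected(self):
        with pytest.raises(InvalidSpecError):
            syn.generate_trn(syn.SyntheticStudySpec(n_tfs=0))

    def test_more_tfs_than_genes_rejected(self):
        with pytest.raises(InvalidSpecError):
            syn.generate_trn(syn.SyntheticStudySpec(n_tfs=10, n_genes=5))

    def test_more_imodulons_than_tfs_rejected(self):
        spec = syn.SyntheticStudySpec(n_tfs=3, n_genes=10, n_imodulons=5)
        with pytest.raises(InvalidSpecError):
            syn.generate_trn(spec)

    def test_density_out_of_range_rejected(self):
        with pytest.raises(InvalidSpecError):
            syn.generate_trn(syn.SyntheticStudySpec(tf_target_density=1.5))

    def test_too_few_control_wells_rejected(self):
        with pytest.raises(InvalidSpecError):
            syn.generate_plate(syn.PlateSpec(n_control_wells=1))


class TestGenerateTrn:
    def test_complete_bipartite_when_density_one(self):
        spec = syn.SyntheticStudySpec(
            n_tfs=2, n_genes=3, tf_target_density=1.0, tf_tf_density=0.0,
            sole_target_fraction=0.0, p_repression=0.0, p_dual=0.0,
            n_imodulons=1,
        )
        trn = syn.generate_trn(spec)
        assert len(trn.records) == 6
        assert set(trn.records["effect"]) == {"activation"}
        per_gene = trn.records.groupby("target")["regulator"].nunique()
        assert (per_gene == 2).all()

    def test_seeded_runs_are_identical(self):
        spec = syn.SyntheticStudySpec(seed=1)
        a = syn.generate_trn(spec)
        b = syn.generate_trn(spec)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_no_self_loops(self):
        trn = syn.generate_trn(syn.SyntheticStudySpec(tf_tf_density=0.5, seed=3))
        assert not (trn.records["regulator"] == trn.records["target"]).any()

    def test_hub_tfs_have_five_times_median_out_degree(self):
        spec = syn.SyntheticStudySpec(hub_tfs=("tf002",), seed=5)
        trn = syn.generate_trn(spec)
        outdeg = trn.records.groupby("regulator")["target"].nunique()
        outdeg = outdeg.reindex(spec.tf_ids, fill_value=0)
        assert outdeg["tf002"] >= 5 * outdeg.median()

    def test_some_genes_have_exactly_one_regulator(self):
        trn = syn.generate_trn(syn.SyntheticStudySpec(seed=7))
        per_gene = trn.records.groupby("target")["regulator"].nunique()
        assert (per_gene == 1).sum() >= 1


class TestExpressionAndDecomposition:
    def test_noiseless_reconstruction_is_exact_and_low_rank(self):
        spec = syn.SyntheticStudySpec(noise_sd=0.0, seed=2, n_imodulons=6)
        trn = syn.generate_trn(spec)
        x, d, _ = syn.generate_expression_and_decomposition(spec, trn)
        recon = d.reconstruct()
        assert np.allclose(x.values.to_numpy(), recon.to_numpy(), atol=1e-12)
        assert np.linalg.matrix_rank(x.values.to_numpy(), tol=1e-8) <= 6

    def test_ko_samples_sit_at_the_no_activity_extreme(self):
        kos = (syn.KnockoutSpec("tf001", 5.0), syn.KnockoutSpec("tf002", 5.0))
        spec = syn.SyntheticStudySpec(seed=4, ko_specs=kos)
        trn = syn.generate_trn(spec)
        x, d, truth = syn.generate_expression_and_decomposition(spec, trn)
        for ks in kos:
            im = truth.imodulon_of_regulator[ks.regulator]
            row = d.A.loc[im]
            ko_ids = x.samples.index[x.samples["ko"] == ks.regulator]
            extreme = row.min() if truth.true_directions[im] == -1 else row.max()
            assert np.allclose(row[ko_ids], extreme)

    def test_residual_matches_declared_noise_scale(self):
        # at 500 genes x 300 samples the empirical rms residual pins the
        # noise sd to within a few percent
        spec = syn.SyntheticStudySpec(
            n_tfs=20, n_genes=480, n_reference_samples=296, noise_sd=0.25, seed=6,
        )
        trn = syn.generate_trn(spec)
        x, d, _ = syn.generate_expression_and_decomposition(spec, trn)
        resid = x.values.to_numpy() - d.reconstruct().to_numpy()
        rms = np.linalg.norm(resid) / np.sqrt(resid.size)
        assert rms == pytest.approx(0.25, rel=0.10)

    def test_unlinked_knockout_regulator_rejected(self):
        kos = (syn.KnockoutSpec("tf019", 5.0),)
        spec = syn.SyntheticStudySpec(seed=1, n_imodulons=5, ko_specs=kos)
        trn = syn.generate_trn(spec)
        with pytest.raises(InvalidSpecError):
            syn.generate_expression_and_decomposition(spec, trn)


class TestGroundTruthConsistency:
    def test_archetype_categories_follow_construction(self, archetype_study):
        truth = archetype_study.ground_truth
        assert truth.true_category == {
            "tf001": "i", "tf002": "ii", "tf003": "iii", "tf004": "iv",
        }
        # category iii's convergent gene lies inside its regulon
        regulon = archetype_study.trn.targets_of("tf003")
        assert truth.true_convergent_genes["tf003"] <= regulon
        # category i's wildtype basal activity is (near) zero
        assert truth.wt_basal_activity["tf001"] < truth.activity_thresholds["tf001"]

    def test_category_ii_convergence_is_outside_the_regulon(self, archetype_study):
        truth = archetype_study.ground_truth
        regulon = archetype_study.trn.targets_of("tf002") | {"tf002"}
        assert not (truth.true_convergent_genes["tf002"] & regulon)


class TestGeneratePlate:
    def test_null_plate_has_no_systematic_growth(self):
        spec = syn.PlateSpec(growth_effect=0.0, noise_sd=1.0)
        plate, truth = syn.generate_plate(spec, seed=0)
        tested = plate.signal.loc[plate.tested_ids].to_numpy()
        controls = plate.signal.loc[plate.control_ids].to_numpy()
        assert abs(tested.mean() - controls.mean()) < 0.5

    def test_noiseless_growth_wells_exceed_control_maximum(self):
        spec = syn.PlateSpec(n_wells=20, n_control_wells=3, growth_effect=30,
                             noise_sd=0.0)
        plate, truth = syn.generate_plate(spec, seed=1)
        ctrl_max = plate.signal.loc[plate.control_ids].to_numpy().max()
        for well, substrate in plate.wells.loc[plate.tested_ids, "substrate"].items():
            well_max = plate.signal.loc[well].max()
            if truth[substrate]:
                assert well_max > ctrl_max
            else:
                assert well_max == pytest.approx(ctrl_max)

    def test_seeded_traces_identical(self):
        spec = syn.PlateSpec()
        p1, _ = syn.generate_plate(spec, seed=9)
        p2, _ = syn.generate_plate(spec, seed=9)
        pd.testing.assert_frame_equal(p1.signal, p2.signal)


class TestGenerateMutations:
    def test_full_convergence_rate_hits_every_lineage(self):
        kos = (syn.KnockoutSpec("tf001", 5.0, convergent_genes=("g0001",),
                                n_lineages=6, convergence_rate=1.0),)
        spec = syn.SyntheticStudySpec(seed=3, ko_specs=kos,
                                      background_mutation_rate=0.0)
        t = syn.generate_mutation_tables(spec)
        iso = t.records[(t.records["sample_type"] == "isolate")
                        & (t.records["gene"] == "g0001")]
        assert iso["lineage"].nunique() == 6

    def test_no_background_and_no_convergence_gives_empty_table(self):
        kos = (syn.KnockoutSpec("tf001", 5.0),)
        spec = syn.SyntheticStudySpec(seed=3, ko_specs=kos,
                                      background_mutation_rate=0.0)
        t = syn.generate_mutation_tables(spec)
        assert t.records.empty

    def test_frequencies_lie_in_unit_interval(self, archetype_study):
        freq = archetype_study.mutations.records["frequency"].astype(float)
        assert ((freq > 0) & (freq <= 1)).all()

    def test_empty_ko_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            syn.generate_mutation_tables(syn.SyntheticStudySpec())


class TestGrowthImpactsAndRates:
    def test_impacts_in_unit_interval(self, archetype_study):
        vals = archetype_study.growth_impacts.impacts
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_zero_high_impact_fraction_caps_impacts(self):
        spec = syn.SyntheticStudySpec(seed=2, high_impact_fraction=0.0)
        trn = syn.generate_trn(spec)
        impacts = syn.generate_growth_impacts(trn, spec)
        assert impacts.impacts.max() < 0.5

    def test_seeded_determinism(self):
        spec = syn.SyntheticStudySpec(seed=8)
        trn = syn.generate_trn(spec)
        a = syn.generate_growth_impacts(trn, spec)
        b = syn.generate_growth_impacts(trn, spec)
        pd.testing.assert_series_equal(a.impacts, b.impacts)

    def test_recovery_flag_drives_evolved_rate(self, archetype_study):
        rates = archetype_study.growth_rates
        assert rates.loc["tf001", "evolved_relative_rate"] >= 0.95
        assert rates.loc["tf004", "evolved_relative_rate"] < 0.95


class TestStudyBundle:
    def test_write_emits_every_artifact(self, archetype_study, tmp_path):
        paths = archetype_study.write(tmp_path / "study")
        expected = {"regulon", "expression", "samples", "m", "a", "annotations",
                    "mutations", "growth_impacts", "growth_rates", "ground_truth"}
        assert expected <= set(paths)
        for p in paths.values():
            assert (tmp_path / "study").exists()
            assert len(open(p, "rb").read()) > 0

    def test_writes_are_byte_identical_across_runs(self, tmp_path):
        spec = syn.archetype_spec(seed=21)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        syn.simulate_study(spec).write(d1)
        syn.simulate_study(spec).write(d2)
        for p1 in sorted(d1.iterdir()):
            p2 = d2 / p1.name
            assert p1.read_bytes() == p2.read_bytes()
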