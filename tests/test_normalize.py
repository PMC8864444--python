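import numpy as np
import pandas as pd
import pytest

from metascreen import normalize
from metascreen.screen_io import ScreenTable, ScreenError


def make_table(values, plate="P1", od=None, inj=None, tclass=None, tid=None,
               dose=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sids = [f"s{i}" for i in range(n)]
    intens = pd.DataFrame(values, index=sids,
                          columns=[f"ion{j}" for j in range(m)])
    plates = [plate] * n if isinstance(plate, str) else list(plate)
    meta = pd.DataFrame(
        {
            "plate_id": plates,
            "batch_id": plates,
            "injection_index": inj if inj is not None else _per_batch_index(plates),
            "od600": od if od is not None else 1.0,
            "treatment_class": tclass if tclass is not None else "drug",
            "treatment_id": tid if tid is not None else "d1",
            "dose": dose if dose is not None else 10.0,
            "timepoint": 0.5,
            "genotype": "WT",
            "replicate": 1,
        },
        index=sids,
    )
    return ScreenTable(intens, meta)


def _per_batch_index(plates):
    seen = {}
    out = []
    for p in plates:
        out.append(seen.get(p, 0))
        seen[p] = out[-1] + 1
    return out


class TestOutlierFilter:
    def test_identical_samples_keep_everything(self):
        table = make_table(np.ones((6, 3)) * 5)
        out, report = normalize.filter_outlier_samples(table, 4.0)
        assert out.n_samples == 6
        assert report.samples_removed == []

    def test_extreme_tic_sample_removed(self):
        vals = np.ones((6, 3)) * 10
        vals[5] = 1000  # TIC 100x the plate median
        vals[np.arange(5), 0] += np.linspace(0, 0.4, 5)  # nonzero MAD
        table = make_table(vals)
        out, report = normalize.filter_outlier_samples(table, 4.0)
        assert ("s5", "tic_outlier") in report.samples_removed
        assert "s5" not in out.sample_ids

    def test_od_outlier_removed_with_reason(self):
        od = [1.0, 1.01, 0.99, 1.02, 0.98, 3.0]
        table = make_table(np.ones((6, 3)), od=od)
        out, report = normalize.filter_outlier_samples(table, 4.0)
        assert ("s5", "od600_outlier") in report.samples_removed

    def test_infinite_multiplier_is_identity(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.lognormal(10, 1, (8, 4)))
        out, report = normalize.filter_outlier_samples(table, np.inf)
        assert out.sample_ids == table.sample_ids

    def test_small_plate_skipped_with_message(self):
        table = make_table(np.ones((3, 3)))
        out, report = normalize.filter_outlier_samples(table, 4.0)
        assert out.n_samples == 3
        assert any("fewer than 4" in m for m in report.messages)


class TestArtifactIons:
    def test_empty_list_is_identity(self):
        table = make_table(np.ones((4, 3)))
        out, _ = normalize.remove_drug_artifact_ions(table, [])
        assert out.ion_ids == table.ion_ids

    def test_present_ions_dropped_absent_warned(self):
        table = make_table(np.ones((4, 4)))
        with pytest.warns(UserWarning, match="ionX"):
            out, report = normalize.remove_drug_artifact_ions(
                table, ["ion1", "ionX"]
            )
        assert out.n_ions == 3
        assert ("ion1", "drug_artifact") in report.ions_removed


class TestDriftCorrection:
    def test_constant_signal_is_untouched(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(100, 200, 5)
        table = make_table(np.tile(base, (24, 1)))
        out, _ = normalize.correct_injection_drift(table, 0.3)
        assert np.allclose(out.intensities.to_numpy(),
                           table.intensities.to_numpy(), rtol=1e-6)

    def test_planted_linear_drift_removed_exactly_without_noise(self):
        n = 48
        inj = np.arange(n)
        vals = 1000.0 + 5.0 * inj[:, None] * np.ones((1, 3))
        table = make_table(vals, inj=list(inj))
        out, report = normalize.correct_injection_drift(table, 0.3)
        # local linear smoothing reproduces a line exactly: residual trend is
        # numerical dust, far below the 5 units/injection planted drift
        resid = out.intensities.to_numpy() - np.median(vals, axis=0)
        assert np.abs(resid).max() < 1e-6

    def test_planted_drift_removed_under_noise(self):
        rng = np.random.default_rng(8)
        n = 96
        inj = np.arange(n)
        drift = 5.0 * inj + 40.0 * np.sin(2 * np.pi * inj / n)
        vals = 1000.0 + drift[:, None] + rng.normal(0, 3.0, (n, 4))
        table = make_table(vals, inj=list(inj))
        out, report = normalize.correct_injection_drift(table, 0.3)
        # the drift (amplitude ~ 500 units) collapses to near the noise floor
        resid_sd = out.intensities.std(axis=0)
        assert (resid_sd < 10.0).all()
        assert report.drift_after["P1"] < 0.5 * report.drift_before["P1"]

    def test_batch_medians_aligned_to_global(self):
        vals = np.concatenate([np.full((10, 2), 100.0), np.full((10, 2), 200.0)])
        vals[:, 1] += np.tile(np.linspace(-1, 1, 10), 2)  # small spread
        plates = ["A"] * 10 + ["B"] * 10
        table = make_table(vals, plate=plates)
        out, _ = normalize.correct_injection_drift(table, 0.6)
        med_a = out.intensities.iloc[:10].median()
        med_b = out.intensities.iloc[10:].median()
        assert np.allclose(med_a, med_b, atol=1e-8)


class TestBiomassCorrection:
    def test_no_od_dependence_gives_zero_slopes(self):
        rng = np.random.default_rng(2)
        table = make_table(np.tile(rng.uniform(50, 60, 4), (12, 1)),
                           od=list(rng.normal(1, 0.1, 12)))
        out, report = normalize.correct_biomass(table)
        assert np.allclose(list(report.od_slopes.values()), 0.0, atol=1e-9)
        assert np.allclose(out.intensities, table.intensities)

    def test_residuals_orthogonal_to_od(self):
        rng = np.random.default_rng(3)
        od = rng.normal(1, 0.1, 20)
        vals = 10.0 * od[:, None] + rng.normal(0, 0.01, (20, 3))
        table = make_table(vals, od=list(od))
        out, _ = normalize.correct_biomass(table)
        for ion in out.ion_ids:
            r = np.corrcoef(out.intensities[ion], od)[0, 1]
            assert abs(r) < 1e-10

    def test_single_sample_rejected(self):
        table = make_table(np.ones((1, 2)))
        with pytest.raises(ScreenError):
            normalize.correct_biomass(table)

    def test_constant_od_is_noop_with_warning(self):
        table = make_table(np.arange(12.0).reshape(6, 2), od=[1.0] * 6)
        with pytest.warns(UserWarning, match="constant OD600"):
            out, _ = normalize.correct_biomass(table)
        assert np.allclose(out.intensities, table.intensities)


class TestZScore:
    def test_plate_zscores_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        plates = ["A"] * 8 + ["B"] * 8
        table = make_table(rng.lognormal(5, 1, (16, 5)), plate=plates)
        out, _ = normalize.zscore_plate(table)
        for _, idx in out.meta.groupby("plate_id").groups.items():
            sub = out.intensities.loc[idx]
            assert np.allclose(sub.mean(axis=0), 0.0, atol=1e-9)
            assert np.allclose(sub.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_hand_example_sample_sd_convention(self):
        table = make_table(np.array([[1.0], [2.0], [3.0]]))
        out, _ = normalize.zscore_plate(table)
        assert np.allclose(out.intensities["ion0"], [-1.0, 0.0, 1.0])

    def test_constant_ion_flagged_zero_variance(self):
        vals = np.column_stack([np.ones(5), np.arange(5.0)])
        table = make_table(vals)
        out, report = normalize.zscore_plate(table)
        assert out.intensities["ion0"].isna().all()
        assert ("ion0", "zero_variance") in report.ions_removed

    def test_single_sample_plate_rejected(self):
        table = make_table(np.ones((1, 2)))
        with pytest.raises(ScreenError):
            normalize.zscore_plate(table)

    def test_control_scheme_hand_example(self):
        # controls (10, 12, 14): mean 12, sample sd 2; treated 16 -> z = 2
        vals = np.array([[10.0], [12.0], [14.0], [16.0]])
        tclass = ["wt_control"] * 3 + ["overexpression"]
        table = make_table(vals, tclass=tclass, tid=["WT"] * 3 + ["G1"],
                           dose=[0.0, 0.0, 0.0, 100.0])
        out, _ = normalize.zscore_vs_control(table)
        assert out.intensities.loc["s3", "ion0"] == pytest.approx(2.0)
        assert np.allclose(out.intensities.iloc[:3, 0].mean(), 0.0, atol=1e-9)

    def test_missing_controls_error_names_plate(self):
        table = make_table(np.ones((4, 2)))
        with pytest.raises(ScreenError, match="P1"):
            normalize.zscore_vs_control(table)


class TestAverage:
    def make_replicated(self):
        vals = np.array([[1.0, 5.0], [3.0, 7.0], [2.0, 2.0], [2.0, 2.0]])
        return make_table(vals, tid=["d1", "d1", "d2", "d2"],
                          inj=[0, 1, 2, 3])

    def test_replicates_average(self):
        table = self.make_replicated()
        prof = normalize.restrict_and_average(table, restrict=False)
        key = ("drug", "d1", 10.0, 0.5)
        assert prof.values.loc[key, "ion0"] == 2.0
        assert prof.values.loc[key, "ion1"] == 6.0
        assert prof.n_replicates[key] == 2

    def test_restriction_limits_ion_count(self):
        table = self.make_replicated()
        ann = pd.DataFrame(
            {"ion_id": ["ion0", "ion1"], "compound_id": ["c0", "c1"],
             "is_organism_compound": [True, False]}
        )
        prof = normalize.restrict_and_average(table, ann, restrict=True)
        assert prof.ion_ids == ["ion0"]

    def test_profile_frame_round_trip(self):
        table = self.make_replicated()
        prof = normalize.restrict_and_average(table, restrict=False)
        back = normalize.ProfileMatrix.from_frame(prof.to_frame())
        pd.testing.assert_frame_equal(back.values, prof.values)


class TestFoldChanges:
    def make_fc_table(self):
        vals = np.array([[8.0, 2.0], [8.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        return make_table(
            vals,
            tclass=["drug", "drug", "vehicle_control", "vehicle_control"],
            tid=["d1", "d1", "DMSO", "DMSO"],
            dose=[10.0, 10.0, 0.0, 0.0],
        )

    def test_fourfold_ion_gives_log2_of_two(self):
        prof = normalize.log2_fold_changes(self.make_fc_table())
        key = ("drug", "d1", 10.0, 0.5)
        assert prof.values.loc[key, "ion0"] == pytest.approx(2.0)
        assert prof.values.loc[key, "ion1"] == pytest.approx(0.0)

    def test_nonpositive_reference_is_missing(self):
        table = self.make_fc_table()
        table.intensities.loc[["s2", "s3"], "ion0"] = 0.0
        prof = normalize.log2_fold_changes(table)
        assert np.isnan(prof.values.iloc[0]["ion0"])


def test_full_chain_recovers_planted_effect_pattern(small_params):
    """With artifacts off and tiny measurement noise, the normalized induced
    profile ranks ions exactly as the true effect vector does."""
    import dataclasses

    from metascreen import match, simulate

    params = dataclasses.replace(
        small_params, drift_amplitude=0.0, od_effect_scale=0.0, noise_cv=0.01,
        doses=[0.0, 1e7], seed=5,
    )
    truth = simulate.generate_truth(params)
    screen = simulate.simulate_oe_screen(truth, params)
    from metascreen import PipelineConfig

    cfg = PipelineConfig(mad_multiplier=float("inf"))  # near-noiseless fixture
    prof, _ = normalize.normalize_screen(screen, None, cfg, scheme="control",
                                         restrict=False)
    gene = truth.genes[0]
    profile = prof.profile("overexpression", gene, dose=1e7)
    v = truth.gene_effects.loc[gene]
    support = v[v != 0].index
    rho = match.similarity(profile[support], v[support], "spearman",
                           min_overlap=2)
    # drift/biomass detrending of randomized-order screens mildly attenuates
    # condition effects, so perfect rank agreement is not expected even here
    assert rho > 0.8
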