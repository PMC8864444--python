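import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metascreen import single_dose
from metascreen.single_dose import KnownInteraction, pooled_roc, signed_score
from tests import oracles


class TestSignedScore:
    @pytest.mark.parametrize(
        "sim,mode,state,expected",
        [
            (0.4, "agonist", "induced", 0.4),
            (0.4, "antagonist", "induced", -0.4),
            (-0.3, "antagonist", "uninduced", -0.3),
            (-0.3, "agonist", "uninduced", 0.3),
        ],
    )
    def test_sign_conventions(self, sim, mode, state, expected):
        assert signed_score(sim, mode, state) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=-1, max_value=1))
    def test_agonist_antagonist_antisymmetry(self, sim):
        for state in ("induced", "uninduced"):
            assert signed_score(sim, "agonist", state) == pytest.approx(
                -signed_score(sim, "antagonist", state)
            )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            signed_score(0.1, "inverse_agonist", "induced")


class TestRankings:
    def make_profiles(self, sims_by_drug):
        from metascreen.normalize import ProfileMatrix

        rng = np.random.default_rng(0)
        ions = [f"ion{i}" for i in range(40)]
        target = rng.normal(0, 1, 40)
        rows, keys = [], []
        for drug, wanted in sims_by_drug.items():
            noise = rng.normal(0, 1, 40)
            noise -= noise @ target / (target @ target) * target
            vec = wanted * target / np.linalg.norm(target) + np.sqrt(
                max(1 - wanted**2, 1e-9)
            ) * noise / np.linalg.norm(noise)
            rows.append(vec)
            keys.append(("drug", drug, 10.0, 0.5))
        idx = pd.MultiIndex.from_tuples(
            keys, names=["treatment_class", "treatment_id", "dose", "timepoint"]
        )
        profiles = ProfileMatrix(pd.DataFrame(rows, index=idx, columns=ions),
                                 pd.Series(2, index=idx))
        return pd.Series(target, index=ions), profiles

    def test_descending_order_with_alphabetical_ties(self):
        target, profiles = self.make_profiles({"a": 0.2, "b": 0.9, "c": -0.1})
        ranked = single_dose.rank_drugs_per_gene(target, profiles, "cosine")
        assert [d for d, _ in ranked] == ["b", "a", "c"]
        # exact ties break alphabetically
        ranked_tie = sorted([("b", 0.5), ("a", 0.5)], key=lambda p: (-p[1], p[0]))
        assert [d for d, _ in ranked_tie] == ["a", "b"]


class TestPooledRoc:
    def rankings_of(self, scores):
        return {"G1": [(f"d{i}", s) for i, s in enumerate(scores)]}

    def test_top_ranked_positives_give_auc_one(self):
        rankings = {
            "G1": [("p1", 0.9), ("n1", 0.5), ("n2", 0.3)],
            "G2": [("p2", 0.8), ("n3", 0.2), ("n4", 0.1)],
        }
        known = [KnownInteraction("G1", "p1", "agonist"),
                 KnownInteraction("G2", "p2", "agonist")]
        roc = pooled_roc(known, rankings, "induced")
        assert roc.auc == pytest.approx(1.0)
        assert roc.points[0] == pytest.approx([0.0, 0.0])
        assert roc.points[-1] == pytest.approx([1.0, 1.0])
        assert np.all(np.diff(roc.points, axis=0) >= 0)

    def test_auc_matches_pair_counting_oracle(self):
        # pos scores (0.9, 0.7, 0.3), neg (0.8, 0.6, 0.4, 0.2, 0.1): the
        # pooled AUC equals brute-force concordant-pair counting, 11/15
        scores = {"p0": 0.9, "p1": 0.7, "p2": 0.3,
                  "n0": 0.8, "n1": 0.6, "n2": 0.4, "n3": 0.2, "n4": 0.1}
        rankings = {"G1": sorted(scores.items(), key=lambda p: -p[1])}
        known = [KnownInteraction("G1", d, "agonist") for d in ("p0", "p1", "p2")]
        roc = pooled_roc(known, rankings, "induced")
        expected = oracles.auc_pair_counting([0.9, 0.7, 0.3],
                                             [0.8, 0.6, 0.4, 0.2, 0.1])
        assert expected == pytest.approx(11 / 15)  # 5 + 4 + 2 concordant, no ties
        assert roc.auc == pytest.approx(expected, abs=1e-12)

    def test_auc_with_ties_counts_half(self):
        scores = {"p0": 0.8, "p1": 0.4, "n0": 0.8, "n1": 0.4, "n2": 0.1}
        rankings = {"G1": sorted(scores.items(), key=lambda p: (-p[1], p[0]))}
        known = [KnownInteraction("G1", d, "agonist") for d in ("p0", "p1")]
        roc = pooled_roc(known, rankings, "induced")
        expected = oracles.auc_pair_counting([0.8, 0.4], [0.8, 0.4, 0.1])
        assert roc.auc == pytest.approx(expected, abs=1e-12)

    def test_null_positives_give_auc_half(self):
        # positives drawn from the same score distribution as negatives:
        # mean AUC over 500 draws is 0.5 within binomial noise
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(500):
            sims = rng.uniform(0, 1, 40)  # nonnegative: |s| == s == signed
            rankings = {"G1": [(f"d{i}", s) for i, s in enumerate(sims)]}
            pos = rng.choice(40, 4, replace=False)
            known = [KnownInteraction("G1", f"d{i}", "agonist") for i in pos]
            aucs.append(pooled_roc(known, rankings, "induced").auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.03

    def test_missing_gene_is_an_error(self):
        known = [KnownInteraction("GX", "d1", "agonist")]
        with pytest.raises(Exception, match="GX"):
            pooled_roc(known, {"G1": [("d1", 0.5)]}, "induced")


class TestSignificantMetabolites:
    def make_table(self, drug_vals, veh_vals):
        from metascreen.screen_io import ScreenTable

        drug_vals = np.asarray(drug_vals, float)
        veh_vals = np.asarray(veh_vals, float)
        vals = np.vstack([drug_vals, veh_vals])
        n_d = len(drug_vals)
        sids = [f"s{i}" for i in range(len(vals))]
        meta = pd.DataFrame(
            {
                "plate_id": "P1", "batch_id": "P1",
                "injection_index": range(len(vals)), "od600": 1.0,
                "treatment_class": ["drug"] * n_d
                + ["vehicle_control"] * len(veh_vals),
                "treatment_id": ["dX"] * n_d + ["DMSO"] * len(veh_vals),
                "dose": [10.0] * n_d + [0.0] * len(veh_vals),
                "timepoint": 0.5, "genotype": "WT", "replicate": 1,
            },
            index=sids,
        )
        cols = [f"ion{j}" for j in range(vals.shape[1])]
        return ScreenTable(pd.DataFrame(vals, index=sids, columns=cols), meta)

    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (4, 10))
        table = self.make_table(base, base)
        assert single_dose.count_significant_metabolites(table, "dX") == 0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        veh = rng.normal(0, 1, (4, 10))
        drug = rng.normal(0, 1, (4, 10))
        drug[:, 0] += 10.0
        table = self.make_table(drug, veh)
        assert single_dose.count_significant_metabolites(table, "dX") >= 1

    def test_missing_controls_rejected(self):
        table = self.make_table(np.zeros((4, 5)), np.zeros((1, 5)))
        with pytest.raises(Exception):
            single_dose.count_significant_metabolites(table, "dX")


class TestTop20:
    def test_single_gene_counts(self):
        rng = np.random.default_rng(4)
        rankings = {"G1": [(f"d{i}", s) for i, s in
                           enumerate(rng.uniform(-1, 1, 50))]}
        counts, hist = single_dose.tabulate_top20(rankings)
        counted = {d for d, c in counts.items() if c > 0}
        assert len(counted) == 20
        assert all(counts[d] == 1 for d in counted)
        assert hist[1] == 20 and hist[0] == 30

    def test_counts_conserved_across_genes(self):
        rng = np.random.default_rng(5)
        rankings = {
            f"G{g}": [(f"d{i}", s) for i, s in enumerate(rng.uniform(-1, 1, 60))]
            for g in range(5)
        }
        counts, _ = single_dose.tabulate_top20(rankings)
        assert sum(counts.values()) == 20 * 5

    def test_top_selection_uses_absolute_similarity(self):
        rankings = {"G1": [("pos", 0.3), ("neg", -0.9)] +
                    [(f"d{i}", 0.01 * i) for i in range(30)]}
        counts, _ = single_dose.tabulate_top20(rankings)
        assert counts["neg"] == 1

    def test_eligibility_filter_and_short_gene_warns(self):
        rankings = {"G1": [(f"d{i}", 0.1 * i) for i in range(10)]}
        with pytest.warns(UserWarning, match="eligible"):
            counts, _ = single_dose.tabulate_top20(
                rankings, eligible_drugs={"d1", "d2"}
            )
        assert set(d for d, c in counts.items() if c > 0) == {"d1", "d2"}


def test_planted_agonist_ranks_first_in_clean_conditions():
    """A noiseless planted agonist matches its induced gene profile better
    than any background drug."""
    from metascreen import normalize, simulate

    params = simulate.SimulationParams(
        n_genes=6, n_drugs=20, n_ions=80, n_planted=3, timepoints=(1.5,),
        drift_amplitude=0.0, od_effect_scale=0.0,
        noise_cv=0.02, seed=21, antagonist_fraction=0.0,
    )
    truth = simulate.generate_truth(params)
    # single saturating inducer concentration, as in a one-dose design
    oe = simulate.simulate_oe_screen(truth, params, doses=[0.0, 1e7])
    dr = simulate.simulate_drug_screen(truth, params)
    from metascreen import PipelineConfig

    cfg = PipelineConfig(mad_multiplier=float("inf"))  # near-noiseless fixture
    oe_prof, _ = normalize.normalize_screen(oe, None, cfg, scheme="control",
                                            restrict=False)
    dr_prof, _ = normalize.normalize_screen(dr, None, cfg, scheme="plate",
                                            restrict=False)
    rankings = single_dose.rankings_from_profiles(oe_prof, dr_prof, "induced")
    top_hits = 0
    for pair in truth.pairs:
        ranked = rankings[pair.gene]
        if ranked[0][0] == pair.drug:
            top_hits += 1
    assert top_hits >= 2
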