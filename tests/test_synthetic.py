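"""Synthetic community generator: determinism, planted effects, round trips."""

import numpy as np
import pandas as pd
import pytest

from mtxprof.design import Sample, StudyDesign
from mtxprof.modules import Module, ModuleCatalog, ModuleCatalogError
from mtxprof.quantify import count_aligned_nucleotides
from mtxprof.synthetic import (
    CommunityTruth,
    PlantedEffect,
    ScfaEffect,
    SyntheticDataError,
    default_design,
    default_truth,
    expected_activity,
    generate_catalog,
    read_truth,
    simulate_alignment_records,
    simulate_expression,
    simulate_scfa_panel,
    write_truth,
)

from conftest import per_base_count_oracle

ONE_MODULE = ModuleCatalog([Module("M1", "acetate kinase module", frozenset({"K00925"}))])


def _flat_truth(families=("FamA", "FamB"), planted=(), seed=0, scfa=None):
    frac = {f: 1.0 / len(families) for f in families}
    frac[families[0]] += 1.0 - sum(frac.values())
    return CommunityTruth(
        families=tuple(families),
        base_family_fraction={d: dict(frac) for d in ("NPLF", "NPHF", "HPLF", "HPHF")},
        planted_effects=tuple(planted),
        scfa_effects=scfa or {},
        seed=seed,
    )


def _design(n=2):
    return StudyDesign(
        [Sample(f"NPLF_{i}", "NPLF") for i in range(1, n + 1)]
        + [Sample(f"HPLF_{i}", "HPLF") for i in range(1, n + 1)]
    )


class TestGenerateCatalog:
    def test_deterministic_regeneration(self):
        args = dict(
            n_families=2, orfs_per_family=5, ko_pool={"K00925", "K2", "K3"},
            module_catalog=ONE_MODULE, seed=7,
        )
        c1, cat1, hits1, ko1 = generate_catalog(**args)
        c2, cat2, hits2, ko2 = generate_catalog(**args)
        assert len(cat1) == 10
        assert c1 == c2
        assert hits1 == hits2 and ko1 == ko2
        assert [(o.orf_id, o.start, o.end, o.ko) for o in cat1] == [
            (o.orf_id, o.start, o.end, o.ko) for o in cat2
        ]

    def test_module_ko_carried_by_orfs_in_two_families(self):
        _, cat, _, ko_map = generate_catalog(
            n_families=3, orfs_per_family=6, ko_pool={"K00925", "K2"},
            module_catalog=ONE_MODULE, seed=1,
        )
        carriers = [oid for oid, ko in ko_map.items() if ko == "K00925"]
        assert len(carriers) >= 1
        fams = {cat.family_map()[oid] for oid in carriers}
        assert len(fams) >= 2

    def test_orf_lengths_are_codon_multiples_in_range(self):
        _, cat, _, _ = generate_catalog(
            n_families=2, orfs_per_family=8, ko_pool={"K00925", "K2"},
            module_catalog=ONE_MODULE, seed=2,
        )
        for orf in cat:
            assert 300 <= orf.length <= 3000
            assert orf.length % 3 == 0

    def test_best_hit_carries_true_family(self):
        _, cat, hits, _ = generate_catalog(
            n_families=3, orfs_per_family=4, ko_pool={"K00925"},
            module_catalog=ONE_MODULE, seed=3, ko_assignment_rate=0.5,
        )
        from mtxprof.taxfun import assign_family_best_hit

        assigned = assign_family_best_hit(hits, orf_ids=cat.orf_ids)
        assert assigned == cat.family_map()

    def test_zero_orfs_per_family_rejected(self):
        with pytest.raises(SyntheticDataError):
            generate_catalog(2, 0, {"K00925"}, ONE_MODULE, seed=0)

    def test_empty_ko_pool_rejected(self):
        with pytest.raises(SyntheticDataError, match="empty"):
            generate_catalog(2, 5, set(), ONE_MODULE, seed=0)

    def test_module_ko_outside_pool_rejected(self):
        with pytest.raises(ModuleCatalogError, match="outside"):
            generate_catalog(2, 5, {"K99999"}, ONE_MODULE, seed=0)


class TestExpectedActivity:
    def test_single_family_equal_lengths_no_effects_equal_expectation(self):
        truth = _flat_truth(families=("FamA", "FamB"))
        _, cat, _, _ = generate_catalog(
            2, 3, {"K00925", "K2"}, ONE_MODULE, seed=4,
            families=["FamA", "FamB"], orf_length_range=(600, 600)
        )
        exp = expected_activity(truth, _design(), cat, ONE_MODULE)
        # all ORFs same length, fractions flat within family: within-family equality
        fam_map = cat.family_map()
        for fam in ("FamA", "FamB"):
            rows = [o for o in exp.index if fam_map[o] == fam]
            col = exp.loc[rows, "NPLF_1"]
            assert np.allclose(col, col.iloc[0], atol=1e-15)
        assert np.allclose(exp.sum(axis=0), 1.0, atol=1e-12)

    def test_planted_hp_fold_four_ratio_is_exactly_four(self):
        truth = _flat_truth(planted=[PlantedEffect("M1", "HP", 4.0)])
        _, cat, _, ko_map = generate_catalog(
            2, 10, {"K00925", "K2", "K3"}, ONE_MODULE, seed=5, families=["FamA", "FamB"]
        )
        exp = expected_activity(truth, _design(), cat, ONE_MODULE)
        carriers = [oid for oid, ko in ko_map.items() if ko == "K00925"]
        ratio = exp.loc[carriers, "HPLF_1"].mean() / exp.loc[carriers, "NPLF_1"].mean()
        assert ratio == pytest.approx(4.0, abs=1e-12)

    def test_fold_below_one_rejected(self):
        with pytest.raises(SyntheticDataError):
            PlantedEffect("M1", "HP", 0.5)

    def test_family_fractions_must_sum_to_one(self):
        with pytest.raises(SyntheticDataError, match="sum"):
            CommunityTruth(
                families=("A", "B"),
                base_family_fraction={"NPLF": {"A": 0.6, "B": 0.6}},
                planted_effects=(),
                scfa_effects={},
                seed=0,
            )


class TestSimulateExpression:
    def test_columns_sum_to_depth_and_are_integers(self):
        truth = _flat_truth()
        _, cat, _, _ = generate_catalog(2, 6, {"K00925", "K2"}, ONE_MODULE, seed=6, families=["FamA", "FamB"])
        expr = simulate_expression(truth, _design(), cat, ONE_MODULE, depth=5000, seed=1)
        assert (expr.values.sum(axis=0) == 5000).all()
        assert expr.values.to_numpy().dtype.kind == "i"

    def test_fixed_seed_identical_counts(self):
        truth = _flat_truth()
        _, cat, _, _ = generate_catalog(2, 6, {"K00925", "K2"}, ONE_MODULE, seed=6, families=["FamA", "FamB"])
        e1 = simulate_expression(truth, _design(), cat, ONE_MODULE, depth=5000, seed=9)
        e2 = simulate_expression(truth, _design(), cat, ONE_MODULE, depth=5000, seed=9)
        pd.testing.assert_frame_equal(e1.values, e2.values)

    def test_dispersed_replicate_mean_within_three_se_of_expectation(self):
        truth = _flat_truth()
        design = StudyDesign([Sample("NPLF_1", "NPLF")])
        _, cat, _, _ = generate_catalog(2, 6, {"K00925", "K2"}, ONE_MODULE, seed=8, families=["FamA", "FamB"])
        exp = expected_activity(truth, design, cat, ONE_MODULE)
        depth = 20_000
        rng = np.random.default_rng(17)
        draws = np.empty((2000, len(cat)))
        for r in range(2000):
            e = simulate_expression(
                truth, design, cat, ONE_MODULE, depth=depth, dispersion=0.3,
                seed=int(rng.integers(2**31)), expected=exp,
            )
            draws[r] = e.values["NPLF_1"].to_numpy()
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(2000)
        target = depth * exp["NPLF_1"].to_numpy()
        assert (np.abs(mean - target) <= 3 * se + 1e-9).all()

    def test_invalid_depth_and_dispersion_rejected(self):
        truth = _flat_truth()
        _, cat, _, _ = generate_catalog(2, 3, {"K00925"}, ONE_MODULE, seed=0, families=["FamA", "FamB"])
        with pytest.raises(SyntheticDataError):
            simulate_expression(truth, _design(), cat, ONE_MODULE, depth=0)
        with pytest.raises(SyntheticDataError):
            simulate_expression(truth, _design(), cat, ONE_MODULE, dispersion=-1)


class TestAlignmentRoundTrip:
    def test_recounting_reproduces_expression_exactly(self):
        truth = _flat_truth()
        _, cat, _, _ = generate_catalog(2, 8, {"K00925", "K2"}, ONE_MODULE, seed=10, families=["FamA", "FamB"])
        expr = simulate_expression(truth, _design(), cat, ONE_MODULE, depth=30_000, seed=2)
        records = simulate_alignment_records(expr, cat, read_length=100, seed=3)
        recounted = count_aligned_nucleotides(records, cat, samples=expr.sample_ids)
        pd.testing.assert_frame_equal(recounted.values, expr.values)

    def test_single_read_contributes_its_length(self):
        _, cat, _, _ = generate_catalog(2, 3, {"K00925"}, ONE_MODULE, seed=11)
        orf = cat.orfs[0]
        values = pd.DataFrame(
            {"s1": [100 if o.orf_id == orf.orf_id else 0 for o in cat]},
            index=pd.Index(cat.orf_ids, name="orf_id"),
        )
        from mtxprof.quantify import ExpressionMatrix

        expr = ExpressionMatrix(values=values, mode="raw")
        records = simulate_alignment_records(expr, cat, read_length=100, seed=0)
        assert len(records) == 1
        assert records[0].aligned_length == 100
        assert records[0].start >= orf.start
        assert records[0].start + 100 <= orf.end

    def test_boundary_reads_match_per_base_overlap_oracle(self):
        truth = _flat_truth()
        _, cat, _, _ = generate_catalog(2, 4, {"K00925"}, ONE_MODULE, seed=12, families=["FamA", "FamB"])
        expr = simulate_expression(truth, _design(1), cat, ONE_MODULE, depth=3_000, seed=4)
        records = simulate_alignment_records(
            expr, cat, read_length=80, seed=5, boundary_reads=True
        )
        recounted = count_aligned_nucleotides(records, cat, samples=expr.sample_ids)
        oracle = per_base_count_oracle(records, cat)
        pd.testing.assert_frame_equal(
            recounted.values[oracle.columns], oracle, check_dtype=False
        )


class TestScfaPanel:
    def _truth(self, sd=0.0):
        scfa = {
            acid: ScfaEffect(
                means={"NPLF": 1.0, "NPHF": 1.0, "HPLF": 2.0, "HPHF": 2.0}, sd=sd
            )
            for acid in ("acetate", "propionate", "butyrate", "valerate",
                         "iso-butyrate", "iso-valerate")
        }
        return _flat_truth(scfa=scfa)

    def test_zero_noise_reproduces_diet_means(self):
        panel = simulate_scfa_panel(self._truth(), _design(), seed=0)
        assert (panel.loc[panel.diet == "NPLF", "concentration"] == 1.0).all()
        assert (panel.loc[panel.diet == "HPLF", "concentration"] == 2.0).all()
        assert set(panel["acid"]) == {
            "acetate", "propionate", "butyrate", "valerate", "iso-butyrate", "iso-valerate"
        }

    def test_forced_separation_flagged_by_group_test(self):
        from mtxprof.diffstats import scfa_group_test

        panel = simulate_scfa_panel(self._truth(), _design(4), seed=0)
        out = scfa_group_test(panel, pairings=[("NPLF", "HPLF")])
        iso = out[out.acid == "iso-butyrate"].iloc[0]
        assert iso["p_value"] == 0.0 and bool(iso["significant"])

    def test_fixed_seed_identical_panel(self):
        truth = self._truth(sd=0.4)
        p1 = simulate_scfa_panel(truth, _design(), seed=6)
        p2 = simulate_scfa_panel(truth, _design(), seed=6)
        pd.testing.assert_frame_equal(p1, p2)

    def test_concentrations_never_negative(self):
        truth = self._truth(sd=5.0)
        panel = simulate_scfa_panel(truth, _design(4), seed=7)
        assert (panel["concentration"] >= 0).all()

    def test_negative_sd_rejected(self):
        with pytest.raises(SyntheticDataError):
            ScfaEffect(means={"NPLF": 1.0}, sd=-0.1)


class TestDefaults:
    def test_default_truth_fractions_sum_to_one_each_diet(self):
        truth = default_truth(seed=0)
        for diet, fr in truth.base_family_fraction.items():
            assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)
        ery = truth.base_family_fraction
        assert ery["HPLF"]["Erysipelotrichaceae"] > ery["NPLF"]["Erysipelotrichaceae"]
        assert ery["HPLF"]["Lachnospiraceae"] < ery["NPLF"]["Lachnospiraceae"]

    def test_default_design_allows_three_mouse_nplf_group(self):
        design = default_design(replicates=4, nplf_replicates=3, seed=0)
        diets = [s.diet for s in design]
        assert diets.count("NPLF") == 3 and diets.count("HPHF") == 4

    def test_truth_yaml_round_trip(self, tmp_path):
        truth = default_truth(seed=42)
        write_truth(truth, tmp_path / "truth.yaml")
        back = read_truth(tmp_path / "truth.yaml")
        assert back.seed == truth.seed
        assert back.families == truth.families
        assert back.planted_effects == truth.planted_effects
        assert back.base_family_fraction == truth.base_family_fraction
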