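import numpy as np
import pandas as pd
import pytest

from funcodak.globalmapper import (
    DEFAULT_PEC_VALUES,
    TaxonAbundanceTable,
    aggregate_levels,
    cometabolism_profile,
    core_functions,
    independent_profile,
    pathway_coverage,
    pool_enzymes,
    run_global_mapper,
)
from funcodak.reference import CopyNumberTable, TaxonKey
from funcodak.synth import SynthSpec, make_abundance_tables, make_reference

from oracles import naive_profiles, random_small_instance


def _single(table_data: dict[str, float]) -> TaxonAbundanceTable:
    return TaxonAbundanceTable(data=pd.DataFrame(table_data, index=["s1"]))


class TestEnzymePooling:
    def test_hand_pool(self, hand_table, hand_abundance):
        pool = pool_enzymes(hand_abundance, hand_table)
        row = pool.data.loc["s1"]
        assert row["1.1.1.1"] == pytest.approx(1.0)
        assert row["1.1.1.2"] == pytest.approx(1.5)
        assert row["1.1.1.3"] == pytest.approx(0.5)

    def test_single_taxon_pool_is_its_profile(self, hand_table):
        pool = pool_enzymes(_single({"Alphagenus": 100.0}), hand_table)
        assert dict(pool.data.loc["s1"][pool.data.loc["s1"] > 0]) == {
            "1.1.1.1": 2.0,
            "1.1.1.3": 1.0,
        }

    def test_zero_abundance_gives_zero_pool(self, hand_table):
        ab = TaxonAbundanceTable(
            data=pd.DataFrame({"Alphagenus": [0.0], "Betagenus": [0.0]}, index=["s1"])
        )
        pool = pool_enzymes(ab, hand_table)
        assert (pool.data.values == 0).all()
        assert "s1" in pool.resolution.empty_samples

    def test_unresolved_taxa_dropped_and_reported(self, hand_table):
        ab = TaxonAbundanceTable(
            data=pd.DataFrame(
                {"Alphagenus": [50.0], "Unclassified": [50.0]}, index=["s1"]
            )
        )
        pool = pool_enzymes(ab, hand_table)
        assert "Unclassified" in pool.resolution.unresolved
        assert pool.resolution.dropped_mass["s1"] == pytest.approx(50.0)
        # remaining mass renormalized to 100 -> full Alphagenus profile
        assert pool.data.loc["s1", "1.1.1.1"] == pytest.approx(2.0)


class TestPathwayCoverage:
    def test_partial_coverage(self, hand_hierarchy):
        assert pathway_coverage({"1.1.1.1", "1.1.1.2"}, "pwA", hand_hierarchy) == pytest.approx(
            66.6667, abs=1e-3
        )

    def test_full_and_empty(self, hand_hierarchy):
        full = {"1.1.1.1", "1.1.1.2", "1.1.1.3", "9.9.9.9"}
        assert pathway_coverage(full, "pwA", hand_hierarchy) == 100.0
        assert pathway_coverage({"9.9.9.9"}, "pwA", hand_hierarchy) == 0.0

    def test_wildcards_never_count(self, hand_hierarchy):
        assert pathway_coverage({"1.1.-.-"}, "pwA", hand_hierarchy) == 0.0

    def test_unknown_pathway_errors(self, hand_hierarchy):
        with pytest.raises(KeyError):
            pathway_coverage(set(), "nope", hand_hierarchy)


class TestCometabolism:
    def test_full_coverage_single_pathway(self, hand_table, hand_hierarchy, hand_abundance):
        pool = pool_enzymes(hand_abundance, hand_table)
        prof = cometabolism_profile(pool, hand_hierarchy, pec=50, drop_eukaryotic=True)
        assert prof.values.loc["s1", "pwA"] == pytest.approx(100.0)
        assert prof.coverage.loc["s1", "pwA"] == pytest.approx(100.0)
        assert prof.raw.loc["s1", "pwA"] == pytest.approx(3.0)

    def test_pec_excludes_undercovered_pathway(self, hand_hierarchy):
        # community lacks 1.1.1.3 -> coverage 66.67 < 70
        table = CopyNumberTable(
            profiles={
                TaxonKey("Alphagenus", "genus"): {"1.1.1.1": 2.0},
                TaxonKey("Betagenus", "genus"): {"1.1.1.2": 3.0},
            }
        )
        ab = _single({"Alphagenus": 50.0, "Betagenus": 50.0})
        pool = pool_enzymes(ab, table)
        prof = cometabolism_profile(pool, hand_hierarchy, pec=70, drop_eukaryotic=True)
        assert prof.values.loc["s1", "pwA"] == 0.0
        prof60 = cometabolism_profile(pool, hand_hierarchy, pec=60, drop_eukaryotic=True)
        assert prof60.values.loc["s1", "pwA"] == pytest.approx(100.0)

    def test_pec_zero_keeps_all_present(self, hand_table, hand_hierarchy, hand_abundance):
        pool = pool_enzymes(hand_abundance, hand_table)
        prof = cometabolism_profile(pool, hand_hierarchy, pec=0, drop_eukaryotic=False)
        assert prof.retained("s1") == {"pwA", "pwEuk"}

    def test_blacklist_filter_zeroes_eukaryotic(self, hand_table, hand_hierarchy, hand_abundance):
        pool = pool_enzymes(hand_abundance, hand_table)
        prof = cometabolism_profile(pool, hand_hierarchy, pec=0, drop_eukaryotic=True)
        assert prof.values.loc["s1", "pwEuk"] == 0.0
        assert prof.values.loc["s1", "pwA"] == pytest.approx(100.0)


class TestIndependent:
    def test_equal_full_encoders_split_contributions(self, hand_hierarchy):
        full = {"1.1.1.1": 1.0, "1.1.1.2": 1.0, "1.1.1.3": 1.0}
        table = CopyNumberTable(
            profiles={
                TaxonKey("T1", "genus"): dict(full),
                TaxonKey("T2", "genus"): dict(full),
            }
        )
        ab = _single({"T1": 50.0, "T2": 50.0})
        _, contrib = independent_profile(ab, table, hand_hierarchy, pec=50)
        col = contrib.per_sample["s1"]["pwA"]
        assert sorted(col.values) == pytest.approx([50.0, 50.0])

    def test_low_coverage_taxon_contributes_nothing(self, hand_table, hand_hierarchy):
        # Betagenus covers 1 of 3 enzymes of pwA -> 33.3 < 70
        ab = _single({"Alphagenus": 50.0, "Betagenus": 50.0})
        _, contrib = independent_profile(ab, hand_table, hand_hierarchy, pec=70)
        assert contrib.per_sample["s1"].loc["Betagenus (genus)", "pwA"] == 0.0

    @pytest.mark.parametrize("pec", DEFAULT_PEC_VALUES)
    def test_single_taxon_equivalence(self, hand_table, hand_hierarchy, pec):
        ab = _single({"Alphagenus": 100.0})
        pool = pool_enzymes(ab, hand_table)
        co = cometabolism_profile(pool, hand_hierarchy, pec=pec)
        ind, _ = independent_profile(ab, hand_table, hand_hierarchy, pec=pec)
        pd.testing.assert_frame_equal(co.values, ind.values)

    def test_contribution_columns_sum_to_100(self, synth_bundle):
        spec, table, _, hierarchy = synth_bundle
        ab = make_abundance_tables(spec, table, hierarchy)[0]
        prof, contrib = independent_profile(ab, table, hierarchy, pec=40)
        for s, mat in contrib.per_sample.items():
            sums = mat.sum(axis=0)
            retained = prof.values.loc[s] > 0
            np.testing.assert_allclose(sums[retained], 100.0, atol=1e-6)
            assert (sums[~retained].abs() < 1e-9).all()


class TestAggregation:
    def test_two_pathways_one_class(self, hand_table, hand_hierarchy, hand_abundance):
        pool = pool_enzymes(hand_abundance, hand_table)
        l3 = cometabolism_profile(pool, hand_hierarchy, pec=0, drop_eukaryotic=False)
        l2, l1 = aggregate_levels(l3, hand_hierarchy)
        assert l2.values.loc["s1"].sum() == pytest.approx(100.0, abs=1e-6)
        assert l1.values.loc["s1", "sc1"] == pytest.approx(100.0, abs=1e-6)

    def test_zero_l3_stays_zero(self, hand_hierarchy):
        from funcodak.globalmapper import FunctionProfile

        zero = FunctionProfile(
            level="L3", pec=30, algorithm="cometabolism",
            values=pd.DataFrame(0.0, index=["s1"], columns=["pwA", "pwEuk"]),
        )
        l2, l1 = aggregate_levels(zero, hand_hierarchy)
        assert (l2.values.values == 0).all() and (l1.values.values == 0).all()

    def test_missing_parent_errors(self, hand_hierarchy):
        from funcodak.globalmapper import FunctionProfile

        bad = FunctionProfile(
            level="L3", pec=30, algorithm="cometabolism",
            values=pd.DataFrame(1.0, index=["s1"], columns=["pwUnknown"]),
        )
        with pytest.raises(KeyError):
            aggregate_levels(bad, hand_hierarchy)

    def test_conservation_across_levels(self, synth_bundle):
        spec, table, _, hierarchy = synth_bundle
        ab = make_abundance_tables(spec, table, hierarchy)[0]
        pool = pool_enzymes(ab, table)
        for pec in (30, 60, 90):
            l3 = cometabolism_profile(pool, hierarchy, pec=pec)
            l2, l1 = aggregate_levels(l3, hierarchy)
            for prof in (l3, l2, l1):
                sums = prof.values.sum(axis=1)
                ok = np.isclose(sums, 100.0, atol=1e-6) | np.isclose(sums, 0.0)
                assert ok.all()


class TestCoreFunctions:
    def _profile(self, values: np.ndarray) -> "object":
        from funcodak.globalmapper import FunctionProfile

        return FunctionProfile(
            level="L3", pec=30, algorithm="cometabolism",
            values=pd.DataFrame(
                values, index=[f"s{i}" for i in range(values.shape[0])],
                columns=[f"pw{j}" for j in range(values.shape[1])],
            ),
        )

    def test_prevalence_threshold_ceiling(self):
        vals = np.ones((10, 1))
        vals[0, 0] = 0.0  # present in 9 of 10
        prof = self._profile(vals)
        assert core_functions(prof, 0.9).functions == {"pw0"}
        assert core_functions(prof, 0.95).functions == set()

    def test_ubiquitous_function_always_core(self):
        prof = self._profile(np.ones((5, 2)))
        assert core_functions(prof, 1.0).functions == {"pw0", "pw1"}

    def test_single_sample_core_is_nonzero_set(self):
        prof = self._profile(np.array([[1.0, 0.0]]))
        assert core_functions(prof, 0.9).functions == {"pw0"}

    def test_bad_threshold_errors(self):
        prof = self._profile(np.ones((2, 1)))
        with pytest.raises(ValueError):
            core_functions(prof, 0.0)
        with pytest.raises(ValueError):
            core_functions(prof, 1.1)


class TestRunGlobalMapper:
    def test_writes_seven_pecs_by_three_levels(self, synth_bundle, tmp_path):
        spec, table, _, hierarchy = synth_bundle
        ab = make_abundance_tables(spec, table, hierarchy)[0]
        run_global_mapper(ab, table, hierarchy, out_dir=tmp_path)
        for alg in ("cometabolism", "independent"):
            files = list(tmp_path.glob(f"{alg}_L*_pec*.tsv"))
            assert len(files) == 7 * 3
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "unresolved_taxa.json").exists()

    def test_retained_sets_nested_over_pec(self, synth_bundle):
        spec, table, _, hierarchy = synth_bundle
        ab = make_abundance_tables(spec, table, hierarchy)[0]
        pool = pool_enzymes(ab, table)
        prev = None
        for pec in DEFAULT_PEC_VALUES:
            prof = cometabolism_profile(pool, hierarchy, pec=pec, drop_eukaryotic=False)
            for s in prof.samples:
                retained = prof.retained(s)
                if prev is not None:
                    assert retained <= prev[s]
            prev = {s: prof.retained(s) for s in prof.samples}

    def test_blacklist_absent_from_all_outputs(self, synth_bundle):
        spec, table, _, hierarchy = synth_bundle
        ab = make_abundance_tables(spec, table, hierarchy)[0]
        res = run_global_mapper(
            ab, table, hierarchy, pec_values=(30,), drop_eukaryotic=True
        )
        for (alg, level, _), prof in res.profiles.items():
            if level == "L3":
                assert (prof.values[sorted(hierarchy.eukaryote_l3)].values == 0).all()


class TestOrderInvariance:
    def test_permuting_taxa_and_samples_permutes_outputs(self, synth_bundle):
        spec, table, _, hierarchy = synth_bundle
        ab = make_abundance_tables(spec, table, hierarchy)[0]
        rng = np.random.default_rng(0)
        shuffled = TaxonAbundanceTable(
            data=ab.data.sample(frac=1, axis=0, random_state=1).sample(
                frac=1, axis=1, random_state=2
            )
        )
        a = cometabolism_profile(pool_enzymes(ab, table), hierarchy, pec=50)
        b = cometabolism_profile(pool_enzymes(shuffled, table), hierarchy, pec=50)
        pd.testing.assert_frame_equal(
            a.values.sort_index(), b.values.sort_index(), check_like=True
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("algorithm", ["cometabolism", "independent"])
    def test_matches_naive_loops_on_small_instances(self, algorithm):
        rng = np.random.default_rng(12)
        for _ in range(30):
            rows, copy_numbers, pathway_enzymes, blacklist, table, hierarchy = (
                random_small_instance(rng)
            )
            pec = float(rng.choice([0, 30, 50, 70, 90]))
            drop = bool(rng.random() < 0.5)
            ab = TaxonAbundanceTable(data=pd.DataFrame(rows).T)
            if algorithm == "cometabolism":
                prof = cometabolism_profile(
                    pool_enzymes(ab, table), hierarchy, pec, drop_eukaryotic=drop
                )
            else:
                prof, _ = independent_profile(
                    ab, table, hierarchy, pec, drop_eukaryotic=drop
                )
            expected = naive_profiles(
                rows, copy_numbers, pathway_enzymes, blacklist, pec, algorithm, drop
            )
            for s, by_p in expected.items():
                for p, v in by_p.items():
                    assert prof.values.loc[s, p] == pytest.approx(v, abs=1e-9)
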