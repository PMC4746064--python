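import math

import numpy as np
import pytest

from funcodak.reference import (
    BundleValidationError,
    CopyNumberTable,
    GenomeCopyTable,
    PathwayHierarchy,
    TaxonKey,
    aggregate_mean_copy_numbers,
    build_copy_number_table,
    load_reference_bundle,
    resolve_taxon,
    zscore_divergence,
)
from funcodak.synth import write_bundle

from oracles import random_small_instance


def _genomes(rows):
    """rows: list of (gid, genus, {ec: cn}); lineage filled mechanically."""
    return GenomeCopyTable(
        rows=[
            (
                gid,
                {
                    "genus": genus,
                    "family": f"{genus}_fam",
                    "order": "O1",
                    "class": "C1",
                    "phylum": "P1",
                },
                prof,
            )
            for gid, genus, prof in rows
        ]
    )


class TestTaxonKey:
    def test_rejects_empty_name_and_bad_rank(self):
        with pytest.raises(ValueError):
            TaxonKey("", "genus")
        with pytest.raises(ValueError):
            TaxonKey("Escherichia", "species")

    def test_duplicate_keys_rejected_case_insensitively(self):
        with pytest.raises(BundleValidationError):
            CopyNumberTable(
                profiles={
                    TaxonKey("Escherichia", "genus"): {},
                    TaxonKey("escherichia", "genus"): {},
                }
            )

    def test_parent_links_must_go_up(self):
        table = CopyNumberTable(
            profiles={
                TaxonKey("A", "family"): {},
                TaxonKey("B", "genus"): {},
            },
            parents={TaxonKey("A", "family"): TaxonKey("B", "genus")},
        )
        assert any("hierarchy" in e for e in table.validate())


class TestBundleIO:
    def test_round_trip_is_identity(self, synth_bundle, tmp_path):
        _, table, genomes, hierarchy = synth_bundle
        paths = write_bundle(table, genomes, hierarchy, tmp_path)
        loaded_table, loaded_hier = load_reference_bundle(
            paths["copy_numbers"], paths["hierarchy"], paths["blacklist"]
        )
        assert {k: v for k, v in loaded_table.profiles.items()} == {
            k: pytest.approx(v) for k, v in table.profiles.items()
        }
        assert loaded_hier.ec_to_l3 == hierarchy.ec_to_l3
        assert loaded_hier.l3_enzymes == hierarchy.l3_enzymes
        assert loaded_hier.l3_to_l2 == hierarchy.l3_to_l2
        assert loaded_hier.l2_to_l1 == hierarchy.l2_to_l1
        assert loaded_hier.eukaryote_l3 == hierarchy.eukaryote_l3

    def test_malformed_ec_cites_the_line(self, tmp_path):
        cn = tmp_path / "copy_numbers.tsv"
        cn.write_text(
            "taxon\trank\tec\tcopy_number\n"
            "Alphagenus\tgenus\t1.1.1.1\t2\n"
            "Alphagenus\tgenus\t1.2.3\t1\n"
        )
        hi = tmp_path / "hierarchy.tsv"
        hi.write_text(
            "ec\tl3_id\tl3_name\tl2_id\tl2_name\tl1_id\tl1_name\n"
            "1.1.1.1\tpw0\tP\tcl0\tC\tsc0\tS\n"
        )
        with pytest.raises(BundleValidationError) as exc:
            load_reference_bundle(cn, hi)
        assert "copy_numbers.tsv:3" in str(exc.value)
        assert "1.2.3" in str(exc.value)

    def test_wildcard_ec_trailing_only(self, tmp_path):
        cn = tmp_path / "cn.tsv"
        cn.write_text(
            "taxon\trank\tec\tcopy_number\n"
            "A\tgenus\t1.1.-.-\t2\n"
            "A\tgenus\t1.-.1.1\t2\n"
        )
        hi = tmp_path / "h.tsv"
        hi.write_text(
            "ec\tl3_id\tl3_name\tl2_id\tl2_name\tl1_id\tl1_name\n"
            "1.1.1.1\tpw0\tP\tcl0\tC\tsc0\tS\n"
        )
        with pytest.raises(BundleValidationError) as exc:
            load_reference_bundle(cn, hi)
        msg = str(exc.value)
        assert "1.-.1.1" in msg and "1.1.-.-" not in msg

    def test_inverse_map_violation_detected(self):
        hierarchy = PathwayHierarchy(
            ec_to_l3={"1.1.1.1": {"pw0"}},
            l3_enzymes={"pw0": {"1.1.1.1", "1.1.1.2"}},  # extra EC not in ec_to_l3
            l3_to_l2={"pw0": "cl0"},
            l2_to_l1={"cl0": "sc0"},
        )
        assert any("inverse" in e for e in hierarchy.validate())

    def test_blacklist_id_missing_from_hierarchy(self):
        hierarchy = PathwayHierarchy(
            ec_to_l3={"1.1.1.1": {"pw0"}},
            l3_enzymes={"pw0": {"1.1.1.1"}},
            l3_to_l2={"pw0": "cl0"},
            l2_to_l1={"cl0": "sc0"},
            eukaryote_l3={"pw_missing"},
        )
        assert any("pw_missing" in e for e in hierarchy.validate())


class TestAggregation:
    def test_mean_over_member_genomes(self):
        genomes = _genomes(
            [("g1", "G", {"1.1.1.1": 2.0}), ("g2", "G", {"1.1.1.1": 4.0})]
        )
        out = aggregate_mean_copy_numbers(genomes, "genus")
        assert out.get(TaxonKey("G", "genus")) == {"1.1.1.1": 3.0}

    def test_absent_enzyme_counts_as_zero(self):
        genomes = _genomes([("g1", "G", {"1.1.1.1": 2.0}), ("g2", "G", {})])
        out = aggregate_mean_copy_numbers(genomes, "genus")
        assert out.get(TaxonKey("G", "genus")) == {"1.1.1.1": 1.0}

    def test_single_genome_is_identity(self):
        prof = {"1.1.1.1": 2.0, "2.1.1.1": 5.0}
        out = aggregate_mean_copy_numbers(_genomes([("g1", "G", prof)]), "genus")
        assert out.get(TaxonKey("G", "genus")) == prof

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            aggregate_mean_copy_numbers(GenomeCopyTable(rows=[]), "genus")

    def test_brute_force_mean_equivalence(self, synth_bundle):
        """Group means recomputed by direct looping match the table."""
        _, table, genomes, _ = synth_bundle
        for rank in ("genus", "phylum"):
            out = aggregate_mean_copy_numbers(genomes, rank)
            groups = {}
            for _, lineage, prof in genomes.rows:
                groups.setdefault(lineage[rank], []).append(prof)
            for name, members in groups.items():
                ecs = {ec for p in members for ec in p}
                expected = {
                    ec: sum(p.get(ec, 0.0) for p in members) / len(members)
                    for ec in ecs
                }
                got = out.get(TaxonKey(name, rank))
                assert set(got) == set(expected)
                for ec in ecs:
                    assert math.isclose(got[ec], expected[ec], abs_tol=1e-12)

    def test_all_ranks_table_has_upward_parents(self, synth_bundle):
        _, _, genomes, _ = synth_bundle
        table = build_copy_number_table(genomes)
        assert table.validate() == []
        assert any(k.rank == "phylum" for k in table.taxa)


class TestZscoreDivergence:
    def test_identical_genomes_all_within_one(self):
        prof = {"1.1.1.1": 3.0, "2.1.1.1": 1.0}
        genomes = _genomes([(f"g{i}", "G", dict(prof)) for i in range(4)])
        summary = zscore_divergence(genomes, "genus")
        assert summary.within_1("genus") == 1.0

    def test_two_point_spread_stays_within_band(self):
        # copies {0, 10}: both z = +-10/(2*sd), sd = 10/sqrt(2) -> |z| ~ 0.707
        genomes = _genomes(
            [("g1", "G", {"1.1.1.1": 10.0}), ("g2", "G", {})]
        )
        summary = zscore_divergence(genomes, "genus")
        assert summary.within_1("genus") == 1.0

    def test_proportions_sum_to_one_per_rank(self, synth_bundle):
        _, _, genomes, _ = synth_bundle
        summary = zscore_divergence(genomes)
        for rank, bands in summary.proportions.items():
            assert math.isclose(sum(bands.values()), 1.0, abs_tol=1e-9)
            assert all(0.0 <= v <= 1.0 for v in bands.values())

    def test_aggregate_then_diverge_on_identical_genomes(self):
        prof = {"1.1.1.1": 2.0}
        genomes = _genomes([(f"g{i}", "G", dict(prof)) for i in range(3)])
        table = aggregate_mean_copy_numbers(genomes, "genus")
        assert table.get(TaxonKey("G", "genus")) == prof
        assert zscore_divergence(genomes, "genus").within_1("genus") == 1.0


class TestResolveTaxon:
    def test_lineage_terminal_genus_hit(self, hand_table):
        res = resolve_taxon(
            "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;"
            "f__Streptococcaceae;g__Alphagenus",
            hand_table,
        )
        assert res is not None and not res.fallback
        assert res.key == TaxonKey("Alphagenus", "genus")
        assert res.profile == {"1.1.1.1": 2.0, "1.1.1.3": 1.0}

    def test_unknown_genus_falls_back_to_family(self, hand_table):
        res = resolve_taxon(
            "k__Bacteria;p__X;c__X;o__X;f__Gammaceae;g__Nosuchgenus", hand_table
        )
        assert res is not None and res.fallback
        assert res.key == TaxonKey("Gammaceae", "family")

    def test_unclassified_is_unresolved(self, hand_table):
        assert resolve_taxon("Unclassified", hand_table) is None

    def test_plain_name_case_and_prefix_insensitive(self, hand_table):
        for label in ("alphagenus", "  Alphagenus ", "g__Alphagenus"):
            res = resolve_taxon(label, hand_table)
            assert res is not None and res.key.name == "Alphagenus"


def test_generated_small_instances_validate():
    rng = np.random.default_rng(5)
    for _ in range(10):
        *_, table, hierarchy = random_small_instance(rng)
        assert table.validate() == []
        assert hierarchy.validate() == []
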