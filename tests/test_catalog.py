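"""Genome metadata parsing, subgroup precedence, and the reference index."""

import io
import itertools
import logging

import pytest

from mdmcensus.catalog import (
    CATEGORY_PRECEDENCE,
    Category,
    GenomeRecord,
    ReferenceIndex,
    assign_category,
    build_index,
    parse_metadata,
    reverse_complement,
    summarize_catalog,
)

HEADER = ("accession\tgtdb_taxonomy\tncbi_genome_category\t"
          "ncbi_assembly_level\tmimag_high_quality\tmimag_medium_quality\t"
          "mimag_low_quality\n")
TAX = "d__Bacteria;p__Proteobacteria;c__C;o__O;f__F;g__G;s__G s"


def _table(*rows: str):
    return io.StringIO(HEADER + "".join(r + "\n" for r in rows))


class TestParseMetadata:
    def test_isolate_rule(self):
        recs = parse_metadata(_table(f"A1\t{TAX}\tnone\tContig\tf\tf\tf"))
        assert recs[0].category == Category.ISOLATION
        assert recs[0].is_isolate

    def test_environmental_complete_genome(self):
        recs = parse_metadata(_table(
            f"A1\t{TAX}\tderived from metagenome\tComplete Genome\tf\tf\tf"))
        assert recs[0].category == Category.COMPLETE

    def test_empty_table_gives_empty_list(self):
        assert parse_metadata(io.StringIO(HEADER)) == []

    def test_missing_mandatory_column_names_it(self):
        with pytest.raises(ValueError, match="ncbi_genome_category"):
            parse_metadata(io.StringIO("accession\tgtdb_taxonomy\nA\tx\n"))

    def test_missing_optional_columns_default_false(self):
        recs = parse_metadata(io.StringIO(
            "accession\tgtdb_taxonomy\tncbi_genome_category\n"
            f"A1\t{TAX}\tderived from metagenome\n"))
        rec = recs[0]
        assert not (rec.mimag_hq or rec.mimag_mq or rec.mimag_lq)
        assert rec.category == Category.UNASSIGNED

    def test_malformed_taxonomy_flagged_not_dropped(self):
        recs = parse_metadata(_table("A1\tnot-a-taxonomy\tnone\tContig\tf\tf\tf"))
        assert len(recs) == 1
        assert recs[0].taxonomy_malformed

    def test_domain_and_phylum_extracted(self):
        recs = parse_metadata(_table(f"A1\t{TAX}\tnone\tContig\tf\tf\tf"))
        assert recs[0].domain == "Bacteria"
        assert recs[0].phylum() == "Proteobacteria"


def _oracle_category(is_isolate, complete, hq, mq, lq):
    """Independent first-rule-wins enumeration of the precedence order."""
    for fired, cat in [
        (is_isolate, Category.ISOLATION),
        (complete, Category.COMPLETE),
        (hq, Category.HQ),
        (mq, Category.MQ),
        (lq, Category.LQ),
    ]:
        if fired:
            return cat
    return Category.UNASSIGNED


class TestAssignCategory:
    @pytest.mark.parametrize("genome_category", ["none", "", "NONE ",
                                                 "derived from metagenome",
                                                 "derived from environmental sample"])
    @pytest.mark.parametrize("level", ["Complete Genome", "complete genome",
                                       "Contig", "Scaffold"])
    def test_full_flag_enumeration_matches_precedence_oracle(
            self, genome_category, level):
        for hq, mq, lq in itertools.product([False, True], repeat=3):
            rec = GenomeRecord("A", taxonomy=TAX,
                               ncbi_genome_category=genome_category,
                               assembly_level=level,
                               mimag_hq=hq, mimag_mq=mq, mimag_lq=lq)
            expected = _oracle_category(
                genome_category.strip().lower() in ("", "none"),
                "complete genome" in level.lower(), hq, mq, lq)
            assert assign_category(rec) == expected

    def test_flipping_lower_precedence_flags_never_changes_category(self):
        for hq, mq, lq in itertools.product([False, True], repeat=3):
            rec = GenomeRecord("A", ncbi_genome_category="x",
                               assembly_level="Contig",
                               mimag_hq=True, mimag_mq=mq, mimag_lq=lq)
            assert assign_category(rec) == Category.HQ

    def test_isolate_outranks_quality_flags(self):
        rec = GenomeRecord("A", ncbi_genome_category="none",
                           assembly_level="Complete Genome", mimag_hq=True)
        assert assign_category(rec) == Category.ISOLATION

    def test_no_rule_fires_gives_unassigned(self):
        rec = GenomeRecord("A", ncbi_genome_category="derived from metagenome",
                           assembly_level="Scaffold")
        assert assign_category(rec) == Category.UNASSIGNED


class TestBuildIndex:
    def test_single_entry_answers_both_strands(self):
        recs = parse_metadata(_table(f"A1\t{TAX}\tnone\tContig\tf\tf\tf"))
        seq = "ACGTACGGTTCAGGCCATTA" * 10
        index = build_index(recs, {"A1": [seq]})
        probe = seq[37:127]
        assert index.search_exact(probe) == ["A1"]
        assert index.search_exact(reverse_complement(probe)) == ["A1"]

    def test_orphan_fasta_accession_kept_unassigned(self, caplog):
        recs = parse_metadata(_table(f"A1\t{TAX}\tnone\tContig\tf\tf\tf"))
        with caplog.at_level(logging.WARNING):
            index = build_index(recs, {"A1": ["ACGT" * 50],
                                       "ORPHAN": ["TTGA" * 50]})
        assert index.category("ORPHAN") == Category.UNASSIGNED
        assert any("ORPHAN" in m for m in caplog.messages)

    def test_zero_sequences_fatal(self):
        recs = parse_metadata(_table(f"A1\t{TAX}\tnone\tContig\tf\tf\tf"))
        with pytest.raises(ValueError):
            build_index(recs, {})

    def test_shared_ssu_returns_both_accessions(self):
        rows = [f"A{i}\t{TAX}\tnone\tContig\tf\tf\tf" for i in (1, 2)]
        shared = "ACGGTTCCAA" * 30
        index = build_index(parse_metadata(_table(*rows)),
                            {"A1": [shared], "A2": [shared]})
        assert index.search_exact(shared[10:100]) == ["A1", "A2"]

    def test_prefix_stripping_joins_rs_gb_accessions(self):
        recs = parse_metadata(_table(f"RS_GCF_1.1\t{TAX}\tnone\tContig\tf\tf\tf"))
        index = build_index(recs, {"GCF_1.1": ["ACGT" * 50]})
        assert index.category("GCF_1.1") == Category.ISOLATION

    def test_without_removes_and_rejects_emptying(self, planted_index):
        reduced = planted_index.without(["G0"])
        assert "G0" not in reduced.accessions
        with pytest.raises(ValueError):
            planted_index.without([f"G{i}" for i in range(5)])


class TestSummarizeCatalog:
    def test_simple_percentages(self):
        recs = []
        for i in range(7):
            recs.append(GenomeRecord(f"I{i}", domain="Bacteria", taxonomy=TAX,
                                     category=Category.ISOLATION))
        for i in range(3):
            recs.append(GenomeRecord(f"M{i}", domain="Bacteria", taxonomy=TAX,
                                     category=Category.MQ))
        summary = summarize_catalog(recs)
        assert summary.percent("Bacteria", Category.ISOLATION) == 70.0
        assert summary.percent("Bacteria", Category.MQ) == 30.0

    def test_counts_sum_to_domain_total(self, small_catalog):
        summary = summarize_catalog(small_catalog.records)
        per_domain = summary.by_category.groupby("domain")["count"].sum()
        assert per_domain["Bacteria"] == len(small_catalog.records)

    def test_matches_generator_tallies(self, small_catalog):
        summary = summarize_catalog(small_catalog.records)
        tallies = small_catalog.truth["category_counts"]
        for cat_name, expected in tallies.items():
            sel = summary.by_category[
                summary.by_category["category"] == cat_name]["count"].sum()
            assert sel == expected

    def test_empty_catalog(self):
        summary = summarize_catalog([])
        assert summary.n_records == 0 and summary.by_category.empty
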