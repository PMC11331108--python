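"""Occurrence-table reading, validation and filtering."""

import io

import numpy as np
import pandas as pd
import pytest

from rangelaw import occurrences as occ
from rangelaw import synthetic as syn


def read_text(text, **kw):
    return occ.read_occurrence_table(io.StringIO(text), **kw)


class TestRead:
    def test_row_count_preserved(self, fossil_tsv_text):
        table = read_text(fossil_tsv_text)
        assert table.n_input_rows == 7
        assert len(table) == 7  # all rows parseable here

    def test_missing_mapped_column_raises(self):
        with pytest.raises(KeyError):
            read_text("LIDNUM\tLAT\nL1\t2.0\n")

    def test_inverted_ages_collected_not_dropped_silently(self):
        text = ("LIDNUM\tLAT\tLONG\tMAX_AGE\tMIN_AGE\tORDER\tFAMILY\tGENUS\tSPECIES\n"
                "L1\t0\t0\t10.0\t14.0\tX\tY\tGen\tsp1\n"
                "L2\t0\t0\t14.0\t10.0\tX\tY\tGen\tsp2\n")
        table = read_text(text)
        assert len(table) == 1
        assert len(table.issues) == 1
        assert table.issues[0].field == "age"
        assert len(table.invalid_rows) == 1

    def test_out_of_range_coordinates_flagged(self):
        text = ("LIDNUM\tLAT\tLONG\tMAX_AGE\tMIN_AGE\tORDER\tFAMILY\tGENUS\tSPECIES\n"
                "L1\t95.0\t0\t12\t10\tX\tY\tGen\tsp\n")
        table = read_text(text)
        assert len(table) == 0
        assert table.issues[0].field == "lat"

    def test_write_read_round_trip(self, rng):
        """A generated table written to its TSV dialect reads back identical."""
        config = syn.GeneratorConfig(n_species=50, qualifier_noise=0.1, cf_fraction=0.1)
        table, _ = syn.generate_fossil_table(config, rng)
        back = read_text(occ.read_table_text(table))
        pd.testing.assert_frame_equal(table.df, back.df, check_dtype=False)

    def test_hexgrid_round_trip(self, rng):
        config = syn.GeneratorConfig(n_species=20, width_dist=syn.Dist("exponential", (300.0,)))
        table, _ = syn.generate_hexgrid_table(config, rng)
        back = read_text(occ.read_table_text(table), source_kind="present_day")
        pd.testing.assert_frame_equal(
            table.df.drop(columns=["family", "age_min", "age_max"]),
            back.df.drop(columns=["family", "age_min", "age_max"]),
            check_dtype=False)


class TestQualifierParsing:
    @pytest.mark.parametrize("name,expected_q,expected_name", [
        ("primus", "exact", "primus"),
        ("cf. primus", "uncertain", "primus"),
        ("CF primus", "uncertain", "primus"),
        ("aff. primus", "uncertain", "primus"),
        ("indet.", "indeterminate", ""),
        ("indet", "indeterminate", ""),
        ("", "indeterminate", ""),
        ("sp.", "unnamed", ""),
        ("sp", "unnamed", ""),
        ("gen.", "unnamed", ""),
    ])
    def test_dialect_tokens(self, name, expected_q, expected_name):
        q, cleaned = occ.DEFAULT_DIALECT.parse(name)
        assert q == expected_q
        assert cleaned == expected_name


class TestFilters:
    def test_identification_filter_species_level(self, fossil_tsv_text):
        """indet./sp. rows drop; cf. rows stay."""
        table = read_text(fossil_tsv_text)
        filtered = occ.filter_identifications(table, "species")
        assert len(filtered) == 5
        kept_quals = set(filtered.df["species_qualifier"])
        assert "indeterminate" not in kept_quals and "unnamed" not in kept_quals
        assert "uncertain" in kept_quals

    def test_identification_filter_genus_level_keeps_species_indet(self, fossil_tsv_text):
        table = read_text(fossil_tsv_text)
        filtered = occ.filter_identifications(table, "genus")
        assert len(filtered) == 7  # all genera are determinate

    def test_all_exact_identity(self):
        text = ("LIDNUM\tLAT\tLONG\tMAX_AGE\tMIN_AGE\tORDER\tFAMILY\tGENUS\tSPECIES\n"
                "L1\t0\t0\t12\t10\tX\tY\tEquus\tcaballus\n")
        table = read_text(text)
        assert len(occ.filter_identifications(table, "species")) == len(table)

    def test_age_span_filter(self, fossil_tsv_text):
        """The 10 My span locality drops; 2 My spans stay."""
        table = read_text(fossil_tsv_text)
        filtered = occ.filter_age_span(table, 3.0)
        assert "L5" not in set(filtered.df["locality_id"])
        assert len(filtered) == 6

    def test_age_span_inclusive_boundary(self):
        text = ("LIDNUM\tLAT\tLONG\tMAX_AGE\tMIN_AGE\tORDER\tFAMILY\tGENUS\tSPECIES\n"
                "L1\t0\t0\t13.0\t10.0\tX\tY\tGen\tspec\n")
        assert len(occ.filter_age_span(read_text(text), 3.0)) == 1

    def test_age_span_on_present_day_rejected(self, rng):
        table, _ = syn.generate_hexgrid_table(syn.GeneratorConfig(n_species=2), rng)
        with pytest.raises(ValueError):
            occ.filter_age_span(table)

    def test_exclusions_default_aquatic(self, fossil_tsv_text):
        """Sirenia (order) and Phocidae (pinniped family) rows drop."""
        table = read_text(fossil_tsv_text)
        filtered = occ.exclude_taxa(table)
        assert set(filtered.df["order"]) == {"Artiodactyla"}

    def test_empty_exclusions_identity(self, fossil_tsv_text):
        table = read_text(fossil_tsv_text)
        assert len(occ.exclude_taxa(table, ())) == len(table)

    def test_filters_idempotent_and_commute(self, fossil_tsv_text):
        table = read_text(fossil_tsv_text)

        def ident(t):
            return occ.filter_identifications(t, "species")

        def span(t):
            return occ.filter_age_span(t, 3.0)

        once = ident(table)
        pd.testing.assert_frame_equal(ident(once).df, once.df)
        ab = span(ident(table)).df
        ba = ident(span(table)).df
        pd.testing.assert_frame_equal(ab.sort_values("locality_id").reset_index(drop=True),
                                      ba.sort_values("locality_id").reset_index(drop=True))


class TestGrouping:
    def test_partition_property(self, fossil_tsv_text):
        table = occ.filter_identifications(read_text(fossil_tsv_text), "species")
        groups = occ.group_by_taxon(table)
        assert sum(len(g.occurrences) for g in groups) == len(table)

    def test_level_changes_group_count(self, fossil_tsv_text):
        table = read_text(fossil_tsv_text)
        at_genus = occ.group_by_taxon(occ.filter_identifications(table, "genus"))
        at_species = occ.group_by_taxon(occ.filter_identifications(table, "species"))
        assert len(at_genus) == 4   # Bison, Ovis, Dugong, Phoca
        assert len(at_species) == 4  # Bison primus, Ovis aries, Dugong dugon, Phoca vitulina

    def test_known_species_count_from_generator(self, rng):
        k = 17
        table, _ = syn.generate_fossil_table(syn.GeneratorConfig(n_species=k), rng)
        groups = occ.group_by_taxon(occ.filter_identifications(table, "species"))
        assert len(groups) == k
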