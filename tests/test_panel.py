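"""Panel fixture integrity, validation rules, and genotype I/O."""

import numpy as np
import pytest

from equistr.panel import (
    GenotypeDataset,
    Individual,
    Motif,
    PanelError,
    build_sequence,
    count_structure_repeats,
    load_panel,
    parse_allele_name,
    parse_structure,
    read_genotypes,
    validate_panel,
    write_genotypes,
)


class TestBuiltinPanel:
    def test_panel_composition(self, panel):
        assert len(panel.markers) == 17
        assert panel.sex_marker is not None and panel.sex_marker.name == "amel"

    def test_eca20_row(self, panel):
        m = panel.get("ECA20.003.8")
        assert m.motif.unit == "TATC"
        assert m.sw_score == 672
        assert m.stutter_pct == 11.2
        assert m.structure_string == "[TATC]18[TGTC]"

    def test_penta_unit_length(self, panel):
        assert panel.get("Eca05").unit_length == 5
        assert panel.get("Eca24").unit_length == 5
        assert panel.get("Eca04b").unit_length == 5

    def test_reference_repeat_counts(self, panel):
        # whole-unit blocks of the printed structure, interrupting units included
        assert panel.get("Eca15").ref_repeats == 16  # 4 + 1 + 11
        assert panel.get("Eca20").ref_repeats == 19  # 18 + 1
        assert panel.get("Eca01").ref_repeats == 19  # 7 + 12

    def test_summary_means_match_published_row(self, panel):
        alleles = [m.observed_alleles for m in panel.markers]
        stutter = [m.stutter_pct for m in panel.markers]
        rates = [m.predicted_mut_rate for m in panel.markers]
        assert round(float(np.mean(alleles)), 1) == 8.3
        assert round(float(np.mean(stutter)), 1) == 6.9
        assert abs(float(np.mean(rates)) - 0.335) < 0.001

    def test_locus_table_means(self, locus_table):
        strs = locus_table[locus_table["marker"] != "amel"]
        assert round(float(strs["ho"].mean()), 2) == 0.66
        assert round(float(strs["he"].mean()), 2) == 0.72

    def test_duplicate_marker_names_rejected(self, tmp_path):
        src = tmp_path / "dup.tsv"
        header = ("name\tchromosome\tposition_mb\tdye\tunit\tstructure\tsws\t"
                  "conc_uM\tref_size\trange_min\trange_max\twt_avg\tn_alleles\t"
                  "stutter_pct\tmut_rate\tprimer_f\tprimer_f_label\tprimer_r\n")
        row = ("X\t1\t1.0\tFAM\tAGAT\t[AGAT]10\t400\t1.0\t200\t180\t220\t200\t"
               "5\t5.0\t0.2\tACGTACGTACGTAA\tFAM\tTGCATGCATGCAAA\n")
        src.write_text(header + row + row)
        with pytest.raises(PanelError, match="duplicate"):
            load_panel(src)

    def test_missing_column_rejected(self, tmp_path):
        src = tmp_path / "bad.tsv"
        src.write_text("name\tdye\nX\tFAM\n")
        with pytest.raises(PanelError, match="missing column"):
            load_panel(src)

    def test_malformed_motif_rejected(self):
        with pytest.raises(PanelError):
            Motif("AGAU")


class TestValidatePanel:
    def test_published_boundary_overlaps_are_warnings(self, panel):
        findings = validate_panel(panel)
        ov = [f for f in findings if f.rule == "range-overlap"]
        assert all(f.severity == "WARN" for f in ov)
        ned = [f for f in ov if "NED" in f.message]
        assert len(ned) == 1 and "2 bp" in ned[0].message
        assert "ECA21" in ned[0].message and "ECA25" in ned[0].message

    def test_hex_channel_clean(self, panel):
        findings = validate_panel(panel)
        assert not any("HEX" in f.message for f in findings
                       if f.rule == "range-overlap")

    def test_chr4_pair_beyond_linkage_threshold(self, panel):
        # 35.5 Mb and 104.2 Mb on chromosome 4: 68.7 Mb apart, no finding
        findings = validate_panel(panel, linkage_threshold_mb=50)
        assert not any(f.rule == "linkage" for f in findings)
        tight = validate_panel(panel, linkage_threshold_mb=70)
        assert any(f.rule == "linkage" and f.severity == "FAIL" for f in tight)

    def test_order_independence(self, panel):
        import copy

        shuffled = copy.copy(panel)
        shuffled.markers = list(reversed(panel.markers))
        a = {(f.severity, f.rule, f.message) for f in validate_panel(panel)}
        b = {(f.severity, f.rule, f.message) for f in validate_panel(shuffled)}
        assert a == b


class TestAlleleNames:
    def test_microvariant_parse(self):
        assert parse_allele_name("17.3", unit_length=4) == (17, 3)
        assert parse_allele_name("17") == (17, 0)

    def test_partial_must_be_below_unit_length(self):
        with pytest.raises(PanelError):
            parse_allele_name("17.9", unit_length=4)

    @pytest.mark.parametrize("bad", ["", "x", "0", "17.0.1", "-3"])
    def test_garbage_rejected(self, bad):
        with pytest.raises(PanelError):
            parse_allele_name(bad)


class TestStructureStrings:
    def test_parse_and_rebuild(self):
        s = "[TCTA]4[TCTG][TCTA]11"
        parts = parse_structure(s)
        assert parts[0] == ("TCTA", 4, True)
        assert build_sequence(s) == "TCTA" * 4 + "TCTG" + "TCTA" * 11

    def test_repeat_count_convention(self):
        assert count_structure_repeats("[TCTA]4[TCTG][TCTA]11", 4) == 16
        assert count_structure_repeats("[ATCT]7ATC[ATCT]12", 4) == 19

    def test_all_panel_structures_rebuild(self, panel):
        for m in panel.markers:
            seq = build_sequence(m.structure_string)
            assert len(seq) > 0
            assert count_structure_repeats(m.structure_string,
                                           m.unit_length) == m.ref_repeats


class TestGenotypeIO:
    @staticmethod
    def _dataset():
        return GenotypeDataset(
            [
                Individual("h1", "Arabian", {"M1": ("12", "14"), "M2": ("17.3", "18")}),
                Individual("h2", "Arabian", {"M1": ("12", "12"), "M2": None}),
                Individual("h3", "Paint", {"M1": None, "M2": ("18", "18")}),
            ],
            ["M1", "M2"],
        )

    @pytest.mark.parametrize("dialect", ["native", "genalex-like"])
    def test_round_trip(self, tmp_path, dialect):
        ds = self._dataset()
        path = tmp_path / "g.csv"
        write_genotypes(ds, path, dialect=dialect)
        back = read_genotypes(path, dialect=dialect)
        assert back.markers == ds.markers
        for a, b in zip(ds.individuals, back.individuals):
            assert (a.id, a.population, a.genotypes) == (b.id, b.population, b.genotypes)

    def test_genalex_header_rows(self, tmp_path):
        ds = self._dataset()
        path = tmp_path / "g.csv"
        write_genotypes(ds, path, dialect="genalex-like")
        lines = path.read_text().splitlines()
        assert lines[0].split(",")[:3] == ["2", "3", "2"]  # loci, samples, pops
        assert "Arabian" in lines[1] and "Paint" in lines[1]

    def test_invalid_partial_rejected_against_panel(self, tmp_path, panel):
        path = tmp_path / "g.csv"
        m = panel.markers[0].name  # a tetranucleotide marker
        path.write_text(f"id,population,{m},{m}\nh1,Arabian,17.9,18\n")
        with pytest.raises(PanelError, match="17.9"):
            read_genotypes(path, panel=panel)

    def test_odd_allele_columns_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("id,population,M1,M1,M2\nh1,Arabian,1,2,3\n")
        with pytest.raises(PanelError, match="odd"):
            read_genotypes(path)
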