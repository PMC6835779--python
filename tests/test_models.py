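"""Domain types, protein-class attribution and tabular I/O."""

import pytest

from grainrisk.models import (
    Confidence,
    DigestLabel,
    Disease,
    EpitopeRecord,
    FormatError,
    IdentifiedPeptide,
    ProteinClass,
    ProteinRecord,
    Stage,
    attribute_protein_class,
    load_cd_epitopes,
    load_conserved_gd_resistant_ids,
    load_presence_matrix,
    load_wa_epitopes,
    read_epitope_table,
    read_fasta,
    read_peptide_table,
    write_epitope_table,
    write_fasta,
    write_peptide_table,
)


class TestProteinRecord:
    def test_rejects_empty_sequence(self):
        with pytest.raises(ValueError):
            ProteinRecord("P1", "P1 x", "")

    def test_rejects_out_of_alphabet_residue(self):
        with pytest.raises(ValueError):
            ProteinRecord("P1", "P1 x", "QQP1FP")

    def test_accepts_unknown_residue_placeholder(self):
        assert ProteinRecord("P1", "P1 x", "QQXPF").sequence == "QQXPF"


class TestFastaIO:
    def test_parse_attributes_class_and_preserves_order(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(
            ">P1 alpha/beta-gliadin\nQPFPQPQLPY\n>P2 serpin Z1C\nMKVLA\n"
        )
        records = read_fasta(path)
        assert [r.accession for r in records] == ["P1", "P2"]
        assert records[0].protein_class is ProteinClass.ALPHA_GLIADIN
        assert records[1].protein_class is ProteinClass.SERPIN

    def test_lowercase_sequences_are_uppercased(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1 gamma-gliadin\nqpfpq\n")
        assert read_fasta(path)[0].sequence == "QPFPQ"

    def test_digit_in_sequence_names_offending_entry(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">GOOD x\nQQQQ\n>BAD y\nQQ9Q\n")
        with pytest.raises(FormatError, match="BAD"):
            read_fasta(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_fasta(path) == []

    def test_write_read_round_trip(self, tmp_path):
        records = [
            ProteinRecord("P1", "P1 omega-gliadin", "QQPFPQQ" * 20,
                          ProteinClass.OMEGA_GLIADIN)
        ]
        path = tmp_path / "out.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert back[0].sequence == records[0].sequence
        assert back[0].protein_class is ProteinClass.OMEGA_GLIADIN


@pytest.mark.parametrize(
    "description, expected",
    [
        ("gamma-gliadin", ProteinClass.GAMMA_GLIADIN),
        ("γ-gliadin", ProteinClass.GAMMA_GLIADIN),
        ("Tri a 26", ProteinClass.HMW_GS),
        ("high molecular weight glutenin subunit x-type", ProteinClass.HMW_GS),
        ("LMW glutenin", ProteinClass.LMW_GS),
        ("Tri a 36", ProteinClass.LMW_GS),
        ("alpha/beta-gliadin", ProteinClass.ALPHA_GLIADIN),
        ("α-20 gliadin", ProteinClass.ALPHA_GLIADIN),
        ("Tri a 21", ProteinClass.ALPHA_GLIADIN),
        ("omega-gliadin", ProteinClass.OMEGA_GLIADIN),
        ("Tri a 19", ProteinClass.OMEGA_GLIADIN),
        ("Tri a 20", ProteinClass.GAMMA_GLIADIN),
        ("alpha-amylase inhibitor CM3", ProteinClass.ATI),
        ("Tri a 28", ProteinClass.ATI),
        ("Tri a 15", ProteinClass.ATI),
        ("non-specific lipid transfer protein", ProteinClass.NS_LTP),
        ("Tri a 14", ProteinClass.NS_LTP),
        ("alpha-purothionin", ProteinClass.PUROTHIONIN),
        ("Tri a 37", ProteinClass.PUROTHIONIN),
        ("serpin Z1A", ProteinClass.SERPIN),
        ("globulin 3A", ProteinClass.GLOBULIN),
        ("γ-gliadin or LMW glutenin", ProteinClass.GAMMA_GLIADIN),
        ("glutenin", ProteinClass.LMW_GS),
        ("hypothetical protein", ProteinClass.UNKNOWN),
        ("", ProteinClass.UNKNOWN),
    ],
)
def test_attribute_protein_class(description, expected):
    assert attribute_protein_class(description) is expected


def test_allergen_code_beats_free_text_keywords():
    # conflicting signals: code wins over the gliadin keyword
    assert (
        attribute_protein_class("omega-gliadin-like (Tri a 26)")
        is ProteinClass.HMW_GS
    )


class TestEpitopeTables:
    def test_packaged_cd_table_has_34_unique_rows(self, cd_epitopes):
        assert len(cd_epitopes) == 34
        assert len({e.epitope_id for e in cd_epitopes}) == 34
        assert all(e.disease is Disease.CD for e in cd_epitopes)

    def test_packaged_wa_table_has_30_unique_rows(self, wa_epitopes):
        assert len(wa_epitopes) == 30
        assert all(e.disease is Disease.WA for e in wa_epitopes)

    def test_known_rows_parse_with_annotations(self, cd_epitopes, wa_epitopes):
        by_id = {e.epitope_id: e for e in cd_epitopes}
        assert by_id["93"].sequence == "FRPQQPYPQ"
        assert by_id["93"].restriction_or_allergen == "DQ2.5"
        assert by_id["93"].core_names == ("DQ2.5-glia-α3",)
        wa = {e.epitope_id: e for e in wa_epitopes}
        assert wa["148843"].sequence == "QQPQQPFPQL"
        assert wa["148843"].core_names == ()

    def test_round_trip_is_identical(self, tmp_path, cd_epitopes, wa_epitopes):
        for table in (cd_epitopes, wa_epitopes):
            path = tmp_path / "epi.csv"
            write_epitope_table(table, path)
            assert read_epitope_table(path) == table

    def test_packaged_fixture_round_trips_bit_identically(self, tmp_path):
        from importlib import resources

        for name, loader in (
            ("cd_epitopes.csv", load_cd_epitopes),
            ("wa_epitopes.csv", load_wa_epitopes),
        ):
            original = (
                resources.files("grainrisk.data").joinpath(name).read_bytes()
            )
            out = tmp_path / name
            write_epitope_table(loader(), out)
            assert out.read_bytes() == original

    def test_duplicate_id_is_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "epitope_id,disease,sequence,restriction_or_allergen,"
            "source_protein_label,core_names\n"
            "93,CD,FRPQQPYPQ,DQ2.5,a,\n93,CD,FRPQQPYPQ,DQ2.5,a,\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_epitope_table(path)

    def test_invalid_disease_code_is_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "epitope_id,disease,sequence,restriction_or_allergen,"
            "source_protein_label,core_names\n1,XX,FRPQQPYPQ,DQ2.5,a,\n"
        )
        with pytest.raises(FormatError, match="disease"):
            read_epitope_table(path)

    def test_missing_column_is_error(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("epitope_id,disease,sequence\n1,CD,FRPQQPYPQ\n")
        with pytest.raises(FormatError, match="missing"):
            read_epitope_table(path)

    def test_epitope_shorter_than_5_rejected(self):
        with pytest.raises(ValueError):
            EpitopeRecord("x", Disease.WA, "QQPF", "Tri a 19", "ω-gliadin")


class TestPresenceAndConservedFixtures:
    def test_presence_matrices_align_with_epitope_tables(
        self, cd_epitopes, wa_epitopes
    ):
        for disease, table in ((Disease.CD, cd_epitopes), (Disease.WA, wa_epitopes)):
            presence = load_presence_matrix(disease)
            assert list(presence.columns) == ["REF", "1", "2", "3", "4", "5"]
            assert set(presence.index) == {e.epitope_id for e in table}

    def test_reference_carries_every_cd_epitope(self):
        presence = load_presence_matrix(Disease.CD)
        assert presence["REF"].all()

    def test_conserved_id_annotations(self):
        cd_ids = load_conserved_gd_resistant_ids(Disease.CD)
        wa_ids = load_conserved_gd_resistant_ids(Disease.WA)
        assert "227" in cd_ids and "1044" in cd_ids
        assert len(wa_ids) == 25 and "17333" in wa_ids


class TestPeptideTables:
    def test_round_trip(self, tmp_path):
        rows = [
            IdentifiedPeptide(
                sequence="QPFPQPQLPY",
                sample_id="REF",
                stage=Stage.GD,
                digest_label=DigestLabel.GD,
                psm_count=4,
                score=2.1,
                confidence=Confidence.HIGH,
                unambiguous=True,
                modifications=((1, "pyroglutamate"),),
                provenance=(DigestLabel.CHY, DigestLabel.THE_CHY),
            )
        ]
        path = tmp_path / "p.tsv"
        write_peptide_table(rows, path)
        assert read_peptide_table(path) == rows

    def test_modification_position_bounds_enforced(self):
        with pytest.raises(ValueError):
            IdentifiedPeptide(
                "QQPF", "S", Stage.F1, modifications=((9, "deamidation"),)
            )

    def test_unknown_modification_rejected(self):
        with pytest.raises(ValueError):
            IdentifiedPeptide(
                "QQPF", "S", Stage.F1, modifications=((1, "phosphorylation"),)
            )
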