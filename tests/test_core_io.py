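"""Parsers, identification filters and TSV round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfaceome.core_io import (
    SampleKey,
    SpectralCountMatrix,
    filter_identifications,
    parse_domain_hits,
    parse_predictor_output,
    parse_topology_string,
    read_count_matrix,
    read_fasta,
    read_identifications,
    read_ratio_table,
    write_count_matrix,
    write_fasta,
    write_identifications,
    write_ratio_table,
)
from surfaceome.localization import CanonicalCompartment, Tool

from conftest import make_identification


class TestFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">Dred_0462 ferredoxin\nMKT\n")
        entries = read_fasta(path)
        assert len(entries) == 1
        assert entries[0].id == "Dred_0462"
        assert entries[0].description == "ferredoxin"
        assert entries[0].length == 3

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">A x\nMKT\n>A y\nMK\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)

    def test_lowercase_residues_uppercased_and_round_trip(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">A desc\nmktLLav\n")
        entries = read_fasta(path)
        assert entries[0].sequence == "MKTLLAV"
        assert entries[0].length == 7
        out = tmp_path / "out.fasta"
        write_fasta(entries, out)
        assert read_fasta(out) == entries

    def test_bad_residue_names_record(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">Dred_0001 z\nMK7\n")
        with pytest.raises(ValueError, match="Dred_0001"):
            read_fasta(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert read_fasta(path) == []
        assert any("no FASTA records" in m for m in caplog.messages)


class TestPredictorParsing:
    def test_tmh_one_line_topology_expansion(self, tmp_path):
        path = tmp_path / "tmh.txt"
        path.write_text("Dred_0462\tlen=120\tExpAA=21.9\tPredHel=1\tTopology=i98-117o\n")
        calls, topologies = parse_predictor_output(path, Tool.TMH_SCAN)
        assert len(calls) == len(topologies) == 1
        topo = topologies[0]
        assert topo.n_helices == 1
        assert topo.segments == ((98, 117),)
        assert topo.n_term_side == "in"
        assert calls[0].canonical_label is CanonicalCompartment.CYTOPLASMIC_MEMBRANE

    def test_tmh_zero_helices_is_uninformative(self, tmp_path):
        path = tmp_path / "tmh.txt"
        path.write_text("A\tlen=300\tPredHel=0\tTopology=o\n")
        calls, topologies = parse_predictor_output(path, Tool.TMH_SCAN)
        assert calls[0].canonical_label is CanonicalCompartment.UNKNOWN
        assert topologies[0].n_helices == 0

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("CytoplasmicMembrane", CanonicalCompartment.CYTOPLASMIC_MEMBRANE),
            ("Unknown", CanonicalCompartment.UNKNOWN),
            ("Non-cytoplasmic", CanonicalCompartment.SURFACE_UNKNOWN),
        ],
    )
    def test_psortb_row_canonicalized(self, tmp_path, raw, expected):
        path = tmp_path / "psortb.tsv"
        path.write_text(f"SeqID\tLocalization\tScore\nDred_1\t{raw}\t9.9\n")
        calls, topologies = parse_predictor_output(path, Tool.PSORTB)
        assert topologies == []
        assert calls[0].raw_label == raw
        assert calls[0].canonical_label is expected

    def test_locatep_flags(self, tmp_path):
        path = tmp_path / "locatep.tsv"
        path.write_text(
            "protein_id\tSubcellular Localization\tLipoprotein\tSecreted\n"
            "A\tMembrane\tyes\tno\nB\tSecreted\tno\tyes\n"
        )
        calls, _ = parse_predictor_output(path, Tool.LOCATEP)
        assert calls[0].lipoprotein and not calls[0].secreted
        assert calls[1].secreted and not calls[1].lipoprotein

    def test_missing_localization_value_names_line(self, tmp_path):
        path = tmp_path / "psortb.tsv"
        path.write_text("SeqID\tLocalization\nA\tCytoplasmic\nB\t\n")
        with pytest.raises(ValueError, match="line 3"):
            parse_predictor_output(path, Tool.PSORTB)

    def test_unknown_tool_rejected(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("SeqID\tLocalization\n")
        with pytest.raises(ValueError):
            parse_predictor_output(path, "SIGNALP")

    def test_one_call_per_row(self, tmp_path):
        rows = "".join(f"P{i}\tCytoplasmic\t1.0\n" for i in range(7))
        path = tmp_path / "psortb.tsv"
        path.write_text("SeqID\tLocalization\tScore\n" + rows)
        calls, _ = parse_predictor_output(path, Tool.PSORTB)
        assert len(calls) == 7


_DOMTBL_ROW = (
    "{name} {acc} 45 {pid} - 300 1e-12 50.0 0.1 1 1 1e-12 {ieval} 50.0 0.1 "
    "1 45 {start} {end} {start} {end} 0.95 -\n"
)


class TestDomainHits:
    def test_version_suffix_stripped(self, tmp_path):
        path = tmp_path / "dom.tbl"
        path.write_text(
            _DOMTBL_ROW.format(name="LysM", acc="PF01476.18", pid="A", ieval="1e-10", start=5, end=49)
        )
        (hit,) = parse_domain_hits(path)
        assert hit.accession == "PF01476"

    def test_comments_only_empty(self, tmp_path):
        path = tmp_path / "dom.tbl"
        path.write_text("# a comment\n# another\n")
        assert parse_domain_hits(path) == []

    def test_three_row_fixture_round_trips_values(self, tmp_path):
        rows = [
            ("LysM", "PF01476.18", "Dred_1", "2e-10", 10, 54),
            ("SLH", "PF00395.2", "Dred_2", "3e-08", 200, 244),
            ("DUF", "PF99999", "Dred_3", "0.5", 1, 45),
        ]
        path = tmp_path / "dom.tbl"
        path.write_text(
            "# comment\n"
            + "".join(
                _DOMTBL_ROW.format(name=n, acc=a, pid=p, ieval=e, start=s, end=t)
                for n, a, p, e, s, t in rows
            )
        )
        hits = parse_domain_hits(path)
        assert len(hits) == 3
        for hit, (name, acc, pid, evalue, start, end) in zip(hits, rows):
            assert hit.name == name
            assert hit.accession == acc.split(".")[0]
            assert hit.protein_id == pid
            assert hit.i_evalue == float(evalue)
            assert (hit.ali_start, hit.ali_end) == (start, end)

    def test_non_numeric_evalue_names_line(self, tmp_path):
        path = tmp_path / "dom.tbl"
        path.write_text(
            _DOMTBL_ROW.format(name="X", acc="PF1", pid="A", ieval="oops", start=1, end=2)
        )
        with pytest.raises(ValueError, match="line 1"):
            parse_domain_hits(path)


class TestIdentificationFilter:
    def test_min_peptides_removes_single_peptide_hits(self):
        records = [make_identification(n_peptides=1), make_identification(n_peptides=2)]
        kept = filter_identifications(records)
        assert kept == [records[1]]

    def test_fdr_threshold(self):
        good = make_identification(protein_fdr=0.005, n_peptides=3)
        bad = make_identification(protein_fdr=0.02, n_peptides=3)
        absent = make_identification(protein_fdr=None, n_peptides=3)
        assert filter_identifications([good, bad, absent]) == [good, absent]

    def test_vacuous_filter_is_identity(self):
        records = [make_identification(n_peptides=k, protein_fdr=0.5) for k in range(4)]
        assert filter_identifications(records, min_peptides=0, max_protein_fdr=1) == records

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.floats(0, 1, allow_nan=False)),
            max_size=30,
        )
    )
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_subsequence_and_idempotence(self, rows):
        records = [
            make_identification(protein_id=f"P{i}", n_peptides=n, protein_fdr=f)
            for i, (n, f) in enumerate(rows)
        ]
        kept = filter_identifications(records)
        it = iter(records)
        assert all(any(r is k for r in it) for k in kept)  # subsequence
        assert filter_identifications(kept) == kept  # idempotent


class TestRoundTrips:
    def test_count_matrix_round_trip(self, tmp_path):
        matrix = SpectralCountMatrix(
            protein_ids=["A", "B"],
            samples=[
                SampleKey("protoplast", "fermentation", "R1", None),
                SampleKey("protoplast", "fe_reduction", "R2", 120),
            ],
            counts=np.array([[3, 0], [7, 11]]),
        )
        path = tmp_path / "counts.tsv"
        write_count_matrix(matrix, path)
        back = read_count_matrix(path)
        assert back.protein_ids == matrix.protein_ids
        assert back.samples == matrix.samples
        assert (back.counts == matrix.counts).all()

    def test_ratio_table_round_trip(self, tmp_path):
        table = pd.DataFrame(
            {
                "protein_id": ["A", "A"],
                "log2_ratio": [0.51, -0.47],
                "intensity": [1.5e7, 1.5e7],
                "comparison": ["fe_vs_ferm"] * 2,
                "label_swapped": [False, True],
            }
        )
        path = tmp_path / "ratios.tsv"
        write_ratio_table(table, path)
        back = read_ratio_table(path)
        pd.testing.assert_frame_equal(back, table)

    def test_identifications_round_trip(self, tmp_path):
        records = [
            make_identification(protein_id="A", protein_fdr=0.004),
            make_identification(protein_id="B", protein_fdr=None, n_peptides=5),
        ]
        path = tmp_path / "ids.tsv"
        write_identifications(records, path)
        assert read_identifications(path) == records

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SpectralCountMatrix(
                protein_ids=["A"],
                samples=[SampleKey("protoplast", "fermentation", "R1", None)],
                counts=np.array([[-1]]),
            )


class TestTopologyString:
    @pytest.mark.parametrize(
        "topo,n,segments,side",
        [
            ("i98-117o", 1, ((98, 117),), "in"),
            ("o5-27i44-66o", 2, ((5, 27), (44, 66)), "out"),
            ("i", 0, (), "in"),
        ],
    )
    def test_decodings(self, topo, n, segments, side):
        record = parse_topology_string("X", topo)
        assert (record.n_helices, record.segments, record.n_term_side) == (
            n,
            segments,
            side,
        )

    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_topology_string("X", "98-117")
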