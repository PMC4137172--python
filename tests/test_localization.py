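"""Consensus localization, anchors, binding mechanisms and the surface split."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfaceome.core_io import DomainHit, PredictorCall, TopologyRecord
from surfaceome.localization import (
    AnchorClass,
    BindingMechanism,
    CanonicalCompartment as C,
    Confidence,
    Tool,
    assign_binding_mechanism,
    canonicalize_label,
    consensus_localization,
    interpret_topology,
    load_label_map,
    partition_surfaceome,
)


def call(tool, compartment, pid="P1"):
    return PredictorCall(
        protein_id=pid, tool=tool, raw_label=compartment.value, canonical_label=compartment
    )


class TestCanonicalize:
    @pytest.mark.parametrize(
        "tool,raw,expected",
        [
            (Tool.PSORTB, "CytoplasmicMembrane", C.CYTOPLASMIC_MEMBRANE),
            (Tool.LOCATEP, "Cytoplasmic", C.CYTOPLASM),
            (Tool.PSORTB, "Cellwall", C.CELL_WALL),
            (Tool.LOCATEP, "Secreted", C.EXTRACELLULAR),
            (Tool.PSORTB, "Unknown", C.UNKNOWN),
            (Tool.PSORTB, "Non-cytoplasmic", C.SURFACE_UNKNOWN),
            (Tool.TMH_SCAN, "PredHel=3", C.CYTOPLASMIC_MEMBRANE),
            (Tool.TMH_SCAN, "PredHel=0", C.UNKNOWN),
        ],
    )
    def test_fixed_mapping(self, tool, raw, expected):
        assert canonicalize_label(tool, raw) is expected

    def test_unmapped_label_falls_back_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert canonicalize_label(Tool.PSORTB, "banana") is C.UNKNOWN
        assert any("banana" in m for m in caplog.messages)

    def test_shipped_yaml_matches_builtin_table(self):
        table = load_label_map()
        assert table["cytoplasmicmembrane"] is C.CYTOPLASMIC_MEMBRANE
        assert table["non-cytoplasmic"] is C.SURFACE_UNKNOWN


def topo(pid, segments, side="in"):
    return TopologyRecord(pid, len(segments), tuple(segments), side)


class TestInterpretTopology:
    def test_single_helix_near_c_terminus(self):
        # one TMH at residues 98-117 of a 120-residue chain: C-terminal anchor
        assert (
            interpret_topology(topo("X", [(98, 117)]), 120)
            is AnchorClass.C_TERMINAL_ANCHOR
        )

    def test_single_helix_at_n_terminus(self):
        assert (
            interpret_topology(topo("X", [(5, 27)]), 300)
            is AnchorClass.N_TERMINAL_ANCHOR
        )

    def test_five_helices_polytopic(self):
        segments = [(i * 40 + 1, i * 40 + 20) for i in range(5)]
        assert interpret_topology(topo("X", segments), 250) is AnchorClass.POLYTOPIC

    def test_no_helices(self):
        assert interpret_topology(topo("X", []), 200) is AnchorClass.NONE

    def test_midpoint_rule_for_internal_helix(self):
        # helix outside both windows: assigned by midpoint half
        assert (
            interpret_topology(topo("X", [(120, 140)]), 400, 35, 40)
            is AnchorClass.N_TERMINAL_ANCHOR
        )
        assert (
            interpret_topology(topo("X", [(260, 280)]), 400, 35, 40)
            is AnchorClass.C_TERMINAL_ANCHOR
        )

    def test_segment_outside_protein_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            interpret_topology(topo("X", [(98, 117)]), 100)


def hit(accession, evalue=1e-10, pid="P1"):
    return DomainHit(pid, accession, accession, 1, 40, evalue)


class TestBindingMechanism:
    @pytest.mark.parametrize(
        "accession,expected",
        [
            ("PF00395", BindingMechanism.SLH),
            ("PF01476", BindingMechanism.LYSM),
            ("PF01473", BindingMechanism.CWBD1),
            ("PF04122", BindingMechanism.CWBD2),
            ("PF13457", BindingMechanism.GW),
        ],
    )
    def test_wall_binding_domains(self, accession, expected):
        assert assign_binding_mechanism([hit(accession)]) is expected

    def test_truncated_slh_accession_not_accepted(self):
        assert assign_binding_mechanism([hit("PF0039")]) is BindingMechanism.NONE

    def test_lpxtg_beats_domains(self):
        assert (
            assign_binding_mechanism([hit("PF00395")], lpxtg=True)
            is BindingMechanism.LPXTG
        )

    def test_priority_is_total_order(self):
        hits = [hit("PF13457"), hit("PF01476"), hit("PF04122")]
        assert assign_binding_mechanism(hits) is BindingMechanism.LYSM

    def test_evalue_cutoff_excludes_weak_hits(self):
        assert (
            assign_binding_mechanism([hit("PF01476", evalue=1e-3)])
            is BindingMechanism.NONE
        )

    def test_lipoprotein_fallback(self):
        assert assign_binding_mechanism([], lipoprotein=True) is BindingMechanism.LIPID_ANCHOR

    def test_tmh_fallback_then_none(self):
        assert (
            assign_binding_mechanism([], anchor=AnchorClass.POLYTOPIC)
            is BindingMechanism.TMH_ANCHOR
        )
        assert assign_binding_mechanism([]) is BindingMechanism.NONE


class TestConsensus:
    def test_unanimous_cytoplasm_excluded_from_surfaceome(self):
        calls = [call(t, C.CYTOPLASM) for t in Tool]
        ann = consensus_localization(calls)
        assert ann.compartment is C.CYTOPLASM
        assert ann.confidence is Confidence.CONSENSUS
        assert not ann.is_surface
        assert ann.supporting_tools == frozenset(Tool)

    def test_two_membrane_calls_one_unknown(self):
        # TMH-derived membrane call corroborated by a second tool
        calls = [
            call(Tool.TMH_SCAN, C.CYTOPLASMIC_MEMBRANE),
            call(Tool.PSORTB, C.CYTOPLASMIC_MEMBRANE),
            call(Tool.LOCATEP, C.UNKNOWN),
        ]
        ann = consensus_localization(calls, anchor=AnchorClass.C_TERMINAL_ANCHOR)
        assert ann.compartment is C.CYTOPLASMIC_MEMBRANE
        assert ann.confidence is Confidence.CONSENSUS
        assert ann.is_surface

    def test_membrane_evidence_against_lone_cytoplasm_call(self):
        # a potentially membrane-bound protein with one cytoplasmic call is
        # kept in the surfaceome as surface-unknown
        calls = [
            call(Tool.TMH_SCAN, C.CYTOPLASMIC_MEMBRANE),
            call(Tool.LOCATEP, C.CYTOPLASM),
            call(Tool.PSORTB, C.UNKNOWN),
        ]
        ann = consensus_localization(calls, anchor=AnchorClass.N_TERMINAL_ANCHOR)
        assert ann.compartment is C.SURFACE_UNKNOWN
        assert ann.confidence is Confidence.UNRESOLVED
        assert ann.is_surface

    def test_single_non_cytoplasm_call_accepted_as_tiebreak(self):
        calls = [call(Tool.PSORTB, C.CELL_WALL), call(Tool.LOCATEP, C.UNKNOWN)]
        ann = consensus_localization(calls)
        assert ann.compartment is C.CELL_WALL
        assert ann.confidence is Confidence.EVIDENCE_TIEBREAK

    def test_lone_cytoplasm_call_without_anchor_stays_cytoplasmic(self):
        ann = consensus_localization([call(Tool.LOCATEP, C.CYTOPLASM)])
        assert ann.compartment is C.CYTOPLASM
        assert not ann.is_surface

    def test_all_unknown_with_anchor_is_surface(self):
        ann = consensus_localization(
            [call(t, C.UNKNOWN) for t in Tool], anchor=AnchorClass.POLYTOPIC
        )
        assert ann.compartment is C.UNKNOWN
        assert ann.is_surface

    def test_duplicate_tool_rejected(self):
        with pytest.raises(ValueError, match="two calls"):
            consensus_localization(
                [call(Tool.PSORTB, C.CYTOPLASM), call(Tool.PSORTB, C.CELL_WALL)]
            )

    @given(
        st.lists(
            st.sampled_from(
                [C.CYTOPLASM, C.CYTOPLASMIC_MEMBRANE, C.CELL_WALL, C.EXTRACELLULAR,
                 C.SURFACE_UNKNOWN, C.UNKNOWN]
            ),
            min_size=0,
            max_size=3,
        ),
        st.sampled_from(list(AnchorClass)),
    )
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_permutation_invariance(self, compartments, anchor):
        calls = [call(t, c) for t, c in zip(Tool, compartments)]
        results = {
            (
                consensus_localization(list(p), anchor=anchor, protein_id="P1").compartment,
                consensus_localization(list(p), anchor=anchor, protein_id="P1").confidence,
            )
            for p in itertools.permutations(calls)
        }
        assert len(results) == 1

    @pytest.mark.parametrize("compartment", [C.CYTOPLASMIC_MEMBRANE, C.CELL_WALL])
    def test_agreeing_call_never_lowers_confidence(self, compartment):
        rank = {
            Confidence.UNRESOLVED: 0,
            Confidence.EVIDENCE_TIEBREAK: 1,
            Confidence.CONSENSUS: 2,
        }
        anchor = AnchorClass.NONE
        one = consensus_localization([call(Tool.PSORTB, compartment)], anchor=anchor)
        two = consensus_localization(
            [call(Tool.PSORTB, compartment), call(Tool.LOCATEP, compartment)],
            anchor=anchor,
        )
        three = consensus_localization(
            [call(t, compartment) for t in Tool], anchor=anchor
        )
        assert rank[one.confidence] <= rank[two.confidence] <= rank[three.confidence]
        assert one.compartment is two.compartment is three.compartment


class TestPartition:
    def test_partition_arithmetic(self):
        annotations = [
            consensus_localization([call(t, C.CYTOPLASM, pid=f"c{i}") for t in Tool])
            for i in range(4)
        ] + [
            consensus_localization(
                [call(t, C.CYTOPLASMIC_MEMBRANE, pid=f"s{i}") for t in Tool]
            )
            for i in range(6)
        ]
        surface, cytoplasm = partition_surfaceome(annotations)
        assert len(surface) == 6
        assert len(cytoplasm) == 4
        assert {a.protein_id for a in surface} | {a.protein_id for a in cytoplasm} == {
            a.protein_id for a in annotations
        }

    def test_empty_input(self):
        assert partition_surfaceome([]) == ([], [])

    def test_duplicate_protein_rejected(self):
        ann = consensus_localization([call(Tool.PSORTB, C.CYTOPLASM)])
        with pytest.raises(ValueError, match="duplicate"):
            partition_surfaceome([ann, ann])
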