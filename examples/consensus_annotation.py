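"""Consensus localization of two borderline proteins.

A membrane-bound hydrogenase subunit with one C-terminal transmembrane helix
is corroborated by a PSORTb-style membrane call (two tools agree, so the
assignment is trusted); a ferredoxin with an N-terminal helix is contradicted
by a cytoplasmic call and lands in the surface-unknown class — kept in the
surfaceome for manual curation because it is potentially membrane bound.
"""

from surfaceome import (
    CanonicalCompartment as C,
    PredictorCall,
    Tool,
    TopologyRecord,
    consensus_localization,
    interpret_topology,
)


def call(pid, tool, compartment):
    return PredictorCall(pid, tool, compartment.value, compartment)


# one TMH at residues 98-117 of a 120-residue chain: a C-terminal anchor
hydrogenase_topology = TopologyRecord("hydrogenase_4fe4s", 1, ((98, 117),), "in")
anchor = interpret_topology(hydrogenase_topology, protein_length=120)
annotation = consensus_localization(
    [
        call("hydrogenase_4fe4s", Tool.TMH_SCAN, C.CYTOPLASMIC_MEMBRANE),
        call("hydrogenase_4fe4s", Tool.PSORTB, C.CYTOPLASMIC_MEMBRANE),
        call("hydrogenase_4fe4s", Tool.LOCATEP, C.UNKNOWN),
    ],
    anchor=anchor,
)
print(f"{annotation.protein_id}: {annotation.compartment.value} "
      f"({annotation.confidence.value}, anchor {annotation.anchor.value}, "
      f"surface={annotation.is_surface})")

ferredoxin_topology = TopologyRecord("ferredoxin_nterm", 1, ((5, 27),), "out")
anchor = interpret_topology(ferredoxin_topology, protein_length=310)
annotation = consensus_localization(
    [
        call("ferredoxin_nterm", Tool.TMH_SCAN, C.CYTOPLASMIC_MEMBRANE),
        call("ferredoxin_nterm", Tool.LOCATEP, C.CYTOPLASM),
        call("ferredoxin_nterm", Tool.PSORTB, C.UNKNOWN),
    ],
    anchor=anchor,
)
print(f"{annotation.protein_id}: {annotation.compartment.value} "
      f"({annotation.confidence.value}, anchor {annotation.anchor.value}, "
      f"surface={annotation.is_surface})")
# The first line reports a consensus membrane protein; the second a
# conflicting case kept as SURFACE_UNKNOWN rather than silently dropped.
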