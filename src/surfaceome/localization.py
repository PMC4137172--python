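"""Consensus subcellular localization for Gram-positive surfaceome annotation.

Secreted and surface-attached proteins of a Gram-positive bacterium live in
one of four compartments: cytoplasm (C), cytoplasmic membrane (CM), cell
wall (CW) or the extracellular milieu (EC).  Individual localization
predictors (a transmembrane-helix scanner, PSORTb-style and LocateP-style
classifiers) disagree frequently, so this module combines their calls under
a majority rule — an assignment supported by at least two tools is trusted —
and falls back on a deterministic evidence hierarchy (membrane-anchor
topology, secretion flags) when the tools conflict.  Proteins whose
cytoplasmic localization can be excluded but whose compartment cannot be
pinned down are assigned the distinct ``SURFACE_UNKNOWN`` class.

The module also classifies the physical surface-attachment mechanism from
Pfam domain hits (LysM, SLH, choline-binding CWBD_1, CWBD_2, GW modules),
covalent LPxTG sorting signals, lipoprotein lipid anchors and transmembrane
helices, under a fixed priority order.

All residue coordinates are 1-based inclusive.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .core_io import DomainHit, PredictorCall, TopologyRecord

logger = logging.getLogger(__name__)


class Tool(str, enum.Enum):
    """The three localization predictors whose outputs are combined."""

    TMH_SCAN = "TMH_SCAN"
    PSORTB = "PSORTB"
    LOCATEP = "LOCATEP"


class CanonicalCompartment(str, enum.Enum):
    CYTOPLASM = "CYTOPLASM"
    CYTOPLASMIC_MEMBRANE = "CYTOPLASMIC_MEMBRANE"
    CELL_WALL = "CELL_WALL"
    EXTRACELLULAR = "EXTRACELLULAR"
    #: not cytoplasmic, but the precise surface compartment is undetermined
    SURFACE_UNKNOWN = "SURFACE_UNKNOWN"
    UNKNOWN = "UNKNOWN"


class AnchorClass(str, enum.Enum):
    NONE = "NONE"
    N_TERMINAL_ANCHOR = "N_TERMINAL_ANCHOR"
    C_TERMINAL_ANCHOR = "C_TERMINAL_ANCHOR"
    POLYTOPIC = "POLYTOPIC"


class BindingMechanism(str, enum.Enum):
    LPXTG = "LPXTG"
    SLH = "SLH"
    LYSM = "LYSM"
    CWBD1 = "CWBD1"
    CWBD2 = "CWBD2"
    GW = "GW"
    LIPID_ANCHOR = "LIPID_ANCHOR"
    TMH_ANCHOR = "TMH_ANCHOR"
    NONE = "NONE"


class Confidence(str, enum.Enum):
    CONSENSUS = "consensus"
    EVIDENCE_TIEBREAK = "evidence_tiebreak"
    UNRESOLVED = "unresolved"


#: Pfam accessions (bare, no version suffix) of the cell-wall binding domains,
#: in the priority order used by assign_binding_mechanism.  Note the SLH
#: accession is PF00395; the truncated form "PF0039" is not accepted.
BINDING_DOMAIN_PRIORITY: tuple[tuple[str, BindingMechanism], ...] = (
    ("PF00395", BindingMechanism.SLH),
    ("PF01476", BindingMechanism.LYSM),
    ("PF01473", BindingMechanism.CWBD1),
    ("PF04122", BindingMechanism.CWBD2),
    ("PF13457", BindingMechanism.GW),
)

# Tool-vocabulary -> canonical compartment.  Keys are lower-cased before
# lookup; the table is shared across tools because their vocabularies do not
# collide.  Shipped also as editable YAML (data/label_map.yaml); see
# load_label_map.
_DEFAULT_LABEL_MAP: dict[str, CanonicalCompartment] = {
    "cytoplasmic": CanonicalCompartment.CYTOPLASM,
    "cytoplasm": CanonicalCompartment.CYTOPLASM,
    "intracellular": CanonicalCompartment.CYTOPLASM,
    "cytoplasmicmembrane": CanonicalCompartment.CYTOPLASMIC_MEMBRANE,
    "cytoplasmic membrane": CanonicalCompartment.CYTOPLASMIC_MEMBRANE,
    "membrane": CanonicalCompartment.CYTOPLASMIC_MEMBRANE,
    "cellwall": CanonicalCompartment.CELL_WALL,
    "cell wall": CanonicalCompartment.CELL_WALL,
    "extracellular": CanonicalCompartment.EXTRACELLULAR,
    "secreted": CanonicalCompartment.EXTRACELLULAR,
    "secretory": CanonicalCompartment.EXTRACELLULAR,
    "unknown": CanonicalCompartment.UNKNOWN,
    "unknown (may have multiple localization sites)": CanonicalCompartment.UNKNOWN,
    "non-cytoplasmic": CanonicalCompartment.SURFACE_UNKNOWN,
    "noncytoplasmic": CanonicalCompartment.SURFACE_UNKNOWN,
    "surface-unknown": CanonicalCompartment.SURFACE_UNKNOWN,
}


def load_label_map(path=None) -> dict[str, CanonicalCompartment]:
    """Load the raw-label -> compartment mapping table.

    With no argument, the table shipped with the package
    (``data/label_map.yaml``) is read; pass a path to substitute an edited
    copy.  Values must name ``CanonicalCompartment`` members.
    """
    import yaml

    if path is None:
        from importlib import resources

        text = resources.files("surfaceome").joinpath("data/label_map.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {str(k).lower(): CanonicalCompartment[v] for k, v in raw.items()}


def canonicalize_label(
    tool: Tool | str,
    raw_label: str,
    label_map: Mapping[str, CanonicalCompartment] | None = None,
) -> CanonicalCompartment:
    """Map a predictor's raw localization string onto the canonical classes.

    The mapping is a fixed, case-insensitive table.  For the TMH scanner the
    raw label encodes the predicted helix count (``PredHel=N``): one or more
    helices imply a membrane call, zero helices are uninformative.  Labels
    outside the table fall back to ``UNKNOWN`` with a logged warning — the
    fallback is deliberate, so an unexpected vocabulary cannot silently
    promote a protein to the surfaceome.
    """
    tool = Tool(tool)
    label = raw_label.strip()
    if tool is Tool.TMH_SCAN and label.lower().startswith("predhel="):
        try:
            n = int(label.split("=", 1)[1])
        except ValueError:
            logger.warning("unparseable TMH-scan label %r -> UNKNOWN", raw_label)
            return CanonicalCompartment.UNKNOWN
        return (
            CanonicalCompartment.CYTOPLASMIC_MEMBRANE
            if n >= 1
            else CanonicalCompartment.UNKNOWN
        )
    table = _DEFAULT_LABEL_MAP if label_map is None else label_map
    try:
        return table[label.lower()]
    except KeyError:
        logger.warning("unmapped %s label %r -> UNKNOWN", tool.value, raw_label)
        return CanonicalCompartment.UNKNOWN


def interpret_topology(
    topology: "TopologyRecord",
    protein_length: int,
    n_term_window: int = 35,
    c_term_window: int = 40,
) -> AnchorClass:
    """Classify a helix topology into a membrane-anchor class.

    Zero predicted helices mean no membrane association; two or more mean a
    polytopic membrane protein.  A single helix is an N-terminal anchor when
    it starts within ``n_term_window`` residues of the N-terminus, a
    C-terminal anchor when it ends within ``c_term_window`` residues of the
    C-terminus, and otherwise is assigned to whichever protein half holds its
    midpoint.  The window defaults reflect typical signal-anchor and
    tail-anchor lengths.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    for start, end in topology.segments:
        if not (1 <= start <= end <= protein_length):
            raise ValueError(
                f"{topology.protein_id}: helix segment ({start},{end}) outside "
                f"[1,{protein_length}]"
            )
    n = topology.n_helices
    if n == 0:
        return AnchorClass.NONE
    if n >= 2:
        return AnchorClass.POLYTOPIC
    start, end = topology.segments[0]
    if start <= n_term_window:
        return AnchorClass.N_TERMINAL_ANCHOR
    if end >= protein_length - c_term_window:
        return AnchorClass.C_TERMINAL_ANCHOR
    midpoint = (start + end) / 2
    if midpoint <= protein_length / 2:
        return AnchorClass.N_TERMINAL_ANCHOR
    return AnchorClass.C_TERMINAL_ANCHOR


def assign_binding_mechanism(
    domains: Iterable["DomainHit"],
    lipoprotein: bool = False,
    lpxtg: bool = False,
    anchor: AnchorClass = AnchorClass.NONE,
    evalue_cutoff: float = 1e-5,
) -> BindingMechanism:
    """Assign the single surface-binding mechanism of a protein.

    Covalent LPxTG sorting beats every non-covalent wall-binding domain;
    among domain hits passing the e-value cutoff the priority is
    SLH > LysM > CWBD_1 > CWBD_2 > GW.  Without wall-binding evidence a
    lipoprotein signal implies a lipid anchor, and any transmembrane helix a
    TMH anchor.  Exactly one mechanism is returned.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    if lpxtg:
        return BindingMechanism.LPXTG
    accepted = {d.accession for d in domains if d.i_evalue <= evalue_cutoff}
    for accession, mechanism in BINDING_DOMAIN_PRIORITY:
        if accession in accepted:
            return mechanism
    if lipoprotein:
        return BindingMechanism.LIPID_ANCHOR
    if anchor is not AnchorClass.NONE:
        return BindingMechanism.TMH_ANCHOR
    return BindingMechanism.NONE


@dataclass(frozen=True)
class SurfaceomeAnnotation:
    """Final per-protein annotation: compartment, anchor, binding, surface flag."""

    protein_id: str
    compartment: CanonicalCompartment
    confidence: Confidence
    anchor: AnchorClass
    binding: BindingMechanism
    is_surface: bool
    supporting_tools: frozenset[Tool]

    def __post_init__(self) -> None:
        if self.confidence is Confidence.CONSENSUS and len(self.supporting_tools) < 2:
            raise ValueError(
                f"{self.protein_id}: consensus confidence requires >=2 supporting tools"
            )


def _is_surface(compartment: CanonicalCompartment, anchor: AnchorClass) -> bool:
    if compartment is CanonicalCompartment.CYTOPLASM:
        return False
    if compartment is CanonicalCompartment.UNKNOWN:
        return anchor is not AnchorClass.NONE
    return True


def consensus_localization(
    calls: Sequence["PredictorCall"],
    anchor: AnchorClass = AnchorClass.NONE,
    protein_id: str | None = None,
    binding: BindingMechanism = BindingMechanism.NONE,
) -> SurfaceomeAnnotation:
    """Combine per-tool localization calls into one consensus annotation.

    An assignment supported by at least two tools is trusted outright
    (``consensus``).  A single informative call is accepted when it is
    compatible with the anchor evidence or places the protein outside the
    cytoplasm (``evidence_tiebreak``).  A cytoplasmic call contradicted by
    membrane-anchor topology yields ``SURFACE_UNKNOWN`` — the protein is
    potentially membrane bound, so it stays in the surfaceome for curation —
    and irreconcilable conflicts are flagged ``unresolved``.  ``UNKNOWN``
    calls never count toward agreement, and the result is independent of the
    order in which tool calls are supplied.
    """
    by_tool: dict[Tool, CanonicalCompartment] = {}
    pid = protein_id
    for call in calls:
        tool = Tool(call.tool)
        if tool in by_tool:
            raise ValueError(f"two calls from tool {tool.value}")
        by_tool[tool] = CanonicalCompartment(call.canonical_label)
        if pid is None:
            pid = call.protein_id
    if pid is None:
        raise ValueError("protein_id required when no calls are supplied")

    informative = {
        t: c for t, c in by_tool.items() if c is not CanonicalCompartment.UNKNOWN
    }
    votes = Counter(informative.values())
    anchored = anchor is not AnchorClass.NONE

    if votes and votes.most_common(1)[0][1] >= 2:
        compartment = votes.most_common(1)[0][0]
        confidence = Confidence.CONSENSUS
        supporting = frozenset(t for t, c in informative.items() if c == compartment)
    elif len(informative) == 1:
        ((tool, compartment),) = informative.items()
        if compartment is not CanonicalCompartment.CYTOPLASM:
            confidence = Confidence.EVIDENCE_TIEBREAK
            supporting = frozenset({tool})
        elif anchored:
            # membrane-anchor evidence against a lone cytoplasmic call
            compartment = CanonicalCompartment.SURFACE_UNKNOWN
            confidence = Confidence.UNRESOLVED
            supporting = frozenset()
        else:
            confidence = Confidence.UNRESOLVED
            supporting = frozenset({tool})
    elif len(informative) >= 2:
        # >=2 distinct informative calls, no majority
        if CanonicalCompartment.CYTOPLASM in votes:
            compartment = (
                CanonicalCompartment.SURFACE_UNKNOWN
                if anchored
                else CanonicalCompartment.UNKNOWN
            )
        else:
            # the tools disagree on the compartment but agree it is not
            # cytoplasmic, which is exactly the surface-unknown class
            compartment = CanonicalCompartment.SURFACE_UNKNOWN
        confidence = Confidence.UNRESOLVED
        supporting = frozenset()
    else:
        compartment = CanonicalCompartment.UNKNOWN
        confidence = Confidence.UNRESOLVED
        supporting = frozenset()

    return SurfaceomeAnnotation(
        protein_id=pid,
        compartment=compartment,
        confidence=confidence,
        anchor=anchor,
        binding=binding,
        is_surface=_is_surface(compartment, anchor),
        supporting_tools=supporting,
    )


def partition_surfaceome(
    annotations: Iterable[SurfaceomeAnnotation],
) -> tuple[list[SurfaceomeAnnotation], list[SurfaceomeAnnotation]]:
    """Split annotations into (surface, cytoplasm) lists.

    The two lists partition the input: every annotation lands in exactly one.
    "Cytoplasm" here means excluded from the surfaceome, i.e. confidently
    cytoplasmic or unknown without any membrane-association evidence.
    """
    seen: set[str] = set()
    surface: list[SurfaceomeAnnotation] = []
    cytoplasm: list[SurfaceomeAnnotation] = []
    for ann in annotations:
        if ann.protein_id in seen:
            raise ValueError(f"duplicate annotation for {ann.protein_id}")
        seen.add(ann.protein_id)
        (surface if ann.is_surface else cytoplasm).append(ann)
    return surface, cytoplasm
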