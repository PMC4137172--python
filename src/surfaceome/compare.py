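"""Cross-experiment membership accounting and function/localization tallies.

The two surface-protein extraction experiments (protoplast formation and
trypsin cell shaving with its shedding control) identify overlapping but
distinct protein sets.  This module does the set algebra — per-experiment
totals, unique-to-experiment and shared counts, each split into surface and
cytoplasm by the localization consensus — and builds the function-category
crosstab: surface proteins by functional class versus compartment,
experiment membership and differential-expression outcome.  Every axis of
the crosstab sums to the same grand total, so the tallies are internally
consistent by construction.

Function assignment uses a transparent ordered rule table (keyword or Pfam
accession -> category, first match wins) shipped as editable TSV; it is a
deliberately simple stand-in for manual curation and documented as an
approximation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .localization import CanonicalCompartment, SurfaceomeAnnotation


class FunctionCategory(str, enum.Enum):
    TRANSPORT = "TRANSPORT"
    CHEMOTAXIS = "CHEMOTAXIS"
    PROTEASE_CW_HYDROLASE = "PROTEASE_CW_HYDROLASE"
    REDOX = "REDOX"
    OTHER_UNKNOWN = "OTHER_UNKNOWN"


#: Display order of the function rows, mirroring the published tally layout.
FUNCTION_ORDER = (
    FunctionCategory.TRANSPORT,
    FunctionCategory.CHEMOTAXIS,
    FunctionCategory.PROTEASE_CW_HYDROLASE,
    FunctionCategory.OTHER_UNKNOWN,
    FunctionCategory.REDOX,
)

LOCALIZATION_CLASSES = ("S-U", "CM", "CW", "EC")
MEMBERSHIP_CLASSES = ("only_P", "only_Sh", "both")
DE_CLASSES = ("up_ferm", "up_fe", "ns")

#: Surface compartments collapsed to tally columns.  UNKNOWN-compartment
#: surface proteins (kept for their membrane-anchor evidence) count as
#: surface-unknown.
_COMPARTMENT_TO_CLASS = {
    CanonicalCompartment.SURFACE_UNKNOWN: "S-U",
    CanonicalCompartment.UNKNOWN: "S-U",
    CanonicalCompartment.CYTOPLASMIC_MEMBRANE: "CM",
    CanonicalCompartment.CELL_WALL: "CW",
    CanonicalCompartment.EXTRACELLULAR: "EC",
}


@dataclass(frozen=True)
class MembershipRow:
    total: int
    surface: int
    cytoplasm: int

    def __post_init__(self) -> None:
        if min(self.total, self.surface, self.cytoplasm) < 0:
            raise ValueError("negative counts")
        if self.total != self.surface + self.cytoplasm:
            raise ValueError("total != surface + cytoplasm")


@dataclass(frozen=True)
class MembershipTally:
    """Per-experiment totals, unique counts and the shared count, each split
    into surface and cytoplasm."""

    experiments: tuple[str, str]
    total: Mapping[str, MembershipRow]
    unique: Mapping[str, MembershipRow]
    shared: MembershipRow

    def to_frame(self) -> pd.DataFrame:
        a, b = self.experiments
        rows = [
            ("total", a, self.total[a]),
            ("total", b, self.total[b]),
            ("unique", a, self.unique[a]),
            ("unique", b, self.unique[b]),
            ("shared", f"{a}&{b}", self.shared),
        ]
        return pd.DataFrame(
            {
                "tier": [t for t, _, _ in rows],
                "experiment": [e for _, e, _ in rows],
                "total_extract": [r.total for _, _, r in rows],
                "surface": [r.surface for _, _, r in rows],
                "cytoplasm": [r.cytoplasm for _, _, r in rows],
            }
        )


def membership_tally(
    sets: Mapping[str, set[str] | frozenset[str]],
    surface: set[str] | frozenset[str],
) -> MembershipTally:
    """Tally protein membership across the two extraction experiments.

    ``sets`` maps exactly two experiment names to their identified protein-id
    sets; ``surface`` is the surfaceome subset of their union.  Unique and
    shared counts come from set algebra, and every row is split by
    intersection with the surface set, so the tally invariants
    (total = unique + shared; total = surface + cytoplasm) hold by
    construction.
    """
    if len(sets) != 2:
        raise ValueError("membership_tally expects exactly two experiments")
    (name_a, set_a), (name_b, set_b) = ((k, frozenset(v)) for k, v in sets.items())
    surface = frozenset(surface)
    extra = surface - (set_a | set_b)
    if extra:
        raise ValueError(
            f"surface set contains proteins absent from both experiments: "
            f"{sorted(extra)[:5]}..."
        )

    def row(ids: frozenset[str]) -> MembershipRow:
        n_surface = len(ids & surface)
        return MembershipRow(
            total=len(ids), surface=n_surface, cytoplasm=len(ids) - n_surface
        )

    shared_ids = set_a & set_b
    return MembershipTally(
        experiments=(name_a, name_b),
        total={name_a: row(set_a), name_b: row(set_b)},
        unique={name_a: row(set_a - set_b), name_b: row(set_b - set_a)},
        shared=row(shared_ids),
    )


# ---------------------------------------------------------------------------
# function categories


@dataclass(frozen=True)
class FunctionRule:
    kind: str  # {keyword, accession}
    pattern: str
    category: FunctionCategory

    def __post_init__(self) -> None:
        if self.kind not in ("keyword", "accession"):
            raise ValueError(f"bad rule kind {self.kind!r}")
        if not self.pattern:
            raise ValueError("empty rule pattern")


def load_function_rules(path=None) -> list[FunctionRule]:
    """Load the ordered (pattern -> category) rule table.

    Default is the table shipped with the package
    (``data/function_rules.tsv``): three tab-separated columns
    ``kind  pattern  category``, ``#`` comments allowed, order significant.
    """
    if path is None:
        from importlib import resources

        text = (
            resources.files("surfaceome")
            .joinpath("data/function_rules.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    rules: list[FunctionRule] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise ValueError(f"rule table line {lineno}: expected 3 columns")
        kind, pattern, category = (f.strip() for f in fields)
        try:
            cat = FunctionCategory[category]
        except KeyError as exc:
            raise ValueError(
                f"rule table line {lineno}: unknown category {category!r}"
            ) from exc
        rules.append(FunctionRule(kind=kind, pattern=pattern, category=cat))
    return rules


def categorize_function(
    description: str,
    domain_accessions: Iterable[str] = (),
    rules: Sequence[FunctionRule] | None = None,
) -> FunctionCategory:
    """Assign a protein to a functional category by the first matching rule.

    Keyword rules match case-insensitively as substrings of the protein
    description; accession rules match bare Pfam accessions of the protein's
    domain hits.  No match falls through to OTHER_UNKNOWN.
    """
    if rules is None:
        rules = load_function_rules()
    text = description.lower()
    accessions = set(domain_accessions)
    for rule in rules:
        if rule.kind == "keyword":
            if rule.pattern.lower() in text:
                return rule.category
        else:
            if rule.pattern in accessions:
                return rule.category
    return FunctionCategory.OTHER_UNKNOWN


# ---------------------------------------------------------------------------
# crosstab


@dataclass(frozen=True)
class CrossTab:
    """Function-by-axis count table over the surface-protein universe.

    ``table`` has one row per function category and MultiIndex columns with
    three axis blocks: localization (S-U, CM, CW, EC), experiment membership
    (only_P, only_Sh, both) and differential expression (up_ferm, up_fe, ns).
    Each block sums to the same grand total.
    """

    table: pd.DataFrame
    grand_total: int

    def axis_totals(self) -> dict[str, int]:
        return {
            axis: int(self.table[axis].to_numpy().sum())
            for axis in ("localization", "experiment", "differential")
        }


def crosstab_surfaceome(
    annotations: Sequence[SurfaceomeAnnotation],
    categories: Mapping[str, FunctionCategory],
    experiment_sets: Mapping[str, set[str] | frozenset[str]],
    de_class: Mapping[str, str],
) -> CrossTab:
    """Cross-tabulate surface proteins by function against three axes.

    The universe is the surface subset of ``annotations``; ``categories`` and
    ``de_class`` (values from ``DE_CLASSES``) must cover it exactly, and every
    surface protein must appear in at least one experiment set.  Axis-sum
    conservation (every block totals the universe size) is checked before
    returning.
    """
    if len(experiment_sets) != 2:
        raise ValueError("expected exactly two experiment sets")
    surface = [a for a in annotations if a.is_surface]
    universe = {a.protein_id for a in surface}
    missing_cat = universe - set(categories)
    missing_de = universe - set(de_class)
    (set_a, set_b) = (frozenset(v) for v in experiment_sets.values())
    missing_exp = universe - (set_a | set_b)
    problems = {
        "categories": missing_cat,
        "de_class": missing_de,
        "experiment sets": missing_exp,
    }
    bad = {k: sorted(v) for k, v in problems.items() if v}
    if bad:
        raise ValueError(f"surface proteins missing from inputs: {bad}")

    columns = pd.MultiIndex.from_tuples(
        [("localization", c) for c in LOCALIZATION_CLASSES]
        + [("experiment", c) for c in MEMBERSHIP_CLASSES]
        + [("differential", c) for c in DE_CLASSES],
        names=["axis", "class"],
    )
    index = pd.Index([c.value for c in FUNCTION_ORDER], name="function")
    table = pd.DataFrame(0, index=index, columns=columns)

    for ann in surface:
        func = categories[ann.protein_id].value
        loc = _COMPARTMENT_TO_CLASS.get(ann.compartment)
        if loc is None:  # cannot happen for a surface annotation
            raise ValueError(f"{ann.protein_id}: non-surface compartment in crosstab")
        in_a, in_b = ann.protein_id in set_a, ann.protein_id in set_b
        membership = "both" if (in_a and in_b) else ("only_P" if in_a else "only_Sh")
        de = de_class[ann.protein_id]
        if de not in DE_CLASSES:
            raise ValueError(f"{ann.protein_id}: bad DE class {de!r}")
        table.loc[func, ("localization", loc)] += 1
        table.loc[func, ("experiment", membership)] += 1
        table.loc[func, ("differential", de)] += 1

    result = CrossTab(table=table, grand_total=len(surface))
    totals = result.axis_totals()
    if set(totals.values()) not in ({len(surface)}, set()) and len(surface) > 0:
        raise AssertionError(f"axis totals diverge: {totals}")
    return result
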