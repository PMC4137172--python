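"""Ground-truthed synthetic inputs emulating a two-method surfaceome study.

The generator mimics the design of a Gram-positive surfaceome experiment:
two extraction methods (protoplast formation, trypsin shaving with a
shedding control) crossed with two growth conditions (pyruvate fermentation,
Fe(III)-citrate reduction), duplicate samples, cytoplasmic contamination
from cell lysis, compartment-dependent predictor error, negative-binomial
spectral counts with spiked fold changes, and dimethyl-label log-ratio pairs
with swapped isotope labels.

Every draw comes from a single :class:`numpy.random.Generator` (PCG64)
seeded from the config, so runs are fully deterministic and reproducible
across platforms.  The truth bookkeeping (:class:`SyntheticTruth`) records
each protein's compartment, anchor, planted binding domain, spike status and
contamination flags, and is the oracle for every recovery test downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    DomainHit,
    PredictorCall,
    ProteinEntry,
    SampleKey,
    SpectralCountMatrix,
    TopologyRecord,
)
from .localization import (
    AnchorClass,
    BindingMechanism,
    CanonicalCompartment,
    Tool,
    interpret_topology,
)

_C = CanonicalCompartment

TRUTH_COMPARTMENTS = (
    _C.CYTOPLASM,
    _C.CYTOPLASMIC_MEMBRANE,
    _C.CELL_WALL,
    _C.EXTRACELLULAR,
)

ConfusionMatrix = Mapping[_C, Mapping[_C, float]]


def _noisy_confusion() -> dict[Tool, dict[_C, dict[_C, float]]]:
    """Default predictor error model.

    Roughly 85% correct per tool with most of the error mass on UNKNOWN —
    predictors more often abstain than mislocalize.  The TMH scanner only
    ever reports membrane (helices found) or unknown (none found).
    """
    return {
        Tool.TMH_SCAN: {
            _C.CYTOPLASM: {_C.UNKNOWN: 0.97, _C.CYTOPLASMIC_MEMBRANE: 0.03},
            _C.CYTOPLASMIC_MEMBRANE: {_C.CYTOPLASMIC_MEMBRANE: 0.95, _C.UNKNOWN: 0.05},
            _C.CELL_WALL: {_C.UNKNOWN: 0.98, _C.CYTOPLASMIC_MEMBRANE: 0.02},
            _C.EXTRACELLULAR: {_C.UNKNOWN: 0.98, _C.CYTOPLASMIC_MEMBRANE: 0.02},
        },
        Tool.PSORTB: {
            _C.CYTOPLASM: {_C.CYTOPLASM: 0.88, _C.UNKNOWN: 0.10, _C.CYTOPLASMIC_MEMBRANE: 0.02},
            _C.CYTOPLASMIC_MEMBRANE: {_C.CYTOPLASMIC_MEMBRANE: 0.88, _C.UNKNOWN: 0.10, _C.CYTOPLASM: 0.02},
            _C.CELL_WALL: {_C.CELL_WALL: 0.80, _C.UNKNOWN: 0.12, _C.SURFACE_UNKNOWN: 0.08},
            _C.EXTRACELLULAR: {_C.EXTRACELLULAR: 0.82, _C.UNKNOWN: 0.10, _C.SURFACE_UNKNOWN: 0.08},
        },
        Tool.LOCATEP: {
            _C.CYTOPLASM: {_C.CYTOPLASM: 0.90, _C.UNKNOWN: 0.08, _C.CYTOPLASMIC_MEMBRANE: 0.02},
            _C.CYTOPLASMIC_MEMBRANE: {_C.CYTOPLASMIC_MEMBRANE: 0.88, _C.UNKNOWN: 0.10, _C.CYTOPLASM: 0.02},
            _C.CELL_WALL: {_C.CELL_WALL: 0.82, _C.UNKNOWN: 0.15, _C.CYTOPLASM: 0.03},
            _C.EXTRACELLULAR: {_C.EXTRACELLULAR: 0.84, _C.UNKNOWN: 0.13, _C.CYTOPLASM: 0.03},
        },
    }


def identity_confusion() -> dict[Tool, dict[_C, dict[_C, float]]]:
    """Perfect predictors: the noise-free limit.

    PSORTb- and LocateP-style tools return the truth with probability one.
    The TMH scanner is the ideal helix detector — membrane for
    membrane-truth proteins, uninformative otherwise — because its one-line
    output dialect can only express helix counts.
    """
    matrices: dict[Tool, dict[_C, dict[_C, float]]] = {
        Tool.TMH_SCAN: {
            truth: {
                (_C.CYTOPLASMIC_MEMBRANE if truth is _C.CYTOPLASMIC_MEMBRANE else _C.UNKNOWN): 1.0
            }
            for truth in TRUTH_COMPARTMENTS
        }
    }
    for tool in (Tool.PSORTB, Tool.LOCATEP):
        matrices[tool] = {truth: {truth: 1.0} for truth in TRUTH_COMPARTMENTS}
    return matrices


@dataclass(frozen=True)
class Spike:
    """A planted differential-expression event."""

    protein_index: int
    fold: float
    up_condition: str  # {fermentation, fe_reduction}

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("spike fold must exceed 1")
        if self.up_condition not in ("fermentation", "fe_reduction"):
            raise ValueError(f"bad up_condition {self.up_condition!r}")


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic benchmark.

    Defaults emulate the real study's conditions: a proteome-scale protein
    set, heavy cytoplasmic contamination of the surface extracts (both
    extraction methods suffered cell lysis), per-tool localization error
    concentrated on abstention, over-dispersed spectral counts and
    intensity-dependent ratio noise with label-swapped duplicates.
    """

    n_proteins: int = 2000
    compartment_proportions: dict[_C, float] = field(
        default_factory=lambda: {
            _C.CYTOPLASM: 0.70,
            _C.CYTOPLASMIC_MEMBRANE: 0.18,
            _C.CELL_WALL: 0.07,
            _C.EXTRACELLULAR: 0.05,
        }
    )
    tool_confusion: dict[Tool, dict[_C, dict[_C, float]]] = field(
        default_factory=_noisy_confusion
    )
    #: probability a cytoplasm-truth protein leaks into a surface extract
    lysis_contamination_rate: float = 0.5
    #: abundance attenuation of leaked cytoplasmic proteins
    contamination_attenuation: float = 0.3
    #: detection probability of a true surface protein per extraction
    detection_rate_protoplast: float = 0.95
    detection_rate_shaving: float = 0.85
    #: negative-binomial count model: per-protein baseline mean is drawn
    #: Gamma(shape=2) around base_mean; dispersion is NB size k
    base_mean: float = 25.0
    dispersion: float = 10.0
    count_noise: str = "nb"  # {nb, poisson, none}
    #: spikes: explicit list, or None to auto-plant n_spikes events
    spike_set: list[Spike] | None = None
    n_spikes: int = 20
    spike_fold: float = 4.0
    spike_baseline_range: tuple[float, float] = (20.0, 60.0)
    #: log2-ratio noise sd = ratio_noise_scale / sqrt(intensity)
    ratio_noise_scale: float = 1000.0
    #: probability a cell-wall-truth protein carries a LysM or SLH domain
    cw_domain_prob: float = 0.8
    #: fraction of membrane-truth proteins that are lipoproteins (no TMH)
    lipoprotein_frac: float = 0.3
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        total = sum(self.compartment_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"compartment proportions sum to {total}, not 1")
        for tool, matrix in self.tool_confusion.items():
            for truth, row in matrix.items():
                s = sum(row.values())
                if abs(s - 1.0) > 1e-12:
                    raise ValueError(
                        f"{Tool(tool).value} confusion row for {truth} sums to {s}"
                    )
        for rate in (
            self.lysis_contamination_rate,
            self.detection_rate_protoplast,
            self.detection_rate_shaving,
            self.cw_domain_prob,
            self.lipoprotein_frac,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.count_noise not in ("nb", "poisson", "none"):
            raise ValueError(f"bad count_noise {self.count_noise!r}")
        return self


@dataclass
class SyntheticTruth:
    """Per-protein ground truth for recovery tests."""

    protein_ids: list[str]
    compartment: dict[str, _C]
    anchor: dict[str, AnchorClass]
    lipoprotein: dict[str, bool]
    planted_binding: dict[str, BindingMechanism]
    #: filled by generate_quantification_inputs
    present_protoplast: set[str] = field(default_factory=set)
    present_shaving: set[str] = field(default_factory=set)
    contaminant_protoplast: set[str] = field(default_factory=set)
    contaminant_shaving: set[str] = field(default_factory=set)
    spikes: dict[str, Spike] = field(default_factory=dict)

    def surface_ids(self) -> set[str]:
        return {
            pid
            for pid, c in self.compartment.items()
            if c is not _C.CYTOPLASM
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "compartment": [self.compartment[p].value for p in self.protein_ids],
                "anchor": [self.anchor[p].value for p in self.protein_ids],
                "lipoprotein": [self.lipoprotein[p] for p in self.protein_ids],
                "planted_binding": [
                    self.planted_binding[p].value for p in self.protein_ids
                ],
                "in_protoplast": [p in self.present_protoplast for p in self.protein_ids],
                "in_shaving": [p in self.present_shaving for p in self.protein_ids],
                "contaminant": [
                    p in self.contaminant_protoplast or p in self.contaminant_shaving
                    for p in self.protein_ids
                ],
                "spike_fold": [
                    self.spikes[p].fold if p in self.spikes else 1.0
                    for p in self.protein_ids
                ],
                "spike_up": [
                    self.spikes[p].up_condition if p in self.spikes else ""
                    for p in self.protein_ids
                ],
            }
        )


@dataclass
class AnnotationInputs:
    proteins: list[ProteinEntry]
    calls: dict[Tool, list[PredictorCall]]
    topologies: list[TopologyRecord]
    domain_hits: list[DomainHit]
    truth: SyntheticTruth


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_RAW_VOCAB: dict[Tool, dict[_C, str]] = {
    Tool.PSORTB: {
        _C.CYTOPLASM: "Cytoplasmic",
        _C.CYTOPLASMIC_MEMBRANE: "CytoplasmicMembrane",
        _C.CELL_WALL: "Cellwall",
        _C.EXTRACELLULAR: "Extracellular",
        _C.SURFACE_UNKNOWN: "Non-cytoplasmic",
        _C.UNKNOWN: "Unknown",
    },
    Tool.LOCATEP: {
        _C.CYTOPLASM: "Intracellular",
        _C.CYTOPLASMIC_MEMBRANE: "Membrane",
        _C.CELL_WALL: "Cell wall",
        _C.EXTRACELLULAR: "Secreted",
        _C.SURFACE_UNKNOWN: "Non-cytoplasmic",
        _C.UNKNOWN: "Unknown",
    },
}


def _draw(rng: np.random.Generator, row: Mapping[_C, float]) -> _C:
    keys = sorted(row, key=lambda c: c.value)  # stable order for determinism
    probs = np.array([row[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _random_topology(
    rng: np.random.Generator, protein_id: str, length: int, n_helices: int
) -> TopologyRecord:
    if n_helices == 0:
        return TopologyRecord(protein_id, 0, (), "in")
    # cap helix count so 20-residue helices fit in disjoint 30-residue slots
    n = min(n_helices, max(1, length // 30))
    slot = length // n
    segments = []
    for h in range(n):
        lo = h * slot + 1
        hi = lo + slot - 21
        start = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
        segments.append((start, start + 19))
    return TopologyRecord(
        protein_id, n, tuple(segments), "in" if rng.random() < 0.5 else "out"
    )


def generate_annotation_inputs(config: GeneratorConfig) -> AnnotationInputs:
    """Generate a proteome with per-tool calls, topologies, domains and truth.

    Deterministic for a fixed ``config.seed``.  Membrane-truth proteins
    (except lipoproteins) get one or more transmembrane helices; cell-wall
    truth proteins carry a LysM or SLH domain with configured probability;
    per-tool calls are drawn from the confusion matrix conditioned on truth.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_proteins
    ids = [f"SYN_{i:05d}" for i in range(n)]

    comps = sorted(config.compartment_proportions, key=lambda c: c.value)
    probs = np.array([config.compartment_proportions[c] for c in comps])
    truth_comp = {
        pid: comps[k] for pid, k in zip(ids, rng.choice(len(comps), size=n, p=probs))
    }

    lengths = np.clip(rng.lognormal(mean=5.6, sigma=0.45, size=n), 60, 1500).astype(int)
    proteins = []
    descriptions = {
        _C.CYTOPLASM: "cytosolic enzyme",
        _C.CYTOPLASMIC_MEMBRANE: "membrane protein",
        _C.CELL_WALL: "cell wall protein",
        _C.EXTRACELLULAR: "secreted protein",
    }
    for pid, length in zip(ids, lengths):
        seq = "M" + "".join(rng.choice(_AA, size=int(length) - 1))
        proteins.append(
            ProteinEntry(id=pid, description=descriptions[truth_comp[pid]], sequence=seq)
        )
    length_of = {pid: int(L) for pid, L in zip(ids, lengths)}

    # --- truth topology / anchor / lipoprotein flags
    lipoprotein: dict[str, bool] = {}
    truth_topology: dict[str, TopologyRecord] = {}
    for pid in ids:
        is_cm = truth_comp[pid] is _C.CYTOPLASMIC_MEMBRANE
        lipo = is_cm and rng.random() < config.lipoprotein_frac
        lipoprotein[pid] = lipo
        if is_cm and not lipo:
            n_helices = 1 if rng.random() < 0.6 else int(rng.integers(2, 9))
        else:
            n_helices = 0
        truth_topology[pid] = _random_topology(rng, pid, length_of[pid], n_helices)
    anchor = {
        pid: interpret_topology(truth_topology[pid], length_of[pid]) for pid in ids
    }

    # --- planted binding domains
    domain_hits: list[DomainHit] = []
    planted: dict[str, BindingMechanism] = {}
    for pid in ids:
        mech = BindingMechanism.NONE
        if truth_comp[pid] is _C.CELL_WALL and rng.random() < config.cw_domain_prob:
            if rng.random() < 0.5:
                accession, name, mech = "PF01476", "LysM", BindingMechanism.LYSM
            else:
                accession, name, mech = "PF00395", "SLH", BindingMechanism.SLH
            start = int(rng.integers(1, max(length_of[pid] - 45, 2)))
            domain_hits.append(
                DomainHit(
                    protein_id=pid,
                    accession=accession,
                    name=name,
                    ali_start=start,
                    ali_end=min(start + 44, length_of[pid]),
                    i_evalue=float(10.0 ** rng.uniform(-12, -6)),
                )
            )
        elif lipoprotein[pid]:
            mech = BindingMechanism.LIPID_ANCHOR
        elif anchor[pid] is not AnchorClass.NONE:
            mech = BindingMechanism.TMH_ANCHOR
        planted[pid] = mech
        if rng.random() < 0.10:  # uninformative decoy domain
            start = int(rng.integers(1, max(length_of[pid] - 30, 2)))
            domain_hits.append(
                DomainHit(
                    protein_id=pid,
                    accession="PF99999",
                    name="DUF_decoy",
                    ali_start=start,
                    ali_end=min(start + 29, length_of[pid]),
                    i_evalue=float(10.0 ** rng.uniform(-8, -2)),
                )
            )

    # --- per-tool calls from the confusion matrices
    calls: dict[Tool, list[PredictorCall]] = {t: [] for t in Tool}
    topologies: list[TopologyRecord] = []
    for pid in ids:
        truth = truth_comp[pid]
        for tool in (Tool.TMH_SCAN, Tool.PSORTB, Tool.LOCATEP):
            # the TMH scanner sees helices, not compartments: membrane-truth
            # lipoproteins carry no helix, so they draw from the no-helix row
            key = truth
            if (
                tool is Tool.TMH_SCAN
                and truth is _C.CYTOPLASMIC_MEMBRANE
                and truth_topology[pid].n_helices == 0
            ):
                key = _C.CYTOPLASM
            called = _draw(rng, config.tool_confusion[tool][key])
            if tool is Tool.TMH_SCAN:
                if called is _C.CYTOPLASMIC_MEMBRANE:
                    topo = truth_topology[pid]
                    if topo.n_helices == 0:  # false-positive helix
                        topo = _random_topology(rng, pid, length_of[pid], 1)
                else:
                    topo = TopologyRecord(pid, 0, (), "in")
                topologies.append(topo)
                raw = f"PredHel={topo.n_helices}"
                canonical = (
                    _C.CYTOPLASMIC_MEMBRANE if topo.n_helices >= 1 else _C.UNKNOWN
                )
                calls[tool].append(
                    PredictorCall(pid, tool, raw, canonical)
                )
            else:
                raw = _RAW_VOCAB[tool][called]
                calls[tool].append(
                    PredictorCall(
                        pid,
                        tool,
                        raw,
                        called,
                        lipoprotein=(tool is Tool.LOCATEP and lipoprotein[pid]),
                        secreted=(
                            tool is Tool.LOCATEP and called is _C.EXTRACELLULAR
                        ),
                    )
                )

    truth = SyntheticTruth(
        protein_ids=ids,
        compartment=truth_comp,
        anchor=anchor,
        lipoprotein=lipoprotein,
        planted_binding=planted,
    )
    return AnnotationInputs(
        proteins=proteins,
        calls=calls,
        topologies=topologies,
        domain_hits=domain_hits,
        truth=truth,
    )


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if config.count_noise == "none":
        return np.rint(mean).astype(int)
    if config.count_noise == "poisson":
        return rng.poisson(mean)
    k = config.dispersion
    p = k / (k + np.maximum(mean, 1e-12))
    return rng.negative_binomial(k, p)


def generate_quantification_inputs(
    config: GeneratorConfig, truth: SyntheticTruth
) -> tuple[SpectralCountMatrix, pd.DataFrame]:
    """Generate the spectral-count matrix and the dimethyl log-ratio table.

    Fills the presence, contamination and spike fields of ``truth`` in
    place.  The count matrix covers the protoplast experiment (two growth
    conditions x duplicate samples, the Fe(III)-reduction duplicates carrying
    60-/120-minute treatment metadata); the ratio table covers the shaving
    experiment with one label-swapped duplicate row per protein.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    ids = truth.protein_ids
    surface = truth.surface_ids()

    present_p: list[str] = []
    present_sh: list[str] = []
    for pid in ids:
        if truth.compartment[pid] is _C.CYTOPLASM:
            if rng.random() < config.lysis_contamination_rate:
                present_p.append(pid)
                truth.contaminant_protoplast.add(pid)
            if rng.random() < config.lysis_contamination_rate:
                present_sh.append(pid)
                truth.contaminant_shaving.add(pid)
        else:
            if rng.random() < config.detection_rate_protoplast:
                present_p.append(pid)
            if rng.random() < config.detection_rate_shaving:
                present_sh.append(pid)
    truth.present_protoplast = set(present_p)
    truth.present_shaving = set(present_sh)

    # --- spikes: planted DE among surface proteins present in both
    # conditions of the protoplast experiment (and in the shaving set when
    # possible so the ratio table sees them too)
    if config.spike_set is None:
        eligible = sorted(surface & truth.present_protoplast & truth.present_shaving)
        n_spikes = min(config.n_spikes, len(eligible))
        chosen = list(rng.choice(len(eligible), size=n_spikes, replace=False))
        spikes = [
            Spike(
                protein_index=ids.index(eligible[j]),
                fold=config.spike_fold,
                up_condition="fermentation" if i % 2 == 0 else "fe_reduction",
            )
            for i, j in enumerate(sorted(chosen))
        ]
    else:
        spikes = list(config.spike_set)
        for s in spikes:
            if not 0 <= s.protein_index < len(ids):
                raise ValueError(f"spike index {s.protein_index} out of range")
    truth.spikes = {ids[s.protein_index]: s for s in spikes}

    # --- protoplast spectral counts
    samples = [
        SampleKey("protoplast", "fermentation", "R1", None),
        SampleKey("protoplast", "fermentation", "R2", None),
        SampleKey("protoplast", "fe_reduction", "R1", 60),
        SampleKey("protoplast", "fe_reduction", "R2", 120),
    ]
    lo, hi = config.spike_baseline_range
    base = {}
    for pid in present_p:
        if pid in truth.spikes:
            base[pid] = float(rng.uniform(lo, hi))
        else:
            base[pid] = float(rng.gamma(shape=2.0, scale=config.base_mean / 2.0))
        if pid in truth.contaminant_protoplast:
            base[pid] *= config.contamination_attenuation
    counts = np.zeros((len(present_p), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        means = []
        for pid in present_p:
            mu = base[pid]
            spike = truth.spikes.get(pid)
            if spike is not None and sample.condition == spike.up_condition:
                mu *= spike.fold
            means.append(mu)
        counts[:, j] = _nb_counts(rng, np.array(means), config)
    matrix = SpectralCountMatrix(
        protein_ids=list(present_p), samples=samples, counts=counts
    )

    # --- shaving/shedding dimethyl ratio table (fe_reduction vs fermentation)
    rows = []
    for pid in present_sh:
        spike = truth.spikes.get(pid)
        if spike is None:
            true_log2 = 0.0
        else:
            sign = 1.0 if spike.up_condition == "fe_reduction" else -1.0
            true_log2 = sign * float(np.log2(spike.fold))
        intensity = float(rng.lognormal(mean=np.log(1e7), sigma=1.0))
        sd = config.ratio_noise_scale / np.sqrt(intensity)
        r1 = true_log2 + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        r2 = -(true_log2 + (rng.normal(0.0, sd) if sd > 0 else 0.0))
        rows.append((pid, r1, intensity, "fe_vs_ferm", False))
        rows.append((pid, r2, intensity, "fe_vs_ferm", True))
    ratio_table = pd.DataFrame(
        rows,
        columns=["protein_id", "log2_ratio", "intensity", "comparison", "label_swapped"],
    )
    return matrix, ratio_table


def experiment_sets(truth: SyntheticTruth) -> dict[str, set[str]]:
    """Protein-id sets per extraction experiment, for membership tallies."""
    return {
        "protoplast": set(truth.present_protoplast),
        "shaving": set(truth.present_shaving),
    }


# ---------------------------------------------------------------------------
# file writers (the formats core_io reads)


def _topology_string(topo: TopologyRecord) -> str:
    side = "i" if topo.n_term_side != "out" else "o"
    out = side
    for start, end in topo.segments:
        side = "o" if side == "i" else "i"
        out += f"{start}-{end}{side}"
    return out


def write_annotation_inputs(inputs: AnnotationInputs, outdir) -> dict[str, str]:
    """Write proteome, predictor outputs, domain table and truth to ``outdir``.

    Produces the exact dialects :mod:`surfaceome.core_io` parses, plus
    ``truth.tsv``.  Returns the mapping of logical names to file paths.
    """
    from pathlib import Path

    from .core_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": str(outdir / "proteome.fasta"),
        "tmh": str(outdir / "tmh_scan.txt"),
        "psortb": str(outdir / "psortb.tsv"),
        "locatep": str(outdir / "locatep.tsv"),
        "domains": str(outdir / "domains.domtblout"),
        "truth": str(outdir / "truth.tsv"),
    }
    write_fasta(inputs.proteins, paths["proteome"])

    length_of = {p.id: p.length for p in inputs.proteins}
    with open(paths["tmh"], "w") as fh:
        for topo in inputs.topologies:
            fh.write(
                f"{topo.protein_id}\tlen={length_of[topo.protein_id]}\t"
                f"PredHel={topo.n_helices}\tTopology={_topology_string(topo)}\n"
            )
    with open(paths["psortb"], "w") as fh:
        fh.write("SeqID\tLocalization\tScore\n")
        for call in inputs.calls[Tool.PSORTB]:
            fh.write(f"{call.protein_id}\t{call.raw_label}\t10.0\n")
    with open(paths["locatep"], "w") as fh:
        fh.write("protein_id\tSubcellular Localization\tLipoprotein\tSecreted\n")
        for call in inputs.calls[Tool.LOCATEP]:
            fh.write(
                f"{call.protein_id}\t{call.raw_label}\t"
                f"{'yes' if call.lipoprotein else 'no'}\t"
                f"{'yes' if call.secreted else 'no'}\n"
            )
    with open(paths["domains"], "w") as fh:
        fh.write("# synthetic hmmscan --domtblout table\n")
        for hit in inputs.domain_hits:
            tlen = hit.ali_end - hit.ali_start + 1
            fields = [
                hit.name, hit.accession, str(tlen), hit.protein_id, "-",
                str(length_of[hit.protein_id]), f"{hit.i_evalue:.3g}", "50.0", "0.1",
                "1", "1", f"{hit.i_evalue:.3g}", f"{hit.i_evalue:.3g}", "50.0", "0.1",
                "1", str(tlen), str(hit.ali_start), str(hit.ali_end),
                str(hit.ali_start), str(hit.ali_end), "0.95", "-",
            ]
            fh.write(" ".join(fields) + "\n")
    inputs.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
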