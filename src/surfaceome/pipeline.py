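"""End-to-end orchestration: simulate -> classify -> quantify -> compare.

Each stage is an ordinary library function usable on its own; ``run_pipeline``
chains them over a shared output directory with a run manifest recording the
package version, seed and thresholds, so a run can be reproduced exactly.
Stage failures leave any files the stage had written behind with a
``.partial`` suffix and produce a non-zero exit status.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .compare import (
    categorize_function,
    crosstab_surfaceome,
    load_function_rules,
    membership_tally,
)
from .core_io import (
    DomainHit,
    PredictorCall,
    ProteinEntry,
    SpectralCountMatrix,
    parse_domain_hits,
    parse_predictor_output,
    read_count_matrix,
    read_fasta,
    read_ratio_table,
    write_count_matrix,
    write_ratio_table,
)
from .localization import (
    AnchorClass,
    SurfaceomeAnnotation,
    Tool,
    assign_binding_mechanism,
    consensus_localization,
    interpret_topology,
)
from .quantify import (
    call_differential_expression,
    normalize_total_spectra,
    significance_b,
    summarize_condition,
)
from .synthetic_data import (
    GeneratorConfig,
    generate_annotation_inputs,
    generate_quantification_inputs,
    write_annotation_inputs,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_STAGE_FAILED = 2
EXIT_MISSING_INPUT = 3


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: Path
    seed: int = 0
    n_proteins: int = 2000
    fold_min: float = 2.0
    abs_min: float = 5.0
    bin_size: int = 300
    alpha: float = 0.05
    evalue_cutoff: float = 1e-5
    generator_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"


# ---------------------------------------------------------------------------
# classify


def classify_proteins(
    proteins: Sequence[ProteinEntry],
    calls_by_tool: Mapping[Tool, Sequence[PredictorCall]],
    topologies: Sequence,
    domain_hits: Sequence[DomainHit],
    evalue_cutoff: float = 1e-5,
) -> list[SurfaceomeAnnotation]:
    """Produce one consensus annotation per protein.

    Wires the parsed predictor outputs together: the TMH topology yields the
    anchor class, the LocateP flags supply lipoprotein/LPxTG evidence, Pfam
    hits the wall-binding domains, and the three compartment calls go through
    the consensus rule.
    """
    length_of = {p.id: p.length for p in proteins}
    topo_of = {t.protein_id: t for t in topologies}
    calls_of: dict[str, list[PredictorCall]] = {p.id: [] for p in proteins}
    for tool_calls in calls_by_tool.values():
        for call in tool_calls:
            if call.protein_id in calls_of:
                calls_of[call.protein_id].append(call)
    hits_of: dict[str, list[DomainHit]] = {p.id: [] for p in proteins}
    for hit in domain_hits:
        if hit.protein_id in hits_of:
            hits_of[hit.protein_id].append(hit)

    annotations = []
    for protein in proteins:
        pid = protein.id
        topo = topo_of.get(pid)
        anchor = (
            interpret_topology(topo, length_of[pid])
            if topo is not None
            else AnchorClass.NONE
        )
        lipoprotein = any(c.lipoprotein for c in calls_of[pid])
        binding = assign_binding_mechanism(
            hits_of[pid],
            lipoprotein=lipoprotein,
            lpxtg=False,
            anchor=anchor,
            evalue_cutoff=evalue_cutoff,
        )
        annotations.append(
            consensus_localization(
                calls_of[pid], anchor=anchor, protein_id=pid, binding=binding
            )
        )
    return annotations


def annotations_to_frame(
    annotations: Sequence[SurfaceomeAnnotation],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in annotations],
            "compartment": [a.compartment.value for a in annotations],
            "confidence": [a.confidence.value for a in annotations],
            "anchor": [a.anchor.value for a in annotations],
            "binding": [a.binding.value for a in annotations],
            "is_surface": [a.is_surface for a in annotations],
            "supporting_tools": [
                ",".join(sorted(t.value for t in a.supporting_tools))
                for a in annotations
            ],
        }
    )


# ---------------------------------------------------------------------------
# quantify


def differential_calls_frame(
    matrix: SpectralCountMatrix,
    fold_min: float = 2.0,
    abs_min: float = 5.0,
) -> pd.DataFrame:
    """Normalize the count matrix and apply the DE rule per protein.

    Condition A is fermentation (semi-difference error over the duplicate
    pair), condition B is Fe(III) reduction (standard-deviation error over
    its samples, 60- and 120-minute halves pooled as plain replicates).
    """
    normalized, _, _ = normalize_total_spectra(matrix)
    ferm_cols = [s.label() for s in matrix.samples if s.condition == "fermentation"]
    fe_cols = [s.label() for s in matrix.samples if s.condition == "fe_reduction"]
    if not ferm_cols or not fe_cols:
        raise ValueError("count matrix must contain both conditions")
    rows = []
    for pid in matrix.protein_ids:
        summary_ferm = summarize_condition(
            pid,
            "fermentation",
            normalized.loc[pid, ferm_cols].to_numpy(),
            error_mode="semi_difference" if len(ferm_cols) == 2 else "sd",
        )
        summary_fe = summarize_condition(
            pid, "fe_reduction", normalized.loc[pid, fe_cols].to_numpy(), "sd"
        )
        call = call_differential_expression(
            summary_ferm, summary_fe, fold_min=fold_min, abs_min=abs_min
        )
        rows.append(
            {
                "protein_id": pid,
                "mean_fermentation": summary_ferm.mean,
                "error_fermentation": summary_ferm.error,
                "mean_fe_reduction": summary_fe.mean,
                "error_fe_reduction": summary_fe.error,
                "direction": call.direction,
                "fold": call.fold,
                "abs_diff": call.abs_diff,
                "separated": call.separated,
            }
        )
    frame = pd.DataFrame(rows)
    # the strict-separation reading of "accounting for the error" is recorded
    # in the output so downstream users can see which rule was applied
    frame.attrs["error_rule"] = "strict_interval_separation"
    return frame


# ---------------------------------------------------------------------------
# the full run


def run_pipeline(config: RunConfig) -> int:
    """Run simulate -> classify -> quantify -> compare; return exit status.

    Writes, under ``config.outdir``: the synthetic input files, the
    annotation table, the DE table, the significance-B table, ``table1.tsv``
    (membership tally), ``table2.tsv`` (function crosstab) and
    ``manifest.json``.  Outputs are byte-identical for identical
    config + seed.  On a stage failure, files written by that stage are
    renamed with a ``.partial`` suffix and a non-zero status is returned.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def fail(stage: str, exc: Exception) -> int:
        logger.error("stage=%s status=failed error=%s", stage, exc)
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        return EXIT_MISSING_INPUT if isinstance(exc, FileNotFoundError) else EXIT_STAGE_FAILED

    # -- simulate
    try:
        written = []
        gen_config = GeneratorConfig(
            n_proteins=config.n_proteins, seed=config.seed, **config.generator_overrides
        )
        inputs = generate_annotation_inputs(gen_config)
        matrix, ratios = generate_quantification_inputs(gen_config, inputs.truth)
        paths = write_annotation_inputs(inputs, outdir / "inputs")
        counts_path = outdir / "inputs" / "counts.tsv"
        ratios_path = outdir / "inputs" / "ratios.tsv"
        write_count_matrix(matrix, counts_path)
        write_ratio_table(ratios, ratios_path)
        written = [Path(p) for p in paths.values()] + [counts_path, ratios_path]
        logger.info("stage=simulate status=ok n_proteins=%d", config.n_proteins)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        return fail("simulate", exc)

    # -- classify (from the files, exercising the parsers)
    try:
        written = []
        proteins = read_fasta(paths["proteome"])
        tmh_calls, topologies = parse_predictor_output(paths["tmh"], Tool.TMH_SCAN)
        psortb_calls, _ = parse_predictor_output(paths["psortb"], Tool.PSORTB)
        locatep_calls, _ = parse_predictor_output(paths["locatep"], Tool.LOCATEP)
        domain_hits = parse_domain_hits(paths["domains"])
        annotations = classify_proteins(
            proteins,
            {
                Tool.TMH_SCAN: tmh_calls,
                Tool.PSORTB: psortb_calls,
                Tool.LOCATEP: locatep_calls,
            },
            topologies,
            domain_hits,
            evalue_cutoff=config.evalue_cutoff,
        )
        annotation_path = outdir / "annotation.tsv"
        annotations_to_frame(annotations).to_csv(annotation_path, sep="\t", index=False)
        written = [annotation_path]
        n_surface = sum(a.is_surface for a in annotations)
        logger.info("stage=classify status=ok n_surface=%d", n_surface)
    except Exception as exc:  # noqa: BLE001
        return fail("classify", exc)

    # -- quantify
    try:
        written = []
        matrix = read_count_matrix(counts_path)
        ratios = read_ratio_table(ratios_path)
        de_frame = differential_calls_frame(
            matrix, fold_min=config.fold_min, abs_min=config.abs_min
        )
        de_path = outdir / "differential_expression.tsv"
        de_frame.to_csv(de_path, sep="\t", index=False, float_format="%.10g")
        sig_frame = significance_b(ratios, bin_size=config.bin_size)
        sig_path = outdir / "significance_b.tsv"
        sig_frame.to_csv(sig_path, sep="\t", index=False, float_format="%.10g")
        written = [de_path, sig_path]
        logger.info(
            "stage=quantify status=ok n_de=%d n_sig=%d",
            (de_frame["direction"] != "none").sum(),
            (sig_frame["p_adjusted"] < config.alpha).sum(),
        )
    except Exception as exc:  # noqa: BLE001
        return fail("quantify", exc)

    # -- compare
    try:
        written = []
        protoplast_ids = set(matrix.protein_ids)
        shaving_ids = set(ratios["protein_id"])
        surface_ids = {a.protein_id for a in annotations if a.is_surface}
        observed = protoplast_ids | shaving_ids
        tally = membership_tally(
            {"P": protoplast_ids, "Sh": shaving_ids}, surface_ids & observed
        )
        table1_path = outdir / "table1.tsv"
        tally.to_frame().to_csv(table1_path, sep="\t", index=False)

        rules = load_function_rules()
        description_of = {p.id: p.description for p in proteins}
        hits_of: dict[str, list[str]] = {}
        for hit in domain_hits:
            hits_of.setdefault(hit.protein_id, []).append(hit.accession)
        surface_observed = [
            a for a in annotations if a.is_surface and a.protein_id in observed
        ]
        categories = {
            a.protein_id: categorize_function(
                description_of[a.protein_id],
                hits_of.get(a.protein_id, ()),
                rules,
            )
            for a in surface_observed
        }
        de_direction = dict(zip(de_frame["protein_id"], de_frame["direction"]))
        de_class = {}
        for a in surface_observed:
            direction = de_direction.get(a.protein_id, "none")
            de_class[a.protein_id] = {
                "up_in_A": "up_ferm",
                "up_in_B": "up_fe",
                "none": "ns",
            }[direction]
        crosstab = crosstab_surfaceome(
            surface_observed,
            categories,
            {"P": protoplast_ids, "Sh": shaving_ids},
            de_class,
        )
        table2_path = outdir / "table2.tsv"
        crosstab.table.to_csv(table2_path, sep="\t")
        written = [table1_path, table2_path]
        logger.info(
            "stage=compare status=ok surface_universe=%d", crosstab.grand_total
        )
    except Exception as exc:  # noqa: BLE001
        return fail("compare", exc)

    manifest = {
        "package": "surfaceome",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fold_min": config.fold_min,
            "abs_min": config.abs_min,
            "bin_size": config.bin_size,
            "alpha": config.alpha,
            "evalue_cutoff": config.evalue_cutoff,
        },
        "n_proteins": config.n_proteins,
        "generator_overrides": {
            k: str(v) for k, v in sorted(config.generator_overrides.items())
        },
        "outputs": sorted(
            str(p.relative_to(outdir))
            for p in outdir.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("stage=manifest status=ok")
    return EXIT_OK
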