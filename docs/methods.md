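# Methods

This note documents the models, rules and numerical choices implemented in
the package, in the order the pipeline applies them, together with what the
synthetic benchmark does and does not emulate.

## Identification filtering

Protein identifications are kept when they carry at least `min_peptides`
distinct peptides (default 2) and a protein-level FDR at most
`max_protein_fdr` (default 0.01); records without an FDR value pass the FDR
clause. The filter is order-preserving and idempotent. A missing spectral
count is zero, not missing-at-random: under spectrum counting, absence of
matched spectra is zero evidence of abundance.

## Consensus localization

Compartments are the canonical classes cytoplasm (C), cytoplasmic membrane
(CM), cell wall (CW), extracellular (EC), plus `SURFACE_UNKNOWN`
("demonstrably not cytoplasmic, compartment undetermined" — e.g. a
PSORTb-style "Non-cytoplasmic" call) and `UNKNOWN`. Raw tool vocabularies
map onto these classes through an editable case-insensitive table
(`data/label_map.yaml`); unmapped labels fall back to `UNKNOWN` with a
warning so an unexpected vocabulary can never silently promote a protein to
the surfaceome.

The consensus rule, per protein:

1. ≥ 2 tools agreeing on a non-UNKNOWN compartment → that compartment,
   confidence `consensus`.
2. Exactly one informative call: accepted as `evidence_tiebreak` when it is
   non-cytoplasmic; a lone cytoplasmic call stands unless contradicted by a
   membrane anchor, in which case the protein becomes `SURFACE_UNKNOWN`
   (`unresolved`) — potentially membrane-bound proteins are retained for
   curation rather than discarded.
3. Two-plus distinct informative calls with no majority: if cytoplasm is
   among them, anchor evidence decides between `SURFACE_UNKNOWN` and
   `UNKNOWN`; if all conflicting calls are non-cytoplasmic the tools agree
   the protein is not cytoplasmic, which is exactly `SURFACE_UNKNOWN`. All
   such cases are flagged `unresolved`. This branch replaces what was
   historically manual case-by-case curation with a deterministic rule;
   the `unresolved` flag marks exactly the proteins a curator should
   revisit.

The result is invariant to the order tools are supplied, and adding an
agreeing call never lowers confidence. A protein is *surface* iff its
compartment is neither cytoplasm nor unknown, or it is unknown but carries
a membrane anchor.

**Anchors.** Zero predicted helices → no anchor; ≥ 2 → polytopic; a single
helix is N-terminal when it starts within 35 residues of the N-terminus,
C-terminal when it ends within 40 residues of the C-terminus, otherwise
assigned by the half of the chain holding its midpoint. The windows reflect
typical signal-anchor and tail-anchor lengths and are configurable. A
single N-terminal helix is treated as an anchor, not a cleaved signal
peptide, unless the LocateP-style call marks the protein secreted.

**Binding mechanisms.** Exactly one per protein, by fixed priority:
LPxTG (covalent sorting, reported by LocateP-style output) > SLH (PF00395)
> LysM (PF01476) > CWBD_1 (PF01473) > CWBD_2 (PF04122) > GW (PF13457) >
lipid anchor (lipoprotein flag) > TMH anchor > none. Domain hits count when
their independent e-value is ≤ 1e-5 (configurable; the threshold is a
package choice — standard hmmscan practice — as no canonical value exists
for this step). Pfam accession version suffixes are stripped at parse time;
the SLH accession is PF00395 and the truncated form "PF0039" is not
accepted.

## Quantification

**Normalized total spectra.** The per-sample totals of the count matrix are
scaled to a common value — the mean of the raw totals — via one factor per
sample. This conserves within-sample rank order and makes totals equal to
within 1e-9 relative error; it presumes comparable protein loads across
samples. A zero-total sample is an error, not a silent drop.

**Condition summaries and the DE rule.** Replicates are averaged
arithmetically; the error is the sample SD (n−1), or the semi-difference
|x₁−x₂|/2 for a duplicate pair (one replicate → error 0). The
Fe(III)-reduction condition pools its 60- and 120-minute halves as plain
replicates, carrying treatment minutes as metadata only. A protein is
differential iff

* mean_hi ≥ `fold_min` × mean_lo (default 2; fold reported as ∞ when
  mean_lo = 0),
* mean_hi − mean_lo ≥ `abs_min` (default 5, guarding low counts), and
* (mean_hi − err_hi) > (mean_lo + err_lo).

"Accounting for the error" is formalized as this strict non-overlap of the
mean ± error intervals; the output records the rule applied
(`error_rule = strict_interval_separation`) since weaker readings are
conceivable. The call is antisymmetric under swapping conditions. Shed
counts are not subtracted from shaved counts.

**Significance B.** Rows are sorted by intensity and cut into consecutive
bins of ≥ `bin_size` rows (default 300; the remainder joins the last bin).
Within a bin, with m the median and u, l the 84.13th/15.87th percentiles
(linear interpolation — the Gaussian ±1σ quantiles), the robust z of ratio
r is (r−m)/(u−m) above the median and (m−r)/(m−l) below; p = erfc(z/√2)
capped at 1; degenerate spread gives z = 0 on the affected side.
Benjamini–Hochberg adjusts across all proteins (the multiple-testing
procedure is a package choice). No re-centering is applied by default — the
ratios are assumed mixing-normalized — but `center_median=True` subtracts
each bin's median first. On a 10,000-row standard-normal null the
empirical type-I error at α = 0.05 is ≈ 0.052–0.054: slightly above
nominal because the bin percentiles are estimated from 300 points, within
three Monte-Carlo standard errors of 0.05.

**ΔΔCt.** ΔCt = Ct(target) − Ct(reference) per condition; ΔΔCt = ΔCt_A −
ΔCt_B; relative expression 2^(−ΔCt), cross-condition fold 2^(−ΔΔCt).

## Tallies

Membership accounting is pure set algebra over exactly two experiment sets,
each row split by intersection with the surface set, so the identities
total = unique + shared and total = surface + cytoplasm hold by
construction. The function crosstab assigns each surface protein one of
five categories (transport, chemotaxis, proteases/CW hydrolases, redox,
other/unknown) by the first matching rule in an ordered keyword/accession
table (`data/function_rules.tsv`) — a transparent, editable approximation
of manual curation, with chemotaxis keywords ordered before transport so
"methyl-accepting chemotaxis protein" is never captured by a broader rule.
Every crosstab axis (localization, experiment membership, differential
class including "ns") sums to the surface-universe size, and the code never
forces a printed total row: published totals are checked against their own
components, not against typeset tables.

## The synthetic benchmark

The generator emulates the study design: 2,000 proteins by default, truth
compartments drawn with proportions C 0.70 / CM 0.18 / CW 0.07 / EC 0.05
(a typical Gram-positive proteome skew), sequence lengths log-normal around
~300 residues. Membrane-truth proteins are 30% lipoproteins (no helix) and
otherwise carry 1 (60%) or 2–8 helices; cell-wall-truth proteins carry a
LysM or SLH domain with probability 0.8; 10% of proteins get an
uninformative decoy domain.

Per-tool calls are drawn from confusion matrices conditioned on truth. The
defaults encode ~85–95% correct calls with the error mass concentrated on
abstention (`UNKNOWN`) rather than wrong compartments, matching the
precision-oriented behaviour of this tool family: asserting cytoplasm for
a true surface protein is the one error the consensus cannot repair without
anchor evidence, and it is correspondingly rare (2–3% per tool). The TMH
scanner is modeled on helix truth, not compartment truth — lipoproteins
draw from the no-helix row — and only ever reports membrane or unknown,
because its one-line dialect expresses helix counts. `identity_confusion()`
gives the noise-free limit (the TMH entry being the ideal helix detector),
under which surfaceome recovery from truth is exact; under the default
noise the consensus recovers ≈ 95–98% of true surface proteins at 2,000
proteins.

Counts are negative-binomial (dispersion k = 10; over-dispersion is the
norm in spectral counting) around per-protein Gamma-distributed baselines
(mean 25); cytoplasmic proteins leak into each surface extract with
probability 0.5 — deliberately high, since neither extraction method fully
avoided lysis — at 0.3× attenuated abundance. Spiked proteins (default 20
per run, fold 4, baselines 20–60) model genuine regulation. Log₂ ratios are
true fold + Gaussian noise with sd = 1000/√intensity, matching the
intensity-binned assumption behind significance B, and each protein
contributes a label-swapped duplicate row with the sign flipped. All draws
come from one `numpy.random.Generator` (PCG64) per stage, seeded from the
config, so outputs are byte-identical across runs and platforms.

What the benchmark does *not* emulate: real protein sequences and their
evolution, peptide-level effects (shared peptides, missed cleavages,
detectability bias), isotope impurity, correlated predictor errors, and
compositional coupling between conditions. Passing recovery tests
therefore demonstrates the correctness and calibration of the pipeline's
logic under the stated error model, not predictor accuracy on real
proteomes.

## Problem sizes and determinism

The shipped tests and the acceptance script use 120–2,000-protein
benchmarks, a 10,000-row null ratio table, and an exhaustive
31 × 31 × 4 × 4 DE-rule grid — sizes at which every check runs in seconds
while keeping binomial/Monte-Carlo intervals tight. All stochastic tests
fix their seeds; the acceptance script derives every seed from `--seed`.

## Known limitations

* The consensus hierarchy resolves conflicts deterministically where the
  original practice was expert judgment; `confidence=unresolved` marks
  exactly the proteins that deserve manual review.
* The function rule table is keyword-based and will miscategorize proteins
  whose descriptions use unusual vocabulary; it is shipped as data so users
  can edit it without code changes.
* Significance B's slight type-I inflation at small bin sizes is inherent
  to estimating tail quantiles from 300 points; increase `bin_size` for
  large tables if exact nominal calibration matters.
* PSORTb long/short output variants are both accepted, but only the
  columns protein-id and localization are interpreted.
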