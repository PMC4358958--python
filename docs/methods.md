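# Methods

## Overview

`mir30design` predicts which 22-nt shRNA guide sequences against a target
mRNA will knock the gene down effectively, and converts the winners into
clone-ready synthesis oligos for the miR30 hairpin context. The pipeline
has five stages: candidate enumeration, feature encoding, potency
regression, filtering/selection, and oligo assembly.

## Candidate enumeration

A guide candidate is defined by a 22-nt target site on the mRNA. The
regression model reads the guide in its own (antisense) orientation
together with 10 nt of context past the guide's 5' end (downstream on
the mRNA) and 16 nt past its 3' end (upstream on the mRNA), a 48-nt
window `flank5 + guide + flank3`. One candidate is emitted per position
where the full window fits inside the transcript and contains no N, so
an N-free transcript of length L yields `L − 48 + 1` candidates.
Coordinates are 0-based half-open in mRNA sense; the internal alphabet is
DNA (U→T on ingest) because the synthesis outputs are DNA. Windows
containing N are skipped rather than encoded — the positional encoding
has no ambiguity channel. An optional coordinate-range restriction
(`region=`) supports CDS-only or 3'UTR-only design; the default is the
whole transcript.

## Feature encoding

Each candidate becomes a 196-dimensional vector:

* **Positional block (192).** A per-position 4-way indicator (one-hot)
  over the 48-nt context, base order A,C,G,T, position-major. An
  alternative 3-D simplex (tetrahedron-vertex) encoding (144 values) is
  available via `encoding="simplex"`; models record which encoding they
  were trained with and refuse vectors from the other schema.
* **Auxiliary block (4).** Historically these signals came from external
  siRNA-scoring, RNA-structure and duplex-thermodynamics tools. Each is
  a *provider* slot: genuine tool output can be ingested from a TSV keyed
  by the 48-nt context, and a deterministic built-in stand-in is used
  otherwise:
  * `sirna_score` — a rule-based score in the style of the classic
    empirical siRNA design criteria (Reynolds-type): +1 for guide GC
    fraction in [0.30, 0.52], +1 per A/T among the five guide-5'-end
    bases, +1 if the 4 terminal stacks at the guide 5' end are weaker
    than −6.5 kcal/mol, and position-specific bonuses/penalties on the
    sense strand (A3, U10, A19 favored; G/C19 and G13 penalized).
    Weights are configurable.
  * `accessibility_posterior` ∈ [0,1] — a local self-complementarity
    heuristic: the fraction of the fifteen 8-nt windows tiling the
    target site whose reverse complement occurs within ±40 nt on the
    transcript, subtracted from 1. It is *not* a partition-function
    posterior; with a structure engine available, ingest its output
    instead.
  * `duplex_dG` (kcal/mol) — nearest-neighbor free energy of the perfect
    guide:target duplex: the sum of the 21 stack energies read 5'→3'
    along the guide. The default parameter set is the RNA/RNA
    Watson-Crick ΔG°37 table of Xia et al. (1998), shipped as a
    plain-text data file (`data/nn_rna_xia1998.txt`); any stack→kcal/mol
    table of the same format can be substituted.
  * `end_asymmetry_ddG` (kcal/mol) — ΔG of the 4 terminal stacks at the
    guide 5' end minus the 4 at the 3' end. Positive values indicate the
    thermodynamic asymmetry (weak 5' end) that favors guide-strand
    loading into RISC.

A provider returning a non-finite value is an error naming the provider;
a tabulated provider with no entry for a requested context is an error,
never a silent default. The feature schema (ordered names) is digested
into a `schema_id` stored with every trained model.

## Label harmonization

Training tables come in two dialects. ProdEn-style potency scores are
consumed as given. Sort-round readout pairs (hybridization `h`,
sequencing `s`, both > 0) are mapped onto the same scale by

    label = 4 · 2^((log₂h + log₂s)/2) − 10 = 4·√(h·s) − 10,

implemented in the √ form (the two forms agree to < 1e−9 over a
100×100 grid spanning six decades, which is unit-tested). Non-positive
readouts are rejected row-wise with a logged reason. Duplicate contexts
across merged tables are kept as independent measurements by default; an
`average` policy collapses them to the mean label. No rescaling is
applied when mixing dialects — the transform exists precisely to put
them on one scale.

## Potency regression

An ε-regression SVM with an RBF kernel maps the 196-dim vector to the
harmonized label. Defaults: cost C = 2.25, γ = 0.1, ε = 0.1 (ε is the
usual default tube width of common SVM toolkits; C and γ are the fixed
design-time values). Training is deterministic given the records and
configuration.

**Scaling.** Only the four auxiliary features are standardized (means
and sds learned on the training set, frozen into the model, applied
unchanged at prediction time). The positional indicators are left on
their native 0/1 scale: they already share a scale, and z-scoring them
multiplies squared distances by ≈ 1/p(1−p) ≈ 5.3 per indicator, which at
γ = 0.1 drives the RBF kernel between any two distinct sequences toward
zero and collapses predictions toward a constant. Measured on the
synthetic benchmark, held-out Spearman ρ falls from ≈ 0.8 (indicator
block unscaled) to ≈ 0.3 (fully z-scored). `scale="all"` and
`scale="none"` remain available.

**Tuning.** `tune()` grid-searches (C, γ) by seeded k-fold
cross-validation (default k = 5) under mean squared error, returning the
full score table for sensitivity reporting; exact ties break toward
(2.25, 0.1), then the smaller cost. Local sensitivity is probed with a
3×3 grid of ±20% multiplicative perturbations around (2.25, 0.1); on
the synthetic benchmark the CV MSE varies by well under 20% across that
neighborhood. The insensitivity is local: over a coarser factor-of-2
grid the MSE roughly doubles from the best to the worst cell, with γ
dominating.

**Kernel locality.** At γ = 0.1 the kernel is local enough that even a
noiseless planted linear signal is recovered at ρ ≈ 0.87 (n = 2000),
not 1.0; widening the kernel (γ = 0.05, C = 10) raises noiseless
recovery above 0.95. The fixed defaults trade some of this ceiling for
robustness on noisy labels; the recovery property test probes plumbing
at the wider kernel, while all headline statistics use the fixed
defaults.

## Selection and filtering

Candidates are ranked by descending SVM score; ties break toward the
5'-most (smallest `target_start`) site. Any candidate whose sequence
contains a homopolymer run longer than 4 nt is excluded before ranking
(the exclusion is score-independent, so filter-then-rank equals
rank-then-filter; this is property-tested). The filter's default scope
is the full 97-mer synthesis oligo — a run introduced at a junction
would also compromise synthesis — with `guide_context` available to
restrict it to the 48-nt window. Every exclusion is logged with the
offending base, position and run length. The top 10 survivors per
transcript (configurable) form the design set. An optional
minimum-separation constraint between selected target sites is off by
default.

## Oligo assembly

Each selected guide is emitted as a 97-nt single-stranded synthesis
template: `anchor5(18) + sense(22) + loop(19) + guide(22) + anchor3(16)`,
with the sense arm the exact reverse complement of the guide (no
engineered mismatches) and the 19-nt loop from the standard miR30
cloning protocol (a named constant; substituting a loop of a different
length fails loudly rather than silently shifting coordinates). In
0-based half-open coordinates: sense [18,40), loop [40,59), guide
[59,81), anchor3 [81,97).

The two anchors are the 3' termini of the universal amplification
primers (forward 72 nt, reverse 56 nt), so a single primer pair converts
any template into a double-stranded product of
72 + (97 − 18) + (56 − 16) = 191 bp (~190 bp) for isothermal assembly.
The PCR simulation uses exact-match annealing of those 18/16-nt
overlaps only; thermodynamic or mismatch-tolerant annealing models are
out of scope. A template whose anchor has been altered yields a
"primer cannot anneal" error, not a product.

## Synthetic benchmark

No training dataset ships with the package. The `synthetic` module
generates random transcripts (i.i.d. bases at a target GC fraction) and
labels their candidates with a known potency function that is linear in
the feature basis: 12 positional effects drawn N(0, 1.5) at context
positions 10–21 (the guide 5'-end region, mimicking the known sequence
asymmetry of effective siRNAs — a test convenience, not a biological
claim) plus a guide-GC term (weight 2), mapped to a ProdEn-like range
(offset 10, scale 2). Labels are corrupted with Gaussian noise; the
default noise sd is half the sd of the true scores. The Tan-style
dialect encodes a noisy score y as h = s = (y + 10)/4 so the
harmonization transform inverts the construction exactly (round-trip
error < 1e−9 at zero noise); scores ≤ −10 cannot be encoded and have
their noise redrawn, logged.

What this benchmark shows: that the encoding, harmonization, fit and
selection plumbing recover a recoverable signal (held-out Spearman
ρ ≥ 0.6 over 5 seeds at n = 2000, train 1500/test 500; |ρ| < 0.15
after label permutation, guarding against leakage through scaling or
fold construction). What it does not show: performance on real pooled
sensor-assay data, whose noise structure, label distribution and
sequence composition differ from this idealized linear model.

## Problem sizes and numerics

Headline statistics use n = 2000 synthetic candidates per seed over 5
seeds, with 5-fold CV for the 3×3 tuning grid; the full statistical
suite runs in a couple of minutes on one CPU. Floating-point contracts:
the two transform forms agree to 1e−9; model serialization round-trips
with bit-identical predictions; all generators and CV splits are pure
functions of their seeds. Degenerate inputs are defined rather than
accidental: transcripts shorter than 48 nt yield zero candidates, an
all-excluded selection returns an explicit empty result, and an
all-rejected training table is a hard error.

## Known limitations

* The auxiliary stand-ins are deliberately simple heuristics; real
  structure/scoring tool outputs, where available, should be ingested
  via the table path.
* No off-target (seed-match) screening, SNP avoidance, or isoform
  handling — out of scope.
* The homopolymer rule, duplex thermodynamics and accessibility operate
  on perfect Watson-Crick assumptions; G:U wobble pairing is ignored.
* Potency scores carry no calibrated uncertainty; they are ranking
  scores, not knockdown percentages.
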