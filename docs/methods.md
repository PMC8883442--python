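# Methods

## The screen and its data

A kinase yeast array measures the growth of colonies expressing one human
kinase (or control protein) per spot, replicated across expression
constructs (multiple ORF clones, with and without a nuclear localisation
sequence), four *S. cerevisiae* strains of different genetic background
(BY4742, L40c, W303, Y258 in the reference configuration), and tens of
growth conditions (alternative carbon sources, detergents, temperature, pH,
metal ions, osmotic stress). Growth reduction is scored visually on an
ordinal 0–3 scale: none, weak, moderate, severe. The long-format score
table is the canonical interchange form; plate grids (384 format, rows A–P ×
columns 1–24) can be read directly, with blank cells treated as *missing*
observations, never as score 0.

**Clone aggregation.** Kinase-level analysis requires one value per
(protein, strain, condition). The default rule is the maximum over clones,
vectors and replicates: any active construct is evidence of activity, and
clone-to-clone differences mostly reflect expression failures rather than
biology. A lower-median rule is available for robustness checks. Kinase-dead
and control constructs carry their own protein identifier and never pool
with the wild-type kinase. The max rule is idempotent, order-invariant, and
dominates every contributing spot — all property-tested.

## Synthetic screens with planted truth

Because the analysis must be testable end to end without external data, the
generator plants a known latent structure and emits data from an explicit
probability model.

**Ordinal score model.** Each spot draws a latent logistic variable `L` and
records `score = #{j : η + L > θ_j}`, i.e. a cumulative-logit (proportional
odds) model with

    η = a·activity_k + b·severity_c + γ_s + d_class(k)

This is the natural generative model for an ordered 0–3 outcome; the
coefficients are artifact parameters, not empirical claims. Defaults:

| parameter | default | meaning |
|---|---|---|
| kinase counts | 41 Y, 179 S/T-ortholog, 46 S/T-non-ortholog | array composition at reference scale |
| controls | 70 unrelated + 10 kinase-dead | phosphotransfer-negative comparison set |
| activity levels | (0, 0.5, 2.0, 3.0) | latent activity per tier (inactive/moderate/high/topmost) |
| tier proportions | (0.25, 0.25, 0.25, 0.25) | see binning note below |
| a (activity coefficient) | 1.6 | scales tier separation |
| b (severity coefficient) | 1.0 | condition harshness effect |
| severity | Normal(0, 0.4); toxic mean 8.0 | ~17 % of conditions are globally toxic |
| γ (strain offsets) | 0.0, 0.3, −0.2, 0.5 | strain sensitivity differences |
| d (class offsets) | Y 1.0, S/T-ortholog 0.5, non-ortholog 0.0 | tyrosine phosphorylation is most harmful; conserved S/T kinases hit conserved processes |
| θ (thresholds) | (5.5, 6.5, 7.5) | calibrated so specific conditions stay well below the toxicity cut |
| clones × replicates | 2 × 2 | ~368,000 spots at reference scale |

Tier assignment is stratified within kinase class, so class comparisons are
never confounded by tier composition; the class effect is carried entirely
by `d_class`.

**Why equal tier proportions.** The profiling stage bins positive condition
counts at the *quartiles* of each strain's positive-count distribution.
Quartile edges land in the gaps between tier count distributions only when
the tiers hold comparable mass; with markedly unequal tiers the edges
necessarily split a tier across bins and no clustering can recover the
planted partition. Equal masses make the planted three-group structure
identifiable by construction — which is precisely what a recovery test
needs — at the cost of a topmost tier somewhat larger than a real screen
would show.

**What the generator does not model.** Spatial plate artifacts (edge
effects, pinning failures) beyond missing-cell injection, clone-specific
expression differences, condition-by-kinase interactions (a kinase that is
harmful only under one stressor), and visual-scoring subjectivity. Passing
recovery tests therefore show that the pipeline is correct under the stated
model, not that a real screen's tiers are this clean.

## Condition quality control

Globally toxic conditions (growth suppression regardless of the expressed
protein) carry no kinase-specific signal. Plotting the number of defective
kinases per condition-strain pair gives a bimodal distribution; the
pipeline:

1. counts kinases with score ≥ 1 per pair (controls excluded from the
   count by default);
2. optionally locates the histogram valley — bins of width 25, the
   lowest-density *interior* region within the search window; a contiguous
   run of equally empty bins yields the run centre, so a clean two-cluster
   gap returns its midpoint; a unimodal histogram returns nothing, with a
   warning;
3. excludes pairs whose count strictly exceeds 175 (the fixed default,
   chosen as an absolute kinase count; a fractional alternative
   `max_defect_frac` is available), and
4. reports the evaluable accounting: retained pairs in total, per strain,
   and conditions retained in every strain.

The filter is applied per condition-strain pair, not per condition pooled
over strains, consistent with accounting in units of condition-strain
pairs. Valley detection is advisory; the fixed threshold is the default and
the detected valley can be passed in its place.

## Activity profiling

Per kinase and strain, the number of retained conditions with score ≥ 1 is
binned 0–4: bin 0 iff the count is 0, positive counts split at the
quartiles of that strain's positive counts, ties to the lower bin (equal
counts always share a bin). A fixed-edges scheme is available to reproduce
externally binned tables. The kinases × strains bin matrix is clustered
agglomeratively (Ward linkage on Euclidean distance by default; average and
complete exposed) and cut at k = 3; tiers are labelled topmost / highly /
moderately by descending cluster mean bin, so labels never depend on
cluster indices. Rows are canonicalised (sorted by bin vector, then id)
before linkage, making the partition invariant to input order even with
tied merge distances. The full linkage matrix is retained for audit. The
top-30 ranking orders kinases by total bin, then total raw count, then
identifier.

Tier recovery is scored with the adjusted Rand index against the planted
tiers collapsed to the three named groups (inactive + moderate →
moderately), since every kinase belongs to one of three tiers in the
reference analysis.

## Strain concordance

For each strain, the set of (kinase, condition) pairs with a defect is
restricted to conditions evaluated *and retained* in that strain — an
unevaluated condition cannot create apparent disagreement. Upset counts
decompose the union of these sets by exact strain membership (the counts
partition the union, an asserted invariant). The severe-defect histogram
uses severity 3 (a kinase is "severe in strain s" iff it scores 3 in ≥ 1
retained condition of s), matching the distinction between any growth
defect and severe growth reduction. Because the reference total of defect
pairs could be counted before or after QC, the analysis reports both,
labelled.

## Group statistics

The unit of comparison is the per-condition-strain group fraction: among a
group's members evaluated in that pair, the fraction with score ≥ a given
severity (default 1 for kinase-vs-control, 3 for "strong" class
comparisons; "strong" is not defined numerically anywhere authoritative, so
it is a configurable default). Two groups' fraction distributions are
compared with a self-contained Mann–Whitney rank-sum test:

* `U = #{(i,j) : x_i > y_j} + ½·ties`;
* **exact**: full enumeration of the permutation null over group
  assignments, used when min(n_x, n_y) ≤ 8 and n_x + n_y ≤ 20 (beyond that
  it falls back with a warning); the two-sided p is twice the smaller tail,
  clipped at 1;
* **normal approximation**: continuity-corrected z with tie-corrected
  variance `σ² = n_x n_y/12 · [(n+1) − Σ(t³−t)/(n(n−1))]`.

The exact path is property-tested against independent full enumeration and
against scipy's permutation method; the asymptotic path against scipy's
asymptotic method. No multiple-testing correction is applied by default
(raw p-values are reported); Benjamini–Hochberg is available for larger
comparison sets.

**Calibration and its limits.** On null screens with equal class
coefficients *and no between-condition severity variation* the empirical
type-I error at α = 0.05 is nominal (the acceptance script measures it over
1000 scaled-down screens of 20 conditions × 2 strains × 60 kinases — sizes
chosen to keep the 1000-replicate null study fast at one CPU). When
conditions differ in severity, both groups' fractions rise and fall
together across pairs; this positive cross-correlation violates the
independence the rank-sum test assumes and makes it *conservative* (we
measure rejection rates near 0.007 at α = 0.05 under the generator's
default severity spread). Conservative is the safe direction for screen
claims, but p-values from heterogeneous condition panels should be read as
upper bounds on evidence, not calibrated probabilities.

## Phospho-Y2H modulation calling

Growth strength of a 1:10 dilution series is scored ordinally as one plus
the deepest still-growing step (0 if nothing grows); non-monotone series
are scored literally with a data-quality warning. The plate baseline per
media is the median over annotated non-related control kinases (replicates
pooled by median), falling back to the plate median with a warning.

A **loss** call requires the SD5 (selective media) score to sit at least
`min_shift = 2` dilution steps below baseline in ≥ 2/3 of replicates — one
step is within scoring noise of this assay, and the reference readout uses
three biological replicates — *and* the SD3 (viability) score within 1 step
of its baseline. The SD3 gate is the assay's central confound control:
growth-toxic kinases (precisely the topmost-active set) would otherwise be
miscalled as loss-of-interaction. A **gain** call is the mirrored rule on a
non-interacting baseline. Toxic kinases are reported with mode `none` and a
toxicity flag; loss and gain are mutually exclusive. Cu²⁺ induction level
is metadata; calls are never made across induction levels.

Pairing each wild-type call with its kinase-dead partner yields the
phospho-dependence flag: modulation by the wild type but not the dead
kinase implicates catalysis; a kinase-dead construct reproducing the effect
indicates a scaffold or ternary-complex mechanism. All call thresholds are
package decisions (no authoritative numeric thresholds exist for this
assay) and are recorded in the output metadata.

## Growth kinetics

Liquid-culture OD595 series (24 h, 10 min sampling) are fitted with the
four-parameter logistic `OD(t) = b + (K−b)/(1+exp(−r(t−t₀)))` — the minimal
sigmoid for batch yeast growth; lag-phase extensions (Gompertz, Baranyi)
are out of scope. Initialisation: b = first OD, K = max OD, t₀ = first
half-range crossing, r = 0.5/h; least squares via `scipy.optimize.curve_fit`.
Convergence is reported, never assumed: optimizer failure returns
`converged=False` with diagnostics, and a curve with amplitude below 0.02 OD
(or 2 % of its maximum) is flagged degenerate without fitting. A fit
returned with negative rate is re-parameterised to the equivalent
increasing-rate orientation. The wild-type vs kinase-dead effect is
`mean(metric_KD) − mean(metric_WT)` (positive = the active kinase inhibits
growth), computed on AUC by default because AUC is defined even for
strongly inhibited, non-sigmoid curves; carrying capacity K falls back to
AUC with a warning when any fit fails.

## Numerical and design notes

* All generators are deterministic given a seed (`numpy.random.default_rng`);
  byte-identical outputs are tested.
* Quartiles use numpy's default linear interpolation; bin ties go to the
  lower bin so equal counts always share a bin.
* The valley detector anchors histogram bins at zero so the reported
  threshold does not depend on the sample minimum.
* Exact rank-sum enumeration cost is bounded by C(20, 8) ≈ 1.3·10⁵
  assignments; beyond the bound the normal approximation is used.
* Problem sizes in the acceptance study (1000 null screens at 20 × 2,
  50 Y2H plates of 100 kinases, 50 noisy growth curves) are the package's
  chosen desk-scale defaults; all complete in well under a minute each.

## Known limitations

* The ordinal simulator has no kinase-by-condition interaction terms, so
  condition-specific kinase biology is not represented.
* Tier recovery is demonstrated under equal planted tier masses (see
  above); real screens with strongly unequal tiers would need the
  fixed-edges binning scheme and external bin boundaries.
* The rank-sum test is conservative under between-condition heterogeneity
  (see Group statistics).
* The Y2H caller assumes a stable per-plate baseline; plate-to-plate
  normalisation is out of scope.
* Construct-count bookkeeping is dataset-defined; the data model does not
  reconcile clone-count discrepancies in source inventories.
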