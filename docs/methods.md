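# Methods

## Overview

`mintscreen` implements a comparative, activity-guided screen for
allelochemicals in essential oils. The design follows the classical logic of
activity-guided fractionation, applied across a panel of related accessions
rather than across chemical fractions: oils from many accessions are profiled
by GC, assayed for bioactivity (cress seed germination inhibition), and the
two data layers are combined into a per-compound score that rewards compounds
that are abundant precisely in the bioactive oils. Candidates are then
characterized by sigmoidal dose–response analysis and two cytotoxicity
readouts in tobacco BY-2 suspension cells. Because comparative screens are
only as good as the identity of their inputs, the panel is first
authenticated with a plastid DNA barcode (the *psbA-trnH* intergenic spacer).

The package ships a synthetic-data generator that emulates all five input
layers with exported ground truth, so that every estimator has a
parameter-recovery test.

## Barcode authentication

**Read merging.** Forward and reverse Sanger reads are merged by scanning all
relative offsets of the forward read against the reverse-complemented reverse
read and keeping the offset with most matching positions (ties: longer
overlap, then smaller offset). The merge requires a minimum overlap (default
20 nt) *and* a minimum overlap identity (default 80%); without the identity
floor any two unrelated reads would "merge" into a run of `N`. Conflicting
overlap positions become `N` rather than picking a base, because no quality
scores are available at this stage.

**Primer trimming.** The merged sequence is trimmed to the insert strictly
between the forward primer match and the reverse-complemented reverse primer
match (Hamming search, configurable mismatch budget, leftmost best hit),
using the universal *psbA*/*trnH* primer pair as defaults. Failures name the
primer that could not be located.

**Distances.** Pairwise distances on the pre-aligned barcodes use p-distance
by default, with Kimura 2-parameter available by flag; sites with a gap or
`N` in either sequence are excluded pair by pair (pairwise deletion). The
distance model behind the published analyses of this assay type is usually a
software default and rarely stated; p-distance was chosen as the assumption-
free option for the short, closely related spacer sequences involved.
Multiple alignment itself is out of scope: inputs are pre-aligned (or
generated aligned).

**Neighbor joining.** Saitou–Nei NJ with two deterministic conventions:
ties in the Q-criterion are broken toward the lexicographically smallest
label pair, and negative branch-length estimates are clamped to zero with
the excess transferred to the sister branch. Clamping keeps every reported
branch length non-negative, which the downstream invariants (path-length
additivity tests) rely on; some phylogenetics packages print the negative
estimates instead. On additive matrices both conventions are inactive and NJ
provably recovers the generating topology; the test suite checks this
against a brute-force least-squares topology search for up to six taxa, and
cross-checks against an independent NJ implementation on noisy matrices.

**Bootstrap.** Alignment columns are resampled with replacement (default
1,000 replicates), NJ is rebuilt per replicate, and a bipartition's support
is 100 × its replicate frequency. The tree is rooted on the declared
outgroup after support annotation, so supports stay attached to unrooted
bipartitions.

**Mislabel flagging.** Each species with at least two declared members is
assigned a *reference clade*: among clades with support ≥ `min_support`
(default 65, the weakest support still considered interpretable here) in
which that species' declared members form a strict majority, the one
containing most of them, largest on ties. An accession inside its own
species' reference is confirmed; outside it but inside another species'
reference it is flagged (with the inferred identity); a singleton species
has nothing to anchor a reference and is "untestable"; everything else is
"unresolved". The strict-majority requirement means that two species
intermixed in one clade — the realistic failure mode of plastid barcodes in
hybridizing groups — yield "unresolved" rather than spurious flags, and the
largest-on-ties rule keeps a planted foreigner inside the reference clade it
invaded instead of shrinking the reference around it. Using per-species
reference clades rather than a per-leaf neighbor vote prevents a mislabeled
accession from causing its innocent nearest neighbor to be flagged as well.

## Chemistry

Per-accession GC peak tables (compound, relative peak area in % of total ion
signal) are validated (non-negative areas, row sums ≤ 100 within 1e-6,
duplicate compounds rejected), whitespace-normalized, and pooled for
interconverting isomers before scoring. The default pooling joins menthone
with isomenthone — the diastereomers interconvert by enolization and are not
meaningfully separable as bioactivity carriers — and the two citral isomers.
Pooling is exact summation; total area is preserved and pooling is
idempotent. The abundance matrix is the union of compounds over accessions
with absent compounds set to 0. **No renormalization is performed at any
stage**: the bioactivity score is defined on raw relative peak areas, and
renormalizing to identified peaks only would silently change every score. A
flag for renormalization exists on the matrix assembly path but defaults to
off. Compound-name matching is exact after whitespace normalization; spelling
variants are expected to be resolved upstream by a synonyms table, not by
fuzzy matching.

## Germination analysis

Inhibition for a treatment is
`g = 100 · (1 − mean(treated germinated) / mean(control germinated))`,
with a delta-method standard error from replicate variances and reporting
clamped to at most 100%. The reference is the treatment's matching solvent
control (ethanol for menthol, which is administered dissolved in ethanol;
n-hexane for oils and the other monoterpenes, which carry hexane traces from
distillation); a water control is used when no solvent is declared.

Dose–response curves use the four-parameter log-logistic
`f(d) = lower + (upper − lower) / (1 + (EC50/d)^slope)`, the standard
sigmoid family for germination and toxicity work ("logistic in log dose" is
the same family in a different parameterization). With fewer than four
points or fewer than three distinct positive doses, a two-parameter variant
(lower = 0, upper = 100) is used. Fitting is bounded least squares with
multi-start initialization (EC50 starts on a 5-point geometric grid spanning
the observed doses; slope starts at 0.5/1/2/4); an optimizer stall returns
`converged = False` rather than raising. Zero dose cannot enter a
log-logistic, so control data define the 0% anchor instead of a d = 0 point.
Doses are treated as nominal labels throughout (the ppm labels of the
germination assay and the % v/v labels of the cell assays live in different
unit systems and are never converted into each other).

Aggregate-level fits (per-dose inhibition or mortality means) are
**unweighted**. With three replicates the empirical per-dose SEs are
extremely noisy and collapse toward zero at saturating doses; weighting by
them concentrates the fit on the saturated tail and biases the EC50. In
simulation, SE-weighted fits recovered a planted 4-fold EC50 ratio with a
low-biased median (3.67) and only 84/100 runs within 25%, while unweighted
fits were unbiased (mean 4.01, 100/100 within 25%). The `se` argument
remains available for callers with externally known errors.

EC50 fold changes are plain ratios with a log-scale propagated SE;
`fold(A,B) · fold(B,A) = 1` holds to machine precision.

## Bioactivity score

For each compound, `B = (1/n) Σᵢ a(i) · g(i)` over the n accessions, where
`a(i)` is the compound's relative peak area (%) in accession *i*'s oil and
`g(i)` the germination inhibition (%) of that oil. The score is linear in
both layers, bounded by 10,000 (a pure compound in fully inhibitory oils),
and descriptive — no p-values are attached, by design. Mildly negative
sampled inhibitions (possible by sampling noise when the true inhibition is
near zero) are clamped to 0 inside the score with a warning, since the
formula presumes inhibition. Ranking is by descending B with lexicographic
tie-breaks; known positives (citral by default, an established
microtubule-active allelochemical that functions as the screen's positive
control) are excluded from the candidate list but reported separately. The
heat-map matrix orders compounds by descending score and carries raw areas,
never normalized values.

## Cytotoxicity

**Evans Blue.** Mortality per replicate is 100 × stained/scored (dye
exclusion: intact cells exclude the dye); condition estimates are means ± SE
over replicates. Time-course (fixed working dose, 15/30 min) and
dose-response (fixed time) analyses are kept separate; no pooling across
time points.

**AO/EB.** Each nucleus's red fraction `r = red/(red+green)` is classified
green (`r < t_low`), orange (`t_low ≤ r < t_high`) or red (`r ≥ t_high`)
with half-open boundaries and defaults `t_low = 0.33`, `t_high = 0.66`.
This ratio-threshold rule is this package's formalization of the
color-class grading used in AO/EB protocols — published descriptions of the
assay do not pin down numeric boundaries, so the thresholds are fully
configurable and reported alongside every distribution. Nuclei with both
intensities zero are tallied as unclassifiable and excluded from
frequencies.

**Line sensitivity.** Mortality dose series of two cell lines (wild type
vs. a cytoskeleton marker line) are each fitted with the two-parameter
log-logistic and compared by EC50 ratio, reported as EC50(A)/EC50(B) so
values above 1 mean line B is the more sensitive.

## The synthetic study generator

The generator's defaults (`paper_scenario`) encode the study conditions the
screen models, as true probabilities:

- **Panel**: 10 accessions in four species (3 × *Mentha spicata*, 3 ×
  *M. longifolia*, 3 × *Agastache rugosa*, 1 × *Melissa officinalis* as
  outgroup), with one planted declared-label swap (ACC03 ↔ ACC06).
- **Sequences**: Jukes–Cantor site substitution along the true species tree
  (per-branch change probability `¾(1 − e^{−4b/3})`), 600 aligned sites;
  within-species pendant branches 0.004 expected substitutions/site versus
  ≥ 0.03 between species, so inter-species distances exceed intra-species
  ones several-fold, as they must for barcode authentication to be
  meaningful at all.
- **Oil profiles**: per-accession compositions drawn from a Dirichlet
  (concentration 300) centred on the species' mean profile, including an
  "unidentified" fraction that is dropped afterwards so identified areas sum
  to < 100, as in real GC tables. The active compound (pooled
  menthone/isomenthone, ~30% mean area) is concentrated in the
  *M. longifolia* and *A. rugosa* groups; *M. spicata* is carvone-rich and
  *M. officinalis* citral-rich. Pooled-vocabulary compounds are emitted as
  their member peaks at fixed ratios (menthone:isomenthone 3:1), leaving
  re-pooling to the chemistry stage.
- **Germination**: germinated ~ Binomial(100 seeds, p_control·(1 − inh)),
  3 replicates. The control germination probability is not a printed study
  quantity; the default 0.95 reflects the high germination of fresh cress
  seed and is configurable. Inhibition acts multiplicatively on p_control,
  which makes inhibition(control) = 0 exact. Planted compound truths:
  menthone/isomenthone 70/80/99% at 0.01/0.1/1 ppm; menthol 30/40/95%;
  linalool 30/35/95%; limonene 5/10/20%. Oil truths at 0.1 ppm: 80–85% for
  the active-rich groups, 25% for *M. spicata*, 5% for *M. officinalis*.
- **Mortality**: stained ~ Binomial(600 cells, p), 3 replicates. The active
  compound follows a two-parameter log-logistic in dose with slope 3 and
  EC50 0.08% v/v in the wild type, divided by 4.0 for the tubulin marker
  line and by 1.6 for the actin line; the six-point dose grid
  0.0125–0.4% v/v is geometric around the 0.2% v/v working dose of the
  time-course design. Time-course truths at 0.2% v/v encode the narrative
  pattern: active compound saturated by 15 min (~94%), menthol intermediate
  and slower (25% → 65% in the wild type, 90% at 30 min in the tubulin
  line), limonene weak (10% → 20%), solvent controls 2–3%.
- **Nuclei**: per nucleus, total intensity ~ Gamma(5, 200) split by a
  Beta-distributed red fraction (concentration 20) whose mean rises
  sigmoidally with dose for permeabilizing compounds, from 0.05 untreated to
  0.95 at saturation; ~275 nuclei × 2 series per condition.

One RNG stream per output table, seeded from `(rng_seed, table tag)`, so
adding or regenerating one table never perturbs the others; identical
(config, seed) gives byte-identical study directories.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: GC co-elution, retention-time drift and
quantitation error (compound areas are noiseless apart from compositional
sampling); germination counts without overdispersion beyond binomial
(real boxes share humidity/temperature microenvironments); mortality counts
without between-replicate batch effects; sequence evolution without indels,
rate heterogeneity or hybridization/plastid capture (the mechanism that
makes real congeneric barcodes unresolvable); and no image-level artifacts
in the intensity data. Recovery results on this generator demonstrate that
the estimators are correct and unbiased under the stated noise model, not
that the assays themselves are this well behaved.

## Numerical choices and degenerate inputs

- Peak-table row sums accept a 1e-6 tolerance above 100.
- K2P raises on log-domain violations (too-divergent pairs) instead of
  returning infinities; a sequence pair with zero comparable sites raises,
  naming the pair.
- `fit_dose_response` raises on all-identical responses (a sigmoid is the
  wrong model for flat data) and on non-positive doses.
- NJ requires ≥ 3 taxa; bootstrap requires ≥ 1 replicate and a present
  outgroup.
- Class-boundary points in nucleus classification are deterministic
  (half-open intervals); a condition with no classifiable nucleus raises.
- Reports round floats to 4–6 decimals before serialization so that JSON
  output is byte-stable across runs.

## Problem sizes used in the verification suite

Recovery tests run at the study's own scale (3 × 100 seeds, 3 × 600 cells,
6-dose series) and average over 10–30 generator seeds; topology and
property sweeps use 4–6-taxon trees (where brute-force enumeration over all
unrooted topologies is feasible) and 100-seed Monte-Carlo loops. Bootstrap
tests use 30–100 replicates, which is sufficient to pin supports for the
well-separated synthetic clades; the pipeline default remains 1,000.

## Known limitations

- The mislabel rule assumes most accessions of a species are correctly
  declared; a majority-mislabelled species will fool any internal-consistency
  check, including this one.
- p-distance/K2P and NJ are appropriate for short, closely related barcode
  spacers; the package deliberately offers no ML or Bayesian inference.
- The bioactivity score is correlational by construction: it cannot separate
  a truly active compound from a compound co-occurring with one. The screen's
  output is a ranked candidate list, not an attribution of causality — the
  dose-response and cytotoxicity stages exist precisely to test the top
  candidates directly.
- EC50s from 2-parameter fits are only as identifiable as the dose grid
  allows; an EC50 at the edge of the grid inflates the fold-change variance.
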