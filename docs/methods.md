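# Methods

## Problem and model

The package compares label-free protein abundances between two cell states
(reference state A, displayed "hiPSC"; differentiated state B, displayed
"iN") measured as iBAQ intensities in a paired-by-batch design: every
culture batch contributes one sample per state. Intensities are modeled as
log-normal; an undetected protein is stored as an exact zero, and
non-detection is treated as left-censored (missing not at random): the
probability of detecting a value falls with its underlying abundance.

The analysis chain is: total-intensity normalization → detection flags →
per-protein differential statistics → annotation funnel → fold-based
receptor selection → knowledgebase join.

## Normalization

Each sample column is divided by its column sum, giving relative iBAQ
fractions that sum to 1 per sample. This removes any per-sample
multiplicative factor exactly — including loading differences and the
generator's per-sample batch effects — and is verified by two properties:
column sums equal 1 to 1e-12, and scaling any raw column by a positive
constant leaves every downstream result unchanged. Consequence of the
compositional constraint: a protein that makes up a non-negligible fraction
of total intensity in one state depresses the normalized values of all
other proteins in that state. This matters for simulation design (see
below) and for interpreting ratios of extremely abundant proteins.

## Detection and the intensity floor

A protein is *quantifiable* in a condition iff it is nonzero in at least
`min_batches` (default 1) of that condition's batches; the four-way
detection class (`both`, `A_only`, `B_only`, `neither`) follows.
`neither`-class proteins are dropped from all downstream tables.

All ratios and log transforms use a single global floor
`floor_factor × quantile(positive normalized intensities, floor_quantile)`;
the defaults (factor 0.5, quantile 0) put the floor at half the smallest
positive normalized intensity, strictly below every observed value. The
ratio is

```
ratio_B_over_A = max(mean_B, floor) / max(mean_A, floor)
```

Flooring *both* sides (rather than only the denominator) is deliberate: it
makes one-sided detections yield large finite ratios in either direction,
keeps the volcano free of infinities, and gives exact antisymmetry — 
swapping the condition labels negates every log2 ratio and leaves every
p-value unchanged, a property the test suite enforces. With a
denominator-only floor, a protein detected only in A would get ratio 0 and
an infinite log ratio, breaking both properties.

## Differential test

P-values come from a two-sample test on `log10(normalized intensity +
floor)` across batches (unpaired; batches are treated as independent
replicates). Three tests are implemented:

- **Student's pooled two-sample t (default).** With 3 batches per state and
  equal within-group variances this test is exactly calibrated: under a
  null simulation with 5,000 proteins the fraction of p < 0.05 lands within
  binomial 99% bounds of 0.05, which the acceptance suite checks.
- **Welch's t** (`test="welch"`), for designs where the two states have
  genuinely different variances. Note that at n=3 per group Welch is
  intrinsically conservative (its observed type-I rate is ≈0.035 at nominal
  0.05, a known small-sample property of the Satterthwaite approximation),
  which is why it is not the default for the 3-batch design.
- **Mann-Whitney U** (`test="mannwhitney"`), retained for larger designs;
  at n=3 per group the rank test cannot reach p < 0.05 and is degenerate.

Both t-tests are verified against independently hand-coded textbook
implementations to 1e-12. Degenerate inputs (zero variance in both groups)
return p = 1.0 when the group means coincide and 0.0 otherwise. With fewer
than two batches in a condition, p is the sentinel 1.0 (with a warning) and
ratios are still computed. No multiple-testing correction is applied by
default — the volcano is conventionally drawn on raw p-values — but
Benjamini-Hochberg adjustment is available (`adjust="bh"`, via
statsmodels).

## Marker panels

Differentiation QC summarizes three gene panels (pluripotency: OCT4, SOX2,
LIN28A; neuronal/synaptic: SYP, SHANK2, SNCA; housekeeping: ATP5F1A,
TUBA1A) as mean ± SEM of normalized intensity per condition across batches.
Each panel gets a qualitative call from the geometric-mean floored B/A
ratio against a 2-fold threshold: `enriched-in-A` / `enriched-in-B` /
`balanced`. Unresolvable symbols are reported, never fatal.

## Annotation funnel

"Membrane protein" is operationalized by a declarative rule file shipped
with the package (`data/annotation_rules.tsv`): UniProt keyword `Membrane`,
or a subcellular-location string containing `Cell membrane` / `Plasma
membrane`. Receptor classes come from a curated list
(`data/receptor_classes.tsv`, 29 growth-factor receptors of which 15
neurotrophic, a synthetic curation assembled to cover the receptors the
analysis must recognize by name) plus any keyword rules; the curated list
wins on conflict. Flags are propagated upward so the nesting invariant
*neurotrophic ⇒ growth-factor receptor ⇒ membrane* always holds, and inputs
that violate it are rejected at load time. Because every funnel count
depends on the annotation snapshot, the annotation `source_version` is
recorded in the run report.

## Receptor selection and ligand matching

Candidates are neurotrophic receptors with `ratio_B_over_A ≥
fold_threshold` (default 10) that are quantifiable in state B
(`require_quantifiable_in_B`, default on). Selection is fold-based by
design: p-values are reported but not filtered on, since the biological
rule of interest is magnitude of enrichment, not significance at n=3.
Ordering is deterministic — descending log2 ratio, ties by ascending
p-value, then accession — and candidate sets shrink monotonically as the
threshold rises (property-tested).

Candidates are joined to the packaged receptor→ligand knowledgebase
(`data/ligand_kb.tsv`; matched by accession when available, else by
symbol). Every matching entry produces one ranked row; candidates without
any entry appear with an `(unmatched)` sentinel and are never flagged for
supplementation. The `selected_for_supplementation` flag requires the fold
and detection criteria and, when `require_ligand_available=true`, a
commercially available ligand — modeling the practical gate that only some
ligands exist as recombinant supplements. The knowledgebase pairs GFRA3
with persephin (PSPN) and GFRA4 redundantly with PSPN, following the
supplementation table this package mirrors rather than the canonical
GFRA3–artemin assignment. `compare_supplement_sets` reports the
added/removed/shared diff between any two ligand sets, e.g. the RLM
selection versus the conventional {BDNF, NT3}.

## Synthetic data generator

`generate(SyntheticConfig)` emits a quantification matrix, a matching
annotation set, a ligand knowledgebase and the full planted truth. The
latent log10 intensity of protein *i* in sample *s* is

```
base + protein_offset_i + condition_effect_is + batch_s + noise_is
```

with `protein_offset ~ N(0, base_log10_sd)` (dynamic range), a per-sample
batch factor `N(0, batch_sd)`, cell noise `N(0, noise_sd)`, and planted
fold changes applied symmetrically (±½·log10 f) so overall abundance stays
balanced. Detection of each cell is Bernoulli with logistic probability
`expit(slope · (log10 intensity − midpoint))`; failed draws become zeros.
Defaults: 3 batches, base 6.0, spread 1.2 (≈5 orders of magnitude across
the proteome), batch_sd 0.15, noise_sd 0.15, midpoint 4.2, slope 2.0 —
overall detection ≈0.9 with strongly depleted low-abundance deciles,
which `censoring_check` verifies against the logistic curve within
binomial error.

Randomness is split into one stream per protein (keyed `[seed, index]`)
plus one stream for batch factors, with a fixed draw order (offset, noise,
detection uniforms), so enlarging a config never perturbs earlier rows and
fixed seeds give byte-identical fixtures.

Proteins can be pinned to an absolute abundance
(`abundance_log10_absolute`), bypassing the random offset. The study-like
scenario (`study_like_config`) uses this for receptor slots: an
11,025-protein proteome, 35.7% membrane, 29 growth-factor receptors (15
neurotrophic) carrying real symbols/accessions, 10 receptors planted at
16-fold iN enrichment, FGFR1 planted 16-fold in the hiPSC direction, TRKC
pinned ~6 log units below the detection midpoint (censored everywhere), and
all other receptors pinned at 10^7 (~10× the proteome median). Pinning
encodes two facts of the emulated conditions — every receptor except TRKC
was reliably quantified, and receptors are nowhere near the proteome's
dominant mass — and avoids two artifacts that random receptor abundances
produce at some seeds: borderline receptors censored asymmetrically into
spurious "B-only" enrichment, and a 16-fold-planted receptor drawing a huge
offset and compressing all other ratios through the compositional
normalization. The scenario's noise_sd is 0.05 (strong signal-to-noise), so
planted 16-fold effects are recovered with sensitivity and specificity 1
and 2-fold effects never pass the 10-fold rule.

What the generator does **not** emulate: peptide-level evidence and
protein inference, correlated protein co-variation (each protein is
independent), protein-specific batch interactions (batch effects are pure
per-sample scalars, which total normalization removes exactly), heavy-tailed
or outlier-contaminated noise, and annotation errors. Passing tests
therefore demonstrate correctness of the computations under the stated
model, not robustness to those real-data complications.

## Problem sizes

The test suite and acceptance script use the study-scale scenario (11,025
proteins × 6 samples, run once per session), a 5,000-protein null
simulation for calibration, 1,000 random proteins for the p-value oracle
comparison, a 600-protein recovery scenario, and ≥100 randomized cases for
each monotonicity property. The full suite runs in well under a minute on
one CPU.

## Known limitations

- Exact reproduction of published funnel counts from a deposited dataset
  depends on the annotation snapshot used; the packaged rule file and
  curated list make this package's definition explicit and swappable, and
  the run report records the version used.
- The floored ratio saturates for one-sided detections: its magnitude
  reflects the floor, not a measured fold change.
- Column-sum normalization is compositional; ratios of proteins
  constituting a large fraction of total intensity are biased.
- The curated receptor-class list and ligand knowledgebase are packaged
  fixtures: real analyses should review and version them for the cell type
  at hand.
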