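# Methods

This note documents the models, conventions and design choices behind
`ppescreen`, in the spirit of a statistical methods appendix. It describes
what the code computes and why; all empirical numbers quoted here are
produced by the test suite or `scripts/acceptance.py`.

## The screen and its assumptions

The pipeline models an inducible-overexpression direct-target screen: a
GR-fusion transcription factor is held cytoplasmic until dexamethasone
(DEX) triggers nuclear translocation, while cycloheximide (CHX) blocks
translation so that only direct transcriptional responses can occur. The
design crosses four injection groups (Six1 alone, Eya1 alone, both,
un-injected) with two treatments (CHX, CHX+DEX) and a small number of
biological replicates (two in the original design). The un-injected group
is essential: genes that respond to DEX itself (glucocorticoid-responsive
artifacts) respond there too, and the control criterion of the filter
cascade removes them.

The biological hypothesis encoded in the gene classes is a
response-threshold model: targets for which endogenous levels of *either*
factor are limiting respond to single-factor overexpression
("high-threshold" responders in the sense that they can be driven by one
factor alone); targets limited by *both* factors respond only to combined
overexpression ("low-threshold" for the joint complex, appearing only in
the combined group). The magnitudes of "high" and "low" are not asserted
as biology; they are configuration parameters of the generator.

## Induction contrasts and the filter cascade

Per injection group, replicate FPKM values are averaged per treatment arm
before the fold change (matching the pooled-FPKM behaviour of the
assembly/quantification tool family this pipeline consumes tables from),
and the contrast is `log2((mean_dex + 1)/(mean_chx + 1))`. The pseudocount
of 1 FPKM stabilises ratios at low expression and matches the
log2(FPKM+1) display convention common for such data; it is configurable.

A gene is differentially expressed in a direction when it clears three
criteria: (1) an expression floor of mean FPKM ≥ 1 in the *higher*
condition — the induced arm for up-regulation, the baseline arm for
down-regulation; (2) |log2FC| ≥ 1; (3) a control criterion. Two control
rules are implemented: the default **delta** rule requires the
experimental fold change to exceed the un-injected fold change by ≥ 1
log2 unit in the tested direction (stated symmetrically for both
directions), and an alternative **absolute** rule requires the control
fold change itself to stay below 0.5 log2 units (above −0.5 for the down
direction). Applying the floor to the higher condition (rather than to
the induced arm always) is deliberate: a strongly down-regulated gene
ends *below* the floor in the induced arm by construction, and a literal
induced-arm floor would exclude nearly all real down-regulation.
Boundaries are inclusive (≥) throughout. With only two replicates per
arm, no per-group p-value is computed; significance enters through the
merged analysis.

## Co-regulation classification

The three groups' DE sets (per direction) are partitioned into the seven
disjoint Venn regions. Classes: all-three-groups → `coregulated_all_three`;
combined-only → `coregulated_combined_only`; DE under Six1 but never under
Eya1 alone → `six1_independent` (and vice versa); DE in both single-factor
groups but not the combined group → `ambiguous_pair_only`, a biologically
inconsistent pattern that is kept as its own class and *excluded* from the
co-regulated aggregate (which is all-three plus combined-only). Summary
fractions report the share of the co-regulated aggregate that is
up-regulated, overall and restricted to all-three support; zero
denominators yield an explicit undefined marker rather than a number.

The top-fraction overlap test ranks two groups' genes by fold change,
takes the top `ceil(fraction·n)` of each (ties broken lexicographically by
gene id for determinism) and applies Fisher's exact test to the resulting
2×2 table, two-sided by default since enrichment direction is a finding,
not an assumption; one-sided alternatives are a flag.

## Merged-replicate significance

Replicates of groups sharing an overexpressed factor are pooled (Six1_m
and Eya1_m with 4 replicates per arm, Six1+Eya1_m with 6) and each gene is
tested for a DEX–CHX difference with an unequal-variance Welch *t*-test on
log2(FPKM+1) replicate values, with Benjamini–Hochberg q-values. This is a
transparent, exactly testable substitute for the negative-binomial
count-model test of the original upstream tooling, whose per-gene
statistics require raw read data and internal dispersion estimates; the
package makes no claim of numerically reproducing that tool's q-values.
A gene is significant only if q < α (default 0.05) *and* it passes the
fold-change/floor/control cascade on the pooled contrast. Degenerate
inputs have fixed conventions: zero variance in both arms with equal
means gives p = 1; zero variance with unequal means gives the minimum
positive double and a `degenerate` flag, so the pipeline never emits
undefined statistics. The BH step-up is implemented directly from the
formula q(i) = min over ranks j ≥ i of p(j)·m/j (capped at 1) and is
cross-checked against an independent library implementation in the tests.

## Enrichment scoring

Per-term enrichment is the one-sided hypergeometric upper tail
P(X ≥ k) for overlap k between query and term within an explicit
background universe (always an input, never implicit). The EASE score is
the same tail evaluated at max(k−1, 0): removing one supporting gene makes
terms with tiny overlaps score conservatively, and guarantees
EASE p ≥ Fisher p. Cluster scores are E = −log10 of the geometric mean of
member-term EASE p-values, computed in log space with p floored at 1e-300;
this is the only reading of a "geometric mean of EASE scores" consistent
with reported cluster scores of order 30–40, which are impossible for a
mean of probabilities. Term-to-cluster groupings are user input; the fuzzy
clustering of hosted annotation services is not reproduced because its
parameters are not recoverable.

## Candidate prioritisation

The well-supported list requires log2FC ≥ 1 in at least two of the three
individual groups, with absent entries (printed as "–" in published
tables) counting as failures, and optionally requires every passing
group's fold change to sit ≥ 1 log2 unit above the control fold change
(enabled only when control values are available). Transcription-factor
status is always an explicit curated list — the package never infers it
from names or domains — and named rescue genes may be carried into the
candidate set despite failing the threshold, flagged as such. Recovery of
externally established targets is reported as presence-with-fold-change,
deliberately looser than the DE criteria, because recovery lists in this
literature include sub-threshold detections.

## qPCR relative quantification

Standard ΔΔCt: per condition, ΔCt = Ct(target) − Ct(reference); per
biological replicate, ΔΔCt = ΔCt(induced) − ΔCt(baseline);
RQ = eff^(−ΔΔCt) with amplification efficiency eff defaulting to the
ideal 2 (no efficiency corrections are applied by default). Technical
replicates are mean-collapsed on Ct before ΔCt. RQ and log2FC are averaged
independently across biological replicates — a distinction that matters
because the mean of RQ is not 2 to the mean of log2FC — and both are
reported with standard deviations.

## The synthetic-data generator

The generator emulates the screen's factorial design with planted classes
(`null`, `coreg_low_threshold`, `coreg_high_threshold`, `six1_only`,
`eya1_only`, `dex_artifact`), each crossed with an up/down direction.
Expression is generated in log2(FPKM+1) space: per gene a baseline is
drawn from a Gaussian (default mean 3, sd 2 — a heavy-tailed, strictly
positive FPKM distribution once exponentiated), the signed planted effect
is added only in DEX arms of the affected groups, i.i.d. Gaussian
replicate noise (default sd 0.3, giving replicate correlations above 0.9
as observed in real screens of this design) is added per sample, and
FPKM = 2^x − 1 clipped at zero. Generating in the shifted space makes a
planted effect of e log2 units *exactly* equal to the pseudocount-1
contrast the pipeline computes, so truth tables and measurements share a
scale; relative to a pure log-normal in FPKM the +1 shift is a
second-order distortion at the default baseline floor. Baselines are
floored at log2(FPKM+1) = 1 (FPKM ≥ 1) by default, i.e. the generator
emulates a transcriptome from which low-expressed genes have already been
removed, which is the substrate the filter cascade actually sees; the
floor can be disabled (`baseline_log2_min=None`) for studying the raw
baseline distribution.

Defaults: 2 replicates per arm; class proportions 87% null, 4%
combined-only co-regulated, 1% all-group co-regulated, 3% each
single-factor, 2% DEX artifact (non-null fraction ≈ 13%, matching the
scale of DE calls relative to a ~16k-gene floored transcriptome, with
combined-only far outnumbering all-group co-regulation as observed); 37%
of each effect-carrying class down-regulated (the observed down share of
DE calls); effect magnitudes Gaussian with mean 3 and sd 0.5 log2 units.
One global seed drives three deterministically derived sub-streams
(effects, baselines, noise), so identical configs are bit-reproducible.

Known limitations of the generator: no mean–variance trend (the
negative-binomial dispersion of count data is not modelled), no
correlation between genes, no library-size or length biases, and
down-regulated effects are attenuated when the baseline sits within
|effect| log2 units of zero expression (expression clips at FPKM 0 — also
true of real data, where an 8-fold repression of a 1-FPKM gene is not
measurable). Passing tests on simulated screens therefore validate the
pipeline's logic and statistics, not the count-level error model of any
particular sequencing workflow.

## Numerical and interface conventions

- Best-hit selection for annotation tables: highest bitscore, ties broken
  by lowest e-value, then lexicographic subject id; e-value cutoff 1e-5.
- Condensing duplicate annotations keeps the transcript model with the
  highest mean FPKM (FPKM is length-normalised, so summing across models
  would double-count); a `sum` rule is available for count-like inputs.
- The transcriptome floor (FPKM < 1 removal) is applied on the mean
  across all samples: stable under replicate noise, while the filter
  cascade separately enforces its condition-specific floor.
- All stage outputs are TSV with a `gene_id` first column; the run
  manifest records versions, seed, a config hash (output-directory
  independent) and per-stage row counts, and identical config + seed
  reproduce every output byte for byte.
- Test problem sizes (up to 2,000 simulated genes, backgrounds ≤ 60 for
  enumeration oracles, 1,000 random tables for the EASE/Fisher
  inequality) were chosen so the full suite completes in seconds while
  keeping at least three-standard-error resolution on the stochastic
  properties it asserts.
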