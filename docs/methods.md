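# Methods

This note records the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions adopted where the procedure leaves a
choice open.

## Two-color miRNA array model and normalization

Each miRNA is measured by several probes (default 8) on a two-channel chip
(Cy3 carrying the OVA-treated RNA pool, Cy5 the PBS control pool), in
duplicate hybridizations.  Processing is:

1. `corrected = max(raw − background, floor)` with `floor = 1.0` intensity
   unit, so the subsequent log2 stays finite on over-subtracted probes;
2. cyclic loess on the probes × (replicate, channel) log2 matrix: for every
   pair of columns a locally-linear loess curve of M = difference on
   A = mean is fitted (span 0.4, three full cycles over all pairs) and
   subtracted symmetrically — half from one column, half into the other —
   which removes intensity-dependent dye bias while preserving each probe
   row's grand mean exactly (to 1e-9, asserted in tests).  With very few
   probes the span is widened to cover at least three points.  The span and
   cycle count are the conventional choices for MA-plot normalization; the
   smoother itself is statsmodels' lowess.
3. per miRNA: fold induction FI = 2^(mean log2 ratio) over
   probes × replicates, and a two-sided one-sample t-test of the log ratios
   against zero.  The chip design yields paired two-channel ratios, which is
   why the test is one-sample on ratios rather than two-sample on channels;
   whether the original laboratory's provider paired across duplicate chips
   instead is not documented, so this convention is recorded rather than
   inferred.  Degenerate zero-variance input reports p = 1 at zero mean and
   p = 0 (with a warning) otherwise, so synthetic edge cases cannot crash
   the pipeline.

## Differential thresholds

* miRNAs: FI ≥ 1.5 or FI ≤ 1/1.5 (inclusive) with p < 0.01 (strict).  The
  inclusive fold bound matches the printed summary tables, which contain
  boundary rows at the two-decimal rendering 0.66 ≈ 1/1.52.
* genes, standard rule: per-probe mean log2 ratio over the two treated
  pools; a single-probe gene is up if the mean exceeds +0.6 (strictly) and
  down below −0.6; a multi-probe gene is called only when all probes agree
  in (strict) sign and at least one probe clears the threshold.  2^0.6
  rounds to a 1.52-fold change.
* genes, both-pools rule (feeds pathway analysis): |log2 ratio| >
  log2(1.5) with a consistent sign in each treated pool separately,
  aggregating probes with the same consistency rule.  "Fold induction
  greater than 1.5" is read as magnitude in either direction because the
  downstream pathway interpretation includes repressed genes.

The two gene rules coexist behind a `rule_tag` because they feed different
stages: the ±0.6 rule drives the inverse-pair tables (whose printed gene
fold changes, e.g. 0.64 and 1.62, sit at the 1.52-fold bound), the
both-pools rule the enrichment stage.

## Inverse pairing

A pair is emitted when the miRNA and gene are modulated at the same time
point in opposite directions and the prediction table links them with
p < 0.05 (strict).  Duplicate prediction edges — one row per predicted
binding site in MicroCosm-style exports — are collapsed to their minimum
p-value at read time so pairing sees one edge per (miRNA, gene, database).
Gene identifiers are matched by upper-cased symbol throughout: the mRNA
arrays, prediction databases and pathway sets all use gene symbols with
inconsistent casing, and no common stable-ID namespace is available across
the three sources.  Pairs are per-database; recurrence across time points
intersects on (miRNA, gene, database) and keeps the per-time-point
directions, which may flip (the early-repressed / late-induced pattern).

## Pathway enrichment

For pathway *P*, time point *t*, database *d*:

* `observed(P)` counts distinct (miRNA, gene) prediction edges with the
  miRNA modulated at *t* (either direction) and the gene in *P* (restricted
  to the array universe).
* `p_miRNA` is the proportion of 1000 permutation trials in which an
  equally-sized uniform draw of miRNAs from the chip universe yields a count
  at least as high (inclusive tie rule, per the procedure's definition).
  The observed configuration is not added to the null; an exact zero is
  clamped to 1/(2·n_trials) because the inverse-normal transform of 0 is
  infinite, and the clamp preserves ranking.  One seeded stream per
  (time point, database), derived from the master seed by hashing the
  labels; within a stream the same trial subsets score every pathway, which
  is statistically identical per pathway to independent draws and much
  cheaper.
* `p_mRNA` is the hypergeometric upper tail P(X ≥ k) with population the
  gene universe, successes the modulated-gene set (both-pools rule), draws
  the pathway∩universe genes and k their overlap with the modulated set.
* `p_combined` is Stouffer's method with equal weights.  Selection uses
  combined p < 0.05 with no multiplicity correction, matching the original
  selection procedure; a Benjamini–Hochberg column is emitted for reference
  but never drives selection.

### Calibration and its limits

Both component p-values are discrete — the permutation p through the
inclusive tie rule on integer counts, the hypergeometric intrinsically — so
the combined test is mildly *conservative*: summing exactly over both null
staircases gives a true null selection rate P(p_combined < 0.05) ≈ 0.033 at
both the desk and full scales (the desk preset keeps pathway sizes and the
modulated fraction unscaled precisely so that overlap counts, and hence
p-value granularity, match the full scale).  The calibration test therefore
uses 10 replicates × 30 pathways (300 draws), where the 3-binomial-SE band
around the nominal 0.05 ([0.012, 0.088]) comfortably contains both the
nominal rate and the intrinsic conservatism while still detecting a
genuinely miscalibrated (anti-conservative or degenerate) pipeline; at much
larger draw counts the band would shrink below the conservatism that any
discrete combined test necessarily has.

## Bench assays

ΔCt = mean(target Ct) − mean of per-reference mean Cts; the reference
aggregate is the arithmetic mean (the procedure names the housekeeping
genes — β2-microglobulin and HPRT1 for mRNA, U6 for miRNA — but no
formula; the arithmetic mean is the recorded convention).  ΔΔCt is the
OVA−PBS difference of group means and the fold change 2^−ΔΔCt.  Platform
concordance is a pure direction rule by default (sign of log FC on each
platform, with an optional no-change band for exploration); the reported
percent is rounded to an integer.  Reporter knockdown divides
protein-normalized luciferase activity in the miRNA condition by the
non-functional-control condition, scaled to control = 100.

## Synthetic data

`simulate_study` emulates, per time point: log-normal chip intensities
(log2 baseline N(10, 1.5), per-probe affinities N(0, 0.3), probe noise
σ = 0.1 on the log2 scale), a smooth slowly-varying intensity-dependent dye
bias on the control channel (amplitude 0.2 — the classic curved MA-plot
trend, which cyclic loess is there to remove), planted miRNA shifts
±log2(FI) with FI uniform on [1.5, 6], probe-level mRNA log ratios for two
pools with 1–3 probes per gene, Bernoulli prediction edges at density 0.03
per database (MicroCosm-style exports list hundreds of targets per miRNA)
with p uniform on (0, 0.05], and GMT pathways of 20–100 genes.  Planted
structure: modulated genes concentrated in one planted pathway, an
edge-density enrichment factor (default 8×, planted-edge p ≤ 0.01) from
modulated miRNAs into the planted pathway, and guaranteed inverse-pair
edges.  Everything is a pure function of (config, seed).

Default scales mirror the nominal study (566 miRNAs, 20,461 genes,
117 pathways, ~650 modulated genes ≈ 10%); the `desk` preset (200 / 2,000 /
30 / 200) shrinks the universes for test-suite runtime while keeping
pathway sizes and the modulated fraction — hence the discreteness structure
of both null distributions — unchanged.  The `null_enrichment` preset keeps
the planted differential signals (so the modulated sets are non-empty and
realistic in size) but plants no pathway or edge enrichment; this is the
null of the enrichment stage and is what the calibration test exercises.  A
literally effect-free simulation produces empty modulated sets and p = 1
everywhere, which verifies the degenerate path but cannot probe
calibration.

What the generator does *not* emulate: sequence-level target prediction
(seed matching, conservation, binding energies), correlated probe effects
within a gene, array spatial artifacts, dye-swap designs, or biological
correlation structure between time points.  Tests passing on this generator
therefore demonstrate that the statistical machinery is correct under its
own model assumptions — recovery of planted effects, calibration under the
null, determinism — not that the thresholds are optimal for any particular
real dataset.

`simulate_ct` plants per-(assay, time point) fold changes as −log2(FC)
shifts of OVA-group Cts against a flat U6 reference with Gaussian replicate
noise, so the comparative-Ct arithmetic recovers the planted value exactly
at zero noise.

## Packaged fixtures

The four transcribed summary tables (fold inductions per time point,
recurrence across time points, and the two inverse-pair tables) ship as
tab-separated package data with a sha256 manifest; `load_fixtures` refuses
tampered files.  The source tables disagree with each other in places —
the long-term block lists 69 rows where the running text counts 67, one
miRNA's long-term fold induction appears as 115.80 in one table and 116.16
in another, and the mid-term fold induction of the one always-up miRNA is
printed 1.55 or 1.56 depending on the table — and the fixtures deliberately
keep each value tagged by its source table rather than resolving the
discrepancies.  The fixtures carry a nominal passing p-value (0.009) for
membership-rule reconstruction because the printed tables report only which
miRNAs cleared the p < 0.01 cut, not the p-values themselves.

## Determinism

Every random stage draws from `numpy.random.default_rng` streams derived
from a single master seed (per-(time point, database) streams via sha256 of
the labels); all set-valued intermediates are sorted before sampling or
serialization.  Re-running any configuration reproduces every output file
byte for byte, which the test suite asserts.

## Problem sizes used by the test suite

Fixture and oracle checks run in milliseconds.  The simulation-based
checks use the desk preset: 20 replicates for planted-pathway recovery
(top rank by combined p required in ≥ 18), 10 replicates × 30 pathways for
null calibration, 20 planted miRNAs at fold 2.0 for recovery through the
normalization chain, and two full pipeline runs at 1000 permutation trials
for the bit-identity check.  The full suite completes in about three
minutes on one CPU.
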