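# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `chprofile`. It is the package's own account of its
science; every number quoted here is computed by the test suite, the
analysis drivers, or `scripts/acceptance.py`.

## Study model

The pipeline analyses a sorted-population expression time course: reporter
positive (GFP+) precursor cells versus the reporter-negative remainder
(GFP−), in quadruplicate, at three developmental timepoints (t1–t3), in
wild-type and optionally proneural-mutant genotypes. All analysis operates
on gene-level log2 intensities; probe-level summarisation and background
correction are upstream of this package (a quantile-normalization step is
provided for matrices that need it).

## Trusted-gene filter

A probe set is *trusted* for gene g when g is the only gene reached by at
least 50% of its oligomers; the threshold is inclusive at exactly 0.5. Sets
where two or more genes reach the fraction are *promiscuous*, all others
*unmapped*. Where several probe sets are trusted to one gene, their
per-sample log2 intensities are averaged — the upstream convention defines
only which sets are reliable, not a combiner, and the mean on the log scale
is the neutral choice. The union of trusted genes is the universe for every
enrichment test.

## Differential expression

Per timepoint and genotype, the GFP+ vs GFP− contrast uses a moderated *t*:
pooled per-gene variances s² (df = n₊+n₋−2) are shrunk toward a prior,

    s̃² = (d₀ s₀² + df s²) / (d₀ + df),
    t  = log2FC / sqrt(s̃² (1/n₊ + 1/n₋)),  p two-sided from t(d₀+df).

The prior (d₀, s₀²) is a scaled inverse-chi-square fitted by the method of
moments **on log s²**: under the model the marginal of s² is s₀²·F(df, d₀),
so E[log s²] and Var[log s²] are closed forms in digamma/trigamma and d₀ is
obtained with a Newton trigamma inverse. Log-scale moments are used because
raw second moments of the F marginal diverge for d₀ ≤ 4 — exactly the regime
the estimator must handle (parameter recovery in the suite: d₀ = 4 planted,
≈ 4.0 recovered from 10⁴ genes). When the observed log-variance dispersion
does not exceed the chi-square sampling component, or fewer than 10 genes
are available, the fit degenerates to full pooling: d₀ = ∞, every gene
assigned the mean variance, normal-theory p-values. `ShrinkagePrior(0, ·)`
reproduces the ordinary pooled two-sample t exactly (asserted against
scipy).

"Enriched" is one-directional (GFP+ above GFP−): two-sided p, BH-FDR
q-values (delegated to statsmodels' step-up implementation; oracle-checked
against a brute-force double loop), then gated by linear fold change
≥ fc_threshold and q ≤ fdr_threshold, both inclusive. Defaults 1.5-fold and
1% FDR; the motif analyses use 2-fold. Reports are ranked by descending
fold change with lexicographic gene-id tie-breaks.

## Over-representation statistics

The 2×2 tests are one-sided upper-tail Fisher exact tests; the
hypergeometric tail is summed in log space (gammaln + logsumexp) so that
tails of order 10⁻³⁰ at N ≈ 14,000 are exact to floating precision
(enumeration oracle: max relative error ~10⁻¹³ over all 135,750 tables with
N ≤ 40; the suite sweeps N ≤ 60). The EASE variant recomputes the tail with
the observed overlap decremented by one (k = 0 ⇒ p = 1); it is provably
never smaller than the plain Fisher p. Set members that do not resolve
against the universe are dropped before m is counted, because the summary
table's percentages use resolved set totals as denominators. Stars in
Table-style reports are raw p < 0.05 with no cross-row multiplicity
correction, matching the reporting convention the pipeline reproduces;
ranked term reports order by EASE p without further correction. Percentages
are formatted round-half-up to one decimal.

Applied to the published contingency marginals (universe 14,075; 429-gene
t3 list), the implementation reproduces the printed summary exactly:
23/28 ⇒ 82.1% and 27-fold; 18/83 ⇒ 21.7% and 7.1-fold; 42/174 ⇒ 8-fold;
76/750 ⇒ 10.1%. (The published source itself prints inconsistent t1
ciliogenesis counts in two places — 14/175 vs 15/174; the package computes
from whatever counts are supplied and does not arbitrate.)

## Motif scanning

Patterns are IUPAC consensus strings (no position-weight scoring).
Coordinates are 0-based half-open; upstream windows read 5′→3′ toward the
TSS on the gene's sense strand: [tss−L, tss) for + genes, (tss, tss+L]
reverse-complemented for − genes, clipped at contig edges. Both strands are
scanned by default (a flag restricts to plus); a genomic site matching in
both orientations — guaranteed for self-reverse-complementary patterns,
possible for near-palindromes — is counted once. Overlapping matches are
all counted.

The X-box and E_ATO consensi are deliberately **not** hard-coded: their
sequences come from the primary literature, so they ship as named
configuration entries the user must supply. The synthetic generator's
default motif (`GTTNCCATRGNAAC`) is a synthetic RFX-flavoured degenerate
14-mer, not a published consensus.

`mutate_ebox` applies the reporter-construct mutagenesis rule CANNTG →
AANNTT left-to-right, resuming at the next base after each rewrite. Resuming
*past* a rewritten hexamer would be unsound: the unchanged inner NN bases
can spell the start of a fresh E box (CACATGTG → AACATTTG still contains
CATTTG), so the exhaustive rule is used and the output provably contains no
plus-strand CANNTG.

## Resampling nulls

List-level enrichment draws n_iter (default 1000) random lists of the
observed size uniformly **without replacement** from the full universe (the
observed list is not excluded — the procedure matches "random gene lists of
equal size" literally), scores each with the supplied statistic, fits a
normal with the n−1 SD, and reports z, one-sided upper-tail p, and
enrichment factor observed/μ. An empirical rank-based p is carried alongside
as a distribution-free cross-check; a constant null (σ = 0) is flagged
degenerate with z and p undefined rather than numeric.

Calibration is validated where the normal approximation is the thing under
test: with 50-gene lists in a 2,000-gene universe and motif-positive gene
rate 0.3, the expected null count is 10 and the exact ideal-threshold
rejection probability P(X > μ+1.645σ) is 0.046; the measured type-I rate
over 800 seeded replicate studies is ≈ 0.046–0.058. At small expected counts
(e.g. 2.5) the rejection band is dominated by count discreteness — the 5%
boundary sits within hundredths of an integer — which measures the
discreteness of the statistic, not the machinery. Power at the planted
condition (list motif rate 0.5 vs background 0.05) is ≈ 1.0.

## Target screen

Candidate proneural targets contrast the same GFP+/GFP− fold change between
genotypes. Tier 1: fc_wt ≥ 2 with q_wt ≤ 0.01 and fc_mut < 2 — the mutant
side is a fold-change magnitude gate only; requiring mutant
*non-significance* as well is available as a strict flag, since a gene can
be below 2-fold yet formally significant. Tier 2 additionally requires
fc_wt/fc_mut ≥ 2. Tier 2 ⊆ tier 1 on all inputs, and the pass sets are
monotone in the ratio threshold. They are **not** monotone in the
fold-change threshold: raising it tightens the wild-type gate but loosens
the mutant gate (fc_mut < T), e.g. fc_wt = 9, fc_mut = 3 fails at T = 2 and
passes at T = 4. Ratios are computed on linear fold changes.

## Synthetic-data generator

The generator is the oracle for every stage. Its model:

* **Noise** — additive Gaussian on the log2 scale; per-gene SDs are
  log-normal around `noise_sd` (default 0.5) with spread
  `variance_heterogeneity` (default 0.1, mild). Baseline intensities
  N(7, 2²). Replicates are independent; correlation between GFP+ and GFP−
  samples from the same sort run is not modelled.
* **Differential expression** — a fraction of genes per timepoint
  (`onset_fractions`, defaults sized to give a few hundred per list at full
  scale) receives a planted GFP+ − GFP− offset of `effect_size` (default 2
  on log2, i.e. 4-fold; per-gene spread `effect_size_sd` defaults to 0 so
  the planted effect is the stated condition). Onset is cumulative by
  default (DE from onset onward), with a transient mode, since real
  temporal lists contain both shared and unique genes.
* **Mutant genotype** — same design with the planted effect zeroed for a
  configurable fraction (default 0.8) of planted genes, modelling
  precursors that fail to be specified.
* **Gene sets** — `geneset_spec` plants (size, DE-overlap rate) pairs;
  defaults (28, 0.8) and (750, 0.1) mirror the shape of curated
  compartmentalised-ciliogenesis and cilia-database collections.
* **Promoters** — i.i.d. uniform A/C/G/T background (composition bias out
  of scope); planted motif instances are concrete expansions of the IUPAC
  pattern at uniform offsets, random strand, minus-strand instances
  reverse-complemented in the emitted sequence; overlapping plants are
  disallowed; background promoters carry a spurious instance at
  `background_motif_rate` per kb. Contigs embed each window so that BED/FASTA
  extraction round-trips the generator's stored windows exactly.
* **Probe alignments** — clean, low-coverage (below the 50% boundary) and
  promiscuous probe sets with known expected classification.

Everything is reproducible byte-for-byte from (config, seed).

What passing tests show — and do not show — about real data: the generator
validates *recovery and calibration of the pipeline's statistics under its
own assumptions* (Gaussian log-scale noise, independent replicates, uniform
background sequence). It does not emulate probe-level artefacts, batch
effects, correlated sorts, dye/array effects, or promoter composition bias,
so passing recovery tests demonstrate correctness of the statistical
machinery, not robustness to those real-world violations.

## Problem sizes

The analysis drivers use a 6,000-gene universe (48 arrays including the
mutant genotype); recovery and calibration checks use 2,000-gene universes,
800/500 replicate studies for type-I calibration, 200 for power, 10⁴ genes
for prior recovery, and exhaustive Fisher enumeration for N ≤ 60 (suite) or
N ≤ 40 (acceptance script). These sizes were chosen so the full pipeline and
suite re-run comfortably on a laptop while keeping every Monte-Carlo
interval tight enough to be meaningful.

## Known limitations

* The moderated-t prior is a method-of-moments fit, not the published
  maximum-likelihood procedure of any specific package; agreement is
  validated by parameter recovery, not numeric identity.
* The EASE/Fisher machinery assumes a flat annotation table; GO DAG
  propagation (true-path rule) is out of scope.
* IUPAC consensus matching is binary; position-weight or conservation
  scoring is out of scope.
* Fold-change thresholds operate on linear fold changes of log2 means
  (geometric means of intensities), the convention of the reports the
  pipeline reproduces.
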