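# Methods

`stressarray` implements the desk-side analysis of a reference-pool
two-color microarray study of stress-activated gene expression in mouse
embryonic fibroblasts (MEFs). Three p38 SAPK activators — osmostress (100 mM
NaCl), the cytokine TNFα and the protein-synthesis inhibitor anisomycin —
are compared in wild-type cells, in wild-type cells pre-treated with the
p38α/β inhibitor SB203580, and in p38α knockout cells. Every treated sample
is hybridized against a common pool of untreated wild-type cDNA, so
expression is a log2(treated/pool) ratio. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Array processing

**Background correction.** Per-channel foreground minus background.
Negative corrected intensities are retained, not floored: flooring biases
low-intensity ratios, and the stabilizing transform below is defined for
non-positive values.

**Variance stabilization.** Each sample and channel is transformed with the
generalized logarithm

    glog2(x) = log2((x + sqrt(x^2 + c^2)) / 2),

which is strictly monotone, defined for all real x, and converges to
log2(x) for x >> c. A full maximum-likelihood variance-stabilization fit
(affine calibration plus noise-model estimation) is deliberately not
implemented: the downstream statistics consume only log2 ratios, for which
the glog with a robust scale estimate preserves the relevant contract —
near-constant variance across the intensity range. The scale c is estimated
per sample and channel from the non-positive background-corrected
intensities: for signals near zero, E[x² | x ≤ 0] equals the additive-noise
variance, so σ_add is taken as the RMS of the non-positive tail and
converted to c = σ_add / (ln 2 · s_mult), where s_mult (default 0.25 log2
units) is the assumed multiplicative noise level that balances the additive
and multiplicative variance components. When a channel has no non-positive
values the additive component is judged negligible, c = 0, and glog2
reduces exactly to log2 — this is what makes the zero-noise identity below
exact rather than approximate. A channel with zero spread raises a
scale-estimation error. Under simulated additive-plus-multiplicative noise
the max/min ratio of post-transform variances across intensity deciles is
below 2 (plain log2 exceeds 10³).

**Ratios, averaging, collapse.** Per probe and sample, M = treated −
reference on the stabilized scale (A = their mean is kept for QC).
Replicate M values are arithmetically averaged per biological condition
*before* probes are collapsed to genes; a missing replicate value is
skipped, never imputed. Probes are then collapsed to unique gene identifiers
by the per-gene mean (median and max-|value| are config switches); probes
absent from the map or mapping to more than one gene are dropped and
counted. Gene identifiers are opaque strings throughout.

**QC.** Replicate reproducibility is the Pearson correlation between
replicate hybridizations of the stabilized channel intensities (treated and
reference channels separately), flagged below 0.9. This is computed on
absolute channel signals, not on M: with only ~1–2% of genes responsive,
the M vectors are noise-dominated and their correlation is uninformative,
whereas the channel signals share the probe-affinity spread. Per-sample
summaries are numeric only: median M, the slope of the M-vs-A trend,
intensity quartiles and an M histogram.

## Response calling and dependency

Up-regulated: linear FC ≥ 2.5; down-regulated: FC ≤ 1/4. Both thresholds
are inclusive (applied with a 1e-9 absolute tolerance on the log2 scale so
that exact boundary values are kept) and config-switchable. A responsive
gene is p38-dependent when its response is reduced by at least 50% in a
perturbed arm. Two interpretations of "reduced" are implemented:

- `induction` (default): the induction above baseline is compared,
  fc_pert − 1 ≤ (1 − r)(fc_wt − 1) with r = 0.5;
- `ratio`: the raw fold changes are compared, fc_pert ≤ (1 − r)·fc_wt.

Every report names the rule it used. For down-regulated genes the rule is
mirrored through the reciprocal fold change (repression depth attenuated).
The boundary (exactly 50%) counts as dependent. Verdicts are computed per
perturbation (`dependent_sb`, `dependent_ko`), with `dependent_any` their
OR and `dependent_two` their AND; `dependent_two` is *not applicable*
(None), rather than False, when only one perturbation was measured, as in
the timecourse where only the inhibitor arm exists.

Set overlaps are exact Venn partitions (all 2^k − 1 regions with member
lists); the common core is the intersection of the up-sets of all
treatments, each member annotated with the two-perturbation verdict per
treatment, and genes lacking dependency data flagged missing rather than
dropped. Timecourse analysis reports, per timepoint, the up-set size, the
SB-dependency fraction, and the same restricted to a designated gene set
(a transcription-factor-activity surrogate term); non-monotone patterns
across timepoints are reported verbatim, never imputed. List outputs are
ordered lexicographically by gene identifier.

## Binomial GO enrichment

For a category with n genes (restricted to the universe) of which x are
differentially expressed, and global DE frequency p = |DE|/|universe|, the
statistic is the upper-tail binomial probability P(X ≥ x), X ~ Binomial(n, p),
computed as a log-space sum of exact pmf terms (gammaln + logsumexp). The
upper tail is an analysis decision — the question is over-representation —
and is recorded in every output; a doubled two-sided variant is available.
Categories with fewer than 20 universe genes are excluded. The universe is
either all genes with at least one annotation in the ontology under test
(default) or the whole array; the choice is recorded. BH step-up q-values
(via statsmodels) are computed within (ontology × condition) strata by
default, mirroring per-heatmap testing; significance classes are `fdr`
(q ≤ 0.05), `nominal` (p ≤ 0.05) and `none`. Cellular-component enrichment
consumes the 2-fold up-set, molecular function and biological process the
2.5-fold up-set. The annotation is taken as a flat term→gene map; GO-DAG
ancestor propagation is out of scope. Hypergeometric/Fisher alternatives
and ranked (GSEA-style) tests are deliberately not offered.

## Synthetic data

The generator emulates the study's structure so every stage is testable
without downloads: 41,175 probes over 19,261 unique genes (each gene 2 or 3
probes by deterministic assignment), two replicates per condition, and a
reference-pool design. Per stress context it plants up/down-responsive gene
fractions, Bernoulli dependency flags, and attenuations drawn from laws
whose supports sit strictly on either side of the 50% boundary (dependent:
residual induction Uniform(0, 0.4); independent: Uniform(0.6, 1.1)), so the
dependency rule is decidable at zero noise. The same attenuation is applied
in the inhibitor and knockout arms, reflecting the very good overlap
observed between the two perturbations. Up-gene log2 fold changes are
Uniform(1.5, 4.0) — safely above the 2.5× cutoff at the default noise —
and down genes Uniform(−4.2, −2.2), below the 4× cutoff.

Default study conditions: the endpoint comparison plants 144/146/178 up and
29/36/22 down genes for TNFα/anisomycin/NaCl(2 h) with a designated 30-gene
core up-regulated by all three stimuli; per-stimulus dependency
probabilities are 0.60/0.74/0.88, spanning the observed 60–88% range
(per-stimulus values are not individually published, so the endpoints and
midpoint of the range were fixed once as defaults), and down-gene
dependency 1.0/1.0/0.70. The osmostress timecourse plants 114/178/321 up
genes at 45 min/2 h/8 h with dependency 0.90/0.74/0.62 (wt and SB arms
only). Non-core up-set memberships are capped at two contexts per gene so
that the all-context intersection equals the designated core exactly; this
removes the (vanishingly rare at this scale) accidental triple overlaps at
the cost of not modelling genuinely shared non-core genes.

Intensities: per-probe baselines are log-normal (median 1000 arbitrary
units, log2-sd 1.5 — a wide dynamic range typical of expression arrays)
drawn once and shared across hybridizations, multiplied per measurement by
2^ε with ε ~ N(0, 0.25) log2 units per channel (the array noise magnitude
is a free parameter, not a published value), plus a constant additive
background recorded exactly in the background columns. Background
subtraction is therefore exact, and at zero noise the pipeline recovers
every planted log2 fold change to floating-point accuracy; the additive
noise behaviour of the glog is exercised by a dedicated simulation instead.
Dye-swap designs, spatial artifacts, print-tip effects and saturation are
not modelled — passing tests say nothing about such artifacts in real data,
nor about probe-annotation errors, which the synthetic map does not contain.

The GO generator emits background terms of uniform random size 20–200, a
planted term (default size 60) over-representing the responsive genes, the
TF-activity surrogate term, and optionally an undersized term for filter
tests. The planted over-representation factor f is converted to a sampling
weight w = f(U − D)/(U − fD) so the expected DE-overlap equals f times the
uniform expectation; f = 1 reduces exactly to uniform sampling.

All randomness flows through `numpy.random.Generator` streams seeded as
(seed, k) with a distinct k per generator stage; no global state is
touched, and identical configs give byte-identical outputs including row
order.

## Problem sizes and determinism in the shipped checks

The test suite exercises the full platform scale (19,261 genes / 41,175
probes) for the zero-noise identity and the core recovery, 20 seeds at full
scale for the stochastic recovery checks (means over seeds are compared at
two binomial standard errors of a single run), 200 seeds for enrichment
power and 500 draws for null calibration at a 2000-gene universe, and
scaled-down 400-gene studies for the orchestration tests. Hypothesis-based
property tests run derandomized. The acceptance script runs the two
full-scale studies end-to-end at the default noise level.

## Known limitations

- The glog scale estimator assumes the additive-noise level is visible in
  the non-positive tail; data background-corrected upstream with negatives
  floored would defeat it (c would be 0 and low-intensity ratios noisier).
- The binomial model treats genes as independent draws; co-annotated,
  co-regulated genes make it anti-conservative, which the flat synthetic
  annotation does not probe.
- `dependent_any` on noisy data is slightly inflated relative to the
  planted marginal dependency because it ORs two noisy verdicts.
- No dye-swap correction, within-array spatial normalization or cross-array
  quantile normalization is provided.
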