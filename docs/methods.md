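# Methods

`desearch` implements content-based retrieval of gene-expression
experiments: each two-group comparison is condensed to a differential-
expression (DE) profile, optionally projected into a reduced feature
space, and a library of such profiles is ranked against a query by a
significance-weighted correlation, with empirical false-discovery
control from a random-pair background. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Differential-expression profiles

An experiment is a log2-intensity matrix (features x samples) with a
two-group comparison over an annotated factor. Values are put on the
log2 scale by a simple detector: any negative value, or a maximum at or
below 50, means the data is already logged; otherwise values are floored
at 1.0 and log2-transformed. The threshold reflects that normalized log2
intensities rarely exceed ~20 while linear intensities reach the
thousands; it is deliberately conservative and logged whenever applied.

Probes are aggregated to genes with the inverse-variance fixed-effect
meta-estimate: probe p with variance v_p (estimated across all samples,
floored at 1e-8) contributes weight 1/v_p, giving per-sample gene values
`sum(x_p/v_p)/sum(1/v_p)` and a per-gene variance `1/sum(1/v_p)`. The
same estimator, one shared implementation, later summarizes gene sets
(module meta-scores). Probe variance is pooled across groups rather than
within them — the convention of fixed-effects meta-analysis, where the
weight reflects measurement precision rather than group structure.

Three score representations are supported:

* **log fold-change** — difference of group-mean log2 values (the
  reference representation);
* **p-value** — `sign(logFC) * -log10(p_adj)`; the sign keeps the
  profile directional so correlations remain meaningful;
* **rank** — probes ranked ascending per sample (average ranks for
  ties), averaged per group; a gene scores the median of
  `rank_A(p) - rank_B(q)` over all ordered probe pairs (p, q) of its
  probe set, including p = q. The ordered-cross-pair reading was chosen
  among the plausible readings of "all pairwise combinations"; it keeps
  the single-probe case exact and is invariant to any strictly
  increasing per-sample transform.

Per-gene significance comes from an empirical-Bayes moderated t: the
gene-wise pooled variance s_g^2 (d_g residual df) is shrunk toward a
prior s_0^2 with d_0 prior df,

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),
    t~_g   = diff_g / (s~_g sqrt(1/n_a + 1/n_b)),  df = d0 + d_g.

(d0, s0^2) are estimated by moment-matching log s_g^2 against its
scaled-F sampling distribution (digamma/trigamma matching, Newton
trigamma inverse). Non-positive excess dispersion yields d0 = inf
(complete shrinkage, normal reference); d0 = 0 reproduces the ordinary
pooled-variance t-test, which the tests verify to 1e-10. Features with
d_g = 0 are excluded from the fit and assigned p = 1. Two-sided
p-values are floored at 1e-300 (the log-weights below need p > 0) and
Benjamini-Hochberg adjusted.

Cross-species profiles are renamed to human gene ids through a
Homologene-style map; only one-to-one homologs survive, and a profile
with no surviving feature is excluded from indexing as "failed to map".

## Dimension reduction

A component basis S (components x genes) defines a linear feature
space; a gene profile X projects to `A[c] = sum_g S[c,g] X[g]` over the
genes shared by profile and basis (missing genes contribute zero). The
projection is linear and, for orthonormal S, norm-preserving. Component
p-values are obtained by projecting each sample's expression onto S and
running the moderated t in component space.

The desk-scale basis-derivation routine mirrors a multi-run ICA
pipeline: (1) balance over-represented conditions by collapsing
near-duplicate samples (average-linkage clustering on correlation
distance, cut at 0.05, medoid representatives); (2) FastICA (logcosh,
PCA whitening) run `n_runs = 20` times with distinct seeds, each capped
at 300 iterations — individual runs need not converge because (3) all
estimated components, unit-normalized and sign-oriented so the heavier
loading tail is positive, are pooled and clustered into the requested
number of groups by partitioning around medoids on the distance
`1 - |r|` (sign-flipped duplicates cluster together), the medoids
forming the basis. PAM uses a greedy build followed by Voronoi-style
medoid updates with index-ordered tie-breaks, so results are
deterministic given the seed.

Modules are the discrete counterpart: per component, the genes loading
more than 3 SD above the component mean (positive direction only, per
the sign orientation); constant or empty components are dropped with a
warning. Gene-set meta-scores reuse the fixed-effect estimator over set
members present in the profile.

## Similarity

Profiles are compared on their shared features (at least 100 in gene
space, 10 in reduced spaces) with weighted Pearson or Spearman
correlation. Three weighting schemes:

* unweighted (w_i = 1);
* inverse compendium variance (w_i = 1/Var_i of the feature's score
  across the indexed library, unless an external variance table is
  given);
* p-weighted: `w_i = [-log(p_i1 p_i2)]^(1/C)` from the two profiles'
  FDR-adjusted p-values, natural log, `C = 2` by default. The log base
  only rescales all weights uniformly, and the correlation is invariant
  to uniform weight rescaling, so the choice is immaterial; it is fixed
  for reproducibility.

Centering uses weighted means (the standard weighted-correlation
definition); Spearman computes average-tie ranks first, unweighted, and
then applies the weighted Pearson formula to the ranks. Each feature's
contribution `w_i (x_i - xbar_w)(y_i - ybar_w) / denom` sums exactly to
the signed correlation, and contributions stay signed even in
absolute-value mode so the genes driving a match keep their direction.
Absolute mode (|r|) is the default for heterogeneous library search,
where comparison direction is arbitrary; the retrieval evaluation uses
signed correlation because its compendium shares a fixed case-vs-control
direction.

## Search, significance, network

An index holds a profile library in one common space, with an exclusion
report for profiles that fail mapping or projection. Significance of a
score is empirical: sample `n_pairs = 10,000` random distinct profile
pairs (self-pairs excluded; same-experiment pairs allowed, which only
makes q conservative), score them under the same settings, and set

    q = (#{background >= score} + 1) / (n_pairs + 1).

The add-one smoothing keeps q positive above the background maximum.
When fewer distinct pairs exist than requested, all pairs are used and
the shortfall logged. Queries rank the whole library by score, ties
broken by target id; the similarity network connects pairs with
q below a threshold (0.001 by default), nodes carrying source-experiment
and factor attributes. For small planted-cluster libraries the
background must come from unrelated comparisons (e.g. a null library):
if the background were the clustered library itself, related pairs would
dominate the tail and — with the pair itself among at most ~2000
background pairs — q < 0.001 would be unattainable by the counting rule.

## Retrieval evaluation

Leave-one-out cross-validation: each labeled profile queries the rest;
same-label targets are relevant. Per-query AUC uses the rank
(Mann-Whitney) formulation with half credit for ties; the summary is the
mean and standard error over queries, with curves averaged vertically on
a 101-point false-positive-rate grid (the averaging convention was an
open choice; vertical averaging is the common default). Precision at
k = 4 is compared to a label-permutation null (rankings fixed, labels
shuffled); for equally sized classes of m among n profiles the null mean
is the hypergeometric expectation (m-1)/(n-1), and a query is flagged
significant when its observed precision exceeds the null's 97.5th
percentile. A measure x reduction grid (Pearson/Spearman x weighting
schemes x feature spaces) reports mean AUC ± SE per cell.

## Synthetic compendium

The generator emulates a curated multi-study compendium: `n_conditions`
conditions (diseases), each with `experiments_per_condition` experiments
on distinct simulated platforms; per condition a fixed signed program of
`program_size` genes (disjoint across conditions when the gene pool
allows); case samples shift by `effect_size` (log2 units) times the
program sign. Noise structure: per-sample gene noise (`noise_sd`),
per-experiment gene-wise batch offsets (`batch_sd`), per-platform gene
dropout (`platform_dropout`) and 1-3 probes per gene with probe offsets
(SD 0.3) and probe noise (SD 0.2), so probe aggregation has real work to
do. A `species_mix` fraction of experiments is labeled mouse with a
generated homolog map in which 5% of entries are flagged
non-one-to-one. Values are generated directly on the log2 scale around
a baseline of 7 ± 1.

Defaults are the study conditions: 3 conditions x 8 experiments, 5000
genes, 200-gene programs, effect 1.0, noise SD 1.0, batch SD 0.25, 20%
dropout, 25% mouse, and 10 samples per group — a typical size for
curated disease studies. Two seeds control generation: `seed` drives
experiments, platforms and noise; `program_seed` (defaulting to `seed`)
drives the biology (baseline and programs). Fixing `program_seed` while
varying `seed` simulates new experiments measuring the same underlying
transcriptional programs — exactly the relationship between a reference
compendium used to derive a component basis and the new studies it is
applied to. The ICA fixture generator mixes sparse gene-loading sources
(5% nonzero) linearly at a chosen signal-to-noise ratio.

What the simulation does *not* emulate: array-chemistry artifacts,
intensity-dependent variance, correlated gene modules beyond the planted
programs, heavy-tailed noise, or partially overlapping disease programs.
Retrieval on these data is therefore easier than on real compendia —
the default conditions give near-ceiling AUC — so passing studies
demonstrate correctness of the machinery and calibration of the nulls,
not field performance.

## Study sizes and runtime choices

The bundled studies (shared by the test suite and
`scripts/acceptance.py`) use: 20 replicate seeds for retrieval in gene
and 50-component space (basis derived from a held-out 3 x 2-experiment,
dropout-free compendium with the same `program_seed`); 20 replicate
seeds at effect 0 for the chance-level check; a 50-profile null library
(2000 genes) for q calibration; 20 seeds of a 3 x 20-experiment,
2000-gene planted-cluster library with a 50-profile noise background for
network purity; 10,000 label permutations for the precision-at-4 null;
and 5 seeds of 200 x 1000 source recovery at SNR 10. These sizes keep
each study in the seconds-to-minutes range on one CPU while leaving the
Monte-Carlo error well inside the margins being checked.

## Known limitations

* The moderated-t prior fit assumes a common variance prior across all
  features; strongly heteroscedastic feature classes (e.g. mixed probe
  qualities) are pooled into one (d0, s0^2).
* The balancing step collapses only near-duplicate samples; the full
  condition-normalization of a production compendium pipeline (cluster-
  level resampling) is out of scope.
* Empirical q-values are conservative when the background contains
  genuinely related pairs, and their resolution is 1/(n_pairs + 1).
* Weighted Spearman applies weights after ranking; it is defined for
  completeness but, as the evaluation grid shows, is a weak measure.
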