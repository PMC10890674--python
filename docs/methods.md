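# Methods

## De novo detection model

Read support at a biallelic site is modelled per trio member as a binomial
draw: given genotype g with expected alternate fraction p(g) — ε for RR, ½
for RA, 1 − ε for AA, with ε the per-read error rate (default 0.005) — the
alternate count is Binomial(depth, p(g)). Zero depth contributes likelihood
1. Trio genotype configurations are enumerated exhaustively (3³ = 27). The
prior puts a uniform 1/9 on parental pairs; given the parents, the proband
genotype prior is Mendelian transmission scaled by (1 − μ), with the
residual de novo mass μ (default 10⁻⁴, configurable) split evenly over
transmission-impossible genotypes, so every configuration keeps positive
prior and the posterior is always well defined. A site is called a
candidate when the posterior mass of {parents RR, proband RA or AA} exceeds
the total mass of all Mendelian-consistent configurations (posterior odds
> 1). The proband's class (het/hom) is its maximum-likelihood genotype.

Assumptions: sites are independent, biallelic, autosomal-like (no
sex-chromosome hemizygosity model), read errors are symmetric and
independent, and parental genotypes are a priori exchangeable. A population
allele-frequency prior would sharpen the parental term but adds a parameter
the calibration layer does not need; uniform was chosen deliberately.

## Bayes-factor quality filter

Calibration data are labelled *concordant* (orthogonal chip call agrees
with the exome call) or *discordant* (disagrees), standing in for
true/false positives. Per QC feature, empirical densities are binned over
equal-width bins spanning the pooled observed range (default 20 bins),
stratified by coverage quantile (quartiles of mean trio depth by default)
and by het/hom class, with a Laplace pseudocount of 0.5 per bin before
normalisation — so no bin mass is zero and the log Bayes factor

    log BF = Σ_features log [ p(feature | concordant) / p(feature | discordant) ]

(natural log throughout) is always finite. Cells with calibration data for
only one label fall back first to the coverage-pooled densities of the same
het/hom class, then to the fully pooled densities.

Threshold calibration returns the smallest cutoff t such that the
discordant proportion among calibration sites with log BF ≥ t is at most
the target (default 5%). With tied scores only the first occurrence of each
distinct score is an admissible cut point, since a cut at a tied value
accepts every tie. If no cutoff attains the target the function warns and
returns +∞. The site filter itself retains sites with log BF ≥ 3 *and*
minimum trio depth ≥ 20, both boundaries inclusive for retention; both
thresholds are parameters.

## Network cluster search

The background network is a weighted undirected gene graph supplied as an
edge list; edge weight scores the evidence that two genes share a
phenotype. Building such a network from functional-genomics features is out
of scope — it is an input. Variant-hit genes enter as *events*: an SNV
contributes one gene, a CNV or GWAS locus a gene set, and at most one gene
per event may join a cluster.

The search seeds from every gene of every event and repeatedly adds the
gene (from a yet-unused event) with the largest increment to the cluster
score S = Σ within-cluster edge weights; ties break on the
lexicographically smallest gene symbol for reproducibility. The best set of
each size k ≤ k_max over all seeds is recorded. Greedy growth is not
guaranteed optimal in general; on small, clearly separated planted
instances it matches exhaustive enumeration (tested), and it never exceeds
the exhaustive optimum.

Null distributions replace every event's genes with a random same-sized set
of network genes (structure-matched: same event count, same genes per
event; optional degree-decile-matched sampling), rerun the search, and take
the best size-k score. Significance uses the add-one empirical rule
p_raw = (1 + #{S₀ ≥ S}) / (1 + n_perm) and z = (S − mean S₀)/sd S₀ (z = 0
when sd = 0). Raw p-values across the k_max − 1 tested sizes are
Bonferroni-adjusted; the reported size minimises p_adj with ties broken by
maximal z, then smaller k. For reporting, an expansion step keeps cluster
genes carrying listed annotations (e.g. microtubule-based process, actin
cytoskeleton, synaptic transmission) and adds their direct interactors from
a physical-interaction edge list.

## Enrichment statistics

The annotation chart tests every term with non-zero overlap against a
user-supplied background universe. The upper hypergeometric tail
P(X ≥ k) is computed exactly with integer combinatorics (one rounding at
the final division), so even extreme tails carry no summation error. The
default statistic is the EASE score — the tail with the observed overlap
reduced to k − 1 (k ≤ 1 gives p = 1) — mirroring the DAVID chart the
original analysis used; the plain Fisher tail is available. Adjustment
defaults to Benjamini–Hochberg ("P_adj" in the published tables does not
name a procedure; BH is the field default). Composition questions (is a GO
category over-contributed by GWAS-tagged genes?) are one-sided Fisher exact
tests on the 2×2 category × tag table. Venn utilities return the full
region partition of named gene lists plus each list's hypergeometric
overlap significance against a reference set. GMT collections are consumed
as flat gene sets; no ontology-graph propagation is performed.

## PolyPhen-2 triage and cohort tables

PolyPhen-2 is consumed as scores only. The triage thresholds — probably
damaging for score > 0.94, possibly damaging for 0.446 < score ≤ 0.94,
benign otherwise — are the tightest cut points consistent with the
published score/label pairs (0.929 → possibly vs 0.947 → probably;
0.414 → benign vs 0.478 → possibly). Neither the standard HumDiv
(0.957/0.453) nor HumVar (0.909/0.447) cutoffs reproduce all 88 published
labels; both thresholds are configurable.

Chromosome-distribution percentages use a denominator of 23 (22 autosomes +
X, Y excluded), which the published arithmetic implies (18/23 = 78%).
Rounding is half away from zero to integer percent, matching every
published cell; the "any" row is rounded from the unrounded sum, so rounded
components may differ from the rounded total by one point (39 + 17 + 4 = 60
vs a printed 61 is a rounding artefact, not an error). The validated list
carries no patient identifiers, so per-patient percentages are computed
from the published per-cohort patient tallies rather than from records.

## Synthetic data

Generators emulate, with known ground truth: trio read counts (Poisson
depths, default mean 60; binomial alternate counts; de novo heterozygotes
planted at rate 10⁻³ per site; other sites drawn from Hardy-Weinberg at
alternate frequency 0.1); labelled calibration features (two-Gaussian
classes per feature, defaults separated by 4 and 2 standard deviations;
Poisson coverage; 80% het); labelled log-BF scores directly from the
stylised mixture true ~ N(4,1) vs false ~ N(0,1); background networks
(Erdős–Rényi edges at p = 0.05 over 200 genes with Exponential(1) weights);
events (48 single-gene + 12 four-gene); and annotation collections (50
terms of 10–100 genes over a 1000-gene universe, one term over-represented
5× in a 40-gene companion list).

A single root seed is split into fixed named substreams, one per generator,
so outputs are byte-identical across reruns and independent across
generators. Planted network modules are cliques whose edge weights are
background draws multiplied by the configured factor (default 3); a factor
of 1 is the identity perturbation — nothing is planted and the truth set is
empty — because an unscaled clique would still be detectable against a
sparse background and could not serve as a null.

What the generators do **not** emulate: real exome coordinates and
target-capture coverage structure, mapping artefacts and strand bias,
linkage between sites, mutation spectra, population structure, or the
topology of real phenotypic-likelihood networks. Passing tests therefore
demonstrate correctness of the algorithms under the stated models, not
performance on real sequencing data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: 10,000 labelled scores for threshold calibration (held-out
false-positive proportion compared with the 5% target within binomial 99%
confidence limits), a few hundred to a thousand trio sites for
detection-vs-oracle checks, 200-gene networks with 200 permutations for
module recovery, and 200 replicates for permutation-p uniformity
(Kolmogorov–Smirnov at α = 0.01). Exhaustive search oracles are limited to
≤ 12-node instances. Degenerate inputs are handled explicitly: zero depth
(likelihood 1), empty event lists (empty result), all-zero networks
(p = 1, z = 0), single-label calibration data (error), out-of-range scores
(error with line numbers on parse).

## Known limitations

- The de novo caller is diploid-biallelic throughout; X-linked variants in
  male probands are treated as diploid, as the published variant table
  prints them.
- The greedy search offers no optimality guarantee at realistic scales;
  permutation significance, not the score itself, carries the inference.
- The published 559-gene (p = 0.012) and 572-gene (p = 0.0028) networks
  depend on a proprietary background network and gene universe that are not
  distributed, so they cannot be reproduced here; the search is validated
  on planted ground truth instead.
- EASE/Fisher charts treat terms independently; no term-redundancy
  clustering or GO-graph propagation is attempted.
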