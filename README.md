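# trionet

Trio-based de novo mutation filtering and gene-network analysis for
schizophrenia cohort studies.

Whole-exome sequencing of patient–mother–father trios identifies candidate
de novo mutations, but raw caller output is dominated by artefacts. This
package implements the analysis stack of a three-cohort schizophrenia trio
study (75 Algerian, 45 French and 61 Japanese families, 88 Sanger-validated
de novo mutations):

1. **De novo candidate detection** (`trionet.trio_denovo`) — per-site
   genotype likelihoods under a binomial read-sampling model. With genotypes
   g ∈ {RR, RA, AA} and expected alternate-read fractions (ε, ½, 1−ε), a
   site is a candidate when the posterior mass of the de novo configuration
   (parents RR, proband RA/AA) exceeds that of every Mendelian-consistent
   trio configuration, enumerated over all 27 genotype combinations.
2. **Empirically calibrated Bayes-factor filter** — a naive-Bayes classifier
   over site QC features, trained on *concordant* vs *discordant* calls
   (sites where genotyping-chip and exome calls agree/disagree), stratified
   by mean coverage and het/hom status:
   log BF = Σ_f log [ p(f | concordant) / p(f | discordant) ].
   The acceptance cutoff is calibrated so accepted sites contain ~5% false
   positives; the published filter (log BF ≥ 3, trio depth ≥ 20) is the
   default.
3. **Network cluster search** (`trionet.network_search`) — NETBAG-style
   greedy search over a gene–gene phenotypic-likelihood network: starting
   from every variant-hit gene, grow the cluster by the gene (≤ 1 per
   SNV/CNV/GWAS event) maximising the weighted sum of within-cluster edges;
   significance by structure-matched random-gene permutations, with
   Bonferroni adjustment across cluster sizes and empirical
   z = (S − mean S₀)/sd S₀.
4. **Enrichment statistics** (`trionet.enrichment`) — DAVID-style annotation
   charts (exact hypergeometric tail or the EASE variant with the overlap
   jackknifed to k−1), Benjamini–Hochberg adjustment, one-sided Fisher
   composition tests, and Venn-overlap significance.
5. **Cohort summary tables** (`trionet.cohort_tables`) — the packaged
   88-variant validated list with PolyPhen-2 triage
   (probably damaging > 0.94 ≥ possibly damaging > 0.446 ≥ benign) and the
   per-cohort mutation/chromosome/patient distributions.
6. **Synthetic data** (`trionet.simulate`) — seeded generators for every
   input (trio reads with planted de novo events, labelled calibration
   features, networks with planted modules, events, annotation sets), so the
   whole pipeline is testable without any external download.

## Worked example

Reproduce the cohort summary tables from the packaged validated-variant
list:

```sh
$ trionet tables --out-dir out/
Validated de novo mutations: 88
Per cohort: Algerian=35, French=21, Japanese=32
Chromosomes hit: Algerian=18, French=14, Japanese=16, union=22
```

The 88 validated mutations split 35/21/32 across the Algerian, French and
Japanese cohorts and fall on 22 distinct chromosomes (18/14/16 per cohort —
the union is smaller than the sum because cohorts share hit chromosomes).
`out/` contains the four summary tables as TSV; `table_pp2.tsv` shows the
PolyPhen-2 triage — 48 probably damaging, 19 possibly damaging, 21 benign.

Simulate a full synthetic study and search for a mutated gene module:

```sh
$ trionet simulate --seed 2 --out-dir sim/
$ trionet netsearch --events sim/events.tsv --network sim/network.tsv \
      --k-max 14 --n-perm 200 --seed 2 --out-prefix sim/search
best cluster: k=14 score=217.330 z=7.58 p_raw=0.004975 p_adj=0.06468
```

The generator planted a fully connected 12-gene module with 3× boosted edge
weights; the reported cluster (score 217.3, the weighted sum of its edges)
recovers all 12 planted genes, scores 7.6 standard deviations above the
permutation null, and attains the smallest permutation p-value the 200
permutations allow (1/201 ≈ 0.005; p_adj is Bonferroni across the 13 tested
cluster sizes).

As a library:

```python
from trionet import detect_candidates, BayesFactorModel, calibrate_threshold
from trionet.simulate import SimulationConfig, simulate_trio_reads

sites, truth = simulate_trio_reads(SimulationConfig(seed=1, n_sites=1000,
                                                    denovo_rate=0.01))
candidates = detect_candidates(sites, error_rate=0.005, denovo_prior=1e-4)
```

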