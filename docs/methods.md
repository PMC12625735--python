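# Methods

## The analysis

### Feature screening

Microbial genus counts are compositional: only relative information survives
sequencing.  We therefore apply the centred log-ratio transform per sample,
`clr(x) = ln(x + c) − mean_features ln(x + c)` with pseudocount `c = 0.5` by
default (configurable; `c = 0` is allowed when all counts are positive).
Every CLR column sums to zero by construction.

Two screens are available:

- **Two-way ANOVA (diet × segment)** on CLR values of genera measured in both
  compartments, with type-II sums of squares computed by model comparison
  (each main effect against the additive model, the interaction against the
  full model).  Type II tolerates mild unbalance and coincides with the other
  SS types on the balanced designs this package targets.  The interaction
  term is the screen for taxa whose diet response differs between segments;
  interaction p-values are BH-adjusted across taxa at FDR 5%.  Features with
  zero residual variance get missing p-values, never 0 or 1.
- **Two-group (HFD vs NC) tests** per layer: Mann–Whitney by default (omics
  scales are heavy-tailed; ranks are robust), Welch's t optional.  Each
  feature gets a log2 fold change (pseudocount-protected for counts; for
  CLR-scale inputs the mean difference divided by ln 2), a direction sign
  (sign of the mean difference), BH q, and a pass flag.  These signs feed the
  network's coherence filter.

Descriptive statistics: Shannon diversity H = −Σ p ln p per sample, and a
compartment-specific genus screen (present in ≥ 50% of one compartment's
samples and absent from the other's — both thresholds configurable; the rule
is a declared choice).

### Network construction

For every unordered feature pair (within and across layers; pairs between the
two microbial compartments are excluded by default, since the compartments
are compared as parallel networks against the host — a flag includes them),
Spearman correlations and p-values (t approximation; exact ±1 handled) are
computed separately inside each diet group.  Requiring an association to hold
in *both* conditions is the meta-analytic core: the two p-values are combined
with Fisher's method, X = −2 Σ ln pᵢ ~ χ²(2k), BH-adjusted jointly across all
candidate pairs, and an edge is retained iff

1. sign(r_NC) = sign(r_HFD) ≠ 0,
2. BH q of the combined p < FDR (default 0.05), and
3. sign(r) = sign(lfc_a) · sign(lfc_b) (coherence; optional but on by default).

The **PUC** — the proportion of edges passing (1)+(2) that violate (3) — is
always reported; under a causally coherent data-generating process it should
be near zero.  Nodes are tagged with layer, compartment, fold change and
differential q; screened features left without edges are dropped from the
graph but reported.  Edge retention is monotone in the FDR threshold.

Correlation p-values of exactly 0 (perfect monotone pairs at small n) are
clamped to the smallest positive float before taking logs.  Pairs with a
constant feature within a group are skipped and counted.

### Topology comparison

All statistics run on the full multi-layer network: a microbe may reach the
transcriptome through a metabolite, matching the information-flow reading of
the graph.

- **Retention**: 2×2 χ² (retained/dropped × compartment), no Yates correction
  by default (flag available).
- **Bipartite edge count** between a compartment and a host layer.
- **Degree / power law**: the discrete-MLE approximation
  α̂ = 1 + n / Σ ln(kᵢ/(k_min − ½)) plus a log–log OLS R² on the degree
  histogram, both descriptive.  The shifted-continuous approximation behind
  α̂ is accurate for k_min ≳ 4–6; at the default k_min = 1 it is reported as
  a qualitative diagnostic only, and the estimator-validation experiment fits
  at k_min = 4.  No bootstrap goodness-of-fit is attempted.
- **BIBC**: for disjoint node sets S₁, S₂,
  BIBC(v) = Σ_{s∈S₁, t∈S₂, s≠v≠t} σ_st(v)/σ_st, computed by Brandes-style
  BFS + dependency accumulation with sources restricted to S₁ and target
  credit restricted to S₂; unweighted edges; unreachable pairs contribute 0.
  Endpoints do not score for their own pairs but may score as interior nodes
  of other pairs.  Exact identity used as a self-check:
  Σ_v BIBC(v) = Σ_{reachable pairs} (d(s,t) − 1).
  Hub extraction takes the top ⌈fraction·n⌉ microbes by score (20% default),
  ties broken deterministically by feature id, and reports each compartment's
  share of that top set.
- **Set-to-set closeness**: BFS length for every (s, t) pair between two node
  sets; unreachable pairs are excluded from the distribution and counted
  (including ∞ would poison the mean).  Compartments are compared per host
  layer with a two-sided Wilcoxon rank-sum test (exact enumeration when both
  samples ≤ 8 — scipy's exact method enumerates through ties — otherwise the
  tie-corrected normal approximation).

### Dense subnetworks and enrichment

Louvain modularity optimisation (seeded; Louvain is order-sensitive) on the
layer-induced subgraph, communities below 10 members discarded, survivors
ranked by internal density 2e/(n(n−1)), top k returned.  The detection
algorithm is pluggable (any partition can be supplied).  Compartment-to-module
closeness reuses the set-to-set machinery over the full network.

Module members are tested for over-representation in caller-supplied GMT gene
sets with the hypergeometric upper tail P[X ≥ overlap], BH across sets.  The
universe defaults to the genes that entered network construction — the
defensible background for network-derived hit lists — not the genome.

## The synthetic-data generator

The generator emulates a two-diet (n = 12 per group), two-compartment mouse
study with liver transcriptome, serum and liver metabolomes and continuous
metabolic phenotypes.  It is a single-factor-per-feature latent Gaussian
model:

- Each sample draws `n_factors` (default 4) independent N(0,1) latent factors
  — shared physiology axes.  Every feature is assigned one factor uniformly
  at random.
- Host features load with fixed magnitude 0.8; compartment-A microbes with
  `loading_A` (default 0.8); compartment-B microbes with `loading_B` (default
  0.3).  Both compartments couple to the *same* factors, so
  `loading_A = loading_B` makes them exactly exchangeable and `loading_B = 0`
  decouples B entirely.  Two features sharing a factor are correlated with
  sign equal to the product of their loading signs; all microbe–host pairs
  sharing a factor are recorded as planted "coupled pairs".
- Loading signs alternate within each factor group rather than being drawn
  at random: the compositional closure (softmax normalisation plus CLR
  centring) subtracts the per-sample mean latent, and with unbalanced random
  signs that mean carries a seed-dependent share of the factor signal,
  attenuating or cancelling planted couplings and diet shifts.
- Diet effects are standardised: each feature shifts by
  `diet_effect_sd × its latent SD` (default 2.0 — a strong intervention, as a
  60% fat diet is), with per-factor signs chosen so that
  sign(effect_a)·sign(effect_b) equals the planted correlation sign for every
  coupled pair; PUC on truth is therefore ≈ 0.  With `diet_effect_sd = 0` the
  diet term is exactly null and its ANOVA p-values are uniform.
  Standardisation matters: unstandardised shifts give the strongly coupled
  compartment systematically lower screen power (its latent variance is
  higher), an artifact unrelated to the planted asymmetry.
- Microbial latents are softmax-normalised per sample and counts drawn
  multinomially at `sequencing_depth` (default 10 000), so every microbial
  sample column sums exactly to the depth.  Genes and metabolites are
  log-normal; phenotypes are linear in the latents.  Baseline spreads
  (SD 1.5 on the log scale) give realistic abundance heterogeneity, including
  rare taxa with zero counts.
- A configurable subset of genera (`n_shared_microbes`, default one third of
  the smaller compartment) is measured in both compartments under the same
  genus id — this is what makes the diet×segment ANOVA and the
  compartment-specific genus screen exercisable; the remaining genera are
  resident in one compartment only, so the presence screen has true
  positives.
- Residual latent noise `noise_sd` defaults to 0.4.  At that value the
  planted microbe–host correlations are ≈ 0.80 for compartment A and ≈ 0.54
  for B at the default loadings, so the weaker compartment still retains
  roughly three quarters of its microbes in the network — a regime resembling
  a real study where both segments form sizeable networks — while the
  asymmetry in retention, edge counts and closeness is decisive.

What the generator does **not** emulate: overdispersion beyond multinomial
sampling (no Dirichlet stage — `noise_sd` on the latents substitutes),
phylogenetic correlation among taxa, multi-factor loadings per feature,
longitudinal sampling, or realistic 16S read-level artifacts.  Passing tests
therefore demonstrate correctness of the analysis machinery and its behaviour
under a known factor-structured truth, not performance on real sequencing
data.

## Numerical and design choices

- Single RNG stream per `generate_dataset` call, consumed in a fixed order
  (factors → per-layer parameters and noise → count draws), so output is
  bit-reproducible across platforms.
- Spearman ties use average ranks (consequential under microbial
  zero-inflation); correlation p-values use the t approximation, which is
  what keeps the within-group screen feasible at thousands of pairs.
- BH is applied within each test family (per-layer differential; all
  candidate edges jointly; gene sets); NaN p-values are excluded from the
  family size and stay NaN.
- Louvain and every simulation consume seeds derived from a single
  config-level seed.
- Degenerate inputs: all-zero microbial samples are a validation error for
  Shannon; constant features get missing p-values and zero signs; zero-margin
  retention tables yield missing χ² with a warning; empty closeness
  distributions yield a missing mean and are never compared.

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

- BIBC equals exhaustive all-shortest-path enumeration on 100 random graphs
  (n ≤ 30) to 1e-9, and the total-score identity holds exactly.
- Fisher's combination of (0.05, 0.05) matches direct numerical integration
  of the χ²(4) density; the exact Wilcoxon p for {1,2} vs {3,4} is 1/3; CLR
  columns sum to zero on fuzzed tables; Shannon of four equal counts is ln 4.
- Under independently permuted samples (global null, 200 features, 12+12,
  10 permutations) the retained-edge fraction at FDR 5% averages ≲ 10⁻⁴;
  under a purely additive two-factor truth the interaction discovery rate
  stays below 7%.
- Planted asymmetry (0.8 vs 0.3, 20 seeds): compartment A wins retention,
  gene-edge count and gene closeness in ≥ 90% of seeds.  Exchangeability
  control (equal loadings, 40 seeds): six win rates (3 metrics × 2
  compartments) are checked against the Bonferroni-adjusted two-sided 95%
  binomial band around 0.5 (≤ 28/40 wins each); the adjustment is required
  because six simultaneous unadjusted bands reject far too often under the
  exchangeable null.
- Two planted gene modules (two factors, equal loadings) are recovered with
  per-module Jaccard ≥ 0.9 in ≥ 9/10 seeds; reported densities equal
  2e/(n(n−1)) exactly.
- The power-law MLE recovers α = 2.5 within [2.3, 2.7] from 5000 exact
  discrete power-law degrees (fit at k_min = 4, see above).
- PUC on default generator output is ≤ 0.05.

Problem sizes (30+30 microbes, 40 genes, 20+20 metabolites, 8 phenotypes,
12 samples per group) are the generator's defaults and keep the whole
validation suite under a minute on one CPU; they scale the study design
(tens of genera per segment, thousands of genes) down to desk scale while
preserving every qualitative regime the comparisons rely on.

## Known limitations

- The meta-analytic sign-consistency rule discards associations specific to
  one diet condition by design; context-dependent edges are invisible.
- Average shortest-path closeness conditions on retention: a compartment that
  retains only its best-connected microbes can look spuriously close.  The
  exchangeability control quantifies this; interpret closeness jointly with
  retention and edge counts.
- The power-law report is descriptive; no likelihood-ratio comparison against
  alternatives is attempted.
- Louvain is a heuristic; with the fixed seed results are reproducible but
  not guaranteed optimal, and the density ranking depends on the partition it
  returns.
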