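# tknet — transkingdom network analysis of paired-compartment multi-omics

`tknet` asks a question microbiome researchers face whenever they choose a
sampling site: **which gut compartment's microbiota is more tightly linked to
host physiology?**  Given microbial count tables from two intestinal segments
(e.g. ileum and colon), host omic layers (liver transcriptome, serum/liver
metabolome, metabolic phenotypes) and a two-group design (normal chow vs
high-fat diet), it

1. screens features (CLR normalisation of compositional counts, two-way
   diet×segment ANOVA, per-layer two-group tests with BH-FDR),
2. builds a **transkingdom correlation network**: Spearman correlations
   computed separately within each diet group, combined by Fisher's method
   (−2 Σ ln pᵢ ~ χ²₂ₖ), and retained only when the sign is consistent across
   groups, the BH-adjusted combined p clears the FDR threshold, and the sign
   is coherent with the product of the endpoints' fold-change directions
   (the fraction of incoherent significant edges is reported as **PUC**), and
3. compares the two compartments' network topology: retention χ², bipartite
   edge counts, degree/power-law diagnostics, **bipartite betweenness
   centrality** BIBC(v) = Σ_{s∈S₁,t∈S₂} σ_st(v)/σ_st, set-to-set shortest-path
   closeness with Wilcoxon rank-sum comparison, and Louvain-detected dense
   gene subnetworks with hypergeometric over-representation analysis of their
   members.

Because real deposited study data are never needed for development or testing,
the package ships a synthetic-data generator with planted ground truth: a
latent Gaussian factor model in which one compartment's microbes couple to the
host layers more strongly than the other's, microbial counts are drawn
multinomially at fixed sequencing depth, and diet-effect signs are assigned so
that true edges are fold-change coherent.  Every downstream claim is testable
against this planted truth.

## Worked example

```python
from tknet import SimulationConfig, generate_dataset, TranskingdomModel

dataset, truth = generate_dataset(SimulationConfig(seed=1))
results = TranskingdomModel.from_dataset(dataset, seed=1).fit()
print(results.summary())
```

```
Transkingdom Network Analysis Results
========================================================================
Nodes: 139   Edges: 1481   Candidates: 9744   PUC: 0.0054
------------------------------------------------------------------------
Retention (features with >=1 edge / screened features):
  compartment A: 29/29 = 1.000
  compartment B: 22/29 = 0.759
  chi2 = 7.961, p = 0.00478
------------------------------------------------------------------------
             edges_A  edges_B  avg_path_A  avg_path_B  wilcoxon_p closer
host_layer
genes            231       64       1.798       2.621    1.44e-20      A
metab_liver      116       37       1.701       2.423   5.283e-09      A
metab_serum      100       19       2.067       2.924   3.208e-12      A
phenotypes        47       12       1.679       2.426   4.334e-05      A
------------------------------------------------------------------------
Top-20% BIBC vs genes: A: 0.64, B: 0.36
------------------------------------------------------------------------
Subnetwork 1: n=14, density=0.978
  distance from A: 1.171
  distance from B: 1.714
Subnetwork 2: n=11, density=0.636
  distance from A: 1.390
  distance from B: 1.682
========================================================================
```

Reading the table: this synthetic study planted compartment A's coupling at
0.8 and B's at 0.3.  The fit recovers exactly that asymmetry — A keeps all 29
screened microbes in the network (B keeps 22/29, χ² p ≈ 0.005), has 3–5× more
direct edges to every host layer, sits roughly one shortest-path hop closer to
the liver transcriptome (1.80 vs 2.62, Wilcoxon p ≈ 10⁻²⁰), dominates the
top-20% BIBC bottleneck set, and is closer to both dense gene modules.  PUC ≈
0.005 confirms that almost all retained edges are fold-change coherent, as the
generator plants them.

The same analysis runs from TSV files on disk
(`TranskingdomModel.from_directory("data/")`) or from the command line:

```bash
tknet simulate --out data/ --seed 1
tknet compare --data data/            # prints the summary above
tknet run --config pipeline.yaml      # full pipeline with artifacts on disk
```

Other subcommands: `diff`, `network`, `topology`, `subnet`, `enrich` (see
`tknet --help`).

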