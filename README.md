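# altigut

Analysis pipeline for gut-microbiome variation along an altitudinal
gradient. Given taxon/function abundance tables and per-sample
altitudes (1,400–4,400 m), the package computes:

- **Alpha diversity** per sample — observed species *S*, Shannon
  *H* = −Σ pᵢ ln pᵢ, Pielou evenness *J* = *H*/ln *S* — plus the
  Bacillota/Bacteroidota (B/B) ratio and TPM-normalised CAZyme class
  totals.
- **Gradient trend models** against altitude: simple linear regression,
  continuous piecewise-linear regression with breakpoints ψ estimated
  by exhaustive grid search, natural cubic regression splines with the
  knot count selected by generalised cross-validation
  (GCV = n·RSS/(n − tr **H**)²), and cubic polynomial fits.
- **Altitude screens**: per-feature Spearman ρ with Benjamini–Hochberg
  adjusted p-values at every taxonomic level.
- **Signed co-occurrence networks** per altitude stratum (six strata,
  1,400–1,800 m … above 3,400 m): edges are taxon pairs with
  |ρ| > 0.60 and BH-adjusted P < 0.01 within the stratum, summarised by
  node/edge counts, average degree 2E/N, seeded Louvain modularity, and
  the percentage of positive edges.
- **Attack-tolerance robustness**: the proportion of nodes remaining
  after randomly removing 50% of a network's nodes and applying
  secondary extinction (surviving nodes left without any edge are also
  removed), replicated 100×, compared across strata with Welch's ANOVA
  and Games–Howell post hoc tests.

A fully seeded synthetic-data generator produces surveys with the
gradient structure this analysis targets — a mid-altitude diversity
peak, monotone altitude responders, and per-stratum correlation blocks
densest at 2,200–2,600 m — so the whole pipeline is testable without
any external data.

Intended users: microbial ecologists analysing field metagenome surveys
along environmental gradients, starting from merged abundance tables
(e.g. Kraken2/Bracken output) rather than raw reads.

## Worked example

Run the full pipeline on a synthetic survey (121 samples, 300 species):

```sh
altigut run --out demo_run
# pipeline complete: 6 networks, 15 pairwise tests, 47 files in demo_run
```

The per-stratum network topology (`demo_run/networks/topology.tsv`):

```
   stratum  n_nodes  n_edges  avg_degree  modularity  pct_positive
S1400_1800       18        9       1.000       0.889        66.667
S1800_2200       10        5       1.000       0.800        40.000
S2200_2600       48      241      10.042       0.651        55.187
S2600_3000       12        6       1.000       0.833        83.333
S3000_3400       14        7       1.000       0.857        57.143
S3400_plus      121      118       1.950       0.834        95.763
```

The mid-altitude stratum (2,200–2,600 m) carries the densest network —
48 nodes, 241 edges, average degree 10.0 versus ≈1–2 elsewhere —
reflecting the planted correlation blocks. Mean robustness under 50%
random node removal peaks there too (0.465 vs 0.22–0.33 in the other
strata), and the omnibus Welch ANOVA across strata is decisive
(F = 497.2, df = 5, 253.2, p ≈ 1e−128; all 15 Games–Howell pairs
reported in `demo_run/robustness/group_tests.json`).

The GCV-selected spline for Shannon diversity versus altitude
(`demo_run/trends/shannon.json`) explains R² = 0.716 (p ≈ 8e−32) with 4
knots, and its fitted curve peaks near the planted 2,400 m diversity
maximum.

Every stage is also available as a library function
(`altigut.fit_piecewise`, `altigut.build_network`,
`altigut.robustness_distribution`, …) and as individual subcommands
(`altigut simulate | diversity | trends | screen | network |
robustness`).

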