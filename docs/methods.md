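# Methods

## Altitude binning

Altitudes are binned into 26 bands of 100 m starting at 1,400 m, the
last band open-ended above 3,900 m, and into six strata of 400 m
starting at 1,400 m, the last open-ended above 3,400 m. Both binnings
use half-open intervals [low, high) so that assignment is a total,
deterministic function on [1,400 m, ∞); each closed band lies inside
exactly one stratum. The band axis 1–26 is treated as an equally
spaced ordinal variable when modelling per-band capture counts.
NDVI rasters are consumed as stored integers and converted with the
archive scale factor 0.0001; values outside [−1, 1] are kept with a
warning rather than rejected, since they indicate an upstream problem
the analyst should see.

## Diversity metrics

Observed species is the count of strictly positive entries per sample;
Shannon diversity uses the natural logarithm; Pielou evenness is
J = H/ln S and is reported as NaN (not an error) for S ≤ 1. Natural
logs are used throughout for consistency with the logₑ(TPM) scale of
the CAZyme totals. The B/B ratio is the per-sample ratio of Bacillota
to Bacteroidota relative abundance; it is scale-invariant, and a zero
Bacteroidota abundance flags the sample as undefined. TPM divides each
count by its feature length in bp and rescales the column to 10⁶.
logₑ of a CAZyme class total applies a pseudocount of 1 only when the
total is exactly zero, leaving all positive totals untouched; affected
cells are flagged.

## Trend models

*Linear*: OLS with the two-sided slope t-test.

*Piecewise linear*: continuous broken-line model with k ∈ {1, 2}
breakpoints ψ. ψ is estimated by exhaustive grid search minimising
RSS, with grid step min(25 m, range/200), ψ restricted to the central
80% of the x-range, and ψ₂ − ψ₁ ≥ 10% of the range for k = 2. The grid
search is deterministic and has no starting-value sensitivity; the
batched normal equations are solved in standardised coordinates with a
negligible (1e−10·n) ridge so that candidates with no data beyond ψ
remain solvable. Significance is an F-test against the plain linear
fit with 2k extra degrees of freedom. The breakpoint count is chosen
by BIC (2 + 2k mean parameters plus a variance), accepting each extra
breakpoint only when it improves BIC by more than 2.

*Spline*: natural cubic regression splines with K knots at equally
spaced x-quantiles, K selected from candidates 3–10 by
GCV = n·RSS/(n − tr **H**)², where tr **H** equals the basis rank for an
unpenalised least-squares fit. The reported `edf` excludes the
intercept (the smooth term's degrees of freedom, the convention used
by GAM software), so linear data fitted with the smallest basis report
edf = 2. The p-value is an approximate F-test against the
intercept-only model; a full penalised GAM with smoothing-parameter
estimation is deliberately out of scope — knot-count selection by GCV
is the procedure being reproduced.

*Cubic*: degree-3 polynomial OLS on a standardised basis solved via QR,
with an F-test against the intercept-only model.

Curve maxima (e.g. the altitude of peak diversity) are read from the
fitted curve on a 2,001-point grid over the observed x-range.

## Screens and multiple testing

Per-feature Spearman ρ against per-sample altitude (not band
midpoints), average ranks for ties, two-sided p from the t
approximation. Benjamini–Hochberg adjustment is applied across all
testable features of one screen; constant features are excluded from
the family and flagged. Direction is classified at raw P < 0.05 —
mirroring how single-taxon altitude associations are conventionally
reported — while the BH-adjusted p-value is reported alongside for
stricter use.

## Co-occurrence networks

Within each stratum, all pairwise Spearman correlations among features
(on relative abundances; ranks make per-sample scaling otherwise
irrelevant only when depths are equal). Zero-variance features are
dropped first and logged. The BH family is all tested pairs within the
stratum, matching per-stratum network construction. Edges require
|ρ| > 0.60 and adjusted P < 0.01; nodes are features with at least one
kept edge. Modularity uses absolute edge weights and seeded Louvain
community detection — any modularity-maximising heuristic would do;
determinism comes from the fixed seed. No prevalence filter is applied
by default (thresholds and filters are configurable).

## Robustness

One replicate removes ⌊fraction·N⌋ nodes uniformly at random
(deterministic count for odd N), then applies secondary extinction:
any surviving node with zero remaining edges is removed. Because
deleting an isolated node frees no edges, the cascade terminates after
a single pass over the induced subgraph; the implementation exploits
this. Robustness is the remaining proportion of the original N. The
degree-zero extinction rule is the minimal interpretation under which
the statistic varies at all — without it every replicate would equal
the survivor fraction exactly; abundance-weighted extinction variants
are out of scope. Distributions use 100 seeded replicates per network
by default.

Strata are compared with Welch's heteroscedastic ANOVA
(Welch–Satterthwaite df) and Games–Howell post hoc tests, whose
p-values come from the studentized-range distribution at q = |t|·√2
(scipy's implementation, accurate well beyond 1e−6); no further
multiplicity correction is applied because the range distribution
already provides family-wise control. Strata whose robustness
replicates are degenerate (zero variance, e.g. a single detected
feature pair) are excluded from the group tests with a warning. The
robustness–altitude curve is a cubic polynomial fitted to all
replicate points with stratum midpoints as x (3,900 m represents the
open top stratum).

## Synthetic data generator

The generator emulates a trapping survey of 121 gut metagenomes along
a 1,400–4,400 m transect, with counts from a lognormal–multinomial
model (per-sample log-abundances exponentiated, closed to proportions,
and multinomially sampled at a fixed depth of 10⁵, reproducing
compositional closure and overdispersion). Altitudes use
stratified-uniform placement — one uniform draw per equal-width slot —
giving even transect coverage with a uniform marginal, as a designed
field survey would.

Planted structure, all reproducible from one seed:

- **Monotone responders** — 20 taxa increasing and 20 decreasing with
  altitude at 1.5 log-units per km (the default screen effect size),
  centred on the diversity-peak altitude so responders stay within a
  realistic abundance envelope at both range ends. Centring matters:
  uncentred trends let responders dominate one end of the gradient,
  which both depresses Shannon diversity asymmetrically and induces
  shared-dilution correlations among all other taxa.
- **Diversity bump** — 80 extra taxa present in a sample with
  probability exp(−(alt − 2,400)²/(2·500²)) (independent Bernoulli
  occupancy). The expected richness follows a Gaussian bump centred at
  2,400 m; independent occupancy keeps bump taxa uncorrelated with one
  another within a stratum, so they do not contaminate the stratum
  networks.
- **Correlation blocks** — disjoint background taxa per stratum share
  one Gaussian factor per block, with signed loadings jittered in
  [0.8, 1] and a loading scale targeting within-block correlation 0.95
  on the log scale. Block members sit at a fixed rare baseline with
  halved dispersion so the factor, not abundance noise, drives their
  ranks. The mid stratum (2,200–2,600 m) holds three large blocks
  (16, 14, 12 taxa) whose detected subnetwork is dense and cohesive;
  all other strata hold only dyads (5–7 pairs), whose detected
  subnetworks are sparse and fragile. This block-size profile is what
  plants the mid-altitude peak in network density and robustness: a
  node's survival under random removal depends on its degree, so
  dyad-dominated networks lose nodes to secondary extinction while the
  dense mid-stratum blocks do not.
- **Functional table** — 150 CAZyme-family features with lengths
  drawn from 300–3,000 bp and 15 planted responders per direction.
- **NDVI** — a three-phase piecewise-linear profile (decline, rise,
  decline) with breakpoints at 2,300 and 3,000 m plus Gaussian noise.

What the generator does **not** emulate: sequencing or taxonomic
assignment error, host-read contamination, uneven sequencing depth,
spatial autocorrelation between neighbouring quadrats, and uneven
sampling effort across altitude. Passing tests therefore demonstrate
that the pipeline recovers the targeted statistical structure from
compositional count data at realistic sample sizes — not that it is
robust to annotation artefacts or depth confounding in real surveys.

With all planted effects disabled (monotone effect 0, block loading 0,
bump amplitude 0) the generator is an exact null for the altitude
screen: every taxon is independent of altitude, so the raw-P flag rate
calibrates to 5%. The bump must be disabled for this null because
occupancy tied to altitude is a genuine (non-monotone) altitude
association, not a false positive.

## Problem sizes and numerical choices

Simulation-based checks use 100 seeds/datasets (200 for the screen and
network nulls), chosen to make recovery rates stable at the percent
level while the full suite and the acceptance script each run in about
one to two minutes. Spearman p-values use the t approximation
everywhere (adequate for n ≥ 10; exactness for tiny n is not needed at
the sample sizes modelled). BH adjustment clips p-values at the
smallest positive float before adjustment so that perfect correlations
(p = 0) remain valid inputs. Ties in ranks use average ranks. The
spline basis is evaluated in standardised x to keep cubic terms well
conditioned; ill-conditioned knot candidates are skipped, and an error
suggests fewer knots if none remain.

## Known limitations

- Spearman co-occurrence on relative abundances ignores compositional
  bias (no SparCC-style correction) — intentional, as plain Spearman
  is the procedure being reproduced.
- The spline p-value is approximate; GAM residual diagnostics are not
  reproduced.
- Breakpoint confidence intervals are not computed.
- Robustness uses unweighted degree-zero extinction only.
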