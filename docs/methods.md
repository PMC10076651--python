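# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `symptomnet`.

## The model

Item responses are treated as discretized observations of a latent
multivariate Gaussian. After marginal normalization, the joint distribution
is modeled as a Gaussian graphical model (GGM): a zero in the precision
matrix Θ means two symptoms are conditionally independent given all others,
and the edge weight between nodes i and j is the partial correlation

    w_ij = −Θ_ij / √(Θ_ii Θ_jj).

Estimation maximizes the L1-penalized log-likelihood
`log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|` (graphical lasso; the diagonal is
unpenalized, matching the EBICglasso convention). The solver is
scikit-learn's coordinate-descent graphical lasso; along a path of 100
log-spaced penalties from λ_max (the largest absolute off-diagonal
correlation) down to 0.01·λ_max, fits are warm-started from the previous
solution, and the model minimizing

    EBIC(Θ) = −2·loglik(Θ; S, n) + E·log n + 4γ·E·log p

is selected, with E the number of nonzero upper-triangle edges. γ defaults
to 0.5, the conventional choice that errs toward sparsity. Converted partial
correlations below 1e−8 in magnitude are snapped to exact zeros so float
noise never inflates edge counts.

**Input correlations.** The default chain is: reverse-key the positively
worded SDS items → nonparanormal transform → product-moment correlations.
Polychoric correlations are deliberately not the default; the nonparanormal
route handles the skew the items actually exhibit and keeps the estimator a
plain correlation matrix. Whether redundancy screening sees raw or
transformed data is a free choice; the default screens raw responses, the
usual usage of the goldbricker procedure.

## Nonparanormal transform

Each column is mapped through its winsorized empirical CDF and the normal
quantile function: with mid-ranks r_i, u_i = clip(r_i/n, δ_n, 1−δ_n) and
z_i = Φ⁻¹(u_i), where δ_n = 1/(4·n^{1/4}·√(π log n)) is the shrinkage bound
of the truncated-ECDF estimator. Columns are then standardized to mean 0,
SD 1. Mid-ranks keep ties tied, so the transform is monotone, idempotent,
and order-preserving; it symmetrizes skew only to the extent the discrete
support allows (an item with 30%+ of its mass in one category stays visibly
skewed — no monotone transform can fix that).

## Redundancy screening

For each candidate pair with |r_ij| ≥ 0.5, every third item k yields a test
of H₀: ρ(i,k) = ρ(j,k) using Steiger's z for dependent correlations with the
Hittner modification (Fisher-transformed correlations, covariance term from
the back-transformed mean). A pair is reported redundant when fewer than 25%
of these tests reject at α = 0.05. The minimum-correlation gate is essential:
without it, two mutually independent items — whose correlation profiles are
identically zero — would be "redundant" by vacuous profile agreement. Flagged
pairs are reported, never dropped automatically.

## Centrality and communities

- Expected influence: EI_i = Σ_{j≠i} w_ij (signed sum; preferred over
  strength when networks contain negative edges).
- Bridge expected influence: the same sum restricted to edges leaving the
  node's group. The default grouping is the two-instrument split (15 burnout
  vs 20 depression items); an empirical Walktrap partition can be passed
  instead.
- Predictability: R² of each node regressed (OLS, with intercept) on its
  network neighbors, floored at 0. This follows the definition directly —
  variance explained by neighboring nodes; a nodewise mode using all other
  items as predictors is available as `mode="all"`.
- Communities: Walktrap with walk length t = 4 (the method's conventional
  default), dendrogram cut at maximum modularity, via python-igraph. Random
  walks need nonnegative weights, so the walk runs on |w|; signed community
  detection is undefined in this framework and the choice is recorded in the
  result metadata. Isolated nodes become singleton communities.

## Bootstrap stability

Edge accuracy uses a nonparametric bootstrap over respondents with the
*entire* pipeline (transform → correlation → EBIC-glasso) re-run per
resample; intervals are 95% percentile intervals (BCa is not implemented —
percentile is the convention in this literature). Difference tests declare
two edges or two nodes different when the percentile interval of the
bootstrapped difference excludes zero.

The case-dropping bootstrap drops a fraction q ∈ {0.1, …, 0.9} of
respondents, re-estimates, and correlates (Pearson by default) subset
centralities with full-sample centralities. The CS coefficient is the
largest q such that at q — and at every smaller q, enforcing the monotone
reading of "can drop up to q" — at least 95% of correlations reach 0.70.
A constant centrality vector (e.g. an empty re-estimated network) counts as
correlation 0, which is what drives CS to 0 on structureless data.
Defaults: nboot = 2,000 for case-dropping, 1,000 for edge CIs; the test
suite uses 150–200 with correspondingly coarse expectations.

## Network comparison test

Observed statistics come from fully re-estimating each group's network:
M = max |w^A_ij − w^B_ij| and S = |GS(A) − GS(B)| with global strength
GS = Σ_{i<j} |w_ij|. The null distribution pools respondents and permutes
group labels at the original group sizes; the nonparanormal transform is
re-run inside every permutation so the resampled statistic is computed by
exactly the observed pipeline (this is what makes the test exact-level under
exchangeability, regardless of estimator settings). P-values use the
add-one convention (1 + #{perm ≥ obs})/(1 + n_perm), so the smallest
attainable p is 1/(n_perm+1) — with Holm correction over p(p−1)/2 edges,
localizing a single edge needs n_perm ≳ 1,000. Pooled rows are put in a
canonical sorted order and the smaller group is always filled first, which
makes results exactly invariant to exchanging the two inputs.

## Synthetic-data generator

The generator emulates a large cross-sectional pharmacist survey: 35 items
(15 MBI-GS, 0–6; 20 SDS, 1–4 with the 10 positively worded items presented
reverse-keyed), n = 1,322 respondents, five planted communities — the three
burnout subscales (5, 4 and 6 items; within-block partial correlations 0.20,
0.22, 0.18) and two 10-item depression clusters (within 0.10; larger values
are impossible for a fully connected 10-node block with a unit-diagonal
precision matrix) — plus three bridge edges of partial correlation 0.10,
0.07 and 0.07 connecting depression items to burnout items, the magnitude
range reported for cross-construct edges in sparse empirical
burnout–depression networks. Item margins are right-skewed (most mass in the
low categories), mirroring how symptom inventories behave in working
populations.

Sampling is a Gaussian copula: latent vectors from N(0, Θ⁻¹) standardized to
unit margins, each margin cut at the normal quantiles of its category
probabilities. The precision matrix has unit diagonal with off-diagonals
equal to the negated requested partials, so the implied edge weights equal
the request exactly; constructions whose smallest eigenvalue is not positive
are rejected with a diagnostic naming the most overloaded block (an
eigenvalue check, not strict diagonal dominance, which would be needlessly
conservative for dense 10-item blocks). All randomness flows from one seed
through spawned child generators.

What the generator does *not* emulate: item-specific factor loadings,
response styles (acquiescence, straight-lining), missing data, demographic
heterogeneity beyond an optional grouping label, and polychoric-scale
attenuation differences between 4- and 7-level items beyond what
discretization itself induces. Passing recovery tests therefore demonstrates
correctness of the estimator on copula-ordinal data with planted sparse
structure — not robustness to survey artifacts.

## Problem sizes in the test suite

The simulation-based checks use sizes chosen to exercise the claims at
desk scale: 20 generator replicates at the full study size (n = 1,322,
p = 35, default 100-penalty path) for edge/community/bridge recovery;
8-node two-block data (n = 300 per group, 100 permutations, 200 replicates,
8-penalty path) for type-I calibration of the comparison test — permutation
exactness makes the rejection rate insensitive to path resolution; and
10-node data (n = 900, nboot = 200, 20-penalty path) for the CS-coefficient
contrasts. Bootstrap unit tests run at nboot = 100–150 and only assert
properties that are stable at that resolution.

## Known limitations

- The graphical lasso solver inherits scikit-learn's coordinate-descent
  behavior: at the smallest penalties of a long path the sweep limit can be
  reached before the 1e−4 duality gap; the affected penalties are reported
  in one aggregate warning and virtually never contain the EBIC minimum.
- Predictability from OLS on selected neighbors is post-selection R² and
  mildly optimistic at small n.
- The CS coefficient is reported on the conventional 0.1–0.9 grid; values
  between grid points are not interpolated.
- Redundancy screening assumes approximately normal scores for the
  dependent-correlation test; heavy ordinal ties make it conservative.
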