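# Methods

This note records the statistical conventions, parameter choices and
known limitations of the package. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Communities and pooling

The unit of analysis is a pooled **community vector**: per-species
counts summed over all samples of one stratum (all species, stygobites,
or non-stygobites) in one group (a year, or a year × site cell).
Species whose pooled count is zero are dropped before any index is
computed, so richness S always refers to species actually observed in
that selection; a master species list may therefore be larger than any
single year's S. Species order is canonical everywhere: descending
abundance, ties broken by lexical species id.

## Diversity, dominance and evenness

Natural logarithms throughout. For a community with proportions
pᵢ = nᵢ/n:

| index | formula | range |
|---|---|---|
| Shannon H′ | −Σ pᵢ ln pᵢ | 0 … ln S |
| Simpson D | Σ pᵢ² | 1/S … 1 |
| Buzas–Gibson E | e^{H′}/S | 0 … 1 |
| Margalef Mg | (S−1)/ln n | n ≥ 2 |
| Menhinick Me | S/√n | — |
| Pielou J′ | H′/ln S | 0 … 1, S ≥ 2 |
| Berger–Parker d | n_max/n | 1/S … 1 |

Conventions: a single-species community has H′ = 0, D = d = 1; J′ is
undefined there and raises an error (inside vectorised resampling loops
a replicate that collapses to one species is assigned J′ = 0 for
continuity — the point estimate never takes that branch). E is
computed as e^{H′}/S, the only form consistent with its verbal
definition (E = 1 iff all species equally abundant): e.g.
H′ = 2.151, S = 21 gives E = 0.409 and J′ = 0.706.

### Bootstrap confidence intervals

Percentile intervals over `reps` (default 9999) multinomial resamples
of the n observed individuals from the observed proportions — the
resampling unit is the individual, not the sample. Consequences users
should expect:

* richness-driven indices (Mg, Me) have **degenerate (zero-width)
  intervals** whenever no plausible resample loses a species, which is
  the rule for communities without singletons;
* percentile intervals need not cover the point estimate for strongly
  discrete indices at small n (lower ≤ upper always holds);
* intervals reflect multinomial counting error only, not between-sample
  heterogeneity (see *Limitations*).

### Between-community permutation test

Null: the two communities are a random partition of the pooled
individuals. Replicates are S×2 contingency tables with the pooled
per-species row totals and (n_a, n_b) column totals, drawn by
Patefield's algorithm via `scipy.stats.random_table` — i.e. from the
margin-conditioned multiple-hypergeometric law, each table weighted by
the number of individual-level arrangements that realise it. The
p-value is two-sided on the absolute index difference with add-one
correction, (#{|Δ*| ≥ |Δ_obs|}+1)/(reps+1), so p > 0 and p = 1 when the
communities are identical. Column order is canonicalised internally so
the test is exactly symmetric in its arguments at fixed seed. The test
conditions on pooled counts; replicate-level structure within a year is
not used.

## Species-abundance models

Observed abundances a_r (rank r = 1…S, descending) are modelled as
independent Poisson draws around the model expectation â_r. The
log-likelihood keeps the ln(a_r!) term, so AIC = 2k − 2 logL values are
absolute and comparable across models (verified to match an independent
R implementation to printed precision on a fixture).

* **Geometric (niche preemption)**, â_r = Jα(1−α)^{r−1}, k = 1. Fitted
  by bounded scalar optimisation of the Poisson likelihood on
  α ∈ (10⁻⁶, 1−10⁻⁶) (xatol 10⁻¹⁰); agrees with a dense grid-search
  oracle to 10⁻³ on all small test communities.
* **Broken stick**, â_r = (J/S)Σ_{x=r}^{S} 1/x, k = 0; expectations sum
  to J exactly (telescoping), AIC = −2 logL.
* **Lognormal**, â_r = exp(μ + σΦ_r), k = 2, fitted as a Poisson GLM
  with log link on the normal score Φ_r. Φ_r is the standard-normal
  quantile at (S − r + 0.5)/S, so rank 1 carries the largest deviate;
  other plotting-position conventions shift (μ, σ) slightly and this one
  is the documented contract.
* **Zipf**, â_r = Jp₁r^γ, k = 2, Poisson GLM on ln r; p₁ = e^{b₀}/J.

J and S are data, never parameters. The log-series model is excluded
by design: it is essentially an alternative representation of the same
abundance structure as the geometric series.

**Selection**: models ranked by AIC; ΔAIC < 2 between the top two is
reported as the verdict "tie" (the conventional "essentially equivalent
support" threshold), otherwise the best model's name.

## Rank-abundance regression

For assemblages following the preemption model, log₁₀(a_r) is linear in
r; OLS gives (b₀, b₁) with standard errors, R², and the overall F on
(1, S−2) df. Base-10 logs are the default (intercepts of communities
with hundreds of individuals sit near 2–3); natural log is an option.
A constant response yields slope 0 and R² reported as 0 with a warning
rather than NaN. Equality of slopes between two assemblages is the
ANCOVA interaction F-test in the pooled model
log(a) ~ rank + group + rank:group, F(1, S_A+S_B−4), computed from the
nested residual sums of squares and verified against the interaction
t² to 10⁻⁸.

## Beta-diversity

Classical count-based Morisita dissimilarity 1 − C with
λ = Σx(x−1)/(X(X−1)); each vector needs ≥ 2 individuals. Because of
the finite-count correction, C can exceed 1 — notably C(x, x) ≥ 1
exactly, so self-dissimilarity is ≤ 0 and only vanishes asymptotically
in the counts. Values are deliberately **not clamped** (a warning is
emitted) because per-year means over site pairs would otherwise be
biased. Morisita–Horn (relative-abundance, bounded [0, 1]) is provided
as an option for non-count data.

Between-year inference on site-pair dissimilarities:

* **paired t-test** on the matched upper triangles, two-sided,
  n_pairs − 1 df. Identical matrices return (t = 0, p = 1); zero
  variance of differences with nonzero mean raises (t unbounded). The
  n(n−1)/2 pairs of a distance matrix are not mutually independent;
  following standard practice for this design no correction is applied.
* **Mantel test**: Pearson r of the upper triangles, permuting one
  matrix's rows and columns simultaneously; one-tailed for positive
  association by default (pattern persistence is the hypothesis of
  interest), two-sided optional; add-one p over `reps` (default 10000)
  sampled permutations. Exhaustive enumeration over all n! relabelings
  is available (`exact=True`) for small site sets and is the oracle the
  sampled version is tested against.

## Synthetic surveys

The generator emulates a 3-year survey of one spring complex: a master
list of 22 species (9 stygobites, 13 non-stygobites), 8 sites × 4 dates
× 3 subsamples = 96 samples of 20 L per year (1920 L/year). Per year
and guild a preset fixes (S, J, α): 1997 — stygobites (9, 582, 0.574),
non-stygobites (12, 410, 0.304); 2005 — (8, 961, 0.621) and
(13, 1789, 0.393); 2012 — (7, 188, 0.462) and (11, 722, 0.311). The
guild marginals were back-derived from per-guild richness/abundance
index pairs of the emulated survey, and the α values are the per-guild
preemption fits; together they reproduce the yearly totals
(992/2750/910), richness (21/21/18) and dominant-species shares
(≈ 0.33 / 0.22–0.26 / 0.25) of the three hydrological years. Species
absent in a year are the lowest-expected-abundance members of their
guild, emulating rare-species turnover.

Generation is two-stage so yearly marginals are exact: (1) each guild's
expected SAD proportions are rounded to integer yearly totals by the
largest-remainder rule (sum exactly J, every retained species ≥ 1 —
deterministic); (2) each species' total is split across the 8 sites
with Dirichlet(θ, …, θ) weights and then multinomially across the 12
replicate samples within each site. θ is the site-heterogeneity dial:
θ → ∞ makes sites compositionally identical (all Morisita
dissimilarities → 0); small θ concentrates species in few sites. The
default θ = 0.5 places the presets' mean inter-site Morisita
dissimilarity inside the 0.3–0.65 band typical of spring complexes fed
by a single aquifer.

What the generator does **not** emulate: temporal autocorrelation among
the 4 sampling dates, overdispersion beyond Dirichlet-multinomial,
detection error, and any species-level biology (the Dirichlet split is
independent across species). Tests passing on synthetic data therefore
demonstrate correctness of the estimators under multinomial sampling,
not robustness to these real-data features.

## Pipeline and reproducibility

`run_full_analysis` executes every stage over all strata and years and
writes four CSV tables plus a JSON manifest (seeds, config echo,
versions). Every stage seed derives from the master seed by a BLAKE2b
hash of (master_seed, stage name), so changing one stage's replication
count cannot perturb another stage's stream; identical (input, seed)
gives byte-identical outputs. Default replication counts: 9999
bootstrap, 9999 permutation, 10000 Mantel, 95 % CIs, ΔAIC tie
threshold 2.

The acceptance script scales its simulations to run in a few seconds on
one CPU: 100 communities (S = 21, J = 1000) for preemption-parameter
recovery and 1000 null pairs (J = 500 each, 499 permutation replicates)
for the type-I calibration; the test suite uses the same sizes.

## Known limitations

* Bootstrap CIs and the permutation test operate on pooled counts, so
  they understate uncertainty when replicate samples are overdispersed
  relative to multinomial sampling.
* Poisson observation error around SAD expectations ignores the
  rank-ordering constraint (abundances are sorted before fitting);
  this is the standard practice the package follows, and it slightly
  biases spread parameters at small S.
* Morisita dissimilarity is undefined for communities of fewer than 2
  individuals; very sparse site × stratum cells raise errors rather
  than returning placeholders.
* The paired t-test on distance pairs inherits the usual
  non-independence caveat of distance-matrix data; its p-values are
  comparative, not exact.
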