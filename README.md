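# stygodiv

Community-structure statistics for spring-dwelling meiofauna surveys —
and for any small, fully censused community of integer counts.

Groundwater-fed springs host copepod communities split between two
ecological guilds: **stygobites** (obligate groundwater species washed
out of the aquifer) and **non-stygobites** (surface or generalist
species).  Comparing such communities across hydrological years means
asking four questions, each with its own statistical machinery:

1. **Has diversity, dominance or evenness changed?**  Seven indices —
   Shannon entropy `H' = −Σ pᵢ ln pᵢ`, Simpson dominance `D = Σ pᵢ²`,
   Buzas–Gibson evenness `E = e^{H'}/S`, Margalef `Mg = (S−1)/ln n`,
   Menhinick `Me = S/√n`, Pielou `J' = H'/ln S`, Berger–Parker
   `d = n_max/n` — with percentile-bootstrap 95 % CIs (multinomial
   resampling of the n observed individuals) and a fixed-margin
   permutation test for between-year differences: random S×2 contingency
   tables with the pooled row totals and the two community sizes as
   column totals (Patefield's algorithm), p = (#{|Δ*| ≥ |Δ_obs|}+1)/(reps+1).
2. **Has the species-abundance distribution (SAD) changed shape?**  Four
   rank-abundance models fitted by maximum likelihood with Poisson error
   and ranked by AIC: geometric series (niche preemption)
   `a_r = Jα(1−α)^{r−1}`, broken stick `a_r = (J/S)Σ_{x=r}^{S} 1/x`
   (zero parameters), lognormal `a_r = exp(μ + σΦ_r)`, and Zipf
   `a_r = Jp₁r^γ`.  ΔAIC < 2 between the top two models is reported as a
   tie ("fitted equally well").
3. **How steep is the dominance decay?**  OLS regression
   `log₁₀(a) = b₀ + b₁r` on the rank-abundance line, with the ANCOVA
   interaction F-test for equality of slopes between assemblages.
4. **Did between-site structure change?**  Classical (count-based)
   Morisita dissimilarity among all site pairs, paired t-tests on
   matched site pairs across years, and Mantel tests (Pearson r,
   permutations of one matrix's site labels).

A synthetic-survey generator (`stygodiv.synthetic`) emulates a
three-year, 8-site × 4-date × 3-subsample design with guild-structured
geometric SADs and Dirichlet-multinomial between-site heterogeneity, so
the whole pipeline is testable without any field data.

## Worked example

```python
import stygodiv as sg

table = sg.generate_scenario("1997", seed=1)   # 22-species master list, 96 samples
c = sg.pool(table, "all")                      # pooled year community

print(c.S, c.n)                                # 21 992
print(round(sg.menhinick(c), 3))               # 0.667
print(round(sg.margalef(c), 3))                # 2.899
print(sg.bootstrap_ci(c, "shannon", reps=9999, seed=7))

sel = sg.select_model(sg.rank_abundances(c))
for f in sel.fits:
    print(f.model, round(f.aic, 2), f.params)
print(sel.verdict)
```

prints

```
21 992
0.667
2.899
(2.1068522427239993, 2.2401878850359785)
lognormal 123.34 {'mu': 2.856, 'sigma': 1.518}
geometric 146.16 {'alpha': 0.256}
zipf 203.31 {'p1': 0.381, 'gamma': -1.291}
broken_stick 364.88 {}
lognormal
```

Reading: the pooled 1997-style community holds 21 species and 992
individuals; Menhinick and Margalef richness follow directly from
(S, n).  The lognormal SAD wins by ΔAIC ≈ 23 over the geometric series,
i.e. a fairly equitable community with a soft dominance tail — the
fitted σ ≈ 1.5 is the spread of log abundances, and the preemption
alternative would claim each species takes ≈ 26 % of the remaining
niche space.  Between-year questions follow the same pattern:

```python
c05 = sg.pool(sg.generate_scenario("2005", seed=2), "all")
r = sg.permutation_compare(c, c05, "berger_parker", reps=9999, seed=11)
print(round(r.observed_diff, 3), r.p)          # 0.08 0.0001

m = sg.beta_matrix(table, 1997, "all")         # 28 site-pair dissimilarities
print(round(m.condensed().mean(), 3))          # 0.412
```

The command line mirrors the library
(`stygodiv simulate | alpha | sad | rad | beta | all`):

```sh
stygodiv simulate --out scenarios --seed 5
stygodiv all -i scenarios/counts_all.csv -m scenarios/samples_all.csv \
             --seed 3 -o results/
```

writes `diversity.csv`, `sad_fits.csv`, `rad_regression.csv`,
`slope_tests.csv`, `beta.csv` and a `manifest.json` recording seeds and
configuration; re-running with the same seed reproduces every number
byte for byte.

## Input format

Wide CSV/TSV: column 1 = species id, column 2 = guild
(`stygobite`/`non_stygobite`), remaining columns = per-sample integer
counts; a companion metadata CSV maps sample id → site, year, replicate.
`stygodiv.read_abundance_table` validates counts (non-negative integers,
no duplicate ids, known guilds) and `write_abundance_table` emits the
identical dialect, so read → write → read is the identity.

See `docs/methods.md` for the statistical details, conventions and known
limitations.
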