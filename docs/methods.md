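# Methods

## Model

Genetic susceptibility to MS is modelled as a threshold over `x + 1`
unlinked autosomal loci: the HLA DRB1 haplotype plus `x` non-HLA loci. Each
locus is either in a "susceptible allelic state" or not, and an individual
is susceptible iff at least `n` loci are in such a state. The per-locus
state is defined by a dominance mode under Hardy–Weinberg equilibrium:

* dominant — carry ≥ 1 copy of the susceptibility allele, state frequency
  `2a − a²`;
* recessive — homozygous, state frequency `a²`;
* mixed — the locus carries one dominant-acting and one recessive-acting
  allele of equal frequency `a`; state frequency `2a`.

The HLA locus is dominant with carrier frequency `h`; non-HLA loci share a
mean state frequency `F = h / r`, where the ratio `r` is a sweep parameter,
not an estimand of interest in itself. Susceptible individuals develop MS
with penetrance `Pt1*` (HLA carriers) or `Pt0*` (non-carriers); the starred
penetrances remove the shared intrauterine / early-postnatal twin effect by
the DZ/sibling recurrence ratio (5.4 / 2.9 = 1.86), giving the default
`Pt* = 0.25 / 1.86 = 0.134`. DZ-twin predictions use the unadjusted
penetrance; an MZ co-twin shares the genotype, so its risk is the
penetrance itself.

Susceptibility here is binary by construction: the threshold form is a
representative summary of an arbitrarily complicated set of susceptible
genotype combinations, with `n` best read as an upper bound on the average
number of loci involved.

## Key parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `h`, `h_m` | HLA carrier frequency, population / cases | 0.24 / 0.55 | probability |
| `C` | HLA-negative fraction of susceptibles (`1 − h_m`) | 0.45 | probability |
| `C*` | `C / (1 − h)` | 0.5921 | ratio |
| `r` | HLA-to-non-HLA state-frequency ratio | swept 0.25…16 | — |
| `n` | loci required for susceptibility | swept 5…60 | loci |
| `x` | non-HLA locus count | solved from `C*` | loci |
| `Pt0*`, `Pt1*` | adjusted penetrances | 0.134 | probability |
| `P(MS)` | observed prevalence target | 0.0015 | probability |

Parameters live in a frozen `ModelParameters` dataclass, loadable from
YAML/JSON with keys mirroring the symbols above; dominance compositions are
given as fractions and converted to integer locus counts by
largest-remainder rounding (deterministic, ties to the lower index). The
same rule partitions the `n − 1` (HLA-carrier proband) or `n` (non-carrier)
"necessarily present" loci across dominance classes, a choice the source
derivations leave open.

## Solver conventions

* `hla_negative_fraction` is evaluated as a direct product of `n` linear
  factors (exact for real `x`), strictly increasing in `x`.
* The continuous root of the constraint is found by `brentq` bisection to
  1e-10 on `(n − 1, ∞)`; the integer range scans `x` in `[max(n, 4), 2000]`
  and keeps values whose fraction lies in the inclusive band `C* ± tol`
  (default `tol = 0.05`, applied to the unrounded `C*`). An empty band is a
  reported outcome, not an error. Note the literal band is broader than the
  historically published integer ranges for the same constants (e.g.
  {48…63} vs 53–57 at `r = 2, n = 13`); the original tolerance convention
  is not recoverable, so spot checks against published ranges are made at
  those ranges' endpoints.
* Prevalence: `Σ_{i∈{0,1}} Pt_i* · P(HLA state = i) · P(Bin(x, F) ≥ n − i)`,
  with tails from `scipy.stats.binom`; impossible summation bounds truncate
  through the tail automatically.
* The `r → ∞` floor replaces the binomial by a Poisson with mean
  `λ = h·C*^{1/n} / (1 − C*^{1/n})` (the constraint's limiting form).
* Recurrence: the relative's susceptible-state count is the HLA indicator
  (Bernoulli with the class's transmission probability `P_H` or `P_h1`)
  plus independent binomials over the conditioned loci (class-specific
  `P_A1/P_A2/P_A3`) and the unconditioned loci (baseline `F`); the risk is
  the penetrance-weighted upper-tail probability of reaching `n`, computed
  by direct convolution of binomial pmfs. The final tail applies the
  complement to the whole convolution, which reduces exactly to the
  prevalence formula when all conditioning probabilities are set to
  baseline.
* Expected recurrence mixes the HLA-positive and HLA-negative proband
  branches with weight `C` on the negative branch (`C²` for the offspring
  of two affected parents — neither parent carries). This weighting is
  exact when `Pt1 = Pt0`.

## Transmission formulas and their limits

The per-class transmission probabilities are closed forms, some of them
deliberate approximations:

* The sibling/parent-child dominant form `0.5(1 + 2a − a²)` assumes a
  single transmitting parent. Exact enumeration over conditioned parental
  diplotypes (`sibling_carrier_exact`) shows the closed form overstates the
  probability by ~2.1% relative at the HLA allele frequency (0.620 vs
  0.607); the non-carrier-proband form `a − 0.25a²` is exact. The exact
  variant is provided for diagnostics and never silently substituted.
* The mixed-mode blend weights the recessive branch by `a/2` (the
  probability the proband's known state is the recessive one). At
  third-degree relationships this blend falls below the mixed baseline `2a`
  once `F ≳ 0.4`: the identity-by-descent bonus at 12.5% sharing is smaller
  than the two-allele baseline. Monotonicity properties are therefore
  asserted on the realistic range `F ≤ 0.4`.
* For the child of two affected parents every locus is elevated: each locus
  has chance `n/x` of sitting among an affected parent's susceptible
  states, and the conjugal forms mix a both-parents branch (weight
  `(n/x)²`) with a one-parent branch. These forms are applied across all
  `x` loci with no baseline remainder. They saturate near the penetrance
  ceiling for most fitted configurations, and they over-predict the
  generative model's own conjugal recurrence substantially (simulation
  gives ~3% where the closed form gives ~13% at the fitted recessive
  configurations) — the conjugal row is the least trustworthy prediction
  and is retained for fidelity, not accuracy.
* The published conjugal HLA form carries a `+a²` where every analogous
  formula has `−a²`; the default keeps it, `conjugal_ph_corrected=True`
  flips the sign.

## Closeness of fit

`CoF = Σ_targets [(H − E)/E + (L − E)/E]²` over six targets (prevalence,
sibling, conjugal offspring, parent/child, second degree, third degree),
where `H`/`L` are the model predictions at the high/low ends of the solved
`x` range and `E` the observed reference point. The statistic is unit-free
and invariant to rescaling a target's triple. Cells with `CoF < 4`
(chi-square, 1 df) are acceptable. Ties at the minimum break toward smaller
`n`, then smaller `r`. With 20% dominant / 80% recessive loci the optimum
lands at `r = 4, n = 16` (CoF 2.15) and the acceptable set spans
`n = 13…22, r ≥ 2` with nothing at `r ≤ 0.5`; an all-dominant sweep has no
acceptable cell (min CoF ≈ 19).

## Synthetic data

The simulator draws founder diplotypes locus-by-locus from HWE (mixed loci
carry a three-way allele draw), transmits alleles by fair Mendelian
segregation through fixed structures (sib/twin pairs, parent–child,
grandparental chains for avuncular and first-cousin pairs, two-proband
conjugal families), scores states, applies the `≥ n` threshold, and draws
affection as an independent Bernoulli by HLA carrier status. Conditioning
on affected probands is by rejection (generate-and-filter), with a warning
when acceptance drops below 1e-4.

Reproducibility: a single root `SeedSequence`; child streams are spawned
per batch of 8192 families (65536 individuals for cohorts), so enlarging a
run appends new families without reshuffling earlier ones, and identical
seed + configuration yields byte-identical TSV output.

What it does *not* emulate: environmental exposure structure, linkage or
linkage disequilibrium between susceptibility loci, sex-specific
frequencies or X-linkage, multiple susceptibility alleles per gene, or
penetrance heterogeneity beyond the HLA split. Passing oracle tests
therefore certify internal consistency of the algebra under the model's own
assumptions, not the model's adequacy for real families.

Default simulation sizes (1–2 × 10⁵ families for oracle checks) keep Monte
Carlo standard errors a few times smaller than the effects being checked;
tests compare at 3–4 standard errors.

## Known limitations

* The integer `x`-range tolerance convention of the original computation is
  unrecoverable; the literal `C* ± 0.05` band is wider than the published
  ranges, which widens the high–low prediction spreads and shifts the CoF
  argmin within the acceptable region (see above).
* Table-level constants quoted from secondary derivations
  (`C*` ceiling 0.79, proband-wise concordances 31%/29%) are treated as
  given inputs, configurable but not re-derived.
* The penetrance-bound solver reproduces the bound ratio `Pt1 ≤ 1.8·Pt0`
  but its unrounded split (0.314 / 0.171) differs in the second decimal
  from the published rounded pair (0.32 / 0.18).
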