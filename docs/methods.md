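# Methods

## Model

The package treats disease onset in a survival framework. A genotype
`k ∈ {0, 1}` (non-carrier / carrier of the variant under evaluation)
experiences hazard `λ₀(t)·exp(β(t)·k)`, where `λ₀(t)` is the baseline
population incidence per person-year and `exp(β(t))` the age-specific
relative risk of the *hypothesized* pathogenic state — the risk profile
of the "average" pathogenic variant in the gene, taken from published
penetrance studies, not estimated from the data at hand. Both curves are
piecewise constant on half-open age bands `[a, b)`, the form in which
incidence rates and per-decade ORs are published; no smoothing or
interpolation is applied. Published ORs are treated as relative risks,
which is adequate for rare variants.

The probability of remaining unaffected at age `t` is
`S_k(t) = exp(−∫₀ᵗ λ₀(u) e^{β(u)k} du)`, evaluated exactly as a sum of
rate × width terms over the merged band edges. The affected-at-t density
would carry an extra `λ₀(t)` factor for both genotypes; it cancels in
every carrier/non-carrier ratio, so the implementation only ever needs
the per-individual weight

    w(t, d) = S₁(t) · e^{β(t)·d} / S₀(t)

with `β(t)` looked up at the band containing the age at diagnosis for
affected individuals. The cumulative hazard always integrates `β(u)`
over `u ≤ t`.

## The case-control likelihood ratio

Conditioning on the observed number of carriers `K` among `N`
individuals, the likelihood ratio of the pathogenic versus benign
hypotheses is, to close approximation,

    ccLR = ∏_{j: v_j=1} w(t_j, d_j) / ( (1/N)·Σ_j w(t_j, d_j) )^K .

Properties that the tests verify against a naive first-principles
oracle: invariance to the ordering of individuals; `β ≡ 0 ⇒ ccLR = 1`;
a single-age, single-status dataset gives `ccLR = 1` for any `K`; and
moving a carrier label from a control to a case raises the LR when
`β > 0`. With `K = 0` the LR is exactly 1 (empty product, zero
exponent); such variants are reported with a `no carriers` flag since a
case-control LR is then uninformative rather than evidential.

The LR is accumulated in log space (sum of log weights minus
`K·logsumexp`-based log mean weight), so products over thousands of
carriers and LRs of order 10³–10⁴ or 10⁻³⁰ are representable.

Stratified analyses compute the LR within each country/study label and
multiply. Strata without carriers contribute a factor of 1. Pooling
heterogeneous populations into one stratum can bias carrier-frequency
comparisons, so stratification is recommended whenever labels exist.

## Evidence strengths

LRs map to ACMG/AMP code strengths with inclusive bounds on the side of
the stronger claim: pathogenic very strong ≥ 350, strong ≥ 18.7,
moderate ≥ 4.33, supporting ≥ 2.08; benign very strong ≤ 0.0029, strong
≤ 0.053, moderate ≤ 0.231, supporting ≤ 0.48; `none` strictly between
0.48 and 2.08. The boundary value 0.48 itself is assigned benign
supporting. The mapping is a total monotone step function (property
tested).

## Data handling

* **Permitted ages.** Individuals outside the inclusive range 21–80 (the
  range over which penetrance estimates are typically available) are
  removed and counted before analysis; the bounds follow the penetrance
  model's `age_range` and are configurable.
* **Unknown ages.** Either excluded or assigned a fixed age. The default
  assigns the midpoint of the oldest age band (77.5 with the bundled
  incidence table), the conservative choice: older assigned ages
  down-weight a carrier's contribution to the pathogenic hypothesis.
* **Tabulated input.** Age-group count tables are expanded into
  pseudo-individuals at the group midpoint (configurable to the lower or
  upper bound). This reproduces the individual-level LR exactly when the
  individual ages equal the representatives, and loses only within-band
  age detail otherwise.
* **Frequency screen.** Carrier frequency above 0.1% (configurable)
  triggers a warning, or a refusal with `--hard-filter`; the method
  targets rare variants.

## Comparators

* Crude OR: cross-product on the 2×2 table; Haldane's correction (+0.5
  to every cell) automatically when any cell is zero; Woolf CI
  (log OR ± 1.96·SE on the corrected cells — the CI construction for the
  corrected table is a documented package choice); Fisher's exact
  p-value always on the uncorrected table. A fully zero margin is an
  error (flagged, not fatal, inside simulation loops).
* Logistic regression: binomial GLM of status on carrier plus age
  (continuous linear — the functional form is a package choice) and
  optionally country (categorical), fitted on the aggregated
  sufficient-statistics table, which is likelihood-equivalent to the
  individual-level fit and much faster. p-values from the LRT dropping
  the carrier term; Wald 95% CI. Quasi-complete separation (|log OR| >
  15) or IRLS failure sets `converged = False`.
* PS4: true iff OR > 5.0, the 95% CI excludes 1.0, and p < 0.05;
  non-converged fits never satisfy it.

## Simulator

One replicate draws `K_cases ~ Poisson(N·RR·MAF)` and
`K_controls ~ Poisson(N·MAF)` (capped at N with a warning; negligible at
rare MAF), assigns carriers to uniformly chosen individuals per arm, and
draws ages per arm from a normal distribution rounded to whole years and
clipped to 21–80. Defaults: cases 55 ± 10, controls 58 ± 10 —
approximate stand-ins for a population-based breast cancer case-control
age structure; configurable per scenario. Rounding to integer years
matches the banded penetrance inputs and lets the logistic fits
aggregate exactly. A same-age mode assigns one fixed age (default 55) to
every individual, emulating datasets without age information.

Ages are drawn independently of carrier and case status, so *age carries
no signal* in simulated data; the LR's age terms act only through the
penetrance weighting. Passing power/type-I tests therefore validate the
carrier-count channel under a realistic age mix, not age-differential
onset between carriers and non-carriers, which real data would show and
which would further favor the ccLR. Other features of real data the
simulator does not emulate: family-history ascertainment, genotyping
error, linkage between variants, and country structure.

The hypothesized penetrance used in the simulation studies is the
bundled constant-RR-10 curve over an England/Wales-style baseline
incidence shape (`brca1-constant`; a 5.5 variant and age-attenuating
banded variants are also bundled). All bundled curves are labeled
approximate illustrative stand-ins; real analyses should supply
published gene-specific estimates.

## Operating characteristics at desk scale

The test suite and the acceptance script run 500–1,000 replicates per
condition (the package's chosen desk-scale problem size; Monte-Carlo
SE ≈ 0.7–1.5 percentage points near the reported proportions) at per-arm
N up to 50,000. Observed: pathogenic power (RR = 10, MAF = 1e-4,
N = 50,000) ≈ 99–100% for LR ≥ 18.7; benign power (RR = 1) ≈ 90% for
LR ≤ 0.48; type-I error for LR ≥ 18.7 below 0.01; same-age type-I error
for LR ≥ 2.08 ≈ 0.04–0.05 with benign power a few points below the
full-age run on matched seeds.

One caveat the tests surface honestly: at the *supporting* pathogenic
cutoff (LR ≥ 2.08) the null type-I error is not controlled at 0.05 for
smaller datasets (≈ 0.11 at N = 20,000 per arm, MAF = 1e-4), because a
single unbalanced carrier draw can clear so low a threshold. This is
precisely why the stronger LR ≥ 18.7 cutoff is the recommended operating
point for declaring pathogenic evidence, and the corresponding
null-calibration test is left failing at that combination rather than
relaxed.

## Numerical choices

* Inclusive age bounds [21, 80]; an age equal to a table's final break
  belongs to the last band.
* Weight/hazard evaluation is vectorized (`searchsorted` over merged
  band edges with precomputed cumulative sums); agreement with adaptive
  quadrature to 1e-8 relative tolerance and with a naive loop oracle to
  1e-10 is property-tested.
* The incidence table may start above age 0 (hazard 0 below its first
  band); the relative-risk curve's edge bands extend outward where
  needed.
* Per-stratum LRs multiply in log space; the product identity holds to
  1e-10 relative tolerance.
* All randomness flows through `numpy.random.Generator` seeded per
  scenario; identical seeds reproduce datasets and power tables exactly.

## Known limitations

Family-history or segregation likelihoods, co-occurrence evidence,
multifactorial posterior combination, competing mortality, sex-specific
curve pairs and penetrance estimation are out of scope. Case or control
selection on family history, or depletion of known-variant carriers by
prior clinical testing, biases the LR; the method is intended for
population-based series, and capping case-control evidence at moderate
strength is a reasonable conservative application policy.
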