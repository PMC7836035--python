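# Methods

## Model and procedure

The package treats the generalized mean p-value (GMP)

    M_{r,K}(p₁,…,p_K) = ((Σᵢ pᵢ^r)/K)^{1/r}

as a test statistic for the grand null hypothesis that all K constituent
p-values are Uniform(0,1). Because the GMP is not itself uniform, a
significance threshold Ψ_{r,K}(ε) is required such that
Pr(M ≤ Ψ) ≤ ε under the null. Two threshold families are implemented:

* **GCLT.** Under independence, Xᵢ = pᵢ^r is Pareto(1, −1/r) for r < 0
  and Beta(1/r, 1) for r > 0, so Y = ΣXᵢ is attracted to an extremal
  stable law S_{λ,1} with λ = min(−1/r, 2) (Nolan S1 parameterization,
  α = λ, β = 1, σ = 1, µ = 0; λ = 2 is exactly Normal(0, 2)). The
  threshold inverts the normalized sum at the appropriate quantile. The
  centering/scaling regimes (r < −1; r = −1; −1 < r < −1/2; r = −1/2;
  r > −1/2) follow the classical tables for sums of non-negative
  regularly varying variables. Validity under dependence is *not*
  guaranteed; for r ≤ −1 the heavy tails supply partial robustness
  (pairwise tail-independence in the Davis–Resnick sense), which the
  simulation harness quantifies empirically.
* **RRA.** Worst-case p-value merging bounds (robust risk analysis),
  linear in ε and valid under arbitrary dependence. For r < −1 the
  multiplier is ((r+1)/r)·K^{−(1+1/r)}; at r = −1 it is 1/log K; for
  r > −1 it is (r+1)^{−1/r}. The printed source for the −1 < r < −1/2
  row is typographically ambiguous; the implementation adopts
  Ψ_RRA = ε·(r+1)^{−1/r} throughout r > −1, the only reading consistent
  with the factor-2 multiplier at r = 1 (the classical two-fold bound for
  the arithmetic mean p-value) and the limit multiplier e as r → 0.

The small-ε closed form Ψ → ε·K^{−(1+1/r)} (r < −1/2) is exposed
separately; its published rendering also drops the sign of the exponent,
which the implementation fixes — the adopted form is the only one that
reaches the Bonferroni threshold ε/K as r → −∞ and ε itself at r = −1.

Inverse maps translate thresholds into realized false positive rates:
`fpr_under_independence` applies the stable CDF to (K·t^r − a)/b, and
`fpr_worst_case` divides by the RRA slope (capped at 1), taking the RRA
bounds as precise.

**Multilevel testing.** Closed testing over subsets ℜ uses the exact
partition identity K·M^r = |ℜ|·M_ℜ^r + |ℜ′|·M_ℜ′^r with the complement at
its least favourable value 1, giving the deflation factor

    f_{|ℜ|} = min{1, ((Ψ_{r,K}^r − (1 − |ℜ|/K)) / ((|ℜ|/K)·Ψ_{r,|ℜ|}^r))^{1/r}}.

For r < −1 both threshold families satisfy Ψ_{r,K}/Ψ_{r,m} =
(m/K)^{1+1/r}, and the package uses the simplified (slightly more
stringent) factor f = |ℜ|/K with the equivalent closed subset thresholds
(m/K)^{−1/r}·Ψ_{r,K}(ε); with the small-ε form this is m^{−1/r}·ε/K. The
general factor keeps the (1 − |ℜ|/K) slack term and is offered for
−1 < r < 0 and r > 0; for r > 0 subsets smaller than K(1 − Ψ^r) can never
force a global rejection through this shortcut and are reported as
NOT_REJECTABLE rather than given a fake threshold. No closed testing
procedure is defined at r = 0.

**Bayes-factor reading.** For Beta(ξ, 1) local alternatives with
ξ = 1 + r ∈ (0, 1), the model-averaged Bayes factor equals
(1+r)·M_{r,K}^r exactly; outside −1 < r < 0 the GMP provides the bound
BF̄ ≤ (1+r)·M_{r⋆,K}^r for r⋆ < r < 0, by monotonicity of the GMP in its
exponent.

## Dependence simulator

Each test is a nested likelihood-ratio test with v free parameters;
its standardized score vector is multivariate normal and the deviance
2 log Rᵢ = Sᵢ′Sᵢ is χ²(v) under the null. Dependence enters through a
single equicorrelation ρ ∈ [0, 1] between *analogous* score components
of different tests (non-analogous components uncorrelated), making the
joint deviances the diagonal of a Wishart(equicorrelated ρ-matrix, v) —
a Wishart-Multivariate-Gamma vector. Defaults: K = 1000 tests, v = 2
(which makes pᵢ = 1/Rᵢ exactly), ε = 0.05, and four canonical scenarios
distinguished by how many tests carry signal and the per-component
Z-statistic: null (0, –), needle (1, 3.0), mixture (100, 1.25),
pervasive (1000, 0.7) — shift sizes calibrated for roughly 50% power
under independence.

Design choices the source leaves open:

* **Shift placement.** Whether the Z-shift enters one or all v score
  components is unstated; the package adds it to *all* v components
  (noncentrality v·Z² per affected test). With v = 2 and Z = 3.0 this
  reproduces the stated ~50% Bonferroni power calibration of the needle
  scenario under independence (measured ≈ 49%), whereas a one-component
  shift (noncentrality 9) gives power near 10%.
* **Sampling route.** Equicorrelation is sampled by its exact one-factor
  representation s = √ρ·z₀ + √(1−ρ)·e per component, rather than a
  Cholesky factor of the vK×vK matrix: O(vK) per draw and exact at the
  degenerate ρ = 1 boundary (all deviances identical). The draw order is
  fixed (shared factors, then idiosyncratic noise, then the mean shift is
  added) so that a zero-shift scenario reproduces the null stream
  bitwise from the same generator state.

What the generator does *not* emulate: heterogeneous degrees of freedom
across tests, correlation between non-analogous parameters, sparse or
blockwise dependence, and conservative (super-uniform) null p-values.
Passing tests therefore demonstrate calibration and power under dense
equicorrelated likelihood-ratio dependence only; real data with
block-structured or tail-asymmetric dependence can behave differently,
and conservative nulls would severely reduce GMP power.

## Numerical choices

* **GMP evaluation** uses exp((1/r)·(logsumexp(r·log p) − log K)); p^r
  would overflow at e.g. r = −10, p = 10⁻³⁰. |r| ≤ 10⁻⁸ is routed to the
  exact geometric mean, ±∞ to min/max. p-values of exactly 0 are
  rejected at validation; an opt-in floor (CLI `--floor`) clips instead.
* **Stable quantiles.** The library stable CDF (S1 parameterization,
  validated against a Chambers–Mallows–Stuck sampling oracle, including
  the S0↔S1 shift convention) is used in the central region. Deep upper
  tails, where the library's piecewise integration saturates, switch to
  the Zolotarev tail expansion
  (1/π)Σ_k (−1)^{k+1}(Γ(kα)/k!)·sin(kπαρ)·secᵏ(πα/2)·x^{−kα}
  (ρ = 1 for α < 1, convergent; ρ = 1 − 1/α for 1 < α < 2, asymptotic,
  truncated at its smallest term), inverted by bracketed root finding on
  log x. At α = 1 the expansion degenerates and the leading tail
  2/(πx) is used beyond x = 300. Switch levels: tail probability 10⁻³
  for the CDF, 5·10⁻³ for the quantile; the hand-over discontinuity is
  below ~3% relative and outside the ε range used by any reported
  quantity. Quantiles at λ = 2 and the Lévy case λ = ½ use closed forms.
* **Extreme exponents.** For λ = −1/r < 0.05 (r < −20) stable quantiles
  exceed double-precision range; there the sum is dominated by its
  largest term and the threshold uses the exact minimum-p-value
  distribution, Ψ = (1 − (1−ε)^{1/K})·K^{−1/r}, which recovers the Šidák
  threshold as r → −∞. The stable scaling constant is evaluated in log
  space (lgamma) to avoid Γ overflow.
* **Warnings, caching, determinism.** Thresholds accept ε ∈ (0, 1) but
  warn above 0.2, where the tail approximations degrade. GCLT thresholds
  are memoized (they are pure in (r, K, ε)). All simulation entry points
  take explicit seeds or generators; sweeps derive one child stream per
  (scenario, ρ) cell from a SeedSequence, and all methods in a cell are
  evaluated on the same replicates, so outputs are byte-identical across
  runs with the same seed.
* **Decision interface.** Every combined test is normalized to "reject
  iff statistic ≤ threshold(ε)"; Fisher's χ² statistic is carried as its
  combined p-value for this purpose. Inherent power re-calibrates the
  threshold at the empirical ε-quantile of the statistic under the
  matched null scenario with the same ρ and replicate count — the source
  does not state its calibration mechanics, and Monte-Carlo null
  calibration is the natural reading of "the power of a test when its
  threshold achieves the target false positive rate".

## Problem sizes

Simulation-backed assertions in the test suite use 2 000–100 000
replicates depending on the tightness of the claim (binomial 3–4 MCSE
bands); the acceptance script uses 10⁴ replicates of K = 1000 for each
stochastic target, matching the design of the original simulation study.
The factorial sweep defaults to the full 10 × 6 × 4 design at 10⁴
replicates; the CLI default is 10³ for exploratory runs.

## Known limitations

* GCLT thresholds for −1 < r < 0 are anti-conservative under even mild
  equicorrelation (measured FPR ≈ 0.29 at r = −0.25, ρ = 0.4, target
  0.05); the multilevel module warns when used in this range.
* The HMP itself shows mild finite-K inflation (≈ 5.2% at the 5% target,
  K = 1000 under independence) — the GCLT is asymptotic in K.
* RRA thresholds are implemented in their large-K closed forms; for very
  small K they inherit the asymptotic approximation error of the bounds.
* Weighted GMPs and conservative/discrete null p-values are out of
  scope, as are dependence-adjusted CLT thresholds for r > −1/2 and
  Brown-style explicit dependence corrections.
* The multilevel shortcut tests single subsets; it does not enumerate
  the full closed testing lattice, and for r > 0 only the
  single-subset shortcut (with its NOT_REJECTABLE region) is available.
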