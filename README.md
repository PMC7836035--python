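# gmpcomb

Combine K dependent p-values with **generalized mean p-values** (GMPs),
with significance thresholds derived from generalized central limit
theorem (GCLT) and from worst-case robust risk analysis (RRA), multilevel
closed-testing for subsets, and a likelihood-ratio-motivated simulator of
dependent p-values.

## Who this is for

Meta-analysts and statistical geneticists who need to aggregate evidence
across many tests — GWAS variants, studies, model fits — when only the
p-values are available and the dependence between them is unknown. The
familiar choices (Bonferroni, Šidák, Fisher, Simes, the harmonic mean
p-value) are all special cases of one statistic, and this package exposes
the whole family together with the threshold theory that makes each of
them a valid test.

## The statistic

The generalized mean p-value with exponent r of p-values p₁,…,p_K is

    M_{r,K}(p₁,…,p_K) = ((p₁^r + ⋯ + p_K^r) / K)^{1/r}

which interpolates the minimum (r → −∞, Bonferroni/Šidák territory), the
harmonic mean p-value (HMP, r = −1), the geometric mean (r → 0, Fisher
territory), the arithmetic mean (r = 1) and the maximum (r → +∞). Under
the grand null the summands pᵢ^r are Pareto-tailed for r < 0, so the sum
converges to an **extremal stable law** S_{λ,1} with tail index
λ = min(−1/r, 2), and the level-ε significance threshold is

    Ψ_GCLT,r,K(ε) = [(a_{r,K} + b_{r,K} · F⁻¹_{λ,1}(1−ε)) / K]^{1/r},   r < 0,

with classical GCLT centering/scaling a, b (Normal(0,2) quantiles apply
for r > −1/2 and for the r > 0 branch). RRA supplies the worst-case
counterpart, linear in ε:

    Ψ_RRA,r,K(ε) = m(r,K) · ε,   m = ((r+1)/r)·K^{−(1+1/r)} (r < −1),
                                  1/log K (r = −1),  (r+1)^{−1/r} (r > −1).

The gap between the two families is the power/robustness trade-off: GCLT
thresholds assume independence but the heavy tails for r ≤ −1 confer real
robustness to dependence, while RRA thresholds are valid under arbitrary
dependence but cost so much power that Bonferroni usually wins. The
package also provides the closed-testing factors that extend any of these
tests to subsets of p-values at controlled strong-sense family-wise error
rate, and an equicorrelated Wishart-Multivariate-Gamma simulator (p-values
as χ²(v) tail probabilities of correlated likelihood-ratio deviances) for
power studies.

## Worked example

Eight p-values in `pvalues.txt` (one per line):

    0.0012 0.31 0.027 0.64 0.0041 0.17 0.88 0.052

Combine them with the harmonic mean p-value at ε = 0.05:

    $ gmpcomb combine --r -1 --eps 0.05 pvalues.txt
    {"method": "gclt", "r": -1.0, "K": 8, "eps": 0.05,
     "gmp": 0.00698500475630107, "psi": 0.04153145251724594, "reject": true}

The HMP of the eight tests is 0.0070, well below the GCLT threshold
0.0415, so the grand null (no test is significant) is rejected at the 5%
level. The worst-case (RRA) threshold is sterner but agrees here:

    $ gmpcomb threshold --method rra --r -1 --K 8 --eps 0.05
    {"method": "rra", "r": -1.0, "K": 8, "eps": 0.05, "psi": 0.024044917348149394}

Multilevel testing localizes the signal: the subset {1, 5} (the two
smallest p-values) is itself significant at strong-sense FWER 5%,

    $ gmpcomb multilevel --r -1 --eps 0.05 --subset 1,5 --small-eps pvalues.txt
    {"subset_size": 2, "K": 8, "r": -1.0, "eps": 0.05, "method": "gclt",
     "factor": 0.25, "subset_threshold": 0.0125,
     "subset_gmp": 0.0018566037735849058, "reject": true}

because the subset HMP 0.0019 falls below the deflated subset threshold
|ℜ|·ε/K = 2·0.05/8 = 0.0125.

The same operations are available as library calls
(`gmpcomb.compute_gmp`, `gmpcomb.gclt_threshold`, `gmpcomb.combine`,
`gmpcomb.multilevel_reject`, …), and `gmpcomb sweep` / `gmpcomb figures`
re-run the full power/false-positive-rate simulation study under
equicorrelated dependence.

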