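# Methods

`overlapfit` quantifies overlapping peptides in one peak cluster of a
singly charged, high-resolution MALDI-TOF spectrum. This note records the
model, the priors, the sampler, the simulation design, and the places where
the design was genuinely open and a choice had to be made.

## The model

A window is the full shape representation of one cluster: intensities
`y_j` at strictly increasing mass coordinates `x_j` (j = 1..N), with the
`x_j` treated as bin right-edges (bin j covers `(x_{j-1}, x_j]`, and
`x_0 = 0` for the first bin — for realistic windows the shape CDF at 0 is
numerically zero, so this convention is inert). Each of Q peptides
contributes an isotope envelope of L peaks:

    E(y_j) = Σ_q Σ_l  H_q · R_{l,q} · ψ(x_j; M_q + (l−1)·S),
    y_j ~ N(E(y_j), σ²)  independently,

where `M_q` is the monoisotopic mass, `H_q` the abundance (the height scale
of the monoisotopic peak), `R_{l,q}` the reference isotopic ratios
(`R_1 ≡ 1`), `S` the isotope spacing (shared by all peptides, ≈ 1.0015 Da),
and ψ a *bin mass*: the probability a peak-shape distribution assigns to
the bin. Two shapes are available behind one interface:

* **normal**, SD `σ_s` (Da);
* **asymmetric Laplace**, scale `σ_s` and skewness `κ ∈ (0,1)`; its CDF is
  `κ²/(1+κ²)·exp(−(√2/(σ_s κ))|x−c|)` left of the location and
  `1 − 1/(1+κ²)·exp(−(√2 κ/σ_s)|x−c|)` at or right of it. With κ < 1 the
  right tail is heavier, matching MALDI-TOF peak tailing. We treat the
  location parameter as the peak position and `σ_s` as the scale exactly as
  the CDF is written; `σ_s` equals the distribution's SD only at κ = 1.
  (The distribution's mean is slightly right of the location; we do not
  re-center.)

An optional constraint mode ties masses to a fixed offset,
`M_q = M_1 + k·(q−1)·S`. With k = 4 this is the ¹⁸O-labeling design: the
labeled partner carries two heavy oxygens, i.e. four isotope spacings.
Only `M_1` then remains a free mass parameter; the others track `M_1` and
`S` deterministically.

## Priors

**Masses.** Peptide monoisotopic masses cluster around near-integer values
(average spacing 1.000495 Da per nominal mass unit). Each candidate
cluster supplies a normal prior `M_q ~ N(η_g, σ_m²)`. When a candidate
mass list is given, clusters are built by splitting the sorted list at gaps
> 0.25 Da; η is the mode of the 0.01-Da histogram of the cluster (ties
broken toward the cluster median, η taken as the mean of the modal bin's
members), the per-cluster spread is max(left, right spread)/3, and all
clusters share the largest spread as σ_m. Without a candidate list the
fallback is one cluster per integer k·1.000495 inside the window with
σ_m = 0.1 Da. The underlying proteome-wide histogram is not shipped, so
these defaults are a stand-in for it.

**Isotopic ratios.** A fourth-order polynomial in `m/1000` predicts the
log consecutive ratios `log C_l` (l = 2..8) with residual variance `σ_l²`;
the coefficient table is shipped as a CSV resource
(`overlapfit/data/isotope_ratio_poly.csv`). Reference-ratio priors follow
by summation: `log R_l ~ N(Σ_{i≤l} μ_i, Σ_{i≤l} σ_i²)` for l ≥ 3. `R_2` is
*not* given its own prior. Instead the odds `(1−p_1)/p_1` get a log-normal
prior and `R_2 = odds − Σ_{l≥3} R_l` — the *virtual constraint*: inflating
the tail ratios shrinks R₂, so the envelope cannot be jointly
overestimated. Proposals implying `R_2 ≤ 0` are rejected.

The odds-prior location comes from a linear model `log p_1 = α + βm`. Its
coefficients are not tabulated anywhere we can ship, so the defaults are
computed *from the polynomial model itself*: a least-squares fit of
`log p_1(m)` over m = 400, 500, …, 4000 Da, where
`p_1(m) = 1/(1 + Σ_l exp(predicted mean log R_l))`; the residual variance
defaults to the largest `σ_l²` (0.0035). This keeps the two prior models
mutually consistent; both are flagged as package defaults, configurable.

The ratio- and odds-prior hyperparameters are evaluated once per candidate
model at the cluster center η_g and held fixed during sampling. They drift
by ~0.1% per Da of mass, so re-evaluating them at the current `M_q` would
couple the ratio priors into every mass move for no practical gain.

**Number of isotopic variants.** L defaults to the smallest l ≤ 8 whose
predicted `R_{l+1}` falls below 0.02 (the next peak would be negligible):
L = 5 near 1.5 kDa, L = 6 near 2 kDa. Configurable.

**Everything else** is weakly informative: `H_q ~ N(0, 1/τ) I(H_q ≥ 0)`
with `τ ~ Γ(0.001, 0.001)`; `σ⁻² ~ Γ(0.001, 0.001)`;
`σ_s ~ N(0, 10⁶) I(0 ≤ σ_s ≤ 0.5)` (isotopic peaks must not merge);
`S ~ N(1, 1/τ_s)` with `τ_s ~ Γ(0.001, 0.001) I(τ_s ≥ 1600)` (spacing
pinned near 1 Da, prior SD ≤ 0.025); `κ ~ U(0.01, 0.99)`. The gamma
constants are the standard "close to zero" choice. One τ is shared across
peptides (the abundance prior is a shared shrinkage scale, not a
per-peptide one). Extrapolating the ratio model below 400 or above
4000 Da warns instead of failing — the polynomial is smooth and border
cases are legitimate.

## Sampler

MH-within-Gibbs. Exact conditionals exist for:

* each `H_q`: normal (the mean is linear in `H_q`) truncated to [0, ∞),
  sampled by inverse CDF with an exponential-rejection fallback deep in
  the tail;
* `σ⁻² ~ Γ(α + N/2, β + SSR/2)`;
* `τ ~ Γ(α* + Q/2, β* + ΣH_q²/2)` (the half-normal normalizer is τ-free,
  so conjugacy survives the truncation of H);
* `τ_s ~ Γ(α** + ½, β** + (S−1)²/2)` truncated at 1600 via inverse CDF.

All other parameters move by Gaussian random walks: `M_q`, `S`, `σ_s`, `κ`
on the natural scale, the odds and tail ratios on the log scale with the
prior expressed in the sampled coordinate (so no separate Jacobian).
After any odds/tail move, `R_2` is recomputed from the virtual constraint;
violations, mass-ordering violations (`M_1 < … < M_Q` in unconstrained
mode — the standard label-switching fix; the ordering is enforced by
rejection) and box-constraint violations are rejected.

Defaults: 20,000 iterations, 5,000 burn-in, thinning 5. Proposal SDs:
mass 0.005 Da, S 0.0005, σ_s 0.002, κ 0.02, log-odds/log-ratio 0.05, all
Robbins–Monro-adapted toward 35% acceptance during burn-in only (step
`t^−0.6`), so the post-burn-in kernel is fixed. Runs are deterministic
given the seed.

**Initialization** is data-driven: a greedy matched filter correlates the
residual spectrum with a prior-median envelope template over a 0.02-Da grid
of candidate monoisotopic positions, subtracting each matched envelope in
turn, then refines the Q positions by coordinate descent with non-negative
least-squares abundances. (Initializing `M_1` at the maximum-intensity
coordinate fails for Q ≥ 2: the global maximum is usually an interior
isotope peak of the more abundant peptide, several Da from `M_1`, and a
0.005-Da random walk cannot travel there.) Abundances start at their NNLS
values, ratios at prior medians, S = 1.0015, σ_s = 0.075, κ = 0.85, σ²
from the NNLS residuals.

**Model fit summaries.** Deviance is −2× the Gaussian log-likelihood.
DIC = mean deviance + p_D with p_D = mean deviance − deviance at the
posterior mean; p_D can be negative for poorly identified models and is
retained as-is with a warning. BIC = deviance at the posterior mean +
k·log N, where k counts parameters entering the likelihood: Q abundances,
the free masses, S, σ_s, κ (asymmetric Laplace only), σ², and Q·(L−1)
ratio parameters; the hyperprior precisions τ, τ_s are excluded.

## Model averaging and model-size selection

One chain per candidate model; candidate g uses seed (master + g).
Weights `w_g ∝ exp(−ΔDIC_g/2)` with ΔDIC relative to the minimum (the Δ
form makes the weights invariant to constant shifts and numerically
stable). Point estimates are weighted means; the standard error is
`Σ_g w_g √(se_g² + (θ_g − θ̄)²)`, combining within-model spread and
between-model disagreement. The 95% intervals are the normal
approximation θ̄ ± 1.96·se (no formula is available for combining
per-candidate quantiles, so the normal approximation is used and
documented).

A candidate model assigns one cluster prior to each free peptide mass:
clusters within 0.6 Da of each greedy preliminary estimate are shortlisted
(nearest two), and their ordered combinations form the candidate set
(capped at four, nearest first). For well-separated envelopes this
typically collapses to a single candidate; for ambiguous windows it keeps
the competing mass assignments alive in the average.

The number of peptides, when unknown, is chosen by fitting Q over a range
and minimizing BIC; each Q's BIC is the minimum across its candidate
models, and each Q runs with seed (master + 1000·Q).

## The simulator

Two overlapping peptides with `M_2 = M_1 + shift + tilt` (integer and
fractional mass difference), base parameters `M_1 = 2000.90`,
`H_1 = 10000`, `σ = 10`, `σ_s = 0.08`, `S = 1.0015`, normal shape, i.i.d.
Gaussian noise. The catalog crosses 30 (shift, tilt, H₂/H₁, ratio-code)
combinations. Generation uses L = 8 isotopic variants, a 0.01-Da grid
(≥ 7 points per σ_s-wide peak flank), and a 1.0-Da window pad; grid
spacing, pad and generation-L are package choices, configurable. A
manifest records every generative parameter and seed; regeneration from a
manifest is bit-exact.

Ratio sets: **A** is the Poisson approximation
`R_l = λ^{l−1}/(l−1)!` with the published linear rate rule
`λ(m) = 0.000594·m − 0.03091` — an external default, not a quantity this
package estimates. **E1/E2** emulate peptides whose second isotopic
variant is extremely small/large for their mass. No tabulation of such
peptides is available, so they are *synthetic stand-ins* constructed from
the shipped population model: the second consecutive ratio at its −3σ/+3σ
population quantile, higher consecutive ratios at their population
medians. (A stand-in placed further out than ±3σ would describe a peptide
the modeled population does not contain, and under near-complete overlap
the resulting prior–truth conflict dominates the relative-abundance
estimate rather than probing separability.)

What the generator does **not** emulate: baseline drift, chemical noise,
detector saturation, isotope-spacing jitter, charge states above one, and
composition-specific isotopic fine structure. Passing tests therefore
demonstrate correct inference under the stated generative model, not
robustness to raw-spectrum artifacts — preprocessing (noise filtering,
cluster detection) is assumed done upstream.

## Desk-scale study sizes

The shipped experiments are scaled to a single CPU: parameter recovery on
setting 22 uses 10 replicates at 20k iterations; the separability grid
(shift 0; tilt 0.04/0.16/0.24; H₂/H₁ 0.2/5; E1/E2 ratio codes, following
the neighbouring catalog cells) uses 5 replicates per cell at 10k
iterations; BIC model-size selection uses 10 replicates of setting 26
fitted at Q = 2 and 3; the difficulty comparison uses 5 replicates each of
settings 3 and 30. A separability cell "passes" when at least 60% of its
replicates recover H₂/H₁ within 20% of truth with the 95% interval
excluding zero. In the misspecified Q = 3 fit, the spurious peptide is
identified by matching the two true masses to the nearest fitted masses
and taking the one left over.

## Numerical choices

* Peak CDFs are evaluated only within ±10 σ_s of each normal peak (omitted
  tail mass ~1e-23); the asymmetric Laplace, whose tails decay more
  slowly, is always evaluated densely.
* The chain caches per-peptide bin-mass matrices and basis columns, so a
  ratio move is a rank-one recombination; an explicit test verifies the
  incremental mean/SSR bookkeeping against a full recompute.
* Degenerate inputs: an all-zero window is allowed (abundances collapse,
  the posterior reverts to the priors); an all-zero basis column skips the
  H update with a warning; a window missing all peak support warns.
* Ties and bounds: σ_s is kept in (0, 0.5], κ in [0.01, 0.99] by proposal
  rejection; the truncated-gamma inverse CDF guards against the bound's
  CDF mass reaching 1.

## Known limitations

* The mass-cluster and isotopic-ratio priors are population models for
  tryptic peptides (400–4000 Da); glycopeptides or labeled species with
  unusual elemental composition violate them.
* The normal-approximation averaged intervals can miss truth when the
  posterior is sharp and the generative pattern sits several population
  SDs from the prior (deliberately the case for the E1/E2 extremes): the
  ratio priors then shrink the fitted ratios noticeably and the relative
  abundance compensates. This is visible as interval under-coverage in
  the hardest overlap cells and is inherent to informative priors, not a
  sampler defect.
* Doubly charged spectra and multi-window joint fits are out of scope.
* DIC weights are computed from single chains; no between-chain
  convergence diagnostic beyond acceptance rates is built in (chains are
  short-memory here because initialization is data-driven).
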