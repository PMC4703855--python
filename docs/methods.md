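# Methods

## The model

A mutualistic community of `A` animal and `P` plant species (`S = A + P`) is
described by a binary bipartite incidence matrix `B` (animals × plants).
Interaction weights follow a degree–strength trade-off,

    W_ij = γ0 · B_ij / k_i^δ   (i ≠ j),      W_ii = −d_i,

where `k_i` is the number of mutualistic partners of the focal species `i`,
`γ0 > 0` the basal mutualistic strength and `δ` the trade-off exponent.
Three scenarios are of interest: the mean-field case `δ = 0` (constant
interaction strength), `δ = 0.5` (specialists interact more strongly per
link) and `δ = −0.5` (generalists interact more strongly).  The species
strength `s_i = Σ_{j≠i} W_ij` is the weighted degree; for `δ = 0` it equals
`γ0 k_i` exactly.

Linearizing Holling Type I population dynamics at the stationary state `x*`
gives the community matrix

    Φ = diag(x*) · W,

a Metzler matrix (nonnegative off-diagonal, negative diagonal `−x*_i d_i`),
so the Perron–Frobenius theorem applies: the leading eigenvalue `λ1` is real
and its right/left eigenvectors `v1`/`u1` can be chosen entrywise
nonnegative.  Stationary abundances are i.i.d. Gamma with mean 1.

A pulse perturbation `ξ` applied at `t = 0` evolves as
`d(δx)/dt = Φ δx`, i.e.

    δx(t) = Σ_α A_α e^(λ_α t) v_α,      A_α = (u_α · ξ)/(u_α · v_α),

with unit-norm eigenvectors.  `λ1` sets the asymptotic recovery rate
(resilience); `A1 = |A_1|` the asymptotic amplitude; the reactivity
`λ_H = λ_max((Φ + Φᵀ)/2) ≥ λ1` the worst-case instantaneous growth rate —
`λ1 < 0 < λ_H` is the stable-but-reactive regime in which perturbations grow
transiently before decaying.

Localization of a unit vector `q` is measured by the inverse participation
ratio `IPR(q) = Σ_i q_i⁴ ∈ [1/S, 1]` (1/S: extended/uniform; 1: a single
species).  Whether a *network* is localized is decided against randomized
ensembles: NM1 re-assigns the `L` links uniformly subject to connectivity;
NM2 re-assigns links while conserving every species degree (checkerboard
swaps).  The relative IPR, `rIPR = IPR/⟨IPR_ran⟩`, with a one-sided
empirical p-value, classifies a network as localized when `rIPR > 1` and
`p < 0.05`; the relative amplitude `A1/⟨A1_ran⟩ < 1` with `p < 0.05`
declares attenuation.  Each null realization re-randomizes the topology,
redraws `x*` and (for amplitude statistics) redraws the perturbation.

## Parameters, units and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `gamma0` | basal mutualistic strength (per-capita rate) | 1.0 | the reference scenario of the analysis |
| `delta` | degree trade-off exponent (dimensionless) | 0.0 | mean-field baseline; 0.5 used in the heterogeneity studies |
| `d` | intraspecific competition (per-capita rate) | 3.5 | places the default synthetic corpus (power-law, S ≈ 100, δ = 0.5, γ0 = 1) in the stable regime, λ1 < 0 for most abundance draws; localization and amplitude *ratios* are insensitive to it |
| `abundance_mean` | ⟨x*⟩ | 1.0 | the standing convention for this parametrization |
| `abundance_sd` | sd of x* | 0.15 | coefficient of variation of a Gamma with shape 40 (1/√40 ≈ 0.158), the shape used in published Holling Type I parametrizations of this model family; larger spreads make Gamma diagonal disorder, not topology, the dominant localizer |
| `zeta` | perturbation noise sd | 0.1 | small relative noise around the unit mean |
| `n` (null ensembles) | realizations | 1000 | the standard ensemble size; tests and demos scale it down |
| `theta` | localization threshold | 1/√S | the component value of the fully extended eigenvector |

A note on the abundance Gamma: published tables for this model family quote
shape `a = 40`, scale `b = 0.05`, whose mean is `a·b = 2` — inconsistent
with ⟨x*⟩ = 1.  The package therefore exposes mean and sd directly
(moment-matched to shape/scale) and adopts mean 1 with the shape-40
coefficient of variation.

## Perturbation types

`ξ_D` is species-independent demographic noise, i.i.d. Normal(1, ζ²).
`ξ_E` is degree-proportional (environmental) noise: `ξ_E(i) = (k_i/k_max)·η(i)`
with `η` a second Normal(1, ζ²) draw (a flag reuses the ξ_D draw instead).
Only proportionality to `k_i` is structurally determined; the normalization
is a design choice.  We scale by the maximum degree so that the
degree-dependent component is bounded by the demographic component's scale
on any topology (and coincides with it on a regular graph).  Normalizing by
the *mean* degree instead makes ξ_E inject, on heterogeneous topologies, a
hub-concentrated component several times ξ_D, which reverses the relative
amplitude against connectivity-only nulls and makes it grow with S — the
opposite of the attenuation behaviour this framework is built to quantify.
`ξ_all = ξ_D + ξ_E` is the default perturbation of the amplitude analyses.

## Synthetic networks

The generator emulates three topology families:

- `connected_random_bipartite`: a uniform random spanning structure (each
  species attached to a random earlier species of the opposite guild)
  guarantees connectivity; the remaining links are uniform over unused
  animal–plant pairs.  This is also the NM1 sampler.
- `powerlaw_bipartite`: animal degrees i.i.d. from `P(k) ∝ k^(−ε)` truncated
  at `k = P`; plants get one guaranteed stub plus a uniform multinomial
  share; stub matching with incremental multi-edge repair and
  degree-preserving cross-component swaps yields a simple connected graph.
- `biregular_bipartite`: every animal degree `dA`, every plant `A·dA/P` —
  the homogeneous control.

Synthetic corpora in the tests use exponent 1.5 with `A = 0.6 S`, which at
`S ≈ 100` yields `L ≈ 300` and hub degrees of 30–40 — the density and
core–periphery regime of mid-size empirical pollination webs, whose fitted
truncated power laws have exponents around 1.1–1.8.  What the generator does
*not* emulate: nestedness beyond what a heavy-tailed degree sequence
induces, guild asymmetries in degree distribution shape, and sampling
artefacts of field data.  Passing the census tests therefore shows that
degree heterogeneity alone reproduces the localization/attenuation
phenomenology; it does not validate conclusions about any particular
empirical web.

## Numerical choices

- Eigen-decompositions use dense LAPACK routines; eigenvalues are sorted by
  descending real part (ties: descending imaginary part, then index).
- Perron eigenvectors are L2-normalized and sign-fixed entrywise
  nonnegative (general eigenvectors: largest-magnitude component positive);
  `u1·v1 > 0` is enforced.  `λ1` must be real to within
  `1e-8·max(1, |λ1|)`; violation raises, as it signals non-Metzler input.
- A leading-eigenvalue gap below `1e-10` triggers a degeneracy warning.
- Mode amplitudes use the rows of `V⁻¹` (left eigenvectors normalized to
  `u_α·v_β = δ_αβ`); an eigenvector-matrix condition number above `1e10`
  (near-defective Φ) raises in amplitude computations and falls back to the
  matrix exponential in propagation.
- Complex conjugate mode pairs are recombined; an imaginary residue above
  `1e-8` (relative) in a trajectory raises.
- NM2 runs 10·L accepted checkerboard swaps (override available); if no
  swap exists (e.g. complete bipartite graph) the input is returned with a
  warning.  Connectivity of NM2 draws is *not* enforced by default — the
  degree-sequence constraint is the defining one — with a
  `require_connected` flag for rejection sampling.
- Empirical p-values use the (r+1)/(n+1) estimator, so they are never zero
  and the localized/attenuated classification (`ratio ≷ 1`, `p < 0.05`)
  is well defined at any ensemble size.
- Per-network seeds in corpus runs derive from the corpus seed via
  `SeedSequence`; identical seeds give bit-identical records.

## Problem sizes used in the shipped analyses

The test-suite census uses 20 power-law networks of S = 100 with 200 null
realizations per model, three biregular controls, and a size ladder
S = 20…200 at 100 realizations for the correlation signs; the acceptance
script uses 10 power-law networks (A = 60, P = 40, exponent 2.2) with 200
degree-preserving randomizations each.  These sizes resolve the
localization/attenuation contrasts cleanly while keeping a full run in
minutes on one core.

## Known limitations

- The framework analyses the linearization only; no nonlinear Holling
  simulations, and no estimation of γ0/δ from data.
- NM1 sampling is uniform over connected graphs only approximately
  (spanning-structure seeding biases degree sequences slightly).
- IPR-based localization is basis-dependent by construction and assumes
  unit-L2 eigenvectors; alternative localization measures (participation
  entropy, pseudospectra) are out of scope.
- For near-tree networks (L close to S−1) the abundance disorder dominates
  eigenvector structure and null-ensemble IPRs become heavy-tailed; ratios
  remain well defined but need larger ensembles for tight p-values.
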