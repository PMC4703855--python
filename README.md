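# ecoloc

Eigenvector localization and perturbation analysis of mutualistic
ecological networks.

## The problem

Plant–pollinator communities are bipartite networks of beneficial
interactions.  Classical stability analysis summarizes their response to
perturbation with a single number — the leading eigenvalue λ1 of the
community matrix — which only gives the asymptotic recovery rate.  Two
things it misses: perturbations can grow substantially *before* decaying
(reactivity), and the *distribution* of the impact across species is set by
the leading eigenvectors.  If those eigenvectors are **localized** —
concentrated on a few species — a perturbation is asymptotically absorbed
by few species at reduced amplitude.  `ecoloc` quantifies this for
empirical or synthetic bipartite webs, for ecologists and network
scientists studying the stability–architecture relationship.

## The machinery

From a binary incidence matrix `B` (A animals × P plants, S = A + P):

- weights `W_ij = γ0 B_ij / k_i^δ`, `W_ii = −d_i` (δ is the interaction
  strength–degree trade-off; species strength `s_i = Σ_j W_ij`);
- community matrix `Φ = diag(x*) W` with Gamma-distributed stationary
  abundances `x*` (mean 1) — the Jacobian of Holling Type I dynamics;
- spectrum: resilience `λ1`, right/left Perron eigenvectors `v1`/`u1`,
  reactivity `λ_H = λ_max((Φ+Φᵀ)/2) ≥ λ1`;
- localization: `IPR(q) = Σ_i q_i⁴ ∈ [1/S, 1]` of the unit eigenvectors,
  compared to null ensembles as `rIPR = IPR/⟨IPR_ran⟩` — NM1 randomizes
  links keeping connectivity, NM2 additionally conserves every species
  degree (checkerboard swaps);
- perturbations: `δx(t) = Σ_α A_α e^(λ_α t) v_α` with
  `A_α = (u_α·ξ)/(u_α·v_α)`; the leading amplitude `A1` versus its null
  ensemble measures attenuation.  Perturbation kinds: demographic
  `ξ_D ~ N(1, ζ²)`, degree-proportional `ξ_E ∝ k_i`, and `ξ_all = ξ_D+ξ_E`.

A network is *localized* when `rIPR > 1` with empirical `p < 0.05`, and
shows *attenuation* when `A1/⟨A1_ran⟩ < 1` with `p < 0.05`.

## Worked example

```sh
python examples/02_null_model_localization.py
```

```
NM1: rIPR[v1] = 1.476 (observed 0.0185 vs null 0.0125 +- 0.0005), p = 0.005 -> LOCALIZED
NM2: rIPR[v1] = 1.001 (observed 0.0185 vs null 0.0184 +- 0.0003), p = 0.428 -> not localized
```

A synthetic power-law pollination web (S = 100, δ = 0.5, γ0 = 1) is
significantly more localized than random connected webs of equal size and
connectance (rIPR ≈ 1.5, p < 0.05) — but indistinguishable from webs with
the *same degree sequence* (rIPR ≈ 1): the localization is carried by the
degree heterogeneity.  `examples/03_perturbation_propagation.py` then shows
the flip side — the leading perturbation amplitude of the heterogeneous web
is attenuated (A1/⟨A1_NM1⟩ ≈ 0.72, p < 0.05) relative to the same nulls.
Other examples cover the spectrum/localization report and a corpus-level
census with topology–localization Spearman correlations.

A thin CLI mirrors the library:

```sh
ecoloc generate --family powerlaw -A 60 -P 40 --exponent 1.5 --seed 0 -o net.tsv
ecoloc nullmodel net.tsv --model NM2 --stat ipr_v1 --n 1000 --delta 0.5 --seed 11
ecoloc perturb net.tsv --kind all --model NM1 --n 1000 --delta 0.5 --seed 11
```

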