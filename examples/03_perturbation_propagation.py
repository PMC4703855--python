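"""Propagate a pulse perturbation through the linearized dynamics: transient
reactive growth, asymptotic decay, and the attenuation of the leading
amplitude relative to randomized topologies."""

import numpy as np

from ecoloc import (
    GeneratorSpec,
    ParamConfig,
    leading_modes,
    make_perturbation,
    parametrize,
    powerlaw_bipartite,
    propagate,
    relative_amplitude,
)

net = powerlaw_bipartite(
    GeneratorSpec(A=60, P=40, family="powerlaw", exponent=1.5, seed=0)
)
cfg = ParamConfig(gamma0=1.0, delta=0.5, seed=1)
_, Phi = parametrize(net, cfg)
s = leading_modes(Phi)

xi = make_perturbation("all", net.S, degrees=net.degrees(), zeta=0.1, seed=2)
res = propagate(Phi, xi.xi)
print(f"leading amplitude A1 = {res.A1:.2f}")
print(f"initial growth rate = {res.initial_growth_rate:.3f} "
      f"(reactivity bound lambdaH = {s.lambdaH:.3f})")
print(f"envelope |dx(t)|/|xi|: max = {res.envelope.max():.3f}, "
      f"final = {res.envelope[-1]:.2e} at t = {res.t_grid[-1]:.1f}")

rel = relative_amplitude(net, cfg, kind="all", model="NM1", n=200, seed=12)
verdict = "ATTENUATED" if rel.significant else "not attenuated"
print(f"\nA1 / <A1_NM1> = {rel.ratio:.3f}, p = {rel.p_value:.3f} -> {verdict}")
print("A ratio below 1 means the localized topology absorbs the asymptotic")
print("perturbation into fewer species at lower amplitude than random webs.")
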