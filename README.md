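# pollinet

Eco-evolutionary simulation of collapse, hysteresis and revival in
mutualistic plant–pollinator networks.

Mutualistic communities can tip abruptly from a high-functioning state to
a collapsed one as environmental conditions degrade, and — because the
positive feedbacks that sustain them create alternative stable states —
restoring the environment often fails to restore the community
(hysteresis). `pollinet` is for theoretical and restoration ecologists
who want to simulate these dynamics on empirical web-of-life incidence
matrices or controlled synthetic networks, locate tipping points, and
test an alternative intervention: reviving a collapsed network by
positively forcing a single well-connected species and letting the
perturbation propagate through the web.

## Model

Each species *i* (plant or pollinator) carries a density *Nᵢ* and a mean
phenotype *uᵢ*; individual phenotypes are Normal(*uᵢ*, σᵢ²) with fixed
variance. Densities follow the trait-averaged growth rate

```
dNᵢ/dt = Nᵢ ⟨ rᵢ(z) ⟩,
rᵢ(z)  = b − Σⱼ αᵢⱼ Nⱼ + Σₖ Aᵢₖ Nₖ ⟨ γ(z, z′) / (1 + H γ(z, z′) Nₖ) ⟩_z′
```

where `A` is the 0/1 incidence matrix, competition `α` acts within a
guild (αᵢᵢ = 1 ≫ αᵢⱼ), and the mutualistic benefit saturates with
partner density through a type-II functional response with handling time
*H*. Benefit depends on trait matching through a Gaussian kernel with a
degree trade-off,

```
γ(z, z′) = (γ₀ / dᵢ) · exp( −(z − z′)² / ω² ),
```

so generalists gain less per partner. Mean traits evolve by the
selection differential, `duᵢ/dt = h² ⟨ (z − uᵢ) rᵢ(z) ⟩`. The average
mutualistic strength γ₀ is the environmental-state parameter: sweeping
it down collapses the network; sweeping it back up reveals hysteresis.
Trait expectations are evaluated by Gauss–Hermite quadrature (the H = 0
closed form is kept as an accuracy oracle), and the coupled ODEs are
integrated with LSODA.

Modules:

- `pollinet.networks` — web-of-life CSV reader, connectance, NODF,
  weighted NODF, bipartite modularity, betweenness, target selection;
- `pollinet.dynamics` — the eco-evolutionary core and integrator;
- `pollinet.experiments` — quasi-static collapse/hysteresis sweeps,
  single-species revival forcing, phase diagrams;
- `pollinet.analysis` — indirect-effect matrix series, quasibinomial
  GLM (hand-rolled IRLS) and OLS for structure–recovery relations,
  restoration-survey visitation summaries;
- `pollinet.synthdata` — synthetic nested networks at exact connectance
  with tunable NODF, Table-style parameter draws, and synthetic
  restoration visitation tables with planted effects.

## Worked example: reviving a collapsed 49-species network

```python
from pollinet import (NetworkSpec, generate_nested_network, sample_params,
                      nodf, connectance, revive)

spec = NetworkSpec(n_plants=21, n_animals=28, connectance=0.17,
                   nodf_target=0.32, seed=42)
net = generate_nested_network(spec, on_infeasible="best")
print(f"network: {net.n_species} species, C = {connectance(net):.2f}, "
      f"NODF = {nodf(net):.2f}")

params = sample_params(net, seed=42, sigma="high", gamma0=1.15,
                       quadrature_nodes=7)
forced = revive(net, params, strategy="highest_degree", nu=0.5, T=500, seed=3)
print(f"forced species degree: {net.degrees[forced.forced[0]]}")
print(f"recovery richness with forcing: {forced.recovery_richness:.2f}")
print(f"mean biomass after forcing stops: {forced.mean_biomass:.2f}")

baseline = revive(net, params, nu=0.0, T=500, seed=3)
print(f"recovery richness without forcing: {baseline.recovery_richness:.2f}")
```

prints

```
network: 49 species, C = 0.17, NODF = 0.32
forced species degree: 28
recovery richness with forcing: 1.00
mean biomass after forcing stops: 1.79
recovery richness without forcing: 0.00
```

γ₀ = 1.15 lies inside the collapse regime, so the unforced community
stays at its collapsed state (recovery richness 0: no unforced species
ever reaches the recovery density 0.5). Forcing the most-connected
species at rate ν = 0.5 for 500 time units pushes its density up, spreads
the perturbation through the nested web, and gives trait evolution at
high trait variation (σ = 0.02) time to re-match partners — after the
forcing is removed every other species ends above density 0.5 (recovery
richness 1.0).

A command-line interface mirrors the main protocols:

```
pollinet generate-net --plants 15 --animals 15 --connectance 0.42 --nodf 0.6 --out net.csv
pollinet metrics net.csv --out metrics.csv
pollinet sweep-collapse net.csv --sigma low --out collapse.csv
pollinet revive --synthetic 21 28 0.17 0.32 --gamma0 1.15 --nu 0.5 --out traj.csv
```

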