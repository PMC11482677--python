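# Methods

## Model

The community is a bipartite mutualistic network of S_P plants and S_A
pollinators whose structure is fixed by a 0/1 incidence matrix A. Each
species i has a density N_i and a mean phenotype u_i; individual
phenotypes are normally distributed around u_i with a fixed, non-evolving
standard deviation sigma_i (a quantitative-genetics approximation: the
trait distribution stays Gaussian, selection moves only the mean).

Density dynamics integrate the phenotype-resolved growth rate over the
trait distribution:

    dN_i/dt = N_i <r_i(z)>
    r_i(z)  = b - sum_j alpha_ij N_j
              + sum_k A_ik N_k <gamma(z, z') / (1 + H gamma(z, z') N_k)>_z'

with b the intrinsic growth rate (0 by default: obligate mutualists),
alpha the competition matrix (alpha_ii = 1; within-guild alpha_ij drawn
from U[0.0001, 0.001]; no competition between guilds), H the handling
time of a type-II functional response, and

    gamma(z, z') = (gamma0 / d_i) exp(-(z - z')^2 / omega^2)

the trait-matching kernel, where d_i is the focal species' degree (the
trade-off keeps total mutualistic input from scaling with partner
count) and gamma0 the average mutualistic strength — the environmental
parameter all experiments sweep or fix. Mean traits evolve by the
selection differential

    du_i/dt = h^2 <(z - u_i) r_i(z)>,

which is proportional to sigma_i^2 times the local fitness gradient;
competition drops out of the gradient because it is trait-independent.

An optional right-skewed kernel, 10 * GammaPDF((z - z')/W + 10; shape
4.5, rate 0.5) with W = 0.1, is provided for robustness checks; its peak
is about 0.81 (vs 1 for the Gaussian) and sits at a trait offset of
-0.3, so matched-trait pairs gain less and revival becomes harder, which
is the documented qualitative contrast.

### Parameters (defaults)

| symbol  | meaning                                | default |
|---------|----------------------------------------|---------|
| b       | intrinsic growth rate                  | 0       |
| H       | handling time (type-II saturation)     | 0.25    |
| gamma0  | average mutualistic strength           | swept   |
| omega   | kernel width (trait units)             | 0.35    |
| h²      | broad-sense heritability               | 0.4     |
| sigma_i | trait standard deviation               | 0.005 ("low") / 0.02 ("high") |
| alpha_ij| within-guild competition               | U[0.0001, 0.001], alpha_ii = 1 |

Initial mean traits are drawn from U[-0.5, 0.5] unless stated otherwise.

## Numerics

The double trait expectation of the type-II term has no closed form, so
it is evaluated by fixed-order Gauss-Hermite quadrature over both trait
distributions (default 21 nodes per dimension). At H = 0 the expectation
has the closed form (gamma0/d_i) sqrt(omega^2/(omega^2 + 2 s^2))
exp(-(u_i - u_k)^2/(omega^2 + 2 s^2)) with s^2 = sigma_i^2 + sigma_k^2,
which serves as the accuracy oracle. Because the study's trait standard
deviations (<= 0.02) are far below the kernel width (0.35), the
integrand is effectively a low-order polynomial over the trait
distribution and 7 nodes already agree with the closed form to ~1e-10;
the simulation experiments and the acceptance script therefore run with
7 nodes. A cheaper mean-field option (kernel at the trait means inside
the type-II denominator only) is available behind a flag and tracks the
full quadrature to a few percent at these variances.

Integration uses scipy's LSODA at rtol 1e-6 / atol 1e-9. An explicit
Runge-Kutta pair was tried first but becomes stability-limited near the
high-density equilibrium (the Jacobian's stiffest direction is the
self-limitation of abundant species), taking ~7x more right-hand-side
evaluations for the same accuracy; LSODA switches to a stiff method
there. Densities are clamped at zero inside the right-hand side and on
the sampled output (negative excursions are integration noise near the
collapsed state; N = 0 is an exact invariant of the model). States are
sampled on a unit time grid; "the last 100 samples" of a 10^3-unit run
means t in [901, 1000]. Forcing a species adds nu * N_j (multiplicative)
or a constant nu_C to its density equation for t < T; the integration is
split at T so the discontinuity never sits inside a solver step.

## Experimental protocols

Collapse sweep (forward branch): gamma0 steps down 5.0, 4.85, ..., 0.05.
The sweep is quasi-static: the first step starts from the intact state
(all N_i = 1, traits U[-0.5, 0.5]) and each subsequent step continues
from the previous step's final state, integrating 10^3 time units per
step. This continuation is essential: it lets traits adapt while the
community is still dense, and it is what makes the forward and backward
branches path-dependent. (An independent-runs variant, fresh initial
conditions per step, is kept behind mode="independent"; it shows no
hysteresis because each segment re-randomizes the trait configuration.)
Species count as collapsed below density 0.05; a network's collapse
threshold is the largest gamma0 whose richness is below 90% (or,
configurably, 80%) of the initial richness.

Hysteresis sweep (backward branch): same grid ascending, starting from a
collapsed state (N_i ~ U[0, 0.005]) with fresh traits and sigma = 0.005,
again carrying the state between steps. A network shows strong
hysteresis when no grid point up to gamma0 = 4.85 reaches full recovery
(every species above 0.5).

Revival: from a collapsed state (N_i ~ U[0, 0.005]) at a gamma0 inside
the collapse regime, one species (or a few) is positively forced for a
duration T (default 500) out of t_end = 10^3, i.e. the community is
observed for 500 unforced units after the forcing stops. Initial mean
traits are the quasi-equilibrium traits: the final traits of a separate
run at gamma0 = 4 (outside the collapse regime) from N_i = 1 — they
represent partners that had adapted to one another before the collapse,
and they are computed under the same parameter set as the revival run
(so a low-variation or no-evolution condition carries its own, less
converged, trait history). Recovery richness is the fraction of
non-forced species whose final density exceeds 0.5 (a variant including
the forced species is provided). Targets are chosen by degree (highest
or lowest), by betweenness centrality (top k, default 3), or uniformly
at random with a seed; degree ties break to the lowest index with plants
ordered before animals. Phase diagrams repeat the revival protocol over
a grid of (nu | nu_C | T) x gamma0.

All stochastic draws in a protocol (competition coefficients, initial
traits and densities, random targets) flow from a single per-run seed
via numpy SeedSequence spawning.

## Network metrics

Connectance defaults to L/(S_P * S_A); the L/(S_P + S_A)^2 convention is
available as an option (the two appear interchangeably in the
literature, and the bipartite product is the one consistent with the
printed values of typical plant-pollinator webs — e.g. a 34-species web
with C = 0.15). NODF is the paired-overlap metric with the
decreasing-fill condition, averaged over row and column pairs, reported
on a 0-1 scale; the weighted variant counts cells where the lower-fill
vector has strictly smaller positive weights and falls back to binary
NODF (with a warning) on unweighted matrices. Modularity is Newman
modularity of a seeded Louvain partition of the bipartite graph;
betweenness is normalized shortest-path betweenness. Indirect effects
summarize the signed per-capita interaction matrix M (trait-averaged
mutualistic strengths, optionally damped by the type-II factor at
current densities; -alpha within guilds): beta3 is the mean entry of
M^3 and beta the mean of sum_{k>=2} M^k = (I - M)^-1 - I - M, defined
only when the spectral radius of M is below 1. The exact assembly of M
is configurable because the convention (with or without the saturation
factor) is a modelling choice; the default includes it.

Regressions are implemented explicitly so their behaviour is pinned by
this package's tests rather than a statistics library's defaults: OLS by
the normal equations, and the quasibinomial GLM (logit link) by
iteratively reweighted least squares with dispersion estimated from the
Pearson chi-square; both reproduce statsmodels to machine precision on
clean data (checked in the tests, where statsmodels serves as the
independent oracle). A degenerate response (zero Pearson dispersion,
e.g. a constant) falls back to the unscaled binomial fit with a warning.

## Synthetic data

The network generator produces 0/1 matrices at an exactly fixed link
count. It starts from a left-packed perfectly nested matrix — choosing
between a strict staircase (maximal nestedness; exactly NODF 1 when the
link budget admits strictly decreasing fills on both axes) and a
geometric-decay fill profile (graded, skewed degree distributions like
empirical webs, rather than a degenerate "full hubs plus singletons"
shape) according to which is closer to the NODF target — and then
relocates single links (never emptying a row or column), accepting moves
that bring NODF closer to the target, until within tolerance (default
0.02, max 10^5 proposals). Infeasible targets either raise (reporting
the best achieved NODF) or return the closest matrix found.

The visitation generator emulates a two-treatment restoration survey
(restored/unrestored x 8 months x 8 plots; ~1 ha plots): each plot-month
is a small bipartite visit-count network whose nestedness varies across
plots, with the mean per-pollinator visit total planted as
intercept_treatment + slope * NODF + noise (restored intercept above
unrestored, default slope 12) and counts drawn from a gamma-Poisson
mixture so downstream quasibinomial/OLS stages see realistic
overdispersion. Every structural link receives at least one visit, so
the realized binary network equals the planted one. The planted truth is
returned alongside the table for parameter-recovery tests. The generator
emulates the design and effect structure of such surveys, not any real
species composition, spatial layout, or the empirical degree
distributions of particular webs — passing tests show the analysis
stages recover known effects under the model's own assumptions, not that
they would be unbiased on field data.

## Study conditions and problem sizes

The packaged experiments and the acceptance script run at desk scale,
as the package's own standard conditions: a 10-network ensemble of
30-species networks (15 x 15) at connectance 0.42 with NODF targets
spanning 0.3-1 for the sweep experiments; a 49-species nested fixture
(21 x 28, C = 0.17, NODF 0.32) for the revival contrasts; 4 x 4
(nu x gamma0) grids with 3 seeds for the trait-variation comparison.
On these conditions the ensemble's collapse thresholds all fall at
gamma0 = 0.95, inside the 0.5-1.5 collapse regime, and the hysteresis
loop is wide: the backward branch stays collapsed up to gamma0 ~ 3.7-4.5
while the forward branch is intact down to ~0.95.

## Known limitations

- On the 30-species dense ensemble the backward branch does recover near
  the top of the gamma0 grid (~4.3-4.7): at gamma0 = 4.85 the collapsed
  state has positive net growth (gamma0 times the mean kernel overlap of
  random traits exceeds the per-capita losses), so full-grid
  non-recovery ("strong hysteresis") is not a property of these study
  conditions under this model; the hysteresis that matters for
  restoration — a wide bistable window where restoring gamma0 does not
  restore the community — is present and tested.
- With high trait variation, the gamma0 = 4 trait-equilibration run
  converges partner traits tightly; the collapsed state at gamma0 ~ 1.15
  is then only marginally stable, and forcing any moderately connected
  (degree >= 2) species can trigger a full cascade. The
  specialist-forcing control therefore uses the minimum-degree species.
- Trait variances are fixed (no drift, no evolving variance), the
  incidence matrix never rewires, and there is no dispersal or spatial
  structure.
- Sweep summaries at collapsed densities are sensitive to the decay
  history across segments; comparisons between branches are meaningful
  at biomass scale, not at the ~1e-3 collapsed-density scale.
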