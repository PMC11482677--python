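"""Collapse sweeps, hysteresis sweeps and single-species revival protocols.

All protocols run one independent integration per grid point (fresh
initial conditions, not continuation runs), summarize the last 100 time
samples, and flow every stochastic draw (initial traits, initial
densities, random targets) from a single per-sweep seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    CommunityState,
    ForcingSpec,
    IntegrationError,
    ModelParams,
    Trajectory,
    quasi_equilibrium_traits,
    simulate,
)
from .networks import BipartiteNetwork, select_targets

__all__ = [
    "SweepResult",
    "PhaseDiagram",
    "ReviveResult",
    "collapse_grid",
    "hysteresis_grid",
    "collapse_sweep",
    "hysteresis_sweep",
    "collapse_threshold",
    "strong_hysteresis",
    "revive",
    "phase_diagram",
]

#: density below which a species counts as collapsed
COLLAPSE_DENSITY = 0.05
#: density a species must reach to count as recovered
RECOVERY_DENSITY = 0.5


def collapse_grid(start: float = 5.0, stop: float = 0.0, step: float = 0.15):
    """Descending gamma0 grid 5.0, 4.85, ..., 0.05."""
    vals = np.arange(start, stop - 1e-9, -step)
    return np.round(vals[vals > stop + 1e-9], 10)


def hysteresis_grid(start: float = 0.0, stop: float = 5.0, step: float = 0.15):
    """Ascending mirror of the collapse grid: 0.05, ..., 4.85, 5.0."""
    return collapse_grid(stop, start, step)[::-1].copy()


@dataclass
class SweepResult:
    """Per-gamma0 equilibrium summaries from one sweep."""

    gamma0: np.ndarray
    richness: np.ndarray            # count of species with final N > collapse threshold
    recovered_fraction: np.ndarray  # fraction with final N > recovery threshold
    total_biomass: np.ndarray       # mean over the last 100 samples of sum(N)
    mean_biomass: np.ndarray
    mean_pollinator_density: np.ndarray
    final_N: np.ndarray             # (n_gamma, S)
    n_species: int
    errors: dict = field(default_factory=dict)
    protocol: str = ""
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gamma0": self.gamma0,
                "richness": self.richness,
                "recovered_fraction": self.recovered_fraction,
                "total_biomass": self.total_biomass,
                "mean_biomass": self.mean_biomass,
                "mean_pollinator_density": self.mean_pollinator_density,
            }
        )


@dataclass
class ReviveResult:
    """Outcome of one revival (forcing) run."""

    trajectory: Trajectory
    forced: list[int]
    recovery_richness: float
    recovery_richness_all: float  # variant counting the forced species too
    mean_biomass: float
    total_biomass: float
    seed: int | None = None


@dataclass
class PhaseDiagram:
    """Recovery richness over an (axis x gamma0) grid."""

    axis_name: str
    axis_values: np.ndarray
    gamma0: np.ndarray
    recovery: np.ndarray  # (len(axis_values), len(gamma0))
    errors: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, a in enumerate(self.axis_values):
            for j, g in enumerate(self.gamma0):
                recs.append(
                    {self.axis_name: a, "gamma0": g, "recovery": self.recovery[i, j]}
                )
        return pd.DataFrame(recs)


def _summarize(traj: Trajectory, n_plants: int, window: int = 100):
    Nw = traj.N[-window:]
    final = traj.N[-1]
    return {
        "richness": int(np.sum(final > COLLAPSE_DENSITY)),
        "recovered_fraction": float(np.mean(final > RECOVERY_DENSITY)),
        "total_biomass": float(Nw.sum(axis=1).mean()),
        "mean_biomass": float(Nw.mean()),
        "mean_pollinator_density": float(Nw[:, n_plants:].mean()),
        "final_N": final,
    }


def _run_sweep(
    net: BipartiteNetwork,
    p: ModelParams,
    grid: np.ndarray,
    seed: int,
    t_end: float,
    trait_range: float,
    density_init: str,
    protocol: str,
    mode: str = "continuation",
) -> SweepResult:
    S = net.n_species
    children = np.random.SeedSequence(seed).spawn(len(grid) + 1)
    out = {k: [] for k in (
        "richness", "recovered_fraction", "total_biomass", "mean_biomass",
        "mean_pollinator_density", "final_N",
    )}
    errors: dict = {}
    rng0 = np.random.default_rng(children[0])
    u_carry = rng0.uniform(-trait_range, trait_range, size=S)
    if density_init == "intact":
        N_carry = np.ones(S)
    else:  # collapsed start
        N_carry = rng0.uniform(0.0, 0.005, size=S)
    for idx, g0 in enumerate(grid):
        if mode == "independent":
            rng = np.random.default_rng(children[idx + 1])
            u0 = rng.uniform(-trait_range, trait_range, size=S)
            N0 = (
                np.ones(S)
                if density_init == "intact"
                else rng.uniform(0.0, 0.005, size=S)
            )
        else:
            N0, u0 = N_carry, u_carry
        try:
            traj = simulate(
                CommunityState(N0, u0), net, p.replace(gamma0=float(g0)), t_end=t_end
            )
            summ = _summarize(traj, net.n_plants)
            if mode == "continuation":
                N_carry = traj.N[-1].copy()
                u_carry = traj.u[-1].copy()
        except IntegrationError as err:
            errors[float(g0)] = str(err)
            summ = {
                "richness": 0, "recovered_fraction": np.nan,
                "total_biomass": np.nan, "mean_biomass": np.nan,
                "mean_pollinator_density": np.nan, "final_N": np.full(S, np.nan),
            }
            if mode == "continuation" and err.last_state is not None:
                N_carry = np.maximum(err.last_state.N, 0.0)
                u_carry = err.last_state.u
        for k in out:
            out[k].append(summ[k])
    return SweepResult(
        gamma0=np.asarray(grid, float),
        richness=np.asarray(out["richness"]),
        recovered_fraction=np.asarray(out["recovered_fraction"]),
        total_biomass=np.asarray(out["total_biomass"]),
        mean_biomass=np.asarray(out["mean_biomass"]),
        mean_pollinator_density=np.asarray(out["mean_pollinator_density"]),
        final_N=np.asarray(out["final_N"]),
        n_species=S,
        errors=errors,
        protocol=protocol,
        seed=seed,
    )


def collapse_sweep(
    net: BipartiteNetwork,
    p: ModelParams,
    grid: Optional[np.ndarray] = None,
    seed: int = 0,
    t_end: float = 1000.0,
    trait_range: float = 0.5,
    mode: str = "continuation",
) -> SweepResult:
    """Forward branch: decrease gamma0 from 5 toward 0 in steps of 0.15.

    The sweep is sequential: it starts from the intact state (all
    densities 1, traits U[-trait_range, trait_range]) at the highest
    gamma0, integrates each step for ``t_end`` time units, and carries
    the final state into the next (lower) gamma0 step.  This
    quasi-static protocol is what makes the forward and backward
    branches path-dependent.  ``mode="independent"`` instead redraws
    fresh initial conditions at every grid point.
    """
    if grid is None:
        grid = collapse_grid()
    return _run_sweep(
        net, p, grid, seed, t_end, trait_range, "intact", "collapse", mode=mode
    )


def hysteresis_sweep(
    net: BipartiteNetwork,
    p: ModelParams,
    grid: Optional[np.ndarray] = None,
    seed: int = 0,
    t_end: float = 1000.0,
    trait_range: float = 0.5,
    mode: str = "continuation",
) -> SweepResult:
    """Backward branch: increase gamma0 from 0 toward 5, collapsed start.

    Starts from the collapsed state (densities U[0, 0.005] per species,
    locally extinct or nearly so) at the lowest gamma0 and carries the
    state upward through the grid, emulating a gradual restoration of
    environmental conditions after a collapse.  The study conditions use
    sigma_i = 0.005 here.  ``mode="independent"`` redraws initial
    conditions at every grid point instead.
    """
    if grid is None:
        grid = hysteresis_grid()
    return _run_sweep(
        net, p, grid, seed, t_end, trait_range, "collapsed", "hysteresis", mode=mode
    )


def collapse_threshold(
    sweep: SweepResult, richness_fraction: float = 0.9
) -> float | None:
    """Largest gamma0 whose richness is below ``richness_fraction`` of S.

    Returns None (the "no-collapse" sentinel) when no grid point is
    collapsed under that convention.
    """
    below = sweep.richness < richness_fraction * sweep.n_species
    if not below.any():
        return None
    return float(sweep.gamma0[below].max())


def strong_hysteresis(
    sweep: SweepResult, gamma_max: float = 4.85
) -> bool:
    """True when the backward branch never fully recovers up to ``gamma_max``.

    Full recovery means every species above the recovery density (0.5).
    """
    mask = sweep.gamma0 <= gamma_max + 1e-9
    return bool(np.all(sweep.recovered_fraction[mask] < 1.0))


def revive(
    net: BipartiteNetwork,
    p: ModelParams,
    strategy: str = "highest_degree",
    nu: float = 0.5,
    nu_C: Optional[float] = None,
    T: float = 500.0,
    t_end: float = 1000.0,
    seed: int = 0,
    k: int = 3,
    u0: Optional[np.ndarray] = None,
    forced: Optional[Sequence[int]] = None,
    trait_range: float = 0.5,
) -> ReviveResult:
    """Force one (or a few) species in a collapsed community.

    Initial densities are U[0, 0.005]; initial traits default to the
    quasi-equilibrium traits obtained at gamma0 = 4 (pass ``u0`` to
    reuse a precomputed vector across runs).  Forcing is multiplicative
    with strength ``nu`` unless ``nu_C`` is given, in which case a
    constant density ``nu_C`` per unit time is added instead.  Recovery
    richness is the fraction of non-forced species whose final density
    exceeds 0.5.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    if u0 is None:
        u0 = quasi_equilibrium_traits(
            net, p, seed=np.random.default_rng(ss[0]), trait_range=trait_range
        )
    rng = np.random.default_rng(ss[1])
    if forced is None:
        forced = select_targets(
            net, strategy=strategy, k=k, seed=int(rng.integers(2**31 - 1))
        )
    forced = [int(j) for j in forced]
    if any(j < 0 or j >= net.n_species for j in forced):
        raise ValueError("forced species index outside the network")
    N0 = rng.uniform(0.0, 0.005, size=net.n_species)
    if nu_C is not None:
        forcing = ForcingSpec(forced, strength=float(nu_C), duration=T, mode="additive")
    else:
        forcing = ForcingSpec(forced, strength=float(nu), duration=T)
    traj = simulate(CommunityState(N0, np.asarray(u0, float)), net, p,
                    t_end=t_end, forcing=forcing)
    final = traj.N[-1]
    others = np.setdiff1d(np.arange(net.n_species), forced)
    recovery = float(np.mean(final[others] > RECOVERY_DENSITY)) if others.size else 0.0
    recovery_all = float(np.mean(final > RECOVERY_DENSITY))
    window = traj.N[-100:]
    return ReviveResult(
        trajectory=traj,
        forced=forced,
        recovery_richness=recovery,
        recovery_richness_all=recovery_all,
        mean_biomass=float(window.mean()),
        total_biomass=float(window.sum(axis=1).mean()),
        seed=seed,
    )


def phase_diagram(
    net: BipartiteNetwork,
    p: ModelParams,
    axis: str,
    axis_values: Sequence[float],
    gamma0_grid: Sequence[float],
    strategy: str = "highest_degree",
    nu: float = 0.5,
    T: float = 500.0,
    t_end: float = 1000.0,
    seed: int = 0,
    k: int = 3,
    trait_range: float = 0.5,
) -> PhaseDiagram:
    """Recovery richness over a grid of (nu | nu_C | T) x gamma0.

    The per-cell protocol is identical to :func:`revive`.  The
    quasi-equilibrium trait vector is computed once per diagram (it does
    not depend on the collapsed-regime gamma0 being probed).
    """
    if axis not in ("nu", "nu_C", "T"):
        raise ValueError("axis must be one of 'nu', 'nu_C', 'T'")
    axis_values = np.asarray(list(axis_values), float)
    gamma0_grid = np.asarray(list(gamma0_grid), float)
    ss = np.random.SeedSequence(seed).spawn(2)
    u0 = quasi_equilibrium_traits(
        net, p, seed=np.random.default_rng(ss[0]), trait_range=trait_range
    )
    cell_seeds = np.random.SeedSequence(ss[1].entropy).generate_state(
        len(axis_values) * len(gamma0_grid)
    ) % (2**31 - 1)
    recovery = np.full((len(axis_values), len(gamma0_grid)), np.nan)
    errors: dict = {}
    for i, a in enumerate(axis_values):
        for j, g0 in enumerate(gamma0_grid):
            kwargs = dict(nu=nu, T=T)
            if axis == "nu":
                kwargs["nu"] = float(a)
            elif axis == "nu_C":
                kwargs["nu_C"] = float(a)
            else:
                kwargs["T"] = float(a)
            try:
                res = revive(
                    net,
                    p.replace(gamma0=float(g0)),
                    strategy=strategy,
                    seed=int(cell_seeds[i * len(gamma0_grid) + j]),
                    k=k,
                    u0=u0,
                    t_end=t_end,
                    **kwargs,
                )
                recovery[i, j] = res.recovery_richness
            except IntegrationError as err:
                errors[(float(a), float(g0))] = str(err)
    return PhaseDiagram(axis, axis_values, gamma0_grid, recovery, errors)
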