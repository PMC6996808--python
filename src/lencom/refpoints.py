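"""Long-term yield analyses: F_MSY, Nash equilibrium, scenario grids.

Fishing mortality enters these analyses through one logistic gear per
species with unit-normalised catchability, so a species' effort equals
the fishing mortality ``F`` (1/yr) on its most-selected length class
and the ``F`` axis is comparable across parameterisations.

* ``calc_fmsy`` maximises one stock's long-term yield over its own
  ``F`` with the other stocks' ``F`` held fixed — the single-species
  MSY embedded in the multispecies model.
* ``calc_nash`` finds the vector ``F_Nash`` at which no stock's
  long-term yield can be increased by changing only its own ``F``
  (best-response iteration over species until a full sweep changes no
  component by more than a tolerance; at the fixed point, re-running
  the single-species optimisation for any stock reproduces its Nash
  value).
* ``run_scenario_grid`` enumerates the full factorial of per-fleet
  effort levels, runs each for a fixed horizon, and flags stocks whose
  final-year mean spawning-stock biomass falls below 10% of its
  unfished level — the collapse criterion.

"Long-term yield" is operationalised as the mean annual catch over the
final ``avg_years`` of a ``years``-long run from a common initial
state (defaults 10 of 50); both are configurable and should be scaled
down together for small exploratory communities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .engine import CommunityState, EffortSchedule, run
from .params import CommunityParams, Gear

__all__ = [
    "per_species_gears",
    "long_term_yield",
    "calc_fmsy",
    "calc_nash",
    "NashResult",
    "ScenarioResult",
    "collapse_flags",
    "enumerate_scenarios",
    "run_scenario_grid",
    "unfished_ssb",
]

#: Fraction of unfished spawning-stock biomass below which a stock is
#: deemed collapsed.
COLLAPSE_FRACTION = 0.10


def per_species_gears(params: CommunityParams) -> list[Gear]:
    """One logistic gear per species, selecting at maturity length.

    The logistic L50 is the species' ``Lmat`` and the steepness matches
    its maturity ogive, giving a smooth but sharp selection curve
    scaled to body size.  With unit-normalised catchability the gear's
    effort equals the F on the most-selected class.
    """
    sp = params.species
    return [
        Gear(
            name=f"F_{sp.names[i]}",
            curves={sp.names[i]: ("logistic", {"eta": sp.kappa[i], "L50": sp.lmat[i]})},
        )
        for i in range(sp.n_s)
    ]


def _yield_params(params: CommunityParams) -> CommunityParams:
    """The community refitted with one unit-normalised gear per species."""
    return params.with_gears(per_species_gears(params))


def long_term_yield(
    params: CommunityParams,
    state0: CommunityState,
    F: np.ndarray,
    years: int = 50,
    avg_years: int = 10,
) -> np.ndarray:
    """Per-species mean annual yield (g/yr) at fishing mortalities ``F``.

    ``params`` must already carry one gear per species (see
    ``per_species_gears``); ``F`` is then the per-species effort
    vector.  Deterministic: identical inputs give identical yields.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (params.n_s,):
        raise ValueError("F must give one fishing mortality per species")
    if params.n_gears != params.n_s:
        raise ValueError("params must carry one gear per species for yield analyses")
    effort = EffortSchedule(np.tile(F, (years, 1)), params.gear_names)
    out = run(params, state0, years=years, effort=effort)
    spy = round(1.0 / params.dt)
    tail = out.Catch[-avg_years * spy :]
    # catch is recorded per gear; gear k targets species k only
    return tail.sum(axis=(0, 1, 2)) / avg_years


def calc_fmsy(
    params: CommunityParams,
    state0: CommunityState,
    species_index: int,
    F_other: np.ndarray,
    F_grid: np.ndarray | None = None,
    years: int = 50,
    avg_years: int = 10,
    tol: float = 0.005,
) -> float:
    """F maximising one stock's long-term yield, others held at ``F_other``.

    Scans ``F_grid`` (default 0 to 2 step 0.1), then refines between
    the best point's neighbours with a bounded scalar minimiser to
    ``tol`` (1/yr).  Ties on a flat profile return the smallest
    maximiser with a warning.
    """
    if F_grid is None:
        F_grid = np.arange(0.0, 2.0001, 0.1)
    F_grid = np.asarray(F_grid, dtype=float)
    if np.any(F_grid < 0) or not np.all(np.isfinite(F_grid)):
        raise ValueError("F grid must be finite and nonnegative")
    F_other = np.asarray(F_other, dtype=float)

    def yield_i(f: float) -> float:
        F = F_other.copy()
        F[species_index] = f
        return long_term_yield(params, state0, F, years=years, avg_years=avg_years)[
            species_index
        ]

    profile = np.array([yield_i(f) for f in F_grid])
    best = int(np.argmax(profile))  # argmax takes the first (smallest) maximiser
    if np.count_nonzero(profile == profile[best]) > 1:
        warnings.warn(
            "yield profile has tied maxima; returning the smallest maximiser",
            stacklevel=2,
        )
        return float(F_grid[best])
    lo = F_grid[max(best - 1, 0)]
    hi = F_grid[min(best + 1, F_grid.size - 1)]
    if hi - lo <= tol:
        return float(F_grid[best])
    res = minimize_scalar(
        lambda f: -yield_i(f), bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


@dataclass(frozen=True)
class NashResult:
    """Outcome of the best-response iteration."""

    F: np.ndarray              # the equilibrium (or last) iterate
    converged: bool
    sweeps: int
    max_change: float          # largest |dF| in the final sweep


def calc_nash(
    params: CommunityParams,
    state0: CommunityState,
    F_init: np.ndarray,
    tol: float = 0.01,
    max_iter: int = 50,
    F_grid: np.ndarray | None = None,
    years: int = 50,
    avg_years: int = 10,
    inner_tol: float = 0.005,
) -> NashResult:
    """Nash-equilibrium fishing mortalities by best-response iteration.

    Cycles over species, replacing each ``F_i`` with its single-species
    optimum holding the others fixed, until the largest change in a
    full sweep is below ``tol`` (1/yr) or ``max_iter`` sweeps elapse.
    """
    F = np.asarray(F_init, dtype=float).copy()
    if F.shape != (params.n_s,) or np.any(F < 0):
        raise ValueError("F_init must be a nonnegative vector, one F per species")
    max_change = np.inf
    for sweep in range(1, max_iter + 1):
        max_change = 0.0
        for i in range(params.n_s):
            new = calc_fmsy(
                params, state0, i, F, F_grid=F_grid,
                years=years, avg_years=avg_years, tol=inner_tol,
            )
            max_change = max(max_change, abs(new - F[i]))
            F[i] = new
        if max_change < tol:
            return NashResult(F=F, converged=True, sweeps=sweep, max_change=max_change)
    warnings.warn(
        f"Nash best-response iteration did not converge in {max_iter} sweeps "
        f"(last sweep moved {max_change:.4f}/yr)",
        stacklevel=2,
    )
    return NashResult(F=F, converged=False, sweeps=max_iter, max_change=max_change)


# ----------------------------------------------------------------------
# mixed-fishery scenario grid


@dataclass(frozen=True)
class ScenarioResult:
    """One cell of the effort factorial."""

    effort: tuple[float, ...]      # one level per fleet
    ssb: np.ndarray                # per-species final-year mean SSB (g)
    unfished_ssb: np.ndarray       # same, from the zero-effort reference
    collapsed: np.ndarray          # bool per species
    n_at_risk: int

    def __post_init__(self) -> None:
        expected = collapse_flags(self.ssb, self.unfished_ssb)
        if not np.array_equal(self.collapsed, expected):
            raise ValueError("collapse flags inconsistent with the 10% rule")
        if self.n_at_risk != int(np.count_nonzero(self.collapsed)):
            raise ValueError("n_at_risk must count the collapsed flags")


def collapse_flags(
    ssb: np.ndarray,
    unfished: np.ndarray,
    fraction: float = COLLAPSE_FRACTION,
) -> np.ndarray:
    """A stock is collapsed iff its SSB is below ``fraction`` of unfished."""
    return np.asarray(ssb, float) < fraction * np.asarray(unfished, float)


def enumerate_scenarios(
    levels: np.ndarray, n_fleets: int
) -> list[tuple[float, ...]]:
    """Full factorial of per-fleet effort levels (levels ** n_fleets cells)."""
    levels = [float(x) for x in np.asarray(levels, float)]
    if any(x < 0 for x in levels):
        raise ValueError("effort levels must be nonnegative")
    return list(itertools.product(levels, repeat=n_fleets))


def _final_year_ssb(params: CommunityParams, out) -> np.ndarray:
    """Mean per-species SSB (g) over the last simulated year."""
    spy = round(1.0 / params.dt)
    tail = out.N[-spy:]
    return (tail * (params.w * params.mature)[None]).sum(axis=1).mean(axis=0)


def unfished_ssb(
    params: CommunityParams, state0: CommunityState, years: int
) -> np.ndarray:
    """Final-year mean SSB of the zero-effort reference run."""
    return _final_year_ssb(params, run(params, state0, years=years))


def run_scenario_grid(
    params: CommunityParams,
    state0: CommunityState,
    levels: np.ndarray = (0.0, 0.5, 1.0, 1.5, 2.0),
    years: int = 50,
) -> list[ScenarioResult]:
    """Run every combination of per-fleet effort levels from one state.

    Each scenario holds its effort vector constant for ``years`` years;
    collapse is judged on the final year's mean SSB against the
    zero-effort reference run of the same length.
    """
    if years < 1:
        raise ValueError("scenario runs need at least one year")
    ref = unfished_ssb(params, state0, years)
    results = []
    for combo in enumerate_scenarios(levels, params.n_gears):
        effort = EffortSchedule(np.tile(combo, (years, 1)), params.gear_names)
        out = run(params, state0, years=years, effort=effort)
        ssb = _final_year_ssb(params, out)
        flags = collapse_flags(ssb, ref)
        results.append(
            ScenarioResult(
                effort=combo,
                ssb=ssb,
                unfished_ssb=ref,
                collapsed=flags,
                n_at_risk=int(np.count_nonzero(flags)),
            )
        )
    return results
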