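"""Assembly of all time-invariant model structures.

Takes the raw inputs — species table, predator-prey interaction matrix
``tau``, gear definitions, size-preference parameters — and builds
everything the time-stepping engine needs: growth transition
proportions ``phi``, the maturity ogive, background mortality ``M1``,
the predation suitability tensor, and the catchability array ``Q``.

Conventions
-----------
* ``phi[j, i]`` is the proportion of species ``i`` individuals leaving
  length class ``j`` per time step ``dt`` through von Bertalanffy
  growth ``dL/dt = k (Linf - L)``.  The transit time of class
  ``[l, u)`` is ``(1/k) ln((Linf - l) / (Linf - u))`` and
  ``phi = dt / transit``, capped at 1; a class whose lower bound
  reaches ``Linf`` has ``phi = 0`` (fish accumulate there).
* The size preference of a predator of weight ``w_pred`` for prey of
  weight ``w_prey`` is a log-normal-shaped kernel in the weight ratio,
  peaking at the preferred predator-prey mass ratio ``mu`` with
  log-scale width ``sigma``; a predator never eats prey at or above
  its own weight.
* Catchability curves are rescaled to unit maximum over the length
  classes a species can actually occupy, so gear effort ``e`` equals
  the fishing mortality on the most-selected class (units 1/yr).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .grid import LengthGrid, build_length_grid
from .species import SpeciesTable

__all__ = [
    "PredationParams",
    "Gear",
    "CommunityParams",
    "validate_tau",
    "calc_phi",
    "calc_maturity",
    "calc_M1",
    "calc_suitability",
    "calc_catchability",
    "build_community",
]

CATCH_FAMILIES = ("logistic", "log_gaussian", "knife-edge")


@dataclass(frozen=True)
class PredationParams:
    """Species-independent predation parameters.

    mu
        Preferred predator-prey mass ratio (dimensionless, > 1).
    sigma
        Width of the log-scale size preference (dimensionless, > 0).
    g0
        Theoretical growth (conversion) efficiency of a fish of length
        zero, in (0, 1); efficiency declines linearly to 0 at ``Linf``.
    other
        Biomass of other food available to predators (grams).
    """

    mu: float = 30.0
    sigma: float = 1.0
    g0: float = 0.5
    other: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= 1:
            raise ValueError("predator-prey mass ratio mu must exceed 1")
        if self.sigma <= 0:
            raise ValueError("size-preference width sigma must be positive")
        if not 0 < self.g0 < 1:
            raise ValueError("growth efficiency g0 must lie in (0, 1)")
        if self.other < 0:
            raise ValueError("other food must be nonnegative")


@dataclass(frozen=True)
class Gear:
    """One fishing gear: a catchability curve family per caught species.

    ``curves`` maps species name -> (family, params).  Families:

    * ``logistic``: params ``eta`` (steepness, 1/cm) and ``L50`` (cm);
      ``q(l) = 1 / (1 + exp(-eta (l - L50)))``.
    * ``log_gaussian``: params ``Lmu`` (modal length, cm) and ``sigma``
      (log-scale width); ``q(l) = exp(-(ln l - ln Lmu)^2 / (2 sigma^2))``.
    * ``knife-edge``: param ``Lmin`` (cm); ``q = 1`` at or above
      ``Lmin``, 0 below (retention above a minimum landing size;
      smaller fish escape or are discarded alive, taking no mortality).

    Species absent from ``curves`` have identically zero catchability.
    """

    name: str
    curves: dict[str, tuple[str, dict[str, float]]]

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError(f"gear {self.name!r} catches no species")
        for sp, (family, pars) in self.curves.items():
            if family not in CATCH_FAMILIES:
                raise ValueError(
                    f"gear {self.name!r}, species {sp!r}: unknown catchability "
                    f"family {family!r}"
                )
            if any(v < 0 for v in pars.values()):
                raise ValueError(
                    f"gear {self.name!r}, species {sp!r}: negative parameter"
                )


def validate_tau(tau: np.ndarray, n_s: int) -> np.ndarray:
    """Validate a predator-prey interaction matrix (row = predator)."""
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (n_s, n_s):
        raise ValueError(f"tau must be {n_s} x {n_s}, got {tau.shape}")
    if np.any(tau < 0) or np.any(tau > 1):
        raise ValueError("tau entries must lie in [0, 1]")
    return tau


# ----------------------------------------------------------------------
# component calculations


def calc_phi(
    grid: LengthGrid, species: SpeciesTable, phi_min: float = 0.1
) -> tuple[np.ndarray, float]:
    """Growth transition proportions and the time step.

    ``phi_min`` is interpreted directly as the time step ``dt`` in
    years (default 0.1, i.e. 10 steps per year).  Any raw proportion
    exceeding 1 (very fast growth relative to the class width) is
    capped at 1 with a warning.
    """
    if not 0 < phi_min <= 1:
        raise ValueError("phi_min (the time step, years) must lie in (0, 1]")
    dt = float(phi_min)
    linf = species.linf
    if np.any(linf <= grid.upper[0]):
        bad = [species.names[i] for i in np.flatnonzero(linf <= grid.upper[0])]
        raise ValueError(
            f"species cannot grow past the first length class: {bad}"
        )
    lower = grid.lower[:, None]
    upper = grid.upper[:, None]
    growable = upper < linf[None, :]  # can traverse the whole class
    with np.errstate(divide="ignore", invalid="ignore"):
        transit = np.where(
            growable,
            (1.0 / species.k[None, :])
            * np.log((linf[None, :] - lower) / (linf[None, :] - upper)),
            np.inf,
        )
    phi = dt / transit
    if np.any(phi > 1):
        warnings.warn(
            "some growth proportions exceeded 1 and were capped; consider a "
            "finer time step or wider length classes",
            stacklevel=2,
        )
        phi = np.minimum(phi, 1.0)
    return phi, dt


def calc_maturity(grid: LengthGrid, species: SpeciesTable) -> np.ndarray:
    """Logistic maturity ogive at class midpoints, in [0, 1]."""
    mid = grid.mid[:, None]
    z = species.kappa[None, :] * (mid - species.lmat[None, :])
    return expit(z)


def calc_M1(grid: LengthGrid, species: SpeciesTable) -> np.ndarray:
    """Background (non-predation, non-fishing) mortality, 1/yr.

    Three families, chosen per species in the table:

    * ``constant`` — ``m1_rate`` in every class;
    * ``linear`` — declines linearly in midpoint length from
      ``m1_rate`` at length 0 to 0 at ``Linf``;
    * ``std_RNM`` (default) — residual natural mortality ``m1_rate``
      on classes with midpoint at most ``m1_prop * Linf``, 0 above
      (large fish escape the residual background mortality).
    """
    mid = grid.mid
    out = np.zeros((grid.n_l, species.n_s))
    for i in range(species.n_s):
        fun = species.m1_fun[i]
        rate, prop, linf = species.m1_rate[i], species.m1_prop[i], species.linf[i]
        if fun == "constant":
            out[:, i] = rate
        elif fun == "linear":
            out[:, i] = rate * np.clip(1.0 - mid / linf, 0.0, None)
        elif fun == "std_RNM":
            out[:, i] = np.where(mid <= prop * linf, rate, 0.0)
        else:  # pragma: no cover - blocked by SpeciesTable validation
            raise ValueError(f"unknown M1 function {fun!r}")
    return out


def calc_suitability(
    grid: LengthGrid,
    species: SpeciesTable,
    tau: np.ndarray,
    pred: PredationParams,
) -> np.ndarray:
    """Predation suitability tensor, shape (pred sp m, pred class n, prey sp i, prey class j).

    ``suit[m, n, i, j] = tau[m, i] * exp(-(ln(w_pred / w_prey) - ln mu)^2
    / (2 sigma^2))``, zeroed wherever the prey weighs at least as much
    as the predator.  Values lie in [0, 1] and depend on weights only
    through the ratio.
    """
    w = species.weight_at(grid.mid)  # (n_l, n_s)
    n_l, n_s = w.shape
    w_pred = w.T[:, :, None, None]   # (m, n, 1, 1)
    w_prey = w.T[None, None, :, :]   # (1, 1, i, j)
    with np.errstate(divide="ignore"):
        log_ratio = np.log(w_pred / w_prey)
    kernel = np.exp(-((log_ratio - np.log(pred.mu)) ** 2) / (2.0 * pred.sigma**2))
    kernel[w_prey >= w_pred] = 0.0
    return tau[:, None, :, None] * kernel


def _reachable(grid: LengthGrid, species: SpeciesTable) -> np.ndarray:
    """Mask (n_l, n_s) of classes a species can occupy (lower < Linf)."""
    return grid.lower[:, None] < species.linf[None, :]


def calc_catchability(
    grid: LengthGrid,
    species: SpeciesTable,
    gears: list[Gear],
    normalise: bool = True,
) -> np.ndarray:
    """Catchability array Q, shape (n_l, n_s, H), units F per unit effort.

    Each species x gear selection curve is evaluated at class midpoints
    and (by default) rescaled so its maximum over the classes the
    species can occupy equals 1: gear effort then equals the fishing
    mortality on the most-selected length class.
    """
    mid = grid.mid
    name_to_col = {n: i for i, n in enumerate(species.names)}
    Q = np.zeros((grid.n_l, species.n_s, len(gears)))
    reach = _reachable(grid, species)
    for k, gear in enumerate(gears):
        for sp, (family, pars) in gear.curves.items():
            if sp not in name_to_col:
                raise ValueError(
                    f"gear {gear.name!r} targets unknown species {sp!r}"
                )
            i = name_to_col[sp]
            if family == "logistic":
                q = expit(pars["eta"] * (mid - pars["L50"]))
            elif family == "log_gaussian":
                with np.errstate(divide="ignore"):
                    q = np.exp(
                        -((np.log(mid) - np.log(pars["Lmu"])) ** 2)
                        / (2.0 * pars["sigma"] ** 2)
                    )
            elif family == "knife-edge":
                q = (mid >= pars["Lmin"]).astype(float)
            else:  # pragma: no cover - blocked by Gear validation
                raise ValueError(f"unknown catchability family {family!r}")
            q = np.where(reach[:, i], q, 0.0)  # no fish of this species there
            if normalise:
                peak = q.max()
                q = q / peak if peak > 0 else q
            Q[:, i, k] = q
    return Q


# ----------------------------------------------------------------------
# the assembled model


@dataclass(frozen=True)
class CommunityParams:
    """Everything the engine needs, fully assembled and validated."""

    grid: LengthGrid
    species: SpeciesTable
    phi: np.ndarray               # (n_l, n_s) per-step growth proportions
    dt: float                     # yr
    steps_per_year: int
    mature: np.ndarray            # (n_l, n_s) maturity ogive
    M1: np.ndarray                # (n_l, n_s), 1/yr
    suit: np.ndarray              # (n_s, n_l, n_s, n_l)
    Q: np.ndarray                 # (n_l, n_s, H), F per unit effort
    gear_names: tuple[str, ...]
    tau: np.ndarray               # (n_s, n_s)
    pred: PredationParams

    def __post_init__(self) -> None:
        n_l, n_s = self.grid.n_l, self.species.n_s
        if self.phi.shape != (n_l, n_s):
            raise ValueError("phi has wrong shape")
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise ValueError("phi must lie in [0, 1]")
        if abs(self.dt * self.steps_per_year - 1.0) > 1e-9:
            raise ValueError("dt * steps_per_year must equal one year")
        if self.M1.shape != (n_l, n_s) or np.any(self.M1 < 0):
            raise ValueError("M1 must be nonnegative with shape (n_l, n_s)")
        if self.suit.shape != (n_s, n_l, n_s, n_l):
            raise ValueError("suitability tensor has wrong shape")
        if self.Q.ndim != 3 or self.Q.shape[:2] != (n_l, n_s):
            raise ValueError("Q must have shape (n_l, n_s, H)")
        if np.any(self.Q < 0):
            raise ValueError("catchability must be nonnegative")
        # no predation where tau says no link
        no_link = self.tau[:, None, :, None] == 0
        if np.any(self.suit * no_link != 0):
            raise ValueError("suitability must vanish where tau is zero")

    @property
    def n_l(self) -> int:
        return self.grid.n_l

    @property
    def n_s(self) -> int:
        return self.species.n_s

    @property
    def n_gears(self) -> int:
        return self.Q.shape[2]

    @property
    def w(self) -> np.ndarray:
        """Midpoint weights (g), shape (n_l, n_s)."""
        return self.species.weight_at(self.grid.mid)

    def with_gears(self, gears: list[Gear], normalise: bool = True) -> "CommunityParams":
        """Same community, different fishery (new Q array)."""
        Q = calc_catchability(self.grid, self.species, gears, normalise=normalise)
        return replace(self, Q=Q, gear_names=tuple(g.name for g in gears))


def build_community(
    species: SpeciesTable,
    tau: np.ndarray | None = None,
    gears: list[Gear] | None = None,
    pred: PredationParams | None = None,
    n_l: int = 32,
    bounds: np.ndarray | None = None,
    phi_min: float = 0.1,
    raw_Q: np.ndarray | None = None,
) -> CommunityParams:
    """Assemble a ready-to-run community model from raw inputs.

    ``tau`` defaults to all ones (every species eats every other,
    subject to the size preference).  ``raw_Q`` accepts a user-supplied
    catchability array verbatim in place of gear definitions.  The grid
    defaults to ``n_l`` equal-width classes up to ``max(Linf)``.
    """
    grid = build_length_grid(n_l=n_l, max_linf=float(species.linf.max()), bounds=bounds)
    tau = np.ones((species.n_s, species.n_s)) if tau is None else validate_tau(tau, species.n_s)
    pred = pred if pred is not None else PredationParams()
    phi, dt = calc_phi(grid, species, phi_min)
    steps_per_year = round(1.0 / dt)
    if raw_Q is not None:
        Q = np.asarray(raw_Q, dtype=float)
        gear_names = tuple(f"gear{k}" for k in range(Q.shape[2]))
    else:
        gears = gears or []
        Q = calc_catchability(grid, species, gears)
        gear_names = tuple(g.name for g in gears)
    return CommunityParams(
        grid=grid,
        species=species,
        phi=phi,
        dt=dt,
        steps_per_year=steps_per_year,
        mature=calc_maturity(grid, species),
        M1=calc_M1(grid, species),
        suit=calc_suitability(grid, species, tau, pred),
        Q=Q,
        gear_names=gear_names,
        tau=tau,
        pred=pred,
    )
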