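"""Species- and community-level summaries of a simulation run.

All indicators are computed per time step from the recorded
numbers-at-length, using midpoint weights, with an option to average
to annual values.  Community indicators aggregate biomass over species
within each length class:

* **LFI** (large fish indicator) — proportion of community biomass in
  classes with midpoint above a length threshold (conventionally
  40 cm).
* **MML** (mean maximum length) — biomass-weighted mean of the
  species' asymptotic lengths ``Linf``.
* **TyL** (typical length) — biomass-weighted geometric mean of class
  midpoint lengths.
* **LQ** (length quantile) — the length below which a given fraction
  of community biomass lies, interpolated linearly within a class.

Catch summaries are per gear: **CPG** (catch per gear, grams per step)
and **CPUE** (catch per unit effort), the latter undefined (NaN) where
effort is zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import SimOutput
from .params import CommunityParams

__all__ = [
    "get_biomass",
    "get_SSB",
    "get_LFI",
    "get_MML",
    "get_TyL",
    "get_LQ",
    "get_CPG",
    "get_CPUE",
    "annual_mean",
]


def _per_step_biomass(output: SimOutput, params: CommunityParams) -> np.ndarray:
    """Biomass (g) per step, class, species: shape (steps, n_l, n_s)."""
    return output.N * params.w[None, :, :]


def annual_mean(series: pd.Series | pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Average a per-step series (indexed by time in years) to years.

    Steps are assigned to the year they fall in: a step ending at time
    ``t`` belongs to year ``ceil(t) - 1`` (0-based).
    """
    years = np.ceil(series.index.to_numpy()).astype(int) - 1
    out = series.groupby(years).mean()
    out.index.name = "year"
    return out


def get_biomass(
    output: SimOutput, params: CommunityParams, annual: bool = False
) -> pd.DataFrame:
    """Per-species total biomass (g) per step (columns = species)."""
    b = _per_step_biomass(output, params).sum(axis=1)
    df = pd.DataFrame(b, index=output.time, columns=params.species.names)
    df.index.name = "time"
    return annual_mean(df) if annual else df


def get_SSB(
    output: SimOutput, params: CommunityParams, annual: bool = False
) -> pd.DataFrame:
    """Per-species spawning-stock biomass (g) per step."""
    b = (output.N * (params.w * params.mature)[None, :, :]).sum(axis=1)
    df = pd.DataFrame(b, index=output.time, columns=params.species.names)
    df.index.name = "time"
    return annual_mean(df) if annual else df


def get_LFI(
    output: SimOutput,
    params: CommunityParams,
    threshold: float = 40.0,
    annual: bool = False,
) -> pd.Series:
    """Community biomass fraction in classes with midpoint > threshold (cm)."""
    grid = params.grid
    if not (grid.lower[0] <= threshold <= grid.upper[-1]):
        raise ValueError(
            f"LFI threshold {threshold} cm lies outside the length grid "
            f"[{grid.lower[0]}, {grid.upper[-1]}]"
        )
    b = _per_step_biomass(output, params)
    large = b[:, grid.mid > threshold, :].sum(axis=(1, 2))
    total = b.sum(axis=(1, 2))
    with np.errstate(invalid="ignore"):
        lfi = np.where(total > 0, large / total, np.nan)
    s = pd.Series(lfi, index=output.time, name="LFI")
    s.index.name = "time"
    return annual_mean(s) if annual else s


def get_MML(
    output: SimOutput, params: CommunityParams, annual: bool = False
) -> pd.Series:
    """Biomass-weighted mean of species' asymptotic lengths (cm)."""
    b_sp = _per_step_biomass(output, params).sum(axis=1)  # (steps, n_s)
    total = b_sp.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mml = np.where(total > 0, b_sp @ params.species.linf / total, np.nan)
    s = pd.Series(mml, index=output.time, name="MML")
    s.index.name = "time"
    return annual_mean(s) if annual else s


def get_TyL(
    output: SimOutput, params: CommunityParams, annual: bool = False
) -> pd.Series:
    """Biomass-weighted geometric mean length (cm) over classes."""
    b_cl = _per_step_biomass(output, params).sum(axis=2)  # (steps, n_l)
    total = b_cl.sum(axis=1)
    logL = np.log(params.grid.mid)
    with np.errstate(invalid="ignore"):
        tyl = np.where(total > 0, np.exp(b_cl @ logL / total), np.nan)
    s = pd.Series(tyl, index=output.time, name="TyL")
    s.index.name = "time"
    return annual_mean(s) if annual else s


def get_LQ(
    output: SimOutput,
    params: CommunityParams,
    prob: float,
    annual: bool = False,
) -> pd.Series:
    """Length (cm) below which ``prob`` of community biomass lies.

    Interpolates linearly within the class where the cumulative biomass
    crosses the target, giving a continuous quantile; ``prob=1``
    returns the upper bound of the top occupied class.
    """
    if not 0 < prob <= 1:
        raise ValueError("quantile probability must lie in (0, 1]")
    grid = params.grid
    b_cl = _per_step_biomass(output, params).sum(axis=2)  # (steps, n_l)
    out = np.full(b_cl.shape[0], np.nan)
    for t in range(b_cl.shape[0]):
        total = b_cl[t].sum()
        if total <= 0:
            continue
        cum = np.cumsum(b_cl[t])
        target = prob * total
        j = int(np.searchsorted(cum, target))
        j = min(j, grid.n_l - 1)
        prev = cum[j - 1] if j > 0 else 0.0
        frac = (target - prev) / b_cl[t, j] if b_cl[t, j] > 0 else 1.0
        out[t] = grid.lower[j] + frac * grid.width[j]
    s = pd.Series(out, index=output.time, name=f"LQ{prob:g}")
    s.index.name = "time"
    return annual_mean(s) if annual else s


def get_CPG(output: SimOutput, annual: bool = False) -> pd.DataFrame:
    """Catch per gear (grams caught per step; columns = gears)."""
    cpg = output.Catch.sum(axis=(1, 2))
    df = pd.DataFrame(cpg, index=output.time, columns=output.gear_names)
    df.index.name = "time"
    return annual_mean(df) if annual else df


def get_CPUE(output: SimOutput, annual: bool = False) -> pd.DataFrame:
    """Catch per unit effort per gear; NaN (undefined) where effort is 0."""
    cpg = output.Catch.sum(axis=(1, 2))          # (steps, H)
    spy = round(1.0 / output.dt)
    effort_steps = np.repeat(output.effort, spy, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cpue = np.where(effort_steps > 0, cpg / effort_steps, np.nan)
    df = pd.DataFrame(cpue, index=output.time, columns=output.gear_names)
    df.index.name = "time"
    return annual_mean(df) if annual else df
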