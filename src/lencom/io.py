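"""File formats: CSV tables and matrices, YAML configs, run archives.

Everything on disk is plain text except the optional ``.npz`` run
archive (a compact binary form for large simulations); the tidy CSV
writer covers the text path for the same data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import EffortSchedule, SimOutput
from .fixtures import Fixture
from .params import (
    CommunityParams,
    Gear,
    PredationParams,
    build_community,
)
from .species import SpeciesTable

__all__ = [
    "read_species_table", "write_species_table",
    "read_named_matrix", "write_named_matrix",
    "read_effort", "write_effort",
    "read_gears", "write_gears",
    "read_predation", "write_predation",
    "write_fixture", "load_community",
    "save_output", "load_output", "output_to_tidy", "write_tidy_output",
    "save_params", "load_params",
]


# ----------------------------------------------------------------------
# species table and matrices


def read_species_table(path: str | Path) -> SpeciesTable:
    return SpeciesTable.from_frame(pd.read_csv(path))


def write_species_table(species: SpeciesTable, path: str | Path) -> None:
    species.to_frame().to_csv(path, index=False)


def read_named_matrix(path: str | Path, names: list[str]) -> np.ndarray:
    """Square matrix CSV with species-name row/column headers."""
    df = pd.read_csv(path, index_col=0)
    missing = set(names) - set(df.index) | set(names) - set(df.columns)
    if missing:
        raise ValueError(f"matrix {path} missing species: {sorted(missing)}")
    return df.loc[names, names].to_numpy(float)


def write_named_matrix(M: np.ndarray, names: list[str], path: str | Path) -> None:
    pd.DataFrame(M, index=names, columns=names).to_csv(path)


def read_effort(path: str | Path) -> EffortSchedule:
    """Effort CSV: one row per year, one column per gear, header = names."""
    df = pd.read_csv(path)
    return EffortSchedule(df.to_numpy(float), tuple(df.columns))


def write_effort(effort: EffortSchedule, path: str | Path) -> None:
    pd.DataFrame(effort.E, columns=effort.gear_names).to_csv(path, index=False)


# ----------------------------------------------------------------------
# gears and predation parameters (YAML)


def write_gears(gears: list[Gear], path: str | Path) -> None:
    doc = [
        {
            "name": g.name,
            "curves": {
                sp: {"family": fam, **{k: float(v) for k, v in pars.items()}}
                for sp, (fam, pars) in g.curves.items()
            },
        }
        for g in gears
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_gears(path: str | Path) -> list[Gear]:
    doc = yaml.safe_load(Path(path).read_text())
    gears = []
    for entry in doc:
        curves = {}
        for sp, c in entry["curves"].items():
            c = dict(c)
            family = c.pop("family")
            curves[sp] = (family, {k: float(v) for k, v in c.items()})
        gears.append(Gear(name=entry["name"], curves=curves))
    return gears


def write_predation(pred: PredationParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "mu": pred.mu, "sigma": pred.sigma, "g0": pred.g0, "other": pred.other,
    }))


def read_predation(path: str | Path) -> PredationParams:
    doc = yaml.safe_load(Path(path).read_text())
    return PredationParams(**{k: float(v) for k, v in doc.items()})


# ----------------------------------------------------------------------
# fixture directory: the on-disk form of a full model input set


def write_fixture(fixture: Fixture, directory: str | Path) -> None:
    """Write species.csv, tau.csv, gears.yaml, predation.yaml, manifest.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_species_table(fixture.species, d / "species.csv")
    write_named_matrix(fixture.tau, fixture.species.names, d / "tau.csv")
    write_gears(fixture.gears, d / "gears.yaml")
    write_predation(fixture.pred, d / "predation.yaml")
    (d / "manifest.json").write_text(json.dumps(fixture.manifest, indent=2) + "\n")


def load_community(
    directory: str | Path, n_l: int = 32, phi_min: float = 0.1
) -> CommunityParams:
    """Assemble a community model from a fixture directory."""
    d = Path(directory)
    species = read_species_table(d / "species.csv")
    tau = read_named_matrix(d / "tau.csv", species.names)
    gears = read_gears(d / "gears.yaml")
    pred = read_predation(d / "predation.yaml")
    return build_community(
        species, tau=tau, gears=gears, pred=pred, n_l=n_l, phi_min=phi_min
    )


# ----------------------------------------------------------------------
# run output


def save_output(output: SimOutput, path: str | Path) -> None:
    """Compact archive of a run (numpy .npz)."""
    np.savez_compressed(
        path,
        N=output.N, Catch=output.Catch, M2=output.M2, R=output.R,
        effort=output.effort, N0=output.N0,
        gear_names=np.array(output.gear_names, dtype=object),
        dt=np.array(output.dt),
    )


def load_output(path: str | Path) -> SimOutput:
    with np.load(path, allow_pickle=True) as z:
        return SimOutput(
            N=z["N"], Catch=z["Catch"], M2=z["M2"], R=z["R"],
            effort=z["effort"], N0=z["N0"],
            gear_names=tuple(z["gear_names"].tolist()),
            dt=float(z["dt"]),
        )


def output_to_tidy(output: SimOutput, species_names: list[str]) -> pd.DataFrame:
    """Long-format frame: step, year, species, class, variable, value.

    Catch rows additionally carry the gear in the ``variable`` column
    (``Catch:<gear>``); recruitment rows have class 0 and variable
    ``R``.  Zero-valued catch cells are kept so the frame round-trips
    exactly.
    """
    steps, n_l, n_s = output.N.shape
    spy = round(1.0 / output.dt)
    step_idx = np.arange(1, steps + 1)
    year_of_step = (step_idx - 1) // spy
    frames = []
    for name, arr in (("N", output.N), ("M2", output.M2)):
        df = pd.DataFrame({
            "step": np.repeat(step_idx, n_l * n_s),
            "year": np.repeat(year_of_step, n_l * n_s),
            "species": np.tile(np.repeat(species_names, 1), steps * n_l),
            "class": np.tile(np.repeat(np.arange(n_l), n_s), steps),
            "variable": name,
            "value": arr.reshape(-1),
        })
        frames.append(df)
    for k, gear in enumerate(output.gear_names):
        arr = output.Catch[:, :, :, k]
        frames.append(pd.DataFrame({
            "step": np.repeat(step_idx, n_l * n_s),
            "year": np.repeat(year_of_step, n_l * n_s),
            "species": np.tile(np.repeat(species_names, 1), steps * n_l),
            "class": np.tile(np.repeat(np.arange(n_l), n_s), steps),
            "variable": f"Catch:{gear}",
            "value": arr.reshape(-1),
        }))
    years = output.R.shape[0]
    frames.append(pd.DataFrame({
        "step": np.repeat(np.arange(years) * spy + 1, n_s),
        "year": np.repeat(np.arange(years), n_s),
        "species": np.tile(species_names, years),
        "class": 0,
        "variable": "R",
        "value": output.R.reshape(-1),
    }))
    return pd.concat(frames, ignore_index=True)


def write_tidy_output(
    output: SimOutput, species_names: list[str], path: str | Path
) -> None:
    output_to_tidy(output, species_names).to_csv(path, index=False)


# ----------------------------------------------------------------------
# assembled-parameter archive


def save_params(params: CommunityParams, path: str | Path) -> None:
    """Archive the fully assembled model to a single .npz file."""
    sp = params.species
    meta = {
        "names": sp.names,
        "rec_fun": sp.rec_fun,
        "m1_fun": sp.m1_fun,
        "gear_names": list(params.gear_names),
        "dt": params.dt,
        "steps_per_year": params.steps_per_year,
        "pred": {
            "mu": params.pred.mu, "sigma": params.pred.sigma,
            "g0": params.pred.g0, "other": params.pred.other,
        },
    }
    np.savez_compressed(
        path,
        lower=params.grid.lower, upper=params.grid.upper,
        linf=sp.linf, lmat=sp.lmat, w_a=sp.w_a, w_b=sp.w_b, k=sp.k,
        rec_a=sp.rec_a, rec_b=sp.rec_b, kappa=sp.kappa,
        m1_rate=sp.m1_rate, m1_prop=sp.m1_prop,
        phi=params.phi, mature=params.mature, M1=params.M1,
        suit=params.suit, Q=params.Q, tau=params.tau,
        meta=np.array(json.dumps(meta)),
    )


def load_params(path: str | Path) -> CommunityParams:
    from .grid import LengthGrid

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        species = SpeciesTable(
            names=meta["names"],
            linf=z["linf"], lmat=z["lmat"], w_a=z["w_a"], w_b=z["w_b"],
            k=z["k"], rec_fun=meta["rec_fun"], rec_a=z["rec_a"],
            rec_b=z["rec_b"], kappa=z["kappa"],
            m1_fun=meta["m1_fun"], m1_rate=z["m1_rate"], m1_prop=z["m1_prop"],
        )
        return CommunityParams(
            grid=LengthGrid(lower=z["lower"], upper=z["upper"]),
            species=species,
            phi=z["phi"],
            dt=float(meta["dt"]),
            steps_per_year=int(meta["steps_per_year"]),
            mature=z["mature"],
            M1=z["M1"],
            suit=z["suit"],
            Q=z["Q"],
            gear_names=tuple(meta["gear_names"]),
            tau=z["tau"],
            pred=PredationParams(**meta["pred"]),
        )
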