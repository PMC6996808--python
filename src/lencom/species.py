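"""Per-species life-history, recruitment, and background-mortality inputs.

The table mirrors the minimum data a length-based community model needs
per species: asymptotic length ``Linf`` (cm), length at 50% maturity
``Lmat`` (cm), length-weight conversion ``w = W_a * L**W_b`` (grams),
the von Bertalanffy growth rate ``k`` (1/yr), a stock-recruitment
function with parameters ``a`` and ``b``, an optional maturity-ogive
steepness ``kappa`` (1/cm), and a background ("other natural")
mortality specification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpeciesTable", "REC_FUNS", "M1_FUNS"]

#: Stock-recruitment families: R as a function of spawning-stock biomass.
REC_FUNS = ("hockey-stick", "ricker", "beverton-holt", "linear", "constant")

#: Background-mortality families. ``std_RNM`` is a capped-constant
#: residual natural mortality: a constant rate on classes up to a fixed
#: fraction of Linf and zero above it.
M1_FUNS = ("std_RNM", "constant", "linear")

_COLUMNS = [
    "name", "Linf", "Lmat", "W_a", "W_b", "k", "rec_fun", "a", "b",
    "kappa", "m1_fun", "m1_rate", "m1_prop",
]


@dataclass
class SpeciesTable:
    """Validated per-species parameter arrays (one entry per species)."""

    names: list[str]
    linf: np.ndarray          # cm
    lmat: np.ndarray          # cm
    w_a: np.ndarray           # g / cm**w_b
    w_b: np.ndarray           # dimensionless, ~3
    k: np.ndarray             # 1/yr
    rec_fun: list[str]
    rec_a: np.ndarray
    rec_b: np.ndarray
    kappa: np.ndarray | None = None      # 1/cm; default 10 / Lmat
    m1_fun: list[str] | None = None      # default std_RNM
    m1_rate: np.ndarray | None = None    # 1/yr; default 0.8
    m1_prop: np.ndarray | None = None    # fraction of Linf; default 0.75

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("linf", "lmat", "w_a", "w_b", "k", "rec_a", "rec_b"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            setattr(self, attr, arr)
            if arr.shape != (n,):
                raise ValueError(f"{attr} must have one value per species")
        if len(self.rec_fun) != n:
            raise ValueError("rec_fun must have one entry per species")
        for fun in self.rec_fun:
            if fun not in REC_FUNS:
                raise ValueError(f"unknown recruitment function {fun!r}")
        if not np.all(self.linf > self.lmat):
            raise ValueError("Linf must exceed Lmat for every species")
        if not np.all(self.lmat > 0):
            raise ValueError("Lmat must be positive")
        if not np.all(self.k > 0):
            raise ValueError("growth rate k must be positive")
        if not np.all(self.w_a > 0):
            raise ValueError("length-weight coefficient W_a must be positive")
        if np.any(self.rec_a < 0) or np.any(self.rec_b < 0):
            raise ValueError("recruitment parameters must be nonnegative")
        if self.kappa is None:
            self.kappa = 10.0 / self.lmat
        else:
            self.kappa = np.asarray(self.kappa, dtype=float)
            if np.any(self.kappa <= 0):
                raise ValueError("maturity steepness kappa must be positive")
        if self.m1_fun is None:
            self.m1_fun = ["std_RNM"] * n
        for fun in self.m1_fun:
            if fun not in M1_FUNS:
                raise ValueError(f"unknown background-mortality function {fun!r}")
        self.m1_rate = (
            np.full(n, 0.8) if self.m1_rate is None
            else np.asarray(self.m1_rate, dtype=float)
        )
        self.m1_prop = (
            np.full(n, 0.75) if self.m1_prop is None
            else np.asarray(self.m1_prop, dtype=float)
        )
        if np.any(self.m1_rate < 0):
            raise ValueError("background mortality rates must be nonnegative")
        if np.any(self.m1_prop <= 0) or np.any(self.m1_prop > 1):
            raise ValueError("std_RNM cutoff proportion must lie in (0, 1]")

    @property
    def n_s(self) -> int:
        return len(self.names)

    @property
    def w_inf(self) -> np.ndarray:
        """Asymptotic weight W_a * Linf**W_b (grams)."""
        return self.w_a * self.linf ** self.w_b

    def weight_at(self, length: np.ndarray) -> np.ndarray:
        """Weight (g) of each species at each length: shape (n_len, n_s)."""
        length = np.asarray(length, dtype=float)
        return self.w_a[None, :] * length[:, None] ** self.w_b[None, :]

    # ------------------------------------------------------------------
    # pandas round trip (CSV interface)
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.names,
            "Linf": self.linf, "Lmat": self.lmat,
            "W_a": self.w_a, "W_b": self.w_b, "k": self.k,
            "rec_fun": self.rec_fun, "a": self.rec_a, "b": self.rec_b,
            "kappa": self.kappa,
            "m1_fun": self.m1_fun, "m1_rate": self.m1_rate,
            "m1_prop": self.m1_prop,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpeciesTable":
        required = {"Linf", "Lmat", "W_a", "W_b", "k", "rec_fun", "a", "b"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"species table missing columns: {sorted(missing)}")
        names = (
            [str(x) for x in df["name"]] if "name" in df.columns
            else [f"sp{i}" for i in range(len(df))]
        )
        opt = lambda col: df[col].to_numpy(float) if col in df.columns else None
        return cls(
            names=names,
            linf=df["Linf"].to_numpy(float),
            lmat=df["Lmat"].to_numpy(float),
            w_a=df["W_a"].to_numpy(float),
            w_b=df["W_b"].to_numpy(float),
            k=df["k"].to_numpy(float),
            rec_fun=[str(x) for x in df["rec_fun"]],
            rec_a=df["a"].to_numpy(float),
            rec_b=df["b"].to_numpy(float),
            kappa=opt("kappa"),
            m1_fun=[str(x) for x in df["m1_fun"]] if "m1_fun" in df.columns else None,
            m1_rate=opt("m1_rate"),
            m1_prop=opt("m1_prop"),
        )
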