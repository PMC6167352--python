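"""External climate drivers: orbital precession and CO2 radiative forcing.

The vegetation model is driven by two slowly varying series — climatic
precession (the eccentricity-modulated precession parameter, dimensionless)
and the radiative forcing of atmospheric CO2 relative to the preindustrial
concentration of 278 ppm.  This module loads the two series from user tables,
converts CO2 concentrations to W m^-2, and resamples both onto the common
annual grid the simulator iterates over.

Time convention: the internal axis is years before present (BP, 1950 datum),
stored oldest -> youngest, i.e. strictly *decreasing* values.  User tables in
ka are multiplied by 1000; the unit must be declared in the column header
(``time_ka`` or ``time_yrBP``) or via an explicit argument — it is never
guessed from magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "PREINDUSTRIAL_CO2_PPM",
    "ForcingSeries",
    "co2_to_forcing",
    "load_forcing",
]

#: Preindustrial CO2 concentration (ppm by volume); F(278) = 0 by definition.
PREINDUSTRIAL_CO2_PPM = 278.0

#: Radiative-forcing coefficient for CO2 (W m^-2 per e-fold of concentration).
CO2_FORCING_COEFF = 5.35


def co2_to_forcing(co2):
    """Radiative forcing (W m^-2) of a CO2 concentration relative to preindustrial.

    Computed as ``5.35 * ln(co2 / 278)`` with ``co2`` in ppm, so 278 ppm maps
    to exactly 0 and a doubling adds 5.35*ln(2) ≈ 3.71 W m^-2.  Operates
    elementwise on arrays.

    Raises
    ------
    ValueError
        If any concentration is not strictly positive (or not finite).
    """
    c = np.asarray(co2, dtype=float)
    if not np.all(np.isfinite(c)) or np.any(c <= 0.0):
        raise ValueError("CO2 concentration must be finite and strictly positive (ppm)")
    out = CO2_FORCING_COEFF * np.log(c / PREINDUSTRIAL_CO2_PPM)
    return float(out) if np.isscalar(co2) else out


@dataclass(frozen=True)
class ForcingSeries:
    """Precession and radiative forcing on a shared, uniform years-BP axis.

    Attributes
    ----------
    time : ndarray
        Years BP, strictly decreasing (oldest first), uniform step equal to
        the simulation timestep.
    P : ndarray
        Climatic precession (dimensionless, typically within ±0.06).
    F : ndarray
        CO2 radiative forcing (W m^-2 relative to preindustrial).
    """

    time: np.ndarray
    P: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        P = np.asarray(self.P, dtype=float)
        F = np.asarray(self.F, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("forcing needs at least two time points")
        if not (P.shape == t.shape and F.shape == t.shape):
            raise ValueError("time, P and F must have equal length")
        steps = np.diff(t)
        if not np.all(steps < 0):
            raise ValueError("time must be strictly decreasing (oldest -> youngest, years BP)")
        if not np.allclose(steps, steps[0]):
            raise ValueError("time axis must be uniform")
        if not (np.all(np.isfinite(P)) and np.all(np.isfinite(F))):
            raise ValueError("P and F must be finite everywhere")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "F", F)

    # -- axis helpers ------------------------------------------------------

    @property
    def dt(self) -> float:
        """Timestep in years (positive)."""
        return float(self.time[0] - self.time[1])

    @property
    def oldest(self) -> float:
        return float(self.time[0])

    @property
    def youngest(self) -> float:
        return float(self.time[-1])

    def __len__(self) -> int:
        return self.time.size

    def slice(self, oldest: float, youngest: float) -> "ForcingSeries":
        """Sub-series covering [oldest, youngest] years BP (inclusive)."""
        if oldest <= youngest:
            raise ValueError("oldest must exceed youngest (years BP)")
        mask = (self.time <= oldest + 1e-9) & (self.time >= youngest - 1e-9)
        if mask.sum() < 2:
            raise ValueError("requested window not covered by this forcing series")
        return ForcingSeries(self.time[mask], self.P[mask], self.F[mask])

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_yrBP": self.time, "P": self.P, "F_Wm2": self.F})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ForcingSeries":
        df = pd.read_csv(path)
        return cls(df["time_yrBP"].to_numpy(), df["P"].to_numpy(), df["F_Wm2"].to_numpy())


def _read_two_column(table, value_col: str, time_unit: str | None):
    """Return (time_yrBP, values) from a CSV path or DataFrame.

    The time column header declares the unit (``time_ka`` or ``time_yrBP``)
    unless ``time_unit`` ('ka' or 'yrBP') overrides it.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table)
    else:
        df = pd.DataFrame(table)
    cols = list(df.columns)
    tcol = cols[0]
    if time_unit is None:
        if tcol == "time_ka":
            time_unit = "ka"
        elif tcol in ("time_yrBP", "time_yr"):
            time_unit = "yrBP"
        else:
            raise ValueError(
                f"cannot infer time unit from column {tcol!r}; "
                "use header time_ka / time_yrBP or pass time_unit explicitly"
            )
    t = df[tcol].to_numpy(dtype=float)
    if time_unit == "ka":
        t = t * 1000.0
    elif time_unit != "yrBP":
        raise ValueError(f"unknown time unit {time_unit!r}")
    vcol = value_col if value_col in df.columns else cols[1]
    v = df[vcol].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("forcing table needs at least 2 rows")
    order = np.argsort(-t, kind="stable")
    t_sorted = t[order]
    if np.any(np.diff(t_sorted) >= 0):
        raise ValueError("input times must be strictly monotone")
    return t_sorted, v[order]


def _interp_bp(t_grid, t_src, v_src):
    # np.interp needs increasing x; our convention is decreasing years BP.
    return np.interp(t_grid[::-1], t_src[::-1], v_src[::-1])[::-1]


def load_forcing(
    precession_table,
    co2_table,
    timestep: float = 1.0,
    *,
    time_unit: str | None = None,
) -> ForcingSeries:
    """Build a :class:`ForcingSeries` from precession and CO2 tables.

    Both tables (CSV path or DataFrame; columns ``time_ka,precession`` and
    ``time_ka,co2_ppm``, or the ``time_yrBP`` variants) are linearly
    interpolated onto a common grid with step ``timestep`` years, spanning the
    overlap of the two records.  No extrapolation is performed.  CO2 is
    converted to radiative forcing via :func:`co2_to_forcing`.

    Parameters
    ----------
    timestep : float
        Grid step in years (the simulation timestep), default 1.
    time_unit : str, optional
        'ka' or 'yrBP'; overrides header-based unit detection for both tables.
    """
    if timestep <= 0:
        raise ValueError("timestep must be positive")
    t_p, p = _read_two_column(precession_table, "precession", time_unit)
    t_c, c = _read_two_column(co2_table, "co2_ppm", time_unit)

    oldest = min(t_p[0], t_c[0])
    youngest = max(t_p[-1], t_c[-1])
    if oldest <= youngest:
        raise ValueError("precession and CO2 tables do not overlap in time")
    # snap the grid inward so it never extrapolates
    old_n = np.floor(oldest / timestep) * timestep
    young_n = np.ceil(youngest / timestep) * timestep
    n = int(round((old_n - young_n) / timestep)) + 1
    grid = old_n - timestep * np.arange(n)

    P = _interp_bp(grid, t_p, p)
    co2 = _interp_bp(grid, t_c, c)
    return ForcingSeries(grid, P, co2_to_forcing(co2))
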