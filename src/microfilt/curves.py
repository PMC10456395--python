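"""Filtration-curve container and CSV I/O.

A constant-pressure filtration experiment is recorded as the cumulative
filtrate volume per unit membrane area, ``v(t)`` (metres), against time
(seconds).  Raw bench data are usually logged as filtrate *mass* on a
balance; :func:`read_curve_csv` converts mass to volume-per-area given the
membrane's active area and the fluid density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Density of water at 25 degC, kg/m^3 — default for mass-to-volume conversion.
WATER_DENSITY = 997.0

_MONOTONE_MSG = "filtrate volume v must be non-decreasing"


@dataclass(frozen=True)
class FiltrationCurve:
    """Cumulative filtrate volume per unit membrane area versus time.

    Parameters
    ----------
    times :
        Sample times in seconds; strictly increasing, first entry >= 0.
    v :
        Filtrate volume per unit membrane area in metres, same length as
        ``times``; non-negative and non-decreasing.  If the curve starts at
        t = 0 then v(0) must be 0.
    flux :
        Optional instantaneous filtration rate J in m/s at the same times.
    """

    times: np.ndarray
    v: np.ndarray
    flux: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        v = np.atleast_1d(np.asarray(self.v, dtype=float))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and v must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("curve is empty")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and v must be finite")
        if t[0] < 0:
            raise ValueError(f"times must start at >= 0, got {t[0]}")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("filtrate volume v must be non-negative")
        if v.size > 1 and np.any(np.diff(v) < 0):
            raise ValueError(_MONOTONE_MSG)
        if t[0] == 0.0 and v[0] != 0.0:
            raise ValueError("v at t = 0 must be 0")
        if self.flux is not None:
            j = np.atleast_1d(np.asarray(self.flux, dtype=float))
            object.__setattr__(self, "flux", j)
            if j.shape != t.shape:
                raise ValueError("flux must match times in length")
            if not np.all(np.isfinite(j)):
                raise ValueError("flux must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    def head(self, n: int) -> "FiltrationCurve":
        """Return a new curve holding the first ``n`` points."""
        if n < 1:
            raise ValueError("n must be >= 1")
        flux = None if self.flux is None else self.flux[:n]
        return FiltrationCurve(self.times[:n].copy(), self.v[:n].copy(), flux)


def read_curve_csv(
    path,
    *,
    area_m2: float | None = None,
    density_kg_m3: float = WATER_DENSITY,
) -> FiltrationCurve:
    """Read a filtration curve from CSV.

    Two dialects are accepted: ``time_s,v_m`` (volume per unit area,
    ready to use) or ``time_s,mass_g`` (balance readings in grams, converted
    via ``v = m / (rho * A)`` — requires ``area_m2``).
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("curve CSV must have a 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if "v_m" in df.columns:
        v = df["v_m"].to_numpy(dtype=float)
    elif "mass_g" in df.columns:
        if area_m2 is None or area_m2 <= 0:
            raise ValueError(
                "mass_g curves need a positive membrane active area (area_m2)"
            )
        v = (df["mass_g"].to_numpy(dtype=float) / 1e3) / (density_kg_m3 * area_m2)
    else:
        raise ValueError("curve CSV must have a 'v_m' or 'mass_g' column")
    return FiltrationCurve(t, v)


def write_curve_csv(curve: FiltrationCurve, path) -> None:
    """Write a curve in the ``time_s,v_m`` dialect."""
    pd.DataFrame({"time_s": curve.times, "v_m": curve.v}).to_csv(path, index=False)
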