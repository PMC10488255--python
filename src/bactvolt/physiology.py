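"""Electrophysiological calibration and growth kinetics.

Two small pieces of physiology anchor the image-based depolarization
read-out to physical quantities:

* The Nernst equilibrium potential for K+ sets the membrane potential that a
  valinomycin-permeabilized cell is clamped to by a given extracellular KCl
  concentration: V_eq = (RT/zF) ln([K+]out/[K+]in).  A KCl series designed
  this way (e.g. 0/15/60/300 mM added on a ~3 mM PBS baseline against ~300 mM
  intracellular K+) spans roughly -75 mV to full depolarization at 0 mV.
* The specific growth rate r_t = d ln N / dt, estimated locally from an
  OD600 time series, characterizes the proliferative state of the culture at
  the sampling time (exponential-phase *B. subtilis*: ~0.011 min^-1,
  doubling time ~64 min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthgen import GrowthSeries

__all__ = [
    "NernstConfig",
    "nernst_potential",
    "kcl_series_design",
    "specific_growth_rate",
]

GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1
FARADAY_CONSTANT = 96485.332  # C mol^-1


@dataclass(frozen=True)
class NernstConfig:
    """Physical constants and ion concentrations for the K+ equilibrium potential.

    Concentrations are millimolar.  Defaults: body-temperature incubation
    (310.15 K), monovalent K+ (z = +1), ~300 mM intracellular K+, and a
    ~3 mM extracellular baseline (1x PBS).
    """

    T: float = 310.15
    z: int = 1
    K_in: float = 300.0
    K_out_base: float = 3.0
    added_KCl: float = 0.0
    R: float = GAS_CONSTANT
    F: float = FARADAY_CONSTANT

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.z == 0:
            raise ValueError("ion valence must be non-zero")
        if self.K_in <= 0:
            raise ValueError("intracellular concentration must be positive")
        if self.K_out_base + self.added_KCl <= 0:
            raise ValueError("total extracellular concentration must be positive")
        if self.added_KCl < 0:
            raise ValueError("added KCl cannot be negative")

    @property
    def K_out(self) -> float:
        return self.K_out_base + self.added_KCl


def nernst_potential(config: NernstConfig) -> float:
    """Equilibrium potential V_eq = (RT/zF) ln(K_out/K_in), in millivolts."""
    return (
        config.R
        * config.T
        / (config.z * config.F)
        * math.log(config.K_out / config.K_in)
        * 1000.0
    )


def kcl_series_design(
    added_list: list[float],
    config: NernstConfig | None = None,
    round_to: float | None = None,
) -> pd.DataFrame:
    """Tabulate the equilibrium potential reached by each added-KCl step.

    ``round_to`` (mV) optionally rounds the reported potential to the nearest
    multiple for presentation — the underlying computation is never rounded.
    Returns columns ``added_KCl_mM, V_eq_mV`` (plus ``V_eq_rounded_mV`` when
    rounding is requested).
    """
    if config is None:
        config = NernstConfig()
    if round_to is not None and round_to <= 0:
        raise ValueError("round_to must be positive")
    rows = []
    for added in added_list:
        if added < 0:
            raise ValueError("added KCl cannot be negative")
        v = nernst_potential(replace(config, added_KCl=float(added)))
        row = {"added_KCl_mM": float(added), "V_eq_mV": v}
        if round_to is not None:
            row["V_eq_rounded_mV"] = float(round_to * np.rint(v / round_to))
        rows.append(row)
    columns = ["added_KCl_mM", "V_eq_mV"] + (
        ["V_eq_rounded_mV"] if round_to is not None else []
    )
    return pd.DataFrame(rows, columns=columns)


def specific_growth_rate(series: GrowthSeries, t: float, window: int = 3) -> float:
    """Local specific growth rate r_t = d ln(OD)/dt at time *t* (min^-1).

    Fits a least-squares line to ln(OD) versus time over ``window``
    consecutive samples centred (as nearly as possible) on *t* and returns
    its slope.  For exactly exponential growth the result is the rate
    constant at every *t*; on a plateau it is 0.
    """
    times = series.times_min
    od = series.od600
    if window < 2:
        raise ValueError("window must span at least 2 points")
    if len(times) < window:
        raise ValueError(f"series has {len(times)} points, fewer than window={window}")
    if not (times[0] <= t <= times[-1]):
        raise ValueError(f"t={t} outside the sampled range [{times[0]}, {times[-1]}]")
    if np.any(od <= 0):
        raise ValueError("OD values must be positive to take logarithms")

    center = int(np.argmin(np.abs(times - t)))
    lo = max(0, min(center - window // 2, len(times) - window))
    sel = slice(lo, lo + window)
    slope = np.polyfit(times[sel], np.log(od[sel]), 1)[0]
    return float(slope)
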