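"""Seeded generators emulating the laboratory and climate designs.

The study designs these generators emulate:

* radial growth at six constant temperatures {15, 20, 25, 30, 33, 35}
  degC with four replicate plates;
* adult-mortality bioassays at five temperatures {10, 15, 20, 25, 30}
  degC, four replicates of 20 insects each, observed daily for 12 days;
* WorldClim-style monthly minimum/maximum temperature grids.

Every generator is a pure function of (design, truth parameters, seed):
the same seed always reproduces the identical dataset, which is what
makes parameter-recovery experiments and the end-to-end
simulate -> fit -> project test meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .bioassay import TIME_MORTALITY_COLUMNS, TimeMortalityTable
from .fitting import ResponseDataset
from .spatial import RasterGrid, TemperatureRasterStack
from .tpc_models import Briere1Params, Logan1Params, eval_briere1, eval_logan1

__all__ = [
    "SimulationDesign",
    "GROWTH_TEMPERATURES",
    "VIRULENCE_TEMPERATURES",
    "simulate_growth",
    "simulate_virulence",
    "simulate_time_mortality",
    "simulate_raster",
]

GROWTH_TEMPERATURES: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 33.0, 35.0)
VIRULENCE_TEMPERATURES: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class SimulationDesign:
    """Experimental layout plus noise model for the generators.

    Defaults mirror the study scale: 4 replicates, 20 insects per
    replicate, 12 observation days, 5% background control mortality so
    the Abbott correction is exercised non-trivially.  ``noise_sd`` is
    the Gaussian sd applied to growth rates (mm/day).
    """

    temperatures: tuple[float, ...] = GROWTH_TEMPERATURES
    replicates: int = 4
    insects_per_replicate: int = 20
    days: int = 12
    noise_sd: float = 0.1
    control_mortality: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.insects_per_replicate < 1 or self.days < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.control_mortality < 1:
            raise ValueError("control mortality must be in [0, 1)")


def simulate_growth(
    design: SimulationDesign, truth: Briere1Params, isolate: str = "SYN-1"
) -> ResponseDataset:
    """Gaussian-noise radial growth rates around a Briere-1 truth curve.

    Responses are ``eval_briere1(truth, T) + N(0, noise_sd)`` floored at
    zero (a plate cannot shrink).
    """
    rng = np.random.default_rng(design.seed)
    temps, resp, reps = [], [], []
    for t in design.temperatures:
        mu = eval_briere1(truth, t)
        draws = mu + rng.normal(0.0, design.noise_sd, size=design.replicates)
        for r, y in enumerate(draws, start=1):
            temps.append(t)
            resp.append(max(float(y), 0.0))
            reps.append(r)
    return ResponseDataset(np.array(temps), np.array(resp), np.array(reps),
                           response_kind="growth_rate", isolate=isolate)


def simulate_virulence(
    design: SimulationDesign, truth: Logan1Params, isolate: str = "SYN-1"
) -> pd.DataFrame:
    """Binomial end-point mortality counts per replicate, with controls.

    The per-insect death probability at temperature T is the truth model
    clipped to [0, 1]; control replicates draw from the design's
    background mortality.  Columns: ``isolate, temperature_c, replicate,
    n_treated, n_dead, is_control``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    n = design.insects_per_replicate
    for t in design.temperatures:
        p = float(np.clip(eval_logan1(truth, t), 0.0, 1.0))
        for r in range(1, design.replicates + 1):
            rows.append((isolate, t, r, n, int(rng.binomial(n, p)), False))
        for r in range(1, design.replicates + 1):
            rows.append((isolate, t, r, n,
                         int(rng.binomial(n, design.control_mortality)), True))
    return pd.DataFrame(
        rows, columns=["isolate", "temperature_c", "replicate",
                       "n_treated", "n_dead", "is_control"]
    )


def simulate_time_mortality(
    design: SimulationDesign,
    intercept: float,
    slope: float,
    isolate: str = "SYN-1",
    temperature_c: float = 25.0,
) -> TimeMortalityTable:
    """Daily death counts from a logistic time-mortality curve.

    The cumulative death probability by day d is
    ``expit(intercept + slope * d)``; each insect's death day is drawn
    once from the implied discrete distribution, so cumulative counts
    are monotone by construction and daily increments are consistent
    binomial draws.  Control replicates die at the design's background
    rate, spread uniformly over days.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    rng = np.random.default_rng(design.seed)
    days = np.arange(1, design.days + 1)
    cum_p = expit(intercept + slope * days)
    rows = []
    n = design.insects_per_replicate
    for rep in range(1, design.replicates + 1):
        u = rng.random(n)
        # death day of each insect: first day with cum_p >= u; survivors never die
        death_day = np.searchsorted(cum_p, u, side="left")
        new_deaths = np.bincount(death_day[death_day < design.days],
                                 minlength=design.days)
        for d, nd in zip(days, new_deaths):
            rows.append((isolate, temperature_c, rep, int(d), int(nd), n, False))
        # controls: background mortality, uniform death day
        n_ctrl_dead = rng.binomial(n, design.control_mortality)
        ctrl_days = rng.integers(1, design.days + 1, size=n_ctrl_dead)
        ctrl_new = np.bincount(ctrl_days - 1, minlength=design.days)
        for d, nd in zip(days, ctrl_new):
            rows.append((isolate, temperature_c, rep, int(d), int(nd), n, True))
    return TimeMortalityTable(pd.DataFrame(rows, columns=TIME_MORTALITY_COLUMNS))


def simulate_raster(
    shape: tuple[int, int] = (20, 20),
    xllcorner: float = 30.0,
    yllcorner: float = -10.0,
    cellsize: float = 0.5,
    base_temp: float = 22.0,
    north_south_gradient: float = 10.0,
    seasonal_amplitude: float = 4.0,
    diurnal_range: float = 8.0,
    nodata_block: tuple[int, int] | None = (2, 2),
    seed: int = 0,
) -> TemperatureRasterStack:
    """Synthetic monthly temperature stack with latitude and season structure.

    The monthly mean in each cell is ``base + gradient * (row fraction
    from south) + amplitude * sin(2 pi (month-1)/12)``; t_min/t_max sit a
    half diurnal range below/above it, so t_min <= t_max everywhere by
    construction.  A small nodata block is carved out of the top-left
    corner for mask testing.  Stands in for WorldClim-style monthly
    grids in tests and demos.
    """
    nr, nc = shape
    if nr < 1 or nc < 1:
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    # row 0 is the northern edge; southern rows are the warm end here
    lat_frac = np.linspace(0.0, 1.0, nr)[:, None] * np.ones((1, nc))
    jitter = rng.normal(0.0, 0.1, size=(nr, nc))
    tmin_grids, tmax_grids = [], []
    for month in range(1, 13):
        mean = (base_temp + north_south_gradient * lat_frac
                + seasonal_amplitude * np.sin(2 * np.pi * (month - 1) / 12.0)
                + jitter)
        lo = mean - diurnal_range / 2.0
        hi = mean + diurnal_range / 2.0
        if nodata_block is not None:
            br, bc = nodata_block
            lo[:br, :bc] = np.nan
            hi[:br, :bc] = np.nan
        tmin_grids.append(RasterGrid(lo, xllcorner, yllcorner, cellsize))
        tmax_grids.append(RasterGrid(hi, xllcorner, yllcorner, cellsize))
    return TemperatureRasterStack(tmin_grids, tmax_grids)
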