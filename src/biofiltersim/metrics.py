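"""Biofilter performance metrics and model-vs-data comparison statistics.

The four standard performance descriptors are

    RE   = 100 (C_in - C_out) / C_in          [%]
    ILR  = Q C_in / V                         [g m^-3 h^-1]
    EC   = Q (C_in - C_out) / V               [g m^-3 h^-1]
    EBRT = V / Q                              [min]

Model-data agreement is summarized by the RMSE of the outlet concentration
and the coefficient of determination r^2 = 1 - SS_res / SS_tot about the
observed mean.  ``synthesize_observations`` draws replicate 'measured'
outlet series around a simulated trajectory (Gaussian noise) for end-to-end
exercises of the comparison pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .column import TimeSeriesResult
from .params import HOURS_PER_DAY

__all__ = [
    "PerformanceRecord",
    "ComparisonStats",
    "performance",
    "compare_series",
    "synthesize_observations",
]


@dataclass(frozen=True)
class PerformanceRecord:
    """One set of performance metrics for an (inlet, outlet) operating point."""

    c_in: float  # [g m^-3]
    c_out: float  # [g m^-3]
    flow_q: float  # [m^3 h^-1]
    volume_v: float  # [m^3]
    re: float  # [%]
    ilr: float  # [g m^-3 h^-1]
    ec: float  # [g m^-3 h^-1]
    ebrt: float  # [min]


def performance(
    c_in: float, c_out: float, flow_q: float, volume_v: float
) -> PerformanceRecord:
    """Compute RE, ILR, EC and EBRT for one operating point."""
    if c_in <= 0:
        raise ValueError("removal efficiency is undefined for c_in <= 0")
    if flow_q <= 0 or volume_v <= 0:
        raise ValueError("flow_q and volume_v must be > 0")
    if c_out < 0:
        raise ValueError("c_out must be >= 0")
    re = 100.0 * (c_in - c_out) / c_in
    ilr = flow_q * c_in / volume_v
    ec = flow_q * (c_in - c_out) / volume_v
    ebrt = volume_v / flow_q * 60.0
    return PerformanceRecord(
        c_in=c_in, c_out=c_out, flow_q=flow_q, volume_v=volume_v,
        re=re, ilr=ilr, ec=ec, ebrt=ebrt,
    )


@dataclass(frozen=True)
class ComparisonStats:
    """Model-vs-observation summary for outlet concentrations."""

    rmse: float  # [g m^-3]
    r_squared: float  # [-]
    n_points: int


def compare_series(model: TimeSeriesResult, observed: pd.DataFrame) -> ComparisonStats:
    """RMSE and r^2 between simulated and observed outlet concentrations.

    ``observed`` needs columns ``time_h`` and ``c_out`` (extra columns are
    ignored).  The simulated outlet is linearly interpolated to the
    observation times; observations outside the simulated span are dropped.
    """
    t_obs = np.asarray(observed["time_h"], dtype=float)
    c_obs = np.asarray(observed["c_out"], dtype=float)
    t_mod = model.samples["time_h"].to_numpy()
    c_mod = model.samples["c_out"].to_numpy()
    inside = (t_obs >= t_mod[0]) & (t_obs <= t_mod[-1])
    if inside.sum() < 2:
        raise ValueError("need at least 2 observation times within the simulated span")
    t_obs, c_obs = t_obs[inside], c_obs[inside]
    c_hat = np.interp(t_obs, t_mod, c_mod)
    resid = c_obs - c_hat
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((c_obs - np.mean(c_obs)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return ComparisonStats(rmse=rmse, r_squared=r2, n_points=int(t_obs.size))


def synthesize_observations(
    result: TimeSeriesResult,
    noise_sd: float = 0.10,
    n_replicates: int = 3,
    seed: int = 0,
    every_h: float = HOURS_PER_DAY,
) -> pd.DataFrame:
    """Synthetic 'measured' outlet series around a simulated trajectory.

    Draws ``n_replicates`` i.i.d. Gaussian readings (sd ``noise_sd``) around
    the simulated outlet at regular sampling times (daily by default) and
    reports the replicate mean and its standard error, mimicking triplicate
    gas-chromatography measurements.  Columns: time_h, c_out (replicate
    mean), c_out_se, n_replicates.  Reproducible given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    t_mod = result.samples["time_h"].to_numpy()
    c_mod = result.samples["c_out"].to_numpy()
    t_obs = np.arange(t_mod[0] + every_h, t_mod[-1] + 1e-9, every_h)
    c_true = np.interp(t_obs, t_mod, c_mod)
    reps = c_true[:, None] + noise_sd * rng.standard_normal((t_obs.size, n_replicates))
    mean = reps.mean(axis=1)
    se = (
        reps.std(axis=1, ddof=1) / np.sqrt(n_replicates)
        if n_replicates > 1
        else np.zeros_like(mean)
    )
    return pd.DataFrame(
        {
            "time_h": t_obs,
            "c_out": mean,
            "c_out_se": se,
            "n_replicates": n_replicates,
        }
    )
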