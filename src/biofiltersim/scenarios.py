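"""Scenario drivers: the daily-ramp run with jump detection, and the
hysteresis check that distinguishes a steady-state jump from biofilm decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .column import TimeSeriesResult, simulate
from .params import HOURS_PER_DAY, InletSchedule, ModelParameters, schedule_ramp

__all__ = [
    "JumpReport",
    "RampResult",
    "ramp_jump_parameters",
    "run_ramp_scenario",
    "check_hysteresis",
]

JUMP_RE_THRESHOLD = 50.0  # % — a day below this marks the activity jump
JUMP_FROM_THRESHOLD = 90.0  # % — the preceding day must have been this high


def ramp_jump_parameters() -> ModelParameters:
    """Parameter set of record for the daily-ramp jump scenario.

    Starts from the "steady_increase" preset (enlarged biofilm surface area
    A = 1.1 m^2 kg^-1) but keeps the biofilm diffusivity of the two-steady-
    states scenario, D = 1.5e-10 m^2 s^-1.  The per-column diffusivities in
    the shipped preset table are mutually inconsistent with a surface-area-
    only change between the two scenarios, and a film with D = 1.5e-11
    m^2 s^-1 cannot sustain near-complete removal at inlet concentrations
    around 8 g m^-3 (its diffusive flux caps column capacity near 7 g m^-3),
    so the ramp phenomenology -- weeks of ~100 % removal ending in a
    one-day collapse -- only exists at the larger diffusivity.
    """
    from dataclasses import replace

    from .params import SECONDS_PER_HOUR, preset

    p = preset("steady_increase")
    return p.with_(
        transport=replace(p.transport, diffusivity_d=1.5e-10 * SECONDS_PER_HOUR)
    )


@dataclass(frozen=True)
class JumpReport:
    """Daily bookkeeping around the first discontinuous drop in RE.

    Day indices are 1-based; RE values are end-of-day removal efficiencies
    [%] and inlet values are the scheduled concentrations [g m^-3].
    """

    jump_day: int  # first day with end-of-day RE below the threshold
    re_before: float  # RE on the last pre-jump day
    re_on: float  # RE on the jump day
    re_after: Optional[float]  # RE one day after (None if run ends)
    inlet_before: float  # inlet on the last pre-jump day
    inlet_on: float  # inlet on the jump day


@dataclass
class RampResult:
    """Ramp-scenario output: the simulated trajectories, the daily summary
    and the jump report (None when no jump occurred)."""

    result: TimeSeriesResult
    daily: pd.DataFrame
    jump: Optional[JumpReport]


def detect_jump(
    daily: pd.DataFrame,
    threshold: float = JUMP_RE_THRESHOLD,
    from_threshold: float = JUMP_FROM_THRESHOLD,
) -> Optional[JumpReport]:
    """First day whose end-of-day RE drops below ``threshold`` % coming from
    a high-activity day (previous day's RE >= ``from_threshold``).  The
    high-activity requirement excludes the start-up phase, where a still-thin
    film removes little.  None when no such drop occurs."""
    re = daily["re_percent"].to_numpy()
    days = daily.index.to_numpy()
    for k in range(1, len(days)):
        if days[k] - 1 != days[k - 1]:
            continue
        if np.isfinite(re[k]) and re[k] < threshold and re[k - 1] >= from_threshold:
            d = int(days[k])
            return _report(daily, d)
    return None


def _report(daily: pd.DataFrame, d: int) -> JumpReport:
    return JumpReport(
        jump_day=d,
        re_before=float(daily.loc[d - 1, "re_percent"]),
        re_on=float(daily.loc[d, "re_percent"]),
        re_after=float(daily.loc[d + 1, "re_percent"]) if d + 1 in daily.index else None,
        inlet_before=float(daily.loc[d - 1, "c_in"]),
        inlet_on=float(daily.loc[d, "c_in"]),
    )


def run_ramp_scenario(
    params: ModelParameters,
    increment: float = 0.272,
    n_days: int = 40,
    start_day_value: Optional[float] = None,
    sample_every: float = 1.0,
) -> RampResult:
    """Simulate a daily staircase of inlet concentrations and report the
    discontinuous RE drop, if any.

    The inlet rises by ``increment`` [g m^-3] each day (starting at one
    increment on day 1 by default).  RE is reported at end-of-day state.
    """
    if increment <= 0:
        raise ValueError("increment must be > 0")
    schedule = schedule_ramp(increment, n_days, start_day_value)
    result = simulate(
        schedule, params, t_end=n_days * HOURS_PER_DAY, sample_every=sample_every
    )
    daily = result.daily_records()
    return RampResult(result=result, daily=daily, jump=detect_jump(daily))


def check_hysteresis(
    ramp: RampResult,
    params: ModelParameters,
    n_days: float = 5.0,
    sample_every: float = 1.0,
) -> pd.DataFrame:
    """Drop the inlet one increment below the jump-day value, restarting from
    the post-jump state, and follow RE for ``n_days`` days.

    A genuine steady-state jump is hysteretic: the column stays on the
    low-activity branch and RE does not recover, whereas recovery would point
    to a mere transient.  Returns the end-of-day records of the continuation
    run (day indices continue the ramp's numbering).
    """
    if ramp.jump is None:
        raise ValueError("ramp run has no jump to continue from")
    t0 = ramp.jump.jump_day * HOURS_PER_DAY
    state = ramp.result.state_at(t0)
    lowered = ramp.jump.inlet_before  # one increment below the jump-day inlet
    schedule = InletSchedule(times_h=(0.0,), values=(lowered,))
    cont = simulate(
        schedule,
        params,
        t_start=t0,
        t_end=t0 + n_days * HOURS_PER_DAY,
        sample_every=sample_every,
        initial_state=state,
    )
    return cont.daily_records()
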