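"""Planar biofilm: Haldane kinetics, reaction-diffusion dynamics, steady
states and their multiplicity.

The film occupies the dimensionless coordinate x' in [0, 1], with the
substratum (packing surface) at x'=0 and the gas interface at x'=1.
Substrate enters at the interface, where Henry's law pins the liquid-phase
concentration to c_gas / H, diffuses inward (Fick's law) and is consumed by
Haldane (substrate-inhibited) kinetics:

    dC/dt = (D / L^2) d2C/dx'^2  -  V_max C rho_bio / (K_s + C + C^2/K_I)

with zero flux at the substratum.  Because the rate peaks at
C = sqrt(K_s K_I) and falls at higher concentrations, a sufficiently thick
film admits two stable steady states over a window of gas concentrations: a
diffusion-limited high-activity state (steep internal gradient) and a
near-saturated low-activity state (flat profile).  ``multiplicity_scan``
maps out that window by natural-parameter continuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .collocation import CollocationGrid, build_grid, integrate_profile
from .params import KineticParams, ModelParameters

__all__ = [
    "BiofilmState",
    "SteadyStateBranch",
    "MultiplicityResult",
    "haldane_rate",
    "growth_haldane_factor",
    "biofilm_rhs",
    "average_rate",
    "interface_flux",
    "solve_biofilm_steady",
    "steady_states",
    "depleted_guess",
    "multiplicity_scan",
    "SolverError",
    "DEGENERATE_THICKNESS",
]

logger = logging.getLogger(__name__)

# Films thinner than this are treated as kinetically degenerate (no removal);
# the PDE divides by L^2.
DEGENERATE_THICKNESS = 1e-12


class SolverError(RuntimeError):
    """Steady-state solver failed to converge; carries the residual norm."""

    def __init__(self, message: str, residual_norm: float):
        super().__init__(f"{message} (residual norm {residual_norm:.3e})")
        self.residual_norm = residual_norm


def haldane_rate(c, kinetics: KineticParams):
    """Volumetric Haldane consumption rate magnitude [g m^-3 h^-1].

    r(c) = V_max * c * rho_bio / (K_s + c + c^2 / K_I); increasing up to
    c = sqrt(K_s K_I), decreasing beyond it.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = kinetics.v_max * c * kinetics.rho_bio / (
        kinetics.k_s + c + c * c / kinetics.k_i
    )
    return float(out) if out.ndim == 0 else out


def growth_haldane_factor(c, kinetics: KineticParams):
    """Specific-growth Haldane factor mu_max*c/(K_s + c + c^2/K_I) [h^-1]."""
    c = np.maximum(np.asarray(c, dtype=float), 0.0)
    out = kinetics.mu_max * c / (kinetics.k_s + c + c * c / kinetics.k_i)
    return float(out) if out.ndim == 0 else out


@dataclass
class BiofilmState:
    """Concentration profile plus film geometry at one axial location.

    c_profile is ordered substratum (x'=0) -> gas interface (x'=1) and has
    one entry per collocation node.  thickness_l and biomass_x are linked by
    L = X / (A rho_bio) whenever both are populated.
    """

    c_profile: np.ndarray
    thickness_l: float
    biomass_x: Optional[float] = None

    def __post_init__(self):
        self.c_profile = np.asarray(self.c_profile, dtype=float)


@dataclass(frozen=True)
class SteadyStateBranch:
    """One steady state found at a given gas-phase concentration."""

    c_gas: float
    surface_concentration: float  # liquid-phase value at x'=1 [g m^-3]
    interface_flux: float  # substrate flux into the film [g m^-2 h^-1]
    branch_label: str  # high_activity | low_activity | intermediate
    profile: np.ndarray


@dataclass
class MultiplicityResult:
    """Outcome of a multiplicity scan over gas concentrations."""

    branches: list  # of SteadyStateBranch
    window: Optional[tuple] = None  # (lower fold, upper fold) [g m^-3]

    def branch_count(self, c_gas: float, rtol: float = 1e-6) -> int:
        return sum(1 for b in self.branches if abs(b.c_gas - c_gas) <= rtol * max(c_gas, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c_gas": [b.c_gas for b in self.branches],
                "flux": [b.interface_flux for b in self.branches],
                "branch_label": [b.branch_label for b in self.branches],
            }
        )


def _close_profile(c_interior: np.ndarray, c_surface: float, grid: CollocationGrid) -> np.ndarray:
    """Assemble the full node profile from interior values: the interface
    node carries the Henry's-law value and the substratum node is slaved to
    the zero-flux condition d1[0,:] . c = 0."""
    n = grid.n_nodes
    c = np.empty(n)
    c[1:-1] = c_interior
    c[-1] = c_surface
    c[0] = -(grid.d1[0, 1:] @ c[1:]) / grid.d1[0, 0]
    return c


def biofilm_rhs(
    state: BiofilmState, c_gas: float, params: ModelParameters, grid: Optional[CollocationGrid] = None
) -> np.ndarray:
    """Time derivative of the full biofilm profile [g m^-3 h^-1].

    Interior nodes receive diffusion minus reaction; the interface node is
    algebraically pinned to c_gas / H and the substratum node to the
    zero-flux condition, so their derivative slots are zero.
    """
    if state.thickness_l <= DEGENERATE_THICKNESS:
        raise ValueError(
            f"degenerate film (L={state.thickness_l!r} m); callers must bypass "
            "the biofilm below the thickness cutoff"
        )
    if grid is None:
        grid = build_grid(params.discretization.n_biofilm - 2)
    kin = params.kinetics
    tr = params.transport
    c = _close_profile(state.c_profile[1:-1], c_gas / tr.henry_h, grid)
    diffusion = (tr.diffusivity_d / state.thickness_l**2) * (grid.d2 @ c)
    reaction = haldane_rate(np.maximum(c, 0.0), kin)
    dcdt = diffusion - reaction
    dcdt[0] = 0.0
    dcdt[-1] = 0.0
    return dcdt


def average_rate(
    state: BiofilmState, kinetics: KineticParams, grid: CollocationGrid
) -> float:
    """Depth-averaged volumetric consumption rate, the quadrature of the
    Haldane rate over x' in [0, 1] [g m^-3 h^-1]."""
    return integrate_profile(grid, haldane_rate(np.maximum(state.c_profile, 0.0), kinetics))


def interface_flux(
    profile: np.ndarray, thickness_l: float, diffusivity_d: float, grid: CollocationGrid
) -> float:
    """Substrate flux into the film at the gas interface, (D/L) dC/dx'|_{x'=1}
    [g m^-2 h^-1]."""
    return float(diffusivity_d / thickness_l * (grid.d1[-1] @ profile))


def _steady_residual(u, c_surface, l2_over_d, kin, grid):
    """Scaled steady residual in the unknowns u = c at nodes 0..n-2.

    Row 0 enforces zero flux at the substratum; interior rows enforce
    diffusion = reaction, scaled by L^2/D so entries are O(reaction)."""
    c = np.empty(grid.n_nodes)
    c[:-1] = u
    c[-1] = c_surface
    res = np.empty(u.size)
    res[0] = grid.d1[0] @ c
    interior = grid.d2[1:-1] @ c - l2_over_d * haldane_rate(np.maximum(c[1:-1], 0.0), kin)
    res[1:] = interior
    return res


def solve_biofilm_steady(
    c_gas: float,
    thickness_l: float,
    params: ModelParameters,
    initial_guess: Optional[np.ndarray] = None,
    grid: Optional[CollocationGrid] = None,
    tol: float = 1e-10,
) -> BiofilmState:
    """Solve the steady reaction-diffusion boundary-value problem.

    Returns the converged :class:`BiofilmState`.  When several steady states
    exist the converged root depends on ``initial_guess`` (full node profile,
    or None for a saturated start at c_gas/H; if the saturated start finds no
    root -- it has none below the lower fold -- a depleted boundary-layer
    start is tried before giving up).
    """
    if c_gas < 0:
        raise ValueError("c_gas must be >= 0")
    if thickness_l <= 0:
        raise ValueError("thickness_l must be > 0")
    if grid is None:
        grid = build_grid(params.discretization.n_biofilm - 2)
    kin = params.kinetics
    tr = params.transport
    c_surface = c_gas / tr.henry_h
    if initial_guess is None:
        guesses = [
            np.full(grid.n_nodes, c_surface),
            depleted_guess(c_surface, thickness_l, params, grid),
        ]
    else:
        guesses = [np.asarray(initial_guess, dtype=float)]
    l2_over_d = thickness_l**2 / tr.diffusivity_d
    # residual is scaled by L^2/D, i.e. in concentration units of the profile
    res_scale = max(c_surface, params.kinetics.k_s)
    res_norm = np.inf
    sol = None
    for guess_full in guesses:
        for method in ("hybr", "lm"):  # lm: fallback for stalled steep layers
            cand = root(
                _steady_residual,
                guess_full[:-1],
                args=(c_surface, l2_over_d, kin, grid),
                method=method,
                tol=tol,
            )
            cand_norm = float(
                np.linalg.norm(
                    _steady_residual(cand.x, c_surface, l2_over_d, kin, grid), np.inf
                )
            )
            if sol is None or cand_norm < res_norm:
                sol, res_norm = cand, cand_norm
            if res_norm <= 1e-6 * res_scale:
                break
        if res_norm <= 1e-6 * res_scale:
            break
    if res_norm > 1e-6 * res_scale:
        raise SolverError("biofilm steady-state solve did not converge", res_norm)
    profile = np.empty(grid.n_nodes)
    profile[:-1] = sol.x
    profile[-1] = c_surface
    # spectral solutions of steep boundary layers undershoot slightly below
    # zero; tolerate small undershoot (clipped) but reject spurious roots
    if profile.min() < -0.1 * max(profile.max(), kin.k_s):
        raise SolverError("steady profile is substantially negative", res_norm)
    return BiofilmState(c_profile=np.maximum(profile, 0.0), thickness_l=thickness_l)


def _try_solve(c_gas, thickness_l, params, guess, grid):
    try:
        return solve_biofilm_steady(c_gas, thickness_l, params, guess, grid)
    except SolverError:
        return None


def depleted_guess(c_surface, thickness_l, params, grid, steepness: float = 1.0):
    """Boundary-layer seed for the diffusion-limited high-activity root:
    an exponential layer of penetration depth sqrt(2 D c_s / r_peak),
    optionally sharpened/flattened by ``steepness``."""
    kin, tr = params.kinetics, params.transport
    r_peak = haldane_rate(kin.c_peak, kin)
    delta = np.sqrt(2.0 * tr.diffusivity_d * max(c_surface, kin.k_s) / r_peak)
    prof = c_surface * np.exp(-(1.0 - grid.nodes) * steepness * thickness_l / delta)
    prof[-1] = c_surface
    return prof


def steady_states(
    c_gas: float,
    thickness_l: float,
    params: ModelParameters,
    grid: Optional[CollocationGrid] = None,
) -> list:
    """All distinct steady states found by multi-start (saturated plus a
    family of boundary-layer seeds), sorted by substratum concentration
    (most depleted, i.e. highest activity, first)."""
    if grid is None:
        grid = build_grid(params.discretization.n_biofilm - 2)
    cs = c_gas / params.transport.henry_h
    seeds = [np.full(grid.n_nodes, cs)]
    for steep in (0.3, 1.0, 3.0, 10.0, 30.0):
        seeds.append(depleted_guess(cs, thickness_l, params, grid, steep))
    found: list[BiofilmState] = []
    for seed in seeds:
        st = _try_solve(c_gas, thickness_l, params, seed, grid)
        if st is None:
            continue
        if not any(
            np.allclose(st.c_profile, f.c_profile, rtol=1e-3, atol=1e-8)
            for f in found
        ):
            found.append(st)
    found.sort(key=lambda s: s.c_profile[0])
    return found


def _is_stable(
    state: BiofilmState, c_gas: float, params: ModelParameters, grid: CollocationGrid
) -> bool:
    """Short relaxation from a 1% perturbation: stable states are recovered."""
    tr = params.transport
    tau = state.thickness_l**2 / tr.diffusivity_d  # diffusion time [h]
    c0 = state.c_profile[1:-1] * 1.01 + 1e-9

    def rhs(_t, u):
        c = _close_profile(u, c_gas / tr.henry_h, grid)
        dc = (tr.diffusivity_d / state.thickness_l**2) * (grid.d2 @ c) - haldane_rate(
            np.maximum(c, 0.0), params.kinetics
        )
        return dc[1:-1]

    sol = solve_ivp(rhs, (0.0, 50.0 * tau), c0, method="BDF", rtol=1e-8, atol=1e-12)
    if not sol.success:
        return False
    # judge recovery by the interface flux, which separates the branches
    # robustly even where interior concentrations are near zero
    relaxed = _close_profile(sol.y[:, -1], c_gas / tr.henry_h, grid)
    f_ref = interface_flux(state.c_profile, state.thickness_l, tr.diffusivity_d, grid)
    f_new = interface_flux(relaxed, state.thickness_l, tr.diffusivity_d, grid)
    return bool(abs(f_new - f_ref) < 0.05 * max(abs(f_ref), 1e-12))


def _flux_of(state: BiofilmState, params: ModelParameters, grid: CollocationGrid) -> float:
    return interface_flux(
        state.c_profile, state.thickness_l, params.transport.diffusivity_d, grid
    )


def multiplicity_scan(
    c_gas_range: Sequence[float],
    thickness_l: float,
    params: ModelParameters,
    label_stability: bool = False,
    fold_tol: float = 1e-3,
) -> MultiplicityResult:
    """Map the steady states of the film over a range of gas concentrations.

    Sweeps the range upward continuing the high-activity (depleted-interior)
    branch and downward continuing the low-activity (saturated) branch, keeps
    every distinct root, and brackets the fold concentrations of the
    hysteresis window by bisection on loss of convergence.  Thin films yield
    a single branch everywhere and an empty window.

    Parameters
    ----------
    c_gas_range : increasing gas concentrations to scan [g m^-3]
    thickness_l : film thickness [m]
    label_stability : additionally relax each root from a perturbation and
        relabel unstable roots "intermediate" (slower)
    fold_tol : relative bracket width for the fold bisection
    """
    c_vals = np.asarray(list(c_gas_range), dtype=float)
    if c_vals.size == 0 or np.any(np.diff(c_vals) <= 0):
        raise ValueError("c_gas_range must be non-empty and increasing")
    grid = build_grid(params.discretization.n_biofilm - 2)
    h = params.transport.henry_h

    def solve_from(c_gas, guess):
        return _try_solve(c_gas, thickness_l, params, guess, grid)

    # upward sweep: continue the most-depleted (high-activity) branch
    up: dict[int, BiofilmState] = {}
    prev = None
    for i, cg in enumerate(c_vals):
        if prev is None:
            # branch not picked up yet: multi-start, and keep trying at the
            # next concentration if every seed fails here
            roots = steady_states(cg, thickness_l, params, grid)
            if not roots:
                continue
            st = roots[0]
        else:
            st = solve_from(cg, prev)
            if st is None:
                break  # branch lost (fold passed)
        up[i] = st
        prev = st.c_profile.copy()

    # downward sweep: continue the most-saturated (low-activity) branch
    down: dict[int, BiofilmState] = {}
    prev = None
    for i in range(c_vals.size - 1, -1, -1):
        cg = c_vals[i]
        if prev is None:
            roots = steady_states(cg, thickness_l, params, grid)
            if not roots:
                continue
            st = roots[-1]
        else:
            st = solve_from(cg, prev)
            if st is None:
                break
        down[i] = st
        prev = st.c_profile.copy()

    branches: list[SteadyStateBranch] = []
    both: list[int] = []
    for i, cg in enumerate(c_vals):
        found: list[BiofilmState] = []
        for src in (up, down):
            st = src.get(i)
            if st is None:
                continue
            if not any(
                np.allclose(st.c_profile, f.c_profile, rtol=1e-4, atol=1e-9)
                for f in found
            ):
                found.append(st)
        if len(found) == 2:
            both.append(i)
            # seed an intermediate (unstable) root between the two
            mid_guess = 0.5 * (found[0].c_profile + found[1].c_profile)
            st_mid = solve_from(cg, mid_guess)
            if st_mid is not None and not any(
                np.allclose(st_mid.c_profile, f.c_profile, rtol=1e-3, atol=1e-8)
                for f in found
            ):
                found.append(st_mid)
        fluxes = [_flux_of(st, params, grid) for st in found]
        order = np.argsort(fluxes)[::-1]
        for rank, j in enumerate(order):
            st = found[j]
            if len(found) == 1:
                label = "high_activity" if i in up else "low_activity"
            elif rank == 0:
                label = "high_activity"
            elif rank == len(found) - 1:
                label = "low_activity"
            else:
                label = "intermediate"
            if label_stability and label != "intermediate" and len(found) > 1:
                if not _is_stable(st, cg, params, grid):
                    label = "intermediate"
            branches.append(
                SteadyStateBranch(
                    c_gas=float(cg),
                    surface_concentration=float(cg / h),
                    interface_flux=float(fluxes[j]),
                    branch_label=label,
                    profile=st.c_profile,
                )
            )

    window = None
    if both:
        i_lo, i_hi = min(both), max(both)
        upper = c_vals[i_hi]
        if i_hi + 1 < c_vals.size:
            upper = _bisect_fold(
                c_vals[i_hi], c_vals[i_hi + 1],
                up[i_hi].c_profile, down[i_hi].c_profile,
                thickness_l, params, grid, fold_tol,
            )
        lower = c_vals[i_lo]
        if i_lo - 1 >= 0:
            lower = _bisect_fold(
                c_vals[i_lo], c_vals[i_lo - 1],
                up[i_lo].c_profile, down[i_lo].c_profile,
                thickness_l, params, grid, fold_tol,
            )
        window = (float(lower), float(upper))
    return MultiplicityResult(branches=branches, window=window)


def _bisect_fold(
    c_two, c_one, high_prof, low_prof, thickness_l, params, grid, rel_tol
):
    """Bisect a fold concentration between ``c_two`` (two distinct steady
    states exist) and ``c_one`` (only one), continuing both branch profiles
    from the two-state side.  Returns the two-state edge of the bracket."""
    lo, hi = c_two, c_one
    hp, lp = high_prof, low_prof
    scale = max(abs(c_two), abs(c_one), 1e-12)
    while abs(hi - lo) > rel_tol * scale:
        mid = 0.5 * (lo + hi)
        h_root = _try_solve(mid, thickness_l, params, hp, grid)
        l_root = _try_solve(mid, thickness_l, params, lp, grid)
        distinct = (
            h_root is not None
            and l_root is not None
            and not np.allclose(
                h_root.c_profile, l_root.c_profile, rtol=1e-3, atol=1e-8
            )
        )
        if distinct:
            lo = mid
            hp, lp = h_root.c_profile, l_root.c_profile
        else:
            hi = mid
    return lo
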