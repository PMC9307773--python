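"""Independent numerical oracles used only by the test suite.

These deliberately avoid the package's collocation machinery: the biofilm
boundary-value problem is re-solved on a dense uniform finite-difference
grid with damped Newton iteration, and integrals are done by brute-force
trapezoid sums, so that agreement with the package is a genuine
cross-method check.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve


def haldane(c, kin):
    c = np.maximum(c, 0.0)
    return kin.v_max * c * kin.rho_bio / (kin.k_s + c + c * c / kin.k_i)


def haldane_prime(c, kin):
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    pos = c >= 0
    cp = np.maximum(c, 0.0)
    den = kin.k_s + cp + cp * cp / kin.k_i
    out[pos] = (kin.v_max * kin.rho_bio * (kin.k_s - cp * cp / kin.k_i) / den**2)[pos]
    return out


def fd_biofilm_steady(c_gas, thickness_l, params, n_points=500, depleted_start=False,
                      max_iter=200, tol=1e-8):
    """Steady biofilm profile by finite differences + damped Newton.

    Solves c'' = (L^2/D) r(c), c'(0) = 0, c(1) = c_gas/H on a uniform grid.
    Returns (x, profile) or None when Newton fails to converge.
    """
    kin = params.kinetics
    tr = params.transport
    cs = c_gas / tr.henry_h
    lam = thickness_l**2 / tr.diffusivity_d
    n = n_points
    h = 1.0 / (n - 1)
    x = np.linspace(0.0, 1.0, n)
    c = np.full(n, 1e-6 * max(cs, 1.0)) if depleted_start else np.full(n, cs)
    c[-1] = cs
    u = c[:-1].copy()  # unknowns: nodes 0..n-2

    main_lap = np.full(n - 1, -2.0 / h**2)
    off = np.full(n - 2, 1.0 / h**2)

    def residual(u):
        cfull = np.append(u, cs)
        f = np.empty(n - 1)
        f[0] = 2.0 * (cfull[1] - cfull[0]) / h**2 - lam * haldane(cfull[0], kin)
        f[1:] = (
            (cfull[:-2] - 2.0 * cfull[1:-1] + cfull[2:]) / h**2
            - lam * haldane(cfull[1:-1], kin)
        )
        return f

    # convergence scale: reaction magnitude plus the roundoff floor of the
    # 1/h^2 Laplacian
    scale = lam * haldane(max(cs, kin.c_peak), kin) + 1e-13 * max(cs, 1.0) / h**2
    for _ in range(max_iter):
        f = residual(u)
        norm = np.max(np.abs(f))
        if norm < tol * scale:
            prof = np.append(u, cs)
            if prof.min() < -1e-6 * max(cs, kin.k_s):
                return None
            return x, np.maximum(prof, 0.0)
        diag = main_lap - lam * haldane_prime(u, kin)
        diag[0] = -2.0 / h**2 - lam * haldane_prime(u[0], kin)
        jac = sparse.diags(
            [off, diag, np.append(2.0 / h**2, off[1:])], offsets=[-1, 0, 1], format="csc"
        )
        step = spsolve(jac, -f)
        # damped update
        alpha = 1.0
        improved = False
        for _ in range(30):
            u_new = u + alpha * step
            if np.max(np.abs(residual(u_new))) < norm:
                u = u_new
                improved = True
                break
            alpha *= 0.5
        if not improved:
            return None
    return None


def fd_interface_flux(x, profile, thickness_l, params):
    """Flux into the film from the steady balance: L * trapz(r(c))."""
    return thickness_l * np.trapezoid(haldane(profile, params.kinetics), x)


def fd_multistart(c_gas, thickness_l, params, n_points=500):
    """All distinct FD steady states from saturated and depleted starts,
    as a list of (x, profile, flux)."""
    out = []
    for depleted in (False, True):
        res = fd_biofilm_steady(c_gas, thickness_l, params, n_points, depleted)
        if res is None:
            continue
        x, prof = res
        flux = fd_interface_flux(x, prof, thickness_l, params)
        if not any(abs(flux - f) <= 1e-3 * max(abs(f), 1e-12) for _, _, f in out):
            out.append((x, prof, flux))
    return out
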