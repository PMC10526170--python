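"""Explicit finite-volume solver for the continuum fields on a polar grid.

Four coupled fields evolve on nodes r_j = j*dr (optionally x theta_k):

* ``Cp`` proliferative cells:  dCp/dt = -div(J_f + J_d) + Cp * eta_p(n, Cp)
* ``n``  nutrient:             dn/dt  = D_n lap(n) - Cp * lambda_p(n)
* ``M``  collagenase:          dM/dt  = D_M lap(M) - zeta * M * f
* ``f``  collagen:             df/dt  = -delta * M * f

with J_f = -D_i grad(Cp) (Fickian default; an experimental density-
dependent "nonconvex" mobility is available) and J_d = +chi_chem Cp
grad(n) (chemotaxis up the nutrient gradient; off by default).

Diffusion/advection terms are discretized conservatively: face fluxes on
the staggered radii r_{j+1/2}, divergence via (1/r) d(r J_r)/dr.  The
r = 0 node is closed by symmetry (finite-volume over the central disk,
equivalent to the L'Hopital limit 4*(u_1 - u_0)/dr^2).  Collagen has no
spatial operator and is integrated exactly per node.  Time marching is
forward Euler under the explicit stability bound held by ``GridSpec``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import (BoundaryConditions, GridSpec, InitialConditions,
                     ModelParameters)

__all__ = [
    "ContinuumState", "FluxField", "initial_state", "compute_cell_fluxes",
    "step_nutrient", "step_collagenase", "step_collagen", "step_cells",
    "run_continuum", "cell_mass", "eta_p", "lambda_p",
]


@dataclass
class ContinuumState:
    """The four concentration fields at one instant.

    Fields are ``(n_r,)`` arrays in axisymmetric mode or ``(n_r, n_theta)``
    on the full polar grid; node j = n_r - 1 is the channel boundary.
    """

    Cp: np.ndarray
    n: np.ndarray
    M: np.ndarray
    f: np.ndarray
    t: float = 0.0

    def copy(self) -> "ContinuumState":
        return ContinuumState(self.Cp.copy(), self.n.copy(), self.M.copy(),
                              self.f.copy(), self.t)

    def check_finite(self) -> None:
        for name in ("Cp", "n", "M", "f"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"non-finite values in field '{name}' at t={self.t:.6g} s")


@dataclass
class FluxField:
    """Face-centered cell fluxes.

    Radial components live on faces r_{j+1/2} (shape ``(n_r-1, ...)``);
    angular components on theta-faces (same shape as the field) or ``None``
    in axisymmetric mode.  ``J_f`` is the random-motility (free-energy)
    flux, ``J_d`` the chemotactic flux; both vanish wherever Cp = 0.
    """

    jf_r: np.ndarray
    jd_r: np.ndarray
    jf_theta: np.ndarray | None = None
    jd_theta: np.ndarray | None = None


_GEOM_CACHE: dict = {}


def _geom(grid: GridSpec) -> dict:
    """Memoized geometry arrays for one grid (faces, radii, FV weights)."""
    key = (grid.R, grid.n_r, grid.n_theta, grid.axisymmetric)
    g = _GEOM_CACHE.get(key)
    if g is None:
        dr = grid.dr
        rf = (np.arange(grid.n_r - 1) + 0.5) * dr
        r = np.arange(grid.n_r) * dr
        g = {
            "rf": rf,
            "r": r,
            "inv_rdr": 1.0 / (r[1:-1] * dr),        # interior nodes
            "inv_v0": 8.0 / (dr * dr),              # 1 / center volume
            "inv_vlast": 1.0 / ((r[-1] - dr / 4.0) * dr / 2.0),
            "inv_r2dth2": None,
        }
        if not grid.axisymmetric:
            with np.errstate(divide="ignore"):
                inv = np.where(r > 0, 1.0 / (r * grid.dtheta), 0.0)
                inv2 = np.where(r > 0, 1.0 / (r ** 2 * grid.dtheta ** 2), 0.0)
            g["inv_rdth"] = inv[:, None]
            g["inv_r2dth2"] = inv2[:, None]
        if len(_GEOM_CACHE) > 64:
            _GEOM_CACHE.clear()
        _GEOM_CACHE[key] = g
    return g


def _faces(grid: GridSpec) -> np.ndarray:
    """Radii of the interior faces r_{j+1/2}, j = 0..n_r-2."""
    return _geom(grid)["rf"]


def _radii(grid: GridSpec) -> np.ndarray:
    return _geom(grid)["r"]


def cell_volumes(grid: GridSpec) -> np.ndarray:
    """Per-node control volumes (area / dtheta, i.e. r dr weights).

    Node 0 owns the disk of radius dr/2, interior node j the annulus
    [r_j - dr/2, r_j + dr/2], the boundary node its inner half-annulus.
    Total cell mass is ``sum(vol * Cp) * 2*pi`` (axisymmetric) or
    ``sum(vol * Cp) * dtheta`` on the full grid.
    """
    dr = grid.dr
    r = _radii(grid)
    vol = r * dr
    vol[0] = dr * dr / 8.0
    vol[-1] = (r[-1] - dr / 4.0) * dr / 2.0
    return vol


def cell_mass(Cp: np.ndarray, grid: GridSpec) -> float:
    """Total cell content, integral of Cp over the disk."""
    vol = cell_volumes(grid)
    if Cp.ndim == 1:
        return float(np.sum(vol * Cp) * 2.0 * np.pi)
    return float(np.sum(vol[:, None] * Cp) * grid.dtheta)


def eta_p(n: np.ndarray, Cp: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Monod proliferation rate, gated off above the critical stress.

    The mechanical stress proxy is P_max * Cp / cp_packing; nodes at or
    above P_cr stop proliferating (contact/stress inhibition).
    """
    rate = params.eta_max * n / (params.n_half + n)
    stress = params.P_max * Cp / params.cp_packing
    return np.where(stress < params.P_cr, rate, 0.0)


def lambda_p(n: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Monod nutrient-consumption rate (per unit cell concentration)."""
    return params.lambda_max * n / (params.n_half + n)


def _radial_gradient_faces(u: np.ndarray, grid: GridSpec) -> np.ndarray:
    """du/dr on the faces r_{j+1/2} (exact for linear profiles)."""
    return np.diff(u, axis=0) / grid.dr


def _laplacian(u: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Conservative polar Laplacian; boundary row is left untouched (0)."""
    dr = grid.dr
    rf = _faces(grid)
    r = _radii(grid)
    lap = np.zeros_like(u)
    if u.ndim == 1:
        flux = rf * np.diff(u) / dr          # r_{j+1/2} * du/dr
        lap[1:-1] = np.diff(flux) / (r[1:-1] * dr)
        lap[0] = 4.0 * (u[1] - u[0]) / (dr * dr)
    else:
        flux = rf[:, None] * np.diff(u, axis=0) / dr
        lap[1:-1] = np.diff(flux, axis=0) / (r[1:-1, None] * dr)
        lap[0] = 4.0 * (u[1].mean() - u[0]) / (dr * dr)
        ang = (np.roll(u, -1, axis=1) - 2.0 * u + np.roll(u, 1, axis=1))
        lap[1:-1] += ang[1:-1] / (r[1:-1, None] ** 2 * grid.dtheta ** 2)
    return lap


def _nonconvex_mobility(cp_face: np.ndarray, params: ModelParameters,
                        well_depth: float = 1.0) -> np.ndarray:
    """Experimental density-dependent mobility for the free-energy flux.

    M(c) = D_i * c/cp * (1 - c/cp) * F''(c) with a double-well
    F(c) = well_depth * c^2 (1-c)^2 in packing units; F'' can change sign,
    producing uphill (aggregating) diffusion at intermediate densities.
    """
    c = np.clip(cp_face / params.cp_packing, 0.0, 1.0)
    fpp = well_depth * (12.0 * c * c - 12.0 * c + 2.0)
    return params.D_i * c * (1.0 - c) * fpp


def compute_cell_fluxes(state: ContinuumState, params: ModelParameters,
                        grid: GridSpec,
                        nonconvex: bool = False) -> FluxField:
    """Face-centered random-motility and chemotactic cell fluxes.

    Default mode is the Fickian limit J_f = -D_i grad(Cp); with
    ``nonconvex=True`` the experimental density-dependent mobility is used
    instead.  J_d = +chi_chem * Cp * grad(n) points up the nutrient
    gradient.
    """
    state.check_finite()
    Cp, n = state.Cp, state.n
    grad_cp = _radial_gradient_faces(Cp, grid)
    grad_n = _radial_gradient_faces(n, grid)
    if Cp.ndim == 1:
        cp_face = 0.5 * (Cp[1:] + Cp[:-1])
    else:
        cp_face = 0.5 * (Cp[1:] + Cp[:-1])
    if nonconvex:
        jf_r = -_nonconvex_mobility(cp_face, params) * grad_cp
    else:
        jf_r = -params.D_i * grad_cp
    jd_r = params.chi_chem * cp_face * grad_n
    jf_theta = jd_theta = None
    if Cp.ndim == 2:
        r = _radii(grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_rdth = np.where(r > 0, 1.0 / (r * grid.dtheta), 0.0)[:, None]
        dcp_th = (np.roll(Cp, -1, axis=1) - Cp) * inv_rdth
        dn_th = (np.roll(n, -1, axis=1) - n) * inv_rdth
        cp_face_th = 0.5 * (np.roll(Cp, -1, axis=1) + Cp)
        if nonconvex:
            jf_theta = -_nonconvex_mobility(cp_face_th, params) * dcp_th
        else:
            jf_theta = -params.D_i * dcp_th
        jd_theta = params.chi_chem * cp_face_th * dn_th
    return FluxField(jf_r=jf_r, jd_r=jd_r, jf_theta=jf_theta,
                     jd_theta=jd_theta)


def step_nutrient(state: ContinuumState, params: ModelParameters,
                  bc: BoundaryConditions, grid: GridSpec,
                  dt: float) -> np.ndarray:
    """One explicit step of nutrient diffusion minus Monod consumption."""
    n = state.n
    out = n + dt * (params.D_n * _laplacian(n, grid)
                    - state.Cp * lambda_p(n, params))
    out[-1] = bc.n0
    np.maximum(out, 0.0, out=out)
    return out


def step_collagenase(state: ContinuumState, params: ModelParameters,
                     bc: BoundaryConditions, grid: GridSpec,
                     dt: float) -> np.ndarray:
    """One explicit step of enzyme diffusion with binding loss zeta*M*f."""
    M = state.M
    out = M + dt * (params.D_M * _laplacian(M, grid)
                    - params.zeta * M * state.f)
    out[-1] = bc.M0
    np.maximum(out, 0.0, out=out)
    return out


def step_collagen(state: ContinuumState, params: ModelParameters,
                  dt: float) -> np.ndarray:
    """Exact per-node integration of df/dt = -delta*M*f over one step."""
    return state.f * np.exp(-params.delta * state.M * dt)


def _divergence(flux: FluxField, grid: GridSpec) -> np.ndarray:
    """Conservative polar divergence of a face-centered flux field."""
    dr = grid.dr
    rf = _faces(grid)
    r = _radii(grid)
    jr = flux.jf_r + flux.jd_r
    if jr.ndim == 1:
        div = np.zeros(grid.n_r)
        rj = rf * jr
        div[1:-1] = np.diff(rj) / (r[1:-1] * dr)
        div[0] = rj[0] / (dr * dr / 8.0)
    else:
        div = np.zeros((grid.n_r, jr.shape[1]))
        rj = rf[:, None] * jr
        div[1:-1] = np.diff(rj, axis=0) / (r[1:-1, None] * dr)
        div[0] = rj[0].mean() / (dr * dr / 8.0)
        jth = flux.jf_theta + flux.jd_theta
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_rdth = np.where(r > 0, 1.0 / (r * grid.dtheta), 0.0)[:, None]
        div[1:-1] += ((jth - np.roll(jth, 1, axis=1)) * inv_rdth)[1:-1]
    return div


def step_cells(state: ContinuumState, fluxes: FluxField,
               params: ModelParameters, bc: BoundaryConditions,
               grid: GridSpec, dt: float) -> np.ndarray:
    """One explicit step of cell transport plus stress-gated proliferation."""
    Cp = state.Cp
    out = Cp + dt * (-_divergence(fluxes, grid)
                     + Cp * eta_p(state.n, Cp, params))
    if bc.cell_bc == "dirichlet":
        out[-1] = bc.C_bc
    else:  # noflux: mirror the flux across the outer face
        rf = _faces(grid)
        r = _radii(grid)
        jr = fluxes.jf_r + fluxes.jd_r
        # undo the outer-face contribution for the boundary-adjacent cell
        # and give the boundary node a half-cell balance with zero outer flux
        if Cp.ndim == 1:
            vol_last = (r[-1] - grid.dr / 4.0) * grid.dr / 2.0
            out[-1] = Cp[-1] + dt * (rf[-1] * jr[-1] / vol_last
                                     + Cp[-1] * eta_p(state.n[-1], Cp[-1],
                                                      params))
        else:
            vol_last = (r[-1] - grid.dr / 4.0) * grid.dr / 2.0
            out[-1] = Cp[-1] + dt * (rf[-1] * jr[-1] / vol_last
                                     + Cp[-1] * eta_p(state.n[-1], Cp[-1],
                                                      params))
    np.maximum(out, 0.0, out=out)
    return out


def initial_state(ic: InitialConditions, grid: GridSpec) -> ContinuumState:
    """Uniform tumoroid disk of radius ``r_tumoroid`` in intact collagen."""
    r = _radii(grid)
    cp_profile = np.where(r <= ic.r_tumoroid, ic.C_i, 0.0)
    if grid.axisymmetric:
        shape = (grid.n_r,)
        Cp = cp_profile
    else:
        shape = (grid.n_r, grid.n_theta)
        Cp = np.repeat(cp_profile[:, None], grid.n_theta, axis=1)
    return ContinuumState(
        Cp=Cp.astype(float),
        n=np.full(shape, ic.n_i, dtype=float),
        M=np.full(shape, ic.M_init, dtype=float),
        f=np.full(shape, ic.f0, dtype=float),
        t=0.0,
    )


def advance(state: ContinuumState, params: ModelParameters,
            bc: BoundaryConditions, grid: GridSpec, dt: float,
            nonconvex: bool = False) -> ContinuumState:
    """Advance all four fields by one time step (new state object)."""
    fluxes = compute_cell_fluxes(state, params, grid, nonconvex=nonconvex)
    Cp = step_cells(state, fluxes, params, bc, grid, dt)
    n = step_nutrient(state, params, bc, grid, dt)
    M = step_collagenase(state, params, bc, grid, dt)
    f = step_collagen(state, params, dt)
    return ContinuumState(Cp=Cp, n=n, M=M, f=f, t=state.t + dt)


class AxisymStepper:
    """Buffered in-place time stepper for the axisymmetric Fickian case.

    Applies the same stencils in the same update order as :func:`advance`
    (agreement to rounding), but reuses preallocated scratch arrays, which
    matters over the several 10^5 explicit steps of a three-day run.  Only
    the default physics (Fickian cell flux, chemotaxis off, Dirichlet cell
    boundary) takes this path.
    """

    def __init__(self, params: ModelParameters, bc: BoundaryConditions,
                 grid: GridSpec, dt: float):
        if params.chi_chem != 0.0:
            raise ValueError("fast path requires chi_chem == 0")
        if bc.cell_bc != "dirichlet":
            raise ValueError("fast path requires the Dirichlet cell BC")
        self.params, self.bc, self.grid, self.dt = params, bc, grid, dt
        g = _geom(grid)
        self.rf, self.inv_rdr = g["rf"], g["inv_rdr"]
        n_r = grid.n_r
        self._flux = np.empty(n_r - 1)
        self._lap = np.empty(n_r)
        self._scr = np.empty(n_r)
        self._dCp = np.empty(n_r)
        self._dn = np.empty(n_r)
        self._dM = np.empty(n_r)
        self._expf = np.empty(n_r)
        self._stress_cap = params.P_cr * params.cp_packing / params.P_max
        self._inv_dr = 1.0 / grid.dr

    def _lap_into(self, u: np.ndarray, out: np.ndarray) -> np.ndarray:
        flux = self._flux
        np.subtract(u[1:], u[:-1], out=flux)
        flux *= self.rf
        flux *= self._inv_dr
        np.subtract(flux[1:], flux[:-1], out=out[1:-1])
        out[1:-1] *= self.inv_rdr
        out[0] = 4.0 * (u[1] - u[0]) * self._inv_dr * self._inv_dr
        out[-1] = 0.0
        return out

    def step(self, state: ContinuumState) -> None:
        """One forward-Euler step; every rate is evaluated on the old fields."""
        p, bc, dt = self.params, self.bc, self.dt
        Cp, n, M, f = state.Cp, state.n, state.M, state.f
        scr = self._scr

        # cell rate: D_i lap(Cp) + Cp * eta_max * n/(n_half+n), stress-gated
        dCp = self._lap_into(Cp, self._dCp)
        dCp *= p.D_i
        np.multiply(n, p.eta_max, out=scr)
        scr /= (p.n_half + n)
        scr *= Cp
        scr[Cp >= self._stress_cap] = 0.0
        dCp += scr

        # nutrient rate: D_n lap(n) - Cp * lambda_max * n/(n_half+n)
        dn = self._lap_into(n, self._dn)
        dn *= p.D_n
        np.multiply(n, p.lambda_max, out=scr)
        scr /= (p.n_half + n)
        scr *= Cp
        dn -= scr

        # collagenase rate: D_M lap(M) - zeta M f
        dM = self._lap_into(M, self._dM)
        dM *= p.D_M
        np.multiply(M, f, out=scr)
        scr *= p.zeta
        dM -= scr

        # collagen decay factor exp(-delta M dt), exact per node
        np.multiply(M, -p.delta * dt, out=self._expf)
        np.exp(self._expf, out=self._expf)

        # apply
        dCp *= dt
        Cp += dCp
        Cp[-1] = bc.C_bc
        np.maximum(Cp, 0.0, out=Cp)
        dn *= dt
        n += dn
        n[-1] = bc.n0
        np.maximum(n, 0.0, out=n)
        dM *= dt
        M += dM
        M[-1] = bc.M0
        np.maximum(M, 0.0, out=M)
        f *= self._expf

        state.t += dt


def run_continuum(params: ModelParameters, bc: BoundaryConditions,
                  ic: InitialConditions, grid: GridSpec,
                  n_snapshots: int = 12,
                  check_every: int = 200) -> list[ContinuumState]:
    """Time-march the continuum system, returning evenly spaced snapshots.

    Deterministic (there is no randomness in the continuum part).  Any
    non-finite node aborts with a diagnostic naming the field and time.
    """
    dt = grid.resolve_dt(params)
    n_steps = max(1, int(round(grid.t_end / dt)))
    snap_at = np.unique(np.linspace(0, n_steps, n_snapshots + 1).astype(int))
    state = initial_state(ic, grid)
    snapshots = [state.copy()]
    for step in range(1, n_steps + 1):
        state = advance(state, params, bc, grid, dt)
        if step % check_every == 0:
            state.check_finite()
        if step in snap_at:
            state.check_finite()
            snapshots.append(state.copy())
    return snapshots
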