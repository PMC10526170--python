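"""Discrete single-cell migration: biased random walk on the polar lattice.

The per-cell movement rule is obtained from the finite-difference form of
the single-cell flux J = -D_i grad(C) + chi_hap C grad(f): discretizing
dC/dt = D_i lap(C) - chi_hap div(C grad(f)) conservatively (face fluxes on
the staggered radii) and reading the update C^{i+1}_{j,k} = P0 C_{j,k} +
P1 C_{j+1,k} + P2 C_{j-1,k} + P3 C_{j,k+1} + P4 C_{j,k-1} as a master
equation gives per-step hop probabilities

    P1/P2 : +r / -r moves,  dt/dr^2 * (r_{j+-1/2}/r_j) * (D_i +- chi_hap*df/2)
    P3/P4 : +theta / -theta moves over the local arc length r_j*dtheta
    P0    : stay put (the remainder)

so the walk is unbiased isotropic diffusion when grad(f) = 0 and is biased
up the collagen gradient (haptotaxis) otherwise.  Raw coefficients that go
negative when the haptotactic term dominates the stencil are clipped at 0;
if the four move probabilities exceed 1 they are rescaled and the cell
never rests.  Cells reflect at the origin, are absorbed (marked dead) at
the channel boundary, and wrap in theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GridSpec, ModelParameters

__all__ = ["Agent", "MoveProbabilities", "AgentPopulation",
           "compute_move_probabilities", "move_probability_arrays",
           "step_agents", "shed_agents"]


@dataclass
class Agent:
    """One discrete invading cell on the (r, theta) lattice."""

    j: int          # radial node index
    k: int          # angular node index
    age: float = 0.0  # time since shedding, s
    alive: bool = True
    birth_t: float = 0.0  # simulation time at shedding, s


@dataclass
class MoveProbabilities:
    """Five-way movement distribution for one lattice site."""

    P0: float  # stay
    P1: float  # +r (forward)
    P2: float  # -r (backward)
    P3: float  # +theta (counterclockwise)
    P4: float  # -theta (clockwise)

    def as_array(self) -> np.ndarray:
        return np.array([self.P0, self.P1, self.P2, self.P3, self.P4])


class AgentPopulation:
    """Vectorized agent store (struct-of-arrays)."""

    def __init__(self):
        self.j = np.empty(0, dtype=np.int64)
        self.k = np.empty(0, dtype=np.int64)
        self.age = np.empty(0, dtype=float)
        self.alive = np.empty(0, dtype=bool)
        self.birth_t = np.empty(0, dtype=float)

    def __len__(self) -> int:
        return self.j.size

    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive))

    def append(self, j: np.ndarray, k: np.ndarray, t: float) -> None:
        m = len(j)
        self.j = np.concatenate([self.j, np.asarray(j, dtype=np.int64)])
        self.k = np.concatenate([self.k, np.asarray(k, dtype=np.int64)])
        self.age = np.concatenate([self.age, np.zeros(m)])
        self.alive = np.concatenate([self.alive, np.ones(m, dtype=bool)])
        self.birth_t = np.concatenate([self.birth_t, np.full(m, t)])

    def radii(self, grid: GridSpec) -> np.ndarray:
        return self.j * grid.dr

    def as_agents(self) -> list[Agent]:
        return [Agent(int(j), int(k), float(a), bool(al), float(b))
                for j, k, a, al, b in zip(self.j, self.k, self.age,
                                          self.alive, self.birth_t)]


def _collagen_at(f_field: np.ndarray, j: np.ndarray,
                 k: np.ndarray, n_theta: int) -> np.ndarray:
    """Sample collagen at lattice sites; axisymmetric fields broadcast."""
    if f_field.ndim == 1:
        return f_field[j]
    return f_field[j, np.mod(k, n_theta)]


def _raw_rates(f_field: np.ndarray, grid: GridSpec, params: ModelParameters,
               j: np.ndarray, k: np.ndarray):
    """Hop rates (per unit time) for the four moves at sites (j, k).

    Conservative stencil: radial hops carry the polar metric factor
    r_{j+-1/2}/r_j, angular hops use the local arc length r_j*dtheta, so
    the diffusion limit is isotropic in physical space.  Negative rates
    (haptotaxis overwhelming the random term) are clipped to zero.
    """
    j = np.asarray(j)
    k = np.asarray(k)
    if np.any((j < 1) | (j > grid.n_r - 2)):
        raise ValueError("move probabilities are defined on strictly "
                         "interior radial nodes (1 <= j <= n_r-2)")
    if not np.all(np.isfinite(f_field)):
        raise FloatingPointError("non-finite collagen values in stencil")
    f_c = _collagen_at(f_field, j, k, grid.n_theta)
    f_p = _collagen_at(f_field, j + 1, k, grid.n_theta)
    f_m = _collagen_at(f_field, j - 1, k, grid.n_theta)
    if f_field.ndim == 1:  # no angular collagen variation
        f_kp = f_km = f_c
    else:
        f_kp = _collagen_at(f_field, j, k + 1, grid.n_theta)
        f_km = _collagen_at(f_field, j, k - 1, grid.n_theta)

    dr = grid.dr
    r = j * dr
    D = params.D_i
    chi = params.chi_hap
    w1 = ((r + 0.5 * dr) / r) * (D + 0.5 * chi * (f_p - f_c)) / dr**2
    w2 = ((r - 0.5 * dr) / r) * (D - 0.5 * chi * (f_c - f_m)) / dr**2
    arc = r * grid.dtheta
    w3 = (D + 0.5 * chi * (f_kp - f_c)) / arc**2
    w4 = (D - 0.5 * chi * (f_c - f_km)) / arc**2
    return (np.maximum(w1, 0.0), np.maximum(w2, 0.0),
            np.maximum(w3, 0.0), np.maximum(w4, 0.0))


def move_probability_arrays(f_field: np.ndarray, grid: GridSpec,
                            params: ModelParameters, j: np.ndarray,
                            k: np.ndarray, dt: float):
    """Vectorized (P0, P1, P2, P3, P4) for sites (j, k).

    After clipping, if the four move probabilities sum above 1 they are
    rescaled to sum to 1 exactly (P0 = 0); otherwise P0 is the remainder,
    so the five always sum to 1 exactly.
    """
    w1, w2, w3, w4 = _raw_rates(f_field, grid, params, j, k)
    p = np.stack([w1, w2, w3, w4]) * dt
    total = p.sum(axis=0)
    scale = np.where(total > 1.0, 1.0 / np.where(total > 0, total, 1.0), 1.0)
    p *= scale
    p0 = 1.0 - p.sum(axis=0)
    np.maximum(p0, 0.0, out=p0)
    return p0, p[0], p[1], p[2], p[3]


def compute_move_probabilities(f_field: np.ndarray, grid: GridSpec,
                               params: ModelParameters,
                               at: tuple[int, int],
                               dt: float | None = None) -> MoveProbabilities:
    """Movement distribution for a single interior site ``at = (j, k)``."""
    if dt is None:
        dt = grid.resolve_dt(params)
    j, k = at
    p0, p1, p2, p3, p4 = move_probability_arrays(
        f_field, grid, params, np.array([j]), np.array([k]), dt)
    return MoveProbabilities(float(p0[0]), float(p1[0]), float(p2[0]),
                             float(p3[0]), float(p4[0]))


def step_agents(pop: AgentPopulation, f_field: np.ndarray, grid: GridSpec,
                params: ModelParameters, dt: float,
                rng: np.random.Generator) -> AgentPopulation:
    """Advance every live agent by one move draw (in place).

    Draws one of {stay, +-r, +-theta} per agent from its local movement
    distribution; reflecting at r = 0, absorbing (alive -> False) at the
    outer boundary, periodic in theta.  Deterministic given the generator
    state.
    """
    live = np.flatnonzero(pop.alive)
    if live.size == 0:
        return pop
    if not np.all(np.isfinite(f_field)):
        raise FloatingPointError("non-finite collagen values in stencil")
    j = pop.j[live]
    k = pop.k[live]
    # clamp into the interior for the stencil; reflection handles j=0
    j_stencil = np.clip(j, 1, grid.n_r - 2)

    # inlined move_probability_arrays (hot path: runs every continuum step)
    dr = grid.dr
    D = params.D_i
    chi = params.chi_hap
    if f_field.ndim == 1:
        f_c = f_field[j_stencil]
        f_p = f_field[j_stencil + 1]
        f_m = f_field[j_stencil - 1]
        dfk_p = dfk_m = None
    else:
        nth = grid.n_theta
        f_c = f_field[j_stencil, k]
        f_p = f_field[j_stencil + 1, k]
        f_m = f_field[j_stencil - 1, k]
        dfk_p = f_field[j_stencil, (k + 1) % nth] - f_c
        dfk_m = f_c - f_field[j_stencil, (k - 1) % nth]
    r = j_stencil * dr
    inv_dr2 = 1.0 / (dr * dr)
    p1 = ((r + 0.5 * dr) / r) * (D + 0.5 * chi * (f_p - f_c)) * inv_dr2
    p2 = ((r - 0.5 * dr) / r) * (D - 0.5 * chi * (f_c - f_m)) * inv_dr2
    inv_arc2 = 1.0 / (r * grid.dtheta) ** 2
    if dfk_p is None:
        p3 = D * inv_arc2
        p4 = p3.copy()
    else:
        p3 = (D + 0.5 * chi * dfk_p) * inv_arc2
        p4 = (D - 0.5 * chi * dfk_m) * inv_arc2
    for p in (p1, p2, p3, p4):
        np.maximum(p, 0.0, out=p)
        p *= dt
    total = p1 + p2 + p3 + p4
    if np.any(total > 1.0):
        scale = np.where(total > 1.0, 1.0 / np.where(total > 0, total, 1.0),
                         1.0)
        for p in (p1, p2, p3, p4):
            p *= scale
        total = p1 + p2 + p3 + p4

    u = rng.random(live.size)
    c1 = np.maximum(1.0 - total, 0.0)  # stay probability
    c2 = c1 + p1
    c3 = c2 + p2
    c4 = c3 + p3
    dj = np.zeros(live.size, dtype=np.int64)
    dk = np.zeros(live.size, dtype=np.int64)
    dj[(u >= c1) & (u < c2)] = 1
    dj[(u >= c2) & (u < c3)] = -1
    dk[(u >= c3) & (u < c4)] = 1
    dk[u >= c4] = -1
    j_new = j + dj
    np.abs(j_new, out=j_new)  # reflect at the origin
    k_new = np.mod(k + dk, grid.n_theta)
    absorbed = j_new >= grid.n_r - 1
    pop.j[live] = np.minimum(j_new, grid.n_r - 1)
    pop.k[live] = k_new
    pop.age[live] += dt
    if np.any(absorbed):
        pop.alive[live[absorbed]] = False
    return pop


def shed_agents(Cp: np.ndarray, f_field: np.ndarray, pop: AgentPopulation,
                grid: GridSpec, params: ModelParameters,
                rng: np.random.Generator, t: float,
                front_alpha: float = 0.05, shed_gain: float = 5000.0,
                front_band_cells: int = 2, max_agents: int = 400,
                force_probability: float | None = None) -> int:
    """Spawn invading cells from the continuum front (in place).

    Nodes in the radial band just behind the ring front spawn an agent per
    angular slot with probability

        p = min(1, shed_gain * (Cp / max Cp) * |df/dr| * R / f_ref)

    i.e. proportional to the local cell concentration and the local
    collagen-gradient magnitude (no gradient, no detachment), capped at
    ``max_agents`` total.  Spawned mass is *not* removed from the
    continuum: agents are markers of invading cells.  Returns the number
    of agents spawned; if no front is found, returns 0.
    """
    profile = Cp if Cp.ndim == 1 else Cp.mean(axis=1)
    pmax = float(profile.max())
    if pmax <= 0.0:
        return 0
    above = np.flatnonzero(profile >= front_alpha * pmax)
    j_front = int(above[-1])
    j_lo = max(1, j_front - front_band_cells + 1)
    j_hi = min(grid.n_r - 2, j_front)
    if j_hi < j_lo:
        return 0
    band = np.arange(j_lo, j_hi + 1)
    f_prof = f_field if f_field.ndim == 1 else f_field.mean(axis=1)
    grad_f = np.abs(f_prof[band + 1] - f_prof[band - 1]) / (2.0 * grid.dr)
    f_ref = max(float(f_prof.max()), np.finfo(float).tiny)
    if force_probability is None:
        p_band = shed_gain * (profile[band] / pmax) * grad_f * grid.R / f_ref
        p_band = np.clip(p_band, 0.0, 1.0)
    else:
        p_band = np.full(band.size, float(force_probability))
    # one spawn trial per (band node, angular slot)
    u = rng.random((band.size, grid.n_theta))
    hits = u < p_band[:, None]
    jj, kk = np.nonzero(hits)
    room = max_agents - len(pop)
    if room <= 0:
        return 0
    if jj.size > room:
        jj, kk = jj[:room], kk[:room]
    pop.append(band[jj], kk, t)
    return int(jj.size)
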