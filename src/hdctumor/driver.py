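"""Orchestration of the coupled continuum/discrete simulation.

One hybrid run interleaves explicit continuum steps with per-step agent
moves (the walkers re-read the collagen field every continuum step by
default) and periodic shedding of discrete invaders from the ring front.
Snapshots, agent tracks and invasion metrics are recorded on an even
cadence; a dose sweep repeats runs over channel collagenase doses with
replicate seeds.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import continuum, metrics, migration
from .config import SECONDS_PER_DAY, SimulationConfig

__all__ = ["SimulationResult", "run_hybrid", "sweep_collagenase"]

log = logging.getLogger("hdctumor")


@dataclass
class SimulationResult:
    """Everything one hybrid run produces."""

    snapshots: list[continuum.ContinuumState]
    tracks: pd.DataFrame          # time_s, agent_id, r_cm, theta_rad, alive
    metrics: pd.DataFrame         # one row per snapshot time
    manifest: dict = field(default_factory=dict)


def _metrics_row(state, pop, cfg: SimulationConfig, r_front0: float) -> dict:
    grid = cfg.grid
    live_r = pop.radii(grid)[pop.alive] if len(pop) else np.empty(0)
    m = metrics.compute_metrics(
        state.Cp, live_r, grid, r_front0, state.t,
        alpha=cfg.hybrid.front_alpha,
        pattern_margin_frac=cfg.hybrid.pattern_margin_frac)
    return {
        "time_s": m.t,
        "day": m.t / SECONDS_PER_DAY,
        "r_front_cm": m.r_front,
        "L_ring_um": m.L_ring * metrics.CM_TO_UM,
        "L_finger_um": m.L_finger * metrics.CM_TO_UM,
        "L_overall_um": m.L_overall * metrics.CM_TO_UM,
        "area_um2": m.area * metrics.CM_TO_UM ** 2,
        "n_agents_alive": pop.n_alive,
        "pattern": m.pattern,
    }


def _tracks_rows(pop, grid, t: float) -> list[dict]:
    rows = []
    r = pop.radii(grid)
    theta = pop.k * grid.dtheta
    for i in range(len(pop)):
        rows.append({"time_s": t, "agent_id": i, "r_cm": float(r[i]),
                     "theta_rad": float(theta[i]),
                     "alive": bool(pop.alive[i])})
    return rows


def run_hybrid(cfg: SimulationConfig, seed: int | None = None,
               record_tracks: bool = True) -> SimulationResult:
    """Run the coupled simulation described by ``cfg``.

    Deterministic given the seed (``cfg.hybrid.seed`` unless overridden).
    A non-finite field aborts with the last good snapshot preserved in
    the raised exception's ``snapshots`` attribute.
    """
    cfg.validate()
    grid, params, bc, hyb = cfg.grid, cfg.params, cfg.boundary, cfg.hybrid
    seed = hyb.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    dt = grid.resolve_dt(params)
    n_steps = max(1, int(round(grid.t_end / dt)))
    snap_every = max(1, int(round(SECONDS_PER_DAY / hyb.snapshots_per_day / dt)))
    shed_every = max(1, int(round(hyb.shed_interval_s / dt)))

    state = continuum.initial_state(cfg.initial, grid)
    pop = migration.AgentPopulation()
    r_front0 = metrics.ring_front_radius(state.Cp, grid, hyb.front_alpha)

    metric_rows = [_metrics_row(state, pop, cfg, r_front0)]
    track_rows = _tracks_rows(pop, grid, 0.0) if record_tracks else []
    snapshots = [state.copy()]

    fast = (state.Cp.ndim == 1 and not hyb.nonconvex_flux
            and params.chi_chem == 0.0 and bc.cell_bc == "dirichlet")
    stepper = (continuum.AxisymStepper(params, bc, grid, dt)
               if fast else None)

    log.info("run_hybrid: seed=%d M0=%.3e M, %d steps of dt=%.3f s",
             seed, bc.M0, n_steps, dt)
    try:
        for step in range(1, n_steps + 1):
            if stepper is not None:
                stepper.step(state)
            else:
                state = continuum.advance(state, params, bc, grid, dt,
                                          nonconvex=hyb.nonconvex_flux)
            if step % shed_every == 0 and hyb.max_agents > 0:
                migration.shed_agents(
                    state.Cp, state.f, pop, grid, params, rng, state.t,
                    front_alpha=hyb.front_alpha, shed_gain=hyb.shed_gain,
                    front_band_cells=hyb.front_band_cells,
                    max_agents=hyb.max_agents)
            if step % hyb.agent_stride == 0 and len(pop):
                migration.step_agents(pop, state.f, grid, params,
                                      dt * hyb.agent_stride, rng)
            if step % snap_every == 0 or step == n_steps:
                state.check_finite()
                snapshots.append(state.copy())
                metric_rows.append(_metrics_row(state, pop, cfg, r_front0))
                if record_tracks:
                    track_rows.extend(_tracks_rows(pop, grid, state.t))
    except FloatingPointError as exc:
        exc.snapshots = snapshots  # last good states for post-mortem
        log.error("run_hybrid aborted: %s", exc)
        raise

    metrics_df = pd.DataFrame(metric_rows)
    tracks_df = pd.DataFrame(
        track_rows, columns=["time_s", "agent_id", "r_cm", "theta_rad",
                             "alive"])
    manifest = {
        "seed": seed,
        "dt_s": dt,
        "n_steps": n_steps,
        "r_front0_cm": r_front0,
        "config": {
            "parameters": asdict(params), "boundary": asdict(bc),
            "initial": asdict(cfg.initial), "grid": asdict(grid),
            "hybrid": asdict(hyb),
        },
    }
    return SimulationResult(snapshots=snapshots, tracks=tracks_df,
                            metrics=metrics_df, manifest=manifest)


def day_table(result: SimulationResult) -> pd.DataFrame:
    """Metric rows nearest to each whole simulated day."""
    df = result.metrics
    days = sorted({int(round(d)) for d in df["day"]})
    rows = []
    for d in days:
        i = (df["day"] - d).abs().idxmin()
        row = df.loc[i].copy()
        row["day"] = d
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def sweep_collagenase(cfg: SimulationConfig, doses, replicates: int = 3,
                      root_seed: int | None = None,
                      record_tracks: bool = False) -> pd.DataFrame:
    """One hybrid run per dose x replicate; tidy long-format day table.

    Replicates differ only by seed (root_seed + 1000 * replicate index),
    and the same seed set is reused across doses so dose contrasts share
    their random streams.  A failed run is flagged in the output and the
    sweep continues.
    """
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    root_seed = cfg.hybrid.seed if root_seed is None else int(root_seed)
    rows = []
    run_id = 0
    for dose_index, dose in enumerate(doses):
        dose_cfg = cfg.with_dose(dose)
        for rep in range(replicates):
            seed = root_seed + 1000 * rep
            label = {"run_id": run_id, "dose_mg_per_ml": dose,
                     "dose_index": dose_index, "replicate": rep,
                     "seed": seed}
            run_id += 1
            try:
                res = run_hybrid(dose_cfg, seed=seed,
                                 record_tracks=record_tracks)
            except (FloatingPointError, ValueError) as exc:
                log.error("sweep run failed (dose=%g rep=%d): %s",
                          dose, rep, exc)
                rows.append({**label, "day": np.nan, "failed": True})
                continue
            for _, mrow in day_table(res).iterrows():
                rows.append({**label, "failed": False, **mrow.to_dict()})
    return pd.DataFrame(rows)
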