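"""Model parameters, discretization settings, boundary/initial conditions.

All quantities are carried in the physical units in which they are usually
reported for this system: lengths in cm, time in s, diffusivities in
cm^2 s^-1, nutrient and cell concentrations in mg mL^-1, collagen and
collagenase concentrations in molar (M), stresses in kPa.  The collagenase
dose applied at the chip channel is stated in mg mL^-1 and converted to
molar units with :func:`dose_to_molar`.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

SECONDS_PER_DAY = 86400.0

#: Default molar mass used to convert a collagenase dose in mg/mL to molar
#: units (typical for MMP1 / collagenase type I), g/mol.  Configurable.
DEFAULT_COLLAGENASE_MOLAR_MASS = 55_000.0


class ConfigError(ValueError):
    """Raised when a configuration fails validation.

    ``errors`` collects every offending key so a bad file is reported in
    one pass rather than one failure at a time.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass
class ModelParameters:
    """Kinetic and transport coefficients of the tumoroid invasion model.

    Defaults are the literature/proposed values for U251 tumoroids in
    bovine fibril collagen.  ``eta_max``/``n_half``/``lambda_max``
    parameterize Monod-type proliferation and nutrient-consumption rates
    eta_p(n) = eta_max * n/(n_half+n) (gated off above the critical
    mechanical stress) and lambda_p(n) = lambda_max * n/(n_half+n).
    """

    D_i: float = 1e-8          # cell random-motility diffusivity, cm^2/s
    D_n: float = 4.2e-6        # nutrient (glucose) diffusivity, cm^2/s
    D_M: float = 1e-9          # collagenase diffusivity, cm^2/s
    chi_hap: float = 2.6e3     # haptotaxis coefficient, cm^2 s^-1 M^-1
    chi_chem: float = 0.0      # chemotaxis coefficient, cm^2 s^-1 (mg/mL)^-1
    zeta: float = 1e-6         # collagenase binding/loss rate, s^-1 M^-1
    delta: float = 1e-2        # collagen degradation rate, s^-1 M^-1
    eta_max: float = 1.0 / (24.0 * 3600.0)  # max proliferation rate, s^-1
    n_half: float = 1.0        # nutrient half-saturation, mg/mL
    lambda_max: float = 2e-10  # nutrient consumption per unit cell conc., s^-1 (mg/mL cells)^-1
    P_cr: float = 1.0          # critical mechanical stress, kPa
    P_max: float = 5.0         # maximum allowable stress, kPa
    cp_packing: float = 1e5    # cell concentration at close packing, mg/mL
    collagenase_molar_mass: float = DEFAULT_COLLAGENASE_MOLAR_MASS  # g/mol

    def validate(self) -> list[str]:
        errs = []
        for key in ("D_i", "D_n", "D_M"):
            if not getattr(self, key) > 0:
                errs.append(f"parameters.{key}: diffusivity must be > 0")
        for key in ("chi_hap", "chi_chem", "zeta", "delta", "eta_max",
                    "lambda_max"):
            if getattr(self, key) < 0:
                errs.append(f"parameters.{key}: rate must be >= 0")
        if not self.n_half > 0:
            errs.append("parameters.n_half: must be > 0")
        if not self.P_cr < self.P_max:
            errs.append("parameters.P_cr: must be < parameters.P_max")
        if not self.cp_packing > 0:
            errs.append("parameters.cp_packing: must be > 0")
        if not self.collagenase_molar_mass > 0:
            errs.append("parameters.collagenase_molar_mass: must be > 0")
        return errs


@dataclass
class BoundaryConditions:
    """Dirichlet values on the outer ring of nodes (the perfused channel).

    ``cell_bc`` selects how the cell field is closed at the channel:
    ``"dirichlet"`` pins Cp to ``C_bc`` (default 0: cells reaching the
    channel are washed away), ``"noflux"`` reflects (used for mass-balance
    benchmarks).
    """

    C_bc: float = 0.0      # cell concentration at the outer boundary, mg/mL
    n0: float = 4.5        # nutrient supply concentration, mg/mL
    M0: float = 0.0        # collagenase at the channel, M
    cell_bc: str = "dirichlet"

    def validate(self) -> list[str]:
        errs = []
        if not self.n0 > 0:
            errs.append("boundary.n0: must be > 0")
        if self.M0 < 0:
            errs.append("boundary.M0: must be >= 0")
        if self.C_bc < 0:
            errs.append("boundary.C_bc: must be >= 0")
        if self.cell_bc not in ("dirichlet", "noflux"):
            errs.append("boundary.cell_bc: must be 'dirichlet' or 'noflux'")
        return errs


@dataclass
class InitialConditions:
    """State at t = 0: a uniform tumoroid disk in intact collagen.

    Collagenase starts at zero everywhere; it only enters through the
    channel boundary.
    """

    C_i: float = 1e4         # initial tumoroid cell concentration, mg/mL
    n_i: float = 4.5         # initial nutrient concentration, mg/mL
    f0: float = 1e-9         # initial collagen fiber concentration, M
    M_init: float = 0.0      # initial collagenase, fixed at 0
    r_tumoroid: float = 0.03  # initial tumoroid radius, cm

    def validate(self, grid: "GridSpec | None" = None) -> list[str]:
        errs = []
        if self.M_init != 0.0:
            errs.append("initial.M_init: must be 0 (enzyme enters only "
                        "through the channel boundary)")
        if not self.f0 > 0:
            errs.append("initial.f0: must be > 0")
        if self.C_i < 0:
            errs.append("initial.C_i: must be >= 0")
        if not self.n_i > 0:
            errs.append("initial.n_i: must be > 0")
        if not self.r_tumoroid > 0:
            errs.append("initial.r_tumoroid: must be > 0")
        elif grid is not None and not self.r_tumoroid < grid.R:
            errs.append("initial.r_tumoroid: must be < grid.R")
        return errs


#: Safety factor applied to the explicit (FTCS) stability bound when the
#: time step is derived automatically.
DEFAULT_DT_SAFETY = 0.8
MAX_DT_SAFETY = 0.9


@dataclass
class GridSpec:
    """Polar grid and time discretization.

    Nodes sit at r_j = j * dr with dr = R / (n_r - 1); the outermost ring
    of nodes carries the Dirichlet data.  ``axisymmetric=True`` collapses
    the angular dimension for the continuum fields (discrete cells still
    move on the full (r, theta) lattice of ``n_theta`` angular slots).
    ``dt=None`` resolves to ``DEFAULT_DT_SAFETY`` times the explicit
    stability bound.
    """

    R: float = 0.25            # outer domain radius, cm
    n_r: int = 96              # radial node count
    n_theta: int = 64          # angular node count
    dt: float | None = None    # time step, s (None: derived from stability)
    t_end: float = 3.0 * SECONDS_PER_DAY  # total simulated time, s
    axisymmetric: bool = True

    @property
    def dr(self) -> float:
        return self.R / (self.n_r - 1)

    @property
    def dtheta(self) -> float:
        return 2.0 * math.pi / self.n_theta

    def stability_bound(self, params: ModelParameters,
                        safety: float = DEFAULT_DT_SAFETY) -> float:
        """Largest stable explicit time step, safety factor included.

        The limiting mesh length is the radial spacing in axisymmetric
        mode; on a full 2-D grid the innermost angular arc r_1 * dtheta is
        usually far smaller and dominates.
        """
        ell = self.dr
        if not self.axisymmetric:
            ell = min(ell, self.dr * self.dtheta)
        d_max = max(params.D_i, params.D_n, params.D_M)
        return safety * ell * ell / (4.0 * d_max)

    def resolve_dt(self, params: ModelParameters) -> float:
        """Return the configured dt, or the auto-derived stable one."""
        if self.dt is not None:
            return self.dt
        return self.stability_bound(params)

    def validate(self, params: ModelParameters | None = None) -> list[str]:
        errs = []
        if self.n_r < 16:
            errs.append("grid.n_r: must be >= 16")
        if self.n_theta < 4:
            errs.append("grid.n_theta: must be >= 4")
        if not self.R > 0:
            errs.append("grid.R: must be > 0")
        if not self.t_end > 0:
            errs.append("grid.t_end: must be > 0")
        if self.dt is not None and not self.dt > 0:
            errs.append("grid.dt: must be > 0")
        elif self.dt is not None and params is not None:
            bound = self.stability_bound(params, safety=MAX_DT_SAFETY)
            if self.dt > bound:
                errs.append(
                    f"grid.dt: {self.dt!r} s exceeds the explicit stability "
                    f"bound {bound:.6g} s (safety {MAX_DT_SAFETY})")
        return errs


@dataclass
class HybridSettings:
    """Knobs of the discrete/continuum coupling and invasion read-out."""

    seed: int = 0
    shed_gain: float = 2e6         # dimensionless spawn-probability gain
    shed_interval_s: float = 3600.0  # how often the front sheds agents, s
    max_agents: int = 600
    agent_stride: int = 1          # continuum steps per agent update
    snapshots_per_day: float = 4.0
    front_alpha: float = 0.05      # ring-front threshold fraction
    front_band_cells: int = 2      # radial band behind the front that sheds
    pattern_margin_frac: float = 0.1  # finger-vs-ring label margin, x r_front0
    nonconvex_flux: bool = False   # experimental density-dependent mobility

    def validate(self) -> list[str]:
        errs = []
        if self.shed_gain < 0:
            errs.append("hybrid.shed_gain: must be >= 0")
        if not self.shed_interval_s > 0:
            errs.append("hybrid.shed_interval_s: must be > 0")
        if self.max_agents < 0:
            errs.append("hybrid.max_agents: must be >= 0")
        if self.agent_stride < 1:
            errs.append("hybrid.agent_stride: must be >= 1")
        if not 0 < self.front_alpha <= 1:
            errs.append("hybrid.front_alpha: must be in (0, 1]")
        if not self.snapshots_per_day > 0:
            errs.append("hybrid.snapshots_per_day: must be > 0")
        return errs


@dataclass
class SimulationConfig:
    """Bundle of every section needed for a hybrid run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    boundary: BoundaryConditions = field(default_factory=BoundaryConditions)
    initial: InitialConditions = field(default_factory=InitialConditions)
    grid: GridSpec = field(default_factory=GridSpec)
    hybrid: HybridSettings = field(default_factory=HybridSettings)

    def validate(self) -> None:
        errs = (self.params.validate() + self.boundary.validate()
                + self.initial.validate(self.grid)
                + self.grid.validate(self.params) + self.hybrid.validate())
        if errs:
            raise ConfigError(errs)

    def with_dose(self, dose_mg_per_ml: float) -> "SimulationConfig":
        """Copy of this config with the channel collagenase set from a dose."""
        m0 = dose_to_molar(dose_mg_per_ml, self.params.collagenase_molar_mass)
        return replace(self, boundary=replace(self.boundary, M0=m0))


def dose_to_molar(dose_mg_per_ml: float,
                  molar_mass: float = DEFAULT_COLLAGENASE_MOLAR_MASS) -> float:
    """Convert a collagenase mass concentration (mg/mL) to molar units.

    mg/mL equals g/L, so the molar concentration is dose / molar_mass.
    """
    if dose_mg_per_ml < 0:
        raise ValueError(f"dose must be >= 0, got {dose_mg_per_ml}")
    if not molar_mass > 0:
        raise ValueError(f"molar_mass must be > 0, got {molar_mass}")
    return dose_mg_per_ml / molar_mass


_SECTIONS = {
    "parameters": ModelParameters,
    "boundary": BoundaryConditions,
    "initial": InitialConditions,
    "grid": GridSpec,
    "hybrid": HybridSettings,
}
# synth is parsed by hdctumor.synth but tolerated here so one file can
# configure a whole study.
_TOLERATED_SECTIONS = {"synth"}


def _coerce(section: str, key: str, value, target_type, errs: list[str]):
    if target_type is bool or isinstance(value, bool):
        if isinstance(value, bool) and target_type is bool:
            return value
        errs.append(f"{section}.{key}: expected {target_type.__name__}, "
                    f"got {value!r}")
        return None
    if target_type is int:
        if isinstance(value, int):
            return value
        errs.append(f"{section}.{key}: expected integer, got {value!r}")
        return None
    if target_type is float:
        if isinstance(value, (int, float)):
            return float(value)
        errs.append(f"{section}.{key}: expected number, got {value!r}")
        return None
    if target_type is str:
        if isinstance(value, str):
            return value
        errs.append(f"{section}.{key}: expected string, got {value!r}")
        return None
    # float | None (grid.dt)
    if isinstance(value, (int, float)):
        return float(value)
    errs.append(f"{section}.{key}: expected number, got {value!r}")
    return None


def _field_types(cls):
    out = {}
    for f in fields(cls):
        t = f.type
        if t in ("float", float):
            out[f.name] = float
        elif t in ("int", int):
            out[f.name] = int
        elif t in ("bool", bool):
            out[f.name] = bool
        elif t in ("str", str):
            out[f.name] = str
        else:  # "float | None"
            out[f.name] = None
    return out


def load_sim_config(path: str | Path) -> SimulationConfig:
    """Load and validate a full simulation configuration from a TOML file.

    Unspecified keys take the package defaults; unknown sections or keys,
    non-numeric values and invariant violations are all collected and
    reported together in a single :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        try:
            doc = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError([f"not parseable as TOML: {exc}"]) from exc

    errs: list[str] = []
    built = {}
    for section, cls in _SECTIONS.items():
        raw = doc.get(section, {})
        if not isinstance(raw, dict):
            errs.append(f"{section}: expected a table")
            raw = {}
        types = _field_types(cls)
        kwargs = {}
        for key, value in raw.items():
            if key not in types:
                errs.append(f"{section}.{key}: unknown key")
                continue
            coerced = _coerce(section, key, value, types[key], errs)
            if coerced is not None:
                kwargs[key] = coerced
        built[section] = cls(**kwargs)
    for section in doc:
        if section not in _SECTIONS and section not in _TOLERATED_SECTIONS:
            errs.append(f"{section}: unknown section")

    cfg = SimulationConfig(
        params=built["parameters"], boundary=built["boundary"],
        initial=built["initial"], grid=built["grid"], hybrid=built["hybrid"])
    try:
        cfg.validate()
    except ConfigError as exc:
        errs.extend(exc.errors)
    if errs:
        raise ConfigError(errs)
    return cfg


def load_config(path: str | Path) -> tuple[ModelParameters, BoundaryConditions,
                                           InitialConditions, GridSpec]:
    """Load a configuration, returning the four core sections."""
    cfg = load_sim_config(path)
    return cfg.params, cfg.boundary, cfg.initial, cfg.grid


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        # repr round-trips float64 bit-exactly
        return repr(value)
    if isinstance(value, int):
        return str(value)
    return '"' + str(value).replace('"', '\\"') + '"'


def config_to_toml(cfg: SimulationConfig) -> str:
    """Render a configuration as TOML; numeric values round-trip bit-exactly."""
    lines = []
    for section, obj in (("parameters", cfg.params), ("boundary", cfg.boundary),
                         ("initial", cfg.initial), ("grid", cfg.grid),
                         ("hybrid", cfg.hybrid)):
        lines.append(f"[{section}]")
        for key, value in asdict(obj).items():
            if value is None:
                continue  # grid.dt=None means "derive from stability"
            lines.append(f"{key} = {_toml_scalar(value)}")
        lines.append("")
    return "\n".join(lines)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(config_to_toml(cfg))


def default_config_toml() -> str:
    """The package defaults, rendered as a TOML document."""
    return config_to_toml(SimulationConfig())
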