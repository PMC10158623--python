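"""Kinetic batch model of adherent cell expansion on microcarriers.

The model tracks eight state variables: total, attached-viable and
suspension cell concentrations (cells mL^-1), glucose, glutamine, lactate
and ammonia (mmol L^-1), and a lumped unobservable limiting substrate
(arbitrary units L^-1, normalised to 1.0 for 100 % fresh medium).

Growth and death are controlled by the limiting substrate alone; glucose
and glutamine are consumed growth-coupled but are never limiting in the
rate laws for growth.  Space limitation on the carriers enters through the
free-surface fraction ``(X_Vmax - X_V)/X_Vmax``.  Cells attach from
suspension only during an initial attachment window of length ``t_att``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CultureState",
    "KineticParameters",
    "CarrierSpec",
    "CultureSetup",
    "Trajectory",
    "CultureMetrics",
    "STATE_COLUMNS",
    "xv_max",
    "specific_growth_rate",
    "specific_death_rate",
    "attachment_rate",
    "uptake_rates",
    "derivatives",
    "simulate_batch",
    "culture_metrics",
]

#: column order used for trajectory tables (time first)
STATE_COLUMNS = ("X_t", "X_V", "X_Sus", "c_Glc", "c_Gln", "c_LS", "c_Lac", "c_Amm")

# cells/L -> cells/mL
_PER_LITRE_TO_PER_ML = 1.0e-3
# cell states are volumetric per mL; substrate balances are per litre
_CELLS_PER_ML_TO_PER_L = 1.0e3


@dataclass(frozen=True)
class CultureState:
    """All dynamic quantities at one time point."""

    t: float  # h
    X_t: float  # total cells, cells mL^-1
    X_V: float  # attached viable cells, cells mL^-1
    X_Sus: float  # suspension cells, cells mL^-1
    c_Glc: float  # mmol L^-1
    c_Gln: float  # mmol L^-1
    c_LS: float  # a.u. L^-1
    c_Lac: float  # mmol L^-1
    c_Amm: float  # mmol L^-1

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.X_t, self.X_V, self.X_Sus, self.c_Glc, self.c_Gln,
             self.c_LS, self.c_Lac, self.c_Amm],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, t: float, y: Sequence[float]) -> "CultureState":
        return cls(t, *map(float, y))


@dataclass(frozen=True)
class KineticParameters:
    """Rate, saturation and yield constants of the batch model.

    All constants are strictly positive except ``t_att`` (>= 0).  The
    default values are a plausible, documented ground-truth fixture used by
    the synthetic data generator; they are not fitted values.
    """

    mu_max: float = 0.045        # h^-1, maximum specific growth rate
    K_S_LS: float = 0.08         # a.u. L^-1, LS half-saturation for growth
    mu_d_min: float = 0.003      # h^-1, minimum specific death rate
    mu_d_max: float = 0.004      # h^-1, maximum additional death rate
    K_d_LS: float = 0.10         # a.u. L^-1, LS half-saturation for death
    k_att_max: float = 0.30      # h^-1, attachment rate during the window
    t_att: float = 20.0          # h, attachment-window length
    K_Lys: float = 0.01          # h^-1, lysis rate of dead cells
    Y_X_Glc: float = 2.6e8       # cells mmol^-1, cell yield on glucose
    k_Glc: float = 0.5           # mmol L^-1
    Y_X_Gln: float = 8.0e8       # cells mmol^-1, cell yield on glutamine
    k_Gln: float = 0.3           # mmol L^-1
    q_LS_max: float = 8.0e-12    # a.u. cell^-1 h^-1, max specific LS uptake
    k_LS: float = 0.05           # a.u. L^-1
    Y_Lac_Glc: float = 1.6       # mmol lactate per mmol glucose
    Y_Amm_Gln: float = 0.85      # mmol ammonia per mmol glutamine
    #: if True, death rises as the limiting substrate is depleted
    #: (inverse-Monod); default False keeps the printed orientation in
    #: which death saturates with c_LS.
    inverse_death: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("t_att", "inverse_death"):
                continue
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v!r}")
        if self.t_att < 0:
            raise ValueError(f"t_att must be >= 0, got {self.t_att}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_values(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)

    @classmethod
    def numeric_names(cls) -> tuple[str, ...]:
        """Names of the numeric parameters, in declaration order."""
        return tuple(f.name for f in fields(cls) if f.name != "inverse_death")


@dataclass(frozen=True)
class CarrierSpec:
    """Physical properties of a microcarrier type."""

    name: str
    area_per_gram: float       # cm^2 g^-1
    max_area_density: float    # cells cm^-2 attachable at confluence

    def __post_init__(self) -> None:
        if self.area_per_gram <= 0:
            raise ValueError("area_per_gram must be > 0")
        if self.max_area_density <= 0:
            raise ValueError("max_area_density must be > 0")


@dataclass(frozen=True)
class CultureSetup:
    """Initial conditions and carrier loading for one shake-flask batch."""

    carrier: CarrierSpec
    c_MC: float                 # g L^-1
    seed_density: float         # cells cm^-2
    c_Glc: float                # mmol L^-1
    c_Gln: float                # mmol L^-1
    c_LS: float = 1.0           # a.u. L^-1, fresh-medium normalisation
    c_Lac: float = 0.0
    c_Amm: float = 0.0
    volume: float = 40.0        # mL, informational

    def __post_init__(self) -> None:
        if self.c_MC < 0:
            raise ValueError("c_MC must be >= 0")
        if self.seed_density < 0:
            raise ValueError("seed_density must be >= 0")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        for name in ("c_Glc", "c_Gln", "c_LS", "c_Lac", "c_Amm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def area_per_ml(self) -> float:
        """Carrier surface per mL of culture (cm^2 mL^-1)."""
        return self.c_MC * self.carrier.area_per_gram * _PER_LITRE_TO_PER_ML

    def inoculum_per_ml(self) -> float:
        """Seeded cells per mL (seed density spread over the carrier area)."""
        return self.seed_density * self.area_per_ml

    def initial_state(self) -> CultureState:
        """Inoculum starts entirely in suspension; attachment moves it to X_V."""
        x0 = self.inoculum_per_ml()
        return CultureState(
            t=0.0, X_t=x0, X_V=0.0, X_Sus=x0,
            c_Glc=self.c_Glc, c_Gln=self.c_Gln, c_LS=self.c_LS,
            c_Lac=self.c_Lac, c_Amm=self.c_Amm,
        )


def xv_max(setup: CultureSetup) -> float:
    """Carrying capacity of the carrier surface, cells mL^-1.

    c_MC [g/L] x area_per_gram [cm^2/g] x max_area_density [cells/cm^2]
    gives cells per litre; returned per mL.
    """
    return (
        setup.c_MC
        * setup.carrier.area_per_gram
        * setup.carrier.max_area_density
        * _PER_LITRE_TO_PER_ML
    )


def _space_fraction(X_V: float, X_V_max: float) -> float:
    if X_V_max <= 0.0:
        return 0.0
    return max(0.0, (X_V_max - X_V) / X_V_max)


def specific_growth_rate(
    c_LS: float, X_V: float, X_V_max: float, params: KineticParameters
) -> float:
    """mu = mu_max * c_LS/(c_LS + K_S_LS) * (X_Vmax - X_V)/X_Vmax, in h^-1."""
    if X_V_max <= 0.0:
        raise ValueError("X_V_max must be > 0 (degenerate setup without carriers)")
    c = max(0.0, c_LS)
    return params.mu_max * c / (c + params.K_S_LS) * _space_fraction(X_V, X_V_max)


def specific_death_rate(c_LS: float, params: KineticParameters) -> float:
    """mu_d = mu_d_min + mu_d_max * c_LS/(c_LS + K_d_LS), in h^-1.

    With ``params.inverse_death`` the Monod term is inverted so that death
    rises as the limiting substrate is depleted.
    """
    c = max(0.0, c_LS)
    monod = c / (c + params.K_d_LS)
    if params.inverse_death:
        monod = 1.0 - monod
    return params.mu_d_min + params.mu_d_max * monod


def attachment_rate(t: float, params: KineticParameters) -> float:
    """k_att(t): k_att_max inside the attachment window, 0 from t_att on."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return params.k_att_max if t < params.t_att else 0.0


def uptake_rates(
    state: CultureState, X_V_max: float, params: KineticParameters
) -> tuple[float, float, float]:
    """Specific uptake rates (q_Glc, q_Gln, q_LS).

    Glucose and glutamine uptake are growth-coupled (mu / yield) with their
    own saturation terms and the free-surface fraction; LS uptake is a plain
    Monod term.
    """
    mu = specific_growth_rate(state.c_LS, state.X_V, X_V_max, params)
    space = _space_fraction(state.X_V, X_V_max)
    c_glc = max(0.0, state.c_Glc)
    c_gln = max(0.0, state.c_Gln)
    c_ls = max(0.0, state.c_LS)
    q_glc = mu / params.Y_X_Glc * c_glc / (c_glc + params.k_Glc) * space
    q_gln = mu / params.Y_X_Gln * c_gln / (c_gln + params.k_Gln) * space
    q_ls = params.q_LS_max * c_ls / (c_ls + params.k_LS)
    return q_glc, q_gln, q_ls


def derivatives(
    t: float,
    state: CultureState,
    setup: CultureSetup,
    params: KineticParameters,
    X_V_max: float | None = None,
) -> np.ndarray:
    """Time derivatives of the eight state variables at ``t``."""
    if X_V_max is None:
        X_V_max = xv_max(setup)
    y = state.as_vector()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state at t={t}: {y}")
    return _rhs(t, y, X_V_max, params, attachment_rate(t, params))


def _rhs(
    t: float,
    y: np.ndarray,
    X_V_max: float,
    p: KineticParameters,
    k_att: float,
) -> np.ndarray:
    X_t, X_V, X_Sus, c_Glc, c_Gln, c_LS, c_Lac, c_Amm = y
    X_V = max(0.0, min(X_V, X_V_max)) if X_V_max > 0 else 0.0
    X_Sus = max(0.0, X_Sus)
    space = _space_fraction(X_V, X_V_max)

    c_ls = max(0.0, c_LS)
    if X_V_max > 0:
        mu = p.mu_max * c_ls / (c_ls + p.K_S_LS) * space
    else:
        mu = 0.0
    mu_d = specific_death_rate(c_ls, p)

    c_glc = max(0.0, c_Glc)
    c_gln = max(0.0, c_Gln)
    q_glc = mu / p.Y_X_Glc * c_glc / (c_glc + p.k_Glc) * space
    q_gln = mu / p.Y_X_Gln * c_gln / (c_gln + p.k_Gln) * space
    q_ls = p.q_LS_max * c_ls / (c_ls + p.k_LS)
    # no LS uptake by a cell-free culture
    attach_flux = k_att * space * X_Sus

    X_V_L = X_V * _CELLS_PER_ML_TO_PER_L  # substrate balances are per litre
    dX_t = mu * X_V - p.K_Lys * max(0.0, X_t - X_V)
    dX_V = (mu - mu_d) * X_V + attach_flux
    dX_Sus = mu_d * X_V - attach_flux
    dc_Glc = -q_glc * X_V_L
    dc_Gln = -q_gln * X_V_L
    dc_LS = -q_ls * X_V_L
    dc_Lac = p.Y_Lac_Glc * q_glc * X_V_L
    dc_Amm = p.Y_Amm_Gln * q_gln * X_V_L
    return np.array([dX_t, dX_V, dX_Sus, dc_Glc, dc_Gln, dc_LS, dc_Lac, dc_Amm])


@dataclass(frozen=True)
class Trajectory:
    """Simulated batch trajectory on a fixed time grid."""

    t: np.ndarray                 # h, shape (n,)
    states: np.ndarray            # shape (n, 8), columns per STATE_COLUMNS
    setup: CultureSetup
    params: KineticParameters

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_COLUMNS.index(name)]

    def state_at(self, i: int) -> CultureState:
        return CultureState.from_vector(float(self.t[i]), self.states[i])

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(self.states, columns=list(STATE_COLUMNS))
        frame.insert(0, "time_h", self.t)
        return frame


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails; carries the parameter set."""

    def __init__(self, message: str, params: KineticParameters):
        super().__init__(f"{message} (parameters: {params.to_dict()})")
        self.params = params


def simulate_batch(
    setup: CultureSetup,
    params: KineticParameters,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float | Sequence[float] | None = None,
    initial_state: CultureState | None = None,
) -> Trajectory:
    """Integrate the batch model over ``t_grid`` (strictly increasing, from 0).

    The attachment-rate switch at ``t_att`` is handled by splitting the
    integration into two segments, so the solver never steps across the
    discontinuity.  ``initial_state`` overrides the default partition
    (inoculum entirely in suspension).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must be a 1-D grid with at least two points")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")

    X_V_max = xv_max(setup)
    y0 = (initial_state or setup.initial_state()).as_vector()
    if atol is None:
        # cells run at 1e4-1e6 mL^-1, metabolites at 1e-1-1e2 mM
        cell_scale = max(y0[0], X_V_max, 1.0)
        atol = np.array([cell_scale * 1e-8] * 3 + [1e-10] * 5)

    t_end = float(t_grid[-1])
    breakpoints = [0.0]
    if 0.0 < params.t_att < t_end:
        breakpoints.append(float(params.t_att))
    breakpoints.append(t_end)

    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    y = y0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        k_att = params.k_att_max if a < params.t_att else 0.0
        mask = (t_grid >= a) & (t_grid <= b)
        t_eval = np.unique(np.concatenate([[a], t_grid[mask], [b]]))
        sol = solve_ivp(
            _rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            args=(X_V_max, params, k_att),
        )
        if not sol.success:
            raise IntegrationError(f"integration failed on [{a}, {b}]: {sol.message}", params)
        keep = np.isin(sol.t, t_grid[mask])
        out_t.append(sol.t[keep])
        out_y.append(sol.y[:, keep].T)
        y = sol.y[:, -1]

    t_all = np.concatenate(out_t)
    y_all = np.vstack(out_y)
    # segment boundaries may duplicate a grid point
    _, idx = np.unique(t_all, return_index=True)
    t_all, y_all = t_all[idx], y_all[idx]
    if len(t_all) != len(t_grid):
        raise IntegrationError("solver did not return all requested times", params)

    y_all = np.clip(y_all, 0.0, None)
    if X_V_max > 0:
        y_all[:, 1] = np.minimum(y_all[:, 1], X_V_max)
    y_all[:, 0] = np.maximum(y_all[:, 0], y_all[:, 1])
    return Trajectory(t=t_all, states=y_all, setup=setup, params=params)


@dataclass(frozen=True)
class CultureMetrics:
    """Endpoint summary of a batch: area-specific maximum and fold expansion."""

    X_max_per_cm2: float   # cells cm^-2, trajectory maximum of attached cells
    t_at_max: float        # h, first time the maximum is attained
    VF: float              # multiplication factor X_max / seed density
    PD: float              # population doublings, log2(VF)


def culture_metrics(trajectory: Trajectory, setup: CultureSetup | None = None) -> CultureMetrics:
    """Area-specific maximum attached cell density, its time, VF and PD."""
    if setup is None:
        setup = trajectory.setup
    if setup.seed_density <= 0:
        raise ValueError("seed_density must be > 0 for fold-expansion metrics")
    area = setup.area_per_ml
    if area <= 0:
        raise ValueError("setup has no carrier surface (c_MC = 0)")
    per_cm2 = trajectory.column("X_V") / area
    i = int(np.argmax(per_cm2))
    x_max = float(per_cm2[i])
    vf = x_max / setup.seed_density
    pd_ = float(np.log2(vf)) if vf > 0 else float("-inf")
    return CultureMetrics(
        X_max_per_cm2=x_max, t_at_max=float(trajectory.t[i]), VF=vf, PD=pd_
    )
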