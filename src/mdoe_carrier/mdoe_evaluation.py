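"""Model-based evaluation of experimental designs under parameter uncertainty.

Each design point is simulated repeatedly with parameter vectors drawn from
the Monte-Carlo distribution; the per-point mean target (maximum attached
cell yield, area-specific by default) and its 10-90 % quantile spread are
scalarised into a desirability in [0, 1].  A quadratic response surface
fitted to the desirabilities is grid-searched to recommend culture
conditions, and whole designs are compared on their best achievable
desirability versus run count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ParameterDistribution
from .doe_designs import Design, FactorSpace, quadratic_model_matrix, n_quadratic_terms
from .kinetic_model import (
    CultureSetup,
    IntegrationError,
    culture_metrics,
    simulate_batch,
)

__all__ = [
    "DesirabilitySpec",
    "PointEvaluation",
    "EvaluationResult",
    "ResponseSurface",
    "simulate_design",
    "desirability",
    "attach_desirability",
    "fit_response_surface",
    "recommend_conditions",
    "compare_designs",
]


@dataclass(frozen=True)
class DesirabilitySpec:
    """Scalarisation anchors for mean target and quantile spread.

    ``lower``/``target`` bracket the larger-is-better ramp for the mean;
    ``spread_max`` anchors the smaller-is-better ramp for the q90-q10
    spread.  Weight exponents shape the two ramps; the ramps are combined
    by geometric mean.
    """

    target_name: str = "X_max_per_cm2"
    lower: float = 0.0
    target: float = 1.0
    spread_max: float = 1.0
    mean_weight: float = 1.0
    spread_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.lower < self.target:
            raise ValueError("lower anchor must be < target anchor")
        if self.spread_max <= 0:
            raise ValueError("spread_max must be > 0")
        if self.mean_weight <= 0 or self.spread_weight <= 0:
            raise ValueError("weight exponents must be > 0")


def desirability(mean_target: float, spread: float, spec: DesirabilitySpec) -> float:
    """Combined desirability D = sqrt(d_mean * d_spread) in [0, 1]."""
    d1 = np.clip((mean_target - spec.lower) / (spec.target - spec.lower), 0.0, 1.0)
    d2 = np.clip((spec.spread_max - spread) / spec.spread_max, 0.0, 1.0)
    return float((d1**spec.mean_weight * d2**spec.spread_weight) ** 0.5)


@dataclass(frozen=True)
class PointEvaluation:
    """Monte-Carlo outcome summary for one design row."""

    factors: dict[str, float]
    samples: np.ndarray          # target metric per Monte-Carlo draw
    n_failed: int = 0
    desirability: float = float("nan")

    @property
    def valid(self) -> bool:
        return self.n_failed <= len(self.samples)  # flagged invalid upstream

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def q10(self) -> float:
        return float(np.quantile(self.samples, 0.1))

    @property
    def q90(self) -> float:
        return float(np.quantile(self.samples, 0.9))

    @property
    def spread(self) -> float:
        return self.q90 - self.q10


@dataclass(frozen=True)
class EvaluationResult:
    """Per-point summaries for one design, plus the desirability spec used."""

    design: Design
    points: list[PointEvaluation]
    spec: DesirabilitySpec | None = None
    invalid_points: tuple[int, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.points):
            row = dict(p.factors)
            row.update(
                mean_target=p.mean, q10=p.q10, q90=p.q90,
                spread=p.spread, desirability=p.desirability,
                n_failed=p.n_failed, valid=i not in self.invalid_points,
            )
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def max_desirability(self) -> float:
        return max(p.desirability for p in self.points)

    @property
    def argmax_factors(self) -> dict[str, float]:
        best = max(self.points, key=lambda p: p.desirability)
        return dict(best.factors)


def _setup_from_factors(template: CultureSetup, factors: dict[str, float]) -> CultureSetup:
    return CultureSetup(
        carrier=template.carrier,
        c_MC=factors.get("c_MC", template.c_MC),
        seed_density=template.seed_density,
        c_Glc=factors.get("c_Glc", template.c_Glc),
        c_Gln=factors.get("c_Gln", template.c_Gln),
        c_LS=template.c_LS, c_Lac=template.c_Lac, c_Amm=template.c_Amm,
        volume=template.volume,
    )


def _target_metric(setup, params, t_grid, per_area: bool, rtol: float) -> float:
    traj = simulate_batch(setup, params, t_grid, rtol=rtol)
    if per_area:
        return culture_metrics(traj, setup).X_max_per_cm2
    return float(traj.column("X_V").max())


def simulate_design(
    design: Design,
    setup_template: CultureSetup,
    param_dist: ParameterDistribution,
    n_sim: int = 100,
    seed: int = 0,
    horizon: float = 264.0,
    dt: float = 8.0,
    per_area: bool = True,
    sim_rtol: float = 1e-6,
    max_failure_fraction: float = 0.5,
) -> EvaluationResult:
    """Monte-Carlo evaluation of every design row.

    For each row, ``n_sim`` parameter vectors are drawn with replacement
    from ``param_dist``, the batch is simulated under the row's factor
    settings, and the target metric (maximum attached cell yield, per cm^2
    of carrier surface unless ``per_area=False``) is recorded.  Rows where
    more than half the simulations fail are flagged invalid.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    if len(param_dist) == 0:
        raise ValueError("parameter distribution is empty")
    rng = np.random.default_rng(seed)
    t_grid = np.arange(0.0, horizon + 1e-9, dt)
    names = design.space.names
    points = []
    invalid = []
    for i, row in enumerate(design.natural):
        factors = dict(zip(names, map(float, row)))
        setup = _setup_from_factors(setup_template, factors)
        samples, failed = [], 0
        for _ in range(n_sim):
            params = param_dist.draw(rng)
            try:
                samples.append(_target_metric(setup, params, t_grid, per_area, sim_rtol))
            except (IntegrationError, ValueError):
                failed += 1
        if failed > max_failure_fraction * n_sim or not samples:
            invalid.append(i)
            samples = samples or [0.0]
        points.append(PointEvaluation(factors=factors, samples=np.array(samples), n_failed=failed))
    return EvaluationResult(design=design, points=points, invalid_points=tuple(invalid))


def default_spec_from_points(
    points: list[PointEvaluation], target_name: str = "X_max_per_cm2"
) -> DesirabilitySpec:
    """Self-scaling anchors: L/T at the 5th/95th percentile of per-point
    means, spread_max at the 95th percentile of spreads."""
    means = np.array([p.mean for p in points])
    spreads = np.array([p.spread for p in points])
    lower = float(np.quantile(means, 0.05))
    target = float(np.quantile(means, 0.95))
    if target <= lower:  # degenerate: all points alike
        target = lower + max(abs(lower), 1.0) * 1e-6
    spread_max = max(float(np.quantile(spreads, 0.95)), 1e-12)
    return DesirabilitySpec(
        target_name=target_name, lower=lower, target=target, spread_max=spread_max
    )


def attach_desirability(
    result: EvaluationResult, spec: DesirabilitySpec | None = None
) -> EvaluationResult:
    """Return a copy of ``result`` with per-point desirabilities filled in."""
    if spec is None:
        spec = default_spec_from_points(result.points)
    points = [
        PointEvaluation(
            factors=p.factors, samples=p.samples, n_failed=p.n_failed,
            desirability=desirability(p.mean, p.spread, spec),
        )
        for p in result.points
    ]
    return EvaluationResult(
        design=result.design, points=points, spec=spec,
        invalid_points=result.invalid_points,
    )


@dataclass(frozen=True)
class ResponseSurface:
    """Quadratic desirability surface over the coded factor space."""

    space: FactorSpace
    coefficients: np.ndarray

    def predict(self, natural: np.ndarray) -> np.ndarray:
        coded = self.space.to_coded(np.atleast_2d(natural))
        raw = quadratic_model_matrix(coded) @ self.coefficients
        return np.clip(raw, 0.0, 1.0)


def fit_response_surface(evaluated: EvaluationResult) -> ResponseSurface:
    """Ordinary least squares of desirability on the quadratic model matrix."""
    space = evaluated.design.space
    y = np.array([p.desirability for p in evaluated.points])
    if np.any(~np.isfinite(y)):
        raise ValueError("desirability not attached; call attach_desirability first")
    x = quadratic_model_matrix(evaluated.design.coded)
    p = n_quadratic_terms(space.k)
    if len(y) < p:
        raise ValueError(f"need >= {p} runs to fit a quadratic surface, got {len(y)}")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design is rank-deficient for a quadratic surface")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return ResponseSurface(space=space, coefficients=coef)


def _dense_grid(space: FactorSpace, points_per_axis: int = 50) -> np.ndarray:
    axes = [np.linspace(f.lower, f.upper, points_per_axis) for f in space.factors]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def recommend_conditions(
    evaluated_designs: dict[str, EvaluationResult],
    top_k: int = 2,
    points_per_axis: int = 50,
) -> pd.DataFrame:
    """Grid-search each design's response surface and rank recommendations.

    Returns the ``top_k`` factor combinations per design, labelled with the
    generating design.  The ranking score is the surface prediction capped
    at the design's maximum evaluated desirability: a quadratic surface can
    extrapolate above anything that was actually simulated (e.g. curl back
    up at the far end of a convex decreasing response), and such promises
    are not allowed to outrank designs with real support at their optimum.
    """
    valid = {
        label: ev for label, ev in evaluated_designs.items()
        if len(ev.invalid_points) < len(ev.points)
    }
    if not valid:
        raise ValueError("all evaluated designs are invalid")
    rows = []
    for label, ev in valid.items():
        surface = fit_response_surface(ev)
        grid = _dense_grid(surface.space, points_per_axis)
        pred = surface.predict(grid)
        score = np.minimum(pred, ev.max_desirability)
        # stable ranking: capped score first, raw prediction as tiebreak
        order = np.lexsort((-pred, -score))[:top_k]
        for rank, idx in enumerate(order, start=1):
            row = {"design": label, "rank": rank,
                   "score": float(score[idx]),
                   "predicted_desirability": float(pred[idx])}
            row.update(dict(zip(surface.space.names, map(float, grid[idx]))))
            rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["score", "design", "rank"], ascending=[False, True, True]
    ).reset_index(drop=True)


def compare_designs(
    space: FactorSpace,
    designs: dict[str, Design],
    setup_template: CultureSetup,
    param_dist: ParameterDistribution,
    n_sim: int = 100,
    seed: int = 0,
    spec: DesirabilitySpec | None = None,
    preference_tolerance: float = 0.05,
    **sim_kwargs,
) -> tuple[pd.DataFrame, dict[str, EvaluationResult]]:
    """Evaluate several designs under one shared desirability scale.

    A shared spec (self-scaled from the pooled points unless given) keeps
    desirabilities comparable across designs.  Designs within
    ``preference_tolerance`` (relative) of the best desirability are
    flagged preferred when they need fewer runs than the best design.
    """
    if len(designs) < 2:
        raise ValueError("need at least two designs to compare")
    raw = {
        label: simulate_design(d, setup_template, param_dist, n_sim=n_sim,
                               seed=seed, **sim_kwargs)
        for label, d in designs.items()
    }
    if spec is None:
        pooled = [p for ev in raw.values() for p in ev.points]
        spec = default_spec_from_points(pooled)
    evaluated = {label: attach_desirability(ev, spec) for label, ev in raw.items()}

    rows = []
    best_d = max(ev.max_desirability for ev in evaluated.values())
    best_runs = min(
        ev.design.n_runs for ev in evaluated.values()
        if ev.max_desirability >= best_d * (1 - 1e-12)
    )
    for label, ev in evaluated.items():
        near_best = ev.max_desirability >= best_d * (1 - preference_tolerance)
        rows.append({
            "design": label,
            "n_runs": ev.design.n_runs,
            "max_desirability": ev.max_desirability,
            **{f"argmax_{k}": v for k, v in ev.argmax_factors.items()},
            "preferred": bool(near_best and ev.design.n_runs <= best_runs),
        })
    table = pd.DataFrame(rows).sort_values(
        ["max_desirability"], ascending=False
    ).reset_index(drop=True)
    return table, evaluated
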