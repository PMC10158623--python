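"""Synthetic shake-flask experiment generator.

Produces time-series datasets with the statistical structure the
calibration and design-evaluation stages assume: an eight-condition
experimental grid over carrier loading and initial substrate levels,
24 h sampling tightening to 48 h late in the run, and multiplicative
relative measurement noise.  Ground truth is a documented fixture
parameter set, not a claim about any fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetic_model import (
    CarrierSpec,
    CultureSetup,
    KineticParameters,
    simulate_batch,
)
from .calibration import Experiment, TimeSeriesDataset, OBSERVABLE_COLUMNS

__all__ = [
    "GroundTruth",
    "DEFAULT_CARRIER",
    "table1_setups",
    "default_sampling_times",
    "generate_experiment",
    "generate_modeling_set",
]

#: Cytodex-3-like carrier fixture: dry surface ~2700 cm^2/g, confluence
#: around 5e5 cells/cm^2.
DEFAULT_CARRIER = CarrierSpec(name="cytodex3-like", area_per_gram=2700.0, max_area_density=5.0e5)


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to generate a synthetic campaign."""

    params: KineticParameters = field(default_factory=KineticParameters)
    carrier: CarrierSpec = DEFAULT_CARRIER
    noise: float = 0.15          # relative measurement error
    sampling_interval: float = 24.0  # h, cadence early in the run
    horizon: float = 264.0       # h

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.horizon <= self.sampling_interval:
            raise ValueError("horizon must exceed the sampling interval")


# (c_MC g/L, c_Glc mM, c_Gln mM); seed density 6000 cells/cm^2 throughout.
_EXPERIMENT_GRID = {
    1: (20.0, 30.0, 12.0),
    2: (20.0, 60.0, 12.0),
    3: (10.0, 5.6, 2.0),
    4: (10.0, 25.0, 12.0),
    5: (10.0, 60.0, 12.0),
    6: (5.0, 60.0, 12.0),
    7: (3.0, 25.0, 4.0),
    8: (1.0, 25.0, 4.0),
}
_MODELING_IDS = (1, 2, 3, 4, 5, 6)
_VERIFICATION_IDS = (7, 8)
_SEED_DENSITY = 6000.0


def table1_setups(carrier: CarrierSpec = DEFAULT_CARRIER) -> dict[int, CultureSetup]:
    """The eight-condition experimental grid, keyed by experiment number."""
    return {
        n: CultureSetup(
            carrier=carrier, c_MC=c_mc, seed_density=_SEED_DENSITY,
            c_Glc=c_glc, c_Gln=c_gln,
        )
        for n, (c_mc, c_glc, c_gln) in _EXPERIMENT_GRID.items()
    }


def default_sampling_times(truth: GroundTruth) -> np.ndarray:
    """Sampling grid: every `sampling_interval` up to 120 h, every 48 h after."""
    dt = truth.sampling_interval
    early = np.arange(0.0, min(120.0, truth.horizon) + 1e-9, dt)
    late = np.arange(early[-1] + 48.0, truth.horizon + 1e-9, 48.0)
    return np.concatenate([early, late])


def generate_experiment(
    setup: CultureSetup,
    truth: GroundTruth,
    seed: int,
    name: str = "synthetic",
) -> Experiment:
    """Simulate one batch and sample it with multiplicative noise.

    Noise factors are Normal(1, noise) truncated at zero, drawn
    independently per observation.  The limiting substrate is never
    emitted: it is unobservable by construction.
    """
    times = default_sampling_times(truth)
    traj = simulate_batch(setup, truth.params, times)
    rng = np.random.default_rng(seed)
    observed = {}
    for col in OBSERVABLE_COLUMNS:
        clean = traj.column(col)
        factors = np.clip(rng.normal(1.0, truth.noise, size=clean.shape), 0.0, None)
        observed[col] = clean * factors
    return Experiment(
        name=name,
        setup=setup,
        times=times,
        observed=observed,
        relative_error={col: max(truth.noise, 1e-6) for col in OBSERVABLE_COLUMNS},
    )


def generate_modeling_set(
    truth: GroundTruth, seed: int
) -> tuple[TimeSeriesDataset, TimeSeriesDataset]:
    """Training set (experiments 1-6) and held-out verification pair (7-8).

    Each experiment gets its own child seed, so noise realisations are
    pairwise different yet fully reproducible from ``seed``.
    """
    setups = table1_setups(truth.carrier)
    child = np.random.SeedSequence(seed).spawn(len(_EXPERIMENT_GRID))
    seeds = {n: int(c.generate_state(1)[0]) for n, c in zip(sorted(_EXPERIMENT_GRID), child)}
    train = TimeSeriesDataset(
        experiments=[
            generate_experiment(setups[n], truth, seeds[n], name=f"exp{n}")
            for n in _MODELING_IDS
        ]
    )
    verify = TimeSeriesDataset(
        experiments=[
            generate_experiment(setups[n], truth, seeds[n], name=f"exp{n}")
            for n in _VERIFICATION_IDS
        ]
    )
    return train, verify
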