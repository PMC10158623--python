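"""Experimental design generators over a bounded factor space.

Implements the classical response-surface designs (central composite,
Box-Behnken), Latin hypercube sampling, and exchange-based D-/I-optimal
designs for a full quadratic model, plus the hybrid that selects a
D-optimal subset out of a Latin hypercube candidate set.

Coded coordinates map the factor bounds onto [-1, +1]; every generator
returns both views, consistent under the affine map.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "Factor",
    "FactorSpace",
    "Design",
    "quadratic_model_matrix",
    "linear_model_matrix",
    "n_model_terms",
    "n_quadratic_terms",
    "make_design",
    "ccd",
    "bbd",
    "lhs",
    "d_optimal",
    "i_optimal",
    "lhsd_plus_d_optimal",
    "DEFAULT_FACTOR_SPACE",
]


@dataclass(frozen=True)
class Factor:
    name: str
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"factor {self.name}: lower must be < upper")


@dataclass(frozen=True)
class FactorSpace:
    """Ordered set of bounded factors with coded/natural conversion."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("factor space must contain at least one factor")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def _centers_halfwidths(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([f.lower for f in self.factors])
        hi = np.array([f.upper for f in self.factors])
        return (lo + hi) / 2.0, (hi - lo) / 2.0

    def to_coded(self, natural: np.ndarray) -> np.ndarray:
        c, h = self._centers_halfwidths()
        return (np.asarray(natural, dtype=float) - c) / h

    def to_natural(self, coded: np.ndarray) -> np.ndarray:
        c, h = self._centers_halfwidths()
        return np.asarray(coded, dtype=float) * h + c

    def clip_natural(self, natural: np.ndarray) -> np.ndarray:
        lo = np.array([f.lower for f in self.factors])
        hi = np.array([f.upper for f in self.factors])
        return np.clip(natural, lo, hi)

    def contains(self, natural: np.ndarray, tol: float = 1e-9) -> bool:
        lo = np.array([f.lower for f in self.factors])
        hi = np.array([f.upper for f in self.factors])
        x = np.asarray(natural, dtype=float)
        return bool(np.all(x >= lo - tol) and np.all(x <= hi + tol))


#: the default three-factor space for the carrier expansion study:
#: initial glucose 5-60 mM, initial glutamine 2-12 mM, carriers 1-20 g/L.
DEFAULT_FACTOR_SPACE = FactorSpace(
    factors=(
        Factor("c_Glc", 5.0, 60.0, "mmol/L"),
        Factor("c_Gln", 2.0, 12.0, "mmol/L"),
        Factor("c_MC", 1.0, 20.0, "g/L"),
    )
)


@dataclass(frozen=True)
class Design:
    """A runs-by-factors design in natural units with generation metadata."""

    design_type: str
    space: FactorSpace
    natural: np.ndarray          # (n_runs, k)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.natural.ndim != 2 or self.natural.shape[1] != self.space.k:
            raise ValueError("design matrix must be (n_runs, k)")

    @property
    def n_runs(self) -> int:
        return self.natural.shape[0]

    @property
    def coded(self) -> np.ndarray:
        return self.space.to_coded(self.natural)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{f.name} ({f.units})" if f.units else f.name for f in self.space.factors]
        return pd.DataFrame(self.natural, columns=cols)


def quadratic_model_matrix(coded: np.ndarray) -> np.ndarray:
    """Expand coded runs into the full quadratic model matrix.

    Column order: intercept, linear terms, two-way interactions in
    lexicographic pair order, then pure quadratics.  For k factors that is
    1 + k + k(k-1)/2 + k columns.
    """
    x = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = x.shape
    cols = [np.ones(n)]
    cols.extend(x[:, i] for i in range(k))
    cols.extend(x[:, i] * x[:, j] for i, j in itertools.combinations(range(k), 2))
    cols.extend(x[:, i] ** 2 for i in range(k))
    return np.column_stack(cols)


def linear_model_matrix(coded: np.ndarray) -> np.ndarray:
    """Intercept + linear terms only (used for tiny exchange instances)."""
    x = np.atleast_2d(np.asarray(coded, dtype=float))
    return np.column_stack([np.ones(len(x)), x])


_MODEL_MATRICES = {"quadratic": quadratic_model_matrix, "linear": linear_model_matrix}


def n_model_terms(k: int, model: str = "quadratic") -> int:
    if model == "linear":
        return 1 + k
    return 1 + k + k * (k - 1) // 2 + k


def n_quadratic_terms(k: int) -> int:
    return n_model_terms(k, "quadratic")


def _design_from_coded(design_type, space, coded, clip=True, **metadata) -> Design:
    natural = space.to_natural(np.asarray(coded, dtype=float))
    if clip:
        natural = space.clip_natural(natural)
    return Design(design_type=design_type, space=space, natural=natural, metadata=metadata)


def ccd(
    space: FactorSpace,
    center_replicates: int = 6,
    alpha_mode: str = "rotatable",
) -> Design:
    """Central composite design: 2^k cube + 2k axial points + centers.

    ``alpha_mode``: "rotatable" puts axial points at (2^k)^(1/4) coded
    units (clipped back to the bounds, since e.g. negative carrier loadings
    are meaningless); "face" puts them on the faces at +/-1.
    """
    k = space.k
    if k < 2:
        raise ValueError("CCD needs at least 2 factors")
    if alpha_mode == "rotatable":
        alpha = (2.0**k) ** 0.25
    elif alpha_mode == "face":
        alpha = 1.0
    else:
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
    cube = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -alpha
        axial[2 * i + 1, i] = alpha
    centers = np.zeros((center_replicates, k))
    coded = np.vstack([cube, axial, centers])
    return _design_from_coded(
        "ccd", space, coded, center_replicates=center_replicates,
        alpha_mode=alpha_mode, alpha=alpha,
    )


def bbd(space: FactorSpace, center_replicates: int = 3) -> Design:
    """Box-Behnken design: +/-1 on every factor pair, 0 elsewhere, + centers."""
    k = space.k
    if k < 3:
        raise ValueError("BBD needs at least 3 factors")
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        for si, sj in itertools.product([-1.0, 1.0], repeat=2):
            row = np.zeros(k)
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend(np.zeros(k) for _ in range(center_replicates))
    return _design_from_coded("bbd", space, np.array(rows),
                              center_replicates=center_replicates)


def lhs(space: FactorSpace, n: int = 16, seed: int = 0) -> Design:
    """Latin hypercube sample: one run per equal-width stratum per factor."""
    if n < 2:
        raise ValueError("LHS needs n >= 2")
    sampler = qmc.LatinHypercube(d=space.k, seed=seed)
    unit = sampler.random(n)
    coded = unit * 2.0 - 1.0
    return _design_from_coded("lhs", space, coded, n=n, seed=seed)


def _candidate_grid(space: FactorSpace, levels: int = 5) -> np.ndarray:
    """Full-factorial coded candidate grid with `levels` per factor."""
    axis = np.linspace(-1.0, 1.0, levels)
    return np.array(list(itertools.product(axis, repeat=space.k)))


def _log_det(model_rows: np.ndarray) -> float:
    m = model_rows.T @ model_rows
    sign, logdet = np.linalg.slogdet(m)
    return logdet if sign > 0 else -np.inf


def _i_criterion(model_rows: np.ndarray, moment: np.ndarray) -> float:
    """Average scaled prediction variance trace(M^-1 B); +inf if singular."""
    m = model_rows.T @ model_rows
    try:
        sol = np.linalg.solve(m, moment)
    except np.linalg.LinAlgError:
        return np.inf
    if not np.all(np.isfinite(sol)):
        return np.inf
    return float(np.trace(sol))


def _moment_matrix(space: FactorSpace, grid_levels: int = 11, model: str = "quadratic") -> np.ndarray:
    grid = _candidate_grid(space, levels=grid_levels)
    f = _MODEL_MATRICES[model](grid)
    return f.T @ f / len(grid)


def _exchange(
    candidates_coded: np.ndarray,
    n: int,
    objective,
    seed: int,
    maximize: bool,
    max_sweeps: int = 50,
    max_restarts: int = 20,
    model: str = "quadratic",
) -> tuple[np.ndarray, float]:
    """Fedorov-style point exchange over a finite candidate set.

    First-improvement scan in fixed candidate order; the objective is
    monotone across accepted exchanges.  Singular random starts are
    re-drawn a bounded number of times.
    """
    rng = np.random.default_rng(seed)
    f_all = _MODEL_MATRICES[model](candidates_coded)
    n_cand = len(candidates_coded)
    if n > n_cand:
        raise ValueError(f"cannot select {n} runs from {n_cand} candidates")
    sign = 1.0 if maximize else -1.0

    idx = None
    for _ in range(max_restarts):
        trial = rng.choice(n_cand, size=n, replace=False)
        if np.isfinite(sign * objective(f_all[trial])):
            idx = trial
            break
    if idx is None:
        raise RuntimeError("could not find a non-singular starting design")

    idx = list(idx)
    best = objective(f_all[idx])
    for _ in range(max_sweeps):
        improved = False
        for pos in range(n):
            for cand in range(n_cand):
                if cand in idx:
                    continue
                old = idx[pos]
                idx[pos] = cand
                val = objective(f_all[idx])
                if sign * val > sign * best + 1e-12:
                    best = val
                    improved = True
                else:
                    idx[pos] = old
        if not improved:
            break
    return np.array(sorted(idx)), best


def d_optimal(
    space: FactorSpace,
    n: int = 16,
    candidates: np.ndarray | None = None,
    seed: int = 0,
    levels: int = 5,
    model: str = "quadratic",
) -> Design:
    """D-optimal design: exchange maximising log det(X'X) of the model matrix."""
    k = space.k
    p = n_model_terms(k, model)
    if n < p:
        raise ValueError(f"n must be >= {p} for a {model} model in {k} factors")
    cand = _candidate_grid(space, levels) if candidates is None else np.asarray(candidates)
    idx, logdet = _exchange(cand, n, _log_det, seed, maximize=True, model=model)
    return _design_from_coded(
        "d_optimal", space, cand[idx], seed=seed, log_det=float(logdet),
        n_candidates=len(cand), model=model,
    )


def i_optimal(
    space: FactorSpace,
    n: int = 16,
    candidates: np.ndarray | None = None,
    seed: int = 0,
    levels: int = 5,
    model: str = "quadratic",
) -> Design:
    """I-optimal design: exchange minimising average prediction variance."""
    k = space.k
    p = n_model_terms(k, model)
    if n < p:
        raise ValueError(f"n must be >= {p} for a {model} model in {k} factors")
    cand = _candidate_grid(space, levels) if candidates is None else np.asarray(candidates)
    moment = _moment_matrix(space, model=model)
    idx, crit = _exchange(
        cand, n, lambda f: _i_criterion(f, moment), seed, maximize=False, model=model
    )
    return _design_from_coded(
        "i_optimal", space, cand[idx], seed=seed, i_criterion=float(crit),
        n_candidates=len(cand), model=model,
    )


def lhsd_plus_d_optimal(
    space: FactorSpace,
    n: int = 16,
    n_lhs_candidates: int = 64,
    seed: int = 0,
) -> Design:
    """D-optimal subset of a Latin hypercube candidate set."""
    if n_lhs_candidates < n:
        raise ValueError("n_lhs_candidates must be >= n")
    base = lhs(space, n=n_lhs_candidates, seed=seed)
    cand = base.coded
    if n_lhs_candidates == n:
        return _design_from_coded(
            "lhsd_d_optimal", space, cand, seed=seed,
            n_lhs_candidates=n_lhs_candidates, log_det=float(_log_det(quadratic_model_matrix(cand))),
        )
    idx, logdet = _exchange(cand, n, _log_det, seed, maximize=True)
    return _design_from_coded(
        "lhsd_d_optimal", space, cand[idx], seed=seed, log_det=float(logdet),
        n_lhs_candidates=n_lhs_candidates,
    )


_GENERATORS = {
    "ccd": lambda space, n, seed: ccd(space),
    "bbd": lambda space, n, seed: bbd(space, center_replicates=12),
    "lhs": lambda space, n, seed: lhs(space, n=n, seed=seed),
    "dopt": lambda space, n, seed: d_optimal(space, n=n, seed=seed),
    "iopt": lambda space, n, seed: i_optimal(space, n=n, seed=seed),
    "lhsd-dopt": lambda space, n, seed: lhsd_plus_d_optimal(space, n=n, seed=seed),
}


def make_design(design_type: str, space: FactorSpace, n: int = 16, seed: int = 0) -> Design:
    """Dispatch by label with presets matching the study run counts
    (ccd: 20 runs via 6 centers; bbd: 24 runs via 12 centers; others: n)."""
    try:
        gen = _GENERATORS[design_type]
    except KeyError:
        raise ValueError(
            f"unknown design type {design_type!r}; choose from {sorted(_GENERATORS)}"
        ) from None
    return gen(space, n, seed)
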