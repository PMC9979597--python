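"""Top-down LJ parameterization: cost function, random training phase,
surrogate-guided Bayesian optimization, and filter-and-average extraction.

The 18 free scalars (sigma and epsilon for each of the nine beads) are
optimized against empirical reference metrics (densities, lattice
dimensions) through a pluggable *backend*: a callable mapping a parameter
dict to ``(completed, metrics)``.  Simulation backends may crash for bad
parameter choices; crashed evaluations receive a large penalty cost and
are kept in the history, and the final parameter set is the componentwise
mean of the completed, low-cost records.

The cost of one evaluation is a weighted sum over metrics of the squared
relative deviation from the reference, scaled by ten:

    cost = sum_i wt_i * (10 * (r_i - r_ref,i) / r_ref,i)**2

It is zero exactly when every weighted metric equals its reference and
grows quadratically with deviation.  (The scale factor could also be read
as multiplying the normalized metric itself; that reading is not zero at
the reference and is not used.)  This implementation minimizes the cost;
a maximizing convention with negated costs and a "highly negative" crash
value is equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    ConstantKernel,
    DotProduct,
    Matern,
    WhiteKernel,
)

__all__ = [
    "MetricSpec",
    "ParameterBounds",
    "OptimizationRecord",
    "cost_function",
    "sample_training",
    "optimize",
    "extract_parameters",
    "bounds_around",
    "records_to_dataframe",
    "records_from_dataframe",
]

DEFAULT_CRASH_PENALTY = 1e6

Backend = Callable[[Mapping[str, float]], tuple[bool, Mapping[str, float]]]


@dataclass(frozen=True)
class MetricSpec:
    """One optimization target: an empirical reference value and a weight."""

    name: str
    reference_value: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_value == 0:
            raise ValueError(f"metric {self.name!r}: reference value must be non-zero")
        if self.weight < 0:
            raise ValueError(f"metric {self.name!r}: weight must be non-negative")


@dataclass
class ParameterBounds:
    """Box bounds for the free LJ scalars, keyed '<BEAD>:sigma'/'<BEAD>:epsilon'."""

    names: list[str]
    lows: np.ndarray
    highs: np.ndarray

    def __post_init__(self) -> None:
        self.lows = np.asarray(self.lows, dtype=float)
        self.highs = np.asarray(self.highs, dtype=float)
        if not (len(self.names) == len(self.lows) == len(self.highs)):
            raise ValueError("names, lows and highs must have equal length")
        if np.any(self.lows >= self.highs):
            bad = [n for n, lo, hi in zip(self.names, self.lows, self.highs) if lo >= hi]
            raise ValueError(f"lower bound must be below upper bound for {bad}")

    @classmethod
    def from_dict(cls, d: Mapping[str, tuple[float, float]]) -> "ParameterBounds":
        names = list(d)
        lows = np.array([d[n][0] for n in names])
        highs = np.array([d[n][1] for n in names])
        return cls(names, lows, highs)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def contains(self, params: Mapping[str, float] | np.ndarray) -> bool:
        x = self.as_vector(params)
        return bool(np.all(x >= self.lows - 1e-12) and np.all(x <= self.highs + 1e-12))

    def as_vector(self, params: Mapping[str, float] | np.ndarray) -> np.ndarray:
        if isinstance(params, Mapping):
            return np.array([params[n] for n in self.names], dtype=float)
        return np.asarray(params, dtype=float)

    def as_dict(self, vector: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(vector, dtype=float)))


def bounds_around(
    ff, sigma_frac: float = 0.2, epsilon_frac: float = 0.3
) -> ParameterBounds:
    """Bounds centred on a model's current LJ values (fractional half-widths).

    Mirrors the design of per-bead limits tied to bead size and expected
    interaction strength; the exact published limits are configuration
    inputs, not constants.
    """
    d: dict[str, tuple[float, float]] = {}
    for name in sorted(ff.lj):
        p = ff.lookup_lj(name)
        d[f"{name}:sigma"] = (p.sigma * (1 - sigma_frac), p.sigma * (1 + sigma_frac))
        d[f"{name}:epsilon"] = (
            p.epsilon * (1 - epsilon_frac),
            p.epsilon * (1 + epsilon_frac),
        )
    return ParameterBounds.from_dict(d)


@dataclass
class OptimizationRecord:
    """One evaluated parameter set with its outcome."""

    params: dict[str, float]
    completed: bool
    metrics: dict[str, float] = field(default_factory=dict)
    cost: float = np.nan
    iteration: int = -1
    phase: str = "train"  # "train" (random) or "bo" (surrogate-guided)


def cost_function(metrics: Mapping[str, float], specs: Sequence[MetricSpec]) -> float:
    """Weighted squared relative deviation of metrics from their references.

    ``sum_i wt_i * (10 * (r_i - r_ref,i)/r_ref,i)**2``; non-negative, zero
    iff every metric with positive weight equals its reference, and
    invariant under joint rescaling of a metric and its reference.
    """
    total = 0.0
    for spec in specs:
        if spec.name not in metrics:
            raise KeyError(f"missing metric {spec.name!r} in backend output")
        rel = (metrics[spec.name] - spec.reference_value) / spec.reference_value
        total += spec.weight * (10.0 * rel) ** 2
    return total


def sample_training(bounds: ParameterBounds, n: int, seed: int = 0) -> np.ndarray:
    """Uniform random parameter matrix (n x n_params) within the bounds."""
    if n <= 0:
        raise ValueError("training sample size must be positive")
    rng = np.random.default_rng(seed)
    return rng.uniform(bounds.lows, bounds.highs, size=(n, bounds.n_params))


def _evaluate(
    backend: Backend,
    x: np.ndarray,
    bounds: ParameterBounds,
    specs: Sequence[MetricSpec],
    crash_penalty: float,
    iteration: int,
    phase: str,
) -> OptimizationRecord:
    params = bounds.as_dict(x)
    try:
        completed, metrics = backend(params)
    except Exception:
        completed, metrics = False, {}
    if completed:
        cost = cost_function(metrics, specs)
        return OptimizationRecord(params, True, dict(metrics), cost, iteration, phase)
    return OptimizationRecord(params, False, dict(metrics), crash_penalty, iteration, phase)


def _fit_surrogate(x01: np.ndarray, y: np.ndarray, seed: int) -> GaussianProcessRegressor:
    """GP surrogate on the unit-cube parameter space.

    The kernel sums a quadratic (squared dot-product) component — the cost
    is a weighted quadratic in the metrics by construction, so near the
    optimum the landscape is bowl-shaped — with a Matern(5/2) component for
    non-quadratic structure and a white-noise term for numerical slack.
    """
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e4)) * DotProduct(sigma_0=1.0) ** 2
        + ConstantKernel(1.0, (1e-4, 1e3))
        * Matern(length_scale=0.5, length_scale_bounds=(1e-2, 1e2), nu=2.5)
        + WhiteKernel(1e-8, (1e-12, 1e-1))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, random_state=seed, n_restarts_optimizer=0
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(x01, y)
    return gp


def _propose_ei(
    gp: GaussianProcessRegressor,
    best_x01: np.ndarray,
    y_best: float,
    n_params: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expected-improvement maximizer over global + local candidates."""
    cands = np.vstack(
        [
            rng.uniform(0, 1, size=(256, n_params)),
            np.clip(best_x01 + rng.normal(0, 0.05, size=(256, n_params)), 0, 1),
        ]
    )
    mu, sd = gp.predict(cands, return_std=True)
    sd = np.maximum(sd, 1e-12)
    imp = y_best - mu
    z = imp / sd
    ei = imp * norm.cdf(z) + sd * norm.pdf(z)
    return cands[int(np.argmax(ei))]


def _propose_mean_min(
    gp: GaussianProcessRegressor,
    best_x01: np.ndarray,
    n_params: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Posterior-mean minimizer (exploitation), multi-start L-BFGS-B."""
    starts = [best_x01] + [
        np.clip(best_x01 + rng.normal(0, 0.05, n_params), 0, 1) for _ in range(2)
    ]
    best = None
    for s0 in starts:
        res = _scipy_minimize(
            lambda z: float(gp.predict(z[None])[0]),
            s0,
            bounds=[(0.0, 1.0)] * n_params,
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
    return np.clip(best.x, 0, 1)


def optimize(
    backend: Backend,
    specs: Sequence[MetricSpec],
    bounds: ParameterBounds,
    n_train: int = 500,
    n_iter: int = 100,
    crash_penalty: float = DEFAULT_CRASH_PENALTY,
    seed: int = 0,
) -> list[OptimizationRecord]:
    """Random training phase followed by surrogate-guided optimization.

    ``n_train`` uniform random parameter sets are evaluated first; the
    (parameters, cost) history then seeds a Gaussian-process surrogate
    that proposes ``n_iter`` further evaluations, always within bounds,
    alternating posterior-mean exploitation with expected-improvement
    exploration.  Backend crashes (returning
    ``completed=False`` or raising) are recorded with the penalty cost and
    retained — the loop never aborts.  The full record history is
    returned in evaluation order; identical seeds and backend give an
    identical history.
    """
    if n_train < 0 or n_iter < 0:
        raise ValueError("budgets must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[OptimizationRecord] = []
    if n_train:
        x_train = sample_training(bounds, n_train, seed=seed)
        for i, x in enumerate(x_train):
            records.append(
                _evaluate(backend, x, bounds, specs, crash_penalty, i, "train")
            )

    span = bounds.highs - bounds.lows

    def to01(x: np.ndarray) -> np.ndarray:
        return (x - bounds.lows) / span

    for k in range(n_iter):
        xs = np.array([bounds.as_vector(r.params) for r in records])
        ys = np.array([r.cost for r in records])
        # cap penalty costs at one decade above the worst completed cost so
        # crashes repel the surrogate without flattening it
        finite = ys[ys < crash_penalty]
        cap = 10.0 * finite.max() if len(finite) else crash_penalty
        ys = np.minimum(ys, cap)
        if len(xs) == 0:
            x_next = rng.uniform(bounds.lows, bounds.highs)
        else:
            gp = _fit_surrogate(to01(xs), ys, seed=seed + 1)
            best = int(np.argmin(ys))
            # exploitation-heavy schedule: the backend is deterministic, so
            # most proposals chase the surrogate's minimum; every fourth
            # iteration explores by expected improvement
            if k % 4 != 3:
                x01 = _propose_mean_min(gp, to01(xs[best]), bounds.n_params, rng)
            else:
                x01 = _propose_ei(gp, to01(xs[best]), ys[best], bounds.n_params, rng)
            x_next = bounds.lows + x01 * span
        records.append(
            _evaluate(
                backend, x_next, bounds, specs, crash_penalty, len(records), "bo"
            )
        )
    return records


def extract_parameters(
    records: Iterable[OptimizationRecord], cost_threshold: float
) -> dict[str, float]:
    """Filter-and-average parameter extraction.

    Keeps records that (a) ran to completion and (b) have cost below the
    threshold, and returns the componentwise mean of their parameter
    vectors.  Crashed records never contribute.
    """
    survivors = [r for r in records if r.completed and r.cost < cost_threshold]
    if not survivors:
        raise ValueError(
            f"no completed records with cost below {cost_threshold}; "
            "raise the threshold or run more iterations"
        )
    names = list(survivors[0].params)
    stack = np.array([[r.params[n] for n in names] for r in survivors])
    return dict(zip(names, stack.mean(axis=0)))


def records_to_dataframe(records: Sequence[OptimizationRecord]) -> pd.DataFrame:
    """History as a flat table: one row per record (persistable as CSV)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "iteration": r.iteration,
            "phase": r.phase,
            "completed": r.completed,
            "cost": r.cost,
        }
        row.update({f"param:{k}": v for k, v in r.params.items()})
        row.update({f"metric:{k}": v for k, v in r.metrics.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_dataframe(df: pd.DataFrame) -> list[OptimizationRecord]:
    records = []
    for _, row in df.iterrows():
        params = {
            c.removeprefix("param:"): float(row[c])
            for c in df.columns
            if c.startswith("param:")
        }
        metrics = {
            c.removeprefix("metric:"): float(row[c])
            for c in df.columns
            if c.startswith("metric:") and pd.notna(row[c])
        }
        records.append(
            OptimizationRecord(
                params=params,
                completed=bool(row["completed"]),
                metrics=metrics,
                cost=float(row["cost"]),
                iteration=int(row["iteration"]),
                phase=str(row["phase"]),
            )
        )
    return records
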