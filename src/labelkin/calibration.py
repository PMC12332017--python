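"""Model calibration: Hellinger fitness minimised by particle-swarm optimization.

The fitness of a candidate parameter vector is the Hellinger distance
between the experimental target histogram and a stochastic simulation of
the chase under the decoded model, both truncated at the autofluorescence
threshold.  In the default ``count`` mode the simulated counts are first
rescaled so their total matches the experimental total over the shared
truncated support — otherwise the distance would measure population growth
rather than distribution shape.

The optimizer is a bound-constrained global-best PSO with the standard
constriction constants (inertia 0.7298, cognitive = social = 1.49618),
velocity clamped to half the bound width and reflecting boundaries.  It is
exposed as a plain function so an alternative optimizer (e.g. a
self-tuning PSO variant) can be swapped in.  Because the objective is
stochastic, the incumbent global best is re-evaluated once per iteration
to limit lock-in on lucky noise.

Each of the ``repetitions`` independent optimization runs gets its own
random stream spawned from the master seed, so a calibration is exactly
reproducible and repetition results are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .histograms import (
    AlignmentError,
    ConfigurationError,
    FluorescenceHistogram,
    align_bins,
    hellinger,
    truncate_at_threshold,
)
from .models import DomainError, ProliferationModel, decode, parameter_bounds
from .simulator import SimulationConfig, simulate

__all__ = [
    "CalibrationSettings",
    "CalibrationResult",
    "fitness",
    "pso_optimize",
    "calibrate",
]

# constricted-PSO constants (Clerc-Kennedy)
_W = 0.7298
_C1 = 1.49618
_C2 = 1.49618


@dataclass(frozen=True)
class CalibrationSettings:
    """Swarm-optimization and fitness-evaluation settings.

    Defaults follow the study protocol: 50 particles, 100 iterations,
    statistics over 30 repeated optimizations, raw-count Hellinger fitness.
    """

    swarm_size: int = 50
    iterations: int = 100
    repetitions: int = 30
    founders_per_eval: int = 1000
    hellinger_mode: str = "count"
    sims_per_eval: int = 1
    max_divisions: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("swarm_size", "iterations", "repetitions", "founders_per_eval", "sims_per_eval", "max_divisions"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class CalibrationResult:
    """Outcome of a repeated swarm calibration of one model."""

    model_id: int
    best_vector: np.ndarray
    best_fitness: float
    repetition_bests: list[tuple[np.ndarray, float]]
    trace: np.ndarray  # per-iteration best-so-far of the winning repetition

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "best_vector": np.asarray(self.best_vector).tolist(),
            "best_fitness": self.best_fitness,
            "repetition_bests": [
                {"vector": np.asarray(v).tolist(), "fitness": f}
                for v, f in self.repetition_bests
            ],
            "trace": np.asarray(self.trace).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(
            model_id=d["model_id"],
            best_vector=np.asarray(d["best_vector"], dtype=float),
            best_fitness=float(d["best_fitness"]),
            repetition_bests=[
                (np.asarray(r["vector"], dtype=float), float(r["fitness"]))
                for r in d["repetition_bests"]
            ],
            trace=np.asarray(d["trace"], dtype=float),
        )


def _compare(
    sim: FluorescenceHistogram,
    target_trunc: FluorescenceHistogram,
    mode: str,
) -> float:
    sim_a, tgt_a = align_bins(sim, target_trunc)
    if mode == "count":
        s = sim_a.total
        if s > 0 and tgt_a.total > 0:
            sim_a = FluorescenceHistogram(
                sim_a.bin_edges,
                sim_a.counts * (tgt_a.total / s),
                sim_a.autofluorescence_threshold,
            )
        return hellinger(sim_a, tgt_a, mode="count")
    return hellinger(sim_a, tgt_a, mode="probability")


def fitness(
    vector,
    model: ProliferationModel,
    initial: FluorescenceHistogram,
    targets: Sequence[tuple[float, FluorescenceHistogram]],
    settings: CalibrationSettings,
    rng: np.random.Generator,
) -> float:
    """Hellinger fitness of a parameter vector against one or more targets.

    ``targets`` is a sequence of ``(horizon_hours, histogram)`` pairs; each
    horizon is used as the simulation length for its target, and the
    per-target fitnesses are summed.  Infeasible vectors (negative
    remainder proportion) score ``+inf`` rather than raising, so the
    optimizer can sample freely near the simplex boundary.
    """
    try:
        m = decode(vector, model)
    except DomainError:
        return float("inf")
    total = 0.0
    for horizon, target in targets:
        if horizon is None:
            raise ConfigurationError("each target needs its acquisition time (hours)")
        tgt = truncate_at_threshold(target)
        vals = []
        for _ in range(settings.sims_per_eval):
            sim = simulate(
                m,
                initial,
                SimulationConfig(
                    horizon=horizon,
                    founders=settings.founders_per_eval,
                    max_divisions=settings.max_divisions,
                ),
                rng,
            )
            try:
                vals.append(_compare(sim, tgt, settings.hellinger_mode))
            except (ZeroDivisionError, AlignmentError):
                vals.append(float("inf"))
        total += float(np.mean(vals))
    return total


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    swarm_size: int,
    iterations: int,
    rng: np.random.Generator,
    reevaluate_gbest: bool = False,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Bound-constrained global-best PSO.

    Positions start uniform in the box with zero velocities; velocities are
    clamped to half the bound width per dimension and out-of-bounds
    positions are reflected onto the boundary with the velocity component
    negated.  Degenerate dimensions (``lo == hi``) are frozen.  Returns the
    best evaluated position, its fitness, and the non-increasing
    best-so-far trace (one entry per iteration, the first being the best of
    the initial swarm).

    With ``reevaluate_gbest`` the incumbent is re-scored each iteration
    (useful for stochastic objectives); the returned trace and best remain
    the running minimum over all evaluations.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(lo > hi) or not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ConfigurationError("bounds must be finite with lo <= hi")
    d = lo.size
    frozen = lo == hi
    width = hi - lo
    vmax = 0.5 * width

    x = lo + rng.random((swarm_size, d)) * width
    x[:, frozen] = lo[frozen]
    v = np.zeros((swarm_size, d))
    f = np.array([objective(x[i]) for i in range(swarm_size)])
    pbest_x = x.copy()
    pbest_f = f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x = pbest_x[g].copy()
    gbest_f = float(pbest_f[g])  # incumbent (may be re-evaluated)
    run_best_x = gbest_x.copy()
    run_best_f = gbest_f  # running minimum over every evaluation
    trace = [run_best_f]

    for _ in range(1, iterations):
        r1 = rng.random((swarm_size, d))
        r2 = rng.random((swarm_size, d))
        v = _W * v + _C1 * r1 * (pbest_x - x) + _C2 * r2 * (gbest_x - x)
        np.clip(v, -vmax, vmax, out=v)
        x = x + v
        # reflect off the box walls, negating the offending velocity component
        for bound, side in ((lo, -1.0), (hi, 1.0)):
            out = (x - bound) * side > 0
            if np.any(out):
                x = np.where(out, 2 * bound - x, x)
                v = np.where(out, -v, v)
        np.clip(x, lo, hi, out=x)
        x[:, frozen] = lo[frozen]
        v[:, frozen] = 0.0

        f = np.array([objective(x[i]) for i in range(swarm_size)])
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]

        if reevaluate_gbest:
            gbest_f = float(objective(gbest_x))
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x = pbest_x[g].copy()
            gbest_f = float(pbest_f[g])
        it_min = float(f.min()) if f.size else float("inf")
        if it_min < run_best_f:
            run_best_f = it_min
            run_best_x = x[int(np.argmin(f))].copy()
        trace.append(run_best_f)

    return run_best_x, run_best_f, np.asarray(trace)


def calibrate(
    model: ProliferationModel,
    initial: FluorescenceHistogram,
    targets: Sequence[tuple[float, FluorescenceHistogram]],
    settings: CalibrationSettings,
) -> CalibrationResult:
    """Fit a model's free parameters by repeated swarm optimization.

    Runs ``settings.repetitions`` independent PSO searches, each with a
    random stream spawned from the master seed, and returns the overall
    best together with every repetition's best (the repetition spread is
    the only uncertainty measure this procedure provides).
    """
    if not targets:
        raise ConfigurationError("calibrate needs at least one (horizon, target) pair")
    bounds = parameter_bounds(model)
    master = np.random.SeedSequence(settings.seed)
    children = master.spawn(settings.repetitions)
    rep_bests: list[tuple[np.ndarray, float]] = []
    traces: list[np.ndarray] = []
    for child in children:
        rng = np.random.default_rng(child)

        def objective(vec: np.ndarray) -> float:
            return fitness(vec, model, initial, targets, settings, rng)

        bx, bf, tr = pso_optimize(
            objective,
            bounds,
            settings.swarm_size,
            settings.iterations,
            rng,
            reevaluate_gbest=True,
        )
        rep_bests.append((bx, bf))
        traces.append(tr)
    winner = int(np.argmin([f for _, f in rep_bests]))
    best_x, best_f = rep_bests[winner]
    return CalibrationResult(
        model_id=model.model_id,
        best_vector=best_x,
        best_fitness=best_f,
        repetition_bests=rep_bests,
        trace=traces[winner],
    )
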