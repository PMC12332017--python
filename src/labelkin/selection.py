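"""Replicate validation of calibrated models and parsimony-aware ranking.

Once each candidate model has been calibrated, it is validated by
re-simulating the chase many times (default 100) at both the calibration
horizon (1 week, 168 h) and a longer hold-out horizon (3 weeks, 504 h),
scoring every replicate against the corresponding experimental histogram.
The replicate fitness distributions expose how much of a model's apparent
quality is luck of the stochastic initialisation.

Ranking operationalises the informal "similar quality, less complexity"
argument: models whose median validation fitness at the ranking horizon
lies within a relative tolerance band (default 5%) of the best median are
re-ordered by ascending free-parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .histograms import ConfigurationError, FluorescenceHistogram
from .calibration import CalibrationSettings, fitness
from .models import ProliferationModel

__all__ = [
    "SummaryStats",
    "FitnessDistribution",
    "SelectionReport",
    "summarize",
    "validate_model",
    "rank_models",
    "plot_fitness_distributions",
]


@dataclass(frozen=True)
class SummaryStats:
    min: float
    max: float
    median: float
    q25: float
    q75: float


def summarize(values: Sequence[float]) -> SummaryStats:
    """Five-number summary with linear-interpolation quantiles.

    The convention where the lower quartile of ``[1, 2, 3, 4, 5]`` is 2,
    fixed so summaries are deterministic across platforms.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty list")
    q25, med, q75 = np.percentile(v, [25.0, 50.0, 75.0], method="linear")
    return SummaryStats(
        min=float(v.min()),
        max=float(v.max()),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
    )


@dataclass
class FitnessDistribution:
    """Replicate validation fitnesses of one model at one horizon."""

    model_id: int
    horizon: float
    values: np.ndarray
    stats: SummaryStats = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("fitness values must be >= 0")
        self.stats = summarize(self.values)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "horizon": self.horizon,
            "values": self.values.tolist(),
            "stats": vars(self.stats).copy(),
        }


@dataclass
class SelectionReport:
    """Ranked model comparison with the parsimony rationale."""

    distributions: list[FitnessDistribution]
    param_counts: dict[int, int]
    ranking: list[int]
    chosen_model_id: int
    rationale: str  # "fitness-dominant" | "parsimony-tiebreak"
    tolerance: float
    ranking_horizon: float

    def to_dict(self) -> dict:
        return {
            "ranking": self.ranking,
            "chosen_model_id": self.chosen_model_id,
            "rationale": self.rationale,
            "tolerance": self.tolerance,
            "ranking_horizon": self.ranking_horizon,
            "param_counts": {str(k): v for k, v in self.param_counts.items()},
            "distributions": [d.to_dict() for d in self.distributions],
        }


def validate_model(
    model: ProliferationModel,
    best_vector,
    initial: FluorescenceHistogram,
    targets: Sequence[tuple[float, FluorescenceHistogram]],
    n_runs: int = 100,
    settings: Optional[CalibrationSettings] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[FitnessDistribution]:
    """Replicate-simulate a calibrated model and score it at each horizon.

    Each of the ``n_runs`` replicates re-runs the stochastic simulation
    from scratch (fresh founder sampling and division schedules) and
    records its fitness against the target for that horizon.
    """
    if not targets:
        raise ConfigurationError("validate_model needs at least one (horizon, target)")
    settings = settings or CalibrationSettings()
    rng = rng if rng is not None else np.random.default_rng(settings.seed)
    one_sim = settings if settings.sims_per_eval == 1 else replace(settings, sims_per_eval=1)
    out = []
    for horizon, target in targets:
        vals = [
            fitness(best_vector, model, initial, [(horizon, target)], one_sim, rng)
            for _ in range(n_runs)
        ]
        out.append(FitnessDistribution(model.model_id, horizon, np.asarray(vals)))
    return out


def rank_models(
    distributions: Sequence[FitnessDistribution],
    param_counts: dict[int, int],
    tolerance: float = 0.05,
) -> SelectionReport:
    """Rank models by median validation fitness with a parsimony tie-break.

    ``distributions`` holds one fitness distribution per model, all at the
    same (long) validation horizon.  Models whose medians fall within
    ``tolerance`` (relative to the best median) are considered of similar
    quality and re-ordered by ascending free-parameter count.
    """
    if len(distributions) < 2:
        raise ConfigurationError("rank_models needs at least two models")
    horizons = {d.horizon for d in distributions}
    if len(horizons) != 1:
        raise ConfigurationError(
            f"all distributions must share one ranking horizon, got {sorted(horizons)}"
        )
    meds = {d.model_id: d.stats.median for d in distributions}
    if len(meds) != len(distributions):
        raise ConfigurationError("duplicate model_id in distributions")
    by_median = sorted(meds, key=lambda m: (meds[m], m))
    best = meds[by_median[0]]
    band = best * (1.0 + tolerance)
    tied = [m for m in by_median if meds[m] <= band]
    rest = [m for m in by_median if m not in tied]
    tied.sort(key=lambda m: (param_counts[m], meds[m], m))
    ranking = tied + rest
    rationale = "parsimony-tiebreak" if len(tied) > 1 else "fitness-dominant"
    return SelectionReport(
        distributions=list(distributions),
        param_counts=dict(param_counts),
        ranking=ranking,
        chosen_model_id=ranking[0],
        rationale=rationale,
        tolerance=tolerance,
        ranking_horizon=distributions[0].horizon,
    )


def plot_fitness_distributions(
    distributions: Sequence[FitnessDistribution], path=None, ax=None
):
    """Violin summary of per-model replicate fitnesses, grouped by horizon."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    groups = sorted(distributions, key=lambda d: (d.model_id, d.horizon))
    data = [d.values for d in groups]
    labels = [f"{d.model_id}\n{d.horizon:g} h" for d in groups]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), labels)
    ax.set_ylabel("Hellinger fitness (lower = better)")
    ax.set_xlabel("model / horizon")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
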