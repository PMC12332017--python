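"""High-level Model / Results interface for label-retention fitting.

Mirrors the ergonomics of statistical-modelling libraries: build a
:class:`LabelRetentionModel` from data (an initial histogram plus one or
more chased target histograms), call :meth:`~LabelRetentionModel.fit`, and
receive a :class:`LabelRetentionResults` carrying the point estimates,
their repetition spread, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence, Union

import numpy as np

from .calibration import CalibrationResult, CalibrationSettings, calibrate
from .histograms import ConfigurationError, FluorescenceHistogram, read_histogram
from .models import (
    ProliferationModel,
    decode,
    free_parameter_count,
    parameter_names,
    standard_model,
)
from .selection import FitnessDistribution, validate_model
from .simulator import SimulationConfig, simulate

__all__ = ["LabelRetentionModel", "LabelRetentionResults"]


class LabelRetentionModel:
    """A proliferation-model structure bound to label-dilution data.

    Parameters
    ----------
    initial : FluorescenceHistogram
        Pre-chase fluorescence histogram (defines founder brightness).
    targets : sequence of (horizon_hours, FluorescenceHistogram)
        Chased histograms with their acquisition times.
    structure : int or ProliferationModel
        One of the four standard structures (1-4) or a custom structure.
    """

    def __init__(
        self,
        initial: FluorescenceHistogram,
        targets: Sequence[tuple[float, FluorescenceHistogram]],
        structure: Union[int, ProliferationModel] = 2,
    ):
        if not targets:
            raise ConfigurationError("at least one (horizon, target) pair is required")
        self.initial = initial
        self.targets = [(float(h), t) for h, t in targets]
        self.structure = (
            standard_model(structure) if isinstance(structure, int) else structure
        )

    @classmethod
    def from_files(
        cls,
        initial_path,
        target_paths: dict[float, str],
        structure: Union[int, ProliferationModel] = 2,
    ) -> "LabelRetentionModel":
        """Build from histogram CSV files keyed by acquisition time (hours)."""
        initial = read_histogram(initial_path)
        targets = [(float(h), read_histogram(p)) for h, p in sorted(target_paths.items())]
        return cls(initial, targets, structure)

    def fit(self, settings: Optional[CalibrationSettings] = None, **kwargs) -> "LabelRetentionResults":
        """Calibrate the free parameters by repeated swarm optimization.

        Keyword arguments override fields of :class:`CalibrationSettings`
        (e.g. ``fit(seed=3, repetitions=5, founders_per_eval=2000)``).
        """
        settings = replace(settings or CalibrationSettings(), **kwargs)
        result = calibrate(self.structure, self.initial, self.targets, settings)
        return LabelRetentionResults(self, result, settings)


class LabelRetentionResults:
    """Calibrated parameters with repetition spread and diagnostics."""

    def __init__(
        self,
        model: LabelRetentionModel,
        calibration: CalibrationResult,
        settings: CalibrationSettings,
    ):
        self.model = model
        self.calibration = calibration
        self.settings = settings
        self.params = np.asarray(calibration.best_vector, dtype=float)
        self.fitted_model = decode(self.params, model.structure)

    # -- estimates -------------------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return parameter_names(self.model.structure)

    @property
    def best_fitness(self) -> float:
        return self.calibration.best_fitness

    @property
    def param_spread(self) -> np.ndarray:
        """Standard deviation of each parameter across repetition bests."""
        vecs = np.array([v for v, _ in self.calibration.repetition_bests])
        return vecs.std(axis=0, ddof=1) if vecs.shape[0] > 1 else np.zeros(vecs.shape[1])

    @property
    def quiescent_fraction(self) -> Optional[float]:
        """Estimated quiescent proportion, or None if the structure has none."""
        for sp in self.fitted_model.subpopulations:
            if sp.is_quiescent:
                return sp.proportion
        return None

    def division_law(self, name: str = "proliferating"):
        for sp in self.fitted_model.subpopulations:
            if sp.name == name:
                return sp.law
        raise KeyError(name)

    # -- diagnostics -----------------------------------------------------
    def validate(
        self,
        n_runs: int = 100,
        horizons: Optional[Sequence[float]] = None,
        seed: Optional[int] = None,
    ) -> list[FitnessDistribution]:
        """Replicate-simulate the fitted model against the targets."""
        targets = self.model.targets
        if horizons is not None:
            wanted = {float(h) for h in horizons}
            targets = [(h, t) for h, t in targets if h in wanted]
            missing = wanted - {h for h, _ in targets}
            if missing:
                raise ConfigurationError(f"no target for horizon(s) {sorted(missing)}")
        rng = np.random.default_rng(self.settings.seed if seed is None else seed)
        return validate_model(
            self.model.structure,
            self.params,
            self.model.initial,
            targets,
            n_runs=n_runs,
            settings=self.settings,
            rng=rng,
        )

    def simulate(
        self, horizon: float, founders: Optional[int] = None, seed: int = 0
    ) -> FluorescenceHistogram:
        """Forward-simulate the fitted model to an arbitrary horizon."""
        cfg = SimulationConfig(
            horizon=horizon,
            founders=founders or self.settings.founders_per_eval,
            max_divisions=self.settings.max_divisions,
        )
        return simulate(self.fitted_model, self.model.initial, cfg, np.random.default_rng(seed))

    def summary(self) -> str:
        """Human-readable fit summary (estimates, spread, fitness)."""
        m = self.fitted_model
        lines = [
            "Label-retention proliferation fit",
            "=" * 54,
            f"structure: model {m.model_id} "
            f"({free_parameter_count(self.model.structure)} free parameters)",
            f"targets:   {', '.join(f'{h:g} h' for h, _ in self.model.targets)}",
            f"fitness:   {self.best_fitness:.6g} "
            f"({self.settings.hellinger_mode}-mode Hellinger, lower = better)",
            f"swarm:     {self.settings.swarm_size} particles x "
            f"{self.settings.iterations} iterations x "
            f"{self.settings.repetitions} repetitions",
            "-" * 54,
            f"{'parameter':<22}{'estimate':>12}{'rep. sd':>12}",
        ]
        for name, val, sd in zip(self.param_names, self.params, self.param_spread):
            lines.append(f"{name:<22}{val:>12.4g}{sd:>12.3g}")
        lines.append("-" * 54)
        for sp in m.subpopulations:
            if sp.is_quiescent:
                lines.append(f"{sp.name:<14} proportion {sp.proportion:.3f}  (no division)")
            else:
                lines.append(
                    f"{sp.name:<14} proportion {sp.proportion:.3f}  "
                    f"division time {sp.law.mean:.2f} +/- {sp.law.sd:.2f} h "
                    f"on [{sp.law.support_lo:g}, {sp.law.support_hi:g}] h"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<LabelRetentionResults model={self.fitted_model.model_id} "
            f"fitness={self.best_fitness:.4g}>"
        )
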