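"""Synthetic label-retention experiments with known ground truth.

Real label-dilution flow data are rarely shipped in a reusable numeric
form, so this module manufactures complete experiments: a bright unimodal
pre-chase histogram (log-normal intensities well above autofluorescence,
emulating the no-doxycycline control), forward dilution under a known
ground-truth proliferation model, and fixed-event acquisition at one or
more chase horizons.  Every pipeline stage — simulation, calibration,
validation, selection — can then be tested against the truth that
generated the data.

Acquisition is emulated by multinomial subsampling of the simulated
population down to a fixed event count, mirroring a cytometer's stopping
rule and decoupling histogram noise from simulated population size.
Instrument artifacts (spillover, saturation, doublets) are not modelled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .histograms import (
    BinSpec,
    ConfigurationError,
    DEFAULT_BINSPEC,
    FluorescenceHistogram,
    build_histogram,
    read_histogram,
    truncate_at_threshold,
    write_histogram,
)
from .models import ProliferationModel, decode, standard_model, validate
from .simulator import SimulationConfig, simulate_events

__all__ = [
    "GroundTruth",
    "SyntheticExperiment",
    "paper_like_truth",
    "generate_initial_histogram",
    "generate_experiment",
    "write_fixture",
    "read_fixture",
    "DEFAULT_HORIZONS",
]

#: chase horizons of the study design: 1 week and 3 weeks, in hours
DEFAULT_HORIZONS = (168.0, 504.0)


@dataclass(frozen=True)
class GroundTruth:
    """Known generating configuration of a synthetic experiment.

    ``log10_mean``/``log10_sd`` parameterize the founders' log-normal
    brightness; the brightness invariant ``log10_mean - 3*log10_sd >
    log10(threshold)`` keeps the initial population clearly label-positive.
    """

    model_id: int
    vector: tuple[float, ...]
    log10_mean: float = 4.0
    log10_sd: float = 0.25
    autofluorescence_threshold: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.autofluorescence_threshold > 0 and (
            self.log10_mean - 3.0 * self.log10_sd
            <= np.log10(self.autofluorescence_threshold)
        ):
            raise ConfigurationError(
                "initial population not clearly above autofluorescence: need "
                "log10_mean - 3*log10_sd > log10(threshold)"
            )
        decoded = self.decode()
        violations = validate(decoded)
        if violations:
            raise ConfigurationError("invalid ground truth: " + "; ".join(violations))

    def decode(self) -> ProliferationModel:
        return decode(np.asarray(self.vector), standard_model(self.model_id))

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "vector": list(self.vector),
            "log10_mean": self.log10_mean,
            "log10_sd": self.log10_sd,
            "autofluorescence_threshold": self.autofluorescence_threshold,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            model_id=d["model_id"],
            vector=tuple(d["vector"]),
            log10_mean=d["log10_mean"],
            log10_sd=d["log10_sd"],
            autofluorescence_threshold=d["autofluorescence_threshold"],
            seed=d["seed"],
        )


def paper_like_truth(seed: int = 0) -> GroundTruth:
    """The canonical regression fixture: a two-population model with a 31%
    quiescent fraction and 44.94 +/- 19.71 h proliferating division times."""
    return GroundTruth(model_id=2, vector=(0.31, 44.94, 19.71), seed=seed)


@dataclass
class SyntheticExperiment:
    """A complete synthetic label-retention experiment."""

    initial: FluorescenceHistogram
    targets: dict[float, FluorescenceHistogram]
    ground_truth: GroundTruth
    acquisition_events: int
    metadata: dict[float, dict] = field(default_factory=dict)

    def target_pairs(self) -> list[tuple[float, FluorescenceHistogram]]:
        """Targets as (horizon, histogram) pairs sorted by horizon."""
        return sorted(self.targets.items())


def generate_initial_histogram(
    n_events: int,
    log10_mean: float,
    log10_sd: float,
    spec: BinSpec = DEFAULT_BINSPEC,
    threshold: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> FluorescenceHistogram:
    """Pre-chase histogram: ``n_events`` log-normal intensities, binned."""
    if n_events < 1:
        raise ConfigurationError("n_events must be >= 1")
    if threshold > 0 and log10_mean - 3.0 * log10_sd <= np.log10(threshold):
        raise ConfigurationError(
            "initial brightness must satisfy log10_mean - 3*log10_sd > log10(threshold)"
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    events = 10.0 ** rng.normal(log10_mean, log10_sd, size=n_events)
    return build_histogram(events, spec, threshold, label="synthetic pre-chase")


def generate_experiment(
    truth: GroundTruth,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    n_acquire: int = 10_000,
    founders: int = 10_000,
    spec: BinSpec = DEFAULT_BINSPEC,
) -> SyntheticExperiment:
    """Generate initial + chased histograms under a known ground truth.

    The simulated population at each horizon is multinomially subsampled to
    exactly ``n_acquire`` events.  All histograms share the full binning
    and the truth's autofluorescence threshold, so they can be truncated
    and compared uniformly downstream.  Fully determined by ``truth.seed``.
    """
    master = np.random.SeedSequence(truth.seed)
    ss_initial, ss_sim = master.spawn(2)
    rng_init = np.random.default_rng(ss_initial)
    initial = generate_initial_histogram(
        n_acquire,
        truth.log10_mean,
        truth.log10_sd,
        spec,
        truth.autofluorescence_threshold,
        rng_init,
    )
    model = truth.decode()
    targets: dict[float, FluorescenceHistogram] = {}
    metadata: dict[float, dict] = {}
    for ss_h, horizon in zip(ss_sim.spawn(len(horizons)), horizons):
        rng = np.random.default_rng(ss_h)
        cells, info = simulate_events(
            model, initial, SimulationConfig(horizon=horizon, founders=founders), rng
        )
        counts, _ = np.histogram(cells, bins=initial.bin_edges)
        sim = FluorescenceHistogram(
            initial.bin_edges,
            counts.astype(float),
            truth.autofluorescence_threshold,
        )
        if truncate_at_threshold(sim).total == 0:
            raise ConfigurationError(
                f"no simulated events above threshold at {horizon} h; "
                "lower the threshold or shorten the horizon"
            )
        acquired = rng.multinomial(n_acquire, sim.counts / sim.total)
        targets[float(horizon)] = FluorescenceHistogram(
            initial.bin_edges,
            acquired.astype(float),
            truth.autofluorescence_threshold,
            label=f"synthetic target @ {horizon:g} h",
        )
        metadata[float(horizon)] = info
    return SyntheticExperiment(
        initial=initial,
        targets=targets,
        ground_truth=truth,
        acquisition_events=n_acquire,
        metadata=metadata,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(exp: SyntheticExperiment, directory) -> Path:
    """Write an experiment as plain-text files plus a checksummed manifest.

    Files: ``initial.csv``, ``target_<hours>.csv`` per horizon,
    ``ground_truth.json`` and ``manifest.json``.  Returns the manifest path.
    """
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"not a directory: {d}")
    files: dict[str, str] = {}
    write_histogram(exp.initial, d / "initial.csv")
    files["initial.csv"] = _sha256(d / "initial.csv")
    horizons = []
    for horizon, target in exp.target_pairs():
        name = f"target_{horizon:g}.csv"
        write_histogram(target, d / name)
        files[name] = _sha256(d / name)
        horizons.append(horizon)
    (d / "ground_truth.json").write_text(
        json.dumps(exp.ground_truth.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
    files["ground_truth.json"] = _sha256(d / "ground_truth.json")
    manifest = {
        "horizons": horizons,
        "acquisition_events": exp.acquisition_events,
        "metadata": {
            f"{h:g}": {k: v for k, v in m.items()} for h, m in exp.metadata.items()
        },
        "files": files,
    }
    path = d / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path


def read_fixture(directory) -> SyntheticExperiment:
    """Read a fixture written by :func:`write_fixture` (bit-exact round trip)."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
    truth = GroundTruth.from_dict(
        json.loads((d / "ground_truth.json").read_text(encoding="utf-8"))
    )
    initial = read_histogram(d / "initial.csv")
    targets = {
        float(h): read_histogram(d / f"target_{h:g}.csv") for h in manifest["horizons"]
    }
    metadata = {float(h): m for h, m in manifest.get("metadata", {}).items()}
    return SyntheticExperiment(
        initial=initial,
        targets=targets,
        ground_truth=truth,
        acquisition_events=manifest["acquisition_events"],
        metadata=metadata,
    )
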