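"""Flow-cytometry fluorescence histograms and the Hellinger-distance fitness.

A :class:`FluorescenceHistogram` is the central data container of the
package: binned event counts on a (typically log-scaled) fluorescence axis
in arbitrary units, together with the experimentally determined
autofluorescence threshold below which labelled cells cannot be
distinguished from background.  Histograms are truncated at that threshold
before any model comparison.

Two Hellinger variants are provided:

``probability``
    ``H = sqrt(1 - sum_i sqrt(p_i * q_i))`` on unit-normalised counts.
    A proper metric bounded by 1; used for property checks.

``count``
    ``H_c = sqrt(sum_i (sqrt(c_i) - sqrt(d_i))^2)`` on raw counts,
    unbounded above.  This is the default calibration fitness: its
    magnitude depends on the number of acquired events, so simulated
    counts must be rescaled to the experimental total before comparison
    (see :func:`labelkin.calibration.fitness`).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentError",
    "ConfigurationError",
    "HistogramParseError",
    "BinSpec",
    "DEFAULT_BINSPEC",
    "FluorescenceHistogram",
    "build_histogram",
    "truncate_at_threshold",
    "hellinger",
    "align_bins",
    "read_histogram",
    "write_histogram",
]


class ConfigurationError(ValueError):
    """An invalid configuration value (bin spec, settings, ...)."""


class AlignmentError(ValueError):
    """Histograms cannot be compared or merged on their current binnings."""


class HistogramParseError(ValueError):
    """A histogram file violates the expected schema."""


@dataclass(frozen=True)
class BinSpec:
    """Binning specification for a fluorescence axis.

    Parameters
    ----------
    lo, hi : float
        Lowest and highest bin edge, arbitrary fluorescence units.
    n_bins : int
        Number of bins.
    scale : {"log10", "linear"}
        Spacing of the edges.  ``log10`` requires ``lo > 0``.
    """

    lo: float
    hi: float
    n_bins: int
    scale: str = "log10"

    def __post_init__(self) -> None:
        if self.scale not in ("log10", "linear"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ConfigurationError(f"need lo < hi, got ({self.lo}, {self.hi})")
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        if self.scale == "log10" and self.lo <= 0:
            raise ConfigurationError("log10 scale requires lo > 0")

    def edges(self) -> np.ndarray:
        """Bin edges, length ``n_bins + 1``."""
        if self.scale == "log10":
            return np.logspace(np.log10(self.lo), np.log10(self.hi), self.n_bins + 1)
        return np.linspace(self.lo, self.hi, self.n_bins + 1)


#: 256 log10-spaced bins over five decades, mimicking a standard cytometer axis.
DEFAULT_BINSPEC = BinSpec(1.0, 1e5, 256, "log10")


@dataclass(eq=False)
class FluorescenceHistogram:
    """Binned fluorescence event counts with an autofluorescence threshold.

    ``bin_edges`` has length ``B + 1`` (strictly increasing, positive) and
    ``counts`` length ``B``.  An empty histogram (``B = 0``) can arise from
    truncation; it carries a single edge.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    autofluorescence_threshold: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("bin_edges and counts must be 1-D")
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError(
                f"bin_edges (len {self.bin_edges.size}) must be one longer "
                f"than counts (len {self.counts.size})"
            )
        if self.counts.size and np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.bin_edges <= 0):
            raise ValueError("bin_edges must be positive")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")
        if self.autofluorescence_threshold < 0:
            raise ValueError("autofluorescence_threshold must be >= 0")

    # -- convenience -----------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        """Unit-normalised counts."""
        t = self.total
        if t == 0:
            raise ZeroDivisionError("cannot normalise an all-zero histogram")
        return self.counts / t

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FluorescenceHistogram):
            return NotImplemented
        return (
            np.array_equal(self.bin_edges, other.bin_edges)
            and np.array_equal(self.counts, other.counts)
            and self.autofluorescence_threshold == other.autofluorescence_threshold
        )


def build_histogram(
    events, spec: BinSpec, threshold: float = 0.0, label: str = ""
) -> FluorescenceHistogram:
    """Bin raw per-event fluorescence values.

    Bins are half-open lower-inclusive ``[e_i, e_{i+1})``; the last bin is
    closed.  Events outside ``[lo, hi]`` are dropped and the number dropped
    is recorded in the returned histogram's ``label``.
    """
    events = np.asarray(events, dtype=float)
    if events.size and (not np.all(np.isfinite(events)) or np.any(events < 0)):
        raise ValueError("events must be finite and >= 0")
    edges = spec.edges()
    counts, _ = np.histogram(events, bins=edges)
    dropped = int(events.size - counts.sum())
    tag = label
    if dropped:
        tag = (label + " " if label else "") + f"[{dropped} out-of-range events dropped]"
    return FluorescenceHistogram(edges, counts.astype(float), threshold, tag)


def truncate_at_threshold(h: FluorescenceHistogram) -> FluorescenceHistogram:
    """Drop all bins whose lower edge lies below the autofluorescence threshold.

    A bin straddling the threshold is dropped entirely (no sub-bin mass is
    invented).  Idempotent.  If no bin survives, an empty histogram is
    returned and a warning is emitted.
    """
    thr = h.autofluorescence_threshold
    k = int(np.searchsorted(h.bin_edges, thr, side="left"))
    if k >= h.n_bins:
        warnings.warn(
            f"autofluorescence threshold {thr} removes every bin", stacklevel=2
        )
        return FluorescenceHistogram(
            h.bin_edges[-1:], h.counts[:0], thr, h.label
        )
    return FluorescenceHistogram(h.bin_edges[k:], h.counts[k:], thr, h.label)


def hellinger(
    h1: FluorescenceHistogram, h2: FluorescenceHistogram, mode: str = "count"
) -> float:
    """Hellinger distance between two identically binned histograms.

    ``probability`` mode operates on unit-normalised counts and is bounded
    by 1; ``count`` mode operates on raw counts and is unbounded.  Lower is
    a better fit.  The caller aligns binnings first (:func:`align_bins`).
    """
    if not np.array_equal(h1.bin_edges, h2.bin_edges):
        raise AlignmentError("histograms have different binnings; align first")
    c, d = h1.counts, h2.counts
    if mode == "probability":
        if c.sum() == 0 or d.sum() == 0:
            raise ZeroDivisionError(
                "probability-mode Hellinger undefined for an all-zero histogram"
            )
        bc = float(np.sqrt(h1.probabilities() * h2.probabilities()).sum())
        return float(np.sqrt(max(0.0, 1.0 - bc)))
    if mode == "count":
        return float(np.sqrt(((np.sqrt(c) - np.sqrt(d)) ** 2).sum()))
    raise ConfigurationError(f"unknown Hellinger mode {mode!r}")


def _transform(x: np.ndarray, scale: str) -> np.ndarray:
    return np.log10(x) if scale == "log10" else x


def align_bins(
    h1: FluorescenceHistogram,
    h2: FluorescenceHistogram,
    scale: str = "log10",
) -> tuple[FluorescenceHistogram, FluorescenceHistogram]:
    """Rebin two histograms onto their finest common binning over the overlap.

    Mass in a bin that is subdivided (or that extends past the overlap) is
    reassigned proportionally to bin width on the ``scale`` axis; total
    counts over the overlap are conserved.  Identically binned inputs are
    returned unchanged.
    """
    if np.array_equal(h1.bin_edges, h2.bin_edges):
        return h1, h2
    if h1.n_bins == 0 or h2.n_bins == 0:
        raise AlignmentError("cannot align an empty histogram")
    lo = max(h1.bin_edges[0], h2.bin_edges[0])
    hi = min(h1.bin_edges[-1], h2.bin_edges[-1])
    if lo >= hi:
        raise AlignmentError(
            f"histogram ranges [{h1.bin_edges[0]}, {h1.bin_edges[-1]}] and "
            f"[{h2.bin_edges[0]}, {h2.bin_edges[-1]}] do not overlap"
        )
    merged = np.union1d(h1.bin_edges, h2.bin_edges)
    merged = merged[(merged >= lo) & (merged <= hi)]

    def rebin(h: FluorescenceHistogram) -> FluorescenceHistogram:
        e = _transform(h.bin_edges, scale)
        m = _transform(merged, scale)
        widths = np.diff(e)
        density = np.where(widths > 0, h.counts / widths, 0.0)
        new_counts = np.empty(merged.size - 1)
        for j in range(merged.size - 1):
            a, b = m[j], m[j + 1]
            ov = np.minimum(e[1:], b) - np.maximum(e[:-1], a)
            new_counts[j] = float((density * np.clip(ov, 0.0, None)).sum())
        return FluorescenceHistogram(
            merged, new_counts, h.autofluorescence_threshold, h.label
        )

    return rebin(h1), rebin(h2)


# -- delimited-text I/O --------------------------------------------------
#
# Schema: optional '# threshold=<value>' and '# label=<text>' comment lines,
# then a CSV with header 'bin_lo,bin_hi,count'.  UTF-8, '.' decimal point.


def write_histogram(h: FluorescenceHistogram, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# threshold={float(h.autofluorescence_threshold)!r}\n")
        if h.label:
            fh.write(f"# label={h.label}\n")
        fh.write("bin_lo,bin_hi,count\n")
        for lo, hi, c in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
            fh.write(f"{float(lo)!r},{float(hi)!r},{float(c)!r}\n")


def read_histogram(path) -> FluorescenceHistogram:
    threshold = 0.0
    label = ""
    body: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("#"):
                meta = s.lstrip("#").strip()
                if meta.startswith("threshold="):
                    threshold = float(meta.split("=", 1)[1])
                elif meta.startswith("label="):
                    label = meta.split("=", 1)[1]
            elif s:
                body.append(line)
    try:
        df = pd.read_csv(io.StringIO("".join(body)), float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise HistogramParseError(f"{path}: {exc}") from exc
    for col in ("bin_lo", "bin_hi", "count"):
        if col not in df.columns:
            raise HistogramParseError(f"{path}: missing column {col!r}")
    lo = df["bin_lo"].to_numpy(float)
    hi = df["bin_hi"].to_numpy(float)
    counts = df["count"].to_numpy(float)
    for i in range(len(df)):
        if not hi[i] > lo[i]:
            raise HistogramParseError(
                f"{path}: row {i}: bin_hi {hi[i]} not above bin_lo {lo[i]}"
            )
        if i and lo[i] != hi[i - 1]:
            raise HistogramParseError(
                f"{path}: row {i}: bins not contiguous "
                f"(bin_lo {lo[i]} != previous bin_hi {hi[i - 1]})"
            )
        if not np.isfinite(counts[i]) or counts[i] < 0:
            raise HistogramParseError(f"{path}: row {i}: invalid count {counts[i]}")
    edges = np.concatenate([lo, hi[-1:]]) if len(df) else np.array([1.0])
    return FluorescenceHistogram(edges, counts, threshold, label)
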