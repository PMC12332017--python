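# Methods

## Model and simulation

A label-dilution chase is simulated as a collection of independent
founder lineages. Founders are sampled from the pre-chase histogram
(multinomially over bins, log-uniformly within a bin) and assigned to
subpopulations multinomially by the model's proportions. A quiescent
subpopulation never divides within the simulated horizon: quiescence is a
no-division sentinel, not a large finite division time, matching its
operational definition (undivided over the whole 504 h chase) and
avoiding an arbitrary cutoff.

Each dividing cell draws its cycle time τ from a normal distribution
truncated to the subpopulation's support (sampled by inversion of the
truncated CDF, which stays exact when the support lies many standard
deviations from the mean, as happens at search-space edges). Division
asynchrony is modelled by placing the first division at u·τ with
u ~ U(0,1) — the standard uniform-phase desynchronisation assumption; a
`synchronous_start` mode (first division at exactly τ) exists for oracle
tests. Daughters inherit half the parent's fluorescence and redraw cycle
times independently; no mother–daughter correlation and no cell death,
migration or non-division fluorescence decay are modelled. Division
events at t ≤ horizon execute, so a division landing exactly on the
horizon counts.

Lineage tracking stops in two ways. (i) Daughters whose halved signal
falls below the autofluorescence threshold are removed (descendants can
only be dimmer); they are tallied, and the untracked background is
estimated by extrapolating each dropped lineage geometrically at its
subpopulation's mean cycle time, 2^((horizon−t_drop)/μ). This estimate
feeds only the `above_threshold_fraction` diagnostic, never the
histogram. (ii) Daughters reaching the division cap (default 8, where a
halved H2B-GFP signal reaches the autofluorescence floor) stay alive and
are binned but schedule no further divisions; this keeps the tracked
population bounded by founders·2⁸ exactly. The returned histogram uses
the initial histogram's binning and is truncated at the threshold.

## Histograms and fitness

Histograms default to 256 log10-spaced bins over [1, 10⁵] a.u. — a
five-decade cytometer axis; the binning is configurable because acquired
data rarely document it. Bins are half-open lower-inclusive with a closed
last bin (numpy's convention). Truncation at the autofluorescence
threshold keeps exactly the bins whose lower edge is at or above the
threshold; a straddling bin is dropped whole rather than inventing
sub-bin mass, and truncation is idempotent. When two histograms disagree
in binning they are rebinned onto the union of their edges over the
overlap, with mass split proportionally to bin width on the log axis;
totals over the overlap are conserved to 1 part in 10⁹.

The calibration fitness is the Hellinger distance. The default operates
on raw counts, H_c = √Σ(√cᵢ−√dᵢ)², with the simulated counts rescaled so
their total matches the experimental total over the shared truncated
support — without the rescaling the distance would measure population
growth rather than distribution shape; with it, typical 10⁴-event fits
score in the 5–15 range. The probability-normalised form
H = √(1−Σ√(pᵢqᵢ)) ∈ [0,1] is a proper metric and is used for invariance
testing; the mode is a configuration switch because the normalisation
convention behind any particular published fitness scale is rarely
stated.

## Calibration

Free parameters are the first k−1 subpopulation proportions (the last is
the remainder; a negative remainder scores +∞ rather than renormalising,
keeping box bounds interpretable) plus (μ, σ) per dividing subpopulation.
The optimizer is a bound-constrained global-best PSO with the
Clerc–Kennedy constants (inertia 0.7298, cognitive = social = 1.49618),
velocities clamped to half the bound width, reflecting walls, and frozen
degenerate dimensions. Because the objective is stochastic (each
evaluation re-simulates), the incumbent best is re-scored once per
iteration to limit lock-in on lucky noise; the reported trace is the
running minimum over all evaluations, so it is non-increasing and its
last entry equals the returned best. A self-tuning optimizer variant can
be swapped in through the `pso_optimize` function interface.

Protocol defaults are 50 particles × 100 iterations × 30 independent
repetitions, each repetition seeded by counter-based spawning from the
master seed (`numpy.random.SeedSequence`), making every calibration
bit-reproducible across platforms. Calibration uses the 1-week (168 h)
target by default; multiple targets are summed, enabling joint
168 h + 504 h fits. The repetition spread is the only uncertainty
reported — no gradient or Bayesian machinery is attached.

## Validation and selection

A calibrated model is validated by re-simulating it n_runs times
(default 100) at 168 h and 504 h and scoring each replicate, yielding
per-model fitness distributions summarised by min/max/median and linearly
interpolated quartiles (the convention where q25 of [1..5] is 2, fixed
for cross-platform determinism). Ranking sorts by median fitness at the
long horizon — the hold-out window where an overfitted short-horizon
model fails — and re-orders any models whose medians lie within a 5%
relative band of the best by ascending free-parameter count. This
operationalises "similar quality, prefer less complexity" as an explicit,
configurable rule; no AIC/BIC-style criterion is implied.

## Synthetic data

Because raw label-retention flow data are rarely redistributable, the
`synthetic` module manufactures complete experiments. Founder brightness
is log-normal (the canonical unimodal shape of reporter-expression
histograms on a log axis), by default 10^𝒩(4.0, 0.25²) a.u. over an
autofluorescence threshold of 100 a.u., enforcing
log10-mean − 3·log10-sd > log10(threshold) so the initial population is
unambiguously label-positive. Dilution is forward-simulated under a known
ground truth; acquisition is emulated by multinomial subsampling to a
fixed event count (default 10⁴, matching a cytometer's stopping rule and
decoupling histogram noise from simulated population size). The canonical
fixture uses the two-population structure with a 31% quiescent fraction
and 44.94 ± 19.71 h division times.

What the generator does *not* emulate: spillover/compensation,
saturation, doublets, gating artefacts, instrument drift, cell death, or
label re-induction. Passing tests therefore demonstrate that the
estimation machinery recovers known truths under the model's own
assumptions — not that those assumptions hold for any particular
instrument or tumour. FCS file ingestion is out of scope; histograms
enter as delimited text (`bin_lo,bin_hi,count` CSV with a
`# threshold=` header) or as raw event lists binned by `build_histogram`.

## Problem sizes and numerical notes

The test and reproduction pipelines run at reduced sizes chosen to keep a
laptop run comfortable while leaving the estimates informative: 10⁴
acquired events and founders for data generation, 1000 founders per
fitness evaluation, swarm 20 × 30 iterations × 2–3 repetitions for
calibration, and 30 validation replicates (the full protocol sizes —
50 × 100 × 30 and 100 replicates — remain the library defaults). At these
sizes parameter recovery on the canonical fixture lands the quiescent
fraction within a few points and the division-time mean within ~20%; the
mean trades off against the truncated σ when only the 1-week histogram is
fitted, which is the main identifiability limit of single-horizon
calibration. Degenerate inputs are handled explicitly: all-zero
histograms refuse probability normalisation, a threshold above all edges
yields an empty histogram with a warning, point-support division laws are
deterministic, and infeasible proportion vectors score +∞.

## Known limitations

- Single-channel analysis only; no cytometry preprocessing.
- The quiescent fraction is defined operationally (undivided within the
  chase); truly slow cycling beyond the horizon is indistinguishable
  from quiescence.
- The geometric background extrapolation is a diagnostic estimate, not a
  simulated population.
- Fitness-based selection compares only the four built-in structures;
  the internal representation supports arbitrary subpopulation lists,
  but the public menu deliberately does not.
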