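# labelkin

Label-retention proliferation kinetics from flow-cytometry histograms.

## The problem

In a label-dilution (pulse–chase) experiment, tumour cells carry a
heritable fluorescent label — here a tet-off histone H2B-GFP fusion —
whose per-cell signal halves at every division once expression is shut
off. After one to three weeks of chase, the fluorescence histogram of the
population encodes how many times each lineage divided: quiescent cells
stay bright, fast-cycling cells dim to the autofluorescence floor within
~8 divisions. `labelkin` turns such histograms into quantitative estimates
of population structure: *what fraction of cells is quiescent, and how
fast do the cycling cells divide?*

It is aimed at groups running H2B-GFP / CFSE-style label-retention assays
(e.g. on patient-derived xenograft material) who want a model-based
readout instead of a single "% label-retaining" gate.

## The model

Four competing subpopulation structures are fitted:

| model | structure | free parameters |
|-------|-----------------------------------------------|-----------------|
| 1 | proliferating | 2 |
| 2 | quiescent + proliferating | 3 |
| 3 | quiescent + fast + slow | 6 |
| 4 | fast + slow | 5 |

Each proliferating subpopulation *i* has division times
τ ~ 𝒩(μᵢ, σᵢ²) truncated to its search support (proliferating: 21–504 h,
σ ∈ 0.01–40 h; fast: 21–63 h, σ ∈ 0.01–30 h; slow: 63–504 h,
σ ∈ 0.01–40 h); quiescent cells never divide within the chase. Cells
divide asynchronously (first division at u·τ, u ~ U(0,1)); each division
halves the cell's fluorescence f → f/2, and a lineage leaves tracking
when its signal falls below the autofluorescence threshold or after 8
divisions.

The fit minimises the Hellinger distance between the chased experimental
histogram and a stochastic simulation started from the pre-chase
histogram, both truncated at the autofluorescence threshold:

H_c(c, d) = √Σᵢ(√cᵢ − √dᵢ)²  (raw counts, simulation rescaled to the
experimental total; a probability-normalised variant H ∈ [0,1] is also
provided). Optimization is a bound-constrained global-best particle
swarm (default 50 particles × 100 iterations × 30 repetitions).
Calibrated models are validated by replicate simulation at 1 and 3 weeks
and ranked by median 3-week fitness, with models of similar quality
(within 5%) re-ordered by parsimony.

## Worked example

```python
import labelkin as lk

# a synthetic experiment with known ground truth: 31% quiescent cells,
# proliferating division times 44.94 +/- 19.71 h on [21, 504] h
exp = lk.generate_experiment(lk.paper_like_truth(seed=1))

model = lk.LabelRetentionModel(exp.initial, exp.target_pairs()[:1], structure=2)
res = model.fit(swarm_size=20, iterations=30, repetitions=3,
                founders_per_eval=1000, seed=1)
print(res.summary())
```

prints

```
Label-retention proliferation fit
======================================================
structure: model 2 (3 free parameters)
targets:   168 h
fitness:   12.2503 (count-mode Hellinger, lower = better)
swarm:     20 particles x 30 iterations x 3 repetitions
------------------------------------------------------
parameter                 estimate     rep. sd
p_quiescent                 0.2531      0.0346
mean_proliferating           36.06        7.36
sd_proliferating             30.56           5
------------------------------------------------------
quiescent      proportion 0.253  (no division)
proliferating  proportion 0.747  division time 36.06 +/- 30.56 h on [21, 504] h
```

The quiescent fraction (25% vs a true 31%) and mean division time (36 h
vs a true 45 h, partly traded against a wider σ) are recovered from the
1-week histogram alone; `res.validate(n_runs=100)` then scores the fit at
both horizons, and `lk.rank_models` compares structures. The same
pipeline is scriptable from the shell via `labelkin synth / simulate /
calibrate / select`.

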