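# scdnet

Latent-variable modeling of memory complaints and resting-state
hub-network analysis for subjective cognitive decline (SCD) cohorts.

People with SCD report worsening memory while performing normally on
objective tests.  Two questions follow: which psychological factors
(emotional distress, metacognitive beliefs, personality,
neuropsychological performance) explain the severity of memory
complaints, and how does the hub organization of resting-state
source-space brain networks differ between people with and without SCD?
This package implements the full analysis chain for both, for
methodologists who want to study or reuse the estimators, with a
synthetic-data layer that plants known ground truth so every stage is
testable without access to clinical data.

## What is inside

- **`scdnet.plssem`** — PLS path modeling (PLS-SEM) with reflective
  mode-A measurement: iterative outer-weight estimation, path
  coefficients β by OLS among standardized composites, R², composite
  reliability ρ_c = (Σλ)² / [(Σλ)² + Σ(1−λ²)], AVE = mean(λ²),
  cross-loadings, per-subject composite scores, percentile bootstrap,
  and a label-permutation multigroup test of |β_A − β_B|.
- **`scdnet.connectivity`** — lagged phase synchronization
  Im(ρ)²/(1−Re(ρ)²) on Hann-tapered epoch spectra, band-averaged over
  delta (1–4 Hz) and theta (4–8 Hz); 58×58 adjacency per subject and
  group averages.
- **`scdnet.graph_hubs`** — weighted betweenness centrality (lengths
  1/w, Brandes), the hub rule BC ≥ mean + 1.5·SD, and Venn partition of
  hub turnover (shared / lost / gained between groups).
- **`scdnet.siminet`** — spatial graph-edit similarity in [0, 1]:
  common / substituted (cost = normalized distance) / inserted / deleted
  nodes plus summed edge-weight differences, normalized so identical
  networks score exactly 1 and fully disjoint ones 0.
- **`scdnet.synthetic_data`** — cohort, hub-network and coupled
  band-limited oscillator generators with planted loadings, paths, hubs
  and coupling weights.
- **`scdnet.pipeline`** / **`scdnet` CLI** — the study flow end to end
  (cutoff grouping → per-group PLS-SEM → composite-score middle-cohort
  selection → networks → similarity → hubs → report).

Numbered drivers under `analysis/` run the whole flow as a narrative
(`01_simulate_cohort.py` … `06_hub_transitions.py`), writing tables and
figures under `results/analysis/`.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_path_model.py
```

prints (seed 1):

```
CCI-S memory by cutoff-assigned group (targets 16.31/32.34):
         size   mean   std
group
SCD        54  31.61  5.91
non-SCD    41  15.06  2.54
...
SCD: R^2(memory complaints) = 0.354; paths:
  neuropsych -> memory_complaints: +0.053
  emotional_distress -> memory_complaints: +0.374
  metacognitive_beliefs -> memory_complaints: +0.349
  personality -> memory_complaints: -0.234
```

The generator plants positive emotional-distress and metacognitive paths
in both groups and a negative personality path (−0.38) only in the SCD
group; the fitted SCD group shows exactly that sign pattern, attenuated
by composite measurement and n ≈ 50 sampling noise.  Continuing with
`03` – `06` selects the middle 24/26 subjects by composite score,
builds per-band networks, and reports e.g.

```
delta: similarity(SCD subject vs non-SCD average) = 0.821 +- 0.002 (n = 26)
rewiring sweep [0.0, 0.1, ..., 0.5] -> similarity [1.0, 0.953, ..., 0.745]
delta: 2 shared, 2 lost in SCD, 3 gained in SCD
```

i.e. the similarity index degrades monotonically with planted rewiring,
and the hub Venn partition recovers the planted hub turnover (5 hubs per
group, 3 shared by construction in that run; detection loses or adds the
odd hub at the threshold).

The same flow is available as one command:

```bash
scdnet run-all --seed 1 --out-dir results/pipeline
```

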