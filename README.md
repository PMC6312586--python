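# plitree

Phase Lag Index connectivity and minimum-spanning-tree topology for
source-space MEG/EEG recordings, with permutation-based group comparison.

## The problem

Resting-state MEG studies often ask whether two cohorts differ in the
*topology* of their functional brain networks: is some region more central
in one group than the other?  A standard analysis chain for this question
is:

1. **Connectivity.**  For region-of-interest time series (here 90 regions
   of the AAL atlas, 512 Hz, ten 8-second epochs per subject), band-pass
   filter into the clinical bands (delta 0.5–4, theta 4–8, alpha 8–13,
   beta 13–30, gamma 30–48 Hz), extract instantaneous phases Φ(t) with the
   Hilbert transform, and compute the **Phase Lag Index** for every pair of
   regions and every epoch:

   PLI = | ⟨ sign( sin ΔΦ(t_k) ) ⟩ |

   with ΔΦ wrapped to [−π, π].  PLI is 0 for nonsynchronous activity and 1
   for perfectly consistent nonzero lag; because sign(sin 0) = 0 it is
   insensitive to volume conduction, at the cost of discarding true
   zero-lag interactions.

2. **Topology.**  From each 90 × 90 PLI matrix, build the **minimum
   spanning tree** on edge weights 1/PLI with Kruskal's algorithm — the
   unique loopless backbone of N nodes and M = N − 1 strongest links, which
   avoids the threshold biases of conventional graph analyses.  Per tree:
   global metrics (leaf fraction, degree divergence κ = ⟨k²⟩/⟨k⟩, tree
   hierarchy Th = L / (2·M·BC_max)) and nodal metrics (degree, betweenness
   centrality, eccentricity), averaged across epochs per subject.

3. **Inference.**  For each (band, metric, node), compare the two cohorts
   with a two-sided label-permutation test (10,000 relabelings, statistic =
   difference of group means) and control the false discovery rate across
   the 90 regions with Benjamini–Hochberg at α = 0.05.

Because recordings of this kind are rarely shareable, the package includes
a first-class **synthetic-data generator**: two cohorts (26 vs 29 subjects)
of 90-ROI recordings carrying 1/f background rhythms, broadband noise, and
phase couplings with controllable lag and jitter — including a planted
high-degree theta-band hub at the right hippocampus that differs between
cohorts.  Every stage can therefore be validated against ground truth.

## Worked example

```python
from plitree import CohortSpec, PipelineConfig, run_pipeline

spec = CohortSpec(seed=7)        # 26 vs 29 subjects, planted theta hub
config = PipelineConfig(seed=7)  # five bands, 10,000 permutations, alpha 0.05
result = run_pipeline(config, spec, out_dir="results/run")

hub = result.comparisons.query(
    "band == 'theta' and metric == 'degree' and node == 'Hippocampus_R'"
)
print(hub[["diff", "direction", "p_raw", "p_fdr", "significant"]])
```

which prints (seed 7, full five-band run):

```
        diff direction   p_raw     p_fdr  significant
313  2.66817         +  0.0001  0.008999         True
```

The planted hub's theta-band MST degree is 2.67 higher in the coupled
cohort (epoch-averaged degree 6.39 ± 0.63 vs 3.72 ± 0.43 across subjects),
the raw permutation p-value sits at its add-one minimum 1/10001, and the
FDR-corrected value across the 90 regions is 0.009.  It is the only
significant *degree* row in any band.  Planting a 10-partner hub also
makes the whole theta tree more star-like, which shows up honestly in the
other families (lower eccentricity across regions, higher leaf fraction).

The same flow is available as numbered drivers,
`analysis/01_simulate_cohorts.py` … `analysis/04_validation_experiments.py`,
which write their tables under `results/`, and as a CLI
(`plitree simulate | connect | topology | compare | run-all`).

## Layout

- `src/plitree/` — the library: `synth` (generator), `spectral`
  (filter/epoch/phase), `connectivity` (PLI), `mst` (Kruskal + metrics),
  `stats` (permutation + FDR), `pipeline`, `io`, `config`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model, parameter and design notes.
- `tests/` — unit, property and acceptance tests.
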