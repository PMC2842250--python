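# stressarray

Analysis of stress-induced, p38 SAPK-dependent gene expression from
reference-pool two-color microarrays — the workflow used to ask, genome-wide,
which genes a stress turns on, and how much of that response runs through
the p38 stress-activated protein kinase.

The package is written for the analyst reproducing or extending this kind
of study: mouse embryonic fibroblasts (wild type, p38α knockout, and wild
type plus the p38 inhibitor SB203580) stimulated with osmostress (NaCl),
TNFα or anisomycin, each sample hybridized against a common untreated cDNA
pool. It provides:

- **Array processing** — background correction, a generalized-log
  (glog) variance-stabilizing transform
  `glog2(x) = log2((x + √(x² + c²))/2)`, per-probe log ratios
  M = log2(treated/reference), replicate QC by Pearson correlation,
  replicate averaging, and probe→gene collapse.
- **Response calling** — fold-change thresholds (up: FC ≥ 2.5,
  down: FC ≤ 1/4), and the p38-dependency rule: a responsive gene is
  dependent when its induction above baseline is reduced ≥ 50% in the
  inhibitor or knockout arm, i.e. `fc_pert − 1 ≤ (1 − r)(fc_wt − 1)` with
  r = 0.5.
- **Set analysis** — exact Venn partitions, the common core induced by all
  stimuli, and timecourse dependency fractions.
- **GO enrichment** — for a category with *n* genes, *x* of them
  differentially expressed, and global DE frequency *p*, the upper-tail
  binomial probability P(X ≥ x), X ~ Binomial(n, p), with
  Benjamini–Hochberg FDR per ontology and ≥ 20-gene category filtering.
- **A synthetic-data generator** that emulates the study design (41,175
  probes / 19,261 genes, 2 replicates, planted responsive and dependent
  gene fractions, a planted enriched GO category) with full ground truth,
  so every stage is testable end-to-end.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

Simulate the osmostress timecourse at the study's scale and measure how the
p38 dependency of the up-regulated genes decays with time:

```python
from stressarray import calling, pipeline, synthetic

cfg = synthetic.timecourse_config(seed=7)        # NaCl 45 min / 2 h / 8 h
run = pipeline.run_synthetic(cfg, with_annotation=False)
points, overlap = calling.timecourse(run.matrix.table, "NaCl", [45, 120, 480])
for p in points:
    print(f"t={p.time_min:>3} min: {p.n_up:>3} genes up, "
          f"{100 * p.dependency_fraction:.1f}% SB-dependent")
```

```
t= 45 min: 113 genes up, 89.4% SB-dependent
t=120 min: 178 genes up, 78.7% SB-dependent
t=480 min: 319 genes up, 58.3% SB-dependent
```

At the default noise level (0.25 log2 units per channel) the pipeline
recovers the planted structure: ~114/178/321 up-regulated genes whose
dependency decays from ~90% through ~74% to ~62% — the early response is
almost entirely p38-driven, the late response only partly.

The same library calls the three-stimulus endpoint comparison
(`synthetic.treatment_config`), classifies dependency against both the
inhibitor and the knockout, intersects the up-sets into the common core,
and runs the binomial GO enrichment.

## Command line

A thin CLI mirrors the library: `stressarray simulate | qc | call |
dependency | overlap | enrich | timecourse | run`, driven by a TOML config
(see `tests/test_pipeline.py` for a complete example). `stressarray run
--config run.toml` executes the whole chain and writes the ratio matrix,
call/dependency tables, overlap JSON, enrichment tables, heatmap matrices,
QC report and an invariant-checked `report.json`. Exit codes: 0 success,
1 user error, 2 internal invariant failure.

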