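# restflow

Tools for asking a systems-level question about cellular *temporal
processing*: when the same mechanical stimulus is delivered continuously or
with rest periods inserted, what changes in the transcriptome, and can those
changes point at the signaling pathways that read the temporal pattern?

The concrete setting is osteoblastic cells under fluid shear (orbital
shaking) profiled under six conditions — no flow, rest-inserted flow and
continuous flow, each sampled immediately after flow and one hour later
(NF0, NF1, RF0, RF1, CF0, CF1) — on a single expression array per condition.
`restflow` implements the full analysis chain for such designs, plus a
synthetic-data generator with ground truth so every step can be validated by
parameter recovery.

## The model

For each gene, flow/no-flow log2 ratios are formed per time point,

    x_t = log2(CF_t) - log2(NF_t),   y_t = log2(RF_t) - log2(NF_t),  t = 0, 1

and time-averaged: `x = (x0 + x1)/2`, `y = (y0 + y1)/2` (averaging halves the
variance of independent per-time-point fluctuations). Each gene is a point in
(x, y) space; genes responding identically to both flow regimens lie on
`y = x`. Rotating the frame by 45°,

    x' = (x + y)/√2    (common response to flow, along the diagonal)
    y' = (y - x)/√2    (differential response to rest insertion; y' > 0 means
                        rest up-regulates)

separates common from differential expression changes. The magnitude
distributions |x|, |y|, |x'|, |y'| are compared by kernel density estimates,
two-sample Kolmogorov–Smirnov tests and *relative distributions* (the
density of one sample expressed on the quantile scale of another; flat at 1
means equality). Signature groups take the top 1% tails of y' — Group A
(rest-up-regulated) and Group B (rest-down-regulated) — and are tested for
gene-set over-representation with upper-tail hypergeometric p-values and
Benjamini–Hochberg FDR, including a sweep of the group size from 5 to 200
genes. Two closed-form assay helpers round out the chain: the orbital-shaker
maximal wall shear stress `τ = a·√(ρη(2πf)³)` and 2^(−ΔΔCT) qPCR
quantification.

Preprocessing follows beadarray conventions: quantile normalization,
flooring of raw intensities at 10, log2 transform, a detection filter
(p < 0.01 in at least one sample) and removal of probes without usable gene
symbols, with probe counts ledgered at every stage.

## Worked example

Run the whole pipeline on a synthetic dataset with two planted signatures:

```python
import pathlib
import restflow as rf

config = rf.PipelineConfig(
    outdir=pathlib.Path("out"), seed=7,
    simulate=rf.SimConfig(
        n_probes=20_000, frac_detected=0.6, frac_unannotated=0.2,
        planted_sets=(rf.PlantedSet("MAPK_LIKE_UP", 40, "up", 0.18),
                      rf.PlantedSet("TNFA_LIKE_DOWN", 40, "down", 0.18)),
    ),
    sweep_sizes=(5, 100, 5), n_decoy_sets=20,
)
report = rf.run_pipeline(config)
```

This run prints/writes (in `out/report.json`):

* provenance `20000 → 11869 detected → 9565 analyzed` — the detection and
  annotation filters at work;
* mean |x'| = 0.0707 vs mean |y'| = 0.0403 — differential changes are about
  half the size of common ones;
* KS on |x'| vs |y'|: D = 0.270, p ≈ 10⁻³⁰⁸ — the rotated magnitude
  distributions are sharply distinct;
* relative density of |y'| against |x'|: 2.02 at the lowest decile, 0.14 at
  the highest — the differential axis is dominated by many small changes;
* Group A = 96 genes, Group B = 95 (top 1% of 9,565 analyzed genes);
* enrichment: `MAPK_LIKE_UP` ranks first for Group A (34/40 genes
  recovered, q ≈ 10⁻⁶³) and `TNFA_LIKE_DOWN` first for Group B — the
  planted signatures are found against 20 decoy sets.

The same stages are exposed as subcommands of the `restflow` CLI
(`simulate`, `preprocess`, `transform`, `distributions`, `groups`, `enrich`,
`sweep`, `shear`, `ddct`, `all`), e.g.

```sh
restflow shear -f 2.2 -a 0.95        # -> 0.4882 (Pa)
restflow all --config pipeline.yaml
```

## Layout

* `restflow.synthetic` — six-condition generator with ground truth and
  planted gene sets
* `restflow.preprocess` — normalization, flooring, log2, filters
* `restflow.transform` — ratios, time averages, rotation, geometry
* `restflow.distributions` — KDEs, KS tests, relative distributions
* `restflow.groups` — signature selection, size-sensitivity sweep
* `restflow.enrichment` — hypergeometric ORA with BH-FDR, GMT collections
* `restflow.assay` — shear stress and 2^(−ΔΔCT) closed forms
* `restflow.io`, `restflow.pipeline`, `restflow.cli` — files, orchestration,
  command line

See `docs/methods.md` for the statistical details and design decisions.
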