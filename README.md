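# bfmap — whole-brain connectivity quantification for basal forebrain cell types

`bfmap` is a tested, reusable re-implementation of the image-analysis
pipeline behind whole-brain input/output mapping of genetically defined
basal forebrain (BF) neurons: cholinergic (ChAT+), glutamatergic (VGLUT2+),
and GABAergic parvalbumin (PV+) and somatostatin (SOM+) cells. Monosynaptic
rabies tracing labels the presynaptic *input* cells of each type;
anterograde tracing labels its axonal *output*. The pipeline turns section
images and cell coordinate tables into normalized per-region distributions
and compares them across cell types.

## What it computes

- **Registration.** Each coronal section is aligned to a reference atlas by
  a 5-parameter planar transform fit to manually chosen landmark pairs:
  `p_atlas = S·R(θ)·p_image + t` with `S = diag(s_ml, s_dv)` — rotation,
  *independent* mediolateral/dorsoventral scales (histological sectioning
  compresses tissue anisotropically), and translation, minimizing the sum of
  squared landmark residuals.
- **Axon detection.** Multi-scale Hessian ridge detection: per scale σ, the
  most-negative Hessian eigenvalue (scale-normalized by σ²) marks bright
  curvilinear structure; directional non-maximum suppression and
  skeletonization yield a binary *ridge image* of 1-px-wide centerlines, so
  the pixel count of an axon tracks its **length, not its thickness**. An
  intensity-distribution mask and a component-size filter remove background
  and speckle noise, optionally iterated; a manual reject mask strikes
  remaining artifacts.
- **Quantification.** Input cells are counted only in coronal sections more
  than 850 µm from the injection site and outside the locally-contaminated
  diagonal-band region; brains with fewer than 200 inputs are dropped.
  Per-region counts (cells, or axon ridge pixels with injection-site and
  fiber-tract regions excluded) are divided by the per-brain total, rolled
  up a hierarchical region ontology (12 major subdivisions, 53 named areas,
  "-other" buckets for unnamed remainders). The convergence index is
  `n_inputs / n_starters`.
- **Comparison.** Pearson correlation coefficients (CCs) between
  distribution vectors at the 12-subdivision scale: matrices between
  cell-type means (input/input, output/output, input/output) and pooled
  within-type vs across-type sample CCs (self-pairs excluded, each
  unordered pair once) with a Welch t-test.
- **Starter maps.** Starter cells binned into 0.24 mm anterior–posterior
  slabs, pooled per cell type, max-normalized, bicubically upsampled.

Because the original study's imagery is not available in machine-readable
form, the package includes a first-class synthetic-data module
(`bfmap.synthetic`) generating atlases, noisy sections with ground-truth
axon centerlines, and cell populations with known region profiles, so every
stage is testable against ground truth.

## A worked example

```python
from bfmap.compare import within_across_cc
from bfmap.synthetic import make_atlas, make_sample_distributions

_, ontology = make_atlas(n_sections=1)
samples = make_sample_distributions(ontology, seed=0)   # 5+5+3+4 brains
res = within_across_cc(samples)
print(f"within {res.within_mean:.2f}  across {res.across_mean:.2f}  p {res.p:.1e}")
```

prints

```
within 0.96  across 0.74  p 3.0e-38
```

— within-type sample pairs correlate more strongly than across-type pairs,
i.e. the four cell types' input maps differ beyond sample-to-sample
variability. The `examples/` directory holds one short script per
capability (registration, detection, quantification, comparison, heat maps,
full pipeline); each prints the numbers it computes and what they mean.

A thin CLI wraps the pipeline:

```bash
bfmap run-all --run-dir out/demo --seed 1
```

runs simulate → register → detect → quantify-cells → quantify-axons →
compare → heatmap (each also available as its own subcommand) and writes
TIFF/CSV/JSON outputs plus a manifest checksumming every file against the
configuration hash and seed.

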