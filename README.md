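# rgcsample

Do different output pathways of the superior colliculus sample distinct
retinal ganglion cell (RGC) types? `rgcsample` is a Python toolbox for the
quantitative machinery behind that question: it profiles the dendritic
stratification of retrogradely labeled ganglion cells, classifies each cell
against a library of reference cell types, and tests whether two circuits —
colliculo-parabigeminal ("Pbg") and colliculo-pulvinar ("LP") — draw on the
same or different types. A synthetic-data module generates every input with
known ground truth, so the whole pipeline is testable end to end without any
imaging data.

It is aimed at retinal/visual-circuits labs that have traced or binarized
single-cell morphologies with ChAT-band annotations, and at anyone who wants
a reference implementation of ChAT-band warping, stratification profiling,
template classification and circuit-bias statistics.

## What it computes

**Depth warping.** The two ChAT bands (starburst amacrine plexi) are fitted
as smoothness-regularized least-squares surfaces from sparse point
annotations, minimizing `Σ(zᵢ − s(xᵢ,yᵢ))² + λ·B(s)` with `B` the thin-plate
bending energy. Arbor points are warped into the band-anchored depth

```
depth(x, y, z) = (z − z_OFF(x, y)) / (z_ON(x, y) − z_OFF(x, y))
```

so the OFF band is depth 0, the ON band depth 1, "above" (sclerad) is
negative and "below" (vitread) exceeds 1.

**Morphometrics.** Per cell: a stratification profile (low-pass-filtered,
normalized depth histogram on a fixed 120-bin grid over [−1, 2]), convex-hull
dendritic-field area and equivalent diameter `D = 2·√(area/π)`, matched-filter
soma detection, and five statistics of a balanced minimum-spanning-tree model
of the arbor (balancing factor 0.4).

**Classification.** Each profile is grouped (bistratified / above / between /
below), scored by linear correlation and Euclidean distance against 56
reference templates (thresholds = squared lower quartile of
molecularly-identified calibration cells), and resolved by a decision tree
using profile shape, dendritic and soma size and PCA splits; the 47
electron-microscopy types collapse to 37 assignable classes after merging
the indistinguishable sets.

**Circuit bias.** Per cell type: the selectivity index
`SI = (%LP − %Pbg)/(%LP + %Pbg)` (0 = equal sampling, ±1 = exclusive), a
retina-level bootstrap (10,000 resamples) for confidence intervals and
p-values, a pooled two-proportion z-test, and Benjamini–Hochberg FDR
correction, with a ≥1% inclusion rule.

**Spike analysis.** PSTHs (50 ms bins), baseline z-scores and the 2-SD
responsivity rule, direction/orientation selectivity
`DSI = |Σ R_k e^{iα_k}| / Σ R_k` (angles doubled for OSI), Fourier band
amplitudes of chirp frequency-sweep responses, response half-widths,
calcium-kernel convolution, chirp-template assignment by three-metric
voting, and retinotopic moving-median size maps.

## Worked example

```python
import numpy as np
import rgcsample as r
from rgcsample import synthetic, chat_surface, morphology, classification, bias_stats

# synthetic ChAT bands with curvature and annotation noise, then fit
bands = synthetic.generate_chat_bands(x_extent=400, y_extent=400,
                                      curvature_amp=8.0, noise_sd=0.5,
                                      n_points=256, seed=7)
on, off = chat_surface.fit_annotation(bands.annotation, smoothness=1.0)

# a synthetic transient ON-alpha cell, warped and profiled
lib = r.default_library()
spec = synthetic.spec_from_template(lib, "6sw", soma_xy=(200, 200), n_points=1200)
arbor = synthetic.generate_arbor(spec, bands, seed=7)
warped = chat_surface.warp_points(arbor, on, off)
profile = morphology.compute_stratification_profile(warped)
area, diameter = morphology.dendritic_field_metrics(arbor)

# classify it (SMI32-positive, so only alpha templates compete)
rng = np.random.default_rng(7)
identified = [(synthetic.profile_draw(lib, n, 0.1, rng), n)
              for n in ("1wt", "4ow", "6sw", "8w", "37c", "37d", "2an", "63", "6t")
              for _ in range(4)]
thr = classification.calibrate_thresholds(identified, lib)
feats = classification.CellFeatures(diameter_um=diameter, soma_area_um2=280.0,
                                    profile=profile)
res = classification.classify_cell(profile, feats, lib, thr, marker="SMI32")

# circuit bias for a type sampled 30% by LP but 10% by Pbg
sample = synthetic.generate_retina_sample(synthetic.CircuitSamplingSpec(
    true_proportions={"LP": {"6sw": 0.30, "other": 0.70},
                      "Pbg": {"6sw": 0.10, "other": 0.90}},
    n_retinas_per_circuit=6, cells_per_retina=100, seed=7))
table = bias_stats.bias_table(sample, n_boot=10_000, seed=7)
```

This prints (via the obvious `print` statements):

```
OFF-band fit RMS residual: 0.02 um
dendritic field: 78198 um^2, equivalent diameter 316 um
stratification peak at depth 0.81 (0 = OFF band, 1 = ON band)
assigned type: 6sw (group: between)
6sw: %LP=28.3, %Pbg=11.3, SI=0.43 [0.34, 0.52], bootstrap p=0.0001, z-test p=0.0000
```

The cell's dendrites peak just above the ON ChAT band (depth 0.81), its
large field (316 µm) separates it from the small transient ON-alpha
look-alike, and the classifier returns `6sw`. The bias table recovers the
imposed LP preference: the empirical percentages (28.3% vs 11.3%) give
SI = 0.43 with a bootstrap interval covering the generating value 0.5, and
both tests reject equal sampling.

A thin CLI mirrors the stages: `rgcsample simulate|warp|profile|classify|
bias|ephys|report`, each with `--seed`, `--out`, `--config`, `--log-level`.

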