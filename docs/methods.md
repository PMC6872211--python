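# Methods

This note documents the models, parameter choices and numerical decisions
behind `rgcsample`, and what the synthetic-data tests do and do not show
about real data.

## Depth frame and band surfaces

All stratification analysis happens in a band-anchored depth coordinate:
0 on the OFF ChAT band, 1 on the ON ChAT band, negative sclerad ("above"),
greater than 1 vitread ("below", toward the ganglion cell layer). The
convention is fixed package-wide; the literature often says only
"above/below the ChAT bands" without a numeric frame.

Each band surface is estimated from manual point annotations by penalized
least squares on a regular lateral grid: grid heights minimize the sum of
squared annotation residuals (bilinear interpolation) plus λ times a
finite-difference thin-plate bending energy (`s_xx² + 2 s_xy² + s_yy²`).
Properties that follow: any plane is reproduced exactly for every λ; as
λ → ∞ the fit tends to the least-squares plane; warping is invariant to
adding a constant to all z.

Defaults: grid spacing 10 µm, λ = 1.0 (µm²-scaled). With annotations at
the field's typical ~20 µm spacing the default grid has more nodes than
data, so the fit interpolates the annotations rather than denoising them;
increase λ (or the spacing) when annotation noise is a concern. A tiny
bending floor (1e−9) keeps nodes outside the data support determined.
Points up to 5 µm outside the annotated support are warped by linear
extrapolation with a warning — real annotations are sparse at scan edges —
and anything farther is rejected.

## Stratification profiles

A profile is the normalized density of a cell's (soma-free) dendritic
points over a fixed grid of 120 bins spanning depth [−1, 2], low-pass
filtered and renormalized. Every profile and every template in a run must
share this grid.

The low-pass filter operates in the Fourier domain on the periodically
extended histogram: harmonics up to the cutoff (default 10 cycles over the
3-depth-unit domain, i.e. features narrower than ≈0.15 depth units are
suppressed) pass unchanged, followed by a raised-cosine roll-off over the
next cutoff/2 harmonics. The roll-off matters: an ideal brick-wall filter
rings around narrow strata, the negative ring lobes must be rectified, and
rectification re-introduces high frequencies — profiles then depend on how
often they have passed through the pipeline. With the tapered filter,
profile recovery from generated arbors is unbiased (Jensen–Shannon
divergence < 0.01 at 2000 points for every packaged template, verified in
the tests).

Depths outside [−1, 2] are clipped and counted; if more than 20% of points
fall outside, the warp is considered suspect and an error is raised.

## Soma detection and tree statistics

The soma is located as the peak of a disc matched filter (default radius
10 µm) applied to the en-face point density, evaluated directly on the
point set with a KD-tree. Detection fails — signaling the caller to supply
the soma manually — when the peak response is under twice the median
response over occupied positions, which is the regime of a blob-free cloud.

Tree statistics come from a balanced minimum-spanning-tree model grown
greedily from the soma: each step attaches the unconnected point minimizing
Euclidean attachment cost plus `bf` times the resulting root-path length
(`bf` = 0.4 by default; `bf` = 0 reduces exactly to Prim's MST, which the
tests verify against an independent oracle). Ties break on the lowest point
index for determinism. The five summary statistics are the mean
path/Euclidean ratio, maximum metric path length, mean branch length
(branch = maximal unbranched path between topological nodes), mean path
length, and z-range over spanning-field width. Clouds above 1500 points
are subsampled deterministically; point-cloud arbors carry no neurite
topology, so the balanced tree is a model, not a reconstruction.

## Template library and classification

The packaged library holds 56 templates: the 47 electron-microscopy
taxonomy types plus nine from molecularly defined sets (HD1/HD2 and a
vertical orientation-selective type; Cdh3/M2 and W7b; four FOXP2⁺ types).
**All packaged profiles are synthetic stand-ins** — Gaussian mixtures over
depth whose peak positions, widths and nominal sizes mimic the qualitative
stratification of each named type — because the real reference profiles
are not ours to redistribute. `load_library` accepts user-supplied real
profiles in the same CSV + JSON-manifest layout. Templates are passed
through the same low-pass as query profiles (so widths are compared on an
equal footing) and iterated to a fixed point of the smooth/rectify/
renormalize projection (so generator output recovers them without bias).

Classification proceeds in four stages:

1. **Group** by profile peaks: ≥2 maxima with prominence ≥0.2× the maximum
   and ≥0.4 depth separation → bistratified; otherwise the dominant peak's
   depth decides above (<−0.05), below (>1.05) or between. A profile whose
   maximum is under twice the uniform level is unclassifiable.
2. **Score** the profile against the marker-compatible templates (SMI32 →
   the four alpha types + W7b; CART → the ON-OFF DS subtypes; FOXP2 → the
   FOXP2 set and its EM counterparts), or against the cell's
   stratification-group templates when no marker is known. Candidates pass
   either the correlation threshold or the distance threshold. Thresholds
   are the squared lower quartile (linear interpolation between order
   statistics) of the scores of molecularly identified calibration cells
   against their own confirmed templates; for the Euclidean distance,
   where "squared lower quartile" is direction-ambiguous, the same rule is
   applied to the similarity s = 1/(1+d). Marker-identified cells with no
   candidate keep their best match; unmarked ones become non-classifiable.
3. **Decision tree.** The best-correlation candidate is provisional;
   per-group rules then adjudicate the specific ambiguities correlation
   cannot separate — extra between-band peaks (25, 85), extension below
   the ON band (27/28 set, 6t), extension beyond both bands (63 vs 5to),
   size splits (6sn/6sw, 4ow vs 4i/4on, 1wt, 1ws, 2an vs 3i/3o, 9w,
   82wi/82wo), the very-large-soma rule for 8w, and nearest-centroid PCA
   splits (72/73, 27/28) in the first three components of standardized
   [size features ∥ profile bins]. Band-extension features use narrow
   probe windows (below-ON: depth 1.08–1.45; above-OFF: −0.45 to −0.08)
   with a pedestal floor of 5% of the profile maximum subtracted, so broad
   low-level noise cannot accumulate into a false extension signal. Rules
   fire only on positive evidence; every firing is appended to a decision
   trace. Final labels live in the merged 37-class set (the four
   indistinguishable pairs and the two direction-selective subtype
   quartets collapse).
4. **Override hook**: an expert reassignment replaces the label, sets a
   flag and preserves the automatic decision in the trace.

On the packaged synthetic corpus (200 draws per template, per-bin noise SD
0.1× the profile peak), aggregate merged-label recovery is ≈98%. The
hardest templates are the deliberately overlapping 27/28 pair (≈75–80%
individually), whose separation leans on the PCA split — mirroring the
fact that some type pairs are genuinely hard in real data too.

## Circuit-bias statistics

Percentages are computed over classified cells within each circuit. The
selectivity index SI = (%LP − %Pbg)/(%LP + %Pbg) is antisymmetric and
bounded in [−1, 1]; it is undefined (error) for a type absent from both
circuits.

The bootstrap resamples **retinas** (the natural exchangeable unit) with
replacement, stratified within circuit so both circuits stay represented,
preserving the per-circuit retina counts; each of the 10,000 default
replicates recomputes every cluster's SI from the pooled resampled counts.
The two-sided p-value doubles the smaller tail fraction (vs 0) with an
add-one floor of 1/(n_boot+1); the interval is the empirical 2.5–97.5%
range. Replicates in which a cluster vanishes from both circuits are
dropped from that cluster's distribution and counted. Under equal sampling
the p-values are approximately uniform, and the 95% interval covers a true
SI of 0.5 in ≥90% of simulation rounds with 6 retinas per circuit — both
verified in the tests at 1000 replicates.

The z-test is the pooled two-proportion test, two-sided, without
continuity correction (z² equals the uncorrected 1-df chi-square, verified
against an oracle); a pooled proportion of 0 or 1 returns p = 1 with a
degenerate flag. Benjamini–Hochberg FDR correction is applied separately
to the bootstrap family and the z-test family over the included clusters
(types holding ≥1% of all cells).

## Spike-train analysis

PSTHs use 50 ms bins (configurable) with baseline statistics from the
pre-stimulus window; spike-count conservation is exact. A cell is
"potentially responding" when its maximal stimulus-window rate exceeds
baseline mean + 2 SD; with a zero baseline SD an absolute-rate criterion
applies. DSI/OSI are the vector-sum magnitudes of background-subtracted,
rectified, max-normalized per-direction peak responses (first 1 s after
onset by default); the OSI doubles the angles. Direction convention: 0° =
rightward, counter-clockwise positive.

Chirp frequency-sweep responses are binned at 1 ms and Fourier transformed;
band amplitudes are means over half-open bands [0.5,1), [1,2), [2,4),
[4,8) Hz — the band edges are package defaults, not established values.
Response half-width is the full width at half prominence of the highest
background-subtracted peak. The calcium-indicator kernel is a unit-area
causal double exponential with rise 70 ms and decay 780 ms by default —
these constants are package defaults for an OGB-1-like indicator, are not
sourced from a publication, and every report should state them. Chirp
responses are resampled to the template grid by linear interpolation;
template assignment ranks linear correlation, Euclidean distance and
summed absolute residual, a template top-2 in ≥2 metrics wins (ties → best
correlation), and otherwise the best-correlation template is taken with
the agreement flag cleared.

Retinotopic size maps use a moving median in a 250 µm-radius window
stepped at 100 µm on a 50×50 grid, smoothed by a missing-data-aware
Gaussian (σ = 200 µm; data and mask filtered separately and divided).
Axis statistics (Pearson r against the naso-temporal coordinate and
against eccentricity) are computed from the raw cells, not the map.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *structure* of the real inputs with known
ground truth: band annotations on smooth low-order cosine surfaces (≤3
harmonics per axis, analytically evaluable anywhere, ON = OFF + gap
exactly); arbors as point clouds with lateral density uniform in a disc
and depths drawn from a template profile; per-retina type counts as
multinomial draws; the chirp stimulus with its published segment structure
(3 s luminance steps, 6 s sweep 0.5→8 Hz, 3 s gray, 5.5 s contrast
modulation at 2 Hz — 29.5 s total); and spikes as inhomogeneous Poisson
trains (thinning algorithm) with a von-Mises direction gain whose
concentration maps monotonically to a target DSI
(`concentration_for_dsi`).

They deliberately do **not** model: neurite topology or realistic branch
geometry (point clouds stand in for binarized voxels), imaging noise and
binarization artifacts, refractoriness or spike-train correlations,
type-dependent viral uptake, or per-retina cell-count variability (uniform
counts per retina are a choice, as no distribution is established).
Passing tests therefore certify the *statistical machinery* — warping
accuracy, profile recovery, classifier behavior under profile noise,
bootstrap calibration — not robustness to every artifact of real imaging
or recording data.

All randomness flows from a single integer seed; sub-streams derive from
fixed offsets, and identical seeds give bit-identical outputs everywhere.

## Problem sizes used in the packaged checks

The packaged verification runs use 1000 bootstrap replicates (the analysis
default remains 10,000), 100 simulation rounds for interval coverage, 200
noisy draws per template for classifier recovery, and 200 null-cluster
p-values (10 independent datasets × 20 clusters) for the uniformity check;
these sizes give stable verdicts for each claim while keeping the full
suite fast.

## Known limitations

- The distance-threshold direction under the "squared lower quartile" rule
  is an interpretation (similarity transform); other implementations may
  have resolved the ambiguity differently.
- Size boundaries in the decision tree derive from the stand-in templates'
  nominal diameters (midpoints between competing sets) and are
  config-overridable; with real templates they should be recalibrated.
- PCA pair splits are fitted on synthetic draws with nominal size
  features; refit them on real corpora before trusting 72/73 or 27/28
  assignments.
- The manual-curation steps of a real pipeline (axon removal, expert
  visual inspection) are represented only as inputs (point-exclusion
  before profiling, the override hook), not automated.
- `bias_table` treats the input counts as classified cells; unclassified
  cells must be excluded upstream.
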