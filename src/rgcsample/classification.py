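"""Template-based ganglion cell type assignment.

The classifier mirrors a four-stage decision process:

1. *Stratification group* — the peak structure of the cell's profile puts
   it in one of four groups: bistratified, above the OFF ChAT band,
   between the bands, or below the ON band.
2. *Template scoring* — linear correlation and Euclidean distance of the
   profile to every library template; templates passing either calibrated
   threshold form the candidate set.  A known molecular marker (SMI32,
   CART, FOXP2) restricts the compared templates to compatible ones first,
   and for marker-identified cells with no candidate above threshold the
   best match is kept.  Unmarked cells with no candidate are
   non-classifiable.
3. *Decision tree* — within-group rules on dendritic/soma size and profile
   shape (extra peaks, extension beyond the bands, PCA splits) resolve the
   remaining ambiguity, defaulting to the best-correlation candidate.
4. *Expert override hook* — a manual reassignment replaces the final label
   while preserving the automatic decision in the trace.

Thresholds are calibrated as the squared lower quartile of the scores of
molecularly identified cells against their own confirmed templates.  For
the Euclidean distance, where smaller is better and squaring a quartile of
raw distances is direction-ambiguous, the same rule is applied to the
similarity transform s = 1/(1 + d); this is an interpretation and is
documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .core import (
    CalibrationError,
    ConfigError,
    GridMismatchError,
    StratificationProfile,
    UnclassifiableProfileError,
)
from .morphology import lowpass_filter
from .templates import TemplateLibrary, merged_label_set

NON_CLASSIFIABLE = "NON_CLASSIFIABLE"

GROUP_BISTRATIFIED = "bistratified"
GROUP_ABOVE = "above"
GROUP_BETWEEN = "between"
GROUP_BELOW = "below"

#: peak separation (depth units) required to call a profile bistratified
BISTRATIFIED_SEPARATION = 0.4
#: prominence floor for counting a peak, relative to the profile maximum
PEAK_PROMINENCE_FRAC = 0.2
#: group boundaries in band-anchored depth
ABOVE_BOUNDARY = -0.05
BELOW_BOUNDARY = 1.05

# decision-tree feature thresholds.  Peak detection is relative to the
# profile maximum; mass features use narrow probe windows just beyond a
# band so that broad low-level noise does not accumulate into a false
# "extension" signal.
_EXTRA_PEAK_HEIGHT_FRAC = 0.20
_EXTRA_PEAK_PROMINENCE_FRAC = 0.12
_BELOW_ON_PROBE = (1.08, 1.45)
_ABOVE_OFF_PROBE = (-0.45, -0.08)
_PROBE_MASS = 0.06
#: for tail detection the density floor (fraction of the profile maximum)
#: is subtracted first, which removes the broad noise pedestal entirely
_TAIL_FLOOR_FRAC = 0.05
_TAIL_EXCESS = 0.03


def assign_stratification_group(profile: StratificationProfile) -> str:
    """Group a profile by the peaks of its dendritic density."""
    d = profile.density
    peak_max = float(d.max())
    uniform = 1.0 / profile.n_bins
    if peak_max < 2.0 * uniform:
        raise UnclassifiableProfileError("profile too flat to carry group information")
    idx, _ = find_peaks(d, prominence=PEAK_PROMINENCE_FRAC * peak_max)
    # a maximum at the domain edge is not found by find_peaks; include it
    if d[0] >= peak_max - 1e-15:
        idx = np.concatenate([[0], idx])
    if d[-1] >= peak_max - 1e-15:
        idx = np.concatenate([idx, [d.size - 1]])
    centers = profile.bin_centers
    if idx.size >= 2 and (centers[idx].max() - centers[idx].min()) >= BISTRATIFIED_SEPARATION:
        return GROUP_BISTRATIFIED
    peak_depth = float(centers[int(np.argmax(d))])
    if peak_depth < ABOVE_BOUNDARY:
        return GROUP_ABOVE
    if peak_depth > BELOW_BOUNDARY:
        return GROUP_BELOW
    return GROUP_BETWEEN


@dataclass(frozen=True)
class Thresholds:
    """Candidate-acceptance thresholds calibrated from identified cells."""

    correlation: float
    distance_similarity: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def calibrate_thresholds(
    identified: list[tuple[StratificationProfile, str]],
    library: TemplateLibrary,
) -> Thresholds:
    """Squared-lower-quartile thresholds from marker-identified cells.

    ``identified`` pairs each calibration profile with its confirmed
    template name.  Quartiles use linear interpolation between order
    statistics.
    """
    if len(identified) < 8:
        raise CalibrationError(
            f"threshold calibration needs >= 8 identified cells, got {len(identified)}"
        )
    corrs, sims = [], []
    for profile, name in identified:
        if name not in library.templates:
            raise ConfigError(f"unknown template {name!r} in calibration set")
        t = library[name].profile.density
        if profile.n_bins != library.n_bins:
            raise GridMismatchError("calibration profile not on the library grid")
        corrs.append(_pearson(profile.density, t))
        d = float(np.linalg.norm(profile.density - t))
        sims.append(1.0 / (1.0 + d))
    q1_corr = float(np.percentile(corrs, 25))
    q1_sim = float(np.percentile(sims, 25))
    return Thresholds(correlation=q1_corr**2, distance_similarity=q1_sim**2)


@dataclass
class MatchResult:
    """Scores, candidates and the final (merged) label for one cell."""

    correlations: dict[str, float]
    distances: dict[str, float]
    candidates: list[str]
    group: str
    final_label: str = NON_CLASSIFIABLE
    decision_trace: list[str] = field(default_factory=list)
    override: bool = False
    marker: str | None = None

    def top(self, n: int = 5) -> list[tuple[str, float]]:
        ranked = sorted(self.correlations.items(), key=lambda kv: -kv[1])
        return ranked[:n]


def template_groups(library: TemplateLibrary) -> dict[str, str]:
    """Stratification group of every template's own profile."""
    return {t.name: assign_stratification_group(t.profile) for t in library}


def score_templates(
    profile: StratificationProfile,
    library: TemplateLibrary,
    marker: str | None = None,
    thresholds: Thresholds | None = None,
    group: str | None = None,
) -> MatchResult:
    """Correlation/distance scoring and candidate selection.

    The compared universe is the marker-compatible template set when a
    marker is known, otherwise the templates of the cell's stratification
    group (all templates if no group is given).  Candidates are templates
    passing either threshold; marker-identified cells keep their best match
    even below threshold, unmarked cells with no candidate are left
    non-classifiable.
    """
    if profile.n_bins != library.n_bins:
        raise GridMismatchError("query profile is not on the library grid")
    if group is None:
        group = assign_stratification_group(profile)
    if marker is not None:
        universe = library.compatible(marker)
    else:
        groups = template_groups(library)
        universe = [n for n in library.names if groups[n] == group]
        if not universe:
            universe = library.names

    correlations = {}
    distances = {}
    for name in universe:
        t = library[name].profile.density
        correlations[name] = _pearson(profile.density, t)
        distances[name] = float(np.linalg.norm(profile.density - t))

    if thresholds is None:
        candidates = list(universe)
    else:
        candidates = [
            n
            for n in universe
            if correlations[n] >= thresholds.correlation
            or 1.0 / (1.0 + distances[n]) >= thresholds.distance_similarity
        ]
    trace = [f"group={group}", f"universe={len(universe)} templates"]
    if not candidates:
        if marker is not None:
            best = max(universe, key=lambda n: correlations[n])
            candidates = [best]
            trace.append(f"marker {marker}: below threshold, best match kept ({best})")
        else:
            trace.append("no candidate above threshold: non-classifiable")
    return MatchResult(
        correlations=correlations,
        distances=distances,
        candidates=candidates,
        group=group,
        decision_trace=trace,
        marker=marker,
    )


# ---------------------------------------------------------------------------
# PCA pair splits


@dataclass
class PairDiscriminator:
    """Nearest-class-centroid split in the first principal components of
    standardized [tree statistics || profile bins] features."""

    labels: tuple[str, str]
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (3, n_features)
    centroids: np.ndarray  # (2, 3)

    @classmethod
    def fit(cls, labels: tuple[str, str], x0: np.ndarray, x1: np.ndarray) -> "PairDiscriminator":
        x = np.vstack([x0, x1])
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0
        z = (x - mean) / scale
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        comps = vt[:3]
        proj = z @ comps.T
        c0 = proj[: x0.shape[0]].mean(axis=0)
        c1 = proj[x0.shape[0]:].mean(axis=0)
        return cls(labels=labels, mean=mean, scale=scale, components=comps,
                   centroids=np.vstack([c0, c1]))

    def predict(self, features: np.ndarray) -> str:
        z = (features - self.mean) / self.scale
        proj = z @ self.components.T
        d = np.linalg.norm(self.centroids - proj, axis=1)
        return self.labels[int(np.argmin(d))]


#: template pairs the decision tree separates in PCA space
PCA_PAIRS: tuple[tuple[str, str], ...] = (("72", "73"), ("27", "28"))


def _noisy_profile(template_density: np.ndarray, noise_sd_frac: float,
                   rng: np.random.Generator, cutoff: int = 10) -> np.ndarray:
    noise = rng.normal(0.0, noise_sd_frac * template_density.max(), template_density.size)
    d = np.clip(lowpass_filter(template_density + noise, cutoff), 0, None)
    return d / d.sum()


def fit_pair_discriminators(
    library: TemplateLibrary,
    pairs: tuple[tuple[str, str], ...] = PCA_PAIRS,
    n_draws: int = 100,
    noise_sd_frac: float = 0.1,
    seed: int = 20190501,
) -> dict[frozenset, PairDiscriminator]:
    """Fit the packaged PCA splits from noisy synthetic template draws.

    Feature vectors combine nominal per-type statistics (diameter, soma
    area) with the profile bins; real tree statistics can be substituted by
    refitting with user data.
    """
    rng = np.random.default_rng(seed)
    out: dict[frozenset, PairDiscriminator] = {}
    for a, b in pairs:
        xs = []
        for name in (a, b):
            t = library[name]
            draws = np.stack([
                _noisy_profile(t.profile.density, noise_sd_frac, rng)
                for _ in range(n_draws)
            ])
            meta = np.column_stack([
                rng.normal(t.nominal_diameter_um, 0.08 * t.nominal_diameter_um, n_draws),
                rng.normal(t.nominal_soma_area_um2, 0.08 * t.nominal_soma_area_um2, n_draws),
            ])
            xs.append(np.hstack([meta, draws]))
        out[frozenset((a, b))] = PairDiscriminator.fit((a, b), xs[0], xs[1])
    return out


# ---------------------------------------------------------------------------
# decision tree


@dataclass
class CellFeatures:
    """Morphological features the decision tree consumes."""

    diameter_um: float
    soma_area_um2: float
    profile: StratificationProfile
    tree_stats: np.ndarray | None = None


def _size_boundary(library: TemplateLibrary, large: list[str], small: list[str]) -> float:
    """Midpoint between the median nominal diameters of two template sets."""
    big = np.median([library[n].nominal_diameter_um for n in large if n in library.templates])
    little = np.median([library[n].nominal_diameter_um for n in small if n in library.templates])
    return float(0.5 * (big + little))


def _has_extra_peak(profile: StratificationProfile, lo: float, hi: float) -> bool:
    """A secondary local maximum with depth in [lo, hi)."""
    d = profile.density
    peak_max = float(d.max())
    idx, _ = find_peaks(
        d,
        height=_EXTRA_PEAK_HEIGHT_FRAC * peak_max,
        prominence=_EXTRA_PEAK_PROMINENCE_FRAC * peak_max,
    )
    centers = profile.bin_centers
    main = float(centers[int(np.argmax(d))])
    for i in idx:
        c = float(centers[i])
        if lo <= c < hi and abs(c - main) > 0.2:
            return True
    return False


def _probe_excess(profile: StratificationProfile, lo: float, hi: float) -> float:
    """Density mass above a pedestal floor within a probe window."""
    c = profile.bin_centers
    d = profile.density
    floor = _TAIL_FLOOR_FRAC * float(d.max())
    sel = (c >= lo) & (c < hi)
    return float(np.clip(d[sel] - floor, 0.0, None).sum())


def _pca_features(features: CellFeatures) -> np.ndarray:
    return np.concatenate([
        [features.diameter_um, features.soma_area_um2],
        features.profile.density,
    ])


def decision_tree(
    result: MatchResult,
    features: CellFeatures,
    library: TemplateLibrary,
    discriminators: dict[frozenset, PairDiscriminator] | None = None,
) -> MatchResult:
    """Resolve the candidate set to a final merged label.

    The best-correlation candidate is provisional; within-group rules then
    adjudicate the specific ambiguities the correlation stage cannot
    separate (size splits between look-alike pairs, extra profile peaks,
    extension beyond the bands, PCA splits).  Every fired rule is appended
    to the decision trace.
    """
    if not result.candidates:
        if result.marker is not None:
            raise ConfigError("marker-identified cell with empty candidate set")
        result.final_label = NON_CLASSIFIABLE
        return result
    trace = result.decision_trace
    cand = result.candidates
    corr = result.correlations
    diam = features.diameter_um
    soma = features.soma_area_um2
    prof = features.profile

    def best(names) -> str:
        names = [n for n in names if n in corr]
        return max(names, key=lambda n: corr[n])

    def demote(exclude: set[str]) -> str:
        rest = [n for n in cand if n not in exclude]
        return best(rest) if rest else best(cand)

    chosen = best(cand)
    trace.append(f"provisional={chosen} (best correlation)")
    group = result.group
    lib = library.templates

    if group == GROUP_BELOW:
        if "85" in cand and _has_extra_peak(prof, ABOVE_BOUNDARY, 0.95):
            chosen = "85"
            trace.append("extra between-band peak -> 85")
        elif "9w" in cand and diam > _size_boundary(library, ["9w"], ["82wo"]) and chosen != "9w":
            chosen = "9w"
            trace.append("very large dendritic tree -> 9w")
        if chosen in {"8n", "8w", "9n"}:
            b = 0.5 * (lib["8w"].nominal_soma_area_um2 + lib["8n"].nominal_soma_area_um2)
            if soma > b and "8w" in cand:
                chosen = "8w"
                trace.append("no dendrites above OFF band; very large soma -> 8w")
            else:
                chosen = "8n" if "8n" in cand else ("9n" if "9n" in cand else chosen)
                trace.append("no dendrites above OFF band; 8n/9n not separable")
        elif chosen in {"82wi", "82wo", "72", "73", "81i", "81o", "82n"}:
            b_soma = 0.5 * (lib["8w"].nominal_soma_area_um2 + lib["82wi"].nominal_soma_area_um2)
            b_diam = _size_boundary(library, ["82wi", "82wo"], ["72", "73", "81i", "81o", "82n", "8n", "9n"])
            wide = [n for n in ("82wi", "82wo") if n in cand]
            if chosen in {"82wi", "82wo"} and soma > b_soma and "8w" in cand:
                chosen = "8w"
                trace.append("very large soma among large candidates -> 8w")
            elif diam < b_diam and chosen in {"82wi", "82wo"}:
                chosen = demote({"82wi", "82wo"})
                trace.append(f"tree too small for 82wi/82wo -> {chosen}")
            elif diam > b_diam and wide and chosen not in {"82wi", "82wo"}:
                chosen = best(wide)
                trace.append(f"significantly larger tree -> {chosen}")
        if chosen in {"72", "73"} and discriminators:
            disc = discriminators.get(frozenset(("72", "73")))
            if disc is not None:
                chosen = disc.predict(_pca_features(features))
                trace.append(f"PCA split 72/73 -> {chosen}")

    elif group == GROUP_BETWEEN:
        below_mass = prof.mass(*_BELOW_ON_PROBE)
        if chosen in {"6t", "Fmidi-ON"} and below_mass < _PROBE_MASS:
            chosen = demote({"6t", "Fmidi-ON"})
            trace.append(f"no below-ON extension -> {chosen}")
        if chosen in {"6sn", "6sw"}:
            b = _size_boundary(library, ["6sw"], ["6sn"])
            chosen = "6sw" if diam > b else "6sn"
            trace.append(f"size split 6sn/6sw at {b:.0f} um -> {chosen}")
        elif chosen in {"5to", "63", "Fmini-ON"}:
            beyond = (
                prof.mass(*_ABOVE_OFF_PROBE) > _PROBE_MASS
                and below_mass > _PROBE_MASS
            )
            if beyond:
                chosen = "Fmini-ON" if chosen == "Fmini-ON" else "63"
                trace.append("broad profile extends beyond both bands -> 63")
            else:
                chosen = "5to"
                trace.append("broad profile confined to the bands -> 5to")
        elif chosen in {"4i", "4on", "4ow"}:
            b = _size_boundary(library, ["4ow"], ["4i", "4on"])
            if diam > b and "4ow" in cand:
                chosen = "4ow"
                trace.append(f"size split at {b:.0f} um -> 4ow")
            else:
                chosen = "4i" if "4i" in cand else ("4on" if "4on" in cand else chosen)
                trace.append("4i/4on not separable")
        elif chosen == "5si":
            if prof.center_of_mass() > 0.5:
                trace.append("ON-band-biased profile -> 5si")

    elif group == GROUP_ABOVE:
        below_excess = _probe_excess(prof, *_BELOW_ON_PROBE)
        if "25" in cand and _has_extra_peak(prof, 0.05, 0.95):
            chosen = "25"
            trace.append("extra between-band peak -> 25")
        elif below_excess > _TAIL_EXCESS:
            deep = [n for n in ("27", "28", "Fmidi-OFF") if n in cand]
            if deep:
                chosen = best(deep)
                trace.append("dendrites extend below ON band -> 27/28 set")
                if chosen in {"27", "28"} and discriminators:
                    disc = discriminators.get(frozenset(("27", "28")))
                    if disc is not None:
                        chosen = disc.predict(_pca_features(features))
                        trace.append(f"PCA split 27/28 -> {chosen}")
        elif chosen in {"27", "28", "Fmidi-OFF"}:
            chosen = demote({"27", "28", "Fmidi-OFF"})
            trace.append(f"no below-ON extension -> {chosen}")
        if chosen in {"1wt", "2aw", "2o", "2i", "W7b"}:
            b = _size_boundary(library, ["1wt"], ["2aw", "2o", "2i"])
            if diam > b and "1wt" in cand and chosen not in {"1wt", "W7b"}:
                trace.append(f"considerably larger tree (> {b:.0f} um) -> 1wt")
                chosen = "1wt"
            elif chosen in {"1wt", "W7b"} and diam < b:
                chosen = demote({"1wt", "W7b"})
                trace.append(f"tree too small for 1wt -> {chosen}")
        if chosen in {"2an", "3i", "3o", "Fmini-OFF"}:
            b = _size_boundary(library, ["3i", "3o"], ["2an"])
            if diam < b:
                if chosen in {"3i", "3o"}:
                    chosen = "2an" if "2an" in cand else chosen
                    trace.append(f"substantially smaller tree (< {b:.0f} um) -> 2an")
            elif chosen in {"2an", "Fmini-OFF"}:
                alt = [n for n in ("3i", "3o") if n in cand]
                if alt:
                    chosen = best(alt)
                    trace.append(f"tree too large for 2an -> {chosen}")
        if chosen == "1ws" and diam < _size_boundary(library, ["1ws"], ["1ni", "1no", "915"]):
            chosen = demote({"1ws"})
            trace.append(f"not the largest type -> {chosen}")
        elif chosen in {"1ni", "1no", "915"} and "1ws" in cand and diam > _size_boundary(
            library, ["1ws"], ["1ni", "1no", "915"]
        ):
            chosen = "1ws"
            trace.append("largest tree in the retina -> 1ws")

    # bistratified group: the DS subtypes merge; best correlation decides

    result.final_label = library.merged_label(chosen)
    trace.append(f"template={chosen} -> label={result.final_label}")
    if result.marker is not None:
        compatible_labels = {library.merged_label(n) for n in library.compatible(result.marker)}
        if result.final_label not in compatible_labels:
            fallback = best(library.compatible(result.marker))
            result.final_label = library.merged_label(fallback)
            trace.append(f"marker constraint enforced -> {result.final_label}")
    return result


def apply_override(result: MatchResult, override_label: str, reason: str,
                   library: TemplateLibrary) -> MatchResult:
    """Expert reassignment hook: replace the final label, keep the trace."""
    merged = set(merged_label_set(library))
    for t in library:
        merged.add(library.merged_label(t.name))
    if override_label not in merged:
        raise ConfigError(f"override label {override_label!r} not in the merged label set")
    new = replace(result)
    new.decision_trace = list(result.decision_trace) + [
        f"override: {result.final_label} -> {override_label} ({reason})"
    ]
    new.final_label = override_label
    new.override = True
    return new


def classify_cell(
    profile: StratificationProfile,
    features: CellFeatures,
    library: TemplateLibrary,
    thresholds: Thresholds,
    marker: str | None = None,
    discriminators: dict[frozenset, PairDiscriminator] | None = None,
) -> MatchResult:
    """Full pipeline: group -> scoring -> decision tree."""
    result = score_templates(profile, library, marker=marker, thresholds=thresholds)
    return decision_tree(result, features, library, discriminators=discriminators)
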