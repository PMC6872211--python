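"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: ChAT-band point
annotations over smooth curved surfaces, dendritic arbors drawn from known
depth profiles, per-retina cell-type count tables with controlled sampling
biases, the full-field chirp stimulus, and Poisson spike trains with
imposed direction tuning or chirp-template firing rates.  All randomness
flows from one explicit integer seed; generator sub-streams are derived
with fixed offsets, so identical seeds give bit-identical outputs.

The generators emulate the *structure* of real recordings, not their
physics: point clouds stand in for binarized confocal voxels, spike trains
are inhomogeneous Poisson (no refractoriness), and band surfaces are
low-order cosine series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chat_surface import ChATAnnotation
from .core import (
    ArborPointCloud,
    CIRCUITS,
    InvalidSpecError,
    StratificationProfile,
    rng_stream,
)
from .morphology import lowpass_filter
from .templates import TemplateLibrary

# stream offsets: one per generator, so generators are independent
_BANDS, _ARBOR, _RETINA, _SPIKES, _PROFILE = 11, 13, 17, 19, 23


# ---------------------------------------------------------------------------
# ChAT bands


@dataclass
class SyntheticBands:
    """Annotation points plus the noiseless generating surfaces."""

    annotation: ChATAnnotation
    off_surface: "CosineSurface"
    on_surface: "CosineSurface"
    band_gap_um: float


@dataclass
class CosineSurface:
    """z(x, y) = offset + sum_jk a_jk cos(pi j x / Lx) cos(pi k y / Ly).

    A low-order (<= 3 harmonics per axis) cosine series: smooth, band
    limited, and analytically evaluable anywhere.
    """

    offset: float
    amplitudes: np.ndarray  # (4, 4); [0, 0] unused (absorbed in offset)
    x_extent: float
    y_extent: float

    def __call__(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.full(np.broadcast(x, y).shape, self.offset, dtype=float)
        for j in range(4):
            for k in range(4):
                a = self.amplitudes[j, k]
                if a == 0.0:
                    continue
                z = z + a * np.cos(np.pi * j * x / self.x_extent) * np.cos(
                    np.pi * k * y / self.y_extent
                )
        return z


def generate_chat_bands(
    x_extent: float = 300.0,
    y_extent: float = 300.0,
    curvature_amp: float = 5.0,
    band_gap: float = 12.0,
    noise_sd: float = 0.5,
    n_points: int = 256,
    seed: int = 0,
    base_z: float = 30.0,
) -> SyntheticBands:
    """Two parallel curved band surfaces sampled as noisy annotation points.

    The OFF band is the shallower surface; the ON band sits ``band_gap`` µm
    deeper everywhere (real bands are ~10-15 µm apart).  Annotation points
    are laid out on a jittered grid, mimicking manual labeling at roughly
    regular spacing, with Gaussian z noise of ``noise_sd`` µm.
    """
    if x_extent <= 0 or y_extent <= 0:
        raise InvalidSpecError("band extents must be positive")
    if band_gap <= 0:
        raise InvalidSpecError("band gap must be positive")
    if n_points < 16:
        raise InvalidSpecError("need at least 16 annotation points per band")
    rng = rng_stream(seed, _BANDS)

    amplitudes = np.zeros((4, 4))
    if curvature_amp > 0:
        raw = rng.normal(0.0, 1.0, (4, 4))
        raw[0, 0] = 0.0
        raw[3, :] *= 0.3  # taper high harmonics
        raw[:, 3] *= 0.3
        norm = np.abs(raw).sum()
        amplitudes = curvature_amp * raw / norm if norm > 0 else raw
    off = CosineSurface(offset=base_z, amplitudes=amplitudes,
                        x_extent=x_extent, y_extent=y_extent)
    on = CosineSurface(offset=base_z + band_gap, amplitudes=amplitudes,
                       x_extent=x_extent, y_extent=y_extent)

    n_side = int(np.ceil(np.sqrt(n_points)))
    gx = np.linspace(0, x_extent, n_side)
    gy = np.linspace(0, y_extent, n_side)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    lateral = np.column_stack([xx.ravel(), yy.ravel()])[:n_points]

    def sample(surface: CosineSurface) -> np.ndarray:
        z = surface(lateral[:, 0], lateral[:, 1])
        if noise_sd > 0:
            z = z + rng.normal(0.0, noise_sd, z.shape)
        return np.column_stack([lateral, z])

    annotation = ChATAnnotation(on_points=sample(on), off_points=sample(off))
    return SyntheticBands(annotation=annotation, off_surface=off, on_surface=on,
                          band_gap_um=band_gap)


# ---------------------------------------------------------------------------
# arbors


@dataclass
class SyntheticCellSpec:
    """Ground-truth description of one synthetic ganglion cell."""

    type_label: str
    field_diameter: float
    soma_xy: tuple[float, float]
    n_points: int
    depth_profile: StratificationProfile
    marker: str | None = None
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.field_diameter <= 0:
            raise InvalidSpecError("field diameter must be positive")
        if self.n_points < 50:
            raise InvalidSpecError("need at least 50 arbor points")


def spec_from_template(
    library: TemplateLibrary,
    type_label: str,
    soma_xy: tuple[float, float],
    n_points: int = 2000,
    cell_id: str = "",
) -> SyntheticCellSpec:
    if type_label not in library.templates:
        raise InvalidSpecError(f"type {type_label!r} not in the template library")
    t = library[type_label]
    marker = next(iter(t.markers)) if t.markers else None
    return SyntheticCellSpec(
        type_label=type_label,
        field_diameter=t.nominal_diameter_um,
        soma_xy=soma_xy,
        n_points=n_points,
        depth_profile=t.profile,
        marker=marker,
        cell_id=cell_id or type_label,
    )


def _sample_depths(profile: StratificationProfile, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw depths from a binned profile (uniform within each bin)."""
    edges = profile.bin_edges
    bins = rng.choice(profile.n_bins, size=n, p=profile.density)
    u = rng.uniform(0.0, 1.0, n)
    return edges[bins] + u * (edges[bins + 1] - edges[bins])


def generate_arbor(
    spec: SyntheticCellSpec,
    bands: SyntheticBands,
    seed: int = 0,
    circuit: str = "unknown",
) -> ArborPointCloud:
    """Point-cloud arbor with lateral density uniform in a disc and depths
    drawn from the spec's profile, mapped through the band surfaces to µm.

    The soma is placed at the profile's median depth and carried as the
    tagged soma position; the true depth of every point is recoverable by
    warping with the generating surfaces.
    """
    rng = rng_stream(seed, _ARBOR)
    n = spec.n_points
    r = 0.5 * spec.field_diameter * np.sqrt(rng.uniform(0.0, 1.0, n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    x = spec.soma_xy[0] + r * np.cos(theta)
    y = spec.soma_xy[1] + r * np.sin(theta)
    _check_extent(x, y, bands)
    depth = _sample_depths(spec.depth_profile, n, rng)
    z_off = bands.off_surface(x, y)
    z_on = bands.on_surface(x, y)
    z = z_off + depth * (z_on - z_off)

    cum = np.cumsum(spec.depth_profile.density)
    median_depth = float(spec.depth_profile.bin_centers[int(np.searchsorted(cum, 0.5))])
    sx, sy = spec.soma_xy
    s_off = float(bands.off_surface(sx, sy))
    s_on = float(bands.on_surface(sx, sy))
    soma = np.array([sx, sy, s_off + median_depth * (s_on - s_off)])

    return ArborPointCloud(
        points=np.column_stack([x, y, z]),
        soma=soma,
        voxel_size_um=(0.5, 0.5, 0.3),
        markers=frozenset([spec.marker]) if spec.marker else frozenset(),
        circuit=circuit,
        cell_id=spec.cell_id,
    )


def _check_extent(x: np.ndarray, y: np.ndarray, bands: SyntheticBands) -> None:
    sx = bands.off_surface.x_extent
    sy = bands.off_surface.y_extent
    if x.min() < 0 or x.max() > sx or y.min() < 0 or y.max() > sy:
        raise InvalidSpecError("arbor extends beyond the band surface support")


def true_depths(arbor: ArborPointCloud, bands: SyntheticBands) -> np.ndarray:
    """Warp arbor points through the noiseless generating surfaces."""
    x, y, z = arbor.points.T
    z_off = bands.off_surface(x, y)
    z_on = bands.on_surface(x, y)
    return (z - z_off) / (z_on - z_off)


def profile_draw(
    library: TemplateLibrary,
    type_label: str,
    noise_sd_frac: float,
    rng: np.random.Generator,
    cutoff: int = 10,
) -> StratificationProfile:
    """A noisy profile draw from a template: template + iid bin noise with
    SD = ``noise_sd_frac`` x peak, low-pass smoothed as the profiling stage
    would, rectified and renormalized."""
    t = library[type_label].profile
    noise = rng.normal(0.0, noise_sd_frac * t.density.max(), t.n_bins)
    d = np.clip(lowpass_filter(t.density + noise, cutoff), 0.0, None)
    total = d.sum()
    if total <= 0:  # pragma: no cover - requires absurd noise levels
        raise InvalidSpecError("noise destroyed the profile")
    return StratificationProfile(density=d / total, n_bins=t.n_bins)


# ---------------------------------------------------------------------------
# per-retina circuit sampling


@dataclass
class CircuitSamplingSpec:
    """Multinomial sampling design for the two circuits' retinas.

    ``true_proportions`` maps circuit -> {cluster -> probability}; each
    circuit's proportions must sum to 1.
    """

    true_proportions: dict[str, dict[str, float]]
    n_retinas_per_circuit: int
    cells_per_retina: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_retinas_per_circuit < 1 or self.cells_per_retina < 1:
            raise InvalidSpecError("retina and cell counts must be >= 1")
        for circuit, props in self.true_proportions.items():
            if circuit not in CIRCUITS:
                raise InvalidSpecError(f"unknown circuit {circuit!r}")
            total = sum(props.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise InvalidSpecError(
                    f"{circuit} proportions sum to {total}, expected 1"
                )


def generate_retina_sample(spec: CircuitSamplingSpec) -> pd.DataFrame:
    """Per-retina cluster counts: tidy frame (retina_id, circuit, cluster,
    count), one multinomial draw per retina."""
    rng = rng_stream(spec.seed, _RETINA)
    rows = []
    for circuit in sorted(spec.true_proportions):
        clusters = sorted(spec.true_proportions[circuit])
        p = np.array([spec.true_proportions[circuit][c] for c in clusters])
        for i in range(spec.n_retinas_per_circuit):
            counts = rng.multinomial(spec.cells_per_retina, p)
            retina_id = f"{circuit}-r{i:02d}"
            for cluster, count in zip(clusters, counts):
                rows.append((retina_id, circuit, cluster, int(count)))
    return pd.DataFrame(rows, columns=["retina_id", "circuit", "cluster", "count"])


# ---------------------------------------------------------------------------
# chirp stimulus


@dataclass
class StimulusTrace:
    """Luminance trace in [0, 1] with named segment boundaries (s)."""

    times: np.ndarray
    luminance: np.ndarray
    segments: dict[str, tuple[float, float]]
    frame_rate: float

    @property
    def duration(self) -> float:
        return float(self.segments[list(self.segments)[-1]][1])


CHIRP_LEVELS = (
    ("gray1", 3.0, 0.5),
    ("black", 3.0, 0.0),
    ("gray2", 3.0, 0.5),
    ("white", 3.0, 1.0),
    ("gray3", 3.0, 0.5),
)
CHIRP_SWEEP_S = 6.0
CHIRP_SWEEP_F0_HZ = 0.5
CHIRP_SWEEP_F1_HZ = 8.0
CHIRP_GRAY_S = 3.0
CHIRP_CONTRAST_S = 5.5
CHIRP_CONTRAST_HZ = 2.0


def generate_chirp_stimulus(frame_rate: float = 60.0) -> StimulusTrace:
    """The full-field chirp: gray-black-gray-white-gray steps (3 s each), a
    6 s frequency sweep 0.5 -> 8 Hz between black and white, 3 s gray, and
    a 5.5 s contrast sweep 0 -> 100% at 2 Hz.  Total 29.5 s."""
    if frame_rate <= 2 * CHIRP_SWEEP_F1_HZ:
        raise InvalidSpecError(
            f"frame rate must exceed {2 * CHIRP_SWEEP_F1_HZ} Hz (Nyquist for the sweep)"
        )
    dt = 1.0 / frame_rate
    segments: dict[str, tuple[float, float]] = {}
    t0 = 0.0
    chunks: list[np.ndarray] = []
    times: list[np.ndarray] = []

    def add(name: str, dur: float, values) -> None:
        nonlocal t0
        t = np.arange(0.0, dur, dt)
        times.append(t0 + t)
        chunks.append(values(t) if callable(values) else np.full(t.shape, values))
        segments[name] = (t0, t0 + dur)
        t0 += dur

    for name, dur, level in CHIRP_LEVELS:
        add(name, dur, level)
    # linear frequency sweep: phase = 2*pi*(f0*t + (f1-f0)/(2*T)*t^2)
    k = (CHIRP_SWEEP_F1_HZ - CHIRP_SWEEP_F0_HZ) / CHIRP_SWEEP_S
    add(
        "frequency_sweep",
        CHIRP_SWEEP_S,
        lambda t: 0.5 + 0.5 * np.sin(2 * np.pi * (CHIRP_SWEEP_F0_HZ * t + 0.5 * k * t**2)),
    )
    add("gray4", CHIRP_GRAY_S, 0.5)
    add(
        "contrast_sweep",
        CHIRP_CONTRAST_S,
        lambda t: 0.5
        + 0.5 * (t / CHIRP_CONTRAST_S) * np.sin(2 * np.pi * CHIRP_CONTRAST_HZ * t),
    )
    return StimulusTrace(
        times=np.concatenate(times),
        luminance=np.clip(np.concatenate(chunks), 0.0, 1.0),
        segments=segments,
        frame_rate=frame_rate,
    )


# ---------------------------------------------------------------------------
# spikes


@dataclass
class TuningSpec:
    """Imposed response properties for the spike generator."""

    baseline_rate: float = 2.0
    peak_rate: float = 30.0
    preferred_direction: float = 0.0
    tuning_concentration: float = 0.0
    chirp_template: np.ndarray | None = None
    n_trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.peak_rate < 0:
            raise InvalidSpecError("rates must be non-negative")
        if not 0.0 <= self.preferred_direction < 360.0:
            raise InvalidSpecError("preferred direction must be in [0, 360)")
        if self.tuning_concentration < 0:
            raise InvalidSpecError("tuning concentration must be >= 0")
        if self.n_trials < 1:
            raise InvalidSpecError("need at least one trial")


@dataclass
class SpikeData:
    """Trial-resolved spike times, stimulus-aligned (s)."""

    trials: pd.DataFrame  # columns: cell_id, stimulus, trial, direction_deg, spike_time_s
    duration: float
    baseline_window: float = 0.0
    n_trials_per_condition: int = 1
    cell_id: str = ""


def _poisson_times(rate_fn, duration: float, rate_max: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson sampling by thinning."""
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration)
    t = np.sort(rng.uniform(0.0, duration, n))
    keep = rng.uniform(0.0, 1.0, n) * rate_max < rate_fn(t)
    return t[keep]


def von_mises_gain(direction_deg: float, preferred_deg: float,
                   concentration: float) -> float:
    """Circular gain in [0, 1]: exp(kappa (cos(a - a_pref) - 1))."""
    delta = np.deg2rad(direction_deg - preferred_deg)
    return float(np.exp(concentration * (np.cos(delta) - 1.0)))


def generate_direction_trials(
    tuning: TuningSpec,
    directions_deg: tuple[float, ...] = (0, 45, 90, 135, 180, 225, 270, 315),
    trial_duration: float = 2.0,
    baseline_window: float = 1.0,
    cell_id: str = "cell",
) -> SpikeData:
    """Moving-bar trials: a response bump whose amplitude follows a
    von-Mises gain around the preferred direction, on a Poisson baseline.

    Each trial spans [-baseline_window, trial_duration]; the response is a
    Gaussian bump centered mid-trial (the bar crossing the receptive
    field).
    """
    rng = rng_stream(tuning.seed, _SPIKES)
    rows = []
    bump_center = 0.5 * trial_duration
    bump_sd = 0.15 * trial_duration
    for direction in directions_deg:
        gain = von_mises_gain(direction, tuning.preferred_direction,
                              tuning.tuning_concentration)
        amp = (tuning.peak_rate - tuning.baseline_rate) * gain

        def rate(t, amp=amp):
            return tuning.baseline_rate + amp * np.exp(
                -0.5 * ((t - bump_center) / bump_sd) ** 2
            )

        rate_max = tuning.baseline_rate + max(amp, 0.0)
        for trial in range(tuning.n_trials):
            spikes = _poisson_times(rate, trial_duration, rate_max, rng)
            base = (
                np.sort(rng.uniform(0.0, baseline_window,
                                    rng.poisson(tuning.baseline_rate * baseline_window)))
                - baseline_window
            )
            for s in np.concatenate([base, spikes]):
                rows.append((cell_id, "moving_bar", trial, float(direction), float(s)))
    frame = pd.DataFrame(
        rows, columns=["cell_id", "stimulus", "trial", "direction_deg", "spike_time_s"]
    )
    return SpikeData(trials=frame, duration=trial_duration,
                     baseline_window=baseline_window,
                     n_trials_per_condition=tuning.n_trials, cell_id=cell_id)


def generate_chirp_response(
    stimulus: StimulusTrace,
    tuning: TuningSpec,
    cell_id: str = "cell",
    baseline_window: float = 2.0,
) -> SpikeData:
    """Poisson spike trains whose rate follows baseline + gain x template.

    ``tuning.chirp_template`` is a non-negative rate modulation sampled on
    the stimulus frame grid (resampled linearly if its length differs).
    """
    rng = rng_stream(tuning.seed, _SPIKES)
    duration = stimulus.duration
    if tuning.chirp_template is None:
        template = np.zeros(stimulus.times.size)
    else:
        template = np.asarray(tuning.chirp_template, dtype=float)
        if template.size != stimulus.times.size:
            template = np.interp(
                stimulus.times,
                np.linspace(0, duration, template.size),
                template,
            )
    template = np.clip(template, 0.0, None)
    peak = template.max()
    gain = (tuning.peak_rate - tuning.baseline_rate) / peak if peak > 0 else 0.0
    rate_samples = tuning.baseline_rate + gain * template

    def rate(t):
        return np.interp(t, stimulus.times, rate_samples)

    rows = []
    for trial in range(tuning.n_trials):
        spikes = _poisson_times(rate, duration, float(rate_samples.max()), rng)
        base = (
            np.sort(rng.uniform(0.0, baseline_window,
                                rng.poisson(tuning.baseline_rate * baseline_window)))
            - baseline_window
        )
        for s in np.concatenate([base, spikes]):
            rows.append((cell_id, "chirp", trial, np.nan, float(s)))
    frame = pd.DataFrame(
        rows, columns=["cell_id", "stimulus", "trial", "direction_deg", "spike_time_s"]
    )
    return SpikeData(trials=frame, duration=duration, baseline_window=baseline_window,
                     n_trials_per_condition=tuning.n_trials, cell_id=cell_id)


def concentration_for_dsi(target_dsi: float) -> float:
    """Numerically invert the concentration -> DSI map for 8 directions.

    The DSI of noiseless von-Mises responses increases monotonically with
    the concentration; this returns the concentration whose ideal DSI
    matches ``target_dsi``.
    """
    if not 0.0 <= target_dsi < 1.0:
        raise InvalidSpecError("target DSI must be in [0, 1)")
    directions = np.deg2rad(np.arange(0, 360, 45))

    def dsi_of(kappa: float) -> float:
        r = np.exp(kappa * (np.cos(directions) - 1.0))
        r = r / r.max()
        return float(np.abs(np.sum(r * np.exp(1j * directions))) / np.sum(r))

    lo, hi = 0.0, 64.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if dsi_of(mid) < target_dsi:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
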