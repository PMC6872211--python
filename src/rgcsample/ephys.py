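"""Spike-train analysis shared by in-vivo and ex-vivo recordings.

PSTHs in 50 ms bins with baseline z-scores, the 2-SD responsivity rule,
direction/orientation selectivity from the vector sum of per-direction
peak responses, Fourier analysis of chirp frequency-sweep responses,
response half-widths, calcium-kernel convolution for comparison with
imaging data sets, chirp-template functional assignment by three distance
metrics with top-two voting, and retinotopic moving-median size maps.

Direction convention: 0 deg = rightward motion, counter-clockwise
positive.  Angles enter the selectivity vector sums in radians; the OSI
doubles them so opposite directions reinforce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import (
    ConfigError,
    InsufficientWindowError,
    InvalidSpecError,
    NoPeakError,
    ZeroResponseError,
)
from .synthetic import SpikeData

DEFAULT_BIN_S = 0.05
#: default Fourier bands for sweep responses, half-open [lo, hi) in Hz
DEFAULT_BANDS_HZ = ((0.5, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, 8.0))
#: default calcium-indicator kernel (ogb1-like), configurable per report
OGB1_RISE_S = 0.07
OGB1_DECAY_S = 0.78


@dataclass
class PSTH:
    bin_width: float
    edges: np.ndarray  # bin edges, from -baseline_window to duration
    rates: np.ndarray  # trial-averaged rate per bin (Hz)
    baseline_mean: float
    baseline_sd: float
    n_trials: int
    z_scores: np.ndarray | None = None
    baseline_undefined: bool = False

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def stimulus_rates(self) -> np.ndarray:
        return self.rates[self.centers >= 0]


def compute_psth(spikes: SpikeData, bin_width: float = DEFAULT_BIN_S,
                 stimulus: str | None = None) -> PSTH:
    """Trial-averaged firing rate in fixed bins, with baseline statistics
    from the pre-stimulus window and per-bin z-scores.

    Rate conservation holds exactly: sum(rate) * bin_width * n_trials
    equals the number of binned spikes.
    """
    frame = spikes.trials
    if stimulus is not None:
        frame = frame[frame["stimulus"] == stimulus]
    n_trials = spikes.n_trials_per_condition
    if n_trials < 1:
        raise InvalidSpecError("need at least one trial")
    n_conditions = max(1, frame["direction_deg"].nunique(dropna=False))
    eff_trials = n_trials * n_conditions

    start = -spikes.baseline_window
    n_bins = int(np.ceil((spikes.duration - start) / bin_width))
    edges = start + bin_width * np.arange(n_bins + 1)
    t = frame["spike_time_s"].to_numpy()
    counts, _ = np.histogram(t, bins=edges)
    rates = counts / (eff_trials * bin_width)

    centers = 0.5 * (edges[:-1] + edges[1:])
    base = rates[centers < 0]
    if base.size:
        baseline_mean = float(base.mean())
        baseline_sd = float(base.std(ddof=0))
    else:
        baseline_mean, baseline_sd = 0.0, 0.0
    undefined = baseline_sd == 0.0
    z = None if undefined else (rates - baseline_mean) / baseline_sd
    return PSTH(bin_width=bin_width, edges=edges, rates=rates,
                baseline_mean=baseline_mean, baseline_sd=baseline_sd,
                n_trials=eff_trials, z_scores=z, baseline_undefined=undefined)


def is_responding(psth: PSTH, min_rate_hz: float = 1.0) -> bool:
    """True iff the maximal stimulus-window response exceeds baseline mean
    + 2 SD ('potentially responding').  With an undefined baseline SD the
    absolute-rate criterion ``min_rate_hz`` above baseline is used."""
    stim = psth.stimulus_rates
    if stim.size == 0:
        return False
    peak = float(stim.max())
    if psth.baseline_undefined:
        return peak > psth.baseline_mean + min_rate_hz
    return peak > psth.baseline_mean + 2.0 * psth.baseline_sd


@dataclass
class TuningResult:
    responses: np.ndarray  # normalized, rectified R_k
    directions_deg: np.ndarray
    dsi: float
    osi: float
    preferred_direction_deg: float


def direction_orientation_selectivity(
    responses, directions_deg=(0, 45, 90, 135, 180, 225, 270, 315)
) -> TuningResult:
    """DSI/OSI as vector-sum magnitudes over the 8 directions.

    ``responses`` are background-subtracted per-direction peak rates;
    negatives are rectified to 0 and the vector is normalized to its
    maximum.  DSI = |sum R_k e^{i a_k}| / sum R_k; the OSI doubles the
    angles.  Both are invariant to positive scaling and to direction
    relabeling.
    """
    r = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    a = np.deg2rad(np.asarray(directions_deg, dtype=float))
    if r.shape != a.shape:
        raise InvalidSpecError("responses and directions must align")
    if r.max() <= 0:
        raise ZeroResponseError("all per-direction responses are zero")
    r = r / r.max()
    vec = np.sum(r * np.exp(1j * a))
    vec2 = np.sum(r * np.exp(2j * a))
    total = r.sum()
    preferred = float(np.rad2deg(np.angle(vec)) % 360.0)
    return TuningResult(
        responses=r,
        directions_deg=np.asarray(directions_deg, dtype=float),
        dsi=float(np.abs(vec) / total),
        osi=float(np.abs(vec2) / total),
        preferred_direction_deg=preferred,
    )


def peak_responses_by_direction(
    spikes: SpikeData,
    window_s: float = 1.0,
    bin_width: float = DEFAULT_BIN_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted peak rate in the first ``window_s`` after
    onset, per direction (the moving-bar analysis window)."""
    frame = spikes.trials
    directions = np.sort(frame["direction_deg"].dropna().unique())
    if directions.size == 0:
        raise InvalidSpecError("spike data carries no direction labels")
    peaks = np.empty(directions.size)
    edges = np.arange(0.0, spikes.duration + bin_width, bin_width)
    base_edges = np.arange(-spikes.baseline_window, 0.0 + 1e-12, bin_width)
    for i, d in enumerate(directions):
        sub = frame[frame["direction_deg"] == d]["spike_time_s"].to_numpy()
        counts, _ = np.histogram(sub, bins=edges)
        rates = counts / (spikes.n_trials_per_condition * bin_width)
        if base_edges.size > 1:
            bcounts, _ = np.histogram(sub, bins=base_edges)
            background = bcounts.mean() / (spikes.n_trials_per_condition * bin_width)
        else:
            background = 0.0
        in_window = rates[: max(1, int(round(window_s / bin_width)))]
        peaks[i] = in_window.max() - background
    return peaks, directions


def chirp_spectrum(
    spikes: SpikeData,
    sweep_window: tuple[float, float],
    bin_width: float = 0.001,
    bands_hz=DEFAULT_BANDS_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier amplitude spectrum of the 1 ms-binned sweep response.

    Returns (frequencies, amplitudes, band_means) with band means over the
    half-open intervals in ``bands_hz``.  The amplitude is |FFT| of the
    trial-averaged rate with the DC component excluded from the bands.
    """
    t0, t1 = sweep_window
    if t1 - t0 < 2.0:
        raise InsufficientWindowError("sweep segment shorter than 2 s")
    t = spikes.trials["spike_time_s"].to_numpy()
    t = t[(t >= t0) & (t < t1)]
    edges = np.arange(t0, t1 + bin_width, bin_width)
    counts, _ = np.histogram(t, bins=edges)
    rate = counts / (spikes.n_trials_per_condition * bin_width)
    amp = np.abs(np.fft.rfft(rate)) / rate.size
    freqs = np.fft.rfftfreq(rate.size, d=bin_width)
    band_means = np.array([
        amp[(freqs >= lo) & (freqs < hi) & (freqs > 0)].mean()
        if np.any((freqs >= lo) & (freqs < hi) & (freqs > 0)) else 0.0
        for lo, hi in bands_hz
    ])
    return freqs, amp, band_means


def response_halfwidth(psth: PSTH) -> float:
    """Full width at half prominence of the highest background-subtracted
    peak, in seconds (linear interpolation between bins)."""
    rates = psth.stimulus_rates - psth.baseline_mean
    if rates.size == 0 or rates.max() <= 0:
        raise NoPeakError("no positive response after background subtraction")
    padded = np.concatenate([[0.0], rates, [0.0]])  # peaks at the edges count
    peaks, _ = signal.find_peaks(padded)
    if peaks.size == 0:
        raise NoPeakError("no response peak found")
    highest = peaks[int(np.argmax(padded[peaks]))]
    widths, _, _, _ = signal.peak_widths(padded, [highest], rel_height=0.5)
    return float(widths[0] * psth.bin_width)


def calcium_kernel(dt: float, rise_s: float = OGB1_RISE_S,
                   decay_s: float = OGB1_DECAY_S) -> np.ndarray:
    """Unit-area causal double-exponential indicator kernel."""
    if rise_s <= 0 or decay_s <= 0:
        raise ConfigError("kernel time constants must be positive")
    t = np.arange(0.0, decay_s * 8.0, dt)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    area = k.sum() * dt
    if area <= 0:
        raise ConfigError("degenerate kernel (rise >= decay?)")
    return k / area


def calcium_convolve(response: np.ndarray, dt: float,
                     rise_s: float = OGB1_RISE_S,
                     decay_s: float = OGB1_DECAY_S) -> np.ndarray:
    """Causal convolution with the unit-area indicator kernel; the output
    has the input's length, so a constant input stays constant."""
    k = calcium_kernel(dt, rise_s, decay_s)
    x = np.asarray(response, dtype=float)
    # pad with the first sample so onset transients reflect history, then
    # convolve causally and trim
    padded = np.concatenate([np.full(k.size - 1, x[0]), x])
    out = np.convolve(padded, k * dt, mode="valid")
    return out


@dataclass
class ChirpTemplateSet:
    """Named chirp-response templates on a common time grid."""

    times: np.ndarray
    traces: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.traces:
            raise ConfigError("template set is empty")
        for name, tr in self.traces.items():
            if np.asarray(tr).size != self.times.size:
                raise ConfigError(f"template {name!r} not on the common grid")


@dataclass
class FunctionalAssignment:
    scores: pd.DataFrame  # index template, columns correlation/euclidean/residual
    ranks: pd.DataFrame
    final_template: str
    agreement: bool
    decision: str = ""


def assign_functional_cluster(
    response: np.ndarray,
    response_times: np.ndarray,
    templates: ChirpTemplateSet,
) -> FunctionalAssignment:
    """Assign a chirp response to a template by three-metric voting.

    Metrics: linear correlation (higher better), Euclidean distance and
    summed absolute residual (lower better).  A template ranked in the top
    two by at least two metrics wins (ties resolved by correlation);
    otherwise the best-correlation template is taken and the agreement
    flag is False.  The response is resampled to the template grid by
    linear interpolation first.
    """
    resp = np.interp(templates.times, response_times, np.asarray(response, float))
    names = list(templates.traces)
    corr = np.empty(len(names))
    eucl = np.empty(len(names))
    resid = np.empty(len(names))
    for i, name in enumerate(names):
        t = templates.traces[name]
        c = np.corrcoef(resp, t)[0, 1]
        corr[i] = 0.0 if np.isnan(c) else c
        eucl[i] = np.linalg.norm(resp - t)
        resid[i] = np.abs(resp - t).sum()
    scores = pd.DataFrame({"correlation": corr, "euclidean": eucl,
                           "residual": resid}, index=names)
    ranks = pd.DataFrame({
        "correlation": stats.rankdata(-corr, method="min"),
        "euclidean": stats.rankdata(eucl, method="min"),
        "residual": stats.rankdata(resid, method="min"),
    }, index=names)
    votes = (ranks <= 2).sum(axis=1)
    winners = votes[votes >= 2]
    if not winners.empty:
        best = winners.index[np.argmax(scores.loc[winners.index, "correlation"].to_numpy())]
        return FunctionalAssignment(scores=scores, ranks=ranks,
                                    final_template=str(best), agreement=True,
                                    decision="top-2 by >= 2 metrics")
    best = names[int(np.argmax(corr))]
    return FunctionalAssignment(scores=scores, ranks=ranks,
                                final_template=str(best), agreement=False,
                                decision="metrics disagree: best correlation")


@dataclass
class SizeMap:
    grid_x: np.ndarray
    grid_y: np.ndarray
    median_map: np.ndarray
    smoothed_map: np.ndarray
    r_nasotemporal: float
    p_nasotemporal: float
    r_eccentricity: float
    p_eccentricity: float
    params: dict = field(default_factory=dict)


def retinotopic_size_map(
    positions_um: np.ndarray,
    diameters_um: np.ndarray,
    window_radius_um: float = 250.0,
    step_um: float = 100.0,
    sigma_um: float = 200.0,
    grid_shape: tuple[int, int] = (50, 50),
) -> SizeMap:
    """Moving-median dendritic-size map over the retina plus axis trends.

    A circular window of ``window_radius_um`` slides with ``step_um`` over
    a ``grid_shape`` grid centred on the data; each node takes the median
    diameter of the cells inside the window.  The median matrix is then
    smoothed with a missing-data-aware Gaussian (sigma in µm): data and
    mask are filtered separately and the ratio taken, so empty nodes do
    not dilute the map.  Pearson correlations of diameter against the
    naso-temporal coordinate (x) and against eccentricity (distance from
    the optic nerve head at the origin) are computed from the raw cells.
    """
    pos = np.asarray(positions_um, dtype=float)
    diam = np.asarray(diameters_um, dtype=float)
    if pos.shape[0] != diam.size or pos.shape[0] < 10:
        raise InvalidSpecError("need >= 10 positioned cells")
    if np.allclose(pos.std(axis=0), 0):
        raise DegenerateGridError()

    nx, ny = grid_shape
    cx = 0.5 * (pos[:, 0].min() + pos[:, 0].max())
    cy = 0.5 * (pos[:, 1].min() + pos[:, 1].max())
    gx = cx + step_um * (np.arange(nx) - (nx - 1) / 2)
    gy = cy + step_um * (np.arange(ny) - (ny - 1) / 2)
    median_map = np.full((nx, ny), np.nan)
    from scipy.spatial import cKDTree

    tree = cKDTree(pos[:, :2])
    for i, xv in enumerate(gx):
        for j, yv in enumerate(gy):
            members = tree.query_ball_point([xv, yv], window_radius_um)
            if members:
                median_map[i, j] = np.median(diam[members])

    sigma_px = sigma_um / step_um
    mask = np.isfinite(median_map).astype(float)
    filled = np.where(mask > 0, median_map, 0.0)
    from scipy.ndimage import gaussian_filter

    num = gaussian_filter(filled, sigma_px)
    den = gaussian_filter(mask, sigma_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(den > 1e-12, num / den, np.nan)

    ecc = np.hypot(pos[:, 0], pos[:, 1])
    if np.ptp(diam) == 0:  # constant field: no gradient, r defined as 0
        r_nt, p_nt = 0.0, 1.0
        r_ecc, p_ecc = 0.0, 1.0
    else:
        r_nt, p_nt = stats.pearsonr(pos[:, 0], diam)
        r_ecc, p_ecc = stats.pearsonr(ecc, diam)
    return SizeMap(
        grid_x=gx, grid_y=gy, median_map=median_map, smoothed_map=smoothed,
        r_nasotemporal=float(r_nt), p_nasotemporal=float(p_nt),
        r_eccentricity=float(r_ecc), p_eccentricity=float(p_ecc),
        params={"window_radius_um": window_radius_um, "step_um": step_um,
                "sigma_um": sigma_um},
    )


class DegenerateGridError(InvalidSpecError):
    """All cells colocated: no retinotopic gradient can be estimated."""

    def __init__(self) -> None:
        super().__init__("all cells are colocated; size map is degenerate")
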