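"""Shared domain types and errors.

All spatial coordinates are micrometres in the retina frame (x, y lateral,
z along the optical/scleral axis, increasing toward the vitreous).  Depth is
the unitless ChAT-band-anchored coordinate used throughout the package:
0 on the OFF ChAT band, 1 on the ON ChAT band, negative values sclerad of
the OFF band ("above"), values > 1 vitread of the ON band ("below", toward
the ganglion cell layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Fixed stratification grid shared by every profile and template in a run.
DEPTH_MIN = -1.0
DEPTH_MAX = 2.0
DEFAULT_N_BINS = 120
DEFAULT_LOWPASS_CUTOFF = 10  # cycles over the [-1, 2] depth domain

MARKERS = ("SMI32", "CART", "FOXP2")
CIRCUITS = ("Pbg", "LP")


class RgcSampleError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(RgcSampleError):
    """A synthetic-data specification violates its invariants."""


class ExtentError(RgcSampleError):
    """Points fall outside the lateral support of a fitted surface."""


class DegenerateGeometryError(RgcSampleError):
    """Input geometry is rank-deficient (e.g. collinear points)."""


class BandCollisionError(RgcSampleError):
    """ON and OFF surfaces coincide locally; depth is undefined."""


class SuspiciousWarpError(RgcSampleError):
    """Too many warped points fall outside the plausible depth range."""


class UnclassifiableProfileError(RgcSampleError):
    """A stratification profile is too flat to carry group information."""


class CalibrationError(RgcSampleError):
    """Not enough molecularly identified cells to calibrate thresholds."""


class GridMismatchError(RgcSampleError):
    """Profile and template library use different depth grids."""


class ConfigError(RgcSampleError):
    """Invalid configuration value (unknown label, bad kernel, ...)."""


class UndefinedSelectivityError(RgcSampleError):
    """Selectivity index requested for a cluster absent from both circuits."""


class ZeroResponseError(RgcSampleError):
    """All per-direction responses are zero; tuning is undefined."""


class InsufficientWindowError(RgcSampleError):
    """Analysis window too short for the requested spectral estimate."""


class NoPeakError(RgcSampleError):
    """No positive response peak after background subtraction."""


@dataclass
class ArborPointCloud:
    """A binarized / traced dendritic arbor as a 3D point set (µm).

    ``points`` has shape (n, 3).  ``soma`` is the soma position in the same
    frame, or None when unknown.  ``markers`` is the set of molecular
    markers the cell stained positive for.  ``retina_position`` is the
    (naso-temporal, dorso-ventral) position of the soma relative to the
    optic nerve head, in µm.
    """

    points: np.ndarray
    soma: np.ndarray | None = None
    voxel_size_um: tuple[float, float, float] | None = None
    markers: frozenset[str] = frozenset()
    retina_position: tuple[float, float] | None = None
    circuit: str = "unknown"
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidSpecError("arbor points must have shape (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise InvalidSpecError("arbor points must be finite")
        unknown = set(self.markers) - set(MARKERS)
        if unknown:
            raise InvalidSpecError(f"unknown markers: {sorted(unknown)}")
        if self.soma is not None:
            self.soma = np.asarray(self.soma, dtype=float).reshape(3)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class WarpedArbor:
    """An arbor mapped into the band-anchored frame: columns (x, y, depth)."""

    points: np.ndarray
    soma_index: int | None = None
    surface_provenance: dict = field(default_factory=dict)
    source: ArborPointCloud | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidSpecError("warped points must have shape (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise InvalidSpecError("warped depths must be finite")

    @property
    def depths(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass
class StratificationProfile:
    """Normalized dendritic density over the fixed depth grid.

    ``density`` sums to 1 over ``n_bins`` bins spanning [-1, 2].  The grid
    is shared library-wide so profiles and templates are comparable.
    """

    density: np.ndarray
    n_bins: int = DEFAULT_N_BINS
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.n_bins,):
            raise GridMismatchError(
                f"profile has {self.density.shape[0]} bins, expected {self.n_bins}"
            )
        if np.any(self.density < -1e-12):
            raise InvalidSpecError("profile density must be non-negative")
        total = float(self.density.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise InvalidSpecError(f"profile density sums to {total}, expected 1")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(DEPTH_MIN, DEPTH_MAX, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def bin_width(self) -> float:
        return (DEPTH_MAX - DEPTH_MIN) / self.n_bins

    def center_of_mass(self) -> float:
        return float(np.sum(self.bin_centers * self.density))

    def mass(self, lo: float, hi: float) -> float:
        """Fraction of dendritic density with depth in [lo, hi)."""
        c = self.bin_centers
        return float(self.density[(c >= lo) & (c < hi)].sum())


@dataclass
class DendriticStats:
    """Five summary statistics of the balanced-tree model of an arbor."""

    mean_path_euclid_ratio: float
    max_path_length_um: float
    mean_branch_length_um: float
    mean_path_length_um: float
    z_range_over_width: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.mean_path_euclid_ratio,
                self.max_path_length_um,
                self.mean_branch_length_um,
                self.mean_path_length_um,
                self.z_range_over_width,
            ]
        )


def profile_grid_centers(n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    edges = np.linspace(DEPTH_MIN, DEPTH_MAX, n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def rng_stream(seed: int, offset: int) -> np.random.Generator:
    """Derive an independent generator from (seed, offset).

    Every source of randomness in the package flows from one explicit seed;
    sub-streams are spawned with fixed integer offsets so that identical
    seeds give bit-identical outputs.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(offset),)))
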