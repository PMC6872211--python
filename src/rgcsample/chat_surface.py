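"""ChAT-band surface fitting and arbor warping.

The two ChAT bands (the dendritic plexi of ON and OFF starburst amacrine
cells) are the universal depth landmarks of the inner plexiform layer.
Each band is fitted from sparse manual point annotations with a
smoothness-regularized least-squares surface: grid node heights z minimize

    sum_i (z_i - s(x_i, y_i))^2 + lambda * B(s)

where s interpolates the grid bilinearly and B is the discretized
thin-plate bending energy (integral of s_xx^2 + 2 s_xy^2 + s_yy^2).
A plane has zero bending energy, so coplanar annotations are reproduced
exactly for any lambda; as lambda grows the fit tends to the least-squares
plane of the annotations.

Warping maps arbor z into the band-anchored depth

    depth(x, y, z) = (z - z_OFF(x, y)) / (z_ON(x, y) - z_OFF(x, y))

so points on the OFF band get depth 0, points on the ON band depth 1,
"above" (sclerad) is negative and "below" (vitread) is > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .core import (
    ArborPointCloud,
    BandCollisionError,
    DegenerateGeometryError,
    ExtentError,
    InvalidSpecError,
    WarpedArbor,
)

#: Points at most this far (µm) outside the annotated support are warped by
#: linear extrapolation with a warning instead of being rejected; real
#: annotations are sparse at the edges of a scan.
EDGE_TOLERANCE_UM = 5.0


@dataclass
class ChATAnnotation:
    """Manually labeled ChAT-band points, one set per band, (n, 3) µm."""

    on_points: np.ndarray
    off_points: np.ndarray

    def __post_init__(self) -> None:
        self.on_points = np.atleast_2d(np.asarray(self.on_points, dtype=float))
        self.off_points = np.atleast_2d(np.asarray(self.off_points, dtype=float))
        for name, pts in (("ON", self.on_points), ("OFF", self.off_points)):
            if pts.shape[0] < 9 or pts.shape[1] != 3:
                raise InvalidSpecError(
                    f"{name} band needs >= 9 points of shape (n, 3), got {pts.shape}"
                )


@dataclass
class BandSurface:
    """A fitted band surface: z values on a regular lateral grid."""

    x_grid: np.ndarray
    y_grid: np.ndarray
    z_values: np.ndarray  # shape (len(x_grid), len(y_grid))
    smoothness: float
    grid_spacing_um: float
    rms_residual_um: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.z_values)):
            raise DegenerateGeometryError("fitted surface contains non-finite z")

    @property
    def support(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the fitted grid."""
        return (
            float(self.x_grid[0]),
            float(self.x_grid[-1]),
            float(self.y_grid[0]),
            float(self.y_grid[-1]),
        )

    def __call__(self, x, y, *, edge_tolerance_um: float = EDGE_TOLERANCE_UM) -> np.ndarray:
        """Evaluate the surface by bilinear interpolation.

        Points up to ``edge_tolerance_um`` outside the grid are evaluated by
        linear extrapolation (with a warning); anything further raises
        :class:`ExtentError`.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, xmax, ymin, ymax = self.support
        over = (
            (x < xmin - edge_tolerance_um)
            | (x > xmax + edge_tolerance_um)
            | (y < ymin - edge_tolerance_um)
            | (y > ymax + edge_tolerance_um)
        )
        if np.any(over):
            idx = np.flatnonzero(np.atleast_1d(over))
            raise ExtentError(
                f"{idx.size} point(s) outside surface support "
                f"(first offenders: {idx[:5].tolist()})"
            )
        outside = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)
        if np.any(outside):
            warnings.warn(
                f"{int(np.count_nonzero(outside))} point(s) marginally outside "
                "annotation support; using surface extrapolation",
                stacklevel=2,
            )
        return _bilinear(self.x_grid, self.y_grid, self.z_values, x, y)


def _bilinear(xg: np.ndarray, yg: np.ndarray, z: np.ndarray, x, y) -> np.ndarray:
    """Bilinear interpolation with linear extrapolation outside the grid."""
    ix = np.clip(np.searchsorted(xg, x, side="right") - 1, 0, len(xg) - 2)
    iy = np.clip(np.searchsorted(yg, y, side="right") - 1, 0, len(yg) - 2)
    tx = (x - xg[ix]) / (xg[ix + 1] - xg[ix])
    ty = (y - yg[iy]) / (yg[iy + 1] - yg[iy])
    z00 = z[ix, iy]
    z10 = z[ix + 1, iy]
    z01 = z[ix, iy + 1]
    z11 = z[ix + 1, iy + 1]
    return (
        z00 * (1 - tx) * (1 - ty)
        + z10 * tx * (1 - ty)
        + z01 * (1 - tx) * ty
        + z11 * tx * ty
    )


def _interp_matrix(xg: np.ndarray, yg: np.ndarray, x: np.ndarray, y: np.ndarray) -> sparse.csr_matrix:
    """Sparse matrix A with A @ z_flat = bilinear surface value at (x, y)."""
    nx, ny = len(xg), len(yg)
    ix = np.clip(np.searchsorted(xg, x, side="right") - 1, 0, nx - 2)
    iy = np.clip(np.searchsorted(yg, y, side="right") - 1, 0, ny - 2)
    tx = (x - xg[ix]) / (xg[ix + 1] - xg[ix])
    ty = (y - yg[iy]) / (yg[iy + 1] - yg[iy])
    rows = np.repeat(np.arange(len(x)), 4)
    cols = np.concatenate(
        [
            ix * ny + iy,
            (ix + 1) * ny + iy,
            ix * ny + iy + 1,
            (ix + 1) * ny + iy + 1,
        ]
    ).reshape(4, -1).T.ravel()
    vals = np.stack(
        [(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty]
    ).T.ravel()
    return sparse.csr_matrix((vals, (rows, cols)), shape=(len(x), nx * ny))


def _bending_penalty(nx: int, ny: int, h: float) -> sparse.csr_matrix:
    """Discrete thin-plate bending penalty P with z^T P z ~ B(s).

    Second differences approximate h^2 * (curvature); summing their squares
    and multiplying by h^2 / h^4 = 1/h^2 yields the energy integral.
    """

    def second_diff(n: int) -> sparse.csr_matrix:
        if n < 3:
            return sparse.csr_matrix((0, n))
        d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
        return d.tocsr()

    def first_diff(n: int) -> sparse.csr_matrix:
        d = sparse.diags([-1.0, 1.0], [0, 1], shape=(n - 1, n))
        return d.tocsr()

    ix = sparse.identity(nx, format="csr")
    iy = sparse.identity(ny, format="csr")
    dxx = sparse.kron(second_diff(nx), iy)
    dyy = sparse.kron(ix, second_diff(ny))
    dxy = sparse.kron(first_diff(nx), first_diff(ny))
    scale = 1.0 / h**2
    return scale * (dxx.T @ dxx + dyy.T @ dyy + 2.0 * (dxy.T @ dxy))


def fit_band_surface(
    points: np.ndarray,
    smoothness: float = 1.0,
    grid_spacing_um: float = 10.0,
    pad_um: float = 0.0,
) -> BandSurface:
    """Fit one band surface to annotated (x, y, z) points.

    Parameters
    ----------
    points : (n, 3) array
        Band annotations in µm; n >= 9.
    smoothness : float
        Bending-energy weight lambda >= 0 (µm²-scaled).  A tiny floor is
        applied so the linear system stays well posed where annotations are
        sparse.
    grid_spacing_um : float
        Lateral node spacing of the fitted grid.
    pad_um : float
        Extra margin added around the annotation bounding box.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 9 or pts.shape[1] != 3:
        raise InvalidSpecError("need >= 9 (x, y, z) points to fit a band surface")
    if smoothness < 0:
        raise InvalidSpecError("smoothness weight must be >= 0")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    xy = np.column_stack([x - x.mean(), y - y.mean()])
    if np.linalg.matrix_rank(xy, tol=1e-8 * max(1.0, np.abs(xy).max())) < 2:
        raise DegenerateGeometryError("annotation points are collinear in (x, y)")

    xg = _grid_axis(x.min() - pad_um, x.max() + pad_um, grid_spacing_um)
    yg = _grid_axis(y.min() - pad_um, y.max() + pad_um, grid_spacing_um)
    nx, ny = len(xg), len(yg)

    a = _interp_matrix(xg, yg, x, y)
    penalty = _bending_penalty(nx, ny, grid_spacing_um)
    lam = max(smoothness, 1e-9)  # floor keeps unsupported nodes determined
    lhs = (a.T @ a + lam * penalty).tocsc()
    rhs = a.T @ z
    z_flat = spsolve(lhs, rhs)
    z_grid = z_flat.reshape(nx, ny)

    fitted = a @ z_flat
    residuals = z - fitted
    rms = float(np.sqrt(np.mean(residuals**2)))
    return BandSurface(
        x_grid=xg,
        y_grid=yg,
        z_values=z_grid,
        smoothness=smoothness,
        grid_spacing_um=grid_spacing_um,
        rms_residual_um=rms,
        diagnostics={
            "n_points": int(pts.shape[0]),
            "max_abs_residual_um": float(np.max(np.abs(residuals))),
        },
    )


def _grid_axis(lo: float, hi: float, spacing: float) -> np.ndarray:
    if spacing <= 0:
        raise InvalidSpecError("grid spacing must be positive")
    n = max(2, int(np.ceil((hi - lo) / spacing)) + 1)
    return np.linspace(lo, hi, n)


def warp_points(
    arbor: ArborPointCloud,
    on: BandSurface,
    off: BandSurface,
    *,
    min_band_gap_um: float = 1e-6,
) -> WarpedArbor:
    """Warp an arbor into the band-anchored depth frame.

    depth = (z - z_OFF) / (z_ON - z_OFF), evaluated with each fitted band
    surface at the point's lateral position.  Adding a constant to every z
    (annotation and arbor alike) leaves depths unchanged, and for fixed
    (x, y) depth is strictly increasing in z.
    """
    x, y, z = arbor.points[:, 0], arbor.points[:, 1], arbor.points[:, 2]
    z_on = np.asarray(on(x, y))
    z_off = np.asarray(off(x, y))
    gap = z_on - z_off
    if np.any(np.abs(gap) < min_band_gap_um):
        raise BandCollisionError("ON and OFF surfaces coincide at some arbor positions")
    depth = (z - z_off) / gap
    warped = np.column_stack([x, y, depth])

    soma_index = None
    if arbor.soma is not None:
        # the soma is carried along as a tagged point appended at the end
        sx, sy, sz = arbor.soma
        s_on = float(np.asarray(on(np.array([sx]), np.array([sy])))[0])
        s_off = float(np.asarray(off(np.array([sx]), np.array([sy])))[0])
        if abs(s_on - s_off) < min_band_gap_um:
            raise BandCollisionError("bands coincide at the soma position")
        s_depth = (sz - s_off) / (s_on - s_off)
        warped = np.vstack([warped, [sx, sy, s_depth]])
        soma_index = warped.shape[0] - 1

    return WarpedArbor(
        points=warped,
        soma_index=soma_index,
        surface_provenance={
            "on": {"lambda": on.smoothness, "spacing_um": on.grid_spacing_um,
                   "rms_residual_um": on.rms_residual_um},
            "off": {"lambda": off.smoothness, "spacing_um": off.grid_spacing_um,
                    "rms_residual_um": off.rms_residual_um},
        },
        source=arbor,
    )


def fit_annotation(
    annotation: ChATAnnotation,
    smoothness: float = 1.0,
    grid_spacing_um: float = 10.0,
) -> tuple[BandSurface, BandSurface]:
    """Fit both band surfaces independently; returns (on, off)."""
    on = fit_band_surface(annotation.on_points, smoothness, grid_spacing_um)
    off = fit_band_surface(annotation.off_points, smoothness, grid_spacing_um)
    return on, off
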