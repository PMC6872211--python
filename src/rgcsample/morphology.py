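"""Per-cell morphological features.

Soma detection, band-anchored stratification profiles, dendritic-field
area/diameter from the en-face convex hull, tree statistics on a greedy
balanced minimum-spanning-tree model of the arbor, and en-face
down-sampling for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import (
    ArborPointCloud,
    DEFAULT_LOWPASS_CUTOFF,
    DEFAULT_N_BINS,
    DEPTH_MAX,
    DEPTH_MIN,
    DegenerateGeometryError,
    DendriticStats,
    InvalidSpecError,
    StratificationProfile,
    SuspiciousWarpError,
    WarpedArbor,
)


# ---------------------------------------------------------------------------
# soma detection


@dataclass
class SomaDetection:
    position: np.ndarray  # (3,) µm
    arbor: ArborPointCloud  # soma-free arbor
    failed: bool
    peak_to_median: float


def detect_soma(
    arbor: ArborPointCloud,
    kernel_radius_um: float = 10.0,
    *,
    grid_step_um: float = 2.0,
    response_ratio_threshold: float = 2.0,
) -> SomaDetection:
    """Locate the soma as the peak of a disc matched filter on the en-face
    point density, and strip soma points from the arbor.

    If the arbor already carries a tagged soma it is returned unchanged (the
    manual-annotation path).  Detection is flagged as failed when the peak
    filter response is below ``response_ratio_threshold`` times the median
    response over occupied positions, in which case the caller should supply
    the soma manually.
    """
    if arbor.n_points == 0:
        raise InvalidSpecError("cannot detect a soma in an empty arbor")
    if arbor.soma is not None:
        return SomaDetection(
            position=arbor.soma.copy(), arbor=arbor, failed=False,
            peak_to_median=float("inf"),
        )

    pts = arbor.points
    x, y = pts[:, 0], pts[:, 1]
    xg = np.arange(x.min(), x.max() + grid_step_um, grid_step_um)
    yg = np.arange(y.min(), y.max() + grid_step_um, grid_step_um)
    # disc matched filter = for every grid position, number of points within
    # kernel_radius; evaluated directly from the point set (no voxelization)
    from scipy.spatial import cKDTree

    tree = cKDTree(pts[:, :2])
    gx, gy = np.meshgrid(xg, yg, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    response = np.asarray(tree.query_ball_point(centers, kernel_radius_um, return_length=True), dtype=float)
    occupied = response > 0
    med = float(np.median(response[occupied])) if np.any(occupied) else 0.0
    peak = float(response.max())
    ratio = peak / med if med > 0 else float("inf")
    failed = med <= 0 or ratio < response_ratio_threshold

    best = centers[int(np.argmax(response))]
    members = tree.query_ball_point(best, kernel_radius_um)
    if members:
        position = pts[members].mean(axis=0)  # density-weighted centroid
    else:  # pragma: no cover - peak always has members when arbor nonempty
        position = np.array([best[0], best[1], float(pts[:, 2].mean())])

    if failed:
        return SomaDetection(position=position, arbor=arbor, failed=True,
                             peak_to_median=ratio)

    keep = np.hypot(pts[:, 0] - position[0], pts[:, 1] - position[1]) > kernel_radius_um
    stripped = ArborPointCloud(
        points=pts[keep],
        soma=position,
        voxel_size_um=arbor.voxel_size_um,
        markers=arbor.markers,
        retina_position=arbor.retina_position,
        circuit=arbor.circuit,
        cell_id=arbor.cell_id,
    )
    return SomaDetection(position=position, arbor=stripped, failed=False,
                         peak_to_median=ratio)


# ---------------------------------------------------------------------------
# stratification profile


def compute_stratification_profile(
    arbor: WarpedArbor,
    n_bins: int = DEFAULT_N_BINS,
    cutoff: int = DEFAULT_LOWPASS_CUTOFF,
    *,
    max_outside_fraction: float = 0.2,
) -> StratificationProfile:
    """Histogram of band-anchored depths, low-pass smoothed and normalized.

    Depths are binned on the fixed [-1, 2] grid; the histogram is smoothed
    by zeroing Fourier components above ``cutoff`` cycles over the domain
    (periodic extension), tiny negative ringing is clipped, and the result
    is renormalized to sum 1.  Depths outside [-1, 2] are clipped into the
    range and counted; more than ``max_outside_fraction`` of them indicates
    a bad warp and raises :class:`SuspiciousWarpError`.
    """
    if n_bins < 40:
        raise InvalidSpecError("need at least 40 profile bins")
    depths = arbor.depths
    if arbor.soma_index is not None:
        depths = np.delete(depths, arbor.soma_index)
    if depths.size == 0:
        raise InvalidSpecError("no dendritic points to profile")
    outside = (depths < DEPTH_MIN) | (depths > DEPTH_MAX)
    n_outside = int(np.count_nonzero(outside))
    if n_outside > max_outside_fraction * depths.size:
        raise SuspiciousWarpError(
            f"{n_outside}/{depths.size} depths outside [{DEPTH_MIN}, {DEPTH_MAX}]"
        )
    clipped = np.clip(depths, DEPTH_MIN, DEPTH_MAX - 1e-12)
    edges = np.linspace(DEPTH_MIN, DEPTH_MAX, n_bins + 1)
    hist, _ = np.histogram(clipped, bins=edges)
    smoothed = lowpass_filter(hist.astype(float), cutoff)
    smoothed = np.clip(smoothed, 0.0, None)
    total = smoothed.sum()
    if total <= 0:
        raise InvalidSpecError("profile vanished after smoothing")
    return StratificationProfile(density=smoothed / total, n_bins=n_bins,
                                 n_clipped=n_outside)


def lowpass_filter(values: np.ndarray, cutoff: int) -> np.ndarray:
    """Interpolating low-pass filter via the FFT.

    Harmonics up to ``cutoff`` pass unchanged; a raised-cosine roll-off
    over the next ``cutoff``/2 harmonics suppresses the ringing a
    brick-wall filter would produce on narrow peaks.
    """
    spec = np.fft.rfft(values)
    k = np.arange(spec.size)
    taper = max(1, int(cutoff) // 2)
    gain = np.ones(spec.size)
    roll = (k > cutoff) & (k <= cutoff + taper)
    gain[roll] = 0.5 * (1.0 + np.cos(np.pi * (k[roll] - cutoff) / taper))
    gain[k > cutoff + taper] = 0.0
    return np.fft.irfft(spec * gain, n=values.size)


# ---------------------------------------------------------------------------
# dendritic field area / diameter


def dendritic_field_metrics(arbor: ArborPointCloud | np.ndarray) -> tuple[float, float]:
    """En-face convex-hull area (µm²) and equivalent diameter (µm).

    D = 2 * sqrt(area / pi): the diameter of the disc with the hull's area.
    Invariant to z and to rigid rotations in the en-face plane.
    """
    pts = arbor.points if isinstance(arbor, ArborPointCloud) else np.asarray(arbor, float)
    xy = pts[:, :2]
    if xy.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 en-face points for a hull")
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise DegenerateGeometryError("en-face points are collinear") from exc
    area = float(hull.volume)  # 2-D hull: 'volume' is the area
    diameter = 2.0 * float(np.sqrt(area / np.pi))
    return area, diameter


# ---------------------------------------------------------------------------
# balanced minimum spanning tree statistics


def _build_balanced_tree(points: np.ndarray, root_index: int, bf: float) -> np.ndarray:
    """Greedy balanced-tree construction.

    Starting from the root, repeatedly attach the unconnected point with the
    smallest cost  d(p, v) + bf * (rootpath(v) + d(p, v))  over tree vertices
    v, i.e. Euclidean wiring cost plus ``bf`` times the resulting root-path
    length.  ``bf`` = 0 reduces to Prim's minimum spanning tree.  Ties are
    broken by the lowest point index.  Returns the parent array.
    """
    n = points.shape[0]
    parent = np.full(n, -1, dtype=int)
    rootpath = np.zeros(n)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[root_index] = True

    # best attachment for every unconnected point, updated incrementally
    d0 = np.linalg.norm(points - points[root_index], axis=1)
    best_cost = d0 + bf * (rootpath[root_index] + d0)
    best_parent = np.full(n, root_index, dtype=int)
    best_cost[root_index] = np.inf

    for _ in range(n - 1):
        cand = np.where(~in_tree, best_cost, np.inf)
        j = int(np.argmin(cand))  # argmin takes the lowest index on ties
        p = best_parent[j]
        parent[j] = p
        rootpath[j] = rootpath[p] + np.linalg.norm(points[j] - points[p])
        in_tree[j] = True
        best_cost[j] = np.inf
        d = np.linalg.norm(points - points[j], axis=1)
        cost = d + bf * (rootpath[j] + d)
        better = (~in_tree) & (cost < best_cost)
        best_parent[better] = j
        best_cost[better] = cost[better]
    return parent


def mst_statistics(
    arbor: ArborPointCloud,
    bf: float = 0.4,
    *,
    max_points: int | None = 1500,
    seed: int = 0,
) -> DendriticStats:
    """Five tree statistics of the balanced-MST model of the arbor.

    The tree is grown greedily from the soma with balancing factor ``bf``
    (default 0.4) trading wiring cost against conduction (root-path) length.
    Statistics: mean path/Euclidean ratio over points, maximum metric path
    length, mean branch length (branch = maximal unbranched path between
    topological nodes), mean path length, and z-range over spanning-field
    width.  Coincident points are deduplicated with a warning.  Very dense
    clouds are subsampled to ``max_points`` for tractability.
    """
    if arbor.soma is None:
        raise InvalidSpecError("tree construction needs a soma position (root)")
    pts = np.vstack([arbor.soma.reshape(1, 3), arbor.points])
    uniq, index = np.unique(np.round(pts, 9), axis=0, return_index=True)
    if uniq.shape[0] < pts.shape[0]:
        warnings.warn(
            f"deduplicated {pts.shape[0] - uniq.shape[0]} coincident point(s)",
            stacklevel=2,
        )
        keep = np.zeros(pts.shape[0], dtype=bool)
        keep[index] = True
        keep[0] = True
        pts = pts[keep]
    if max_points is not None and pts.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(np.arange(1, pts.shape[0]), size=max_points - 1, replace=False)
        pts = np.vstack([pts[0:1], pts[np.sort(chosen)]])
    root = 0
    parent = _build_balanced_tree(pts, root, bf)

    n = pts.shape[0]
    edge_len = np.zeros(n)
    for j in range(n):
        if parent[j] >= 0:
            edge_len[j] = np.linalg.norm(pts[j] - pts[parent[j]])
    # root-path (metric) length per point
    order = _topological_order(parent, root)
    rootpath = np.zeros(n)
    for j in order:
        if parent[j] >= 0:
            rootpath[j] = rootpath[parent[j]] + edge_len[j]
    euclid = np.linalg.norm(pts - pts[root], axis=1)
    nz = euclid > 1e-12
    ratio = float(np.mean(rootpath[nz] / euclid[nz])) if np.any(nz) else 1.0

    branch_lengths = _branch_lengths(parent, edge_len, root)
    mean_branch = float(np.mean(branch_lengths)) if branch_lengths else 0.0

    xy = pts[:, :2]
    d = xy - xy.mean(axis=0)
    width = 2.0 * float(np.max(np.linalg.norm(d, axis=1)))
    if width <= 0:
        raise DegenerateGeometryError("arbor has no lateral extent")
    z_range = float(pts[:, 2].max() - pts[:, 2].min())

    return DendriticStats(
        mean_path_euclid_ratio=max(ratio, 1.0),
        max_path_length_um=float(rootpath.max()),
        mean_branch_length_um=mean_branch,
        mean_path_length_um=float(np.mean(rootpath[1:])) if n > 1 else 0.0,
        z_range_over_width=z_range / width,
    )


def _topological_order(parent: np.ndarray, root: int) -> list[int]:
    children: dict[int, list[int]] = {}
    for j, p in enumerate(parent):
        if p >= 0:
            children.setdefault(p, []).append(j)
    order: list[int] = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(children.get(v, ()))
    return order


def _branch_lengths(parent: np.ndarray, edge_len: np.ndarray, root: int) -> list[float]:
    """Lengths of maximal unbranched paths between topological nodes
    (root, branch points, tips)."""
    n = parent.size
    n_children = np.zeros(n, dtype=int)
    for j in range(n):
        if parent[j] >= 0:
            n_children[parent[j]] += 1
    is_node = (n_children != 1)
    is_node[root] = True
    lengths: list[float] = []
    for j in range(n):
        if not is_node[j] or j == root:
            continue
        # walk up from each non-root topological node to the previous node
        total = edge_len[j]
        p = parent[j]
        while p != root and not is_node[p]:
            total += edge_len[p]
            p = parent[p]
        lengths.append(float(total))
    return lengths


def total_tree_length(arbor: ArborPointCloud, bf: float = 0.4) -> float:
    """Total edge length of the balanced tree (Prim MST when bf = 0)."""
    if arbor.soma is None:
        raise InvalidSpecError("tree construction needs a soma position (root)")
    pts = np.vstack([arbor.soma.reshape(1, 3), arbor.points])
    parent = _build_balanced_tree(pts, 0, bf)
    total = 0.0
    for j in range(1, pts.shape[0]):
        total += float(np.linalg.norm(pts[j] - pts[parent[j]]))
    return total


# ---------------------------------------------------------------------------
# en-face down-sampling


def enface_downsample(
    arbor: ArborPointCloud,
    patch_px: int = 50,
    stride_px: int = 10,
) -> np.ndarray:
    """Sliding-window local median of en-face positions, for plotting.

    Windows of ``patch_px`` x ``patch_px`` pixels slide with ``stride_px``;
    each non-empty window contributes the coordinate-wise median (x, y) of
    its points, and duplicate outputs are removed.  Pixel sizes come from
    the arbor's voxel size.
    """
    if arbor.voxel_size_um is None:
        raise InvalidSpecError("en-face down-sampling needs a voxel size (µm/px)")
    if patch_px <= 0 or stride_px <= 0:
        raise InvalidSpecError("patch and stride must be positive")
    px, py = arbor.voxel_size_um[0], arbor.voxel_size_um[1]
    pts = arbor.points
    if pts.shape[0] == 0:
        return np.empty((0, 2))
    xpix = pts[:, 0] / px
    ypix = pts[:, 1] / py
    x0, y0 = xpix.min(), ypix.min()
    outputs: list[tuple[float, float]] = []
    x_starts = np.arange(x0 - patch_px + stride_px, xpix.max() + 1e-9, stride_px)
    y_starts = np.arange(y0 - patch_px + stride_px, ypix.max() + 1e-9, stride_px)
    for xs in x_starts:
        in_x = (xpix >= xs) & (xpix < xs + patch_px)
        if not np.any(in_x):
            continue
        for ys in y_starts:
            mask = in_x & (ypix >= ys) & (ypix < ys + patch_px)
            if not np.any(mask):
                continue
            outputs.append((
                float(np.median(pts[mask, 0])),
                float(np.median(pts[mask, 1])),
            ))
    if not outputs:
        return np.empty((0, 2))
    return np.unique(np.asarray(outputs), axis=0)
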