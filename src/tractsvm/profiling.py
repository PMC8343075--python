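"""AFQ-style tract profiling: bundle cleaning and 100-node quantification.

A streamline bundle is a set of 3-D polylines ("fibers") with one scalar
(a diffusion property) attached to every point. Profiling proceeds in the
classic automated-fiber-quantification order:

1. every fiber is resampled to ``n_nodes`` points equidistant in arc length
   (scalars interpolated with a cubic spline along arc length);
2. the bundle *core trajectory* is the pointwise mean of the resampled
   fibers, with a per-node positional covariance;
3. outlier fibers are removed — fibers longer than mean + 4 SD of fiber
   length, and fibers whose mean Mahalanobis distance from the core exceeds
   5 (i.e. they sit more than five standard deviations from the core);
4. the tract profile value at each node is a Gaussian-weighted mean of the
   fiber values at that node, with weights decaying in Mahalanobis distance
   from the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .cohort import TractProfile

__all__ = [
    "StreamlineBundle",
    "CoreTrajectory",
    "resample_fiber",
    "core_trajectory",
    "clean_bundle",
    "profile_bundle",
    "fiber_length",
]


@dataclass
class StreamlineBundle:
    """Set of fibers (polylines) with aligned per-point scalar values."""

    fibers: list[np.ndarray]  # each (m_i, 3)
    values: list[np.ndarray]  # each (m_i,)
    tract_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fibers, values = [], []
        if len(self.fibers) != len(self.values):
            raise ValueError("fibers and values must align 1:1")
        for pts, vals in zip(self.fibers, self.values):
            pts = np.asarray(pts, dtype=float)
            vals = np.asarray(vals, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
                raise ValueError("each fiber needs >= 2 three-dimensional points")
            if vals.shape != (pts.shape[0],):
                raise ValueError("per-point values must align with fiber points")
            fibers.append(pts)
            values.append(vals)
        self.fibers, self.values = fibers, values

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)


@dataclass
class CoreTrajectory:
    """Pointwise mean path of a bundle with per-node positional covariance."""

    node_positions: np.ndarray  # (n_nodes, 3)
    node_spread: np.ndarray  # (n_nodes, 3, 3), positive semi-definite


def fiber_length(points: np.ndarray) -> float:
    """Total arc length of a polyline."""
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _arc_positions(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_fiber(
    fiber: np.ndarray, n_nodes: int, values: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Resample a fiber to ``n_nodes`` points equidistant in arc length.

    Geometry is interpolated linearly along the polyline; scalar values are
    interpolated with a cubic spline in arc length (linearly when fewer than
    four distinct points are available, where a cubic is not determined).

    Returns ``(points, values)``; ``values`` is None when none were given.
    """
    fiber = np.asarray(fiber, dtype=float)
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    s = _arc_positions(fiber)
    if s[-1] <= 0:
        raise ValueError("zero-length fiber cannot be resampled")
    # collapse duplicate consecutive points so arc positions strictly increase
    keep = np.concatenate([[True], np.diff(s) > 0])
    s_u = s[keep]
    pts_u = fiber[keep]
    target = np.linspace(0.0, s[-1], n_nodes)
    new_pts = np.column_stack([np.interp(target, s_u, pts_u[:, k]) for k in range(3)])
    new_vals = None
    if values is not None:
        vals_u = np.asarray(values, dtype=float)[keep]
        if len(s_u) >= 4:
            new_vals = CubicSpline(s_u, vals_u)(target)
        else:
            new_vals = np.interp(target, s_u, vals_u)
    return new_pts, new_vals


def _align_fibers(bundle: StreamlineBundle) -> StreamlineBundle:
    """Flip fibers whose endpoints better match the reversed reference.

    The first fiber serves as the orientation reference; ties keep the
    original orientation.
    """
    ref = bundle.fibers[0]
    fibers, values = [], []
    for pts, vals in zip(bundle.fibers, bundle.values):
        fwd = np.linalg.norm(pts[0] - ref[0]) + np.linalg.norm(pts[-1] - ref[-1])
        rev = np.linalg.norm(pts[-1] - ref[0]) + np.linalg.norm(pts[0] - ref[-1])
        if rev < fwd:
            pts, vals = pts[::-1].copy(), vals[::-1].copy()
        fibers.append(pts)
        values.append(vals)
    return StreamlineBundle(fibers, values, bundle.tract_id, dict(bundle.meta))


def _resampled_stack(
    bundle: StreamlineBundle, n_nodes: int
) -> tuple[np.ndarray, np.ndarray]:
    """(n_fibers, n_nodes, 3) points and (n_fibers, n_nodes) values, aligned."""
    aligned = _align_fibers(bundle)
    pts_list, val_list = [], []
    for pts, vals in zip(aligned.fibers, aligned.values):
        p, v = resample_fiber(pts, n_nodes, vals)
        pts_list.append(p)
        val_list.append(v)
    return np.stack(pts_list), np.stack(val_list)


def core_trajectory(bundle: StreamlineBundle, n_nodes: int = 100) -> CoreTrajectory:
    """Pointwise mean and covariance of the resampled, aligned fibers."""
    if bundle.n_fibers < 2:
        raise ValueError("core trajectory needs at least 2 fibers")
    pts, _ = _resampled_stack(bundle, n_nodes)
    mean = pts.mean(axis=0)
    dev = pts - mean  # (F, n, 3)
    cov = np.einsum("fni,fnj->nij", dev, dev) / (bundle.n_fibers - 1)
    return CoreTrajectory(node_positions=mean, node_spread=cov)


def _node_mahalanobis(pts: np.ndarray, core: CoreTrajectory) -> np.ndarray:
    """Per-fiber, per-node Mahalanobis distance to the core. pts: (F, n, 3)."""
    n_f, n_nodes, _ = pts.shape
    dist = np.empty((n_f, n_nodes))
    dev = pts - core.node_positions
    for k in range(n_nodes):
        cov = core.node_spread[k]
        # ridge keeps degenerate (e.g. zero-spread) nodes well-posed
        ridge = 1e-9 * max(np.trace(cov) / 3.0, 1.0) * np.eye(3)
        sol = np.linalg.solve(cov + ridge, dev[:, k, :].T)
        dist[:, k] = np.sqrt(np.einsum("fj,jf->f", dev[:, k, :], sol).clip(min=0.0))
    return dist


def deviation_scores(bundle: StreamlineBundle, n_nodes: int = 100) -> np.ndarray:
    """Per-fiber core-deviation score: mean over nodes of Mahalanobis distance."""
    pts, _ = _resampled_stack(bundle, n_nodes)
    core = core_trajectory(bundle, n_nodes)
    return _node_mahalanobis(pts, core).mean(axis=1)


def clean_bundle(
    bundle: StreamlineBundle,
    length_sd: float = 4.0,
    deviation_sd: float = 5.0,
    n_nodes: int = 100,
    max_passes: int = 5,
) -> StreamlineBundle:
    """Remove outlier fibers by the 4-SD length and 5-SD core-deviation rules.

    A pass removes fibers with arc length above mean + ``length_sd``·SD of
    bundle fiber lengths, then fibers whose mean Mahalanobis distance from
    the core trajectory exceeds ``deviation_sd`` (distances are already in
    SD units). Statistics are recomputed after each pass, up to
    ``max_passes`` or until no fiber is removed.
    """
    if bundle.n_fibers < 3:
        raise ValueError("clean_bundle needs at least 3 fibers")
    current = bundle
    for _ in range(max_passes):
        lengths = np.array([fiber_length(f) for f in current.fibers])
        cutoff = lengths.mean() + length_sd * lengths.std(ddof=1)
        keep = lengths <= cutoff
        current = _subset(current, keep)
        if current.n_fibers < 2:
            raise ValueError("bundle degenerate: cleaning removed nearly all fibers")
        scores = deviation_scores(current, n_nodes)
        keep2 = scores <= deviation_sd
        removed = int((~keep).sum() + (~keep2).sum())
        current = _subset(current, keep2)
        if current.n_fibers < 2:
            raise ValueError("bundle degenerate: cleaning removed nearly all fibers")
        if removed == 0:
            break
    return current


def _subset(bundle: StreamlineBundle, keep: np.ndarray) -> StreamlineBundle:
    return StreamlineBundle(
        [f for f, k in zip(bundle.fibers, keep) if k],
        [v for v, k in zip(bundle.values, keep) if k],
        bundle.tract_id,
        dict(bundle.meta),
    )


def profile_bundle(
    bundle: StreamlineBundle,
    subject_id: str,
    property: str,
    tract_id: str | None = None,
    n_nodes: int = 100,
) -> TractProfile:
    """Summarize a (cleaned) bundle into an ``n_nodes`` tract profile.

    At each node the profile value is the weighted mean of the fiber values,
    with Gaussian weights ``w = exp(-d^2 / 2)`` of the fiber point's
    Mahalanobis distance ``d`` to the core, normalized per node — fibers on
    the core dominate, stray fibers contribute little.
    """
    if bundle.n_fibers < 2:
        raise ValueError("profiling needs at least 2 fibers")
    pts, vals = _resampled_stack(bundle, n_nodes)
    core = core_trajectory(bundle, n_nodes)
    d = _node_mahalanobis(pts, core)
    w = np.exp(-0.5 * d**2)
    totals = w.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero total fiber weight at a node; bundle too dispersed")
    profile = (w * vals).sum(axis=0) / totals
    tract = tract_id or bundle.tract_id
    if tract is None:
        raise ValueError("tract_id must be given on the bundle or as an argument")
    return TractProfile(
        subject_id=subject_id, tract_id=tract, property=property, values=profile
    )
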