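"""Synthetic vessel-tree phantoms with exact ground truth.

Phantoms emulate the situations a coronary CT tracker must survive: smooth
curved tubes, bifurcations, focal stenoses, intensity gaps where a vessel
seems to disappear and re-appear, and bright decoy structures adjacent to
the vessel (the left-ventricle look-alike problem).  Centerlines are cubic
splines through control points; a voxel is foreground when its center lies
within the local radius of the nearest centerline sample and that sample is
not inside a gap interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .volume_io import Volume

#: default intensity levels, ~contrast-enhanced lumen vs myocardium scale
DEFAULT_FOREGROUND = 350.0
DEFAULT_BACKGROUND = 50.0
DEFAULT_NOISE_SIGMA = 20.0
#: arc-length step (mm) of the dense spline discretisation
DENSE_STEP = 0.05


@dataclass
class SegmentSpec:
    """One tubular segment of a phantom tree.

    ``control_points`` are world-mm spline knots; ``radius`` is either a
    scalar (constant tube) or ``(n, 2)`` breakpoints ``[arc_mm, radius_mm]``
    interpolated linearly.  ``stenosis`` entries are
    ``(arc_start, arc_end, radius_scale)`` with scale in (0, 1];
    ``gaps`` entries are ``(arc_start, arc_end)`` arc ranges where the
    foreground paint is suppressed (intensity falls to background level
    while the true centerline continues).
    """

    control_points: np.ndarray
    radius: float | np.ndarray = 1.0
    foreground: float = DEFAULT_FOREGROUND
    stenosis: list[tuple[float, float, float]] = field(default_factory=list)
    gaps: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class DecoyBlob:
    """A bright sphere near the vessel mimicking similar-HU anatomy."""

    center: np.ndarray
    radius: float
    level: float = DEFAULT_FOREGROUND


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic vessel-tree volume."""

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    segments: list[SegmentSpec] = field(default_factory=list)
    #: (parent segment index, parent arc length mm) per non-root segment,
    #: keyed by segment index
    tree_edges: dict[int, tuple[int, float]] = field(default_factory=dict)
    background: float = DEFAULT_BACKGROUND
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    decoys: list[DecoyBlob] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("phantom needs at least one segment")
        max_sp = max(self.spacing)
        for i, seg in enumerate(self.segments):
            arcs, _, radii = _dense_centerline(seg)
            if radii.min() <= max_sp / 2:
                raise ValueError(
                    f"segment {i}: radius {radii.min():.3f} mm not resolvable "
                    f"at spacing {max_sp} mm")
            total = arcs[-1]
            for a0, a1 in seg.gaps:
                if not (0 <= a0 < a1 <= total):
                    raise ValueError(f"segment {i}: gap ({a0}, {a1}) outside "
                                     f"arc range [0, {total:.2f}]")
            for a0, a1, s in seg.stenosis:
                if not (0 <= a0 < a1 <= total) or not (0 < s <= 1):
                    raise ValueError(f"segment {i}: bad stenosis ({a0}, {a1}, {s})")
            if seg.foreground <= self.background:
                raise ValueError(f"segment {i}: foreground must exceed background")


@dataclass
class SegmentTruth:
    """Dense ground-truth centerline of one segment."""

    points: np.ndarray   # (n, 3) mm
    radii: np.ndarray    # (n,) mm, stenosis applied
    arcs: np.ndarray     # (n,) cumulative arc length mm

    @property
    def length(self) -> float:
        return float(self.arcs[-1])


@dataclass
class PhantomTruth:
    """Ground truth for a rasterized phantom."""

    segments: list[SegmentTruth]
    branch_points: np.ndarray  # (k, 3) mm

    def to_json_dict(self) -> dict:
        return {
            "segments": [
                {"polyline": np.column_stack([s.points, s.radii]).tolist(),
                 "length_mm": s.length}
                for s in self.segments
            ],
            "branch_points": self.branch_points.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PhantomTruth":
        segs = []
        for s in d["segments"]:
            arr = np.asarray(s["polyline"], dtype=float)
            pts, radii = arr[:, :3], arr[:, 3]
            arcs = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
            segs.append(SegmentTruth(pts, radii, arcs))
        return cls(segs, np.asarray(d["branch_points"], dtype=float).reshape(-1, 3))


# ---------------------------------------------------------------------- #
# geometry helpers
# ---------------------------------------------------------------------- #
def _dense_centerline(seg: SegmentSpec, step: float = DENSE_STEP):
    """Dense polyline (arcs, points, effective radii) of a segment spline."""
    cp = np.asarray(seg.control_points, dtype=float)
    if cp.ndim != 2 or cp.shape[1] != 3 or len(cp) < 2:
        raise ValueError("control_points must be (n>=2, 3)")
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
    if len(cp) == 2:  # straight segment: spline needs >= 3 knots
        mid = cp.mean(axis=0)
        cp = np.vstack([cp[0], mid, cp[1]])
        chord = np.array([0.0, chord[-1] / 2, chord[-1]])
    spline = CubicSpline(chord, cp, axis=0)
    t = np.arange(0.0, chord[-1] + step / 2, step)
    pts = spline(t)
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arcs = np.concatenate([[0.0], np.cumsum(d)])

    if np.isscalar(seg.radius):
        radii = np.full(len(pts), float(seg.radius))
    else:
        rb = np.asarray(seg.radius, dtype=float)
        radii = np.interp(arcs, rb[:, 0], rb[:, 1])
    for a0, a1, scale in seg.stenosis:
        radii = np.where((arcs >= a0) & (arcs <= a1), radii * scale, radii)
    return arcs, pts, radii


def _gap_mask(seg: SegmentSpec, arcs: np.ndarray) -> np.ndarray:
    gap = np.zeros(len(arcs), dtype=bool)
    for a0, a1 in seg.gaps:
        gap |= (arcs >= a0) & (arcs <= a1)
    return gap


def segment_tangent(truth: SegmentTruth, arc: float) -> np.ndarray:
    """Unit tangent of a truth centerline at arc length ``arc`` (mm)."""
    i = int(np.searchsorted(truth.arcs, arc))
    i = np.clip(i, 1, len(truth.points) - 1)
    t = truth.points[i] - truth.points[i - 1]
    return t / np.linalg.norm(t)


# ---------------------------------------------------------------------- #
# rasterization
# ---------------------------------------------------------------------- #
def rasterize(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Render a phantom spec into a noisy volume plus exact ground truth.

    Deterministic given ``spec.seed``; the truth polylines are sampled at
    ≤ 0.25 × the minimum voxel spacing.
    """
    spec.validate()
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    hi_world = origin + spacing * (np.array(shape) - 1)

    data = np.full(shape, spec.background, dtype=np.float64)
    truth_segments: list[SegmentTruth] = []
    truth_step = 0.25 * float(spacing.min())

    for si, seg in enumerate(spec.segments):
        arcs, pts, radii = _dense_centerline(seg)
        if np.any(pts - radii[:, None] < origin) or \
           np.any(pts + radii[:, None] > hi_world):
            raise ValueError(f"segment {si} leaves the grid")
        gap = _gap_mask(seg, arcs)

        # paint: voxels in the inflated bbox, nearest dense sample decides
        rmax = radii.max()
        lo = np.floor((pts.min(axis=0) - rmax - spacing - origin) / spacing)
        hi = np.ceil((pts.max(axis=0) + rmax + spacing - origin) / spacing)
        lo = np.maximum(lo, 0).astype(int)
        hi = np.minimum(hi, np.array(shape) - 1).astype(int)
        grids = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)],
                            indexing="ij")
        vox_world = np.stack([grids[a] * spacing[a] + origin[a]
                              for a in range(3)], axis=-1).reshape(-1, 3)
        dist, idx = cKDTree(pts).query(vox_world, workers=-1)
        inside = (dist < radii[idx]) & ~gap[idx]
        flat = (grids[0].ravel()[inside], grids[1].ravel()[inside],
                grids[2].ravel()[inside])
        data[flat] = seg.foreground

        stride = max(1, int(np.floor(truth_step / DENSE_STEP)))
        keep = np.unique(np.append(np.arange(0, len(arcs), stride),
                                   len(arcs) - 1))
        truth_segments.append(SegmentTruth(pts[keep], radii[keep], arcs[keep]))

    for blob in spec.decoys:
        c = np.asarray(blob.center, dtype=float)
        lo = np.maximum(np.floor((c - blob.radius - origin) / spacing), 0).astype(int)
        hi = np.minimum(np.ceil((c + blob.radius - origin) / spacing),
                        np.array(shape) - 1).astype(int)
        grids = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)],
                            indexing="ij")
        d2 = sum(((grids[a] * spacing[a] + origin[a]) - c[a]) ** 2
                 for a in range(3))
        sel = d2 <= blob.radius ** 2
        data[grids[0][sel], grids[1][sel], grids[2][sel]] = blob.level

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=shape)

    branch_pts = []
    for child, (parent, arc) in sorted(spec.tree_edges.items()):
        pt_arcs = truth_segments[parent].arcs
        i = int(np.argmin(np.abs(pt_arcs - arc)))
        branch_pts.append(truth_segments[parent].points[i])
    branch_pts = (np.asarray(branch_pts, dtype=float).reshape(-1, 3)
                  if branch_pts else np.zeros((0, 3)))

    vol = Volume(data=data, spacing=spacing, origin=origin)
    return vol, PhantomTruth(truth_segments, branch_pts)


# ---------------------------------------------------------------------- #
# the standard phantom suite
# ---------------------------------------------------------------------- #
def standard_suite(noise_sigma: float = DEFAULT_NOISE_SIGMA,
                   seed: int = 0) -> dict[str, PhantomSpec]:
    """Named phantom specs covering the scenarios the tracker must handle.

    All use a 128³ grid at 0.5 mm isotropic spacing (64 mm cube).  Returns
    STRAIGHT, CURVED, YBRANCH, GAP, YGAP, STENOSIS and DECOY specs.
    """
    base = dict(shape=(128, 128, 128), spacing=(0.5, 0.5, 0.5),
                noise_sigma=noise_sigma, seed=seed)

    def straight_seg(**kw):
        return SegmentSpec(control_points=np.array(
            [[8.0, 32.0, 32.0], [32.0, 32.0, 32.0], [56.0, 32.0, 32.0]]), **kw)

    suite: dict[str, PhantomSpec] = {}
    suite["STRAIGHT"] = PhantomSpec(segments=[straight_seg()], **base)

    # C-shaped arc of curvature radius 20 mm (20x the tube radius)
    theta = np.deg2rad(np.linspace(200.0, 340.0, 9))
    arc_cp = np.column_stack([32.0 + 20.0 * np.cos(theta),
                              48.0 + 20.0 * np.sin(theta),
                              np.full(len(theta), 32.0)])
    suite["CURVED"] = PhantomSpec(segments=[SegmentSpec(control_points=arc_cp)],
                                  **base)

    # parent + daughter leaving at 45 deg from arc length 24 mm (x = 32)
    u = np.array([np.cos(np.deg2rad(45)), np.sin(np.deg2rad(45)), 0.0])
    dcp = np.array([[32.0, 32.0, 32.0],
                    [32.0, 32.0, 32.0] + 10.0 * u,
                    [32.0, 32.0, 32.0] + 20.0 * u])
    ybranch = PhantomSpec(
        segments=[straight_seg(), SegmentSpec(control_points=dcp, radius=0.8)],
        tree_edges={1: (0, 24.0)}, **base)
    suite["YBRANCH"] = ybranch

    # straight tube with a 3 mm intensity gap at mid-vessel
    suite["GAP"] = PhantomSpec(
        segments=[straight_seg(gaps=[(22.5, 25.5)])], **base)

    # branch whose daughter is detached from the parent by a 2 mm gap
    suite["YGAP"] = PhantomSpec(
        segments=[straight_seg(),
                  SegmentSpec(control_points=dcp, radius=0.8, gaps=[(0.0, 2.0)])],
        tree_edges={1: (0, 24.0)}, **base)

    # radius scaled x0.4 over a 5 mm interval
    suite["STENOSIS"] = PhantomSpec(
        segments=[straight_seg(stenosis=[(21.5, 26.5, 0.4)])], **base)

    # tube adjacent to a large bright blob (similar intensity level)
    suite["DECOY"] = PhantomSpec(
        segments=[straight_seg()],
        decoys=[DecoyBlob(center=np.array([32.0, 36.5, 32.0]), radius=2.5)],
        **base)
    return suite


def with_noise(spec: PhantomSpec, sigma: float) -> PhantomSpec:
    """Copy of ``spec`` with a different additive-noise level."""
    return replace(spec, noise_sigma=sigma)
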