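"""Vessel-tree assembly, pruning, centerline export and lumen tube meshing.

Tracking over-generates: active search queues many candidate seeds and some
become short or duplicate tracks.  Assembly links daughters to parents via
their branch events and prunes false positives to a fixpoint, then the tree
can be exported as per-path centerline text files, a JSON document, and a
generalized-tube surface mesh.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .tracker import Centerline, TrackedSegment

log = logging.getLogger(__name__)


@dataclass
class AssembleConfig:
    min_length: float = 3.0        # mm, rule (a)
    vesselness_fraction: float = 0.25  # rule (b): mean v < frac * reference v
    duplicate_fraction: float = 0.5    # rule (c)
    duplicate_radius_factor: float = 1.0


@dataclass
class VesselTree:
    """Segments linked into a forest, with a pruning audit trail."""

    segments: list[Centerline]
    edges: list[tuple[int, float, int]]   # (parent idx, attach arc mm, child idx)
    roots: list[int]
    pruned: list[tuple[int, str]] = field(default_factory=list)
    events: list = field(default_factory=list)

    def children(self, idx: int) -> list[int]:
        return [c for p, _, c in self.edges if p == idx]

    def root_to_leaf_paths(self) -> list[list[int]]:
        """Segment chains from each root to every distal vessel end.

        Every segment's distal end is a leaf (a parent keeps running past
        the bifurcations attached along it), so each segment closes exactly
        one path.
        """
        parent_of = {c: p for p, _, c in self.edges}
        paths = []
        for idx in range(len(self.segments)):
            chain = [idx]
            node = idx
            while node in parent_of:
                node = parent_of[node]
                chain.append(node)
            if chain[-1] in self.roots:
                paths.append(chain[::-1])
        return paths


def _attach_arc(parent: Centerline, point: np.ndarray) -> float:
    pts = parent.points
    arcs = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    j = int(np.argmin(np.linalg.norm(pts - point[None, :], axis=1)))
    return float(arcs[j])


def assemble(segments: list[TrackedSegment], events,
             config: AssembleConfig | None = None) -> VesselTree:
    """Link tracked segments into a tree and prune false positives.

    Pruning (iterated to fixpoint): (a) shorter than the minimum length;
    (b) mean planar vesselness below a fraction of the reference level (the
    per-point median of the longest root segment); (c) duplicates — at
    least half the points within one local radius of another retained
    segment, the longer of the pair kept.  Children of a pruned segment are
    pruned with it.
    """
    if not segments:
        raise ValueError("assemble needs at least one segment")
    if config is None:
        config = AssembleConfig()

    n = len(segments)
    roots = [i for i, s in enumerate(segments) if s.parent is None]
    # reference vesselness from the longest root
    ref_root = max(roots, key=lambda i: segments[i].centerline.arc_length)
    ref_v = float(np.median(segments[ref_root].centerline.vesselness)) \
        if segments[ref_root].centerline.vesselness else 0.0
    v_thr = config.vesselness_fraction * ref_v

    alive = [True] * n
    reasons: dict[int, str] = {}

    def prune(i: int, why: str):
        alive[i] = False
        reasons[i] = why
        for j in range(n):
            if alive[j] and segments[j].parent == i:
                prune(j, "parent pruned")

    changed = True
    while changed:
        changed = False
        for i in range(n):
            if not alive[i] or i == ref_root:
                continue
            cl = segments[i].centerline
            if cl.arc_length < config.min_length:
                prune(i, "too short")
                changed = True
                continue
            if cl.mean_vesselness() < v_thr:
                prune(i, "low vesselness")
                changed = True
                continue
        # duplicates among the survivors
        live = [i for i in range(n) if alive[i]]
        for i in live:
            if not alive[i]:
                continue
            cli = segments[i].centerline
            for j in live:
                if j == i or not alive[j]:
                    continue
                clj = segments[j].centerline
                if len(clj.points) < 2:
                    continue
                tree = cKDTree(clj.points)
                d, idx = tree.query(cli.points)
                frac = float(np.mean(
                    d < config.duplicate_radius_factor * clj.radii[idx]))
                if frac >= config.duplicate_fraction:
                    victim = i if cli.arc_length <= clj.arc_length else j
                    if victim == ref_root:
                        victim = j if victim == i else i
                    prune(victim, "duplicate")
                    changed = True
                    if victim == i:
                        break

    kept = [i for i in range(n) if alive[i]]
    remap = {old: new for new, old in enumerate(kept)}
    out_segments = [segments[i].centerline for i in kept]
    out_edges = []
    for i in kept:
        p = segments[i].parent
        if p is None or p not in remap:
            continue
        ev = segments[i].parent_event
        attach_pt = (np.asarray(ev.point) if ev is not None
                     else segments[i].centerline.points[0])
        arc = _attach_arc(segments[p].centerline, attach_pt)
        edge = (remap[p], arc, remap[i])
        # forest invariant: a closing edge would create a cycle
        if _creates_cycle(out_edges, edge):
            log.warning("dropping cyclic edge proposal %s", edge)
            continue
        out_edges.append(edge)
    out_roots = [remap[i] for i in kept
                 if segments[i].parent is None or segments[i].parent not in remap]
    pruned = [(i, reasons[i]) for i in range(n) if not alive[i]]
    kept_events = [e for e in events
                   if not _event_on_pruned(e, segments, alive)]
    return VesselTree(segments=out_segments, edges=out_edges, roots=out_roots,
                      pruned=pruned, events=kept_events)


def _event_on_pruned(event, segments, alive) -> bool:
    for i, seg in enumerate(segments):
        if seg.parent_event is event:
            return not alive[i]
    return False


def _creates_cycle(edges, new_edge) -> bool:
    parent_of = {c: p for p, _, c in edges}
    p, _, c = new_edge
    if c in parent_of:
        return True
    seen = {c}
    node = p
    while node in parent_of:
        node = parent_of[node]
        if node in seen:
            return True
        seen.add(node)
    return False


# ---------------------------------------------------------------------- #
# export
# ---------------------------------------------------------------------- #
def tree_to_json_dict(tree: VesselTree) -> dict:
    return {
        "segments": [
            {"points": [[float(v) for v in s.x] for s in cl.states],
             "radii": [float(s.r) for s in cl.states],
             "bridged": list(map(bool, cl.bridged)),
             "termination": cl.termination.value if cl.termination else None}
            for cl in tree.segments
        ],
        "edges": [[int(p), float(a), int(c)] for p, a, c in tree.edges],
        "roots": [int(r) for r in tree.roots],
        "pruned": [[int(i), why] for i, why in tree.pruned],
        "branch_events": [e.to_json_dict() for e in tree.events],
    }


def export_centerlines(tree: VesselTree, prefix: str) -> list[Path]:
    """Write one ``x y z r`` text file per root-to-leaf path, plus tree JSON.

    Coordinates are mm with 6 significant digits; files are named
    ``{prefix}_path{n}.txt`` and the JSON ``{prefix}_tree.json``.  Returns
    the list of written paths.
    """
    written: list[Path] = []
    for pi, path in enumerate(tree.root_to_leaf_paths()):
        lines = []
        for k, si in enumerate(path):
            cl = tree.segments[si]
            states = cl.states
            if k > 0:   # child: start after the attachment point
                states = states
            for st in states:
                lines.append(f"{st.x[0]:.6f} {st.x[1]:.6f} {st.x[2]:.6f} "
                             f"{st.r:.6f}")
        p = Path(f"{prefix}_path{pi}.txt")
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append(p)
    jp = Path(f"{prefix}_tree.json")
    jp.write_text(json.dumps(tree_to_json_dict(tree), indent=1, sort_keys=True))
    written.append(jp)
    return written


def read_centerline_file(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an exported ``x y z r`` file back as (points, radii)."""
    arr = np.loadtxt(path, ndmin=2)
    return arr[:, :3], arr[:, 3]


# ---------------------------------------------------------------------- #
# lumen tube mesh
# ---------------------------------------------------------------------- #
def _rmf_frames(points: np.ndarray) -> np.ndarray:
    """Rotation-minimizing normal frames along a polyline (double reflection)."""
    n = len(points)
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    frames = np.empty((n, 2, 3))
    t0 = tangents[0]
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(t0)))] = 1.0
    u = np.cross(t0, ref)
    u /= np.linalg.norm(u)
    frames[0, 0] = u
    frames[0, 1] = np.cross(t0, u)
    for i in range(1, n):
        v1 = points[i] - points[i - 1]
        c1 = float(v1 @ v1)
        if c1 < 1e-14:
            frames[i] = frames[i - 1]
            continue
        uL = frames[i - 1, 0] - (2.0 / c1) * (v1 @ frames[i - 1, 0]) * v1
        tL = tangents[i - 1] - (2.0 / c1) * (v1 @ tangents[i - 1]) * v1
        v2 = tangents[i] - tL
        c2 = float(v2 @ v2)
        u_i = uL if c2 < 1e-14 else uL - (2.0 / c2) * (v2 @ uL) * v2
        u_i = u_i - (u_i @ tangents[i]) * tangents[i]
        u_i /= np.linalg.norm(u_i)
        frames[i, 0] = u_i
        frames[i, 1] = np.cross(tangents[i], u_i)
    return frames


def _tube_mesh(points: np.ndarray, radii: np.ndarray,
               n_ring: int = 16) -> trimesh.Trimesh:
    frames = _rmf_frames(points)
    angles = np.linspace(0.0, 2 * np.pi, n_ring, endpoint=False)
    ca, sa = np.cos(angles), np.sin(angles)
    verts = []
    for i in range(len(points)):
        ring = (points[i][None, :]
                + radii[i] * (ca[:, None] * frames[i, 0][None, :]
                              + sa[:, None] * frames[i, 1][None, :]))
        verts.append(ring)
    verts = np.vstack(verts)
    faces = []
    for i in range(len(points) - 1):
        a0 = i * n_ring
        b0 = (i + 1) * n_ring
        for j in range(n_ring):
            jn = (j + 1) % n_ring
            faces.append([a0 + j, b0 + j, b0 + jn])
            faces.append([a0 + j, b0 + jn, a0 + jn])
    # end caps: fan to the centerline endpoints
    c_start = len(verts)
    verts = np.vstack([verts, points[0][None, :], points[-1][None, :]])
    c_end = c_start + 1
    last = (len(points) - 1) * n_ring
    for j in range(n_ring):
        jn = (j + 1) % n_ring
        faces.append([c_start, jn, j])
        faces.append([c_end, last + j, last + jn])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                           process=False)


def make_mesh(tree: VesselTree, n_ring: int = 16) -> trimesh.Trimesh:
    """Generalized-tube lumen mesh of the whole tree.

    Each segment becomes a capped tube with ``n_ring`` vertices per ring,
    ring radius equal to the stored per-point radius, connected by
    rotation-minimizing frames.  Daughter rings within one parent radius of
    the attachment point are omitted (no junction blending).
    """
    meshes = []
    for idx, cl in enumerate(tree.segments):
        pts, radii = cl.points, cl.radii
        if len(pts) < 2:
            continue
        parent_edge = [(p, a) for p, a, c in tree.edges if c == idx]
        if parent_edge:
            p_idx, _ = parent_edge[0]
            attach = pts[0]
            p_tree = cKDTree(tree.segments[p_idx].points)
            d, j = p_tree.query(attach)
            parent_r = float(tree.segments[p_idx].radii[j])
            keep = np.linalg.norm(pts - attach[None, :], axis=1) > parent_r
            if keep.sum() < 2:
                continue
            first = int(np.argmax(keep))
            pts, radii = pts[first:], radii[first:]
        meshes.append(_tube_mesh(pts, radii, n_ring))
    if not meshes:
        return trimesh.Trimesh()
    return trimesh.util.concatenate(meshes)


def export_mesh(tree: VesselTree, prefix: str) -> list[Path]:
    """Write the lumen mesh as binary-little-endian PLY and as OBJ."""
    mesh = make_mesh(tree)
    ply = Path(f"{prefix}_lumen.ply")
    obj = Path(f"{prefix}_lumen.obj")
    mesh.export(ply, file_type="ply")
    mesh.export(obj, file_type="obj")
    return [ply, obj]
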