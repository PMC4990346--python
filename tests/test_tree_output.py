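"""Tree assembly, pruning, export round-trips and tube meshing."""

import json

import numpy as np
import pytest

import corotrack as ct
from corotrack.tracker import Centerline, TrackedSegment, Termination
from corotrack.tree_output import _tube_mesh
from corotrack.vessel_model import VesselState

from conftest import tracked


def make_centerline(points, radii=None, v=300.0):
    points = np.asarray(points, dtype=float)
    if radii is None:
        radii = np.ones(len(points))
    states = [VesselState(x=p, r=float(r), f=350.0, b=50.0)
              for p, r in zip(points, radii)]
    cl = Centerline(states=states, bridged=[False] * len(states),
                    vesselness=[v] * len(states),
                    termination=Termination.LOW_VESSELNESS)
    return cl


def line(n, start=0.0, step=1.0):
    return np.column_stack([start + step * np.arange(n),
                            np.zeros(n), np.zeros(n)])


def test_single_segment_tree():
    seg = TrackedSegment(make_centerline(line(10)))
    tree = ct.assemble([seg], [])
    assert len(tree.segments) == 1
    assert tree.roots == [0]
    assert tree.edges == []


def test_duplicate_segments_pruned_keep_longer():
    long_seg = TrackedSegment(make_centerline(line(12)))
    dup = TrackedSegment(make_centerline(line(8)))
    tree = ct.assemble([long_seg, dup], [])
    assert len(tree.segments) == 1
    assert tree.pruned == [(1, "duplicate")]
    assert tree.segments[0].arc_length == pytest.approx(11.0)


def test_short_segment_pruned():
    root = TrackedSegment(make_centerline(line(12)))
    stub = TrackedSegment(make_centerline(np.array(
        [[0, 5.0, 0], [0, 6.0, 0]])), parent=0)
    tree = ct.assemble([root, stub], [])
    assert len(tree.segments) == 1
    assert tree.pruned == [(1, "too short")]


def test_low_vesselness_segment_pruned_with_children():
    root = TrackedSegment(make_centerline(line(12), v=400.0))
    weak = TrackedSegment(make_centerline(
        np.column_stack([np.zeros(6), 3.0 + np.arange(6), np.zeros(6)]),
        v=10.0), parent=0)
    child = TrackedSegment(make_centerline(
        np.column_stack([np.zeros(6), 9.0 + np.arange(6), 2.0 + np.zeros(6)]),
        v=400.0), parent=1)
    tree = ct.assemble([root, weak, child], [])
    assert len(tree.segments) == 1
    assert ("low vesselness" in dict(tree.pruned).values()
            or dict(tree.pruned)[1] == "low vesselness")
    assert dict(tree.pruned)[2] == "parent pruned"


def test_pruning_keeps_accurate_segments_on_phantoms():
    for name in ("STRAIGHT", "CURVED", "YBRANCH"):
        tree, truth, segments, _ = tracked(name, sigma=0.0)
        # no surviving-truth segment may have been pruned away entirely
        for ref in truth.segments:
            pts = np.vstack([cl.points for cl in tree.segments])
            m = ct.overlap_metrics(pts, ref.points, ref.radii)
            assert m.ov >= 0.8


def test_export_roundtrip_and_paths(tmp_path):
    tree, _, _, _ = tracked("YBRANCH", sigma=0.0)
    prefix = str(tmp_path / "yb")
    files = ct.export_centerlines(tree, prefix)
    path_files = [f for f in files if f.suffix == ".txt"]
    assert len(path_files) == 2   # two root-to-leaf paths
    pts, radii = ct.read_centerline_file(path_files[0])
    orig = tree.segments[0]
    assert np.allclose(pts[:len(orig.states)], orig.points, atol=1e-6)
    assert np.allclose(radii[:len(orig.states)], orig.radii, atol=1e-6)
    doc = json.loads((tmp_path / "yb_tree.json").read_text())
    assert len(doc["segments"]) == len(tree.segments)
    assert doc["branch_events"]


def test_export_empty_tree(tmp_path):
    tree = ct.VesselTree(segments=[], edges=[], roots=[])
    files = ct.export_centerlines(tree, str(tmp_path / "empty"))
    assert [f for f in files if f.suffix == ".txt"] == []
    doc = json.loads((tmp_path / "empty_tree.json").read_text())
    assert doc["segments"] == []


def test_three_point_export_parses_back(tmp_path):
    seg = TrackedSegment(make_centerline(
        np.array([[1.25, 2.5, 3.75], [2.25, 2.5, 3.75], [3.25, 2.5, 3.75]]),
        radii=[0.8, 0.9, 1.0]))
    tree = ct.assemble([seg], [])
    files = ct.export_centerlines(tree, str(tmp_path / "t"))
    pts, radii = ct.read_centerline_file(files[0])
    assert pts.shape == (3, 3)
    assert np.allclose(pts, [[1.25, 2.5, 3.75], [2.25, 2.5, 3.75],
                             [3.25, 2.5, 3.75]], atol=1e-6)
    assert np.allclose(radii, [0.8, 0.9, 1.0], atol=1e-6)


def test_cylinder_mesh_area_and_watertightness():
    mesh = _tube_mesh(np.array([[0.0, 0, 0], [10.0, 0, 0]]),
                      np.array([1.0, 1.0]), n_ring=32)
    expected = 2 * np.pi * 1.0 * 10.0 + 2 * np.pi * 1.0 ** 2
    assert mesh.area == pytest.approx(expected, rel=0.05)
    assert mesh.is_watertight


def test_ring_radii_follow_stored_radius():
    pts = line(5)
    radii = np.array([0.5, 0.75, 1.0, 1.25, 1.5])
    mesh = _tube_mesh(pts, radii, n_ring=16)
    verts = mesh.vertices[:5 * 16].reshape(5, 16, 3)
    for i in range(5):
        d = np.linalg.norm(verts[i] - pts[i][None, :], axis=1)
        assert np.allclose(d, radii[i], atol=1e-9)


def test_tracked_mesh_close_to_true_tube_surface():
    tree, truth, _, _ = tracked("STRAIGHT", sigma=0.0)
    mesh = ct.make_mesh(tree)
    ref = truth.segments[0]
    # distance of mesh vertices to the analytic tube surface (axis y=z=32, r=1)
    v = mesh.vertices
    inside = (v[:, 0] > ref.points[0][0] + 1) & (v[:, 0] < ref.points[-1][0] - 1)
    axis_dist = np.sqrt((v[inside, 1] - 32.0) ** 2 + (v[inside, 2] - 32.0) ** 2)
    assert np.mean(np.abs(axis_dist - 1.0)) <= 0.25


def test_mesh_export_formats(tmp_path):
    tree, _, _, _ = tracked("STRAIGHT", sigma=0.0)
    ply, obj = ct.export_mesh(tree, str(tmp_path / "m"))
    assert ply.stat().st_size > 0 and obj.stat().st_size > 0
    import trimesh
    back = trimesh.load(ply)
    assert len(back.vertices) > 0
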