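"""Planar Hessian vesselness: analytic checks and phantom behavior."""

import numpy as np
import pytest

import corotrack as ct
from corotrack.vesselness import CrossSection, hessian2d, planar_vesselness

from conftest import phantom


def make_cs(image_fn, n=41, pixel=0.2, sigma=1.0):
    x = (np.arange(n) - n // 2) * pixel
    xx, yy = np.meshgrid(x, x, indexing="ij")
    return CrossSection(image=image_fn(xx, yy), pixel=pixel,
                        half_extent=x[-1], sigma=sigma,
                        center=np.zeros(3), basis_u=np.eye(3)[0],
                        basis_w=np.eye(3)[1])


def test_hessian_of_negative_paraboloid():
    ixx, iyy, ixy = hessian2d(make_cs(lambda x, y: -(x ** 2 + y ** 2)))
    assert ixx == pytest.approx(-2.0, rel=0.05)
    assert iyy == pytest.approx(-2.0, rel=0.05)
    assert ixy == pytest.approx(0.0, abs=0.05)


def test_hessian_of_saddle_xy():
    ixx, iyy, ixy = hessian2d(make_cs(lambda x, y: x * y))
    assert ixy == pytest.approx(1.0, rel=0.05)
    assert ixx == pytest.approx(0.0, abs=0.05)
    assert iyy == pytest.approx(0.0, abs=0.05)


def test_constant_section_scores_zero():
    assert planar_vesselness(make_cs(lambda x, y: np.full_like(x, 7.0))) == 0.0


def test_dark_disc_scores_zero():
    dark = make_cs(lambda x, y: -100.0 * np.exp(-(x ** 2 + y ** 2) / 2))
    assert planar_vesselness(dark) == 0.0
    bright = make_cs(lambda x, y: 100.0 * np.exp(-(x ** 2 + y ** 2) / 2))
    assert planar_vesselness(bright) > 0.0


def test_sigma_below_pixel_rejected():
    cs = make_cs(lambda x, y: x * y, pixel=0.5, sigma=0.1)
    with pytest.raises(ValueError):
        hessian2d(cs)


def test_extract_cross_section_constant(constant_volume):
    cs = ct.extract_cross_section(constant_volume, np.array([6.0, 6.0, 6.0]),
                                  np.array([0.0, 0.0, 1.0]),
                                  half_extent=2.0, pixel=0.5)
    assert np.allclose(cs.image, 55.0)
    n = cs.image.shape[0]
    assert n % 2 == 1 and cs.image.shape == (n, n)


def test_extract_cross_section_bright_center_on_tube():
    vol, truth = phantom("STRAIGHT", sigma=0.0)
    c = truth.segments[0].points[len(truth.segments[0].points) // 2]
    cs = ct.extract_cross_section(vol, c, np.array([1.0, 0.0, 0.0]),
                                  half_extent=4.0, pixel=0.5)
    mid = cs.image.shape[0] // 2
    assert cs.image[mid, mid] >= 350.0 - 1e-6
    assert cs.image[0, 0] == pytest.approx(50.0)


def test_flipped_direction_gives_flipped_section(constant_volume):
    vol, truth = phantom("YBRANCH", sigma=0.0)
    c = np.array([30.0, 32.0, 32.0])
    cs_f = ct.extract_cross_section(vol, c, np.array([1.0, 0.0, 0.0]),
                                    half_extent=4.0, pixel=0.5)
    cs_b = ct.extract_cross_section(vol, c, np.array([-1.0, 0.0, 0.0]),
                                    half_extent=4.0, pixel=0.5)
    # the basis rule mirrors one in-plane axis when the direction flips
    assert np.allclose(cs_b.image, cs_f.image[::-1, :]) or \
        np.allclose(cs_b.image, cs_f.image[:, ::-1]) or \
        np.allclose(cs_b.image, cs_f.image[::-1, ::-1].T) or \
        np.allclose(cs_b.image, cs_f.image.T)


def test_vesselness_on_vs_off_vessel_ratio():
    vol, truth = phantom("STRAIGHT", sigma=0.0)
    v_on = ct.vesselness_at(vol, np.array([32.0, 32.0, 32.0]),
                            np.array([1.0, 0.0, 0.0]), 1.0)
    v_off = ct.vesselness_at(vol, np.array([32.0, 45.0, 32.0]),
                             np.array([1.0, 0.0, 0.0]), 1.0)
    assert v_on > 0
    assert v_off <= 0.05 * v_on
    assert v_on / max(v_off, 1e-12) >= 10.0


def test_profile_single_point_and_past_end():
    vol, truth = phantom("STRAIGHT", sigma=0.0)
    mid = len(truth.segments[0].points) // 2
    single = ct.vesselness_profile(vol, truth.segments[0].points[mid])
    assert single.shape == (1,)
    # extend 5 mm past the distal end: trailing vesselness collapses
    end = truth.segments[0].points[-1]
    ext = end + np.outer(np.arange(1.0, 6.0), np.array([1.0, 0.0, 0.0]))
    inside = truth.segments[0].points[::40]
    prof = ct.vesselness_profile(vol, np.vstack([inside, ext]), radii=1.0)
    assert np.median(prof[:len(inside)]) > 100.0
    assert np.all(prof[-3:] < 0.05 * np.median(prof[:len(inside)]))


def test_in_plane_rotation_invariance():
    """v from a rotated in-plane basis agrees within 2%.

    Sampled finely (pixel 0.125 mm) so that trilinear resampling error does
    not mask the rotational symmetry of the measure itself.
    """
    vol, truth = phantom("STRAIGHT", sigma=0.0)
    c = np.array([32.0, 32.0, 32.0])
    d = np.array([1.0, 0.0, 0.0])
    pixel, sigma = 0.125, 0.75
    cs = ct.extract_cross_section(vol, c, d, half_extent=4.0, pixel=pixel,
                                  sigma=sigma)
    base = planar_vesselness(cs)
    assert base > 0
    for ang in (20.0, 45.0, 77.0):
        th = np.deg2rad(ang)
        u = np.cos(th) * cs.basis_u + np.sin(th) * cs.basis_w
        w = -np.sin(th) * cs.basis_u + np.cos(th) * cs.basis_w
        offs = (np.arange(cs.image.shape[0]) - cs.image.shape[0] // 2) * pixel
        a, b = np.meshgrid(offs, offs, indexing="ij")
        pts = c[None, :] + a.reshape(-1, 1) * u + b.reshape(-1, 1) * w
        img = vol.sample_trilinear(pts).reshape(a.shape)
        rot_cs = CrossSection(image=img, pixel=pixel,
                              half_extent=cs.half_extent, sigma=sigma,
                              center=c, basis_u=u, basis_w=w)
        assert planar_vesselness(rot_cs) == pytest.approx(base, rel=0.02)


def test_profile_csv_export(tmp_path):
    pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    vals = [1.0, 2.0, 3.0]
    path = tmp_path / "prof.csv"
    from corotrack.vesselness import export_profile_csv
    export_profile_csv(path, pts, vals)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "index,arc_mm,vesselness"
    assert lines[2].startswith("1,1.000000,2.000000")
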