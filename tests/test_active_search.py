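"""Active search: Poisson branch model, neighborhood probing, gap bridging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import corotrack as ct
from corotrack.active_search import ActiveSearchConfig

from conftest import phantom, tracked, tree_points

TABLE_DISTANCES = [21.00, 21.96, 17.94, 17.64, 10.86, 22.38, 15.69, 11.19]


# ---------------------------------------------------------------------- #
# Poisson model
# ---------------------------------------------------------------------- #
def test_fit_poisson_on_training_distances():
    model = ct.fit_poisson(TABLE_DISTANCES)
    assert model.lam == pytest.approx(17.3325, abs=1e-10)
    assert model.trained_distances == TABLE_DISTANCES


def test_packaged_distances_reproduce_lambda():
    assert ct.default_branch_model().lam == pytest.approx(17.3325, abs=1e-10)


@pytest.mark.parametrize("dists,lam", [([5.0], 5.0), ([2, 4], 3.0)])
def test_fit_poisson_small_samples(dists, lam):
    assert ct.fit_poisson(dists).lam == pytest.approx(lam)


def test_fit_poisson_rejects_bad_input():
    with pytest.raises(ValueError):
        ct.fit_poisson([])
    with pytest.raises(ValueError):
        ct.fit_poisson([3.0, -1.0])


@given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=20),
       st.floats(0.5, 4.0))
@settings(deadline=None, max_examples=50)
def test_fit_poisson_permutation_invariant_scale_covariant(dists, c):
    lam = ct.fit_poisson(dists).lam
    assert ct.fit_poisson(list(reversed(dists))).lam == pytest.approx(lam)
    assert ct.fit_poisson([c * d for d in dists]).lam == \
        pytest.approx(c * lam, rel=1e-9)


def test_poisson_pmf_closed_form_and_normalization():
    unit = ct.PoissonBranchModel(lam=1.0)
    assert ct.poisson_pmf(unit, 0) == pytest.approx(np.exp(-1.0))
    model = ct.default_branch_model()
    total = sum(ct.poisson_pmf(model, x) for x in range(201))
    assert total == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        ct.poisson_pmf(model, -1)


def test_poisson_mode_is_floor_of_lambda():
    model = ct.default_branch_model()
    pmf = [ct.poisson_pmf(model, x) for x in range(101)]
    assert int(np.argmax(pmf)) == 17


def test_type3_monitor_quantile_behavior():
    model = ct.default_branch_model()
    # oracle: scan the CDF for the 0.9 quantile
    cdf, q = 0.0, None
    for x in range(200):
        cdf += ct.poisson_pmf(model, x)
        if cdf >= 0.9:
            q = x
            break
    assert 5.0 < q < 30.0
    assert ct.type3_monitor(5.0, 0, model) is ct.Type3Action.OK
    assert ct.type3_monitor(30.0, 0, model) is ct.Type3Action.TRIGGER_SEARCH
    assert ct.type3_monitor(30.0, 1, model) is ct.Type3Action.OK
    assert ct.poisson_quantile(model, 0.9) == q


# ---------------------------------------------------------------------- #
# neighborhood probing
# ---------------------------------------------------------------------- #
def test_search_region_empty_in_pure_background(noise_only_volume):
    seeds = ct.search_region(noise_only_volume, np.array([16.0, 16.0, 16.0]),
                             np.array([15.0, 16.0, 16.0]),
                             ActiveSearchConfig(),
                             fg_estimate=350.0, noise_sigma=20.0)
    assert seeds == []


def test_search_region_finds_distal_tube_across_gap():
    vol, truth = phantom("GAP", sigma=0.0)
    # gap spans x in [30.5, 33.5]; probe forward from the gap entrance
    seeds = ct.search_region(vol, np.array([30.0, 32.0, 32.0]),
                             np.array([29.0, 32.0, 32.0]),
                             ActiveSearchConfig(),
                             fg_estimate=350.0, noise_sigma=20.0)
    assert len(seeds) >= 1
    dists = [abs(s.position[1] - 32.0) + abs(s.position[2] - 32.0)
             for s in seeds if s.position[0] > 33.5]
    assert dists and min(dists) <= 1.0
    assert all(s.provenance == "active_search" for s in seeds)


def test_search_region_respects_cone_and_radius():
    vol, _ = phantom("GAP", sigma=0.0)
    cfg = ActiveSearchConfig(t_th=2.0)   # shorter than the 3 mm gap
    seeds = ct.search_region(vol, np.array([30.5, 32.0, 32.0]),
                             np.array([29.5, 32.0, 32.0]), cfg,
                             fg_estimate=350.0, noise_sigma=20.0)
    assert all(np.linalg.norm(s.position - [30.5, 32, 32]) <= 2.0 + 1e-9
               for s in seeds)


def test_search_region_config_validation():
    with pytest.raises(ValueError):
        ActiveSearchConfig(t_th=-1.0)
    with pytest.raises(ValueError):
        ActiveSearchConfig(t_theta_deg=120.0)


# ---------------------------------------------------------------------- #
# type 1 / type 2 end-to-end behavior
# ---------------------------------------------------------------------- #
def test_gap_bridged_within_true_gap():
    tree, truth, _, _ = tracked("GAP", sigma=20.0)
    assert len(tree.root_to_leaf_paths()) == 1
    ref = truth.segments[0]
    m = ct.overlap_metrics(tree_points(tree), ref.points, ref.radii)
    assert m.ov >= 0.9
    root = tree.segments[0]
    bridged_x = [s.x[0] for s, bf in zip(root.states, root.bridged) if bf]
    assert bridged_x, "bridging must have occurred"
    assert all(30.5 - 1.0 <= x <= 33.5 + 1.0 for x in bridged_x)


def test_gap_not_recovered_without_active_search():
    tree, truth, _, _ = tracked("GAP", sigma=20.0, active=False)
    ref = truth.segments[0]
    m = ct.overlap_metrics(tree_points(tree), ref.points, ref.radii)
    assert m.ov <= 0.6
    assert not any(any(cl.bridged) for cl in tree.segments)


def test_straight_track_is_never_bridged():
    tree, _, _, _ = tracked("STRAIGHT", sigma=20.0)
    assert not any(any(cl.bridged) for cl in tree.segments)


def test_type2_recovers_detached_daughter():
    tree, truth, _, _ = tracked("YGAP", sigma=20.0)
    daughter = truth.segments[1]
    m = ct.overlap_metrics(tree_points(tree), daughter.points, daughter.radii)
    assert m.ov >= 0.8


def test_type2_finds_nothing_on_straight_tube():
    tree, _, segments, events = tracked("STRAIGHT", sigma=0.0)
    vol, _ = phantom("STRAIGHT", sigma=0.0)
    seeds = ct.type2_branch_search(
        vol, tree.segments[0], events, ActiveSearchConfig(),
        tree_points(tree), np.concatenate([cl.radii for cl in tree.segments]))
    assert seeds == []


def test_decoy_tree_reduces_to_single_segment():
    tree, _, _, _ = tracked("DECOY", sigma=20.0)
    assert len(tree.segments) == 1
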