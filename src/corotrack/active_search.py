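"""Active search: recovering seemingly disconnected vessels and branches.

Sequential tracking stops at intensity gaps caused by plaque, noise or
turbulence near bifurcations.  Three exhaustive local searches compensate:

* **type 1** — a track that ends abruptly (vesselness and radius were still
  healthy) probes a forward cone for the vessel's continuation and splices
  the two pieces across the gap;
* **type 2** — bright blobs just outside the tracked lumen that clustering
  missed are probed for detached daughter branches;
* **type 3** — a Poisson model of the first left-main bifurcation distance
  flags a track that has gone suspiciously far without branching and
  re-runs the type-2 search proximally with relaxed thresholds.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import poisson as _poisson

from .branch_detect import Seed
from .vesselness import vesselness_at
from .volume_io import Volume


@dataclass
class ActiveSearchConfig:
    """Geometry of the exhaustive neighborhood search.

    ``t_th`` is the maximum search distance from the query point (mm);
    ``t_theta_deg`` the half-angle of the forward cone around the current
    tracking direction; ``grid_step`` the spacing of the equally spaced
    probe points; ``merge_distance`` collapses surviving probes closer than
    this to one seed.  ``intensity_sigma`` is how many noise-sigmas below
    the local foreground estimate a probe may be and still pass.
    """

    t_th: float = 6.0
    t_theta_deg: float = 60.0
    grid_step: float = 0.5
    merge_distance: float = 1.0
    intensity_sigma: float = 1.0
    min_probe_distance: float = 1.0

    def __post_init__(self) -> None:
        if self.t_th <= 0:
            raise ValueError("t_th must be > 0")
        if not (0 < self.t_theta_deg <= 90):
            raise ValueError("t_theta_deg must be in (0, 90]")


# ---------------------------------------------------------------------- #
# Poisson branch-occurrence model (type 3)
# ---------------------------------------------------------------------- #
@dataclass
class PoissonBranchModel:
    """Discrete model of the first-branch distance from the ostium (mm)."""

    lam: float
    trained_distances: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


def fit_poisson(distances) -> PoissonBranchModel:
    """Maximum-likelihood Poisson fit: lambda = arithmetic mean of distances."""
    distances = [float(d) for d in distances]
    if not distances:
        raise ValueError("need at least one training distance")
    if min(distances) <= 0:
        raise ValueError("distances must be > 0")
    return PoissonBranchModel(lam=float(np.mean(distances)),
                              trained_distances=distances)


def training_distances() -> list[float]:
    """The packaged expert-annotated first-branch distances (mm)."""
    text = (importlib.resources.files("corotrack") / "data"
            / "lm_first_branch_mm.txt").read_text()
    return [float(line) for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def default_branch_model() -> PoissonBranchModel:
    """Poisson model fitted to the packaged training distances."""
    return fit_poisson(training_distances())


def poisson_pmf(model: PoissonBranchModel, x: int) -> float:
    """P(x) = exp(-lambda) lambda^x / x! for integer mm-bin x >= 0."""
    if x < 0 or int(x) != x:
        raise ValueError("x must be a nonnegative integer")
    return float(_poisson.pmf(int(x), model.lam))


def poisson_quantile(model: PoissonBranchModel, p: float = 0.9) -> int:
    """Smallest integer x with CDF(x) >= p."""
    return int(_poisson.ppf(p, model.lam))


class Type3Action(enum.Enum):
    OK = "ok"
    TRIGGER_SEARCH = "trigger_search"


def type3_monitor(arc_length_mm: float, branches_found: int,
                  model: PoissonBranchModel, p: float = 0.9) -> Type3Action:
    """Flag a left-main track that passed the upper p-quantile unbranched.

    Inert once any branch has been recorded.
    """
    if branches_found > 0:
        return Type3Action.OK
    if arc_length_mm > poisson_quantile(model, p):
        return Type3Action.TRIGGER_SEARCH
    return Type3Action.OK


# ---------------------------------------------------------------------- #
# neighborhood probing (shared by types 1 and 2)
# ---------------------------------------------------------------------- #
def search_region(vol: Volume, x_i, x_prev, config: ActiveSearchConfig,
                  fg_estimate: float, noise_sigma: float,
                  intensity_sigma: float | None = None) -> list[Seed]:
    """Probe the forward cone around ``x_i`` for vessel-like points.

    Enumerates grid points ``s`` anchored at ``x_i`` with
    ``dist(s, x_i) <= T_th`` and ``angle(s - x_i, x_i - x_prev) <=
    T_theta``; keeps points whose intensity is at least the local
    foreground estimate minus ``intensity_sigma`` noise-sigmas and whose
    planar vesselness along ``s - x_i`` is positive; merges survivors
    closer than ``merge_distance`` (nearest to ``x_i`` wins).  Returned
    seeds carry provenance ``active_search``.
    """
    x_i = np.asarray(x_i, dtype=np.float64)
    x_prev = np.asarray(x_prev, dtype=np.float64)
    axis = x_i - x_prev
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("x_i and x_prev coincide")
    axis /= nrm
    if intensity_sigma is None:
        intensity_sigma = config.intensity_sigma

    g = config.grid_step
    n = int(np.floor(config.t_th / g))
    offs = np.arange(-n, n + 1) * g
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    rel = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    dist = np.linalg.norm(rel, axis=1)
    keep = (dist <= config.t_th) & (dist >= config.min_probe_distance)
    rel, dist = rel[keep], dist[keep]
    cosang = (rel @ axis) / dist
    keep = cosang >= np.cos(np.deg2rad(config.t_theta_deg))
    rel, dist = rel[keep], dist[keep]
    pts = x_i[None, :] + rel

    inb = np.array([vol.contains(p) for p in pts])
    pts, dist = pts[inb], dist[inb]
    if len(pts) == 0:
        return []
    vals = vol.sample_trilinear(pts)
    ok = vals >= fg_estimate - intensity_sigma * noise_sigma
    pts, dist = pts[ok], dist[ok]

    order = np.argsort(dist, kind="stable")
    seeds: list[Seed] = []
    accepted: list[np.ndarray] = []
    for i in order:
        p = pts[i]
        if any(np.linalg.norm(p - q) < config.merge_distance for q in accepted):
            continue
        d = (p - x_i) / np.linalg.norm(p - x_i)
        if vesselness_at(vol, p, d, radius=1.0) <= 0.0:
            continue
        accepted.append(p)
        seeds.append(Seed(position=p, direction=d, provenance="active_search"))
    return seeds


# ---------------------------------------------------------------------- #
# type 1: bridge a locally disconnected vessel
# ---------------------------------------------------------------------- #
def _is_abrupt(cl, config) -> bool:
    """A termination is abrupt when vesselness and radius were still healthy."""
    if len(cl.vesselness) < 5:
        return False
    tail_v = float(np.mean(cl.vesselness[-5:]))
    med_r = float(np.median(cl.radii))
    return (tail_v >= 3.0 * max(cl.termination_threshold, 1e-9)
            and cl.states[-1].r >= 0.5 * med_r)


def type1_bridge(vol: Volume, centerline, search_cfg: ActiveSearchConfig,
                 tracker_cfg, mask=None, avoid_points=None, avoid_radii=None):
    """Extend an abruptly terminated centerline across an intensity gap.

    Probes the forward cone from the terminus; if a vessel-like point is
    found, tracks onward from the nearest such seed and splices the pieces
    with straight interpolated states (flagged ``bridged``) at the step
    spacing.  Returns the input unchanged when the termination was not
    abrupt, nothing was found, or the continuation track failed.
    """
    from .tracker import Termination, track  # local import: no module cycle

    cl = centerline
    if cl.termination is not Termination.LOW_VESSELNESS or len(cl.states) < 2:
        return cl
    if not _is_abrupt(cl, tracker_cfg):
        return cl

    terminus = cl.states[-1]
    prev = cl.states[-2]
    sigma_est = float(np.std(vol.data[vol.data < np.median(vol.data)
                                      + 1e-9])) or 1.0
    seeds = search_region(vol, terminus.x, prev.x, search_cfg,
                          fg_estimate=terminus.f, noise_sigma=sigma_est)
    if not seeds:
        return cl
    best = seeds[0]   # search_region orders survivors nearest-first

    cont = track(vol, best, tracker_cfg, mask=mask,
                 avoid_points=avoid_points, avoid_radii=avoid_radii)
    if len(cont.states) < 5:
        return cl

    # straight interpolated gap states between terminus and continuation
    s = tracker_cfg.model.step
    start, end = terminus.x, cont.states[0].x
    gap_vec = end - start
    gap_len = float(np.linalg.norm(gap_vec))
    n_mid = max(0, int(np.floor(gap_len / s)) - 0)
    from .vessel_model import VesselState
    bridge_states = []
    for k in range(1, n_mid + 1):
        t = k * s / gap_len
        if t >= 1.0 - 1e-9:
            break
        bridge_states.append(VesselState(
            x=start + t * gap_vec,
            r=(1 - t) * terminus.r + t * cont.states[0].r,
            f=(1 - t) * terminus.f + t * cont.states[0].f,
            b=(1 - t) * terminus.b + t * cont.states[0].b))

    cl.states.extend(bridge_states)
    cl.bridged.extend([True] * len(bridge_states))
    cl.vesselness.extend([cl.termination_threshold] * len(bridge_states))
    offset = len(cl.states)
    cl.states.extend(cont.states)
    cl.bridged.extend(cont.bridged)
    cl.vesselness.extend(cont.vesselness)
    for ev in cont.events:
        ev.parent_step += offset
        cl.events.append(ev)
    cl.termination = cont.termination
    cl.termination_threshold = cont.termination_threshold
    return cl


# ---------------------------------------------------------------------- #
# type 2: detached-branch search from local intensity
# ---------------------------------------------------------------------- #
def type2_branch_search(vol: Volume, centerline, events,
                        search_cfg: ActiveSearchConfig,
                        tracked_points, tracked_radii, config=None,
                        max_arc: float | None = None,
                        relax_sigma: float | None = None,
                        min_blob_voxels: int = 5) -> list[Seed]:
    """Probe bright off-lumen blobs along a tracked centerline for branches.

    At each state without a nearby branch event, voxels above the local
    foreground threshold in the shell ``r_i .. 3 r_i`` (lumen removed) are
    26-connected-labelled; a sufficiently large blob triggers
    :func:`search_region` with the cone relaxed to 90 degrees.  Seeds within
    2 local radii of any tracked center are dropped (false positives are
    deleted later, at tree assembly).
    """
    if len(centerline.states) < 3:
        return []
    pts = centerline.points
    radii = centerline.radii
    arcs = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    med = float(np.median(vol.data))
    sigma_est = 1.4826 * float(np.median(np.abs(vol.data - med))) or 1.0
    isig = relax_sigma if relax_sigma is not None else search_cfg.intensity_sigma

    wide = ActiveSearchConfig(
        t_th=search_cfg.t_th, t_theta_deg=90.0,
        grid_step=search_cfg.grid_step,
        merge_distance=search_cfg.merge_distance,
        intensity_sigma=isig,
        min_probe_distance=search_cfg.min_probe_distance)

    out: list[Seed] = []
    spacing = vol.spacing
    for i in range(1, len(pts) - 1):
        if max_arc is not None and arcs[i] > max_arc:
            break
        x_i, r_i = pts[i], float(radii[i])
        if any(np.linalg.norm(np.asarray(e.point) - x_i) < 2.0 for e in events):
            continue
        # crop a box of half-width 3 r_i and look for off-lumen bright voxels
        lo = np.maximum(np.floor(vol.world_to_voxel(x_i - 3 * r_i)).astype(int), 0)
        hi = np.minimum(np.ceil(vol.world_to_voxel(x_i + 3 * r_i)).astype(int),
                        np.array(vol.shape) - 1)
        if np.any(lo >= hi):
            continue
        sub = vol.data[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        gi, gj, gk = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)],
                                 indexing="ij")
        world = np.stack([gi * spacing[0] + vol.origin[0],
                          gj * spacing[1] + vol.origin[1],
                          gk * spacing[2] + vol.origin[2]], axis=-1)
        d_center = np.linalg.norm(world - x_i, axis=-1)
        thr = centerline.states[i].f - isig * sigma_est
        bright = (sub >= thr) & (d_center <= 3 * r_i)
        # remove the current lumen: voxels within r of the local centerline
        j0, j1 = max(0, i - 6), min(len(pts), i + 7)
        for j in range(j0, j1):
            bright &= np.linalg.norm(world - pts[j], axis=-1) > radii[j]
        if not bright.any():
            continue
        labels, n_lab = ndimage.label(bright, structure=np.ones((3, 3, 3), int))
        sizes = ndimage.sum_labels(np.ones_like(sub), labels,
                                   index=np.arange(1, n_lab + 1))
        if not np.any(sizes >= min_blob_voxels):
            continue
        for sd in search_region(vol, x_i, pts[i - 1], wide,
                                fg_estimate=centerline.states[i].f,
                                noise_sigma=sigma_est,
                                intensity_sigma=isig):
            if _too_close(sd.position, tracked_points, tracked_radii):
                continue
            if any(np.linalg.norm(sd.position - o.position) <
                   search_cfg.merge_distance for o in out):
                continue
            out.append(sd)
    # strongest vessel evidence first: a clean in-lumen seed must be tracked
    # before a marginal junction-wedge seed can occupy the same territory
    out.sort(key=lambda s: (-vesselness_at(vol, s.position, s.direction, 1.0),
                            tuple(np.round(s.position, 9))))
    return out


def _too_close(x, pts, radii, factor: float = 2.0) -> bool:
    if len(pts) == 0:
        return False
    d = np.linalg.norm(pts - np.asarray(x)[None, :], axis=1)
    return bool(np.any(d < factor * radii))
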