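"""Bifurcation detection from clustering of high-posterior hemisphere candidates.

At each tracking step the candidate points on the forward hemisphere carry a
posterior cost.  Near a bifurcation the low-cost candidates split into (at
least) two spatially separated groups — one down the parent, one down each
daughter.  Detection selects the best-quantile candidates, groups them by
single linkage, and emits one branch event per significant non-principal
cluster whose centroid is far enough from the principal one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


class BranchSource(enum.Enum):
    CLUSTERING = "clustering"
    ACTIVE_SEARCH_TYPE2 = "active_search_type2"
    ACTIVE_SEARCH_TYPE3 = "active_search_type3"


@dataclass
class BranchEvent:
    """A detected bifurcation: where it is and where the daughter goes."""

    parent_step: int
    point: np.ndarray          # world mm
    direction: np.ndarray      # unit vector toward the daughter
    separation: float          # inter-cluster centroid distance, mm
    source: BranchSource = BranchSource.CLUSTERING

    def to_json_dict(self) -> dict:
        return {"parent_step": int(self.parent_step),
                "point": [float(v) for v in self.point],
                "direction": [float(v) for v in self.direction],
                "separation": float(self.separation),
                "source": self.source.value}


@dataclass
class BranchConfig:
    """Knobs of the clustering detector (none are printed in the literature).

    ``quantile``: fraction of candidates (by best posterior cost) entering
    clustering.  ``link_angle_deg``: single-linkage linking distance is
    ``S * sin(link_angle_deg)``.  ``separation_factor``: minimum centroid
    separation as a multiple of the step S.  ``min_cluster``: minimum
    members for a cluster to count.
    """

    quantile: float = 0.25
    #: candidates costlier than best + window never count as high-posterior
    cost_window: float = 50.0
    link_angle_deg: float = 15.0
    separation_factor: float = 0.7
    min_cluster: int = 3
    #: a daughter within this angle of the forward direction is the parent
    min_angle_deg: float = 25.0
    #: suppress events closer than this (mm) to a previously emitted one
    dedup_distance: float = 2.0


def detect_branch(candidates, step_index: int, current_center, step: float,
                  config: BranchConfig | None = None,
                  forward=None) -> list[BranchEvent]:
    """Detect bifurcations among one step's hemisphere candidates.

    ``candidates`` is a sequence of objects with ``.x`` (world mm) and
    ``.posterior_cost``.  Returns an empty list when fewer than 3 candidates
    are given or no second significant cluster exists; with >= 3 clusters
    (multifurcation) one event per non-principal cluster is emitted.
    """
    if config is None:
        config = BranchConfig()
    if len(candidates) < 3:
        return []
    xs = np.asarray([np.asarray(c.x, dtype=float) for c in candidates])
    costs = np.asarray([float(c.posterior_cost) for c in candidates])

    n_sel = max(config.min_cluster, int(round(config.quantile * len(xs))))
    order = np.argsort(costs, kind="stable")
    sel = order[:n_sel]
    sel = sel[costs[sel] <= costs[order[0]] + config.cost_window]
    if len(sel) < 2 * config.min_cluster:
        return []
    pts = xs[sel]

    link_dist = step * np.sin(np.deg2rad(config.link_angle_deg))
    if len(pts) < 2:
        return []
    labels = fcluster(linkage(pdist(pts), method="single"),
                      t=link_dist, criterion="distance")

    clusters = [np.where(labels == lab)[0] for lab in np.unique(labels)]
    clusters = [idx for idx in clusters if len(idx) >= config.min_cluster]
    if len(clusters) < 2:
        return []

    # principal cluster = the one containing the globally best candidate
    best_local = int(np.argmin(costs[sel]))
    principal = None
    for idx in clusters:
        if best_local in idx:
            principal = idx
            break
    if principal is None:
        # best candidate fell in a too-small cluster; use largest as principal
        principal = max(clusters, key=len)

    current_center = np.asarray(current_center, dtype=float)
    p_centroid = pts[principal].mean(axis=0)
    events: list[BranchEvent] = []
    for idx in clusters:
        if idx is principal:
            continue
        centroid = pts[idx].mean(axis=0)
        sep = float(np.linalg.norm(centroid - p_centroid))
        if sep <= config.separation_factor * step:
            continue
        d = centroid - current_center
        nrm = np.linalg.norm(d)
        if nrm == 0:
            continue
        d = d / nrm
        if forward is not None:
            cosang = float(np.clip(d @ np.asarray(forward), -1.0, 1.0))
            if np.degrees(np.arccos(cosang)) < config.min_angle_deg:
                continue   # collinear with the parent: not a daughter
        events.append(BranchEvent(parent_step=step_index,
                                  point=current_center.copy(),
                                  direction=d,
                                  separation=sep))
    return events


@dataclass
class Seed:
    """A tracking start point: position, optional direction, provenance."""

    position: np.ndarray
    direction: np.ndarray | None = None
    provenance: str = "user"   # user | branch | active_search
    #: index of the parent segment this seed hangs off, if any
    parent_segment: int | None = None
    parent_event: BranchEvent | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=np.float64)
            nrm = np.linalg.norm(d)
            if nrm == 0:
                raise ValueError("seed direction must be nonzero")
            self.direction = d / nrm


def spawn_daughter(event: BranchEvent, step: float) -> Seed:
    """Seed for the daughter vessel: one step along the daughter direction."""
    return Seed(position=np.asarray(event.point) + step * np.asarray(event.direction),
                direction=np.asarray(event.direction),
                provenance="branch",
                parent_event=event)
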