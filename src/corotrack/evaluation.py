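"""Centerline accuracy metrics and the planar-vs-3-D vesselness comparison.

The overlap measures are simplified phantom analogues of the challenge-style
OV / OF / OT / AI scores: a reference point is *covered* when the nearest
candidate point is within the reference radius; OV is the covered fraction,
OF the covered prefix fraction from the reference start, OT the covered
fraction over clinically relevant points (radius above a cutoff), and AI
the mean matched distance over covered points.  They preserve the intent of
the official challenge definitions but are not the official scoring (which
needs annotated clinical correspondence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .volume_io import Volume


@dataclass
class OverlapResult:
    ov: float
    of: float
    ot: float
    ai: float   # mm; 0 when nothing is covered

    def to_json_dict(self) -> dict:
        return {"OV": self.ov, "OF": self.of, "OT": self.ot, "AI": self.ai}


def overlap_metrics(candidate_points, reference_points, reference_radii,
                    clinical_cutoff_radius: float = 0.75) -> OverlapResult:
    """Simplified OV / OF / OT / AI of a candidate against a reference.

    Both polylines need at least 2 points; the reference carries per-point
    radii (mm) used as the coverage tolerance.
    """
    cand = np.atleast_2d(np.asarray(candidate_points, dtype=float))
    ref = np.atleast_2d(np.asarray(reference_points, dtype=float))
    radii = np.asarray(reference_radii, dtype=float)
    if len(cand) < 2 or len(ref) < 2:
        raise ValueError("need at least 2 points in both polylines")
    if len(radii) != len(ref):
        raise ValueError("reference radii must match reference points")

    d, _ = cKDTree(cand).query(ref)
    covered = d <= radii
    ov = float(np.mean(covered))
    # overlap until first error: longest covered prefix
    first_miss = int(np.argmax(~covered)) if not covered.all() else len(ref)
    of = first_miss / len(ref)
    clinical = radii >= clinical_cutoff_radius
    ot = float(np.mean(covered[clinical])) if clinical.any() else 0.0
    ai = float(np.mean(d[covered])) if covered.any() else 0.0
    return OverlapResult(ov=ov, of=of, ot=ot, ai=ai)


# ---------------------------------------------------------------------- #
# reference 3-D multiscale vesselness comparison
# ---------------------------------------------------------------------- #
def frangi_reference_volume(vol: Volume, sigmas_mm=(0.5, 1.0, 1.5)) -> Volume:
    """Multiscale 3-D tube-filter response volume (bright ridges).

    Serves as the independent reference the planar measure is compared to;
    scales are given in mm and converted to voxels of the smallest spacing.
    """
    from skimage.filters import frangi

    sigmas_vox = [s / float(min(vol.spacing)) for s in sigmas_mm]
    resp = frangi(vol.data, sigmas=sigmas_vox, black_ridges=False)
    return Volume(data=resp, spacing=vol.spacing.copy(),
                  origin=vol.origin.copy(), fill_value=0.0)


def compare_vesselness(vol: Volume, points, radii=None,
                       reference: Volume | None = None):
    """Pearson correlation of planar vs reference 3-D vesselness profiles.

    Both measures are evaluated at the same centerline points (>= 10).
    Returns ``(r, planar_profile, reference_profile)``; ``r`` is ``nan``
    when either profile has zero variance (degenerate input, e.g. constant
    volume), which callers should treat as "undefined".
    """
    from .vesselness import vesselness_profile

    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 10:
        raise ValueError("need at least 10 centerline points")
    planar = vesselness_profile(vol, points, radii=radii)
    if reference is None:
        reference = frangi_reference_volume(vol)
    ref_prof = np.asarray(reference.sample_trilinear(points), dtype=float)
    if np.ptp(planar) < 1e-12 or np.ptp(ref_prof) < 1e-12:
        return float("nan"), planar, ref_prof
    r, _ = pearsonr(planar, ref_prof)
    return float(r), planar, ref_prof
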