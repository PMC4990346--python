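"""Stochastic vessel state model and the per-step MAP objective.

The vessel is a hidden autoregressive process over states
``V_i = [x_i, f_i, b_i, r_i]``: the center follows the second-order
constant-velocity recursion ``x_i = 2 x_{i-1} - x_{i-2} + eps_x`` (a straight
line when unforced), the radius is a random walk ``r_i = r_{i-1} + eps_r``,
and the foreground/background mean intensities follow second-order averages
``f_i = (f_{i-1} + f_{i-2})/2 + eps_f`` (likewise for ``b``).  Tracking
minimises, per step, the sum of squared residuals of these recursions scaled
by their noise parameters, plus an additive contrast reward favouring
candidates whose local foreground mean clearly exceeds the background mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume, default_shell_outer


@dataclass
class VesselState:
    """One tracking step: lumen center, radius and local intensity means."""

    x: np.ndarray          # world mm
    r: float               # mm
    f: float               # foreground mean intensity (sphere of radius r)
    b: float               # background mean intensity (shell outside r)
    posterior_cost: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.r <= 0:
            raise ValueError("radius must be > 0")
        if not (np.isfinite(self.f) and np.isfinite(self.b)):
            raise ValueError("intensity means must be finite")


@dataclass
class ModelParams:
    """Noise scales of the state recursions and the step geometry.

    The squared residuals are divided by the raw ``sigma`` values (treated
    as variance-scale tuning constants).  ``step`` is the inter-state
    spacing S in mm — also the radius of the candidate hemisphere.
    ``contrast_weight`` scales the additive reward ``-w (f - b)``; the
    reward is clipped below at ``contrast_floor`` so a single very bright
    candidate cannot dominate the geometric prior.
    """

    sigma_x: float = 0.5       # mm
    sigma_r: float = 0.2       # mm
    sigma_f: float = 400.0     # intensity^2-scale
    sigma_b: float = 400.0
    step: float = 1.0          # mm
    contrast_weight: float = 1.0 / 300.0
    contrast_floor: float = -3.0

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_r, self.sigma_f, self.sigma_b) <= 0:
            raise ValueError("all sigma values must be > 0")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.contrast_weight < 0:
            raise ValueError("contrast_weight must be >= 0")


def predict_center(prev2, prev1) -> np.ndarray:
    """Unforced center prediction ``2 x_{i-1} - x_{i-2}`` (straight line)."""
    prev2 = np.asarray(prev2, dtype=np.float64)
    prev1 = np.asarray(prev1, dtype=np.float64)
    if np.allclose(prev1, prev2):
        raise ValueError("coincident previous centers: direction undefined")
    return 2.0 * prev1 - prev2


def predict_scalars(prev2: VesselState, prev1: VesselState):
    """Predicted (f, b, r): second-order means for f, b; random walk for r."""
    return ((prev1.f + prev2.f) / 2.0,
            (prev1.b + prev2.b) / 2.0,
            prev1.r)


def step_cost(cand: VesselState, prev1: VesselState, prev2: VesselState,
              params: ModelParams) -> float:
    """Penalised residual of one tracking step (lower is better).

    Sum of the three quadratic recursion residuals (center, foreground,
    background), each divided by its sigma, plus the clipped contrast
    reward ``max(-w (f - b), floor)``.  Exactly zero for a candidate on the
    straight-line prediction with matching scalars and ``contrast_weight=0``.
    """
    x_pred = predict_center(prev2.x, prev1.x)
    f_pred, b_pred, _ = predict_scalars(prev2, prev1)
    geo = float(np.sum((cand.x - x_pred) ** 2)) / params.sigma_x
    fg = (cand.f - f_pred) ** 2 / params.sigma_f
    bg = (cand.b - b_pred) ** 2 / params.sigma_b
    contrast = max(-params.contrast_weight * (cand.f - cand.b),
                   params.contrast_floor)
    return geo + fg + bg + contrast


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis perpendicular to ``direction``.

    ``u = normalize(direction x e)`` with ``e`` the canonical axis least
    parallel to ``direction``; ``w = direction x u``.
    """
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(d)))] = 1.0
    u = np.cross(d, e)
    u /= np.linalg.norm(u)
    w = np.cross(d, u)
    return u, w


def _disc_points(c, u, w, radii, n_angles: int = 12) -> np.ndarray:
    """Deterministic polar sampling points on the plane spanned by (u, w)."""
    pts = [np.asarray(c, dtype=np.float64)]
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    for rad in radii:
        for a in angles:
            pts.append(c + rad * (np.cos(a) * u + np.sin(a) * w))
    return np.asarray(pts)


def fit_radius(vol: Volume, c, direction, r_prev: float,
               params: ModelParams) -> float:
    """Radius maximising in-plane disc-vs-annulus contrast near ``r_prev``.

    Scans radii on a 0.1 mm grid in ``[max(0.3, 0.5 r_prev), 2 r_prev]``;
    the contrast of each candidate radius is penalised by
    ``(r - r_prev)^2 / sigma_r``.  A flat contrast profile (degenerate,
    e.g. constant volume) returns ``r_prev`` unchanged.
    """
    if r_prev <= 0:
        raise ValueError("r_prev must be > 0")
    u, w = _plane_basis(direction)
    c = np.asarray(c, dtype=np.float64)
    lo = max(0.3, 0.5 * r_prev)
    hi = max(lo + 0.1, 2.0 * r_prev)
    candidates = np.arange(lo, hi + 1e-9, 0.1)
    ds = float(min(vol.spacing)) / 2.0

    best_r, best_score = r_prev, -np.inf
    contrasts = []
    for r in candidates:
        disc_r = np.arange(ds, r, ds)
        disc = vol.sample_trilinear(_disc_points(c, u, w, disc_r))
        ann_out = r + max(float(np.linalg.norm(vol.spacing)), 0.5 * r)
        ann_r = np.arange(r + ds / 2, ann_out, ds)
        if len(ann_r) == 0:
            ann_r = np.array([r + ds])
        annulus = vol.sample_trilinear(_disc_points(c, u, w, ann_r)[1:])
        contrast = float(disc.mean() - annulus.mean())
        contrasts.append(contrast)
        score = contrast - (r - r_prev) ** 2 / params.sigma_r
        if score > best_score + 1e-12:
            best_score, best_r = score, float(r)
    if np.ptp(contrasts) < 1e-6:  # flat contrast: no information
        return float(r_prev)
    return best_r
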