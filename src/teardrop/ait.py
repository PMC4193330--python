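"""Model AIT: teardrop cells and the closure-based feedback signal.

A teardrop cell groups convex cells whose RF sizes increase linearly along
one of eight integration directions, at equally spaced positions: the cell's
own position holds the largest convex RF of the ramp and progressively
smaller RFs lie at equally spaced offsets along the opposite direction —
the geometry of a medial-axis segment running into a corner or a tapering
end of a figure.  Ramps of every top scale (2..7) are evaluated and the
best-matching ramp determines the cell's drive, so figures much smaller
than the largest RF still drive teardrop cells through short ramps.

Teardrop cells with different integration directions at one position share
the offset-0 (largest-RF) input.  Agreement across directions is the
model's evidence for boundary closure: where many directions are active the
position is likely on the medial axis of a closed figure and feedback to
convex cells is excitatory; where few are active, feedback is inhibitory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .v4 import DIRECTIONS, RADII


@dataclass(frozen=True)
class TeardropGeometry:
    """Sampling geometry of the teardrop ramps.

    ``spacing`` is the distance between consecutive samples:
    ``lam * (r_max - r_min) / (K - 1)`` with the default ``lam = 1.5``
    approximating the corner-bisector relation between medial-axis position
    and inscribed-circle radius.  ``min_top_scale`` is the smallest ramp
    length considered (a one-sample "ramp" carries no closure evidence).
    """

    radii: tuple[float, ...] = RADII
    lam: float = 1.5
    min_top_scale: int = 2
    blur_sigma: float = 1.5
    scale_leak: float = 0.25
    sample_half: float = 0.2
    floor_activity: float = 0.02
    threshold: float = 0.25

    @property
    def n_scales(self) -> int:
        return len(self.radii)

    @property
    def spacing(self) -> float:
        return self.lam * (self.radii[-1] - self.radii[0]) / (self.n_scales - 1)

    def offsets(self, top_scale: int) -> list[tuple[int, float]]:
        """(scale index, offset along -direction) pairs of one ramp."""
        return [(j, self.spacing * (top_scale - 1 - j))
                for j in range(top_scale - 1, -1, -1)]


def _shift_stack(stack: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Bilinear shift of an (S, H, W) stack by a subpixel offset, zero fill.

    Implemented with integer rolls and bilinear weights so that shifting by
    a 90-degree-rotated offset is exactly the rotation of the shifted map —
    the property the rotation-equivariance of the teardrop layer rests on.
    """
    y0, x0 = int(np.floor(dy)), int(np.floor(dx))
    ay, ax = dy - y0, dx - x0
    out = np.zeros_like(stack)
    for (iy, ix, w) in ((y0, x0, (1 - ay) * (1 - ax)),
                        (y0 + 1, x0, ay * (1 - ax)),
                        (y0, x0 + 1, (1 - ay) * ax),
                        (y0 + 1, x0 + 1, ay * ax)):
        if w == 0.0:
            continue
        src_y = slice(max(0, -iy), min(stack.shape[1], stack.shape[1] - iy))
        dst_y = slice(max(0, iy), min(stack.shape[1], stack.shape[1] + iy))
        src_x = slice(max(0, -ix), min(stack.shape[2], stack.shape[2] - ix))
        dst_x = slice(max(0, ix), min(stack.shape[2], stack.shape[2] + ix))
        out[:, dst_y, dst_x] += w * stack[:, src_y, src_x]
    return out


@dataclass(frozen=True)
class TeardropField:
    """Teardrop-cell activity: (H, W, 8 directions), nonnegative."""

    activity: np.ndarray

    def __post_init__(self) -> None:
        if self.activity.ndim != 3 or self.activity.shape[2] != len(DIRECTIONS):
            raise ValueError("activity must be (H, W, 8)")


def teardrop_drive(convex: np.ndarray,
                   geom: TeardropGeometry = TeardropGeometry(),
                   return_top_scale: bool = False):
    """Per-(position, direction) teardrop drive from the convex field.

    For direction d and top scale ``tau`` the ramp response at p is the mean
    of (jitter-blurred, saturated) convex activity of scales ``tau, tau-1,
    .., 1`` sampled at offsets ``0, spacing, 2*spacing, ..`` along ``-d``;
    sample positions outside the canvas are dropped and the mean
    renormalized by the in-grid count.  Each sample is passed through the
    saturating transform ``v / (v + sample_half)`` before averaging, so a
    ramp scores highly only when *most* of its ordered samples are active
    — one strongly active convex cell cannot carry a ramp on its own.  The
    drive is the best ramp over ``tau``, rectified against the geometry
    threshold.  All directions at p share the offset-0 sample, which holds
    the largest RF of the ramp.
    """
    h, w, n_scales = convex.shape
    # contrast normalization: teardrop cells judge the spatial *pattern* of
    # convex activity, not its absolute level, so the field is referred to
    # its own maximum before sampling.  This keeps closure judgments stable
    # while recurrent feedback rescales the convex layer.
    peak = float(convex.max())
    normed = convex / peak if peak > 1e-6 else convex
    # RF jitter: small spatial blur plus leak between neighbouring scales
    sm = np.stack([gaussian_filter(normed[:, :, s], geom.blur_sigma)
                   for s in range(n_scales)])
    if geom.scale_leak > 0:
        leak = np.zeros_like(sm)
        leak[1:] += sm[:-1]
        leak[:-1] += sm[1:]
        sm = sm + geom.scale_leak * leak
    sm = sm / (sm + geom.sample_half)   # saturating per-sample agreement
    # geometric-mean scoring: a ramp is a conjunction of its samples, so
    # the log-domain mean makes one missing sample cost a multiplicative
    # penalty instead of an additive one
    log_sm = np.log(np.maximum(sm, geom.floor_activity))
    ones = np.ones((1, h, w))

    n_dirs = len(DIRECTIONS)
    out = np.zeros((h, w, n_dirs))
    top_scale = np.zeros((h, w), dtype=np.int64)
    for d, (uy, ux) in enumerate(DIRECTIONS):
        # cumulative shifts: shifted[m] = log_sm displaced by m*spacing
        # along -d; samples outside the canvas are dropped and the mean
        # renormalized over the in-grid count (with a floor of two samples)
        z, o = log_sm, ones
        shifted = [z]
        counts = [o[0]]
        for _m in range(1, n_scales):
            # _shift_stack moves content by (+dy, +dx), so shifting by
            # +spacing*u makes shifted[m](p) = field(p - m*spacing*u):
            # the sample m steps along -d, per the ramp convention
            z = _shift_stack(z, geom.spacing * uy, geom.spacing * ux)
            o = _shift_stack(o, geom.spacing * uy, geom.spacing * ux)
            shifted.append(z)
            counts.append(o[0])
        best = np.zeros((h, w))
        best_tau = np.zeros((h, w), dtype=np.int64)
        for tau in range(geom.min_top_scale, n_scales + 1):
            num = np.zeros((h, w))
            den = np.zeros((h, w))
            for m in range(tau):
                cnt = np.clip(counts[m], 0.0, 1.0)
                num += shifted[m][tau - 1 - m] * cnt
                den += cnt
            ramp = np.exp(num / np.maximum(den, min(2.0, tau)))
            improved = ramp > best
            best_tau[improved] = tau
            np.maximum(best, ramp, out=best)
        active = best > geom.threshold
        out[:, :, d] = np.maximum(best - geom.threshold, 0.0)
        np.maximum(top_scale, np.where(active, best_tau, 0), out=top_scale)
    if return_top_scale:
        return out, top_scale
    return out


def sigmoid_agreement(t: np.ndarray, half: float, power: float = 4.0) -> np.ndarray:
    """Steep saturating signal function g(y) = y^p / (y^p + half^p).

    The high-order Hill form is close to a soft step at ``half``: a
    direction counts toward closure only once its teardrop cell is
    decisively active, so many weakly active directions cannot masquerade
    as closure.
    """
    tp = t ** power
    return tp / (tp + half ** power)


def teardrop_feedback(teardrop: np.ndarray,
                      geom: TeardropGeometry = TeardropGeometry(),
                      g_half: float = 0.3,
                      theta_f: float = 1.9,
                      g_pow: float = 4.0) -> np.ndarray:
    """Signed closure feedback F(p) from the eight directions at p.

    ``F = sum_d g(T_d) - theta_f`` with g saturating: positive where
    sufficiently many integration directions agree (closure evidence →
    excitatory feedback to convex cells), negative where few do
    (inhibitory feedback), and ``-theta_f`` where no teardrop cell is
    active.  The default threshold makes four moderately active directions
    (g around 0.5) the tipping point between suppression and enhancement.
    """
    g = sigmoid_agreement(teardrop, g_half, g_pow)
    return g.sum(axis=-1) - theta_f


def size_invariance_probe(scales=(0.7, 1.0, 1.3), base_side: int = 21,
                          lesion=None, params=None) -> dict[float, float]:
    """Max teardrop activity for a square figure at several sizes.

    Runs the full model on squares of side ``round(base_side * sigma)`` and
    returns {sigma: the largest teardrop activity reached during the run}.
    The closure-detection peak is the meaningful teardrop response: at
    equilibrium the suppressive feedback the teardrops themselves trigger
    may erode the convex evidence that fed them.  Figures whose half-width
    exceeds the largest annulus radius are excluded (the model has no RF
    large enough to span them, so response collapse is expected).
    """
    from .dynamics import LesionConfig, SimParams, run
    from .stimuli import CANVAS, _centered_rect, _display_from_mask

    params = params or SimParams()
    lesion = lesion or LesionConfig()
    out: dict[float, float] = {}
    for sig in scales:
        side = int(round(base_side * sig))
        if side / 2 > max(RADII) or side > CANVAS - 8:
            continue
        disp = _display_from_mask(_centered_rect(CANVAS, side, side),
                                  f"square_{side}")
        traj = run(disp, lesion=lesion, params=params)
        out[sig] = float(traj.teardrop_peak)
    return out
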