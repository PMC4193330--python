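"""Model V4: curved-contour cells.

Each cell is tuned to one of eight 45-degree arcs of a circle at one of
seven radii (scales).  A cell at position p, arc k, scale s matches the
oriented edge energy along the arc of the circle of radius ``radii[s]``
centred at p, requiring the local edge orientation to be near the circle
tangent.  Template mass is normalized to one per (arc, scale) so responses
are comparable across scales, and the match is rectified against a
threshold so a blank edge map yields a zero field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .stimuli import EdgeMap

#: The seven annulus radii (pixels), linearly spaced.  Linear spacing makes
#: the scale ramp sampled by the teardrop geometry equally spaced in space,
#: matching the corner-bisector medial-axis geometry.
RADII = (3.0, 6.5, 10.0, 13.5, 17.0, 20.5, 24.0)

N_ARCS = 8
N_ORIENT = 8

#: Exact unit vectors (dy, dx) for the 8 directions at 45-degree spacing,
#: built from a single sqrt(1/2) constant so that a 90-degree rotation maps
#: direction d exactly onto direction d + 2.
_S = float(np.sqrt(0.5))
DIRECTIONS = (
    (0.0, 1.0), (-_S, _S), (-1.0, 0.0), (-_S, -_S),
    (0.0, -1.0), (_S, -_S), (1.0, 0.0), (_S, _S),
)


@dataclass(frozen=True)
class ArcBank:
    """Per-(arc, scale) oriented convolution kernels.

    ``kernels[(k, s)]`` is an array of shape (K, K, n_orient): channel o of
    the kernel weights edge energy in orientation channel o at each offset.
    Arc k of scale s covers polar angles ``[k*45, (k+1)*45)`` degrees of the
    circle of radius ``radii[s]``; sample points are spaced ~1 px along the
    arc, splatted bilinearly (so kernels are exactly equivariant under
    90-degree rotations), and weighted by a Gaussian orientation-tuning
    profile centred on the local tangent.
    """

    radii: tuple[float, ...] = RADII
    n_arcs: int = N_ARCS
    n_orient: int = N_ORIENT
    orient_tol_deg: float = 22.5
    threshold: float = 0.4
    gain: float = 20.0
    kernels: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_scales(self) -> int:
        return len(self.radii)


#: Radial tolerance (px) of the arc templates: each sample is blurred by an
#: isotropic Gaussian so templates forgive the ~1 px jitter of rasterized
#: boundaries while still separating adjacent radii (3.5 px apart).
RING_SIGMA = 1.2


def _arc_kernel(radius: float, arc: int, n_arcs: int, n_orient: int,
                orient_tol: float, ring_sigma: float = RING_SIGMA) -> np.ndarray:
    """Rasterize one (arc, scale) template into an oriented kernel stack."""
    half = int(np.ceil(radius)) + 4
    size = 2 * half + 1
    kern = np.zeros((size, size, n_orient))
    arc_span = 2.0 * np.pi / n_arcs
    n_samples = max(3, int(round(radius * arc_span)))  # ~1 px spacing
    phis = (arc + (np.arange(n_samples) + 0.5) / n_samples) * arc_span
    chan = np.arange(n_orient) * np.pi / n_orient
    for phi in phis:
        dy = -radius * np.sin(phi)   # image rows grow downward
        dx = radius * np.cos(phi)
        tangent = np.mod(phi + 0.5 * np.pi, np.pi)
        d = np.abs(tangent - chan)
        d = np.minimum(d, np.pi - d)
        w_o = np.exp(-(d / np.deg2rad(orient_tol)) ** 2)
        w_o /= w_o.sum()
        # bilinear splat of the sample point
        fy, fx = dy + half, dx + half
        y0, x0 = int(np.floor(fy)), int(np.floor(fx))
        ay, ax = fy - y0, fx - x0
        for (yy, xx, w) in ((y0, x0, (1 - ay) * (1 - ax)),
                            (y0 + 1, x0, ay * (1 - ax)),
                            (y0, x0 + 1, (1 - ay) * ax),
                            (y0 + 1, x0 + 1, ay * ax)):
            kern[yy, xx, :] += w * w_o
    kern = gaussian_filter(kern, sigma=(ring_sigma, ring_sigma, 0),
                           mode="constant")
    kern /= kern.sum()  # unit template mass per (arc, scale)
    return kern


def build_arc_bank(radii=RADII, n_arcs: int = N_ARCS,
                   orient_tol_deg: float = 22.5,
                   n_orient: int = N_ORIENT,
                   threshold: float = 0.4,
                   gain: float = 20.0,
                   ring_sigma: float = RING_SIGMA) -> ArcBank:
    """Construct the multi-scale arc template bank.

    Radii must be strictly increasing and at least 2 px; the default
    orientation tolerance of 22.5 degrees (half the inter-channel spacing)
    lets corners partially drive the two arcs adjacent to the corner's
    orientations, so piecewise-linear contours are grouped as well as
    smooth arcs.
    """
    radii = tuple(float(r) for r in radii)
    if any(r < 2 for r in radii):
        raise ValueError("all radii must be >= 2 px")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    kernels = {
        (k, s): _arc_kernel(r, k, n_arcs, n_orient, orient_tol_deg, ring_sigma)
        for s, r in enumerate(radii) for k in range(n_arcs)
    }
    return ArcBank(radii=radii, n_arcs=n_arcs, n_orient=n_orient,
                   orient_tol_deg=orient_tol_deg, threshold=threshold,
                   gain=gain, kernels=kernels)


@dataclass(frozen=True)
class CurvedField:
    """Curved-contour cell activity: (H, W, n_arcs, n_scales), nonnegative."""

    activity: np.ndarray

    def __post_init__(self) -> None:
        if self.activity.ndim != 4:
            raise ValueError("activity must be (H, W, n_arcs, n_scales)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.activity.shape


def curved_response(edge_map: EdgeMap, bank: ArcBank) -> CurvedField:
    """Rectified arc-template match of the edge map.

    ``activity[y, x, k, s]`` is the correlation of the oriented edge energy
    with arc template (k, s) centred at (y, x), multiplied by the bank gain,
    minus the bank threshold and rectified at zero.  The gain is fixed so a
    well-matched arc on a rasterized boundary responds near one; a straight
    contour responds less per unit contour length because its orientation
    only partially matches the arc tangents.
    """
    E = edge_map.energy
    if E.shape[2] != bank.n_orient:
        raise ValueError("edge map and bank disagree on orientation channels")
    h, w, _ = E.shape
    out = np.zeros((h, w, bank.n_arcs, bank.n_scales))
    for s in range(bank.n_scales):
        for k in range(bank.n_arcs):
            kern = bank.kernels[(k, s)]
            acc = np.zeros((h, w))
            for o in range(bank.n_orient):
                ko = kern[:, :, o]
                if ko.any():
                    # correlation = convolution with the flipped kernel
                    acc += fftconvolve(E[:, :, o], ko[::-1, ::-1], mode="same")
            out[:, :, k, s] = acc
    out *= bank.gain
    np.maximum(out - bank.threshold, 0.0, out=out)
    return CurvedField(activity=out)
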