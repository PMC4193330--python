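"""Model PIT: convex cells with annular on-surround receptive fields.

A convex cell at position p and scale s pools the eight arc-sector outputs
of the curved-contour cells of scale s centred near p, so it fires when
boundary contours fall on the ring of radius ``radii[s]`` around p — a
point detector for the figure's medial axis.  Three interactions shape the
field:

* an opposing-sector gate that silences cells lacking boundary contours on
  both sides of the RF;
* a coarse-to-fine recurrent circuit in which large-RF cells (which respond
  to the closure of a figure's outer boundary) suppress smaller cells whose
  own boundary input is *not* shared with them — the cancellation that
  spares true medial-axis cells and suppresses cells inside concavities;
* faster-than-linear cross-scale competition among cells sharing an RF
  centre, which sharpens the scale profile toward the best-fitting annulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .v4 import RADII, CurvedField


@dataclass(frozen=True)
class AnnulusParams:
    """Geometry and gating of the convex-cell annuli.

    ``opposing_gate`` is the minimum circular separation, in sectors of 45
    degrees, between two simultaneously active arc sectors required for a
    cell to receive any feedforward drive: the default of 2 demands contours
    at least 90 degrees apart around the ring, so both opposite-wall
    contacts (bars) and perpendicular-wall contacts (corners) pass while a
    contour on one side only does not.  ``gate_threshold`` is the sector
    activity level that counts as "active".  ``jitter_frac`` sets the
    spatial pooling of sector inputs (sigma = max(1, jitter_frac * radius)),
    standing in for RF-centre jitter.
    """

    radii: tuple[float, ...] = RADII
    ring_width: float = 1.5
    opposing_gate: int = 2
    gate_threshold: float = 0.08
    jitter_frac: float = 1 / 6
    jitter_floor: float = 1.0
    cover_half: float = 0.1
    cover_pow: float = 1.5
    jitter_leak: float = 0.0
    jitter_leak_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.ring_width < 1:
            raise ValueError("ring_width must be >= 1")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be strictly increasing")


@dataclass(frozen=True)
class ConvexField:
    """Convex-cell activity: (H, W, n_scales), bounded in [0, B]."""

    activity: np.ndarray
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if self.activity.ndim != 3:
            raise ValueError("activity must be (H, W, n_scales)")


def _radial_kernel(radius: float, width: float, disk: bool) -> np.ndarray:
    half = int(np.ceil(radius + 3 * width))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    rho = np.hypot(yy, xx)
    if disk:
        k = (rho <= radius).astype(float)
    else:
        k = np.exp(-0.5 * ((rho - radius) / width) ** 2)
    return k / k.sum()


@dataclass
class PitKernels:
    """Precomputed normalized ring and disk pooling kernels per scale."""

    params: AnnulusParams = field(default_factory=AnnulusParams)

    def __post_init__(self) -> None:
        w = self.params.ring_width
        self.rings = [_radial_kernel(r, w, disk=False) for r in self.params.radii]
        self.disks = [_radial_kernel(r, w, disk=True) for r in self.params.radii]

    def ringpool(self, img: np.ndarray, s: int) -> np.ndarray:
        """Mean of ``img`` over the ring of scale s around each pixel."""
        return fftconvolve(img, self.rings[s], mode="same")

    def diskpool(self, img: np.ndarray, s: int) -> np.ndarray:
        """Mean of ``img`` over the disk of scale s around each pixel."""
        return fftconvolve(img, self.disks[s], mode="same")


def annulus_drive(curved: CurvedField, params: AnnulusParams = AnnulusParams(),
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Feedforward drive to convex cells, with the opposing-sector gate.

    Returns ``(drive, gate)``: ``drive[y, x, s]`` is the mean over the eight
    arc sectors of the (spatially pooled) curved activity of scale s, zeroed
    wherever no two active sectors are at least ``opposing_gate`` sectors
    apart around the ring; ``gate`` is the boolean gate itself.  Cells
    without boundary contours on more than one side of the RF therefore
    receive no drive.
    """
    act = curved.activity
    h, w, n_arcs, n_scales = act.shape
    half = n_arcs // 2
    drive = np.zeros((h, w, n_scales))
    gate = np.zeros((h, w, n_scales), bool)
    for s in range(n_scales):
        sigma = max(params.jitter_floor, params.jitter_frac * params.radii[s])
        sectors = np.stack(
            [gaussian_filter(act[:, :, k, s], sigma) for k in range(n_arcs)],
            axis=-1)
        active = sectors > params.gate_threshold
        g = np.zeros((h, w), bool)
        for sep in range(params.opposing_gate, half + 1):
            for k in range(n_arcs):
                g |= active[..., k] & active[..., (k + sep) % n_arcs]
        gate[:, :, s] = g
        # closure sensitivity: the drive grows supra-linearly with the
        # fraction of the ring contacted by contours, so a fully enclosed
        # cell (boundary all around the annulus) responds far more strongly
        # than one touching a contour on two sides only
        coverage = (sectors / (sectors + params.cover_half)).mean(axis=-1)
        drive[:, :, s] = g * sectors.mean(axis=-1) * coverage ** params.cover_pow
        if params.jitter_leak > 0:
            # RF-centre jitter: a fraction of each cell's drive leaks to
            # nearby cells whose own (idealized) annulus misses the contour,
            # emulating the scatter of RF centres within a cortical column
            drive[:, :, s] = ((1 - params.jitter_leak) * drive[:, :, s]
                              + params.jitter_leak * gaussian_filter(
                                  drive[:, :, s], params.jitter_leak_sigma))
    return drive, gate


def convex_recurrent_inhibition(
    convex: np.ndarray,
    edge_total: np.ndarray,
    kernels: PitKernels,
    kappa: float = 1.0,
    edge_ring: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Coarse-to-fine inhibition with shared-boundary cancellation.

    For a target cell (p, s) the inhibitory interneuron collects the pooled
    activity of every larger-scale cell whose annulus covers p, minus
    ``kappa`` times the cell's *supported* boundary input — the fraction of
    edge energy on its own ring that also lies on the rings of active
    larger-scale cells.  When the small cell and the large cells see the
    same contours the two terms cancel (medial-axis case); when the large
    cells respond to a closed outer boundary the small cell does not see
    (concavity case) the inhibition survives rectification.

    Parameters
    ----------
    convex:
        Current convex activity, (H, W, S).
    edge_total:
        Per-pixel total edge energy of the display (static).
    edge_ring:
        Optional precomputed ``ringpool(edge_total, s)`` per scale.
    """
    h, w, n_scales = convex.shape
    ring_x = [kernels.ringpool(convex[:, :, s], s) for s in range(n_scales)]
    if edge_ring is None:
        edge_ring = [kernels.ringpool(edge_total, s) for s in range(n_scales)]
    inhib = np.zeros_like(convex)
    cov = np.zeros((h, w))
    c1pool = np.zeros((h, w))
    # accumulate from coarsest scale downward: scale s sees only s' > s
    for s in range(n_scales - 2, -1, -1):
        cov += ring_x[s + 1]
        c1pool += kernels.diskpool(convex[:, :, s + 1], s + 1)
        supported = kernels.ringpool(edge_total * cov, s)
        support_frac = supported / (edge_ring[s] + 1e-9)
        inhib[:, :, s] = np.maximum(c1pool - kappa * support_frac, 0.0)
    return inhib


def cross_scale_competition(convex: np.ndarray) -> np.ndarray:
    """Quadratic cross-scale inhibition among cells sharing an RF centre.

    Scale s receives the summed squared activity of all other scales at the
    same position; the faster-than-linear signal function makes the
    recurrent competition contrast-enhancing, so a non-uniform scale
    profile sharpens toward its winner while a uniform profile is left
    unchanged by symmetry.
    """
    sq = convex ** 2
    return sq.sum(axis=-1, keepdims=True) - sq
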