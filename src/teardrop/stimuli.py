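"""Parametric visual displays, edge maps, and ground-truth masks.

Every simulation input used by the model is generated here: filled
rectangles, C-shapes (a rectangle with one rectangular concavity), crosses,
2x2 square-texture arrays, randomly grown block figures, and a fixed set of
named exemplar figures (square, C-shape, cross, texture, thin bar, crescent,
triangle, and a texture-defined square paired with its background-only
control).  Each display carries the raster image, a boolean figure mask, the
figure's inner boundary, and the ground-truth medial axis (skeleton) used by
the figure-ground indices.

Displays are deterministic functions of their parameters (and a seed, for
the random block generator): regenerating a display reproduces all masks
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import medial_axis as _skimage_medial_axis

#: Default canvas edge length in pixels.  Figures are sized relative to the
#: seven annulus radii (see :mod:`teardrop.v4`), whose largest default radius
#: is 24 px, so a 64 px canvas leaves room for the largest receptive field.
CANVAS = 64


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisualDisplay:
    """A raster figure-on-background display with ground-truth masks.

    Attributes
    ----------
    image:
        2-D float array in [0, 1]; figure pixels are 1 on a 0 background
        (texture displays additionally draw oriented strokes for rendering).
    figure_mask:
        Boolean array, True on the figure interior including its boundary.
    boundary_mask:
        Inner one-pixel boundary of ``figure_mask``.
    medial_mask:
        Ground-truth skeleton of the figure (subset of ``figure_mask``).
    name:
        Display identifier, e.g. ``"rect_20x11"``.
    params:
        Generator parameters, recorded for provenance.
    seed:
        Seed used by stochastic generators, or ``None``.
    """

    image: np.ndarray
    figure_mask: np.ndarray
    boundary_mask: np.ndarray
    medial_mask: np.ndarray
    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        shp = self.image.shape
        for m in (self.figure_mask, self.boundary_mask, self.medial_mask):
            if m.shape != shp:
                raise ValueError("all masks must share the image shape")
        if not self.figure_mask.any():
            raise ValueError("figure_mask is empty")
        if (self.boundary_mask & ~self.figure_mask).any():
            raise ValueError("boundary_mask must be a subset of figure_mask")
        if (self.medial_mask & ~self.figure_mask).any():
            raise ValueError("medial_mask must be a subset of figure_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass(frozen=True)
class EdgeMap:
    """Orientation-indexed, polarity-insensitive boundary-energy field.

    ``energy[y, x, o]`` is the edge energy at pixel (y, x) in orientation
    channel ``o``; the ``n_orient`` channels span 180 degrees at even
    spacing (channel o prefers orientation ``o * 180 / n_orient`` degrees,
    measured from the +x image axis).  This stands in for the output of V1
    complex cells: it is nonnegative and carries no contrast polarity.
    """

    energy: np.ndarray
    n_orient: int = 8

    def __post_init__(self) -> None:
        if self.energy.ndim != 3 or self.energy.shape[2] != self.n_orient:
            raise ValueError("energy must be (H, W, n_orient)")
        if (self.energy < 0).any():
            raise ValueError("edge energy must be nonnegative")

    @property
    def total(self) -> np.ndarray:
        """Per-pixel energy summed over orientation channels."""
        return self.energy.sum(axis=2)


@dataclass(frozen=True)
class BlockShapeParams:
    """Parameters of the random block-growth figure generator."""

    n_blocks: int = 4
    base_size: int = 12
    block_size_range: tuple[int, int] = (4, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        lo, hi = self.block_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid block_size_range")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_CROSS3 = ndimage.generate_binary_structure(2, 1)   # 4-connectivity
_SQUARE3 = np.ones((3, 3), bool)                    # Chebyshev <= 1


def _inner_boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, structure=_CROSS3)


def _display_from_mask(
    mask: np.ndarray,
    name: str,
    params: dict | None = None,
    seed: int | None = None,
    image: np.ndarray | None = None,
    medial: np.ndarray | None = None,
) -> VisualDisplay:
    if image is None:
        image = mask.astype(float)
    if medial is None:
        medial = compute_medial_axis(mask)
    return VisualDisplay(
        image=image,
        figure_mask=mask,
        boundary_mask=_inner_boundary(mask),
        medial_mask=medial,
        name=name,
        params=dict(params or {}),
        seed=seed,
    )


def _blank(canvas: int) -> np.ndarray:
    return np.zeros((canvas, canvas), bool)


def _centered_rect(canvas: int, h: int, w: int) -> np.ndarray:
    """Axis-aligned h x w rectangle centered on the canvas."""
    mask = _blank(canvas)
    y0 = (canvas - h) // 2
    x0 = (canvas - w) // 2
    if y0 < 0 or x0 < 0:
        raise ValueError(f"{h}x{w} rectangle does not fit a {canvas}px canvas")
    mask[y0:y0 + h, x0:x0 + w] = True
    return mask


# ---------------------------------------------------------------------------
# medial axis and region masks
# ---------------------------------------------------------------------------

def compute_medial_axis(figure_mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide skeleton of a binary figure.

    The skeleton is the ridge of the Euclidean distance transform thinned to
    unit width while preserving topology, i.e. the set of interior points
    whose maximal inscribed disk touches the boundary at two or more points.
    Connected figures yield connected skeletons.
    """
    figure_mask = np.asarray(figure_mask, bool)
    if not figure_mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    # thinning breaks ties in a pseudo-random pixel order; fix the seed so
    # regenerating a display reproduces its skeleton bit-exactly
    return _skimage_medial_axis(figure_mask, rng=0)


def region_masks(display: VisualDisplay, tol: int = 1) -> dict[str, np.ndarray]:
    """Partition the display into the regions used by the indices.

    ``medial_band`` and ``boundary_band`` are the medial axis and boundary
    dilated by ``tol`` pixels (Chebyshev metric, so ``tol=1`` means "within
    one pixel"); ``interior_rest`` is the remainder of the figure interior,
    ``ground`` the complement of the figure, and ``elsewhere`` everything
    outside the boundary band.  The medial band is clipped to the figure:
    where a skeleton branch runs into a corner, its dilation must not claim
    ground pixels as "medial".
    """
    fig = display.figure_mask
    if tol > 0:
        medial_band = ndimage.binary_dilation(
            display.medial_mask, structure=_SQUARE3, iterations=tol) & fig
        boundary_band = ndimage.binary_dilation(
            display.boundary_mask, structure=_SQUARE3, iterations=tol)
    else:
        medial_band = display.medial_mask.copy()
        boundary_band = display.boundary_mask.copy()
    return {
        "figure": fig,
        "ground": ~fig,
        "medial_band": medial_band,
        "interior_rest": fig & ~medial_band,
        "boundary_band": boundary_band,
        "elsewhere": ~boundary_band,
    }


# ---------------------------------------------------------------------------
# edge maps
# ---------------------------------------------------------------------------

def compute_edge_map(display: VisualDisplay, n_orient: int = 8) -> EdgeMap:
    """Oriented, polarity-insensitive boundary-energy map of a display.

    Each boundary pixel carries unit energy, soft-assigned across the
    orientation channels according to the local boundary tangent (estimated
    from the gradient of the smoothed figure mask).  Energy is strictly
    confined to the one-pixel inner boundary of the figure.

    For texture-defined displays the boundary is the orientation-contrast
    outline of the figure, not the individual texture strokes; a display
    whose ``params["figure_present"]`` is False (the background-only control
    of the texture pair) has no orientation contrast and yields zero energy.
    """
    h, w = display.shape
    energy = np.zeros((h, w, n_orient))
    if not display.params.get("figure_present", True):
        return EdgeMap(energy=energy, n_orient=n_orient)

    boundary = display.boundary_mask
    smooth = ndimage.gaussian_filter(display.figure_mask.astype(float), sigma=2.0)
    gy, gx = np.gradient(smooth)
    # tangent orientation = normal + 90 deg, folded onto [0, pi)
    tangent = np.mod(np.arctan2(gy, gx) + 0.5 * np.pi, np.pi)

    ys, xs = np.nonzero(boundary)
    theta = tangent[ys, xs]
    chan = np.arange(n_orient) * np.pi / n_orient
    # circular distance on orientation (period pi)
    d = np.abs(theta[:, None] - chan[None, :])
    d = np.minimum(d, np.pi - d)
    sigma_o = 0.30  # rad, ~17 deg tuning width
    wts = np.exp(-(d / sigma_o) ** 2)
    wts /= wts.sum(axis=1, keepdims=True)
    energy[ys, xs, :] = wts
    return EdgeMap(energy=energy, n_orient=n_orient)


# ---------------------------------------------------------------------------
# parametric generators
# ---------------------------------------------------------------------------

def make_rectangle(aspect_ratio: float, area_scale: int = 16,
                   canvas: int = CANVAS) -> VisualDisplay:
    """Axis-aligned filled rectangle of a given width/height aspect ratio.

    ``area_scale`` sets the overall size: height is ``area_scale /
    sqrt(aspect)`` (rounded) and width is ``aspect * height`` (rounded), so
    the area is roughly ``area_scale ** 2``.
    """
    if not (1 / 8 <= aspect_ratio <= 8):
        raise ValueError("aspect_ratio must lie in [1/8, 8]")
    h = int(round(area_scale / np.sqrt(aspect_ratio)))
    w = int(round(aspect_ratio * h))
    if h < 3 or w < 3:
        raise ValueError(f"degenerate rectangle {h}x{w}: both sides must be >= 3 px")
    mask = _centered_rect(canvas, h, w)
    return _display_from_mask(
        mask, f"rect_{w}x{h}",
        {"aspect_ratio": aspect_ratio, "area_scale": area_scale, "h": h, "w": w})


#: Side lengths of the 8 x 8 rectangle grid: geometric spacing whose extreme
#: ratio is 8, so width/height aspects span 1/8 .. 8.
RECT_SIDES = (6, 8, 11, 15, 20, 27, 36, 48)


def rectangle_set(canvas: int = CANVAS) -> list[VisualDisplay]:
    """The 64-display rectangle set (8 widths x 8 heights, aspect 1/8..8)."""
    out = []
    for h in RECT_SIDES:
        for w in RECT_SIDES:
            mask = _centered_rect(canvas, h, w)
            out.append(_display_from_mask(
                mask, f"rect_{w}x{h}",
                {"h": h, "w": w, "aspect_ratio": w / h}))
    return out


_C_OUTER_SCALE = 26


def make_c_shape(aspect_ratio: float, thickness: int,
                 outer_scale: int = _C_OUTER_SCALE,
                 canvas: int = CANVAS) -> VisualDisplay:
    """Three-sided C figure: a rectangle with a rectangular concavity.

    The concavity opens to the right.  ``aspect_ratio`` is the outer
    width/height ratio; ``thickness`` is the arm thickness in pixels.
    """
    if not (1 <= thickness <= 6):
        raise ValueError("thickness must lie in 1..6")
    if not (1 / 4 <= aspect_ratio <= 4):
        raise ValueError("aspect_ratio must lie in [1/4, 4]")
    h = int(round(outer_scale / np.sqrt(aspect_ratio)))
    w = int(round(aspect_ratio * h))
    if h - 2 * thickness < 1 or w - thickness < 1:
        raise ValueError("thickness too large: the concavity vanishes")
    mask = _centered_rect(canvas, h, w)
    y0 = (canvas - h) // 2
    x0 = (canvas - w) // 2
    mask[y0 + thickness:y0 + h - thickness, x0 + thickness:x0 + w] = False
    return _display_from_mask(
        mask, f"c_{w}x{h}_t{thickness}",
        {"aspect_ratio": aspect_ratio, "thickness": thickness, "h": h, "w": w})


def c_shape_set(canvas: int = CANVAS) -> list[VisualDisplay]:
    """The 96-display C-shape set: 16 aspects x 6 thicknesses."""
    aspects = np.linspace(0.25, 4.0, 16)
    return [make_c_shape(a, t, canvas=canvas)
            for a in aspects for t in range(1, 7)]


def make_cross(thickness: int, size: int, canvas: int = CANVAS) -> VisualDisplay:
    """Plus-sign figure with 4-fold rotational symmetry.

    ``thickness`` is the arm width and ``size`` the full extent; both must be
    even so the cross is centred on the pixel-grid centre of the (even-sided)
    canvas and maps onto itself under 90-degree rotation.
    """
    if thickness >= size:
        raise ValueError("thickness must be smaller than size")
    if thickness % 2 or size % 2:
        raise ValueError("thickness and size must be even for exact 4-fold symmetry")
    mask = _centered_rect(canvas, thickness, size)
    mask |= _centered_rect(canvas, size, thickness)
    return _display_from_mask(
        mask, f"cross_s{size}_t{thickness}", {"thickness": thickness, "size": size})


def cross_set(canvas: int = CANVAS) -> list[VisualDisplay]:
    """The 36-display cross set: 6 thicknesses x 6 sizes."""
    return [make_cross(t, s, canvas=canvas)
            for t in (4, 6, 8, 10, 12, 14) for s in (18, 22, 26, 30, 34, 38)]


def _texture_image(figure: np.ndarray, present: bool = True) -> np.ndarray:
    """Stroke rendering of a texture display: 45-deg strokes on the figure,
    135-deg strokes on the background.  The background-only control extends
    the figure texture uniformly, so the pixels inside any interior probe
    window are identical in the two displays and only the orientation
    contrast at the outline distinguishes them."""
    h, w = figure.shape
    yy, xx = np.mgrid[0:h, 0:w]
    bg = ((xx + yy) % 4 == 0).astype(float)
    fg = ((xx - yy) % 4 == 0).astype(float)
    if not present:
        return fg
    return np.where(figure, fg, bg)


def make_square_texture(element_size: int, displacement: int,
                        canvas: int = CANVAS) -> VisualDisplay:
    """2 x 2 array of square elements separated by ``displacement`` pixels.

    The figure mask is the union of the four elements and the ground-truth
    skeleton is the union of the per-element skeletons.  The image renders
    the elements as orientation-contrast texture; the edge map places energy
    on the element outlines only.
    """
    if displacement < 1:
        raise ValueError("displacement must be >= 1")
    pitch = element_size + displacement
    extent = element_size + pitch
    if extent > canvas - 4:
        raise ValueError("texture array does not fit the canvas")
    mask = _blank(canvas)
    y0 = (canvas - extent) // 2
    x0 = (canvas - extent) // 2
    for dy in (0, pitch):
        for dx in (0, pitch):
            mask[y0 + dy:y0 + dy + element_size,
                 x0 + dx:x0 + dx + element_size] = True
    return _display_from_mask(
        mask, f"sqtex_e{element_size}_d{displacement}",
        {"element_size": element_size, "displacement": displacement,
         "pitch": pitch, "texture": True},
        image=_texture_image(mask))


def square_texture_set(canvas: int = CANVAS) -> list[VisualDisplay]:
    """The 36-display square-texture set: 6 displacements x 6 element sizes."""
    return [make_square_texture(e, d, canvas=canvas)
            for d in (3, 5, 7, 9, 11, 13) for e in (5, 7, 9, 11, 13, 15)]


def make_random_blocks(params: BlockShapeParams,
                       canvas: int = CANVAS) -> VisualDisplay:
    """Randomly grown block figure: a base rectangle plus adjacent blocks.

    Growth starts from a centred ``base_size x (2*base_size/3)`` rectangle.
    Each iteration picks a random empty pixel 4-adjacent to the shape grown
    so far (so blocks may attach to the base rectangle or to any previously
    added block) and stamps a random square block covering it, keeping the
    figure 4-connected by construction.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    base_h = max(3, (2 * params.base_size) // 3)
    mask = _centered_rect(canvas, base_h, params.base_size)
    margin = 6
    lo, hi = params.block_size_range
    for _ in range(params.n_blocks):
        placed = False
        for _attempt in range(200):
            ring = ndimage.binary_dilation(mask, structure=_CROSS3) & ~mask
            ys, xs = np.nonzero(ring)
            i = rng.integers(len(ys))
            cy, cx = int(ys[i]), int(xs[i])
            side = int(rng.integers(lo, hi + 1))
            oy = int(rng.integers(side))
            ox = int(rng.integers(side))
            y0, x0 = cy - oy, cx - ox
            if (y0 < margin or x0 < margin
                    or y0 + side > canvas - margin or x0 + side > canvas - margin):
                continue
            mask[y0:y0 + side, x0:x0 + side] = True
            placed = True
            break
        if not placed:
            raise RuntimeError("no legal block placement found after 200 retries")
    return _display_from_mask(
        mask, f"blocks_n{params.n_blocks}_s{params.seed}",
        {"n_blocks": params.n_blocks, "base_size": params.base_size,
         "block_size_range": params.block_size_range},
        seed=params.seed)


def block_set(complexity: str, n: int = 500, seed: int = 0,
              canvas: int = CANVAS) -> list[VisualDisplay]:
    """A set of random block displays.

    ``complexity`` is ``"LC"``, ``"MC"`` or ``"HC"`` (4, 16 or 32 added
    blocks).  Display i uses seed ``seed * 1_000_003 + i`` so sets drawn with
    different master seeds do not overlap.
    """
    n_blocks = {"LC": 4, "MC": 16, "HC": 32}[complexity.upper()]
    return [make_random_blocks(
        BlockShapeParams(n_blocks=n_blocks, seed=seed * 1_000_003 + i),
        canvas=canvas) for i in range(n)]


# ---------------------------------------------------------------------------
# exemplars
# ---------------------------------------------------------------------------

def _exemplar_square(canvas: int = CANVAS) -> VisualDisplay:
    mask = _centered_rect(canvas, 27, 27)
    return _display_from_mask(mask, "square", {"side": 27})


def _exemplar_c_shape(canvas: int = CANVAS) -> VisualDisplay:
    # Outer 39 x 39 with 13 px arms: the concavity is as wide as the arms are
    # thick, so feedforward responses inside the concavity rival those on the
    # true medial axis and feedback must break the tie.
    h = w = 39
    t = 13
    mask = _centered_rect(canvas, h, w)
    y0 = (canvas - h) // 2
    x0 = (canvas - w) // 2
    mask[y0 + t:y0 + h - t, x0 + t:x0 + w] = False
    return _display_from_mask(mask, "c_shape", {"h": h, "w": w, "thickness": t})


def _exemplar_cross(canvas: int = CANVAS) -> VisualDisplay:
    d = make_cross(12, 40, canvas=canvas)
    return _display_from_mask(d.figure_mask, "cross", dict(d.params))


def _exemplar_square_texture(canvas: int = CANVAS) -> VisualDisplay:
    d = make_square_texture(13, 9, canvas=canvas)
    return _display_from_mask(d.figure_mask, "square_texture", dict(d.params),
                              image=d.image)


def _exemplar_thin_bar(canvas: int = CANVAS) -> VisualDisplay:
    # 3 px wide: thinner than the diameter (6 px) of the smallest annulus.
    mask = _centered_rect(canvas, 3, 31)
    return _display_from_mask(mask, "thin_bar", {"h": 3, "w": 31})


def _exemplar_crescent(canvas: int = CANVAS) -> VisualDisplay:
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    c = (canvas - 1) / 2.0
    outer = (yy - c) ** 2 + (xx - c) ** 2 <= 17.0 ** 2
    inner = (yy - c) ** 2 + (xx - (c + 7)) ** 2 <= 12.0 ** 2
    mask = outer & ~inner
    return _display_from_mask(mask, "crescent",
                              {"r_outer": 17.0, "r_inner": 12.0, "offset": 7})


def _exemplar_triangle(canvas: int = CANVAS) -> VisualDisplay:
    # isoceles triangle, apex up; base 33 px, height 30 px
    base, height = 33, 30
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    cx = (canvas - 1) / 2.0
    y_top = (canvas - height) // 2
    frac = (yy - y_top) / height
    half = frac * (base / 2.0)
    mask = (yy >= y_top) & (yy < y_top + height) & (np.abs(xx - cx) <= half)
    return _display_from_mask(mask, "triangle", {"base": base, "height": height})


def _exemplar_texture_pair(canvas: int = CANVAS) -> tuple[VisualDisplay, VisualDisplay]:
    mask = _centered_rect(canvas, 27, 27)
    fig = _display_from_mask(
        mask, "texture_pair_figure",
        {"texture": True, "figure_present": True, "side": 27},
        image=_texture_image(mask))
    gnd = _display_from_mask(
        mask, "texture_pair_ground",
        {"texture": True, "figure_present": False, "side": 27},
        image=_texture_image(mask, present=False))
    return fig, gnd


def make_exemplars(canvas: int = CANVAS) -> list[VisualDisplay]:
    """The named exemplar displays used throughout the simulations.

    Returns nine displays: square, C-shape, cross, square texture, thin bar,
    crescent, triangle, and the texture-defined-square pair (figure display
    plus the background-only control, which shares the figure display's
    pixels inside any interior probe RF).
    """
    fig, gnd = _exemplar_texture_pair(canvas)
    return [
        _exemplar_square(canvas),
        _exemplar_c_shape(canvas),
        _exemplar_cross(canvas),
        _exemplar_square_texture(canvas),
        _exemplar_thin_bar(canvas),
        _exemplar_crescent(canvas),
        _exemplar_triangle(canvas),
        fig,
        gnd,
    ]


def get_exemplar(name: str, canvas: int = CANVAS) -> VisualDisplay:
    """Look up a single exemplar display by name."""
    for d in make_exemplars(canvas):
        if d.name == name:
            return d
    raise KeyError(f"unknown exemplar {name!r}")


DISPLAY_SETS = {
    "rectangles": rectangle_set,
    "c_shapes": c_shape_set,
    "crosses": cross_set,
    "square_textures": square_texture_set,
}


def get_display_set(name: str, n: int = 500, seed: int = 0,
                    canvas: int = CANVAS) -> list[VisualDisplay]:
    """Materialize a named display set.

    ``name`` is one of ``rectangles``, ``c_shapes``, ``crosses``,
    ``square_textures``, ``LC``, ``MC``, ``HC`` or ``exemplars``.  ``n`` and
    ``seed`` apply to the stochastic block sets only.
    """
    if name in DISPLAY_SETS:
        return DISPLAY_SETS[name](canvas=canvas)
    if name.upper() in ("LC", "MC", "HC"):
        return block_set(name.upper(), n=n, seed=seed, canvas=canvas)
    if name == "exemplars":
        return make_exemplars(canvas)
    raise KeyError(f"unknown display set {name!r}")
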