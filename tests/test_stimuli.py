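"""Display generators, edge maps, medial axes and region masks."""

import numpy as np
import pytest
from scipy import ndimage

from teardrop import (
    BlockShapeParams,
    compute_edge_map,
    compute_medial_axis,
    make_c_shape,
    make_cross,
    make_exemplars,
    make_random_blocks,
    make_rectangle,
    make_square_texture,
    region_masks,
)
from teardrop.stimuli import (
    _centered_rect,
    _display_from_mask,
    block_set,
    c_shape_set,
    cross_set,
    rectangle_set,
    square_texture_set,
)


# ---------------------------------------------------------------------------
# set cardinalities and shared invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("factory,expected", [
    (rectangle_set, 64),
    (c_shape_set, 96),
    (cross_set, 36),
    (square_texture_set, 36),
])
def test_set_cardinalities(factory, expected):
    displays = factory()
    assert len(displays) == expected
    masks = {d.figure_mask.tobytes() for d in displays}
    assert len(masks) == expected, "displays in a set must be distinct"


def test_display_invariants_hold_for_every_generated_display():
    displays = (rectangle_set() + c_shape_set()[:10] + cross_set()[:10]
                + square_texture_set()[:10] + make_exemplars())
    for d in displays:
        assert d.figure_mask.any()
        assert not (d.boundary_mask & ~d.figure_mask).any()
        assert not (d.medial_mask & ~d.figure_mask).any()
        assert d.image.shape == d.figure_mask.shape


# ---------------------------------------------------------------------------
# individual generators
# ---------------------------------------------------------------------------

def test_rectangle_aspect_one_is_square():
    d = make_rectangle(1.0)
    assert d.params["h"] == d.params["w"]


def test_rectangle_aspect_two_doubles_the_height():
    d = make_rectangle(2.0)
    assert d.params["w"] == 2 * d.params["h"]


def test_rectangle_rejects_degenerate_sides():
    with pytest.raises(ValueError):
        make_rectangle(8.0, area_scale=4)   # height would fall below 3 px


def test_c_shape_is_subset_of_its_bounding_rectangle():
    d = make_c_shape(1.0, 4)
    h, w = d.params["h"], d.params["w"]
    rect = _centered_rect(64, h, w)
    assert not (d.figure_mask & ~rect).any()
    assert rect.sum() > d.figure_mask.sum()


def test_c_shape_concavity_outside_figure_and_boundary():
    d = make_c_shape(1.0, 4)
    h, w, t = d.params["h"], d.params["w"], d.params["thickness"]
    y0, x0 = (64 - h) // 2, (64 - w) // 2
    concavity = np.zeros((64, 64), bool)
    concavity[y0 + t:y0 + h - t, x0 + t:x0 + w] = True
    assert not (concavity & d.figure_mask).any()
    assert not (concavity & d.boundary_mask).any()


def test_c_shape_rejects_thickness_that_erases_the_concavity():
    with pytest.raises(ValueError):
        make_c_shape(4.0, 6, outer_scale=12)


def test_cross_has_exact_fourfold_symmetry():
    d = make_cross(8, 26)
    assert np.array_equal(d.figure_mask, np.rot90(d.figure_mask))


def test_cross_area_matches_closed_form():
    for t, s in [(4, 18), (8, 26), (12, 34)]:
        d = make_cross(t, s)
        assert d.figure_mask.sum() == 2 * t * s - t * t


def test_cross_rejects_thickness_not_smaller_than_size():
    with pytest.raises(ValueError):
        make_cross(18, 18)


def test_square_texture_element_centres_form_a_lattice():
    d = make_square_texture(9, 7)
    lbl, n = ndimage.label(d.figure_mask)
    assert n == 4
    centres = np.array(ndimage.center_of_mass(d.figure_mask, lbl, range(1, 5)))
    pitch = d.params["pitch"]
    ys = np.unique(np.round(centres[:, 0], 5))
    xs = np.unique(np.round(centres[:, 1], 5))
    assert len(ys) == 2 and len(xs) == 2
    assert ys[1] - ys[0] == pytest.approx(pitch)
    assert xs[1] - xs[0] == pytest.approx(pitch)


def test_block_generator_base_case_and_determinism():
    base = make_random_blocks(BlockShapeParams(n_blocks=0, seed=5))
    rect = _centered_rect(64, 8, 12)
    assert np.array_equal(base.figure_mask, rect)
    a = make_random_blocks(BlockShapeParams(n_blocks=16, seed=42))
    b = make_random_blocks(BlockShapeParams(n_blocks=16, seed=42))
    assert np.array_equal(a.figure_mask, b.figure_mask)


def test_block_figures_are_4_connected():
    for seed in range(10):
        d = make_random_blocks(BlockShapeParams(n_blocks=32, seed=seed))
        _, n = ndimage.label(d.figure_mask,
                             structure=ndimage.generate_binary_structure(2, 1))
        assert n == 1


def test_block_set_draws_are_essentially_all_distinct():
    displays = block_set("HC", n=500, seed=0)
    distinct = {d.figure_mask.tobytes() for d in displays}
    assert len(distinct) >= 495


def test_exemplars_are_the_named_set():
    names = [d.name for d in make_exemplars()]
    assert names == ["square", "c_shape", "cross", "square_texture",
                     "thin_bar", "crescent", "triangle",
                     "texture_pair_figure", "texture_pair_ground"]


def test_thin_bar_is_thinner_than_smallest_annulus():
    from teardrop import RADII
    bar = next(d for d in make_exemplars() if d.name == "thin_bar")
    rows = np.nonzero(bar.figure_mask.any(axis=1))[0]
    assert rows[-1] - rows[0] + 1 < 2 * RADII[0]


def test_texture_pair_shares_pixels_inside_an_interior_probe():
    ds = {d.name: d for d in make_exemplars()}
    fig, gnd = ds["texture_pair_figure"], ds["texture_pair_ground"]
    # probe window well inside the figure, away from the outline
    assert np.array_equal(fig.image[28:36, 28:36], gnd.image[28:36, 28:36])


# ---------------------------------------------------------------------------
# medial axis
# ---------------------------------------------------------------------------

def brute_force_medial(mask):
    """Maximal-disk oracle: p is medial iff no other figure pixel's inscribed
    disk contains p's inscribed disk (pairwise distances, no library calls)."""
    ys, xs = np.nonzero(mask)
    P = np.stack([ys, xs], 1).astype(float)
    B = np.stack(np.nonzero(~mask), 1).astype(float)
    D = np.sqrt(((P[:, None, :] - B[None, :, :]) ** 2).sum(-1)).min(1)
    pd = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
    contained = (D[None, :] >= D[:, None] + pd) & ~np.eye(len(P), dtype=bool)
    out = np.zeros_like(mask)
    out[ys, xs] = ~contained.any(1)
    return out


@pytest.mark.parametrize("h,w", [(8, 8), (8, 16), (12, 20), (16, 16),
                                 (32, 32), (32, 8), (24, 32), (5, 31)])
def test_medial_axis_matches_maximal_disk_oracle_on_rectangles(h, w):
    mask = np.zeros((h + 8, w + 8), bool)
    mask[4:4 + h, 4:4 + w] = True
    got = compute_medial_axis(mask)
    oracle = brute_force_medial(mask)
    # thinning resolves the oracle's 2-px ridges; compare within the 1-px
    # tolerance of the discrete skeleton
    grow = ndimage.binary_dilation(got, structure=np.ones((3, 3)))
    grow_o = ndimage.binary_dilation(oracle, structure=np.ones((3, 3)))
    sym = (got & ~grow_o).sum() + (oracle & ~grow).sum()
    assert sym <= 2


def test_medial_axis_of_disk_is_symmetric_about_the_centre():
    # the rasterized disk is a polygon with short flat sides, so its exact
    # discrete skeleton is the centre plus thin axis spokes; the centre must
    # carry the maximal inscribed disk and the whole skeleton must share the
    # disk's 4-fold symmetry
    yy, xx = np.mgrid[0:41, 0:41]
    disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 12 ** 2
    sk = compute_medial_axis(disk)
    assert sk[19:22, 19:22].any()   # centre within 1 px (thinning may open
    assert np.array_equal(sk, np.rot90(sk))   # the exact crossing pixel)
    ys, xs = np.nonzero(sk)
    on_axes_or_diag = ((ys == 20) | (xs == 20)
                       | (ys - 20 == xs - 20) | (ys - 20 == 20 - xs))
    assert on_axes_or_diag.all()


def test_medial_axis_of_one_pixel_bar_is_the_bar():
    mask = np.zeros((16, 32), bool)
    mask[8, 4:28] = True
    assert np.array_equal(compute_medial_axis(mask), mask)


def test_medial_axis_rejects_empty_mask():
    with pytest.raises(ValueError):
        compute_medial_axis(np.zeros((8, 8), bool))


def test_medial_axis_connected_for_connected_figures():
    d = make_random_blocks(BlockShapeParams(n_blocks=8, seed=3))
    sk = compute_medial_axis(d.figure_mask)
    _, n = ndimage.label(sk, structure=np.ones((3, 3)))
    assert n == 1


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------

def test_region_masks_partition_and_dilation(exemplars):
    d = exemplars["square"]
    mk = region_masks(d, tol=1)
    assert not (mk["medial_band"] & mk["interior_rest"]).any()
    assert np.array_equal(mk["medial_band"] | mk["interior_rest"]
                          | (d.figure_mask & ~mk["medial_band"]
                             & ~mk["interior_rest"]), d.figure_mask)
    assert mk["boundary_band"].sum() >= d.boundary_mask.sum()
    mk0 = region_masks(d, tol=0)
    assert np.array_equal(mk0["medial_band"], d.medial_mask)


def test_medial_band_stays_inside_convex_figures():
    for d in rectangle_set()[::9]:
        mk = region_masks(d, tol=1)
        assert not (mk["medial_band"] & mk["ground"]).any()


# ---------------------------------------------------------------------------
# edge maps
# ---------------------------------------------------------------------------

def test_edge_energy_confined_to_boundary_band(exemplars):
    for name in ("square", "c_shape", "crescent"):
        d = exemplars[name]
        em = compute_edge_map(d)
        band = ndimage.binary_dilation(d.boundary_mask, np.ones((3, 3)))
        assert em.total[~band].max() == 0.0
        assert em.total[d.boundary_mask].min() > 0.9


def test_blank_texture_control_has_zero_energy(exemplars):
    em = compute_edge_map(exemplars["texture_pair_ground"])
    assert em.total.max() == 0.0


def test_horizontal_boundary_peaks_in_horizontal_channel():
    d = _display_from_mask(_centered_rect(64, 17, 31), "wide")
    em = compute_edge_map(d)
    ys, xs = np.nonzero(d.boundary_mask)
    top = ys.min()
    mid_cols = (xs > xs.min() + 4) & (xs < xs.max() - 4) & (ys == top)
    px = em.energy[ys[mid_cols], xs[mid_cols], :]
    assert (px.argmax(axis=1) == 0).all()   # channel 0 = horizontal


def test_total_energy_tracks_perimeter():
    for h, w in [(25, 25), (25, 41), (31, 31)]:
        d = _display_from_mask(_centered_rect(64, h, w), "r")
        em = compute_edge_map(d)
        assert em.total.sum() == pytest.approx(2 * h + 2 * w, rel=0.05)


def test_edge_map_rotation_permutes_orientation_channels(exemplars):
    d = exemplars["c_shape"]
    em = compute_edge_map(d)
    rot = _display_from_mask(np.rot90(d.figure_mask), "rot")
    em_rot = compute_edge_map(rot)
    # 90 deg rotation shifts orientation by n_orient/2 channels
    expected = np.rot90(np.roll(em.energy, 4, axis=2), axes=(0, 1))
    assert np.allclose(em_rot.energy, expected, atol=1e-8)


def test_generators_are_deterministic():
    a = make_square_texture(9, 7)
    b = make_square_texture(9, 7)
    assert np.array_equal(a.medial_mask, b.medial_mask)
    assert np.array_equal(a.image, b.image)
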