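"""Convex cells: annulus drive, gating, competition, recurrent circuit."""

import numpy as np
import pytest

from teardrop import RADII, build_arc_bank, compute_edge_map, curved_response
from teardrop.pit import (
    AnnulusParams,
    PitKernels,
    annulus_drive,
    convex_recurrent_inhibition,
    cross_scale_competition,
)
from teardrop.v4 import CurvedField

from conftest import circle_display


@pytest.fixture(scope="module")
def annulus():
    return AnnulusParams()


def test_annulus_params_validation():
    with pytest.raises(ValueError):
        AnnulusParams(ring_width=0.5)
    with pytest.raises(ValueError):
        AnnulusParams(radii=(3.0, 2.0))


@pytest.mark.parametrize("s", [1, 2, 3, 4, 5])
def test_circle_maximally_drives_matching_scale_at_its_centre(bank, annulus, s):
    d = circle_display(RADII[s] + 0.5)
    cf = curved_response(compute_edge_map(d), bank)
    drive, gate = annulus_drive(cf, annulus)
    centre = drive[30:34, 30:34].max(axis=(0, 1))
    assert centre.argmax() == s
    assert gate[31, 31, s]
    # neighbouring scales respond strictly less at the centre
    assert centre[s] > centre[s - 1] and centre[s] > centre[s + 1]


def test_one_sided_edge_fragment_fails_the_gate(bank, annulus):
    # a single short fragment tangent to one side of the ring
    s = 2
    r = RADII[s]
    h = w = 64
    energy = np.zeros((h, w, 8))
    for dx in range(-4, 5):
        energy[int(32 - r), 32 + dx, 0] = 1.0   # horizontal tangent above p
    cf = curved_response(
        __import__("teardrop").stimuli.EdgeMap(energy=energy), bank)
    drive, gate = annulus_drive(cf, annulus)
    assert not gate[32, 32, s]
    assert drive[32, 32, s] == 0.0


def test_closed_contour_peaks_at_its_centre(bank, annulus):
    # the drive of the matching scale is maximal at the circle's centre:
    # exterior cells see the contour on one side only (or as mismatched
    # chords) and cannot beat the fully enclosed cell
    s = 2
    d_circ = circle_display(RADII[s] + 0.5)
    dr, _ = annulus_drive(curved_response(compute_edge_map(d_circ), bank), annulus)
    flat = int(np.argmax(dr[:, :, s]))
    py, px = flat // 64, flat % 64
    assert abs(py - 31.5) < 1.6 and abs(px - 31.5) < 1.6


def test_competition_is_symmetric_and_spares_single_scales():
    x = np.zeros((4, 4, 7))
    x[1, 1, :] = 0.3
    comp = cross_scale_competition(x)
    assert np.allclose(comp[1, 1], comp[1, 1, 0])   # uniform profile -> equal
    x2 = np.zeros((4, 4, 7))
    x2[2, 2, 3] = 0.8
    comp2 = cross_scale_competition(x2)
    assert comp2[2, 2, 3] == 0.0                    # lone scale uninhibited
    assert comp2[2, 2, 0] == pytest.approx(0.64)


def test_two_scale_competition_sharpens_the_winner():
    # iterate the shunting system with drives (0.6, 0.4) and quadratic
    # cross-inhibition to its fixed point: the winner's share must exceed
    # its feedforward share
    e = np.array([0.6, 0.4])
    x = np.zeros(2)
    beta = 8.0
    for _ in range(2000):
        inh = beta * (x[::-1] ** 2)
        x = x + 0.05 * (-x + (1 - x) * 4 * e - x * inh)
    assert x[0] / (x[0] + x[1]) > 0.6


def test_recurrent_inhibition_cancellation_logic():
    kernels = PitKernels(AnnulusParams())
    h = w = 48
    x = np.zeros((h, w, 7))
    x[24, 24, 5] = 0.8                      # one active large cell (C1)
    edge = np.zeros((h, w))
    inh_no_support = convex_recurrent_inhibition(x, edge, kernels, kappa=1.0)
    # a small cell covered by C1's annulus is inhibited
    assert inh_no_support[24, 24, 1] > 0
    # now give the small cell boundary input that C1 also sees: edge energy
    # on C1's ring that is simultaneously on the small cell's ring
    r_small, r_big = RADII[1], RADII[5]
    # place the small cell so the rings intersect, and put edge energy there
    p_small = (24, int(24 + r_big - r_small))
    yy, xx = np.mgrid[0:h, 0:w]
    on_big = np.abs(np.hypot(yy - 24, xx - 24) - r_big) < 1.0
    on_small = np.abs(np.hypot(yy - p_small[0], xx - p_small[1]) - r_small) < 1.0
    edge2 = (on_big & on_small).astype(float) * 5.0
    inh_support = convex_recurrent_inhibition(x, edge2, kernels, kappa=5.0)
    assert inh_support[p_small[0], p_small[1], 1] < \
        inh_no_support[p_small[0], p_small[1], 1]


def test_concavity_receives_more_net_inhibition_than_the_medial_axis(
        bank, exemplars, fast_params):
    """Static pass on the C-shape: with the feedforward field as input, the
    coarse-to-fine circuit inhibits small-scale cells inside the concavity
    more than cells on the true medial axis of the arms."""
    from teardrop import LESION_CONDITIONS, run
    from teardrop.stimuli import region_masks

    d = exemplars["c_shape"]
    traj = run(d, lesion=LESION_CONDITIONS["none"], params=fast_params)
    x = traj.final.convex
    em = compute_edge_map(d)
    kernels = PitKernels(AnnulusParams())
    inh = convex_recurrent_inhibition(x, em.total, kernels, kappa=1.0)
    mk = region_masks(d)
    t = d.params["thickness"]
    h = d.params["h"]
    y0 = x0 = (64 - h) // 2
    concavity = np.zeros((64, 64), bool)
    concavity[y0 + t + 2:y0 + h - t - 2, x0 + t + 2:x0 + h - 2] = True
    s_dom = int(np.argmax(x.max(axis=(0, 1))))
    inh_conc = inh[:, :, s_dom][concavity].mean()
    inh_med = inh[:, :, s_dom][mk["medial_band"]].mean()
    assert inh_conc > inh_med


def test_shunting_bound_holds_for_random_inputs(fast_params):
    """Random nonnegative drives can never push activities out of [0, B]."""
    rng = np.random.default_rng(7)
    B, A, dt = 1.0, 1.0, 0.3
    x = rng.uniform(0, 1, size=(16, 16, 7))
    for _ in range(1000):
        E = rng.exponential(2.0, size=x.shape)
        I = rng.exponential(2.0, size=x.shape)
        rate = A + E + I
        x_eq = B * E / rate
        x = x_eq + (x - x_eq) * np.exp(-rate * dt)
        assert x.min() >= 0.0 and x.max() <= B + 1e-12
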