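"""Figure-ground indices, kurtosis diagnostic, and medial readout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teardrop import (
    bi,
    ioi,
    mai,
    normalize_across_conditions,
    readout_medial,
    region_masks,
    scale_profile_kurtosis,
)
from teardrop.metrics import evaluate
from teardrop.stimuli import _centered_rect, _display_from_mask


@pytest.fixture(scope="module")
def square_masks():
    d = _display_from_mask(_centered_rect(64, 27, 27), "sq")
    return d, region_masks(d)


def _map_with_region_means(masks, **level_per_region):
    amap = np.zeros(next(iter(masks.values())).shape)
    for region, level in level_per_region.items():
        amap[masks[region]] = level
    return amap


def test_ioi_direct_values(square_masks):
    d, mk = square_masks
    amap = _map_with_region_means(mk, figure=0.3, ground=0.1)
    assert ioi(amap, mk) == pytest.approx(0.5)
    amap_eq = _map_with_region_means(mk, figure=0.2, ground=0.2)
    assert ioi(amap_eq, mk) == pytest.approx(0.0)
    amap_fig = _map_with_region_means(mk, figure=0.4, ground=0.0)
    assert ioi(amap_fig, mk) == pytest.approx(1.0)


def test_mai_boundary_cases(square_masks):
    d, mk = square_masks
    only_medial = _map_with_region_means(mk, medial_band=0.7)
    assert mai(only_medial, mk) == pytest.approx(1.0)
    flat = _map_with_region_means(mk, medial_band=0.4, interior_rest=0.4)
    assert mai(flat, mk) == pytest.approx(0.0)


def test_bi_direct_value(square_masks):
    d, mk = square_masks
    amap = _map_with_region_means(mk, boundary_band=0.4, elsewhere=0.1)
    assert bi(amap, mk) == pytest.approx(0.6)
    on_boundary = _map_with_region_means(mk, boundary_band=1.0)
    assert bi(on_boundary, mk) == pytest.approx(1.0)


def test_zero_over_zero_returns_zero_with_warning(square_masks):
    d, mk = square_masks
    with pytest.warns(RuntimeWarning):
        assert ioi(np.zeros(d.shape), mk) == 0.0


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 50.0))
def test_indices_bounded_scale_invariant_and_match_brute_force(seed, c):
    d = _display_from_mask(_centered_rect(64, 27, 27), "sq")
    mk = region_masks(d)
    amap = np.random.default_rng(seed).uniform(0, 1, size=d.shape)
    for fn, (ra, rb) in ((ioi, ("figure", "ground")),
                         (mai, ("medial_band", "interior_rest")),
                         (bi, ("boundary_band", "elsewhere"))):
        v = fn(amap, mk)
        assert -1.0 <= v <= 1.0
        # scale invariance
        assert fn(c * amap, mk) == pytest.approx(v, abs=1e-12)
        # brute-force mask means
        a, b = amap[mk[ra]].mean(), amap[mk[rb]].mean()
        assert v == pytest.approx((a - b) / (a + b), abs=1e-12)


def test_kurtosis_closed_forms():
    x = np.zeros((4, 4, 7))
    x[0, 0, 0] = 1.0
    x[1, 1, 6] = 1.0
    # equal mass on the two extreme scales: mu4/mu2^2 = 1
    assert scale_profile_kurtosis(x) == pytest.approx(1.0)
    u = np.zeros((4, 4, 7))
    u[2, 2, :] = 0.5
    # uniform mass on 7 points: mu2 = 4, mu4 = 28 -> 1.75
    assert scale_profile_kurtosis(u) == pytest.approx(1.75)


def test_kurtosis_ranks_narrow_profiles_above_uniform():
    narrow = np.zeros((4, 4, 7))
    narrow[0, 0] = [0.0, 0.05, 0.9, 1.0, 0.9, 0.05, 0.0]
    uniform = np.zeros((4, 4, 7))
    uniform[0, 0] = 1.0
    assert scale_profile_kurtosis(narrow) > scale_profile_kurtosis(uniform)


def test_kurtosis_rejects_zero_profile():
    with pytest.raises(ValueError):
        scale_profile_kurtosis(np.zeros((4, 4, 7)))


def test_readout_single_cell_and_tie_break():
    x = np.zeros((8, 8, 7))
    x[3, 5, 2] = 0.9
    sel, s = readout_medial(x)
    assert s == 2
    assert sel[3, 5] and sel.sum() == 1
    # ties across scales break toward the smaller scale
    x[3, 5, 4] = 0.9
    _, s2 = readout_medial(x)
    assert s2 == 2


def test_readout_rejects_zero_field():
    with pytest.raises(ValueError):
        readout_medial(np.zeros((8, 8, 7)))


def test_normalization_across_conditions():
    vals = {"intact": 0.8, "teardrop_only": 0.6, "convex_only": 0.3,
            "none": 0.2}
    norm = normalize_across_conditions(vals)
    assert norm["intact"] == 1.0 and norm["none"] == 0.0
    assert all(0.0 <= v <= 1.0 for v in norm.values())
    assert normalize_across_conditions({"a": 0.5, "b": 0.5}) == {"a": 0.5,
                                                                 "b": 0.5}


def test_evaluate_produces_consistent_report(square_masks):
    d, mk = square_masks
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, size=(*d.shape, 7)) * mk["figure"][:, :, None]
    rep = evaluate(d, x)
    assert rep.display == "sq"
    assert -1 <= rep.ioi <= 1 and -1 <= rep.mai <= 1 and -1 <= rep.bi <= 1
    assert len(rep.per_scale_max) == 7
    row = rep.as_row()
    assert row["max_scale_1"] == pytest.approx(rep.per_scale_max[0])
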