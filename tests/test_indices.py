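"""Vegetation-index formulas against independent scalar oracles, plus
algebraic properties (bounds, antisymmetry, scale invariance)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burnmap import (
    ConfigurationError,
    InputError,
    compute_index,
    index_difference,
    masked_mean_difference,
    screen_indices,
)

from .conftest import make_scene


# --- independent scalar oracles (plain-float evaluation of the formulas) ---

def oracle(name: str, nir: float, red: float = 0.1, blue: float = 0.05,
           yellow: float = 0.09, green_i: float = 0.08, green: float = 0.09,
           a: float = 0.1) -> float:
    if name == "NDVI":
        return (nir - red) / (nir + red)
    if name == "SR":
        return nir / red
    if name == "SAVI":
        return 1.5 * (nir - red) / (nir + red + 0.5)
    if name == "EVI":
        return 2.5 * (nir - red) / (nir + 6 * red - 7.5 * blue + 1)
    if name == "GEMI":
        n = (2 * (nir**2 - red**2) + 1.5 * nir + 0.5 * red) / (nir + red + 0.5)
        return n * (1 - 0.25 * n) - (red - 0.125) / (1 - red)
    if name == "MSR":
        r = nir / red
        return (r - 1) / (r + 1)
    if name == "WDRVI":
        return (a * nir - red) / (a * nir + red)
    if name == "YNDVI":
        return (nir - yellow) / (nir + yellow)
    if name == "GNDVI1":
        return (nir - green_i) / (nir + green_i)
    if name == "GNDVI2":
        return (nir - green) / (nir + green)
    raise KeyError(name)


REFLECTANCES = {"NIR": 0.5, "RED": 0.1, "BLUE": 0.05, "YELLOW": 0.09,
                "GREEN_I": 0.08, "GREEN": 0.09}

# frozen expected values, computed with the scalar oracle above
FROZEN = {
    "NDVI": 0.4 / 0.6,
    "SR": 5.0,
    "SAVI": 1.5 * 0.4 / 1.1,
    "EVI": 1.0 / 1.725,
    "GEMI": 0.8529017447199265,
    "MSR": 4.0 / 6.0,
    "WDRVI": -0.05 / 0.15,
    "YNDVI": 0.41 / 0.59,
    "GNDVI1": 0.42 / 0.58,
    "GNDVI2": 0.41 / 0.59,
}


@pytest.mark.parametrize("name", sorted(FROZEN))
def test_index_matches_scalar_oracle(name):
    scene = make_scene(REFLECTANCES)
    img = compute_index(scene, name, {"wdrvi_a": 0.1})
    assert img.values[0, 0] == pytest.approx(oracle(name, 0.5), abs=1e-12)
    assert img.values[0, 0] == pytest.approx(FROZEN[name], abs=1e-9)
    assert not img.nodata_mask.any()


def test_ndvi_symmetry_zero():
    scene = make_scene({"NIR": 0.3, "RED": 0.3})
    assert compute_index(scene, "NDVI").values[0, 0] == 0.0


def test_yndvi_example():
    scene = make_scene({"NIR": 0.45, "YELLOW": 0.09})
    assert compute_index(scene, "YNDVI").values[0, 0] == pytest.approx(2 / 3, abs=1e-9)


def test_gemi_intermediate_n():
    # n for NIR=0.5, RED=0.1 is 1.28 / 1.1
    n = (2 * (0.25 - 0.01) + 0.75 + 0.05) / 1.1
    assert n == pytest.approx(1.1636363636, abs=1e-9)


def test_zero_denominator_becomes_nodata():
    scene = make_scene({"NIR": 0.2, "RED": -0.2})
    img = compute_index(scene, "NDVI")
    assert img.nodata_mask.all()


def test_unknown_index_and_missing_band():
    scene = make_scene({"NIR": 0.5})
    with pytest.raises(InputError):
        compute_index(scene, "NBR")
    partial = make_scene({"NIR": 0.5})
    partial.band_map = {"NIR": 7, "RED": 5}  # no BLUE -> EVI unavailable
    with pytest.raises(ConfigurationError):
        compute_index(partial, "EVI")


def test_wdrvi_a_bounds_enforced():
    scene = make_scene({"NIR": 0.5, "RED": 0.1})
    with pytest.raises(ConfigurationError):
        compute_index(scene, "WDRVI", {"wdrvi_a": 0.5})


# --- properties over random positive reflectances ---

pos = st.floats(min_value=1e-3, max_value=1.0)


@given(a=pos, b=pos)
@settings(max_examples=200, derandomize=True)
def test_normalized_difference_antisymmetry_and_bounds(a, b):
    s1 = make_scene({"NIR": a, "RED": b, "YELLOW": b, "GREEN_I": b, "GREEN": b})
    s2 = make_scene({"NIR": b, "RED": a, "YELLOW": a, "GREEN_I": a, "GREEN": a})
    for name in ("NDVI", "YNDVI", "GNDVI1", "GNDVI2"):
        v1 = compute_index(s1, name).values[0, 0]
        v2 = compute_index(s2, name).values[0, 0]
        assert v1 == pytest.approx(-v2, abs=1e-12)
        assert -1.0 <= v1 <= 1.0
    assert compute_index(s1, "SR").values[0, 0] >= 0.0
    assert -1.0 <= compute_index(s1, "MSR").values[0, 0] <= 1.0
    assert -1.0 <= compute_index(s1, "WDRVI", {"wdrvi_a": 0.15}).values[0, 0] <= 1.0


@given(a=pos, b=pos, c=st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=200, derandomize=True)
def test_ratio_indices_scale_invariant(a, b, c):
    base = make_scene({"NIR": a, "RED": b, "YELLOW": b, "GREEN_I": b, "GREEN": b})
    scaled = make_scene({"NIR": c * a, "RED": c * b, "YELLOW": c * b,
                         "GREEN_I": c * b, "GREEN": c * b})
    for name in ("NDVI", "SR", "MSR", "YNDVI", "GNDVI1", "GNDVI2"):
        assert compute_index(base, name).values[0, 0] == pytest.approx(
            compute_index(scaled, name).values[0, 0], rel=1e-9
        )


# --- differencing and masked means ---

class TestDifference:
    def test_identity_gives_zero(self):
        s = make_scene({"NIR": 0.5, "RED": 0.1})
        img = compute_index(s, "NDVI")
        d = index_difference(img, img)
        assert np.all(d.values == 0.0)

    def test_vegetation_loss_positive(self):
        pre = compute_index(make_scene({"NIR": 0.56, "RED": 0.08}), "NDVI")
        post = compute_index(make_scene({"NIR": 0.32, "RED": 0.32}), "NDVI")
        d = index_difference(pre, post)
        assert d.values[0, 0] == pytest.approx(0.75, abs=1e-12)

    def test_name_mismatch_rejected(self):
        s = make_scene({"NIR": 0.5, "RED": 0.1})
        with pytest.raises(InputError):
            index_difference(compute_index(s, "NDVI"), compute_index(s, "SR"))

    def test_nodata_union(self):
        s1 = make_scene({"NIR": 0.5, "RED": 0.1})
        s2 = make_scene({"NIR": 0.4, "RED": 0.1})
        s1.nodata_mask[0, 0] = True
        s2.nodata_mask[1, 1] = True
        d = index_difference(compute_index(s1, "NDVI"), compute_index(s2, "NDVI"))
        assert d.nodata_mask[0, 0] and d.nodata_mask[1, 1]
        assert d.nodata_mask.sum() == 2


class TestMaskedMean:
    def test_two_point_mean(self):
        s1 = make_scene({"NIR": 0.5, "RED": 0.1}, n_rows=1, n_cols=4)
        s2 = make_scene({"NIR": 0.5, "RED": 0.1}, n_rows=1, n_cols=4)
        d = index_difference(compute_index(s1, "NDVI"), compute_index(s2, "NDVI"))
        d.values[0, :2] = [0.2, 0.4]
        mask = np.array([[True, True, False, False]])
        assert masked_mean_difference(d, mask) == pytest.approx(0.3)

    def test_linear_in_difference(self):
        s1 = make_scene({"NIR": 0.5, "RED": 0.1})
        d = index_difference(compute_index(s1, "NDVI"), compute_index(s1, "NDVI"))
        rng = np.random.default_rng(0)
        d.values[:] = rng.random(d.values.shape)
        mask = rng.random(d.values.shape) > 0.5
        m1 = masked_mean_difference(d, mask)
        d.values *= 3.0
        assert masked_mean_difference(d, mask) == pytest.approx(3.0 * m1)

    def test_empty_mask_rejected(self):
        s = make_scene({"NIR": 0.5, "RED": 0.1})
        d = index_difference(compute_index(s, "NDVI"), compute_index(s, "NDVI"))
        with pytest.raises(InputError):
            masked_mean_difference(d, np.zeros(d.values.shape, dtype=bool))


class TestScreening:
    def test_identical_scenes_all_zero(self):
        s = make_scene({"NIR": 0.5, "RED": 0.1})
        table = screen_indices(s, s)
        assert np.allclose(table["mean_difference"], 0.0)
        assert len(table) == 10

    def test_burn_scene_mean_inside_exceeds_outside(self, small_scenario):
        cfg, pre, post, truth = small_scenario
        d = index_difference(compute_index(pre, "NDVI"), compute_index(post, "NDVI"))
        inside = masked_mean_difference(d, truth.burn_mask)
        outside = masked_mean_difference(d, ~truth.burn_mask)
        assert inside > outside
        assert inside - outside > 5 * cfg.noise_sigma

    def test_ratio_indices_rank_top(self, small_scenario):
        # SR and the linear MSR amplify relative change, so they lead the table
        _, pre, post, truth = small_scenario
        table = screen_indices(pre, post, truth.burn_mask)
        assert table.iloc[0]["index_name"] == "SR"

    def test_missing_yellow_band_omits_yndvi_with_warning(self, small_scenario):
        _, pre, post, _ = small_scenario
        bm = {k: v for k, v in pre.band_map.items() if k != "YELLOW"}
        pre2 = type(pre)(grid=pre.grid, bands=pre.bands, band_map=bm)
        post2 = type(post)(grid=post.grid, bands=post.bands, band_map=bm)
        with pytest.warns(UserWarning, match="YNDVI"):
            table = screen_indices(pre2, post2)
        assert "YNDVI" not in set(table["index_name"])
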