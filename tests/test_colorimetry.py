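"""Colour-science foundations: sRGB transfer, spectral integration, CIELAB,
CIEDE2000 (checked against an independently coded stepwise oracle and the
published reference pairs)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbisim import (
    SpectralGrid,
    Spectrum,
    ciede2000,
    delta_e_ab,
    lab_to_xyz,
    spectra_to_xyz,
    spectrum_to_xyz,
    srgb_decode,
    srgb_encode,
    xyz_to_lab,
)
from nbisim.colorimetry import cmf_1931, equal_energy_illuminant, white_point


# --------------------------------------------------------------------------
# sRGB transfer
# --------------------------------------------------------------------------


def test_srgb_fixed_points():
    assert srgb_decode(0.0) == 0.0
    assert srgb_decode(1.0) == pytest.approx(1.0, abs=1e-12)
    assert srgb_encode(0.0) == 0.0
    assert srgb_encode(1.0) == pytest.approx(1.0, abs=1e-12)


def test_srgb_decode_midpoint_closed_form():
    # independent evaluation of ((0.5 + 0.055) / 1.055) ** 2.4
    expected = math.pow((0.5 + 0.055) / 1.055, 2.4)
    assert srgb_decode(0.5) == pytest.approx(expected, abs=1e-15)
    assert expected == pytest.approx(0.2140, abs=5e-5)
    assert srgb_encode(expected) == pytest.approx(0.5, abs=1e-12)


def test_srgb_round_trip_and_monotonicity():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, 1000)
    assert np.max(np.abs(srgb_encode(srgb_decode(x)) - x)) < 1e-12
    fine = np.arange(0.0, 1.0 + 1e-4 / 2, 1e-4)
    assert np.all(np.diff(srgb_decode(fine)) > 0)


@pytest.mark.parametrize("value", [-0.1, 1.5])
def test_srgb_out_of_range_names_value(value):
    with pytest.raises(ValueError, match=str(value)):
        srgb_decode(value)


@settings(derandomize=True, max_examples=200)
@given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
def test_srgb_round_trip_property(x):
    assert abs(srgb_encode(srgb_decode(x)) - x) < 1e-12


@settings(derandomize=True, max_examples=100)
@given(
    st.tuples(
        st.floats(0, 100), st.floats(-80, 80), st.floats(-80, 80)
    ),
    st.tuples(
        st.floats(0, 100), st.floats(-80, 80), st.floats(-80, 80)
    ),
)
def test_ciede2000_symmetry_property(lab1, lab2):
    d12 = ciede2000(np.array(lab1), np.array(lab2))
    d21 = ciede2000(np.array(lab2), np.array(lab1))
    assert d12 >= 0
    assert d12 == pytest.approx(d21, abs=1e-12)


# --------------------------------------------------------------------------
# spectrum -> XYZ
# --------------------------------------------------------------------------


def test_perfect_reflector_has_y_100(illuminant, cmf, grid):
    xyz = spectrum_to_xyz(Spectrum.constant(grid, 1.0), illuminant, cmf)
    assert xyz[1] == pytest.approx(100.0, abs=1e-9)


def test_zero_reflector_is_black(illuminant, cmf, grid):
    xyz = spectrum_to_xyz(Spectrum.constant(grid, 0.0), illuminant, cmf)
    assert np.allclose(xyz, 0.0)


def test_gaussian_reflectance_matches_fine_grid_quadrature(grid):
    """Coarse 1 nm integration agrees with an independent 0.1 nm quadrature."""
    r_fn = lambda wl: 0.8 * np.exp(-0.5 * ((wl - 550.0) / 60.0) ** 2)
    coarse = spectrum_to_xyz(
        Spectrum(grid, r_fn(grid.wavelengths)),
        equal_energy_illuminant(grid),
        cmf_1931(grid),
    )
    fine = SpectralGrid(380.0, 780.0, 0.1)
    fcmf = cmf_1931(fine)
    r = r_fn(fine.wavelengths)
    k = 100.0 / np.trapezoid(fcmf["ybar"].values, fine.wavelengths)
    oracle = np.array(
        [
            k * np.trapezoid(r * fcmf[c].values, fine.wavelengths)
            for c in ("xbar", "ybar", "zbar")
        ]
    )
    assert np.allclose(coarse, oracle, rtol=2e-3)


def test_integration_linear_in_reflectance(grid, illuminant, cmf):
    rng = np.random.default_rng(7)
    r1 = rng.uniform(0, 1, grid.n_bands)
    r2 = rng.uniform(0, 1, grid.n_bands)
    a, b = 0.3, 0.6
    lhs = spectra_to_xyz((a * r1 + b * r2)[None], illuminant, cmf)[0]
    rhs = a * spectra_to_xyz(r1[None], illuminant, cmf)[0] + b * spectra_to_xyz(
        r2[None], illuminant, cmf
    )[0]
    assert np.allclose(lhs, rhs, rtol=1e-10)


# --------------------------------------------------------------------------
# CIELAB
# --------------------------------------------------------------------------


def test_lab_white_and_black(illuminant, cmf):
    white = white_point(illuminant, cmf)
    assert np.allclose(xyz_to_lab(white, white), [100.0, 0.0, 0.0], atol=1e-9)
    assert np.allclose(xyz_to_lab(np.zeros(3), white), 0.0, atol=1e-9)


def test_lab_half_white_neutral_axis(illuminant, cmf):
    white = white_point(illuminant, cmf)
    lab = xyz_to_lab(white / 2.0, white)
    assert lab[1] == pytest.approx(0.0, abs=1e-9)
    assert lab[2] == pytest.approx(0.0, abs=1e-9)
    assert lab[0] == pytest.approx(116.0 * 0.5 ** (1.0 / 3.0) - 16.0, abs=1e-9)


def test_lab_round_trip(illuminant, cmf):
    white = white_point(illuminant, cmf)
    rng = np.random.default_rng(3)
    xyz = rng.uniform(1, 95, (50, 3))
    assert np.allclose(lab_to_xyz(xyz_to_lab(xyz, white), white), xyz, atol=1e-9)


def test_lab_rejects_bad_white():
    with pytest.raises(ValueError):
        xyz_to_lab(np.array([50.0, 50.0, 50.0]), np.array([95.0, -1.0, 108.0]))


# --------------------------------------------------------------------------
# CIEDE2000
# --------------------------------------------------------------------------


def _ciede2000_oracle(lab1, lab2):
    """Independent scalar stepwise evaluation of the CIEDE2000 formula."""
    L1, a1, b1 = lab1
    L2, a2, b2 = lab2
    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cm = (C1 + C2) / 2.0
    G = 0.5 * (1.0 - math.sqrt(Cm**7 / (Cm**7 + 25.0**7)))
    a1p, a2p = (1 + G) * a1, (1 + G) * a2
    C1p, C2p = math.hypot(a1p, b1), math.hypot(a2p, b2)

    def hue(ap, b):
        if ap == 0 and b == 0:
            return 0.0
        h = math.degrees(math.atan2(b, ap))
        return h + 360.0 if h < 0 else h

    h1p, h2p = hue(a1p, b1), hue(a2p, b2)
    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0:
        dhp = 0.0
    else:
        d = h2p - h1p
        if abs(d) <= 180:
            dhp = d
        elif d > 180:
            dhp = d - 360
        else:
            dhp = d + 360
    dHp = 2 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2)
    Lbp = (L1 + L2) / 2
    Cbp = (C1p + C2p) / 2
    if C1p * C2p == 0:
        hbp = h1p + h2p
    elif abs(h1p - h2p) <= 180:
        hbp = (h1p + h2p) / 2
    elif h1p + h2p < 360:
        hbp = (h1p + h2p + 360) / 2
    else:
        hbp = (h1p + h2p - 360) / 2
    T = (
        1
        - 0.17 * math.cos(math.radians(hbp - 30))
        + 0.24 * math.cos(math.radians(2 * hbp))
        + 0.32 * math.cos(math.radians(3 * hbp + 6))
        - 0.20 * math.cos(math.radians(4 * hbp - 63))
    )
    dtheta = 30 * math.exp(-(((hbp - 275) / 25) ** 2))
    RC = 2 * math.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1 + 0.015 * (Lbp - 50) ** 2 / math.sqrt(20 + (Lbp - 50) ** 2)
    SC = 1 + 0.045 * Cbp
    SH = 1 + 0.015 * Cbp * T
    RT = -math.sin(math.radians(2 * dtheta)) * RC
    return math.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )


# Published CIEDE2000 reference pairs (Sharma, Wu & Dalal 2005), frozen.
REFERENCE_PAIRS = [
    ((50, 2.6772, -79.7751), (50, 0, -82.7485), 2.0425),
    ((50, 3.1571, -77.2803), (50, 0, -82.7485), 2.8615),
    ((50, 2.8361, -74.0200), (50, 0, -82.7485), 3.4412),
    ((50, -1.3802, -84.2814), (50, 0, -82.7485), 1.0000),
    ((50, -1.1848, -84.8006), (50, 0, -82.7485), 1.0000),
    ((50, -0.9009, -85.5211), (50, 0, -82.7485), 1.0000),
    ((50, 0, 0), (50, -1, 2), 2.3669),
    ((50, -1, 2), (50, 0, 0), 2.3669),
    ((50, 2.49, -0.001), (50, -2.49, 0.0009), 7.1792),
    ((50, 2.49, -0.001), (50, -2.49, 0.0010), 7.1792),
    ((50, 2.49, -0.001), (50, -2.49, 0.0011), 7.2195),
    ((50, 2.49, -0.001), (50, -2.49, 0.0012), 7.2195),
    ((50, 2.5, 0), (73, 25, -18), 27.1492),
    ((50, 2.5, 0), (61, -5, 29), 22.8977),
    ((50, 2.5, 0), (56, -27, -3), 31.9030),
    ((50, 2.5, 0), (58, 24, 15), 19.4535),
    ((50, 2.5, 0), (50, 3.1736, 0.5854), 1.0000),
    ((50, 2.5, 0), (50, 3.2972, 0), 1.0000),
    ((50, 2.5, 0), (50, 1.8634, 0.5757), 1.0000),
    ((50, 2.5, 0), (50, 3.2592, 0.3350), 1.0000),
    ((60.2574, -34.0099, 36.2677), (60.4626, -34.1751, 39.4387), 1.2644),
    ((63.0109, -31.0961, -5.8663), (62.8187, -29.7946, -4.0864), 1.2630),
    ((61.2901, 3.7196, -5.3901), (61.4292, 2.2480, -4.9620), 1.8731),
    ((35.0831, -44.1164, 3.7933), (35.0232, -40.0716, 1.5901), 1.8645),
    ((22.7233, 20.0904, -46.6940), (23.0331, 14.9730, -42.5619), 2.0373),
    ((36.4612, 47.8580, 18.3852), (36.2715, 50.5065, 21.2231), 1.4146),
    ((90.8027, -2.0831, 1.4410), (91.1528, -1.6435, 0.0447), 1.4441),
    ((90.9257, -0.5406, -0.9208), (88.6381, -0.8985, -0.7239), 1.5381),
    ((6.7747, -0.2908, -2.4247), (5.8714, -0.0985, -2.2286), 0.6377),
    ((2.0776, 0.0795, -1.1350), (0.9033, -0.0636, -0.5514), 0.9082),
]


@pytest.mark.parametrize("lab1,lab2,expected", REFERENCE_PAIRS)
def test_ciede2000_reference_pairs(lab1, lab2, expected):
    assert ciede2000(lab1, lab2) == pytest.approx(expected, abs=5e-5)


def test_ciede2000_matches_stepwise_oracle():
    rng = np.random.default_rng(42)
    lab1 = rng.uniform([0, -80, -80], [100, 80, 80], (1000, 3))
    lab2 = rng.uniform([0, -80, -80], [100, 80, 80], (1000, 3))
    vec = ciede2000(lab1, lab2)
    oracle = [_ciede2000_oracle(p, q) for p, q in zip(lab1, lab2)]
    assert np.max(np.abs(vec - oracle)) < 1e-10


def test_ciede2000_metric_properties():
    rng = np.random.default_rng(5)
    lab1 = rng.uniform([0, -60, -60], [100, 60, 60], (1000, 3))
    lab2 = rng.uniform([0, -60, -60], [100, 60, 60], (1000, 3))
    d12 = ciede2000(lab1, lab2)
    d21 = ciede2000(lab2, lab1)
    assert np.all(d12 >= 0)
    assert np.allclose(d12, d21, atol=1e-12)
    assert np.allclose(ciede2000(lab1, lab1), 0.0, atol=1e-12)
    assert np.all(d12 > 0)  # distinct random pairs


def test_delta_e_ab_closed_form():
    assert delta_e_ab([50, 0, 0], [50, 3, 4]) == pytest.approx(5.0)
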