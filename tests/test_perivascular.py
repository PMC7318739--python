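"""Vessel classification and lumen-anchored AQP4 radial profiles."""

import numpy as np
import pytest

from brainfluid.perivascular import (
    FluorescenceImage,
    ProfileExtractionError,
    RadialProfile,
    VesselAnnotation,
    background_stats,
    classify_vessel,
    extract_profile,
    mean_profile_per_animal,
    normalize_profile,
    profile_auc,
    region_mean_intensity,
    sample_vessels,
)
from brainfluid.synthetic import PhantomSpec, analytic_halo_auc, make_fluorescence_phantom


def make_vessel(vid="v", short=6.0, long=24.0, myosin=False, centre_um=(60.0, 60.0),
                pixel_size=0.5, animal="A", region="Cx"):
    """Elliptical lumen annotation, long axis horizontal, in pixel coordinates."""
    theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    cx, cy = centre_um[0] / pixel_size, centre_um[1] / pixel_size
    poly = np.stack(
        [cx + (long / 2 / pixel_size) * np.cos(theta),
         cy + (short / 2 / pixel_size) * np.sin(theta)], axis=1
    )
    return VesselAnnotation(
        vessel_id=vid, polygon_px=poly, centroid_px=(cx, cy),
        shortest_axis_um=short, longest_axis_um=long,
        myosin_positive=myosin, region=region, animal_id=animal,
    )


def halo_image(centre_um, a_um, b_um, height=2.0, sigma=2.0, offset=1.5,
               background=100.0, size_um=(120.0, 120.0), pixel_size=0.5):
    """Analytic vertical-distance halo around an elongated lumen.

    With the profile ray vertical and the lumen near-flat over the band, the
    true boundary distance equals the vertical distance to the lumen edge.
    """
    w, h = int(size_um[0] / pixel_size), int(size_um[1] / pixel_size)
    yy, xx = np.mgrid[0:h, 0:w].astype(float) * pixel_size
    dx = xx - centre_um[0]
    dy = yy - centre_um[1]
    # signed vertical distance to the ellipse edge along x = const
    edge = b_um * np.sqrt(np.clip(1.0 - (dx / a_um) ** 2, 0.0, None))
    d = np.abs(dy) - edge
    halo = height * np.exp(-((d - offset) ** 2) / (2 * sigma**2))
    halo[np.abs(dx) >= a_um] = 0.0
    img = background * (1.0 + halo)
    return FluorescenceImage(channels={"aqp4": img}, pixel_size_um=pixel_size)


# --- classification ---------------------------------------------------------

@pytest.mark.parametrize(
    "short, myosin, expected",
    [
        (25.0, True, "arteriole"),
        (25.0, False, "venule"),
        (6.0, False, "capillary"),
        (6.0, True, "capillary"),
        (20.0, True, "capillary"),  # boundary: rule requires strictly > 20 µm
    ],
)
def test_classification_rule(short, myosin, expected):
    v = make_vessel(short=short, long=max(short, 30.0), myosin=myosin)
    assert classify_vessel(v) == expected


def test_sampling_is_seeded_and_checks_availability():
    vessels = (
        [make_vessel(f"a{i}", 25, 40, True, (60 + 5 * i, 60)) for i in range(7)]
        + [make_vessel(f"c{i}", 6, 24, False, (60 + 5 * i, 80)) for i in range(7)]
        + [make_vessel(f"v{i}", 25, 40, False, (60 + 5 * i, 100)) for i in range(7)]
    )
    s1 = sample_vessels(vessels, 5, seed=42)
    s2 = sample_vessels(vessels, 5, seed=42)
    assert all(
        [v.vessel_id for v in s1[c]] == [v.vessel_id for v in s2[c]] for c in s1
    )
    assert all(len(s1[c]) == 5 for c in s1)
    # exactly n available -> identity selection
    five = vessels[:5] + vessels[7:12] + vessels[14:19]
    s3 = sample_vessels(five, 5, seed=0)
    assert {v.vessel_id for vs in s3.values() for v in vs} == {v.vessel_id for v in five}
    with pytest.raises(ValueError):
        sample_vessels(five, 6, seed=0)


# --- profile extraction -----------------------------------------------------

def test_constant_channel_gives_flat_profile():
    img = FluorescenceImage(
        channels={"aqp4": np.full((300, 300), 7.0)}, pixel_size_um=0.5
    )
    v = make_vessel(centre_um=(75.0, 75.0))
    prof = extract_profile(img, v, threshold=0.0)
    assert prof.distances_um[0] == 0.0
    assert prof.distances_um[-1] == pytest.approx(50.0)
    np.testing.assert_allclose(prof.intensity, 7.0, rtol=1e-9)


def test_phantom_style_halo_peak_and_auc():
    """The extracted profile must peak at the constructed offset (within one
    pixel) and integrate to the analytic bump AUC within 2%."""
    img = halo_image(centre_um=(60.0, 35.0), a_um=12.0, b_um=3.0)
    v = make_vessel("cap", 6.0, 24.0, centre_um=(60.0, 35.0))
    prof = extract_profile(img, v, threshold=101.0)
    norm = normalize_profile(prof, background=100.0)
    peak_um = norm.distances_um[np.argmax(norm.intensity)]
    assert abs(peak_um - 1.5) <= img.pixel_size_um + 1e-9
    expected = analytic_halo_auc(height=2.0, decay_um=2.0, offset_um=1.5)
    assert profile_auc(norm) == pytest.approx(expected, rel=0.02)


def test_translation_invariance():
    """Translating vessel and halo together leaves the profile unchanged."""
    profs = []
    for centre in ((60.0, 35.0), (75.0, 50.0)):  # integer-pixel shift at 0.5 µm/px
        img = halo_image(centre_um=centre, a_um=12.0, b_um=3.0)
        v = make_vessel("cap", 6.0, 24.0, centre_um=centre)
        profs.append(extract_profile(img, v, threshold=101.0).intensity)
    np.testing.assert_allclose(profs[0], profs[1], rtol=1e-9)


def test_vessel_too_close_to_border_errors():
    img = FluorescenceImage(
        channels={"aqp4": np.full((100, 400), 7.0)}, pixel_size_um=0.5
    )  # 50 µm tall: neither vertical ray has 50 µm clearance
    v = make_vessel(centre_um=(100.0, 25.0))
    with pytest.raises(ProfileExtractionError, match="no valid profile ray"):
        extract_profile(img, v, threshold=0.0)


def test_ray_crossing_neighbour_lumen_errors():
    img = FluorescenceImage(
        channels={"aqp4": np.full((400, 400), 7.0)}, pixel_size_um=0.5
    )
    v = make_vessel("v1", centre_um=(100.0, 30.0))
    below = make_vessel("v2", centre_um=(100.0, 60.0))  # in the downward ray path
    with pytest.raises(ProfileExtractionError, match="crosses vessel"):
        extract_profile(img, v, threshold=0.0, neighbours=[v, below])


def test_no_immunoreactive_pixel_errors():
    img = FluorescenceImage(
        channels={"aqp4": np.full((400, 400), 7.0)}, pixel_size_um=0.5
    )
    v = make_vessel(centre_um=(100.0, 100.0))
    with pytest.raises(ProfileExtractionError):
        extract_profile(img, v, threshold=10.0)


# --- normalization, averaging, AUC ------------------------------------------

def grid_profile(values, animal="A", cls="capillary", region="Cx"):
    vals = np.asarray(values, dtype=float)
    return RadialProfile(
        distances_um=np.linspace(0, 50, vals.size), intensity=vals,
        vessel_class=cls, region=region, animal_id=animal,
    )


def test_normalization():
    p = grid_profile(np.full(11, 80.0))
    assert np.all(normalize_profile(p, 80.0).intensity == 0.0)
    p3 = grid_profile(np.full(11, 240.0))
    assert np.all(normalize_profile(p3, 80.0).intensity == 2.0)
    # scale invariance: doubling raw and background together changes nothing
    a = normalize_profile(grid_profile([100.0, 150.0, 90.0]), 80.0).intensity
    b = normalize_profile(grid_profile([200.0, 300.0, 180.0]), 160.0).intensity
    np.testing.assert_allclose(a, b, rtol=1e-12)
    with pytest.raises(ValueError):
        normalize_profile(p, 0.0)


def test_mean_profile_per_animal():
    p = grid_profile(np.arange(11.0))
    same = mean_profile_per_animal([p, p])
    np.testing.assert_allclose(same.mean_profile.intensity, p.intensity)
    assert same.n_vessels == 2
    neg = grid_profile(-np.arange(11.0))
    zero = mean_profile_per_animal([p, neg])
    np.testing.assert_allclose(zero.mean_profile.intensity, 0.0)
    assert zero.auc == 0.0
    other = grid_profile(np.arange(11.0), animal="B")
    with pytest.raises(ValueError, match="mix animals"):
        mean_profile_per_animal([p, other])


def test_auc():
    assert profile_auc(grid_profile(np.zeros(11))) == 0.0
    assert profile_auc(grid_profile(np.ones(11))) == pytest.approx(50.0)
    # quadrature oracle for a Gaussian bump
    d = np.linspace(0, 50, 201)
    bump = 2.0 * np.exp(-((d - 1.5) ** 2) / (2 * 5.0**2))
    p = RadialProfile(distances_um=d, intensity=bump)
    assert profile_auc(p) == pytest.approx(
        analytic_halo_auc(2.0, 5.0, 1.5), rel=0.01
    )
    # linearity: scaling the profile scales the AUC
    p3 = RadialProfile(distances_um=d, intensity=3.0 * bump)
    assert profile_auc(p3) == pytest.approx(3.0 * profile_auc(p), rel=1e-12)


def test_region_mean_intensity():
    img = FluorescenceImage(
        channels={"gfap": np.full((10, 10), 7.0)}, pixel_size_um=0.5
    )
    mask = np.zeros((10, 10), dtype=int)
    assert region_mean_intensity(img, mask, 0, "gfap") == 7.0
    half = np.where(np.arange(100).reshape(10, 10) < 50, 0.0, 10.0)
    img2 = FluorescenceImage(channels={"x": half}, pixel_size_um=1.0)
    assert region_mean_intensity(img2, mask, 0, "x") == 5.0
    with pytest.raises(ValueError, match="empty"):
        region_mean_intensity(img, mask, 3, "gfap")
    with pytest.raises(KeyError):
        region_mean_intensity(img, mask, 0, "missing")


# --- end-to-end on one phantom micrograph ------------------------------------

def test_class_auc_ordering_on_cortex_phantom():
    """Arteriole > venule > capillary per-animal AUC ordering, mirroring the
    constructed decay-length ordering."""
    spec = PhantomSpec(seed=9)
    img, vessels = make_fluorescence_phantom(spec, "WKY", "Cx", "WKY05")
    bg_mean, bg_sd = background_stats(img, vessels)
    thr = bg_mean + 2 * bg_sd
    aucs = {}
    for cls, chosen in sample_vessels(vessels, 5, seed=123).items():
        profs = [
            normalize_profile(
                extract_profile(img, v, threshold=thr, neighbours=vessels), bg_mean
            )
            for v in chosen
        ]
        aucs[cls] = mean_profile_per_animal(profs).auc
    assert aucs["arteriole"] > aucs["venule"] > aucs["capillary"]
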