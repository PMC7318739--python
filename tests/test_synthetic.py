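"""Phantom generator: determinism, volume fidelity, analytic oracles."""

import numpy as np
import pytest

from brainfluid.adc import fit_adc
from brainfluid.perivascular import background_stats, extract_profile, normalize_profile, profile_auc
from brainfluid.protein import ACTIN_WINDOW, AQP4_WINDOW, aqp4_actin_ratio, integrate_peak
from brainfluid.synthetic import (
    PhantomSpec,
    analytic_halo_auc,
    fluorescence_truth,
    make_electropherograms,
    make_fluorescence_phantom,
    make_gravimetry_records,
    make_imaging_phantom,
    make_study,
    wes_truth,
)
from brainfluid.volumetry import region_volume


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(b_values=(800.0,))  # no b=0
    with pytest.raises(ValueError):
        PhantomSpec(water_content_pct={"WKY": 101.0, "SHR": 77.0})
    with pytest.raises(ValueError):
        PhantomSpec(noise_sd_fraction=-0.1)
    with pytest.raises(ValueError):
        PhantomSpec(matrix=4)


def test_unknown_strain_and_region_rejected():
    spec = PhantomSpec(seed=0)
    with pytest.raises(KeyError):
        make_imaging_phantom(spec, "LEW", "LEW01")
    with pytest.raises(KeyError):
        make_fluorescence_phantom(spec, "WKY", "cerebellum")


def test_identical_seed_gives_identical_outputs():
    spec = PhantomSpec(seed=5)
    g1, d1, m1, t1 = make_imaging_phantom(spec, "WKY", "WKY02")
    g2, d2, m2, t2 = make_imaging_phantom(PhantomSpec(seed=5), "WKY", "WKY02")
    np.testing.assert_array_equal(d1.signals, d2.signals)
    np.testing.assert_array_equal(m1.labels, m2.labels)
    np.testing.assert_array_equal(g1.intensities, g2.intensities)
    i1, v1 = make_fluorescence_phantom(spec, "SHR", "Hc", "SHR04")
    i2, v2 = make_fluorescence_phantom(PhantomSpec(seed=5), "SHR", "Hc", "SHR04")
    np.testing.assert_array_equal(i1.channels["aqp4"], i2.channels["aqp4"])
    assert [a.vessel_id for a in v1] == [a.vessel_id for a in v2]
    r1 = make_gravimetry_records(spec)
    r2 = make_gravimetry_records(PhantomSpec(seed=5))
    assert [(a.wet_g, a.dry_g) for a in r1] == [(b.wet_g, b.dry_g) for b in r2]
    # a different seed changes the data
    d3 = make_imaging_phantom(PhantomSpec(seed=6), "WKY", "WKY02")[1]
    assert not np.array_equal(d1.signals, d3.signals)


def test_mask_volume_fidelity_and_connectedness():
    """Every region's achieved volume is within one voxel volume of its
    (per-animal) target, and each region is a single connected component."""
    from scipy.ndimage import label as cc_label

    spec = PhantomSpec(seed=7, volume_animal_cv=0.0)
    for strain, animal in (("WKY", "WKY01"), ("SHR", "SHR05")):
        _, _, mask, _ = make_imaging_phantom(spec, strain, animal)
        vv = spec.voxel_volume_mm3
        for region in ("IC", "LV", "3V", "cc", "Hc"):
            target = spec.region_volumes_mm3[(strain, region)]
            rep = region_volume(mask, region, spec.spacing)
            assert abs(rep.volume_mm3 - target) <= vv, region
        for region in ("LV", "3V", "cc", "Hc"):
            comp, n = cc_label(mask.region_indicator(region))
            assert n == 1, f"{region} not connected"


def test_noiseless_signals_invert_to_true_adc():
    spec = PhantomSpec(seed=2, noise_sd_fraction=0.0)
    _, dwi, _, true_map = make_imaging_phantom(spec, "SHR", "SHR02")
    fitted = fit_adc(dwi)
    np.testing.assert_array_equal(fitted.valid, true_map.valid)
    np.testing.assert_allclose(
        fitted.adc[fitted.valid], true_map.adc[true_map.valid], atol=1e-15
    )
    # closed-form inversion of the raw signals agrees too
    s0 = dwi.signals[0, 0][true_map.valid]
    sb = dwi.signals[1, 0][true_map.valid]
    np.testing.assert_allclose(
        np.log(s0 / sb) / 800.0, true_map.adc[true_map.valid], atol=1e-15
    )


def test_csf_regions_carry_higher_adc_than_parenchyma():
    spec = PhantomSpec(seed=2, noise_sd_fraction=0.0)
    _, _, mask, true_map = make_imaging_phantom(spec, "WKY", "WKY03")
    csf = true_map.adc[mask.region_indicator("LV")].mean()
    tissue = true_map.adc[mask.region_indicator("parenchyma")].mean()
    assert csf > 2.0 * tissue


def test_zero_noise_zero_jitter_spec_is_exactly_reproducible():
    spec = PhantomSpec(seed=1, water_jitter_sd_pct=0.0, dry_weight_cv=0.0)
    for rec in make_gravimetry_records(spec):
        assert rec.percent_water == pytest.approx(
            spec.water_content_pct[rec.strain], abs=1e-12
        )
    # the inverse construction: dry 1 g at 50% water -> wet 2 g
    spec50 = PhantomSpec(
        seed=1, water_jitter_sd_pct=0.0, dry_weight_cv=0.0,
        water_content_pct={"WKY": 50.0, "SHR": 50.0},
        dry_weight_g={"WKY": 1.0, "SHR": 1.0},
    )
    rec = make_gravimetry_records(spec50)[0]
    assert rec.wet_g == pytest.approx(2.0)


def test_rendered_halo_auc_matches_analytic_within_two_percent():
    spec = PhantomSpec(seed=8)
    img, vessels = make_fluorescence_phantom(spec, "WKY", "Cx", "WKY07")
    truth = fluorescence_truth(spec, "WKY", "Cx", "WKY07")
    bg_mean, bg_sd = background_stats(img, vessels)
    for v in vessels:
        prof = normalize_profile(
            extract_profile(img, v, threshold=bg_mean + 2 * bg_sd, neighbours=vessels),
            bg_mean,
        )
        assert profile_auc(prof) == pytest.approx(truth[v.vessel_id]["auc"], rel=0.02)


def test_halo_truth_orders_arteriole_above_venule_above_capillary():
    spec = PhantomSpec(seed=8)
    truth = fluorescence_truth(spec, "SHR", "Cx", "SHR01")
    by_class = {}
    for t in truth.values():
        by_class.setdefault(t["class"], []).append(t["auc"])
    assert min(by_class["arteriole"]) > max(by_class["venule"])
    assert min(by_class["venule"]) > max(by_class["capillary"])


def test_zero_halo_height_gives_flat_background():
    spec = PhantomSpec(seed=8)
    halos = {k: type(v)(0.0, v.peak_offset_um, v.decay_um)
             for k, v in spec.halo_params.items()}
    flat_spec = PhantomSpec(seed=8, halo_params=halos, fluor_noise_sd=0.0)
    img, _ = make_fluorescence_phantom(flat_spec, "WKY", "Tha", "WKY01")
    np.testing.assert_allclose(img.channels["aqp4"], flat_spec.fluor_background, rtol=1e-6)


def test_annotations_carry_construction_truth():
    spec = PhantomSpec(seed=8)
    _, vessels = make_fluorescence_phantom(spec, "WKY", "Cx", "WKY01")
    arterioles = [v for v in vessels if v.myosin_positive]
    assert len(arterioles) == spec.n_vessels_per_class
    for v in arterioles:
        assert v.shortest_axis_um > 20.0
        assert v.longest_axis_um >= v.shortest_axis_um


def test_electropherogram_ratio_recovery():
    spec = PhantomSpec(seed=4)
    traces = make_electropherograms(spec)
    truth = wes_truth(spec)
    for animal in ("WKY01", "SHR03"):
        areas = [
            (integrate_peak(t, AQP4_WINDOW), integrate_peak(t, ACTIN_WINDOW))
            for t in traces[animal]
        ]
        assert aqp4_actin_ratio(areas) == pytest.approx(truth[animal], rel=0.01)


def test_study_bundle(study_dataset):
    assert len(study_dataset.animals) == 21
    strains = [s for _, s in study_dataset.animals]
    assert strains.count("WKY") == 11 and strains.count("SHR") == 10
    assert len(study_dataset.gravimetry) == 21
    assert len(study_dataset.electropherograms) == 21
    assert len(study_dataset.outlier_cells) == 4
    # outliers never land in the regions carrying the injected strain effect
    assert all(region not in ("cc", "Cx") for _, region in study_dataset.outlier_cells)


def test_null_spec_shows_no_water_content_effect():
    """With identical group parameters, the gated comparison is null."""
    from brainfluid.stats import compare_groups

    spec = PhantomSpec(seed=13, water_content_pct={"WKY": 76.5, "SHR": 76.5})
    recs = make_gravimetry_records(spec)
    groups = {"WKY": [], "SHR": []}
    for r in recs:
        groups[r.strain].append(r.percent_water)
    assert compare_groups(groups).p_value > 0.05


def test_effects_summary_reports_injected_effects():
    eff = PhantomSpec(seed=0).effects_summary()
    assert eff["lv_volume_ratio"] == pytest.approx(63.6 / 35.6)
    assert eff["water_content_diff_pp"] == pytest.approx(0.8)
    assert eff["cc_capillary_halo_ratio"] == pytest.approx(0.6)
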