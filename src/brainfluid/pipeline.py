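"""End-to-end study analysis.

``run_study`` consumes a :class:`~brainfluid.synthetic.StudyDataset` (or, on
real data, the equivalent per-animal inputs), runs every quantification
stage — mask volumetry, ADC mapping with CSF exclusion, perivascular AQP4
profiling, gravimetry and electropherogram ratios — assembles the tidy
per-animal study table, and applies the statistics layer: gated two-group
tests per scalar measurement, Grubbs screening of the region-wise capillary
AQP4 AUCs per (region, strain) cell, and two-way ANOVA with Bonferroni post
hocs for region- and class-resolved measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from zlib import crc32

import numpy as np
import pandas as pd

from . import perivascular as pv
from .adc import fit_adc, roi_adc
from .protein import AQP4_WINDOW, ACTIN_WINDOW, aqp4_actin_ratio, integrate_peak
from .stats import StatsResult, TwoWayAnovaResult, compare_groups, grubbs_filter, two_way_anova_bonferroni
from .synthetic import ADC_ROI_REGIONS, CSF_REGIONS, MICROSCOPY_REGIONS, StudyDataset
from .volumetry import parenchymal_volume, region_volume

__all__ = ["StudyReport", "run_study"]

#: scalar measurements compared between strains with the gated two-group test
TWO_GROUP_MEASUREMENTS = (
    "volume_IC", "volume_LV", "volume_3V", "volume_cc", "volume_Hc",
    "volume_parenchyma", "adc_whole_brain", "water_pct", "water_g_per_g",
    "aqp4_actin_ratio",
)


@dataclass
class StudyReport:
    """Everything the statistics layer produces for one study."""

    study_table: pd.DataFrame  # animal_id, strain, measurement, region, value
    two_group: dict[str, StatsResult]
    anova: dict[str, TwoWayAnovaResult]
    grubbs_removed: pd.DataFrame  # region, strain, value removed by the screen
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_grubbs_removed(self) -> int:
        return len(self.grubbs_removed)


def _profile_for(img, vessel, threshold, others):
    raw = pv.extract_profile(img, vessel, threshold=threshold, neighbours=others)
    return raw


def _analyse_microscopy(dataset: StudyDataset, animal_id: str, n_select: int, rows: list):
    """Per-animal AQP4 profiling and GFAP intensity over all regions."""
    spec = dataset.spec
    strain = dataset.strain_of(animal_id)
    for region in MICROSCOPY_REGIONS:
        img, vessels = dataset.microscopy(animal_id, region)
        bg_mean, bg_sd = pv.background_stats(img, vessels)
        threshold = bg_mean + 2.0 * bg_sd
        select_seed = (spec.seed * 2654435761 + crc32(f"{animal_id}/{region}".encode())) % (2**31)
        if region == "Cx":
            selection = pv.sample_vessels(vessels, n_select, seed=select_seed)
        else:
            caps = [v for v in vessels if pv.classify_vessel(v) == "capillary"]
            rng = np.random.default_rng(select_seed)
            idx = sorted(rng.choice(len(caps), size=n_select, replace=False))
            selection = {"capillary": [caps[i] for i in idx]}
        for cls, chosen in selection.items():
            profiles = [
                pv.normalize_profile(
                    _profile_for(img, v, threshold, vessels), background=bg_mean
                )
                for v in chosen
            ]
            summary = pv.mean_profile_per_animal(profiles, group_by="vessel_class")
            if region == "Cx":
                rows.append((animal_id, strain, "aqp4_auc_class", cls, summary.auc))
            if cls == "capillary":
                rows.append((animal_id, strain, "aqp4_auc_capillary", region, summary.auc))
        full = np.zeros(img.shape, dtype=np.int8)  # the micrograph is the region
        rows.append(
            (animal_id, strain, "gfap", region,
             pv.region_mean_intensity(img, full, 0, "gfap"))
        )


def _analyse_imaging(dataset: StudyDataset, animal_id: str, rows: list):
    strain = dataset.strain_of(animal_id)
    _, dwi, mask, _ = dataset.imaging(animal_id)
    spacing = dataset.spec.spacing

    reports = {r: region_volume(mask, r, spacing) for r in ("IC", "LV", "3V", "cc", "Hc")}
    for r, rep in reports.items():
        rows.append((animal_id, strain, f"volume_{r}", None, rep.volume_mm3))
    rows.append(
        (animal_id, strain, "volume_parenchyma", None,
         parenchymal_volume(reports["IC"], reports["LV"], reports["3V"]))
    )

    adc_map = fit_adc(dwi)
    whole = roi_adc(adc_map, mask, "IC", csf_labels=CSF_REGIONS)
    rows.append((animal_id, strain, "adc_whole_brain", None, whole.mean_adc))
    for region in ADC_ROI_REGIONS:
        rep = roi_adc(adc_map, mask, region, csf_labels=CSF_REGIONS)
        rows.append((animal_id, strain, "adc", region, rep.mean_adc))


def run_study(dataset: StudyDataset, n_select: int = 5) -> StudyReport:
    """Run every stage over the cohort and apply the statistics layer.

    ``n_select`` vessels per class (cortex) and per region (capillaries) are
    drawn at random per animal, mirroring the blinded manual selection.
    Re-running with the same dataset seed reproduces the report exactly.
    """
    rows: list[tuple] = []
    for animal_id, strain in dataset.animals:
        _analyse_imaging(dataset, animal_id, rows)
        _analyse_microscopy(dataset, animal_id, n_select, rows)

    for rec in dataset.gravimetry:
        rows.append((rec.animal_id, rec.strain, "water_pct", None, rec.percent_water))
        rows.append((rec.animal_id, rec.strain, "water_g_per_g", None, rec.water_per_dry))

    for animal_id, strain in dataset.animals:
        runs = dataset.electropherograms[animal_id]
        areas = [(integrate_peak(t, AQP4_WINDOW), integrate_peak(t, ACTIN_WINDOW)) for t in runs]
        rows.append((animal_id, strain, "aqp4_actin_ratio", None, aqp4_actin_ratio(areas)))

    table = pd.DataFrame(rows, columns=["animal_id", "strain", "measurement", "region", "value"])

    # --- statistics layer -------------------------------------------------
    two_group: dict[str, StatsResult] = {}
    for m in TWO_GROUP_MEASUREMENTS:
        sub = table[table.measurement == m]
        groups = {s: sub.loc[sub.strain == s, "value"].to_numpy() for s in sub.strain.unique()}
        two_group[m] = compare_groups(groups)

    # Grubbs screen of capillary AQP4 AUCs per (region, strain) cell
    cap = table[table.measurement == "aqp4_auc_capillary"].copy()
    removed_rows = []
    keep_mask = pd.Series(True, index=cap.index)
    for (region, strain), cell in cap.groupby(["region", "strain"]):
        _, removed = grubbs_filter(cell["value"].to_numpy())
        for val in removed:
            idx = cell.index[np.isclose(cell["value"], val)][0]
            keep_mask.loc[idx] = False
            removed_rows.append({"region": region, "strain": strain, "value": val,
                                 "animal_id": cell.loc[idx, "animal_id"]})
    cap_clean = cap[keep_mask]
    grubbs_removed = pd.DataFrame(removed_rows, columns=["region", "strain", "value", "animal_id"])

    anova: dict[str, TwoWayAnovaResult] = {}
    adc_regions = table[table.measurement == "adc"].rename(columns={"region": "region"})
    anova["adc_regions"] = two_way_anova_bonferroni(adc_regions)
    anova["aqp4_capillary_regions"] = two_way_anova_bonferroni(cap_clean)
    cortex = table[table.measurement == "aqp4_auc_class"].rename(columns={"region": "region"})
    anova["aqp4_cortex_classes"] = two_way_anova_bonferroni(cortex)
    anova["gfap_regions"] = two_way_anova_bonferroni(table[table.measurement == "gfap"])

    summaries = (
        table.groupby(["measurement", "region", "strain"], dropna=False)["value"]
        .agg(n="count", mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )

    return StudyReport(
        study_table=table,
        two_group=two_group,
        anova=anova,
        grubbs_removed=grubbs_removed,
        summaries=summaries,
    )
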