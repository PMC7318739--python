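"""Synthetic study generator.

Emits every input the quantification pipeline consumes — co-registered
T2w/DWI volumes with segmentation masks, multi-channel fluorescence
micrographs with vessel annotations, gravimetric weight records and
electropherogram traces — for a two-strain cohort (normotensive WKY and
spontaneously hypertensive SHR rats) with *known ground truth*, so every
downstream stage is testable without any acquisition.

Design notes
------------
* Anatomy is deliberately schematic: regions are connected quasi-spherical
  voxel sets whose voxel count is the closest achievable to the target
  volume. Exact countability, not anatomy, is what volumetry needs.
* DWI noise is Gaussian on the magnitude signal (relative SD
  ``noise_sd_fraction``); at the SNR simulated here the Rician bias is
  negligible.
* Perivascular AQP4 halos are Gaussian bumps of given height peaking at a
  fixed offset outside the lumen and decaying with a class-specific length,
  so the profile AUC has a closed form (:func:`analytic_halo_auc`).
* All randomness derives from one root seed through per-animal,
  per-component seed sequences: identical seeds give bit-identical outputs
  and any component can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence
from zlib import crc32

import numpy as np
from scipy.special import erf

from .adc import AdcMap, DwiSeries
from .gravimetry import GravimetryRecord
from .perivascular import FluorescenceImage, VesselAnnotation
from .protein import Electropherogram
from .volumetry import SegmentationMask, VoxelGrid

__all__ = [
    "PhantomSpec",
    "HaloParams",
    "StudyDataset",
    "STRAINS",
    "MASK_REGIONS",
    "MICROSCOPY_REGIONS",
    "CSF_REGIONS",
    "analytic_halo_auc",
    "make_imaging_phantom",
    "make_fluorescence_phantom",
    "fluorescence_truth",
    "make_gravimetry_records",
    "make_electropherograms",
    "make_study",
]

STRAINS = ("WKY", "SHR")
#: base labels of the imaging phantom's segmentation mask
MASK_REGIONS = ("parenchyma", "LV", "3V", "cc", "Hc", "Cx", "Tha", "Hy", "Pir")
CSF_REGIONS = ("LV", "3V")
#: regions in which perivascular AQP4 is quantified
MICROSCOPY_REGIONS = ("Cx", "cc", "Hc", "Tha", "Hy", "Pir")
ADC_ROI_REGIONS = ("cc", "Cx", "Hc", "Tha", "Hy", "Pir")

_LABELS = {name: i + 1 for i, name in enumerate(MASK_REGIONS)}
_COMPOSITES = {"IC": tuple(MASK_REGIONS)}

# region centres (mm offsets from the grid centre): two rings of four slots
# at z = ±3 mm, large regions placed opposite each other so that every
# sub-structure ball fits inside the intracranial ball with margin at the
# jitter extremes
_REGION_OFFSETS = {
    "cc": (0.0, 3.8, 3.0),
    "Hc": (0.0, -3.8, 3.0),
    "3V": (3.8, 0.0, 3.0),
    "Pir": (-3.8, 0.0, 3.0),
    "Tha": (0.0, 3.8, -3.0),
    "Cx": (0.0, -3.8, -3.0),
    "LV": (3.8, 0.0, -3.0),
    "Hy": (-3.8, 0.0, -3.0),
}

# lumen diameters (µm); sections cut vessels obliquely, so lumina are drawn
# elongated — the shortest axis is the classification-relevant diameter
_VESSEL_GEOM = {
    "arteriole": {"short": 25.0, "long": 44.0},
    "venule": {"short": 25.0, "long": 40.0},
    "capillary": {"short": 6.0, "long": 24.0},
}

# stream codes for derived seed sequences
_IMAGING, _FLUOR, _GRAV, _WES, _OUTLIER, _SELECT = 1, 2, 3, 4, 5, 6


@dataclass(frozen=True)
class HaloParams:
    """Perivascular AQP4 halo: Gaussian bump on the background plateau."""

    peak_height: float  # unitless, relative to background
    peak_offset_um: float  # peak position outside the lumen edge
    decay_um: float  # Gaussian sigma of the bump

    def __post_init__(self) -> None:
        if self.peak_height < 0 or self.peak_offset_um <= 0 or self.decay_um <= 0:
            raise ValueError(f"invalid halo parameters {self}")


def _default_volumes() -> dict[tuple[str, str], float]:
    # IC/LV/cc follow the reported group values; 3V direction follows the
    # report (larger in SHR); Hc equal by report; ADC-ROI regions are
    # schematic 40 mm³ pockets. IC values chosen so that the derived
    # parenchymal volume is ~7% lower in SHR, matching the reported decrease.
    v = {
        ("WKY", "IC"): 2300.0, ("SHR", "IC"): 2173.0,
        ("WKY", "LV"): 35.6, ("SHR", "LV"): 63.6,
        ("WKY", "3V"): 7.0, ("SHR", "3V"): 10.0,
        ("WKY", "cc"): 71.8, ("SHR", "cc"): 61.7,
        ("WKY", "Hc"): 80.0, ("SHR", "Hc"): 80.0,
    }
    for strain in STRAINS:
        for region in ("Cx", "Tha", "Hy", "Pir"):
            v[(strain, region)] = 40.0
    return v


def _default_adc() -> dict[tuple[str, str], float]:
    # mm²/s; whole-brain parenchyma 0.96e-3 (WKY) vs 0.86e-3 (SHR); the SHR
    # reduction localizes to cc/Tha/Hy (and the bulk parenchyma), while
    # Cx/Hc/Pir are strain-null; ventricular CSF is fast-diffusing
    adc = {
        ("WKY", "parenchyma"): 0.96e-3, ("SHR", "parenchyma"): 0.86e-3,
        ("WKY", "CSF"): 3.0e-3, ("SHR", "CSF"): 3.0e-3,
    }
    for region in ADC_ROI_REGIONS:
        adc[("WKY", region)] = 0.96e-3
        adc[("SHR", region)] = 0.86e-3 if region in ("cc", "Tha", "Hy") else 0.96e-3
    return adc


def _default_halos() -> dict[tuple[str, str, str], HaloParams]:
    # equal peak heights across vessel classes at 1.5 µm outside the lumen;
    # decay lengths order arteriole > venule > capillary; SHR corpus-callosum
    # capillary halo reduced (the strain effect the pipeline must detect)
    decay = {"arteriole": 8.0, "venule": 4.0, "capillary": 1.5}
    halos: dict[tuple[str, str, str], HaloParams] = {}
    for strain in STRAINS:
        for region in MICROSCOPY_REGIONS:
            for cls, sigma in decay.items():
                height = 2.0
                if strain == "SHR" and region == "cc" and cls == "capillary":
                    height = 1.2
                halos[(strain, cls, region)] = HaloParams(height, 1.5, sigma)
    return halos


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic two-strain study.

    Defaults encode the study conditions: 11 WKY vs 10 SHR animals, b =
    0/800 s/mm² in 3 orthogonal directions over a 35 mm FOV with 1 mm
    slices, group effects on ventricular volume, parenchymal ADC, water
    content and the corpus-callosum capillary AQP4 halo, and a perivascular
    AQP4 peak 1.5 µm outside the lumen.
    """

    seed: int = 0
    n_per_group: Mapping[str, int] = field(default_factory=lambda: {"WKY": 11, "SHR": 10})
    region_volumes_mm3: Mapping[tuple[str, str], float] = field(default_factory=_default_volumes)
    region_adc: Mapping[tuple[str, str], float] = field(default_factory=_default_adc)
    noise_sd_fraction: float = 0.02
    b_values: tuple[float, ...] = (0.0, 800.0)
    n_directions: int = 3
    fov_mm: float = 35.0
    matrix: int = 128
    n_slices: int = 26
    slice_thickness_mm: float = 1.0
    #: multiplicative between-animal spread of parenchymal ADC (Gaussian CV)
    adc_animal_cv: float = 0.02
    #: multiplicative between-animal spread of region volumes (Gaussian CV)
    volume_animal_cv: float = 0.03
    halo_params: Mapping[tuple[str, str, str], HaloParams] = field(default_factory=_default_halos)
    #: half-width of the bounded-uniform per-(animal, region) expression factor
    halo_animal_jitter: float = 0.15
    halo_vessel_cv: float = 0.02
    pixel_size_um: float = 0.25
    fluor_background: float = 100.0
    fluor_noise_sd: float = 1.0
    gfap_mean: Mapping[str, float] = field(default_factory=lambda: {"WKY": 40.0, "SHR": 40.0})
    gfap_animal_sd: float = 1.0
    n_vessels_per_class: int = 6
    water_content_pct: Mapping[str, float] = field(
        default_factory=lambda: {"WKY": 76.3, "SHR": 77.1}
    )
    water_jitter_sd_pct: float = 0.25
    dry_weight_g: Mapping[str, float] = field(
        default_factory=lambda: {"WKY": 0.260, "SHR": 0.236}
    )
    dry_weight_cv: float = 0.03
    wes_ratio: Mapping[str, float] = field(default_factory=lambda: {"WKY": 0.5, "SHR": 0.5})
    wes_animal_cv: float = 0.05
    wes_run_cv: float = 0.05
    n_wes_runs: int = 4
    #: gross outliers injected into the region-wise capillary AQP4 halos
    n_auc_outliers: int = 4
    auc_outlier_factor: float = 6.0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not self.n_per_group or any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("n_per_group must give at least one animal per strain")
        if any(v <= 0 for v in self.region_volumes_mm3.values()):
            raise ValueError("all region volumes must be positive")
        if any(a <= 0 for a in self.region_adc.values()):
            raise ValueError("all true ADC values must be positive")
        b = np.asarray(self.b_values, dtype=float)
        if 0.0 not in b or not np.any(b > 0):
            raise ValueError("b_values must contain 0 and at least one positive value")
        for name, val in (
            ("fov_mm", self.fov_mm), ("slice_thickness_mm", self.slice_thickness_mm),
            ("pixel_size_um", self.pixel_size_um), ("fluor_background", self.fluor_background),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.matrix < 16 or self.n_slices < 1 or self.n_directions < 1:
            raise ValueError("matrix/n_slices/n_directions too small")
        if self.noise_sd_fraction < 0 or self.fluor_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        for strain, pct in self.water_content_pct.items():
            if not 0.0 < pct < 100.0:
                raise ValueError(f"water content percent for {strain} must lie in (0, 100)")
        if self.n_auc_outliers < 0 or self.auc_outlier_factor <= 0:
            raise ValueError("invalid outlier injection settings")

    # -- convenience -----------------------------------------------------
    @property
    def spacing(self) -> tuple[float, float, float]:
        d = self.fov_mm / self.matrix
        return (d, d, self.slice_thickness_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def animals(self) -> list[tuple[str, str]]:
        """Stable ``(animal_id, strain)`` roster, e.g. WKY01..WKY11, SHR01..SHR10."""
        out = []
        for strain in self.n_per_group:
            for i in range(self.n_per_group[strain]):
                out.append((f"{strain}{i + 1:02d}", strain))
        return out

    def effects_summary(self) -> dict[str, float]:
        """Injected between-strain effects, as SHR/WKY ratios or differences."""
        vol = self.region_volumes_mm3
        adc = self.region_adc
        halo = self.halo_params
        return {
            "lv_volume_ratio": vol[("SHR", "LV")] / vol[("WKY", "LV")],
            "ic_volume_ratio": vol[("SHR", "IC")] / vol[("WKY", "IC")],
            "cc_volume_ratio": vol[("SHR", "cc")] / vol[("WKY", "cc")],
            "parenchymal_adc_ratio": adc[("SHR", "parenchyma")] / adc[("WKY", "parenchyma")],
            "water_content_diff_pp": self.water_content_pct["SHR"] - self.water_content_pct["WKY"],
            "cc_capillary_halo_ratio": (
                halo[("SHR", "capillary", "cc")].peak_height
                / halo[("WKY", "capillary", "cc")].peak_height
            ),
        }


def _rng(spec: PhantomSpec, code: int, *keys: str | int) -> np.random.Generator:
    ints = [spec.seed, code] + [
        crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(ints))


def _strain_of(spec: PhantomSpec, animal_id: str) -> str:
    for aid, strain in spec.animals():
        if aid == animal_id:
            return strain
    raise KeyError(f"unknown animal {animal_id!r}")


# ---------------------------------------------------------------------------
# imaging phantom
# ---------------------------------------------------------------------------

def _animal_imaging_latents(spec: PhantomSpec, strain: str, animal_id: str):
    """Per-animal true region volumes and the parenchymal ADC factor."""
    rng = _rng(spec, _IMAGING, strain, animal_id, 0)
    vols = {}
    for region in ("IC",) + tuple(r for r in MASK_REGIONS if r != "parenchyma"):
        base = spec.region_volumes_mm3[(strain, region)]
        vols[region] = base * (1.0 + spec.volume_animal_cv * rng.standard_normal())
    adc_factor = 1.0 + spec.adc_animal_cv * rng.standard_normal()
    return vols, adc_factor


def make_imaging_phantom(
    spec: PhantomSpec, strain: str, animal_id: str
) -> tuple[VoxelGrid, DwiSeries, SegmentationMask, AdcMap]:
    """Build one animal's co-registered T2w volume, DWI series, mask and true ADC.

    Every labelled region is a connected voxel set whose count is
    ``round(target / voxel volume)`` — the closest achievable volume. The
    ventricles carry CSF-like fast diffusion; parenchymal regions carry the
    spec's strain/region ADC scaled by a per-animal factor. DWI signals obey
    ``S(b) = S0 exp(-b ADC)`` with relative Gaussian noise.
    """
    if strain not in spec.n_per_group:
        raise KeyError(f"unknown strain {strain!r}; have {list(spec.n_per_group)}")
    vols, adc_factor = _animal_imaging_latents(spec, strain, animal_id)
    nx = ny = spec.matrix
    nz = spec.n_slices
    dx, dy, dz = spec.spacing
    vv = spec.voxel_volume_mm3

    xs = (np.arange(nx) + 0.5) * dx - spec.fov_mm / 2.0
    ys = (np.arange(ny) + 0.5) * dy - spec.fov_mm / 2.0
    zs = (np.arange(nz) + 0.5) * dz - nz * dz / 2.0
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    def nearest_voxels(centre: tuple[float, float, float], n: int) -> np.ndarray:
        d2 = (X - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (Z - centre[2]) ** 2
        flat = d2.ravel()
        if n > flat.size:
            raise ValueError("matrix too small to place requested volumes")
        idx = np.argpartition(flat, n - 1)[:n]
        return idx

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    n_ic = int(round(vols["IC"] / vv))
    ic_idx = nearest_voxels((0.0, 0.0, 0.0), n_ic)
    # the intracranial ball must not touch the grid border
    ii, jj, kk = np.unravel_index(ic_idx, labels.shape)
    if (ii.min() == 0 or jj.min() == 0 or kk.min() == 0
            or ii.max() == nx - 1 or jj.max() == ny - 1 or kk.max() == nz - 1):
        raise ValueError("matrix too small to place requested volumes")
    labels.ravel()[ic_idx] = _LABELS["parenchyma"]

    for region, offset in _REGION_OFFSETS.items():
        n = int(round(vols[region] / vv))
        idx = nearest_voxels(offset, n)
        if not np.all(labels.ravel()[idx] == _LABELS["parenchyma"]):
            raise ValueError(
                f"region {region!r} does not fit inside the intracranial ball; "
                "matrix too small or volumes too large"
            )
        labels.ravel()[idx] = _LABELS[region]

    mask = SegmentationMask(
        labels=labels, label_table=dict(_LABELS), composites=dict(_COMPOSITES),
        spacing=spec.spacing,
    )

    # true ADC per voxel
    adc_true = np.zeros(labels.shape)
    valid = labels > 0
    adc_true[labels == _LABELS["parenchyma"]] = (
        spec.region_adc[(strain, "parenchyma")] * adc_factor
    )
    for region in _REGION_OFFSETS:
        value = (
            spec.region_adc[(strain, "CSF")]
            if region in CSF_REGIONS
            else spec.region_adc[(strain, region)] * adc_factor
        )
        adc_true[labels == _LABELS[region]] = value
    adc_true[~valid] = np.nan
    true_map = AdcMap(adc=adc_true, valid=valid)

    # DWI signals
    rng = _rng(spec, _IMAGING, strain, animal_id, 1)
    b = np.asarray(spec.b_values, dtype=float)
    s0 = np.where(valid, 1200.0, 0.0)
    decay = np.where(valid[None], np.exp(-b[:, None, None, None] * np.nan_to_num(adc_true)[None]), 0.0)
    clean = s0[None, None] * decay[:, None]
    signals = clean * (1.0 + spec.noise_sd_fraction * rng.standard_normal(
        (b.size, spec.n_directions) + labels.shape))
    np.maximum(signals, 0.0, out=signals)
    dwi = DwiSeries(signals=signals, b_values=b, spacing=spec.spacing)

    # schematic T2w contrast: CSF bright, parenchyma mid, background dark
    t2 = np.full(labels.shape, 20.0)
    t2[valid] = 500.0
    t2[np.isin(labels, [_LABELS[r] for r in CSF_REGIONS])] = 900.0
    t2 += 5.0 * _rng(spec, _IMAGING, strain, animal_id, 2).standard_normal(labels.shape)
    grid = VoxelGrid(intensities=t2.astype(np.float32), spacing=spec.spacing)

    return grid, dwi, mask, true_map


# ---------------------------------------------------------------------------
# fluorescence phantom
# ---------------------------------------------------------------------------

def analytic_halo_auc(
    height: float, decay_um: float, offset_um: float = 1.5, length_um: float = 50.0
) -> float:
    """Closed-form AUC of the normalized halo profile over [0, length] µm.

    The normalized profile from the lumen edge is
    ``g(x) = height * exp(-(x - offset)² / (2 decay²))``, so
    ``AUC = height * decay * sqrt(pi/2) * (erf((L-off)/(decay sqrt2)) + erf(off/(decay sqrt2)))``.
    """
    s2 = decay_um * math.sqrt(2.0)
    return (
        height * decay_um * math.sqrt(math.pi / 2.0)
        * (erf((length_um - offset_um) / s2) + erf(offset_um / s2))
    )


def _ellipse_signed_distance(dx: np.ndarray, dy: np.ndarray, a: float, b: float) -> np.ndarray:
    """Signed distance from points to an axis-aligned ellipse boundary.

    Positive outside, negative inside (distance to the nearest boundary
    point). Vectorized Newton iteration on the boundary angle; a/b are
    semi-axes. Accuracy degrades only deep inside near the centre, where the
    halo is zero anyway.
    """
    px = np.abs(dx)
    py = np.abs(dy)
    inside = (px / a) ** 2 + (py / b) ** 2 <= 1.0
    t = np.arctan2(a * py, b * px)
    ab = a * a - b * b
    for _ in range(10):
        ct, st = np.cos(t), np.sin(t)
        f = ab * ct * st - px * a * st + py * b * ct
        fp = ab * (ct * ct - st * st) - px * a * ct - py * b * st
        step = f / np.where(np.abs(fp) > 1e-12, fp, 1e-12)
        t = np.clip(t - step, 0.0, math.pi / 2.0)
    ct, st = np.cos(t), np.sin(t)
    d = np.hypot(a * ct - px, b * st - py)
    d[inside] *= -1.0
    return d


def _vessel_plan(spec: PhantomSpec, strain: str, region: str, animal_id: str,
                 capillary_height_factor: float = 1.0):
    """Deterministic per-vessel geometry and halo truth for one micrograph."""
    if strain not in spec.n_per_group:
        raise KeyError(f"unknown strain {strain!r}")
    if region not in MICROSCOPY_REGIONS:
        raise KeyError(f"unknown microscopy region {region!r}; have {MICROSCOPY_REGIONS}")
    classes = ("arteriole", "capillary", "venule") if region == "Cx" else ("capillary",)
    ncols = spec.n_vessels_per_class
    col_spacing = 80.0 if region == "Cx" else 50.0
    row_spacing = 130.0
    margin_x = 60.0 if region == "Cx" else 45.0
    margin_top, margin_bottom = 80.0, 80.0
    width_um = 2 * margin_x + (ncols - 1) * col_spacing
    height_um = margin_top + (len(classes) - 1) * row_spacing + margin_bottom

    rng = _rng(spec, _FLUOR, strain, animal_id, region)
    # per-(animal, region) expression factor: bounded uniform, so that gross
    # injected outliers are the only values outside the Grubbs envelope
    j = spec.halo_animal_jitter
    animal_factor = float(rng.uniform(1.0 - j, 1.0 + j))

    vessels = []
    for irow, cls in enumerate(classes):
        geom = _VESSEL_GEOM[cls]
        halo = spec.halo_params[(strain, cls, region)]
        for icol in range(ncols):
            cx = margin_x + icol * col_spacing + float(rng.uniform(-3.0, 3.0))
            cy = margin_top + irow * row_spacing + float(rng.uniform(-2.0, 2.0))
            scale = 1.0 + float(rng.uniform(-0.05, 0.05))
            a = geom["long"] / 2.0 * scale
            bsemi = geom["short"] / 2.0 * scale
            height = halo.peak_height * animal_factor * (
                1.0 + spec.halo_vessel_cv * float(rng.standard_normal())
            )
            if cls == "capillary":
                height *= capillary_height_factor
            vessels.append(
                {
                    "id": f"{animal_id}-{region}-{cls}{icol + 1}",
                    "class": cls,
                    "cx_um": cx, "cy_um": cy,
                    "a_um": a, "b_um": bsemi,
                    "height": max(height, 0.0),
                    "offset_um": halo.peak_offset_um,
                    "decay_um": halo.decay_um,
                }
            )
    return vessels, (width_um, height_um)


def make_fluorescence_phantom(
    spec: PhantomSpec,
    strain: str,
    region: str,
    animal_id: str = "A00",
    capillary_height_factor: float = 1.0,
) -> tuple[FluorescenceImage, list[VesselAnnotation]]:
    """Render one micrograph (aqp4/myosin/nuclei/gfap channels) plus annotations.

    Vessels are elliptical lumina in a clearance-respecting grid layout
    (cortex: a row each of arterioles, capillaries and venules; other
    regions: capillaries only). The AQP4 channel is a uniform background plus
    per-vessel Gaussian halo bumps outside the lumen; myosin marks arteriole
    walls only. ``capillary_height_factor`` scales capillary halos (used for
    gross-outlier injection by :func:`make_study`).
    """
    vessels, (width_um, height_um) = _vessel_plan(
        spec, strain, region, animal_id, capillary_height_factor
    )
    px = spec.pixel_size_um
    w = int(round(width_um / px))
    h = int(round(height_um / px))
    B = spec.fluor_background

    halo_add = np.zeros((h, w))
    myosin_add = np.zeros((h, w))
    for v in vessels:
        a_px, b_px = v["a_um"] / px, v["b_um"] / px
        cx_px, cy_px = v["cx_um"] / px, v["cy_um"] / px
        reach = v["offset_um"] + 6.0 * v["decay_um"] + 3.0
        x0 = max(int(cx_px - a_px - reach / px), 0)
        x1 = min(int(cx_px + a_px + reach / px) + 2, w)
        y0 = max(int(cy_px - b_px - reach / px), 0)
        y1 = min(int(cy_px + b_px + reach / px) + 2, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        ddx = (xx - cx_px) * px
        ddy = (yy - cy_px) * px
        # signed distance keeps the halo smooth across the lumen edge, as a
        # point-spread function would; the bump tail decays to ~0 inside
        d = _ellipse_signed_distance(ddx, ddy, v["a_um"], v["b_um"])
        halo_add[y0:y1, x0:x1] += (
            B * v["height"]
            * np.exp(-((d - v["offset_um"]) ** 2) / (2.0 * v["decay_um"] ** 2))
        )
        if v["class"] == "arteriole":
            ring = (d > 0) & (d < 2.5)
            myosin_add[y0:y1, x0:x1][ring] += 150.0

    rng = _rng(spec, _FLUOR, strain, animal_id, region, 1)
    aqp4 = B + halo_add
    aqp4 += spec.fluor_noise_sd * rng.standard_normal((h, w))
    myosin = 20.0 + myosin_add + 2.0 * rng.standard_normal((h, w))
    nuclei = 10.0 + 2.0 * rng.standard_normal((h, w))
    gfap_level = spec.gfap_mean[strain] + spec.gfap_animal_sd * float(
        _rng(spec, _FLUOR, strain, animal_id, region, 2).standard_normal()
    )
    gfap = gfap_level + 2.0 * rng.standard_normal((h, w))

    img = FluorescenceImage(
        channels={
            "aqp4": aqp4.astype(np.float32),
            "myosin": myosin.astype(np.float32),
            "nuclei": nuclei.astype(np.float32),
            "gfap": gfap.astype(np.float32),
        },
        pixel_size_um=px,
    )

    theta = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
    annotations = []
    for v in vessels:
        poly = np.stack(
            [
                (v["cx_um"] + v["a_um"] * np.cos(theta)) / px,
                (v["cy_um"] + v["b_um"] * np.sin(theta)) / px,
            ],
            axis=1,
        )
        annotations.append(
            VesselAnnotation(
                vessel_id=v["id"],
                polygon_px=poly,
                centroid_px=(v["cx_um"] / px, v["cy_um"] / px),
                shortest_axis_um=2.0 * v["b_um"],
                longest_axis_um=2.0 * v["a_um"],
                myosin_positive=v["class"] == "arteriole",
                region=region,
                animal_id=animal_id,
            )
        )
    return img, annotations


def fluorescence_truth(
    spec: PhantomSpec,
    strain: str,
    region: str,
    animal_id: str = "A00",
    capillary_height_factor: float = 1.0,
) -> dict[str, dict[str, float]]:
    """Ground truth per vessel id: halo parameters and analytic profile AUC."""
    vessels, _ = _vessel_plan(spec, strain, region, animal_id, capillary_height_factor)
    return {
        v["id"]: {
            "class": v["class"],
            "height": v["height"],
            "offset_um": v["offset_um"],
            "decay_um": v["decay_um"],
            "auc": analytic_halo_auc(v["height"], v["decay_um"], v["offset_um"]),
        }
        for v in vessels
    }


# ---------------------------------------------------------------------------
# gravimetry + electropherograms
# ---------------------------------------------------------------------------

def make_gravimetry_records(spec: PhantomSpec) -> list[GravimetryRecord]:
    """Wet/dry hemisphere weights reproducing each strain's water percent.

    The water mass *fraction* is drawn around the strain target with Gaussian
    jitter (``water_jitter_sd_pct`` percentage points); the dry weight is
    drawn around the strain's dry mass; the wet weight is the inverse
    construction ``dry / (1 - fraction)``, so zero jitter reproduces the
    target percent exactly.
    """
    records = []
    for animal_id, strain in spec.animals():
        rng = _rng(spec, _GRAV, strain, animal_id)
        frac = (
            spec.water_content_pct[strain]
            + spec.water_jitter_sd_pct * float(rng.standard_normal())
        ) / 100.0
        if not 0.0 < frac < 1.0:
            raise ValueError("drawn water fraction left (0, 1); reduce jitter")
        dry = spec.dry_weight_g[strain] * (
            1.0 + spec.dry_weight_cv * float(rng.standard_normal())
        )
        records.append(
            GravimetryRecord(animal_id=animal_id, strain=strain,
                             wet_g=dry / (1.0 - frac), dry_g=dry)
        )
    return records


_WES_KDA = np.arange(12.0, 230.0 + 0.25, 0.25)
_WES_SIGMA = {"aqp4": 0.8, "actin": 1.0}
_WES_CENTRE = {"aqp4": 34.0, "actin": 48.0}


def make_electropherograms(spec: PhantomSpec) -> dict[str, list[Electropherogram]]:
    """Replicate separation traces per animal with Gaussian AQP4/actin peaks."""
    out: dict[str, list[Electropherogram]] = {}
    for animal_id, strain in spec.animals():
        rng = _rng(spec, _WES, strain, animal_id)
        ratio_animal = spec.wes_ratio[strain] * (
            1.0 + spec.wes_animal_cv * float(rng.standard_normal())
        )
        runs = []
        for run in range(spec.n_wes_runs):
            amp_actin = 3000.0 * (1.0 + 0.05 * float(rng.standard_normal()))
            ratio_run = ratio_animal * (1.0 + spec.wes_run_cv * float(rng.standard_normal()))
            amp_aqp4 = ratio_run * amp_actin * _WES_SIGMA["actin"] / _WES_SIGMA["aqp4"]
            signal = (
                5.0
                + amp_aqp4 * np.exp(-((_WES_KDA - _WES_CENTRE["aqp4"]) ** 2)
                                    / (2.0 * _WES_SIGMA["aqp4"] ** 2))
                + amp_actin * np.exp(-((_WES_KDA - _WES_CENTRE["actin"]) ** 2)
                                     / (2.0 * _WES_SIGMA["actin"] ** 2))
                + 1.0 * rng.standard_normal(_WES_KDA.size)
            )
            runs.append(
                Electropherogram(kda=_WES_KDA.copy(), signal=np.maximum(signal, 0.0),
                                 run_id=f"run{run + 1}", animal_id=animal_id)
            )
        out[animal_id] = runs
    return out


def wes_truth(spec: PhantomSpec) -> dict[str, float]:
    """Per-animal ground-truth mean AQP4/actin ratio (mean of per-run targets)."""
    truths = {}
    for animal_id, strain in spec.animals():
        rng = _rng(spec, _WES, strain, animal_id)
        ratio_animal = spec.wes_ratio[strain] * (
            1.0 + spec.wes_animal_cv * float(rng.standard_normal())
        )
        run_ratios = []
        for _ in range(spec.n_wes_runs):
            rng.standard_normal()  # amp_actin draw
            run_ratios.append(ratio_animal * (1.0 + spec.wes_run_cv * float(rng.standard_normal())))
            rng.standard_normal(_WES_KDA.size)  # trace noise draw
        truths[animal_id] = float(np.mean(run_ratios))
    return truths


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyDataset:
    """All inputs for one synthetic study, with per-animal lazy imaging.

    Imaging and microscopy are generated on demand (deterministically) to
    keep memory flat over a 21-animal cohort; gravimetry and
    electropherograms are small and held eagerly.
    """

    spec: PhantomSpec
    animals: list[tuple[str, str]]
    gravimetry: list[GravimetryRecord]
    electropherograms: dict[str, list[Electropherogram]]
    outlier_cells: list[tuple[str, str]]  # (animal_id, region) with a gross halo outlier

    def strain_of(self, animal_id: str) -> str:
        return _strain_of(self.spec, animal_id)

    def imaging(self, animal_id: str):
        return make_imaging_phantom(self.spec, self.strain_of(animal_id), animal_id)

    def microscopy(self, animal_id: str, region: str):
        factor = (
            self.spec.auc_outlier_factor
            if (animal_id, region) in self.outlier_cells
            else 1.0
        )
        return make_fluorescence_phantom(
            self.spec, self.strain_of(animal_id), region, animal_id,
            capillary_height_factor=factor,
        )

    def microscopy_truth(self, animal_id: str, region: str):
        factor = (
            self.spec.auc_outlier_factor
            if (animal_id, region) in self.outlier_cells
            else 1.0
        )
        return fluorescence_truth(
            self.spec, self.strain_of(animal_id), region, animal_id,
            capillary_height_factor=factor,
        )

    def imaging_truth(self, animal_id: str):
        strain = self.strain_of(animal_id)
        vols, adc_factor = _animal_imaging_latents(self.spec, strain, animal_id)
        return {"volumes_mm3": vols, "adc_factor": adc_factor}


def make_study(spec: PhantomSpec) -> StudyDataset:
    """Bundle the full two-strain study with the spec's group effects injected.

    Gross capillary-halo outliers (``n_auc_outliers`` of them, scaled by
    ``auc_outlier_factor``) are injected into randomly chosen
    (animal, region) cells drawn from the regions that carry no strain
    effect, so outlier screening and effect detection stay separable.
    """
    animals = spec.animals()
    candidate_regions = ("Hc", "Tha", "Hy", "Pir")
    combos = [(aid, region) for aid, _ in animals for region in candidate_regions]
    rng = _rng(spec, _OUTLIER, "outliers")
    if spec.n_auc_outliers > len(combos):
        raise ValueError("more outliers requested than available (animal, region) cells")
    chosen = rng.choice(len(combos), size=spec.n_auc_outliers, replace=False)
    outliers = [combos[i] for i in sorted(chosen)]
    return StudyDataset(
        spec=spec,
        animals=animals,
        gravimetry=make_gravimetry_records(spec),
        electropherograms=make_electropherograms(spec),
        outlier_cells=outliers,
    )
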