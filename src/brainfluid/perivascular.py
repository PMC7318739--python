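"""Perivascular AQP4 quantification from fluorescence micrographs.

AQP4 is concentrated at astrocytic endfeet that ensheath brain vessels, so
its spatial extent is scored from lumen-anchored radial intensity profiles:

* vessels are classified from their annotation — arteriole if the shortest-
  axis diameter exceeds 20 µm with myosin immunoreactivity, venule if the
  same size without myosin, capillary otherwise;
* a 50 µm long, 8.5 µm wide straight band is cast perpendicular to the
  vessel's longest axis, starting at the first AQP4-immunoreactive pixel
  seen from the lumen;
* profiles are normalized to the image's AQP4 background (background maps
  to zero), averaged per animal, and scored by trapezoidal area under the
  curve (AUC) over 0–50 µm.

Vessel annotation (lumen polygon, axes, myosin flag) is an input — from a
human or from the phantom generator; vessel segmentation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "FluorescenceImage",
    "VesselAnnotation",
    "RadialProfile",
    "ProfileSummary",
    "VESSEL_CLASSES",
    "ProfileExtractionError",
    "classify_vessel",
    "sample_vessels",
    "background_stats",
    "extract_profile",
    "normalize_profile",
    "mean_profile_per_animal",
    "profile_auc",
    "region_mean_intensity",
]

VESSEL_CLASSES = ("arteriole", "capillary", "venule")

# classification constants: shortest-axis diameter above which a vessel is
# arteriole/venule rather than capillary
LARGE_VESSEL_DIAMETER_UM = 20.0


class ProfileExtractionError(ValueError):
    """Raised when no valid 50 µm profile can be cast for a vessel."""


@dataclass
class FluorescenceImage:
    """Named 2-D channels (at least aqp4, myosin, nuclei) at one pixel pitch."""

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"all channels must share a shape, got {shapes}")
        self.channels = {name: np.asarray(ch, dtype=float) for name, ch in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}; have {sorted(self.channels)}") from None


@dataclass
class VesselAnnotation:
    """Vessel geometry: closed lumen polygon (px, (x, y) order) plus axes in µm."""

    vessel_id: str
    polygon_px: np.ndarray  # (N, 2), closed implicitly (last joins first)
    centroid_px: tuple[float, float]
    shortest_axis_um: float
    longest_axis_um: float
    myosin_positive: bool
    region: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.polygon_px = np.asarray(self.polygon_px, dtype=float)
        if self.polygon_px.ndim != 2 or self.polygon_px.shape[1] != 2 or len(self.polygon_px) < 3:
            raise ValueError("polygon_px must be an (N>=3, 2) array")
        if self.shortest_axis_um > self.longest_axis_um:
            raise ValueError("shortest axis exceeds longest axis")
        poly = Polygon(self.polygon_px)
        if not poly.is_valid:
            raise ValueError(f"lumen polygon of vessel {self.vessel_id!r} is not simple")

    def shapely(self) -> Polygon:
        return Polygon(self.polygon_px)


@dataclass
class RadialProfile:
    """Intensity against distance (µm) from the immunoreactivity anchor."""

    distances_um: np.ndarray
    intensity: np.ndarray
    vessel_id: str = ""
    vessel_class: str = ""
    region: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.distances_um.shape != self.intensity.shape:
            raise ValueError("distances and intensity must share a shape")
        if not np.all(np.diff(self.distances_um) > 0):
            raise ValueError("distances must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("profile intensity must be finite")


@dataclass
class ProfileSummary:
    """Per-animal mean profile and its AUC for one grouping key (class or region)."""

    animal_id: str
    key: str
    mean_profile: RadialProfile
    auc: float
    n_vessels: int


def classify_vessel(v: VesselAnnotation) -> str:
    """Rule-based class: >20 µm shortest axis splits arteriole (myosin+) from
    venule (myosin-); everything at or below 20 µm is a capillary."""
    if v.shortest_axis_um > LARGE_VESSEL_DIAMETER_UM:
        return "arteriole" if v.myosin_positive else "venule"
    return "capillary"


def sample_vessels(
    vessels: Sequence[VesselAnnotation], n_per_class: int, seed: int
) -> dict[str, list[VesselAnnotation]]:
    """Uniform without-replacement sample of ``n_per_class`` vessels per class."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[VesselAnnotation]] = {c: [] for c in VESSEL_CLASSES}
    for v in vessels:
        by_class[classify_vessel(v)].append(v)
    out: dict[str, list[VesselAnnotation]] = {}
    for cls in VESSEL_CLASSES:
        pool = by_class[cls]
        if len(pool) < n_per_class:
            raise ValueError(
                f"cannot sample {n_per_class} {cls}s: only {len(pool)} available"
            )
        idx = rng.choice(len(pool), size=n_per_class, replace=False)
        out[cls] = [pool[i] for i in sorted(idx)]
    return out


def background_stats(
    img: FluorescenceImage,
    vessels: Sequence[VesselAnnotation],
    channel: str = "aqp4",
    min_distance_um: float = 25.0,
    subsample: int = 4,
) -> tuple[float, float]:
    """Mean and SD of the channel at least ``min_distance_um`` from any vessel.

    The exclusion zone uses a conservative bounding-circle distance per vessel
    (centroid distance minus the longest semi-axis plus halo margin), which is
    ample for background estimation.
    """
    ch = img.channel(channel)
    h, w = ch.shape
    ys, xs = np.mgrid[0:h:subsample, 0:w:subsample]
    pos = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    keep = np.ones(len(pos), dtype=bool)
    min_px = min_distance_um / img.pixel_size_um
    for v in vessels:
        c = np.asarray(v.centroid_px)
        r_px = (v.longest_axis_um / 2.0) / img.pixel_size_um
        d = np.hypot(pos[:, 0] - c[0], pos[:, 1] - c[1]) - r_px
        keep &= d > min_px
    if not keep.any():
        raise ValueError("no background pixels at the requested vessel clearance")
    vals = ch[ys.ravel()[keep], xs.ravel()[keep]]
    return float(vals.mean()), float(vals.std(ddof=1))


def _major_axis_direction(polygon_px: np.ndarray) -> np.ndarray:
    """Unit vector of the lumen polygon's major axis from vertex second moments."""
    pts = polygon_px - polygon_px.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, np.argmax(evals)]
    return u / np.hypot(*u)


def _ray_candidates(u: np.ndarray) -> list[np.ndarray]:
    """The two rays perpendicular to the major axis, positive axis first."""
    w = np.array([-u[1], u[0]])
    if w[1] < 0 or (w[1] == 0 and w[0] < 0):
        w = -w
    return [w, -w]


def _sample(ch: np.ndarray, pts_px: np.ndarray) -> np.ndarray:
    """Bilinear samples of ``ch`` at (x, y) pixel positions."""
    return map_coordinates(ch, [pts_px[:, 1], pts_px[:, 0]], order=1, mode="nearest")


def extract_profile(
    img: FluorescenceImage,
    v: VesselAnnotation,
    length_um: float = 50.0,
    width_um: float = 8.5,
    *,
    channel: str = "aqp4",
    threshold: float = 0.0,
    neighbours: Iterable[VesselAnnotation] = (),
    max_anchor_search_um: float = 10.0,
) -> RadialProfile:
    """Cast the wide-line profile for one vessel.

    The ray runs perpendicular to the vessel's longest axis, outward from the
    centroid, on whichever side offers the full ``length_um`` of clearance
    (positive image axis first when both do). The profile starts at the first
    pixel along the ray — searching outward from the lumen boundary — whose
    ``channel`` intensity exceeds ``threshold`` (see :func:`background_stats`
    for the conventional ``mean + 2 SD`` threshold). Samples are means over
    ``width_um`` of parallel sub-rays at pixel pitch, bilinearly interpolated.

    Raises :class:`ProfileExtractionError` if no side has clearance, if no
    immunoreactive pixel lies within ``max_anchor_search_um`` of the lumen,
    or if the ray crosses a neighbouring vessel's lumen.
    """
    ch = img.channel(channel)
    px = img.pixel_size_um
    h, w = ch.shape
    poly = v.shapely()
    centroid = np.asarray(v.centroid_px, dtype=float)
    u = _major_axis_direction(v.polygon_px)
    length_px = length_um / px
    half_band_px = (width_um / 2.0) / px

    chosen = None
    reasons = []
    for d in _ray_candidates(u):
        # lumen exit point of the outward ray
        far = centroid + d * (length_px + max(h, w))
        hit = poly.exterior.intersection(LineString([tuple(centroid), tuple(far)]))
        if hit.is_empty:
            reasons.append("ray does not leave the lumen")
            continue
        pts = getattr(hit, "geoms", [hit])
        boundary = min(
            (np.array([g.x, g.y]) for g in pts if isinstance(g, Point)),
            key=lambda p: np.hypot(*(p - centroid)),
            default=None,
        )
        if boundary is None:
            reasons.append("degenerate lumen boundary intersection")
            continue
        # anchor: first immunoreactive pixel outward from the lumen boundary
        n_search = int(np.ceil(max_anchor_search_um / px)) + 1
        search_pts = boundary[None, :] + np.arange(n_search)[:, None] * d[None, :]
        vals = _sample(ch, search_pts)
        above = np.flatnonzero(vals > threshold)
        if above.size == 0:
            reasons.append(
                f"no pixel above threshold {threshold:.3g} within "
                f"{max_anchor_search_um} µm of the lumen"
            )
            continue
        anchor = search_pts[above[0]]
        # clearance: band corners at both ends must stay inside the image
        perp = np.array([-d[1], d[0]])
        corners = np.array(
            [
                anchor + s * half_band_px * perp + t * length_px * d
                for s in (-1.0, 1.0)
                for t in (0.0, 1.0)
            ]
        )
        if (corners[:, 0].min() < 0 or corners[:, 0].max() > w - 1
                or corners[:, 1].min() < 0 or corners[:, 1].max() > h - 1):
            reasons.append("ray exits the image before the full profile length")
            continue
        chosen = (d, anchor, perp)
        break
    if chosen is None:
        raise ProfileExtractionError(
            f"vessel {v.vessel_id!r}: no valid profile ray ({'; '.join(reasons)})"
        )
    d, anchor, perp = chosen

    n_samples = int(round(length_px)) + 1
    distances_px = np.linspace(0.0, length_px, n_samples)
    ray_pts = anchor[None, :] + distances_px[:, None] * d[None, :]

    for other in neighbours:
        if other.vessel_id == v.vessel_id:
            continue
        opoly = other.shapely()
        if any(opoly.contains(Point(*p)) for p in ray_pts[::4]):
            raise ProfileExtractionError(
                f"vessel {v.vessel_id!r}: profile crosses vessel {other.vessel_id!r}; "
                "reselect the vessel"
            )

    n_sub = int(round(width_um / px))
    offsets = (np.arange(n_sub + 1) - n_sub / 2.0)  # px, spanning width_um
    intensity = np.zeros(n_samples)
    for off in offsets:
        intensity += _sample(ch, ray_pts + off * perp[None, :])
    intensity /= offsets.size

    return RadialProfile(
        distances_um=distances_px * px,
        intensity=intensity,
        vessel_id=v.vessel_id,
        vessel_class=classify_vessel(v),
        region=v.region,
        animal_id=v.animal_id,
    )


def normalize_profile(p: RadialProfile, background: float) -> RadialProfile:
    """Express intensity relative to background: ``raw/background - 1``.

    Background-level signal maps to exactly zero, and rescaling raw intensity
    and background together leaves the result unchanged.
    """
    if background <= 0:
        raise ValueError(f"background must be positive, got {background}")
    return replace(p, intensity=p.intensity / background - 1.0)


def mean_profile_per_animal(
    profiles: Sequence[RadialProfile], group_by: str = "vessel_class"
) -> ProfileSummary:
    """Pointwise mean of one animal's profiles sharing a class (or region)."""
    if not profiles:
        raise ValueError("no profiles supplied")
    if group_by not in ("vessel_class", "region"):
        raise ValueError("group_by must be 'vessel_class' or 'region'")
    animals = {p.animal_id for p in profiles}
    if len(animals) != 1:
        raise ValueError(f"profiles mix animals: {sorted(animals)}")
    keys = {getattr(p, group_by) for p in profiles}
    if len(keys) != 1:
        raise ValueError(f"profiles mix {group_by} values: {sorted(keys)}")
    grid = profiles[0].distances_um
    for p in profiles[1:]:
        if p.distances_um.shape != grid.shape or not np.allclose(p.distances_um, grid):
            raise ValueError("profiles are sampled on different distance grids")
    mean_int = np.mean([p.intensity for p in profiles], axis=0)
    mean = RadialProfile(
        distances_um=grid,
        intensity=mean_int,
        vessel_class=profiles[0].vessel_class,
        region=profiles[0].region,
        animal_id=profiles[0].animal_id,
    )
    return ProfileSummary(
        animal_id=profiles[0].animal_id,
        key=str(keys.pop()),
        mean_profile=mean,
        auc=profile_auc(mean),
        n_vessels=len(profiles),
    )


def profile_auc(p: RadialProfile | ProfileSummary) -> float:
    """Trapezoidal AUC over the profile; negative excursions are retained."""
    prof = p.mean_profile if isinstance(p, ProfileSummary) else p
    return float(np.trapezoid(prof.intensity, prof.distances_um))


def region_mean_intensity(
    img: FluorescenceImage, region_mask: np.ndarray, region: int, channel: str
) -> float:
    """Arithmetic mean of a channel over the pixels of one labelled region."""
    ch = img.channel(channel)
    region_mask = np.asarray(region_mask)
    if region_mask.shape != ch.shape:
        raise ValueError("region mask must match the image shape")
    sel = region_mask == region
    if not sel.any():
        raise ValueError(f"region {region!r} is empty")
    return float(ch[sel].mean())
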