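"""File formats.

NIfTI for volumes and label masks (spacing in the affine), multi-page TIFF
for fluorescence channels (channel names and pixel pitch in the image
description), JSON for vessel annotations and DWI sidecars, CSV for
gravimetry, electropherograms and result tables, YAML for the phantom spec.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .adc import DwiSeries
from .gravimetry import GravimetryRecord
from .perivascular import FluorescenceImage, VesselAnnotation
from .protein import Electropherogram
from .synthetic import HaloParams, PhantomSpec, StudyDataset, make_study
from .volumetry import SegmentationMask, VoxelGrid

__all__ = [
    "save_volume", "load_volume", "save_mask", "load_mask",
    "save_dwi", "load_dwi", "save_fluorescence", "load_fluorescence",
    "save_annotations", "load_annotations",
    "save_gravimetry", "load_gravimetry",
    "save_electropherogram", "load_electropherogram",
    "save_spec", "load_spec", "simulate_to_dir",
]


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume(grid: VoxelGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(grid.intensities, dtype=np.float32),
                             _affine(grid.spacing)), str(path))


def load_volume(path: str | Path) -> VoxelGrid:
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return VoxelGrid(intensities=np.asarray(img.dataobj), spacing=spacing)


def save_mask(mask: SegmentationMask, nifti_path: str | Path, labels_path: str | Path) -> None:
    if mask.spacing is None:
        raise ValueError("mask needs spacing to be written as NIfTI")
    nib.save(nib.Nifti1Image(np.asarray(mask.labels, dtype=np.int16),
                             _affine(mask.spacing)), str(nifti_path))
    with open(labels_path, "w") as fh:
        yaml.safe_dump(
            {"label_table": dict(mask.label_table),
             "composites": {k: list(v) for k, v in mask.composites.items()}},
            fh,
        )


def load_mask(nifti_path: str | Path, labels_path: str | Path) -> SegmentationMask:
    img = nib.load(str(nifti_path))
    with open(labels_path) as fh:
        meta = yaml.safe_load(fh)
    return SegmentationMask(
        labels=np.asarray(img.dataobj).astype(np.int16),
        label_table=meta["label_table"],
        composites={k: tuple(v) for k, v in meta.get("composites", {}).items()},
        spacing=tuple(float(s) for s in img.header.get_zooms()[:3]),
    )


def save_dwi(dwi: DwiSeries, nifti_path: str | Path, sidecar_path: str | Path) -> None:
    nb, nd = dwi.signals.shape[:2]
    flat = dwi.signals.reshape((nb * nd,) + dwi.shape).transpose(1, 2, 3, 0)
    nib.save(nib.Nifti1Image(flat.astype(np.float32), _affine(dwi.spacing)), str(nifti_path))
    with open(sidecar_path, "w") as fh:
        json.dump({"b_values": list(map(float, dwi.b_values)), "n_directions": nd}, fh)


def load_dwi(nifti_path: str | Path, sidecar_path: str | Path) -> DwiSeries:
    img = nib.load(str(nifti_path))
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    b = np.asarray(meta["b_values"], dtype=float)
    nd = int(meta["n_directions"])
    data = np.asarray(img.dataobj)
    signals = data.transpose(3, 0, 1, 2).reshape((b.size, nd) + data.shape[:3])
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return DwiSeries(signals=signals, b_values=b, spacing=spacing)


def save_fluorescence(img: FluorescenceImage, path: str | Path) -> None:
    names = sorted(img.channels)
    stack = np.stack([img.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(
        str(path), stack, photometric="minisblack",
        description=json.dumps({"channels": names, "pixel_size_um": img.pixel_size_um}),
    )


def load_fluorescence(path: str | Path) -> FluorescenceImage:
    with tifffile.TiffFile(str(path)) as tf:
        meta = json.loads(tf.pages[0].description)
        stack = tf.asarray()
    return FluorescenceImage(
        channels={n: stack[i] for i, n in enumerate(meta["channels"])},
        pixel_size_um=float(meta["pixel_size_um"]),
    )


def save_annotations(vessels: list[VesselAnnotation], path: str | Path) -> None:
    payload = [
        {
            "vessel_id": v.vessel_id,
            "polygon_px": v.polygon_px.tolist(),
            "centroid_px": list(v.centroid_px),
            "shortest_axis_um": v.shortest_axis_um,
            "longest_axis_um": v.longest_axis_um,
            "myosin_positive": v.myosin_positive,
            "region": v.region,
            "animal_id": v.animal_id,
        }
        for v in vessels
    ]
    Path(path).write_text(json.dumps(payload))


def load_annotations(path: str | Path) -> list[VesselAnnotation]:
    payload = json.loads(Path(path).read_text())
    return [
        VesselAnnotation(
            vessel_id=d["vessel_id"],
            polygon_px=np.asarray(d["polygon_px"]),
            centroid_px=tuple(d["centroid_px"]),
            shortest_axis_um=d["shortest_axis_um"],
            longest_axis_um=d["longest_axis_um"],
            myosin_positive=d["myosin_positive"],
            region=d.get("region", ""),
            animal_id=d.get("animal_id", ""),
        )
        for d in payload
    ]


def save_gravimetry(records: list[GravimetryRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"animal_id": r.animal_id, "strain": r.strain, "wet_g": r.wet_g,
             "dry_g": r.dry_g, "pct_water": r.percent_water,
             "g_per_g_dry": r.water_per_dry}
            for r in records
        ]
    ).to_csv(path, index=False)


def load_gravimetry(path: str | Path) -> list[GravimetryRecord]:
    df = pd.read_csv(path)
    return [
        GravimetryRecord(animal_id=str(r.animal_id), strain=str(r.strain),
                         wet_g=float(r.wet_g), dry_g=float(r.dry_g))
        for r in df.itertuples()
    ]


def save_electropherogram(trace: Electropherogram, path: str | Path) -> None:
    pd.DataFrame({"kda": trace.kda, "signal": trace.signal}).to_csv(path, index=False)


def load_electropherogram(path: str | Path, run_id: str = "", animal_id: str = "") -> Electropherogram:
    df = pd.read_csv(path)
    return Electropherogram(kda=df["kda"].to_numpy(), signal=df["signal"].to_numpy(),
                            run_id=run_id, animal_id=animal_id)


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    # tuple-keyed maps -> nested string maps for YAML
    d["region_volumes_mm3"] = _nest(spec.region_volumes_mm3)
    d["region_adc"] = _nest(spec.region_adc)
    d["halo_params"] = {
        "/".join(k): list(dataclasses.astuple(v)) if dataclasses.is_dataclass(v) else list(v)
        for k, v in spec.halo_params.items()
    }
    d["b_values"] = list(spec.b_values)
    for key in ("n_per_group", "water_content_pct", "dry_weight_g", "wes_ratio", "gfap_mean"):
        d[key] = dict(getattr(spec, key))
    return d


def _nest(m) -> dict:
    out: dict = {}
    for (a, b), v in m.items():
        out.setdefault(a, {})[b] = float(v)
    return out


def _unnest(m: dict) -> dict:
    return {(a, b): v for a, inner in m.items() for b, v in inner.items()}


def save_spec(spec: PhantomSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh)


def load_spec(path: str | Path) -> PhantomSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["region_volumes_mm3"] = _unnest(d["region_volumes_mm3"])
    d["region_adc"] = _unnest(d["region_adc"])
    d["halo_params"] = {
        tuple(k.split("/")): HaloParams(*v) for k, v in d["halo_params"].items()
    }
    d["b_values"] = tuple(d["b_values"])
    return PhantomSpec(**d)


def simulate_to_dir(spec: PhantomSpec, outdir: str | Path) -> StudyDataset:
    """Materialize a full synthetic study on disk (one directory per animal)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = make_study(spec)
    save_spec(spec, outdir / "spec.yaml")
    save_gravimetry(dataset.gravimetry, outdir / "gravimetry.csv")
    for animal_id, strain in dataset.animals:
        adir = outdir / animal_id
        adir.mkdir(exist_ok=True)
        grid, dwi, mask, _ = dataset.imaging(animal_id)
        save_volume(grid, adir / "t2w.nii.gz")
        save_dwi(dwi, adir / "dwi.nii.gz", adir / "dwi.json")
        save_mask(mask, adir / "mask.nii.gz", adir / "labels.yaml")
        for region in ("Cx", "cc", "Hc", "Tha", "Hy", "Pir"):
            img, vessels = dataset.microscopy(animal_id, region)
            save_fluorescence(img, adir / f"fluor_{region}.tif")
            save_annotations(vessels, adir / f"vessels_{region}.json")
        for trace in dataset.electropherograms[animal_id]:
            save_electropherogram(trace, adir / f"wes_{trace.run_id}.csv")
    return dataset
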