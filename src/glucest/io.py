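"""NIfTI + JSON-sidecar readers/writers and cohort (de)serialization.

Every image series is stored as a NIfTI volume with the acquisition axis
(offset/TR/TE/b/TI) as the 4th dimension and a JSON sidecar carrying the
axis arrays with explicit units.  Spectra are two-column CSV plus JSON
metadata.  Coordinates are voxel-index space, 0-based, row-major; there is
no world-space registration.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cest import ZSpectrumSeries
from .mrs import MRSpectrum
from .phantom import AcquisitionSchedule, AnimalDataset, Cohort
from .relaxometry import RelaxationSeries

_AXIS_UNITS = {"ppm": "ppm", "TR": "ms", "TE": "ms", "b": "s/mm^2",
               "TI": "ms"}


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def write_image(path, array: np.ndarray, sidecar: dict | None = None):
    """Write an array as NIfTI (identity affine) with optional sidecar."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), np.eye(4))
    nib.save(img, str(path))
    if sidecar is not None:
        _sidecar_path(path).write_text(json.dumps(_jsonable(sidecar),
                                                  indent=1))


def read_image(path):
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    sc = _sidecar_path(path)
    sidecar = json.loads(sc.read_text()) if sc.exists() else {}
    return arr, sidecar


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_series(path, data: np.ndarray, axis_name: str, axis_values,
                 units: str, extra: dict | None = None):
    sidecar = {"axis": axis_name, axis_name: list(np.asarray(axis_values)),
               "units": units}
    if extra:
        sidecar.update(extra)
    write_image(path, data, sidecar)


def read_zspectrum_series(path, reference_path=None) -> ZSpectrumSeries:
    """Load a saturation series + sidecar into a ZSpectrumSeries.

    The sidecar must carry ``offsets_ppm`` (and the reference image either
    embedded as ``reference`` or as a separate NIfTI).
    """
    data, sidecar = read_image(path)
    if "offsets_ppm" not in sidecar:
        raise ValueError(f"sidecar of {path} lacks 'offsets_ppm'")
    offsets = np.asarray(sidecar["offsets_ppm"], dtype=float)
    if data.shape[-1] != offsets.size:
        raise ValueError(f"series {path} has {data.shape[-1]} frames but "
                         f"the sidecar lists {offsets.size} offsets")
    if reference_path is not None:
        reference, _ = read_image(reference_path)
    elif "reference" in sidecar:
        reference = np.asarray(sidecar["reference"], dtype=float)
    else:
        raise ValueError(f"no S0 reference for {path}")
    mask = np.asarray(sidecar.get("mask", reference > 0), dtype=bool)
    return ZSpectrumSeries(data=data, offsets=offsets, reference=reference,
                           mask=mask)


def read_relaxation_series(path) -> RelaxationSeries:
    data, sidecar = read_image(path)
    kind = sidecar.get("axis")
    if kind not in ("TR", "TE", "b", "TI"):
        raise ValueError(f"sidecar of {path} lacks a valid 'axis' entry")
    values = np.asarray(sidecar[kind], dtype=float)
    if data.shape[-1] != values.size:
        raise ValueError(f"series {path} has {data.shape[-1]} frames but "
                         f"the sidecar lists {values.size} {kind} values")
    flag = sidecar.get("selective_flag")
    mask = sidecar.get("mask")
    return RelaxationSeries(
        data=data, axis_values=values, axis_kind=kind,
        selective_flag=None if flag is None else np.asarray(flag, bool),
        mask=None if mask is None else np.asarray(mask, bool))


def write_spectrum(path_csv, spectrum: MRSpectrum):
    pd.DataFrame({"ppm": spectrum.ppm_axis,
                  "intensity": spectrum.intensity}).to_csv(path_csv,
                                                           index=False)
    meta = {"water_reference_area": spectrum.water_reference_area,
            "acquisition": spectrum.acquisition}
    Path(path_csv).with_suffix(".json").write_text(
        json.dumps(_jsonable(meta), indent=1))


def read_spectrum(path_csv) -> MRSpectrum:
    df = pd.read_csv(path_csv)
    meta_path = Path(path_csv).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return MRSpectrum(ppm_axis=df["ppm"].to_numpy(),
                      intensity=df["intensity"].to_numpy(),
                      water_reference_area=float(
                          meta.get("water_reference_area", 1.0)),
                      acquisition=meta.get("acquisition", {}))


# --------------------------------------------------------------------------
# cohort round trip

def save_cohort(cohort: Cohort, out_dir):
    """Write a simulated cohort as per-animal NIfTI/CSV files + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sched = cohort.schedule
    (out / "schedule.json").write_text(json.dumps(_jsonable({
        "cest_offsets_ppm": sched.cest_offsets,
        "wassr_offsets_ppm": sched.wassr_offsets,
        "sat_power_uT": sched.sat_power,
        "sat_duration_ms": sched.sat_duration,
        "wassr_power_uT": sched.wassr_power,
        "wassr_duration_ms": sched.wassr_duration,
        "tr_ms": sched.tr_list, "te_ms": sched.te_list,
        "b_s_per_mm2": sched.b_values, "ti_ms": sched.ti_list,
        "field_hz_per_ppm": sched.field_strength}), indent=1))
    (out / "config.json").write_text(json.dumps(_jsonable(cohort.config),
                                                indent=1))
    rows = []
    for a in cohort.animals:
        d = out / a.animal_id
        d.mkdir(exist_ok=True)
        common = {"mask": a.cest.mask}
        write_image(d / "cest.nii.gz", a.cest.data,
                    {"offsets_ppm": a.cest.offsets, "units": "a.u.",
                     "reference": a.cest.reference, **common})
        write_image(d / "wassr.nii.gz", a.wassr.data,
                    {"offsets_ppm": a.wassr.offsets, "units": "a.u.",
                     "reference": a.wassr.reference, **common})
        write_image(d / "b1pair.nii.gz",
                    np.stack(a.b1_pair, axis=-1),
                    {"flip_angles_deg": [30.0, 60.0], "units": "a.u."})
        write_image(d / "labels.nii.gz",
                    a.label_image.astype(float),
                    {"codes": {"background": 0, "brain": 1,
                               "left_hippocampus": 2,
                               "right_hippocampus": 3}})
        for key, axis in (("t1", "TR"), ("t2", "TE"), ("adc", "b"),
                          ("fair", "TI")):
            if key in a.relaxometry:
                s = a.relaxometry[key]
                sc = {"axis": axis, axis: s.axis_values,
                      "units": _AXIS_UNITS[axis], "mask": s.mask}
                if s.selective_flag is not None:
                    sc["selective_flag"] = s.selective_flag
                write_image(d / f"{key}.nii.gz", s.data, sc)
        if a.mrs is not None:
            write_spectrum(d / "mrs.csv", a.mrs)
        (d / "truth.json").write_text(json.dumps(_jsonable(a.truth),
                                                 indent=1))
        rows.append({"animal": a.animal_id, "group": a.group,
                     "path": a.animal_id})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def load_schedule(out_dir) -> AcquisitionSchedule:
    d = json.loads((Path(out_dir) / "schedule.json").read_text())
    return AcquisitionSchedule(
        cest_offsets=d["cest_offsets_ppm"],
        wassr_offsets=d["wassr_offsets_ppm"],
        sat_power=d["sat_power_uT"], sat_duration=d["sat_duration_ms"],
        wassr_power=d["wassr_power_uT"],
        wassr_duration=d["wassr_duration_ms"],
        tr_list=d["tr_ms"], te_list=d["te_ms"],
        b_values=d["b_s_per_mm2"], ti_list=d["ti_ms"],
        field_strength=d["field_hz_per_ppm"])


def load_cohort(out_dir) -> Cohort:
    """Load a cohort written by :func:`save_cohort` (ground-truth scalar
    metadata is restored; full truth maps are not round-tripped)."""
    out = Path(out_dir)
    manifest = pd.read_csv(out / "manifest.csv")
    schedule = load_schedule(out)
    config = json.loads((out / "config.json").read_text())
    animals = []
    for _, row in manifest.iterrows():
        d = out / str(row["path"])
        if not d.exists():
            raise FileNotFoundError(
                f"animal {row['animal']}: directory {d} missing")
        for required in ("cest.nii.gz", "wassr.nii.gz", "b1pair.nii.gz",
                         "labels.nii.gz"):
            if not (d / required).exists():
                raise FileNotFoundError(
                    f"animal {row['animal']}: missing {required}")
        cest = read_zspectrum_series(d / "cest.nii.gz")
        wassr = read_zspectrum_series(d / "wassr.nii.gz")
        b1arr, _ = read_image(d / "b1pair.nii.gz")
        labels, _ = read_image(d / "labels.nii.gz")
        relax = {}
        for key in ("t1", "t2", "adc", "fair"):
            p = d / f"{key}.nii.gz"
            if p.exists():
                relax[key] = read_relaxation_series(p)
        mrs = read_spectrum(d / "mrs.csv") if (d / "mrs.csv").exists() \
            else None
        truth = json.loads((d / "truth.json").read_text()) \
            if (d / "truth.json").exists() else {}
        animals.append(AnimalDataset(
            animal_id=str(row["animal"]), group=str(row["group"]),
            phantom=None, cest=cest, wassr=wassr,
            b1_pair=(b1arr[..., 0], b1arr[..., 1]), relaxometry=relax,
            mrs=mrs, truth=truth, labels=labels.astype(np.int16)))
    return Cohort(animals=animals, schedule=schedule, config=config)
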