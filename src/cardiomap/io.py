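"""Reading and writing of pipeline artifacts.

Rasters (acquisition series, parameter maps, segment label maps) are
NIfTI-1 files written through nibabel, with JSON sidecars for metadata that
the NIfTI header cannot carry (timing vectors, modality tags, validity
flags, segment name tables). Tabular artifacts (segment statistics,
histology scores) are CSV via pandas. Floating-point rasters are stored as
float64, so round-trips are exact; label rasters are int16.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .histology import SCORE_PARAMETERS, HistologyScoreSet
from .phantom import AcquisitionSeries, PhantomGroundTruth
from .relaxometry import ParameterMap
from .segmentation import SegmentLabelMap

__all__ = [
    "write_series", "read_series",
    "write_parameter_map", "read_parameter_map",
    "write_labelmap", "read_labelmap",
    "write_segment_table", "read_segment_table",
    "write_score_set", "read_score_set",
    "write_phantom",
]

_IDENTITY = np.eye(4)


def _sidecar_path(nii_path: Path) -> Path:
    name = nii_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return nii_path.with_name(name[: -len(suffix)] + ".json")
    return nii_path.with_suffix(".json")


def _require(sidecar: dict, key: str, path: Path):
    if key not in sidecar:
        raise KeyError(f"sidecar {path} is missing required key {key!r}")
    return sidecar[key]


def write_series(series: AcquisitionSeries, path: str | Path) -> Path:
    """Write an acquisition series as a NIfTI volume plus JSON sidecar."""
    path = Path(path)
    # frames [n_t, H, W] -> spatial-first [H, W, n_t] for the NIfTI volume
    vol = np.moveaxis(series.frames, 0, -1)
    nib.save(nib.Nifti1Image(vol.astype(np.float64), _IDENTITY), str(path))
    sidecar = {
        "modality": series.modality,
        "times_ms": series.times_ms.tolist(),
        "valid": series.valid.astype(bool).tolist(),
        "rr_interval_ms": series.rr_interval_ms,
    }
    sp = _sidecar_path(path)
    sp.write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path: str | Path) -> AcquisitionSeries:
    path = Path(path)
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    sp = _sidecar_path(path)
    sidecar = json.loads(sp.read_text())
    return AcquisitionSeries(
        frames=np.moveaxis(vol, -1, 0),
        times_ms=np.asarray(_require(sidecar, "times_ms", sp), dtype=float),
        modality=_require(sidecar, "modality", sp),
        valid=np.asarray(_require(sidecar, "valid", sp), dtype=bool),
        rr_interval_ms=sidecar.get("rr_interval_ms"),
    )


def write_parameter_map(pmap: ParameterMap, path: str | Path) -> Path:
    """Write map values plus companion R^2 / mask volumes and a sidecar."""
    path = Path(path)
    stem = path.name.replace(".nii.gz", "").replace(".nii", "")
    nib.save(nib.Nifti1Image(pmap.values.astype(np.float64), _IDENTITY), str(path))
    nib.save(nib.Nifti1Image(pmap.r_squared.astype(np.float64), _IDENTITY),
             str(path.with_name(f"{stem}_r2.nii.gz")))
    nib.save(nib.Nifti1Image(pmap.valid_mask.astype(np.uint8), _IDENTITY),
             str(path.with_name(f"{stem}_mask.nii.gz")))
    _sidecar_path(path).write_text(json.dumps({"modality": pmap.modality}, indent=1))
    return path


def read_parameter_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    stem = path.name.replace(".nii.gz", "").replace(".nii", "")
    sp = _sidecar_path(path)
    sidecar = json.loads(sp.read_text())
    values = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    r2 = np.asarray(nib.load(str(path.with_name(f"{stem}_r2.nii.gz"))).dataobj, dtype=float)
    mask = np.asarray(nib.load(str(path.with_name(f"{stem}_mask.nii.gz"))).dataobj) > 0
    return ParameterMap(values=values, r_squared=r2, valid_mask=mask,
                        modality=_require(sidecar, "modality", sp))


def write_labelmap(labelmap: SegmentLabelMap, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(labelmap.labels.astype(np.int16), _IDENTITY), str(path))
    sidecar = {
        "level": labelmap.level,
        "names": {str(k): v for k, v in labelmap.names.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_labelmap(path: str | Path) -> SegmentLabelMap:
    path = Path(path)
    sp = _sidecar_path(path)
    sidecar = json.loads(sp.read_text())
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int16)
    names = {int(k): v for k, v in _require(sidecar, "names", sp).items()}
    return SegmentLabelMap(labels=labels, names=names,
                           level=_require(sidecar, "level", sp))


def write_segment_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_segment_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_score_set(score_set: HistologyScoreSet, path: str | Path) -> Path:
    """Per-segment scores as CSV plus a JSON header for the global scores."""
    path = Path(path)
    score_set.scores.to_csv(path, index=False)
    header = {
        "macroscopic": score_set.macroscopic,
        "n_sections": score_set.n_sections,
        "scorer_seed": score_set.scorer_seed,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return path


def read_score_set(path: str | Path) -> HistologyScoreSet:
    path = Path(path)
    hp = path.with_suffix(".json")
    header = json.loads(hp.read_text())
    scores = pd.read_csv(path)
    for p in SCORE_PARAMETERS:
        scores[p] = scores[p].astype(int)
    return HistologyScoreSet(
        scores=scores,
        macroscopic=int(_require(header, "macroscopic", hp)),
        n_sections=int(header.get("n_sections", 4)),
        scorer_seed=int(header.get("scorer_seed", 0)),
    )


def write_phantom(phantom: PhantomGroundTruth, directory: str | Path) -> Path:
    """Write every ground-truth field as one NIfTI file per field."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fields = {
        "t1": phantom.t1_map, "t2": phantom.t2_map, "t2star": phantom.t2star_map,
        "pd": phantom.pd_map, "edema": phantom.edema_map,
        "infiltration": phantom.infiltration_map, "fibrosis": phantom.fibrosis_map,
        "iron": phantom.iron_map, "rbc": phantom.rbc_map,
    }
    for name, arr in fields.items():
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), _IDENTITY),
                 str(directory / f"truth_{name}.nii.gz"))
    nib.save(nib.Nifti1Image(phantom.myocardium_mask.astype(np.uint8), _IDENTITY),
             str(directory / "truth_mask.nii.gz"))
    return directory
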