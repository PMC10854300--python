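"""Readers and writers for the formats the pipeline touches.

TIFF stacks are grayscale multi-page files; acquisition metadata (exposure,
cutoff) travels in a JSON sidecar next to the TIFF (``<name>.tiff.json``)
because TIFF tags are unreliable across writers.  Instrument HDF5 files are
read by user-named dataset path, with metadata taken from HDF5 attributes
when present.  Tables are UTF-8 CSV with a header row; spectra are
two-column ``wavelength_nm,value`` CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .contrast import ContrastImage
from .roi import ROI
from .spectra import Spectrum
from .stack import ImageStack

__all__ = [
    "read_tiff_stack", "write_tiff_stack", "read_h5_stack", "write_h5_stack",
    "read_roi_json", "write_roi_json", "read_spectrum_csv",
    "write_spectrum_csv", "read_manifest", "load_config", "write_results",
]

PathLike = Union[str, Path]

MANIFEST_COLUMNS = ["subject", "condition", "time_h", "file", "exposure_ms",
                    "cutoff_nm", "bandage"]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_tiff_stack(path: PathLike, exposure_ms: Optional[float] = None,
                    cutoff_nm: Optional[int] = None) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Metadata priority: explicit arguments, then the JSON sidecar, then
    defaults (exposure 1 ms).  RGB files and unreadable/truncated files
    raise ``ValueError`` — never a silent partial read.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if any(page.photometric not in
                   (tifffile.PHOTOMETRIC.MINISBLACK, tifffile.PHOTOMETRIC.MINISWHITE)
                   for page in tif.pages):
                raise ValueError(f"{path} is not a grayscale TIFF")
            arr = tif.asarray()
    except ValueError:
        raise
    except Exception as exc:                      # truncated/corrupt files
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if exposure_ms is None:
        exposure_ms = float(meta.get("exposure_ms", 1.0))
    if cutoff_nm is None:
        cutoff_nm = meta.get("cutoff_nm")
    return ImageStack(arr.astype(np.float64), exposure_ms=exposure_ms,
                      cutoff_nm=cutoff_nm, unit=meta.get("unit", "counts"),
                      meta=meta.get("meta", {}))


def write_tiff_stack(stack: ImageStack, path: PathLike,
                     dtype: str = "float32") -> Path:
    """Write a stack as a multi-page grayscale TIFF plus its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(dtype),
                     photometric="minisblack")
    sidecar = {"exposure_ms": stack.exposure_ms, "cutoff_nm": stack.cutoff_nm,
               "unit": stack.unit, "meta": _jsonable(stack.meta)}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_h5_stack(path: PathLike, dataset: str) -> ImageStack:
    """Read a 2-D or 3-D numeric dataset from an instrument HDF5 file.

    Exposure/cutoff are taken from the dataset attributes ``exposure_ms``
    and ``cutoff_nm`` when present.  A missing dataset raises ``KeyError``
    listing every dataset in the file.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if dataset not in f:
            available: list[str] = []
            f.visititems(lambda name, obj: available.append(name)
                         if isinstance(obj, h5py.Dataset) else None)
            raise KeyError(
                f"dataset {dataset!r} not in {path}; available: {available}")
        ds = f[dataset]
        arr = np.asarray(ds, dtype=np.float64)
        exposure = float(ds.attrs.get("exposure_ms", 1.0))
        cutoff = ds.attrs.get("cutoff_nm")
        cutoff = int(cutoff) if cutoff is not None else None
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"dataset {dataset!r} has ndim {arr.ndim}, need 2 or 3")
    return ImageStack(arr, exposure_ms=exposure, cutoff_nm=cutoff)


def write_h5_stack(stack: ImageStack, path: PathLike,
                   dataset: str = "frames") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(dataset, data=stack.frames)
        ds.attrs["exposure_ms"] = stack.exposure_ms
        if stack.cutoff_nm is not None:
            ds.attrs["cutoff_nm"] = stack.cutoff_nm
    return path


def read_roi_json(path: PathLike) -> list[ROI]:
    """Read a JSON list of ``{label, type, frame, params}`` ROI records."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, Mapping):
        data = [data]
    return [ROI.from_dict(d) for d in data]


def write_roi_json(rois: Sequence[ROI], path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps([r.to_dict() for r in rois], indent=1))
    return path


def read_spectrum_csv(path: PathLike, label: str = "") -> Spectrum:
    """Two-column ``wavelength_nm,value`` CSV; condition metadata may live in
    a sidecar JSON with a ``label`` key."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, got {list(df.columns)}")
    if not label:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            label = json.loads(sidecar.read_text()).get("label", "")
    return Spectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                    label=label or path.stem)


def write_spectrum_csv(spectrum: Spectrum, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                  "value": spectrum.values}).to_csv(path, index=False)
    if spectrum.label:
        _sidecar_path(path).write_text(json.dumps({"label": spectrum.label}))
    return path


def read_manifest(path: PathLike) -> pd.DataFrame:
    """Read and validate an acquisition manifest CSV.

    Columns: ``subject, condition, time_h, file, exposure_ms, cutoff_nm,
    bandage``.  Every referenced file must exist and the key
    (subject, condition, time_h, bandage) must be unique.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} lacks columns {missing_cols}")
    df["bandage"] = df["bandage"].astype(bool)
    base = path.parent
    files = [base / f if not Path(f).is_absolute() else Path(f)
             for f in df["file"]]
    absent = [str(f) for f in files if not f.exists()]
    if absent:
        raise FileNotFoundError(f"manifest references missing files: {absent}")
    df["file"] = [str(f) for f in files]
    key = df[["subject", "condition", "time_h", "bandage"]]
    if key.duplicated().any():
        raise ValueError("manifest keys (subject, condition, time_h, bandage) "
                         "are not unique")
    return df


def load_config(path: PathLike) -> dict:
    """Load a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(out_dir: PathLike,
                  tables: Mapping[str, pd.DataFrame] | None = None,
                  images: Mapping[str, Union[np.ndarray, ContrastImage]] | None = None,
                  config: Mapping | None = None) -> dict[str, Path]:
    """Write CSV tables, float-TIFF dB maps / mask TIFFs and run metadata.

    Contrast images produce two files: ``<name>_db.tiff`` (32-bit float, NaN
    outside validity) and ``<name>_mask.tiff`` (8-bit, 255 above threshold).
    ``config`` (seed, parameter choices) is written to ``run_metadata.json``
    together with package versions.  Rerunning with identical inputs and
    seed reproduces every file byte for byte.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in (tables or {}).items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False)
        written[name] = p
    for name, image in (images or {}).items():
        if isinstance(image, ContrastImage):
            p_db = out_dir / f"{name}_db.tiff"
            tifffile.imwrite(p_db, image.db.astype(np.float32),
                             photometric="minisblack")
            p_mask = out_dir / f"{name}_mask.tiff"
            tifffile.imwrite(p_mask,
                             (image.above_threshold.astype(np.uint8) * 255),
                             photometric="minisblack")
            written[f"{name}_db"] = p_db
            written[f"{name}_mask"] = p_mask
        else:
            p = out_dir / f"{name}.tiff"
            tifffile.imwrite(p, np.asarray(image, dtype=np.float32),
                             photometric="minisblack")
            written[name] = p
    metadata = {"package": "swirquant", "version": __version__,
                "numpy": np.__version__,
                "config": _jsonable(dict(config or {}))}
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=1, sort_keys=True))
    written["run_metadata"] = meta_path
    return written
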