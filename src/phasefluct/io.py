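"""Readers/writers shared by the CLI: NPY/TIFF stacks, YAML sidecars, manifests.

Videos travel as NPY arrays (primary) or multi-page 32-bit float TIFF
(interchange), each with a YAML metadata sidecar (``frame_rate_hz``,
``wavelength_nm``, ``carrier_freq``, ``pixel_size_um`` as applicable).
Datasets are described by a CSV manifest with columns
``cell_id, label, opd_path[, fluct_path]``.
"""

from __future__ import annotations

import hashlib
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .holography import OPDVideo

__all__ = [
    "load_array",
    "save_array",
    "load_video",
    "save_video",
    "sidecar_path",
    "read_sidecar",
    "write_sidecar",
    "read_manifest",
    "write_manifest",
    "write_provenance",
]

VALID_LABELS = ("primary", "metastatic")


def load_array(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    raise ValueError(f"unsupported array format '{path.suffix}'")


def save_array(path, array: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npy":
        np.save(path, array)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    else:
        raise ValueError(f"unsupported array format '{path.suffix}'")


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".yaml")


def read_sidecar(path) -> dict:
    with open(sidecar_path(path)) as fh:
        return yaml.safe_load(fh) or {}


def write_sidecar(path, meta: dict) -> None:
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_video(path, frame_rate_hz: float | None = None) -> OPDVideo:
    """Load an OPD video; the frame rate comes from the sidecar if not given."""
    frames = load_array(path)
    meta = {}
    if sidecar_path(path).exists():
        meta = read_sidecar(path)
    fps = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    if fps is None:
        raise ValueError(f"no frame rate for '{path}': pass frame_rate_hz "
                         "or provide a sidecar with that field")
    return OPDVideo(frames, float(fps), pixel_size_um=meta.get("pixel_size_um"))


def save_video(path, video: OPDVideo, extra_meta: dict | None = None) -> None:
    save_array(path, video.frames.astype(np.float32))
    meta = {"frame_rate_hz": float(video.frame_rate_hz)}
    if video.pixel_size_um is not None:
        meta["pixel_size_um"] = float(video.pixel_size_um)
    meta.update(extra_meta or {})
    write_sidecar(path, meta)


def read_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Read and validate a dataset manifest CSV."""
    df = pd.read_csv(path)
    required = {"cell_id", "label", "opd_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        raise ValueError("manifest cell_id values must be unique")
    bad = set(df["label"]) - set(VALID_LABELS)
    if bad:
        raise ValueError(f"manifest labels must be in {VALID_LABELS}, got {sorted(bad)}")
    if check_files:
        base = Path(path).parent
        for col in ("opd_path", "fluct_path"):
            if col not in df.columns:
                continue
            for p in df[col].dropna():
                full = (base / p) if not Path(p).is_absolute() else Path(p)
                if not full.exists():
                    raise FileNotFoundError(f"manifest references missing file '{p}'")
    return df


def write_manifest(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, config: dict, seed: int | None) -> None:
    """Add provenance (config hash, seed, package version) to a sidecar.

    Merges with any existing sidecar content for the same artifact.
    """
    try:
        ver = _pkg_version("phasefluct")
    except Exception:  # pragma: no cover
        ver = "unknown"
    meta = read_sidecar(path) if sidecar_path(path).exists() else {}
    meta.update({"config_hash": config_hash(config),
                 "seed": seed, "package_version": ver})
    write_sidecar(path, meta)
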