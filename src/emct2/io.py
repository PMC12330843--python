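"""NIfTI + JSON-sidecar readers/writers.

Conventions: 4D stacks are (X, Y, Z, E) with the third spatial axis as the
slice axis; sidecars are BIDS-style with EchoTime in seconds; internal times
are milliseconds (conversion confined to this module); every output volume
inherits the input affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .sequence import MESEProtocol


class SidecarError(ValueError):
    pass


def _sidecar_path(nifti_path: Path) -> Path:
    name = nifti_path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return nifti_path.with_name(name[: -len(suf)] + ".json")
    return nifti_path.with_suffix(".json")


def read_mese(path: str | Path, sidecar: str | Path | None = None,
              protocol: MESEProtocol | None = None):
    """Load a 4D echo stack with its sidecar.

    Returns (data, affine, sidecar_dict).  Validates presence and monotonic
    ordering of EchoTime, the echo count against the 4th axis, and — when a
    protocol is given — agreement with TE_k = k * esp.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise SidecarError(f"{path}: expected a 4D stack, got shape {data.shape}")
    sc_path = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sc_path.exists():
        raise SidecarError(f"missing sidecar {sc_path}")
    meta = json.loads(sc_path.read_text())
    tes = meta.get("EchoTime")
    if tes is None:
        raise SidecarError(f"{sc_path}: no EchoTime entry")
    tes = np.asarray(tes, dtype=float)
    if tes.size != data.shape[3]:
        raise SidecarError(
            f"{sc_path}: {tes.size} echo times for a {data.shape[3]}-echo stack")
    if np.any(np.diff(tes) <= 0):
        raise SidecarError(f"{sc_path}: echo times must be strictly increasing")
    if protocol is not None:
        expect = protocol.echo_times_ms / 1000.0
        if tes.size != protocol.etl or not np.allclose(tes, expect, rtol=1e-6, atol=1e-6):
            raise SidecarError(
                f"{sc_path}: echo times disagree with protocol esp*k "
                f"({protocol.echo_spacing_ms} ms x {protocol.etl})")
    return data, img.affine, meta


def write_mese(path: str | Path, data: np.ndarray, affine: np.ndarray,
               sidecar: dict) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path):
    img = nib.load(Path(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_volume(path: str | Path, data: np.ndarray, affine: np.ndarray,
                 dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), Path(path))


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
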