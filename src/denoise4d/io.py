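"""Volume readers and writers: NIfTI-1 and raw binary with a JSON sidecar.

Both formats carry the full Volume4D metadata (extent, spacing, axis order,
dtype, valid intervals, periodic-time flag) and round-trip bit exactly.
NIfTI has no native field for valid intervals, so both formats keep a JSON
sidecar next to the data file.  Raw volumes are stored x-fastest (Fortran
order over x, y, z, t).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .conv_engine import Volume4D

__all__ = ["read_volume", "write_volume", "sidecar_path",
           "save_tensor_field", "load_tensor_field"]

_DTYPES = {"float32": np.float32, "float64": np.float64}


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _sidecar_dict(vol: Volume4D, dtype: str) -> dict:
    return {
        "extent": list(vol.shape),
        "spacing": list(vol.spacing),
        "axis_order": "x,y,z,t",
        "dtype": dtype,
        "valid": [list(v) for v in vol.valid],
        "periodic_t": bool(vol.periodic_t),
    }


def write_volume(vol: Volume4D, path, dtype: str = "float64") -> None:
    """Write a volume as .nii/.nii.gz or raw (.raw/.bin) + JSON sidecar."""
    path = Path(path)
    if dtype not in _DTYPES:
        raise ValueError(f"dtype must be float32 or float64, got {dtype!r}")
    data = np.asarray(vol.values, dtype=_DTYPES[dtype])
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        affine = np.diag(list(vol.spacing[:3]) + [1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
    elif path.suffix in (".raw", ".bin"):
        data.flatten(order="F").tofile(path)
    else:
        raise ValueError(f"unrecognized volume format {path.suffix!r}")
    sidecar_path(path).write_text(json.dumps(_sidecar_dict(vol, dtype), indent=1))


def read_volume(path) -> Volume4D:
    """Read a NIfTI or raw+sidecar volume.

    3D inputs are promoted to 4D with a single time point (with a warning).
    Malformed headers, truncated raw files and non-finite data raise with
    the offending field named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = None
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        for key in ("extent", "dtype"):
            if key not in meta:
                raise ValueError(f"malformed sidecar: missing field {key!r}")
        if meta.get("axis_order", "x,y,z,t") != "x,y,z,t":
            raise ValueError(
                f"unsupported axis_order {meta['axis_order']!r} (need x,y,z,t)")

    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()
    elif path.suffix in (".raw", ".bin"):
        if meta is None:
            raise ValueError(f"raw volume {path} requires a sidecar {sc}")
        extent = tuple(int(n) for n in meta["extent"])
        dt = _DTYPES.get(meta["dtype"])
        if dt is None:
            raise ValueError(f"malformed sidecar: unknown dtype {meta['dtype']!r}")
        expected = int(np.prod(extent)) * np.dtype(dt).itemsize
        actual = path.stat().st_size
        if actual != expected:
            raise ValueError(
                f"truncated raw file: field extent implies {expected} bytes, "
                f"file has {actual}")
        data = np.fromfile(path, dtype=dt).reshape(extent, order="F")
        zooms = None
    else:
        raise ValueError(f"unrecognized volume format {path.suffix!r}")

    if data.ndim == 3:
        warnings.warn("3D input promoted to 4D with a single time point")
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"field extent: expected 3D or 4D data, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError("field values: volume contains non-finite entries")

    if meta is not None:
        spacing = tuple(meta.get("spacing", (1.0,) * 4))[:4]
        valid = tuple(tuple(v) for v in meta.get(
            "valid", [(0, n) for n in data.shape]))
        if len(valid) == 3:
            valid = valid + ((0, data.shape[3]),)
        periodic_t = bool(meta.get("periodic_t", True))
    else:
        spacing = tuple(float(z) for z in zooms[:4]) if zooms is not None \
            and len(zooms) >= 4 else tuple(zooms[:3]) + (1.0,)
        valid = None
        periodic_t = True
    return Volume4D(np.asarray(data, dtype=float), spacing=spacing,
                    valid=valid, periodic_t=periodic_t)


def save_tensor_field(tf, path) -> None:
    """Store a tensor field as one named HDF5 dataset per component."""
    import h5py

    from .tensor_estimation import TensorField4D  # noqa: F401 (type)

    with h5py.File(path, "w") as f:
        f.attrs["dim"] = tf.dim
        f.attrs["valid"] = json.dumps([list(v) for v in tf.valid])
        for k in range(tf.comps.shape[-1]):
            f.create_dataset(f"t{k + 1}", data=tf.comps[..., k])


def load_tensor_field(path):
    import h5py

    from .tensor_estimation import TensorField4D

    with h5py.File(path, "r") as f:
        dim = int(f.attrs["dim"])
        valid = tuple(tuple(v) for v in json.loads(f.attrs["valid"]))
        n = dim * (dim + 1) // 2
        comps = np.stack([f[f"t{k + 1}"][()] for k in range(n)], axis=-1)
    return TensorField4D(comps, dim=dim, valid=valid)
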