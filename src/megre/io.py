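"""NIfTI + JSON-sidecar serialisation of multi-echo series and maps.

A simulated (or measured) series is stored as one 3-D NIfTI volume with
the echo index on the third axis, next to a ``.json`` sidecar carrying the
echo times (ms), per-echo parity labels, the noise level and the seed, so
any dataset on disk regenerates its fitting context exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom_sim import SimulatedSeries
from .protocol import EchoTrain

_SIDECAR_SUFFIX = ".json"


def _base_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii", ".json"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)])
    return p


def save_series(series: SimulatedSeries, path: str | Path) -> Path:
    """Write ``<path>.nii.gz`` plus ``<path>.json``; returns the image path."""
    base = _base_path(path)
    img_path = base.with_name(base.name + ".nii.gz")
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32), np.eye(4))
    nib.save(img, img_path)
    sidecar = {
        "te_ms": series.train.te.tolist(),
        "parity": series.train.parity.tolist(),
        "sigma": series.sigma_true,
        "seed": series.seed,
        "provenance": series.provenance,
    }
    base.with_name(base.name + _SIDECAR_SUFFIX).write_text(
        json.dumps(sidecar, indent=2)
    )
    return img_path


def load_series(path: str | Path) -> SimulatedSeries:
    """Load a series written by :func:`save_series`."""
    base = _base_path(path)
    img_path = base.with_name(base.name + ".nii.gz")
    if not img_path.exists():
        img_path = base.with_name(base.name + ".nii")
    sidecar = json.loads(base.with_name(base.name + _SIDECAR_SUFFIX).read_text())
    data = np.asarray(nib.load(img_path).dataobj, dtype=float)
    train = EchoTrain(np.asarray(sidecar["te_ms"]), np.asarray(sidecar["parity"]))
    return SimulatedSeries(
        data=data,
        train=train,
        sigma_true=float(sidecar["sigma"]),
        seed=sidecar.get("seed"),
        provenance=sidecar.get("provenance", {}),
    )


def save_map(array: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D parameter map as NIfTI."""
    base = _base_path(path)
    img_path = base.with_name(base.name + ".nii.gz")
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), np.eye(4)), img_path)
    return img_path
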