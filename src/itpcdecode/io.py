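"""On-disk epoch container and run configuration files.

Epochs live in a self-describing HDF5 file per subject: datasets
``data`` (trials × locations × times), ``times`` (ms) and ``labels``
(UTF-8 strings), with ``sampling_rate``, ``subject``, ``band`` and
``schema_version`` attributes.  Run configurations are YAML (see
:func:`itpcdecode.pipeline.RunConfig.from_yaml` for the schema).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .bands import BandSpec
from .containers import LabeledEpochs

__all__ = ["read_epochs", "write_epochs", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def write_epochs(epochs: LabeledEpochs, path: str | Path) -> None:
    """Write a :class:`LabeledEpochs` container; round-trips exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        labels = np.asarray([str(l) for l in epochs.labels], dtype=object)
        f.create_dataset("labels", data=labels, dtype=h5py.string_dtype("utf-8"))
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        f.attrs["subject"] = epochs.subject
        f.attrs["schema_version"] = SCHEMA_VERSION
        if epochs.band is not None:
            f.attrs["band_name"] = epochs.band.name
            f.attrs["band_low"] = epochs.band.low
            f.attrs["band_high"] = epochs.band.high


def read_epochs(path: str | Path) -> LabeledEpochs:
    """Read a :class:`LabeledEpochs` container written by :func:`write_epochs`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"epoch container schema mismatch in {path}: found "
                f"{version!r}, this reader supports version {SCHEMA_VERSION}"
            )
        for name in ("data", "times", "labels"):
            if name not in f:
                raise ValueError(
                    f"epoch container schema error in {path}: missing array {name!r} "
                    f"(schema version {SCHEMA_VERSION})"
                )
        band = None
        if "band_name" in f.attrs:
            band = BandSpec(
                str(f.attrs["band_name"]),
                float(f.attrs["band_low"]),
                float(f.attrs["band_high"]),
            )
        return LabeledEpochs(
            data=f["data"][()],
            labels=np.asarray([l.decode() if isinstance(l, bytes) else str(l) for l in f["labels"][()]]),
            times=f["times"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            subject=str(f.attrs["subject"]),
            band=band,
        )
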