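"""HDF5 / CSV persistence for epochs, layouts and gaze logs.

The HDF5 epoch container stores datasets ``epochs`` (trials x channels x
time), ``labels``, ``fs``, ``window`` and ``channel_ids``, with the
generating seed and config JSON as attributes when the file was written from
a synthetic dataset.  An optional reader maps epoched FIF files (planar
gradiometer channels only) onto the same in-memory container.
"""

from __future__ import annotations

import h5py
import numpy as np

from .preprocessing import EpochSet
from .synthetic import SyntheticDataset

__all__ = ["save_epochs", "load_epochs", "save_dataset", "load_fif_epochs"]


def save_epochs(epochs: EpochSet, path, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=np.asarray(epochs.labels))
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset("window", data=np.asarray(epochs.window, float))
        f.create_dataset(
            "channel_ids", data=np.array(epochs.channel_ids, dtype=h5py.string_dtype())
        )
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["epochs"][()],
            fs=float(f["fs"][()]),
            window=tuple(f["window"][()]),
            labels=f["labels"][()],
            channel_ids=[c.decode() if isinstance(c, bytes) else str(c) for c in f["channel_ids"][()]],
        )


def save_dataset(ds: SyntheticDataset, path) -> None:
    """Write a synthetic dataset with its provenance (seed, config JSON)."""
    epochs = EpochSet(
        data=ds.epochs,
        fs=ds.config.fs,
        window=ds.config.epoch_window,
        labels=ds.labels,
        channel_ids=ds.layout.channel_ids,
    )
    save_epochs(epochs, path, attrs={"seed": ds.config.seed, "config": ds.config.to_json()})


def load_fif_epochs(path) -> EpochSet:
    """Read an epoched FIF file, keeping planar gradiometers only.

    Requires :mod:`mne` (optional dependency); gradiometer channels are
    selected by channel type.
    """
    import mne  # deferred: optional dependency

    ep = mne.read_epochs(path, preload=True, verbose="error")
    ep.pick("grad")
    labels = ep.events[:, 2]
    return EpochSet(
        data=ep.get_data(copy=True),
        fs=float(ep.info["sfreq"]),
        window=(float(ep.tmin), float(ep.tmax)),
        labels=labels,
        channel_ids=list(ep.ch_names),
    )
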