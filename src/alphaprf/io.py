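"""Disk formats: HDF5 voltage/epoch/spectrum arrays with TSV/JSON sidecars.

The layout mirrors a BIDS-iEEG derivative tree loosely: voltage as an
electrode x time HDF5 array per run, events as tab-separated tables with
onset/duration columns in seconds, epochs and spectra as HDF5 with a JSON
sidecar describing the window and rate.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import VoltageEpochs
from .spectral import SpectrumSet
from .synth import SimulatedRecording

__all__ = [
    "write_recording",
    "read_voltage",
    "read_events",
    "write_epochs",
    "read_epochs",
    "write_spectra",
]


def write_recording(rec: SimulatedRecording, directory: str | Path) -> Path:
    """Write voltage, per-run event tables and the aperture sequence."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with h5py.File(directory / "ieeg.h5", "w") as f:
        f.create_dataset("voltage", data=rec.voltage)
        f.create_dataset("apertures", data=rec.apertures.masks)
        f.attrs["sample_rate"] = rec.sample_rate
        f.create_dataset("coordinates", data=rec.coordinates)
    for r in range(rec.voltage.shape[0]):
        rec.events.to_csv(
            directory / f"events_run-{r + 1:02d}.tsv", sep="\t", index=False
        )
    return directory


def read_voltage(directory: str | Path) -> tuple[np.ndarray, float]:
    with h5py.File(Path(directory) / "ieeg.h5", "r") as f:
        return f["voltage"][()], float(f.attrs["sample_rate"])


def read_events(directory: str | Path, run: int = 1) -> pd.DataFrame:
    return pd.read_csv(Path(directory) / f"events_run-{run:02d}.tsv", sep="\t")


def write_epochs(epochs: VoltageEpochs, path: str | Path,
                 keep: np.ndarray | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        if keep is not None:
            f.create_dataset("keep", data=keep)
    epochs.metadata.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    sidecar = {
        "sample_rate": epochs.sample_rate,
        "window": [float(epochs.times[0]), float(epochs.times[-1])],
        "n_epochs": int(epochs.n_epochs),
        "n_electrodes": int(epochs.n_electrodes),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_epochs(path: str | Path) -> tuple[VoltageEpochs, np.ndarray | None]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        keep = f["keep"][()] if "keep" in f else None
    meta = pd.read_csv(path.with_suffix(".tsv"), sep="\t")
    rate = float(json.loads(path.with_suffix(".json").read_text())["sample_rate"])
    return VoltageEpochs(data, times, rate, meta), keep


def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("psd", data=spectra.psd)
        f.create_dataset("baseline", data=spectra.baseline)
        f.create_dataset("freqs", data=spectra.freqs)
        f.attrs["run_averaged"] = spectra.run_averaged
    spectra.metadata.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
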