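"""Epoched EEG container and HDF5 / mne interchange.

An :class:`EpochSet` holds one subject's segmented EEG for one locking event
(stimulus or response): a ``trials x channels x time`` array plus montage,
sampling rate, the time of the first sample relative to the locking event, and
per-trial metadata.  Units are tracked explicitly: ``"potential"`` (µV) before
the current-source-density transform, ``"csd"`` (µV/m²) after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .montage import Montage

__all__ = ["EpochSet", "save_epochs", "load_epochs", "from_mne_epochs", "read_raw"]

STIMULUS = "stimulus"
RESPONSE = "response"


@dataclass
class EpochSet:
    """Segmented single-subject EEG.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Amplitudes, µV for ``units="potential"`` or µV/m² for ``units="csd"``.
    sfreq : float
        Sampling rate in Hz.
    t0_ms : float
        Time of the first sample relative to the locking event, in ms.
    locking : {"stimulus", "response"}
    montage : Montage
    trial_info : pandas.DataFrame
        One row per trial; at least columns ``subject``, ``task``, ``correct``.
    units : {"potential", "csd"}
    """

    data: np.ndarray
    sfreq: float
    t0_ms: float
    locking: str
    montage: Montage
    trial_info: pd.DataFrame = field(repr=False)
    units: str = "potential"

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if self.data.shape[1] != len(self.montage):
            raise ValueError("channel axis does not match montage")
        if self.locking not in (STIMULUS, RESPONSE):
            raise ValueError(f"unknown locking {self.locking!r}")
        if self.units not in ("potential", "csd"):
            raise ValueError(f"unknown units {self.units!r}")
        if len(self.trial_info) != self.data.shape[0]:
            raise ValueError("trial_info length does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_times) * 1000.0 / self.sfreq

    def copy_with(self, **kw) -> "EpochSet":
        if "data" in kw:
            kw.setdefault("trial_info", self.trial_info.copy())
        return replace(self, **kw)

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        """Sample slice for the analysis window ``[start_ms, end_ms)``.

        The first sample is the one at or immediately before ``start_ms`` and
        the end is exclusive, so a window of W ms always covers
        ``ceil(W * sfreq / 1000)`` samples regardless of grid phase.
        """
        if start_ms >= end_ms:
            raise ValueError("window start must precede end")
        i0 = int(np.floor((start_ms - self.t0_ms) * self.sfreq / 1000.0 + 1e-9))
        i1 = int(np.floor((end_ms - self.t0_ms) * self.sfreq / 1000.0 + 1e-9))
        if i0 < 0 or i1 > self.n_times:
            raise ValueError(
                f"window ({start_ms}, {end_ms}) ms outside epoch span "
                f"({self.t0_ms}, {self.times_ms[-1]}) ms"
            )
        return slice(i0, i1)


def save_epochs(epochs: EpochSet, path, group: str = "/") -> None:
    """Write an EpochSet to HDF5.

    Layout: dataset ``data`` (trial, channel, time, float32) with attrs
    ``sfreq``, ``t0_ms``, ``locking``, ``units``; datasets ``channel_names``,
    ``channel_positions``; trial metadata as one dataset per column.
    """
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        if "data" in g:
            del g["data"], g["channel_names"], g["channel_positions"]
            del g["trials"]
        d = g.create_dataset("data", data=epochs.data.astype(np.float32))
        d.attrs["sfreq"] = float(epochs.sfreq)
        d.attrs["t0_ms"] = float(epochs.t0_ms)
        d.attrs["locking"] = epochs.locking
        d.attrs["units"] = epochs.units
        g.create_dataset(
            "channel_names",
            data=np.array(epochs.montage.names, dtype=h5py.string_dtype()),
        )
        g.create_dataset("channel_positions", data=epochs.montage.positions)
        t = g.create_group("trials")
        for col in epochs.trial_info.columns:
            vals = epochs.trial_info[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind == "U":
                vals = np.array([str(v) for v in vals], dtype=h5py.string_dtype())
            t.create_dataset(col, data=vals)


def load_epochs(path, group: str = "/") -> EpochSet:
    with h5py.File(path, "r") as f:
        g = f[group]
        d = g["data"]
        names = tuple(n.decode() if isinstance(n, bytes) else str(n)
                      for n in g["channel_names"][()])
        montage = Montage(names=names, positions=g["channel_positions"][()])
        cols = {}
        for col in g["trials"]:
            vals = g["trials"][col][()]
            if vals.dtype.kind in ("S", "O"):
                vals = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                 for v in vals])
            cols[col] = vals
        return EpochSet(
            data=d[()].astype(float),
            sfreq=float(d.attrs["sfreq"]),
            t0_ms=float(d.attrs["t0_ms"]),
            locking=str(d.attrs["locking"]),
            montage=montage,
            trial_info=pd.DataFrame(cols),
            units=str(d.attrs["units"]),
        )


def from_mne_epochs(mne_epochs, trial_info: pd.DataFrame, locking: str = STIMULUS,
                    units: str = "potential") -> EpochSet:
    """Convert an ``mne.Epochs``/``EpochsArray`` object (volts) to an EpochSet (µV).

    Channel positions are taken from the attached montage and projected onto
    the unit sphere (the CSD estimator works on the unit sphere; absolute head
    radius is a separate scaling).
    """
    data = mne_epochs.get_data(copy=True) * 1e6  # V -> µV
    names = tuple(mne_epochs.ch_names)
    mont = mne_epochs.get_montage()
    if mont is None:
        raise ValueError("mne epochs carry no montage; positions are required")
    pos_map = mont.get_positions()["ch_pos"]
    pos = np.array([pos_map[n] for n in names], float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return EpochSet(
        data=data,
        sfreq=float(mne_epochs.info["sfreq"]),
        t0_ms=float(mne_epochs.times[0] * 1000.0),
        locking=locking,
        montage=Montage(names=names, positions=pos),
        trial_info=trial_info,
        units=units,
    )


def read_raw(path, **kwargs):
    """Read a raw BrainVision (.vhdr) or EDF (.edf) recording via mne.

    Thin convenience wrapper; returns the mne Raw object for subsequent
    event extraction and epoching, after which :func:`from_mne_epochs`
    converts into the native container.  Requires the optional ``mne``
    dependency.
    """
    import mne  # local import: optional dependency

    p = str(path)
    if p.lower().endswith(".vhdr"):
        return mne.io.read_raw_brainvision(p, preload=True, **kwargs)
    if p.lower().endswith(".edf"):
        return mne.io.read_raw_edf(p, preload=True, **kwargs)
    raise ValueError("expected a .vhdr (BrainVision) or .edf file")
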