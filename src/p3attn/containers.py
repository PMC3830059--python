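"""In-memory containers for epoched EEG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Montage

SFREQ_HZ = 250.0
TMIN_MS = -300.0
TMAX_MS = 800.0

#: condition labels used throughout
CONDITIONS = ("explicit_target", "implicit_target", "distractor")


def default_times_ms(sfreq: float = SFREQ_HZ, tmin_ms: float = TMIN_MS,
                     tmax_ms: float = TMAX_MS) -> np.ndarray:
    """Epoch time axis, inclusive of both endpoints.

    At 250 Hz and -300..800 ms this is 276 samples, 4 ms apart.
    """
    n = int(round((tmax_ms - tmin_ms) * sfreq / 1000.0)) + 1
    return tmin_ms + np.arange(n) * 1000.0 / sfreq


def window_mask(times_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask for the half-open window ``[start, end)`` in ms."""
    start, end = window
    return (times_ms >= start) & (times_ms < end)


@dataclass
class EpochSet:
    """Epochs x channels x samples voltage array with condition labels.

    Voltages are in microvolts.  ``reference`` records whether the data are
    still in the recording reference ("vertex") or have been re-referenced
    to the channel average ("average").  ``metadata`` optionally carries one
    row per epoch (e.g. ITD / azimuth of the word that evoked it) and
    ``provenance`` is an append-only log of processing steps.
    """

    data: np.ndarray                # (n_epochs, n_channels, n_samples), uV
    times_ms: np.ndarray            # (n_samples,)
    labels: np.ndarray              # (n_epochs,) of condition strings
    montage: Montage
    reference: str = "vertex"
    metadata: pd.DataFrame | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        n_ep, n_ch, n_s = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if len(self.times_ms) != n_s:
            raise ValueError("time axis length does not match data")
        if len(self.labels) != n_ep:
            raise ValueError("labels length does not match data")
        if self.reference not in ("vertex", "average"):
            raise ValueError("reference must be 'vertex' or 'average'")
        if self.metadata is not None and len(self.metadata) != n_ep:
            raise ValueError("metadata length does not match data")
        if not np.isfinite(self.data).all():
            raise ValueError("data contain non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def sfreq(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.times_ms)))

    def log(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})

    def select(self, labels=None, epoch_mask=None) -> "EpochSet":
        """Subset epochs by condition label and/or boolean mask."""
        mask = np.ones(self.n_epochs, dtype=bool)
        if labels is not None:
            if isinstance(labels, str):
                labels = (labels,)
            mask &= np.isin(self.labels, list(labels))
        if epoch_mask is not None:
            mask &= np.asarray(epoch_mask, dtype=bool)
        meta = None
        if self.metadata is not None:
            meta = self.metadata.loc[mask].reset_index(drop=True)
        return EpochSet(
            data=self.data[mask],
            times_ms=self.times_ms,
            labels=self.labels[mask],
            montage=self.montage,
            reference=self.reference,
            metadata=meta,
            provenance=list(self.provenance),
        )

    def average(self, label: str | None = None) -> np.ndarray:
        """ERP: mean over (optionally label-selected) epochs, (n_ch, n_s)."""
        ep = self if label is None else self.select(label)
        if ep.n_epochs == 0:
            raise ValueError(f"no epochs with label {label!r}")
        return ep.data.mean(axis=0)

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            labels=self.labels.copy(),
            montage=self.montage,
            reference=self.reference,
            metadata=None if self.metadata is None else self.metadata.copy(),
            provenance=list(self.provenance),
        )


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording in microvolts."""

    data: np.ndarray          # (n_channels, n_samples), uV
    sfreq: float
    ch_names: tuple[str, ...]
    reference: str = "vertex"
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match data")
        if not np.isfinite(self.data).all():
            raise ValueError("data contain non-finite values")

    def log(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})
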