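"""File I/O: epochs container, continuous recordings, event tables.

The epochs container is a binary numeric array (``<stem>.npy``) plus a JSON
sidecar (``<stem>.json``) carrying dimensions, time axis, labels, montage,
reference state, per-epoch metadata and the provenance log.  Continuous
input is accepted as EDF (via mne) or as a plain numeric matrix
(``.npy`` or whitespace-separated text) with a JSON sidecar giving the
sampling rate and channel names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousEEG, EpochSet
from .montage import Montage


def _stem(path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in (".npy", ".json") else p


def save_epochs(ep: EpochSet, path) -> tuple[Path, Path]:
    """Write ``<stem>.npy`` + ``<stem>.json``; returns both paths."""
    stem = _stem(path)
    npy = stem.with_suffix(".npy")
    sidecar = stem.with_suffix(".json")
    np.save(npy, ep.data)
    meta = {
        "shape": list(ep.data.shape),
        "units": "uV",
        "times_ms": ep.times_ms.tolist(),
        "labels": [str(x) for x in ep.labels],
        "montage": ep.montage.to_dict(),
        "reference": ep.reference,
        "metadata": None if ep.metadata is None
        else ep.metadata.to_dict(orient="list"),
        "provenance": ep.provenance,
    }
    sidecar.write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return npy, sidecar


def load_epochs(path) -> EpochSet:
    stem = _stem(path)
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text(encoding="utf-8"))
    md = meta.get("metadata")
    return EpochSet(
        data=data,
        times_ms=np.asarray(meta["times_ms"], dtype=float),
        labels=np.array(meta["labels"], dtype=object),
        montage=Montage.from_dict(meta["montage"]),
        reference=meta["reference"],
        metadata=None if md is None else pd.DataFrame(md),
        provenance=list(meta.get("provenance", [])),
    )


def read_continuous_edf(path) -> ContinuousEEG:
    """Read a continuous EDF recording (data returned in microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne stores volts
    cont = ContinuousEEG(
        data=data_uv,
        sfreq=float(raw.info["sfreq"]),
        ch_names=tuple(raw.ch_names),
        reference="vertex",
    )
    cont.log("read_continuous_edf", path=str(path))
    return cont


def read_continuous_matrix(path, sidecar=None) -> ContinuousEEG:
    """Read a plain numeric channels x samples matrix with a JSON sidecar.

    The sidecar (default ``<stem>.json``) must provide ``sfreq_hz`` and
    ``ch_names``; an optional ``reference`` defaults to ``"vertex"``.
    """
    p = Path(path)
    if sidecar is None:
        sidecar = p.with_suffix(".json")
    meta = json.loads(Path(sidecar).read_text(encoding="utf-8"))
    if p.suffix == ".npy":
        data = np.load(p)
    else:
        data = np.loadtxt(p)
    cont = ContinuousEEG(
        data=np.atleast_2d(data),
        sfreq=float(meta["sfreq_hz"]),
        ch_names=tuple(meta["ch_names"]),
        reference=meta.get("reference", "vertex"),
    )
    cont.log("read_continuous_matrix", path=str(p))
    return cont
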