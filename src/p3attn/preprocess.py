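"""Preprocessing chain for continuous and epoched EEG.

Implements the analysis pipeline's standard ERP preprocessing: zero-phase
0.5-20 Hz band-pass filtering, epoching -300..800 ms around word onsets,
baseline correction, normalised-variance rejection of noisy channels and
epochs, Perrin-type spherical-spline interpolation of rejected channels,
and re-referencing to the channel average.

Window convention: the epoch time axis includes both endpoint samples
(tmin and tmax); every *window selection* thereafter is half-open
``[start, end)`` in milliseconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin
from scipy.special import eval_legendre

from .containers import ContinuousEEG, EpochSet
from .montage import Montage


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filtering

def _design_bandpass(low_hz: float, high_hz: float, sfreq: float) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) band-pass FIR kernel.

    The kernel length is set by the narrow low-frequency transition band
    (one octave below ``low_hz``); cutoffs are the -6 dB points.
    """
    trans = low_hz / 2.0  # Hz; transition width of the high-pass edge
    numtaps = int(np.ceil(3.3 * sfreq / trans))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                  window="hamming", fs=sfreq)


def bandpass_filter(cont: ContinuousEEG, low_hz: float = 0.5,
                    high_hz: float = 20.0) -> ContinuousEEG:
    """Zero-phase band-pass filter (default 0.5-20 Hz).

    A symmetric FIR kernel applied with reflective edge padding gives zero
    phase delay; the DC component is removed (high-pass) along with the
    channel mean.
    """
    nyq = cont.sfreq / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise PreprocessError(
            f"cutoffs must satisfy 0 < {low_hz} < {high_hz} < Nyquist ({nyq})"
        )
    h = _design_bandpass(low_hz, high_hz, cont.sfreq)
    pad = len(h) // 2
    x = cont.data - cont.data.mean(axis=1, keepdims=True)
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    y = fftconvolve(xp, h[np.newaxis, :], mode="same", axes=1)[:, pad:-pad]
    out = ContinuousEEG(y, cont.sfreq, cont.ch_names, cont.reference,
                        list(cont.provenance))
    out.log("bandpass_filter", low_hz=low_hz, high_hz=high_hz, numtaps=len(h))
    return out


# ---------------------------------------------------------------------------
# epoching

def epoch_continuous(cont: ContinuousEEG, events: pd.DataFrame,
                     montage: Montage,
                     tmin_ms: float = -300.0, tmax_ms: float = 800.0,
                     strict: bool = False) -> EpochSet:
    """Cut epochs around event onsets.

    ``events`` needs columns ``onset_ms`` and ``category`` (condition
    label); ``itd_us``/``azimuth_deg`` are carried into epoch metadata when
    present.  Each epoch spans ``tmin_ms..tmax_ms`` inclusive of both
    endpoint samples.  Events too close to the recording edge are skipped
    (or raise, in strict mode).
    """
    if tuple(cont.ch_names) != tuple(montage.names):
        raise PreprocessError("montage does not match recording channels")
    sf = cont.sfreq
    i0 = int(round(tmin_ms * sf / 1000.0))
    i1 = int(round(tmax_ms * sf / 1000.0))
    n_samp = i1 - i0 + 1
    times_ms = (np.arange(i0, i1 + 1)) * 1000.0 / sf

    data, labels, meta_rows, skipped = [], [], [], []
    for row in events.itertuples():
        center = int(round(row.onset_ms * sf / 1000.0))
        a, b = center + i0, center + i1
        if a < 0 or b >= cont.data.shape[1]:
            if strict:
                raise PreprocessError(
                    f"event at {row.onset_ms} ms too close to recording edge"
                )
            skipped.append(float(row.onset_ms))
            continue
        data.append(cont.data[:, a:b + 1])
        labels.append(row.category)
        meta_rows.append(
            {
                "onset_ms": float(row.onset_ms),
                "itd_us": getattr(row, "itd_us", np.nan),
                "azimuth_deg": getattr(row, "azimuth_deg", np.nan),
            }
        )

    shape = (len(data), len(cont.ch_names), n_samp)
    arr = np.array(data) if data else np.empty(shape)
    ep = EpochSet(
        data=arr.reshape(shape),
        times_ms=times_ms,
        labels=np.array(labels, dtype=object),
        montage=montage,
        reference=cont.reference,
        metadata=pd.DataFrame(
            meta_rows, columns=["onset_ms", "itd_us", "azimuth_deg"]
        ),
        provenance=list(cont.provenance),
    )
    ep.log("epoch_continuous", tmin_ms=tmin_ms, tmax_ms=tmax_ms,
           n_events=len(events), n_skipped=len(skipped))
    return ep


# ---------------------------------------------------------------------------
# baseline correction

def baseline_correct(ep: EpochSet,
                     window: tuple[float, float] | str = (-300.0, 0.0)
                     ) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``window``.

    ``window`` is a half-open ``[start, end)`` interval in ms, or the
    string ``"whole_epoch"`` to use the entire epoch extent.  Idempotent.
    """
    if isinstance(window, str):
        if window != "whole_epoch":
            raise PreprocessError(f"unknown baseline mode {window!r}")
        mask = np.ones_like(ep.times_ms, dtype=bool)
    else:
        start, end = window
        mask = (ep.times_ms >= start) & (ep.times_ms < end)
    if not mask.any():
        raise PreprocessError("baseline window contains no samples")
    out = ep.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    out.log("baseline_correct", window=str(window))
    return out


# ---------------------------------------------------------------------------
# normalised-variance rejection

@dataclass
class RejectionReport:
    """Channels/epochs flagged by normalised variance."""

    bad_channels: list
    bad_epochs: list
    channel_scores: dict   # name -> variance / median variance
    epoch_scores: list     # per-epoch variance / median variance
    channel_threshold: float
    epoch_threshold: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "RejectionReport":
        return cls(**json.loads(s))


def detect_bad(ep: EpochSet, channel_threshold: float = 5.0,
               epoch_threshold: float = 4.0) -> RejectionReport:
    """Flag channels and epochs whose normalised variance is excessive.

    The normalised variance of an item (channel or epoch) is its variance
    divided by the median variance across items of the same kind; items
    above the threshold are flagged.
    """
    if ep.n_channels < 8 or ep.n_epochs < 8:
        raise PreprocessError("need at least 8 channels and 8 epochs")
    ch_var = ep.data.var(axis=(0, 2))
    ep_var = ep.data.var(axis=(1, 2))
    ch_score = ch_var / np.median(ch_var)
    ep_score = ep_var / np.median(ep_var)
    bad_ch = [ep.montage.names[i]
              for i in np.flatnonzero(ch_score > channel_threshold)]
    bad_ep = [int(i) for i in np.flatnonzero(ep_score > epoch_threshold)]
    if len(bad_ch) == ep.n_channels or len(bad_ep) == ep.n_epochs:
        raise PreprocessError("all items flagged; thresholds unusable")
    return RejectionReport(
        bad_channels=bad_ch,
        bad_epochs=bad_ep,
        channel_scores={n: float(s) for n, s in zip(ep.montage.names, ch_score)},
        epoch_scores=[float(s) for s in ep_score],
        channel_threshold=channel_threshold,
        epoch_threshold=epoch_threshold,
    )


def apply_rejection(ep: EpochSet, report: RejectionReport) -> EpochSet:
    """Drop flagged epochs and interpolate flagged channels."""
    keep = np.ones(ep.n_epochs, dtype=bool)
    keep[report.bad_epochs] = False
    out = ep.select(epoch_mask=keep)
    out.log("drop_epochs", n_dropped=int((~keep).sum()))
    if report.bad_channels:
        out = interpolate_channels(out, report.bad_channels)
    return out


# ---------------------------------------------------------------------------
# spherical-spline interpolation (Perrin et al. style)

def _g_matrix(cosang: np.ndarray, m: int, nmax: int) -> np.ndarray:
    """Spherical-spline kernel g(cos theta), Legendre series of degree nmax."""
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, nmax + 1):
        g += (2 * n + 1) / (n * (n + 1)) ** m * eval_legendre(n, cosang)
    return g / (4.0 * np.pi)


def interpolation_matrix(montage: Montage, bad_names, m: int = 4,
                         nmax: int = 7, reg: float = 1e-5) -> np.ndarray:
    """Operator mapping good-channel data to estimates at bad channels.

    Solves the spherical-spline system on the good channels (spline order
    ``m``, Legendre series truncated at degree ``nmax``, ridge
    regularisation ``reg`` on the kernel diagonal) and evaluates the spline
    at the bad-channel positions.  Returns ``(n_bad, n_good)``.
    """
    bad_idx = [montage.index(n) for n in bad_names]
    good_idx = [i for i in range(montage.n_channels) if i not in bad_idx]
    pos = montage.positions
    cos_gg = np.clip(pos[good_idx] @ pos[good_idx].T, -1.0, 1.0)
    cos_bg = np.clip(pos[bad_idx] @ pos[good_idx].T, -1.0, 1.0)
    G = _g_matrix(cos_gg, m, nmax)
    Gb = _g_matrix(cos_bg, m, nmax)
    k = len(good_idx)
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G + reg * np.eye(k)
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    # solve A [w; c] = [v; 0] for every time sample at once: precompute
    # the operator rows. interp = Gb @ w + c
    Ainv = np.linalg.pinv(A)
    W = Ainv[:k, :k]     # v -> w
    cvec = Ainv[k, :k]   # v -> c
    return Gb @ W + cvec[np.newaxis, :]


def interpolate_channels(ep: EpochSet, bad_names, m: int = 4, nmax: int = 7,
                         reg: float = 1e-5) -> EpochSet:
    """Replace bad channels by spherical-spline estimates from good ones."""
    bad_names = list(bad_names)
    if not bad_names:
        return ep
    unknown = [n for n in bad_names if n not in ep.montage.names]
    if unknown:
        raise PreprocessError(f"unknown channel(s) {unknown}")
    if len(bad_names) >= ep.n_channels:
        raise PreprocessError("bad set must be a strict subset of channels")
    if len(bad_names) > 0.2 * ep.n_channels:
        raise PreprocessError(
            f"{len(bad_names)} bad channels exceed 20% of "
            f"{ep.n_channels}; insufficient support for interpolation"
        )
    bad_idx = [ep.montage.index(n) for n in bad_names]
    good_idx = [i for i in range(ep.n_channels) if i not in bad_idx]
    M = interpolation_matrix(ep.montage, bad_names, m=m, nmax=nmax, reg=reg)
    out = ep.copy()
    out.data[:, bad_idx, :] = np.einsum("bg,ngt->nbt", M, ep.data[:, good_idx, :])
    out.log("interpolate_channels", bad=bad_names, m=m, nmax=nmax, reg=reg)
    return out


# ---------------------------------------------------------------------------
# referencing

def average_reference(ep: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous average of all channels.

    Idempotent; updates the container's reference state.
    """
    if ep.n_channels < 2:
        raise PreprocessError("need at least 2 channels")
    out = ep.copy()
    out.data -= out.data.mean(axis=1, keepdims=True)
    out.reference = "average"
    out.log("average_reference")
    return out
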