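"""Synthetic epoched EEG with condition-dependent P3a/P3b components.

Each simulated epoch is a sum of ERP components -- a rank-one spatial map
(x) temporal kernel product scaled by a condition-specific gain in uV --
plus spatially and temporally correlated background noise:

    epoch = sum_c gain[label][c] * map_c (x) kernel_c
            + sd_spatial * (spatial smoothing @ AR(1) noise)
            + sd_sensor * white noise

The P3a component is a fronto-centrally anchored positivity peaking at
250 ms; the P3b a centro-parietal positivity peaking at 550 ms; a third
"diffuse parietal" component (sustained 100-700 ms) emulates the temporally
indiscriminate parietal responses seen in some patients.  Spatial maps are
average-referenced (zero-mean across channels) and normalised to unit GFP,
so a gain of g uV produces a peak GFP contribution of about g uV in a
noise-free average.

Built-in subject profiles emulate the response patterns of healthy
volunteers and of characteristic patients with disorders of consciousness:
an exogenous-plus-endogenous responder, exogenous-only responders, a
temporally/conditionally indiscriminate responder, and a null (no-response)
profile.  Default gains and noise levels are frozen so that single-subject
randomization tests behave realistically at the study's trial counts
(~240 per target condition, ~500 distractors): components are invisible in
single trials but clear in the average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .containers import CONDITIONS, EpochSet, default_times_ms
from .montage import (
    CENTROPARIETAL_ANCHOR,
    FRONTOCENTRAL_ANCHOR,
    Montage,
    PARIETAL_ANCHOR,
    make_montage,
)
from .paradigm import DISTRACTOR_ITDS_US, TARGET_ITD_US, itd_to_azimuth

COMPONENTS = ("P3a", "P3b", "diffuse_parietal")

#: component time windows (ms), half-open
P3A_WINDOW_MS = (100.0, 400.0)
P3B_WINDOW_MS = (400.0, 700.0)


@dataclass(frozen=True)
class ERPTemplate:
    """Rank-one ERP component: spatial map (x) temporal kernel."""

    spatial_map: np.ndarray      # (n_channels,), zero-mean, unit GFP
    temporal_kernel: np.ndarray  # (n_samples,), unit peak
    kind: str                    # "P3a" | "P3b" | "diffuse_parietal"


def _gaussian_on_sphere(montage: Montage, anchor: np.ndarray,
                        fwhm_deg: float) -> np.ndarray:
    """Zero-mean, unit-GFP Gaussian lobe centred on ``anchor``."""
    cosang = np.clip(montage.positions @ anchor, -1.0, 1.0)
    ang_deg = np.degrees(np.arccos(cosang))
    sigma = fwhm_deg / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    m = np.exp(-0.5 * (ang_deg / sigma) ** 2)
    m -= m.mean()
    gfp = np.sqrt(np.mean(m**2))
    return m / gfp


def _raised_cosine(times_ms: np.ndarray, center_ms: float,
                   fwhm_ms: float) -> np.ndarray:
    """Raised-cosine bump with unit peak; FWHM equals ``fwhm_ms``."""
    half_support = fwhm_ms  # value 0.5 at +-fwhm/2, zero at +-fwhm
    x = (times_ms - center_ms) / half_support
    k = np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return k


def make_template(kind: str, montage: Montage,
                  times_ms: np.ndarray | None = None) -> ERPTemplate:
    """Construct one of the built-in ERP component templates.

    P3a: fronto-central lobe, kernel centred at 250 ms, supported exactly
    on 100-400 ms.  P3b: centro-parietal lobe, kernel centred at 550 ms,
    supported exactly on 400-700 ms (confining each component to its
    canonical analysis window keeps cross-window contrasts clean).
    diffuse_parietal: parietal lobe, sustained kernel spanning the epoch.
    """
    if times_ms is None:
        times_ms = default_times_ms()
    if kind == "P3a":
        smap = _gaussian_on_sphere(montage, FRONTOCENTRAL_ANCHOR, fwhm_deg=70.0)
        kernel = _raised_cosine(times_ms, 250.0, 150.0)
    elif kind == "P3b":
        smap = _gaussian_on_sphere(montage, CENTROPARIETAL_ANCHOR, fwhm_deg=80.0)
        kernel = _raised_cosine(times_ms, 550.0, 150.0)
    elif kind == "diffuse_parietal":
        smap = _gaussian_on_sphere(montage, PARIETAL_ANCHOR, fwhm_deg=90.0)
        # flat top 200-600 ms with 100-ms cosine ramps: sustained 100-700 ms
        up = _raised_cosine(times_ms, 200.0, 200.0)
        kernel = np.where(
            (times_ms >= 200.0) & (times_ms <= 600.0),
            1.0,
            np.maximum(up * (times_ms < 200.0),
                       _raised_cosine(times_ms, 600.0, 200.0) * (times_ms > 600.0)),
        )
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    return ERPTemplate(spatial_map=smap, temporal_kernel=kernel, kind=kind)


@dataclass
class NoiseParams:
    """Background-noise model parameters.

    ``sd_spatial_uv``: SD of the spatially smoothed AR(1) process per
    channel; ``smoothing_fwhm_deg``: FWHM of the spatial Gaussian smoothing
    kernel on the sphere; ``ar_coef``: lag-1 autoregressive coefficient at
    250 Hz; ``sd_sensor_uv``: SD of additive white sensor noise.
    """

    sd_spatial_uv: float = 10.0
    sd_sensor_uv: float = 2.0
    smoothing_fwhm_deg: float = 60.0
    ar_coef: float = 0.95


@dataclass
class SubjectProfile:
    """Condition x component gains (uV), noise model and trial counts."""

    name: str
    gains: dict = field(default_factory=dict)  # gains[cond][component] -> uV
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_trials: dict = field(
        default_factory=lambda: {
            "explicit_target": 240,
            "implicit_target": 240,
            "distractor": 500,
        }
    )

    def validate(self) -> None:
        for cond, comps in self.gains.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            for comp, g in comps.items():
                if comp not in COMPONENTS:
                    raise ValueError(f"unknown component {comp!r}")
                if not np.isfinite(g) or g < 0:
                    raise ValueError(f"gain {cond}/{comp} must be finite and >= 0")
        for cond, n in self.n_trials.items():
            if n < 1:
                raise ValueError(f"trial count for {cond} must be >= 1")

    def gain(self, cond: str, comp: str) -> float:
        return float(self.gains.get(cond, {}).get(comp, 0.0))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SubjectProfile":
        d = json.loads(s)
        d["noise"] = NoiseParams(**d["noise"])
        return cls(**d)


def builtin_profiles() -> dict[str, SubjectProfile]:
    """Named subject profiles emulating the study's response patterns.

    HEALTHY: P3a to all three conditions, P3b to explicit targets only.
    P1_LIKE: P3b to explicit targets only; P3a to implicit targets with a
        near-zero distractor response (exogenous + endogenous responder).
    P10_LIKE: equal P3a to all conditions, no P3b.
    P11_LIKE: sustained diffuse parietal response to all conditions,
        no discrimination.
    P20_LIKE: P3a larger for targets than distractors, no P3b.
    NULL: no evoked response at all (noise only).
    """
    p3a, p3b, dif = COMPONENTS
    return {
        "HEALTHY": SubjectProfile(
            name="HEALTHY",
            gains={
                "explicit_target": {p3a: 4.0, p3b: 5.0},
                "implicit_target": {p3a: 4.0},
                "distractor": {p3a: 4.0},
            },
        ),
        "P1_LIKE": SubjectProfile(
            name="P1_LIKE",
            gains={
                "explicit_target": {p3b: 5.0},
                "implicit_target": {p3a: 4.0},
                "distractor": {p3a: 0.5},
            },
        ),
        "P10_LIKE": SubjectProfile(
            name="P10_LIKE",
            gains={
                "explicit_target": {p3a: 4.0},
                "implicit_target": {p3a: 4.0},
                "distractor": {p3a: 4.0},
            },
        ),
        "P11_LIKE": SubjectProfile(
            name="P11_LIKE",
            gains={
                "explicit_target": {dif: 4.0},
                "implicit_target": {dif: 4.0},
                "distractor": {dif: 4.0},
            },
        ),
        "P20_LIKE": SubjectProfile(
            name="P20_LIKE",
            gains={
                "explicit_target": {p3a: 4.0},
                "implicit_target": {p3a: 4.0},
                "distractor": {p3a: 1.5},
            },
        ),
        "NULL": SubjectProfile(name="NULL", gains={}),
    }


def _smoothing_matrix(montage: Montage, fwhm_deg: float) -> np.ndarray:
    """Spatial Gaussian smoothing kernel, rows normalised to unit L2 norm.

    Unit row norms keep the marginal variance of smoothed white noise equal
    to one on every channel (homogeneous across the cap).
    """
    ang_deg = np.degrees(montage.angles())
    sigma = fwhm_deg / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    K = np.exp(-0.5 * (ang_deg / sigma) ** 2)
    K /= np.linalg.norm(K, axis=1, keepdims=True)
    return K


def _correlated_noise(n_epochs: int, montage: Montage, n_samples: int,
                      noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially smoothed AR(1) noise, (n_ep, n_ch, n_s).

    The AR(1) process starts from its exact stationary distribution (via
    the filter's initial condition), so every sample -- including the
    baseline period -- has identical marginal statistics.  Noise is drawn
    and filtered in single precision for speed; callers accumulate into
    double precision.
    """
    n_ch = montage.n_channels
    a = np.float32(noise.ar_coef)
    w = rng.standard_normal((n_epochs, n_ch, n_samples), dtype=np.float32)
    x_prev = rng.standard_normal((n_epochs, n_ch, 1), dtype=np.float32)
    x_prev /= np.sqrt(np.float32(1.0) - a * a)
    b_coef = np.array([1.0], dtype=np.float32)
    a_coef = np.array([1.0, -a], dtype=np.float32)
    x, _ = lfilter(b_coef, a_coef, w, axis=-1, zi=a * x_prev)
    x *= np.sqrt(np.float32(1.0) - a * a)  # unit marginal variance
    K = _smoothing_matrix(montage, noise.smoothing_fwhm_deg).astype(np.float32)
    return np.matmul(K, x)  # batched over epochs


def simulate_epochs(profile: SubjectProfile,
                    montage: Montage | None = None,
                    rng: np.random.Generator | int | None = None,
                    times_ms: np.ndarray | None = None) -> EpochSet:
    """Simulate one subject's epoched EEG under a response profile.

    Epochs are generated per condition (trial counts from the profile),
    each as the gain-weighted sum of component templates plus correlated
    background noise.  Per-epoch metadata assigns target ITDs (+-660 us,
    half left / half right) and uniform distractor ITDs, so lateralisation
    contrasts can be formed downstream.  Deterministic given the seed.
    """
    profile.validate()
    if montage is None:
        montage = make_montage()
    if times_ms is None:
        times_ms = default_times_ms()
    if not isinstance(rng, np.random.Generator):
        # SFC64: fast bulk normal generation for the large noise arrays
        rng = np.random.Generator(np.random.SFC64(np.random.SeedSequence(rng)))

    templates = {k: make_template(k, montage, times_ms) for k in COMPONENTS}

    data, labels, itds = [], [], []
    for cond in CONDITIONS:
        n = int(profile.n_trials.get(cond, 0))
        if n == 0:
            continue
        signal = np.zeros((montage.n_channels, len(times_ms)))
        for comp in COMPONENTS:
            g = profile.gain(cond, comp)
            if g:
                t = templates[comp]
                signal += g * np.outer(t.spatial_map, t.temporal_kernel)
        noise = profile.noise
        x = _correlated_noise(n, montage, len(times_ms), noise, rng)
        x *= np.float32(noise.sd_spatial_uv)
        if noise.sd_sensor_uv:
            w = rng.standard_normal(x.shape, dtype=np.float32)
            w *= np.float32(noise.sd_sensor_uv)
            x += w
        x += signal.astype(np.float32)
        data.append(x)
        labels.extend([cond] * n)
        if cond == "distractor":
            itds.extend(int(v) for v in rng.choice(DISTRACTOR_ITDS_US, size=n))
        else:
            side = np.array([-TARGET_ITD_US] * (n // 2)
                            + [TARGET_ITD_US] * (n - n // 2))
            rng.shuffle(side)
            itds.extend(int(v) for v in side)

    if not data:
        raise ValueError("profile has no trials in any condition")
    meta = pd.DataFrame(
        {
            "itd_us": itds,
            "azimuth_deg": [itd_to_azimuth(v) for v in itds],
        }
    )
    ep = EpochSet(
        data=np.concatenate(data, axis=0),
        times_ms=times_ms,
        labels=np.array(labels, dtype=object),
        montage=montage,
        reference="average",
        metadata=meta,
    )
    ep.log("simulate_epochs", profile=profile.name,
           n_trials=dict(profile.n_trials))
    return ep


def inject_variance_spike(epochs: EpochSet, channel: int | None = None,
                          epoch: int | None = None,
                          factor: float = 10.0,
                          rng: np.random.Generator | int | None = None
                          ) -> EpochSet:
    """Multiply one channel's (or one epoch's) noise by ``factor``.

    Test utility for exercising normalised-variance bad-channel/epoch
    detection; there is no physiological artifact model.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = epochs.copy()
    if channel is not None:
        out.data[:, channel, :] *= factor
        out.log("inject_variance_spike", channel=int(channel), factor=factor)
    if epoch is not None:
        out.data[epoch, :, :] *= factor
        out.log("inject_variance_spike", epoch=int(epoch), factor=factor)
    return out
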