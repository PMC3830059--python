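"""Peak localisation and topographic similarity.

Peaks are picked on the GFP time course by default (the time point within
a window -- or within a significant cluster -- at which GFP is maximal);
an alternative picks the time of maximal absolute amplitude across all
electrodes.  Topographic similarity between two scalp maps is the standard
channel-wise Pearson correlation; its parametric p-value ignores the
spatial autocorrelation of scalp fields, so it is returned together with
an explicit caveat flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .containers import window_mask
from .gfp_stats import GFPTimeCourse, StatError


@dataclass
class PeakTopography:
    """Scalp map at the GFP (or amplitude) peak within a window."""

    peak_time_ms: float
    values: np.ndarray          # per-channel voltages at the peak (uV)
    window_ms: tuple

    def to_json(self) -> str:
        d = asdict(self)
        d["values"] = np.asarray(d["values"]).tolist()
        return json.dumps(d, indent=1)


def peak_time(gfp_tc: GFPTimeCourse, window: tuple[float, float],
              restrict_to_cluster: tuple[float, float] | None = None) -> float:
    """Time (ms) of maximal GFP within a window.

    When a significant cluster extent is supplied, the search is restricted
    to it.  Exact ties resolve to the earliest sample.
    """
    mask = window_mask(gfp_tc.times_ms, window)
    if restrict_to_cluster is not None:
        c0, c1 = restrict_to_cluster
        mask &= (gfp_tc.times_ms >= c0) & (gfp_tc.times_ms <= c1)
    if not mask.any():
        raise StatError("peak search window/cluster restriction is empty")
    idx = np.flatnonzero(mask)
    vals = gfp_tc.values[idx]
    return float(gfp_tc.times_ms[idx[np.argmax(vals)]])  # argmax: first max


def peak_topography(erp: np.ndarray, times_ms: np.ndarray,
                    window: tuple[float, float],
                    restrict_to_cluster: tuple[float, float] | None = None,
                    pick: str = "gfp") -> PeakTopography:
    """Scalp map of an ERP at its within-window peak.

    ``pick="gfp"`` (default) locates the peak on the GFP time course;
    ``pick="amplitude"`` uses the maximal absolute voltage across all
    electrodes.
    """
    erp = np.asarray(erp, dtype=float)
    if pick == "gfp":
        from .gfp_stats import gfp
        tc = GFPTimeCourse(gfp(erp), times_ms, 1)
    elif pick == "amplitude":
        tc = GFPTimeCourse(np.abs(erp).max(axis=0), times_ms, 1)
    else:
        raise StatError(f"unknown peak picker {pick!r}")
    t = peak_time(tc, window, restrict_to_cluster)
    i = int(np.argmin(np.abs(times_ms - t)))
    return PeakTopography(peak_time_ms=t, values=erp[:, i].copy(),
                          window_ms=tuple(window))


@dataclass
class TopoCorrelation:
    """Channel-wise Pearson correlation between two scalp maps."""

    r: float
    p: float
    n_channels: int
    #: the parametric p assumes independent channels; neighbouring sensors
    #: are spatially correlated, which inflates apparent significance
    spatial_autocorrelation_caveat: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def topo_correlation(map_a: np.ndarray, map_b: np.ndarray) -> TopoCorrelation:
    """Pearson r between two scalp maps over their paired channel values.

    The p-value comes from the t-distribution with N-2 degrees of freedom
    and carries the spatial-autocorrelation caveat flag.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatError("maps must be 1-D with equal channel sets")
    if len(a) < 3:
        raise StatError("need at least 3 channels")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise StatError("zero-variance map has no defined correlation")
    r, p = stats.pearsonr(a, b)
    return TopoCorrelation(r=float(r), p=float(p), n_channels=len(a))
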