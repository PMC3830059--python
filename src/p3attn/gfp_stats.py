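"""Reference-free ERP statistics: GFP, cluster randomization tests, TCT.

Global Field Power (GFP) is the spatial standard deviation of the scalp
voltage field at one time point -- a reference-free scalar summary of field
strength (Lehmann & Skrandies).  The tests here operate on GFP time
courses:

* **Temporal-cluster randomization test.**  The observed GFP difference
  D(t) between two ERPs is compared, at every time point of a window of
  interest, against the *maximum* difference each of ``n_iter`` random
  relabelings produces within that window (max-statistic familywise-error
  control).  Time points whose Monte-Carlo p falls below alpha are grouped
  by temporal contiguity; each cluster is scored by the sum of pointwise
  t-values (z-scores of D(t) against the randomization ensemble), and the
  largest observed cluster score is referred to the distribution of largest
  cluster scores obtained by re-applying the identical procedure to every
  randomization iteration (leave-one-out against the remaining iterations'
  maxima).
* **Condition-vs-baseline variant.**  Each epoch contributes two
  equal-length segments (analysis window, baseline window); randomization
  swaps the two segment labels independently per epoch; one-sided.
* **Topographic Consistency Test (TCT).**  The GFP of the ERP is compared
  to GFPs of surrogate ERPs in which every epoch's scalp topography is
  destroyed by an independent random channel permutation (fresh permutation
  per epoch per iteration).

All Monte-Carlo p-values use the plus-one convention
``p = (1 + #exceedances) / (n_iter + 1)`` and ties count as exceedances, so
p is never zero.  With ``exhaustive=True`` the full permutation group is
enumerated instead of sampled.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._perm import permuted_channel_averages
from .containers import window_mask


class StatError(ValueError):
    pass


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# GFP

def gfp(erp: np.ndarray) -> np.ndarray:
    """Global Field Power of a (..., n_channels, n_samples) voltage array.

    ``GFP(t) = sqrt(mean_i (v_i(t) - vbar(t))^2)`` across channels; the
    instantaneous channel mean is subtracted, making the value independent
    of the recording reference.
    """
    erp = np.asarray(erp, dtype=float)
    if erp.shape[-2] < 2:
        raise StatError("GFP requires at least 2 channels")
    return erp.std(axis=-2, ddof=0)


@dataclass
class GFPTimeCourse:
    """Per-sample GFP of an ERP."""

    values: np.ndarray
    times_ms: np.ndarray
    n_inputs: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.shape != self.times_ms.shape:
            raise StatError("values and times must have equal length")

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("time_ms\tgfp_uv\n")
            for t, v in zip(self.times_ms, self.values):
                fh.write(f"{t:.6g}\t{v:.9g}\n")


def gfp_timecourse(items: np.ndarray, times_ms: np.ndarray) -> GFPTimeCourse:
    """GFP of the average of ``items`` (n_items, n_channels, n_samples)."""
    items = np.asarray(items, dtype=float)
    return GFPTimeCourse(gfp(items.mean(axis=0)), times_ms, items.shape[0])


# ---------------------------------------------------------------------------
# results

@dataclass
class ClusterResult:
    """Largest supra-threshold temporal cluster and its Monte-Carlo p."""

    window_ms: tuple
    extent_ms: tuple | None      # (start, end) of the largest cluster, or None
    cluster_level_t: float       # sum of constituent pointwise t-values
    cluster_mean_t: float        # mean of constituent pointwise t-values
    p: float
    n_iter: int
    alpha: float
    direction: str
    pointwise_p: np.ndarray = None
    pointwise_t: np.ndarray = None
    times_ms: np.ndarray = None

    @property
    def significant(self) -> bool:
        return self.extent_ms is not None and self.p < self.alpha

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("pointwise_p", "pointwise_t", "times_ms"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        d["significant"] = self.significant
        return json.dumps(d, indent=1)


@dataclass
class TCTResult:
    """Topographic Consistency Test outcome for one window."""

    window_ms: tuple
    times_ms: np.ndarray
    pointwise_p: np.ndarray
    window_p: float
    n_iter: int

    @property
    def significant(self) -> bool:
        return self.window_p < 0.05

    def to_json(self) -> str:
        d = asdict(self)
        d["times_ms"] = np.asarray(d["times_ms"]).tolist()
        d["pointwise_p"] = np.asarray(d["pointwise_p"]).tolist()
        return json.dumps(d, indent=1)


# ---------------------------------------------------------------------------
# cluster machinery

def _contiguous_runs(sig: np.ndarray):
    """Inclusive (start, end) index pairs of True runs in a boolean vector."""
    padded = np.concatenate([[False], sig, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts, ends))

def _largest_cluster(sig: np.ndarray, t: np.ndarray):
    """(cluster-level t, n_points, (i0, i1)) of the largest cluster, else zeros."""
    best = (0.0, 0, None)
    for i0, i1 in _contiguous_runs(sig):
        score = float(t[i0:i1 + 1].sum())
        if best[2] is None or score > best[0]:
            best = (score, i1 - i0 + 1, (int(i0), int(i1)))
    return best


def _null_cluster_scores(S_k: np.ndarray, M: np.ndarray, alpha: float,
                         leave_one_out: bool) -> np.ndarray:
    """Largest cluster-level t per randomization iteration.

    Applies the observed-data clustering steps to every iteration's GFP
    difference, comparing it against the (other) iterations' window maxima.
    """
    n_iter, _ = S_k.shape
    M_sorted = np.sort(M)
    # cnt[k, tau] = #{j : M_j >= S_k[tau]}  (own iteration always counts,
    # because M_k is the max over tau of S_k)
    cnt = n_iter - np.searchsorted(M_sorted, S_k, side="left")
    if leave_one_out:
        p_k = cnt / n_iter  # (1 + (cnt - 1)) / ((n_iter - 1) + 1)
        tot = S_k.sum(axis=0)
        tot2 = (S_k**2).sum(axis=0)
        mean_loo = (tot - S_k) / (n_iter - 1)
        var_loo = (tot2 - S_k**2 - (n_iter - 1) * mean_loo**2) / (n_iter - 2)
        sd = np.sqrt(np.clip(var_loo, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z_k = np.where(sd > 0, (S_k - mean_loo) / sd, 0.0)
    else:
        p_k = (1.0 + cnt) / (n_iter + 1.0)
        mean = S_k.mean(axis=0)
        sd = S_k.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_k = np.where(sd > 0, (S_k - mean) / sd, 0.0)
    sig_k = p_k < alpha
    scores = np.zeros(n_iter)
    for k in range(n_iter):
        if sig_k[k].any():
            scores[k] = _largest_cluster(sig_k[k], z_k[k])[0]
    return scores


def _cluster_randomization(S_obs: np.ndarray, S_k: np.ndarray,
                           times_win: np.ndarray, window: tuple,
                           alpha: float, direction: str, n_iter: int,
                           leave_one_out: bool) -> ClusterResult:
    """Shared core: pointwise max-statistic p/t, clustering, cluster p."""
    M = S_k.max(axis=1)
    M_sorted = np.sort(M)
    cnt = n_iter - np.searchsorted(M_sorted, S_obs, side="left")
    pointwise_p = (1.0 + cnt) / (n_iter + 1.0)
    mean = S_k.mean(axis=0)
    sd = S_k.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pointwise_t = np.where(sd > 0, (S_obs - mean) / sd, 0.0)

    sig = pointwise_p < alpha
    if not sig.any():
        res = ClusterResult(window, None, 0.0, 0.0, 1.0, n_iter, alpha,
                            direction, pointwise_p, pointwise_t, times_win)
        assert res.p > 0
        return res

    T_obs, n_pts, (i0, i1) = _largest_cluster(sig, pointwise_t)
    null_scores = _null_cluster_scores(S_k, M, alpha, leave_one_out)
    p = (1.0 + np.count_nonzero(null_scores >= T_obs)) / (n_iter + 1.0)
    assert p > 0
    return ClusterResult(
        window_ms=tuple(window),
        extent_ms=(float(times_win[i0]), float(times_win[i1])),
        cluster_level_t=T_obs,
        cluster_mean_t=T_obs / n_pts,
        p=float(p),
        n_iter=n_iter,
        alpha=alpha,
        direction=direction,
        pointwise_p=pointwise_p,
        pointwise_t=pointwise_t,
        times_ms=times_win,
    )


def _directional(D: np.ndarray, direction: str) -> np.ndarray:
    if direction == "two-sided":
        return np.abs(D)
    if direction == "greater":
        return D
    if direction == "less":
        return -D
    raise StatError(f"unknown direction {direction!r}")


def _check_window(times_win: np.ndarray):
    if len(times_win) < 3:
        raise StatError("window must contain at least 3 samples")


def _check_n_iter(n_iter: int):
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} < 100 gives a coarse Monte-Carlo p",
                      stacklevel=3)


def cluster_test_conditions(items_a: np.ndarray, items_b: np.ndarray,
                            times_ms: np.ndarray,
                            window: tuple[float, float],
                            n_iter: int = 1000, alpha: float = 0.05,
                            direction: str = "two-sided",
                            rng=None, exhaustive: bool = False,
                            leave_one_out: bool = True) -> ClusterResult:
    """Cluster randomization test between two sets of epochs/averages.

    ``items_a``/``items_b`` are (n_items, n_channels, n_samples) arrays --
    single epochs in single-subject mode, subject-wise averages in group
    mode.  Labels are permuted preserving the two set sizes; the GFP
    difference of the reaveraged sets provides the randomization ensemble.
    ``direction="greater"`` tests A > B; the default is two-sided on |D|.
    """
    A = np.asarray(items_a, dtype=float)
    B = np.asarray(items_b, dtype=float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise StatError("need at least 2 items per condition")
    mask = window_mask(times_ms, window)
    times_win = times_ms[mask]
    _check_window(times_win)

    A = A[:, :, mask]
    B = B[:, :, mask]
    nA, nB = A.shape[0], B.shape[0]
    n = nA + nB
    X = np.concatenate([A, B], axis=0)
    n_ch, n_s = X.shape[1], X.shape[2]
    Xf = X.reshape(n, n_ch * n_s)
    total = Xf.sum(axis=0)

    S_obs = _directional(gfp(A.mean(0)) - gfp(B.mean(0)), direction)

    if exhaustive:
        from math import comb
        n_perm = comb(n, nA)
        if n_perm > 2**14:
            raise StatError(
                f"exhaustive enumeration of {n_perm} splits is too large"
            )
        W = np.zeros((n_perm, n), dtype=bool)
        for k, idx in enumerate(itertools.combinations(range(n), nA)):
            W[k, list(idx)] = True
        n_iter = n_perm
    else:
        _check_n_iter(n_iter)
        rng = _as_rng(rng)
        W = np.zeros((n_iter, n), dtype=bool)
        for k in range(n_iter):
            W[k, rng.permutation(n)[:nA]] = True

    sumA = W.astype(float) @ Xf
    meanA = (sumA / nA).reshape(n_iter, n_ch, n_s)
    meanB = ((total - sumA) / nB).reshape(n_iter, n_ch, n_s)
    S_k = _directional(gfp(meanA) - gfp(meanB), direction)
    if exhaustive:
        # the first enumerated split is the observed labelling; reusing its
        # row makes the observed-vs-itself tie exact (ties count as
        # exceedances)
        S_obs = S_k[0]

    return _cluster_randomization(S_obs, S_k, times_win, window, alpha,
                                  direction, n_iter, leave_one_out)


def cluster_test_vs_baseline(items: np.ndarray, times_ms: np.ndarray,
                             window: tuple[float, float],
                             baseline: tuple[float, float] = (-300.0, 0.0),
                             n_iter: int = 1000, alpha: float = 0.05,
                             rng=None, exhaustive: bool = False,
                             leave_one_out: bool = True) -> ClusterResult:
    """One-sided cluster test of an analysis window against baseline.

    Each epoch contributes two equal-length segments (analysis, baseline);
    the randomization independently swaps, per epoch, which segment carries
    the analysis label.  Tests analysis > baseline.
    """
    X = np.asarray(items, dtype=float)
    if X.shape[0] < 2:
        raise StatError("need at least 2 epochs")
    amask = window_mask(times_ms, window)
    bmask = window_mask(times_ms, baseline)
    if amask.sum() != bmask.sum():
        raise StatError(
            f"analysis window ({int(amask.sum())} samples) and baseline "
            f"({int(bmask.sum())} samples) must have equal length: the "
            "randomization swaps the two segments within each epoch"
        )
    times_win = times_ms[amask]
    _check_window(times_win)

    A = X[:, :, amask]
    B = X[:, :, bmask]
    n, n_ch, n_s = A.shape
    Y = (A - B).reshape(n, n_ch * n_s)
    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)

    S_obs = gfp(mean_a) - gfp(mean_b)

    if exhaustive:
        if n > 14:
            raise StatError(f"exhaustive enumeration of 2^{n} swaps is too large")
        n_iter = 2**n
        W = np.array(
            [[(k >> e) & 1 for e in range(n)] for k in range(n_iter)],
            dtype=bool,
        )
    else:
        _check_n_iter(n_iter)
        rng = _as_rng(rng)
        W = rng.random((n_iter, n)) < 0.5

    shift = (W.astype(float) @ Y / n).reshape(n_iter, n_ch, n_s)
    S_k = gfp(mean_a[np.newaxis] - shift) - gfp(mean_b[np.newaxis] + shift)
    if exhaustive:
        S_obs = S_k[0]  # the all-zero swap pattern is the observed labelling

    return _cluster_randomization(S_obs, S_k, times_win, window, alpha,
                                  "greater", n_iter, leave_one_out)


# ---------------------------------------------------------------------------
# Topographic Consistency Test

def tct(items: np.ndarray, times_ms: np.ndarray,
        window: tuple[float, float], n_iter: int = 1000,
        rng=None) -> TCTResult:
    """Topographic Consistency Test within a time window.

    Per iteration, every epoch's channel values are permuted across
    channels with a fresh independent permutation, epochs are averaged and
    the surrogate GFP computed.  Pointwise p compares the observed GFP to
    the surrogate ensemble at the same time point; ``window_p`` applies the
    same comparison to the window-mean GFP.
    """
    X = np.asarray(items, dtype=float)
    if X.shape[0] < 2:
        raise StatError("TCT needs at least 2 epochs")
    if X.shape[1] < 3:
        raise StatError("TCT needs at least 3 channels")
    _check_n_iter(n_iter)
    mask = window_mask(times_ms, window)
    times_win = times_ms[mask]
    _check_window(times_win)
    X = X[:, :, mask]
    n, n_ch, n_s = X.shape
    rng = _as_rng(rng)

    # single precision: the surrogate ensemble is memory-bound and the
    # Monte-Carlo resolution (1/n_iter) dwarfs float32 rounding
    Xf = np.ascontiguousarray(X, dtype=np.float32)
    gfp_obs = gfp(Xf.mean(axis=0))
    gfp_k = gfp(permuted_channel_averages(Xf, n_iter, rng))  # (n_iter, n_s)

    exceed = np.count_nonzero(gfp_k >= gfp_obs[np.newaxis, :], axis=0)
    pointwise_p = (1.0 + exceed) / (n_iter + 1.0)
    wm_obs = gfp_obs.mean()
    wm_k = gfp_k.mean(axis=1)
    window_p = (1.0 + np.count_nonzero(wm_k >= wm_obs)) / (n_iter + 1.0)
    assert window_p > 0 and (pointwise_p > 0).all()

    return TCTResult(
        window_ms=tuple(window),
        times_ms=times_win,
        pointwise_p=pointwise_p,
        window_p=float(window_p),
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# multiple comparisons

def holm_correct(pvals, alpha: float = 0.05):
    """Step-down Holm correction.

    Returns ``(reject_flags, adjusted_p)`` for the family of p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise StatError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adj
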