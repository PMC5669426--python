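"""Empirical mode decomposition, its multivariate extension, and cumulative modes.

EMD iteratively "sifts" a signal into intrinsic mode functions (IMFs):
narrow-band, amplitude/frequency-modulated components ordered from fastest
to slowest, plus a residual trend.  The multivariate extension (MEMD)
projects the d-channel signal vector onto a set of direction vectors on the
unit (d-1)-sphere, interpolates the multichannel signal at the extrema of
each projection, and subtracts the direction-averaged envelope; because all
channels are sifted against one common local mean, the same oscillatory
scale lands at the same mode index in every channel (mode alignment).

Cumulative IMFs (CIMFs) are running sums from the fastest mode down:
``CIMF_j = IMF_1 + ... + IMF_j``, a high-band partial reconstruction whose
bandwidth grows with j.  For dyadic mode spacing, mode i peaks near
``rate / 2**(i+1)`` Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import qmc

from .io_preproc import Recording

__all__ = [
    "SiftParams",
    "IMFDecomposition",
    "CIMFStack",
    "emd",
    "memd",
    "cumulate",
    "imf_peak_frequency",
    "zero_crossing_rate",
]


@dataclass(frozen=True)
class SiftParams:
    """Two-threshold envelope-symmetry sifting criterion (plus a hard cap).

    Sifting of one mode stops when the normalized envelope mean ``|m|/a`` is
    below ``theta1`` on at least a ``1 - alpha`` fraction of samples and
    below ``theta2`` everywhere, or after ``max_sift`` iterations.
    """

    theta1: float = 0.05
    theta2: float = 0.5
    alpha: float = 0.05
    max_sift: int = 1000


@dataclass
class IMFDecomposition:
    """IMFs (n_scales x n_channels x n_samples) plus the residual trend."""

    imfs: np.ndarray
    residual: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.imfs = np.asarray(self.imfs, dtype=float)
        self.residual = np.atleast_2d(np.asarray(self.residual, dtype=float))
        if self.imfs.ndim != 3:
            raise ValueError("imfs must have shape (n_scales, n_channels, n_samples)")

    @property
    def n_scales(self) -> int:
        return self.imfs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.residual.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs plus the residual (equals the input signal)."""
        return self.imfs.sum(axis=0) + self.residual


@dataclass
class CIMFStack:
    """Cumulative IMFs: ``cimfs[j] = imfs[0] + ... + imfs[j]`` (0-based)."""

    cimfs: np.ndarray
    rate: float

    @property
    def n_scales(self) -> int:
        return self.cimfs.shape[0]


def imf_peak_frequency(i: int, rate: float) -> float:
    """Peak frequency of mode ``i`` (1-based) under dyadic spacing: rate / 2**(i+1)."""
    if i < 1:
        raise ValueError("scale index is 1-based and must be >= 1")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return rate / 2.0 ** (i + 1)


def zero_crossing_rate(x: np.ndarray, rate: float) -> float:
    """Zero crossings per second, a cheap proxy for mean frequency."""
    x = np.asarray(x, dtype=float)
    s = np.signbit(x)
    n_cross = int(np.count_nonzero(s[1:] != s[:-1]))
    return n_cross * rate / max(len(x), 1)


# ---------------------------------------------------------------------------
# extrema and envelopes

def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; flat tops contribute their midpoint."""
    dx = np.diff(x)
    # Collapse zero slopes to the sign of the previous non-zero slope so that
    # plateaus register a single extremum (at the plateau's trailing edge).
    sign = np.sign(dx)
    nz = sign != 0
    if not nz.any():
        return np.empty(0, dtype=int)
    idx_nz = np.nonzero(nz)[0]
    fill_positions = np.cumsum(nz) - 1
    filled = np.where(fill_positions >= 0, sign[idx_nz][np.clip(fill_positions, 0, None)], 0.0)
    down = (filled[:-1] > 0) & (filled[1:] < 0)
    return np.nonzero(down)[0] + 1


def _extrema_count(x: np.ndarray) -> int:
    return len(_local_maxima(x)) + len(_local_maxima(-x))


def _mirror_knots(idx: np.ndarray, val: np.ndarray, n: int, n_mirror: int = 2):
    """Extend extrema past both ends by reflection so the spline is anchored."""
    t = idx.astype(float)
    k = min(n_mirror, len(idx))
    left_t = 2 * t[0] - t[1:k + 1][::-1] if len(idx) > 1 else np.array([t[0] - n])
    left_v = val[1:k + 1][::-1] if len(idx) > 1 else val[:1]
    right_t = 2 * t[-1] - t[-k - 1:-1][::-1] if len(idx) > 1 else np.array([t[-1] + n])
    right_v = val[-k - 1:-1][::-1] if len(idx) > 1 else val[-1:]
    # Guarantee coverage of [0, n-1]
    if left_t[0] > 0:
        left_t = np.concatenate([[min(left_t[0] - 1.0, -1.0)], left_t])
        left_v = np.concatenate([val[:1] if val.ndim == 1 else val[:1], left_v])
    if right_t[-1] < n - 1:
        right_t = np.concatenate([right_t, [max(right_t[-1] + 1.0, float(n))]])
        right_v = np.concatenate([right_v, val[-1:]])
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, val, right_v])
    # enforce strictly increasing knots
    keep = np.concatenate([[True], np.diff(tt) > 1e-9])
    return tt[keep], vv[keep]


def _envelope(idx: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through ``values`` (n_knots[, d]) at sample ``idx``."""
    if len(idx) < 2:
        # Too few anchors for a spline: constant envelope.
        v = values[0] if len(idx) else np.zeros(values.shape[1:])
        return np.broadcast_to(v, (n,) + values.shape[1:]).copy()
    tt, vv = _mirror_knots(idx, values, n)
    if len(tt) < 4:
        from scipy.interpolate import interp1d
        f = interp1d(tt, vv, axis=0, kind="linear", fill_value="extrapolate")
        return f(np.arange(n))
    return CubicSpline(tt, vv, axis=0)(np.arange(n))


# ---------------------------------------------------------------------------
# univariate EMD

def _zero_crossings(x: np.ndarray) -> int:
    s = np.signbit(x)
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _sift_univariate(x: np.ndarray, stop: SiftParams) -> np.ndarray | None:
    """Extract one IMF from ``x`` by classic two-envelope sifting.

    Stops when the envelope-symmetry criterion holds *and* the candidate
    satisfies the defining IMF count property (extrema and zero crossings
    equal or differing by one).
    """
    n = len(x)
    h = x.copy()
    for _ in range(stop.max_sift):
        mx = _local_maxima(h)
        mn = _local_maxima(-h)
        if len(mx) + len(mn) < 3:
            return None
        upper = _envelope(mx, h[mx], n)
        lower = _envelope(mn, h[mn], n)
        m = 0.5 * (upper + lower)
        a = 0.5 * np.abs(upper - lower)
        sx = np.abs(m) / np.maximum(a, 1e-12)
        h = h - m
        if (np.mean(sx > stop.theta1) < stop.alpha) and (sx < stop.theta2).all():
            if abs(_extrema_count(h) - _zero_crossings(h)) <= 1:
                return h
    return h


def emd(signal: np.ndarray, rate: float, stop: SiftParams | None = None,
        max_modes: int | None = None) -> IMFDecomposition:
    """Univariate empirical mode decomposition.

    Sifting proceeds until the residual is monotone or has fewer than three
    extrema; a constant or monotone input yields zero IMFs with the input as
    residual.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if len(x) < 16:
        raise ValueError("signal too short for EMD (need >= 16 samples)")
    stop = stop or SiftParams()
    cap = max_modes or int(np.ceil(np.log2(len(x)))) + 3
    r = x.copy()
    modes: list[np.ndarray] = []
    while len(modes) < cap and _extrema_count(r) >= 3:
        imf = _sift_univariate(r, stop)
        if imf is None:
            break
        modes.append(imf)
        r = r - imf
    imfs = (np.stack(modes)[:, None, :] if modes
            else np.empty((0, 1, len(x))))
    return IMFDecomposition(imfs=imfs, residual=r[None, :], rate=rate)


# ---------------------------------------------------------------------------
# multivariate EMD

def direction_vectors(d: int, n_directions: int, seed: int = 0) -> np.ndarray:
    """Low-discrepancy direction set on the unit (d-1)-sphere.

    d=1 uses {+1, -1} (recovering classic upper/lower envelopes); d=2 uses a
    seeded uniform fan on the circle; d>=3 maps a scrambled Halton sequence
    through the normal quantile function and normalizes.
    """
    if d < 1 or n_directions < 2:
        raise ValueError("need d >= 1 and n_directions >= 2")
    if d == 1:
        return np.array([[1.0], [-1.0]])
    rng = np.random.default_rng(seed)
    if d == 2:
        offset = rng.uniform(0, 1)
        ang = 2 * np.pi * (np.arange(n_directions) + offset) / n_directions
        return np.column_stack([np.cos(ang), np.sin(ang)])
    from scipy.stats import norm
    sampler = qmc.Halton(d=d, scramble=True, seed=rng)
    pts = sampler.random(n_directions)
    vecs = norm.ppf(np.clip(pts, 1e-9, 1 - 1e-9))
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms < 1e-12] = 1.0
    return vecs / norms[:, None]


def default_n_directions(d: int) -> int:
    """max(8, next power of two >= 2d) — grows with channel count."""
    return max(8, int(2 ** np.ceil(np.log2(max(2 * d, 2)))))


def _memd_mean_envelope(h: np.ndarray, dirs: np.ndarray):
    """Direction-averaged local mean of the d x n signal ``h``.

    For every direction the signal is interpolated at both the maxima and
    the minima of the scalar projection; the per-direction mean is the
    midline of those two envelopes and the amplitude is half their spread
    (Euclidean norm over channels).  Returns (mean envelope (d, n),
    amplitude (n,), n_usable_directions).
    """
    d, n = h.shape
    means = np.zeros((n, d))
    amp = np.zeros(n)
    used = 0
    for v in dirs:
        p = v @ h
        mx = _local_maxima(p)
        mn = _local_maxima(-p)
        if len(mx) < 2 or len(mn) < 2:
            continue
        e_max = _envelope(mx, h[:, mx].T, n)   # (n, d)
        e_min = _envelope(mn, h[:, mn].T, n)
        means += 0.5 * (e_max + e_min)
        amp += 0.5 * np.linalg.norm(e_max - e_min, axis=1)
        used += 1
    if used < 1:
        return None, None, 0
    return (means / used).T, amp / used, used


def memd(rec: Recording | np.ndarray, n_directions: int | None = None,
         stop: SiftParams | None = None, seed: int = 0, rate: float | None = None,
         max_modes: int | None = None) -> IMFDecomposition:
    """Multivariate EMD with cross-channel mode alignment.

    All channels are decomposed jointly: each sifting step subtracts one
    common local-mean estimate obtained by averaging signal envelopes taken
    at the extrema of projections onto ``n_directions`` directions, so every
    channel ends up with one shared set of scales.
    """
    if isinstance(rec, Recording):
        X = rec.data
        rate = rec.rate
    else:
        X = np.atleast_2d(np.asarray(rec, dtype=float))
        if rate is None:
            raise ValueError("rate required when passing a bare array")
    d, n = X.shape
    if n < 16:
        raise ValueError("signal too short for MEMD (need >= 16 samples)")
    if n_directions is None:
        n_directions = default_n_directions(d)
    if d > 1 and n_directions < 2 * d:
        raise ValueError("n_directions must be >= 2 * n_channels")
    # Looser thresholds than the univariate default are customary for
    # projection-based sifting.  The low sift cap matters: over-sifting
    # fragments modes and destroys the quasi-dyadic filterbank behaviour
    # (the spacing ratio drops from ~1.9 to ~1.45), inflating the mode
    # count well beyond log2(n).
    stop = stop or SiftParams(theta1=0.075, theta2=0.75, alpha=0.075, max_sift=10)
    dirs = direction_vectors(d, n_directions, seed=seed)
    cap = max_modes or int(np.ceil(np.log2(n))) + 3

    r = X.copy()
    modes: list[np.ndarray] = []
    while len(modes) < cap:
        # decomposition terminates once projections no longer oscillate
        proj_extrema = max((len(_local_maxima(v @ r)) + len(_local_maxima(-(v @ r)))
                            for v in dirs), default=0)
        if proj_extrema < 3:
            break
        h = r.copy()
        imf = None
        for _ in range(stop.max_sift):
            m, a, k_used = _memd_mean_envelope(h, dirs)
            if m is None:
                imf = h if _extrema_count(h.ravel()) >= 3 else None
                break
            sx = np.linalg.norm(m, axis=0) / np.maximum(a, 1e-12)
            h = h - m
            if (np.mean(sx > stop.theta1) < stop.alpha) and (sx < stop.theta2).all():
                imf = h
                break
        else:
            imf = h
        if imf is None:
            break
        modes.append(imf)
        r = r - imf
    imfs = np.stack(modes) if modes else np.empty((0, d, n))
    return IMFDecomposition(imfs=imfs, residual=r, rate=float(rate))


def cumulate(dec: IMFDecomposition) -> CIMFStack:
    """Running sum of IMFs from the fastest scale down."""
    if dec.n_scales < 1:
        raise ValueError("cannot cumulate an empty decomposition")
    return CIMFStack(cimfs=np.cumsum(dec.imfs, axis=0), rate=dec.rate)
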