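"""MEMD-enhanced multiscale, multivariate entropy curves.

The pipeline: decompose the *entire* multichannel recording with MEMD,
accumulate the modes into CIMFs (or keep individual IMFs), restrict to an
analysis window, cut the windowed track into short non-overlapping
snippets, estimate entropy per snippet at every scale, and report the
snippet mean with its standard error — one curve value per scale.  The
undecomposed window provides the "raw" uniscale reference value.

Estimator names follow the multivariate conventions: ``mmse`` (multivariate
sample entropy of each snippet), ``mmrqe`` / ``mmshe`` (univariate Rényi
quadratic / kernel-Shannon entropy per channel, averaged over channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import (EmbeddingParams, KernelParams, Snippet,
                      UndefinedEntropyError, channel_averaged_entropy,
                      sample_entropy, silverman_bandwidth)
from .io_preproc import Recording
from .memd import IMFDecomposition, SiftParams, cumulate, memd

__all__ = ["EntropyCurve", "segment_snippets", "multiscale_curve",
           "harmonize_curves", "ESTIMATORS"]

ESTIMATORS = ("mmse", "mmrqe", "mmshe")


@dataclass
class EntropyCurve:
    """Entropy per scale with snippet-level dispersion.

    ``values[j]`` is the mean entropy at scale j+1 (1-based reporting);
    ``raw_value`` is the uniscale entropy of the undecomposed window.
    """

    values: np.ndarray
    dispersion: np.ndarray
    scale_mode: str
    estimator: str
    n_snippets: int
    snippet_ms: float
    channels: list[str]
    raw_value: float = float("nan")
    raw_dispersion: float = float("nan")

    @property
    def n_scales(self) -> int:
        return len(self.values)

    def at_scale(self, i: int) -> tuple[float, float]:
        """(value, stderr) at 1-based scale index ``i``."""
        return float(self.values[i - 1]), float(self.dispersion[i - 1])


def segment_snippets(track, rate: float | None = None, snippet_ms: float = 100.0,
                     max_snippets: int | None = None) -> list[Snippet]:
    """Cut a track into non-overlapping snippets from the start.

    ``track`` is a Recording or a d x n array (then ``rate`` is required).
    Snippet length is ``floor(snippet_ms * rate / 1000)`` samples; the
    trailing remainder is dropped.
    """
    if isinstance(track, Recording):
        data, rate = track.data, track.rate
    else:
        data = np.atleast_2d(np.asarray(track, dtype=float))
        if rate is None:
            raise ValueError("rate required when passing a bare array")
    n_per = int(np.floor(snippet_ms * rate / 1000.0))
    if n_per < 2:
        raise ValueError(f"snippet of {snippet_ms} ms at {rate} Hz has "
                         f"{n_per} sample(s); need >= 2")
    n_snips = data.shape[1] // n_per
    if n_snips < 1:
        raise ValueError("track shorter than one snippet")
    if max_snippets is not None:
        n_snips = min(n_snips, int(max_snippets))
    return [Snippet(data[:, i * n_per:(i + 1) * n_per]) for i in range(n_snips)]


def _window_slice(n_samples: int, rate: float, window) -> slice:
    """Resolve a window spec to a sample slice.

    ``None`` = whole track; ``("last", seconds)`` = trailing segment;
    ``(t0, t1)`` = absolute seconds from track start.
    """
    if window is None:
        return slice(0, n_samples)
    kind = window[0]
    if kind == "last":
        n_win = int(round(float(window[1]) * rate))
        if n_win > n_samples:
            raise ValueError("analysis window longer than recording")
        return slice(n_samples - n_win, n_samples)
    t0, t1 = float(window[0]), float(window[1])
    i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
    if not (0 <= i0 < i1 <= n_samples):
        raise ValueError("analysis window outside recording")
    return slice(i0, i1)


def _entropy_over_snippets(track: np.ndarray, rate: float, estimator: str,
                           snippet_ms: float, max_snippets: int | None,
                           ep: EmbeddingParams):
    """Mean and SE of per-snippet entropy of a d x n (windowed) track.

    The track is z-scored per channel first, so Silverman bandwidths and the
    sample-entropy tolerance derive from the whole windowed track rather
    than from individual snippets.
    """
    sd = track.std(axis=1, keepdims=True)
    if (sd < 1e-15).any():
        raise ValueError("zero-variance channel in analysis window")
    z = (track - track.mean(axis=1, keepdims=True)) / sd
    snippets = segment_snippets(z, rate, snippet_ms, max_snippets)
    d, n_per = snippets[0].d, snippets[0].n
    vals = []
    if estimator == "mmse":
        epd = ep.for_channels(d)
        tol = epd.r * z.std()
        for s in snippets:
            try:
                vals.append(sample_entropy(s.data, epd, tol=tol))
            except UndefinedEntropyError:
                vals.append(np.nan)
    else:
        est = "rqe" if estimator == "mmrqe" else "shannon"
        # per-channel bandwidth from the z-scored windowed track (SD = 1)
        kps = [KernelParams(silverman_bandwidth(1.0, n_per, 1)) for _ in range(d)]
        for s in snippets:
            vals.append(channel_averaged_entropy(s, est, kps))
    vals = np.asarray(vals, dtype=float)
    ok = np.isfinite(vals)
    n_ok = int(ok.sum())
    if n_ok == 0:
        return np.nan, np.nan, len(vals)
    mean = float(vals[ok].mean())
    se = float(vals[ok].std(ddof=1) / np.sqrt(n_ok)) if n_ok > 1 else 0.0
    return mean, se, len(vals)


def multiscale_curve(rec: Recording, estimator: str = "mmrqe",
                     scale_mode: str = "cimf", window=("last", 100.0),
                     snippet_ms: float = 100.0, max_snippets: int | None = None,
                     channels: list[str] | None = None,
                     select_before_memd: bool = True,
                     n_directions: int | None = None,
                     stop: SiftParams | None = None, seed: int = 0,
                     embedding: EmbeddingParams | None = None,
                     decomposition: IMFDecomposition | None = None) -> EntropyCurve:
    """MEMD-enhanced multiscale multivariate entropy curve of one recording.

    MEMD runs on the entire recording; entropies are computed on snippets
    inside ``window`` only.  ``channels`` restricts the analysis; with
    ``select_before_memd`` the decomposition itself is computed on the
    subset (the subset defines the joint scales), otherwise on all channels
    with the subset taken afterwards.  A precomputed ``decomposition`` can
    be injected to reuse one MEMD across estimators or channel subsets.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if scale_mode not in ("cimf", "imf"):
        raise ValueError("scale_mode must be 'cimf' or 'imf'")
    ep = embedding or EmbeddingParams()

    work = rec.pick(channels) if (channels and select_before_memd) else rec
    if decomposition is None:
        decomposition = memd(work, n_directions=n_directions, stop=stop, seed=seed)
    if decomposition.n_scales < 1:
        raise ValueError("decomposition produced no modes")
    scales = (cumulate(decomposition).cimfs if scale_mode == "cimf"
              else decomposition.imfs)
    labels = list(work.labels)
    if channels and not select_before_memd:
        idx = [rec.labels.index(c) for c in channels]
        scales = scales[:, idx, :]
        labels = list(channels)
        raw_data = rec.data[idx]
    else:
        raw_data = work.data

    sl = _window_slice(scales.shape[2], rec.rate, window)
    values, disp = [], []
    n_snips = 0
    for j in range(scales.shape[0]):
        try:
            mean, se, n_snips = _entropy_over_snippets(
                scales[j][:, sl], rec.rate, estimator, snippet_ms, max_snippets, ep)
        except ValueError:
            mean, se = np.nan, np.nan
        values.append(mean)
        disp.append(se)
    raw_mean, raw_se, n_snips = _entropy_over_snippets(
        raw_data[:, sl], rec.rate, estimator, snippet_ms, max_snippets, ep)
    return EntropyCurve(values=np.asarray(values), dispersion=np.asarray(disp),
                        scale_mode=scale_mode, estimator=estimator,
                        n_snippets=n_snips, snippet_ms=snippet_ms,
                        channels=labels, raw_value=raw_mean, raw_dispersion=raw_se)


def harmonize_curves(curves: list[EntropyCurve], n_scales: int = 15) -> np.ndarray:
    """Stack curves to one fixed scale count for group display/statistics.

    Shorter curves are padded by repeating their last value (the cumulative
    curve is asymptotically flat); longer ones are truncated.
    """
    out = np.full((len(curves), n_scales), np.nan)
    for i, c in enumerate(curves):
        k = min(c.n_scales, n_scales)
        out[i, :k] = c.values[:k]
        if k < n_scales and k > 0:
            out[i, k:] = c.values[k - 1]
    return out
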