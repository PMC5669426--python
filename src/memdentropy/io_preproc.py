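"""Reading multichannel recordings and the standard offline preprocessing chain.

A :class:`Recording` is a channels-by-samples matrix with a single sampling
rate and unique channel labels.  The preprocessing operations — zero-phase
Butterworth band-pass, anti-aliased integer-factor downsampling, and
re-referencing to the mean of a set of reference channels — are all pure:
they return a new ``Recording`` and append a provenance entry to ``meta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Recording",
    "UnsupportedLayoutError",
    "read_recording",
    "bandpass",
    "decimate",
    "rereference",
]


class UnsupportedLayoutError(ValueError):
    """Raised when a container mixes sampling rates across channels."""


@dataclass
class Recording:
    """Multichannel time series: ``data`` has shape (n_channels, n_samples)."""

    data: np.ndarray
    rate: float
    labels: list[str]
    meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    def with_data(self, data: np.ndarray, *, rate: float | None = None,
                  labels: list[str] | None = None, step: dict | None = None) -> "Recording":
        """Derive a new Recording, copying provenance and appending ``step``."""
        meta = [dict(m) for m in self.meta]
        if step is not None:
            meta.append(step)
        return Recording(
            data=np.array(data, dtype=float),
            rate=self.rate if rate is None else rate,
            labels=list(self.labels) if labels is None else list(labels),
            meta=meta,
        )

    def pick(self, labels: list[str]) -> "Recording":
        """Channel subset, in the order given."""
        idx = [self._index(l) for l in labels]
        return self.with_data(self.data[idx], labels=list(labels),
                              step={"op": "pick", "labels": list(labels)})

    def _index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None


def read_recording(path: str | Path, format: str = "auto",
                   rate: float | None = None) -> Recording:
    """Read an EDF/BDF/CSV container into a :class:`Recording`.

    CSV files must carry a header row of channel labels (one column per
    channel, one row per sample) and the sampling rate must be supplied by
    the caller; EDF/BDF carry their own rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        ext = path.suffix.lower().lstrip(".")
        if ext not in ("edf", "bdf", "csv"):
            raise ValueError(f"cannot resolve format from extension {path.suffix!r}")
        fmt = ext
    if fmt == "csv":
        if rate is None:
            raise ValueError("CSV input requires an explicit sampling rate")
        df = pd.read_csv(path)
        if df.shape[1] < 1 or df.shape[0] < 1:
            raise OSError(f"empty or unreadable CSV: {path}")
        return Recording(
            data=df.to_numpy(dtype=float).T,
            rate=float(rate),
            labels=[str(c) for c in df.columns],
            meta=[{"op": "read", "source": str(path), "format": "csv"}],
        )
    if fmt in ("edf", "bdf"):
        import mne  # heavy import, deferred

        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        extras = getattr(raw, "_raw_extras", None)
        if extras:
            n_samps = np.asarray(extras[0].get("n_samps", []))
            if n_samps.size and len(np.unique(n_samps[n_samps > 0])) > 1:
                raise UnsupportedLayoutError(
                    f"{path}: channels with differing sampling rates in one container")
        return Recording(
            data=raw.get_data(),
            rate=float(raw.info["sfreq"]),
            labels=list(raw.ch_names),
            meta=[{"op": "read", "source": str(path), "format": fmt}],
        )
    raise ValueError(f"unknown format {format!r}")


def bandpass(rec: Recording, low: float = 0.5, high: float = 30.0,
             order: int = 4) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass.

    The filter is applied with ``sosfiltfilt`` so the effective magnitude
    response is the squared ``order``-th-order Butterworth and no group
    delay is introduced.
    """
    nyq = rec.rate / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must lie below Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(out, step={"op": "bandpass", "low": low, "high": high,
                                    "order": order, "zero_phase": True})


def decimate(rec: Recording, target_rate: float = 128.0) -> Recording:
    """Anti-aliased downsampling by an integer factor.

    A zero-phase order-8 Butterworth low-pass with cutoff at 0.8x the target
    Nyquist precedes the sample selection; the two-pass order-8 response is
    down by well over 30 dB at the target Nyquist.
    """
    factor = rec.rate / target_rate
    k = int(round(factor))
    if abs(factor - k) > 1e-9 or k < 1:
        raise ValueError(
            f"rate {rec.rate} is not an integer multiple of target {target_rate}")
    if k == 1:
        return rec.with_data(rec.data, step={"op": "decimate", "factor": 1})
    cutoff = 0.8 * (target_rate / 2.0)
    sos = sps.butter(8, cutoff, btype="lowpass", fs=rec.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    out = filtered[:, ::k]
    return rec.with_data(out, rate=target_rate,
                         step={"op": "decimate", "factor": k,
                               "anti_alias_cutoff_hz": cutoff})


def rereference(rec: Recording, ref_labels: list[str],
                drop_refs: bool = False) -> Recording:
    """Subtract the mean of the reference channels from every channel."""
    if isinstance(ref_labels, str):
        ref_labels = [ref_labels]
    idx = [rec._index(l) for l in ref_labels]
    ref = rec.data[idx].mean(axis=0)
    out = rec.data - ref[None, :]
    labels = list(rec.labels)
    if drop_refs:
        keep = [i for i in range(rec.n_channels) if i not in set(idx)]
        out = out[keep]
        labels = [rec.labels[i] for i in keep]
    return rec.with_data(out, labels=labels,
                         step={"op": "rereference", "refs": list(ref_labels),
                               "dropped": bool(drop_refs)})
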