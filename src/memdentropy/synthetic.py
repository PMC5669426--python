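"""Seeded generators for signals with the structure the analyses assume.

Four generators cover the full pipeline without any recorded data:

* :func:`gen_recording` — band-limited multichannel signals: a sum of
  (possibly AM/FM-modulated) oscillatory components plus white, AR(1), or
  pink noise.
* :func:`gen_complexity_conditions` — a cohort of subject x item
  recordings whose broadband randomness is planted to increase with the
  item's complexity level, by mixing strongly autocorrelated AR(1) noise
  with white noise at a level-dependent weight (variance matched).
* :func:`gen_coupled_pair` — two signals whose instantaneous phases are
  coupled segment-by-segment at a target phase-locking value, via von Mises
  phase jitter with concentration chosen through the Bessel-ratio relation
  ``PLV = I1(kappa) / I0(kappa)``.
* :func:`gen_ratings` — rater x item matrices whose expected interval
  agreement (Krippendorff alpha) matches a target level, using the
  closed-form finite-sample relation between alpha and the between/within
  variance split.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .agreement import RatingsMatrix
from .io_preproc import Recording

__all__ = [
    "SyntheticSpec",
    "Component",
    "gen_recording",
    "gen_complexity_conditions",
    "gen_coupled_pair",
    "gen_ratings",
    "vonmises_kappa_for_plv",
]


@dataclass
class Component:
    """One oscillatory component: frequency (Hz), amplitude, channel mask.

    ``am`` / ``fm`` are optional (depth, rate-Hz) tuples for sinusoidal
    amplitude / frequency modulation.
    """

    freq: float
    amplitude: float = 1.0
    channels: list | None = None       # None = all channels
    am: tuple | None = None
    fm: tuple | None = None


@dataclass
class SyntheticSpec:
    n_channels: int = 2
    rate: float = 128.0
    duration: float = 10.0
    components: list = field(default_factory=list)
    noise: str = "white"               # white | ar1 | pink
    noise_sd: float = 1.0
    ar1_rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 1.0:
            raise ValueError("duration must be at least 1 s")
        for c in self.components:
            if c.freq >= self.rate / 2:
                raise ValueError(f"component at {c.freq} Hz >= Nyquist")


def _noise(kind: str, shape, rng, sd: float, rho: float = 0.9) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    w = rng.standard_normal(shape)
    if kind == "white":
        return sd * w
    if kind == "ar1":
        out = np.empty_like(w)
        out[..., 0] = w[..., 0] / np.sqrt(1 - rho ** 2)
        for t in range(1, shape[-1]):
            out[..., t] = rho * out[..., t - 1] + w[..., t]
        # stationary variance of the recursion is 1/(1-rho^2); rescale to sd
        return sd * out * np.sqrt(1 - rho ** 2)
    if kind == "pink":
        spec = np.fft.rfft(w, axis=-1)
        f = np.fft.rfftfreq(shape[-1])
        f[0] = f[1]
        spec /= np.sqrt(f)
        out = np.fft.irfft(spec, n=shape[-1], axis=-1)
        out /= out.std(axis=-1, keepdims=True)
        return sd * out
    raise ValueError(f"unknown noise kind {kind!r}")


def gen_recording(spec: SyntheticSpec) -> Recording:
    """Deterministic synthetic multichannel recording from a spec."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    data = _noise(spec.noise, (spec.n_channels, n), rng, spec.noise_sd,
                  spec.ar1_rho)
    for c in spec.components:
        chans = range(spec.n_channels) if c.channels is None else c.channels
        phase = 2 * np.pi * c.freq * t
        if c.fm is not None:
            depth, rate_hz = c.fm
            phase = phase + depth * np.sin(2 * np.pi * rate_hz * t)
        wave = np.sin(phase)
        if c.am is not None:
            depth, rate_hz = c.am
            wave = wave * (1 + depth * np.sin(2 * np.pi * rate_hz * t))
        for k in chans:
            data[k] += c.amplitude * wave
    labels = [f"ch{k + 1}" for k in range(spec.n_channels)]
    return Recording(data=data, rate=spec.rate, labels=labels,
                     meta=[{"op": "synthetic", "seed": spec.seed,
                            "noise": spec.noise}])


def gen_complexity_conditions(n_subjects: int = 10, n_items: int = 2,
                              effect: list | None = None,
                              n_channels: int = 3, rate: float = 128.0,
                              duration: float = 30.0, rho: float = 0.9,
                              subject_jitter: float = 0.05,
                              seed: int = 0) -> tuple[dict, list]:
    """Cohort of recordings with a planted complexity ordering over items.

    ``effect`` gives each item's complexity level in [0, 1]: the weight of
    white noise mixed (variance-matched) with AR(1) noise.  Higher levels
    mean more broadband randomness, hence higher multiscale entropy.
    Subject-specific jitter perturbs the level slightly.  Returns
    ``(recordings, ordering)`` where ``recordings[(subject, item)]`` is a
    Recording and ``ordering`` lists item indices from least to most
    complex.
    """
    if n_subjects < 2 or n_items < 2:
        raise ValueError("need at least 2 subjects and 2 items")
    if effect is None:
        effect = list(np.linspace(0.2, 0.8, n_items))
    if len(effect) != n_items:
        raise ValueError("one complexity level per item required")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    recordings: dict = {}
    for s in range(n_subjects):
        for it in range(n_items):
            lam = float(np.clip(effect[it] + subject_jitter * rng.standard_normal(),
                                0.0, 1.0))
            white = rng.standard_normal((n_channels, n))
            ar = _noise("ar1", (n_channels, n), rng, 1.0, rho)
            data = np.sqrt(lam) * white + np.sqrt(1 - lam) * ar
            recordings[(s, it)] = Recording(
                data=data, rate=rate,
                labels=[f"ch{k + 1}" for k in range(n_channels)],
                meta=[{"op": "synthetic-cohort", "subject": s, "item": it,
                       "level": lam}])
    ordering = list(np.argsort(effect))
    return recordings, ordering


def vonmises_kappa_for_plv(plv: float) -> float:
    """Invert ``PLV = I1(kappa)/I0(kappa)`` (von Mises mean resultant length)."""
    if not (0 <= plv <= 1):
        raise ValueError("target PLV must lie in [0, 1]")
    if plv < 1e-6:
        return 0.0
    if plv > 1 - 1e-6:
        return np.inf
    # exponentially scaled Bessel functions avoid overflow; the ratio is the same
    return brentq(lambda k: i1e(k) / i0e(k) - plv, 1e-6, 1e4)


def _bandlimited_noise(n: int, rate: float, band, rng) -> np.ndarray:
    from scipy import signal as sps
    w = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, w)
    return x / x.std()


def gen_coupled_pair(duration: float = 40.0, rate: float = 128.0,
                     coupling_profile=(0.0, 1.0), jitter_smooth: int = 5,
                     band=(4.0, 16.0), seed: int = 0) -> tuple[Recording, Recording]:
    """Pair of signals phase-coupled segment-by-segment at target PLVs.

    The first signal is band-limited noise.  In each equal-duration segment
    with target PLV ``p``: for ``p ~ 0`` the second signal is independent
    noise; otherwise its phase copies the first's plus von Mises jitter
    with concentration ``kappa(p)``, lightly smoothed so the analytic-signal
    phase tracks it.  Measured PLV approximates the target (the smoothing
    raises it slightly; exact for p = 1 with zero jitter).
    """
    from scipy import signal as sps
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    x = _bandlimited_noise(n, rate, band, rng)
    analytic = sps.hilbert(x)
    amp = np.abs(analytic)
    phase = np.angle(analytic)
    y = np.empty(n)
    bounds = np.linspace(0, n, len(coupling_profile) + 1).astype(int)
    for seg, p in enumerate(coupling_profile):
        i0_, i1_ = bounds[seg], bounds[seg + 1]
        if p < 0.05:
            y[i0_:i1_] = _bandlimited_noise(n, rate, band, rng)[i0_:i1_]
            continue
        kappa = vonmises_kappa_for_plv(p)
        theta = (np.zeros(i1_ - i0_) if np.isinf(kappa)
                 else rng.vonmises(0.0, kappa, size=i1_ - i0_))
        if jitter_smooth > 1 and not np.isinf(kappa):
            kernel = np.ones(jitter_smooth) / jitter_smooth
            theta = np.convolve(theta, kernel, mode="same")
        y[i0_:i1_] = amp[i0_:i1_] * np.cos(phase[i0_:i1_] + theta)
    ra = Recording(x[None, :], rate, ["a"], meta=[{"op": "synthetic-pair", "role": "driver"}])
    rb = Recording(y[None, :], rate, ["b"], meta=[{"op": "synthetic-pair", "role": "follower"}])
    return ra, rb


def gen_ratings(n_raters: int = 30, n_items: int = 5, agreement: float = 0.7,
                seed: int = 0) -> RatingsMatrix:
    """Ratings with expected interval Krippendorff alpha ~ ``agreement``.

    Values are ``mu_item + noise`` with unit between-item variance and the
    within-rater noise variance solved from the finite-sample expectation
    ``E[alpha] = g sigma_b^2 / (sigma_e^2 + g sigma_b^2)`` where ``g`` is
    the fraction-of-cross-item-pairs factor of the expected-disagreement
    denominator.
    """
    if not (0 <= agreement <= 1):
        raise ValueError("agreement target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_raters * n_items
    if agreement == 0:
        mu = np.zeros(n_items)
        sigma_e = 1.0
    else:
        mu = rng.standard_normal(n_items)
        mu = (mu - mu.mean()) / (mu.std() if mu.std() > 0 else 1.0)
        # With item means centred and scaled to unit empirical variance,
        # E[D_o] = 2 sigma_e^2 and E[D_e] = 2 sigma_e^2 + 2 n/(n-1), so
        # E[alpha] ~ g / (sigma_e^2 + g) with g = n/(n-1).
        g = n / (n - 1)
        sigma_e = np.sqrt(g * (1 - agreement) / agreement) if agreement < 1 else 0.0
    values = mu[None, :] + sigma_e * rng.standard_normal((n_raters, n_items))
    return RatingsMatrix(values,
                         rater_ids=[f"s{k}" for k in range(n_raters)],
                         item_ids=[f"item{k}" for k in range(n_items)])
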