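"""Inter-rater discriminability statistics.

Krippendorff's alpha (interval metric) measures chance-corrected agreement
between raters scoring a common set of items: ``alpha = 1 - D_o / D_e``,
with observed disagreement ``D_o`` averaging squared differences between
pairable values *within* items and expected disagreement ``D_e`` averaging
them over *all* pairable values.  Alpha is 1 for perfect agreement, ~0 at
chance, and can be negative for systematic disagreement.

In the analyses this package targets, "raters" are subjects, "items" are
stimulus/emotion categories, and the rated value is a scale-6 entropy, but
the statistics are agnostic to that interpretation.  On top of plain alpha
the module provides a block bootstrap over rater subsets, per-channel alpha
maps, a greedy channel-subset search, and a group comparison test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "AgreementMap",
    "krippendorff_alpha_interval",
    "bootstrap_alpha",
    "channel_alpha_map",
    "greedy_channel_search",
    "group_alpha_test",
    "alpha_over_windows",
]


@dataclass
class RatingsMatrix:
    """Raters x items continuous ratings; NaN marks missing entries."""

    values: np.ndarray
    rater_ids: list | None = None
    item_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        r, i = self.values.shape
        if r < 2:
            raise ValueError("need at least 2 raters")
        if i < 1:
            raise ValueError("need at least 1 item")
        if self.rater_ids is None:
            self.rater_ids = [f"r{k}" for k in range(r)]
        if self.item_ids is None:
            self.item_ids = [f"item{k}" for k in range(i)]

    @property
    def n_raters(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def subset_raters(self, idx) -> "RatingsMatrix":
        return RatingsMatrix(self.values[np.asarray(idx)],
                             rater_ids=[self.rater_ids[k] for k in idx],
                             item_ids=list(self.item_ids))


@dataclass
class AgreementMap:
    """Per-channel alpha values with optional bootstrap and p-value layers."""

    alpha_per_channel: dict
    bootstrap: dict = field(default_factory=dict)
    p_per_channel: dict = field(default_factory=dict)


def krippendorff_alpha_interval(rm: RatingsMatrix | np.ndarray) -> float:
    """Interval-metric Krippendorff alpha via pairable-value coincidences.

    Missing (NaN) entries are excluded pairwise; items with fewer than two
    pairable values contribute nothing.  If all pairable values are
    identical, ``D_e = 0`` and alpha is 1 by convention.  Raises
    ``ValueError`` when no item has two pairable values.
    """
    values = rm.values if isinstance(rm, RatingsMatrix) else np.atleast_2d(np.asarray(rm, float))
    cols = []          # per item: pairable value vectors (>= 2 entries)
    for u in range(values.shape[1]):
        v = values[:, u]
        v = v[np.isfinite(v)]
        if len(v) >= 2:
            cols.append(v)
    if not cols:
        raise ValueError("alpha undefined: no item has >= 2 pairable values")
    n_total = sum(len(v) for v in cols)
    # observed disagreement: within-item ordered pairs, weighted 1/(m_u - 1)
    d_obs = 0.0
    for v in cols:
        m_u = len(v)
        diffs = v[:, None] - v[None, :]
        d_obs += (diffs ** 2).sum() / (m_u - 1)
    d_obs /= n_total
    # expected disagreement: ordered pairs across all pairable values
    allv = np.concatenate(cols)
    d_exp = ((allv[:, None] - allv[None, :]) ** 2).sum() / (n_total * (n_total - 1))
    if d_exp == 0.0:
        return 1.0
    return float(1.0 - d_obs / d_exp)


def bootstrap_alpha(rm: RatingsMatrix, n_boot: int = 1000, subset_size: int = 5,
                    seed: int = 0) -> np.ndarray:
    """Block bootstrap: alpha of ``n_boot`` rater subsets drawn with replacement."""
    if n_boot < 1 or subset_size < 2:
        raise ValueError("need n_boot >= 1 and subset_size >= 2")
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, rm.n_raters, size=subset_size)
        try:
            out[b] = krippendorff_alpha_interval(rm.subset_raters(list(idx)))
        except ValueError:
            out[b] = np.nan
    return out


def channel_alpha_map(per_channel_ratings: dict, n_boot: int | None = None,
                      subset_size: int = 5, seed: int = 0) -> AgreementMap:
    """Alpha per channel; optionally attach bootstrap distributions."""
    alphas, boots = {}, {}
    for b, (ch, rm) in enumerate(per_channel_ratings.items()):
        try:
            alphas[ch] = krippendorff_alpha_interval(rm)
        except ValueError:
            alphas[ch] = float("nan")
            continue
        if n_boot:
            boots[ch] = bootstrap_alpha(rm, n_boot=n_boot,
                                        subset_size=subset_size, seed=seed + b)
    return AgreementMap(alpha_per_channel=alphas, bootstrap=boots)


def greedy_channel_search(recordings: dict, ranking: list, k_max: int,
                          value_fn) -> dict:
    """Greedy forward channel-subset search on the agreement statistic.

    ``recordings`` maps ``(rater, item) -> Recording`` (or any object
    ``value_fn`` accepts).  Channels are added in ``ranking`` order (most
    significant first); for each subset size k the multiscale entropy is
    *recomputed* on the selected channels only via
    ``value_fn(recording, channels) -> float``, a ratings matrix is built
    across raters x items, and alpha computed.  Returns the alpha trace,
    the ordered channels, and the argmax subset.
    """
    if k_max < 1 or k_max > len(ranking):
        raise ValueError("k_max must lie in [1, n_candidate_channels]")
    raters = sorted({r for r, _ in recordings})
    items = sorted({i for _, i in recordings})
    trace = []
    for k in range(1, k_max + 1):
        chans = list(ranking[:k])
        vals = np.full((len(raters), len(items)), np.nan)
        for (r, it), rec in recordings.items():
            vals[raters.index(r), items.index(it)] = value_fn(rec, chans)
        rm = RatingsMatrix(vals, rater_ids=raters, item_ids=items)
        trace.append(krippendorff_alpha_interval(rm))
    trace = np.asarray(trace)
    best_k = int(np.nanargmax(trace)) + 1
    return {"alpha": trace, "channels": list(ranking[:k_max]),
            "best_size": best_k, "best_channels": list(ranking[:best_k])}


def group_alpha_test(alpha_main: dict, boot_control: dict,
                     method: str = "ttest") -> dict:
    """Per-channel comparison of a main-group alpha against a control
    bootstrap distribution.

    ``method='ttest'``: two-sided one-sample t-test of the control
    bootstrap values against the main alpha (note the bootstrap values are
    not independent draws, so p-values are optimistic; see the percentile
    alternative).  ``method='percentile'``: two-sided exceedance
    probability of the main alpha within the control distribution.
    """
    out = {}
    for ch, a in alpha_main.items():
        boot = np.asarray(boot_control.get(ch, []), dtype=float)
        boot = boot[np.isfinite(boot)]
        if len(boot) < 2 or not np.isfinite(a):
            out[ch] = float("nan")
            continue
        if boot.std() == 0.0:
            out[ch] = 1.0 if boot[0] == a else np.nextafter(0, 1)
            continue
        if method == "ttest":
            t, p = stats.ttest_1samp(boot, a)
            out[ch] = float(p)
        elif method == "percentile":
            frac = np.mean(boot >= a)
            out[ch] = float(min(1.0, 2 * min(frac, 1 - frac) + 1.0 / (len(boot) + 1)))
        else:
            raise ValueError("method must be 'ttest' or 'percentile'")
    return out


def alpha_over_windows(recordings: dict, windows: list, value_fn) -> np.ndarray:
    """Temporal evolution of alpha: one alpha per analysis window.

    ``windows`` is a list of window specs (passed to ``value_fn`` as
    ``value_fn(recording, window) -> float``); a cumulative-from-start
    schedule is the typical choice.  Returns the alpha trace.
    """
    raters = sorted({r for r, _ in recordings})
    items = sorted({i for _, i in recordings})
    trace = []
    for w in windows:
        vals = np.full((len(raters), len(items)), np.nan)
        for (r, it), rec in recordings.items():
            vals[raters.index(r), items.index(it)] = value_fn(rec, w)
        trace.append(krippendorff_alpha_interval(RatingsMatrix(vals)))
    return np.asarray(trace)


def cumulative_windows(total_seconds: float, step_seconds: float,
                       min_seconds: float | None = None) -> list:
    """Cumulative-from-start window schedule: (0, t) for growing t."""
    start = min_seconds if min_seconds is not None else step_seconds
    ts = np.arange(start, total_seconds + 1e-9, step_seconds)
    return [(0.0, float(t)) for t in ts]
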