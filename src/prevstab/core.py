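"""Prevalence-curve resampling and windowed stability-point detection.

The question answered here: given a binary presence/absence sample, how
many units would have sufficed to estimate the prevalence (percent of
units with a presence) reliably? The procedure subsamples the data without
replacement at every size k = 1..k_MAX, averages the subsample prevalence
over ``n_replicates`` replicates to get a curve m(k), and declares the
curve stable at the first window of ``successive_points`` consecutive
means that is flat in two senses:

* every successive difference ``|m(k) - m(k-1)|`` inside the window is
  below ``mean_diff_threshold / sqrt(k)`` (the threshold shrinks with k
  because sampling noise does), and
* the window's range (max - min of its means, "delta") is below
  ``delta_threshold``.

The stability point is the sample size at which the window is complete,
i.e. the index of the window's last mean. If no window qualifies — or the
window is longer than the curve — the verdict is "na": the sampling effort
is insufficient.

Resampling modes
----------------
``cumulative`` (default): each replicate draws one random permutation of
the units and reads all k prefixes off it, so within a replicate the size-k
and size-(k+1) subsamples share k units and the curve is smooth; each m(k)
still has the exact without-replacement (hypergeometric) marginal
distribution. ``independent``: a fresh size-k subset is drawn for every
(replicate, k); the per-k marginals are identical but successive means are
independent, so the curve is far rougher and stabilises much later. The
cumulative curve is the one whose stability points behave like the
published reference values.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import (
    OccurrenceTable,
    PrevalenceCurve,
    StabilityParams,
    StabilityResult,
)

__all__ = [
    "subsample_proportions",
    "resample_prevalence_curve",
    "successive_differences",
    "detect_stability",
    "estimate_all",
    "pair_rng",
]

_PAIR_SALT = "prevstab-pair"


def _pair_entropy(group: str, species: str) -> int:
    # stable across processes, unlike hash()
    h = hashlib.sha256(f"{_PAIR_SALT}\x1f{group}\x1f{species}".encode()).digest()
    return int.from_bytes(h[:8], "big")


def pair_rng(seed: int | None, group: str, species: str) -> np.random.Generator:
    """Reproducible generator for one (group, species) pair.

    Streams are derived by hashing the pair label, so adding or removing
    other species never perturbs this pair's results.
    """
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0xFFFFFFFF, _pair_entropy(group, species)])
    )


def _clean_column(column: Sequence[float] | np.ndarray) -> np.ndarray:
    vals = np.asarray(column, dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no data for this group/species: column is empty after dropping missing")
    bad = vals[(vals != 0.0) & (vals != 1.0)]
    if bad.size:
        raise ValueError(f"occurrence values must be 0 or 1; found {bad[:5]!r}")
    return vals.astype(np.int64)


def subsample_proportions(
    values: np.ndarray, k: int, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Proportions of presences in ``n_replicates`` independent uniform
    size-``k`` subsets (without replacement) of ``values``.

    Exposed separately so the sampling distribution (hypergeometric mean
    and finite-population variance) can be examined per replicate.
    """
    values = np.asarray(values)
    n_units = values.size
    if not 1 <= k <= n_units:
        raise ValueError(f"k must lie in [1, {n_units}], got {k}")
    keys = rng.random((n_replicates, n_units))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return np.take(values, idx).sum(axis=1) / k


def _mean_counts_cumulative(values: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Mean presence count at each prefix size over n random permutations."""
    n_units = values.size
    # argsort of random keys = uniform random permutation, vectorised per row
    order = np.argsort(rng.random((n, n_units)), axis=1)
    cums = np.take(values, order).cumsum(axis=1)
    return cums.sum(axis=0, dtype=np.int64) / n


def _mean_counts_independent(values: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    n_units = values.size
    totals = np.empty(n_units)
    for k in range(1, n_units + 1):
        keys = rng.random((n, n_units))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        totals[k - 1] = np.take(values, idx).sum(dtype=np.int64)
    return totals / n


def resample_prevalence_curve(
    column: Sequence[float] | np.ndarray,
    params: StabilityParams,
    rng: np.random.Generator | None = None,
    *,
    resampling: str = "cumulative",
    group: str = "",
    species: str = "",
) -> PrevalenceCurve:
    """Build the mean prevalence curve m(k), k = 1..k_MAX, for one column.

    Missing entries are dropped first; ``k_MAX`` is the number of scored
    units. ``m(k_MAX)`` equals the observed full-sample prevalence exactly
    for every seed, because a size-k_MAX subsample without replacement is
    the sample itself.
    """
    vals = _clean_column(column)
    if rng is None:
        rng = pair_rng(params.seed, group, species)
    n = params.n_replicates
    if resampling == "cumulative":
        mean_counts = _mean_counts_cumulative(vals, n, rng)
    elif resampling == "independent":
        mean_counts = _mean_counts_independent(vals, n, rng)
    else:
        raise ValueError(f"unknown resampling mode {resampling!r}")
    k_arr = np.arange(1, vals.size + 1)
    means = mean_counts / k_arr * 100.0
    observed = int(vals.sum()) / vals.size * 100.0
    return PrevalenceCurve(
        group=group,
        species=species,
        k_max=vals.size,
        means=means,
        observed_prevalence=observed,
        n_replicates=n,
        resampling=resampling,
    )


def successive_differences(curve: PrevalenceCurve) -> np.ndarray:
    """Absolute successive differences d(k) = |m(k) - m(k-1)|, k = 2..k_MAX."""
    return np.abs(np.diff(curve.means))


def detect_stability(
    curve: PrevalenceCurve,
    params: StabilityParams,
    *,
    sqrt_index: str = "later",
    window: str = "means",
    report_point: str = "window_end",
) -> StabilityResult:
    """Scan the curve for the first qualifying flatness window.

    Windows start at s = 1, 2, ... in increasing order. A window
    qualifies iff every within-window successive difference d(k) is
    strictly below ``mean_diff_threshold / sqrt(k)`` and the range of the
    window means is strictly below ``delta_threshold``. Ties at a
    threshold fail. The first qualifying window wins.

    Keyword switches cover the defensible alternate readings of the rule:

    * ``sqrt_index``: whether the sqrt(k) correction uses the ``"later"``
      (default) or ``"earlier"`` member of each difference pair;
    * ``window``: ``"means"`` (default) spans x means / x-1 differences,
      ``"differences"`` spans x differences / x+1 means;
    * ``report_point``: ``"window_end"`` (default) reports the sample size
      at which the window is complete; ``"window_start"`` reports its
      first index.
    """
    if sqrt_index not in ("later", "earlier"):
        raise ValueError(f"unknown sqrt_index {sqrt_index!r}")
    if report_point not in ("window_end", "window_start"):
        raise ValueError(f"unknown report_point {report_point!r}")
    if window == "means":
        wlen = params.successive_points
    elif window == "differences":
        wlen = params.successive_points + 1
    else:
        raise ValueError(f"unknown window mode {window!r}")

    m = curve.means
    k_max = curve.k_max

    def na(note: str) -> StabilityResult:
        return StabilityResult(
            group=curve.group,
            species=curve.species,
            stability_point=None,
            estimated_prevalence=np.nan,
            tail_prevalence=float(m[-1]),
            k_max=k_max,
            params=params,
            window_delta=np.nan,
            note=note,
        )

    if k_max < wlen:
        return na("window exceeds available samples")

    d = np.abs(np.diff(m))
    later_k = np.arange(2, k_max + 1)
    corr_k = later_k if sqrt_index == "later" else later_k - 1
    diff_ok = d < params.mean_diff_threshold / np.sqrt(corr_k)

    if wlen > 1:
        window_diffs_ok = sliding_window_view(diff_ok, wlen - 1).all(axis=1)
    else:  # pragma: no cover - wlen >= 3 given successive_points >= 2
        window_diffs_ok = np.ones(k_max, dtype=bool)
    wins = sliding_window_view(m, wlen)
    deltas = wins.max(axis=1) - wins.min(axis=1)
    qualifies = window_diffs_ok & (deltas < params.delta_threshold)

    if not qualifies.any():
        return na("no stable window")
    s0 = int(np.argmax(qualifies))  # 0-based start of first qualifying window
    k_star = s0 + wlen if report_point == "window_end" else s0 + 1
    return StabilityResult(
        group=curve.group,
        species=curve.species,
        stability_point=k_star,
        estimated_prevalence=float(m[k_star - 1]),
        tail_prevalence=float(m[-1]),
        k_max=k_max,
        params=params,
        window_delta=float(deltas[s0]),
        note="",
    )


def estimate_all(
    table: OccurrenceTable,
    params: StabilityParams,
    *,
    resampling: str = "cumulative",
    include_empty: bool = False,
    return_curves: bool = False,
    **detect_kwargs,
):
    """Run the full curve + detector pipeline for every (group, species) pair.

    Pairs with zero scored entries are skipped by default; with
    ``include_empty=True`` they yield an "na" result flagged ``"no data"``
    instead. Each pair gets its own reproducible random substream derived
    from ``params.seed``. Ordering: groups by first appearance, species in
    column order.

    Returns a list of :class:`StabilityResult`, or, with
    ``return_curves=True``, a list of ``(PrevalenceCurve, StabilityResult)``
    pairs (empty pairs carry ``None`` for the curve).
    """
    out = []
    for group, species in table.pairs():
        col = table.column(group, species)
        if np.all(np.isnan(col)):
            if include_empty:
                res = StabilityResult(
                    group=group,
                    species=species,
                    stability_point=None,
                    estimated_prevalence=np.nan,
                    tail_prevalence=np.nan,
                    k_max=0,
                    params=params,
                    window_delta=np.nan,
                    note="no data",
                )
                out.append((None, res) if return_curves else res)
            continue
        rng = pair_rng(params.seed, group, species)
        curve = resample_prevalence_curve(
            col, params, rng, resampling=resampling, group=group, species=species
        )
        res = detect_stability(curve, params, **detect_kwargs)
        out.append((curve, res) if return_curves else res)
    return out
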