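"""Spearman rank correlation and correlation-vs-time/window tracks.

The central comparison of the analysis is a rank correlation between a
fluorescence readout (level, ratio, or windowed relative rate) and the
variant melting temperature, computed across all variant x replicate
points at each time or window.  Spearman's rho is implemented from
first principles -- mid-ranks (average ranks for ties) followed by the
Pearson formula -- so tie handling is explicit and testable against an
independent implementation.

Correlations are reported signed; no absolute values are taken.  No
p-values are attached by default; an exact permutation p-value is
available for small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, UndefinedCorrelationError, ValidationError
from .summaries_rates import SummarySeries

__all__ = [
    "CorrelationTrack",
    "midranks",
    "spearman_rho",
    "spearman_exact_pvalue",
    "track_vs_tm",
    "rate_track_vs_tm",
    "rate_vs_rate",
]


def midranks(x) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of the tied positions."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        # positions i..j (0-based) share the mean of ranks i+1..j+1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Raises :class:`UndefinedCorrelationError` when either vector has no
    rank variance (all values tied) instead of returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValidationError(f"need at least 3 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    rx, ry = midranks(x), midranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    sx, sy = float(dx @ dx), float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError(
            "zero rank variance: correlation undefined (all values tied)")
    return float((dx @ dy) / math.sqrt(sx * sy))


def spearman_exact_pvalue(x, y) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n <= 10)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size > 10:
        raise ValidationError("exact permutation p-value limited to n <= 10")
    observed = abs(spearman_rho(x, y))
    count = total = 0
    for perm in itertools.permutations(range(x.size)):
        try:
            rho = spearman_rho(x, y[list(perm)])
        except UndefinedCorrelationError:  # pragma: no cover - guarded above
            continue
        total += 1
        if abs(rho) >= observed - 1e-12:
            count += 1
    return count / total


@dataclass
class CorrelationTrack:
    """Signed rho against time or window, with point counts and status.

    ``status[i]`` is ``'ok'`` or ``'undefined'`` (zero rank variance at
    that position; ``rho[i]`` is NaN there, surfaced rather than
    silently dropped).
    """

    x_descriptor: str
    y_descriptor: str
    times_or_windows: list
    rho: np.ndarray
    n_points: np.ndarray
    status: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.x_descriptor, "y": self.y_descriptor,
            "at": [str(t) for t in self.times_or_windows],
            "rho": self.rho, "n": self.n_points, "status": self.status})

    def rho_at(self, key) -> float:
        for t, r in zip(self.times_or_windows, self.rho):
            if t == key:
                return float(r)
        raise KeyError(key)


def _check_tm_coverage(variants, tm_map: dict[str, float]) -> None:
    missing = sorted(set(variants) - set(tm_map))
    if missing:
        raise ConfigError(f"no melting temperature configured for variants: {missing}")


def track_vs_tm(summaries: list[SummarySeries], tm_map: dict[str, float],
                readout: str = "red", times=None) -> CorrelationTrack:
    """Rho between a per-time summary readout and variant Tm, per time.

    At each time the correlation pools all variant x replicate points
    (24 for the default 8 x 3 panel), pairing each point's readout with
    its variant's Tm.
    """
    if not summaries:
        raise ValidationError("track_vs_tm: no summaries given")
    _check_tm_coverage([s.variant for s in summaries], tm_map)
    if times is None:
        times = summaries[0].times_min
    rhos, ns, status = [], [], []
    for t in times:
        vals, tms = [], []
        for s in summaries:
            idx = np.nonzero(s.times_min == t)[0]
            if idx.size:
                vals.append(s.series(readout)[idx[0]])
                tms.append(tm_map[s.variant])
        if len(vals) < 3:
            rhos.append(np.nan); ns.append(len(vals)); status.append("undefined")
            continue
        try:
            rhos.append(spearman_rho(tms, vals))
            status.append("ok")
        except UndefinedCorrelationError:
            rhos.append(np.nan)
            status.append("undefined")
        ns.append(len(vals))
    return CorrelationTrack("variant Tm", f"mean_{readout}", list(times),
                            np.asarray(rhos), np.asarray(ns), status)


def rate_track_vs_tm(rates: pd.DataFrame, tm_map: dict[str, float],
                     channel: str = "green", windows=None) -> CorrelationTrack:
    """Rho between a windowed relative rate and variant Tm, per window.

    ``rates`` is the tidy table from
    :func:`dnakflow.summaries_rates.rate_table`.
    """
    sub = rates[(rates["channel"] == channel) & (rates["status"] == "ok")]
    if sub.empty:
        raise ValidationError(f"no usable rate rows for channel {channel!r}")
    _check_tm_coverage(sub["variant"].unique(), tm_map)
    if windows is None:
        windows = sorted({(a, b) for a, b in
                          zip(sub["window_start"], sub["window_end"])})
    rhos, ns, status = [], [], []
    for lo, hi in windows:
        w = sub[(sub["window_start"] == lo) & (sub["window_end"] == hi)]
        if len(w) < 3:
            rhos.append(np.nan); ns.append(len(w)); status.append("undefined")
            continue
        tms = [tm_map[v] for v in w["variant"]]
        try:
            rhos.append(spearman_rho(tms, w["relative_rate"].to_numpy()))
            status.append("ok")
        except UndefinedCorrelationError:
            rhos.append(np.nan)
            status.append("undefined")
        ns.append(len(w))
    return CorrelationTrack("variant Tm", f"{channel} relative rate",
                            [tuple(w) for w in windows],
                            np.asarray(rhos), np.asarray(ns), status)


def rate_vs_rate(rates_x: pd.DataFrame, rates_y: pd.DataFrame,
                 windows=None) -> CorrelationTrack:
    """Rho between two rate collections per window, matched on keys.

    Rows are matched on (variant, replicate, window); unmatched keys
    raise :class:`AlignmentError` listing the offenders.
    """
    cols = ["variant", "replicate", "window_start", "window_end"]
    x = rates_x[rates_x["status"] == "ok"]
    y = rates_y[rates_y["status"] == "ok"]
    kx = set(map(tuple, x[cols].itertuples(index=False)))
    ky = set(map(tuple, y[cols].itertuples(index=False)))
    if kx != ky:
        raise AlignmentError(
            f"unmatched rate keys; only in x: {sorted(kx - ky)[:5]}, "
            f"only in y: {sorted(ky - kx)[:5]}")
    merged = x.merge(y, on=cols, suffixes=("_x", "_y"))
    if windows is None:
        windows = sorted({(a, b) for a, b in
                          zip(merged["window_start"], merged["window_end"])})
    rhos, ns, status = [], [], []
    for lo, hi in windows:
        w = merged[(merged["window_start"] == lo) & (merged["window_end"] == hi)]
        if len(w) < 3:
            rhos.append(np.nan); ns.append(len(w)); status.append("undefined")
            continue
        try:
            rhos.append(spearman_rho(w["relative_rate_x"].to_numpy(),
                                     w["relative_rate_y"].to_numpy()))
            status.append("ok")
        except UndefinedCorrelationError:
            rhos.append(np.nan)
            status.append("undefined")
        ns.append(len(w))
    xch = x["channel"].iloc[0] if len(x) else "?"
    ych = y["channel"].iloc[0] if len(y) else "?"
    return CorrelationTrack(f"{xch} relative rate", f"{ych} relative rate",
                            [tuple(w) for w in windows],
                            np.asarray(rhos), np.asarray(ns), status)
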