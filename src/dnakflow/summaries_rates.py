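"""Per-timepoint summaries and windowed relative rates.

Turns event tables into the statistics used throughout the analysis:

* doublet gating: a rectangular forward/side-scatter gate (default the
  1st-99th percentile of each scatter channel, a permissive stand-in
  for the usual singlet gate),
* per-sample arithmetic means of each channel plus the green/red
  ratio (mean of per-event ratios by default -- robust to plasmid
  copy-number spread because both reporters sit on the same plasmid;
  ratio-of-means available as a switch),
* windowed rates: the ordinary-least-squares slope of a summary series
  inside a closed time window, normalised by the mean level in the
  same window to give a *relative rate* in min^-1.  Windows are closed
  intervals, so a schedule point on a boundary belongs to both
  adjacent windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySampleError, InsufficientDataError, ValidationError
from .synthetic_data import TimepointSample

__all__ = [
    "GateSpec",
    "SummarySeries",
    "RateEstimate",
    "DEFAULT_WINDOWS",
    "gate_singlets",
    "percentile_gate",
    "summarize",
    "fit_rate",
    "rate_table",
]

#: Analysis windows (min): initial, early, late, and two post-peak windows.
DEFAULT_WINDOWS = ((0.0, 30.0), (30.0, 60.0), (60.0, 90.0),
                   (150.0, 180.0), (180.0, 210.0))

CHANNELS = ("red", "green", "ratio")


@dataclass(frozen=True)
class GateSpec:
    """Rectangular scatter gate; events inside both closed intervals pass."""

    fsc_bounds: tuple[float, float]
    ssc_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("fsc_bounds", self.fsc_bounds),
                               ("ssc_bounds", self.ssc_bounds)):
            if not (lo < hi):
                raise ValidationError(f"{name}: lower bound must be < upper bound")


def percentile_gate(samples: list[TimepointSample], lower: float = 1.0,
                    upper: float = 99.0) -> GateSpec:
    """Permissive rectangular gate at scatter percentiles pooled over samples."""
    if not samples:
        raise ValidationError("need at least one sample to derive a gate")
    fsc = np.concatenate([s.events["fsc"].to_numpy() for s in samples])
    ssc = np.concatenate([s.events["ssc"].to_numpy() for s in samples])
    return GateSpec(tuple(np.percentile(fsc, [lower, upper])),
                    tuple(np.percentile(ssc, [lower, upper])))


def gate_singlets(sample: TimepointSample, gate: GateSpec) -> TimepointSample:
    """Retain events with fsc and ssc inside the gate; input is not mutated."""
    e = sample.events
    mask = (e["fsc"].between(*gate.fsc_bounds) & e["ssc"].between(*gate.ssc_bounds))
    return TimepointSample(sample.variant, sample.replicate, sample.time_min,
                           e.loc[mask].copy())


@dataclass
class SummarySeries:
    """Per-time channel means for one variant/replicate."""

    variant: str
    replicate: int
    times_min: np.ndarray
    mean_red: np.ndarray
    mean_green: np.ndarray
    mean_ratio: np.ndarray
    mean_fsc: np.ndarray
    mean_ssc: np.ndarray

    def series(self, channel: str) -> np.ndarray:
        try:
            return getattr(self, f"mean_{channel}")
        except AttributeError:
            raise ValidationError(f"unknown channel {channel!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant": self.variant, "replicate": self.replicate,
            "time_min": self.times_min, "mean_red": self.mean_red,
            "mean_green": self.mean_green, "mean_ratio": self.mean_ratio,
            "mean_fsc": self.mean_fsc, "mean_ssc": self.mean_ssc})


def summarize(samples: list[TimepointSample], gate: GateSpec | None = None,
              ratio_of_means: bool = False) -> SummarySeries:
    """Summarise one variant/replicate's samples into per-time means.

    All samples must share variant and replicate.  ``mean_ratio`` is the
    arithmetic mean of per-event green/red ratios unless
    ``ratio_of_means`` is set, in which case it is
    ``mean_green / mean_red``.
    """
    if not samples:
        raise ValidationError("summarize: empty sample list")
    keys = {(s.variant, s.replicate) for s in samples}
    if len(keys) != 1:
        raise ValidationError(f"summarize: samples mix variant/replicate keys {sorted(keys)}")
    ordered = sorted(samples, key=lambda s: s.time_min)
    rows = {"t": [], "red": [], "green": [], "ratio": [], "fsc": [], "ssc": []}
    for s in ordered:
        g = gate_singlets(s, gate) if gate is not None else s
        if g.n_events == 0:
            raise EmptySampleError(
                f"no events left after gating: {s.variant} rep {s.replicate} "
                f"t = {s.time_min:g} min")
        e = g.events
        rows["t"].append(s.time_min)
        rows["red"].append(e["red"].mean())
        rows["green"].append(e["green"].mean())
        if ratio_of_means:
            rows["ratio"].append(e["green"].mean() / e["red"].mean())
        else:
            rows["ratio"].append((e["green"] / e["red"]).mean())
        rows["fsc"].append(e["fsc"].mean())
        rows["ssc"].append(e["ssc"].mean())
    variant, replicate = next(iter(keys))
    return SummarySeries(variant, replicate, np.asarray(rows["t"]),
                         np.asarray(rows["red"]), np.asarray(rows["green"]),
                         np.asarray(rows["ratio"]), np.asarray(rows["fsc"]),
                         np.asarray(rows["ssc"]))


@dataclass(frozen=True)
class RateEstimate:
    """Windowed OLS slope and relative rate of one summary series."""

    channel: str
    window: tuple[float, float]
    slope: float          # a.u. min^-1
    mean_in_window: float  # a.u.
    relative_rate: float   # min^-1 = slope / mean_in_window
    n_points: int


def fit_rate(times_min, values, window: tuple[float, float],
             channel: str = "") -> RateEstimate:
    """OLS trendline of ``values`` against time inside a closed window.

    The relative rate is the slope divided by the in-window mean; it is
    invariant under rescaling of the values, which removes gain and
    maturation-amplitude differences between channels.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("times and values must be 1-d arrays of equal length")
    lo, hi = window
    if not (lo < hi):
        raise ValidationError(f"window must satisfy start < end, got {window}")
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"window [{lo:g}, {hi:g}] contains {int(mask.sum())} point(s); need >= 2")
    tw, yw = t[mask], y[mask]
    slope = float(np.polyfit(tw, yw, 1)[0])
    mean = float(yw.mean())
    if mean == 0.0:
        raise ValidationError("zero mean in window: relative rate undefined")
    return RateEstimate(channel, (float(lo), float(hi)), slope, mean,
                        slope / mean, int(mask.sum()))


def rate_table(summaries: list[SummarySeries], windows=DEFAULT_WINDOWS,
               channels=CHANNELS) -> pd.DataFrame:
    """One rate estimate per variant/replicate/channel/window.

    Returns a tidy DataFrame.  A window with fewer than two schedule
    points yields an explicit row with ``status = 'absent'`` and NaN
    estimates rather than a silent omission.
    """
    for ch in channels:
        if ch not in CHANNELS:
            raise ValidationError(f"unknown channel {ch!r}; expected one of {CHANNELS}")
    rows = []
    for summ in summaries:
        for ch in channels:
            y = summ.series(ch)
            for window in windows:
                base = dict(variant=summ.variant, replicate=summ.replicate,
                            channel=ch, window_start=float(window[0]),
                            window_end=float(window[1]))
                try:
                    est = fit_rate(summ.times_min, y, window, channel=ch)
                except InsufficientDataError:
                    rows.append({**base, "slope": np.nan, "mean": np.nan,
                                 "relative_rate": np.nan, "n_points": 0,
                                 "status": "absent"})
                else:
                    rows.append({**base, "slope": est.slope, "mean": est.mean_in_window,
                                 "relative_rate": est.relative_rate,
                                 "n_points": est.n_points, "status": "ok"})
    return pd.DataFrame(rows)
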