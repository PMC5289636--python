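"""Collective-displacement spectra, inactivity gaps and stimulus response.

The "spectra" are the per-record mean x (lateral) and mean y (vertical)
coordinate series over time, in raw pixel units (y grows downward).  Gap
records appear as NaN and never contribute to any statistic.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np

from .session import Session

__all__ = [
    "Spectra",
    "PresenceSchedule",
    "IntervalReport",
    "compute_spectra",
    "detect_gaps",
    "activity_index",
    "presence_response",
    "write_report_csv",
    "write_spectra_csv",
    "plot_spectra",
]


@dataclass
class Spectra:
    t: np.ndarray
    lateral: np.ndarray  # mean_x per record, NaN at gaps
    vertical: np.ndarray  # mean_y per record, NaN at gaps

    def series(self, axis: str) -> np.ndarray:
        if axis == "lateral":
            return self.lateral
        if axis == "vertical":
            return self.vertical
        raise ValueError(f"axis must be 'lateral' or 'vertical', got {axis!r}")

    @property
    def interval(self) -> float:
        """Record spacing, estimated as the median timestamp difference."""
        if len(self.t) < 2:
            return 0.0
        return float(np.median(np.diff(self.t)))


@dataclass
class PresenceSchedule:
    """Labeled, non-overlapping, increasing stimulus-presence intervals."""

    intervals: list[tuple[str, float, float]]  # (label, t_start, t_end)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, lo, hi in self.intervals:
            if hi <= lo:
                raise ValueError(f"{label}: empty interval [{lo}, {hi})")
            if lo < prev_end:
                raise ValueError(f"{label}: intervals overlap or are out of order")
            prev_end = hi

    def contains(self, t: float) -> bool:
        return any(lo <= t < hi for _, lo, hi in self.intervals)

    @classmethod
    def periodic(cls, k: int, first_start: float, duration: float, gap: float) -> "PresenceSchedule":
        """k equal presence intervals separated by non-presence gaps (P1..Pk)."""
        out = []
        t = first_start
        for m in range(k):
            out.append((f"P{m + 1}", t, t + duration))
            t += duration + gap
        return cls(out)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "PresenceSchedule":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != ["label", "t_start", "t_end"]:
                raise ValueError("schedule CSV must have header label,t_start,t_end")
            rows = [(r[0], float(r[1]), float(r[2])) for r in reader if r]
        return cls(rows)

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "t_start", "t_end"])
            writer.writerows(self.intervals)


@dataclass
class IntervalReport:
    """Per-presence-interval activity comparison, one axis pair each.

    ``*_inside`` is the activity index within the interval, ``*_flank``
    over the equal-length non-presence windows flanking it, ``*_diff``
    their difference (inside minus flank) and ``*_shift`` the change in
    mean position (inside minus flank).  NaN marks undefined values.
    """

    label: str
    t_start: float
    t_end: float
    lateral_inside: float
    lateral_flank: float
    lateral_diff: float
    lateral_shift: float
    vertical_inside: float
    vertical_flank: float
    vertical_diff: float
    vertical_shift: float


def compute_spectra(session: Session) -> Spectra:
    """Project a session onto its lateral/vertical mean-position series."""
    if not session.records:
        raise ValueError("session has no records")
    t = np.array([r.t for r in session.records], dtype=float)
    lat = np.array(
        [np.nan if r.mean_x is None else r.mean_x for r in session.records]
    )
    ver = np.array(
        [np.nan if r.mean_y is None else r.mean_y for r in session.records]
    )
    return Spectra(t, lat, ver)


def detect_gaps(spectra: Spectra, min_duration: float) -> list[tuple[float, float]]:
    """Maximal runs of gap records lasting at least ``min_duration`` seconds.

    Each run of consecutive missing records spanning timestamps
    ``t_first..t_last`` is reported as ``[t_first, t_last + interval)``.
    """
    if min_duration < 0:
        raise ValueError(f"min_duration must be >= 0, got {min_duration}")
    missing = np.isnan(spectra.lateral)
    interval = spectra.interval
    gaps = []
    k = 0
    n = len(missing)
    while k < n:
        if missing[k]:
            start = k
            while k < n and missing[k]:
                k += 1
            lo = float(spectra.t[start])
            hi = float(spectra.t[k - 1]) + interval
            if hi - lo >= min_duration:
                gaps.append((lo, hi))
        else:
            k += 1
    return gaps


def _pair_diffs(spectra: Spectra, series: np.ndarray, windows, exclude=None) -> np.ndarray:
    """|first differences| whose both endpoints fall inside one window.

    Pairs with a member inside an ``exclude`` schedule are dropped.
    """
    out = []
    t = spectra.t
    for lo, hi in windows:
        sel = (t >= lo) & (t < hi)
        if exclude is not None:
            sel &= ~np.array([exclude.contains(x) for x in t])
        idx = np.flatnonzero(sel)
        for a, b in zip(idx[:-1], idx[1:]):
            if b == a + 1 and not (np.isnan(series[a]) or np.isnan(series[b])):
                out.append(abs(series[b] - series[a]))
    return np.array(out)


def activity_index(
    spectra: Spectra, window: tuple[float, float], axis: str = "vertical"
) -> float:
    """Mean absolute first difference of the series over ``window``.

    Pairs with a missing member are skipped; NaN is returned when fewer
    than one usable pair remains (undefined activity).
    """
    series = spectra.series(axis)
    diffs = _pair_diffs(spectra, series, [window])
    if len(diffs) == 0:
        return float("nan")
    return float(diffs.mean())


def _masked_mean(spectra: Spectra, series: np.ndarray, windows, schedule) -> float:
    t = spectra.t
    sel = np.zeros(len(t), dtype=bool)
    for lo, hi in windows:
        sel |= (t >= lo) & (t < hi)
    if schedule is not None:
        sel &= ~np.array([schedule.contains(x) for x in t])
    vals = series[sel]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def presence_response(
    spectra: Spectra, schedule: PresenceSchedule
) -> list[IntervalReport]:
    """Compare activity and mean position inside each presence interval
    against equal-length flanking windows.

    Flanks are the windows immediately before and after the interval, of
    the same length, truncated at the session span; timestamps that fall
    inside *any* presence interval are excluded from the flanks.
    """
    if not len(spectra.t):
        raise ValueError("empty spectra")
    t0 = float(spectra.t[0])
    t_end = float(spectra.t[-1]) + spectra.interval
    reports = []
    for label, lo, hi in schedule.intervals:
        length = hi - lo
        flanks = [
            (max(t0, lo - length), lo),
            (hi, min(t_end, hi + length)),
        ]
        flanks = [(a, b) for a, b in flanks if b > a]

        row: dict[str, float] = {}
        for axis in ("lateral", "vertical"):
            series = spectra.series(axis)
            inside = activity_index(spectra, (lo, hi), axis)
            fd = (
                np.concatenate(
                    [
                        _pair_diffs(spectra, series, [(a, b)], exclude=schedule)
                        for a, b in flanks
                    ]
                )
                if flanks
                else np.array([])
            )
            flank = float(fd.mean()) if len(fd) else float("nan")
            row[f"{axis}_inside"] = inside
            row[f"{axis}_flank"] = flank
            row[f"{axis}_diff"] = inside - flank
            mean_in = _masked_mean(spectra, series, [(lo, hi)], None)
            mean_fl = _masked_mean(spectra, series, flanks, schedule)
            row[f"{axis}_shift"] = mean_in - mean_fl
        reports.append(IntervalReport(label, lo, hi, **row))
    return reports


def write_report_csv(reports: list[IntervalReport], path: str | os.PathLike) -> None:
    cols = [
        "label", "t_start", "t_end",
        "lateral_inside", "lateral_flank", "lateral_diff", "lateral_shift",
        "vertical_inside", "vertical_flank", "vertical_diff", "vertical_shift",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rep in reports:
            writer.writerow([getattr(rep, c) for c in cols])


def write_spectra_csv(spectra: Spectra, path: str | os.PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "lateral", "vertical"])
        for k in range(len(spectra.t)):
            writer.writerow(
                [
                    spectra.t[k],
                    "" if np.isnan(spectra.lateral[k]) else spectra.lateral[k],
                    "" if np.isnan(spectra.vertical[k]) else spectra.vertical[k],
                ]
            )


def plot_spectra(
    spectra: Spectra,
    path: str | os.PathLike,
    schedule: PresenceSchedule | None = None,
) -> None:
    """Two-panel lateral/vertical displacement plot with presence shading."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(10, 6))
    for ax, axis in zip(axes, ("lateral", "vertical")):
        ax.plot(spectra.t, spectra.series(axis), lw=0.8, color="k")
        ax.set_ylabel(f"{axis} distance (a.u.)")
        if schedule is not None:
            for label, lo, hi in schedule.intervals:
                ax.axvspan(lo, hi, color="tab:orange", alpha=0.2)
                ax.text(lo, ax.get_ylim()[1], label, fontsize=8, va="top")
    axes[1].set_xlabel("t (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
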