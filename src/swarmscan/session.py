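"""Timestamped collective-position records and the plain-text session log.

Log dialect (one record per line after a 3-line header)::

    #location=<text>
    #freq_range=<text>
    #start=<ISO-8601> interval=<float>
    t=<float>\tn=<int>\tblobs=<x1>,<y1>;<x2>,<y2>;...\tavg=<x>,<y>

Blob coordinates are printed with 2 decimal places; the per-record
averages with 6 (so that the mean of the printed blob coordinates
round-trips).  Records with no detected blobs ("gap records") have an
empty ``blobs=`` field and ``avg=NA,NA``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

__all__ = [
    "FrameRecord",
    "SessionMeta",
    "Session",
    "SessionFormatError",
    "SessionParseError",
    "aggregate_frame",
    "make_record",
    "write_session",
    "read_session",
    "to_csv",
]

DEFAULT_INTERVAL = 2.0  # seconds between records


class SessionFormatError(ValueError):
    """Missing or malformed session header."""


class SessionParseError(ValueError):
    """Malformed record line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class FrameRecord:
    t: float
    centroids: list[tuple[float, float]]
    mean_x: float | None
    mean_y: float | None

    @property
    def n(self) -> int:
        return len(self.centroids)

    @property
    def is_gap(self) -> bool:
        return self.n == 0


@dataclass
class SessionMeta:
    location: str = ""
    freq_range: str = ""
    start: str = "1970-01-01T00:00:00"
    interval: float = DEFAULT_INTERVAL

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError(f"interval must be > 0, got {self.interval}")
        for name in ("location", "freq_range", "start"):
            if any(c in getattr(self, name) for c in "\n\r\t"):
                raise ValueError(f"{name} must not contain newlines or tabs")


@dataclass
class Session:
    meta: SessionMeta = field(default_factory=SessionMeta)
    records: list[FrameRecord] = field(default_factory=list)


def make_record(t: float, centroids: list[tuple[float, float]]) -> FrameRecord:
    """Build a record from raw centroids; empty list yields a gap record."""
    if t < 0:
        raise ValueError(f"timestamp must be >= 0, got {t}")
    centroids = [(float(x), float(y)) for x, y in centroids]
    if not centroids:
        return FrameRecord(t, [], None, None)
    mx = sum(x for x, _ in centroids) / len(centroids)
    my = sum(y for _, y in centroids) / len(centroids)
    return FrameRecord(t, centroids, mx, my)


def aggregate_frame(blobs, t: float) -> FrameRecord:
    """Collapse a frame's blobs into one record (mean x/y of centroids)."""
    return make_record(t, [b.centroid for b in blobs])


def _format_record(rec: FrameRecord) -> str:
    blobs = ";".join(f"{x:.2f},{y:.2f}" for x, y in rec.centroids)
    if rec.is_gap:
        avg = "NA,NA"
    else:
        avg = f"{rec.mean_x:.6f},{rec.mean_y:.6f}"
    return f"t={rec.t!r}\tn={rec.n}\tblobs={blobs}\tavg={avg}"


def write_session(session: Session, path: str | os.PathLike) -> None:
    """Serialize a session to the plain-text log format."""
    meta = session.meta
    lines = [
        f"#location={meta.location}",
        f"#freq_range={meta.freq_range}",
        f"#start={meta.start} interval={meta.interval!r}",
    ]
    lines.extend(_format_record(r) for r in session.records)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_record(line: str, lineno: int) -> FrameRecord:
    fields = line.split("\t")
    if len(fields) != 4:
        raise SessionParseError(lineno, f"expected 4 tab-separated fields, got {len(fields)}")
    try:
        keys = [f.split("=", 1) for f in fields]
        tags = [k[0] for k in keys]
        if tags != ["t", "n", "blobs", "avg"]:
            raise SessionParseError(lineno, f"unexpected field tags {tags}")
        t = float(keys[0][1])
        n = int(keys[1][1])
        blobs_str = keys[2][1]
        centroids: list[tuple[float, float]] = []
        if blobs_str:
            for pair in blobs_str.split(";"):
                xs, ys = pair.split(",")
                centroids.append((float(xs), float(ys)))
        avg = keys[3][1]
        if avg == "NA,NA":
            mean_x = mean_y = None
        else:
            mxs, mys = avg.split(",")
            mean_x, mean_y = float(mxs), float(mys)
    except SessionParseError:
        raise
    except (ValueError, IndexError) as exc:
        raise SessionParseError(lineno, str(exc)) from exc
    if n != len(centroids):
        raise SessionParseError(lineno, f"n={n} but {len(centroids)} centroids listed")
    if (mean_x is None) != (n == 0):
        raise SessionParseError(lineno, "avg must be NA,NA exactly for gap records")
    return FrameRecord(t, centroids, mean_x, mean_y)


def read_session(path: str | os.PathLike) -> Session:
    """Parse a session log; raises on malformed header or record lines."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise SessionFormatError("session file must have a 3-line header")
    if not lines[0].startswith("#location=") or not lines[1].startswith("#freq_range="):
        raise SessionFormatError("missing #location/#freq_range header lines")
    if not lines[2].startswith("#start="):
        raise SessionFormatError("missing #start header line")
    head = lines[2][len("#start=") :]
    if " interval=" not in head:
        raise SessionFormatError("missing interval in #start header line")
    start, interval_str = head.rsplit(" interval=", 1)
    try:
        interval = float(interval_str)
    except ValueError as exc:
        raise SessionFormatError(f"bad interval {interval_str!r}") from exc
    meta = SessionMeta(
        location=lines[0][len("#location=") :],
        freq_range=lines[1][len("#freq_range=") :],
        start=start,
        interval=interval,
    )
    records = [
        _parse_record(line, lineno)
        for lineno, line in enumerate(lines[3:], start=4)
        if line
    ]
    return Session(meta, records)


def to_csv(session: Session, path: str | os.PathLike) -> None:
    """Flat CSV export: t,n,mean_x,mean_y with empty means at gap records."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "n", "mean_x", "mean_y"])
        for rec in session.records:
            writer.writerow(
                [
                    rec.t,
                    rec.n,
                    "" if rec.mean_x is None else rec.mean_x,
                    "" if rec.mean_y is None else rec.mean_y,
                ]
            )
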