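"""Reading, validating and writing annual growth-increment series.

Growth-increment widths from bivalve shells (or tree rings) travel in two
plain-text formats: the Tucson decadal ring-width format (``.rwl``) used by
the ITRDB and most dendro software, and a long-form CSV that can also carry
per-shell metadata (pith offset, collection status/year, station) and
*floating* series whose calendar placement is unknown.

An increment is labelled with the calendar year in which its growing season
begins; a partially formed final increment from a live-collected shell can be
dropped on read via ``drop_final_partial``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "IncrementSeries",
    "SeriesCollection",
    "read_rwl",
    "write_rwl",
    "read_csv_long",
    "write_csv_long",
    "ParseError",
    "ValidationError",
]

#: Terminator sentinels accepted in Tucson RWL files.
RWL_TERMINATORS = (999, -9999)

CSV_COLUMNS = [
    "shell_id",
    "year",
    "width",
    "pith_offset",
    "collection_status",
    "collection_year",
    "station",
]


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """A series violates an invariant (e.g. non-positive width)."""


@dataclass(frozen=True)
class IncrementSeries:
    """One shell's annual increment-width series.

    Parameters
    ----------
    shell_id : str
        Unique sample identifier.
    widths : np.ndarray
        Annual increment widths, all positive and finite (stored in file
        units; downstream statistics are unit-invariant).
    first_year : int or None
        Calendar year CE of the first measured increment, or ``None`` for a
        floating (undated) series.
    pith_offset : int
        Number of unmeasured early-ontogeny increments preceding the first
        measured one.
    collection_status : str
        ``"live"`` or ``"dead"``.
    collection_year : int or None
        Calendar year of collection, if known.
    station : str
        Collection station label.
    """

    shell_id: str
    widths: np.ndarray
    first_year: int | None = None
    pith_offset: int = 0
    collection_status: str = "live"
    collection_year: int | None = None
    station: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "widths", w)
        if w.ndim != 1 or w.size < 1:
            raise ValidationError(f"{self.shell_id}: need at least one width")
        if not np.all(np.isfinite(w)):
            raise ValidationError(f"{self.shell_id}: non-finite widths present")
        if np.any(w <= 0):
            bad = np.nonzero(w <= 0)[0]
            if self.first_year is not None:
                where = ", ".join(str(self.first_year + i) for i in bad[:10])
            else:
                where = ", ".join(f"position {i}" for i in bad[:10])
            raise ValidationError(
                f"{self.shell_id}: non-positive widths at {where}"
            )
        if self.pith_offset < 0:
            raise ValidationError(f"{self.shell_id}: negative pith offset")
        if self.collection_status not in ("live", "dead"):
            raise ValidationError(
                f"{self.shell_id}: collection_status must be 'live' or 'dead'"
            )
        if (
            self.dated
            and self.collection_status == "live"
            and self.collection_year is not None
            and self.last_year > self.collection_year
        ):
            raise ValidationError(
                f"{self.shell_id}: last year {self.last_year} postdates "
                f"collection year {self.collection_year}"
            )

    # -- derived attributes -------------------------------------------------

    @property
    def dated(self) -> bool:
        return self.first_year is not None

    @property
    def n(self) -> int:
        return int(self.widths.size)

    @property
    def last_year(self) -> int:
        if self.first_year is None:
            raise ValueError(f"{self.shell_id} is floating (undated)")
        return self.first_year + self.n - 1

    @property
    def years(self) -> np.ndarray:
        """Calendar years (dated) or 0-based positions (floating)."""
        start = self.first_year if self.first_year is not None else 0
        return np.arange(start, start + self.n)

    def to_series(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.shell_id)

    def with_first_year(self, first_year: int | None) -> "IncrementSeries":
        return replace(self, first_year=first_year)


@dataclass
class SeriesCollection:
    """A set of :class:`IncrementSeries`, keyed by unique ``shell_id``."""

    series: dict[str, IncrementSeries] = field(default_factory=dict)
    provenance: str = ""

    def add(self, s: IncrementSeries) -> None:
        if s.shell_id in self.series:
            raise ValidationError(f"duplicate shell_id {s.shell_id!r}")
        self.series[s.shell_id] = s

    def __iter__(self) -> Iterator[IncrementSeries]:
        return iter(self.series.values())

    def __len__(self) -> int:
        return len(self.series)

    def __getitem__(self, shell_id: str) -> IncrementSeries:
        return self.series[shell_id]

    def __contains__(self, shell_id: str) -> bool:
        return shell_id in self.series

    @property
    def dated(self) -> "SeriesCollection":
        """Sub-collection of dated series."""
        return SeriesCollection(
            {k: v for k, v in self.series.items() if v.dated}, self.provenance
        )

    @property
    def floating(self) -> "SeriesCollection":
        return SeriesCollection(
            {k: v for k, v in self.series.items() if not v.dated},
            self.provenance,
        )

    @classmethod
    def from_series(
        cls, items: Iterable[IncrementSeries], provenance: str = ""
    ) -> "SeriesCollection":
        coll = cls(provenance=provenance)
        for s in items:
            coll.add(s)
        return coll

    def to_frame(self) -> pd.DataFrame:
        """Wide year x shell table of widths (dated series only)."""
        return pd.DataFrame(
            {s.shell_id: s.to_series() for s in self if s.dated}
        ).sort_index()


# ---------------------------------------------------------------------------
# Tucson RWL (decadal) format
# ---------------------------------------------------------------------------


def read_rwl(path: str | Path | io.TextIOBase) -> SeriesCollection:
    """Read a Tucson decadal ring-width (RWL) file.

    Each data line holds a series id, the calendar year of the first value on
    the line, and up to ten integer widths; the series ends with a terminator
    sentinel (999 or -9999, auto-detected per series).
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = "<stream>"
    else:
        name = str(path)
        lines = Path(path).read_text().splitlines()

    raw: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{name}:{lineno}: expected id, year and values")
        sid = parts[0]
        try:
            year = int(parts[1])
            values = [int(v) for v in parts[2:]]
        except ValueError as exc:
            raise ParseError(f"{name}:{lineno}: non-integer field: {exc}") from None
        if len(values) > 10:
            raise ParseError(f"{name}:{lineno}: more than 10 values on a line")
        raw.setdefault(sid, [])
        if sid not in order:
            order.append(sid)
        raw[sid].append((year, values))

    coll = SeriesCollection(provenance=f"read_rwl({name})")
    for sid in order:
        chunks = raw[sid]
        first = chunks[0][0]
        widths: list[int] = []
        terminated = False
        for year, values in chunks:
            if widths and year != first + len(widths):
                raise ParseError(
                    f"{name}: series {sid!r}: line starting {year} does not "
                    f"continue from {first + len(widths) - 1}"
                )
            for v in values:
                if v in RWL_TERMINATORS:
                    terminated = True
                    break
                widths.append(v)
            if terminated:
                break
        if not terminated:
            raise ParseError(f"{name}: series {sid!r} missing terminator sentinel")
        if not widths:
            raise ParseError(f"{name}: series {sid!r} has no data values")
        first_year = chunks[0][0]
        coll.add(IncrementSeries(sid, np.array(widths, dtype=float), first_year))
    return coll


def write_rwl(collection: SeriesCollection, path: str | Path) -> Path:
    """Write a dated collection as Tucson RWL with -9999 terminators.

    Values are written as integers in file units (0.001 mm convention);
    non-integral widths are rounded. Floating series cannot be represented
    in RWL; write them with :func:`write_csv_long` instead.
    """
    undated = [s.shell_id for s in collection if not s.dated]
    if undated:
        raise ValidationError(
            f"floating series {undated} cannot be written as RWL; "
            "use write_csv_long"
        )
    out: list[str] = []
    for s in collection:
        vals = [int(round(v)) for v in s.widths] + [-9999]
        years = list(range(s.first_year, s.first_year + len(vals)))
        i = 0
        while i < len(vals):
            start = years[i]
            # fill to the end of the decade row
            row_len = min(10 - (start % 10), len(vals) - i)
            row = vals[i : i + row_len]
            out.append(
                f"{s.shell_id:<8s}{start:>5d}" + "".join(f"{v:>6d}" for v in row)
            )
            i += row_len
    Path(path).write_text("\n".join(out) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# Long-form CSV
# ---------------------------------------------------------------------------


def read_csv_long(path: str | Path | io.TextIOBase) -> SeriesCollection:
    """Read a long-form CSV (``shell_id,year,width`` plus optional metadata).

    A blank ``year`` for every row of a shell marks that series as floating;
    within a dated shell, years must be contiguous.
    """
    df = pd.read_csv(path, dtype={"shell_id": str})
    missing = {"shell_id", "year", "width"} - set(df.columns)
    if missing:
        raise ParseError(f"missing required columns: {sorted(missing)}")
    if df["width"].isna().any():
        bad = df.index[df["width"].isna()].tolist()[:10]
        raise ParseError(f"missing width values at rows {bad}")

    coll = SeriesCollection(provenance=f"read_csv_long({path})")
    for sid, grp in df.groupby("shell_id", sort=False):
        years = grp["year"]
        if years.isna().all():
            first_year = None
            widths = grp["width"].to_numpy(dtype=float)
        elif years.isna().any():
            raise ParseError(f"series {sid!r}: mixed blank and dated years")
        else:
            grp = grp.sort_values("year")
            yr = grp["year"].to_numpy(dtype=int)
            if not np.array_equal(yr, np.arange(yr[0], yr[0] + len(yr))):
                raise ParseError(f"series {sid!r}: non-contiguous years")
            first_year = int(yr[0])
            widths = grp["width"].to_numpy(dtype=float)

        def _meta(col, default, cast):
            if col not in grp.columns:
                return default
            v = grp[col].iloc[0]
            return default if pd.isna(v) else cast(v)

        coll.add(
            IncrementSeries(
                shell_id=str(sid),
                widths=widths,
                first_year=first_year,
                pith_offset=_meta("pith_offset", 0, int),
                collection_status=_meta("collection_status", "live", str),
                collection_year=_meta("collection_year", None, int),
                station=_meta("station", "", str),
            )
        )
    return coll


def write_csv_long(collection: SeriesCollection, path: str | Path) -> Path:
    """Write a collection (dated and floating series) as long-form CSV."""
    rows = []
    for s in collection:
        for i, w in enumerate(s.widths):
            rows.append(
                {
                    "shell_id": s.shell_id,
                    "year": (s.first_year + i) if s.dated else None,
                    "width": w,
                    "pith_offset": s.pith_offset,
                    "collection_status": s.collection_status,
                    "collection_year": s.collection_year,
                    "station": s.station,
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    return Path(path)


def drop_final_partial(series: IncrementSeries) -> IncrementSeries:
    """Drop the final increment of a live-collected shell.

    A shell collected before the end of the growing season carries a
    partially formed final increment that under-represents that year's
    growth; it is excluded before chronology construction.
    """
    if series.n < 2:
        raise ValidationError(f"{series.shell_id}: cannot drop only increment")
    return replace(series, widths=series.widths[:-1])
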