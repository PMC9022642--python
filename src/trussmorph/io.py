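"""Reading and writing landmark data: TPS digitization files and tables.

The TPS dialect accepted here is the one produced by the tpsUtil/tpsDig
family: ``LM=<n>`` followed by n whitespace-separated ``x y`` lines, then
optional ``IMAGE=``, ``ID=`` and ``SCALE=`` records. Keys are matched
case-insensitively; unknown keys are ignored with a logged warning.
Coordinates are y-up Cartesian as digitized — no image-row flipping is
applied (orientation is handled downstream by Procrustes alignment).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dataset import LandmarkDataset

logger = logging.getLogger(__name__)

_KEY_RE = re.compile(r"^([A-Za-z]+)\s*=\s*(.*)$")

#: fixed text precision for all numeric output
FLOAT_FMT = "%.6f"


@dataclass
class TpsRecord:
    """One specimen record of a TPS landmark file."""

    coords: list[tuple[float, float]] = field(default_factory=list)
    image: str = ""
    id: str = ""
    scale: float | None = None

    @property
    def landmark_count(self) -> int:
        return len(self.coords)

    def __post_init__(self) -> None:
        if self.scale is not None and self.scale <= 0:
            raise ValueError(f"SCALE must be > 0, got {self.scale} (record {self.id!r})")


class TpsParseError(ValueError):
    """Raised when a TPS file violates the format."""


def read_tps(path: str | Path) -> list[TpsRecord]:
    """Parse a TPS landmark file into a list of :class:`TpsRecord`.

    Tolerates Windows/Unix line endings and trailing blank lines.
    Raises :class:`TpsParseError` naming the record / line on a malformed
    LM count or a non-numeric coordinate.
    """
    text = Path(path).read_text()
    records: list[TpsRecord] = []
    current: TpsRecord | None = None
    expected = 0

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _KEY_RE.match(line)
        if m:
            key, value = m.group(1).upper(), m.group(2).strip()
            if key == "LM":
                if current is not None:
                    _check_count(current, expected, len(records) + 1)
                    records.append(current)
                try:
                    expected = int(value)
                except ValueError:
                    raise TpsParseError(
                        f"line {lineno}: LM count {value!r} is not an integer"
                    ) from None
                current = TpsRecord()
            elif current is None:
                raise TpsParseError(f"line {lineno}: {key}= before any LM= record")
            elif key == "IMAGE":
                current.image = value
            elif key == "ID":
                current.id = value
            elif key == "SCALE":
                try:
                    current.scale = float(value)
                except ValueError:
                    raise TpsParseError(
                        f"line {lineno}: SCALE value {value!r} is not numeric"
                    ) from None
                if current.scale <= 0:
                    raise TpsParseError(f"line {lineno}: SCALE must be > 0")
            else:
                logger.warning("ignoring unknown TPS key %s= at line %d", key, lineno)
        else:
            if current is None:
                raise TpsParseError(f"line {lineno}: coordinates before any LM= record")
            parts = line.split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"line {lineno}: expected 'x y' coordinate pair, got {line!r}"
                )
            try:
                current.coords.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise TpsParseError(
                    f"line {lineno}: non-numeric coordinate {line!r}"
                ) from None
    if current is not None:
        _check_count(current, expected, len(records) + 1)
        records.append(current)
    return records


def _check_count(record: TpsRecord, expected: int, index: int) -> None:
    if record.landmark_count != expected:
        name = record.id or f"#{index}"
        raise TpsParseError(
            f"record {name}: LM={expected} but {record.landmark_count} "
            "coordinate pairs found"
        )


def write_tps(records: list[TpsRecord], path: str | Path) -> None:
    """Write TPS records with 6-decimal fixed coordinate formatting."""
    lines: list[str] = []
    for rec in records:
        lines.append(f"LM={rec.landmark_count}")
        for x, y in rec.coords:
            lines.append(f"{x:.6f} {y:.6f}")
        if rec.image:
            lines.append(f"IMAGE={rec.image}")
        lines.append(f"ID={rec.id}")
        if rec.scale is not None:
            lines.append(f"SCALE={rec.scale:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def to_dataset(
    records: list[TpsRecord],
    group_map: dict[str, str],
    n_landmarks: int = 9,
) -> LandmarkDataset:
    """Assemble TPS records into a :class:`LandmarkDataset`.

    Coordinates are multiplied by each record's SCALE (1 when absent),
    giving mm. Every record must carry exactly ``n_landmarks`` landmarks
    and an id present in ``group_map``.
    """
    import numpy as np

    bad = [r.id or "<no id>" for r in records if r.landmark_count != n_landmarks]
    if bad:
        raise ValueError(
            f"records with landmark count != {n_landmarks}: {bad}"
        )
    missing = [r.id for r in records if r.id not in group_map]
    if missing:
        raise KeyError(f"ids missing from group_map: {missing}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated specimen ids: {dupes}")
    scales = np.array([r.scale if r.scale is not None else 1.0 for r in records])
    coords = np.array([r.coords for r in records]) * scales[:, None, None]
    return LandmarkDataset(ids, [group_map[i] for i in ids], coords, scales)


def from_dataset(data: LandmarkDataset) -> list[TpsRecord]:
    """Convert a dataset back to TPS records (coords already in mm, SCALE=1)."""
    return [
        TpsRecord(
            coords=[tuple(xy) for xy in data.coords[i]],
            id=data.specimen_ids[i],
            scale=1.0,
        )
        for i in range(data.n_specimens)
    ]


def write_table(data: LandmarkDataset, path: str | Path, sep: str = ",") -> None:
    """Write the delimited wide-table form (id, group, x1..y9, scale)."""
    data.to_frame().to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path, sep: str | None = None) -> LandmarkDataset:
    """Read a delimited landmark table (comma or tab, header required)."""
    if sep is None:
        sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    required = {"id", "group", "x1", "y1"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"landmark table must contain columns {sorted(required)}; "
            f"got {list(frame.columns)}"
        )
    return LandmarkDataset.from_frame(frame)
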