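"""Single-cell lineage data model and track-table I/O.

A :class:`LineageSet` holds the per-cell time series produced by time-lapse
tracking of growing microcolonies: for every cell a trace of (time, length,
fluorescence) frames plus lineage links (mother/daughters), the observed
division time, the post-stress fate and, for survivors, a resuscitation time.

Times are minutes with 0 = start of recording; lengths are µm; fluorescence
is in arbitrary units.  The on-disk representation is a plain UTF-8 TSV
"track table" with a frame section (one row per cell per frame) and a cell
section (one row per cell), documented in :func:`write_track_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "FATE_SURVIVED",
    "FATE_DIED",
    "FATE_UNOBSERVED",
    "CellRecord",
    "LineageSet",
    "LineageError",
    "TrackTableParseError",
    "read_track_table",
    "write_track_table",
    "assign_pole_ages",
    "validate_lineage",
]

FATE_SURVIVED = "survived"
FATE_DIED = "died"
FATE_UNOBSERVED = "unobserved"

_FATE_TO_CODE = {FATE_SURVIVED: "S", FATE_DIED: "D", FATE_UNOBSERVED: "U"}
_CODE_TO_FATE = {v: k for k, v in _FATE_TO_CODE.items()}

#: tolerance used when comparing times that should coincide (minutes)
_TIME_TOL = 1e-6


class LineageError(ValueError):
    """Raised when lineage structure is inconsistent (names the offending cell)."""


class TrackTableParseError(ValueError):
    """Raised on malformed track-table rows; carries the 1-based line number."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass
class CellRecord:
    """One tracked cell.

    ``times``/``lengths``/``fluor`` are parallel arrays, strictly increasing
    in time; ``fluor`` uses NaN where no fluorescence was recorded.
    ``old_pole_daughter`` marks whether this cell inherited its mother's old
    pole at division (for founders the flag is vacuous and set True).
    """

    cell_id: str
    colony_id: str
    parent_id: str | None
    birth_time: float
    division_time: float | None
    times: np.ndarray
    lengths: np.ndarray
    fluor: np.ndarray
    old_pole_daughter: bool = True
    fate: str = FATE_UNOBSERVED
    resuscitation_time: float | None = None
    pole_age: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.fluor is None:
            self.fluor = np.full_like(self.times, np.nan)
        self.fluor = np.asarray(self.fluor, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def is_founder(self) -> bool:
        return self.parent_id is None

    def frames_until(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(times, lengths) restricted to frames at or before ``t``."""
        m = self.times <= t + _TIME_TOL
        return self.times[m], self.lengths[m]

    def validate(self) -> None:
        if self.n_frames == 0:
            raise LineageError(f"cell {self.cell_id}: no frames")
        if len(self.lengths) != self.n_frames or len(self.fluor) != self.n_frames:
            raise LineageError(f"cell {self.cell_id}: frame arrays differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise LineageError(f"cell {self.cell_id}: frame times not strictly increasing")
        if np.any(self.lengths <= 0):
            raise LineageError(f"cell {self.cell_id}: non-positive length")
        if self.birth_time > self.times[0] + _TIME_TOL:
            raise LineageError(
                f"cell {self.cell_id}: birth_time {self.birth_time} after first frame"
            )
        if self.division_time is not None and self.division_time < self.times[-1] - _TIME_TOL:
            raise LineageError(
                f"cell {self.cell_id}: division_time {self.division_time} before last frame"
            )
        if self.fate not in _FATE_TO_CODE:
            raise LineageError(f"cell {self.cell_id}: unknown fate {self.fate!r}")


@dataclass
class LineageSet:
    """A collection of tracked cells from one or more microcolonies."""

    cells: dict[str, CellRecord]
    frame_interval: float
    shock_time: float | None = None
    _children: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rebuild_children()

    def _rebuild_children(self) -> None:
        self._children = {}
        for cid, cell in self.cells.items():
            if cell.parent_id is not None:
                self._children.setdefault(cell.parent_id, []).append(cid)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[CellRecord]:
        return iter(self.cells.values())

    def __getitem__(self, cell_id: str) -> CellRecord:
        return self.cells[cell_id]

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self.cells

    def children_of(self, cell_id: str) -> list[CellRecord]:
        """Daughters in insertion order (old-pole daughter convention: see
        :func:`assign_pole_ages`)."""
        return [self.cells[c] for c in self._children.get(cell_id, [])]

    def parent_of(self, cell_id: str) -> CellRecord | None:
        pid = self.cells[cell_id].parent_id
        return self.cells[pid] if pid is not None and pid in self.cells else None

    def founders(self) -> list[CellRecord]:
        return [c for c in self if c.is_founder]

    def leaves(self) -> list[CellRecord]:
        return [c for c in self if not self._children.get(c.cell_id)]

    def sibling_pairs(self) -> list[tuple[CellRecord, CellRecord]]:
        """All (daughter, daughter) pairs sharing a mother, in insertion order."""
        out = []
        for pid, kids in self._children.items():
            if len(kids) == 2:
                out.append((self.cells[kids[0]], self.cells[kids[1]]))
        return out

    def add(self, cell: CellRecord) -> None:
        if cell.cell_id in self.cells:
            raise LineageError(f"duplicate cell_id {cell.cell_id}")
        self.cells[cell.cell_id] = cell
        if cell.parent_id is not None:
            self._children.setdefault(cell.parent_id, []).append(cell.cell_id)

    def subset(self, cell_ids: Iterable[str]) -> "LineageSet":
        keep = set(cell_ids)
        cells = {cid: c for cid, c in self.cells.items() if cid in keep}
        return LineageSet(cells, self.frame_interval, self.shock_time)

    def validate(self, require_complete_divisions: bool = True) -> None:
        validate_lineage(self, require_complete_divisions=require_complete_divisions)


def validate_lineage(ls: LineageSet, require_complete_divisions: bool = True) -> None:
    """Check all structural invariants, raising :class:`LineageError`.

    ``require_complete_divisions=False`` relaxes the two-daughters rule so
    that analysis subsets produced by cell filtering remain representable.
    """
    for cell in ls:
        cell.validate()
        if cell.parent_id is not None:
            if cell.parent_id not in ls:
                raise LineageError(
                    f"cell {cell.cell_id}: parent {cell.parent_id} not in lineage set"
                )
            parent = ls[cell.parent_id]
            if parent.division_time is None:
                raise LineageError(
                    f"cell {cell.cell_id}: parent {cell.parent_id} has no division_time"
                )
            if abs(parent.division_time - cell.birth_time) > _TIME_TOL:
                raise LineageError(
                    f"cell {cell.cell_id}: birth_time {cell.birth_time} != parent "
                    f"{cell.parent_id} division_time {parent.division_time}"
                )
    for cid, kids in ls._children.items():
        if len(kids) > 2:
            raise LineageError(f"cell {cid}: more than two children ({kids})")
    if require_complete_divisions:
        for cell in ls:
            if cell.division_time is not None:
                kids = ls._children.get(cell.cell_id, [])
                if len(kids) != 2:
                    raise LineageError(
                        f"cell {cell.cell_id}: divides but has {len(kids)} child(ren)"
                    )


def assign_pole_ages(ls: LineageSet) -> LineageSet:
    """Assign old-pole generation ages (Stewart-style counting).

    Founders get pole_age 1.  At each division the daughter inheriting the
    mother's old pole gets ``mother_pole_age + 1``; the new-pole daughter gets
    1.  Which daughter is old-pole comes from the ``old_pole_daughter`` flag;
    if neither daughter carries the flag, the first-listed daughter is taken
    as old-pole by convention.  Returns a new LineageSet.
    """
    validate_lineage(ls, require_complete_divisions=False)
    new_cells = {cid: replace(c) for cid, c in ls.cells.items()}
    out = LineageSet(new_cells, ls.frame_interval, ls.shock_time)
    stack = [c.cell_id for c in out.founders()]
    for cid in stack:
        out.cells[cid].pole_age = 1
    while stack:
        cid = stack.pop()
        cell = out.cells[cid]
        kids = out.children_of(cid)
        if not kids:
            continue
        flagged = [k for k in kids if k.old_pole_daughter]
        old_pole = flagged[0] if len(flagged) == 1 else kids[0]
        for k in kids:
            k.pole_age = cell.pole_age + 1 if k is old_pole else 1
            stack.append(k.cell_id)
    return out


# ---------------------------------------------------------------------------
# Track-table serialization
# ---------------------------------------------------------------------------

_FRAME_COLS = ["cell_id", "colony_id", "frame_index", "time_min", "length_um", "fluor_au"]
_CELL_COLS = [
    "cell_id",
    "colony_id",
    "parent_id",
    "birth_time_min",
    "division_time_min",
    "old_pole_daughter",
    "fate",
    "resuscitation_min",
    "pole_age",
]


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return format(float(x), ".17g")


def write_track_table(ls: LineageSet, path) -> None:
    """Write ``ls`` as a track-table TSV.

    Layout: '#'-prefixed comment/metadata lines, a ``# [frames]`` section with
    one row per cell per frame, then a ``# [cells]`` section with one row per
    cell.  Missing numeric values are serialized as empty strings, never as
    NaN text.  The round trip through :func:`read_track_table` is lossless
    (identifiers exactly, numerics to 1e-9).
    """
    lines: list[str] = []
    lines.append("# sibfate track-table v1")
    lines.append(f"# frame_interval_min={_fmt(ls.frame_interval)}")
    if ls.shock_time is not None:
        lines.append(f"# shock_time_min={_fmt(ls.shock_time)}")
    lines.append("# [frames]")
    lines.append("\t".join(_FRAME_COLS))
    for cell in ls:
        for i in range(cell.n_frames):
            lines.append(
                "\t".join(
                    [
                        cell.cell_id,
                        cell.colony_id,
                        str(i),
                        _fmt(cell.times[i]),
                        _fmt(cell.lengths[i]),
                        _fmt(cell.fluor[i]),
                    ]
                )
            )
    lines.append("# [cells]")
    lines.append("\t".join(_CELL_COLS))
    for cell in ls:
        lines.append(
            "\t".join(
                [
                    cell.cell_id,
                    cell.colony_id,
                    cell.parent_id or "",
                    _fmt(cell.birth_time),
                    _fmt(cell.division_time),
                    "1" if cell.old_pole_daughter else "0",
                    _FATE_TO_CODE[cell.fate],
                    _fmt(cell.resuscitation_time),
                    "" if cell.pole_age is None else str(cell.pole_age),
                ]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_float(s: str, line_no: int, col: str) -> float | None:
    s = s.strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise TrackTableParseError(f"column {col}: cannot parse {s!r} as number", line_no)


def read_track_table(path) -> LineageSet:
    """Read a track-table TSV written by :func:`write_track_table`.

    Raises :class:`TrackTableParseError` (with the line number) on malformed
    rows and :class:`LineageError` (naming the cell) on dangling parent
    references or other lineage inconsistencies.
    """
    frame_interval: float | None = None
    shock_time: float | None = None
    section = None  # None | "frames" | "cells"
    header: list[str] | None = None
    frames: dict[str, list[tuple[float, float, float]]] = {}
    colony: dict[str, str] = {}
    meta_rows: dict[str, dict] = {}
    order: list[str] = []

    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body == "[frames]":
                    section, header = "frames", None
                elif body == "[cells]":
                    section, header = "cells", None
                elif "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key == "frame_interval_min":
                        frame_interval = _parse_float(val, line_no, key)
                    elif key == "shock_time_min":
                        shock_time = _parse_float(val, line_no, key)
                continue
            fields = line.split("\t")
            if section is None:
                raise TrackTableParseError("data row before any section marker", line_no)
            if header is None:
                header = [f.strip() for f in fields]
                expected = _FRAME_COLS if section == "frames" else _CELL_COLS
                if header != expected:
                    raise TrackTableParseError(
                        f"unexpected {section} header {header!r}; expected {expected!r}",
                        line_no,
                    )
                continue
            expected_n = len(_FRAME_COLS) if section == "frames" else len(_CELL_COLS)
            if len(fields) != expected_n:
                raise TrackTableParseError(
                    f"expected {expected_n} columns, got {len(fields)}", line_no
                )
            if section == "frames":
                cid, col_id, _idx, t, ln, fl = fields
                t_v = _parse_float(t, line_no, "time_min")
                l_v = _parse_float(ln, line_no, "length_um")
                if t_v is None or l_v is None:
                    raise TrackTableParseError("time_min/length_um must not be empty", line_no)
                f_v = _parse_float(fl, line_no, "fluor_au")
                frames.setdefault(cid, []).append(
                    (t_v, l_v, np.nan if f_v is None else f_v)
                )
                colony.setdefault(cid, col_id)
            else:
                (cid, col_id, pid, bt, dt, opd, fate, rt, pa) = fields
                if fate not in _CODE_TO_FATE:
                    raise TrackTableParseError(f"unknown fate code {fate!r}", line_no)
                if opd not in ("0", "1"):
                    raise TrackTableParseError(f"old_pole_daughter must be 0/1, got {opd!r}", line_no)
                bt_v = _parse_float(bt, line_no, "birth_time_min")
                if bt_v is None:
                    raise TrackTableParseError("birth_time_min must not be empty", line_no)
                pa_s = pa.strip()
                meta_rows[cid] = dict(
                    colony_id=col_id,
                    parent_id=pid.strip() or None,
                    birth_time=bt_v,
                    division_time=_parse_float(dt, line_no, "division_time_min"),
                    old_pole_daughter=opd == "1",
                    fate=_CODE_TO_FATE[fate],
                    resuscitation_time=_parse_float(rt, line_no, "resuscitation_min"),
                    pole_age=int(pa_s) if pa_s else None,
                )
                order.append(cid)

    if frame_interval is None:
        frame_interval = 1.0
    cells: dict[str, CellRecord] = {}
    for cid in order:
        meta = meta_rows[cid]
        if cid not in frames:
            raise LineageError(f"cell {cid}: listed in cell section but has no frames")
        rows = sorted(frames[cid])
        arr = np.array(rows, dtype=float)
        cells[cid] = CellRecord(
            cell_id=cid,
            colony_id=meta["colony_id"],
            parent_id=meta["parent_id"],
            birth_time=meta["birth_time"],
            division_time=meta["division_time"],
            times=arr[:, 0],
            lengths=arr[:, 1],
            fluor=arr[:, 2],
            old_pole_daughter=meta["old_pole_daughter"],
            fate=meta["fate"],
            resuscitation_time=meta["resuscitation_time"],
            pole_age=meta["pole_age"],
        )
    for cid in frames:
        if cid not in cells:
            raise LineageError(f"cell {cid}: has frames but no cell-section row")
    ls = LineageSet(cells, frame_interval, shock_time)
    validate_lineage(ls, require_complete_divisions=False)
    return ls
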