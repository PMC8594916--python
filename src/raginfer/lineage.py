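"""Core data model for single-cell lineage time series.

Time-lapse experiments on growing microcolonies yield, for every tracked
cell, a time series of lengths sampled at a fixed frame interval (3 min by
default) together with genealogy links to its mother and daughters.  This
module provides the in-memory containers for such data (:class:`CellRecord`,
:class:`LineageTable`), readers/writers for the canonical delimited text
format, and structural validation.

Conventions
-----------
* Within a record, times are minutes *since that cell's birth* and start at
  0; the absolute (colony-clock) birth time is kept separately so genealogy
  can be checked.  Interior samples are uniformly spaced at the sampling
  interval; the final sample may close a partial interval because division
  is an event between frames.
* A cell is *divided* when the table contains daughters referencing it (or
  when its record is explicitly flagged); otherwise it is censored and has
  neither a division length ``ld`` nor a generation time ``T``.

Canonical file format
---------------------
UTF-8 delimited text, one row per cell per frame, header row with columns
``cell_id,parent_id,time_min,length_um[,area_um2][,midcell_au]``; empty
``parent_id`` marks a founder; ``time_min`` is on the colony clock.
Metadata travel as ``# key=json-value`` comment lines before the header.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "LineageTable",
    "LineageError",
    "LineageFormatError",
    "LineageValidationError",
    "read_lineage_table",
    "write_lineage_table",
    "validate_lineage",
]

#: required columns of the canonical lineage file, in order
LINEAGE_COLUMNS = ("cell_id", "parent_id", "time_min", "length_um")
#: optional trailing columns
OPTIONAL_COLUMNS = ("area_um2", "midcell_au")

#: relative tolerance used when checking frame-grid uniformity
_GRID_RTOL = 1e-6


class LineageError(Exception):
    """Base class for lineage data errors."""


class LineageFormatError(LineageError):
    """Raised when an input file does not match the canonical format."""


class LineageValidationError(LineageError):
    """Raised when a structural invariant of the data is violated."""


@dataclass
class CellRecord:
    """Length trajectory of one cell, from birth to division (or censoring).

    Parameters
    ----------
    cell_id, parent_id
        Opaque identifiers; ``parent_id`` is ``None`` for founder cells.
    times
        Minutes since this cell's birth; strictly increasing, ``times[0]==0``.
    lengths
        Cell lengths in µm, one per time point.
    birth_time
        Birth moment on the colony clock (min); used only for genealogy checks.
    divided
        Whether the trajectory ends in a division event.  If so the last
        sample defines the division length ``ld`` and generation time ``T``.
    """

    cell_id: str
    parent_id: str | None
    times: np.ndarray
    lengths: np.ndarray
    birth_time: float = 0.0
    divided: bool = False
    areas: np.ndarray | None = None
    midcell_signal: np.ndarray | None = None
    pole_new: str | None = None
    pole_old: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.shape != self.lengths.shape:
            raise LineageValidationError(
                f"cell {self.cell_id}: times and lengths differ in cardinality"
            )

    @property
    def lb(self) -> float:
        """Birth length (µm): the length at the first frame."""
        return float(self.lengths[0])

    @property
    def ld(self) -> float | None:
        """Division length (µm), or ``None`` for censored cells."""
        return float(self.lengths[-1]) if self.divided else None

    @property
    def T(self) -> float | None:
        """Generation time (min), or ``None`` for censored cells."""
        return float(self.times[-1]) if self.divided else None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def length_at(self, t: float, atol: float = 1e-6) -> float | None:
        """Recorded length at time-since-birth ``t``, or ``None`` if no frame
        lies within ``atol`` of ``t``."""
        idx = np.searchsorted(self.times, t)
        for j in (idx - 1, idx):
            if 0 <= j < len(self.times) and abs(self.times[j] - t) <= atol:
                return float(self.lengths[j])
        return None

    def alive_at(self, t: float) -> bool:
        """True while the cell has not yet divided at time-since-birth ``t``."""
        return t <= self.times[-1] + _GRID_RTOL


@dataclass
class LineageTable:
    """A collection of :class:`CellRecord` with genealogy and metadata."""

    cells: list[CellRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("sampling_interval", 3.0)
        self.metadata.setdefault("length_unit", "um")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    @property
    def sampling_interval(self) -> float:
        return float(self.metadata["sampling_interval"])

    def by_id(self) -> dict[str, CellRecord]:
        return {c.cell_id: c for c in self.cells}

    def children_of(self) -> dict[str, list[CellRecord]]:
        kids: dict[str, list[CellRecord]] = {}
        for c in self.cells:
            if c.parent_id is not None:
                kids.setdefault(c.parent_id, []).append(c)
        return kids

    def divided_cells(self) -> list[CellRecord]:
        return [c for c in self.cells if c.divided]

    def subset(self, keep: Iterable[str]) -> "LineageTable":
        """Table restricted to ``keep`` cell ids (genealogy links to removed
        cells are retained as dangling ids; use for sub-population reruns)."""
        keep = set(keep)
        return LineageTable(
            cells=[c for c in self.cells if c.cell_id in keep],
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_lineage_table(source, dialect: str = "csv") -> LineageTable:
    """Read a canonical lineage file into a validated :class:`LineageTable`.

    ``source`` may be a path or an open text stream.  ``dialect`` selects the
    delimiter: ``"csv"`` (default) or ``"tsv"``.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise LineageFormatError(f"unknown dialect {dialect!r}")

    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()

    metadata: dict = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                key, _, val = stripped.partition("=")
                try:
                    metadata[key.strip()] = json.loads(val.strip())
                except json.JSONDecodeError:
                    metadata[key.strip()] = val.strip()
        else:
            body_lines.append(line)

    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep=sep,
                     dtype={"cell_id": str, "parent_id": str})
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise LineageFormatError(f"missing mandatory column(s): {missing}")

    if df.duplicated(subset=["cell_id", "time_min"]).any():
        dup = df[df.duplicated(subset=["cell_id", "time_min"])].iloc[0]
        raise LineageValidationError(
            f"duplicated (cell_id, time) row for cell {dup['cell_id']}"
        )

    cells: list[CellRecord] = []
    order = df["cell_id"].drop_duplicates().tolist()
    grouped = dict(tuple(df.groupby("cell_id", sort=False)))
    for cid in order:
        g = grouped[cid]
        t_abs = g["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t_abs) <= 0):
            raise LineageValidationError(
                f"non-monotone times within cell {cid}"
            )
        parent = g["parent_id"].iloc[0]
        parent = None if (pd.isna(parent) or parent == "") else str(parent)
        cells.append(
            CellRecord(
                cell_id=str(cid),
                parent_id=parent,
                times=t_abs - t_abs[0],
                lengths=g["length_um"].to_numpy(dtype=float),
                birth_time=float(t_abs[0]),
                areas=(g["area_um2"].to_numpy(dtype=float)
                       if "area_um2" in g.columns else None),
                midcell_signal=(g["midcell_au"].to_numpy(dtype=float)
                                if "midcell_au" in g.columns else None),
            )
        )

    table = LineageTable(cells=cells, metadata=metadata)
    # division is encoded by the presence of daughters
    has_kids = {c.parent_id for c in cells if c.parent_id is not None}
    explicit = set(metadata.get("divided_cells", []))
    for c in table.cells:
        c.divided = c.cell_id in has_kids or c.cell_id in explicit
    return table


def write_lineage_table(table: LineageTable, sink) -> None:
    """Write ``table`` in the canonical format (deterministic row order:
    cell_id, then time).  Numeric fields are kept to 6 decimals."""
    rows = []
    have_area = any(c.areas is not None for c in table.cells)
    have_mid = any(c.midcell_signal is not None for c in table.cells)
    # divided leaves carry no daughters, so flag them in metadata
    kids = table.children_of()
    explicit = sorted(c.cell_id for c in table.cells
                      if c.divided and c.cell_id not in kids)
    meta = dict(table.metadata)
    if explicit:
        meta["divided_cells"] = explicit

    for c in sorted(table.cells, key=lambda c: c.cell_id):
        for i in range(c.n_frames):
            row = {
                "cell_id": c.cell_id,
                "parent_id": "" if c.parent_id is None else c.parent_id,
                "time_min": round(c.birth_time + c.times[i], 6),
                "length_um": round(float(c.lengths[i]), 6),
            }
            if have_area:
                row["area_um2"] = ("" if c.areas is None
                                   else round(float(c.areas[i]), 6))
            if have_mid:
                row["midcell_au"] = ("" if c.midcell_signal is None
                                     else round(float(c.midcell_signal[i]), 6))
            rows.append(row)

    cols = list(LINEAGE_COLUMNS)
    if have_area:
        cols.append("area_um2")
    if have_mid:
        cols.append("midcell_au")
    df = pd.DataFrame(rows, columns=cols)

    header = "".join(f"# {k}={json.dumps(v)}\n" for k, v in sorted(meta.items()))
    csv_text = header + df.to_csv(index=False, float_format="%.6f")
    if hasattr(sink, "write"):
        sink.write(csv_text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(csv_text)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _default_mass_tolerance(table: LineageTable) -> float:
    """Exact conservation by default; widened when the table declares a
    measurement-noise sd (three noisy lengths enter the daughter-sum check)."""
    sd = float(table.metadata.get("meas_noise_sd", 0.0) or 0.0)
    return 6.0 * math.sqrt(3.0) * sd if sd > 0 else 1e-9


def validate_lineage(table: LineageTable,
                     mass_tolerance: float | None = None) -> list[str]:
    """Check all structural invariants; return the list of violations
    (empty list = valid).  This is a reporting operation and never raises."""
    report: list[str] = []
    ids = [c.cell_id for c in table.cells]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        report.append(f"duplicate cell ids: {sorted(dups)}")

    by_id = table.by_id()
    dt = table.sampling_interval

    for c in table.cells:
        if c.times[0] != 0:
            report.append(f"cell {c.cell_id}: times do not start at 0")
        diffs = np.diff(c.times)
        if np.any(diffs <= 0):
            report.append(f"cell {c.cell_id}: times not strictly increasing")
        elif len(diffs) > 2 and not np.allclose(diffs[:-1], dt, rtol=_GRID_RTOL,
                                                atol=1e-9):
            report.append(
                f"cell {c.cell_id}: interior frames not uniformly spaced "
                f"at {dt} min"
            )
        if np.any(c.lengths <= 0):
            report.append(f"cell {c.cell_id}: non-positive length")
        if c.parent_id is not None:
            parent = by_id.get(c.parent_id)
            if parent is None:
                report.append(
                    f"cell {c.cell_id}: orphan parent_id {c.parent_id}"
                )
            elif parent.divided and parent.T is not None:
                t_div = parent.birth_time + parent.T
                if c.birth_time < t_div - 1e-6:
                    report.append(
                        f"cell {c.cell_id}: born before parent "
                        f"{c.parent_id} divided"
                    )

    # genealogy: acyclicity and fan-out
    kids = table.children_of()
    for pid, ch in kids.items():
        if len(ch) > 2:
            report.append(f"cell {pid}: more than two children")
    for c in table.cells:
        seen = {c.cell_id}
        p = c.parent_id
        while p is not None and p in by_id:
            if p in seen:
                report.append(f"cell {c.cell_id}: cyclic parent links")
                break
            seen.add(p)
            p = by_id[p].parent_id

    # mass conservation at division
    tol = _default_mass_tolerance(table) if mass_tolerance is None \
        else mass_tolerance
    for pid, ch in kids.items():
        parent = by_id.get(pid)
        if parent is None or not parent.divided or len(ch) != 2:
            continue
        total = ch[0].lb + ch[1].lb
        if abs(total - parent.ld) > tol:
            report.append(
                f"cell {pid}: daughter birth lengths sum to {total:.4f} µm "
                f"but division length is {parent.ld:.4f} µm"
            )
    return report
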