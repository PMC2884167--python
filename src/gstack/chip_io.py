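"""Readers and writers for probe annotation tables and intensity files.

Supported formats are the tab-separated Affymetrix probe-tab dialect, the
ASCII CEL version-3 text dialect and plain ``x  y  intensity`` TSV files.
Coordinates are 0-based with ``x`` the grid column and ``y`` the grid row.
Binary CEL files (v4/AGCC) are rejected with a clear message.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from ._sequtil import (
    MIDDLE_POSITION,
    PROBE_LENGTH,
    complement,
    encode_many,
)

ROLE_PM = "PM"
ROLE_MM = "MM"

__all__ = [
    "ProbeRecord",
    "ChipData",
    "IntensityMap",
    "read_probe_table",
    "write_probe_table",
    "read_intensities",
    "write_intensities",
    "pair_pm_mm",
]


@dataclass(frozen=True)
class ProbeRecord:
    """A single probe: 25-mer sequence at grid cell (x, y) within a probe set."""

    probe_set_id: str
    x: int
    y: int
    sequence: str
    role: str = ROLE_PM
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError(
                f"probe at ({self.x}, {self.y}): sequence length "
                f"{len(self.sequence)} != {PROBE_LENGTH}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError(
                f"probe at ({self.x}, {self.y}): sequence contains "
                "non-ACGT characters"
            )
        if self.role not in (ROLE_PM, ROLE_MM):
            raise ValueError(f"unknown probe role {self.role!r}")


class IntensityMap(NamedTuple):
    """Per-cell intensities plus the grid dimensions they live on."""

    values: dict[tuple[int, int], float]
    n_cols: int
    n_rows: int


@dataclass
class ChipData:
    """In-memory chip model: probes, their intensities and set membership."""

    probes: list[ProbeRecord]
    intensities: dict[tuple[int, int], float]
    n_cols: int
    n_rows: int
    probe_sets: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.probe_sets:
            sets: dict[str, list[int]] = {}
            for i, probe in enumerate(self.probes):
                sets.setdefault(probe.probe_set_id, []).append(i)
            self.probe_sets = sets
        seen: set[tuple[int, int]] = set()
        for probe in self.probes:
            key = (probe.x, probe.y)
            if key in seen:
                raise ValueError(f"duplicate probe coordinate {key}")
            seen.add(key)
            if not (0 <= probe.x < self.n_cols and 0 <= probe.y < self.n_rows):
                raise ValueError(
                    f"probe at {key} lies outside the {self.n_cols}x{self.n_rows} grid"
                )

    @classmethod
    def assemble(
        cls,
        probes: Iterable[ProbeRecord],
        intensities: IntensityMap | dict[tuple[int, int], float],
        n_cols: int | None = None,
        n_rows: int | None = None,
    ) -> "ChipData":
        probes = list(probes)
        if isinstance(intensities, IntensityMap):
            values, cols, rows = intensities
            n_cols = cols if n_cols is None else n_cols
            n_rows = rows if n_rows is None else n_rows
        else:
            values = dict(intensities)
        if n_cols is None or n_rows is None:
            n_cols = 1 + max(p.x for p in probes)
            n_rows = 1 + max(p.y for p in probes)
        return cls(probes=probes, intensities=values, n_cols=n_cols, n_rows=n_rows)

    # -- vectorized accessors -------------------------------------------------

    def intensity_array(self) -> np.ndarray:
        """Raw intensities aligned with ``self.probes``."""
        try:
            return np.array(
                [self.intensities[(p.x, p.y)] for p in self.probes], dtype=float
            )
        except KeyError as exc:
            raise KeyError(f"no intensity for probe at {exc.args[0]}") from exc

    def sequence_codes(self) -> np.ndarray:
        return encode_many([p.sequence for p in self.probes])

    def set_index(self) -> tuple[np.ndarray, list[str]]:
        """Probe-set membership as (per-probe integer labels, set names)."""
        names = list(self.probe_sets)
        lookup = {name: i for i, name in enumerate(names)}
        labels = np.array([lookup[p.probe_set_id] for p in self.probes], dtype=np.int64)
        return labels, names

    def probe_mask(self, set_ids: Iterable[str]) -> np.ndarray:
        wanted = set(set_ids)
        return np.array([p.probe_set_id in wanted for p in self.probes], dtype=bool)


# ---------------------------------------------------------------------------
# probe tables
# ---------------------------------------------------------------------------

_SET_COLUMNS = ("probe set name", "probe_set_id", "probeset_id", "probe set id")
_X_COLUMNS = ("probe x", "x", "probe_x")
_Y_COLUMNS = ("probe y", "y", "probe_y")
_SEQ_COLUMNS = ("probe sequence", "sequence", "probe_sequence")
_ROLE_COLUMNS = ("probe type", "role", "probe interrogation type")
_PAIR_COLUMNS = ("pair_id", "pair id")


def _find_column(header: list[str], candidates: tuple[str, ...], what: str) -> int:
    lowered = [h.strip().lower() for h in header]
    for cand in candidates:
        if cand in lowered:
            return lowered.index(cand)
    raise ValueError(f"probe table header lacks a {what} column (header: {header})")


def _maybe_column(header: list[str], candidates: tuple[str, ...]) -> int | None:
    lowered = [h.strip().lower() for h in header]
    for cand in candidates:
        if cand in lowered:
            return lowered.index(cand)
    return None


def read_probe_table(path: str | Path, dialect: str = "affy_tab") -> list[ProbeRecord]:
    """Read a probe annotation table into :class:`ProbeRecord` objects.

    Both dialects are tab-separated with a header line naming probe-set,
    x, y and sequence columns; a role column (PM/MM) is honoured when present,
    otherwise every probe is taken as PM.
    """
    if dialect not in ("affy_tab", "tsv"):
        raise ValueError(f"unknown probe table dialect {dialect!r}")
    path = Path(path)
    records: list[ProbeRecord] = []
    with path.open("r", encoding="ascii", errors="strict") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        i_set = _find_column(header, _SET_COLUMNS, "probe-set")
        i_x = _find_column(header, _X_COLUMNS, "x")
        i_y = _find_column(header, _Y_COLUMNS, "y")
        i_seq = _find_column(header, _SEQ_COLUMNS, "sequence")
        i_role = _maybe_column(header, _ROLE_COLUMNS)
        i_pair = _maybe_column(header, _PAIR_COLUMNS)
        n_fields = len(header)
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {n_fields} fields, "
                    f"got {len(fields)}"
                )
            try:
                record = ProbeRecord(
                    probe_set_id=fields[i_set],
                    x=int(fields[i_x]),
                    y=int(fields[i_y]),
                    sequence=fields[i_seq].upper(),
                    role=fields[i_role].upper() if i_role is not None else ROLE_PM,
                    pair_id=(fields[i_pair] or None) if i_pair is not None else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
            records.append(record)
    return records


def write_probe_table(records: Iterable[ProbeRecord], path: str | Path) -> None:
    """Write probes in the Affymetrix probe-tab dialect (with a role column)."""
    path = Path(path)
    with path.open("w", encoding="ascii") as handle:
        handle.write(
            "Probe Set Name\tProbe X\tProbe Y\tProbe Sequence\tProbe Type\tPair Id\n"
        )
        for rec in records:
            handle.write(
                f"{rec.probe_set_id}\t{rec.x}\t{rec.y}\t{rec.sequence}\t"
                f"{rec.role}\t{rec.pair_id if rec.pair_id is not None else ''}\n"
            )


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------


def _reject_binary(path: Path) -> None:
    with path.open("rb") as handle:
        head = handle.read(512)
    if b"\x00" in head or (head and head[0] not in b"[xX0123456789 \t\r\n#"):
        raise ValueError(
            f"{path.name}: not an ASCII file; binary CEL (v4/AGCC) is not "
            "supported, convert to the text CEL v3 dialect first"
        )


def read_intensities(path: str | Path, format: str = "cel_ascii") -> IntensityMap:
    """Read probe intensities (the CEL MEAN column, or a TSV intensity column)."""
    path = Path(path)
    _reject_binary(path)
    if format == "cel_ascii":
        return _read_cel_ascii(path)
    if format == "tsv":
        return _read_intensity_tsv(path)
    raise ValueError(f"unknown intensity format {format!r}")


def _read_cel_ascii(path: Path) -> IntensityMap:
    text = path.read_text(encoding="ascii")
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            current = sections.setdefault(stripped[1:-1].upper(), [])
        elif current is not None:
            current.append(line)
    for section in ("CEL", "HEADER", "INTENSITY"):
        if section not in sections:
            raise ValueError(f"{path.name}: missing [{section}] section")

    header = {}
    for line in sections["HEADER"]:
        if "=" in line:
            key, _, value = line.partition("=")
            header[key.strip().lower()] = value.strip()
    try:
        n_cols = int(header["cols"])
        n_rows = int(header["rows"])
    except KeyError as exc:
        raise ValueError(f"{path.name}: [HEADER] lacks {exc.args[0]!r}") from exc

    n_cells: int | None = None
    values: dict[tuple[int, int], float] = {}
    for line in sections["INTENSITY"]:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower().startswith("numbercells="):
            n_cells = int(stripped.partition("=")[2])
            continue
        if stripped.lower().startswith("cellheader="):
            continue
        fields = stripped.split()
        if len(fields) < 3:
            raise ValueError(f"{path.name}: malformed intensity row {stripped!r}")
        x, y, mean = int(fields[0]), int(fields[1]), float(fields[2])
        if mean < 0:
            raise ValueError(f"{path.name}: negative intensity at ({x}, {y})")
        values[(x, y)] = mean
    if n_cells is None:
        raise ValueError(f"{path.name}: [INTENSITY] lacks NumberCells")
    if len(values) != n_cells:
        raise ValueError(
            f"{path.name}: NumberCells={n_cells} but {len(values)} rows parsed"
        )
    return IntensityMap(values, n_cols, n_rows)


def _read_intensity_tsv(path: Path) -> IntensityMap:
    values: dict[tuple[int, int], float] = {}
    with path.open("r", encoding="ascii") as handle:
        header = [h.strip().lower() for h in handle.readline().rstrip("\n").split("\t")]
        try:
            i_x, i_y = header.index("x"), header.index("y")
            i_val = header.index("intensity")
        except ValueError as exc:
            raise ValueError(
                f"{path.name}: TSV header must name x, y and intensity columns"
            ) from exc
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            x, y, value = int(fields[i_x]), int(fields[i_y]), float(fields[i_val])
            if value < 0:
                raise ValueError(f"{path.name}:{lineno}: negative intensity")
            values[(x, y)] = value
    if not values:
        raise ValueError(f"{path.name}: no intensity rows")
    n_cols = 1 + max(x for x, _ in values)
    n_rows = 1 + max(y for _, y in values)
    return IntensityMap(values, n_cols, n_rows)


def write_intensities(chip: ChipData, path: str | Path, format: str = "cel_ascii") -> None:
    """Write chip intensities re-readably; round trips hold to 6 significant digits."""
    path = Path(path)
    if not chip.intensities:
        raise ValueError("chip has no intensities to write")
    items = sorted(chip.intensities.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    if format == "cel_ascii":
        with path.open("w", encoding="ascii") as handle:
            handle.write("[CEL]\nVersion=3\n\n[HEADER]\n")
            handle.write(f"Cols={chip.n_cols}\nRows={chip.n_rows}\n\n")
            handle.write("[INTENSITY]\n")
            handle.write(f"NumberCells={len(items)}\n")
            handle.write("CellHeader=X\tY\tMEAN\tSTDV\tNPIXELS\n")
            for (x, y), value in items:
                handle.write(f"{x}\t{y}\t{value:.8g}\t0\t1\n")
    elif format == "tsv":
        with path.open("w", encoding="ascii") as handle:
            handle.write("x\ty\tintensity\n")
            for (x, y), value in items:
                handle.write(f"{x}\t{y}\t{value:.8g}\n")
    else:
        raise ValueError(f"unknown intensity format {format!r}")


# ---------------------------------------------------------------------------
# PM/MM pairing
# ---------------------------------------------------------------------------


def _check_pair(pm: ProbeRecord, mm: ProbeRecord) -> None:
    mid = MIDDLE_POSITION - 1
    for i, (a, b) in enumerate(zip(pm.sequence, mm.sequence)):
        if i == mid:
            continue
        if a != b:
            raise ValueError(
                f"PM at ({pm.x}, {pm.y}) and MM at ({mm.x}, {mm.y}) differ at "
                f"position {i + 1}; only the middle base ({MIDDLE_POSITION}) may differ"
            )
    if mm.sequence[mid] != complement(pm.sequence[mid]):
        raise ValueError(
            f"MM at ({mm.x}, {mm.y}) does not carry the complemented middle base "
            f"of its PM at ({pm.x}, {pm.y})"
        )


def pair_pm_mm(probes: Iterable[ProbeRecord]) -> list[tuple[ProbeRecord, ProbeRecord]]:
    """Pair each PM probe with its MM partner.

    Explicit roles (and pair ids) take precedence; otherwise the GeneChip
    layout convention is used: the MM sits directly below its PM at
    ``(x, y + 1)`` with PM probes on even rows.
    """
    probes = list(probes)
    explicit = any(p.role == ROLE_MM for p in probes)
    by_pos = {(p.x, p.y): p for p in probes}
    pairs: list[tuple[ProbeRecord, ProbeRecord]] = []
    if explicit:
        for probe in probes:
            if probe.role != ROLE_PM:
                continue
            mm = by_pos.get((probe.x, probe.y + 1))
            if mm is None or mm.role != ROLE_MM:
                raise ValueError(
                    f"PM at ({probe.x}, {probe.y}) has no MM partner at "
                    f"({probe.x}, {probe.y + 1})"
                )
            _check_pair(probe, mm)
            pairs.append((probe, mm))
    else:
        for probe in probes:
            if probe.y % 2 != 0:
                continue
            mm = by_pos.get((probe.x, probe.y + 1))
            if mm is None:
                raise ValueError(
                    f"probe at ({probe.x}, {probe.y}) has no partner at "
                    f"({probe.x}, {probe.y + 1})"
                )
            _check_pair(probe, mm)
            pairs.append((probe, mm))
    return pairs
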