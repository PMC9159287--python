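"""Reflection-file I/O and the in-memory observation container.

Three dialects are supported:

* a minimal XDS_ASCII.HKL reader (header lines starting with ``!`` carrying
  ``SPACE_GROUP_NUMBER`` and ``UNIT_CELL_CONSTANTS``, then whitespace-separated
  ``H K L IOBS SIGMA(IOBS)`` records),
* an internal TSV format (three comment header lines: space group, unit cell,
  column names) used by the simulator,
* a SHELX HKLF-4 fixed-width writer for merged groups (input to downstream
  substructure/phasing programs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cells import UnitCell
from .symmetry import SymmetrySetting, get_symmetry, map_to_asu, space_group_number

log = logging.getLogger("ssir")

__all__ = [
    "ObservationTable",
    "FormatError",
    "read_xds_ascii",
    "read_internal",
    "write_internal",
    "write_xds_ascii",
    "read_pool",
    "write_pool",
    "write_shelx_hkl",
    "read_shelx_hkl",
]

OBS_COLUMNS = ["dataset_id", "h", "k", "l", "intensity", "sigma"]


class FormatError(ValueError):
    """Raised for malformed or unsupported reflection files."""


@dataclass
class ObservationTable:
    """Unmerged reflection observations from one or more partial datasets.

    ``df`` has columns dataset_id, h, k, l, intensity, sigma; every record
    has sigma > 0 and all datasets share one space-group setting.  Per-dataset
    unit cells live in ``cells``.
    """

    df: pd.DataFrame
    cells: dict[str, UnitCell]
    symmetry: SymmetrySetting
    _asu: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        if len(self.df) and not (self.df["sigma"] > 0).all():
            raise ValueError("all sigmas must be positive")
        ids = set(self.df["dataset_id"].unique())
        if ids - set(self.cells):
            raise ValueError("every dataset_id needs a unit cell")

    @property
    def dataset_ids(self) -> list[str]:
        return sorted(self.cells)

    @property
    def n_datasets(self) -> int:
        return len(self.cells)

    def __len__(self) -> int:
        return len(self.df)

    def mean_cell(self) -> UnitCell:
        arr = np.array([self.cells[d].as_tuple() for d in self.dataset_ids])
        return UnitCell(*arr.mean(axis=0))

    def asu_hkl(self) -> np.ndarray:
        """(N,3) ASU-mapped indices for every observation (cached)."""
        if self._asu is None or len(self._asu) != len(self.df):
            hkl = self.df[["h", "k", "l"]].to_numpy(dtype=np.int64)
            object.__setattr__(self, "_asu", map_to_asu(hkl, sym=self.symmetry))
        return self._asu

    def subset(self, dataset_ids: Iterable[str]) -> "ObservationTable":
        ids = set(dataset_ids)
        mask = self.df["dataset_id"].isin(ids).to_numpy()
        return ObservationTable(
            self.df.loc[mask].reset_index(drop=True),
            {d: c for d, c in self.cells.items() if d in ids},
            self.symmetry,
        )

    @classmethod
    def concat(cls, tables: Iterable["ObservationTable"]) -> "ObservationTable":
        tables = list(tables)
        if not tables:
            raise ValueError("nothing to concatenate")
        sym = tables[0].symmetry
        for t in tables[1:]:
            if t.symmetry.space_group_symbol != sym.space_group_symbol:
                raise ValueError("datasets in one pool must share a space group")
        df = pd.concat([t.df for t in tables], ignore_index=True)
        cells: dict[str, UnitCell] = {}
        for t in tables:
            cells.update(t.cells)
        return cls(df, cells, sym)


def _parse_records(lines, path, start_line=1):
    rows = []
    n_dropped = 0
    for lineno, line in lines:
        parts = line.split()
        if len(parts) < 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        try:
            h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
            i, s = float(parts[3]), float(parts[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric record: {line.strip()!r}") from exc
        if s <= 0:
            n_dropped += 1
            continue
        rows.append((h, k, l, i, s))
    if n_dropped:
        log.info("%s: dropped %d records with sigma <= 0", path, n_dropped)
    return rows


def read_xds_ascii(path) -> ObservationTable:
    """Read one partial dataset from an XDS_ASCII.HKL-style file.

    Only SPACE_GROUP_NUMBER and UNIT_CELL_CONSTANTS are honoured in the
    header; all other ``!`` lines are ignored.  The dataset_id is the file
    stem.  Records with sigma <= 0 are dropped (count logged).
    """
    path = Path(path)
    sg_number = None
    cell = None
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("!"):
                body = line[1:].strip()
                if body.startswith("SPACE_GROUP_NUMBER"):
                    try:
                        sg_number = int(body.split("=", 1)[1].split()[0])
                    except (IndexError, ValueError) as exc:
                        raise FormatError(f"{path}:{lineno}: bad SPACE_GROUP_NUMBER") from exc
                elif body.startswith("UNIT_CELL_CONSTANTS"):
                    try:
                        vals = [float(x) for x in body.split("=", 1)[1].split()[:6]]
                        cell = UnitCell(*vals)
                    except (IndexError, ValueError, TypeError) as exc:
                        raise FormatError(f"{path}:{lineno}: bad UNIT_CELL_CONSTANTS") from exc
                elif body.startswith("END_OF_DATA"):
                    break
                continue
            records.append((lineno, line))
    if sg_number is None:
        raise FormatError(f"{path}: missing mandatory header key SPACE_GROUP_NUMBER")
    if cell is None:
        raise FormatError(f"{path}: missing mandatory header key UNIT_CELL_CONSTANTS")
    rows = _parse_records(records, path)
    dataset_id = path.stem
    df = pd.DataFrame(rows, columns=["h", "k", "l", "intensity", "sigma"])
    df.insert(0, "dataset_id", dataset_id)
    if df.empty:
        raise FormatError(f"{path}: no valid observations")
    return ObservationTable(df, {dataset_id: cell}, get_symmetry(sg_number))


def write_xds_ascii(table: ObservationTable, directory) -> list[Path]:
    """Write one XDS-dialect file per dataset; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    sg = space_group_number(table.symmetry.space_group_symbol)
    for ds in table.dataset_ids:
        cell = table.cells[ds]
        sub = table.df[table.df["dataset_id"] == ds]
        p = directory / f"{ds}.HKL"
        with open(p, "w") as fh:
            fh.write("!FORMAT=XDS_ASCII    MERGE=FALSE\n")
            fh.write(f"!SPACE_GROUP_NUMBER= {sg}\n")
            fh.write(
                "!UNIT_CELL_CONSTANTS= "
                + " ".join(f"{v:.4f}" for v in cell.as_tuple())
                + "\n"
            )
            fh.write("!END_OF_HEADER\n")
            for h, k, l, i, s in sub[["h", "k", "l", "intensity", "sigma"]].itertuples(index=False):
                fh.write(f"{int(h):6d}{int(k):6d}{int(l):6d} {i:14.4f} {s:12.4f}\n")
            fh.write("!END_OF_DATA\n")
        paths.append(p)
    return paths


def write_internal(table: ObservationTable, directory) -> list[Path]:
    """Write the internal TSV dialect, one file per dataset."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in table.dataset_ids:
        cell = table.cells[ds]
        sub = table.df[table.df["dataset_id"] == ds]
        p = directory / f"{ds}.tsv"
        with open(p, "w") as fh:
            fh.write(f"# space_group: {table.symmetry.space_group_symbol}\n")
            fh.write("# unit_cell: " + " ".join(f"{v:.6f}" for v in cell.as_tuple()) + "\n")
            fh.write("h\tk\tl\tintensity\tsigma\n")
            for h, k, l, i, s in sub[["h", "k", "l", "intensity", "sigma"]].itertuples(index=False):
                fh.write(f"{int(h)}\t{int(k)}\t{int(l)}\t{i:.6f}\t{s:.6f}\n")
        paths.append(p)
    return paths


def read_internal(path) -> ObservationTable:
    """Read one internal-TSV dataset file."""
    path = Path(path)
    with open(path) as fh:
        line1 = fh.readline().strip()
        line2 = fh.readline().strip()
        line3 = fh.readline().strip()
        if not line1.startswith("# space_group:"):
            raise FormatError(f"{path}: missing '# space_group:' header")
        if not line2.startswith("# unit_cell:"):
            raise FormatError(f"{path}: missing '# unit_cell:' header")
        symbol = line1.split(":", 1)[1].strip()
        try:
            cell = UnitCell(*[float(x) for x in line2.split(":", 1)[1].split()])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}:2: bad unit cell") from exc
        if line3.split("\t") != ["h", "k", "l", "intensity", "sigma"]:
            raise FormatError(f"{path}:3: unexpected column names")
        rows = _parse_records(((i + 4, ln) for i, ln in enumerate(fh) if ln.strip()), path)
    dataset_id = path.stem
    df = pd.DataFrame(rows, columns=["h", "k", "l", "intensity", "sigma"])
    df.insert(0, "dataset_id", dataset_id)
    if df.empty:
        raise FormatError(f"{path}: no valid observations")
    return ObservationTable(df, {dataset_id: cell}, get_symmetry(symbol))


def read_pool(directory) -> ObservationTable:
    """Read every dataset file (``*.tsv`` internal or ``*.HKL`` XDS) in a directory."""
    directory = Path(directory)
    tables = []
    failures = []
    for p in sorted(directory.iterdir()):
        try:
            if p.suffix == ".tsv":
                tables.append(read_internal(p))
            elif p.suffix.upper() == ".HKL":
                tables.append(read_xds_ascii(p))
        except FormatError as exc:
            failures.append(str(exc))
    if failures:
        log.warning("unreadable inputs:\n%s", "\n".join(failures))
    if not tables:
        raise FormatError(f"no readable dataset files in {directory}")
    return ObservationTable.concat(tables)


def write_pool(table: ObservationTable, directory, fmt: str = "internal") -> list[Path]:
    if fmt == "internal":
        return write_internal(table, directory)
    if fmt == "xds":
        return write_xds_ascii(table, directory)
    raise ValueError(f"unknown pool format {fmt!r}")


def write_shelx_hkl(merged, path) -> Path:
    """Write a merged group in SHELX HKLF-4 fixed width (3I4, 2F8.2).

    Terminated by the conventional all-zero record.  Raises FormatError on
    field overflow (|h|,|k|,|l| >= 1000 or intensity/sigma too wide).
    """
    path = Path(path)
    hkl = merged.hkl
    if len(hkl) == 0:
        raise FormatError("refusing to write an empty merged group")
    lines = []
    for (h, k, l), i, s in zip(hkl, merged.intensity, merged.sigma):
        if max(abs(int(h)), abs(int(k)), abs(int(l))) >= 1000:
            raise FormatError(f"index ({h},{k},{l}) does not fit HKLF-4 width 4")
        fi, fs = f"{i:8.2f}", f"{s:8.2f}"
        if len(fi) > 8 or len(fs) > 8:
            raise FormatError(f"intensity/sigma field overflow at ({h},{k},{l}): {i!r}, {s!r}")
        lines.append(f"{int(h):4d}{int(k):4d}{int(l):4d}{fi}{fs}")
    lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_shelx_hkl(path) -> pd.DataFrame:
    """Read back an HKLF-4 file (used for round-trip checks)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
        i, s = float(line[12:20]), float(line[20:28])
        if h == 0 and k == 0 and l == 0:
            break
        rows.append((h, k, l, i, s))
    return pd.DataFrame(rows, columns=["h", "k", "l", "intensity", "sigma"])
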