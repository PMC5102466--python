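"""Reading and writing plate fluorescence exports, rating tables and call tables.

Thermal cyclers export per-well, per-cycle fluorescence as flat text files
whose exact schema is proprietary and instrument-specific.  This module
defines two plain TSV dialects that carry the same information:

* ``wide``  — one row per well::

      plate  well  target  sample  c1  c2  ...  cN

* ``long``  — one row per well x cycle, either pre-normalized::

      plate  well  target  sample  cycle  rn

  or as raw reporter/passive-reference emissions (FAM at 520 nm, ROX at
  610 nm), which are normalized on read::

      plate  well  target  sample  cycle  fam  rox

Lines starting with ``#`` are treated as comments in every dialect.
Normalized fluorescence (Rn) is the reporter emission divided by the
passive-reference emission, cycle by cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PlateParseError",
    "NormalizationError",
    "RawWellRead",
    "AmplificationCurve",
    "RatingTable",
    "CallRecord",
    "normalize_fluorescence",
    "read_plate_export",
    "write_plate_export",
    "read_rating_table",
    "read_call_table",
    "write_call_table",
]

#: Text written in place of an undetermined quantity (e.g. a Cq with no
#: threshold crossing) in call tables.
NA = "NA"

MIN_CYCLES = 5


class PlateParseError(ValueError):
    """A plate, rating or call file does not conform to its dialect."""


class NormalizationError(ValueError):
    """Reporter/reference normalization is impossible (bad reference value)."""


def normalize_fluorescence(
    reporter: Sequence[float], reference: Sequence[float]
) -> np.ndarray:
    """Normalize reporter emission by the passive-reference emission.

    Parameters
    ----------
    reporter : sequence of float
        Reporter-dye emission (e.g. FAM, 520 nm), one value per cycle.
    reference : sequence of float
        Passive-reference emission (e.g. ROX, 610 nm), same length.

    Returns
    -------
    numpy.ndarray
        Rn, the element-wise ratio reporter/reference.

    Raises
    ------
    PlateParseError
        If the sequences differ in length.
    NormalizationError
        If any reference value is zero or negative; the message names the
        offending cycle (1-based).
    """
    rep = np.asarray(reporter, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if rep.shape != ref.shape or rep.ndim != 1:
        raise PlateParseError(
            f"reporter and reference lengths differ ({rep.size} vs {ref.size})"
        )
    bad = np.nonzero(ref <= 0)[0]
    if bad.size:
        cycle = int(bad[0]) + 1
        raise NormalizationError(
            f"reference emission is not positive at cycle {cycle}"
            f" (value {ref[bad[0]]!r})"
        )
    return rep / ref


@dataclass
class RawWellRead:
    """Raw two-channel emissions for one well, prior to normalization."""

    plate_id: str
    well_id: str
    target: str
    sample_id: str
    reporter_520: np.ndarray
    reference_610: np.ndarray

    def __post_init__(self) -> None:
        self.reporter_520 = np.asarray(self.reporter_520, dtype=float)
        self.reference_610 = np.asarray(self.reference_610, dtype=float)
        if self.reporter_520.shape != self.reference_610.shape:
            raise PlateParseError("reporter/reference length mismatch")
        if self.reporter_520.size < MIN_CYCLES:
            raise PlateParseError(
                f"need at least {MIN_CYCLES} cycles, got {self.reporter_520.size}"
            )
        if not (
            np.all(np.isfinite(self.reporter_520))
            and np.all(np.isfinite(self.reference_610))
        ):
            raise PlateParseError("non-finite emission value")

    def normalize(self) -> "AmplificationCurve":
        rn = normalize_fluorescence(self.reporter_520, self.reference_610)
        return AmplificationCurve(
            self.plate_id, self.well_id, self.target, self.sample_id, rn
        )


@dataclass
class AmplificationCurve:
    """Normalized fluorescence (Rn) of one reaction, indexed by cycle 1..N."""

    plate_id: str
    well_id: str
    target: str
    sample_id: str
    rn: np.ndarray

    def __post_init__(self) -> None:
        self.rn = np.asarray(self.rn, dtype=float)
        if self.rn.ndim != 1 or self.rn.size < MIN_CYCLES:
            raise PlateParseError(
                f"curve {self.well_id!r}: need at least {MIN_CYCLES} cycles,"
                f" got {self.rn.size}"
            )
        if not np.all(np.isfinite(self.rn)):
            raise PlateParseError(f"curve {self.well_id!r}: non-finite Rn value")

    @property
    def n_cycles(self) -> int:
        return int(self.rn.size)

    @property
    def cycles(self) -> np.ndarray:
        """1-based cycle indices."""
        return np.arange(1, self.n_cycles + 1)

    def key(self) -> tuple[str, str]:
        return (self.plate_id, self.well_id)


@dataclass
class RatingTable:
    """Per-well binary calls from one or more raters.

    ``calls[(plate, well)]`` is an ordered list with one 0/1 entry per rater,
    in the column order of ``raters``.
    """

    raters: list[str]
    calls: dict[tuple[str, str], list[int]]

    def __post_init__(self) -> None:
        if not self.raters:
            raise PlateParseError("rating table has no rater columns")
        for key, row in self.calls.items():
            if not row:
                raise PlateParseError(f"well {key} has no calls")
            if any(c not in (0, 1) for c in row):
                raise PlateParseError(f"well {key} has a non-binary call")

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.calls

    def __getitem__(self, key: tuple[str, str]) -> list[int]:
        return self.calls[key]


@dataclass
class CallRecord:
    """One row of the per-well call table."""

    plate_id: str
    well_id: str
    target: str
    sample_id: str
    cq: float | None = None
    fcn: float | None = None
    mr: float | None = None
    ct_call: int | None = None
    mr_call: int | None = None


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping comments/blanks."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _as_float(token: str, path: str | Path, lineno: int, what: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise PlateParseError(
            f"{path}: line {lineno}: non-numeric {what} {token!r}"
        ) from None
    if not math.isfinite(value):
        raise PlateParseError(f"{path}: line {lineno}: non-finite {what} {token!r}")
    return value


_WIDE_PREFIX = ["plate", "well", "target", "sample"]


def read_plate_export(
    path: str | Path, dialect: str = "wide"
) -> list[AmplificationCurve]:
    """Read a TSV plate export into a list of amplification curves.

    ``dialect`` is ``"wide"`` (one row per well) or ``"long"`` (one row per
    well x cycle; a ``fam``/``rox`` pair of columns is normalized on read).
    Cycle order is preserved; ``#`` comment lines are ignored.
    """
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = list(_data_lines(path))
    if not rows:
        raise PlateParseError(f"{path}: no data lines")
    header_lineno, header = rows[0]
    header = [h.strip().lower() for h in header]
    if header[: len(_WIDE_PREFIX)] != _WIDE_PREFIX:
        raise PlateParseError(
            f"{path}: line {header_lineno}: header must start with "
            + "\t".join(_WIDE_PREFIX)
        )
    body = rows[1:]
    if dialect == "wide":
        return _read_wide(path, header, body)
    return _read_long(path, header, body)


def _read_wide(path, header, body) -> list[AmplificationCurve]:
    n_cycles = len(header) - len(_WIDE_PREFIX)
    if n_cycles < MIN_CYCLES:
        raise PlateParseError(f"{path}: wide header lists {n_cycles} cycle columns")
    curves = []
    for lineno, fields in body:
        if len(fields) != len(header):
            raise PlateParseError(
                f"{path}: line {lineno}: expected {len(header)} columns,"
                f" got {len(fields)} (ragged cycle counts)"
            )
        plate, well, target, sample = (f.strip() for f in fields[:4])
        rn = [
            _as_float(tok, path, lineno, "fluorescence") for tok in fields[4:]
        ]
        curves.append(AmplificationCurve(plate, well, target, sample, np.array(rn)))
    return curves


def _read_long(path, header, body) -> list[AmplificationCurve]:
    tail = header[4:]
    if tail[:1] != ["cycle"]:
        raise PlateParseError(f"{path}: long header must have a 'cycle' column")
    if tail[1:] == ["rn"]:
        raw_channels = False
    elif tail[1:] == ["fam", "rox"]:
        raw_channels = True
    else:
        raise PlateParseError(
            f"{path}: long header must end with 'rn' or 'fam\\trox'"
        )
    per_well: dict[tuple, dict] = {}
    for lineno, fields in body:
        if len(fields) != len(header):
            raise PlateParseError(
                f"{path}: line {lineno}: expected {len(header)} columns,"
                f" got {len(fields)}"
            )
        plate, well, target, sample = (f.strip() for f in fields[:4])
        cycle = int(_as_float(fields[4], path, lineno, "cycle"))
        entry = per_well.setdefault(
            (plate, well), {"target": target, "sample": sample, "cycles": {}}
        )
        if cycle in entry["cycles"]:
            raise PlateParseError(
                f"{path}: line {lineno}: duplicate cycle {cycle} for well {well}"
            )
        if raw_channels:
            fam = _as_float(fields[5], path, lineno, "fam emission")
            rox = _as_float(fields[6], path, lineno, "rox emission")
            entry["cycles"][cycle] = (fam, rox)
        else:
            entry["cycles"][cycle] = _as_float(fields[5], path, lineno, "rn")
    counts = {len(e["cycles"]) for e in per_well.values()}
    if len(counts) > 1:
        raise PlateParseError(
            f"{path}: ragged cycle counts across wells: {sorted(counts)}"
        )
    curves = []
    for (plate, well), entry in per_well.items():
        cycles = sorted(entry["cycles"])
        if cycles != list(range(1, len(cycles) + 1)):
            raise PlateParseError(
                f"{path}: well {well}: cycles are not contiguous from 1"
            )
        values = [entry["cycles"][c] for c in cycles]
        if raw_channels:
            fam = [v[0] for v in values]
            rox = [v[1] for v in values]
            rn = normalize_fluorescence(fam, rox)
        else:
            rn = np.array(values)
        curves.append(
            AmplificationCurve(plate, well, entry["target"], entry["sample"], rn)
        )
    curves.sort(key=lambda c: (c.plate_id, c.well_id))
    return curves


def write_plate_export(
    curves: Sequence[AmplificationCurve], path: str | Path, dialect: str = "wide"
) -> None:
    """Write curves as a TSV plate export (full ``repr`` precision)."""
    curves = sorted(curves, key=lambda c: (c.plate_id, c.well_id))
    if not curves:
        raise ValueError("no curves to write")
    n = curves[0].n_cycles
    if any(c.n_cycles != n for c in curves):
        raise ValueError("curves have differing cycle counts")
    with open(path, "wt", encoding="utf-8") as fh:
        if dialect == "wide":
            header = _WIDE_PREFIX + [f"c{i}" for i in range(1, n + 1)]
            fh.write("\t".join(header) + "\n")
            for c in curves:
                row = [c.plate_id, c.well_id, c.target, c.sample_id]
                row += [repr(float(v)) for v in c.rn]
                fh.write("\t".join(row) + "\n")
        elif dialect == "long":
            fh.write("\t".join(_WIDE_PREFIX + ["cycle", "rn"]) + "\n")
            for c in curves:
                for cyc, v in zip(c.cycles, c.rn):
                    fh.write(
                        "\t".join(
                            [
                                c.plate_id,
                                c.well_id,
                                c.target,
                                c.sample_id,
                                str(int(cyc)),
                                repr(float(v)),
                            ]
                        )
                        + "\n"
                    )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


_CALL_ALIASES = {"1": 1, "0": 0, "positive": 1, "negative": 0, "pos": 1, "neg": 0}


def read_rating_table(path: str | Path) -> RatingTable:
    """Read a TSV rating table: columns ``plate  well  <rater> ...``.

    Cells may be ``0``/``1`` or ``positive``/``negative`` (case-insensitive).
    """
    rows = list(_data_lines(path))
    if not rows:
        raise PlateParseError(f"{path}: no data lines")
    _, header = rows[0]
    header = [h.strip() for h in header]
    if len(header) < 3 or [h.lower() for h in header[:2]] != ["plate", "well"]:
        raise PlateParseError(
            f"{path}: rating header must be plate\\twell\\t<rater>..."
        )
    raters = header[2:]
    calls: dict[tuple[str, str], list[int]] = {}
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise PlateParseError(
                f"{path}: line {lineno}: expected {len(header)} columns,"
                f" got {len(fields)}"
            )
        key = (fields[0].strip(), fields[1].strip())
        row = []
        for tok in fields[2:]:
            call = _CALL_ALIASES.get(tok.strip().lower())
            if call is None:
                raise PlateParseError(
                    f"{path}: line {lineno}: non-binary rating {tok!r}"
                )
            row.append(call)
        calls[key] = row
    return RatingTable(raters=raters, calls=calls)


_CALL_COLUMNS = [
    "plate",
    "well",
    "target",
    "sample",
    "cq",
    "fcn",
    "mr",
    "ct_call",
    "mr_call",
]


def _fmt(value) -> str:
    if value is None:
        return NA
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return repr(float(value))


def write_call_table(records: Iterable[CallRecord], path: str | Path) -> None:
    """Write per-well results as TSV, one row per well.

    Rows are sorted by (plate, well); undetermined values print as ``NA``.
    """
    records = sorted(records, key=lambda r: (r.plate_id, r.well_id))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.plate_id,
                        r.well_id,
                        r.target,
                        r.sample_id,
                        _fmt(r.cq),
                        _fmt(r.fcn),
                        _fmt(r.mr),
                        _fmt(r.ct_call),
                        _fmt(r.mr_call),
                    ]
                )
                + "\n"
            )


def read_call_table(path: str | Path) -> list[CallRecord]:
    """Read back a call table written by :func:`write_call_table`."""
    rows = list(_data_lines(path))
    if not rows:
        raise PlateParseError(f"{path}: no data lines")
    _, header = rows[0]
    if [h.strip().lower() for h in header] != _CALL_COLUMNS:
        raise PlateParseError(f"{path}: unexpected call-table header")
    records = []
    for lineno, fields in rows[1:]:
        if len(fields) != len(_CALL_COLUMNS):
            raise PlateParseError(
                f"{path}: line {lineno}: expected {len(_CALL_COLUMNS)} columns"
            )
        plate, well, target, sample = (f.strip() for f in fields[:4])

        def opt_float(tok: str) -> float | None:
            tok = tok.strip()
            return None if tok == NA else _as_float(tok, path, lineno, "value")

        def opt_int(tok: str) -> int | None:
            tok = tok.strip()
            if tok == NA:
                return None
            if tok not in ("0", "1"):
                raise PlateParseError(
                    f"{path}: line {lineno}: non-binary call {tok!r}"
                )
            return int(tok)

        records.append(
            CallRecord(
                plate,
                well,
                target,
                sample,
                cq=opt_float(fields[4]),
                fcn=opt_float(fields[5]),
                mr=opt_float(fields[6]),
                ct_call=opt_int(fields[7]),
                mr_call=opt_int(fields[8]),
            )
        )
    return records
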