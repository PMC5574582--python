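"""Core data structures for mark-recapture capture histories.

A capture history records, for each individual and each sampling period,
whether the individual was detected (0/1).  Everything downstream — the
closed-population estimators, the robust-design composite, and the tests of
equal catchability — consumes either a :class:`CaptureMatrix` or the
capture-frequency summary :class:`FrequencyTable` (the counts ``f_i`` of
individuals captured exactly ``i`` times, which is the sufficient statistic
for all the closed-population models implemented here).

Two interchange formats are supported:

* a delimited text format (one row per observed individual:
  ``id, sex, p1, ..., pt``), with optional ``#``-prefixed metadata lines, and
* the MARK ``.inp`` encounter-history format with two group-frequency
  columns (males first, then females), ``;``-terminated records and
  ``/* ... */`` comments.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "SexLabel",
    "CaptureMatrix",
    "FrequencyTable",
    "MarkedCounts",
    "CaptureFormatError",
    "build_frequency_table",
    "marked_counts",
    "collapse_primaries",
    "write_capture_file",
    "read_capture_file",
]


class SexLabel(str, Enum):
    """Sex of an individual; exactly two levels."""

    MALE = "male"
    FEMALE = "female"


class CaptureFormatError(ValueError):
    """Raised for malformed capture-history files; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _as_sex_array(sex) -> np.ndarray:
    out = np.asarray(
        [s.value if isinstance(s, SexLabel) else str(s) for s in sex], dtype="U6"
    )
    bad = set(out.tolist()) - {SexLabel.MALE.value, SexLabel.FEMALE.value}
    if bad:
        raise ValueError(f"invalid sex labels: {sorted(bad)}")
    return out


@dataclass
class CaptureMatrix:
    """Binary individuals x periods detection matrix with per-row sex labels.

    Parameters
    ----------
    detections
        0/1 integer array of shape ``(n_individuals, n_periods)``.
    sex
        One :class:`SexLabel` (or its string value) per row.
    ids
        Optional individual identifiers (defaults to ``0..n-1``).
    period_labels
        Optional ordered period identifiers (defaults to ``p1..pt``).
    primary_blocks
        Optional tuple of consecutive primary-period block sizes summing to
        the number of columns (robust-design metadata), e.g. ``(3, 3, 3, 3)``.
    """

    detections: np.ndarray
    sex: np.ndarray
    ids: np.ndarray | None = None
    period_labels: tuple[str, ...] | None = None
    primary_blocks: tuple[int, ...] | None = None

    def __post_init__(self):
        det = np.asarray(self.detections)
        if det.ndim != 2:
            raise ValueError("detections must be a 2-D array")
        if det.size and not np.isin(det, (0, 1)).all():
            raise ValueError("detections must be binary (0/1)")
        self.detections = det.astype(np.int8)
        self.sex = _as_sex_array(self.sex)
        if len(self.sex) != det.shape[0]:
            raise ValueError("one sex label required per individual (row)")
        if self.ids is None:
            self.ids = np.arange(det.shape[0])
        else:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != det.shape[0]:
                raise ValueError("one id required per row")
        if self.period_labels is None:
            self.period_labels = tuple(f"p{j + 1}" for j in range(det.shape[1]))
        else:
            self.period_labels = tuple(str(p) for p in self.period_labels)
            if len(self.period_labels) != det.shape[1]:
                raise ValueError("one period label required per column")
        if self.primary_blocks is not None:
            blocks = tuple(int(b) for b in self.primary_blocks)
            if any(b < 1 for b in blocks) or sum(blocks) != det.shape[1]:
                raise ValueError(
                    "primary_blocks must be positive sizes covering all columns"
                )
            self.primary_blocks = blocks

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def n_periods(self) -> int:
        return self.detections.shape[1]

    def capture_counts(self) -> np.ndarray:
        """Number of periods each individual was detected in."""
        return self.detections.sum(axis=1)

    def is_male(self) -> np.ndarray:
        return self.sex == SexLabel.MALE.value

    def subset(self, rows) -> "CaptureMatrix":
        rows = np.asarray(rows)
        return CaptureMatrix(
            self.detections[rows],
            self.sex[rows],
            ids=self.ids[rows],
            period_labels=self.period_labels,
            primary_blocks=self.primary_blocks,
        )


@dataclass
class FrequencyTable:
    """Counts ``f_i`` of individuals captured exactly ``i`` times in ``t`` periods."""

    t: int
    f: np.ndarray

    def __post_init__(self):
        self.t = int(self.t)
        if self.t < 2:
            raise ValueError("at least two sampling periods required (t >= 2)")
        f = np.asarray(self.f)
        if len(f) != self.t:
            raise ValueError("f must have length t (counts for i = 1..t)")
        if (f < 0).any() or not np.issubdtype(f.dtype, np.integer) and not (
            f == np.round(f)
        ).all():
            raise ValueError("f_i must be nonnegative integers")
        self.f = f.astype(np.int64)

    @property
    def n(self) -> int:
        """Number of distinct individuals observed."""
        return int(self.f.sum())

    @property
    def total_captures(self) -> int:
        """Grand total of captures, sum over i of i * f_i."""
        return int((np.arange(1, self.t + 1) * self.f).sum())


@dataclass(frozen=True)
class MarkedCounts:
    """Distinct marked individuals per sex and the naive marked sex ratio."""

    males_marked: int
    females_marked: int

    @property
    def marked_ratio(self) -> float:
        """Marked males per marked female; NaN when no female was marked."""
        if self.females_marked == 0:
            return float("nan")
        return self.males_marked / self.females_marked

    @property
    def ratio_defined(self) -> bool:
        return self.females_marked > 0


def build_frequency_table(matrix: CaptureMatrix, rows=None) -> FrequencyTable:
    """Summarise a capture matrix into its capture-frequency table.

    Rows with no detections carry no information for the closed-population
    models and are dropped with a warning; if every selected row is empty a
    ``ValueError`` is raised.
    """
    counts = matrix.capture_counts()
    if rows is not None:
        counts = counts[np.asarray(rows)]
    if counts.size == 0 or (counts == 0).all():
        raise ValueError("no observed individuals (all capture histories empty)")
    if (counts == 0).any():
        warnings.warn(
            f"dropping {(counts == 0).sum()} all-zero capture histories",
            stacklevel=2,
        )
        counts = counts[counts > 0]
    t = matrix.n_periods
    f = np.bincount(counts, minlength=t + 1)[1:]
    return FrequencyTable(t=t, f=f)


def marked_counts(matrix: CaptureMatrix) -> MarkedCounts:
    """Distinct captured (marked) individuals of each sex."""
    seen = matrix.capture_counts() >= 1
    male = matrix.is_male()
    return MarkedCounts(
        males_marked=int((seen & male).sum()),
        females_marked=int((seen & ~male).sum()),
    )


def collapse_primaries(matrix: CaptureMatrix) -> CaptureMatrix:
    """Collapse secondary periods to one column per primary block.

    An individual is detected in a primary period iff it was detected in at
    least one of that block's secondary periods.
    """
    if matrix.primary_blocks is None:
        raise ValueError("capture matrix has no primary_blocks partition")
    starts = np.concatenate([[0], np.cumsum(matrix.primary_blocks)[:-1]]).astype(int)
    collapsed = (np.add.reduceat(matrix.detections, starts, axis=1) > 0).astype(np.int8)
    return CaptureMatrix(
        collapsed,
        matrix.sex,
        ids=matrix.ids,
        period_labels=tuple(
            f"primary{j + 1}" for j in range(len(matrix.primary_blocks))
        ),
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_INP_RECORD = re.compile(r"^([01]+)\s+(\d+)\s+(\d+)\s*;$")


def write_capture_file(matrix: CaptureMatrix, path, dialect: str = "delimited") -> None:
    """Write a capture matrix as delimited text or MARK ``.inp``."""
    if dialect == "delimited":
        lines = []
        if matrix.primary_blocks is not None:
            lines.append(
                "# primary_block_sizes: "
                + ",".join(str(b) for b in matrix.primary_blocks)
            )
        lines.append("id,sex," + ",".join(matrix.period_labels))
        for i in range(matrix.n_individuals):
            lines.append(
                f"{matrix.ids[i]},{matrix.sex[i]},"
                + ",".join(str(int(v)) for v in matrix.detections[i])
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif dialect == "mark_inp":
        with open(path, "w") as fh:
            fh.write("/* capture histories; group columns: male female */\n")
            for i in range(matrix.n_individuals):
                hist = "".join(str(int(v)) for v in matrix.detections[i])
                male = int(matrix.sex[i] == SexLabel.MALE.value)
                fh.write(f"{hist} {male} {1 - male};\n")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def _read_delimited(path) -> CaptureMatrix:
    blocks = None
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        m = re.match(r"#\s*primary_block_sizes:\s*([\d,\s]+)", line)
        if m:
            blocks = tuple(int(b) for b in m.group(1).replace(",", " ").split())
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[body_start:])), dtype=str)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["id", "sex"]:
        raise CaptureFormatError("expected header 'id,sex,<period columns>'")
    period_labels = tuple(df.columns[2:])
    det = np.empty((len(df), len(period_labels)), dtype=np.int8)
    for r, (_, row) in enumerate(df.iterrows()):
        for c, col in enumerate(period_labels):
            v = str(row[col]).strip()
            if v not in ("0", "1"):
                raise CaptureFormatError(
                    f"non-binary detection value {v!r}", line=body_start + 2 + r
                )
            det[r, c] = int(v)
    return CaptureMatrix(
        det,
        df["sex"].to_numpy(),
        ids=df["id"].to_numpy(),
        period_labels=period_labels,
        primary_blocks=blocks,
    )


def _read_inp(path) -> CaptureMatrix:
    with open(path) as fh:
        text = fh.read()
    # strip /* ... */ comments (may span lines); keep newlines for line numbers
    text = re.sub(r"/\*.*?\*/", lambda m: "\n" * m.group(0).count("\n"), text, flags=re.S)
    histories, sexes = [], []
    t = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _INP_RECORD.match(line)
        if m is None:
            raise CaptureFormatError(f"malformed .inp record {raw!r}", line=lineno)
        hist, n_male, n_female = m.group(1), int(m.group(2)), int(m.group(3))
        if t is None:
            t = len(hist)
        elif len(hist) != t:
            raise CaptureFormatError(
                f"history length {len(hist)} != expected {t}", line=lineno
            )
        row = [int(ch) for ch in hist]
        for _ in range(n_male):
            histories.append(row)
            sexes.append(SexLabel.MALE.value)
        for _ in range(n_female):
            histories.append(row)
            sexes.append(SexLabel.FEMALE.value)
    if not histories:
        raise CaptureFormatError("no capture-history records found")
    return CaptureMatrix(np.asarray(histories, dtype=np.int8), np.asarray(sexes))


def read_capture_file(path, dialect: str = "delimited") -> CaptureMatrix:
    """Read a capture matrix written by :func:`write_capture_file`."""
    if dialect == "delimited":
        return _read_delimited(path)
    if dialect == "mark_inp":
        return _read_inp(path)
    raise ValueError(f"unknown dialect: {dialect!r}")
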