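"""Central composite designs (CCD) for bead-milling lysis experiments.

A CCD for ``k`` factors stacks three blocks: the 2^k factorial cube at coded
levels ±1, 2k axial ("star") points at ±alpha on one axis at a time, and
replicated center points.  Factors are handled in *coded* units,
``coded = (actual - center) / step``, so that a quadratic polynomial fitted on
the coded scale has directly comparable coefficients.

The packaged 30-run, four-factor dataset (feed rate, bead load, cell load,
run time -> recovered cholesterol oxidase in g/L) is exposed through
:func:`table1_fixture` and is the reference design used throughout the test
suite and documentation.
"""

from __future__ import annotations

import csv
import io
import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "Factor",
    "DesignPoint",
    "DesignTable",
    "TABLE1_FACTORS",
    "CSV_COLUMNS",
    "DEFAULT_ALPHA",
    "build_ccd",
    "code",
    "decode",
    "load_design_csv",
    "write_design_csv",
    "table1_fixture",
    "replicate_groups",
    "pure_error_df",
]

#: Axial distance implied by the packaged design's actual levels (400 ± 141.42
#: on the feed-rate axis), i.e. sqrt(2) printed to four decimals.
DEFAULT_ALPHA = 1.4142

#: Rotatable axial distance 2^(k/4) for a k-factor cube, available as an
#: alternative to :data:`DEFAULT_ALPHA`.
def rotatable_alpha(n_factors: int) -> float:
    return float(2.0 ** (n_factors / 4.0))


class DesignError(ValueError):
    """Invalid design configuration or malformed design file."""


@dataclass(frozen=True)
class Factor:
    """One process variable of the design.

    ``center`` and ``step`` define the coding transform: coded level 0 sits at
    ``center`` and one coded unit spans ``step`` actual units.
    """

    name: str
    unit: str
    center: float
    step: float
    role: str = "generic"

    _ROLES = ("feed_rate", "bead_load", "cell_load", "run_time", "generic")

    def __post_init__(self) -> None:
        if not math.isfinite(self.center):
            raise DesignError(f"factor {self.name!r}: center must be finite")
        if not (self.step > 0 and math.isfinite(self.step)):
            raise DesignError(f"factor {self.name!r}: step must be positive")
        if self.role not in self._ROLES:
            raise DesignError(f"factor {self.name!r}: unknown role {self.role!r}")

    def code(self, value: float) -> float:
        return (value - self.center) / self.step

    def decode(self, coded: float) -> float:
        return self.center + self.step * coded


def code(value, factor: Factor):
    """Actual units -> coded level, ``(value - center) / step``."""
    return (np.asarray(value, dtype=float) - factor.center) / factor.step


def decode(coded, factor: Factor):
    """Coded level -> actual units; exact inverse of :func:`code`."""
    return factor.center + factor.step * np.asarray(coded, dtype=float)


#: Factors of the packaged 30-run bead-milling design, with the centers and
#: steps implied by its actual levels.
TABLE1_FACTORS: tuple[Factor, ...] = (
    Factor("feed_rate", "mL/h", 400.0, 100.0, role="feed_rate"),
    Factor("bead_load", "% v/v", 70.0, 10.0, role="bead_load"),
    Factor("cell_load", "OD600", 60.0, 10.0, role="cell_load"),
    Factor("run_time", "min", 25.0, 5.0, role="run_time"),
)

#: Canonical CSV schema (response column optional on input).
CSV_COLUMNS = (
    "run",
    "feed_rate_ml_h",
    "bead_load_pct",
    "cell_load_od600",
    "run_time_min",
    "cod_g_L",
)

_CLASS_TOL = 1e-6


def classify_point(coded: Sequence[float], tol: float = _CLASS_TOL) -> str:
    """Classify a coded point as ``center``, ``factorial``, ``axial`` or ``other``."""
    c = np.asarray(coded, dtype=float)
    nonzero = np.abs(c) > tol
    if not nonzero.any():
        return "center"
    if nonzero.all() and np.allclose(np.abs(c), 1.0, atol=tol):
        return "factorial"
    if nonzero.sum() == 1:
        return "axial"
    return "other"


@dataclass(frozen=True)
class DesignPoint:
    run_id: int
    coded: tuple[float, ...]
    actual: tuple[float, ...]
    point_class: str


@dataclass
class DesignTable:
    """A design matrix plus (optionally) its observed responses.

    ``metadata`` carries free-form annotations; the packaged fixture records
    the three-decimal response extremes there.
    """

    factors: tuple[Factor, ...]
    points: list[DesignPoint]
    response: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.factors)
        for pt in self.points:
            if len(pt.coded) != k or len(pt.actual) != k:
                raise DesignError(
                    f"run {pt.run_id}: point dimension does not match {k} factors"
                )
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=float)
            if self.response.shape != (len(self.points),):
                raise DesignError("response length does not match number of runs")

    # -- array views ------------------------------------------------------
    @property
    def n_runs(self) -> int:
        return len(self.points)

    @property
    def run_ids(self) -> list[int]:
        return [pt.run_id for pt in self.points]

    @property
    def coded_matrix(self) -> np.ndarray:
        return np.array([pt.coded for pt in self.points], dtype=float)

    @property
    def actual_matrix(self) -> np.ndarray:
        return np.array([pt.actual for pt in self.points], dtype=float)

    def with_response(self, response: Iterable[float]) -> "DesignTable":
        return DesignTable(
            self.factors, list(self.points), np.asarray(list(response), float),
            dict(self.metadata),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {"run": self.run_ids}
        names = _csv_factor_names(self.factors)
        for j, name in enumerate(names):
            cols[name] = self.actual_matrix[:, j]
        if self.response is not None:
            cols[CSV_COLUMNS[-1]] = self.response
        return pd.DataFrame(cols)


def _csv_factor_names(factors: Sequence[Factor]) -> list[str]:
    if tuple(f.name for f in factors) == tuple(f.name for f in TABLE1_FACTORS):
        return list(CSV_COLUMNS[1:5])
    return [f.name for f in factors]


def build_ccd(
    factors: Sequence[Factor],
    alpha: float = DEFAULT_ALPHA,
    n_center: int = 6,
) -> DesignTable:
    """Build a full central composite design.

    Blocks are emitted in the order factorial cube (first factor varying
    fastest), axial pairs (-alpha then +alpha per factor), then center
    replicates; run ids are 1..N.
    """
    factors = tuple(factors)
    if len(factors) < 2:
        raise DesignError("a CCD needs at least 2 factors")
    if not (alpha > 0 and math.isfinite(alpha)):
        raise DesignError("alpha must be a positive finite number")
    if n_center < 1:
        raise DesignError("n_center must be >= 1")

    k = len(factors)
    rows: list[tuple[float, ...]] = []
    # 2^k cube, first factor fastest to match the conventional run order
    for combo in itertools.product((-1.0, 1.0), repeat=k):
        rows.append(tuple(reversed(combo)))
    for j in range(k):
        for sign in (-1.0, 1.0):
            axial = [0.0] * k
            axial[j] = sign * alpha
            rows.append(tuple(axial))
    rows.extend([(0.0,) * k] * n_center)

    points = []
    for i, coded in enumerate(rows, start=1):
        actual = tuple(factors[j].decode(coded[j]) for j in range(k))
        points.append(DesignPoint(i, coded, actual, classify_point(coded)))
    return DesignTable(factors, points)


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_cell(text: str, row: int, column: str) -> float:
    text = text.strip()
    if not text:
        raise DesignError(f"missing value at row {row}, column {column!r}")
    try:
        return float(text)
    except ValueError as exc:
        raise DesignError(
            f"non-numeric value {text!r} at row {row}, column {column!r}"
        ) from exc


def load_design_csv(
    path, factors: Sequence[Factor] = TABLE1_FACTORS
) -> DesignTable:
    """Load a design (and optional response column) from CSV.

    The file must have a header row; factor columns are matched by position
    after the run-id column.  Coded levels and point classes are derived from
    the actual values via each factor's (center, step).
    """
    factors = tuple(factors)
    if hasattr(path, "read"):
        handle = path
        lines = handle.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        raise DesignError("empty design file") from None
    n_expected = 1 + len(factors)
    if len(header) < n_expected:
        raise DesignError(
            f"header has {len(header)} columns, expected at least {n_expected}"
        )
    has_response_col = len(header) > n_expected

    points: list[DesignPoint] = []
    response: list[float] = []
    any_response = False
    for row_no, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < n_expected:
            raise DesignError(f"row {row_no}: expected {n_expected}+ columns")
        run_id = int(_parse_cell(row[0], row_no, header[0]))
        actual = tuple(
            _parse_cell(row[1 + j], row_no, header[1 + j]) for j in range(len(factors))
        )
        coded = tuple(factors[j].code(actual[j]) for j in range(len(factors)))
        points.append(DesignPoint(run_id, coded, actual, classify_point(coded)))
        if has_response_col and len(row) > n_expected and row[n_expected].strip():
            response.append(_parse_cell(row[n_expected], row_no, header[n_expected]))
            any_response = True
        elif any_response:
            raise DesignError(f"row {row_no}: missing response value")
    table = DesignTable(tuple(factors), points)
    if any_response:
        if len(response) != len(points):
            raise DesignError("response column present for only some rows")
        table = table.with_response(response)
    return table


def write_design_csv(table: DesignTable, path) -> None:
    """Write a design table in the canonical CSV schema."""
    df = table.to_dataframe()
    if hasattr(path, "write"):
        df.to_csv(path, index=False, float_format="%.6g")
    else:
        df.to_csv(Path(path), index=False, float_format="%.6g")


def table1_fixture() -> DesignTable:
    """The packaged 30-run bead-milling CCD with observed COD recoveries.

    Responses are the two-decimal printed values; the three-decimal extremes
    (0.794 g/L minimum, 3.282 g/L maximum) are recorded in ``metadata``.
    """
    text = (
        resources.files("beadmill").joinpath("data/table1.csv").read_text()
    )
    table = load_design_csv(io.StringIO(text))
    table.metadata.update(
        {"response_min_precise": 0.794, "response_max_precise": 3.282}
    )
    return table


def replicate_groups(table: DesignTable) -> list[list[int]]:
    """Partition run ids into groups sharing an identical coded point.

    Groups are returned in order of first appearance; groups of size >= 2 are
    the replicate sets that supply pure-error degrees of freedom.
    """
    if table.n_runs == 0:
        raise DesignError("empty design table")
    groups: dict[tuple, list[int]] = {}
    for pt in table.points:
        key = tuple(round(c, 9) for c in pt.coded)
        groups.setdefault(key, []).append(pt.run_id)
    return list(groups.values())


def pure_error_df(table: DesignTable) -> int:
    """Pure-error degrees of freedom, sum over replicate groups of (size - 1)."""
    return sum(len(g) - 1 for g in replicate_groups(table))
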