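"""Study data: bundled tree-year records and tabular I/O.

The package ships the full calibration dataset: 20 peach trees (cv
Suncrest/GF677) observed in 2005 and 2006, each tree-year characterised by
the total length of 1-yr-old wood before winter pruning (L_W1, meters), the
pruning intensity (PI, fraction of L_W1 removed) and the fraction of buds
that developed into long shoots (P_LS).

Two fixture variants are bundled.  ``raw`` reproduces the published table
verbatim.  Seven of its P_LS cells are printed with a single decimal (0.9,
0.8, 0.7) where every other cell has two; those values are wildly
inconsistent with the fitted model (which predicts 0.08-0.21 at the same
covariates) and a dropped leading zero is the most plausible transcription
artifact.  ``corrected`` (the default for reproduction runs) reads them as
0.09, 0.08, 0.07.  The correction is a documented hypothesis, never applied
silently: both variants are first-class.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import DataFormatError, DataValidationError

__all__ = [
    "TreeYearRecord",
    "CORRECTED_CELLS",
    "load_table1",
    "read_records",
    "write_records",
    "records_to_frame",
]

COLUMNS = ("tree_id", "year", "lw1_m", "pi", "pls")

#: (tree_id, year) of the P_LS cells read differently by the two variants.
CORRECTED_CELLS = frozenset(
    [(1, 2005), (5, 2005), (16, 2005), (8, 2005), (20, 2005), (15, 2005), (7, 2006)]
)


@dataclass(frozen=True)
class TreeYearRecord:
    """One tree-year observation.

    Invariants: lw1 > 0 (meters), 0 <= pi <= 1, and 0 < pls < 1 — the open
    bounds on pls are required by the logit transform used for fitting.
    """

    tree_id: int
    year: int
    lw1: float
    pi: float
    pls: float

    def __post_init__(self) -> None:
        problems = _check(self.lw1, self.pi, self.pls)
        if problems:
            raise DataValidationError(
                f"invalid record (tree {self.tree_id}, year {self.year}): "
                + "; ".join(problems)
            )


def _check(lw1: float, pi: float, pls: float) -> list[str]:
    problems = []
    if not lw1 > 0:
        problems.append(f"lw1 must be > 0, got {lw1}")
    if not 0 <= pi <= 1:
        problems.append(f"pi must lie in [0, 1], got {pi}")
    if not 0 < pls < 1:
        problems.append(f"pls must lie strictly in (0, 1), got {pls}")
    return problems


def load_table1(variant: str = "corrected") -> list[TreeYearRecord]:
    """Load the bundled 40-record calibration dataset.

    ``variant`` is ``"raw"`` (values exactly as published) or ``"corrected"``
    (leading-zero repair of the seven suspect P_LS cells; see module
    docstring).
    """
    if variant not in ("raw", "corrected"):
        raise ValueError(f"variant must be 'raw' or 'corrected', got {variant!r}")
    ref = resources.files("budfate.data") / f"table1_{variant}.csv"
    with resources.as_file(ref) as path:
        return read_records(path)


def _frame_to_records(frame: pd.DataFrame, source: str) -> list[TreeYearRecord]:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{source}: missing column(s) {missing}; expected {list(COLUMNS)}")
    records, bad_rows, messages = [], [], []
    for i, row in enumerate(frame.itertuples(index=False)):
        # header is line 1, so data row i sits on file line i + 2
        line = i + 2
        try:
            tree_id, year = int(row.tree_id), int(row.year)
            lw1, pi, pls = float(row.lw1_m), float(row.pi), float(row.pls)
        except (TypeError, ValueError) as err:
            bad_rows.append(line)
            messages.append(f"line {line}: {err}")
            continue
        problems = _check(lw1, pi, pls)
        if problems:
            bad_rows.append(line)
            messages.append(f"line {line}: " + "; ".join(problems))
            continue
        records.append(TreeYearRecord(tree_id, year, lw1, pi, pls))
    if bad_rows:
        raise DataValidationError(
            f"{source}: {len(bad_rows)} invalid row(s)\n" + "\n".join(messages),
            rows=bad_rows,
        )
    return records


def read_records(path: str | Path) -> list[TreeYearRecord]:
    """Read tree-year records from a CSV file.

    Expects a header with columns tree_id, year, lw1_m, pi, pls ('.' decimal
    separator, UTF-8).  Raises :class:`DataFormatError` on a malformed header
    and :class:`DataValidationError` naming the offending line(s) when rows
    violate record invariants.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise DataFormatError(f"{path}: not parseable as CSV ({err})") from err
    return _frame_to_records(frame, str(path))


def records_to_frame(records: Iterable[TreeYearRecord]) -> pd.DataFrame:
    rows = [(r.tree_id, r.year, r.lw1, r.pi, r.pls) for r in records]
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_records(records: Iterable[TreeYearRecord], path: str | Path) -> None:
    """Write records as CSV in the schema read_records expects."""
    records_to_frame(records).to_csv(path, index=False)
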