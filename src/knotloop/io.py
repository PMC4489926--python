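"""Run-ledger persistence and XYZ trajectory I/O.

Ledgers are plain CSV — append-only, greppable, and mergeable across
concurrent batches (one file per batch, concatenated at report time).
Every number reported in an :class:`~knotloop.experiment.ExperimentSummary`
is recomputable from the ledger alone.  Coordinates travel as XYZ frames
(beads are not atoms, so PDB would be a poor fit); the comment line of
each frame carries the step count and adhesion flags.

Bead indices are 0-based everywhere inside the package; human-facing CLI
output labels indices explicitly where it prints them.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, fields
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RunRecord",
    "LedgerError",
    "XYZParseError",
    "ledger_append",
    "ledger_load",
    "write_xyz",
    "read_xyz",
]

LEDGER_SCHEMA_VERSION = "1"

_COLUMNS = [
    "schema",
    "run_id",
    "config_hash",
    "seed",
    "placement",
    "circularized",
    "censored",
    "steps",
    "knot_label",
    "det_minus1",
    "det_minus2",
    "loop_closed",
    "relevant",
]


class LedgerError(ValueError):
    """A ledger file violates the schema or its row invariants."""


class XYZParseError(ValueError):
    """Malformed XYZ input; carries the offending line number."""


@dataclass
class RunRecord:
    """One ledger row: everything the statistics need about one run.

    Invariants (validated on load): knot fields are present iff the run
    circularized and was classified; ``relevant`` is present only for
    knotted runs with a closed sticky loop.
    """

    run_id: str
    config_hash: str
    seed: int
    placement: str
    circularized: bool
    censored: bool
    steps: int
    knot_label: Optional[str] = None
    det_minus1: Optional[int] = None
    det_minus2: Optional[int] = None
    loop_closed: Optional[bool] = None
    relevant: Optional[bool] = None
    #: transient, never serialized
    outcome: object = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        if self.circularized == self.censored:
            raise LedgerError(
                f"{self.run_id}: run must be exactly one of circularized/censored"
            )
        if self.censored and self.knot_label is not None:
            raise LedgerError(f"{self.run_id}: censored run carries knot fields")
        if self.knot_label is not None and (
            self.det_minus1 is None or self.det_minus2 is None
        ):
            raise LedgerError(f"{self.run_id}: knot label without determinants")
        if self.relevant is not None:
            if self.knot_label in (None, "0_1") or not self.loop_closed:
                raise LedgerError(
                    f"{self.run_id}: relevance requires a knotted run with closed loop"
                )


def _to_cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, (bool, np.bool_)):
        return "1" if v else "0"
    return str(v)


def _bool_cell(s: str) -> Optional[bool]:
    return None if s == "" else s == "1"


def _int_cell(s: str) -> Optional[int]:
    return None if s == "" else int(s)


def ledger_append(path, records: Sequence[RunRecord]) -> None:
    """Append records to a CSV ledger, writing the header if new."""
    new_file = not os.path.exists(path) or os.path.getsize(path) == 0
    with open(path, "a", newline="") as fh:
        w = csv.writer(fh)
        if new_file:
            w.writerow(_COLUMNS)
        for r in records:
            r.validate()
            w.writerow(
                [
                    LEDGER_SCHEMA_VERSION,
                    r.run_id,
                    r.config_hash,
                    r.seed,
                    r.placement,
                    _to_cell(r.circularized),
                    _to_cell(r.censored),
                    r.steps,
                    _to_cell(r.knot_label),
                    _to_cell(r.det_minus1),
                    _to_cell(r.det_minus2),
                    _to_cell(r.loop_closed),
                    _to_cell(r.relevant),
                ]
            )


def ledger_load(path) -> List[RunRecord]:
    """Load and validate a CSV ledger (or several concatenated batches)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return []
        if header != _COLUMNS:
            raise LedgerError(
                f"{path}: unknown ledger schema {header!r}; "
                f"expected version {LEDGER_SCHEMA_VERSION} columns"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if row == _COLUMNS:
                continue  # merged batch files repeat the header
            if row[0] != LEDGER_SCHEMA_VERSION:
                raise LedgerError(
                    f"{path}:{line_no}: schema version {row[0]!r} needs migration"
                )
            rec = RunRecord(
                run_id=row[1],
                config_hash=row[2],
                seed=int(row[3]),
                placement=row[4],
                circularized=row[5] == "1",
                censored=row[6] == "1",
                steps=int(row[7]),
                knot_label=row[8] or None,
                det_minus1=_int_cell(row[9]),
                det_minus2=_int_cell(row[10]),
                loop_closed=_bool_cell(row[11]),
                relevant=_bool_cell(row[12]),
            )
            rec.validate()
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# XYZ trajectory I/O
# ---------------------------------------------------------------------------

@dataclass
class XYZFrame:
    """One frame: coordinates plus the run metadata on the comment line."""

    positions: np.ndarray
    comment: str = ""


def write_xyz(frames: Sequence[XYZFrame], path) -> None:
    """Multi-frame XYZ with 9-significant-digit coordinates."""
    with open(path, "w") as fh:
        for fr in frames:
            pos = np.asarray(fr.positions, dtype=float)
            fh.write(f"{len(pos)}\n")
            fh.write(f"{fr.comment}\n")
            for x, y, z in pos:
                fh.write(f"B {x:.9g} {y:.9g} {z:.9g}\n")


def read_xyz(path) -> List[XYZFrame]:
    """Parse a multi-frame XYZ file written by :func:`write_xyz`."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if lines[i].strip() == "":
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise XYZParseError(f"line {i + 1}: expected atom count") from exc
        if i + 1 + count >= n_lines + 1 and count > 0:
            raise XYZParseError(f"line {i + 1}: truncated frame (expected {count} atoms)")
        comment = lines[i + 1].rstrip("\n") if i + 1 < n_lines else ""
        pos = np.empty((count, 3))
        for k in range(count):
            ln = i + 2 + k
            if ln >= n_lines:
                raise XYZParseError(f"line {ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {ln + 1}: malformed coordinate line")
            try:
                pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise XYZParseError(f"line {ln + 1}: malformed coordinate") from exc
        frames.append(XYZFrame(positions=pos, comment=comment))
        i += 2 + count
    return frames


def frame_comment(run_id: str, steps: int, bonded_termini: bool, bonded_internal: bool) -> str:
    return (
        f"run_id={run_id} steps={steps} "
        f"bonded_termini={int(bonded_termini)} bonded_internal={int(bonded_internal)}"
    )
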