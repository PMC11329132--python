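"""Thick-to-thin slice location mapping and training-example assembly.

Each thick slice j (thickness ratio k, odd) covers k thin slices; the
middle one is its *corresponding* (C) thin slice, ``C = k*j + (k-1)/2``.
Five position models are trained, one per thin-slice offset from C:

====== ======  =========================
label  offset  meaning
====== ======  =========================
2P      -2     two slices before C
1P      -1     one slice before C
C        0     the corresponding slice
1N      +1     one slice after C
2N      +2     two slices after C
====== ======  =========================

Positions whose thin index falls outside the thin volume (the first and
last thick slices) are absent from the mapping and skipped, not padded.

Two training-target constructions are supported:

* method 1 — the raw thin slice on the signed [-1, 1] scale;
* method 2 — the residual (difference image) ``unit(thin) - unit(thick)``,
  which lies in [-1, 1] by construction and is added back to the
  [0, 1]-scaled input at inference.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

from .volume_io import to_signed_unit, to_unit

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import PairedCase


class PositionLabel(str, Enum):
    """The five thin-slice positions relative to a thick slice."""

    P2 = "2P"
    P1 = "1P"
    C = "C"
    N1 = "1N"
    N2 = "2N"

    @property
    def offset(self) -> int:
        return {"2P": -2, "1P": -1, "C": 0, "1N": 1, "2N": 2}[self.value]

    @classmethod
    def from_string(cls, s: "str | PositionLabel") -> "PositionLabel":
        return s if isinstance(s, cls) else cls(s)


POSITIONS: tuple[PositionLabel, ...] = tuple(PositionLabel)


@dataclass(frozen=True)
class MappingTable:
    """Rows of thick-index -> {position: thin index} correspondences."""

    rows: tuple[dict, ...]  # each: {"thick_index": int, PositionLabel: int, ...}
    k: int
    n_thin: int

    def row(self, thick_index: int) -> dict:
        return self.rows[thick_index]

    def positions_present(self, thick_index: int) -> list[PositionLabel]:
        return [p for p in POSITIONS if p in self.rows[thick_index]]

    def __len__(self) -> int:
        return len(self.rows)

    def to_csv(self) -> str:
        cols = ["thick_index"] + [f"pos_{p.value}" for p in POSITIONS]
        lines = [",".join(cols)]
        for r in self.rows:
            cells = [str(r["thick_index"])]
            cells += [str(r[p]) if p in r else "" for p in POSITIONS]
            lines.append(",".join(cells))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_csv(cls, text: str, k: int, n_thin: int) -> "MappingTable":
        import csv

        rows = []
        for rec in csv.DictReader(io.StringIO(text)):
            row = {"thick_index": int(rec["thick_index"])}
            for p in POSITIONS:
                cell = rec.get(f"pos_{p.value}", "")
                if cell not in ("", None):
                    row[p] = int(cell)
            rows.append(row)
        return cls(rows=tuple(rows), k=k, n_thin=n_thin)


def build_mapping(n_thin: int, k: int = 3) -> MappingTable:
    """Build the slice-location mapping table for a thin/thick pair.

    For thick index j the corresponding thin index is
    ``C = k*j + (k-1)//2``; the other four positions are C-2, C-1, C+1,
    C+2.  Entries outside [0, n_thin) are absent.  Rows exist for
    j in [0, floor(n_thin/k)).
    """
    if k % 2 == 0:
        raise ValueError(f"even thickness ratio k={k}: centre slice undefined")
    if k < 3:
        raise ValueError(f"thickness ratio k must be an odd integer >= 3, got {k}")
    if n_thin < k:
        raise ValueError(f"need n_thin >= k, got n_thin={n_thin}, k={k}")
    rows = []
    for j in range(n_thin // k):
        c = k * j + (k - 1) // 2
        row: dict = {"thick_index": j}
        for p in POSITIONS:
            idx = c + p.offset
            if 0 <= idx < n_thin:
                row[p] = idx
        rows.append(row)
    return MappingTable(rows=tuple(rows), k=k, n_thin=n_thin)


@dataclass(frozen=True)
class TrainingExample:
    """One (thick input, thin target) pair for a position model.

    ``input`` is the thick slice on the signed [-1, 1] scale; ``target``
    is the raw thin slice on the same scale (method 1) or the
    ``unit(thin) - unit(thick)`` residual (method 2).
    """

    input: np.ndarray
    target: np.ndarray
    position: PositionLabel
    method: int
    case_id: str
    thick_index: int
    thin_index: int


def make_training_examples(case: "PairedCase", position: PositionLabel | str,
                           method: int) -> list[TrainingExample]:
    """Materialise the training pairs of one position model from a case."""
    position = PositionLabel.from_string(position)
    if method not in (1, 2):
        raise ValueError(f"method must be 1 or 2, got {method}")
    examples = []
    for row in case.mapping.rows:
        if position not in row:
            continue  # boundary row: this position falls outside the thin volume
        j = row["thick_index"]
        thin_idx = row[position]
        thick_slice = case.thick.slice(j)
        x = to_signed_unit(thick_slice).array
        if method == 1:
            target = to_signed_unit(case.thin.slice(thin_idx)).array
        else:
            target = to_unit(case.thin.slice(thin_idx)).array - to_unit(thick_slice).array
        examples.append(TrainingExample(
            input=x, target=target, position=position, method=method,
            case_id=case.case_id, thick_index=j, thin_index=thin_idx,
        ))
    if not examples:
        raise ValueError(
            f"no training examples for position {position.value}: "
            "all mapping rows lack this position"
        )
    return examples
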