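"""Entropy-based alignment objective for EC-code sequences.

An alignment is a rectangular grid whose cells are three-level EC codes
or gaps; rows read left-to-right reproduce their sequences exactly (only
gaps vary).  Quality is a *minimized* objective

    O.F. = 0.9 * Homogeneity + 0.05 * GapPenalty + 0.05 * ColumnIncrement

Homogeneity averages a per-column score 0.6*E + 0.4*Gaps, where E is a
weighted normalized Shannon entropy of the three EC levels (weights
15/10/5, most weight on the EC class) with the gap counted as one extra
symbol at every level, and Gaps = (#gap cells)/(S-1) compensates the
"false homogeneity" of gap-heavy columns.  GapPenalty is the gap-block
concentration S̄GB/GP over internal gap runs (leading and trailing gaps
are ignored; zero when there are no gaps).  ColumnIncrement is C0/C1,
the longest unaligned sequence length over the aligned width.

The two gap-related terms are implemented exactly as the printed
formulas; both also have an ``inverted`` variant behind
:class:`ScoringConfig` for users who prefer the prose reading (reward
concentrated gap blocks / penalize added columns).

All-gap columns are removed before any evaluation.
"""

from __future__ import annotations

import json
import math
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ec import GAP, GAP_CHAR, ECCode

#: Eq-level constants of the method (objective weights, homogeneity
#: weights, EC-level entropy weights).
OBJECTIVE_WEIGHTS = (0.9, 0.05, 0.05)
HOMOGENEITY_WEIGHTS = (0.6, 0.4)
LEVEL_WEIGHTS = (15.0, 10.0, 5.0)


@dataclass(frozen=True)
class ScoringConfig:
    """Switchable readings of the scoring formulas.

    entropy_normalization
        ``"rows"`` (default): divide column entropy by log2(S), the
        maximum achievable with S rows.  ``"distinct"``: divide by
        log2(#distinct symbols in the column).
    gap_concentration_mode / column_increment_mode
        ``"literal"`` (default) follows the printed formulas
        (GC = S̄GB/GP, CI = C0/C1); ``"inverted"`` follows the prose
        intent (GC = GP/S̄GB, CI = C1/C0).
    """

    entropy_normalization: str = "rows"
    gap_concentration_mode: str = "literal"
    column_increment_mode: str = "literal"

    def __post_init__(self) -> None:
        if self.entropy_normalization not in ("rows", "distinct"):
            raise ValueError(f"bad entropy_normalization {self.entropy_normalization!r}")
        for mode in (self.gap_concentration_mode, self.column_increment_mode):
            if mode not in ("literal", "inverted"):
                raise ValueError(f"bad mode {mode!r}")

    @property
    def is_default(self) -> bool:
        return self == ScoringConfig()


DEFAULT_CONFIG = ScoringConfig()


@dataclass(frozen=True)
class ScoreBreakdown:
    """The three objective terms and their weighted sum."""

    homogeneity: float
    gap_penalty: float
    column_increment: float

    @property
    def objective(self) -> float:
        w_h, w_g, w_c = OBJECTIVE_WEIGHTS
        return w_h * self.homogeneity + w_g * self.gap_penalty + w_c * self.column_increment

    def to_dict(self) -> dict[str, float]:
        return {
            "homogeneity": self.homogeneity,
            "gap_penalty": self.gap_penalty,
            "column_increment": self.column_increment,
            "objective": self.objective,
        }


Cell = Optional[ECCode]
Grid = tuple[tuple[Cell, ...], ...]


def strip_all_gap_columns(rows: Sequence[Sequence[Cell]]) -> Grid:
    """Drop every column consisting only of gaps."""
    if not rows:
        return ()
    width = len(rows[0])
    keep = [j for j in range(width) if any(r[j] is not GAP for r in rows)]
    return tuple(tuple(r[j] for j in keep) for r in rows)


@dataclass(frozen=True)
class Alignment:
    """A rectangular EC-or-gap grid over named rows.

    The constructor enforces rectangularity; use :meth:`build` to also
    strip all-gap columns.
    """

    row_ids: tuple[str, ...]
    grid: Grid

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.grid):
            raise ValueError("row_ids and grid size mismatch")
        if not self.grid:
            raise ValueError("alignment needs at least one row")
        widths = {len(r) for r in self.grid}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment, widths {sorted(widths)}")

    @classmethod
    def build(cls, row_ids: Sequence[str], rows: Sequence[Sequence[Cell]]) -> "Alignment":
        return cls(tuple(row_ids), strip_all_gap_columns(rows))

    @property
    def n_rows(self) -> int:
        return len(self.grid)

    @property
    def n_columns(self) -> int:
        return len(self.grid[0])

    def column(self, j: int) -> tuple[Cell, ...]:
        return tuple(r[j] for r in self.grid)

    def row_steps(self, r: int) -> tuple[ECCode, ...]:
        """Non-gap cells of row r, left to right (the unaligned sequence)."""
        return tuple(c for c in self.grid[r] if c is not GAP)


def column_level_entropy(
    symbols: Sequence, config: ScoringConfig = DEFAULT_CONFIG
) -> float:
    """Normalized Shannon entropy of one EC level down a column.

    ``symbols`` holds one token per row; gaps are a symbol like any
    other.  Normalization divides by log2(S) (or by log2(#distinct) in
    ``distinct`` mode) so the value lies in [0, 1]; identical symbols
    give 0.
    """
    s = len(symbols)
    if s < 2:
        raise ValueError("column entropy needs at least two rows")
    counts = Counter(symbols)
    if len(counts) == 1:
        return 0.0
    entropy = -sum((c / s) * math.log2(c / s) for c in counts.values())
    if config.entropy_normalization == "rows":
        norm = math.log2(s)
    else:
        norm = math.log2(len(counts))
    return entropy / norm


def column_ec_entropy(
    column: Sequence[Cell], config: ScoringConfig = DEFAULT_CONFIG
) -> float:
    """Weighted mean of the three per-level entropies (weights 15/10/5);
    a gap cell contributes a gap token at every level."""
    w1, w2, w3 = LEVEL_WEIGHTS
    levels = []
    for k in range(3):
        levels.append([c.levels[k] if c is not GAP else GAP for c in column])
    e1, e2, e3 = (column_level_entropy(lv, config) for lv in levels)
    return (w1 * e1 + w2 * e2 + w3 * e3) / (w1 + w2 + w3)


def column_gap_fraction(column: Sequence[Cell]) -> float:
    """(#gap cells) / (S - 1); the column must not be all gaps."""
    s = len(column)
    if s < 2:
        raise ValueError("gap fraction needs at least two rows")
    n_gaps = sum(1 for c in column if c is GAP)
    if n_gaps == s:
        raise ValueError("all-gap column should have been removed")
    return n_gaps / (s - 1)


def column_homogeneity(
    column: Sequence[Cell], config: ScoringConfig = DEFAULT_CONFIG
) -> float:
    """0.6 * EC entropy + 0.4 * gap fraction; 0 for a conserved column."""
    w_e, w_g = HOMOGENEITY_WEIGHTS
    return w_e * column_ec_entropy(column, config) + w_g * column_gap_fraction(column)


def homogeneity(aln: Alignment, config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Mean column homogeneity over the whole alignment."""
    if aln.n_columns == 0:
        raise ValueError("alignment has zero columns")
    return sum(
        column_homogeneity(aln.column(j), config) for j in range(aln.n_columns)
    ) / aln.n_columns


def _internal_gap_runs(row: Sequence[Cell]) -> list[int]:
    """Lengths of maximal gap runs not touching either end of the row."""
    runs: list[int] = []
    start = None
    for j, cell in enumerate(row):
        if cell is GAP:
            if start is None:
                start = j
        else:
            if start is not None:
                if start > 0:  # run not touching the left edge
                    runs.append(j - start)
                start = None
    # a run still open at the end touches the right edge: excluded
    return runs


def gap_concentration(aln: Alignment, config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Gap-block concentration over internal gap runs of every row.

    literal: (mean run length) / (total internal gap count); 0 without
    internal gaps.  inverted: total / mean.
    """
    runs: list[int] = []
    for r in range(aln.n_rows):
        runs.extend(_internal_gap_runs(aln.grid[r]))
    total = sum(runs)
    if total == 0:
        return 0.0
    mean_len = total / len(runs)
    if config.gap_concentration_mode == "literal":
        return mean_len / total
    return total / mean_len


def column_increment(aln: Alignment, config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """literal: C0/C1 with C0 the longest unaligned row and C1 the
    aligned width; inverted: C1/C0."""
    c0 = max(len(aln.row_steps(r)) for r in range(aln.n_rows))
    c1 = aln.n_columns
    if config.column_increment_mode == "literal":
        return c0 / c1
    return c1 / c0


def objective(aln: Alignment, config: ScoringConfig = DEFAULT_CONFIG) -> ScoreBreakdown:
    """Full weighted objective; all-gap columns are removed first."""
    stripped = strip_all_gap_columns(aln.grid)
    if stripped != aln.grid:
        aln = Alignment(aln.row_ids, stripped)
    if aln.n_columns == 0:
        raise ValueError("alignment has zero non-gap columns")
    return ScoreBreakdown(
        homogeneity=homogeneity(aln, config),
        gap_penalty=gap_concentration(aln, config),
        column_increment=column_increment(aln, config),
    )


# ---------------------------------------------------------------------------
# text formats


def format_alignment(aln: Alignment) -> str:
    """One row per line: row id, then cells, tab-separated; gap is '-'."""
    lines = []
    for rid, row in zip(aln.row_ids, aln.grid):
        cells = [str(c) if c is not GAP else GAP_CHAR for c in row]
        lines.append("\t".join([rid, *cells]))
    return "\n".join(lines) + "\n"


def write_alignment(aln: Alignment, path_or_buf) -> None:
    text = format_alignment(aln)
    if isinstance(path_or_buf, (str, os.PathLike)):
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    else:
        path_or_buf.write(text)


def read_alignment(path_or_buf) -> Alignment:
    if isinstance(path_or_buf, (str, os.PathLike)):
        with open(path_or_buf) as fh:
            text = fh.read()
    else:
        text = path_or_buf.read()
    row_ids: list[str] = []
    rows: list[list[Cell]] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        row_ids.append(fields[0])
        rows.append(
            [GAP if tok == GAP_CHAR else ECCode.parse(tok) for tok in fields[1:]]
        )
    return Alignment(tuple(row_ids), tuple(tuple(r) for r in rows))


def write_score_report(breakdown: ScoreBreakdown, path_or_buf) -> None:
    payload = json.dumps(breakdown.to_dict(), indent=2) + "\n"
    if isinstance(path_or_buf, (str, os.PathLike)):
        with open(path_or_buf, "w") as fh:
            fh.write(payload)
    else:
        path_or_buf.write(payload)
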