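"""Progressive GA multiple alignment of a cluster of sequences.

Members are ordered by similarity (most similar pair first, then the
unplaced member closest on average to the placed set); the first two are
aligned with the pairwise GA and each further member is folded in by a
GA over a frozen-relative profile: previously aligned rows move only via
whole-block gap-column insertion, so their mutual gap pattern never
changes, while the incoming row places its own gaps freely.  The full
entropy objective over the whole block is minimized at every step, and
the trivially padded block is always injected into the initial
population so the result can never be worse than simply stacking the
sequences.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ec import GAP
from .ess import ESSCollection
from .ga import Chromosome, GAParams, evolve, ga_align
from .scoring import Alignment, ScoreBreakdown, objective
from .similarity import SimilarityMatrix

_SEED_MOD = 2**31


def build_guide_order(
    cluster_members: Sequence[str], matrix: SimilarityMatrix
) -> list[str]:
    """Most-similar pair first, then nearest-on-average unplaced member;
    all ties break lexicographically by ess_id."""
    members = sorted(cluster_members)
    if len(members) < 2:
        raise ValueError("guide order needs at least two members")
    best_pair = None
    best_fit = float("inf")
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            fit = matrix.get(a, b)
            if fit < best_fit - 1e-12:
                best_fit = fit
                best_pair = (a, b)
    assert best_pair is not None
    order = list(best_pair)
    remaining = [m for m in members if m not in order]
    while remaining:
        means = [
            (float(np.mean([matrix.get(m, p) for p in order])), m) for m in remaining
        ]
        means.sort()
        order.append(means[0][1])
        remaining.remove(means[0][1])
    return order


def _extend_profile(
    block: Alignment,
    new_id: str,
    new_steps: tuple,
    params: GAParams,
    step_seed: int,
) -> Alignment:
    """GA extension of an aligned block by one sequence.

    The chromosome has two mask rows: one over the block's columns (a 0
    inserts an all-gap column into every frozen row) and one over the new
    sequence's enzymes.
    """
    n_cols = block.n_columns
    rows = (tuple(range(n_cols)), tuple(new_steps))

    def decode_block(ch: Chromosome) -> tuple[tuple, ...]:
        col_mask, new_mask = ch.masks
        grid_rows: list[list] = [[] for _ in range(block.n_rows + 1)]
        ib = inew = 0
        for j in range(ch.width):
            if col_mask[j]:
                for r in range(block.n_rows):
                    grid_rows[r].append(block.grid[r][ib])
                ib += 1
            else:
                for r in range(block.n_rows):
                    grid_rows[r].append(GAP)
            if new_mask[j]:
                grid_rows[-1].append(new_steps[inew])
                inew += 1
            else:
                grid_rows[-1].append(GAP)
        return tuple(tuple(r) for r in grid_rows)

    row_ids = (*block.row_ids, new_id)

    def fitness(ch: Chromosome) -> float:
        return objective(Alignment.build(row_ids, decode_block(ch)), params.scoring).objective

    width = max(n_cols, len(new_steps))
    trivial = Chromosome(
        rows,
        [
            [1] * n_cols + [0] * (width - n_cols),
            [1] * len(new_steps) + [0] * (width - len(new_steps)),
        ],
    )
    best = None
    best_fit = float("inf")
    for r in range(params.replicates):
        rng = np.random.default_rng((step_seed + r) % _SEED_MOD)
        elite, fit = evolve(rows, fitness, params, rng, inject=[trivial])
        if fit < best_fit - 1e-12:
            best, best_fit = elite, fit
    assert best is not None
    return Alignment.build(row_ids, decode_block(best))


def progressive_msa(
    cluster_members: Sequence[str],
    matrix: SimilarityMatrix,
    collection: ESSCollection,
    params: Optional[GAParams] = None,
) -> tuple[Alignment, ScoreBreakdown]:
    """Align all members of one cluster following the guide order."""
    if params is None:
        params = GAParams()
    order = build_guide_order(cluster_members, matrix)
    seqs = {m: collection.by_id(m) for m in order}
    block, _ = ga_align([seqs[order[0]], seqs[order[1]]], params)
    for step, member in enumerate(order[2:], start=1):
        step_seed = (params.seed + 101 * step) % _SEED_MOD
        block = _extend_profile(
            block, member, tuple(seqs[member].steps), params, step_seed
        )
    return block, objective(block, params.scoring)


def conserved_columns(aln: Alignment, min_identity: float = 0.8) -> list[int]:
    """Columns whose modal non-gap EC code covers at least
    ``min_identity`` of the column's non-gap cells."""
    out = []
    for j in range(aln.n_columns):
        col = [c for c in aln.column(j) if c is not GAP]
        if not col:
            continue
        top = max({c: col.count(c) for c in set(col)}.values())
        if top / len(col) >= min_identity:
            out.append(j)
    return out


def column_report(aln: Alignment) -> pd.DataFrame:
    """Per-column modal EC and identity fraction (for rendering MSAs)."""
    records = []
    for j in range(aln.n_columns):
        col = [c for c in aln.column(j) if c is not GAP]
        counts = {c: col.count(c) for c in set(col)}
        modal = max(sorted(counts, key=str), key=lambda c: counts[c])
        records.append(
            {
                "column": j,
                "modal_ec": str(modal),
                "identity_fraction": counts[modal] / len(col),
                "n_gaps": aln.n_rows - len(col),
            }
        )
    return pd.DataFrame.from_records(records)


def write_column_report(aln: Alignment, path) -> None:
    column_report(aln).to_csv(path, sep="\t", index=False)
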