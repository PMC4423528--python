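"""Genetic-algorithm optimization of EC-sequence alignments.

Chromosomes are variable-width binary gap masks (1 = enzyme, 0 = gap),
one row per sequence; decoding a mask against its sequence reproduces the
aligned row, so EC content is immutable by construction and only gaps
vary.  The population evolves by tournament selection, one-point
crossover that cuts the second parent where it has consumed the same
number of enzymes as the first parent's left side, and a gap mutation
that extends/shrinks an existing gap or opens a new one.  The best
individual is carried over unchanged (elitism) and the run stops after a
fixed number of generations without improvement of the elite objective.

Two reference aligners accompany the GA: an exhaustive enumeration
(:func:`brute_force_align`, exact on small instances) and a
Needleman-Wunsch minimizer (:func:`dp_align`) that optimizes the
homogeneity term column-by-column and is re-scored with the full
objective.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

from .ec import GAP, ECCode
from .ess import ESS
from .scoring import (
    Alignment,
    DEFAULT_CONFIG,
    ScoreBreakdown,
    ScoringConfig,
    objective,
)

_SEED_MOD = 2**31
_EPS = 1e-12


@dataclass(frozen=True)
class GAParams:
    """GA hyperparameters; defaults follow the published configuration
    (population 100, 1% mutation rate, 90% crossover, stop after 20
    stagnant generations, best of 10 replicates)."""

    population_size: int = 100
    mutation_rate: float = 0.01
    crossover_rate: float = 0.90
    stagnation_generations: int = 20
    replicates: int = 10
    tournament_size: int = 2
    #: initial-population gap budget: extra columns beyond the longest
    #: sequence available when sampling random chromosomes
    max_extra_columns: int = 3
    seed: int = 0
    #: ``per_individual``: each individual receives one mutation event per
    #: generation with probability ``individual_mutation_prob``;
    #: ``per_position``: every cell independently mutates with
    #: probability ``mutation_rate``.
    mutation_policy: str = "per_individual"
    individual_mutation_prob: float = 1.0
    max_generations: int = 500
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.mutation_policy not in ("per_individual", "per_position"):
            raise ValueError(f"bad mutation_policy {self.mutation_policy!r}")

    @classmethod
    def from_file(cls, path) -> "GAParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        scoring = data.pop("scoring", None)
        if scoring is not None:
            data["scoring"] = ScoringConfig(**scoring)
        return cls(**data)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "population_size",
                "mutation_rate",
                "crossover_rate",
                "stagnation_generations",
                "replicates",
                "tournament_size",
                "max_extra_columns",
                "seed",
                "mutation_policy",
                "individual_mutation_prob",
                "max_generations",
            )
        }
        d["scoring"] = {
            "entropy_normalization": self.scoring.entropy_normalization,
            "gap_concentration_mode": self.scoring.gap_concentration_mode,
            "column_increment_mode": self.scoring.column_increment_mode,
        }
        return d


def _strip_mask_columns(masks: list[list[int]]) -> list[list[int]]:
    """Remove columns that are gaps in every row."""
    width = len(masks[0])
    keep = [j for j in range(width) if any(m[j] for m in masks)]
    if len(keep) == width:
        return masks
    return [[m[j] for j in keep] for m in masks]


@dataclass
class Chromosome:
    """Binary gap masks over fixed per-row item tuples.

    ``rows`` holds the unaligned items of each row (EC codes for plain
    alignments; opaque items for profile extension).  Row r's mask has
    exactly ``len(rows[r])`` ones.
    """

    rows: tuple[tuple, ...]
    masks: list[list[int]]
    fitness: Optional[float] = None

    def __post_init__(self) -> None:
        widths = {len(m) for m in self.masks}
        if len(widths) != 1:
            raise ValueError("ragged chromosome masks")
        for items, mask in zip(self.rows, self.masks):
            if sum(mask) != len(items):
                raise ValueError("mask ones do not match row item count")

    @property
    def width(self) -> int:
        return len(self.masks[0])

    def copy(self) -> "Chromosome":
        return Chromosome(self.rows, [m[:] for m in self.masks], self.fitness)

    def decode(self) -> tuple[tuple, ...]:
        """Expand masks into grid rows (items interleaved with gaps)."""
        grid = []
        for items, mask in zip(self.rows, self.masks):
            it = iter(items)
            grid.append(tuple(next(it) if bit else GAP for bit in mask))
        return tuple(grid)


def _random_chromosome(
    rows: tuple[tuple, ...], params: GAParams, rng: np.random.Generator
) -> Chromosome:
    lmax = max(len(r) for r in rows)
    width = int(rng.integers(lmax, lmax + params.max_extra_columns + 1))
    masks = []
    for items in rows:
        mask = [0] * width
        for pos in rng.choice(width, size=len(items), replace=False):
            mask[int(pos)] = 1
        masks.append(mask)
    return Chromosome(rows, _strip_mask_columns(masks))


def init_population(
    seqs: Sequence[ESS], params: GAParams, rng: Optional[np.random.Generator] = None
) -> list[Chromosome]:
    """Random initial population of variable-width chromosomes; every
    chromosome decodes back to the input sequences."""
    if len(seqs) < 2:
        raise ValueError("alignment needs at least two sequences")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rows = tuple(tuple(s.steps) for s in seqs)
    return [
        _random_chromosome(rows, params, rng) for _ in range(params.population_size)
    ]


def tournament_select(
    population: Sequence[Chromosome], params: GAParams, rng: np.random.Generator
) -> Chromosome:
    """Sample ``tournament_size`` individuals with replacement; return the
    minimal-objective one, ties broken by first sampled."""
    if not population:
        raise ValueError("empty population")
    idx = rng.integers(0, len(population), size=params.tournament_size)
    best = population[int(idx[0])]
    for i in idx[1:]:
        cand = population[int(i)]
        if cand.fitness < best.fitness:  # strict: first-sampled wins ties
            best = cand
    return best


def _cut_after_consumed(mask: Sequence[int], n_items: int) -> int:
    """Index just after the position where ``mask`` has consumed
    ``n_items`` ones (the shortest such prefix)."""
    if n_items == 0:
        return 0
    seen = 0
    for j, bit in enumerate(mask):
        seen += bit
        if seen == n_items:
            return j + 1
    raise ValueError("mask holds fewer items than requested")


def crossover(
    parent1: Chromosome, parent2: Chromosome, cut_column: int
) -> tuple[Chromosome, Chromosome]:
    """One-point crossover at ``cut_column`` of parent 1.

    Parent 2 is cut per row after consuming the same number of enzymes as
    parent 1 holds left of the cut, so EC content is conserved; shorter
    sides are padded with gaps (right sides on their left edge, left
    sides on their right edge) to keep offspring rectangular.
    """
    if parent1.rows != parent2.rows:
        raise ValueError("parents encode different sequence sets")
    if not 1 <= cut_column < parent1.width:
        raise ValueError(f"cut_column {cut_column} outside 1..{parent1.width - 1}")
    lefts1 = [m[:cut_column] for m in parent1.masks]
    cuts2 = [
        _cut_after_consumed(m2, sum(l1))
        for m2, l1 in zip(parent2.masks, lefts1)
    ]
    rights2 = [m[c:] for m, c in zip(parent2.masks, cuts2)]
    lefts2 = [m[:c] for m, c in zip(parent2.masks, cuts2)]
    rights1 = [m[cut_column:] for m in parent1.masks]

    r2max = max(len(r) for r in rights2)
    off1 = [
        l + [0] * (r2max - len(r)) + r for l, r in zip(lefts1, rights2)
    ]
    l2max = max(len(l) for l in lefts2)
    off2 = [
        l + [0] * (l2max - len(l)) + r for l, r in zip(lefts2, rights1)
    ]
    return (
        Chromosome(parent1.rows, _strip_mask_columns(off1)),
        Chromosome(parent1.rows, _strip_mask_columns(off2)),
    )


def mutate(ch: Chromosome, rng: np.random.Generator) -> Chromosome:
    """One gap-mutation event at a uniformly chosen (row, position).

    A gap is extended or removed with equal probability; an enzyme
    position gets a gap inserted before it.  Rows are re-padded to stay
    rectangular and all-gap columns are dropped.
    """
    n_rows = len(ch.masks)
    width = ch.width
    flat = int(rng.integers(0, n_rows * width))
    r, p = divmod(flat, width)
    masks = [m[:] for m in ch.masks]
    if masks[r][p] == 0:
        if rng.random() < 0.5:
            masks[r].insert(p, 0)  # extend the gap by one
            for i in range(n_rows):
                if i != r:
                    masks[i].append(0)
        else:
            del masks[r][p]  # shrink the gap
            masks[r].append(0)
    else:
        masks[r].insert(p, 0)  # open a gap before this enzyme
        for i in range(n_rows):
            if i != r:
                masks[i].append(0)
    return Chromosome(ch.rows, _strip_mask_columns(masks))


def _apply_mutation(
    ch: Chromosome, params: GAParams, rng: np.random.Generator
) -> Chromosome:
    if params.mutation_policy == "per_individual":
        if rng.random() < params.individual_mutation_prob:
            return mutate(ch, rng)
        return ch
    # per_position: number of events ~ Binomial(cells, rate), applied
    # sequentially (coordinates re-drawn each event as masks reshape)
    n_events = int(rng.binomial(len(ch.masks) * ch.width, params.mutation_rate))
    for _ in range(n_events):
        ch = mutate(ch, rng)
    return ch


# ---------------------------------------------------------------------------
# fitness


def _fast_pair_objective(
    mask_a: Sequence[int],
    mask_b: Sequence[int],
    levels_a: Sequence[tuple[str, str, str]],
    levels_b: Sequence[tuple[str, str, str]],
) -> float:
    """Two-row objective under the default scoring config, inlined for
    speed; must agree with :func:`essalign.scoring.objective` (tested)."""
    width = len(mask_a)
    ia = ib = 0
    hom = 0.0
    for j in range(width):
        a = mask_a[j]
        b = mask_b[j]
        if a and b:
            la = levels_a[ia]
            lb = levels_b[ib]
            ia += 1
            ib += 1
            d = 0.0
            if la[0] != lb[0]:
                d += 15.0
            if la[1] != lb[1]:
                d += 10.0
            if la[2] != lb[2]:
                d += 5.0
            hom += 0.6 * (d / 30.0)
        else:
            # exactly one gap (all-gap columns are stripped): entropy 1 at
            # every level and gap fraction 1/(2-1)
            hom += 1.0
            if a:
                ia += 1
            else:
                ib += 1
    h = hom / width
    gc = _mask_gap_concentration(mask_a, mask_b)
    ci = max(len(levels_a), len(levels_b)) / width
    return 0.9 * h + 0.05 * gc + 0.05 * ci


def _internal_runs_of_mask(mask: Sequence[int]) -> tuple[int, int]:
    """(total internal gaps, internal gap-block count) of one mask row."""
    total = blocks = 0
    start = None
    for j, bit in enumerate(mask):
        if bit == 0:
            if start is None:
                start = j
        else:
            if start is not None and start > 0:
                total += j - start
                blocks += 1
            start = None
    return total, blocks


def _mask_gap_concentration(mask_a: Sequence[int], mask_b: Sequence[int]) -> float:
    ga, ba = _internal_runs_of_mask(mask_a)
    gb, bb = _internal_runs_of_mask(mask_b)
    total = ga + gb
    if total == 0:
        return 0.0
    # literal GC = mean block length / total gaps = 1 / block count
    return 1.0 / (ba + bb)


def _make_fitness(
    rows: tuple[tuple, ...], row_ids: tuple[str, ...], config: ScoringConfig
) -> Callable[[Chromosome], float]:
    if len(rows) == 2 and config.is_default:
        levels_a = [ec.levels for ec in rows[0]]
        levels_b = [ec.levels for ec in rows[1]]

        def fast(ch: Chromosome) -> float:
            return _fast_pair_objective(ch.masks[0], ch.masks[1], levels_a, levels_b)

        return fast

    def generic(ch: Chromosome) -> float:
        aln = Alignment(row_ids, ch.decode())
        return objective(aln, config).objective

    return generic


def evolve(
    rows: tuple[tuple, ...],
    fitness_fn: Callable[[Chromosome], float],
    params: GAParams,
    rng: np.random.Generator,
    inject: Sequence[Chromosome] = (),
) -> tuple[Chromosome, float]:
    """One GA run over gap masks for arbitrary row items.

    ``inject`` seeds known-feasible chromosomes into the initial
    population (the remainder is random).  Returns the elite chromosome
    and its objective.  The elite is copied unchanged each generation and
    the run stops after ``stagnation_generations`` generations without
    improvement.
    """
    cache: dict[tuple, float] = {}

    def evaluate(ch: Chromosome) -> Chromosome:
        key = tuple(tuple(m) for m in ch.masks)
        f = cache.get(key)
        if f is None:
            f = fitness_fn(ch)
            cache[key] = f
        ch.fitness = f
        return ch

    population = [evaluate(ch.copy()) for ch in inject]
    while len(population) < params.population_size:
        population.append(evaluate(_random_chromosome(rows, params, rng)))

    elite = min(population, key=lambda c: c.fitness)
    best_fit = elite.fitness
    two_rows = len(rows) == 2
    stagnant = 0
    generation = 0
    while stagnant < params.stagnation_generations and generation < params.max_generations:
        if two_rows and best_fit <= 0.05 + _EPS:
            break  # provable two-row optimum (identical sequences, gapless)
        generation += 1
        new_pop = [elite.copy()]
        while len(new_pop) < params.population_size:
            p1 = tournament_select(population, params, rng)
            p2 = tournament_select(population, params, rng)
            if rng.random() < params.crossover_rate and p1.width > 1:
                cut = int(rng.integers(1, p1.width))
                c1, c2 = crossover(p1, p2, cut)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                child = _apply_mutation(child, params, rng)
                new_pop.append(evaluate(child))
                if len(new_pop) >= params.population_size:
                    break
        population = new_pop
        gen_best = min(population, key=lambda c: c.fitness)
        if gen_best.fitness < best_fit - _EPS:
            best_fit = gen_best.fitness
            elite = gen_best
            stagnant = 0
        else:
            stagnant += 1
    return elite, best_fit


def ga_align(
    seqs: Sequence[ESS], params: Optional[GAParams] = None
) -> tuple[Alignment, ScoreBreakdown]:
    """Best-of-replicates GA alignment of two or more sequences.

    The unordered input is canonicalized by ess_id before seeding so that
    ``ga_align(A, B)`` and ``ga_align(B, A)`` produce the same objective;
    output rows follow the input order.
    """
    if params is None:
        params = GAParams()
    if len(seqs) < 2:
        raise ValueError("alignment needs at least two sequences")
    order = sorted(range(len(seqs)), key=lambda i: seqs[i].ess_id)
    canon = [seqs[i] for i in order]
    rows = tuple(tuple(s.steps) for s in canon)
    row_ids = tuple(s.ess_id for s in canon)
    fitness_fn = _make_fitness(rows, row_ids, params.scoring)

    best: Optional[Chromosome] = None
    best_fit = float("inf")
    for r in range(params.replicates):
        rng = np.random.default_rng((params.seed + r) % _SEED_MOD)
        elite, fit = evolve(rows, fitness_fn, params, rng)
        if fit < best_fit - _EPS:
            best, best_fit = elite, fit
        if len(rows) == 2 and best_fit <= 0.05 + _EPS:
            break
    assert best is not None
    grid = best.decode()
    # back to input row order
    inverse = [0] * len(order)
    for rank, i in enumerate(order):
        inverse[i] = rank
    aln = Alignment(
        tuple(seqs[i].ess_id for i in range(len(seqs))),
        tuple(grid[inverse[i]] for i in range(len(seqs))),
    )
    return aln, objective(aln, params.scoring)


# ---------------------------------------------------------------------------
# exhaustive oracle


def _level_codes(
    seqs: Sequence[tuple[ECCode, ...]]
) -> list[np.ndarray]:
    """Map level tokens to small ints; gap stays -1."""
    vocab: dict[str, int] = {}

    def code(tok: str) -> int:
        if tok not in vocab:
            vocab[tok] = len(vocab)
        return vocab[tok]

    out = []
    for steps in seqs:
        arr = np.array([[code(t) for t in ec.levels] for ec in steps], dtype=np.int32)
        out.append(arr)
    return out


def _mask_tables(length: int, width: int):
    """All placements of ``length`` symbols in ``width`` columns.

    Returns (positions array [n, length], internal gap counts [n],
    internal block counts [n], gap bitmasks [n]) in lexicographic
    position order.
    """
    combos = list(itertools.combinations(range(width), length))
    pos = np.array(combos, dtype=np.int32).reshape(len(combos), length)
    gaps = np.zeros(len(combos), dtype=np.int64)
    blocks = np.zeros(len(combos), dtype=np.int64)
    bits = np.zeros(len(combos), dtype=np.int64)
    full = (1 << width) - 1
    for i, c in enumerate(combos):
        internal = (c[-1] - c[0] + 1) - length
        gaps[i] = internal
        blocks[i] = sum(1 for a, b in zip(c, c[1:]) if b - a > 1)
        occupied = 0
        for p in c:
            occupied |= 1 << p
        bits[i] = full & ~occupied
    return pos, gaps, blocks, bits


def brute_force_align(
    seq_a: ESS,
    seq_b: ESS,
    max_width: Optional[int] = None,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> tuple[Alignment, ScoreBreakdown]:
    """Global optimum over every pairwise gap placement up to
    ``max_width`` columns (default: len(A)+len(B)).

    Deterministic tie-break: fewest columns first, then lexicographic
    symbol-position pattern.  Instances are capped at length 6 per
    sequence.  Default scoring is evaluated with a vectorized scorer
    equivalent to :func:`essalign.scoring.objective`; non-default
    configs fall back to plain enumeration.
    """
    la, lb = len(seq_a), len(seq_b)
    if la > 6 or lb > 6:
        raise ValueError("brute force capped at sequence length 6")
    lmax, lsum = max(la, lb), la + lb
    if max_width is None:
        max_width = lsum
    if not lmax <= max_width <= lsum:
        raise ValueError(f"max_width must lie in [{lmax}, {lsum}]")
    if not config.is_default:
        return _brute_force_naive(seq_a, seq_b, max_width, config)

    lv_a, lv_b = _level_codes([tuple(seq_a.steps), tuple(seq_b.steps)])
    weights = np.array([15.0, 10.0, 5.0])
    best_val = np.inf
    best_pick = None  # (width, positions_a, positions_b)
    for width in range(lmax, max_width + 1):
        pos_a, gaps_a, blocks_a, bits_a = _mask_tables(la, width)
        pos_b, gaps_b, blocks_b, bits_b = _mask_tables(lb, width)
        # expand sequences into gapped level grids, gap = -1
        grid_a = np.full((len(pos_a), width, 3), -1, dtype=np.int32)
        np.put_along_axis(grid_a, pos_a[:, :, None], lv_a[None, :, :], axis=1)
        grid_b = np.full((len(pos_b), width, 3), -1, dtype=np.int32)
        np.put_along_axis(grid_b, pos_b[:, :, None], lv_b[None, :, :], axis=1)

        chunk = 256
        n_one_gap = 2 * width - lsum  # gap cells in any valid alignment
        ci = lmax / width
        for start in range(0, len(pos_a), chunk):
            ga = grid_a[start : start + chunk]
            diff = ga[:, None, :, :] != grid_b[None, :, :, :]
            wsum = (diff @ weights).sum(axis=2)  # per pair, over columns
            hom = (0.6 * wsum / 30.0 + 0.4 * n_one_gap) / width
            gp = gaps_a[start : start + chunk, None] + gaps_b[None, :]
            blocks = blocks_a[start : start + chunk, None] + blocks_b[None, :]
            with np.errstate(divide="ignore"):
                gc = np.where(gp > 0, 1.0 / np.maximum(blocks, 1), 0.0)
            val = 0.9 * hom + 0.05 * gc + 0.05 * ci
            invalid = (bits_a[start : start + chunk, None] & bits_b[None, :]) != 0
            val = np.where(invalid, np.inf, val)
            flat = int(np.argmin(val))
            if val.flat[flat] < best_val - _EPS:
                best_val = float(val.flat[flat])
                i, j = divmod(flat, val.shape[1])
                best_pick = (width, pos_a[start + i], pos_b[j])
    assert best_pick is not None
    width, pa, pb = best_pick
    row_a: list = [GAP] * width
    for k, p in enumerate(pa):
        row_a[int(p)] = seq_a.steps[k]
    row_b: list = [GAP] * width
    for k, p in enumerate(pb):
        row_b[int(p)] = seq_b.steps[k]
    aln = Alignment((seq_a.ess_id, seq_b.ess_id), (tuple(row_a), tuple(row_b)))
    return aln, objective(aln, config)


def _brute_force_naive(
    seq_a: ESS, seq_b: ESS, max_width: int, config: ScoringConfig
) -> tuple[Alignment, ScoreBreakdown]:
    """Plain enumeration scoring each candidate with the public
    objective; used for non-default configs and as a cross-check."""
    la, lb = len(seq_a), len(seq_b)
    best: Optional[tuple[Alignment, ScoreBreakdown]] = None
    for width in range(max(la, lb), max_width + 1):
        for pa in itertools.combinations(range(width), la):
            row_a: list = [GAP] * width
            for k, p in enumerate(pa):
                row_a[p] = seq_a.steps[k]
            for pb in itertools.combinations(range(width), lb):
                row_b: list = [GAP] * width
                for k, p in enumerate(pb):
                    row_b[p] = seq_b.steps[k]
                if any(a is GAP and b is GAP for a, b in zip(row_a, row_b)):
                    continue
                aln = Alignment(
                    (seq_a.ess_id, seq_b.ess_id), (tuple(row_a), tuple(row_b))
                )
                score = objective(aln, config)
                if best is None or score.objective < best[1].objective - _EPS:
                    best = (aln, score)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# dynamic-programming baseline


def dp_align(
    seq_a: ESS, seq_b: ESS, config: ScoringConfig = DEFAULT_CONFIG
) -> tuple[Alignment, ScoreBreakdown]:
    """Needleman-Wunsch minimization with the method's column costs.

    Substituting two ECs costs 0.6 * their two-row column entropy; a gap
    column costs 1.0 (the homogeneity of an [EC, gap] column).  The two
    global terms (gap concentration, column increment) cannot enter the
    recursion, so the traced-back alignment is re-scored with the full
    objective to stay comparable with the GA.  Tie preference:
    substitution, then gap in B, then gap in A.
    """
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise ValueError("empty sequence")
    la, lb = len(seq_a), len(seq_b)
    gap_cost = 1.0

    def sub_cost(a: ECCode, b: ECCode) -> float:
        d = 0.0
        if a.level1 != b.level1:
            d += 15.0
        if a.level2 != b.level2:
            d += 10.0
        if a.level3 != b.level3:
            d += 5.0
        return 0.6 * d / 30.0

    dist = np.zeros((la + 1, lb + 1))
    move = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up(gap B), 2 left(gap A)
    dist[:, 0] = np.arange(la + 1) * gap_cost
    dist[0, :] = np.arange(lb + 1) * gap_cost
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = dist[i - 1, j - 1] + sub_cost(seq_a.steps[i - 1], seq_b.steps[j - 1])
            up = dist[i - 1, j] + gap_cost
            left = dist[i, j - 1] + gap_cost
            best, m = diag, 0
            if up < best - _EPS:
                best, m = up, 1
            if left < best - _EPS:
                best, m = left, 2
            dist[i, j] = best
            move[i, j] = m
    row_a: list = []
    row_b: list = []
    i, j = la, lb
    while i > 0 or j > 0:
        m = move[i, j]
        if m == 0:
            row_a.append(seq_a.steps[i - 1])
            row_b.append(seq_b.steps[j - 1])
            i -= 1
            j -= 1
        elif m == 1:
            row_a.append(seq_a.steps[i - 1])
            row_b.append(GAP)
            i -= 1
        else:
            row_a.append(GAP)
            row_b.append(seq_b.steps[j - 1])
            j -= 1
    aln = Alignment(
        (seq_a.ess_id, seq_b.ess_id), (tuple(row_a[::-1]), tuple(row_b[::-1]))
    )
    return aln, objective(aln, config)
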