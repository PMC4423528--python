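"""All-against-all similarity, significance, and k-medoids clustering.

The fitness (objective) of the best GA alignment of every unordered pair
of sequences fills a symmetric matrix with zero diagonal; low values mean
similar sequences, so the matrix doubles as a dissimilarity for PAM-style
k-medoids.  Significance is assessed against shuffled sequence sets that
conserve every sequence's length and the global EC composition, with the
score cutoff taken as mean - 3*SD of the real score distribution.  The
number of clusters is picked where the quality curve bends most sharply
(maximal discrete second derivative), and clusters are *depurated* by
dropping members whose mean fitness with their cluster mates exceeds the
cutoff.
"""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .ec import ECCode
from .ess import ESS, ESSCollection
from .ga import GAParams, ga_align

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of best pairwise alignment objectives."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def index(self, ess_id: str) -> int:
        try:
            return self.ids.index(ess_id)
        except ValueError:
            raise KeyError(ess_id) from None

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle scores (one per unordered pair)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def submatrix(self, ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.index(i) for i in ids]
        return SimilarityMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(["ess_id", *self.ids]) + "\n")
            for i, rid in enumerate(self.ids):
                fh.write(
                    "\t".join([rid, *(f"{v:.10g}" for v in self.values[i])]) + "\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "SimilarityMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(tuple(header), np.array(rows, dtype=float))

    def write_long_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\tfitness\n")
            for i, a in enumerate(self.ids):
                for j in range(i + 1, len(self.ids)):
                    fh.write(f"{a}\t{self.ids[j]}\t{self.values[i, j]:.10g}\n")


def _pair_seed(base_seed: int, id_a: str, id_b: str) -> int:
    a, b = sorted((id_a, id_b))
    return (base_seed + zlib.crc32(f"{a}\t{b}".encode())) % _SEED_MOD


def _params_key(params: GAParams) -> str:
    return f"{zlib.crc32(json.dumps(params.to_dict(), sort_keys=True).encode()):08x}"


def all_vs_all(
    collection: ESSCollection,
    params: Optional[GAParams] = None,
    cache_path=None,
    progress: bool = False,
) -> SimilarityMatrix:
    """GA objective for every unordered pair, stored symmetrically with a
    zero diagonal.

    Each pair gets a deterministic sub-seed derived from the base seed
    and the pair's ids, so the matrix is reproducible and independent of
    computation order.  An optional on-disk cache (long-format TSV keyed
    by pair and parameter hash) makes reruns resumable.
    """
    if params is None:
        params = GAParams()
    if len(collection) < 2:
        raise ValueError("need at least two sequences")
    items = list(collection)
    ids = tuple(e.ess_id for e in items)
    pkey = _params_key(params)
    cached: dict[tuple[str, str], float] = {}
    if cache_path is not None and os.path.exists(cache_path):
        with open(cache_path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 4 and fields[2] == pkey:
                    cached[(fields[0], fields[1])] = float(fields[3])
    cache_fh = open(cache_path, "a") if cache_path is not None else None
    n = len(items)
    values = np.zeros((n, n))
    n_pairs = n * (n - 1) // 2
    done = 0
    try:
        for i in range(n):
            for j in range(i + 1, n):
                key = tuple(sorted((ids[i], ids[j])))
                if key in cached:
                    score = cached[key]
                else:
                    pair_params = replace(
                        params, seed=_pair_seed(params.seed, ids[i], ids[j])
                    )
                    _, breakdown = ga_align([items[i], items[j]], pair_params)
                    score = breakdown.objective
                    if cache_fh is not None:
                        cache_fh.write(f"{key[0]}\t{key[1]}\t{pkey}\t{score:.12g}\n")
                values[i, j] = values[j, i] = score
                done += 1
                if progress and done % 200 == 0:
                    logger.info("all_vs_all: %d/%d pairs", done, n_pairs)
    finally:
        if cache_fh is not None:
            cache_fh.close()
    return SimilarityMatrix(ids, values)


def shuffle_ess(collection: ESSCollection, seed: int) -> ESSCollection:
    """Pool every EC token, permute uniformly, and redistribute into
    sequences of the original lengths and order.  Conserves the global
    EC composition and every sequence's length exactly."""
    if len(collection) == 0:
        raise ValueError("empty collection")
    rng = np.random.default_rng(seed)
    pool: list[ECCode] = [ec for e in collection for ec in e.steps]
    perm = rng.permutation(len(pool))
    shuffled = [pool[int(k)] for k in perm]
    items = []
    cursor = 0
    for e in collection:
        steps = tuple(shuffled[cursor : cursor + len(e)])
        cursor += len(e)
        items.append(ESS(e.ess_id, e.map_id, e.root_id, steps))
    return ESSCollection(items=items, provenance=list(collection.provenance))


def significance_threshold(real_scores: Sequence[float]) -> float:
    """mean - 3*SD (sample SD) of the real score distribution."""
    scores = np.asarray(real_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores")
    return float(scores.mean() - 3.0 * scores.std(ddof=1))


def fraction_below(
    scores: Sequence[float], threshold: float, strict: bool = True
) -> float:
    """Proportion of scores below the threshold (strictly by default)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty scores")
    hits = scores < threshold if strict else scores <= threshold
    return float(hits.mean())


@dataclass
class NullModel:
    """Shuffled-set null distribution for alignment scores."""

    n_sets: int
    shuffled_sets: list[ESSCollection]
    null_scores: list[np.ndarray]
    threshold: float

    @property
    def null_fractions(self) -> list[float]:
        return [fraction_below(s, self.threshold) for s in self.null_scores]


def build_null_model(
    collection: ESSCollection,
    real_scores: Sequence[float],
    params: Optional[GAParams] = None,
    n_sets: int = 10,
    seed: int = 0,
    threshold: Optional[float] = None,
) -> NullModel:
    """Construct ``n_sets`` shuffled collections, align each all-vs-all,
    and compare against a threshold (mean - 3*SD of the real scores by
    default)."""
    if threshold is None:
        threshold = significance_threshold(real_scores)
    sets = []
    scores = []
    for t in range(n_sets):
        shuffled = shuffle_ess(collection, (seed + 7919 * (t + 1)) % _SEED_MOD)
        sets.append(shuffled)
        matrix = all_vs_all(shuffled, params)
        scores.append(matrix.condensed())
    return NullModel(
        n_sets=n_sets, shuffled_sets=sets, null_scores=scores, threshold=threshold
    )


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterModel:
    """k-medoids partition over a similarity matrix.

    ``assignment`` keeps every id (including ones flagged by depuration);
    ``quality`` is the total dissimilarity of non-removed members to
    their medoids.
    """

    k: int
    medoids: tuple[str, ...]
    assignment: dict[str, int]
    quality: float
    removed_by_depuration: tuple[str, ...] = ()

    def members(self, cluster: int, include_removed: bool = True) -> list[str]:
        removed = set(self.removed_by_depuration)
        return [
            i
            for i, c in self.assignment.items()
            if c == cluster and (include_removed or i not in removed)
        ]

    def to_json(self, path=None) -> str:
        payload = {
            "k": self.k,
            "medoids": list(self.medoids),
            "clusters": [
                {"id": c, "medoid": self.medoids[c], "members": self.members(c)}
                for c in range(self.k)
            ],
            "removed": list(self.removed_by_depuration),
            "quality": self.quality,
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            payload = json.load(fh)
        assignment = {
            m: cl["id"] for cl in payload["clusters"] for m in cl["members"]
        }
        return cls(
            k=payload["k"],
            medoids=tuple(payload["medoids"]),
            assignment=assignment,
            quality=payload["quality"],
            removed_by_depuration=tuple(payload["removed"]),
        )

    def write_tsv(self, path) -> None:
        removed = set(self.removed_by_depuration)
        with open(path, "w") as fh:
            fh.write("ess_id\tcluster\tremoved\n")
            for i, c in self.assignment.items():
                fh.write(f"{i}\t{c}\t{int(i in removed)}\n")


def kmedoids(
    matrix: SimilarityMatrix,
    k: int,
    replicates: int = 20,
    seed: int = 0,
) -> ClusterModel:
    """PAM-style alternating k-medoids on the precomputed matrix; best
    quality over ``replicates`` random initializations."""
    n = len(matrix.ids)
    if not 2 <= k < n:
        raise ValueError(f"k must lie in [2, {n - 1}]")
    dist = matrix.values
    rng = np.random.default_rng(seed)
    best: Optional[tuple[float, np.ndarray, np.ndarray]] = None
    for _ in range(replicates):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        for _ in range(200):
            assign = np.argmin(dist[:, medoids], axis=1)
            assign[medoids] = np.arange(k)  # a medoid stays in its own cluster
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(assign == c)
                within = dist[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[int(np.argmin(within))]
            new_medoids = np.sort(new_medoids)
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        assign = np.argmin(dist[:, medoids], axis=1)
        assign[medoids] = np.arange(k)
        quality = float(dist[np.arange(n), medoids[assign]].sum())
        if best is None or quality < best[0] - 1e-12:
            best = (quality, medoids, assign)
    assert best is not None
    quality, medoids, assign = best
    return ClusterModel(
        k=k,
        medoids=tuple(matrix.ids[m] for m in medoids),
        assignment={matrix.ids[i]: int(assign[i]) for i in range(n)},
        quality=quality,
    )


@dataclass
class ElbowResult:
    """Cluster count selected by the maximal discrete second derivative
    of the quality curve, with the curve and candidate peaks retained
    for inspection."""

    k: int
    ks: tuple[int, ...]
    quality: tuple[float, ...]
    second_diff: dict[int, float]
    peaks: tuple[int, ...]
    degenerate: bool = False


def elbow_select(
    matrix: SimilarityMatrix,
    k_min: int = 2,
    k_max: int = 100,
    replicates: int = 20,
    seed: int = 0,
) -> ElbowResult:
    """Compute Q(k) (best of ``replicates``) for k_min..k_max and return
    the k maximizing Q(k-1) - 2 Q(k) + Q(k+1); ties take the smallest k
    and are flagged as degenerate."""
    n = len(matrix.ids)
    if k_max >= n:
        raise ValueError(f"k_max must be < number of sequences ({n})")
    ks = list(range(k_min, k_max + 1))
    if len(ks) < 3:
        raise ValueError("elbow selection needs at least three k values")
    quality = [
        kmedoids(matrix, k, replicates=replicates, seed=seed).quality for k in ks
    ]
    second = {
        ks[i]: quality[i - 1] - 2.0 * quality[i] + quality[i + 1]
        for i in range(1, len(ks) - 1)
    }
    best_k = min(second)
    for k in sorted(second):
        if second[k] > second[best_k] + 1e-12:
            best_k = k
    values = sorted(set(round(v, 12) for v in second.values()))
    degenerate = len(values) == 1
    if degenerate:
        logger.warning("elbow: flat second derivative, returning smallest k")
    peaks = tuple(sorted(second, key=lambda k: (-second[k], k))[:5])
    return ElbowResult(
        k=best_k,
        ks=tuple(ks),
        quality=tuple(quality),
        second_diff=second,
        peaks=peaks,
        degenerate=degenerate,
    )


def depurate(
    model: ClusterModel,
    matrix: SimilarityMatrix,
    cutoff: float,
    cascade: bool = False,
) -> ClusterModel:
    """Flag members whose mean fitness with the rest of their cluster
    exceeds ``cutoff``.

    Single pass by default: means are computed against the cluster's
    full original membership and removals applied once, which makes the
    operation idempotent.  ``cascade`` re-evaluates against survivors
    until a fixpoint.  Singleton clusters are retained untouched.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    removed = set(model.removed_by_depuration)

    def pass_over(active_only: bool) -> set[str]:
        newly: set[str] = set()
        for c in range(model.k):
            members = model.members(c)
            if active_only:
                members = [m for m in members if m not in removed]
            for m in members:
                others = [o for o in members if o != m]
                if not others:
                    continue
                mean_fit = float(
                    np.mean([matrix.get(m, o) for o in others])
                )
                if mean_fit > cutoff:
                    newly.add(m)
        return newly

    if cascade:
        while True:
            newly = pass_over(active_only=True) - removed
            if not newly:
                break
            removed |= newly
    else:
        removed |= pass_over(active_only=False)

    survivors_quality = 0.0
    for i, c in model.assignment.items():
        if i in removed:
            continue
        survivors_quality += matrix.get(i, model.medoids[c])
    return ClusterModel(
        k=model.k,
        medoids=model.medoids,
        assignment=dict(model.assignment),
        quality=survivors_quality,
        removed_by_depuration=tuple(sorted(removed)),
    )
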