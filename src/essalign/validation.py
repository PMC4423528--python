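"""End-to-end validation experiments on synthetic data.

These drivers reproduce, at desk scale, the qualitative behaviour the
method is expected to show: the GA matching an exhaustive oracle on
small instances, operator contracts holding under fuzzing, planted
cluster structure being recovered by the elbow criterion and k-medoids,
shuffled sequence sets scoring clearly worse than real ones, and the
dynamic-programming baseline ranking pairs like the GA does.

The GA settings used here are scaled down from the published defaults
(smaller populations, fewer replicates) so a full battery runs in
minutes on one CPU; the defaults on :class:`~essalign.ga.GAParams`
remain the published configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from .ec import ECCode
from .ess import ESS
from .ga import GAParams, brute_force_align, dp_align, ga_align, init_population, mutate, crossover
from .scoring import Alignment, objective
from .similarity import (
    all_vs_all,
    depurate,
    elbow_select,
    fraction_below,
    kmedoids,
    shuffle_ess,
)
from .synthetic import (
    diverse_alphabet,
    generate_ess_blocks,
    merge_collections,
    random_ess_collection,
)

_SEED_MOD = 2**31

#: scaled-down GA for the exhaustive oracle sweep (short sequences)
SWEEP_GA = GAParams(
    population_size=20,
    replicates=2,
    stagnation_generations=8,
    max_extra_columns=2,
)

#: scaled-down GA for matrix-scale experiments (hundreds of pairs)
EXPERIMENT_GA = GAParams(
    population_size=16,
    replicates=1,
    stagnation_generations=6,
    max_extra_columns=2,
)

#: three-code alphabet exercising third-level-only and all-level
#: disagreements
SWEEP_ALPHABET = (
    ECCode("2", "7", "1"),
    ECCode("2", "7", "2"),
    ECCode("5", "3", "1"),
)


def _enumerate_sequences(alphabet: Sequence[ECCode], max_len: int) -> list[ESS]:
    seqs = []
    idx = 0
    for length in range(1, max_len + 1):
        for combo in itertools.product(alphabet, repeat=length):
            seqs.append(
                ESS(ess_id=f"e{idx:04d}", map_id="enum", root_id="r0", steps=combo)
            )
            idx += 1
    return seqs


def oracle_sweep(
    seed: int = 0,
    max_len: int = 4,
    n_random: int = 200,
    ga_params: Optional[GAParams] = None,
) -> dict:
    """GA vs exhaustive optimum vs DP baseline on every unordered pair
    of sequences up to ``max_len`` over the three-code alphabet, plus
    ``n_random`` random extra pairs."""
    if ga_params is None:
        ga_params = SWEEP_GA
    seqs = _enumerate_sequences(SWEEP_ALPHABET, max_len)
    pairs = list(itertools.combinations(range(len(seqs)), 2))
    rng = np.random.default_rng(seed)
    extra = []
    for i in range(n_random):
        la, lb = rng.integers(1, max_len + 1, size=2)
        a = ESS(
            f"r{i:04d}a", "rnd", "r0",
            tuple(SWEEP_ALPHABET[int(k)] for k in rng.integers(3, size=la)),
        )
        b = ESS(
            f"r{i:04d}b", "rnd", "r0",
            tuple(SWEEP_ALPHABET[int(k)] for k in rng.integers(3, size=lb)),
        )
        extra.append((a, b))

    n_match = n_below = n_dp_ge = 0
    total = 0
    for pair_idx, ab in enumerate(
        itertools.chain(((seqs[i], seqs[j]) for i, j in pairs), extra)
    ):
        a, b = ab
        _, bf = brute_force_align(a, b)
        params = replace(ga_params, seed=(seed + pair_idx) % _SEED_MOD)
        _, ga = ga_align([a, b], params)
        _, dp = dp_align(a, b)
        total += 1
        if abs(ga.objective - bf.objective) <= 1e-9:
            n_match += 1
        if ga.objective < bf.objective - 1e-9:
            n_below += 1
        if dp.objective >= bf.objective - 1e-9:
            n_dp_ge += 1
    return {
        "n_pairs": total,
        "ga_match_rate": n_match / total,
        "ga_below_oracle": n_below,
        "dp_ge_oracle_rate": n_dp_ge / total,
    }


def operator_fuzz(n_cases: int = 10000, seed: int = 0) -> dict:
    """Fuzz the GA operators: crossover and mutation must preserve
    per-row EC multisets and decode invariance, keep chromosomes
    rectangular, and leave no all-gap column; alignment scores must be
    row-permutation invariant and unaffected by an appended all-gap
    column (checked on a subsample)."""
    rng = np.random.default_rng(seed)
    alphabet = SWEEP_ALPHABET
    violations = 0
    params = GAParams(population_size=2, max_extra_columns=3)
    for case in range(n_cases):
        n_rows = int(rng.integers(2, 5))
        seqs = [
            ESS(
                f"f{case}_{r}", "fuzz", "r0",
                tuple(
                    alphabet[int(k)]
                    for k in rng.integers(3, size=int(rng.integers(1, 6)))
                ),
            )
            for r in range(n_rows)
        ]
        pop = init_population(seqs, params, rng)
        parent1, parent2 = pop[0], pop[1]
        if rng.random() < 0.5 and parent1.width > 1:
            cut = int(rng.integers(1, parent1.width))
            children = crossover(parent1, parent2, cut)
        else:
            children = (mutate(parent1, rng), mutate(parent2, rng))
        for child in children:
            ok = True
            widths = {len(m) for m in child.masks}
            ok &= len(widths) == 1
            ok &= all(
                any(m[j] for m in child.masks) for j in range(child.width)
            )
            grid = child.decode()
            for r, seq in enumerate(seqs):
                ok &= child.rows[r] == tuple(seq.steps)
                ok &= tuple(c for c in grid[r] if c is not None) == tuple(seq.steps)
            if not ok:
                violations += 1
        if case % 50 == 0:
            # score invariances on the decoded parent alignment
            aln = Alignment.build(
                tuple(s.ess_id for s in seqs), parent1.decode()
            )
            base = objective(aln).objective
            perm = rng.permutation(n_rows)
            permuted = Alignment(
                tuple(aln.row_ids[int(p)] for p in perm),
                tuple(aln.grid[int(p)] for p in perm),
            )
            if abs(objective(permuted).objective - base) > 1e-12:
                violations += 1
            padded = Alignment(
                aln.row_ids, tuple(row + (None,) for row in aln.grid)
            )
            if abs(objective(padded).objective - base) > 1e-12:
                violations += 1
    return {"n_cases": n_cases, "violations": violations}


def planted_cluster_experiment(
    n_seeds: int = 20,
    seed: int = 0,
    ga_params: Optional[GAParams] = None,
    n_clusters: int = 3,
    per_cluster: int = 6,
    length: int = 6,
    divergence: float = 0.1,
    n_outliers: int = 3,
    cutoff: float = 0.4,
    elbow_k_max: int = 8,
) -> dict:
    """Planted-partition recovery: elbow selection, k-medoids labels,
    and depuration.

    Per seed: generate the planted blocks plus a few random outliers,
    align everything all-vs-all once, run the elbow criterion and
    k-medoids on the planted submatrix against the ground truth, then
    depurate a clustering of the extended matrix at the fitness cutoff
    (outliers should be flagged, planted members should not).
    """
    if ga_params is None:
        ga_params = EXPERIMENT_GA
    per_seed = []
    for s in range(n_seeds):
        sub = (seed + 104729 * (s + 1)) % _SEED_MOD
        blocks, labels = generate_ess_blocks(
            n_clusters, per_cluster, length, divergence, seed=sub
        )
        outliers = random_ess_collection(
            n_outliers, length, seed=sub + 1, avoid=blocks
        )
        extended = merge_collections(blocks, outliers)
        matrix_ext = all_vs_all(extended, replace(ga_params, seed=sub + 2))
        planted_ids = [e.ess_id for e in blocks]
        matrix = matrix_ext.submatrix(planted_ids)

        elbow = elbow_select(matrix, k_min=2, k_max=elbow_k_max, replicates=20, seed=sub)
        model = kmedoids(matrix, n_clusters, replicates=20, seed=sub)
        pred = [model.assignment[i] for i in planted_ids]
        ari = adjusted_rand_score(labels, pred)

        model_ext = kmedoids(matrix_ext, n_clusters, replicates=20, seed=sub)
        depurated = depurate(model_ext, matrix_ext, cutoff)
        removed = set(depurated.removed_by_depuration)
        outlier_ids = {e.ess_id for e in outliers}
        per_seed.append(
            {
                "elbow_k": elbow.k,
                "ari": ari,
                "planted_removed": len(removed & set(planted_ids)),
                "outliers_removed": len(removed & outlier_ids),
            }
        )
    n = len(per_seed)
    return {
        "n_seeds": n,
        "n_sequences": n_clusters * per_cluster,
        "elbow_k_correct_rate": sum(r["elbow_k"] == n_clusters for r in per_seed) / n,
        "ari_perfect_rate": sum(r["ari"] >= 1.0 - 1e-12 for r in per_seed) / n,
        "planted_removed_total": sum(r["planted_removed"] for r in per_seed),
        "outlier_removed_rate": sum(r["outliers_removed"] for r in per_seed)
        / (n * max(1, n_outliers)),
        "per_seed": per_seed,
    }


def significance_experiment(
    n_seeds: int = 20,
    seed: int = 0,
    ga_params: Optional[GAParams] = None,
    n_planted_pairs: int = 10,
    length: int = 6,
    divergence: float = 0.1,
    alphabet_size: int = 60,
    threshold: float = 0.4,
    n_shuffled_sets: int = 2,
) -> dict:
    """Real-vs-shuffled score separation at the fitness cutoff.

    The fixture emulates a genome-scale inventory: a diverse EC
    vocabulary (random codes, so unrelated pairs land near the
    dissimilar extreme) in which a small fraction of pairs are planted
    near-copies -- the regime where only a few percent of real pairs
    but almost no shuffled pairs score below the cutoff.  Shuffling
    conserves length and composition, destroying only the order that
    makes the planted pairs alignable.
    """
    if ga_params is None:
        ga_params = EXPERIMENT_GA
    per_seed = []
    for s in range(n_seeds):
        sub = (seed + 104729 * (s + 1)) % _SEED_MOD
        alphabet = diverse_alphabet(alphabet_size, seed=sub + 9)
        coll, _ = generate_ess_blocks(
            n_planted_pairs, 2, length, divergence, seed=sub, alphabet=alphabet
        )
        matrix = all_vs_all(coll, replace(ga_params, seed=sub + 2))
        real_frac = fraction_below(matrix.condensed(), threshold)
        null_fracs = []
        for t in range(n_shuffled_sets):
            shuffled = shuffle_ess(coll, (sub + 31 * (t + 1)) % _SEED_MOD)
            null_matrix = all_vs_all(shuffled, replace(ga_params, seed=sub + 3 + t))
            null_fracs.append(fraction_below(null_matrix.condensed(), threshold))
        per_seed.append(
            {
                "real_fraction_below": real_frac,
                "null_fraction_below": float(np.mean(null_fracs)),
            }
        )
    n = len(per_seed)
    return {
        "n_seeds": n,
        "threshold": threshold,
        "separation_count": sum(
            r["real_fraction_below"] > r["null_fraction_below"] for r in per_seed
        ),
        "mean_real_fraction_below": float(
            np.mean([r["real_fraction_below"] for r in per_seed])
        ),
        "mean_null_fraction_below": float(
            np.mean([r["null_fraction_below"] for r in per_seed])
        ),
        "per_seed": per_seed,
    }


def shuffle_fuzz(n_cases: int = 1000, seed: int = 0) -> dict:
    """Shuffling must conserve the global EC multiset and the per-
    sequence length vector exactly."""
    rng = np.random.default_rng(seed)
    violations = 0
    for case in range(n_cases):
        blocks, _ = generate_ess_blocks(
            n_clusters=int(rng.integers(2, 4)),
            per_cluster=int(rng.integers(1, 4)),
            length=int(rng.integers(2, 7)),
            divergence=float(rng.random() * 0.5),
            seed=int(rng.integers(_SEED_MOD)),
        )
        shuffled = shuffle_ess(blocks, int(rng.integers(_SEED_MOD)))
        before = sorted(str(ec) for e in blocks for ec in e.steps)
        after = sorted(str(ec) for e in shuffled for ec in e.steps)
        if before != after:
            violations += 1
        if [len(e) for e in blocks] != [len(e) for e in shuffled]:
            violations += 1
    return {"n_cases": n_cases, "violations": violations}


def dp_ga_correlation(
    n_pairs: int = 100, seed: int = 0, ga_params: Optional[GAParams] = None
) -> dict:
    """Spearman rank correlation between DP and GA objectives over a
    mixed sample of planted and random pairs."""
    if ga_params is None:
        ga_params = EXPERIMENT_GA
    blocks, _ = generate_ess_blocks(3, 6, 6, 0.1, seed=seed)
    extra = random_ess_collection(6, 6, seed=seed + 1)
    pool = list(merge_collections(blocks, extra))
    rng = np.random.default_rng(seed + 2)
    all_pairs = list(itertools.combinations(range(len(pool)), 2))
    chosen = rng.choice(len(all_pairs), size=min(n_pairs, len(all_pairs)), replace=False)
    dp_scores = []
    ga_scores = []
    for t, idx in enumerate(chosen):
        i, j = all_pairs[int(idx)]
        _, dp = dp_align(pool[i], pool[j])
        _, ga = ga_align([pool[i], pool[j]], replace(ga_params, seed=(seed + t) % _SEED_MOD))
        dp_scores.append(dp.objective)
        ga_scores.append(ga.objective)
    rho = float(spearmanr(dp_scores, ga_scores).statistic)
    return {"n_pairs": len(dp_scores), "spearman_rho": rho}
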