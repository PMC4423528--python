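"""GA operators, the evolutionary loop, and the two reference aligners."""

from dataclasses import replace

import numpy as np
import pytest

from essalign.ec import GAP
from essalign.ga import (
    Chromosome,
    GAParams,
    _brute_force_naive,
    brute_force_align,
    crossover,
    dp_align,
    ga_align,
    init_population,
    mutate,
    tournament_select,
)
from essalign.scoring import Alignment, objective

from conftest import make_ess

FAST = GAParams(
    population_size=20, replicates=2, stagnation_generations=8, max_extra_columns=2
)


def decode_row(ch, r):
    return tuple(c for c in ch.decode()[r] if c is not GAP)


class TestInitPopulation:
    def test_zero_gap_budget_forces_the_unique_gapless_alignment(self):
        seqs = [make_ess("a", "1.1.1 2.2.2 3.3.3"), make_ess("b", "4.4.4 5.5.5 6.6.6")]
        params = replace(FAST, max_extra_columns=0, population_size=10)
        pop = init_population(seqs, params, np.random.default_rng(0))
        assert all(ch.width == 3 and all(all(m) for m in ch.masks) for ch in pop)

    def test_same_seed_same_population(self):
        seqs = [make_ess("a", "1.1.1 2.2.2"), make_ess("b", "3.3.3")]
        p1 = init_population(seqs, FAST, np.random.default_rng(42))
        p2 = init_population(seqs, FAST, np.random.default_rng(42))
        assert [c.masks for c in p1] == [c.masks for c in p2]

    def test_every_chromosome_decodes_to_its_sequences(self):
        seqs = [make_ess("a", "1.1.1 2.2.2 3.3.3"), make_ess("b", "5.3.1 2.7.1")]
        for ch in init_population(seqs, FAST, np.random.default_rng(1)):
            assert decode_row(ch, 0) == seqs[0].steps
            assert decode_row(ch, 1) == seqs[1].steps

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            init_population([make_ess("a", "1.1.1")], FAST)


class TestTournament:
    def _pop(self, fits):
        pop = []
        for f in fits:
            ch = Chromosome(rows=(("x",),), masks=[[1]])
            ch.fitness = f
            pop.append(ch)
        return pop

    def test_whole_population_tournament_returns_global_best(self):
        pop = self._pop([0.5, 0.1, 0.9])
        params = replace(FAST, tournament_size=30)
        winner = tournament_select(pop, params, np.random.default_rng(0))
        assert winner.fitness == 0.1

    def test_minimization_wins(self):
        pop = self._pop([0.1, 0.5])
        params = replace(FAST, tournament_size=10)
        assert (
            tournament_select(pop, params, np.random.default_rng(3)).fitness == 0.1
        )

    def test_deterministic_under_fixed_seed_with_ties(self):
        pop = self._pop([0.2, 0.2, 0.2])
        picks = {
            id(tournament_select(pop, FAST, np.random.default_rng(7))) for _ in range(3)
        }
        assert len(picks) == 1

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            tournament_select([], FAST, np.random.default_rng(0))


class TestCrossover:
    def _parents(self, seed=0):
        seqs = [make_ess("a", "1.1.1 2.2.2 3.3.3"), make_ess("b", "5.3.1 2.7.1")]
        rng = np.random.default_rng(seed)
        pop = init_population(seqs, replace(FAST, population_size=2), rng)
        return seqs, pop[0], pop[1]

    def test_self_crossover_is_closed(self):
        seqs, p1, _ = self._parents()
        for cut in range(1, p1.width):
            c1, c2 = crossover(p1, p1, cut)
            assert decode_row(c1, 0) == seqs[0].steps
            assert c1.masks == p1.masks == c2.masks

    def test_offspring_decode_to_their_sequences_for_every_cut(self):
        for seed in range(20):
            seqs, p1, p2 = self._parents(seed)
            for cut in range(1, p1.width):
                for child in crossover(p1, p2, cut):
                    assert decode_row(child, 0) == seqs[0].steps
                    assert decode_row(child, 1) == seqs[1].steps

    def test_ec_multisets_conserved(self):
        seqs, p1, p2 = self._parents(5)
        c1, c2 = crossover(p1, p2, 1)
        for child in (c1, c2):
            for r, s in enumerate(seqs):
                assert sorted(map(str, decode_row(child, r))) == sorted(
                    map(str, s.steps)
                )

    def test_mismatched_parents_rejected(self):
        _, p1, _ = self._parents(0)
        seqs2 = [make_ess("a", "9.9.9"), make_ess("b", "8.8.8")]
        other = init_population(
            seqs2, replace(FAST, population_size=2), np.random.default_rng(0)
        )[0]
        with pytest.raises(ValueError):
            crossover(p1, other, 1)


class TestMutate:
    def test_gapless_chromosome_always_gains_a_gap(self):
        # only the enzyme branch of the operator is reachable: a gap is
        # opened in the hit row (and the added column pads the others)
        seqs = [make_ess("a", "1.1.1 2.2.2"), make_ess("b", "3.3.3 4.4.4")]
        gapless = Chromosome(
            rows=tuple(tuple(s.steps) for s in seqs), masks=[[1, 1], [1, 1]]
        )
        for seed in range(30):
            child = mutate(gapless, np.random.default_rng(seed))
            assert child.width == 3
            assert [m.count(0) for m in child.masks] == [1, 1]

    def test_deleting_the_only_gap_restores_the_gapless_alignment(self):
        # once the internal gap is deleted the trailing column is all-gap
        # and is stripped, leaving the gapless width-2 alignment
        seqs = [make_ess("a", "1.1.1 2.2.2"), make_ess("b", "3.3.3 4.4.4")]
        ch = Chromosome(
            rows=tuple(tuple(s.steps) for s in seqs), masks=[[1, 0, 1], [1, 1, 0]]
        )
        seen_gapless = False
        for seed in range(60):
            child = mutate(ch, np.random.default_rng(seed))
            if child.width == 2:
                assert child.masks == [[1, 1], [1, 1]]
                seen_gapless = True
            assert decode_row(child, 0) == seqs[0].steps
        assert seen_gapless

    def test_ec_multiset_never_changes(self):
        seqs = [make_ess("a", "1.1.1 2.2.2 3.3.3"), make_ess("b", "5.3.1")]
        ch = init_population(
            seqs, replace(FAST, population_size=1), np.random.default_rng(2)
        )[0]
        rng = np.random.default_rng(9)
        for _ in range(50):
            ch = mutate(ch, rng)
            for r, s in enumerate(seqs):
                assert decode_row(ch, r) == s.steps


class TestGAAlign:
    def test_identical_sequences_reach_the_known_optimum(self):
        a = make_ess("a", "2.7.1 5.3.1 4.1.2")
        b = make_ess("b", "2.7.1 5.3.1 4.1.2")
        _, score = ga_align([a, b], replace(FAST, seed=5))
        assert score.objective == pytest.approx(0.05, abs=1e-12)

    def test_fixed_seed_is_reproducible(self):
        a = make_ess("a", "2.7.1 5.3.1 2.7.2 3.1.3")
        b = make_ess("b", "5.3.1 2.7.1 3.1.3")
        r1 = ga_align([a, b], replace(FAST, seed=11))
        r2 = ga_align([a, b], replace(FAST, seed=11))
        assert r1[0].grid == r2[0].grid
        assert r1[1].objective == r2[1].objective

    def test_argument_order_does_not_change_the_objective(self):
        a = make_ess("a", "2.7.1 5.3.1 2.7.2")
        b = make_ess("b", "5.3.1 2.7.2")
        sab = ga_align([a, b], replace(FAST, seed=3))[1].objective
        sba = ga_align([b, a], replace(FAST, seed=3))[1].objective
        assert sab == pytest.approx(sba, abs=1e-12)

    def test_matches_brute_force_on_small_pairs(self):
        pairs = [
            ("2.7.1 5.3.1", "5.3.1 2.7.1"),
            ("2.7.1 2.7.2 5.3.1", "2.7.1 5.3.1"),
            ("1.1.1", "2.7.1 1.1.1 5.3.1"),
        ]
        for i, (sa, sb) in enumerate(pairs):
            a, b = make_ess("a", sa), make_ess("b", sb)
            _, bf = brute_force_align(a, b)
            _, ga = ga_align([a, b], replace(FAST, seed=100 + i))
            assert ga.objective == pytest.approx(bf.objective, abs=1e-9)

    def test_result_rows_strip_to_inputs(self):
        a = make_ess("a", "2.7.1 5.3.1 2.7.2")
        b = make_ess("b", "5.3.1 2.7.2 3.1.3")
        aln, _ = ga_align([a, b], replace(FAST, seed=8))
        assert aln.row_steps(0) == a.steps
        assert aln.row_steps(1) == b.steps


class TestBruteForce:
    def test_identity_pair_is_gapless_at_optimum(self):
        a = make_ess("a", "2.7.1 5.3.1")
        b = make_ess("b", "2.7.1 5.3.1")
        aln, score = brute_force_align(a, b)
        assert score.objective == pytest.approx(0.05, abs=1e-12)
        assert aln.n_columns == 2

    def test_single_column_fully_distinct(self):
        a = make_ess("a", "2.7.1")
        b = make_ess("b", "3.1.3")
        _, score = brute_force_align(a, b, max_width=1)
        assert score.objective == pytest.approx(0.59, abs=1e-12)

    def test_containment_pins_the_shared_code(self):
        a = make_ess("a", "2.7.1")
        b = make_ess("b", "2.7.1 5.3.1")
        aln, _ = brute_force_align(a, b)
        assert aln.grid[0][0] is not GAP  # 2.7.1 aligned against 2.7.1
        assert aln.grid[0][1] is GAP

    def test_fast_path_agrees_with_naive_enumeration(self):
        cases = [
            ("2.7.1 5.3.1 2.7.2", "5.3.1 2.7.1"),
            ("2.7.1 2.7.2", "2.7.2 2.7.1 5.3.1"),
            ("5.3.1", "2.7.1"),
            ("2.7.1 2.7.1", "2.7.1 2.7.1"),
        ]
        from essalign.scoring import DEFAULT_CONFIG

        for sa, sb in cases:
            a, b = make_ess("a", sa), make_ess("b", sb)
            _, fast = brute_force_align(a, b)
            _, naive = _brute_force_naive(
                a, b, len(a.steps) + len(b.steps), DEFAULT_CONFIG
            )
            assert fast.objective == pytest.approx(naive.objective, abs=1e-12)

    def test_size_cap_enforced(self):
        a = make_ess("a", " ".join(["1.1.1"] * 7))
        with pytest.raises(ValueError):
            brute_force_align(a, a)


class TestDPAlign:
    def test_identity_reaches_the_optimum(self):
        a = make_ess("a", "2.7.1 5.3.1 4.1.2")
        b = make_ess("b", "2.7.1 5.3.1 4.1.2")
        aln, score = dp_align(a, b)
        assert score.objective == pytest.approx(0.05, abs=1e-12)
        assert aln.n_columns == 3

    def test_never_beats_the_exhaustive_optimum(self):
        codes = ["2.7.1", "2.7.2", "5.3.1"]
        import itertools

        seqs = [
            " ".join(combo)
            for n in (1, 2, 3)
            for combo in itertools.product(codes, repeat=n)
        ]
        for i, sa in enumerate(seqs[::4]):
            for sb in seqs[1::5]:
                a, b = make_ess("a", sa), make_ess("b", sb)
                _, bf = brute_force_align(a, b)
                _, dp = dp_align(a, b)
                assert dp.objective >= bf.objective - 1e-9

    def test_third_level_mismatch_costs_the_expected_column_price(self):
        # pairing 2.7.1 with 2.7.2: substitution cost 0.6 * 1/6, plus the
        # column-increment term -> 0.9*0.1 + 0.05
        a = make_ess("a", "2.7.1")
        b = make_ess("b", "2.7.2")
        _, score = dp_align(a, b)
        assert score.objective == pytest.approx(0.14, abs=1e-12)

    def test_rows_strip_to_inputs(self):
        a = make_ess("a", "2.7.1 5.3.1")
        b = make_ess("b", "5.3.1 2.7.1 2.7.2")
        aln, _ = dp_align(a, b)
        assert aln.row_steps(0) == a.steps
        assert aln.row_steps(1) == b.steps


def test_fast_fitness_matches_public_objective():
    """The inlined two-row scorer used inside the GA must agree with the
    reference objective on random chromosomes."""
    from essalign.ga import _fast_pair_objective

    rng = np.random.default_rng(123)
    for _ in range(200):
        la, lb = rng.integers(1, 6, size=2)
        codes = ["2.7.1", "2.7.2", "5.3.1", "3.1.3", "5.x.x"]
        a = make_ess("a", " ".join(codes[int(k)] for k in rng.integers(5, size=la)))
        b = make_ess("b", " ".join(codes[int(k)] for k in rng.integers(5, size=lb)))
        ch = init_population(
            [a, b], replace(FAST, population_size=1, max_extra_columns=3), rng
        )[0]
        fast = _fast_pair_objective(
            ch.masks[0], ch.masks[1],
            [c.levels for c in a.steps], [c.levels for c in b.steps],
        )
        ref = objective(Alignment(("a", "b"), ch.decode())).objective
        assert fast == pytest.approx(ref, abs=1e-12)
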