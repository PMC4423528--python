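"""Similarity matrix, shuffled-set significance, k-medoids and depuration."""

from dataclasses import replace

import numpy as np
import pytest

from essalign.ess import ESSCollection
from essalign.ga import GAParams
from essalign.similarity import (
    ClusterModel,
    SimilarityMatrix,
    all_vs_all,
    depurate,
    elbow_select,
    fraction_below,
    kmedoids,
    shuffle_ess,
    significance_threshold,
)

from conftest import make_ess

FAST = GAParams(
    population_size=16, replicates=1, stagnation_generations=6, max_extra_columns=2
)


def planted_matrix(sizes, within=0.1, between=0.9):
    """Block matrix with perfect planted structure."""
    n = sum(sizes)
    values = np.full((n, n), between)
    start = 0
    for s in sizes:
        values[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(values, 0.0)
    ids = tuple(f"s{i:02d}" for i in range(n))
    return SimilarityMatrix(ids, values)


@pytest.fixture(scope="module")
def trio():
    coll = ESSCollection(
        items=[
            make_ess("a", "2.7.1 5.3.1 4.1.2"),
            make_ess("b", "2.7.1 5.3.1 4.1.2"),
            make_ess("c", "3.1.3 6.3.2 1.1.1"),
        ]
    )
    return coll, all_vs_all(coll, replace(FAST, seed=7))


class TestAllVsAll:
    def test_symmetric_with_zero_diagonal(self, trio):
        _, m = trio
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0.0)

    def test_duplicate_sequences_hit_the_identity_optimum(self, trio):
        _, m = trio
        assert m.get("a", "b") == pytest.approx(0.05, abs=1e-12)

    def test_dissimilar_pair_scores_high(self, trio):
        _, m = trio
        assert m.get("a", "c") > 0.4

    def test_too_few_sequences_rejected(self):
        coll = ESSCollection(items=[make_ess("a", "1.1.1")])
        with pytest.raises(ValueError):
            all_vs_all(coll, FAST)

    def test_cache_makes_rerun_identical(self, trio, tmp_path):
        coll, m = trio
        cache = tmp_path / "pairs.tsv"
        m1 = all_vs_all(coll, replace(FAST, seed=7), cache_path=cache)
        m2 = all_vs_all(coll, replace(FAST, seed=7), cache_path=cache)
        assert np.array_equal(m1.values, m2.values)
        assert np.array_equal(m1.values, m.values)

    def test_tsv_round_trip(self, trio, tmp_path):
        _, m = trio
        path = tmp_path / "matrix.tsv"
        m.write_tsv(path)
        back = SimilarityMatrix.read_tsv(path)
        assert back.ids == m.ids
        assert np.allclose(back.values, m.values)


class TestShuffle:
    @pytest.fixture
    def coll(self):
        return ESSCollection(
            items=[
                make_ess("a", "2.7.1 5.3.1 4.1.2 2.7.1"),
                make_ess("b", "3.1.3 6.3.2"),
                make_ess("c", "1.1.1 2.7.2 5.3.1"),
            ]
        )

    def test_global_ec_multiset_conserved(self, coll):
        shuffled = shuffle_ess(coll, seed=3)
        before = sorted(str(ec) for e in coll for ec in e.steps)
        after = sorted(str(ec) for e in shuffled for ec in e.steps)
        assert before == after

    def test_lengths_conserved_in_order(self, coll):
        shuffled = shuffle_ess(coll, seed=4)
        assert [len(e) for e in shuffled] == [len(e) for e in coll]
        assert [e.ess_id for e in shuffled] == [e.ess_id for e in coll]

    def test_different_seeds_generally_differ(self, coll):
        texts = {
            tuple(e.text for e in shuffle_ess(coll, seed=s)) for s in range(10)
        }
        assert len(texts) > 1


class TestThreshold:
    def test_mean_minus_three_sd(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0.7, 0.1, size=4000)
        # exact arithmetic on the realized sample
        expected = scores.mean() - 3 * scores.std(ddof=1)
        assert significance_threshold(scores) == pytest.approx(expected, abs=1e-12)

    def test_constant_scores_give_the_constant(self):
        assert significance_threshold([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_synthetic_mean_and_sd_recover_the_published_cutoff(self):
        # a distribution with mean 0.7 and sample SD 0.1 thresholds at 0.4
        scores = [0.6, 0.8, 0.6, 0.8]
        sd = np.std(scores, ddof=1)
        scaled = 0.7 + (np.array(scores) - 0.7) * (0.1 / sd)
        assert significance_threshold(scaled) == pytest.approx(0.4, abs=1e-12)

    def test_fraction_below_counts_strictly(self):
        assert fraction_below([0.1, 0.5, 0.9], 0.4) == pytest.approx(1 / 3)
        assert fraction_below([0.5, 0.9], 0.4) == 0.0
        assert fraction_below([0.1, 0.2], 0.4) == 1.0
        assert fraction_below([0.4, 0.1], 0.4) == 0.5  # boundary not counted
        assert fraction_below([0.4, 0.1], 0.4, strict=False) == 1.0


class TestKMedoids:
    def test_planted_blocks_recovered_exactly(self):
        m = planted_matrix([4, 4, 4])
        model = kmedoids(m, 3, replicates=10, seed=0)
        groups = [
            {model.assignment[f"s{i:02d}"] for i in range(4 * g, 4 * g + 4)}
            for g in range(3)
        ]
        assert all(len(g) == 1 for g in groups)
        assert len({next(iter(g)) for g in groups}) == 3

    def test_k_equals_n_minus_one_pairs_exactly_two(self):
        m = planted_matrix([6])
        model = kmedoids(m, 5, replicates=5, seed=1)
        sizes = sorted(
            len(model.members(c)) for c in range(5)
        )
        assert sizes == [1, 1, 1, 1, 2]

    def test_same_seed_same_model(self):
        m = planted_matrix([3, 3])
        a = kmedoids(m, 2, replicates=4, seed=9)
        b = kmedoids(m, 2, replicates=4, seed=9)
        assert a.assignment == b.assignment and a.quality == b.quality

    def test_quality_matches_definition(self):
        m = planted_matrix([3, 3])
        model = kmedoids(m, 2, replicates=4, seed=2)
        total = sum(
            m.get(i, model.medoids[c]) for i, c in model.assignment.items()
        )
        assert model.quality == pytest.approx(total, abs=1e-12)

    def test_k_out_of_range_rejected(self):
        m = planted_matrix([3, 3])
        with pytest.raises(ValueError):
            kmedoids(m, 1)
        with pytest.raises(ValueError):
            kmedoids(m, 6)


class TestElbow:
    def test_three_planted_blocks_select_k3(self):
        m = planted_matrix([5, 5, 5])
        result = elbow_select(m, k_min=2, k_max=8, replicates=10, seed=0)
        assert result.k == 3

    def test_quality_nonincreasing_in_k(self):
        m = planted_matrix([5, 5, 5], within=0.2, between=0.8)
        result = elbow_select(m, k_min=2, k_max=10, replicates=10, seed=1)
        diffs = np.diff(result.quality)
        assert np.all(diffs <= 1e-9)

    def test_degenerate_flat_curve_flagged(self):
        # all points equidistant: quality falls linearly, no unique kink
        n = 8
        values = np.full((n, n), 0.5)
        np.fill_diagonal(values, 0.0)
        m = SimilarityMatrix(tuple(f"s{i}" for i in range(n)), values)
        result = elbow_select(m, k_min=2, k_max=6, replicates=3, seed=0)
        assert result.degenerate
        assert result.k == min(result.second_diff)

    def test_k_max_must_stay_below_n(self):
        m = planted_matrix([3, 3])
        with pytest.raises(ValueError):
            elbow_select(m, k_min=2, k_max=6)


class TestDepurate:
    def _model(self, m, k=2):
        return kmedoids(m, k, replicates=5, seed=0)

    def test_member_above_cutoff_removed(self):
        m = planted_matrix([4, 4], within=0.1, between=0.9)
        # poison one member of cluster 0: mean 0.5 against its mates
        v = m.values.copy()
        v[0, 1:4] = v[1:4, 0] = 0.5
        poisoned = SimilarityMatrix(m.ids, v)
        model = self._model(poisoned)
        out = depurate(model, poisoned, cutoff=0.4)
        assert "s00" in out.removed_by_depuration

    def test_tight_cluster_keeps_everyone(self):
        m = planted_matrix([4, 4], within=0.1)
        out = depurate(self._model(m), m, cutoff=0.4)
        assert out.removed_by_depuration == ()

    def test_two_member_cluster_above_cutoff_loses_both(self):
        values = np.array(
            [
                [0.0, 0.45, 0.9, 0.9],
                [0.45, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        m = SimilarityMatrix(("a", "b", "c", "d"), values)
        model = self._model(m)
        out = depurate(model, m, cutoff=0.4)
        assert {"a", "b"} <= set(out.removed_by_depuration)
        assert {"c", "d"} & set(out.removed_by_depuration) == set()

    def test_single_pass_is_idempotent(self):
        m = planted_matrix([4, 4], within=0.35, between=0.9)
        model = self._model(m)
        once = depurate(model, m, cutoff=0.4)
        twice = depurate(once, m, cutoff=0.4)
        assert once.removed_by_depuration == twice.removed_by_depuration

    def test_negative_cutoff_rejected(self):
        m = planted_matrix([3, 3])
        with pytest.raises(ValueError):
            depurate(self._model(m), m, cutoff=-0.1)

    def test_json_round_trip(self, tmp_path):
        m = planted_matrix([3, 3])
        model = depurate(self._model(m), m, cutoff=0.4)
        path = tmp_path / "clusters.json"
        model.to_json(path)
        back = ClusterModel.from_json(path)
        assert back.k == model.k
        assert back.assignment == model.assignment
        assert back.removed_by_depuration == model.removed_by_depuration
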