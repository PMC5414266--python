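"""Mate selection and offspring dispersal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare, kstest

from phenosim import (
    NO_MATE,
    MateAssignment,
    assign_mates_assortative,
    assign_mates_random,
    dispersal_box,
    spawn_offspring_asexual,
    spawn_offspring_sexual,
)

import helpers


class TestAssortative:
    def test_forced_by_distances(self, rng):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        mates = assign_mates_assortative(pts, rng)
        assert mates.mate[0] == 1 and mates.alternate[0] == 2
        assert mates.mate[1] == 0 and mates.alternate[1] == 2
        assert mates.mate[2] == 1 and mates.alternate[2] == 0

    def test_exact_ties_broken_both_ways(self):
        # right isoceles triple: organism 0 is exactly equidistant (1.0)
        # from organisms 1 and 2 in floating point
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        seen = set()
        for seed in range(200):
            mates = assign_mates_assortative(pts, np.random.default_rng(seed))
            assert {mates.mate[0], mates.alternate[0]} == {1, 2}
            assert mates.mate[1] == 0 and mates.mate[2] == 0  # distances 1 < sqrt(2)
            seen.add(int(mates.mate[0]))
        assert seen == {1, 2}, "both tie orders should occur"

    def test_matches_brute_force(self, random_point_sets, rng):
        for pts in random_point_sets:
            mates = assign_mates_assortative(pts, rng)
            nn_idx, nn_d, snn_idx, snn_d = helpers.brute_force_neighbours(pts)
            np.testing.assert_array_equal(mates.mate, nn_idx)
            np.testing.assert_array_equal(mates.alternate, snn_idx)

    def test_pair_need_not_be_mutual(self, rng):
        # 1 is nearest to 0 and to 2, but 1's own mate is 0: 2 is unreciprocated
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0]])
        mates = assign_mates_assortative(pts, rng)
        assert mates.mate[2] == 1 and mates.mate[1] == 0

    def test_requires_two(self, rng):
        with pytest.raises(ValueError):
            assign_mates_assortative(np.array([[1.0, 1.0]]), rng)


class TestRandomMating:
    def test_n2_forced(self, rng):
        mates = assign_mates_random(2, rng)
        assert mates.mate[0] == 1 and mates.mate[1] == 0
        assert (mates.alternate == NO_MATE).all()

    def test_n3_mate_frequencies(self):
        counts = {1: 0, 2: 0}
        trials = 4000
        for seed in range(trials):
            mates = assign_mates_random(3, np.random.default_rng(seed))
            counts[int(mates.mate[0])] += 1
        # binomial(4000, 0.5): 4 sigma band
        sigma = np.sqrt(trials * 0.25)
        assert abs(counts[1] - trials / 2) < 4 * sigma

    def test_mate_uniform_chi2(self):
        n = 10
        gen = np.random.default_rng(5)
        draws = np.concatenate(
            [assign_mates_random(n, gen).mate for _ in range(10_000)]
        )
        # pool all organisms' mates; by symmetry offsets (mate - i) mod n
        # are uniform over 1..n-1
        offsets = (draws - np.tile(np.arange(n), 10_000)) % n
        observed = np.bincount(offsets, minlength=n)[1:]
        assert chisquare(observed).pvalue > 0.01

    def test_validity_and_distinctness(self, rng):
        for n in (2, 3, 7, 50):
            mates = assign_mates_random(n, rng)
            i = np.arange(n)
            assert (mates.mate != i).all()
            defined = mates.alternate != NO_MATE
            assert (mates.alternate[defined] != i[defined]).all()
            assert (mates.alternate[defined] != mates.mate[defined]).all()
            if n >= 3:
                assert defined.all()


class TestDispersal:
    def test_box_hand_example(self):
        box = dispersal_box((1.0, 1.0), (2.0, 3.0), 0.5)
        assert (box.xmin, box.xmax, box.ymin, box.ymax) == (0.5, 2.5, 0.5, 3.5)

    def test_box_degenerates_to_asexual_square(self):
        box = dispersal_box((10.0, 10.0), (10.0, 10.0), 0.3)
        assert (box.xmin, box.xmax, box.ymin, box.ymax) == pytest.approx(
            (9.7, 10.3, 9.7, 10.3)
        )

    def test_box_mu_zero_is_parent_hull(self):
        box = dispersal_box((0.0, 2.0), (1.0, 0.0), 0.0)
        assert (box.xmin, box.xmax, box.ymin, box.ymax) == (0.0, 1.0, 0.0, 2.0)

    @given(
        x1=st.floats(-5, 5), y1=st.floats(-5, 5),
        x2=st.floats(-5, 5), y2=st.floats(-5, 5),
        mu=st.floats(0, 2),
    )
    @settings(derandomize=True, max_examples=50)
    def test_box_contains_both_parents(self, x1, y1, x2, y2, mu):
        box = dispersal_box((x1, y1), (x2, y2), mu)
        assert box.contains([(x1, y1), (x2, y2)]).all()
        assert box.xmin <= box.xmax and box.ymin <= box.ymax

    def test_sexual_spawn_count_and_containment(self, rng):
        pts = rng.random((12, 2)) * 5
        mates = assign_mates_assortative(pts, rng)
        for f in (1, 2, 3):
            off = spawn_offspring_sexual(pts, mates, f, 0.4, rng)
            assert off.shape == (12 * f, 2)
            per_parent = off.reshape(12, f, 2)
            for i in range(12):
                box = dispersal_box(pts[i], pts[mates.mate[i]], 0.4)
                assert box.contains(per_parent[i]).all()

    def test_asexual_spawn_count_and_containment(self, rng):
        pts = rng.random((9, 2)) * 5
        off = spawn_offspring_asexual(pts, 2, 0.3, rng)
        assert off.shape == (18, 2)
        per_parent = off.reshape(9, 2, 2)
        assert (np.abs(per_parent - pts[:, None, :]) <= 0.3).all()

    def test_asexual_mu_zero_offspring_coincide(self, rng):
        pts = np.array([[4.0, 4.0], [1.0, 2.0]])
        off = spawn_offspring_asexual(pts, 2, 0.0, rng)
        np.testing.assert_allclose(off, np.repeat(pts, 2, axis=0))

    def test_asexual_dispersal_uniform(self):
        gen = np.random.default_rng(3)
        parent = np.array([[10.0, 10.0]])
        off = spawn_offspring_asexual(parent, 100_000, 0.3, gen)
        for axis in (0, 1):
            stat = kstest(off[:, axis], "uniform", args=(9.7, 0.6))
            assert stat.pvalue > 0.01


def test_mate_assignment_rejects_self_mating():
    with pytest.raises(ValueError):
        MateAssignment(mate=np.array([0, 0]), alternate=np.array([-1, -1]))
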