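"""Constrained shuffle, Monte-Carlo null, p-value rule, and coordination index."""

import collections

import numpy as np
import pytest

from nestcoord.core import Bout, BoutSequence, Category, TripLabel, ValidationError
from nestcoord.overlap import OverlapValue
from nestcoord.randomization import (
    RandomizationResult,
    constrained_shuffle,
    coordination_index,
    mc_null,
)

from conftest import random_sandwich_sequence
from oracles import (
    enumerate_arrangements,
    exact_null_mean_opposite,
    second_scan_codes,
)

C, N, F = Category.COLONY, Category.NEST, Category.FORAGING


def seq(*spec, duration=None):
    bouts = [Bout(cat, s, e) for cat, s, e in spec]
    return BoutSequence(bouts, duration or bouts[-1].end)


EXAMPLE = seq((C, 0, 2), (N, 2, 10), (C, 10, 11), (F, 11, 20), (C, 20, 22))


def bout_multiset(s: BoutSequence):
    return collections.Counter((b.category, b.length) for b in s)


class TestConstrainedShuffle:
    def test_conservation_of_multiset(self, rng):
        for _ in range(40):
            s = random_sandwich_sequence(rng)
            out = constrained_shuffle(s, rng)
            assert out.duration == s.duration
            assert bout_multiset(out) == bout_multiset(s)

    def test_sandwich_structure_preserved(self, rng):
        for _ in range(40):
            s = random_sandwich_sequence(rng)
            out = constrained_shuffle(s, rng)
            prev = None
            for b in out:
                if prev is not None and prev is not C:
                    assert b.category is C, "away bouts must be separated by colony"
                prev = b.category
        # every interior away bout is sandwiched by colony by the check above

    def test_reachable_arrangements_match_enumeration(self):
        """The shuffle's support equals the brute-force enumeration: for the
        worked 22-s example that is 3 colony-orders x 2 away-orders = 6
        distinct timelines, each with its exact probability (identity 1/6)."""
        arrs = enumerate_arrangements(EXAMPLE)
        assert len(arrs) == 6
        keys = {a.tobytes() for a in arrs}
        identity = second_scan_codes(EXAMPLE).tobytes()
        assert identity in keys
        gen = np.random.default_rng(11)
        counts = collections.Counter()
        n = 12_000
        for _ in range(n):
            out = constrained_shuffle(EXAMPLE, gen)
            counts[second_scan_codes(out).tobytes()] += 1
        assert set(counts) == keys
        # identity arrangement arises from 2 of the 3! colony perms times
        # 1 of the 2! away perms: probability 1/6, within 3 MC standard errors
        p = 1.0 / 6.0
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts[identity] / n - p) < 3 * se
        # uniformity over distinct timelines weighted by multiplicity:
        # each of the 6 timelines has probability 1/6 here (equal colony pair)
        for k in keys:
            assert abs(counts[k] / n - p) < 4 * se

    def test_single_away_bout_keeps_duration(self, rng):
        s = seq((C, 0, 5), (F, 5, 50), (C, 50, 60))
        out = constrained_shuffle(s, rng)
        (away,) = [b for b in out if b.category is F]
        assert away.length == 45

    def test_violating_sandwich_rejected(self, rng):
        bad = seq((N, 0, 5), (F, 5, 10), (C, 10, 20))
        with pytest.raises(ValidationError, match="sandwich"):
            constrained_shuffle(bad, rng)

    def test_edge_sentinels_allow_away_at_edges(self, rng):
        s = seq((N, 0, 5), (C, 5, 10), (F, 10, 20))
        out = constrained_shuffle(s, rng)
        assert bout_multiset(out) == bout_multiset(s)


class TestMcNull:
    def _session(self, seed):
        g = np.random.default_rng(seed)
        f = random_sandwich_sequence(g, duration=150, max_away=3)
        m = random_sandwich_sequence(g, duration=f.duration, max_away=3)
        # re-roll m until spans agree (stripping can change duration)
        while m.duration != f.duration:
            f = random_sandwich_sequence(g, duration=150, max_away=3)
            m = random_sandwich_sequence(g, duration=f.duration, max_away=3)
        return f, m

    def test_null_mean_matches_exact_enumeration(self):
        f, m = self._session(5)
        res = mc_null(f, m, n_iter=10_000, rng=3)
        exact = exact_null_mean_opposite(f, m)
        se = res.null_seconds.std(ddof=1) / np.sqrt(res.n_iter)
        assert abs(res.expected - exact) <= 3 * max(se, 1e-9)

    def test_p_value_count_rule(self):
        res = RandomizationResult(
            observed=OverlapValue(5, 100),
            null_seconds=np.array([3, 4, 6, 7]),
            p_value=float(np.mean(np.array([3, 4, 6, 7]) > 5)),
            n_iter=4,
        )
        assert res.p_value == 0.5
        assert res.smoothed_p_value() == pytest.approx(3 / 5)

    def test_observed_largest_gives_p_zero(self):
        f = seq((C, 0, 10), (N, 10, 100), (C, 100, 110), (F, 110, 190), (C, 190, 200))
        m = seq((C, 0, 10), (F, 10, 100), (C, 100, 110), (N, 110, 190), (C, 190, 200))
        res = mc_null(f, m, n_iter=200, rng=0)
        assert res.observed.seconds >= res.null_seconds.max()
        # ties (observed == null) never count toward p
        assert res.p_value == float(np.mean(res.null_seconds > res.observed.seconds))

    def test_ties_do_not_count(self):
        # single away bout each: the null is nearly degenerate, heavy ties
        f = seq((C, 0, 50), (N, 50, 150), (C, 150, 200))
        m = seq((C, 0, 50), (F, 50, 150), (C, 150, 200))
        res = mc_null(f, m, n_iter=500, rng=1)
        assert res.p_value == float(np.mean(res.null_seconds > res.observed.seconds))

    def test_determinism(self):
        f, m = self._session(9)
        a = mc_null(f, m, n_iter=300, rng=77)
        b = mc_null(f, m, n_iter=300, rng=77)
        assert a.observed == b.observed
        assert np.array_equal(a.null_seconds, b.null_seconds)
        assert a.p_value == b.p_value and a.index == b.index

    def test_provisioning_mode_conserves_and_scores(self):
        s = seq(
            (C, 0, 20),
            (F, 20, 60),
            (C, 60, 80),
            (F, 80, 200),
            (C, 200, 220),
            duration=220,
        )
        m = seq(
            (C, 0, 10),
            (F, 10, 130),
            (C, 130, 150),
            (F, 150, 190),
            (C, 190, 220),
            duration=220,
        )
        res = mc_null(
            s,
            m,
            n_iter=400,
            rng=5,
            mode="provisioning",
            trip_labels_f=[TripLabel.SHORT, TripLabel.LONG],
            trip_labels_m=[TripLabel.LONG, TripLabel.SHORT],
        )
        assert 0 <= res.observed.seconds <= 220
        assert res.statistic == "shortlong"

    def test_missing_trip_label_rejected(self):
        s = seq((C, 0, 20), (F, 20, 60), (C, 60, 100))
        with pytest.raises(ValidationError, match="label"):
            mc_null(s, s, n_iter=10, rng=0, mode="provisioning")

    def test_zero_expected_warns_and_index_none(self):
        f = seq((C, 0, 50), (N, 50, 150), (C, 150, 200))
        m = seq((C, 0, 50), (N, 50, 150), (C, 150, 200))  # no foraging at all
        with pytest.warns(RuntimeWarning, match="undefined"):
            res = mc_null(f, m, n_iter=50, rng=2)
        assert res.index is None


class TestCoordinationIndex:
    @pytest.mark.parametrize(
        "obs,exp,expected",
        [(10.0, 5.0, 1.0), (0.0, 5.0, -1.0), (5.0, 5.0, 0.0)],
    )
    def test_formula(self, obs, exp, expected):
        assert coordination_index(obs, exp) == expected

    def test_expected_zero_errors(self):
        with pytest.raises(ValueError):
            coordination_index(1.0, 0.0)
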