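"""Motif, pairwise-bounded and decoy samplers: construction guarantees,
uniformity against full enumeration, and rejection statistics."""

from itertools import product

import numpy as np
import pytest
from scipy.stats import chisquare

from smclwmr import (
    BINARY,
    consensus_exists,
    expected_motif_weight,
    expected_pair_distance,
    is_pairwise_bounded,
    rejection_curve,
    sample_decoy_sets,
    sample_motif_set,
    sample_pairwise_bounded,
    sample_pairwise_bounded_gibbs,
    weight,
)
from smclwmr.samplers import (
    SamplingError,
    _set_weights,
    motif_sets_packed,
    pairwise_bounded_gibbs_packed,
    pairwise_bounded_rejection_packed,
)
from smclwmr.seqcore import DNA, PackedSpace


class TestMotifSampler:
    def test_d_zero_gives_identical_copies(self, rng):
        s = sample_motif_set(10, 0, 6, rng)
        assert len(set(s)) == 1

    def test_every_set_has_a_consensus(self, rng):
        for _ in range(10):
            s, cons = sample_motif_set(15, 4, 20, rng, return_consensus=True)
            res = consensus_exists(s, 4)
            assert res.exists
            assert max(
                sum(1 for x, y in zip(cons, m) if x != y) for m in s
            ) <= 4

    def test_mean_weight_matches_closed_form(self, rng):
        # C(n,2) E[H(X,Y)] for X, Y iid uniform on the radius-d ball
        space = PackedSpace(15, DNA)
        _, sets = motif_sets_packed(space, 4, 20, 2000, rng)
        w = _set_weights(space, sets)
        mu = expected_motif_weight(15, 4, 20)
        se = w.std(ddof=1) / np.sqrt(len(w))
        assert abs(w.mean() - mu) < 3 * se

    def test_pair_distance_closed_form_against_simulation(self, rng):
        space = PackedSpace(12, DNA)
        center = space.random(200_000, rng)
        x = space.sample_ball(center, 3, rng)
        y = space.sample_ball(center, 3, rng)
        h = space.hamming(x, y).astype(float)
        se = h.std() / np.sqrt(len(h))
        assert abs(h.mean() - expected_pair_distance(12, 3)) < 3 * se


def enumerate_pairwise_bounded_binary(l, d, n):
    """All pairwise-bounded n-sequences over the binary alphabet (oracle)."""
    universe = ["".join(t) for t in product("01", repeat=l)]
    out = []
    for seq in product(universe, repeat=n):
        if is_pairwise_bounded(list(seq), d, BINARY):
            out.append(seq)
    return out


class TestPairwiseBoundedSamplers:
    def test_accepted_sets_are_pairwise_bounded(self, rng):
        s, stats = sample_pairwise_bounded(15, 4, 3, rng)
        assert is_pairwise_bounded(s, 4)
        assert stats.accepted == 1

    def test_large_d_never_rejects(self, rng):
        # d >= ceil(l/2): any generated set is pairwise bounded
        for _ in range(5):
            _, stats = sample_pairwise_bounded(8, 4, 6, rng)
            assert stats.total_rejected == 0

    def test_n_two_never_rejects(self, rng):
        # the second string is drawn inside the 2d-ball by construction
        _, stats = sample_pairwise_bounded(12, 2, 2, rng)
        assert stats.total_rejected == 0

    def test_budget_exhaustion_is_explicit(self, rng):
        with pytest.raises(SamplingError) as exc:
            sample_pairwise_bounded(15, 4, 20, rng, max_attempts=2000)
        assert exc.value.stats.accepted == 0

    def test_rejection_uniform_over_enumerated_sequences(self, rng):
        # binary, l=3, d=1, n=3: compare frequencies with the exhaustive list
        oracle = enumerate_pairwise_bounded_binary(3, 1, 3)
        index = {seq: i for i, seq in enumerate(oracle)}
        space = PackedSpace(3, BINARY)
        sets, _ = pairwise_bounded_rejection_packed(space, 1, 3, 30_000, rng)
        counts = np.zeros(len(oracle))
        for row in sets:
            counts[index[tuple(space.decode(v) for v in row)]] += 1
        assert counts.sum() == 30_000
        assert chisquare(counts).pvalue > 0.001

    def test_gibbs_uniform_over_enumerated_sequences(self, rng):
        oracle = enumerate_pairwise_bounded_binary(3, 1, 3)
        index = {seq: i for i, seq in enumerate(oracle)}
        space = PackedSpace(3, BINARY)
        sets = pairwise_bounded_gibbs_packed(space, 1, 3, 30_000, rng, sweeps=8)
        counts = np.zeros(len(oracle))
        for row in sets:
            counts[index[tuple(space.decode(v) for v in row)]] += 1
        assert counts.sum() == 30_000
        assert chisquare(counts).pvalue > 0.001

    def test_gibbs_agrees_with_rejection_at_small_n(self, rng):
        # the two routes target the same uniform law; compare mean weights
        space = PackedSpace(15, DNA)
        rej, _ = pairwise_bounded_rejection_packed(space, 4, 4, 250, rng)
        gib = pairwise_bounded_gibbs_packed(space, 4, 4, 1500, rng)
        wr = _set_weights(space, rej).astype(float)
        wg = _set_weights(space, gib).astype(float)
        se = np.sqrt(wr.var(ddof=1) / len(wr) + wg.var(ddof=1) / len(wg))
        assert abs(wr.mean() - wg.mean()) < 4 * se

    def test_rejections_follow_geometric_law(self, rng):
        space = PackedSpace(15, DNA)
        _, stats = pairwise_bounded_rejection_packed(space, 4, 4, 400, rng)
        r = np.array(stats.rejections_per_accept, dtype=float)
        p = 1.0 / (1.0 + r.mean())
        geo_var = (1 - p) / p**2
        # broad tolerance: 400 draws of a heavy-tailed variable
        assert 0.3 * geo_var < r.var(ddof=1) < 3.0 * geo_var


class TestDecoySampler:
    def test_decoys_are_bounded_but_consensus_free(self, rng):
        sets, _ = sample_decoy_sets(8, 2, 4, 5, rng)
        for s in sets:
            assert is_pairwise_bounded(s, 2)
            assert not consensus_exists(s, 2).exists

    def test_decoy_example_would_be_accepted(self):
        s = ["000", "011", "101", "110"]
        assert is_pairwise_bounded(s, 1, BINARY)
        assert not consensus_exists(s, 1, BINARY).exists

    def test_gibbs_route_at_large_n(self, rng):
        sets, n_motif = sample_decoy_sets(15, 4, 20, 3, rng)
        for s in sets:
            assert is_pairwise_bounded(s, 4)
            assert not consensus_exists(s, 4).exists
        assert n_motif >= 0


class TestRejectionCurve:
    def test_trivial_regime_has_zero_rejections(self, rng):
        df = rejection_curve([(8, 4, 5)], 50, rng)
        assert df.mean_rejections.iloc[0] == 0.0

    def test_acceptance_probability_nonincreasing_in_n(self, rng):
        # exponential decay in n; testable only in the feasible small-n range
        df = rejection_curve([(15, 4, n) for n in (3, 4, 5)], 250, rng)
        acc = df.acceptance_rate.to_numpy()
        assert acc[0] > acc[1] > acc[2]

    def test_self_consistency_across_seeds(self):
        df1 = rejection_curve([(15, 4, 3)], 400, np.random.default_rng(1))
        df2 = rejection_curve([(15, 4, 3)], 400, np.random.default_rng(2))
        m1, m2 = df1.mean_rejections.iloc[0], df2.mean_rejections.iloc[0]
        # geometric: SE of the mean ~ sqrt((1-p)/p^2 / k)
        p = 1 / (1 + max(m1, m2))
        se = np.sqrt((1 - p) / p**2 / 400)
        assert abs(m1 - m2) < 4 * se
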