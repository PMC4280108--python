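import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hemisync as hs
from hemisync.clusterstats import space_freq_adjacency


class TestMotionIndex:
    def test_worked_example(self):
        assert hs.motion_index(0.55, 0.50, 0.45, 0.50) == pytest.approx(0.10)

    def test_all_equal_zero(self):
        assert hs.motion_index(0.5, 0.5, 0.5, 0.5) == 0.0

    @given(
        st.tuples(*[st.floats(0.0, 1.0) for _ in range(4)])
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_phase_swap(self, mrs):
        a, b, c, d = mrs
        assert hs.motion_index(a, b, c, d) == pytest.approx(
            -hs.motion_index(c, d, a, b)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hs.motion_index(1.2, 0.5, 0.5, 0.5)


class TestRtoT:
    def test_zero_maps_to_zero(self):
        assert hs.r_to_t(0.0, 14) == 0.0

    def test_worked_example(self):
        assert hs.r_to_t(0.6, 14) == pytest.approx(2.598, abs=0.001)

    @given(st.floats(-0.99, 0.99), st.integers(3, 100))
    @settings(max_examples=50, deadline=None)
    def test_odd_in_r(self, r, n):
        assert hs.r_to_t(-r, n) == pytest.approx(-hs.r_to_t(r, n), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            hs.r_to_t(1.0, 14)
        with pytest.raises(ValueError):
            hs.r_to_t(0.5, 2)


@pytest.fixture(scope="module")
def adjacency(layout):
    return layout.adjacency_matrix()


class TestClusterPermTtest:
    def test_null_data_rarely_significant(self, adjacency):
        rng = np.random.default_rng(0)
        sig = 0
        for _ in range(30):
            a = rng.standard_normal((14, 31))
            b = rng.standard_normal((14, 31))
            res = hs.cluster_perm_ttest(a, b, adjacency, n_perm=200, seed=1)
            sig += bool(res.significant(0.05))
        assert sig <= 5  # ~5% nominal rate, binomial slack

    def test_seeded_block_effect_detected(self, layout, adjacency):
        # seed a d=1.5 effect in a 4-sensor adjacent posterior block
        block = list(layout.pairs[layout.pair_of_interest])
        block += list(layout.adjacency[block[0]])[:2]
        block = sorted(set(block))[:4]
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((14, 31))
            b = rng.standard_normal((14, 31))
            a[:, block] += 1.5
            res = hs.cluster_perm_ttest(a, b, adjacency, n_perm=300, seed=seed)
            sig = res.significant(0.05)
            if sig and len(set(sig[0].members) & set(block)) >= 3:
                hits += 1
        assert hits >= 9  # >= 90% of seeds

    def test_reproducible_with_seed(self, adjacency):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((14, 31))
        b = rng.standard_normal((14, 31)) + 0.4
        r1 = hs.cluster_perm_ttest(a, b, adjacency, n_perm=300, seed=9)
        r2 = hs.cluster_perm_ttest(a, b, adjacency, n_perm=300, seed=9)
        assert [(c.members, c.stat, c.p) for c in r1.clusters] == [
            (c.members, c.stat, c.p) for c in r2.clusters
        ]

    def test_p_floor_respected(self, adjacency):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((14, 31)) + 3.0  # massive global effect
        b = rng.standard_normal((14, 31))
        res = hs.cluster_perm_ttest(a, b, adjacency, n_perm=200, seed=0)
        assert res.clusters
        assert min(c.p for c in res.clusters) == pytest.approx(1 / 201)

    def test_subject_relabeling_invariance(self, adjacency):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((14, 31))
        b = rng.standard_normal((14, 31)) + 0.5
        perm = np.random.default_rng(1).permutation(14)
        r1 = hs.cluster_perm_ttest(a, b, adjacency, n_perm=200, seed=3)
        r2 = hs.cluster_perm_ttest(a[perm], b[perm], adjacency, n_perm=200, seed=3)
        # observed clusters are permutation-invariant; p-values agree closely
        assert [c.members for c in r1.clusters] == [c.members for c in r2.clusters]

    def test_too_few_subjects_rejected(self, adjacency):
        with pytest.raises(ValueError):
            hs.cluster_perm_ttest(
                np.zeros((1, 31)), np.zeros((1, 31)), adjacency
            )


class TestClusterPermCorrelation:
    def test_no_coupling_rarely_significant(self, adjacency):
        rng = np.random.default_rng(1)
        sig = 0
        for _ in range(30):
            mi = rng.normal(0, 0.05, 14)
            maps = rng.normal(0, 0.1, (14, 31))
            res = hs.cluster_perm_correlation(mi, maps, adjacency, n_perm=200, seed=2)
            sig += bool(res.significant(0.05))
        assert sig <= 5

    def test_injected_block_coupling_detected(self, layout, adjacency):
        block = sorted(
            set(layout.pairs[layout.pair_of_interest])
            | set(list(layout.adjacency[layout.pairs[layout.pair_of_interest][0]])[:2])
        )
        hits = 0
        for seed in range(10):
            mi, maps = hs.generate_coupled_delta_maps(
                14, 31, block, beta=2.0, noise_sd=0.02, seed=seed
            )
            res = hs.cluster_perm_correlation(mi, maps, adjacency, n_perm=300, seed=seed)
            sig = res.significant(0.05)
            if sig and len(set(sig[0].members) & set(block)) >= 2:
                hits += 1
        assert hits >= 9

    def test_single_channel_effect_never_reported(self, adjacency):
        # a supra-threshold singleton must be filtered by the 2-channel rule
        rng = np.random.default_rng(3)
        mi = rng.normal(0, 0.05, 14)
        maps = rng.normal(0, 1e-3, (14, 31))
        maps[:, 7] = mi * 5.0  # perfect single-channel correlation
        res = hs.cluster_perm_correlation(mi, maps, adjacency, n_perm=200, seed=0)
        for c in res.significant(0.05):
            assert c.size >= 2
            assert c.members != (7,)

    def test_shuffle_mi_variant_runs(self, adjacency):
        rng = np.random.default_rng(4)
        mi = rng.normal(0, 0.05, 14)
        maps = rng.normal(0, 0.1, (14, 31))
        res = hs.cluster_perm_correlation(
            mi, maps, adjacency, n_perm=100, seed=0, permute="shuffle_mi"
        )
        assert res.kind == "correlation"


class TestSpaceFreqAdjacency:
    def test_structure(self):
        space = np.zeros((3, 3), dtype=bool)
        space[0, 1] = space[1, 0] = True
        adj = space_freq_adjacency(space, n_freq=4)
        a = adj.toarray()
        assert a.shape == (12, 12)
        assert a[0, 1]  # (s0,f0)-(s0,f1)
        assert a[0, 4]  # (s0,f0)-(s1,f0)
        assert not a[0, 8]  # s0-s2 not linked
        assert not a[3, 4]  # (s0,f3)-(s1,f0) not linked
        assert (a == a.T).all()
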