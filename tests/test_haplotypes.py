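"""Haplotype statistics against combinatorial and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dupsweep import haplotypes as H
from dupsweep import simulate
from dupsweep.io import HaplotypeMatrix


def _hm(haps, positions=None):
    haps = np.asarray(haps, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, haps.shape[0] + 1)
    return HaplotypeMatrix(
        chrom="2R", positions=positions, haplotypes=haps,
        haplotype_ids=[f"h{j}" for j in range(haps.shape[1])],
    )


class TestRogersHuffR:
    def test_identical_and_complementary(self):
        x = np.array([0, 1, 2, 1, 0, 2], float)
        assert H.rogers_huff_r(x, x) == pytest.approx(1.0)
        assert H.rogers_huff_r(x, 2 - x) == pytest.approx(-1.0)

    def test_matches_direct_pearson(self, rng):
        x = rng.integers(0, 3, 6).astype(float)
        y = rng.integers(0, 3, 6).astype(float)
        if x.std() == 0 or y.std() == 0:
            pytest.skip("degenerate draw")
        assert H.rogers_huff_r(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(H.rogers_huff_r(np.ones(5), np.arange(5.0)))

    def test_pairwise_deletion(self):
        x = np.array([0, 1, 2, np.nan, 2])
        y = np.array([0, 1, 2, 0, 2])
        assert H.rogers_huff_r(x, y) == pytest.approx(1.0)


class TestFindTaggingVariants:
    def _tracks(self, rows):
        return pd.DataFrame(rows, columns=["start", "end", "haplotype_score", "coverage"])

    def test_constructed_truth(self, rng):
        """3 sites in perfect LD with the focal SNP inside diploid windows
        are returned, and only those."""
        n = 40
        focal = rng.integers(0, 3, n).astype(float)
        dosages = np.vstack(
            [
                focal,                      # 0: focal itself (excluded)
                focal,                      # 1: perfect LD, diploid window
                2 - focal,                  # 2: perfect negative LD, diploid
                focal,                      # 3: perfect LD, tetraploid window
                rng.integers(0, 3, n),      # 4: unlinked
                focal,                      # 5: perfect LD, diploid window
            ]
        ).astype(float)
        positions = np.array([100, 200, 300, 400, 500, 600])
        tracks = self._tracks(
            [
                (1, 350, 2.0, 2.0),
                (351, 450, 4.0, 4.1),    # tetraploid
                (451, 700, 2.1, 1.9),
            ]
        )
        got = H.find_tagging_variants(
            dosages, positions, focal_index=0,
            window_tracks=tracks, phased_positions=positions,
        )
        assert got == [1, 2, 5]

    def test_all_tetraploid_coverage_empty(self, rng):
        focal = rng.integers(0, 3, 30).astype(float)
        dosages = np.vstack([focal, focal])
        tracks = self._tracks([(1, 1000, 4.0, 4.0)])
        got = H.find_tagging_variants(
            dosages, np.array([10, 20]), 0, tracks, np.array([10, 20])
        )
        assert got == []


def brute_force_mst_weight(dist):
    """Minimum spanning-tree weight by enumeration over all spanning trees."""
    n = dist.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = None
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            w = sum(dist[i, j] for i, j in combo)
            best = w if best is None else min(best, w)
    return best


class TestHaplotypeNetwork:
    def test_all_identical_single_node(self):
        hm = _hm(np.zeros((5, 8)))
        net = H.build_haplotype_network(hm)
        assert len(net.nodes) == 1
        assert net.nodes[0].size == 8
        assert net.edges == []

    def test_distance_1_1_2_keeps_two_edges(self):
        # three clusters: 000, 100, 001 -> distances {1,1,2}
        haps = np.array([
            [0, 0, 1, 1, 0, 0],
            [0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 1, 1],
        ])
        net = H.build_haplotype_network(_hm(haps))
        assert len(net.nodes) == 3
        assert len(net.edges) == 2
        assert all(w == 1 for *_, w in net.edges)
        # MST weight agrees with the exhaustive spanning-tree oracle
        reps = np.array([[0, 1, 0], [0, 0, 0], [0, 0, 1]])
        dist = np.array(
            [[(reps[:, i] != reps[:, j]).sum() for j in range(3)] for i in range(3)]
        )
        assert sum(w for *_, w in net.edges) + sum(
            w for *_, w in net.dropped_edges
        ) == brute_force_mst_weight(dist)

    def test_mst_weight_matches_enumeration(self, rng):
        haps = rng.integers(0, 2, size=(3, 8)).astype(np.int8)
        net = H.build_haplotype_network(_hm(haps), max_edge_distance=10**9)
        reps, members = H._cluster_identical(haps, [str(i) for i in range(8)])
        n = reps.shape[1]
        assert 2 <= n <= 7, "fixture seed must give a non-degenerate clustering"
        dist = np.array(
            [[(reps[:, i] != reps[:, j]).sum() for j in range(n)] for i in range(n)]
        )
        assert sum(w for *_, w in net.edges) == brute_force_mst_weight(dist)

    def test_node_sizes_sum_to_haplotype_count(self, sweep_haps):
        window = H._hm_window(sweep_haps, 140, 160)
        net = H.build_haplotype_network(window)
        assert sum(n.size for n in net.nodes) == sweep_haps.n_haplotypes

    def test_largest_cluster_enriched_for_swept_allele(self, sweep_haps):
        window = H._hm_window(sweep_haps, 130, 170)
        tag = sweep_haps.haplotypes[150]
        net = H.build_haplotype_network(window, tag_alleles=tag)
        biggest = max(net.nodes, key=lambda n: n.size)
        assert biggest.tag_allele == 1

    def test_empty_window_rejected(self):
        with pytest.raises(H.HaplotypeError):
            H.build_haplotype_network(_hm(np.zeros((0, 0))))


class TestGarudH:
    def test_all_identical(self):
        assert H.garud_h(np.zeros((4, 10))) == pytest.approx((1.0, 1.0, 0.0, 0.0))

    def test_two_equal_clusters(self):
        haps = np.zeros((3, 10), dtype=int)
        haps[:, 5:] = 1
        h1, h12, h2, ratio = H.garud_h(haps)
        assert (h1, h12, h2, ratio) == pytest.approx((0.5, 1.0, 0.25, 0.5))

    def test_h12_minus_h1_identity(self, sweep_haps):
        """H12 − H1 = 2·p1·p2 for every window."""
        for start in range(0, 250, 50):
            sub = sweep_haps.haplotypes[start:start + 50]
            h1, h12, _, _ = H.garud_h(sub)
            p = H._cluster_freqs(sub)
            p2 = p[1] if len(p) > 1 else 0.0
            assert h12 - h1 == pytest.approx(2 * p[0] * p2, abs=1e-12)

    def test_sweep_beats_frequency_matched_neutral(self):
        """Paired-seed replicates: H12 at the focal window is larger under
        the sweep than under a neutral (high-recombination) control."""
        wins = 0
        n_rep = 200
        for seed in range(n_rep):
            common = dict(
                n_haplotypes=80, n_variants=100, focal_index=50, seed=seed,
                swept_frequency=0.5,
            )
            sw = simulate.simulate_sweep(simulate.SweepSimConfig(**common))
            ne = simulate.simulate_sweep(
                simulate.SweepSimConfig(**common, recombination_scale=100.0)
            )
            wins += (
                H.garud_h(sw.haplotypes[30:70])[1]
                > H.garud_h(ne.haplotypes[30:70])[1]
            )
        assert wins / n_rep >= 0.95

    def test_too_few_haplotypes(self):
        with pytest.raises(H.HaplotypeError):
            H.garud_h(np.zeros((3, 1)))


class TestHaplotypeDiversity:
    def test_degenerate_cases(self):
        assert H.haplotype_diversity(np.zeros((3, 6))) == 0.0
        distinct = np.eye(5, dtype=int)[:, :5]
        assert H.haplotype_diversity(distinct) == pytest.approx(1.0)

    def test_hand_computation_2_1_1(self):
        haps = np.array([[0, 0, 1, 0], [0, 0, 0, 1]])
        expected = (1 - (0.25 + 0.0625 + 0.0625)) * 4 / 3
        assert H.haplotype_diversity(haps) == pytest.approx(expected)


def ehh_pair_oracle(haps, core, step):
    """EHH by direct pair counting over the [core..step] slice."""
    n = haps.shape[1]
    pairs = identical = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            identical += np.array_equal(
                haps[core:step + 1, i], haps[core:step + 1, j]
            )
    return identical / pairs


class TestEhhDecay:
    def test_core_step_is_one_when_core_monomorphic(self):
        haps = np.zeros((5, 6), dtype=int)
        haps[2:] = np.random.default_rng(0).integers(0, 2, (3, 6))
        assert H.ehh_decay(haps, 0)[0] == 1.0

    def test_two_two_split(self):
        haps = np.array([[0, 0, 0, 0], [0, 0, 1, 1]])
        ehh = H.ehh_decay(haps, 0)
        assert ehh[1] == pytest.approx((1 + 1) / 6)

    def test_matches_pair_counting_oracle(self, rng):
        haps = rng.integers(0, 2, size=(10, 8))
        ehh = H.ehh_decay(haps, 3, direction="right")
        for step in range(3, 10):
            assert ehh[step - 3] == pytest.approx(
                ehh_pair_oracle(haps, 3, step)
            )

    def test_monotone_non_increasing_both_directions(self, sweep_haps):
        for direction in ("right", "left"):
            ehh = H.ehh_decay(sweep_haps.haplotypes, 150, direction)
            assert np.all(np.diff(ehh) <= 1e-12)

    def test_swept_carriers_decay_slower(self, sweep_haps):
        tag = sweep_haps.haplotypes[150].astype(bool)
        carriers = sweep_haps.haplotypes[:, tag]
        background = sweep_haps.haplotypes[:, ~tag]
        auc_c = H.ehh_decay(carriers, 150).sum()
        auc_b = H.ehh_decay(background, 150).sum()
        assert auc_c > auc_b


class TestFlankJackknife:
    def test_insensitive_statistic_zero_se(self):
        _, se = H.flank_average_with_jackknife(
            np.zeros((4, 10)), lambda h: 1.23
        )
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_matches_leave_one_out_enumeration(self, rng):
        haps = rng.integers(0, 2, (6, 7))
        stat = lambda h: H.garud_h(h)[0]
        mean, se = H.flank_average_with_jackknife(haps, stat)
        loo = np.array(
            [stat(np.delete(haps, j, axis=1)) for j in range(7)]
        )
        expected = np.sqrt(6 / 7 * ((loo - loo.mean()) ** 2).sum())
        assert mean == pytest.approx(stat(haps))
        assert se == pytest.approx(expected, rel=1e-12)

    def test_se_shrinks_with_more_haplotypes(self, rng):
        ses = []
        for n in (10, 40, 160):
            haps = rng.integers(0, 2, (5, n))
            _, se = H.flank_average_with_jackknife(haps, lambda h: H.garud_h(h)[0])
            ses.append(se)
        assert ses[2] < ses[0]


def test_moving_statistic_window_overlap_readings(sweep_haps):
    share = H.moving_statistic(
        sweep_haps, lambda h: H.garud_h(h)[0], window_size=100,
        overlap_fraction=0.2, step_mode="share",
    )
    step = H.moving_statistic(
        sweep_haps, lambda h: H.garud_h(h)[0], window_size=100,
        overlap_fraction=0.2, step_mode="step",
    )
    # share-mode: step 80 (adjacent windows share 20 variants);
    # step-mode: step 20
    assert share.loc[1, "first_variant"] == 80
    assert step.loc[1, "first_variant"] == 20
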