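"""Two-point RF estimation, grouping, ordering, and map distances."""

import itertools

import numpy as np
import pytest
from scipy import stats

from bingbs.core import A, B, C, D, H, MISSING
from bingbs.linkage import (
    build_linkage_map,
    estimate_rf,
    group_markers,
    joint_genotype_probs,
    map_distances,
    marey_profile,
    observable_probs,
    order_markers,
    pairwise_rf,
)


def _simulate_pair(r, n, rng):
    """Two-locus F2 genotypes at true recombination fraction r."""
    g = np.zeros((2, n), dtype=np.int64)
    for _ in range(2):  # two gametes
        h1 = rng.integers(0, 2, size=n)
        h2 = np.where(rng.random(n) < r, 1 - h1, h1)
        g[0] += h1
        g[1] += h2
    return g[0], g[1]


class TestJointTable:
    @pytest.mark.parametrize("r", [0.0, 0.1, 0.25, 0.5])
    def test_distribution_sums_to_one(self, r):
        P = joint_genotype_probs(r)
        assert P.sum() == pytest.approx(1.0)
        assert (P >= 0).all()

    def test_independence_at_half(self):
        P = joint_genotype_probs(0.5)
        marg = np.array([0.25, 0.5, 0.25])
        np.testing.assert_allclose(P, np.outer(marg, marg), atol=1e-12)

    def test_perfect_linkage_at_zero(self):
        P = joint_genotype_probs(0.0)
        np.testing.assert_allclose(np.diag(P), [0.25, 0.5, 0.25], atol=1e-12)
        assert P.sum() == pytest.approx(1.0)

    def test_symmetric_under_allele_relabeling(self, subtests=None):
        P = joint_genotype_probs(0.2)
        np.testing.assert_allclose(P, P[::-1, ::-1], atol=1e-12)

    def test_matches_empirical_frequencies(self):
        rng = np.random.default_rng(0)
        gA, gB = _simulate_pair(0.2, 200_000, rng)
        emp = np.zeros((3, 3))
        for i, j in zip(gA, gB):
            emp[i, j] += 1
        emp /= emp.sum()
        np.testing.assert_allclose(joint_genotype_probs(0.2), emp, atol=5e-3)


class TestEstimateRf:
    def test_identical_vectors_give_zero(self):
        rng = np.random.default_rng(1)
        g = rng.choice([A, H, B], p=[0.25, 0.5, 0.25], size=200)
        est = estimate_rf(g, g)
        assert est.rhat == pytest.approx(0.0, abs=1e-4)
        assert est.lod > 10
        assert est.n_informative == 200

    def test_independent_markers_near_half(self):
        rng = np.random.default_rng(2)
        gA = rng.choice([A, H, B], p=[0.25, 0.5, 0.25], size=350)
        gB = rng.choice([A, H, B], p=[0.25, 0.5, 0.25], size=350)
        est = estimate_rf(gA, gB)
        assert est.rhat > 0.4
        assert est.lod < 2

    def test_symmetric_in_arguments_and_label_swap(self):
        rng = np.random.default_rng(3)
        gA, gB = _simulate_pair(0.15, 300, rng)
        e1 = estimate_rf(gA, gB)
        e2 = estimate_rf(gB, gA)
        swap = {A: B, B: A, H: H}
        e3 = estimate_rf(np.vectorize(swap.get)(gA), np.vectorize(swap.get)(gB))
        assert e1.rhat == pytest.approx(e2.rhat, abs=1e-6)
        assert e1.rhat == pytest.approx(e3.rhat, abs=1e-6)

    def test_unbiased_at_true_r(self):
        # oracle: the estimator should recover the generating r on average
        rng = np.random.default_rng(4)
        rhats = []
        for _ in range(300):
            gA, gB = _simulate_pair(0.1, 350, rng)
            rhats.append(estimate_rf(gA, gB).rhat)
        assert np.mean(rhats) == pytest.approx(0.1, abs=0.01)

    def test_composite_and_missing_codes_supported(self):
        rng = np.random.default_rng(5)
        gA, gB = _simulate_pair(0.1, 400, rng)
        gA2 = gA.copy()
        gA2[gA == B] = C  # degrade some calls to "not MM"
        gA2[:20] = MISSING
        est_full = estimate_rf(gA, gB)
        est_part = estimate_rf(gA2, gB)
        assert est_part.n_informative == 380
        assert est_part.rhat == pytest.approx(est_full.rhat, abs=0.05)

    def test_too_few_informative_pairs_flagged(self):
        gA = np.array([A, MISSING, MISSING])
        gB = np.array([MISSING, H, B])
        est = estimate_rf(gA, gB)
        assert np.isnan(est.rhat)


def test_pairwise_matches_single_pair_estimates():
    rng = np.random.default_rng(6)
    G = np.empty((6, 300), dtype=np.int64)
    G[0], G[1] = _simulate_pair(0.05, 300, rng)
    G[2], G[3] = _simulate_pair(0.2, 300, rng)
    G[4], G[5] = _simulate_pair(0.45, 300, rng)
    G[5, :30] = MISSING
    rhat, lod, ninf = pairwise_rf(G)
    for i, j in itertools.combinations(range(6), 2):
        ref = estimate_rf(G[i], G[j])
        assert rhat[i, j] == pytest.approx(ref.rhat, abs=3e-3)
        assert lod[i, j] == pytest.approx(ref.lod, abs=0.15)
        assert ninf[i, j] == ref.n_informative
    np.testing.assert_allclose(rhat, rhat.T, atol=1e-4)


class TestGrouping:
    def test_recovers_simulated_chromosomes(self, medium_binned, medium_cross):
        markers, _, _, codes, _ = medium_binned
        _, truth = medium_cross
        rhat, lod, _ = pairwise_rf(codes)
        groups = group_markers(rhat, lod)
        chrom_of = dict(zip(truth.placement["scaffold"],
                            truth.placement["chromosome"]))
        truth_chrom = np.array([chrom_of[s] for s in markers["scaffold"]])
        assert len(groups) == truth_chrom.max()
        for g in groups:
            assert len(set(truth_chrom[g])) == 1

    def test_infinite_lod_threshold_isolates_markers(self, medium_binned):
        _, _, _, codes, _ = medium_binned
        rhat, lod, _ = pairwise_rf(codes)
        groups = group_markers(rhat, lod, lod_min=np.inf)
        assert all(len(g) == 1 for g in groups)


class TestOrdering:
    def test_three_markers_exhaustive(self):
        rng = np.random.default_rng(7)
        # chain at r = 0.05 twice; ends ~0.10
        h = np.zeros((3, 700), dtype=np.int64)
        for k in range(2):
            h1 = rng.integers(0, 2, size=700)
            h2 = np.where(rng.random(700) < 0.05, 1 - h1, h1)
            h3 = np.where(rng.random(700) < 0.05, 1 - h2, h2)
            h[0] += h1
            h[1] += h2
            h[2] += h3
        rhat, _, _ = pairwise_rf(h[:, :350])
        order = order_markers(np.array([0, 1, 2]), rhat)
        # oracle: best of the 3 distinct orders by summed adjacent rhat
        best = min(
            itertools.permutations(range(3)),
            key=lambda p: rhat[p[0], p[1]] + rhat[p[1], p[2]],
        )
        assert list(order) in [list(best), list(best[::-1])]
        assert list(order) == [0, 1, 2]

    def test_two_markers_normalized_deterministically(self):
        rhat = np.array([[0.0, 0.1], [0.1, 0.0]])
        assert list(order_markers(np.array([1, 0]), rhat)) == [0, 1]

    def test_recovers_physical_order_on_simulation(self, medium_binned):
        markers, _, _, codes, _ = medium_binned
        rhat, lod, _ = pairwise_rf(codes)
        groups = group_markers(rhat, lod)
        for g in groups:
            order = order_markers(g, rhat)
            phys = markers.iloc[order].sort_values(["scaffold", "bin_index"])
            tau = stats.kendalltau(
                np.arange(len(order)),
                [list(order).index(i) for i in phys.index.map(
                    lambda x: list(markers.index).index(x))],
            ).statistic
            assert abs(tau) >= 0.95

    def test_invariant_under_marker_relabeling(self):
        rng = np.random.default_rng(8)
        n = 8
        pos = np.sort(rng.uniform(0, 0.3, size=n))
        rhat = 0.5 * (1 - np.exp(-2 * np.abs(pos[:, None] - pos[None, :])))
        base = order_markers(np.arange(n), rhat)
        perm = rng.permutation(n)
        rp = rhat[np.ix_(perm, perm)]
        reordered = order_markers(np.arange(n), rp)
        relabeled = perm[reordered]
        assert list(relabeled) in [list(base), list(base[::-1])]


class TestMapDistances:
    def test_closed_forms(self):
        np.testing.assert_allclose(map_distances([0.0]), [0.0, 0.0])
        assert map_distances([0.1])[1] == pytest.approx(11.157, abs=1e-3)
        assert map_distances([0.1], "kosambi")[1] == pytest.approx(10.137,
                                                                   abs=1e-3)

    def test_half_is_infinite_distance_error(self):
        with pytest.raises(ValueError):
            map_distances([0.5])

    def test_unknown_function_rejected(self):
        with pytest.raises(ValueError):
            map_distances([0.1], "carter-falconer")


def test_map_length_matches_simulated_recombination(medium_binned, medium_cross):
    # 3 chromosomes x 3 Mb x 4 cM/Mb = 36 cM expected in total
    markers, _, _, codes, _ = medium_binned
    names = list(markers["marker"])
    keys = [(s, b) for s, b in zip(markers["scaffold"], markers["bin_index"])]
    lm, _, _ = build_linkage_map(codes, names, physical_keys=keys)
    assert len(lm.groups) == 3
    assert lm.total_cM == pytest.approx(36.0, rel=0.25)


class TestMarey:
    def test_uniform_rate_profile_is_flat(self, medium_binned):
        import pandas as pd

        markers, _, _, codes, _ = medium_binned
        names = list(markers["marker"])
        keys = [(s, b) for s, b in zip(markers["scaffold"], markers["bin_index"])]
        lm, _, _ = build_linkage_map(codes, names, physical_keys=keys)
        chrom_of = {f"{i}": 1 + i // 2 for i in range(6)}
        offset = {f"{i}": (i % 2) * 1_500_000 for i in range(6)}
        phys = pd.DataFrame({
            "marker": markers["marker"],
            "chromosome": [chrom_of[s] for s in markers["scaffold"]],
            "bp": [offset[s] + mp for s, mp in
                   zip(markers["scaffold"], markers["midpoint_bp"])],
        })
        profile, suppression = marey_profile(lm.table, phys)
        rates = profile["cM_per_Mb"].dropna()
        assert rates.mean() == pytest.approx(4.0, rel=0.3)
        assert suppression.empty

    def test_zero_recombination_run_flagged(self):
        import pandas as pd

        table = pd.DataFrame({
            "group": "LG1",
            "marker": [f"m{i}" for i in range(8)],
            "cM": [0, 1, 2, 2, 2, 2, 3, 4],
        })
        phys = pd.DataFrame({
            "marker": [f"m{i}" for i in range(8)],
            "chromosome": 1,
            "bp": np.arange(8) * 1_000_000 + 1,
        })
        _, suppression = marey_profile(table, phys, min_zero_run=3)
        assert len(suppression) == 1
        assert suppression.iloc[0]["start_bp"] == 2_000_001
        assert suppression.iloc[0]["end_bp"] == 5_000_001
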