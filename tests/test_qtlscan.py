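"""Pseudomarkers, HMM genotype probabilities, HK scan, permutations, peaks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootkin.qtlscan import (
    GENO_CODES,
    build_cross,
    find_peaks,
    genotype_probabilities,
    haldane_r,
    hk_scan,
    insert_pseudomarkers,
    permutation_threshold,
    ril_selfing_R,
    variance_explained,
)
from rootkin.synthdata import make_genetic_map, simulate_ril_genotypes
from rootkin.types import GeneticMap, LODProfile


def single_chrom_map(positions, length=None):
    positions = np.asarray(positions, dtype=float)
    return GeneticMap(
        chromosomes=["chr1"],
        lengths={"chr1": float(length if length is not None else positions[-1])},
        positions={"chr1": positions},
        marker_names={"chr1": [f"m{i}" for i in range(len(positions))]},
    )


def enumerate_posteriors(positions, obs_codes, error_rate):
    """Brute-force posterior over all 2^m hidden paths (test oracle)."""
    m = len(positions)
    R = ril_selfing_R(haldane_r(np.diff(positions)))
    post = np.zeros((m, 2))
    total = 0.0
    for path in itertools.product([0, 1], repeat=m):
        p = 0.5
        for i in range(1, m):
            p *= R[i - 1] if path[i] != path[i - 1] else 1 - R[i - 1]
        for i, o in enumerate(obs_codes):
            if o >= 0:
                p *= (1 - error_rate) if path[i] == o else error_rate
        total += p
        for i in range(m):
            post[i, path[i]] += p
    return post / total


class TestPseudomarkers:
    def test_fills_integer_grid(self):
        grid = insert_pseudomarkers(single_chrom_map([0.0, 3.0]), step=1.0)
        np.testing.assert_allclose(grid.positions["chr1"], [0, 1, 2, 3])

    def test_large_step_leaves_map_unchanged(self):
        gmap = single_chrom_map([0.0, 3.0, 7.0])
        grid = insert_pseudomarkers(gmap, step=100.0)
        np.testing.assert_allclose(grid.positions["chr1"], gmap.positions["chr1"])

    def test_gap_bound_and_counting(self):
        gmap = single_chrom_map([0.0, 21.5])
        grid = insert_pseudomarkers(gmap, step=1.0)
        pos = grid.positions["chr1"]
        # counting oracle: 1 + sum over gaps of ceil(gap/step) grid points
        assert pos.size == 1 + int(np.ceil(21.5 / 1.0))
        assert np.diff(pos).max() <= 1.0 + 1e-9
        assert 0.0 in pos and 21.5 in pos

    def test_true_markers_retained_with_names(self):
        gmap = single_chrom_map([0.0, 2.5, 10.0])
        grid = insert_pseudomarkers(gmap, step=2.0)
        for name in gmap.marker_names["chr1"]:
            assert name in grid.marker_names["chr1"]


class TestGenotypeProbabilities:
    def test_observed_marker_is_certain_without_error(self):
        gmap = single_chrom_map([0.0, 10.0])
        geno = pd.DataFrame({"m0": ["AA"], "m1": ["BB"]}, index=["RIL001"])
        probs = genotype_probabilities(gmap, geno, error_rate=0.0)["chr1"]
        assert probs[0, 0, 0] == pytest.approx(1.0, abs=1e-12)
        assert probs[0, 1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_two_marker_closed_form(self):
        # observed AA then missing: P(BB at the far marker) = 2r/(1+2r)
        gmap = single_chrom_map([0.0, 10.0])
        geno = pd.DataFrame({"m0": ["AA"], "m1": [None]}, index=["RIL001"])
        probs = genotype_probabilities(gmap, geno, error_rate=0.0)["chr1"]
        assert probs[0, 1, 1] == pytest.approx(0.153453, abs=1e-6)

    @pytest.mark.parametrize("error_rate", [0.0, 0.001, 0.05])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_path_enumeration(self, error_rate, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 9))
        positions = np.sort(rng.uniform(0, 40, m))
        positions[0] = 0.0
        gmap = single_chrom_map(positions, length=positions[-1] + 1)
        obs = rng.choice([-1, 0, 1], size=m, p=[0.3, 0.35, 0.35])
        codes = {0: "AA", 1: "BB", -1: None}
        geno = pd.DataFrame(
            {f"m{i}": [codes[int(o)]] for i, o in enumerate(obs)}, index=["RIL001"]
        )
        got = genotype_probabilities(gmap, geno, error_rate=error_rate)["chr1"][0]
        want = enumerate_posteriors(positions, obs, error_rate)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_rows_sum_to_one_on_pseudomarker_grid(self, genotype_frame, small_map):
        cross = build_cross(small_map, genotype_frame, step=1.0, error_rate=0.001)
        for chrom, probs in cross.genoprobs.items():
            np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-10)

    def test_invalid_codes_rejected(self, small_map):
        geno = pd.DataFrame(
            {m: ["AA"] * 2 for m in ["m1", "m2", "m3", "m4", "m5"]},
            index=["RIL001", "RIL002"],
        )
        geno.loc["RIL002", "m3"] = "AB"
        with pytest.raises(ValueError, match="genotype codes"):
            build_cross(small_map, geno)


def _simulated_cross(n_rils=60, seed=0, n_markers=40, lengths=(80.0, 60.0)):
    gmap = make_genetic_map(n_markers=n_markers, chrom_lengths=lengths)
    geno = simulate_ril_genotypes(gmap, n_rils, missing_rate=0.02, seed=seed)
    return gmap, geno, build_cross(gmap, geno, step=1.0, error_rate=0.001)


class TestHKScan:
    def test_constant_phenotype_gives_zero_lod(self):
        _, geno, cross = _simulated_cross()
        pheno = pd.DataFrame({"flat": np.ones(len(geno))}, index=geno.index)
        profile = hk_scan(cross, pheno)
        assert np.allclose(profile.lod["flat"], 0.0)

    def test_perfect_signal_localizes_at_marker(self):
        gmap, geno, cross = _simulated_cross(n_rils=20, seed=3)
        marker = gmap.marker_names["chr1"][5]
        code = np.where(geno[marker] == "BB", 1.0, 0.0)
        code = np.where(geno[marker].isna(), 0.5, code)
        rng = np.random.default_rng(0)
        pheno = pd.DataFrame({"y": code + 1e-3 * rng.standard_normal(20)},
                             index=geno.index)
        profile = hk_scan(cross, pheno)
        pbb, chroms, poss = cross.prob_bb_matrix()
        best = int(np.argmax(profile.lod["y"]))
        assert chroms[best] == "chr1"
        assert abs(poss[best] - gmap.positions["chr1"][5]) < 1e-9

    def test_matches_explicit_normal_equations(self, genotype_frame, small_map):
        """8-RIL worked cross: LOD from hand-computed OLS at each position."""
        cross = build_cross(small_map, genotype_frame, step=5.0, error_rate=0.001)
        rng = np.random.default_rng(7)
        y = rng.standard_normal(8)
        pheno = pd.DataFrame({"y": y}, index=genotype_frame.index)
        with pytest.warns(UserWarning, match="unstable"):
            profile = hk_scan(cross, pheno)
        pbb, _, _ = cross.prob_bb_matrix()
        n = y.size
        rss0 = np.sum((y - y.mean()) ** 2)
        for j in range(pbb.shape[1]):
            X = np.column_stack([np.ones(n), pbb[:, j]])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            rss1 = np.sum((y - X @ beta) ** 2)
            expected = (n / 2.0) * np.log10(rss0 / rss1)
            assert profile.lod["y"][j] == pytest.approx(expected, abs=1e-8)

    def test_missing_phenotypes_dropped_traitwise(self):
        _, geno, cross = _simulated_cross(n_rils=40, seed=5)
        y = np.random.default_rng(1).standard_normal(40)
        y[:5] = np.nan
        profile = hk_scan(cross, pd.DataFrame({"y": y}, index=geno.index))
        assert profile.n_used["y"] == 35

    def test_all_missing_rejected(self):
        _, geno, cross = _simulated_cross(n_rils=20, seed=6)
        pheno = pd.DataFrame({"y": np.full(20, np.nan)}, index=geno.index)
        with pytest.raises(ValueError):
            hk_scan(cross, pheno)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, scale, shift):
        _, geno, cross = _simulated_cross(n_rils=30, seed=8, n_markers=12,
                                          lengths=(40.0,))
        y = np.random.default_rng(2).standard_normal(30)
        base = hk_scan(cross, pd.DataFrame({"y": y}, index=geno.index))
        trans = hk_scan(
            cross, pd.DataFrame({"y": scale * y + shift}, index=geno.index)
        )
        np.testing.assert_allclose(base.lod["y"], trans.lod["y"], atol=1e-8)


class TestPermutations:
    def test_seed_reproducibility_and_quantile_monotonicity(self):
        _, geno, cross = _simulated_cross(n_rils=30, seed=9, n_markers=20,
                                          lengths=(50.0, 40.0))
        y = pd.Series(np.random.default_rng(3).standard_normal(30),
                      index=geno.index)
        t1 = permutation_threshold(cross, y, n_perm=200, seed=11)
        t2 = permutation_threshold(cross, y, n_perm=200, seed=11)
        assert t1 == t2
        t_lo = permutation_threshold(cross, y, n_perm=200, quantile=0.5, seed=11)
        t_hi = permutation_threshold(cross, y, n_perm=200, quantile=1.0, seed=11)
        assert t_lo <= t1 <= t_hi

    def test_too_few_permutations_rejected(self):
        _, geno, cross = _simulated_cross(n_rils=20, seed=10, n_markers=10,
                                          lengths=(30.0,))
        y = pd.Series(np.ones(20), index=geno.index)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_threshold(cross, y, n_perm=10)


class TestPeaks:
    def test_zero_profile_yields_no_hits(self):
        _, geno, cross = _simulated_cross(n_rils=20, seed=12, n_markers=10,
                                          lengths=(30.0,))
        pheno = pd.DataFrame({"flat": np.ones(20)}, index=geno.index)
        profile = hk_scan(cross, pheno)
        assert find_peaks(profile, cross, pheno, threshold=1.0) == []

    def test_unimodal_support_interval_endpoints(self):
        """For a unimodal profile the interval spans the outermost grid
        points with LOD >= peak - drop."""
        pos = np.arange(0.0, 21.0)
        lod = 4.0 - 0.3 * np.abs(pos - 10.0)  # peak LOD 4 at 10 cM
        profile = LODProfile(
            chromosome=np.full(pos.size, "chr1", dtype=object),
            position=pos,
            lod={"y": lod},
            n_used={"y": 20},
        )
        _, geno, cross = _simulated_cross(n_rils=20, seed=13, n_markers=21,
                                          lengths=(20.0,))
        # make grid match
        cross.grid_map.positions["chr1"] = pos
        pheno = pd.DataFrame({"y": np.random.default_rng(0).standard_normal(20)},
                             index=geno.index)
        hits = find_peaks(profile, cross, pheno, threshold=3.0, drop=1.5)
        assert len(hits) == 1
        h = hits[0]
        inside = pos[lod >= 4.0 - 1.5]
        assert h.ci_lo == inside.min() and h.ci_hi == inside.max()

    def test_effect_is_half_class_mean_difference(self):
        gmap, geno, cross = _simulated_cross(n_rils=50, seed=14)
        marker = gmap.marker_names["chr1"][3]
        idx_pos = np.nonzero(
            np.isclose(cross.grid_map.positions["chr1"],
                       gmap.positions["chr1"][3])
        )[0][0]
        code = np.where(geno[marker] == "BB", 1.0, 0.0)
        rng = np.random.default_rng(4)
        y = 2.0 * code + 0.05 * rng.standard_normal(50)
        pheno = pd.DataFrame({"y": y}, index=geno.index)
        profile = hk_scan(cross, pheno)
        hits = find_peaks(profile, cross, pheno, threshold=3.0)
        h = next(h for h in hits if h.chromosome == "chr1")
        grp_bb = y[geno[marker] == "BB"].mean()
        grp_aa = y[geno[marker] == "AA"].mean()
        assert h.effect == pytest.approx((grp_bb - grp_aa) / 2.0, abs=0.05)


class TestVarianceExplained:
    def test_no_hits_zero(self):
        _, geno, cross = _simulated_cross(n_rils=20, seed=15, n_markers=10,
                                          lengths=(30.0,))
        y = pd.Series(np.ones(20), index=geno.index)
        assert variance_explained(cross, y, []) == 0.0

    def test_exact_linear_phenotype_r2_one(self):
        _, geno, cross = _simulated_cross(n_rils=40, seed=16)
        pbb, chroms, poss = cross.prob_bb_matrix()
        j = 7
        y = pd.Series(3.0 * pbb[:, j] - 1.0, index=geno.index)
        pheno = pd.DataFrame({"y": y})
        profile = hk_scan(cross, pheno)
        hits = find_peaks(profile, cross, pheno, threshold=0.5)
        r2 = variance_explained(cross, y, hits)
        assert r2 == pytest.approx(1.0, abs=1e-6)
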