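"""Nearest-neighbor separation/clustering statistics against brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mectopo import synthio, topography
from mectopo.topography import (
    inter_intra_ratio, interclass_analysis, interclass_nn,
    label_permutation_reference, mask_region, pairwise_distance_stat,
    withinclass_clustering,
)


def _nn_oracle(a, b, min_pair, same_set=False):
    """Double-loop nearest-neighbor mean."""
    dists = []
    for i, p in enumerate(a):
        best = np.inf
        for j, q in enumerate(b):
            if same_set and i == j:
                continue
            d = np.hypot(p[0] - q[0], p[1] - q[1])
            if d >= min_pair and d < best:
                best = d
        if np.isfinite(best):
            dists.append(best)
    return np.mean(dists) if dists else np.nan


class TestMaskRegion:
    def test_keeps_only_requested_region(self):
        df = pd.DataFrame({"anat_x_um": [0, 100, 200], "anat_y_um": [0, 0, 0],
                           "region": ["MEC", "PAS", "MEC"]})
        out = mask_region(df, "MEC")
        assert len(out) == 2 and set(out.region) == {"MEC"}

    def test_all_matching_region_unchanged(self):
        df = pd.DataFrame({"anat_x_um": [0, 1], "anat_y_um": [0, 1],
                           "region": ["MEC", "MEC"]})
        assert len(mask_region(df)) == 2


class TestInterclassNN:
    def test_translated_copy_has_exact_nn_distance(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 300, (12, 2))
        b = a + np.array([10.0, 0.0])
        res = interclass_nn(a, b, min_pair_um=10.0, n_subsamples=5, seed=1)
        assert res.data_mean_um == pytest.approx(10.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            a = rng.uniform(0, 400, (rng.integers(6, 30), 2))
            b = rng.uniform(0, 400, (len(a), 2))  # equal sizes: no subsampling
            res = interclass_nn(a, b, n_subsamples=1, seed=trial)
            assert res.data_mean_um == pytest.approx(_nn_oracle(a, b, 10.0), abs=1e-9)

    def test_segregated_halves_normalize_above_one(self):
        rng = np.random.default_rng(2)
        pts = []
        for i in range(40):
            pts.append({"anat_x_um": rng.uniform(0, 180), "anat_y_um": rng.uniform(0, 400),
                        "label": "grid", "region": "MEC"})
        for i in range(40):
            pts.append({"anat_x_um": rng.uniform(220, 400), "anat_y_um": rng.uniform(0, 400),
                        "label": "hd", "region": "MEC"})
        res = interclass_analysis(pd.DataFrame(pts), "grid", "hd", seed=3,
                                  n_subsamples=20, n_perm=100)
        assert res.normalized > 1.1

    def test_exchangeable_layout_normalizes_to_one(self):
        rng = np.random.default_rng(3)
        vals = []
        for rep in range(30):
            pts = pd.DataFrame({
                "anat_x_um": rng.uniform(0, 367, 60),
                "anat_y_um": rng.uniform(0, 558, 60),
                "label": ["grid"] * 30 + ["hd"] * 30,
                "region": "MEC",
            })
            res = interclass_analysis(pts, "grid", "hd", seed=rep,
                                      n_subsamples=10, n_perm=60)
            vals.append(res.normalized)
        ci = 1.96 * np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) <= ci + 0.02

    def test_too_few_starters_rejected(self):
        with pytest.raises(ValueError):
            interclass_nn(np.zeros((3, 2)), np.zeros((10, 2)))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 300, (15, 2))
        b = rng.uniform(0, 300, (15, 2))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        res1 = interclass_nn(a, b, n_subsamples=1, seed=5)
        res2 = interclass_nn(a @ rot.T + 50, b @ rot.T + 50, n_subsamples=1, seed=5)
        assert res1.data_mean_um == pytest.approx(res2.data_mean_um, abs=1e-9)


class TestPermutationReference:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 300, (30, 2))
        r1 = label_permutation_reference(xy, (10, 10), n_perm=50, seed=6)
        r2 = label_permutation_reference(xy, (10, 10), n_perm=50, seed=6)
        assert r1 == r2

    def test_matches_exhaustive_enumeration_on_eight_cells(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 200, (8, 2))
        na = nb = 2
        # enumerate all disjoint (A, B) assignments
        vals = []
        idx = range(8)
        for a_idx in combinations(idx, na):
            rest = [i for i in idx if i not in a_idx]
            for b_idx in combinations(rest, nb):
                vals.append(_nn_oracle(xy[list(a_idx)], xy[list(b_idx)], 10.0))
        expected = np.nanmean(vals)
        got = label_permutation_reference(xy, (na, nb), n_perm=4000, seed=7)
        assert got == pytest.approx(expected, rel=0.01)

    def test_insufficient_population_rejected(self):
        with pytest.raises(ValueError):
            label_permutation_reference(np.zeros((5, 2)), (3, 3))


class TestInterIntraRatio:
    def test_identical_distributions_near_one(self):
        rng = np.random.default_rng(7)
        vals = [inter_intra_ratio(rng.uniform(0, 367, (25, 2)),
                                  rng.uniform(0, 367, (25, 2)),
                                  n_subsamples=10, seed=i) for i in range(20)]
        assert abs(np.mean(vals) - 1.0) < 0.1

    def test_segregated_halves_exceed_one(self):
        rng = np.random.default_rng(8)
        a = np.c_[rng.uniform(0, 150, 25), rng.uniform(0, 400, 25)]
        b = np.c_[rng.uniform(250, 400, 25), rng.uniform(0, 400, 25)]
        assert inter_intra_ratio(a, b, n_subsamples=10, seed=9) > 1.5

    def test_interleaved_duplicate_class_below_one(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 400, (20, 2))
        b = a + np.array([10.0, 0.0])     # each B hugs an A at exactly 10 um
        assert inter_intra_ratio(a, b, n_subsamples=5, seed=10) < 1.0


class TestWithinclassClustering:
    def _background(self, rng, n=150):
        return np.c_[rng.uniform(0, 367, n), rng.uniform(0, 558, n)]

    def test_tight_cluster_scores_below_one(self):
        rng = np.random.default_rng(10)
        starters = rng.normal([180, 280], 25, (20, 2))
        others = self._background(rng)
        allpts = np.vstack([starters, others])
        res = withinclass_clustering(starters, others, allpts, k=5,
                                     n_subsamples=30, seed=11)
        assert res.starter_norm < 0.85
        assert res.ref_norm == pytest.approx(1.0, abs=0.15)

    def test_uniform_starters_score_near_one(self):
        rng = np.random.default_rng(11)
        vals = []
        for rep in range(15):
            allpts = self._background(rng, 120)
            pick = rng.choice(120, 20, replace=False)
            starters = allpts[pick]
            others = np.delete(allpts, pick, axis=0)
            res = withinclass_clustering(starters, others, allpts, k=5,
                                         n_subsamples=15, seed=rep)
            vals.append(res.starter_norm)
        assert abs(np.mean(vals) - 1.0) < 0.05

    def test_clustered_layout_detected_across_k(self):
        spec = synthio.EnsembleSpec(counts={"grid": 25, "hd": 50, "untuned": 75},
                                    layout="clustered", cluster_sigma_um=45.0, seed=12)
        cells = synthio.make_ensemble(spec)
        df = pd.DataFrame([{"anat_x_um": c.anat_x_um, "anat_y_um": c.anat_y_um,
                            "cls": c.true_class} for c in cells])
        grid = df[df.cls == "grid"][["anat_x_um", "anat_y_um"]].to_numpy()
        rest = df[df.cls != "grid"][["anat_x_um", "anat_y_um"]].to_numpy()
        allpts = df[["anat_x_um", "anat_y_um"]].to_numpy()
        for k in range(3, 11):
            res = withinclass_clustering(grid, rest, allpts, k=k,
                                         n_subsamples=20, seed=13)
            assert res.starter_norm < 1.0

    def test_invalid_k_rejected(self):
        rng = np.random.default_rng(12)
        s = rng.uniform(0, 100, (16, 2))
        with pytest.raises(ValueError):
            withinclass_clustering(s, s, s, k=16)


class TestPairwiseDistanceStat:
    def test_two_starters_equal_population_is_exactly_one(self):
        pts = np.array([[0.0, 0.0], [50.0, 0.0]])
        assert pairwise_distance_stat(pts, pts, n_subsamples=10, seed=14) == 1.0

    def test_clustered_starters_below_one(self):
        rng = np.random.default_rng(13)
        starters = rng.normal([100, 100], 20, (15, 2))
        allpts = np.vstack([starters, rng.uniform(0, 367, (100, 2))])
        assert pairwise_distance_stat(starters, allpts, n_subsamples=30, seed=15) < 0.7

    def test_uniform_starters_near_one(self):
        rng = np.random.default_rng(14)
        vals = []
        for rep in range(15):
            allpts = rng.uniform(0, 367, (80, 2))
            starters = allpts[rng.choice(80, 15, replace=False)]
            vals.append(pairwise_distance_stat(starters, allpts,
                                               n_subsamples=20, seed=rep))
        assert abs(np.mean(vals) - 1.0) < 0.07


class TestTerritoryMasking:
    def test_masking_boundary_region_shrinks_separation(self):
        # grid cells on the MEC side, hd on the PAS side: comparing within MEC
        # only (hd cells that leaked via mixing) weakens measured separation
        spec = synthio.EnsembleSpec(counts={"grid": 60, "hd": 60}, layout="territory",
                                    boundary_x_um=180.0, mixing=0.4, seed=16)
        cells = synthio.make_ensemble(spec)
        df = pd.DataFrame([{"anat_x_um": c.anat_x_um, "anat_y_um": c.anat_y_um,
                            "label": c.true_class, "region": c.region} for c in cells])
        full = interclass_analysis(df, "grid", "hd", seed=17, n_subsamples=20, n_perm=100)
        mec = mask_region(df, "MEC")
        masked = interclass_analysis(mec, "grid", "hd", seed=17, n_subsamples=20, n_perm=100)
        assert full.normalized > 1.0
        assert masked.normalized < full.normalized
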