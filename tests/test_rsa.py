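import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import procrustes

from pairdiff.design import DesignSpec, make_stimulus_set
from pairdiff.estimation import RoiMask
from pairdiff.rsa import (
    SimilarityMatrix,
    build_similarity_matrix,
    condition_summary,
    fisher_z,
    mds_embed,
    pair_difference_scores,
)


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_matches_log_form_oracle(self):
        # 0.5 * ln((1+r)/(1-r)) at r = 0.5
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(1.5 / 0.5), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)

    def test_unity_clipped_finite(self):
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))
        assert np.isfinite(fisher_z(-1.0))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @given(st.floats(-0.99, 0.98), st.floats(1e-4, 0.009))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, r, dr):
        assert fisher_z(r + dr) > fisher_z(r)


@pytest.fixture(scope="module")
def toy_stimset():
    return make_stimulus_set(
        DesignSpec(n_pairs_total=6, n_pairs_per_condition=2, seed=3)
    )


def _random_patterns(stimset, n_vox, seed):
    rng = np.random.default_rng(seed)
    names = list(stimset.scenes)
    return names, rng.standard_normal((len(names), n_vox))


class TestBuildSimilarityMatrix:
    def test_default_dimensions(self, default_stimset, rng):
        names, data = _random_patterns(default_stimset, 50, 0)
        sim = build_similarity_matrix((names, data), None, default_stimset)
        assert sim.z.shape == (36, 36)
        assert sim.valid_mask.shape == (36, 36)
        # diagonal is always within-condition, hence valid
        assert np.diag(sim.valid_mask).all()

    def test_rows_are_set_a_cols_set_b(self, toy_stimset):
        names, data = _random_patterns(toy_stimset, 30, 1)
        sim = build_similarity_matrix((names, data), None, toy_stimset)
        for scene in sim.row_scenes:
            assert toy_stimset.set_half[scene] == "A"
        for scene in sim.col_scenes:
            assert toy_stimset.set_half[scene] == "B"

    def test_voxel_permutation_invariance(self, toy_stimset, rng):
        names, data = _random_patterns(toy_stimset, 40, 2)
        perm = rng.permutation(40)
        a = build_similarity_matrix((names, data), None, toy_stimset)
        b = build_similarity_matrix((names, data[:, perm]), None, toy_stimset)
        np.testing.assert_allclose(a.z, b.z, atol=1e-12)

    def test_matches_bruteforce_oracle(self, toy_stimset):
        names, data = _random_patterns(toy_stimset, 25, 3)
        sim = build_similarity_matrix((names, data), None, toy_stimset)
        idx = {s: i for i, s in enumerate(names)}
        for i, pa in enumerate(sim.pair_ids):
            for j, pb in enumerate(sim.pair_ids):
                a = data[idx[toy_stimset.pairs[pa][0]]]
                b = data[idx[toy_stimset.pairs[pb][1]]]
                r = np.corrcoef(a, b)[0, 1]
                assert sim.z[i, j] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_across_condition_cells_masked(self, toy_stimset):
        names, data = _random_patterns(toy_stimset, 30, 4)
        sim = build_similarity_matrix((names, data), None, toy_stimset)
        for i in range(sim.n_pairs):
            for j in range(sim.n_pairs):
                expected = sim.conditions[i] == sim.conditions[j]
                assert sim.valid_mask[i, j] == expected

    def test_zero_variance_names_scene(self, toy_stimset):
        names, data = _random_patterns(toy_stimset, 30, 5)
        data[2] = 1.0
        with pytest.raises(ValueError, match=names[2]):
            build_similarity_matrix((names, data), None, toy_stimset)

    def test_small_roi_rejected(self, toy_stimset):
        names, data = _random_patterns(toy_stimset, 30, 6)
        mask = RoiMask(mask=np.array([True] + [False] * 29), label="tiny")
        with pytest.raises(ValueError, match="2 voxels"):
            build_similarity_matrix((names, data), mask, toy_stimset)


def _manual_simmat(z, conditions):
    n = len(conditions)
    cond = np.asarray(conditions)
    return SimilarityMatrix(
        z=np.asarray(z, dtype=float),
        valid_mask=cond[:, None] == cond[None, :],
        pair_ids=tuple(f"pair{i:02d}" for i in range(n)),
        conditions=tuple(conditions),
        row_scenes=tuple(f"s{i}A" for i in range(n)),
        col_scenes=tuple(f"s{i}B" for i in range(n)),
    )


class TestPairDifferenceScores:
    def test_hand_oracle(self):
        # pair 0: diagonal 0.8; same-condition row cells {0.2, 0.3} and
        # column cells {0.1, 0.4} -> mean 0.25 -> score 0.55
        z = np.zeros((5, 5))
        z[0, 0] = 0.8
        z[0, 1], z[0, 2] = 0.2, 0.3
        z[1, 0], z[2, 0] = 0.1, 0.4
        scores = pair_difference_scores(_manual_simmat(z, ["a", "a", "a", "b", "b"]))
        row = scores.iloc[0]
        assert row["mean_nonpairmate_z"] == pytest.approx(0.25, abs=1e-12)
        assert row["difference_score"] == pytest.approx(0.55, abs=1e-12)

    def test_all_equal_cells_give_zero(self):
        scores = pair_difference_scores(_manual_simmat(np.full((4, 4), 0.37), ["a"] * 4))
        assert np.allclose(scores["difference_score"], 0.0, atol=1e-12)

    def test_uses_22_cells_at_default_size(self, default_stimset):
        names, data = _random_patterns(default_stimset, 40, 7)
        sim = build_similarity_matrix((names, data), None, default_stimset)
        i = 0
        others = [j for j in range(36) if j != i and sim.valid_mask[i, j]]
        assert len(others) == 11  # 11 row + 11 column cells = 22
        scores = pair_difference_scores(sim)
        cells = np.concatenate([sim.z[i, others], sim.z[others, i]])
        assert scores.iloc[0]["mean_nonpairmate_z"] == pytest.approx(cells.mean(), abs=1e-12)

    def test_single_pair_condition_rejected(self):
        with pytest.raises(ValueError, match="no same-condition nonpairmates"):
            pair_difference_scores(_manual_simmat(np.zeros((3, 3)), ["a", "b", "b"]))

    def test_score_identity_property(self, rng):
        for _ in range(20):
            z = rng.normal(0, 0.5, size=(6, 6))
            scores = pair_difference_scores(_manual_simmat(z, ["a", "a", "a", "b", "b", "b"]))
            resid = scores["difference_score"] - (
                scores["pairmate_z"] - scores["mean_nonpairmate_z"]
            )
            assert np.abs(resid).max() < 1e-12

    def test_matrix_to_score_path_matches_bruteforce(self, toy_stimset):
        """Whole-path oracle: loop over all pairs/scenes with plain
        corrcoef + arctanh and condition bookkeeping."""
        names, data = _random_patterns(toy_stimset, 30, 8)
        sim = build_similarity_matrix((names, data), None, toy_stimset)
        scores = pair_difference_scores(sim)
        idx = {s: i for i, s in enumerate(names)}
        for _, row in scores.iterrows():
            pid = row["pair"]
            a, b = toy_stimset.pairs[pid]
            pairmate = np.arctanh(np.corrcoef(data[idx[a]], data[idx[b]])[0, 1])
            cells = []
            for qid, (c, d) in toy_stimset.pairs.items():
                if qid == pid or toy_stimset.condition[qid] != toy_stimset.condition[pid]:
                    continue
                cells.append(np.arctanh(np.corrcoef(data[idx[a]], data[idx[d]])[0, 1]))
                cells.append(np.arctanh(np.corrcoef(data[idx[c]], data[idx[b]])[0, 1]))
            expected = pairmate - np.mean(cells)
            assert row["difference_score"] == pytest.approx(expected, abs=1e-10)


class TestConditionSummary:
    def test_single_subject_mean(self):
        table = pd.DataFrame(
            {
                "subject": [0, 0],
                "condition": ["a", "a"],
                "difference_score": [0.1, 0.3],
                "pairmate_z": [0.5, 0.7],
                "mean_nonpairmate_z": [0.4, 0.4],
            }
        )
        summ = condition_summary(table)
        assert summ.loc[0, "difference_score_mean"] == pytest.approx(0.2)

    def test_two_subject_sem_oracle(self):
        table = pd.DataFrame(
            {
                "subject": [0, 1],
                "condition": ["a", "a"],
                "difference_score": [0.1, 0.3],
                "pairmate_z": [0.0, 0.0],
                "mean_nonpairmate_z": [0.0, 0.0],
            }
        )
        summ = condition_summary(table)
        assert summ.loc[0, "difference_score_mean"] == pytest.approx(0.2)
        # sd(ddof=1)/sqrt(2) = 0.1414.. / 1.414.. = 0.1
        assert summ.loc[0, "difference_score_sem"] == pytest.approx(0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            condition_summary(pd.DataFrame())


class TestMds:
    def test_equilateral_from_equal_dissimilarities(self):
        D = np.ones((3, 3)) - np.eye(3)
        emb = mds_embed(D)
        X = emb.coords[["x", "y"]].to_numpy()
        d01 = np.linalg.norm(X[0] - X[1])
        d02 = np.linalg.norm(X[0] - X[2])
        d12 = np.linalg.norm(X[1] - X[2])
        assert d01 == pytest.approx(d02, abs=1e-9)
        assert d01 == pytest.approx(d12, abs=1e-9)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)

    def test_recovers_planted_2d_configuration(self, rng):
        pts = rng.normal(size=(8, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        emb = mds_embed(D)
        X = emb.coords[["x", "y"]].to_numpy()
        emb_d = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(emb_d, D, atol=1e-8)
        _, _, disparity = procrustes(pts, X)
        assert disparity < 1e-10
        assert emb.stress < 1e-8

    def test_too_few_items(self):
        with pytest.raises(ValueError, match="at least 3"):
            mds_embed(np.zeros((2, 2)))

    @staticmethod
    def _pairmate_vs_nonpairmate_distance(stimset, c_pair):
        from pairdiff.synth import RepresentationModel, sample_ground_truth_patterns

        model = RepresentationModel(
            n_voxels=200, n_units=100, c_global=0.1, c_pair=c_pair, seed=5
        )
        pats = sample_ground_truth_patterns(model, stimset)
        sim = build_similarity_matrix((list(pats.scene_ids), pats.pattern), None, stimset)
        emb = mds_embed(sim)
        coords = emb.coords.set_index("scene")[["x", "y"]]
        pair_d, nonpair_d = [], []
        for pid, (a, b) in stimset.pairs.items():
            pair_d.append(np.linalg.norm(coords.loc[a] - coords.loc[b]))
            for qid, (c, d) in stimset.pairs.items():
                if qid != pid:
                    pair_other = np.linalg.norm(coords.loc[a] - coords.loc[d])
                    nonpair_d.append(pair_other)
        return np.mean(pair_d), np.mean(nonpair_d)

    def test_clustering_vs_repulsion(self, toy_stimset):
        pair_d, nonpair_d = self._pairmate_vs_nonpairmate_distance(toy_stimset, 0.5)
        assert pair_d < nonpair_d  # clustered at baseline
        pair_d, nonpair_d = self._pairmate_vs_nonpairmate_distance(toy_stimset, -0.5)
        assert pair_d > nonpair_d  # repulsion reverses the ordering
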