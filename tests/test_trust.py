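"""SGNS training and semantic-axis construction/projection."""

import dataclasses

import numpy as np
import pytest

from trustshift.trust import (
    AnchorSet,
    EmbeddingModel,
    SgnsConfig,
    TermSet,
    build_axis,
    compare_periods,
    project_term,
    train_sgns,
)


def toy_model(vectors: dict[str, list[float]]) -> EmbeddingModel:
    vocab = {w: i for i, w in enumerate(vectors)}
    mat = np.array([vectors[w] for w in vocab], dtype=float)
    return EmbeddingModel(
        vocab=vocab,
        vectors=mat,
        context_vectors=np.zeros_like(mat),
        counts=np.ones(len(vocab), dtype=np.int64),
        config=SgnsConfig(dim=mat.shape[1], min_count=1),
    )


class TestBuildAxis:
    def test_single_pair_analytic(self):
        m = toy_model({"good": [1.0, 0.0], "bad": [-1.0, 0.0]})
        anchors = AnchorSet(positive=("good",), negative=("bad",))
        np.testing.assert_allclose(build_axis(m, anchors), [1.0, 0.0])

    def test_two_pair_mean_analytic(self):
        m = toy_model(
            {
                "g1": [1.0, 0.0], "b1": [0.0, 0.0],
                "g2": [0.0, 1.0], "b2": [0.0, 0.0],
            }
        )
        anchors = AnchorSet(positive=("g1", "g2"), negative=("b1", "b2"))
        np.testing.assert_allclose(
            build_axis(m, anchors), [1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_swapping_lists_negates_axis_exactly(self):
        m = toy_model(
            {"g1": [0.8, 0.1], "b1": [-0.5, 0.2], "g2": [0.3, 0.9], "b2": [0.1, -0.7]}
        )
        anchors = AnchorSet(positive=("g1", "g2"), negative=("b1", "b2"))
        np.testing.assert_allclose(
            build_axis(m, anchors), -build_axis(m, anchors.swapped())
        )

    def test_pair_order_invariance(self):
        m = toy_model(
            {"g1": [0.8, 0.1], "b1": [-0.5, 0.2], "g2": [0.3, 0.9], "b2": [0.1, -0.7]}
        )
        a1 = build_axis(m, AnchorSet(positive=("g1", "g2"), negative=("b1", "b2")))
        a2 = build_axis(m, AnchorSet(positive=("g2", "g1"), negative=("b2", "b1")))
        np.testing.assert_allclose(a1, a2)

    def test_oov_pairs_skipped_all_missing_is_error(self):
        m = toy_model({"g1": [1.0, 0.0], "b1": [-1.0, 0.0]})
        mixed = AnchorSet(positive=("g1", "gX"), negative=("b1", "bX"))
        np.testing.assert_allclose(build_axis(m, mixed), [1.0, 0.0])
        with pytest.raises(ValueError):
            build_axis(m, AnchorSet(positive=("gX",), negative=("bX",)))

    def test_invalid_anchor_sets_rejected(self):
        with pytest.raises(ValueError):
            AnchorSet(positive=("a", "b"), negative=("c",))
        with pytest.raises(ValueError):
            AnchorSet(positive=("a",), negative=("a",))


class TestProjectTerm:
    m = toy_model(
        {
            "good": [1.0, 0.0], "bad": [-1.0, 0.0],
            "along": [2.0, 0.0], "ortho": [0.0, 3.0], "null": [0.0, 0.0],
        }
    )
    axis = build_axis(m, AnchorSet(positive=("good",), negative=("bad",)))

    def test_own_direction_scores_plus_one(self):
        assert project_term(self.m, self.axis, "along") == pytest.approx(1.0)

    def test_orthogonal_scores_zero(self):
        assert project_term(self.m, self.axis, "ortho") == pytest.approx(0.0)

    def test_oov_returns_marker_not_score(self):
        assert project_term(self.m, self.axis, "missing") is None

    def test_zero_norm_vector_rejected(self):
        with pytest.raises(ValueError):
            project_term(self.m, self.axis, "null")

    def test_scores_rotation_invariant(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        rotated = toy_model({w: list(q @ self.m.vector(w)) for w in self.m.vocab})
        axis_r = build_axis(
            rotated, AnchorSet(positive=("good",), negative=("bad",))
        )
        for term in ("along", "ortho"):
            assert project_term(rotated, axis_r, term) == pytest.approx(
                project_term(self.m, self.axis, term), abs=1e-10
            )


def two_cluster_docs(n_docs=300, seed=0):
    rng = np.random.default_rng(seed)
    c0 = [f"red{i}" for i in range(8)]
    c1 = [f"blue{i}" for i in range(8)]
    docs = []
    for j in range(n_docs):
        vocab = c0 if j % 2 == 0 else c1
        docs.append([vocab[int(i)] for i in rng.integers(8, size=10)])
    return docs, c0, c1


class TestTrainSgns:
    cfg = SgnsConfig(dim=20, window=3, epochs=3, min_count=2, seed=1)

    def test_deterministic_given_seed(self):
        docs, _, _ = two_cluster_docs(60)
        m1 = train_sgns(docs, self.cfg)
        m2 = train_sgns(docs, self.cfg)
        assert m1.vocab == m2.vocab
        np.testing.assert_array_equal(m1.vectors, m2.vectors)

    def test_cluster_separation(self):
        """Words that never co-occur across clusters separate: mean
        within-cluster cosine exceeds mean across-cluster cosine."""
        docs, c0, c1 = two_cluster_docs()
        m = train_sgns(docs, self.cfg)

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        within, across = [], []
        for i, w1 in enumerate(c0):
            for w2 in c0[i + 1:]:
                within.append(cos(m.vector(w1), m.vector(w2)))
            for w2 in c1:
                across.append(cos(m.vector(w1), m.vector(w2)))
        assert np.mean(within) > np.mean(across)

    def test_probe_loss_decreases(self):
        docs, _, _ = two_cluster_docs()
        m = train_sgns(docs, dataclasses.replace(self.cfg, epochs=5))
        # index 0 is the pre-training baseline
        assert all(l < m.epoch_losses[0] for l in m.epoch_losses[1:])
        assert m.epoch_losses[-1] < m.epoch_losses[1]

    def test_min_count_filters_vocabulary(self):
        docs = [["common"] * 5 + ["rare"]]
        m = train_sgns(docs, SgnsConfig(dim=4, min_count=2, epochs=1))
        assert "common" in m and "rare" not in m

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_sgns([], self.cfg)

    def test_nonzero_finite_vectors(self):
        docs, _, _ = two_cluster_docs(100)
        m = train_sgns(docs, self.cfg)
        assert np.isfinite(m.vectors).all()
        assert (np.linalg.norm(m.vectors, axis=1) > 0).all()

    def test_word2vec_text_round_trip(self, tmp_path):
        docs, _, _ = two_cluster_docs(60)
        m = train_sgns(docs, self.cfg)
        path = tmp_path / "vecs.txt"
        m.save_word2vec(path)
        lines = path.read_text().splitlines()
        v, d = map(int, lines[0].split())
        assert v == len(m.vocab) and d == 20 and len(lines) == v + 1


class TestComparePeriods:
    anchors = AnchorSet(positive=("red0", "red1"), negative=("blue0", "blue1"))
    terms = TermSet(clinician=("red2",), health_information=("blue2", "ghost"))

    def test_identical_corpora_zero_deltas(self):
        docs, _, _ = two_cluster_docs(120)
        cfg = SgnsConfig(dim=16, epochs=2, min_count=2, seed=7)
        m1, m2 = train_sgns(docs, cfg), train_sgns(docs, cfg)
        report = compare_periods(m1, m2, self.anchors, self.terms)
        assert report.delta("red2") == 0.0
        assert report.delta("blue2") == 0.0

    def test_term_missing_one_period(self):
        docs, _, _ = two_cluster_docs(120)
        docs_with_ghost = docs + [["ghost", "blue0", "blue1"] * 3] * 4
        cfg = SgnsConfig(dim=16, epochs=2, min_count=2, seed=7)
        m_pre = train_sgns(docs, cfg)
        m_post = train_sgns(docs_with_ghost, cfg)
        report = compare_periods(m_pre, m_post, self.anchors, self.terms)
        assert report.score("ghost", "pre") is None
        assert report.score("ghost", "post") is not None
        assert report.delta("ghost") is None

    def test_report_csv(self, tmp_path):
        docs, _, _ = two_cluster_docs(120)
        cfg = SgnsConfig(dim=16, epochs=2, min_count=2, seed=7)
        m = train_sgns(docs, cfg)
        report = compare_periods(m, m, self.anchors, self.terms)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        header, *rows = path.read_text().splitlines()
        assert header == "term,group,period,score,oov"
        assert len(rows) == 2 * 3  # two periods x three terms
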