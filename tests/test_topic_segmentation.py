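"""Window construction, LDA fitting/inference, HMM segmentation, model selection."""

import numpy as np
import pytest

from narrec.corpus_io import transcript_from_text
from narrec.exceptions import ParameterError
from narrec.ground_truth import GroundTruthBoundaries, boundary_f1
from narrec.synthetic_data import gen_story
from narrec.topic_segmentation import (
    TopicTrajectory,
    WindowSet,
    build_windows,
    fit_topic_model,
    grid_search,
    hmm_segment,
    infer_topics,
    segment_transcript,
    select_num_events,
)


def _dummy_transcript(n):
    return transcript_from_text(" ".join(f"tok{i % 97} " for i in range(n)) + ".")


class TestBuildWindows:
    @pytest.mark.parametrize(
        "n,w,s,expected",
        [
            (10, 5, 5, [(0, 5), (5, 10)]),
            (12, 5, 5, [(0, 5), (5, 10), (10, 12)]),
            (4, 10, 2, [(0, 4)]),
        ],
    )
    def test_window_layout(self, n, w, s, expected):
        ws = build_windows(_dummy_transcript(n), w, s)
        assert ws.windows == expected

    def test_948_word_story_yields_44_windows(self):
        ws = build_windows(_dummy_transcript(948), 55, 21)
        assert ws.n_windows == 44

    def test_windows_cover_transcript(self):
        ws = build_windows(_dummy_transcript(231), 25, 7)
        assert ws.windows[0][0] == 0 and ws.windows[-1][1] == 231
        for (a0, b0), (a1, _) in zip(ws.windows, ws.windows[1:]):
            assert a1 - a0 == 7 and a1 <= b0  # coverage without gaps

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ParameterError):
            build_windows(_dummy_transcript(20), 5, 6)

    def test_stop_words_removed_from_counts(self):
        t = transcript_from_text("the cat and the hat sat on the mat.")
        ws = build_windows(t, 9, 9)
        assert "the" not in ws.vocabulary and "cat" in ws.vocabulary


def _alternating_windows(n_windows=12, block=50):
    """Windows drawing from two disjoint 50-word vocabularies, alternating."""
    V = 2 * block
    vocab = [f"tok{i}" for i in range(V)]
    rng = np.random.default_rng(0)
    counts = np.zeros((n_windows, V), dtype=np.int64)
    for i in range(n_windows):
        lo = 0 if i % 2 == 0 else block
        idx = rng.integers(lo, lo + block, size=30)
        np.add.at(counts[i], idx, 1)
    return WindowSet(window_size_words=30, step_words=30,
                     windows=[(30 * i, 30 * i + 30) for i in range(n_windows)],
                     counts=counts, vocabulary=vocab)


class TestTopicModel:
    def test_disjoint_vocabularies_separate_into_topics(self):
        ws = _alternating_windows()
        model = fit_topic_model(ws, 2, seed=0)
        traj = infer_topics(model, ws)
        dom = np.argmax(traj.vectors, axis=1)
        assert np.all(dom[::2] == dom[0]) and np.all(dom[1::2] == dom[1]) and dom[0] != dom[1]

    def test_fit_deterministic(self):
        ws = _alternating_windows()
        a = fit_topic_model(ws, 2, seed=3)
        b = fit_topic_model(ws, 2, seed=3)
        assert np.array_equal(a.topic_word, b.topic_word)

    def test_rows_on_simplex_and_shape(self, story6_transcript):
        ws = build_windows(story6_transcript, 25, 12)
        model = fit_topic_model(ws, 12, seed=0)
        assert model.topic_word.shape == (12, len(ws.vocabulary))
        assert np.allclose(model.topic_word.sum(axis=1), 1.0, atol=1e-9)

    def test_infer_identical_windows_identical_vectors(self):
        ws = _alternating_windows()
        model = fit_topic_model(ws, 2, seed=0)
        dup = WindowSet(ws.window_size_words, ws.step_words, ws.windows[:2] * 2,
                        np.vstack([ws.counts[:2]] * 2), ws.vocabulary)
        traj = infer_topics(model, dup)
        assert np.allclose(traj.vectors[0], traj.vectors[2])
        assert np.allclose(traj.vectors[1], traj.vectors[3])

    def test_out_of_vocabulary_window_uniform_with_warning(self):
        ws = _alternating_windows()
        model = fit_topic_model(ws, 2, seed=0)
        alien = WindowSet(30, 30, [(0, 30)], np.array([[3, 1]]), ["zzz", "qqq"])
        with pytest.warns(UserWarning, match="no in-vocabulary"):
            traj = infer_topics(model, alien)
        assert np.allclose(traj.vectors[0], 0.5)


def _two_block_traj(n=10, split=5, K=4):
    V = np.full((n, K), 0.02)
    V[:split, 0] = 0.94
    V[split:, 1] = 0.94
    return TopicTrajectory(vectors=V, window_map=[(5 * i, 5 * i + 5) for i in range(n)])


class TestHMMSegment:
    def test_two_block_boundary_exact(self):
        seg = hmm_segment(_two_block_traj(), 2)
        assert seg.boundaries == [0, 25]
        assert seg.n_events == 2

    def test_single_event(self):
        seg = hmm_segment(_two_block_traj(), 1)
        assert seg.boundaries == [0]
        assert seg.event_vectors.shape[0] == 1

    def test_invalid_event_count(self):
        with pytest.raises(ParameterError):
            hmm_segment(_two_block_traj(), 11)

    def test_loglik_nondecreasing(self, story6, story6_transcript):
        ws = build_windows(story6_transcript, 25, 5)
        model = fit_topic_model(ws, 12, seed=0)
        traj = infer_topics(model, ws)
        seg = hmm_segment(traj, 6)
        ll = np.asarray(seg.loglik_history)
        assert np.all(np.diff(ll) >= -1e-8)

    def test_events_partition_words(self, story6_transcript):
        ws = build_windows(story6_transcript, 25, 5)
        model = fit_topic_model(ws, 12, seed=0)
        traj = infer_topics(model, ws)
        seg = hmm_segment(traj, 6)
        iv = seg.intervals()
        assert iv[0][0] == 0 and iv[-1][1] == story6_transcript.n_words
        for (a0, b0), (a1, _) in zip(iv, iv[1:]):
            assert b0 == a1 and a0 < b0

    def test_topic_label_invariance(self, story6_transcript):
        ws = build_windows(story6_transcript, 25, 5)
        model = fit_topic_model(ws, 12, seed=0)
        traj = infer_topics(model, ws)
        perm = np.random.default_rng(1).permutation(traj.n_topics)
        traj_p = TopicTrajectory(vectors=traj.vectors[:, perm], window_map=traj.window_map)
        assert hmm_segment(traj, 6).boundaries == hmm_segment(traj_p, 6).boundaries

    def test_planted_boundary_recovery_within_one_window(self, story6, story6_transcript):
        ws = build_windows(story6_transcript, 25, 5)
        model = fit_topic_model(ws, 12, seed=0)
        traj = infer_topics(model, ws)
        seg = hmm_segment(traj, story6.n_events)
        err = np.abs(np.asarray(seg.boundaries[1:]) - np.asarray(story6.true_boundaries[1:]))
        assert err.max() <= 5  # one 5-word step


class TestSelectNumEvents:
    def test_constant_trajectory_smallest_candidate(self):
        traj = TopicTrajectory(vectors=np.full((8, 3), 1 / 3), window_map=[(i, i + 1) for i in range(8)])
        assert select_num_events(traj, [2, 3, 4]) == 2

    def test_two_block_selects_two(self):
        assert select_num_events(_two_block_traj(), [2, 3, 4]) == 2

    def test_two_block_matches_brute_force_criterion(self):
        """Independently score each candidate from the segmentation labels."""
        traj = _two_block_traj()
        scores = {}
        for E in (2, 3, 4):
            labels = hmm_segment(traj, E).window_states
            C = np.corrcoef(traj.vectors)
            within, across = [], []
            for e in range(E):
                idx = np.flatnonzero(labels == e)
                for i in idx:
                    for j in idx:
                        if i < j:
                            within.append(C[i, j])
                if e + 1 < E:
                    jdx = np.flatnonzero(labels == e + 1)
                    across.extend(C[i, j] for i in idx for j in jdx)
            scores[E] = (np.mean(within) if within else 0.0) - (np.mean(across) if across else 0.0)
        assert select_num_events(traj, [2, 3, 4]) == max(sorted(scores), key=lambda E: scores[E])

    def test_planted_six_event_recovery(self):
        story = gen_story(n_events=6, words_per_event_range=(80, 120), topic_concentration=0.02, seed=3)
        tr = transcript_from_text(story.text())
        ws = build_windows(tr, 25, 12)
        model = fit_topic_model(ws, 12, seed=0)
        traj = infer_topics(model, ws)
        assert select_num_events(traj, list(range(2, 13))) == 6

    def test_empty_candidates_rejected(self):
        with pytest.raises(ParameterError):
            select_num_events(_two_block_traj(), [])


class TestSegmentTranscript:
    def test_recall_copy_of_event_matches_that_event(self, story6, story6_transcript):
        seg, model = segment_transcript(story6_transcript, w=25, s=12, K=12, E=story6.n_events, seed=0)
        ev = 2
        a, b = seg.intervals()[ev]
        recall = transcript_from_text(" ".join(story6_transcript.words[a:b]) + ".")
        rseg, _ = segment_transcript(recall, w=25, s=12, E=1, seed=0, model=model)
        corr = [np.corrcoef(rseg.event_vectors[0], v)[0, 1] for v in seg.event_vectors]
        assert int(np.argmax(corr)) == ev

    def test_empty_recall_zero_events(self, story6_transcript):
        seg, model = segment_transcript(story6_transcript, w=25, s=12, K=8, E=4, seed=0)
        empty = transcript_from_text("")
        rseg, _ = segment_transcript(empty, model=model)
        assert rseg.n_events == 0 and rseg.boundaries == []


class TestGridSearch:
    def _truth(self, story):
        return GroundTruthBoundaries(
            boundary_words=list(story.true_boundaries),
            boundary_times_ms=[story.word_onsets_ms[b][0] for b in story.true_boundaries],
            threshold=float("nan"),
            n_iterations=0,
        )

    def test_single_cell_grid(self, story6, story6_transcript):
        res = grid_search(story6_transcript, self._truth(story6), [25], [12], [12], seed=0)
        assert len(res.table) == 1
        assert res.best == (25, 12, 12)

    def test_best_attains_max(self, story6, story6_transcript):
        res = grid_search(story6_transcript, self._truth(story6), [25, 40], [12], [8, 12], seed=0)
        assert res.best_f1 == res.table["f1"].max()
        assert res.table["f1"].iloc[0] == res.best_f1

    def test_invalid_pairs_skipped_and_empty_grid_rejected(self, story6, story6_transcript):
        truth = self._truth(story6)
        with pytest.raises(ParameterError):
            grid_search(story6_transcript, truth, [10], [21], [8], seed=0)
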