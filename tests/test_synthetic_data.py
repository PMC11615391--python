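"""Generator contracts: planted structure, determinism, degenerate parameters."""

import numpy as np
import pytest

from narrec.exceptions import ParameterError
from narrec.synthetic_data import (
    AnnotatorParams,
    RecallBehaviorParams,
    gen_annotations,
    gen_recalls,
    gen_story,
)


class TestGenStory:
    def test_fixed_lengths_force_boundaries(self):
        s = gen_story(n_events=2, words_per_event_range=(50, 50), seed=1)
        assert s.true_boundaries == [0, 50]
        assert s.n_words == 100

    def test_deterministic_given_seed(self):
        a = gen_story(n_events=5, seed=7)
        b = gen_story(n_events=5, seed=7)
        assert a.words == b.words
        assert a.true_boundaries == b.true_boundaries
        assert np.array_equal(a.topic_word_dists, b.topic_word_dists)
        assert a.sentence_ends == b.sentence_ends

    def test_stochastic_matrices_and_timings(self):
        s = gen_story(n_events=4, seed=3)
        assert np.allclose(s.topic_word_dists.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(s.event_topic_mix.sum(axis=1), 1.0, atol=1e-9)
        on = np.array([a for a, _ in s.word_onsets_ms])
        off = np.array([b for _, b in s.word_onsets_ms])
        assert np.all(off > on) and np.all(on[1:] >= off[:-1])

    def test_sentences_align_with_event_boundaries(self):
        s = gen_story(n_events=6, seed=5)
        starts = {0} | {e + 1 for e in s.sentence_ends}
        assert set(s.true_boundaries) <= starts
        lengths = np.diff([0] + [e + 1 for e in s.sentence_ends])
        assert lengths.min() >= 1 and lengths.max() <= 22  # 8-15 plus merged tail

    def test_within_event_similarity_exceeds_across(self):
        """Near-one-hot event mixtures produce lexically coherent events."""
        s = gen_story(n_events=8, words_per_event_range=(100, 100), topic_concentration=0.02, seed=9)
        V = s.topic_word_dists.shape[1]
        halves = []
        for a, b in s.event_intervals():
            mid = (a + b) // 2
            for lo, hi in ((a, mid), (mid, b)):
                c = np.zeros(V)
                for wtok in s.words[lo:hi]:
                    c[int(wtok[1:])] += 1
                halves.append(c / np.linalg.norm(c))
        halves = np.asarray(halves)
        cos = halves @ halves.T
        within = [cos[2 * e, 2 * e + 1] for e in range(8)]
        across = [cos[i, j] for i in range(16) for j in range(i + 1, 16) if i // 2 != j // 2]
        assert np.mean(within) > np.mean(across)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            gen_story(n_events=1)
        with pytest.raises(ParameterError):
            gen_story(n_events=4, words_per_event_range=(10, 5))
        with pytest.raises(ParameterError):
            gen_story(n_events=4, n_topics=4, vocab_size=20)


class TestGenRecalls:
    def test_degenerate_full_recall_in_order(self, story6):
        params = RecallBehaviorParams(p_recall=1.0, contiguity=1.0, p_first_is_first=1.0)
        recs = gen_recalls(story6, params, 5, seed=2)
        for r in recs:
            assert r.true_recalled_events == list(range(story6.n_events))

    def test_zero_recall_probability_gives_empty(self, story6):
        recs = gen_recalls(story6, RecallBehaviorParams(p_recall=0.0), 5, seed=2)
        for r in recs:
            assert r.words == [] and r.true_recalled_events == []

    def test_empirical_recall_rate_matches_planted(self, story6):
        recs = gen_recalls(story6, RecallBehaviorParams(p_recall=0.5), 2000, words_per_recalled_event=1, seed=4)
        E = story6.n_events
        rate = np.zeros(E)
        for r in recs:
            rate[r.true_recalled_events] += 1
        rate /= len(recs)
        assert np.all(np.abs(rate - 0.5) < 0.03)

    def test_contiguity_one_takes_minimal_forward_lag(self, story6):
        recs = gen_recalls(story6, RecallBehaviorParams(p_recall=0.7, contiguity=1.0), 50, seed=6)
        for r in recs:
            seq = r.true_recalled_events
            for i in range(len(seq) - 1):
                remaining = set(seq[i + 1 :])
                fwd = [e for e in remaining if e > seq[i]]
                if fwd:
                    assert seq[i + 1] == min(fwd)

    def test_primacy_boost_raises_event0_rate(self, story6):
        recs = gen_recalls(
            story6, RecallBehaviorParams(p_recall=0.3, primacy_boost=5.0), 1500, words_per_recalled_event=1, seed=8
        )
        rate0 = np.mean([0 in r.true_recalled_events for r in recs])
        # boosted odds: 5*(0.3/0.7) -> p ~ 0.682
        assert abs(rate0 - 5 * 3 / 7 / (1 + 5 * 3 / 7)) < 0.05

    def test_deterministic(self, story6):
        p = RecallBehaviorParams()
        a = gen_recalls(story6, p, 10, seed=3)
        b = gen_recalls(story6, p, 10, seed=3)
        assert [r.words for r in a] == [r.words for r in b]
        assert [r.true_recalled_events for r in a] == [r.true_recalled_events for r in b]


class TestGenAnnotations:
    def test_no_jitter_presses_exactly_at_onsets(self, story6):
        ann = gen_annotations(
            story6, AnnotatorParams(n_annotators=3, p_detect=1.0, jitter_sd_ms=0.0, false_alarm_rate_hz=0.0), seed=1
        )
        onsets = [story6.word_onsets_ms[b][0] for b in story6.true_boundaries[1:]]
        for vec in ann.vectors:
            assert sorted(np.flatnonzero(vec)) == sorted(onsets)

    def test_zero_detection_gives_silence(self, story6):
        ann = gen_annotations(
            story6, AnnotatorParams(n_annotators=4, p_detect=0.0, false_alarm_rate_hz=0.0), seed=1
        )
        assert ann.vectors.sum() == 0

    def test_press_counts_binomial(self, story6):
        n, p = 50, 0.8
        ann = gen_annotations(
            story6,
            AnnotatorParams(n_annotators=n, p_detect=p, jitter_sd_ms=0.0, false_alarm_rate_hz=0.0),
            seed=5,
        )
        sd = np.sqrt(n * p * (1 - p))
        for b in story6.true_boundaries[1:]:
            count = ann.vectors[:, story6.word_onsets_ms[b][0]].sum()
            assert abs(count - n * p) <= 3 * sd

    def test_deterministic(self, story6):
        p = AnnotatorParams(n_annotators=5)
        a = gen_annotations(story6, p, seed=9)
        b = gen_annotations(story6, p, seed=9)
        assert np.array_equal(a.vectors, b.vectors)

    def test_param_validation(self):
        with pytest.raises(ParameterError):
            AnnotatorParams(n_annotators=0)
        with pytest.raises(ParameterError):
            AnnotatorParams(p_detect=1.5)
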