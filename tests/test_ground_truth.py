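"""Annotator-consensus boundary derivation and boundary F1 scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from narrec.corpus_io import WordTimings, transcript_from_text
from narrec.exceptions import DegenerateInputError, ParameterError
from narrec.ground_truth import (
    AnnotationSet,
    BinnedAnnotations,
    bins_to_boundaries,
    boundary_f1,
    downsample,
    significant_bins,
)
from narrec.synthetic_data import AnnotatorParams, gen_annotations


class TestDownsample:
    def test_single_press_lands_in_first_bin(self):
        v = np.zeros((1, 10000), dtype=np.uint8)
        v[0, 2345] = 1
        binned = downsample(AnnotationSet(vectors=v), 5000)
        assert binned.binned.tolist() == [[1, 0]]

    def test_half_open_bin_convention(self):
        v = np.zeros((1, 10000), dtype=np.uint8)
        v[0, 4999] = 1
        v[0, 5000] = 1
        binned = downsample(AnnotationSet(vectors=v), 5000)
        assert binned.binned.tolist() == [[1, 1]]

    def test_all_zero(self):
        binned = downsample(AnnotationSet(vectors=np.zeros((3, 12000), dtype=np.uint8)), 5000)
        assert binned.binned.sum() == 0 and np.all(binned.mean_curve == 0)
        assert binned.n_bins == 3  # final partial bin included

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_bin_membership_matches_raw(self, seed):
        rng = np.random.default_rng(seed)
        v = (rng.random((2, 7000)) < 0.001).astype(np.uint8)
        binned = downsample(AnnotationSet(vectors=v), 1000)
        for a in range(2):
            for b in range(7):
                assert binned.binned[a, b] == v[a, b * 1000 : (b + 1) * 1000].any()


class TestSignificantBins:
    def test_uniform_signal_yields_nothing(self):
        binned = BinnedAnnotations(bin_ms=5000, binned=np.ones((20, 10), dtype=np.uint8))
        sig, thr = significant_bins(binned, n_iter=200, seed=0)
        assert sig == []

    def test_single_loaded_bin_detected(self):
        binned_mat = np.zeros((50, 20), dtype=np.uint8)
        binned_mat[:, 7] = 1
        sig, thr = significant_bins(BinnedAnnotations(5000, binned_mat), n_iter=1000, seed=1)
        assert sig == [7]
        assert thr < 1.0

    def test_annotator_order_invariance(self):
        rng = np.random.default_rng(2)
        mat = (rng.random((30, 40)) < 0.2).astype(np.uint8)
        mat[:, 5] = 1
        sig1, thr1 = significant_bins(BinnedAnnotations(5000, mat), n_iter=300, seed=3)
        perm = rng.permutation(30)
        sig2, thr2 = significant_bins(BinnedAnnotations(5000, mat[perm]), n_iter=300, seed=3)
        assert sig1 == sig2

    def test_permute_method_agrees_on_strong_signal(self):
        mat = np.zeros((40, 30), dtype=np.uint8)
        mat[:, 11] = 1
        sig, _ = significant_bins(BinnedAnnotations(5000, mat), n_iter=300, seed=0, method="permute")
        assert sig == [11]

    def test_single_bin_degenerate(self):
        with pytest.raises(DegenerateInputError):
            significant_bins(BinnedAnnotations(5000, np.ones((5, 1), dtype=np.uint8)), n_iter=100)


def _timings(story):
    return WordTimings(entries=[(w, a, b) for w, (a, b) in zip(story.words, story.word_onsets_ms)])


class TestBinsToBoundaries:
    def test_peak_at_sentence_initial_word(self):
        # 40 words at 500 ms; sentence starts at 0 and 24; peak presses at word 24's onset
        words = " ".join(f"alpha{i}" for i in range(24)) + ". " + " ".join(f"beta{i}" for i in range(16)) + "."
        t = transcript_from_text(words)
        vec = np.zeros((10, 20000), dtype=np.uint8)
        vec[:, 12000] = 1  # onset of word 24
        ann = AnnotationSet(vectors=vec)
        tim = WordTimings(entries=[(w, 500 * i, 500 * i + 450) for i, w in enumerate(t.words)])
        gt = bins_to_boundaries([2], ann, tim, t, bin_ms=5000)
        assert gt.boundary_words == [0, 24]

    def test_adjacent_bins_same_sentence_merge(self):
        words = " ".join(f"alpha{i}" for i in range(24)) + ". " + " ".join(f"beta{i}" for i in range(16)) + "."
        t = transcript_from_text(words)
        vec = np.zeros((10, 20000), dtype=np.uint8)
        vec[:, 11900] = 1
        vec[:, 12100] = 1
        ann = AnnotationSet(vectors=vec)
        tim = WordTimings(entries=[(w, 500 * i, 500 * i + 450) for i, w in enumerate(t.words)])
        gt = bins_to_boundaries([1, 2], ann, tim, t, bin_ms=5000)
        assert gt.boundary_words == [0, 24]

    def test_end_to_end_recovery_from_synthetic_annotations(self, story6, story6_transcript):
        ann = gen_annotations(
            story6,
            AnnotatorParams(n_annotators=205, p_detect=0.9, jitter_sd_ms=500.0, false_alarm_rate_hz=0.005),
            seed=6,
        )
        binned = downsample(ann, 5000)
        bins, thr = significant_bins(binned, n_iter=500, seed=7)
        gt = bins_to_boundaries(bins, ann, _timings(story6), story6_transcript, threshold=thr, n_iterations=500)
        assert gt.boundary_words == story6.true_boundaries


class TestBoundaryF1:
    def test_identity_is_perfect(self):
        prf = boundary_f1([0, 100, 200], [0, 100, 200], tol_words=10)
        assert prf.f1 == 1.0 and prf.n_matched == 2  # word 0 excluded

    def test_empty_prediction_zero(self):
        assert boundary_f1([0], [0, 50, 120], tol_words=10).f1 == 0.0

    def test_partial_match_example(self):
        prf = boundary_f1([100, 210], [95, 300], tol_words=10)
        assert prf.n_matched == 1
        assert prf.precision == 0.5 and prf.recall == 0.5 and prf.f1 == 0.5
        # brute force over all one-to-one matchings confirms 1 is the max
        best = 0
        for pairing in itertools.permutations([95, 300], 2):
            best = max(best, sum(abs(a - b) <= 10 for a, b in zip([100, 210], pairing)))
        assert best == prf.n_matched

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_swaps_precision_recall(self, seed):
        rng = np.random.default_rng(seed)
        pred = sorted(set(rng.integers(1, 500, size=6).tolist()))
        truth = sorted(set(rng.integers(1, 500, size=4).tolist()))
        a = boundary_f1(pred, truth, tol_words=15)
        b = boundary_f1(truth, pred, tol_words=15)
        assert a.precision == b.recall and a.recall == b.precision and a.f1 == b.f1

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ParameterError):
            boundary_f1([10], [12], tol_words=-1)
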