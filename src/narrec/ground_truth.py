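"""Consensus event boundaries from annotator button presses, and boundary F1.

Many annotators listen to a story and press a button at each perceived event
boundary, yielding per-annotator binary vectors at 1000 Hz.  The consensus
pipeline is: downsample to coarse bins (any press in a bin = 1), find bins
where cross-annotator agreement beats a circular-shift permutation null,
locate the 1000 Hz agreement peak inside each significant bin, map it to the
word with the nearest onset, snap to the nearest sentence start, and merge
duplicates.  Predicted segmentations are scored against these boundaries
with a tolerance-based F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Transcript, WordTimings
from .exceptions import AlignmentError, DegenerateInputError, ParameterError

__all__ = [
    "AnnotationSet",
    "BinnedAnnotations",
    "GroundTruthBoundaries",
    "PRF",
    "downsample",
    "significant_bins",
    "bins_to_boundaries",
    "boundary_f1",
]


@dataclass
class AnnotationSet:
    """Per-annotator binary press vectors at 1000 Hz (n_annotators x D ms)."""

    vectors: np.ndarray
    story_id: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 2:
            raise ParameterError("vectors must be 2-d (annotators x ms)")
        if not np.isin(self.vectors, (0, 1)).all():
            raise ParameterError("annotation vectors must be binary")

    @property
    def n_annotators(self) -> int:
        return self.vectors.shape[0]

    @property
    def duration_ms(self) -> int:
        return self.vectors.shape[1]


@dataclass
class BinnedAnnotations:
    bin_ms: int
    binned: np.ndarray  # n_annotators x n_bins, binary
    mean_curve: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.binned = np.asarray(self.binned)
        self.mean_curve = self.binned.mean(axis=0)

    @property
    def n_bins(self) -> int:
        return self.binned.shape[1]


@dataclass
class GroundTruthBoundaries:
    boundary_words: list[int]  # sorted, 0 prepended
    boundary_times_ms: list[int]
    threshold: float
    n_iterations: int

    def __post_init__(self) -> None:
        b = np.asarray(self.boundary_words)
        if b.size == 0 or b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ParameterError("boundary_words must start at 0 and be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.boundary_words)


@dataclass
class PRF:
    precision: float
    recall: float
    f1: float
    tol_words: int
    n_matched: int


def downsample(annotations: AnnotationSet, bin_ms: int = 5000) -> BinnedAnnotations:
    """Code any press inside each half-open ``[k*bin_ms, (k+1)*bin_ms)`` bin as 1.

    The final partial bin is included.
    """
    if bin_ms < 1:
        raise ParameterError("bin_ms must be >= 1")
    n, D = annotations.vectors.shape
    n_bins = int(np.ceil(D / bin_ms))
    binned = np.zeros((n, n_bins), dtype=np.uint8)
    for b in range(n_bins):
        seg = annotations.vectors[:, b * bin_ms : min((b + 1) * bin_ms, D)]
        binned[:, b] = seg.any(axis=1)
    return BinnedAnnotations(bin_ms=bin_ms, binned=binned)


def significant_bins(
    binned: BinnedAnnotations,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "shift",
) -> tuple[list[int], float]:
    """Bins where annotator agreement exceeds a time-shuffled null (1-tailed).

    The null shuffles each annotator's binned vector across time and pools
    the resulting per-bin averages over ``n_iter`` iterations into a single
    null distribution; the threshold is its ``1 - alpha`` quantile and a bin
    is significant when the observed mean agreement strictly exceeds it.

    method="shift" (default) circularly shifts each annotator's vector by an
    independent uniform offset per iteration, preserving each annotator's
    press count and within-vector run structure; method="permute" instead
    permutes bin positions independently per annotator.
    """
    if n_iter < 100:
        raise ParameterError("n_iter must be >= 100")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    B = binned.n_bins
    if B < 2:
        raise DegenerateInputError("need at least 2 bins for the permutation test")
    n = binned.binned.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, B))
    cols = np.arange(B)
    if method == "shift":
        offsets = rng.integers(0, B, size=(n_iter, n))
        for it in range(n_iter):
            idx = (cols[None, :] - offsets[it][:, None]) % B
            null[it] = binned.binned[np.arange(n)[:, None], idx].mean(axis=0)
    elif method == "permute":
        for it in range(n_iter):
            idx = rng.random((n, B)).argsort(axis=1)
            null[it] = binned.binned[np.arange(n)[:, None], idx].mean(axis=0)
    else:
        raise ParameterError(f"unknown method {method!r}")
    threshold = float(np.quantile(null, 1.0 - alpha))
    sig = np.flatnonzero(binned.mean_curve > threshold)
    return [int(b) for b in sig], threshold


def bins_to_boundaries(
    sig_bins: list[int],
    annotations: AnnotationSet,
    timings: WordTimings,
    transcript: Transcript,
    bin_ms: int = 5000,
    threshold: float = float("nan"),
    n_iterations: int = 0,
) -> GroundTruthBoundaries:
    """Align significant bins to words and snap to sentence starts.

    Runs of consecutive significant bins are treated as one boundary event
    (annotator agreement around a single perceived boundary regularly
    spills across a bin edge).  Per run: locate the 1000 Hz peak of the
    annotator-average curve inside the run (earliest millisecond on ties),
    map it to the word whose onset is nearest that time, then snap to the
    nearest sentence start by word distance (the earlier sentence on
    ties).  Duplicate boundaries collapsing onto the same sentence merge;
    the story start (word 0) is always prepended.
    """
    if not timings.entries:
        raise AlignmentError("word timings required to align bins to words")
    onsets = np.asarray(timings.onsets_ms)
    D = annotations.duration_ms
    if sig_bins and (max(sig_bins) + 1) * bin_ms <= 0:
        raise ParameterError("invalid bins")
    avg = annotations.vectors.mean(axis=0)
    starts = np.asarray(transcript.sentence_starts)
    if starts.size == 0:
        raise AlignmentError("transcript has no sentences")

    # group consecutive significant bins into runs
    runs: list[tuple[int, int]] = []
    for b in sorted(set(int(x) for x in sig_bins)):
        if runs and b == runs[-1][1]:
            runs[-1] = (runs[-1][0], b + 1)
        else:
            runs.append((b, b + 1))

    words: set[int] = set()
    for b0, b1 in runs:
        lo, hi = b0 * bin_ms, min(b1 * bin_ms, D)
        if lo >= D:
            raise AlignmentError(f"bin {b0} outside annotated duration")
        peak_ms = lo + int(np.argmax(avg[lo:hi]))
        word = int(np.argmin(np.abs(onsets - peak_ms)))  # earliest on ties
        word = min(word, len(transcript.words) - 1)
        # snap: candidate sentence starts are the start of the containing
        # sentence and the start of the following one
        k = int(np.searchsorted(starts, word, side="right")) - 1
        cands = [int(starts[k])]
        if k + 1 < starts.size:
            cands.append(int(starts[k + 1]))
        snapped = min(cands, key=lambda s: (abs(s - word), s))
        words.add(snapped)

    words.discard(0)
    boundary_words = [0] + sorted(words)
    boundary_times = []
    for w in boundary_words:
        boundary_times.append(int(onsets[w]) if w < onsets.size else int(onsets[-1]))
    return GroundTruthBoundaries(
        boundary_words=boundary_words,
        boundary_times_ms=boundary_times,
        threshold=threshold,
        n_iterations=n_iterations,
    )


def boundary_f1(pred: list[int], truth: list[int], tol_words: int = 10) -> PRF:
    """Greedy one-to-one boundary matching within a word tolerance.

    Word index 0 (the trivial story start) is excluded from both sides.
    Candidate pairs with ``|pred - truth| <= tol_words`` are matched in
    order of increasing distance, each boundary used at most once;
    precision = matched/|pred|, recall = matched/|truth|.
    """
    if tol_words < 0:
        raise ParameterError("tol_words must be >= 0")
    p = sorted({int(x) for x in pred} - {0})
    t = sorted({int(x) for x in truth} - {0})
    if not p and not t:
        return PRF(1.0, 1.0, 1.0, tol_words, 0)
    pairs = sorted(
        ((abs(a - b), i, j) for i, a in enumerate(p) for j, b in enumerate(t) if abs(a - b) <= tol_words),
    )
    used_p: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i not in used_p and j not in used_t:
            used_p.add(i)
            used_t.add(j)
            matched += 1
    precision = matched / len(p) if p else 0.0
    recall = matched / len(t) if t else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return PRF(precision, recall, f1, tol_words, matched)
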