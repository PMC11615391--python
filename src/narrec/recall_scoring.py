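"""Match recall events to story events and compute recall-probability curves.

Each recall event is assigned to the story event whose topic vector it
correlates with most strongly (Pearson over the K topic dimensions).  Story
events with no matching recall event count as forgotten.  The resulting
participants x story-events binary matrix yields per-event recall
probabilities with bootstrap confidence intervals, and a within-participant
event-order permutation test flags events recalled significantly more often
than the typical event of that story.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import pearson
from .exceptions import DataError, ParameterError
from .topic_segmentation import EventSegmentation

__all__ = [
    "EventMatching",
    "RecallMatrix",
    "RecallCurve",
    "match_events",
    "recall_matrix",
    "recall_probability",
    "significant_events",
]


@dataclass
class EventMatching:
    """One participant's recall events mapped to story events, in recall order."""

    participant_id: str
    story_id: str
    matched_story_events: list[int]
    match_correlations: list[float]

    def __post_init__(self) -> None:
        if len(self.matched_story_events) != len(self.match_correlations):
            raise ParameterError("matched events and correlations must align")


@dataclass
class RecallMatrix:
    matrix: np.ndarray  # n_participants x E, binary
    participant_ids: list[str]
    story_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or not np.isin(self.matrix, (0, 1)).all():
            raise ParameterError("recall matrix must be binary 2-d")

    @property
    def n_participants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_events(self) -> int:
        return self.matrix.shape[1]


@dataclass
class RecallCurve:
    prob: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    sig_threshold: float | None = None
    sig_events: np.ndarray | None = None


def match_events(
    recall_seg: EventSegmentation,
    story_seg: EventSegmentation,
    participant_id: str = "",
    story_id: str = "",
    min_r: float | None = None,
) -> EventMatching:
    """Assign each recall event to its best-correlated story event.

    Ties break toward the earlier story event.  Recall events whose vector
    has zero variance (correlation undefined) are skipped with a warning;
    ``min_r`` optionally discards matches below a correlation floor
    (sensitivity analyses only; no floor by default).
    """
    S = np.asarray(story_seg.event_vectors, dtype=float)
    matched: list[int] = []
    rs: list[float] = []
    for i, rvec in enumerate(np.asarray(recall_seg.event_vectors, dtype=float)):
        if rvec.std() == 0:
            warnings.warn(f"recall event {i}: zero-variance vector, skipped", stacklevel=2)
            continue
        corr = np.array([pearson(rvec, svec) if svec.std() > 0 else -np.inf for svec in S])
        best = int(np.argmax(corr))  # argmax takes the earliest on exact ties
        if not np.isfinite(corr[best]):
            warnings.warn(f"recall event {i}: no valid story correlations, skipped", stacklevel=2)
            continue
        if min_r is not None and corr[best] < min_r:
            continue
        matched.append(best)
        rs.append(float(corr[best]))
    return EventMatching(
        participant_id=participant_id,
        story_id=story_id,
        matched_story_events=matched,
        match_correlations=rs,
    )


def recall_matrix(matchings: list[EventMatching], E: int) -> RecallMatrix:
    """Binary participants x story-events matrix (1 = event recalled)."""
    mat = np.zeros((len(matchings), E), dtype=np.uint8)
    for row, m in enumerate(matchings):
        for e in m.matched_story_events:
            if not 0 <= e < E:
                raise DataError(f"matched event index {e} outside [0, {E})")
            mat[row, e] = 1
    return RecallMatrix(
        matrix=mat,
        participant_ids=[m.participant_id for m in matchings],
        story_id=matchings[0].story_id if matchings else "",
    )


def recall_probability(matrix: RecallMatrix, n_boot: int = 10000, seed: int = 0) -> RecallCurve:
    """Per-event recall probability with percentile bootstrap 95% CIs.

    Participants are resampled with replacement ``n_boot`` times.
    """
    X = matrix.matrix
    n = matrix.n_participants
    if n == 0:
        raise DataError("empty recall matrix")
    prob = X.mean(axis=0)
    if n < 2 or n_boot < 1:
        return RecallCurve(prob=prob, ci_low=prob.copy(), ci_high=prob.copy(), n_boot=0)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, matrix.n_events))
    chunk = max(1, min(n_boot, int(2e7 / max(n * matrix.n_events, 1))))
    for a in range(0, n_boot, chunk):
        b = min(a + chunk, n_boot)
        idx = rng.integers(0, n, size=(b - a, n))
        boot[a:b] = X[idx].mean(axis=1)
    ci_low = np.quantile(boot, 0.025, axis=0)
    ci_high = np.quantile(boot, 0.975, axis=0)
    # percentile CIs always bracket the point estimate up to resampling noise;
    # clip to enforce the documented invariant exactly
    ci_low = np.minimum(ci_low, prob)
    ci_high = np.maximum(ci_high, prob)
    return RecallCurve(prob=prob, ci_low=ci_low, ci_high=ci_high, n_boot=n_boot)


def significant_events(
    matrix: RecallMatrix,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Events recalled more often than the permutation null of the typical event.

    The null permutes event order within each participant, recomputes the
    per-event mean recall, and pools all per-event means over ``n_perm``
    repetitions into one distribution; with a 2-tailed alpha of 0.05 an
    event is flagged when its recall probability strictly exceeds the
    97.5th percentile of that null.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    X = matrix.matrix
    n, E = X.shape
    if n == 0:
        raise DataError("empty recall matrix")
    rng = np.random.default_rng(seed)
    rows = np.arange(n)[:, None]
    null = np.empty((n_perm, E))
    for it in range(n_perm):
        idx = rng.random((n, E)).argsort(axis=1)
        null[it] = X[rows, idx].mean(axis=0)
    threshold = float(np.quantile(null, 1.0 - alpha / 2.0))
    flags = X.mean(axis=0) > threshold
    return threshold, flags
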