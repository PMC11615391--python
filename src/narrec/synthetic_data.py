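"""Synthetic stories, recalls and annotator press vectors with known ground truth.

The generator emulates the structure of the spoken-narrative free-recall
study at configurable scale: topic-structured stories with planted event
boundaries, partial ordered verbal recalls with controllable recall
probability / primacy / temporal-contiguity parameters, and per-annotator
button-press vectors (1000 Hz) with boundary jitter and false alarms.  Every
downstream stage of the pipeline therefore has a parameter-recovery test
that needs no download.

Generative model
----------------
A story of ``E`` events draws each event's word count uniformly from
``words_per_event_range``.  Each of ``T`` topics is a sparse categorical
distribution over the vocabulary (Dirichlet with small concentration), and
each event holds a mixture over topics drawn from a symmetric Dirichlet with
concentration ``topic_concentration``; the mixture is rotated so that event
``e``'s dominant topic is ``e mod T``, which guarantees adjacent events are
dominated by different topics.  Low ``topic_concentration`` therefore yields
near-one-hot, well-separated events.  Words are drawn i.i.d. from the
event's topic mixture.  Sentence lengths are uniform on 8–15 words and
sentences never straddle an event boundary, so every planted boundary is a
sentence start.  Word onsets are synthesized at a constant 500 ms per word
(~10 words per 5 s, the spacing events are assumed to respect).

Recalls draw a recalled-event set by per-event Bernoulli probabilities
(``primacy_boost`` multiplies event 0's odds), order the set with a
temporal-contiguity rule, and emit words from the recalled events' topic
mixtures with a ``noise_level`` fraction replaced by uniform vocabulary
draws.  Annotators press near true boundary onsets with probability
``p_detect``, Gaussian jitter, plus a Poisson process of false alarms.

All generators are bit-reproducible given their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._utils import check_prob
from .exceptions import ParameterError
from .ground_truth import AnnotationSet

__all__ = [
    "SyntheticStory",
    "SyntheticRecall",
    "RecallBehaviorParams",
    "AnnotatorParams",
    "gen_story",
    "gen_recalls",
    "gen_annotations",
    "write_corpus",
]

MS_PER_WORD = 500  # constant synthesized word pacing
_WORD_GAP_MS = 50  # silence between consecutive words


@dataclass
class SyntheticStory:
    words: list[str]
    true_boundaries: list[int]  # event-start word indices, first = 0
    topic_word_dists: np.ndarray  # T x V, rows on the simplex
    event_topic_mix: np.ndarray  # E x T, rows on the simplex
    sentence_ends: list[int]
    word_onsets_ms: list[tuple[int, int]]  # per-word (onset, offset)

    def __post_init__(self) -> None:
        n = len(self.words)
        b = np.asarray(self.true_boundaries)
        if not (b[0] == 0 and np.all(np.diff(b) > 0) and b[-1] < n):
            raise ParameterError("true_boundaries must be strictly increasing in [0, n_words)")
        for name, mat in (("topic_word_dists", self.topic_word_dists), ("event_topic_mix", self.event_topic_mix)):
            if not np.allclose(np.asarray(mat).sum(axis=1), 1.0, atol=1e-9):
                raise ParameterError(f"rows of {name} must sum to 1")
        on = np.array([a for a, _ in self.word_onsets_ms])
        off = np.array([b_ for _, b_ in self.word_onsets_ms])
        if not (np.all(off > on) and np.all(on[1:] >= off[:-1])):
            raise ParameterError("word timings must be increasing and non-overlapping")

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def n_events(self) -> int:
        return len(self.true_boundaries)

    @property
    def duration_ms(self) -> int:
        return self.word_onsets_ms[-1][1] + _WORD_GAP_MS if self.words else 0

    def event_intervals(self) -> list[tuple[int, int]]:
        """Half-open [start, end) word intervals of the planted events."""
        b = list(self.true_boundaries) + [self.n_words]
        return [(b[i], b[i + 1]) for i in range(self.n_events)]

    def event_words(self, e: int) -> list[str]:
        a, b = self.event_intervals()[e]
        return self.words[a:b]

    def text(self) -> str:
        return _render(self.words, self.sentence_ends)


@dataclass
class SyntheticRecall:
    participant_id: str
    words: list[str]
    true_recalled_events: list[int]
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        if bool(self.words) != bool(self.true_recalled_events):
            raise ParameterError("words nonempty iff true_recalled_events nonempty")

    def text(self) -> str:
        if not self.words:
            return ""
        ends = list(range(9, len(self.words), 10))
        if not ends or ends[-1] != len(self.words) - 1:
            ends.append(len(self.words) - 1)
        return _render(self.words, ends)


@dataclass
class RecallBehaviorParams:
    """Planted recall behaviour.

    p_recall
        Per-event recall probability (scalar broadcast to all events).
    primacy_boost
        Multiplier on event 0's recall odds (1 = no primacy).
    contiguity
        Probability each transition goes to the nearest not-yet-recalled
        event in the forward direction rather than a random remaining one.
    p_first_is_first
        Probability the first item produced is the earliest recalled event
        (event 0 whenever it is in the recalled set); otherwise the first
        item is uniform over the remaining recalled events.
    noise_level
        Fraction of recall words replaced by uniform vocabulary draws.
    """

    p_recall: float | np.ndarray = 0.5
    primacy_boost: float = 1.0
    contiguity: float = 0.5
    p_first_is_first: float = 0.3
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p_recall, dtype=float))
        if np.any(p < 0) or np.any(p > 1):
            raise ParameterError("p_recall entries must lie in [0, 1]")
        if self.primacy_boost < 0:
            raise ParameterError("primacy_boost must be >= 0")
        check_prob("contiguity", self.contiguity)
        check_prob("p_first_is_first", self.p_first_is_first)
        check_prob("noise_level", self.noise_level)


@dataclass
class AnnotatorParams:
    n_annotators: int = 50
    p_detect: float = 0.8
    jitter_sd_ms: float = 1000.0
    false_alarm_rate_hz: float = 0.01

    def __post_init__(self) -> None:
        if self.n_annotators < 1:
            raise ParameterError("n_annotators must be >= 1")
        check_prob("p_detect", self.p_detect)
        if self.jitter_sd_ms < 0:
            raise ParameterError("jitter_sd_ms must be >= 0")
        if self.false_alarm_rate_hz < 0:
            raise ParameterError("false_alarm_rate_hz must be >= 0")


def _render(words: list[str], sentence_ends: list[int]) -> str:
    out = []
    for i, w in enumerate(words):
        out.append(w + "." if i in set(sentence_ends) else w)
    return " ".join(out)


def _vocab_token(i: int) -> str:
    return f"w{i:04d}"


def gen_story(
    n_events: int,
    words_per_event_range: tuple[int, int] = (80, 120),
    n_topics: int | None = None,
    vocab_size: int | None = None,
    topic_concentration: float = 0.05,
    word_concentration: float = 0.1,
    seed: int = 0,
) -> SyntheticStory:
    """Generate a topic-structured story with planted event boundaries."""
    if n_events < 2:
        raise ParameterError("n_events must be >= 2")
    lo, hi = words_per_event_range
    if not (1 <= lo <= hi):
        raise ParameterError(f"invalid words_per_event_range {words_per_event_range}")
    T = n_topics if n_topics is not None else n_events
    if T < 2:
        raise ParameterError("n_topics must be >= 2")
    V = vocab_size if vocab_size is not None else 20 * T
    if V < 10 * T:
        raise ParameterError("vocab_size must be >= 10 * n_topics")
    if topic_concentration <= 0 or word_concentration <= 0:
        raise ParameterError("concentrations must be > 0")

    rng = np.random.default_rng(seed)
    topic_word = rng.dirichlet(np.full(V, word_concentration), size=T)
    mix = np.empty((n_events, T))
    for e in range(n_events):
        v = rng.dirichlet(np.full(T, topic_concentration))
        mix[e] = np.roll(v, (e % T) - int(np.argmax(v)))

    lengths = rng.integers(lo, hi + 1, size=n_events)
    boundaries = [0] + list(np.cumsum(lengths)[:-1])
    words: list[str] = []
    for e in range(n_events):
        topics = rng.choice(T, size=lengths[e], p=mix[e])
        for k in topics:
            words.append(_vocab_token(rng.choice(V, p=topic_word[k])))

    # sentences of 8-15 words, never straddling an event boundary; a short
    # tail (< 8 words) merges into the previous sentence so no sentence is
    # degenerate (keeps sentence snapping of boundaries well-posed)
    sentence_ends: list[int] = []
    for e in range(n_events):
        start = boundaries[e]
        end = start + int(lengths[e])
        ends_e: list[int] = []
        pos = start
        while pos < end:
            pos = min(pos + int(rng.integers(8, 16)), end)
            ends_e.append(pos - 1)
        if len(ends_e) >= 2 and ends_e[-1] - ends_e[-2] < 8:
            ends_e.pop(-2)
        sentence_ends.extend(ends_e)

    onsets = [(i * MS_PER_WORD, i * MS_PER_WORD + (MS_PER_WORD - _WORD_GAP_MS)) for i in range(len(words))]
    return SyntheticStory(
        words=words,
        true_boundaries=[int(b) for b in boundaries],
        topic_word_dists=topic_word,
        event_topic_mix=mix,
        sentence_ends=sentence_ends,
        word_onsets_ms=onsets,
    )


def _order_events(recalled: list[int], params: RecallBehaviorParams, rng: np.random.Generator) -> list[int]:
    remaining = sorted(recalled)
    order: list[int] = []
    if not remaining:
        return order
    if rng.random() < params.p_first_is_first or len(remaining) == 1:
        first = remaining[0]
    else:
        first = remaining[int(rng.integers(1, len(remaining)))]
    order.append(first)
    remaining.remove(first)
    while remaining:
        cur = order[-1]
        if rng.random() < params.contiguity:
            fwd = [e for e in remaining if e > cur]
            nxt = min(fwd) if fwd else max(e for e in remaining if e < cur)
        else:
            nxt = remaining[int(rng.integers(len(remaining)))]
        order.append(nxt)
        remaining.remove(nxt)
    return order


def gen_recalls(
    story: SyntheticStory,
    params: RecallBehaviorParams,
    n_participants: int,
    words_per_recalled_event: int = 30,
    seed: int = 0,
) -> list[SyntheticRecall]:
    """Generate ordered partial recalls of a synthetic story."""
    if n_participants < 1:
        raise ParameterError("n_participants must be >= 1")
    if words_per_recalled_event < 1:
        raise ParameterError("words_per_recalled_event must be >= 1")
    E = story.n_events
    T, V = story.topic_word_dists.shape
    p = np.broadcast_to(np.atleast_1d(np.asarray(params.p_recall, dtype=float)), (E,)).copy()
    if params.primacy_boost != 1.0 and 0.0 < p[0] < 1.0:
        odds = params.primacy_boost * p[0] / (1.0 - p[0])
        p[0] = odds / (1.0 + odds)

    rng = np.random.default_rng(seed)
    out: list[SyntheticRecall] = []
    for i in range(n_participants):
        recalled = [e for e in range(E) if rng.random() < p[e]]
        order = _order_events(recalled, params, rng)
        words: list[str] = []
        for e in order:
            topics = rng.choice(T, size=words_per_recalled_event, p=story.event_topic_mix[e])
            for k in topics:
                if params.noise_level > 0 and rng.random() < params.noise_level:
                    words.append(_vocab_token(int(rng.integers(V))))
                else:
                    words.append(_vocab_token(rng.choice(V, p=story.topic_word_dists[k])))
        out.append(
            SyntheticRecall(
                participant_id=f"p{i:03d}",
                words=words,
                true_recalled_events=order,
                noise_level=params.noise_level,
            )
        )
    return out


def gen_annotations(story: SyntheticStory, params: AnnotatorParams, seed: int = 0) -> AnnotationSet:
    """Simulate annotator button presses at 1000 Hz over the story duration.

    Each true boundary except the story start is pressed with probability
    ``p_detect`` at the boundary word's onset plus truncated Gaussian jitter;
    false alarms arrive as a Poisson process at ``false_alarm_rate_hz``.
    """
    D = story.duration_ms
    if D <= 0:
        raise ParameterError("story has no word timings")
    rng = np.random.default_rng(seed)
    onsets = [story.word_onsets_ms[b][0] for b in story.true_boundaries[1:]]
    vectors = np.zeros((params.n_annotators, D), dtype=np.uint8)
    for a in range(params.n_annotators):
        for t0 in onsets:
            if rng.random() < params.p_detect:
                t = t0 + rng.normal(0.0, params.jitter_sd_ms)
                t = int(min(max(t, 0), D - 1))
                vectors[a, t] = 1
        n_fa = rng.poisson(params.false_alarm_rate_hz * D / 1000.0)
        if n_fa:
            vectors[a, rng.integers(0, D, size=n_fa)] = 1
    return AnnotationSet(vectors=vectors, story_id="synthetic")


# ---------------------------------------------------------------------------
# On-disk corpus in the public layout
# ---------------------------------------------------------------------------


def write_corpus(
    root: str | Path,
    stories: dict[str, SyntheticStory],
    recalls: dict[str, list[SyntheticRecall]],
    seed: int | None = None,
    params: dict | None = None,
) -> Path:
    """Write stories/recalls in the public dataset layout plus a ground-truth side-car.

    Layout matches :func:`narrec.corpus_io.load_dataset`; the side-car
    ``data/ground_truth.json`` records planted boundaries, recalled-event
    sets, generator parameters and the seed.
    """
    root = Path(root)
    stim = root / "experiment_materials" / "stimuli"
    stim.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": seed, "params": params or {}, "stories": {}}
    for sid, story in stories.items():
        (stim / f"{sid}.txt").write_text(story.text() + "\n", encoding="utf-8")
        truth["stories"][sid] = {
            "true_boundaries": list(map(int, story.true_boundaries)),
            "sentence_ends": list(map(int, story.sentence_ends)),
            "n_words": story.n_words,
            "recalled_events": {},
        }
    for sid, recs in recalls.items():
        rt = root / "data" / "recall_transcripts" / sid
        rt.mkdir(parents=True, exist_ok=True)
        for rec in recs:
            text = rec.text()
            if text:
                (rt / f"{rec.participant_id}.txt").write_text(text + "\n", encoding="utf-8")
            truth["stories"][sid]["recalled_events"][rec.participant_id] = list(map(int, rec.true_recalled_events))
    (root / "data" / "survey").mkdir(parents=True, exist_ok=True)
    gt_path = root / "data" / "ground_truth.json"
    gt_path.write_text(json.dumps(truth, indent=1), encoding="utf-8")
    return gt_path
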