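"""Sliding-window LDA topic trajectories and left-to-right HMM event segmentation.

The segmentation method represents a transcript as a sequence of topic
mixtures over overlapping word windows (Latent Dirichlet Allocation fitted
to the window x vocabulary count matrix) and partitions that sequence into
consecutive events with a constrained hidden Markov model whose states may
only stay or advance by one.  Stories are segmented with a model fitted on
their own windows; recalls are transformed through the story's fitted model
so that story and recall event vectors live in the same topic space.

The HMM is fitted by an EM-style alternation: emission log-density of window
``t`` under event ``e`` is ``-||z(x_t) - z(m_e)||^2 / 2`` on per-dimension
z-scored topic vectors (an isotropic Gaussian with shared variance), state
posteriors come from a constrained forward-backward pass (forced start in
state 0 and end in state E-1), and event means are re-estimated as
posterior-weighted averages until the log-likelihood change falls below
``tol``.  The log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation

from .corpus_io import Transcript
from .exceptions import DataError, ParameterError
from .ground_truth import GroundTruthBoundaries, boundary_f1
from .stopwords import STOP_WORDS

__all__ = [
    "WindowSet",
    "TopicModel",
    "TopicTrajectory",
    "EventSegmentation",
    "GridSearchResult",
    "build_windows",
    "fit_topic_model",
    "infer_topics",
    "hmm_segment",
    "select_num_events",
    "segment_transcript",
    "event_texts",
    "grid_search",
    "DEFAULT_WINDOW",
    "DEFAULT_STEP",
    "DEFAULT_TOPICS",
]

#: Default hyperparameters: 55-word windows stepped by 21 words, 40 topics
#: (the grid-search optimum carried over to all stories).
DEFAULT_WINDOW = 55
DEFAULT_STEP = 21
DEFAULT_TOPICS = 40


@dataclass
class WindowSet:
    window_size_words: int
    step_words: int
    windows: list[tuple[int, int]]  # half-open word intervals
    counts: np.ndarray  # n_windows x V
    vocabulary: list[str]

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class TopicModel:
    n_topics: int
    topic_word: np.ndarray  # K x V, rows on the simplex
    vocabulary: list[str]
    fit_seed: int
    _lda: LatentDirichletAllocation | None = field(default=None, repr=False, compare=False)

    @property
    def vocab_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocabulary)}


@dataclass
class TopicTrajectory:
    vectors: np.ndarray  # n_windows x K, rows on the simplex
    window_map: list[tuple[int, int]]

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_topics(self) -> int:
        return self.vectors.shape[1]


@dataclass
class EventSegmentation:
    boundaries: list[int]  # event-start word indices, first = 0
    n_events: int
    event_vectors: np.ndarray  # E x K
    loglik: float
    n_words: int = 0
    loglik_history: list[float] = field(default_factory=list)
    window_states: np.ndarray | None = None  # per-window event labels

    def intervals(self) -> list[tuple[int, int]]:
        b = list(self.boundaries) + [self.n_words]
        return [(b[i], b[i + 1]) for i in range(self.n_events)]


@dataclass
class GridSearchResult:
    table: "object"  # pandas.DataFrame: w, s, K, f1, precision, recall
    best: tuple[int, int, int]
    best_f1: float


def build_windows(transcript: Transcript, w: int, s: int) -> WindowSet:
    """Overlapping word windows with stop-word-filtered count vectors.

    Windows start at 0, s, 2s, …; the final window is truncated at the
    transcript end; a transcript shorter than ``w`` yields one window.
    """
    if not (1 <= s <= w):
        raise ParameterError(f"need 1 <= step <= window, got w={w}, s={s}")
    n = transcript.n_words
    if n < 1:
        raise ParameterError("transcript is empty")
    if n <= w:
        windows = [(0, n)]
    else:
        n_win = int(np.ceil((n - w) / s)) + 1
        windows = [(i * s, min(i * s + w, n)) for i in range(n_win)]
    vocab = sorted({tok for tok in transcript.words if tok not in STOP_WORDS})
    index = {tok: i for i, tok in enumerate(vocab)}
    counts = np.zeros((len(windows), len(vocab)), dtype=np.int64)
    for wi, (a, b) in enumerate(windows):
        for tok in transcript.words[a:b]:
            j = index.get(tok)
            if j is not None:
                counts[wi, j] += 1
    return WindowSet(window_size_words=w, step_words=s, windows=windows, counts=counts, vocabulary=vocab)


def fit_topic_model(windows: WindowSet, K: int, seed: int = 0, n_init: int = 1) -> TopicModel:
    """Fit LDA by batch variational inference on the window count matrix.

    The variational objective is multi-modal, so the model is fitted from
    ``n_init`` random initializations (seeds derived deterministically from
    ``seed``) and the fit with the highest evidence lower bound is kept.
    """
    if K < 2:
        raise ParameterError("K must be >= 2")
    if n_init < 1:
        raise ParameterError("n_init must be >= 1")
    if len(windows.vocabulary) == 0:
        raise DataError("empty vocabulary after stop-word removal")
    if windows.n_windows < K:
        warnings.warn(
            f"only {windows.n_windows} windows for K={K} topics; fit may be unstable",
            stacklevel=2,
        )
    best_lda, best_bound = None, -np.inf
    for restart in range(n_init):
        lda = LatentDirichletAllocation(
            n_components=K,
            learning_method="batch",
            max_iter=50,
            random_state=(seed + 7919 * restart) % (2**32),
        )
        lda.fit(windows.counts)
        bound = lda.score(windows.counts)
        if bound > best_bound:
            best_lda, best_bound = lda, bound
    topic_word = best_lda.components_ / best_lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(n_topics=K, topic_word=topic_word, vocabulary=list(windows.vocabulary), fit_seed=seed, _lda=best_lda)


def infer_topics(model: TopicModel, windows: WindowSet) -> TopicTrajectory:
    """Posterior topic mixtures of windows under a fixed model.

    Window tokens are mapped through the model vocabulary (out-of-vocabulary
    tokens dropped); a window with no in-vocabulary tokens gets the uniform
    mixture with a warning.
    """
    if model._lda is None:
        raise DataError("TopicModel lacks its fitted LDA object")
    K = model.n_topics
    if windows.vocabulary == model.vocabulary:
        counts = windows.counts
    else:
        counts = np.zeros((windows.n_windows, len(model.vocabulary)), dtype=np.int64)
        vindex = model.vocab_index
        for j, tok in enumerate(windows.vocabulary):
            mj = vindex.get(tok)
            if mj is not None:
                counts[:, mj] += windows.counts[:, j]
    vectors = np.full((windows.n_windows, K), 1.0 / K)
    nonempty = counts.sum(axis=1) > 0
    if (~nonempty).any():
        warnings.warn(
            f"{int((~nonempty).sum())} window(s) with no in-vocabulary tokens; using uniform mixtures",
            stacklevel=2,
        )
    if nonempty.any():
        doc_topic = model._lda.transform(counts[nonempty])
        vectors[nonempty] = doc_topic / doc_topic.sum(axis=1, keepdims=True)
    return TopicTrajectory(vectors=vectors, window_map=list(windows.windows))


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _forward_backward(logB: np.ndarray, log_stay: float, log_adv: float) -> tuple[np.ndarray, float]:
    """Constrained forward-backward: start in state 0, end in the last state."""
    T, E = logB.shape
    alpha = np.full((T, E), -np.inf)
    alpha[0, 0] = logB[0, 0]
    for t in range(1, T):
        stay = alpha[t - 1] + log_stay
        adv = np.full(E, -np.inf)
        adv[1:] = alpha[t - 1, :-1] + log_adv
        alpha[t] = np.logaddexp(stay, adv) + logB[t]
    beta = np.full((T, E), -np.inf)
    beta[T - 1, E - 1] = 0.0
    for t in range(T - 2, -1, -1):
        stay = beta[t + 1] + logB[t + 1] + log_stay
        adv = np.full(E, -np.inf)
        adv[:-1] = beta[t + 1, 1:] + logB[t + 1, 1:] + log_adv
        beta[t] = np.logaddexp(stay, adv)
    ll = float(alpha[T - 1, E - 1])
    log_gamma = alpha + beta - ll
    gamma = np.exp(log_gamma)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, ll


def _viterbi(logB: np.ndarray, log_stay: float, log_adv: float) -> np.ndarray:
    T, E = logB.shape
    delta = np.full((T, E), -np.inf)
    psi = np.zeros((T, E), dtype=np.int64)
    delta[0, 0] = logB[0, 0]
    for t in range(1, T):
        stay = delta[t - 1] + log_stay
        adv = np.full(E, -np.inf)
        adv[1:] = delta[t - 1, :-1] + log_adv
        choose_adv = adv > stay
        delta[t] = np.where(choose_adv, adv, stay) + logB[t]
        psi[t] = np.where(choose_adv, np.arange(E) - 1, np.arange(E))
    states = np.empty(T, dtype=np.int64)
    states[-1] = E - 1
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return states


def hmm_segment(
    traj: TopicTrajectory,
    E: int,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> EventSegmentation:
    """Segment a topic trajectory into ``E`` consecutive events.

    Left-to-right HMM with ``E`` states; transitions may stay or advance by
    one; the chain is forced to start in state 0 and end in state ``E-1``.
    Event assignment is the per-window argmax posterior state (monotone by
    construction; a Viterbi pass is substituted in the rare case a state is
    skipped by the argmax).  Window boundaries are mapped to word indices as
    the start word of the event's first window plus half the window overlap
    ``(w - s) // 2``: a window flips to the new event once most of its span
    lies past the true boundary, so the bare start word systematically
    undershoots by about half the overlap, and the correction vanishes for
    non-overlapping windows.
    """
    X = np.asarray(traj.vectors, dtype=float)
    T = X.shape[0]
    if not (1 <= E <= T):
        raise ParameterError(f"need 1 <= E <= n_windows={T}, got E={E}")
    n_words = traj.window_map[-1][1]
    if E == 1:
        v = X.mean(axis=0)
        v = v / v.sum() if v.sum() > 0 else v
        return EventSegmentation([0], 1, v[None, :], 0.0, n_words=n_words, window_states=np.zeros(T, dtype=int))

    Z = _zscore(X)
    # expected E-1 advances over T-1 transitions
    p_adv = float(np.clip((E - 1) / max(T - 1, 1), 1e-6, 1 - 1e-6))
    log_stay, log_adv = float(np.log1p(-p_adv)), float(np.log(p_adv))

    # initialize means from E contiguous equal blocks
    blocks = np.array_split(np.arange(T), E)
    M = np.stack([Z[b].mean(axis=0) for b in blocks])

    history: list[float] = []
    ll = -np.inf
    gamma = None
    for _ in range(max_iter):
        logB = -0.5 * ((Z[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
        gamma, ll_new = _forward_backward(logB, log_stay, log_adv)
        history.append(ll_new)
        mass = gamma.sum(axis=0)
        M_new = M.copy()
        ok = mass > 1e-12
        M_new[ok] = (gamma.T @ Z)[ok] / mass[ok, None]
        if np.isfinite(ll) and abs(ll_new - ll) < tol:
            ll = ll_new
            M = M_new
            break
        ll = ll_new
        M = M_new

    states = np.maximum.accumulate(np.argmax(gamma, axis=1))
    if len(np.unique(states)) < E:
        logB = -0.5 * ((Z[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
        states = _viterbi(logB, log_stay, log_adv)

    first_windows = [int(np.flatnonzero(states == e)[0]) for e in range(E)]
    w_size = traj.window_map[0][1] - traj.window_map[0][0]
    step = traj.window_map[1][0] - traj.window_map[0][0] if T > 1 else w_size
    offset = max((w_size - step) // 2, 0)
    boundaries = [min(traj.window_map[i][0] + offset, n_words - 1) for i in first_windows]
    boundaries[0] = 0
    event_vectors = np.empty((E, X.shape[1]))
    for e in range(E):
        v = X[states == e].mean(axis=0)
        event_vectors[e] = v / v.sum() if v.sum() > 0 else v
    return EventSegmentation(
        boundaries=boundaries,
        n_events=E,
        event_vectors=event_vectors,
        loglik=float(ll),
        n_words=n_words,
        loglik_history=history,
        window_states=states,
    )


def _window_states(traj: TopicTrajectory, E: int) -> np.ndarray:
    """Window-level state labels from an E-event segmentation of ``traj``."""
    return hmm_segment(traj, E).window_states


def select_num_events(traj: TopicTrajectory, candidates: list[int]) -> int:
    """Pick the event count maximizing within- minus across-adjacent-event coherence.

    For each candidate E the trajectory is segmented and scored as (mean
    Pearson correlation of window-vector pairs within the same event) minus
    (mean correlation of pairs in adjacent events); ties break toward the
    smallest E.
    """
    if not candidates:
        raise ParameterError("candidates must be nonempty")
    T = traj.n_windows
    cands = sorted(set(int(c) for c in candidates))
    if any(not (1 <= c <= T) for c in cands):
        raise ParameterError(f"candidates must lie in [1, n_windows={T}]")
    X = np.asarray(traj.vectors, dtype=float)
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.nan_to_num(C, nan=0.0)
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0

    best_E, best_score = cands[0], -np.inf
    for E in cands:
        labels = _window_states(traj, E)
        within, across = [], []
        for e in range(E):
            idx = np.flatnonzero(labels == e)
            if idx.size >= 2:
                sub = C[np.ix_(idx, idx)]
                within.extend(sub[np.triu_indices(idx.size, k=1)])
            if e + 1 < E:
                jdx = np.flatnonzero(labels == e + 1)
                if idx.size and jdx.size:
                    across.extend(C[np.ix_(idx, jdx)].ravel())
        score = (float(np.mean(within)) if within else 0.0) - (float(np.mean(across)) if across else 0.0)
        if score > best_score + 1e-12:
            best_E, best_score = E, score
    return best_E


def segment_transcript(
    transcript: Transcript,
    w: int = DEFAULT_WINDOW,
    s: int = DEFAULT_STEP,
    K: int = DEFAULT_TOPICS,
    E: int | str = "auto",
    seed: int = 0,
    model: TopicModel | None = None,
    max_auto_events: int | None = None,
) -> tuple[EventSegmentation, TopicModel]:
    """Full segmentation pipeline for one transcript.

    Builds windows, fits LDA (or reuses ``model`` — recalls are transformed
    through the story's model, never re-fitted), infers the topic
    trajectory and segments it.  ``E="auto"`` selects the event count with
    :func:`select_num_events` over 2..min(50, n_windows) for stories and
    1..min(20, n_windows) for recalls (``model`` given).
    """
    if transcript.n_words == 0:
        K_eff = model.n_topics if model is not None else K
        return (
            EventSegmentation([], 0, np.zeros((0, K_eff)), 0.0, n_words=0),
            model if model is not None else TopicModel(K, np.zeros((K, 0)), [], seed),
        )
    windows = build_windows(transcript, w, s)
    if model is None:
        model = fit_topic_model(windows, K, seed=seed)
        is_recall = False
    else:
        is_recall = True
    traj = infer_topics(model, windows)
    if E == "auto":
        cap = max_auto_events if max_auto_events is not None else (20 if is_recall else 50)
        lo = 1 if is_recall else 2
        hi = min(cap, traj.n_windows)
        cands = list(range(lo, hi + 1)) if hi >= lo else [1]
        E_used = select_num_events(traj, cands)
    else:
        E_used = min(int(E), traj.n_windows)
    seg = hmm_segment(traj, E_used)
    return seg, model


def event_texts(transcript: Transcript, seg: EventSegmentation) -> list[str]:
    """Raw word text of each event (for embedding backends)."""
    return [" ".join(transcript.words[a:b]) for a, b in seg.intervals()]


def grid_search(
    story: Transcript,
    truth: GroundTruthBoundaries,
    w_grid: list[int],
    s_grid: list[int],
    K_grid: list[int],
    tol_words: int = 10,
    seed: int = 0,
) -> GridSearchResult:
    """Search (window, step, topics) for the best boundary F1 against ground truth.

    Each configuration segments the story with E fixed to the number of
    ground-truth events and scores the boundaries with
    :func:`narrec.ground_truth.boundary_f1`.  Invalid pairs (s > w) are
    skipped.  Ties break toward smaller K, then w, then s.
    """
    import pandas as pd

    E = truth.n_events
    rows = []
    for w in w_grid:
        for s in s_grid:
            if s > w or s < 1:
                continue
            for K in K_grid:
                seg, _ = segment_transcript(story, w=w, s=s, K=K, E=E, seed=seed)
                prf = boundary_f1(seg.boundaries, truth.boundary_words, tol_words=tol_words)
                rows.append({"w": w, "s": s, "K": K, "f1": prf.f1, "precision": prf.precision, "recall": prf.recall})
    if not rows:
        raise ParameterError("empty effective grid (all pairs had s > w)")
    table = pd.DataFrame(rows).sort_values(
        ["f1", "K", "w", "s"], ascending=[False, True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    best_row = table.iloc[0]
    return GridSearchResult(
        table=table,
        best=(int(best_row.w), int(best_row.s), int(best_row.K)),
        best_f1=float(best_row.f1),
    )
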