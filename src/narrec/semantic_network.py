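"""Event-level semantic networks and the centrality → recall effect.

Each narrative event's text is embedded as a unit vector; pairwise cosine
similarities define an undirected weighted graph (edges where similarity
meets a threshold, 0.35 by default).  Semantic centrality of an event is its
mean cosine similarity to all other events of the same story, computed on
the unthresholded matrix so it does not depend on the edge threshold.  The
behavioural effect of interest is whether semantically central events are
more likely to be recalled; it is estimated with a linear mixed-effects
model of recalled (0/1) on within-story z-scored centrality with random
intercepts for participants (and a story variance component when several
stories are pooled).

The default embedding backend is TF-IDF followed by truncated SVD fitted on
the event texts themselves — fully offline and deterministic.  Heavyweight
sentence encoders can be plugged in as a callable ``texts -> matrix``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import DataError, ParameterError
from .recall_scoring import RecallMatrix

__all__ = [
    "EventEmbeddings",
    "SemanticNetwork",
    "MixedModelResult",
    "embed_events",
    "build_network",
    "centrality_recall_effect",
]


@dataclass
class EventEmbeddings:
    vectors: np.ndarray  # E x d, unit-norm rows (zero rows for empty texts)
    backend_id: str
    event_texts: list[str]

    @property
    def n_events(self) -> int:
        return self.vectors.shape[0]


@dataclass
class SemanticNetwork:
    similarity: np.ndarray  # E x E cosine matrix
    threshold: float
    edges: list[tuple[int, int, float]]  # (i, j, weight), i < j
    centrality: np.ndarray  # mean off-diagonal similarity per event


@dataclass
class MixedModelResult:
    beta: float
    se: float
    p: float
    n_obs: int
    grouping: str
    converged: bool = True
    notes: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.notes is None:
            self.notes = []

    def summary(self) -> str:
        sig = "" if not np.isfinite(self.p) else ("***" if self.p < 0.001 else "**" if self.p < 0.01 else "*" if self.p < 0.05 else "")
        lines = [
            "Centrality -> recall mixed-effects model",
            f"  grouping : {self.grouping}",
            f"  n_obs    : {self.n_obs}",
            f"  beta     : {self.beta:+.4f} (SE {self.se:.4f}) {sig}",
            f"  p-value  : {self.p:.3g}",
            f"  converged: {self.converged}",
        ]
        lines += [f"  note: {n}" for n in self.notes]
        return "\n".join(lines)


def _tfidf_svd_backend(texts: Sequence[str], d: int = 128, seed: int = 0) -> np.ndarray:
    from sklearn.decomposition import TruncatedSVD
    from sklearn.feature_extraction.text import TfidfVectorizer

    vec = TfidfVectorizer(token_pattern=r"(?u)\b\w+\b")
    X = vec.fit_transform(texts)
    d_eff = min(d, min(X.shape) - 1)
    if d_eff < 2:
        # too few texts/terms for a meaningful subspace: raw TF-IDF keeps
        # disjoint-vocabulary texts orthogonal
        return np.asarray(X.todense(), dtype=float)
    svd = TruncatedSVD(n_components=d_eff, random_state=seed)
    return svd.fit_transform(X)


def embed_events(
    event_texts: Sequence[str],
    backend: str | Callable[[Sequence[str]], np.ndarray] = "tfidf_svd",
    d: int = 128,
) -> EventEmbeddings:
    """Embed event texts as L2-normalized vectors.

    ``backend`` may be the built-in ``"tfidf_svd"`` or any callable mapping
    a list of texts to a matrix with one row per text.  Empty texts yield a
    zero (no-information) vector with a warning.
    """
    texts = list(event_texts)
    if not texts:
        raise ParameterError("event_texts must be nonempty")
    nonblank = [t if t.strip() else "" for t in texts]
    if callable(backend):
        V = np.asarray(backend(texts), dtype=float)
        backend_id = getattr(backend, "__name__", "custom")
    elif backend == "tfidf_svd":
        fill = [t if t.strip() else "__empty__" for t in nonblank]
        V = _tfidf_svd_backend(fill, d=d)
        backend_id = "tfidf_svd"
    else:
        raise ParameterError(f"unknown backend {backend!r}")
    if V.shape[0] != len(texts):
        raise DataError("backend returned wrong number of rows")
    norms = np.linalg.norm(V, axis=1)
    out = np.zeros_like(V, dtype=float)
    ok = norms > 0
    out[ok] = V[ok] / norms[ok, None]
    for i, t in enumerate(nonblank):
        if not t:
            out[i] = 0.0
            warnings.warn(f"event {i}: empty text, zero-information embedding", stacklevel=2)
    return EventEmbeddings(vectors=out, backend_id=backend_id, event_texts=texts)


def build_network(emb: EventEmbeddings, threshold: float = 0.35) -> SemanticNetwork:
    """Thresholded cosine-similarity graph plus threshold-free centrality.

    Edges keep pairs with cosine >= ``threshold``; centrality is the mean
    cosine similarity of each event to all other events, computed on the
    unthresholded matrix.
    """
    E = emb.n_events
    if E < 2:
        raise ParameterError("need at least 2 events")
    sim = emb.vectors @ emb.vectors.T
    sim = (sim + sim.T) / 2.0
    edges = [
        (i, j, float(sim[i, j]))
        for i in range(E)
        for j in range(i + 1, E)
        if sim[i, j] >= threshold
    ]
    centrality = (sim.sum(axis=1) - np.diag(sim)) / (E - 1)
    return SemanticNetwork(similarity=sim, threshold=threshold, edges=edges, centrality=centrality)


def _zscore_safe(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd == 0:
        return None
    return (x - x.mean()) / sd


def centrality_recall_effect(
    matrices: list[RecallMatrix],
    networks: list[SemanticNetwork],
    model: str = "linear",
) -> MixedModelResult:
    """Mixed-effects estimate of the semantic-centrality effect on recall.

    Builds long-format observations (participant, story, event, recalled,
    centrality z-scored within story) and fits ``recalled ~ centrality``
    with a random intercept per participant; when several stories are
    pooled a story variance component is added.  ``model="logistic"`` fits
    a Bayesian binomial mixed GLM instead (posterior mean / SD reported).
    """
    import pandas as pd

    if len(matrices) != len(networks) or not matrices:
        raise ParameterError("need matching, nonempty lists of matrices and networks")
    rows = []
    notes: list[str] = []
    for s, (mat, net) in enumerate(zip(matrices, networks)):
        if mat.n_events != net.centrality.size:
            raise DataError(f"story {s}: matrix has {mat.n_events} events, network {net.centrality.size}")
        if mat.n_participants < 2:
            raise ParameterError("need >= 2 participants per story")
        z = _zscore_safe(net.centrality)
        if z is None:
            notes.append(f"story {s}: constant centrality, no within-story variance")
            continue
        sid = mat.story_id or f"story{s}"
        for p in range(mat.n_participants):
            pid = mat.participant_ids[p] if mat.participant_ids else str(p)
            for e in range(mat.n_events):
                rows.append((f"{sid}:{pid}" if len(matrices) == 1 else pid, sid, e, int(mat.matrix[p, e]), z[e]))
    if not rows:
        warnings.warn("no within-story centrality variance; effect undefined", stacklevel=2)
        return MixedModelResult(np.nan, np.nan, np.nan, 0, "none", converged=False, notes=notes)
    df = pd.DataFrame(rows, columns=["participant", "story", "event", "recalled", "centrality"])
    n_stories = df["story"].nunique()

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if model == "linear":
        kwargs = {}
        grouping = "random intercept: participant"
        if n_stories > 1:
            kwargs["vc_formula"] = {"story": "0 + C(story)"}
            grouping += " + story variance component"
        md = smf.mixedlm("recalled ~ centrality", data=df, groups=df["participant"], **kwargs)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            fit = md.fit(reml=True, method="lbfgs")
        conv = bool(getattr(fit, "converged", True))
        for wi in wlist:
            if "singular" in str(wi.message).lower() or "converge" in str(wi.message).lower():
                notes.append(str(wi.message))
        return MixedModelResult(
            beta=float(fit.params["centrality"]),
            se=float(fit.bse["centrality"]),
            p=float(fit.pvalues["centrality"]),
            n_obs=len(df),
            grouping=grouping,
            converged=conv,
            notes=notes,
        )
    if model == "logistic":
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        md = BinomialBayesMixedGLM.from_formula(
            "recalled ~ centrality", {"participant": "0 + C(participant)"}, df
        )
        fit = md.fit_vb()
        i = list(fit.model.exog_names).index("centrality")
        beta = float(fit.fe_mean[i])
        se = float(fit.fe_sd[i])
        from scipy.stats import norm

        p = float(2 * norm.sf(abs(beta / se))) if se > 0 else np.nan
        return MixedModelResult(
            beta=beta, se=se, p=p, n_obs=len(df),
            grouping="logistic; random intercept: participant (VB posterior)",
            converged=True, notes=notes,
        )
    raise ParameterError(f"unknown model {model!r}")
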