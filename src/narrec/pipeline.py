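"""End-to-end orchestration: simulate a corpus, run the validation analyses.

``simulate`` writes a synthetic corpus in the public dataset layout (with a
ground-truth side-car) and ``run_validation`` executes the full analysis on
any corpus in that layout: per story, segment the story and every recall,
match recall events to story events, build the recall matrix, compute
recall-probability / PFR / lag-CRP curves with bootstrap CIs and permutation
significance, build the semantic network, and pool stories into the
centrality → recall mixed model.  Outputs are tidy CSV/JSON files plus a
markdown summary; every stochastic stage consumes a named seed derived from
the master seed, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from .corpus_io import DatasetBundle, load_dataset
from .exceptions import ParameterError
from .list_learning import lag_crp, order_permutation_test, pfr_curve
from .recall_scoring import match_events, recall_matrix, recall_probability, significant_events
from .semantic_network import build_network, centrality_recall_effect, embed_events
from .synthetic_data import (
    AnnotatorParams,
    RecallBehaviorParams,
    gen_annotations,
    gen_recalls,
    gen_story,
    write_corpus,
)
from .topic_segmentation import (
    DEFAULT_STEP,
    DEFAULT_TOPICS,
    DEFAULT_WINDOW,
    event_texts,
    segment_transcript,
)

__all__ = ["RunConfig", "RunReport", "simulate", "run_validation"]


@dataclass
class RunConfig:
    """Configuration of a full run; defaults follow the published analysis
    (55-word window, 21-word step, 40 topics, 10,000 bootstrap resamples and
    10,000 permutations, alpha = 0.05, cosine edge threshold 0.35)."""

    data_root: str = "corpus"
    out_dir: str = "narrec_out"
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    n_topics: int = DEFAULT_TOPICS
    events: int | str = "auto"
    n_boot: int = 10000
    n_perm: int = 10000
    alpha: float = 0.05
    seed: int = 0
    embed_backend: str = "tfidf_svd"
    edge_threshold: float = 0.35
    min_r: float | None = None
    mixed_model: str = "linear"
    # synthetic-corpus generation (simulate)
    n_stories: int = 4
    n_participants: int = 100
    n_events: int = 10
    words_per_event: tuple[int, int] = (80, 120)
    topic_concentration: float = 0.05
    recall: RecallBehaviorParams = field(default_factory=RecallBehaviorParams)
    annotators: AnnotatorParams = field(default_factory=AnnotatorParams)

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ParameterError(f"step ({self.step}) must be <= window ({self.window})")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if isinstance(raw.get("recall"), dict):
            raw["recall"] = RecallBehaviorParams(**raw["recall"])
        if isinstance(raw.get("annotators"), dict):
            raw["annotators"] = AnnotatorParams(**raw["annotators"])
        if isinstance(raw.get("words_per_event"), list):
            raw["words_per_event"] = tuple(raw["words_per_event"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    per_story: dict
    effect: dict | None
    provenance: dict
    out_dir: str


def simulate(config: RunConfig, with_annotations: bool = False) -> Path:
    """Write a synthetic corpus (and ground-truth side-car) to config.data_root."""
    stories = {}
    recalls = {}
    annotations = {}
    for i in range(config.n_stories):
        sid = f"story{i:02d}"
        story = gen_story(
            n_events=config.n_events,
            words_per_event_range=config.words_per_event,
            topic_concentration=config.topic_concentration,
            seed=derive_seed(config.seed, f"story:{sid}"),
        )
        stories[sid] = story
        recalls[sid] = gen_recalls(
            story,
            config.recall,
            n_participants=config.n_participants,
            seed=derive_seed(config.seed, f"recalls:{sid}"),
        )
        if with_annotations:
            annotations[sid] = gen_annotations(
                story, config.annotators, seed=derive_seed(config.seed, f"annot:{sid}")
            )
    root = Path(config.data_root)
    gt = write_corpus(root, stories, recalls, seed=config.seed, params={"config": config.to_dict()})
    if with_annotations:
        ann_dir = root / "data" / "annotations"
        ann_dir.mkdir(parents=True, exist_ok=True)
        for sid, ann in annotations.items():
            np.savetxt(ann_dir / f"{sid}.csv.gz", ann.vectors, fmt="%d", delimiter=",")
            (ann_dir / f"{sid}.json").write_text(
                json.dumps({"story_id": sid, "n_annotators": ann.n_annotators, "duration_ms": ann.duration_ms})
            )
    return gt


def _analyze_story(
    sid: str,
    bundle: DatasetBundle,
    config: RunConfig,
) -> dict:
    story = bundle.stories[sid]
    seed = derive_seed(config.seed, f"analyze:{sid}")
    story_seg, model = segment_transcript(
        story, w=config.window, s=config.step, K=config.n_topics, E=config.events, seed=seed
    )
    matchings = []
    for (pid, s2), rec in sorted(bundle.recalls.items()):
        if s2 != sid:
            continue
        try:
            rec_seg, _ = segment_transcript(rec, w=config.window, s=config.step, E="auto", seed=seed, model=model)
        except Exception as exc:
            warnings.warn(f"recall {pid}/{sid}: segmentation failed ({exc})", stacklevel=2)
            continue
        matchings.append(match_events(rec_seg, story_seg, participant_id=pid, story_id=sid, min_r=config.min_r))
    E = story_seg.n_events
    mat = recall_matrix(matchings, E)
    curve = recall_probability(mat, n_boot=config.n_boot, seed=derive_seed(config.seed, f"boot:{sid}"))
    thr, flags = significant_events(
        mat, n_perm=config.n_perm, alpha=config.alpha, seed=derive_seed(config.seed, f"perm:{sid}")
    )
    curve.sig_threshold, curve.sig_events = thr, flags
    pfr = pfr_curve(matchings, E, n_boot=config.n_boot, seed=derive_seed(config.seed, f"pfr:{sid}"))
    crp = lag_crp(matchings, E, n_boot=config.n_boot, seed=derive_seed(config.seed, f"crp:{sid}"))
    pfr.p_first_event = order_permutation_test(
        matchings, E, "pfr_first", n_perm=config.n_perm, seed=derive_seed(config.seed, f"permpfr:{sid}")
    )[0]
    crp.p_lag1 = order_permutation_test(
        matchings, E, "crp_lag1", n_perm=config.n_perm, seed=derive_seed(config.seed, f"permcrp:{sid}")
    )[0]
    emb = embed_events(event_texts(story, story_seg), backend=config.embed_backend)
    net = build_network(emb, threshold=config.edge_threshold)
    return {
        "story_seg": story_seg,
        "matchings": matchings,
        "matrix": mat,
        "curve": curve,
        "pfr": pfr,
        "crp": crp,
        "network": net,
    }


def run_validation(config: RunConfig) -> RunReport:
    """Run segment → score → effects → network for every story and write outputs."""
    bundle = load_dataset(config.data_root)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_story: dict = {}
    matrices, networks = [], []
    for sid in sorted(bundle.stories):
        try:
            res = _analyze_story(sid, bundle, config)
        except Exception as exc:
            per_story[sid] = {"error": f"stage failure for {sid}: {exc}"}
            warnings.warn(f"story {sid} failed: {exc}", stacklevel=2)
            continue
        per_story[sid] = res
        matrices.append(res["matrix"])
        networks.append(res["network"])
        _write_story_outputs(out, sid, res)
    effect = None
    if matrices:
        try:
            eff = centrality_recall_effect(matrices, networks, model=config.mixed_model)
            effect = {"beta": eff.beta, "se": eff.se, "p": eff.p, "n_obs": eff.n_obs, "grouping": eff.grouping}
            (out / "centrality_effect.json").write_text(json.dumps(effect, indent=1))
        except Exception as exc:
            warnings.warn(f"centrality effect failed: {exc}", stacklevel=2)
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "narrec_version": __version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    _write_summary_md(out, per_story, effect, provenance)
    return RunReport(per_story=per_story, effect=effect, provenance=provenance, out_dir=str(out))


def _write_story_outputs(out: Path, sid: str, res: dict) -> None:
    seg = res["story_seg"]
    (out / f"{sid}_segmentation.json").write_text(
        json.dumps(
            {
                "story_id": sid,
                "boundaries": list(map(int, seg.boundaries)),
                "n_events": seg.n_events,
                "event_vectors": np.asarray(seg.event_vectors).tolist(),
                "loglik": seg.loglik,
            },
            indent=1,
        )
    )
    curve, pfr, crp = res["curve"], res["pfr"], res["crp"]
    pd.DataFrame(
        {
            "event": np.arange(curve.prob.size),
            "prob_recall": curve.prob,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
            "significant": np.asarray(curve.sig_events, dtype=bool),
        }
    ).to_csv(out / f"{sid}_recall_curve.csv", index=False)
    pd.DataFrame(
        {"position": np.arange(pfr.pfr.size) + 1, "pfr": pfr.pfr, "ci_low": pfr.ci_low, "ci_high": pfr.ci_high}
    ).to_csv(out / f"{sid}_pfr.csv", index=False)
    pd.DataFrame(
        {"lag": crp.lags, "crp": crp.crp, "ci_low": crp.ci_low, "ci_high": crp.ci_high}
    ).to_csv(out / f"{sid}_crp.csv", index=False)
    net = res["network"]
    (out / f"{sid}_network.json").write_text(
        json.dumps(
            {
                "similarity": net.similarity.tolist(),
                "threshold": net.threshold,
                "edges": [[int(i), int(j), w] for i, j, w in net.edges],
                "centrality": net.centrality.tolist(),
            },
            indent=1,
        )
    )
    pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in res["matchings"]],
            "matched_events": [" ".join(map(str, m.matched_story_events)) for m in res["matchings"]],
            "correlations": [" ".join(f"{r:.4f}" for r in m.match_correlations) for m in res["matchings"]],
        }
    ).to_csv(out / f"{sid}_matchings.csv", index=False)


def _write_summary_md(out: Path, per_story: dict, effect: dict | None, provenance: dict) -> None:
    lines = ["# narrec validation run", "", f"config hash: `{provenance['config_hash']}`", ""]
    for sid, res in per_story.items():
        if "error" in res:
            lines.append(f"## {sid}\n\nFAILED: {res['error']}\n")
            continue
        curve, pfr, crp = res["curve"], res["pfr"], res["crp"]
        n_sig = int(np.asarray(curve.sig_events).sum())
        E = curve.prob.size
        lines += [
            f"## {sid}",
            "",
            f"- events: {E}; participants: {res['matrix'].n_participants}",
            f"- mean recall probability: {curve.prob.mean():.3f}; significant events: {n_sig}/{E} ({100*n_sig/E:.1f}%)",
            f"- PFR(position 1): {pfr.pfr[0]:.3f} (perm p = {pfr.p_first_event:.4g})",
            f"- lag-CRP(+1): {crp.crp[crp.lags.tolist().index(1)]:.3f} (perm p = {crp.p_lag1:.4g})",
            f"- network edges: {len(res['network'].edges)}",
            "",
        ]
    if effect is not None:
        lines += [
            "## Pooled centrality effect",
            "",
            f"- beta = {effect['beta']:.3f} (SE {effect['se']:.3f}), p = {effect['p']:.3g}, n_obs = {effect['n_obs']}",
            "",
        ]
    (out / "summary.md").write_text("\n".join(lines))
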