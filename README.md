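# narrec — automated analysis of naturalistic narrative free recall

When people listen to a spoken story and then retell it aloud, there is no
list of discrete items to score: what was "recalled" has to be inferred from
the meaning of the retelling.  `narrec` implements a fully automated
pipeline for this problem, aimed at researchers working with story/recall
transcript corpora:

1. **Event segmentation.**  A story transcript is represented as a sequence
   of topic mixtures over sliding word windows (Latent Dirichlet Allocation
   on the window × vocabulary count matrix, default 55-word windows stepped
   by 21 words, K = 40 topics).  A left-to-right hidden Markov model with E
   states — transitions may only stay or advance by one, emission
   log-density −‖z(xₜ) − z(mₑ)‖²/2 on z-scored topic vectors — partitions
   the trajectory into E consecutive events.
2. **Ground truth from annotators.**  Independent listeners press a button
   at perceived event boundaries (1000 Hz binary vectors).  Presses are
   binned (5 s), agreement is tested against a circular-shift permutation
   null (threshold = 95th percentile of the pooled null), significant bins
   are aligned to the word nearest the 1000 Hz agreement peak and snapped to
   sentence starts.  Predicted boundaries are scored against these with a
   tolerance-based F1.
3. **Recall scoring.**  Each recall transcript is segmented with the
   *story's* topic model; every recall event is matched to the story event
   whose topic vector it best correlates with (Pearson).  Unmatched story
   events count as forgotten.  The participants × events binary matrix
   yields per-event recall probability X̄ with bootstrap 95% CIs, and a
   within-participant event-permutation null flags events recalled more
   often than the typical event (97.5th percentile rule).
4. **List-learning statistics.**  Probability of first recall (PFR) by
   serial position, and the lag-conditional response probability (lag-CRP):
   for consecutive recalls of story events i → j the lag j − i is counted,
   normalized within participant, averaged across participants.
   Within-participant order permutations give p-values for the
   first-position PFR and the lag +1 contiguity effect.
5. **Semantic networks.**  Event texts are embedded (offline TF-IDF + SVD
   backend by default; any `texts → vectors` callable can be plugged in),
   cosine similarities ≥ 0.35 define edges, and semantic centrality (mean
   unthresholded similarity of an event to all others) predicts recall in a
   linear mixed-effects model (`recalled ~ centrality`, random intercepts by
   participant, story variance component when stories are pooled).

A first-class synthetic-data generator (`narrec.synthetic_data`) emulates
the whole study — topic-structured stories with planted boundaries, ordered
partial recalls with controllable recall probability / primacy /
temporal-contiguity, and annotator press vectors with jitter and false
alarms — and writes corpora in the same on-disk layout as the public
dataset, so every stage has a parameter-recovery test that runs offline.

## Worked example

```python
from narrec.pipeline import RunConfig, simulate, run_validation
from narrec.synthetic_data import RecallBehaviorParams

cfg = RunConfig(
    data_root="corpus", out_dir="out", window=25, step=12, n_topics=12, events=8,
    n_boot=2000, n_perm=2000, seed=3, n_stories=2, n_participants=60, n_events=8,
    words_per_event=(80, 120), topic_concentration=0.01,
    recall=RecallBehaviorParams(p_recall=0.55, primacy_boost=2.0,
                                contiguity=0.6, p_first_is_first=0.35),
)
simulate(cfg)              # writes the corpus + ground-truth side-car
report = run_validation(cfg)
print(open("out/summary.md").read())
```

prints (excerpt):

```
## story00

- events: 8; participants: 60
- mean recall probability: 0.500; significant events: 1/8 (12.5%)
- PFR(position 1): 0.333 (perm p = 0.0004998)
- lag-CRP(+1): 0.211 (perm p = 0.0004998)
- network edges: 1

## Pooled centrality effect

- beta = -0.053 (SE 0.015), p = 0.000396, n_obs = 960
```

Reading the numbers: 60 simulated participants recalled half the events on
average; the planted primacy (`primacy_boost=2`, `p_first_is_first=0.35`)
shows as PFR(1) = 0.33 ≫ 1/8 chance with permutation p < 0.001, and the
planted contiguity (`contiguity=0.6`) as a lag-CRP(+1) of 0.21 with
p < 0.001.  The generator plants *no* relationship between an event's
semantic centrality and its recall probability, so the pooled centrality
slope is small and its sign is incidental — with real narratives this
coefficient is the replication target of interest.  Full per-event curves,
matchings and networks are written as tidy CSV/JSON under `out/`.

The same stages are exposed on the command line:

```bash
narrec simulate --out corpus --seed 3
narrec segment --story corpus/experiment_materials/stimuli/story00.txt \
               --window 25 --step 12 --topics 12 --events 8 --seed 0 --out seg.json
narrec run --data-root corpus --out out --seed 3
narrec gridsearch --story story.txt --truth truth.json --out grid.csv
```

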