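"""Reading and writing the dataset's on-disk formats.

The free-recall corpus layout mirrors its public release: an
``experiment_materials/stimuli`` directory with one plain-text transcript per
story, and a ``data`` directory with per-story sub-folders of cleaned recall
transcripts (``recall_transcripts``), word-level Praat TextGrid alignments
(``recall_aligned``) and a ``survey`` table.  Synthetic corpora produced by
:mod:`narrec.synthetic_data` are written in the same layout, so the rest of
the pipeline cannot distinguish synthetic from real input.

Conventions used throughout the package and fixed here:

* word indices are 0-based; events are half-open ``[start, end)`` intervals
  in word coordinates;
* times are integer milliseconds (annotation vectors are sampled at 1000 Hz);
* tokenization splits on whitespace, strips edge punctuation, keeps internal
  hyphens/apostrophes and lowercases; sentences are detected from terminal
  ``. ! ?`` with a fallback of one sentence per 12 words for unpunctuated
  input.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._utils import tokenize
from .exceptions import AlignmentError, EmptyTranscriptError, FormatError, StructureError

__all__ = [
    "Transcript",
    "WordTimings",
    "DatasetBundle",
    "read_transcript",
    "transcript_from_text",
    "read_textgrid",
    "write_textgrid",
    "load_dataset",
]

#: TextGrid labels that denote noises rather than words: breaths {BR},
#: coughs {CG}, laughter {LG}, long silences {SL}, noise {NS}, and the
#: aligner's short-pause / silence markers.
_NOISE_LABELS = {"sp", "sil", "<unk>", ""}


@dataclass
class Transcript:
    """Ordered word tokens of one story or recall."""

    words: list[str]
    sentence_ends: list[int]
    source_id: str = ""
    raw_text: str = ""

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def sentence_starts(self) -> list[int]:
        """Word index of the first word of each sentence."""
        return [0] + [e + 1 for e in self.sentence_ends[:-1]] if self.words else []

    def __post_init__(self) -> None:
        if self.words:
            if any(not (0 <= e < len(self.words)) for e in self.sentence_ends):
                raise FormatError("sentence_ends outside [0, n_words)")
            if self.sentence_ends and self.sentence_ends[-1] != len(self.words) - 1:
                raise FormatError("last sentence must end at the final word")


@dataclass
class WordTimings:
    """Word-level forced-alignment times, integer milliseconds."""

    entries: list[tuple[str, int, int]]
    noises: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for w, a, b in self.entries:
            if a >= b:
                raise FormatError(f"word {w!r} has start {a} >= end {b}")
        self.entries = sorted(self.entries, key=lambda e: e[1])

    @property
    def words(self) -> list[str]:
        return [w for w, _, _ in self.entries]

    @property
    def onsets_ms(self) -> list[int]:
        return [a for _, a, _ in self.entries]


@dataclass
class DatasetBundle:
    stories: dict[str, Transcript]
    recalls: dict[tuple[str, str], Transcript]
    timings: dict[tuple[str, str], WordTimings]
    survey: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def participant_ids(self) -> list[str]:
        return sorted({pid for pid, _ in self.recalls})


def transcript_from_text(text: str, source_id: str = "") -> Transcript:
    words, ends = tokenize(text)
    return Transcript(words=words, sentence_ends=ends, source_id=source_id, raw_text=text)


def read_transcript(path: str | Path, dialect: str = "story") -> Transcript:
    """Read a plain-text story or recall transcript.

    Tokens are lowercased with edge punctuation stripped; sentence ends are
    recorded from terminal punctuation.  An empty file signals a lost
    recording and raises :class:`EmptyTranscriptError`.
    """
    if dialect not in ("story", "recall"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise EmptyTranscriptError(f"{path}: empty transcript (lost recording?)")
    return transcript_from_text(text, source_id=path.stem)


def is_noise_label(label: str) -> bool:
    label = label.strip()
    return label.lower() in _NOISE_LABELS or (label.startswith("{") and label.endswith("}"))


# ---------------------------------------------------------------------------
# Praat TextGrid (long and short text formats)
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def _ms(seconds: float) -> int:
    return int(round(float(seconds) * 1000))


def read_textgrid(path: str | Path) -> WordTimings:
    """Parse a Praat TextGrid (long or short text format).

    Only interval tiers are considered.  The word tier is the tier whose
    name contains ``word`` (case-insensitive), falling back to the first
    interval tier.  Noise labels (``{BR}``, ``{CG}``, ``{LG}``, ``sp`` …)
    are routed to :attr:`WordTimings.noises`; empty intervals are dropped.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8", errors="replace")
    if "TextGrid" not in text.split("\n", 3)[1] and "TextGrid" not in text:
        raise FormatError(f"{path}: not a TextGrid file")
    tiers = _parse_long(text) if re.search(r"^\s*item\s*\[", text, re.M) else _parse_short(text)
    if not tiers:
        raise FormatError(f"{path}: no interval tiers found")
    word_tier = next((t for n, t in tiers if "word" in n.lower()), tiers[0][1])
    entries, noises = [], []
    for xmin, xmax, label in word_tier:
        label = label.strip()
        if xmax <= xmin:
            continue
        if not label:
            continue
        if is_noise_label(label):
            noises.append((label, _ms(xmin), _ms(xmax)))
        else:
            entries.append((label, _ms(xmin), _ms(xmax)))
    if not entries and not noises:
        raise FormatError(f"{path}: word tier is empty")
    return WordTimings(entries=entries, noises=noises)


def _parse_long(text: str) -> list[tuple[str, list[tuple[float, float, str]]]]:
    tiers: list[tuple[str, list]] = []
    cur_class = cur_name = None
    cur: list | None = None
    interval: dict | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if m := re.match(r'class\s*=\s*"(.*)"', line):
            cur_class = m.group(1)
        elif m := re.match(r'name\s*=\s*"(.*)"', line):
            cur_name = m.group(1)
            if cur_class == "IntervalTier":
                cur = []
                tiers.append((cur_name, cur))
            else:
                cur = None
        elif re.match(r"intervals\s*\[\d+\]", line):
            interval = {}
        elif m := re.match(r"xmin\s*=\s*(\S+)", line):
            if interval is not None:
                interval["xmin"] = float(m.group(1))
        elif m := re.match(r"xmax\s*=\s*(\S+)", line):
            if interval is not None:
                interval["xmax"] = float(m.group(1))
        elif m := re.match(r'text\s*=\s*"(.*)"', line):
            if interval is not None and cur is not None:
                cur.append((interval.get("xmin", 0.0), interval.get("xmax", 0.0), m.group(1)))
                interval = None
    return tiers


def _parse_short(text: str) -> list[tuple[str, list[tuple[float, float, str]]]]:
    # short format: bare values, one per line, after the two header lines
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    vals = lines[2:]  # drop File type / Object class
    i = 0

    def take() -> str:
        nonlocal i
        v = vals[i]
        i += 1
        return v

    def unquote(s: str) -> str:
        return s[1:-1] if len(s) >= 2 and s[0] == '"' and s[-1] == '"' else s

    try:
        take()  # global xmin
        take()  # global xmax
        flag = take()
        if "exists" not in flag:
            i -= 1
        n_tiers = int(take())
        tiers = []
        for _ in range(n_tiers):
            klass = unquote(take())
            name = unquote(take())
            take()
            take()  # tier xmin / xmax
            n_items = int(take())
            items = []
            for _ in range(n_items):
                if klass == "IntervalTier":
                    xmin = float(take())
                    xmax = float(take())
                    label = unquote(take())
                    items.append((xmin, xmax, label))
                else:  # TextTier point: time + mark
                    take()
                    take()
            if klass == "IntervalTier":
                tiers.append((name, items))
        return tiers
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed short TextGrid: {exc}") from exc


def write_textgrid(timings: WordTimings, path: str | Path, tier_name: str = "word") -> None:
    """Write word + noise intervals as a long-format TextGrid."""
    items = sorted(
        [(w, a, b) for w, a, b in timings.entries]
        + [(lbl, a, b) for lbl, a, b in timings.noises],
        key=lambda e: e[1],
    )
    if not items:
        raise AlignmentError("cannot write a TextGrid with no intervals")
    xmax = max(b for _, _, b in items) / 1000.0
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.3f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {xmax:.3f}",
        f"        intervals: size = {len(items)}",
    ]
    for k, (label, a, b) in enumerate(items, start=1):
        out += [
            f"        intervals [{k}]:",
            f"            xmin = {a / 1000.0:.3f}",
            f"            xmax = {b / 1000.0:.3f}",
            f'            text = "{label}"',
        ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Dataset layout
# ---------------------------------------------------------------------------


def load_dataset(
    root: str | Path,
    recall_pattern: str = "*.txt",
    textgrid_pattern: str = "*.TextGrid",
) -> DatasetBundle:
    """Load a corpus directory (real or synthetic) into a :class:`DatasetBundle`.

    Expected layout::

        root/
          experiment_materials/stimuli/<story_id>.txt
          data/recall_transcripts/<story_id>/<participant_id>.txt
          data/recall_aligned/<story_id>/<participant_id>.TextGrid
          data/survey/survey.csv

    Parse failures are collected as warnings; partial loads are allowed.
    The file-naming scheme inside the recall folders is configurable via
    the glob patterns (participant id = file stem).
    """
    root = Path(root)
    data_dir = root / "data"
    if not data_dir.is_dir():
        raise StructureError(f"{root}: missing 'data' directory")
    stim_dir = root / "experiment_materials" / "stimuli"
    warns: list[str] = []

    stories: dict[str, Transcript] = {}
    if stim_dir.is_dir():
        for f in sorted(stim_dir.rglob("*.txt")):
            try:
                stories[f.stem] = read_transcript(f, dialect="story")
            except Exception as exc:  # collected, not fatal
                warns.append(f"story {f}: {exc}")
    else:
        warns.append(f"{stim_dir}: missing stimuli directory")

    recalls: dict[tuple[str, str], Transcript] = {}
    rt_dir = data_dir / "recall_transcripts"
    if rt_dir.is_dir():
        for story_dir in sorted(p for p in rt_dir.iterdir() if p.is_dir()):
            if story_dir.name not in stories:
                warns.append(f"recalls for unknown story {story_dir.name!r}: excluded")
                continue
            for f in sorted(story_dir.glob(recall_pattern)):
                try:
                    recalls[(f.stem, story_dir.name)] = read_transcript(f, dialect="recall")
                except EmptyTranscriptError as exc:
                    warns.append(str(exc))
                except Exception as exc:
                    warns.append(f"recall {f}: {exc}")

    timings: dict[tuple[str, str], WordTimings] = {}
    ra_dir = data_dir / "recall_aligned"
    if ra_dir.is_dir():
        for story_dir in sorted(p for p in ra_dir.iterdir() if p.is_dir()):
            if story_dir.name not in stories:
                warns.append(f"alignments for unknown story {story_dir.name!r}: excluded")
                continue
            for f in sorted(story_dir.glob(textgrid_pattern)):
                try:
                    timings[(f.stem, story_dir.name)] = read_textgrid(f)
                except Exception as exc:
                    warns.append(f"textgrid {f}: {exc}")

    survey = None
    survey_csv = data_dir / "survey" / "survey.csv"
    if survey_csv.is_file():
        try:
            survey = pd.read_csv(survey_csv)
        except Exception as exc:
            warns.append(f"survey {survey_csv}: {exc}")

    for msg in warns:
        warnings.warn(msg, stacklevel=2)
    return DatasetBundle(stories=stories, recalls=recalls, timings=timings, survey=survey, warnings=warns)
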