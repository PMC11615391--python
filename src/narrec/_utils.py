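"""Internal helpers: seed derivation, tokenization, small numerics."""

from __future__ import annotations

import re
import string
import zlib

import numpy as np

# characters stripped from token edges; internal hyphens/apostrophes survive
_EDGE_PUNCT = string.punctuation + "‘’“”–—…"
_SENT_END_RE = re.compile(r"[.!?][\"'’”)\]]*$")


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage seed in [0, 2**31) derived from a master seed.

    Every stochastic stage of the pipeline consumes a named seed so that
    stages can be re-run in isolation and still reproduce a full run.
    """
    return zlib.crc32(f"{int(master)}:{label}".encode()) & 0x7FFFFFFF


def rng_for(seed: int, label: str | None = None) -> np.random.Generator:
    return np.random.default_rng(seed if label is None else derive_seed(seed, label))


def tokenize(text: str) -> tuple[list[str], list[int]]:
    """Whitespace tokenization with punctuation-based sentence detection.

    Returns ``(words, sentence_ends)`` where *words* are lowercased tokens
    with edge punctuation stripped (internal hyphens and apostrophes kept)
    and *sentence_ends* holds the index of the last word of each sentence,
    detected from terminal ``. ! ?``.  The last word always closes the final
    sentence.  Numerals are kept as words.
    """
    words: list[str] = []
    ends: list[int] = []
    saw_terminal = False
    for tok in text.split():
        core = tok.strip(_EDGE_PUNCT).lower()
        closes = bool(_SENT_END_RE.search(tok))
        if core:
            words.append(core)
            if closes:
                ends.append(len(words) - 1)
                saw_terminal = True
        elif closes and words and (not ends or ends[-1] != len(words) - 1):
            # punctuation-only token ("...", "!") still closes the sentence
            ends.append(len(words) - 1)
            saw_terminal = True
    if not words:
        return [], []
    if not saw_terminal:
        # degraded input with no punctuation: fall back to a sentence every
        # 12 words so downstream sentence snapping still has targets
        ends = list(range(11, len(words), 12))
    if not ends or ends[-1] != len(words) - 1:
        ends.append(len(words) - 1)
    return words, ends


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r between two 1-d vectors; 0.0 when either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(xc @ yc / denom)


def check_prob(name: str, value: float) -> float:
    from .exceptions import ParameterError

    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must lie in [0, 1], got {value}")
    return value
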