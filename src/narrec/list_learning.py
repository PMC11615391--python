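"""List-learning statistics over story events: PFR and lag-CRP.

Probability of first recall (PFR) is the distribution over serial positions
of the first event each participant produces; a primacy effect shows as mass
at position 1.  The lag-conditional response probability (lag-CRP) counts,
for every pair of consecutively recalled events, the serial-position lag
between their story events; counts are normalized within participant (by the
participant's total retained transitions) and averaged across participants.
A temporal-contiguity effect shows as a peak at lag +1.  Significance for
the first-position PFR and the lag +1 CRP comes from permuting recall order
within participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, ParameterError
from .recall_scoring import EventMatching

__all__ = ["PFRCurve", "CRPCurve", "pfr_curve", "lag_crp", "order_permutation_test"]


@dataclass
class PFRCurve:
    pfr: np.ndarray  # per serial position (0-based event index)
    n_participants_used: int
    n_participants_excluded: int
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_first_event: float | None = None


@dataclass
class CRPCurve:
    lags: np.ndarray  # -(E-1)..(E-1) excluding 0
    crp: np.ndarray  # mean conditional probability per lag (nan = never available)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_participants_used: int
    n_lag0_dropped: int = 0
    p_lag1: float | None = None


def _first_positions(matchings: list[EventMatching]) -> list[int]:
    return [m.matched_story_events[0] for m in matchings if m.matched_story_events]


def pfr_curve(
    matchings: list[EventMatching],
    E: int,
    n_boot: int = 10000,
    seed: int = 0,
) -> PFRCurve:
    """Probability that each serial position is recalled first.

    Participants with empty recalls are excluded (and counted).  Bootstrap
    CIs resample the used participants.
    """
    firsts = np.array(_first_positions(matchings), dtype=int)
    excluded = len(matchings) - firsts.size
    if firsts.size == 0:
        raise DataError("all recalls are empty; PFR undefined")
    if np.any((firsts < 0) | (firsts >= E)):
        raise DataError("first-recall index outside [0, E)")
    pfr = np.bincount(firsts, minlength=E) / firsts.size
    if n_boot >= 1 and firsts.size >= 2:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, E))
        for it in range(n_boot):
            res = firsts[rng.integers(0, firsts.size, size=firsts.size)]
            boot[it] = np.bincount(res, minlength=E) / firsts.size
        ci_low, ci_high = np.quantile(boot, 0.025, axis=0), np.quantile(boot, 0.975, axis=0)
        ci_low, ci_high = np.minimum(ci_low, pfr), np.maximum(ci_high, pfr)
    else:
        ci_low, ci_high = pfr.copy(), pfr.copy()
    return PFRCurve(
        pfr=pfr,
        n_participants_used=int(firsts.size),
        n_participants_excluded=int(excluded),
        ci_low=ci_low,
        ci_high=ci_high,
    )


def _lag_fractions(seq: list[int], E: int, keep_lag0: bool) -> tuple[np.ndarray | None, int]:
    """Per-lag fraction vector for one participant; None if no retained transition.

    Returns (fractions over lags -(E-1)..(E-1) excluding 0, n lag-0 dropped).
    """
    lags = np.diff(np.asarray(seq, dtype=int))
    dropped = int((lags == 0).sum())
    if not keep_lag0:
        lags = lags[lags != 0]
    if lags.size == 0:
        return None, dropped
    counts = np.zeros(2 * E - 1)
    for lag in lags:
        counts[lag + E - 1] += 1
    counts = counts / lags.size
    return np.delete(counts, E - 1), dropped  # drop the lag-0 slot


def _availability_fractions(seq: list[int], E: int) -> np.ndarray | None:
    """Classical availability-conditioned CRP for one participant."""
    actual = np.zeros(2 * E - 1)
    possible = np.zeros(2 * E - 1)
    recalled: set[int] = set()
    for i, cur in enumerate(seq[:-1]):
        recalled.add(cur)
        nxt = seq[i + 1]
        if nxt == cur:
            continue
        for e in range(E):
            if e not in recalled and e != cur:
                possible[e - cur + E - 1] += 1
        actual[nxt - cur + E - 1] += 1
    if possible.sum() == 0:
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(possible > 0, actual / np.maximum(possible, 1), np.nan)
    return np.delete(frac, E - 1)


def lag_crp(
    matchings: list[EventMatching],
    E: int,
    n_boot: int = 10000,
    seed: int = 0,
    keep_lag0: bool = False,
    availability: bool = False,
) -> CRPCurve:
    """Lag-conditional response probability curve across participants.

    Per participant the lags of consecutive matched story events are
    counted and divided by the participant's total retained transitions
    (lag-0 pairs — two recall events matched to the same story event — are
    dropped by default); the curve is the per-lag mean over participants
    with at least one retained transition.  ``availability=True`` computes
    the classical availability-conditioned variant instead.
    """
    if E < 2:
        raise ParameterError("E must be >= 2")
    per_part: list[np.ndarray] = []
    n_dropped = 0
    for m in matchings:
        seq = m.matched_story_events
        if len(seq) < 2:
            continue
        if availability:
            frac = _availability_fractions(seq, E)
            _, d = _lag_fractions(seq, E, keep_lag0)
        else:
            frac, d = _lag_fractions(seq, E, keep_lag0)
        n_dropped += d
        if frac is not None:
            per_part.append(frac)
    if not per_part:
        raise DataError("no participant with a valid transition; lag-CRP undefined")
    P = np.vstack(per_part)
    with np.errstate(invalid="ignore"):
        crp = np.nanmean(P, axis=0)
    lags = np.concatenate([np.arange(-(E - 1), 0), np.arange(1, E)])
    n_used = P.shape[0]
    if n_boot >= 1 and n_used >= 2:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, P.shape[1]))
        for it in range(n_boot):
            idx = rng.integers(0, n_used, size=n_used)
            with np.errstate(invalid="ignore"):
                boot[it] = np.nanmean(P[idx], axis=0)
        with np.errstate(invalid="ignore"):
            ci_low = np.nanquantile(boot, 0.025, axis=0)
            ci_high = np.nanquantile(boot, 0.975, axis=0)
        ci_low = np.fmin(ci_low, crp)
        ci_high = np.fmax(ci_high, crp)
    else:
        ci_low, ci_high = crp.copy(), crp.copy()
    return CRPCurve(
        lags=lags,
        crp=crp,
        ci_low=ci_low,
        ci_high=ci_high,
        n_participants_used=n_used,
        n_lag0_dropped=n_dropped,
    )


def _statistic_seqs(seqs: list[list[int]], E: int, which: str) -> float:
    if which == "pfr_first":
        firsts = [s[0] for s in seqs if s]
        if not firsts:
            return 0.0
        return float(np.mean(np.asarray(firsts) == 0))
    if which == "crp_lag1":
        vals = []
        for seq in seqs:
            if len(seq) < 2:
                continue
            lags = np.diff(np.asarray(seq))
            lags = lags[lags != 0]
            if lags.size:
                vals.append(float(np.mean(lags == 1)))
        return float(np.mean(vals)) if vals else 0.0
    raise ParameterError(f"unknown statistic {which!r}")


def order_permutation_test(
    matchings: list[EventMatching],
    E: int,
    statistic: str = "crp_lag1",
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Within-participant recall-order permutation test.

    Each permutation shuffles every participant's matched story-event
    sequence uniformly and recomputes the statistic (``"pfr_first"`` — the
    probability the first recall is event 0 — or ``"crp_lag1"``).  Returns
    ``(p_value, observed, null)`` with the add-one rule
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    seqs = [list(m.matched_story_events) for m in matchings]
    observed = _statistic_seqs(seqs, E, statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for it in range(n_perm):
        permuted = [[seq[j] for j in rng.permutation(len(seq))] for seq in seqs]
        null[it] = _statistic_seqs(permuted, E, statistic)
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return p, observed, null
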