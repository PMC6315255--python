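"""Nonwear detection and valid-day selection for minute-epoch counts.

A nonwear period is a continuous run of zero counts spanning more than
90 minutes, where the run may contain interruptions of at most 2
consecutive minutes each with counts below 100.  A minute with a count
of 100 or more, or a third consecutive nonzero minute, terminates the
run.  Runs never bridge calendar days.  A day is valid when it has at
least 10 hours (600 minutes) of wear time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NONWEAR_SPAN_MIN = 90        # strict: a run must exceed this many minutes
INTERRUPT_MAX_RUN = 2        # max consecutive tolerated nonzero minutes
INTERRUPT_MAX_COUNT = 100    # tolerated minutes must have count < this
VALID_DAY_WEAR_MIN = 600     # >= 10 h wear


@dataclass(frozen=True)
class WearBout:
    """A maximal contiguous run of wear minutes within one subject-day."""

    subject_id: str
    day: object
    start: int
    end: int            # half-open, minutes within the day's record
    counts: np.ndarray

    def __len__(self) -> int:
        return self.end - self.start


def detect_nonwear(counts) -> np.ndarray:
    """Return a boolean wear mask (True = wear) for one day's counts.

    A candidate run starts at a zero-count minute and extends through
    zeros and interruptions of up to 2 consecutive sub-100 minutes.  The
    run's span goes from its first to its last zero; trailing
    interruption minutes are not part of the span.  Runs whose span
    exceeds 90 minutes are flagged nonwear, interruption minutes inside
    the flagged span included.  Runs touching the day's edges are
    eligible like any other.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    n = counts.shape[0]
    wear = np.ones(n, dtype=bool)
    i = 0
    while i < n:
        if counts[i] != 0:
            i += 1
            continue
        last_zero = i
        interrupt = 0
        k = i + 1
        while k < n:
            c = counts[k]
            if c == 0:
                last_zero = k
                interrupt = 0
            elif c < INTERRUPT_MAX_COUNT:
                interrupt += 1
                if interrupt > INTERRUPT_MAX_RUN:
                    break
            else:
                break
            k += 1
        span = last_zero - i + 1
        if span > NONWEAR_SPAN_MIN:
            wear[i : last_zero + 1] = False
        i = last_zero + 1
    return wear


def valid_day(mask) -> bool:
    """True when the day carries at least 600 wear minutes."""
    mask = np.asarray(mask, dtype=bool)
    return int(mask.sum()) >= VALID_DAY_WEAR_MIN


def extract_bouts(counts, mask, subject_id: str = "", day=None) -> list[WearBout]:
    """Split one day into maximal contiguous wear bouts.

    The concatenation of bout counts equals the day's wear-minute
    subsequence in order.
    """
    counts = np.asarray(counts, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    if counts.shape != mask.shape:
        raise ValueError("mask must align with counts")
    bouts: list[WearBout] = []
    n = counts.shape[0]
    if n == 0:
        return bouts
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        bouts.append(
            WearBout(
                subject_id=subject_id,
                day=day,
                start=int(start),
                end=int(end),
                counts=counts[start:end].copy(),
            )
        )
    return bouts
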