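"""Neighbouring-matches filter (diagonal co-occurrence).

A pairwise candidate seed (i, j) is kept only if enough candidate seeds lie
on the *same diagonal* (constant i - j) within a window of length D centred
on it: the total number of seeds (i', j') with i' - j' = i - j and
|i - i'| <= D/2 must reach the threshold tau.  Very close hits on a diagonal
are likely redundant, so neighbours only count when they do not overlap the
candidate: |i - i'| >= span, where span is the (maximum) seed-pattern span.

By default the candidate itself counts toward tau, so tau = 2 demands at
least one valid neighbour; ``count_self=False`` switches to the stricter
convention where tau counts neighbours only.

The implementation sorts candidates per (sequence pair, diagonal) and counts
neighbours with a sliding window (two binary searches per candidate), so the
decision for each candidate is independent of processing order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seed_finding import Seed

logger = logging.getLogger("geoseed")

DEFAULT_D = 1000
DEFAULT_TAU = 2


@dataclass
class DiagonalIndex:
    """Candidates grouped by (sequence-id pair, diagonal i - j), i sorted."""

    diagonals: dict[tuple[str, str, int], np.ndarray]

    @property
    def n_diagonals(self) -> int:
        return len(self.diagonals)


def build_diagonal_index(candidates: list[Seed]) -> DiagonalIndex:
    """Group pairwise candidates by (sequence pair, i - j) with sorted i."""
    groups: dict[tuple[str, str, int], list[int]] = {}
    for s in candidates:
        if len(s.coords) != 2:
            raise ValueError("diagonal filtering is defined for pairwise seeds only")
        groups.setdefault((s.seq1, s.seq2, s.i - s.j), []).append(s.i)
    return DiagonalIndex(
        {key: np.array(sorted(pos), dtype=np.int64) for key, pos in groups.items()}
    )


def filter_neighbouring(
    candidates: list[Seed],
    D: float = DEFAULT_D,
    tau: int = DEFAULT_TAU,
    span: int = 1,
    count_self: bool = True,
) -> list[Seed]:
    """Keep candidates with >= tau same-diagonal seeds within |i-i'| <= D/2.

    Neighbours closer than ``span`` (|i - i'| < span, overlapping matches) do
    not count; the candidate itself counts iff ``count_self``.  Output is a
    subset of the input in canonical order, tagged stage='m4-pass'.
    """
    if D < 0 or tau < 1 or span < 1:
        raise ValueError("require D >= 0, tau >= 1, span >= 1")
    index = build_diagonal_index(candidates)
    half = D / 2.0
    kept: list[Seed] = []
    for s in candidates:
        pos = index.diagonals[(s.seq1, s.seq2, s.i - s.j)]
        if span - 1 <= half:
            in_window = np.searchsorted(pos, s.i + half, "right") - np.searchsorted(
                pos, s.i - half, "left"
            )
            # entries with |i-i'| < span overlap the candidate (incl. itself)
            too_close = np.searchsorted(pos, s.i + span - 1, "right") - np.searchsorted(
                pos, s.i - span + 1, "left"
            )
            neighbours = int(in_window) - int(too_close)
        else:
            # non-overlap distance exceeds the counting window: nothing counts
            neighbours = 0
        total = neighbours + (1 if count_self else 0)
        if total >= tau:
            kept.append(Seed(coords=s.coords, pattern_id=s.pattern_id, stage="m4-pass"))
    kept.sort(key=Seed.sort_key)
    logger.info("m4 filter: kept %d of %d candidates", len(kept), len(candidates))
    return kept
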