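"""Spaced-seed patterns and pattern-induced k-mers.

A spaced-seed pattern is a binary string over {0,1}: 1s are *match* positions,
0s are *don't care* positions.  Its *weight* k is the number of match
positions, its *span* l the total length; a contiguous k-mer pattern is the
special case k = l.  Applying a pattern to a sequence window of length l
induces a k-mer by concatenating the residues at the match positions.

Repeat-masked and ambiguous residues are tested *at match positions only*
(don't-care positions may be masked or ambiguous); a window containing a
masked (when mask filtering is on) or ambiguous residue at a match position
induces no k-mer.  A span-wide variant of the mask test is available for
sensitivity analysis.

k-mers are bit-packed, 2 bits per base, for hashing speed; the textual k-mer
is the interface contract and the packed form is an implementation detail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .core_io import MaskedSequence, _DECODE

logger = logging.getLogger("geoseed")

MAX_WEIGHT = 31  # 2 bits per base in an int64, sign bit spared


@dataclass(frozen=True)
class SeedPattern:
    """A binary match/don't-care pattern.

    ``match_positions`` mirrors the customary 1-based index of the s-th match
    position; ``offsets`` is the 0-based equivalent used internally.
    """

    bits: str
    id: str
    weight: int = field(init=False)
    span: int = field(init=False)
    match_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.bits or set(self.bits) - {"0", "1"}:
            raise ValueError(f"pattern {self.bits!r}: characters must be 0/1")
        if self.bits[0] != "1" or self.bits[-1] != "1":
            raise ValueError(
                f"pattern {self.bits!r}: leading/trailing 0s are meaningless"
            )
        w = self.bits.count("1")
        if w > MAX_WEIGHT:
            raise ValueError(f"pattern weight {w} exceeds supported maximum {MAX_WEIGHT}")
        object.__setattr__(self, "weight", w)
        object.__setattr__(self, "span", len(self.bits))
        object.__setattr__(
            self,
            "match_positions",
            tuple(i + 1 for i, c in enumerate(self.bits) if c == "1"),
        )

    @property
    def offsets(self) -> np.ndarray:
        """0-based match offsets within a window."""
        return np.array(self.match_positions, dtype=np.int64) - 1

    @property
    def is_contiguous(self) -> bool:
        return self.weight == self.span


def parse_pattern(text: str, id: str | None = None) -> SeedPattern:
    """Parse and validate a binary pattern string."""
    return SeedPattern(bits=text, id=id if id is not None else text)


def contiguous_pattern(k: int, id: str | None = None) -> SeedPattern:
    if k < 1:
        raise ValueError("weight must be >= 1")
    return parse_pattern("1" * k, id=id or f"contig{k}")


@dataclass(frozen=True)
class PatternSet:
    """A set of spaced-seed patterns of equal weight with unique ids."""

    patterns: tuple[SeedPattern, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("empty pattern set")
        weights = {p.weight for p in self.patterns}
        if len(weights) != 1:
            raise ValueError(f"mixed pattern weights {sorted(weights)}")
        ids = [p.id for p in self.patterns]
        if len(set(ids)) != len(ids):
            raise ValueError("pattern ids must be unique")

    @property
    def m(self) -> int:
        return len(self.patterns)

    @property
    def weight(self) -> int:
        return self.patterns[0].weight

    @property
    def max_span(self) -> int:
        return max(p.span for p in self.patterns)

    def __iter__(self) -> Iterator[SeedPattern]:
        return iter(self.patterns)


def induce_kmer(
    seq: MaskedSequence,
    pattern: SeedPattern,
    start: int,
    mask_filter: bool = True,
    mask_span_wide: bool = False,
) -> str | None:
    """k-mer induced by ``pattern`` at window start ``start`` (0-based).

    Returns ``None`` when a match position holds an ambiguous residue, or a
    masked one while ``mask_filter`` is on.  Raises on out-of-range starts.
    """
    if not (0 <= start <= len(seq) - pattern.span):
        raise IndexError(
            f"start {start} out of range for span {pattern.span} in |S|={len(seq)}"
        )
    idx = start + pattern.offsets
    codes = seq.codes[idx]
    if (codes < 0).any():
        return None
    if mask_filter:
        window = seq.masked[start : start + pattern.span] if mask_span_wide else seq.masked[idx]
        if window.any():
            return None
    return _DECODE[codes].tobytes().decode("ascii")


def enumerate_kmers(
    seq: MaskedSequence,
    pattern: SeedPattern,
    mask_filter: bool = True,
    mask_span_wide: bool = False,
) -> Iterator[tuple[int, str]]:
    """Yield every ``(start, kmer)`` with a valid induced k-mer, in order.

    The number of skipped (filtered) window starts is logged on exhaustion.
    """
    starts, codes = induced_kmer_codes(seq, pattern, mask_filter, mask_span_wide)
    n_windows = max(len(seq) - pattern.span + 1, 0)
    for a, c in zip(starts.tolist(), codes.tolist()):
        yield a, decode_kmer(c, pattern.weight)
    logger.debug(
        "enumerate_kmers(%s,%s): %d windows, %d skipped",
        seq.id, pattern.id, n_windows, n_windows - len(starts),
    )


def induced_kmer_codes(
    seq: MaskedSequence,
    pattern: SeedPattern,
    mask_filter: bool = True,
    mask_span_wide: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bulk form: all valid window starts and bit-packed k-mers.

    Returns ``(starts, codes)`` where ``codes[t]`` packs the induced k-mer of
    window ``starts[t]`` at 2 bits per base, most significant base first.
    """
    n = len(seq) - pattern.span + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    acc = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for off in pattern.offsets:
        c = seq.codes[off : off + n]
        valid &= c >= 0
        if mask_filter and not mask_span_wide:
            valid &= ~seq.masked[off : off + n]
        acc <<= 2
        acc |= np.where(c >= 0, c, 0).astype(np.int64)
    if mask_filter and mask_span_wide:
        # window invalid if any of its span positions is masked
        cum = np.concatenate(([0], np.cumsum(seq.masked.astype(np.int64))))
        valid &= (cum[pattern.span :] - cum[:n]) == 0
    starts = np.nonzero(valid)[0].astype(np.int64)
    return starts, acc[valid]


def decode_kmer(code: int, k: int) -> str:
    out = bytearray(k)
    for s in range(k - 1, -1, -1):
        out[s] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode("ascii")
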