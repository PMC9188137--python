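"""Seed-candidate generation.

A *seed* is a tuple of (sequence id, position) coordinates, one per genome,
proposed as homologous positions and usable as an alignment anchor.  This
module produces seed candidates by

* exact contiguous k-mer matching (the classical baseline),
* (multiple) spaced-seed matching: two windows match when the k-mers induced
  by a pattern (any pattern of the set) are identical,
* the multi-genome generalization: a shared induced k-mer in all s genomes.

Matching is all-vs-all across genome labels: a hash of induced k-mers is
built over every sequence of the first genome and the second genome is
streamed against it; sequences sharing a genome label are never matched with
each other.  A matching window pair (a, b) is reported as the *midpoint* seed
(a + span//2, b + span//2): the methods identify small similar region pairs,
and the midpoint is the natural single-position summary.

Repetitive k-mers are tamed by a subsampling cap: if one (pattern, k-mer)
leads to more than ``max_per_kmer`` candidate pairs, a uniform random
subsample of exactly ``max_per_kmer`` pairs is kept (default 10).

Seeds found by different patterns at identical coordinates are de-duplicated,
and output is canonically sorted, so results do not depend on hash iteration
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .core_io import MaskedSequence
from .patterns import (
    PatternSet,
    SeedPattern,
    contiguous_pattern,
    induced_kmer_codes,
    parse_pattern,
)

logger = logging.getLogger("geoseed")

DEFAULT_MAX_PER_KMER = 10


@dataclass(frozen=True)
class Seed:
    """An alignment-seed candidate: one (sequence id, position) per genome.

    ``coords`` has length 2 for pairwise seeds and s for multi-genome seeds;
    positions are 0-based.  ``stage`` tags the pipeline stage that emitted
    the seed (candidate | m4-pass | ghash-pass).
    """

    coords: tuple[tuple[str, int], ...]
    pattern_id: str | None = None
    stage: str = "candidate"

    @property
    def i(self) -> int:
        return self.coords[0][1]

    @property
    def j(self) -> int:
        return self.coords[1][1]

    @property
    def seq1(self) -> str:
        return self.coords[0][0]

    @property
    def seq2(self) -> str:
        return self.coords[1][0]

    def sort_key(self):
        return tuple(x for c in self.coords for x in c)


@dataclass
class MatchIndex:
    """Sorted global occurrence index of induced k-mers for one genome.

    ``codes`` is sorted ascending; ``seq_idx``/``pos`` are co-sorted window
    starts (index into the sequence list, 0-based start).
    """

    codes: np.ndarray
    seq_idx: np.ndarray
    pos: np.ndarray

    @classmethod
    def build(
        cls,
        seqs: Sequence[MaskedSequence],
        pattern: SeedPattern,
        mask_filter: bool = True,
    ) -> "MatchIndex":
        codes_l, sidx_l, pos_l = [], [], []
        for idx, s in enumerate(seqs):
            starts, codes = induced_kmer_codes(s, pattern, mask_filter)
            codes_l.append(codes)
            pos_l.append(starts)
            sidx_l.append(np.full(len(starts), idx, dtype=np.int64))
        codes = np.concatenate(codes_l) if codes_l else np.empty(0, np.int64)
        sidx = np.concatenate(sidx_l) if sidx_l else np.empty(0, np.int64)
        pos = np.concatenate(pos_l) if pos_l else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        return cls(codes[order], sidx[order], pos[order])

    def occurrences(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.codes, code, "left")
        hi = np.searchsorted(self.codes, code, "right")
        return self.seq_idx[lo:hi], self.pos[lo:hi]


def subsample_pairs(
    occurrences1: Sequence[int] | np.ndarray,
    occurrences2: Sequence[int] | np.ndarray,
    max_pairs: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Cartesian product of two occurrence lists, capped by uniform sampling.

    If the product has at most ``max_pairs`` elements it is returned in full;
    otherwise exactly ``max_pairs`` distinct pairs are drawn uniformly without
    replacement (reproducible under the supplied generator).
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    occurrences1 = np.asarray(occurrences1)
    occurrences2 = np.asarray(occurrences2)
    n1, n2 = len(occurrences1), len(occurrences2)
    total = n1 * n2
    if total <= max_pairs:
        return [(int(a), int(b)) for a in occurrences1 for b in occurrences2]
    flat = rng.choice(total, size=max_pairs, replace=False)
    ai, bi = np.unravel_index(flat, (n1, n2))
    return [(int(occurrences1[a]), int(occurrences2[b])) for a, b in zip(ai, bi)]


def expected_random_matches(n1: float, n2: float, m: int, k: int) -> float:
    """Expected matching window-pair count between i.i.d. uniform sequences.

    Each of the ~n1*n2 window pairs matches one weight-k pattern with
    probability 4**-k; summed over m patterns: m*n1*n2/4**k.  Analytic test
    oracle for the uniform random model; boundary effects (span-1 windows per
    sequence end) are neglected.
    """
    if min(n1, n2, m, k) <= 0:
        raise ValueError("all arguments must be positive")
    return m * n1 * n2 / 4.0 ** k


def _check_genome_labels(seqs1, seqs2) -> tuple[str, str]:
    l1 = {s.genome_label for s in seqs1}
    l2 = {s.genome_label for s in seqs2}
    if len(l1) != 1 or len(l2) != 1:
        raise ValueError(f"each input set must carry one genome label, got {l1} / {l2}")
    (g1,), (g2,) = l1, l2
    if g1 == g2:
        raise ValueError(f"both inputs carry genome label {g1!r}; seeds need two genomes")
    return g1, g2


def _match_pattern_arrays(
    seqs1: Sequence[MaskedSequence],
    seqs2: Sequence[MaskedSequence],
    pattern: SeedPattern,
    max_per_kmer: int,
    rng: np.random.Generator,
    mask_filter: bool,
) -> np.ndarray:
    """All (capped) matching window pairs for one pattern.

    Returns an (n, 4) int64 array of rows (seq_idx1, start1, seq_idx2, start2).
    """
    idx1 = MatchIndex.build(seqs1, pattern, mask_filter)
    idx2 = MatchIndex.build(seqs2, pattern, mask_filter)
    if len(idx1.codes) == 0 or len(idx2.codes) == 0:
        return np.empty((0, 4), dtype=np.int64)
    common = np.intersect1d(idx1.codes, idx2.codes)
    if len(common) == 0:
        return np.empty((0, 4), dtype=np.int64)
    lo1 = np.searchsorted(idx1.codes, common, "left")
    hi1 = np.searchsorted(idx1.codes, common, "right")
    lo2 = np.searchsorted(idx2.codes, common, "left")
    hi2 = np.searchsorted(idx2.codes, common, "right")
    c1 = hi1 - lo1
    c2 = hi2 - lo2
    rows: list[np.ndarray] = []

    # fast path: unique-unique k-mers pair directly
    single = (c1 == 1) & (c2 == 1)
    if single.any():
        a = lo1[single]
        b = lo2[single]
        rows.append(
            np.column_stack([idx1.seq_idx[a], idx1.pos[a], idx2.seq_idx[b], idx2.pos[b]])
        )

    n_capped = 0
    for t in np.nonzero(~single)[0]:
        s1 = slice(lo1[t], hi1[t])
        s2 = slice(lo2[t], hi2[t])
        o1 = np.arange(lo1[t], hi1[t])
        o2 = np.arange(lo2[t], hi2[t])
        if c1[t] * c2[t] > max_per_kmer:
            n_capped += 1
        pairs = subsample_pairs(o1, o2, max_per_kmer, rng)
        block = np.empty((len(pairs), 4), dtype=np.int64)
        for r, (a, b) in enumerate(pairs):
            block[r] = (idx1.seq_idx[a], idx1.pos[a], idx2.seq_idx[b], idx2.pos[b])
        rows.append(block)
    if n_capped:
        logger.debug("pattern %s: %d k-mers capped at %d pairs", pattern.id, n_capped, max_per_kmer)
    return np.concatenate(rows, axis=0) if rows else np.empty((0, 4), dtype=np.int64)


def find_spaced_seeds(
    seqs1: Sequence[MaskedSequence],
    seqs2: Sequence[MaskedSequence],
    patterns: PatternSet | Sequence[SeedPattern],
    max_per_kmer: int = DEFAULT_MAX_PER_KMER,
    rng_seed: int | np.random.Generator = 0,
    mask_filter: bool = True,
) -> list[Seed]:
    """Spaced-seed candidates between two genomes for a set of patterns.

    For each pattern a global k-mer index over ``seqs1`` is built and every
    sequence of ``seqs2`` is streamed against it; each matching window pair
    (a, b) yields the midpoint seed (a + span//2, b + span//2).  Subsampling
    is applied per (pattern, k-mer); seeds coinciding in all coordinates
    across patterns are de-duplicated (the first pattern in set order wins);
    output is sorted canonically.
    """
    if not isinstance(patterns, PatternSet):
        patterns = PatternSet(tuple(patterns))
    _check_genome_labels(seqs1, seqs2)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    blocks = []
    pat_ids = []
    for p_idx, pattern in enumerate(patterns):
        arr = _match_pattern_arrays(seqs1, seqs2, pattern, max_per_kmer, rng, mask_filter)
        if len(arr) == 0:
            continue
        half = pattern.span // 2
        arr = arr.copy()
        arr[:, 1] += half
        arr[:, 3] += half
        blocks.append(np.column_stack([arr, np.full(len(arr), p_idx, dtype=np.int64)]))
        pat_ids.append(pattern.id)
        logger.info("pattern %s: %d matching window pairs", pattern.id, len(arr))
    if not blocks:
        return []
    all_rows = np.concatenate(blocks, axis=0)

    # de-duplicate on coordinates; ties broken by pattern order (stable sort)
    order = np.lexsort(
        (all_rows[:, 4], all_rows[:, 3], all_rows[:, 2], all_rows[:, 1], all_rows[:, 0])
    )
    srt = all_rows[order]
    coords = srt[:, :4]
    keep = np.ones(len(srt), dtype=bool)
    keep[1:] = (coords[1:] != coords[:-1]).any(axis=1)
    srt = srt[keep]

    pattern_list = list(patterns)
    out = [
        Seed(
            coords=(
                (seqs1[r[0]].id, int(r[1])),
                (seqs2[r[2]].id, int(r[3])),
            ),
            pattern_id=pattern_list[r[4]].id,
        )
        for r in srt
    ]
    logger.info("find_spaced_seeds: %d de-duplicated seeds", len(out))
    return out


def find_contiguous_seeds(
    seqs1: Sequence[MaskedSequence],
    seqs2: Sequence[MaskedSequence],
    k: int,
    max_per_kmer: int = DEFAULT_MAX_PER_KMER,
    rng_seed: int | np.random.Generator = 0,
    mask_filter: bool = True,
) -> list[Seed]:
    """Exact contiguous k-mer matching: the weight-k, span-k special case."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if all(len(s) < k for s in list(seqs1) + list(seqs2)):
        logger.warning("k=%d longer than every input sequence; no seeds", k)
        _check_genome_labels(seqs1, seqs2)
        return []
    return find_spaced_seeds(
        seqs1, seqs2, [contiguous_pattern(k)], max_per_kmer, rng_seed, mask_filter
    )


def find_multi_genome_seeds(
    genomes: Sequence[Sequence[MaskedSequence]],
    patterns: PatternSet | Sequence[SeedPattern],
    max_per_kmer: int = DEFAULT_MAX_PER_KMER,
    rng_seed: int | np.random.Generator = 0,
    mask_filter: bool = True,
) -> list[Seed]:
    """Seed candidates shared by all s genomes.

    A candidate requires the same induced k-mer to occur in every genome;
    per-genome occurrence lists of the shared k-mer are intersected and their
    Cartesian product taken, with the same per-(pattern, k-mer) cap applied to
    the full product.  For s = 2 this reproduces :func:`find_spaced_seeds`.
    """
    if not isinstance(patterns, PatternSet):
        patterns = PatternSet(tuple(patterns))
    s_dim = len(genomes)
    if s_dim < 2:
        raise ValueError("need at least two genomes")
    labels = []
    for g in genomes:
        lab = {s.genome_label for s in g}
        if len(lab) != 1:
            raise ValueError(f"each genome set must carry one label, got {lab}")
        labels.append(lab.pop())
    if len(set(labels)) != s_dim:
        raise ValueError(f"genome labels must be pairwise distinct, got {labels}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    seen: dict[tuple, str] = {}
    for pattern in patterns:
        half = pattern.span // 2
        indexes = [MatchIndex.build(g, pattern, mask_filter) for g in genomes]
        common = indexes[0].codes
        for idx in indexes[1:]:
            common = np.intersect1d(common, idx.codes)
            if len(common) == 0:
                break
        for code in common:
            occs = [idx.occurrences(int(code)) for idx in indexes]
            counts = [len(o[0]) for o in occs]
            total = int(np.prod(counts))
            if total <= max_per_kmer:
                chosen = np.arange(total)
            else:
                chosen = rng.choice(total, size=max_per_kmer, replace=False)
            multi = np.unravel_index(chosen, counts)
            for tup in zip(*multi):
                coords = tuple(
                    (
                        genomes[g][int(occs[g][0][t])].id,
                        int(occs[g][1][t]) + half,
                    )
                    for g, t in enumerate(tup)
                )
                seen.setdefault(coords, pattern.id)
    out = [
        Seed(coords=c, pattern_id=pid)
        for c, pid in sorted(seen.items(), key=lambda kv: kv[0])
    ]
    logger.info("find_multi_genome_seeds: %d de-duplicated seeds", len(out))
    return out


def load_bundled_patterns(name: str) -> PatternSet:
    """Load one of the bundled example pattern sets by name (e.g. 'weight15')."""
    text = resources.files("geoseed").joinpath("data/default_patterns.yaml").read_text()
    groups = yaml.safe_load(text)
    if name not in groups:
        raise KeyError(f"no bundled pattern set {name!r}; have {sorted(groups)}")
    return PatternSet(tuple(parse_pattern(d["bits"], d["id"]) for d in groups[name]))


def load_pattern_file(path) -> PatternSet:
    """Load a pattern set from a YAML file: list of {id, bits} mappings."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict) and "patterns" in data:
        data = data["patterns"]
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a YAML list of {{id, bits}} entries")
    return PatternSet(
        tuple(
            parse_pattern(d["bits"], d.get("id", f"p{i}"))
            for i, d in enumerate(data)
        )
    )
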