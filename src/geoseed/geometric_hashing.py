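"""Geometric hashing of seed candidates.

Candidate seeds from homologous genes share similar position differences
i - j even when they come from exons that are tens of kilobases apart,
because introns change length only moderately between orthologs.  The
geometric map quantizes that difference to multiples of a tile size F,

    g(S1, i, S2, j) = (S1, S2, floor((i - j) / F)),

collecting candidates of one sequence pair with similar diagonals into a
*tile* (a diagonal band of width F in the pairwise alignment space).  Tiles
are scored and all candidates of a tile are reported iff its score reaches a
threshold; isolated random matches end up alone in their tile and fall below
it.

Scoring subdivides a tile into b sub-tiles by the within-band diagonal
remainder and into chunks of length h along the anti-diagonal i + j.  With
n_{r,s} candidates in sub-tile r, chunk s, the score is the normalized
p-norm

    Score(t) = (sum_{r,s} n_{r,s}^p)^(1/p) / (lambda * b * (s_max + 1)),

where lambda = A*L/(n1*n2) (A = h*F/b, the chunk "area") is the expected
per-chunk count if all L observed candidates were scattered evenly over the
input of total lengths n1, n2, and s_max is the largest feasible chunk index
of the tile.  Large p (default 6) rewards candidates that concentrate on few
chunks, the signature of conserved exons.

Also provided: the two-step variant (a sparse high-weight pattern pre-selects
promising tiles and their +-1 neighbours; sensitive low-weight patterns then
search only inside them), the s-genome generalization of the map, and a
false-positive-rate calibration that picks the score threshold from an
internally simulated i.i.d. null dataset of matched size.

All floor operations round toward -infinity (Python // semantics), which
matters for negative position differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import MaskedSequence
from .patterns import PatternSet, SeedPattern
from .seed_finding import Seed, find_spaced_seeds

logger = logging.getLogger("geoseed")

#: parameter preset for the two-step variant (sparse weight-19 pre-pass,
#: four weight-8 patterns in the main pass, link count and score thresholds 3)
TWO_STEP_PRESET = {"k_prime": 19, "k": 8, "tau_prime": 3, "tau_score": 3.0}


@dataclass
class GHParams:
    """Geometric-hashing parameters.

    F: tile size in bp (diagonal band width); b: sub-tiles per tile;
    h: chunk length in bp along the anti-diagonal; p_norm: score exponent;
    tau_score: tile score threshold (None = must be supplied or calibrated);
    n1, n2: total input lengths per genome for the lambda normalization
    (taken from the sequences at run time when unset).
    """

    F: int = 10_000
    b: int = 50
    h: int = 400
    p_norm: float = 6.0
    tau_score: float | None = None
    n1: float | None = None
    n2: float | None = None

    def __post_init__(self) -> None:
        if self.F <= 0 or self.b < 1 or self.h < 1 or self.p_norm < 1:
            raise ValueError("require F > 0, b >= 1, h >= 1, p_norm >= 1")
        if self.tau_score is not None and self.tau_score < 0:
            raise ValueError("tau_score must be >= 0")


@dataclass
class Tile:
    """One tile of the geometric map with its members and chunk counts."""

    key: tuple
    members: list[Seed] = field(default_factory=list)
    chunk_counts: dict[tuple[int, int], int] = field(default_factory=dict)
    smax: int | None = None
    score: float | None = None

    @property
    def count(self) -> int:
        return len(self.members)


def geometric_map(seed: Seed, F: int) -> tuple:
    """Pairwise geometric map: (S1, S2, floor((i - j)/F))."""
    if len(seed.coords) != 2:
        raise ValueError("geometric_map is pairwise; use multi_genome_map")
    return (seed.seq1, seed.seq2, (seed.i - seed.j) // F)


def multi_genome_map(seed: Seed, F: int) -> tuple:
    """s-genome map: sequence ids plus s-1 floored differences to genome 1."""
    ids = tuple(sid for sid, _ in seed.coords)
    i1 = seed.coords[0][1]
    offsets = tuple((i1 - pos) // F for _, pos in seed.coords[1:])
    return ids + offsets


def tile_key(seed: Seed, F: int) -> tuple:
    return geometric_map(seed, F) if len(seed.coords) == 2 else multi_genome_map(seed, F)


def assign_chunk(seed: Seed, params: GHParams) -> tuple[int, int]:
    """(sub-tile r, chunk s) of a seed within its tile.

    r = floor(d*b/F) with d the within-band remainder of the (first)
    position difference; s = floor(sum of positions / h).
    """
    i1 = seed.coords[0][1]
    i2 = seed.coords[1][1]
    diff = i1 - i2
    d = diff - params.F * (diff // params.F)
    r = d * params.b // params.F
    s = sum(pos for _, pos in seed.coords) // params.h
    return int(r), int(s)


def compute_smax(key: tuple, seq_lengths: dict[str, int], params: GHParams) -> int:
    """Largest feasible chunk index of a tile given the sequence lengths.

    Maximizes sum of positions over the tile's diagonal band intersected with
    the coordinate rectangle.  The objective is nondecreasing in the
    reference position i1, so the maximum sits at the upper end of the
    feasible i1 range (closed form; validated against brute force in tests).
    """
    s_dim = (len(key) + 1) // 2
    ids = key[:s_dim]
    offsets = key[s_dim:]
    lengths = [seq_lengths[sid] for sid in ids]
    F, h = params.F, params.h
    i1_hi = lengths[0] - 1
    i1_lo = 0
    for o_g, n_g in zip(offsets, lengths[1:]):
        i1_hi = min(i1_hi, (o_g + 1) * F + n_g - 2)
        i1_lo = max(i1_lo, o_g * F)
    if i1_hi < i1_lo:
        raise ValueError(f"tile {key} has no feasible positions within sequence bounds")
    total = i1_hi + sum(
        min(n_g - 1, i1_hi - o_g * F) for o_g, n_g in zip(offsets, lengths[1:])
    )
    return total // h


def compute_lambda(params: GHParams, L: int, n_totals: Sequence[float] | None = None) -> float:
    """Expected per-chunk candidate count under even scattering.

    Pairwise: lambda = A*L/(n1*n2) with chunk area A = h*F/b.  For s > 2
    genomes the chunk area generalizes to the volume h*F^(s-1)/b and the
    denominator to the product of all genome totals.
    """
    totals = tuple(n_totals) if n_totals is not None else (params.n1, params.n2)
    if any(t is None or t <= 0 for t in totals):
        raise ValueError("positive per-genome totals required for lambda")
    s_dim = len(totals)
    volume = params.h * float(params.F) ** (s_dim - 1) / params.b
    return volume * L / math.prod(totals)


def score_tile(tile: Tile, params: GHParams, lam: float) -> float:
    """Normalized p-norm of the tile's chunk counts."""
    if lam <= 0:
        raise ValueError("lambda must be positive to normalize tile scores")
    if tile.smax is None:
        raise ValueError("tile smax must be computed before scoring")
    if not tile.chunk_counts:
        return 0.0
    p = params.p_norm
    norm = float(sum(n ** p for n in tile.chunk_counts.values())) ** (1.0 / p)
    return norm / (lam * params.b * (tile.smax + 1))


def group_into_tiles(candidates: Sequence[Seed], params: GHParams) -> dict[tuple, Tile]:
    """Partition candidates into tiles and tally their chunk counts."""
    tiles: dict[tuple, Tile] = {}
    for seed in candidates:
        key = tile_key(seed, params.F)
        tile = tiles.setdefault(key, Tile(key))
        tile.members.append(seed)
        rc = assign_chunk(seed, params)
        tile.chunk_counts[rc] = tile.chunk_counts.get(rc, 0) + 1
    return tiles


def _genome_totals(
    candidates: Sequence[Seed], seq_lengths: dict[str, int], s_dim: int
) -> tuple[float, ...]:
    totals = []
    for g in range(s_dim):
        ids = {s.coords[g][0] for s in candidates}
        totals.append(float(sum(seq_lengths[sid] for sid in ids)))
    return tuple(totals)


def run_geometric_hashing(
    candidates: Sequence[Seed],
    seq_lengths: dict[str, int],
    params: GHParams,
    n_totals: Sequence[float] | None = None,
) -> tuple[list[Seed], pd.DataFrame]:
    """Score tiles and emit members of tiles with score >= tau_score.

    ``n_totals`` (total bp per genome) feeds the lambda normalization; when
    absent it falls back to params.n1/n2, then to the summed lengths of the
    sequences that actually carry candidates.  Returns the passing seeds
    (stage 'ghash-pass', canonical order) and a per-tile report.
    """
    if params.tau_score is None:
        raise ValueError("tau_score must be set (explicitly or via calibration)")
    candidates = list(candidates)
    dims = {len(s.coords) for s in candidates}
    if len(dims) > 1:
        raise ValueError(f"mixed seed dimensionalities {sorted(dims)}")
    if not candidates:
        return [], _empty_report()
    s_dim = dims.pop()
    if n_totals is None:
        if params.n1 is not None and params.n2 is not None and s_dim == 2:
            n_totals = (params.n1, params.n2)
        else:
            n_totals = _genome_totals(candidates, seq_lengths, s_dim)

    tiles = group_into_tiles(candidates, params)
    L = len(candidates)
    lam = compute_lambda(params, L, n_totals)
    rows = []
    passed: list[Seed] = []
    for key in sorted(tiles, key=lambda k: tuple(map(str, k))):
        tile = tiles[key]
        tile.smax = compute_smax(key, seq_lengths, params)
        tile.score = score_tile(tile, params, lam)
        ok = tile.score >= params.tau_score
        rows.append(
            {
                "tile": "|".join(map(str, key)),
                "members": tile.count,
                "smax": tile.smax,
                "score": tile.score,
                "passed": ok,
            }
        )
        if ok:
            passed.extend(
                replace(s, stage="ghash-pass") for s in tile.members
            )
    passed.sort(key=Seed.sort_key)
    report = pd.DataFrame(rows, columns=["tile", "members", "smax", "score", "passed"])
    logger.info(
        "geometric hashing: %d/%d tiles passed, %d/%d seeds kept (lambda=%.3g)",
        int(report["passed"].sum()), len(report), len(passed), L, lam,
    )
    return passed, report


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(columns=["tile", "members", "smax", "score", "passed"])


def select_tiles_by_count(
    candidates: Sequence[Seed], F: int, tau_prime: int, include_neighbours: bool = True
) -> set[tuple]:
    """Tiles holding >= tau_prime candidates, optionally with +-1 neighbours."""
    counts: dict[tuple, int] = {}
    for s in candidates:
        key = tile_key(s, F)
        counts[key] = counts.get(key, 0) + 1
    selected = {k for k, c in counts.items() if c >= tau_prime}
    if include_neighbours:
        expanded = set(selected)
        for k in selected:
            expanded.add(k[:-1] + (k[-1] - 1,))
            expanded.add(k[:-1] + (k[-1] + 1,))
        selected = expanded
    return selected


def two_step_filter(
    seqs1: Sequence[MaskedSequence],
    seqs2: Sequence[MaskedSequence],
    high_pattern: SeedPattern,
    tau_prime: int,
    low_patterns: PatternSet,
    params: GHParams,
    max_per_kmer: int = 10,
    rng_seed: int | np.random.Generator = 0,
    mask_filter: bool = True,
) -> tuple[list[Seed], pd.DataFrame]:
    """Two-step geometric hashing.

    Pass 1 maps candidates of a sparse high-weight pattern (weight k' > k) to
    tiles and selects the tile set T' with raw candidate count >= tau_prime,
    expanded by the +-1 offset neighbours.  Pass 2 finds candidates with the
    sensitive low-weight pattern set, discards those outside T', and runs the
    normal tile scoring on the remainder.
    """
    if high_pattern.weight <= low_patterns.weight:
        raise ValueError(
            f"pre-pass weight k'={high_pattern.weight} must exceed "
            f"main weight k={low_patterns.weight}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    high = find_spaced_seeds(seqs1, seqs2, [high_pattern], max_per_kmer, rng, mask_filter)
    selected = select_tiles_by_count(high, params.F, tau_prime)
    logger.info("two-step pass 1: %d candidates -> %d selected tiles", len(high), len(selected))
    low = find_spaced_seeds(seqs1, seqs2, low_patterns, max_per_kmer, rng, mask_filter)
    restricted = [s for s in low if tile_key(s, params.F) in selected]
    logger.info("two-step pass 2: %d of %d candidates inside T'", len(restricted), len(low))
    seq_lengths = {s.id: len(s) for s in list(seqs1) + list(seqs2)}
    n_totals = (
        float(sum(len(s) for s in seqs1)),
        float(sum(len(s) for s in seqs2)),
    )
    return run_geometric_hashing(restricted, seq_lengths, params, n_totals)


def calibrate_tau_score(
    seqs1: Sequence[MaskedSequence],
    seqs2: Sequence[MaskedSequence],
    patterns: PatternSet | Sequence[SeedPattern],
    params: GHParams,
    max_per_kmer: int = 10,
    rng_seed: int = 0,
    margin: float = 2.0,
    observed_candidates: int | None = None,
) -> float:
    """Score threshold yielding zero passing tiles on a matched i.i.d. null.

    Simulates uniform random sequence pairs of the same lengths and genome
    labels as the inputs, runs seed finding and tile scoring on them, and
    returns the smallest threshold at which no null tile passes, multiplied
    by a safety margin (default 2.0) so the zero-false-positive behaviour
    transfers to independent null data.

    Because the score normalizes by lambda, which is proportional to the
    run's total candidate count L at fixed sequence totals, score *scales*
    differ between runs of different candidate density.  When
    ``observed_candidates`` (the L of the run the threshold will be applied
    to) is given, the calibrated level is converted into that run's score
    units via the factor L_null / L_app; without it the threshold is only
    valid for runs of null-like candidate density.
    """
    from .synthetic import random_dna

    rng = np.random.default_rng(rng_seed)
    null1 = [
        MaskedSequence(f"null1_{i}", seqs1[0].genome_label, random_dna(rng, len(s)))
        for i, s in enumerate(seqs1)
    ]
    null2 = [
        MaskedSequence(f"null2_{i}", seqs2[0].genome_label, random_dna(rng, len(s)))
        for i, s in enumerate(seqs2)
    ]
    cand = find_spaced_seeds(null1, null2, patterns, max_per_kmer, rng)
    if not cand:
        return margin * np.finfo(float).tiny
    seq_lengths = {s.id: len(s) for s in null1 + null2}
    probe = replace(params, tau_score=float("inf"))
    _, report = run_geometric_hashing(cand, seq_lengths, probe)
    max_score = float(report["score"].max())
    tau = margin * float(np.nextafter(max_score, np.inf))
    if observed_candidates:
        tau *= len(cand) / observed_candidates
    logger.info("calibrated tau_score=%.4g (null max score %.4g over %d null "
                "candidates, margin %.2f)", tau, max_score, len(cand), margin)
    return tau
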