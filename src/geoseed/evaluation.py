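"""Evaluation statistics for seed-finding runs.

* CDS-support sensitivity: a pairwise seed supports a CDS of its first
  genome if the seed's first position falls inside the CDS interval and the
  two sequences are an annotated homologous pair (the second position is
  deliberately *not* required to be homologous, which keeps the measure
  independent of any reference alignment).  Sensitivity is the fraction of
  first-genome CDS with at least one supporting seed.
* FP-hat: a false-positive count between random sequence sets of total
  lengths n1, n2, extrapolated to false seeds per genome position for two
  genomes of reference size N:  FP_hat = #FP * N / (n1 * n2).
* The exact one-sided Poisson upper confidence bound on FP-hat when few or
  zero false positives are observed.
* The maximal exon offset Omega: the largest absolute difference between
  relative exon-start offsets of two orthologous genes, i.e. the cumulative
  indel effect a tile must absorb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneAnnotation
from .seed_finding import Seed

#: human genome size used for extrapolation, bp
DEFAULT_N = 3.22e9


@dataclass
class EvalConstants:
    """Constants of the false-positive extrapolation.

    N: reference genome size (bp); n1, n2: total lengths of the two input
    sets (bp); alpha: complement of the confidence level for Poisson bounds.
    """

    n1: float
    n2: float
    N: float = DEFAULT_N
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if min(self.N, self.n1, self.n2) <= 0:
            raise ValueError("N, n1, n2 must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def sensitivity(
    seeds: Sequence[Seed],
    annotations: Sequence[GeneAnnotation],
    exclude: set[tuple[str, int, int]] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of first-genome CDS supported by at least one seed.

    ``annotations`` describe the first genome's sequences and carry the
    homologous-partner links; a CDS [a, b) is supported when a seed between
    the annotated pair has a <= i < b (the half-open interval equals the
    customary closed 1-based range).  ``exclude`` removes listed
    (sequence_id, start, end) CDS from the denominator, mirroring the option
    to ignore exons that cannot be anchored.  Returns the fraction and a
    per-CDS support table.
    """
    exclude = exclude or set()
    # positions of seeds per (first sequence, second sequence)
    by_pair: dict[tuple[str, str], list[int]] = {}
    for s in seeds:
        if len(s.coords) != 2:
            raise ValueError("sensitivity is defined for pairwise seeds")
        by_pair.setdefault((s.seq1, s.seq2), []).append(s.i)
    pos_sorted = {k: np.sort(np.array(v, dtype=np.int64)) for k, v in by_pair.items()}

    rows = []
    for ann in annotations:
        partner = ann.homolog_partner
        pos = (
            pos_sorted.get((ann.sequence_id, partner), np.empty(0, np.int64))
            if partner is not None
            else np.empty(0, np.int64)
        )
        for a, b in ann.cds_intervals:
            if (ann.sequence_id, a, b) in exclude:
                continue
            hit = bool(
                np.searchsorted(pos, b, "left") > np.searchsorted(pos, a, "left")
            )
            rows.append(
                {"sequence_id": ann.sequence_id, "start": a, "end": b, "supported": hit}
            )
    table = pd.DataFrame(rows, columns=["sequence_id", "start", "end", "supported"])
    if len(table) == 0:
        raise ValueError("no CDS to evaluate")
    return float(table["supported"].mean()), table


def fp_hat(n_fp: float, consts: EvalConstants) -> float:
    """Extrapolated false seeds per genome position: #FP * N / (n1 * n2)."""
    if n_fp < 0:
        raise ValueError("count must be >= 0")
    return n_fp * consts.N / (consts.n1 * consts.n2)


def poisson_upper_count_bound(observed: int, alpha: float) -> float:
    """Exact one-sided (1 - alpha) upper bound on a Poisson mean.

    The smallest mean mu with P(X <= observed) = alpha; for observed = 0 this
    is -ln(alpha).  Computed via the chi-square quantile identity.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    return float(stats.chi2.ppf(1.0 - alpha, 2 * (observed + 1)) / 2.0)


def poisson_zero_upper_bound(observed: int, consts: EvalConstants) -> float:
    """Upper confidence bound on FP-hat from an observed (small) FP count."""
    return fp_hat(poisson_upper_count_bound(observed, consts.alpha), consts)


def max_exon_offset(starts1: Sequence[int], starts2: Sequence[int]) -> int:
    """Maximal exon offset Omega between two orthologous genes.

    Given the CDS starts of the two genes (equal count, gene order), Omega is
    max_i |(a1_i - a1_0) - (a2_i - a2_0)|: how far exon starts drift apart,
    relative to the first exon, through intron length changes.
    """
    if len(starts1) != len(starts2):
        raise ValueError("CDS start lists must have equal length")
    if len(starts1) < 1:
        raise ValueError("need at least one CDS")
    a1 = np.asarray(starts1, dtype=np.int64)
    a2 = np.asarray(starts2, dtype=np.int64)
    return int(np.abs((a1 - a1[0]) - (a2 - a2[0])).max())
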