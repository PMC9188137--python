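"""Synthetic test data: i.i.d. random genome pairs and planted ortholog pairs.

Two generators cover the two halves of the evaluation protocol:

* a *negative set* of sequence pairs with independent, uniformly distributed
  nucleotides — the null model under which every seed is a false positive
  (and under which the analytic expectation m*n1*n2/4^k holds);
* a *positive set* of orthologous gene pairs: multi-exon genes whose exons
  are drawn once and copied into both genomes with i.i.d. substitutions such
  that the per-base identity between the copies equals the configured value
  (default 0.85, the typical identity of human-mouse coding exons), while
  introns and flanks are drawn independently per genome.  Independently drawn
  intron lengths shift exon starts between the two copies, producing the
  maximal exon offsets (Omega) that the tile size of geometric hashing must
  absorb; flank lengths default to the [5000, 10000] range.

Exons carry no indels (the seed model is substitution-only inside a match
window); intron length variation is the sole indel proxy.  Substitutions are
uniform over the three alternative bases.  All output is reproducible from
the configuration seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    GeneAnnotation,
    MaskedSequence,
    write_fasta,
    write_gff_cds,
    write_homolog_pairs,
)
from .evaluation import max_exon_offset

logger = logging.getLogger("geoseed")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Configuration of the synthetic data generator.

    Ranges are inclusive (low, high) tuples.  Exon count/length defaults
    (3-12 exons of 60-400 bp) echo the ~150 bp mean length of uninterrupted
    coding alignment fragments in human-mouse orthologs; intron length
    ranges differ between the genomes to induce nonzero exon offsets.
    """

    seed: int = 0
    identity: float = 0.85
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 12)
    exon_length: tuple[int, int] = (60, 400)
    intron_length_1: tuple[int, int] = (500, 3000)
    intron_length_2: tuple[int, int] = (500, 3000)
    flank_length: tuple[int, int] = (5000, 10000)
    genome_label_1: str = "genome1"
    genome_label_2: str = "genome2"
    negative_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")
        for lo, hi in (
            self.exons_per_gene, self.exon_length,
            self.intron_length_1, self.intron_length_2, self.flank_length,
        ):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must satisfy 1 <= low <= high")


def random_dna(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform DNA string of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute each base independently with probability 1 - identity.

    Substitutions are uniform over the three alternative bases, so the
    per-base match probability between input and output equals ``identity``.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(raw)) < (1.0 - identity)
    n = int(hit.sum())
    if n:
        codes = np.searchsorted(_BASES, raw[hit])
        shift = rng.integers(1, 4, size=n)  # 1..3: always a different base
        raw[hit] = _BASES[(codes + shift) % 4]
    return raw.tobytes().decode("ascii")


def split_total(total: int, n_parts: int) -> list[int]:
    """Split a total length into n near-equal positive parts summing exactly."""
    if n_parts < 1 or total < n_parts:
        raise ValueError("need total >= n_parts >= 1")
    base = total // n_parts
    rem = total % n_parts
    return [base + (1 if i < rem else 0) for i in range(n_parts)]


def simulate_negative_pairs(
    lengths: Sequence[tuple[int, int]],
    rng: np.random.Generator | int = 0,
    genome_label_1: str = "rand1",
    genome_label_2: str = "rand2",
    id_prefix: str = "neg",
) -> tuple[list[MaskedSequence], list[MaskedSequence]]:
    """i.i.d. uniform random sequence pairs (no masking, no ambiguity)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seqs1, seqs2 = [], []
    for idx, (l1, l2) in enumerate(lengths):
        seqs1.append(
            MaskedSequence(f"{id_prefix}{idx}_1", genome_label_1, random_dna(rng, l1))
        )
        seqs2.append(
            MaskedSequence(f"{id_prefix}{idx}_2", genome_label_2, random_dna(rng, l2))
        )
    return seqs1, seqs2


def simulate_ortholog_pair(
    config: SimConfig, rng: np.random.Generator, index: int = 0
) -> tuple[MaskedSequence, MaskedSequence, GeneAnnotation, GeneAnnotation, int]:
    """One orthologous gene pair with truth annotations and realized Omega.

    Exon sequences are drawn once and placed in both genomes, the second copy
    mutated to the configured identity; intron and flank sequences and
    lengths are independent between the genomes.
    """
    n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    exons = [
        random_dna(rng, int(rng.integers(config.exon_length[0], config.exon_length[1] + 1)))
        for _ in range(n_exons)
    ]

    def assemble(intron_range, flank_range, exon_seqs):
        parts = [random_dna(rng, int(rng.integers(flank_range[0], flank_range[1] + 1)))]
        intervals = []
        for e_idx, exon in enumerate(exon_seqs):
            if e_idx > 0:
                parts.append(
                    random_dna(rng, int(rng.integers(intron_range[0], intron_range[1] + 1)))
                )
            start = sum(len(p) for p in parts)
            parts.append(exon)
            intervals.append((start, start + len(exon)))
        parts.append(random_dna(rng, int(rng.integers(flank_range[0], flank_range[1] + 1))))
        return "".join(parts), intervals

    res1, iv1 = assemble(config.intron_length_1, config.flank_length, exons)
    exons2 = [mutate(rng, e, config.identity) for e in exons]
    res2, iv2 = assemble(config.intron_length_2, config.flank_length, exons2)

    id1, id2 = f"gene{index}_1", f"gene{index}_2"
    seq1 = MaskedSequence(id1, config.genome_label_1, res1)
    seq2 = MaskedSequence(id2, config.genome_label_2, res2)
    ann1 = GeneAnnotation(id1, iv1, homolog_partner=id2)
    ann2 = GeneAnnotation(id2, iv2, homolog_partner=id1)
    omega = max_exon_offset([a for a, _ in iv1], [a for a, _ in iv2])
    return seq1, seq2, ann1, ann2, omega


def simulate_ortholog_set(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> tuple[list[MaskedSequence], list[MaskedSequence], list[GeneAnnotation], list[int]]:
    """The configured number of gene pairs; annotations for both genomes.

    Returns (genome-1 sequences, genome-2 sequences, annotations, omegas);
    the annotation list holds genome-1 entries first, then genome-2.
    """
    if rng is None:
        rng = config.seed
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seqs1, seqs2, anns1, anns2, omegas = [], [], [], [], []
    for g in range(config.n_genes):
        s1, s2, a1, a2, omega = simulate_ortholog_pair(config, rng, g)
        seqs1.append(s1)
        seqs2.append(s2)
        anns1.append(a1)
        anns2.append(a2)
        omegas.append(omega)
    return seqs1, seqs2, anns1 + anns2, omegas


def write_simulation(out_dir: str | Path, config: SimConfig) -> dict:
    """Run both generators and write FASTA/GFF3/pairs TSV/truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    seqs1, seqs2, annotations, omegas = simulate_ortholog_set(config, rng)
    write_fasta(out / "positives_genome1.fa", seqs1)
    write_fasta(out / "positives_genome2.fa", seqs2)
    write_gff_cds(out / "positives.gff3", annotations)
    pairs = [(s1.id, s2.id) for s1, s2 in zip(seqs1, seqs2)]
    write_homolog_pairs(out / "positives_pairs.tsv", pairs)

    if config.negative_pairs:
        neg1, neg2 = simulate_negative_pairs(
            config.negative_pairs, rng,
            config.genome_label_1, config.genome_label_2,
        )
        write_fasta(out / "negatives_genome1.fa", neg1)
        write_fasta(out / "negatives_genome2.fa", neg2)

    truth = {
        "omegas": {p[0]: int(o) for p, o in zip(pairs, omegas)},
        "config": {
            "seed": config.seed,
            "identity": config.identity,
            "n_genes": config.n_genes,
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    logger.info("simulation written to %s (%d gene pairs)", out, config.n_genes)
    return truth
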