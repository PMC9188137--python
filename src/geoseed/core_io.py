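"""Sequence and annotation I/O.

Defines the canonical in-memory representation of a softmasked DNA sequence
(:class:`MaskedSequence`) and of CDS annotations with homology links
(:class:`GeneAnnotation`), plus readers/writers for the plain-text formats the
toolkit touches: FASTA (lowercase = repeat-masked), GFF3 (CDS features only),
a TSV format for seeds, and a two-column TSV for homologous sequence pairs.

All internal coordinates are 0-based, half-open.  1-based inclusive
conventions (GFF3, and the field's customary notation) are converted at the
I/O boundary so that no other module needs to think about off-by-one shifts.
Only the forward strand is represented.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("geoseed")

# 2-bit encoding of the unambiguous alphabet; anything else is ambiguous (-1).
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(b"ACGT"):
    _CODE[_ch] = _i
    _CODE[_ch + 32] = _i  # lowercase
_LOWER = np.zeros(256, dtype=bool)
for _ch in range(ord("a"), ord("z") + 1):
    _LOWER[_ch] = True

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class MaskedSequence:
    """A named DNA string with per-position mask and validity classification.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA record id).
    genome_label : str
        Which genome/assembly the sequence belongs to.  Seeds are only formed
        between sequences carrying *different* genome labels.
    residues : str
        The residues with original case preserved; lowercase marks softmasked
        (repeat-derived) positions, characters outside ACGT/acgt are ambiguous.
    """

    id: str
    genome_label: str
    residues: str
    codes: np.ndarray = field(init=False, repr=False, compare=False)
    masked: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        raw = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        self.codes = _CODE[raw]
        self.masked = _LOWER[raw]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def ambiguous(self) -> np.ndarray:
        """Boolean array: True where the residue is not an unambiguous base."""
        return self.codes < 0


@dataclass
class GeneAnnotation:
    """CDS intervals of one sequence plus its homologous partner, if any.

    ``cds_intervals`` are 0-based half-open ``(start, end)`` tuples.
    """

    sequence_id: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    homolog_partner: str | None = None

    def validate(self, sequence_length: int | None = None) -> None:
        for a, b in self.cds_intervals:
            if a > b:
                raise ValueError(f"interval start {a} > end {b} on {self.sequence_id}")
            if sequence_length is not None and not (0 <= a and b <= sequence_length):
                raise ValueError(
                    f"interval [{a},{b}) outside sequence {self.sequence_id} "
                    f"of length {sequence_length}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | os.PathLike,
    genome_label: str | None = None,
    label_map: dict[str, str] | None = None,
) -> list[MaskedSequence]:
    """Read a (softmasked) FASTA file into :class:`MaskedSequence` records.

    The genome label of each record is looked up in ``label_map`` by record
    id, falling back to ``genome_label``, falling back to the file stem.
    Residue case is preserved (lowercase = masked).
    """
    path = Path(path)
    default_label = genome_label if genome_label is not None else path.stem
    out: list[MaskedSequence] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            label = (label_map or {}).get(rec.id, default_label)
            out.append(MaskedSequence(rec.id, label, str(rec.seq)))
    except (ValueError, UnicodeDecodeError) as exc:
        raise ParseError(f"malformed FASTA {path}: {exc}") from exc
    if not out:
        raise ParseError(f"no FASTA records in {path}")
    return out


def write_fasta(path: str | os.PathLike, seqs: Iterable[MaskedSequence], width: int = 80) -> None:
    """Write sequences preserving residue case (mask information)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (CDS features)
# ---------------------------------------------------------------------------

def read_gff_cds(
    path: str | os.PathLike,
    sequence_ids: set[str] | None = None,
    homolog_pairs: Sequence[tuple[str, str]] | None = None,
) -> list[GeneAnnotation]:
    """Extract CDS features from a GFF3 file.

    GFF3 coordinates are 1-based inclusive; they are converted to the internal
    0-based half-open convention (start-1, end).  Features on sequence ids not
    in ``sequence_ids`` (when given) are ignored; their number is logged.
    ``homolog_pairs`` attaches symmetric homology links to the annotations.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"malformed GFF3 {path}: {exc}") from exc

    partner: dict[str, str] = {}
    for a, b in homolog_pairs or []:
        partner[a] = b
        partner[b] = a

    by_seq: dict[str, GeneAnnotation] = {}
    skipped = 0
    for feat in db.features_of_type("CDS"):
        if sequence_ids is not None and feat.seqid not in sequence_ids:
            skipped += 1
            continue
        ann = by_seq.setdefault(
            feat.seqid, GeneAnnotation(feat.seqid, [], partner.get(feat.seqid))
        )
        ann.cds_intervals.append((int(feat.start) - 1, int(feat.end)))
    if skipped:
        logger.warning("read_gff_cds: ignored %d CDS on unknown sequence ids", skipped)
    if not by_seq:
        logger.warning("read_gff_cds: no CDS features found in %s", path)
    return list(by_seq.values())


def write_gff_cds(path: str | os.PathLike, annotations: Iterable[GeneAnnotation]) -> None:
    """Write CDS intervals back to GFF3 (internal half-open → 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            for idx, (a, b) in enumerate(ann.cds_intervals):
                fh.write(
                    f"{ann.sequence_id}\tgeoseed\tCDS\t{a + 1}\t{b}\t.\t+\t0\t"
                    f"ID=cds-{ann.sequence_id}-{idx}\n"
                )


# ---------------------------------------------------------------------------
# Seed TSV
# ---------------------------------------------------------------------------

def write_seeds(path: str | os.PathLike, seeds: Sequence) -> None:
    """Write seeds as TSV: one (sequence id, position) pair per genome, then
    pattern id and stage tag.  All seeds must share one dimensionality."""
    seeds = list(seeds)
    dims = {len(s.coords) for s in seeds}
    if len(dims) > 1:
        raise ValueError(f"mixed seed dimensionalities {sorted(dims)}")
    s_dim = dims.pop() if dims else 2
    header = []
    for g in range(1, s_dim + 1):
        header += [f"seqid_{g}", f"pos_{g}"]
    header += ["pattern_id", "stage"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for s in seeds:
            row: list = []
            for sid, pos in s.coords:
                row += [sid, pos]
            row += [s.pattern_id if s.pattern_id is not None else "", s.stage]
            w.writerow(row)


def read_seeds(path: str | os.PathLike) -> list:
    """Read a seed TSV written by :func:`write_seeds` (round-trip inverse)."""
    from .seed_finding import Seed

    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        try:
            header = next(r)
        except StopIteration:
            raise ParseError(f"empty seed file {path}") from None
        if len(header) < 4 or (len(header) - 2) % 2 != 0:
            raise ParseError(f"bad seed header in {path}: {header}")
        s_dim = (len(header) - 2) // 2
        out = []
        for lineno, row in enumerate(r, start=2):
            if len(row) != len(header):
                raise ParseError(f"{path}: ragged row {lineno}")
            try:
                coords = tuple(
                    (row[2 * g], int(row[2 * g + 1])) for g in range(s_dim)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: bad coordinate in row {lineno}") from exc
            pattern_id = row[-2] or None
            out.append(Seed(coords=coords, pattern_id=pattern_id, stage=row[-1]))
    return out


# ---------------------------------------------------------------------------
# Homolog pair TSV
# ---------------------------------------------------------------------------

def read_homolog_pairs(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Two-column TSV of homologous sequence-id pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ParseError(f"{path}: expected 2 columns in row {lineno}")
            pairs.append((row[0], row[1]))
    return pairs


def write_homolog_pairs(path: str | os.PathLike, pairs: Iterable[tuple[str, str]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a, b in pairs:
            w.writerow([a, b])
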