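"""Readers and writers for the formats the pipeline touches.

Internally every coordinate is 1-based inclusive (the VCF convention).
BEDPE input/output (0-based half-open) is converted exactly once, at this
boundary. SNVs are the only substitutions consumed; indels, MNVs and
symbolic alleles are counted and skipped at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
SV_TYPES = ("DEL", "DUP", "INV", "TRA")

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "sv_type",
]


class ParseError(ValueError):
    """Malformed input row; the message names the offending line."""


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic single-nucleotide variant (1-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"non-SNV alleles {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 2:
            raise ValueError(f"pos {self.pos} has no 5' neighbor")


@dataclass(frozen=True)
class RearrangementRecord:
    """One somatic rearrangement: two breakpoints plus a type.

    DEL/DUP/INV are intra-chromosomal with pos2 > pos1; TRA joins two
    chromosomes and has no defined size.
    """

    sample_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(
                f"unknown sv_type {self.sv_type!r}; accepted: {', '.join(SV_TYPES)}"
            )
        if self.sv_type == "TRA":
            if self.chrom1 == self.chrom2:
                raise ValueError("TRA requires chrom1 != chrom2")
        else:
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{self.sv_type} requires chrom1 == chrom2")
            if self.pos2 <= self.pos1:
                raise ValueError("intra-chromosomal record requires pos2 > pos1")

    @property
    def is_intra(self) -> bool:
        return self.sv_type != "TRA"

    @property
    def size(self) -> int | None:
        """Rearranged segment size in bp; None for translocations."""
        return self.pos2 - self.pos1 if self.is_intra else None


class ReferenceContext:
    """Trinucleotide-context lookup over an indexed FASTA.

    ``fetch(chrom, pos)`` returns the uppercase 3-mer centered at the
    1-based position ``pos``; positions within 1 bp of a contig edge are an
    error because no 5' or 3' neighbor exists.
    """

    def __init__(self, fasta_path: str | Path):
        self.path = Path(fasta_path)
        self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    @property
    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def contig_length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} absent from {self.path}")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, pos: int) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} absent from {self.path}")
        n = len(self._fasta[chrom])
        if pos < 2 or pos > n - 1:
            raise ValueError(
                f"position {chrom}:{pos} lacks a flanking base (contig length {n})"
            )
        # pyfaidx slices are 0-based half-open
        return str(self._fasta[chrom][pos - 2 : pos + 1])

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos)[1]


def read_mutations(path: str | Path, sample_id: str | None = None) -> list[MutationRecord]:
    """Read biallelic SNVs from a VCF file.

    Sample identity is taken from ``sample_id`` or, when omitted, from the
    file stem. Non-SNV rows (indels, MNVs, symbolic or multi-allelic ALTs)
    are skipped; the skip count is logged.
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem.removesuffix(".vcf")
    records: list[MutationRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            alts = row.alts
            if (
                alts is None
                or len(alts) != 1
                or len(row.ref) != 1
                or len(alts[0]) != 1
                or row.ref.upper() not in VALID_BASES
                or alts[0].upper() not in VALID_BASES
            ):
                skipped += 1
                continue
            try:
                records.append(
                    MutationRecord(
                        sample_id=sid,
                        chrom=row.chrom,
                        pos=row.pos,
                        ref=row.ref.upper(),
                        alt=alts[0].upper(),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: malformed SNV at {row.chrom}:{row.pos}: {exc}")
    if skipped:
        logger.info("%s: skipped %d non-SNV rows", path.name, skipped)
    return records


def read_mutations_dir(vcf_dir: str | Path, pattern: str = "*.vcf") -> list[MutationRecord]:
    """Read every per-sample VCF in a directory (sample id = file stem)."""
    records: list[MutationRecord] = []
    for path in sorted(Path(vcf_dir).glob(pattern)):
        records.extend(read_mutations(path))
    return records


def read_rearrangements(path: str | Path) -> list[RearrangementRecord]:
    """Read rearrangements from a BEDPE file with an ``sv_type`` column.

    BEDPE starts are 0-based half-open and are converted to 1-based
    breakpoint positions. Intra-chromosomal records are canonically ordered
    so that pos2 > pos1. The sample id comes from the ``name`` column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=BEDPE_COLUMNS, dtype={"chrom1": str, "chrom2": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse BEDPE: {exc}") from exc
    records: list[RearrangementRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sv_type = str(row.sv_type).upper()
        if sv_type not in SV_TYPES:
            raise ParseError(
                f"{path}, line {i}: unknown sv_type {row.sv_type!r}; "
                f"accepted: {', '.join(SV_TYPES)}"
            )
        pos1 = int(row.start1) + 1  # 0-based half-open -> 1-based
        pos2 = int(row.start2) + 1
        chrom1, chrom2 = str(row.chrom1), str(row.chrom2)
        if sv_type != "TRA" and pos2 < pos1:
            pos1, pos2 = pos2, pos1
        try:
            records.append(
                RearrangementRecord(
                    sample_id=str(row.name), chrom1=chrom1, pos1=pos1,
                    chrom2=chrom2, pos2=pos2, sv_type=sv_type,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}, line {i}: {exc}") from exc
    return records


def write_rearrangements(records: Iterable[RearrangementRecord], path: str | Path) -> None:
    """Write rearrangements as BEDPE (inverse of :func:`read_rearrangements`)."""
    rows = []
    for r in records:
        rows.append(
            (r.chrom1, r.pos1 - 1, r.pos1, r.chrom2, r.pos2 - 1, r.pos2,
             r.sample_id, ".", "+", "-", r.sv_type)
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def write_matrix_tsv(matrix, row_labels: Sequence[str], col_labels: Sequence[str],
                     path: str | Path, index_name: str = "") -> None:
    """Write a labelled matrix as TSV (rows = features, columns = samples)."""
    df = pd.DataFrame(matrix, index=list(row_labels), columns=list(col_labels))
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
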