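"""The 96-channel trinucleotide mutation catalog.

Somatic SNVs are collapsed onto the pyrimidine strand and indexed by
substitution class and flanking bases: channel = 16*class + 4*five_prime +
three_prime, with classes ordered (C>A, C>G, C>T, T>A, T>C, T>G) and bases
ordered (A, C, G, T). This is the COSMIC-style lexicographic layout, so
profiles can be compared channel-by-channel with published reference
signature tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import MutationRecord, ReferenceContext

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_CLASS_INDEX = {c: i for i, c in enumerate(SUBSTITUTION_CLASSES)}

N_CHANNELS = 96


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_labels() -> list[str]:
    """The 96 channel labels, e.g. ``A[C>A]A``, in catalog column order."""
    labels = []
    for cls in SUBSTITUTION_CLASSES:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{cls}]{three}")
    return labels


CHANNEL_LABELS = channel_labels()


def classify_substitution(ref: str, alt: str, context: str) -> int:
    """Map an SNV plus its reference 3-mer to a channel index in 0..95.

    Purine-reference mutations are reverse-complemented onto the pyrimidine
    strand before indexing, so each biological event has exactly one channel.

    Raises ``ValueError`` when the context middle base disagrees with
    ``ref`` or when the context contains a base outside A/C/G/T.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3:
        raise ValueError(f"context {context!r} is not a 3-mer")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref == alt:
        raise ValueError("ref equals alt")
    if any(b not in _BASE_INDEX for b in context) or alt not in _BASE_INDEX:
        raise ValueError(f"ambiguous base in {context!r}>{alt!r}")
    if ref in "AG":  # collapse onto the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = reverse_complement(context)
    cls = _CLASS_INDEX[f"{ref}>{alt}"]
    return 16 * cls + 4 * _BASE_INDEX[context[0]] + _BASE_INDEX[context[2]]


@dataclass
class TrinucCatalog:
    """Samples x 96 matrix of trinucleotide mutation counts."""

    sample_ids: list[str]
    counts: np.ndarray  # shape (n_samples, 96), non-negative ints
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), N_CHANNELS):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({len(self.sample_ids)}, {N_CHANNELS})"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def matrix(self) -> np.ndarray:
        """Channels x samples orientation (the NMF input M)."""
        return self.counts.T

    def to_tsv(self, path) -> None:
        from .io_formats import write_matrix_tsv

        write_matrix_tsv(self.matrix, self.channel_labels, self.sample_ids,
                         path, index_name="channel")


def build_catalog(
    mutations: Iterable[MutationRecord],
    reference: ReferenceContext,
    sample_ids: Sequence[str] | None = None,
) -> TrinucCatalog:
    """Count classifiable SNVs per sample into the 96-channel catalog.

    Rows follow the order of first appearance (or ``sample_ids`` when
    given, which may declare samples with zero mutations). Duplicate calls
    at the same (sample, chrom, pos) are dropped keeping the first;
    mutations whose context contains N are excluded with a logged count.
    """
    order: list[str] = list(sample_ids) if sample_ids is not None else []
    index = {s: i for i, s in enumerate(order)}
    rows: list[list[MutationRecord]] = [[] for _ in order]
    seen: set[tuple[str, str, int]] = set()
    n_ambiguous = n_duplicate = 0

    counts = np.zeros((len(order), N_CHANNELS), dtype=np.int64)
    for rec in mutations:
        if rec.sample_id not in index:
            if sample_ids is not None:
                raise ValueError(f"sample {rec.sample_id!r} not in declared sample_ids")
            index[rec.sample_id] = len(order)
            order.append(rec.sample_id)
            counts = np.vstack([counts, np.zeros((1, N_CHANNELS), dtype=np.int64)])
        key = (rec.sample_id, rec.chrom, rec.pos)
        if key in seen:
            n_duplicate += 1
            continue
        seen.add(key)
        if rec.chrom not in reference.contigs:
            raise ValueError(f"contig {rec.chrom!r} absent from reference")
        context = reference.fetch(rec.chrom, rec.pos)
        try:
            channel = classify_substitution(rec.ref, rec.alt, context)
        except ValueError as exc:
            if "ambiguous" in str(exc):
                n_ambiguous += 1
                continue
            raise
        counts[index[rec.sample_id], channel] += 1

    if n_ambiguous:
        logger.info("excluded %d mutations with ambiguous (N) context", n_ambiguous)
    if n_duplicate:
        logger.info("dropped %d duplicate calls", n_duplicate)
    return TrinucCatalog(sample_ids=order, counts=counts, channel_labels=list(CHANNEL_LABELS))
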