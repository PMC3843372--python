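"""Per-contig and whole-assembly statistics: GC, lengths, span, N50.

GC is computed over unambiguous bases only: N and other IUPAC ambiguity
codes are excluded from both numerator and denominator, so gappy
scaffolds are not systematically depressed. N50 is the length-weighted
median: the length at which the descending cumulative sum of contig
lengths first reaches half the assembly span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, List

from tagcplot.formats_io import ContigSeq

logger = logging.getLogger(__name__)

_GC_BASES = frozenset("GCgc")
_AT_BASES = frozenset("ATat")


@dataclass(frozen=True)
class AssemblySummary:
    n_contigs: int
    span: int  # total bases, counting N
    mean_length: float
    n50: int
    min_length_applied: int = 0


def gc_fraction(contig: ContigSeq) -> float:
    """(G + C) / (A + C + G + T), case-insensitive; 0.0 when the contig
    has no unambiguous base (logged)."""
    gc = at = 0
    for base in contig.residues:
        if base in _GC_BASES:
            gc += 1
        elif base in _AT_BASES:
            at += 1
    denom = gc + at
    if denom == 0:
        logger.warning("contig %s has no unambiguous bases; GC reported as 0", contig.id)
        return 0.0
    return gc / denom


def filter_min_length(
    contigs: Iterable[ContigSeq], min_len: int = 200
) -> Iterator[ContigSeq]:
    """Keep contigs of length >= min_len ('smaller than' removed), order
    preserved."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    for contig in contigs:
        if len(contig) >= min_len:
            yield contig


def assembly_summary(
    contigs: Iterable[ContigSeq], min_length_applied: int = 0
) -> AssemblySummary:
    lengths = [(len(c), c.id) for c in contigs]
    if not lengths:
        return AssemblySummary(0, 0, 0.0, 0, min_length_applied)
    span = sum(length for length, _ in lengths)
    n50 = _n50(lengths, span)
    return AssemblySummary(
        n_contigs=len(lengths),
        span=span,
        mean_length=span / len(lengths),
        n50=n50,
        min_length_applied=min_length_applied,
    )


def _n50(lengths: List[tuple], span: int) -> int:
    # stable descending order by (length, seqid) for a deterministic tie rule
    ordered = sorted(lengths, key=lambda t: (-t[0], t[1]))
    cumulative = 0
    for length, _ in ordered:
        cumulative += length
        if cumulative >= span / 2:
            return length
    return 0  # unreachable for non-empty input
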