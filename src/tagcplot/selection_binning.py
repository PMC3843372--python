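"""Contig selection in TAGC space and pair-complete read binning.

Selections are declarative: keep/exclude rules over taxon labels, GC
and coverage ranges, and rotated ellipses drawn in (GC, log10 coverage)
space. Read binning collects every read with a primary alignment to a
selected contig plus its mate (mate rescue), so downstream reassembly
always sees complete pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from tagcplot.errors import FormatError
from tagcplot.formats_io import (
    AlignmentRecord,
    BlastHit,
    FastqRecord,
    TagcTable,
    normalize_read_id,
    read_fastq_pairs,
    write_fastq,
)
from tagcplot.taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

#: pseudo-coverage for zero-depth contigs on the log axis
DEFAULT_COV_FLOOR = 0.01


@dataclass(frozen=True)
class Ellipse:
    """A rotated ellipse in (gc, log10 coverage) space.

    ``rotation`` is counterclockwise radians; ``a`` is the semi-axis
    along gc before rotation, ``b`` along log10 coverage.
    """

    center_gc: float
    center_log_cov: float
    a: float
    b: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


def point_in_ellipse(e: Ellipse, gc: float, log10_cov: float) -> bool:
    """Boundary-inclusive membership: translate by -center, rotate by
    -rotation, test (x/a)^2 + (y/b)^2 <= 1."""
    dx = gc - e.center_gc
    dy = log10_cov - e.center_log_cov
    cos_t, sin_t = math.cos(-e.rotation), math.sin(-e.rotation)
    x = dx * cos_t - dy * sin_t
    y = dx * sin_t + dy * cos_t
    return (x / e.a) ** 2 + (y / e.b) ** 2 <= 1.0


KEEP = "keep"
EXCLUDE = "exclude"


@dataclass
class SelectionRule:
    """One keep/exclude filter; criteria within a rule combine by AND."""

    mode: str = KEEP
    taxa: Optional[Set[str]] = None
    rank: str = "order"
    gc_range: Optional[Tuple[float, float]] = None
    cov_range: Optional[Tuple[float, float]] = None
    library: str = "total"
    ellipses: Optional[List[Ellipse]] = None
    cov_floor: float = DEFAULT_COV_FLOOR

    def __post_init__(self) -> None:
        if self.mode not in (KEEP, EXCLUDE):
            raise ValueError(f"mode must be keep/exclude, got {self.mode!r}")
        if self.taxa is None and self.gc_range is None \
                and self.cov_range is None and not self.ellipses:
            raise ValueError("rule must carry at least one criterion")

    def matches(self, row) -> bool:
        if self.taxa is not None and row.taxa.get(self.rank) not in self.taxa:
            return False
        if self.gc_range is not None:
            lo, hi = self.gc_range
            if not (lo <= row.gc <= hi):
                return False
        if self.cov_range is not None:
            lo, hi = self.cov_range
            if not (lo <= row.coverages[self.library] <= hi):
                return False
        if self.ellipses:
            cov = max(row.coverages[self.library], self.cov_floor)
            y = math.log10(cov)
            if not any(point_in_ellipse(e, row.gc, y) for e in self.ellipses):
                return False
        return True


def select_contigs(table: TagcTable, rules: Iterable[SelectionRule]) -> Set[str]:
    """Apply rules in order to the full contig set.

    Keep-rules intersect the running set with their matches;
    exclude-rules subtract theirs. An unknown taxon name matches nothing
    (warning, not error). Empty rule list selects everything.
    """
    selected = set(table.seqids())
    known_taxa = {
        row.taxa[rank] for row in table.rows for rank in table.rank_labels
    }
    for rule in rules:
        if rule.taxa is not None:
            if rule.rank not in table.rank_labels:
                raise ValueError(f"rank {rule.rank!r} not present in table")
            for taxon in rule.taxa - known_taxa:
                logger.warning("taxon %r matches no contig", taxon)
        if (rule.cov_range is not None or rule.ellipses) \
                and rule.library not in table.library_labels:
            raise ValueError(f"library {rule.library!r} not present in table")
        matched = {row.seqid for row in table.rows if rule.matches(row)}
        if rule.mode == KEEP:
            selected &= matched
        else:
            selected -= matched
    return selected


@dataclass(frozen=True)
class ConservativeDiscardPolicy:
    """Discard a contig only when its best hit is to a contaminant AND no
    hit to the target taxon beats a permissive e-value cutoff.

    Chimeric contigs can join target and contaminant sequence; this
    keeps any contig with even weak target evidence.
    """

    contaminant_taxa: frozenset
    target_taxon: str
    permissive_evalue: float = 1e-2
    rank: str = "order"

    def __post_init__(self) -> None:
        if self.permissive_evalue <= 0:
            raise ValueError("permissive_evalue must be > 0")


def conservative_discard(
    hits: Iterable[BlastHit],
    tree: TaxonomyTree,
    policy: ConservativeDiscardPolicy,
) -> Set[str]:
    """Contigs to discard under the policy. Hits must carry e-values."""
    per_contig: Dict[str, List[BlastHit]] = {}
    for hit in hits:
        if hit.evalue is None:
            raise FormatError(
                f"hit for {hit.query_id!r} lacks an e-value; conservative "
                "discard needs 4-column hit tables"
            )
        per_contig.setdefault(hit.query_id, []).append(hit)

    discard: Set[str] = set()
    for contig, contig_hits in per_contig.items():
        best = min(
            contig_hits, key=lambda h: (h.evalue, -(h.bitscore or 0.0), h.file_rank)
        )
        best_taxon = tree.rank_of(best.taxids[0], policy.rank)
        if best_taxon not in policy.contaminant_taxa:
            continue
        has_target = any(
            h.evalue <= policy.permissive_evalue
            and tree.rank_of(h.taxids[0], policy.rank) == policy.target_taxon
            for h in contig_hits
        )
        if not has_target:
            discard.add(contig)
    return discard


def reads_for_contigs(
    alignments: Iterable[AlignmentRecord], contig_set: Set[str]
) -> Set[str]:
    """Normalized ids of reads with a primary alignment to any contig in
    the set, mate-rescued: both mates share one normalized id, so the
    returned set is pair-closed by construction."""
    out: Set[str] = set()
    for rec in alignments:
        if rec.is_primary and rec.is_mapped and rec.contig_id in contig_set:
            out.add(normalize_read_id(rec.read_id))
    return out


def filter_fastq(
    in1,
    in2,
    out1,
    out2,
    exclusion: Set[str],
    invert: bool = False,
) -> Tuple[int, int]:
    """Split synchronized pair files against a normalized-id exclusion set.

    With ``invert=False`` keeps pairs NOT in the set (cleaned target
    reads); with ``invert=True`` keeps only excluded pairs (e.g. to
    reassemble a symbiont bin). Pair-level semantics: one excluded mate
    excludes the pair. Returns (pairs written, pairs suppressed).
    """
    kept1: List[FastqRecord] = []
    kept2: List[FastqRecord] = []
    written = suppressed = 0
    for rec1, rec2 in read_fastq_pairs(in1, in2):
        excluded = normalize_read_id(rec1[0]) in exclusion
        if excluded == invert:
            kept1.append(rec1)
            kept2.append(rec2)
            written += 1
        else:
            suppressed += 1
    write_fastq(kept1, out1)
    write_fastq(kept2, out2)
    return written, suppressed
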