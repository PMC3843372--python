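"""Per-contig, per-library mean read depth from alignment streams.

Depth of a contig is the total number of reference bases consumed by
match/mismatch operations of primary mapped records, divided by contig
length. Secondary and supplementary alignments are excluded so each read
contributes at most once; duplicates are not removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping

from tagcplot.errors import StructuralError
from tagcplot.formats_io import AlignmentRecord


@dataclass
class LibraryCoverage:
    library_label: str
    depth_by_contig: Dict[str, float] = field(default_factory=dict)
    n_reads_total: int = 0
    n_reads_mapped: int = 0


def compute_coverage(
    alignments: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
    label: str,
) -> LibraryCoverage:
    """Mean read depth per contig for one library.

    Every contig in ``contig_lengths`` appears in the result (depth 0
    when unaligned). A mapped record naming an unknown contig is an
    error, guarding against assembly/alignment mismatches.
    """
    bases: Dict[str, int] = {cid: 0 for cid in contig_lengths}
    n_total = n_mapped = 0
    for rec in alignments:
        if not rec.is_primary:
            continue
        n_total += 1
        if not rec.is_mapped:
            continue
        if rec.contig_id not in bases:
            raise StructuralError(
                f"alignment to contig {rec.contig_id!r} absent from the assembly "
                f"(library {label!r})"
            )
        n_mapped += 1
        bases[rec.contig_id] += rec.aligned_ref_bases
    return LibraryCoverage(
        library_label=label,
        depth_by_contig={
            cid: bases[cid] / contig_lengths[cid] for cid in contig_lengths
        },
        n_reads_total=n_total,
        n_reads_mapped=n_mapped,
    )


def mapped_fraction(cov: LibraryCoverage) -> float:
    if cov.n_reads_total == 0:
        raise ValueError(f"library {cov.library_label!r} has no reads")
    return cov.n_reads_mapped / cov.n_reads_total


def merge_coverages(
    covs: List[LibraryCoverage], combined_label: str = "total"
) -> LibraryCoverage:
    """Combine libraries: depth is additive in reads, counts are summed."""
    if not covs:
        raise ValueError("no libraries to merge")
    contigs = set(covs[0].depth_by_contig)
    for cov in covs[1:]:
        if set(cov.depth_by_contig) != contigs:
            raise StructuralError(
                f"library {cov.library_label!r} covers a different contig set "
                f"than {covs[0].library_label!r}"
            )
    return LibraryCoverage(
        library_label=combined_label,
        depth_by_contig={
            cid: sum(cov.depth_by_contig[cid] for cov in covs) for cid in contigs
        },
        n_reads_total=sum(c.n_reads_total for c in covs),
        n_reads_mapped=sum(c.n_reads_mapped for c in covs),
    )
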