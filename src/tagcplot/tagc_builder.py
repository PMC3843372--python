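"""Collate GC, coverage and taxonomy into the TAGC table.

Also provides deterministic subsampling (large assemblies overwhelm both
the similarity search and interactive display, ~20k contigs being a
comfortable ceiling), the 1%-of-annotated-contigs legend rule, and the
relative-molarity calculation for read mixtures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

from tagcplot.contig_stats import gc_fraction
from tagcplot.coverage import LibraryCoverage, merge_coverages
from tagcplot.errors import StructuralError
from tagcplot.formats_io import ContigSeq, TagcRow, TagcTable
from tagcplot.taxonomy import NOT_ANNOTATED, UNRESOLVED

#: label of the appended combined-coverage column
TOTAL_LABEL = "total"


@dataclass(frozen=True)
class MixtureComponent:
    """One genome in a read mixture: fraction of reads and genome size (Mb)."""

    label: str
    read_fraction: float
    genome_size: float


def build_table(
    contigs: Sequence[ContigSeq],
    coverages: Sequence[LibraryCoverage],
    annotations: Mapping[str, Mapping[str, str]],
    ranks: Sequence[str],
) -> TagcTable:
    """One row per contig in assembly order, with a combined 'total'
    coverage column appended after the per-library columns."""
    labels = [cov.library_label for cov in coverages]
    if len(set(labels)) != len(labels):
        raise StructuralError(f"duplicate library labels: {labels}")
    for cov in coverages:
        for contig in contigs:
            if contig.id not in cov.depth_by_contig:
                raise StructuralError(
                    f"contig {contig.id!r} missing from coverage "
                    f"{cov.library_label!r}"
                )
    combined = merge_coverages(list(coverages), TOTAL_LABEL)
    all_covs = list(coverages) + [combined]
    table = TagcTable(
        library_labels=labels + [TOTAL_LABEL], rank_labels=list(ranks)
    )
    for contig in contigs:
        row_covs: Dict[str, float] = {}
        for cov in all_covs:
            if contig.id not in cov.depth_by_contig:
                raise StructuralError(
                    f"contig {contig.id!r} missing from coverage "
                    f"{cov.library_label!r}"
                )
            row_covs[cov.library_label] = cov.depth_by_contig[contig.id]
        if contig.id not in annotations:
            raise StructuralError(f"contig {contig.id!r} missing from annotations")
        ann = annotations[contig.id]
        table.rows.append(
            TagcRow(
                seqid=contig.id,
                length=len(contig),
                gc=gc_fraction(contig),
                coverages=row_covs,
                taxa={rank: ann[rank] for rank in ranks},
            )
        )
    table.validate()
    return table


def subsample(table: TagcTable, n: int, seed: int) -> TagcTable:
    """Uniform sample of min(n, size) rows without replacement.

    Deterministic for a fixed (table, n, seed); surviving rows keep
    their original order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= len(table.rows):
        keep = list(range(len(table.rows)))
    else:
        rng = random.Random(seed)
        keep = sorted(rng.sample(range(len(table.rows)), n))
    return TagcTable(
        rows=[table.rows[i] for i in keep],
        library_labels=list(table.library_labels),
        rank_labels=list(table.rank_labels),
    )


def relative_molarity(
    components: Iterable[MixtureComponent], reference_label: str
) -> Dict[str, float]:
    """Molar abundance read_fraction/genome_size per component, scaled so
    the reference equals 1."""
    components = list(components)
    by_label = {c.label: c for c in components}
    if reference_label not in by_label:
        raise ValueError(f"reference component {reference_label!r} not present")
    for c in components:
        if c.genome_size <= 0:
            raise ValueError(f"component {c.label!r} has non-positive genome size")
    ref = by_label[reference_label]
    ref_molarity = ref.read_fraction / ref.genome_size
    if ref_molarity == 0:
        raise ValueError("reference component has zero read fraction")
    return {
        c.label: (c.read_fraction / c.genome_size) / ref_molarity
        for c in components
    }


def legend_taxa(
    table: TagcTable, rank: str, threshold: float = 0.01
) -> List[str]:
    """Taxa worth a legend entry at ``rank``.

    A taxon is hidden when its contig count is below ``threshold`` of
    the number of annotated contigs (exactly-at-threshold is shown);
    sentinels are excluded from both counts and the denominator. Sorted
    by descending count, then name.
    """
    if rank not in table.rank_labels:
        raise ValueError(f"rank {rank!r} not in table ranks {table.rank_labels}")
    counts: Dict[str, int] = {}
    for row in table.rows:
        taxon = row.taxa[rank]
        if taxon in (NOT_ANNOTATED, UNRESOLVED):
            continue
        counts[taxon] = counts.get(taxon, 0) + 1
    n_annotated = sum(counts.values())
    if n_annotated == 0:
        return []
    cutoff = threshold * n_annotated
    shown = [t for t, c in counts.items() if c >= cutoff]
    return sorted(shown, key=lambda t: (-counts[t], t))


def legend_counts(table: TagcTable, rank: str) -> Dict[str, int]:
    """Contig count per non-sentinel taxon at ``rank``."""
    counts: Dict[str, int] = {}
    for row in table.rows:
        taxon = row.taxa[rank]
        if taxon in (NOT_ANNOTATED, UNRESOLVED):
            continue
        counts[taxon] = counts.get(taxon, 0) + 1
    return counts
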