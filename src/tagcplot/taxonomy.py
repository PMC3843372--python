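"""Taxid lineage resolution and rank rollup.

A :class:`TaxonomyTree` stores ``taxid -> (parent, rank, name)`` and
supports walking a node's ancestor chain to find the name carried at a
requested canonical rank (e.g. rolling a species-level best hit up to
its order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

from tagcplot.errors import StructuralError

logger = logging.getLogger(__name__)

#: Canonical rank labels, broadest first.
CANONICAL_RANKS: Tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "order",
    "family",
    "genus",
    "species",
)

#: Label for contigs that have no database hit at all.
NOT_ANNOTATED = "not_annotated"

#: Label for hits whose lineage carries no node at the requested rank
#: (also used for taxids absent from the tree, e.g. retired ids).
UNRESOLVED = "unresolved"


@dataclass
class TaxonomyTree:
    """taxid -> (parent_taxid, rank, name) store with lineage walks.

    Exactly one node (the root) is its own parent; every other node's
    parent chain must reach the root without cycles.
    """

    nodes: Dict[int, Tuple[int, str, str]] = field(default_factory=dict)
    root_taxid: int = 1
    #: count of rank_of() calls that hit an unknown taxid
    unknown_taxid_count: int = 0

    def add_node(self, taxid: int, parent: int, rank: str, name: str) -> None:
        self.nodes[taxid] = (parent, rank, name)
        if taxid == parent:
            self.root_taxid = taxid

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def name_of(self, taxid: int) -> str:
        return self.nodes[taxid][2]

    def validate(self) -> None:
        """Check the single-root / no-orphan / no-cycle invariants."""
        roots = [t for t, (p, _, _) in self.nodes.items() if t == p]
        if len(roots) != 1:
            raise StructuralError(
                f"taxonomy must have exactly one self-parent root, found {roots!r}"
            )
        orphans = sorted(
            t for t, (p, _, _) in self.nodes.items() if p not in self.nodes
        )
        if orphans:
            raise StructuralError(f"orphan taxids (parent absent): {orphans}")
        for taxid in self.nodes:
            self._walk_to_root(taxid)

    def _walk_to_root(self, taxid: int) -> List[int]:
        """Ancestor chain from taxid (inclusive) to root; cycle-safe."""
        chain: List[int] = []
        seen = set()
        node = taxid
        while True:
            if node in seen:
                raise StructuralError(f"cycle in taxonomy at taxid {node}")
            seen.add(node)
            chain.append(node)
            parent = self.nodes[node][0]
            if parent == node:
                return chain
            node = parent

    def lineage(self, taxid: int) -> List[int]:
        """Taxids from ``taxid`` up to and including the root."""
        return self._walk_to_root(taxid)

    def rank_of(self, taxid: int, rank: str) -> str:
        """Name of the first ancestor-or-self of ``taxid`` at ``rank``.

        Returns :data:`UNRESOLVED` when the lineage has no node of that
        rank, or when the taxid is unknown (warning counted, not fatal:
        public databases routinely contain retired taxids).
        """
        if taxid not in self.nodes:
            self.unknown_taxid_count += 1
            logger.warning("unknown taxid %d; reporting %s", taxid, UNRESOLVED)
            return UNRESOLVED
        for node in self._walk_to_root(taxid):
            parent, node_rank, name = self.nodes[node]
            if node_rank == rank:
                return name
        return UNRESOLVED


def best_hit_per_contig(hits: Iterable["BlastHit"]) -> Dict[str, int]:
    """Resolve each contig to the taxid of its best hit.

    Best = lowest e-value, ties broken by highest bitscore then lowest
    file rank. With two-column input (no e-value) the first row per
    contig wins. Multi-taxid fields contribute their first taxid.
    """
    best: Dict[str, Tuple[float, float, int, int]] = {}
    for hit in hits:
        evalue = hit.evalue if hit.evalue is not None else float("inf")
        bitscore = hit.bitscore if hit.bitscore is not None else float("-inf")
        key = (evalue, -bitscore, hit.file_rank)
        taxid = hit.taxids[0]
        prev = best.get(hit.query_id)
        if prev is None or key < prev[:3]:
            best[hit.query_id] = (*key, taxid)
    return {contig: entry[3] for contig, entry in best.items()}


def annotate_contigs(
    tree: TaxonomyTree,
    best_hits: Mapping[str, int],
    all_contigs: Iterable[str],
    ranks: Iterable[str],
) -> Dict[str, Dict[str, str]]:
    """Roll every contig's best-hit taxid up to each requested rank.

    Contigs without a hit are labeled :data:`NOT_ANNOTATED` at every
    rank; every contig in ``all_contigs`` appears in the output.
    """
    ranks = list(ranks)
    if not ranks:
        raise ValueError("at least one rank required")
    out: Dict[str, Dict[str, str]] = {}
    for contig in all_contigs:
        if contig in best_hits:
            taxid = best_hits[contig]
            out[contig] = {rank: tree.rank_of(taxid, rank) for rank in ranks}
        else:
            out[contig] = {rank: NOT_ANNOTATED for rank in ranks}
    return out
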