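"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own interval/lineage/geometry
code paths: depth is computed by marking individual bases, lineages by
enumerating full ancestor chains, ellipse membership by an explicit
affine transform applied pointwise.
"""

import math
import random

from tagcplot.formats_io import AlignmentRecord

# --- per-base pileup depth -------------------------------------------------

SAM_OPS = "MIDNSHP=X"
_CONSUMES_REF = {"M": True, "I": False, "D": True, "N": True, "S": False,
                 "H": False, "P": False, "=": True, "X": True}
_ADDS_DEPTH = {"M", "=", "X"}


def pileup_intervals_from_cigar(pos, cigar_ops):
    """Mark each reference base covered by a match/mismatch op, one base
    at a time, then re-assemble maximal runs."""
    covered = set()
    cursor = pos
    for op, length in cigar_ops:
        for _ in range(length):
            if op in _ADDS_DEPTH:
                covered.add(cursor)
            if _CONSUMES_REF[op]:
                cursor += 1
    runs = []
    for base in sorted(covered):
        if runs and runs[-1][1] == base:
            runs[-1] = (runs[-1][0], base + 1)
        else:
            runs.append((base, base + 1))
    return tuple(runs)


def pileup_depths(records, contig_lengths):
    """Per-contig mean depth by counting every covered base of every
    primary mapped record individually."""
    counts = {cid: [0] * length for cid, length in contig_lengths.items()}
    for rec in records:
        if not (rec.is_primary and rec.is_mapped):
            continue
        for start, end in rec.reference_consumed_intervals:
            for base in range(start, end):
                counts[rec.contig_id][base] += 1
    return {
        cid: (sum(bases) / len(bases) if bases else 0.0)
        for cid, bases in counts.items()
    }


def random_alignment_set(rng, n_contigs=4, n_records=30, max_len=60):
    """A toy set of AlignmentRecords with random multi-block intervals."""
    lengths = {f"c{i}": rng.randint(20, max_len) for i in range(n_contigs)}
    records = []
    for j in range(n_records):
        cid = rng.choice(sorted(lengths))
        clen = lengths[cid]
        intervals = []
        cursor = rng.randint(0, clen - 1)
        for _ in range(rng.randint(1, 3)):
            if cursor >= clen:
                break
            span = rng.randint(1, max(1, min(10, clen - cursor)))
            intervals.append((cursor, cursor + span))
            cursor += span + rng.randint(1, 5)
        records.append(
            AlignmentRecord(
                read_id=f"r{j}",
                contig_id=cid,
                is_mapped=True,
                is_primary=rng.random() > 0.1,
                reference_consumed_intervals=tuple(intervals),
            )
        )
    # a few unmapped records
    for j in range(rng.randint(0, 4)):
        records.append(
            AlignmentRecord(
                read_id=f"u{j}", contig_id=None, is_mapped=False,
                is_primary=True, reference_consumed_intervals=(),
            )
        )
    return records, lengths


# --- taxonomy --------------------------------------------------------------

def brute_force_rank_name(tree, taxid, rank):
    """Enumerate the full ancestor-or-self chain and scan it for the rank."""
    if taxid not in tree.nodes:
        return "unresolved"
    chain = []
    node = taxid
    while True:
        chain.append(node)
        parent = tree.nodes[node][0]
        if parent == node:
            break
        node = parent
    for node in chain:
        _, node_rank, name = tree.nodes[node]
        if node_rank == rank:
            return name
    return "unresolved"


def random_tree(rng, n_nodes, ranks):
    """Random rooted tree over taxids 1..n with random rank labels."""
    from tagcplot.taxonomy import TaxonomyTree

    tree = TaxonomyTree()
    tree.add_node(1, 1, "no rank", "root")
    for taxid in range(2, n_nodes + 1):
        parent = rng.randint(1, taxid - 1)
        rank = rng.choice(list(ranks) + ["no rank", "clade"])
        tree.add_node(taxid, parent, rank, f"taxon{taxid}")
    tree.validate()
    return tree


# --- ellipse geometry ------------------------------------------------------

def point_in_ellipse_oracle(center, axes, rotation, x, y):
    """Apply the inverse affine transform explicitly via a 2x2 rotation
    matrix, then the canonical ellipse inequality."""
    cx, cy = center
    a, b = axes
    cos_t = math.cos(rotation)
    sin_t = math.sin(rotation)
    dx, dy = x - cx, y - cy
    # rotate by -rotation: R(-t) = [[cos t, sin t], [-sin t, cos t]]
    u = cos_t * dx + sin_t * dy
    v = -sin_t * dx + cos_t * dy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


# --- assembly stats --------------------------------------------------------

def brute_force_n50(lengths):
    """Definition oracle: descending cumulative sum, first length
    reaching half the span."""
    if not lengths:
        return 0
    span = sum(lengths)
    total = 0
    for length in sorted(lengths, reverse=True):
        total += length
        if total >= span / 2:
            return length
    raise AssertionError("unreachable")
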