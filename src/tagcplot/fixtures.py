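"""Seeded synthetic-data generator with known ground truth.

Produces every input the pipeline consumes — assembly FASTA, per-library
SAM, paired FASTQ, a best-hit table and a miniature taxdump — for a
mixture of genomes with controlled GC, size and read depth. Alignments
are emitted directly from the known simulation coordinates (no mapper is
run), keeping tests hermetic; users wanting realistic alignments can map
the emitted FASTQ with any aligner instead.

Reads are error-free by default; an optional uniform substitution rate
exists but coverage/GC logic does not depend on errors. The mini taxdump
uses small fixed taxids rather than real NCBI ids so fixtures are
self-describing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from tagcplot.formats_io import (
    BlastHit,
    ContigSeq,
    FastqRecord,
    write_fasta,
    write_fastq,
    write_taxdump,
)
from tagcplot.taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomeSpec:
    """One genome in the simulated mixture."""

    label: str
    planted_order: str
    planted_taxid: int
    size: int
    gc: float
    target_depth: float
    n_contigs: int

    def __post_init__(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if self.size < self.n_contigs * 500:
            raise ValueError(
                f"genome {self.label!r}: size {self.size} too small for "
                f"{self.n_contigs} contigs (need >= {self.n_contigs * 500})"
            )


@dataclass
class SimulatedLibrary:
    """One read library: synchronized FASTQ mates plus SAM lines."""

    label: str
    fastq1: List[FastqRecord] = field(default_factory=list)
    fastq2: List[FastqRecord] = field(default_factory=list)
    sam_lines: List[str] = field(default_factory=list)
    #: normalized read id -> source genome label ("unmapped" for spike-ins)
    read_truth: Dict[str, str] = field(default_factory=dict)


@dataclass
class FixtureBundle:
    """Everything the pipeline needs, with per-contig/per-read truth."""

    contigs: List[ContigSeq]
    contig_lengths: Dict[str, int]
    libraries: List[SimulatedLibrary]
    hits: List[BlastHit]
    tree: TaxonomyTree
    truth_contigs: Dict[str, str]  # contig id -> genome label
    genome_specs: List[GenomeSpec]

    def read_truth(self) -> Dict[str, str]:
        merged: Dict[str, str] = {}
        for lib in self.libraries:
            merged.update(lib.read_truth)
        return merged

    def write(self, outdir) -> Dict[str, Path]:
        """Write the bundle as plain-text files; returns path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}

        paths["assembly"] = outdir / "assembly.fasta"
        write_fasta(self.contigs, paths["assembly"])

        header = sam_header(self.contig_lengths)
        for lib in self.libraries:
            sam = outdir / f"{lib.label}.sam"
            with open(sam, "w") as fh:
                fh.write(header)
                fh.write("\n".join(lib.sam_lines))
                if lib.sam_lines:
                    fh.write("\n")
            paths[f"sam_{lib.label}"] = sam
            f1 = outdir / f"{lib.label}_1.fastq"
            f2 = outdir / f"{lib.label}_2.fastq"
            write_fastq(lib.fastq1, f1)
            write_fastq(lib.fastq2, f2)
            paths[f"fastq1_{lib.label}"] = f1
            paths[f"fastq2_{lib.label}"] = f2

        paths["hits"] = outdir / "hits.tsv"
        with open(paths["hits"], "w") as fh:
            for hit in self.hits:
                taxids = ";".join(str(t) for t in hit.taxids)
                fh.write(f"{hit.query_id}\t{taxids}\n")

        paths["nodes"] = outdir / "nodes.dmp"
        paths["names"] = outdir / "names.dmp"
        write_taxdump(self.tree, paths["nodes"], paths["names"])

        paths["truth"] = outdir / "truth.tsv"
        with open(paths["truth"], "w") as fh:
            fh.write("contig_id\tgenome_label\n")
            for cid, label in self.truth_contigs.items():
                fh.write(f"{cid}\t{label}\n")
        return paths


def sam_header(contig_lengths: Dict[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for cid, length in contig_lengths.items():
        lines.append(f"@SQ\tSN:{cid}\tLN:{length}")
    return "\n".join(lines) + "\n"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_genome(spec: GenomeSpec, seed: int) -> List[ContigSeq]:
    """i.i.d. bases with P(G)+P(C)=gc split equally and P(A)=P(T), cut
    into n_contigs near-equal contigs named ``<label>_c<k>``."""
    rng = np.random.default_rng(seed)
    p_gc = spec.gc / 2.0
    p_at = (1.0 - spec.gc) / 2.0
    draw = rng.choice(_BASES, size=spec.size, p=[p_at, p_gc, p_gc, p_at])
    sequence = draw.tobytes().decode("ascii")
    bounds = np.linspace(0, spec.size, spec.n_contigs + 1).astype(int)
    contigs = []
    for k in range(spec.n_contigs):
        residues = sequence[bounds[k]: bounds[k + 1]]
        contigs.append(ContigSeq(id=f"{spec.label}_c{k + 1}", residues=residues))
    return contigs


def simulate_reads_and_alignments(
    contigs: List[ContigSeq],
    depth: float,
    seed: int,
    read_len: int = 100,
    insert: int = 300,
    id_prefix: str = "r",
    error_rate: float = 0.0,
) -> SimulatedLibrary:
    """Uniformly sample error-free read pairs and emit matching SAM lines.

    Fragments of length ``insert`` start uniformly on each contig; mate 1
    copies the fragment start (forward), mate 2 the fragment end (reverse
    complemented in FASTQ). SAM lines are written directly from the known
    coordinates. Contigs shorter than the insert are skipped with a
    warning.
    """
    if insert < 2 * read_len:
        raise ValueError("insert must be >= 2 * read_len")
    rng = np.random.default_rng(seed)
    lib = SimulatedLibrary(label=id_prefix)
    for contig in contigs:
        length = len(contig)
        if length < insert:
            logger.warning(
                "contig %s (len %d) shorter than insert %d; skipped",
                contig.id, length, insert,
            )
            continue
        n_pairs = int(round(depth * length / (2 * read_len)))
        starts = np.sort(rng.integers(0, length - insert + 1, size=n_pairs))
        for i, start in enumerate(starts):
            start = int(start)
            rid = f"{id_prefix}_{contig.id}_{i}"
            seq1 = contig.residues[start: start + read_len]
            pos2 = start + insert - read_len
            seq2_fwd = contig.residues[pos2: pos2 + read_len]
            if error_rate > 0:
                seq1 = _mutate(seq1, error_rate, rng)
                seq2_fwd = _mutate(seq2_fwd, error_rate, rng)
            qual = "I" * read_len
            lib.fastq1.append((f"{rid}/1", seq1, qual))
            lib.fastq2.append((f"{rid}/2", revcomp(seq2_fwd), qual))
            # flags: 99 = paired,proper,mate-reverse,first; 147 = paired,proper,reverse,second
            lib.sam_lines.append(
                f"{rid}\t99\t{contig.id}\t{start + 1}\t60\t{read_len}M\t=\t"
                f"{pos2 + 1}\t{insert}\t{seq1}\t{qual}"
            )
            lib.sam_lines.append(
                f"{rid}\t147\t{contig.id}\t{pos2 + 1}\t60\t{read_len}M\t=\t"
                f"{start + 1}\t{-insert}\t{seq2_fwd}\t{qual}"
            )
            lib.read_truth[rid] = contig.id
    return lib


def add_unmapped_pairs(
    lib: SimulatedLibrary, n_pairs: int, seed: int, read_len: int = 100
) -> None:
    """Append random unmapped spike-in pairs (flags 77/141) to a library."""
    rng = np.random.default_rng(seed)
    for i in range(n_pairs):
        rid = f"{lib.label}_unmapped_{i}"
        seqs = []
        for _ in range(2):
            draw = rng.choice(_BASES, size=read_len, p=[0.25, 0.25, 0.25, 0.25])
            seqs.append(draw.tobytes().decode("ascii"))
        qual = "I" * read_len
        lib.fastq1.append((f"{rid}/1", seqs[0], qual))
        lib.fastq2.append((f"{rid}/2", seqs[1], qual))
        lib.sam_lines.append(f"{rid}\t77\t*\t0\t0\t*\t*\t0\t0\t{seqs[0]}\t{qual}")
        lib.sam_lines.append(f"{rid}\t141\t*\t0\t0\t*\t*\t0\t0\t{seqs[1]}\t{qual}")
        lib.read_truth[rid] = "unmapped"


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    arr[hit] = rng.choice(_BASES, size=int(hit.sum()))
    return arr.tobytes().decode("ascii")


def mini_taxdump() -> TaxonomyTree:
    """root -> two superkingdoms -> phyla -> orders -> species, small
    fixed taxids."""
    tree = TaxonomyTree()
    rows = [
        (1, 1, "no rank", "root"),
        (2, 1, "superkingdom", "Eukaryota"),
        (3, 1, "superkingdom", "Bacteria"),
        (4, 2, "phylum", "Nematoda"),
        (5, 3, "phylum", "Proteobacteria"),
        (6, 3, "phylum", "Actinobacteria"),
        (10, 4, "order", "Rhabditida"),
        (11, 5, "order", "Pseudomonadales"),
        (12, 6, "order", "Actinomycetales"),
        (20, 10, "species", "Caenorhabditis simtest"),
        (21, 11, "species", "Pseudomonas simtest"),
        (22, 12, "species", "Mycobacterium simtest"),
    ]
    for taxid, parent, rank, name in rows:
        tree.add_node(taxid, parent, rank, name)
    tree.validate()
    return tree


STANDARD_SPECS: Tuple[GenomeSpec, ...] = (
    GenomeSpec("target", "Rhabditida", 20, 120_000, 0.40, 100.0, 6),
    GenomeSpec("contamA", "Pseudomonadales", 21, 40_000, 0.62, 10.0, 4),
    GenomeSpec("contamB", "Actinomycetales", 22, 40_000, 0.66, 200.0, 4),
)


def make_standard_fixture(
    seed: int,
    specs: Optional[Tuple[GenomeSpec, ...]] = None,
    n_libraries: int = 2,
    unannotated_target_fraction: float = 0.10,
    read_len: int = 100,
    insert: int = 300,
) -> FixtureBundle:
    """Three-genome mixture: a mid-GC high-coverage target plus a low-
    coverage and a very-high-coverage high-GC bacterial contaminant.

    Depth is split evenly across ``n_libraries`` read libraries. A
    fraction of target contigs receives no database hit, emulating the
    gray unannotated points of real plots.
    """
    specs = specs if specs is not None else STANDARD_SPECS
    root_rng = np.random.default_rng(seed)
    sub_seeds = root_rng.integers(0, 2**31 - 1, size=1000)
    seed_iter = iter(int(s) for s in sub_seeds)

    contigs: List[ContigSeq] = []
    truth_contigs: Dict[str, str] = {}
    per_genome_contigs: Dict[str, List[ContigSeq]] = {}
    for spec in specs:
        genome_contigs = simulate_genome(spec, next(seed_iter))
        per_genome_contigs[spec.label] = genome_contigs
        contigs.extend(genome_contigs)
        for contig in genome_contigs:
            truth_contigs[contig.id] = spec.label

    libraries: List[SimulatedLibrary] = []
    for k in range(n_libraries):
        label = f"lib{k + 1}"
        lib = SimulatedLibrary(label=label)
        for spec in specs:
            part = simulate_reads_and_alignments(
                per_genome_contigs[spec.label],
                depth=spec.target_depth / n_libraries,
                seed=next(seed_iter),
                read_len=read_len,
                insert=insert,
                id_prefix=f"{label}_{spec.label}",
            )
            lib.fastq1.extend(part.fastq1)
            lib.fastq2.extend(part.fastq2)
            lib.sam_lines.extend(part.sam_lines)
            for rid in part.read_truth:
                lib.read_truth[rid] = spec.label
        libraries.append(lib)

    hits: List[BlastHit] = []
    rank = 0
    target_label = specs[0].label
    target_ids = [c.id for c in per_genome_contigs[target_label]]
    n_skip = int(round(unannotated_target_fraction * len(target_ids)))
    skip_rng = np.random.default_rng(next(seed_iter))
    skipped = set(
        skip_rng.choice(target_ids, size=n_skip, replace=False)
    ) if n_skip else set()
    for spec in specs:
        for contig in per_genome_contigs[spec.label]:
            if contig.id in skipped:
                continue
            hits.append(
                BlastHit(query_id=contig.id, taxids=(spec.planted_taxid,),
                         file_rank=rank)
            )
            rank += 1

    return FixtureBundle(
        contigs=contigs,
        contig_lengths={c.id: len(c) for c in contigs},
        libraries=libraries,
        hits=hits,
        tree=mini_taxdump(),
        truth_contigs=truth_contigs,
        genome_specs=list(specs),
    )
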