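"""Readers and writers for every external format the pipeline touches.

FASTA / FASTQ / SAM-BAM / BLAST+ tabular hits / NCBI-style taxdump /
the TAGC TSV table. All readers present clean streams of domain records;
coordinates are 0-based half-open internally (SAM positions converted on
read). Plain and gzip-compressed text inputs are both accepted.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, IO, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import pysam

from tagcplot.errors import FormatError, StructuralError
from tagcplot.taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# mate roles on AlignmentRecord
FIRST_IN_PAIR = "first"
SECOND_IN_PAIR = "second"
UNPAIRED = "unpaired"


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigSeq:
    """A named assembly sequence (id = FASTA header up to first whitespace)."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-contig alignment, reduced to what depth/binning need.

    ``reference_consumed_intervals`` holds sorted, non-overlapping
    0-based half-open intervals on the contig covered by the alignment's
    match/mismatch cigar operations (M, =, X). Deletions and skips
    consume reference but carry no read base, so they are excluded.
    """

    read_id: str
    contig_id: Optional[str]
    is_mapped: bool
    is_primary: bool
    reference_consumed_intervals: Tuple[Tuple[int, int], ...]
    mate_role: str = UNPAIRED

    @property
    def aligned_ref_bases(self) -> int:
        return sum(e - s for s, e in self.reference_consumed_intervals)


@dataclass(frozen=True)
class BlastHit:
    """One row of a BLAST+ tabular hit file (qseqid staxids [evalue bitscore])."""

    query_id: str
    taxids: Tuple[int, ...]
    evalue: Optional[float] = None
    bitscore: Optional[float] = None
    file_rank: int = 0


@dataclass
class TagcRow:
    seqid: str
    length: int
    gc: float
    coverages: Dict[str, float]
    taxa: Dict[str, str]


@dataclass
class TagcTable:
    """The pipeline's central artifact: one row per contig.

    All rows share the same ordered library and rank labels; seqids are
    unique.
    """

    rows: List[TagcRow] = field(default_factory=list)
    library_labels: List[str] = field(default_factory=list)
    rank_labels: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def seqids(self) -> List[str]:
        return [r.seqid for r in self.rows]

    def validate(self) -> None:
        seen = set()
        for row in self.rows:
            if row.seqid in seen:
                raise StructuralError(f"duplicate seqid {row.seqid!r}")
            seen.add(row.seqid)
            if list(row.coverages) != self.library_labels:
                raise StructuralError(
                    f"row {row.seqid!r} library labels differ from table's"
                )
            if list(row.taxa) != self.rank_labels:
                raise StructuralError(
                    f"row {row.seqid!r} rank labels differ from table's"
                )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


_PAIR_SUFFIX = re.compile(r"/[12]$")


def normalize_read_id(read_id: str) -> str:
    """Canonical id shared by both mates of a pair.

    Strips any whitespace-delimited comment and a trailing ``/1`` or
    ``/2`` mate suffix.
    """
    head = read_id.split(None, 1)[0]
    return _PAIR_SUFFIX.sub("", head)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> Iterator[ContigSeq]:
    """Yield contigs in file order; ids truncated at first whitespace,
    residues uppercased."""
    header: Optional[str] = None
    chunks: List[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield _fasta_record(header, chunks, lineno)
                header = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence before first '>' header at line {lineno}"
                    )
                chunks.append(line)
        if header is not None:
            yield _fasta_record(header, chunks, lineno)


def _fasta_record(header: str, chunks: List[str], lineno: int) -> ContigSeq:
    residues = "".join(chunks).upper()
    if not residues:
        raise FormatError(f"empty sequence for record {header!r} near line {lineno}")
    return ContigSeq(id=header, residues=residues)


def write_fasta(contigs: Iterable[ContigSeq], path: PathLike, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for contig in contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, len(contig.residues), width):
                fh.write(contig.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------

# cigar ops that consume the reference (per the SAM spec)
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M D N = X
# ops contributing read support to depth
_MATCH_OPS = {0, 7, 8}  # M = X


def cigar_reference_intervals(
    pos: int, cigartuples: Sequence[Tuple[int, int]]
) -> Tuple[Tuple[int, int], ...]:
    """Reference intervals covered by match/mismatch ops of a cigar.

    ``pos`` is the 0-based leftmost reference coordinate. Adjacent match
    blocks are merged; deletions/skips advance the cursor but add no
    interval.
    """
    intervals: List[Tuple[int, int]] = []
    cursor = pos
    for op, length in cigartuples:
        if op in _MATCH_OPS:
            if intervals and intervals[-1][1] == cursor:
                intervals[-1] = (intervals[-1][0], cursor + length)
            else:
                intervals.append((cursor, cursor + length))
            cursor += length
        elif op in _REF_CONSUMING:
            cursor += length
    return tuple(intervals)


def read_alignments(path: PathLike) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM or BAM file.

    Secondary/supplementary alignments are flagged not-primary; mapped
    records lacking a cigar are skipped (warning logged with a running
    count). A mapped record naming a reference absent from the header is
    a format error.

    SAM text is parsed directly (pysam's SAM parser silently demotes
    both pathologies above to unmapped records, erasing the distinction
    this contract requires); BAM goes through pysam.
    """
    if str(path).endswith(".bam"):
        yield from _read_bam(path)
    else:
        yield from _read_sam_text(path)


def _mate_role(flag: int) -> str:
    if flag & 0x1:
        return FIRST_IN_PAIR if flag & 0x40 else SECOND_IN_PAIR
    return UNPAIRED


_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_OP_NUM = {op: i for i, op in enumerate("MIDNSHP=X")}


def _parse_cigar(text: str) -> List[Tuple[int, int]]:
    tokens = _CIGAR_TOKEN.findall(text)
    if "".join(f"{n}{op}" for n, op in tokens) != text:
        raise ValueError(f"bad cigar {text!r}")
    return [(_CIGAR_OP_NUM[op], int(n)) for n, op in tokens]


def _read_sam_text(path: PathLike) -> Iterator[AlignmentRecord]:
    skipped = 0
    references: Dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    tags = dict(
                        f.split(":", 1) for f in line.split("\t")[1:] if ":" in f
                    )
                    if "SN" in tags:
                        references[tags["SN"]] = int(tags.get("LN", 0))
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 11 SAM columns, got {len(fields)}"
                )
            read_id, flag_s, rname, pos_s, _, cigar = fields[:6]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            role = _mate_role(flag)
            primary = not (flag & 0x100 or flag & 0x800)
            if flag & 0x4:
                yield AlignmentRecord(
                    read_id=read_id, contig_id=None, is_mapped=False,
                    is_primary=primary, reference_consumed_intervals=(),
                    mate_role=role,
                )
                continue
            if rname not in references:
                raise FormatError(
                    f"{path}:{lineno}: reference {rname!r} absent from header"
                )
            if cigar == "*":
                skipped += 1
                logger.warning(
                    "%s:%d: mapped record %r has no cigar; skipped (%d so far)",
                    path, lineno, read_id, skipped,
                )
                continue
            try:
                cigartuples = _parse_cigar(cigar)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            yield AlignmentRecord(
                read_id=read_id,
                contig_id=rname,
                is_mapped=True,
                is_primary=primary,
                reference_consumed_intervals=cigar_reference_intervals(
                    pos - 1, cigartuples
                ),
                mate_role=role,
            )


def _read_bam(path: PathLike) -> Iterator[AlignmentRecord]:
    skipped = 0
    try:
        afile = pysam.AlignmentFile(str(path), "rb", require_index=False,
                                    check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot open alignments: {exc}") from exc
    with afile:
        try:
            for aln in afile:
                role = _mate_role(aln.flag)
                primary = not (aln.is_secondary or aln.is_supplementary)
                if aln.is_unmapped:
                    yield AlignmentRecord(
                        read_id=aln.query_name, contig_id=None,
                        is_mapped=False, is_primary=primary,
                        reference_consumed_intervals=(), mate_role=role,
                    )
                    continue
                if aln.cigartuples is None:
                    skipped += 1
                    logger.warning(
                        "%s: mapped record %r has no cigar; skipped (%d so far)",
                        path, aln.query_name, skipped,
                    )
                    continue
                yield AlignmentRecord(
                    read_id=aln.query_name,
                    contig_id=aln.reference_name,
                    is_mapped=True,
                    is_primary=primary,
                    reference_consumed_intervals=cigar_reference_intervals(
                        aln.reference_start, aln.cigartuples
                    ),
                    mate_role=role,
                )
        except ValueError as exc:
            raise FormatError(f"{path}: malformed alignment data: {exc}") from exc


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------

def read_hits(path: PathLike) -> Iterator[BlastHit]:
    """Stream hits from a tab-separated file: qseqid, ';'-joined staxids,
    and optionally evalue and bitscore in columns 3-4."""
    with _open_text(path) as fh:
        rank = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            try:
                taxids = tuple(int(tok) for tok in fields[1].split(";") if tok)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer taxid in {fields[1]!r}"
                ) from exc
            if not taxids:
                raise FormatError(f"{path}:{lineno}: empty taxid field")
            evalue = bitscore = None
            try:
                if len(fields) >= 3 and fields[2] != "":
                    evalue = float(fields[2])
                if len(fields) >= 4 and fields[3] != "":
                    bitscore = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad numeric field: {exc}") from exc
            if evalue is not None and evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative evalue {evalue}")
            yield BlastHit(
                query_id=fields[0],
                taxids=taxids,
                evalue=evalue,
                bitscore=bitscore,
                file_rank=rank,
            )
            rank += 1


# ---------------------------------------------------------------------------
# NCBI taxdump
# ---------------------------------------------------------------------------

def _split_dmp(line: str) -> List[str]:
    # fields separated by "\t|\t" with trailing "\t|"
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def read_taxdump(nodes_path: PathLike, names_path: PathLike) -> TaxonomyTree:
    """Parse nodes.dmp/names.dmp into a validated TaxonomyTree.

    Each node's name is its scientific name when one exists, else the
    first name listed for that taxid.
    """
    names: Dict[int, str] = {}
    scientific: Dict[int, bool] = {}
    with _open_text(names_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 4:
                raise FormatError(f"{names_path}:{lineno}: expected 4 name fields")
            taxid = int(fields[0])
            name, name_class = fields[1], fields[3]
            if name_class == "scientific name":
                names[taxid] = name
                scientific[taxid] = True
            elif taxid not in names:
                names[taxid] = name
                scientific[taxid] = False

    tree = TaxonomyTree()
    with _open_text(nodes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise FormatError(f"{nodes_path}:{lineno}: expected >= 3 node fields")
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            tree.add_node(taxid, parent, rank, names.get(taxid, str(taxid)))
    tree.validate()
    return tree


def write_taxdump(tree: TaxonomyTree, nodes_path: PathLike, names_path: PathLike) -> None:
    """Write a tree back out in the nodes.dmp/names.dmp dialect."""
    with _open_text(nodes_path, "wt") as fh:
        for taxid in sorted(tree.nodes):
            parent, rank, _ = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with _open_text(names_path, "wt") as fh:
        for taxid in sorted(tree.nodes):
            name = tree.nodes[taxid][2]
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")


# ---------------------------------------------------------------------------
# TAGC TSV
# ---------------------------------------------------------------------------

COV_PREFIX = "cov_"
TAX_PREFIX = "taxlevel_"
_FIXED_COLUMNS = ("seqid", "length", "gc")


def write_tagc_tsv(table: TagcTable, path: PathLike) -> None:
    """Write the table: seqid, length, gc, cov_<lib>..., taxlevel_<rank>...

    GC is printed with 4 decimals and coverage with 3, so two successive
    write/read cycles are idempotent.
    """
    table.validate()
    header = (
        list(_FIXED_COLUMNS)
        + [COV_PREFIX + lib for lib in table.library_labels]
        + [TAX_PREFIX + rank for rank in table.rank_labels]
    )
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in table.rows:
            cells = [row.seqid, str(row.length), f"{row.gc:.4f}"]
            cells += [f"{row.coverages[lib]:.3f}" for lib in table.library_labels]
            cells += [row.taxa[rank] for rank in table.rank_labels]
            fh.write("\t".join(cells) + "\n")


def read_tagc_tsv(path: PathLike) -> TagcTable:
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        if tuple(header[:3]) != _FIXED_COLUMNS:
            raise FormatError(
                f"{path}: header must start with {_FIXED_COLUMNS}, got {header[:3]}"
            )
        libs: List[str] = []
        ranks: List[str] = []
        for col in header[3:]:
            if col.startswith(COV_PREFIX) and not ranks:
                libs.append(col[len(COV_PREFIX):])
            elif col.startswith(TAX_PREFIX):
                ranks.append(col[len(TAX_PREFIX):])
            else:
                raise FormatError(f"{path}: unknown or misplaced column {col!r}")
        table = TagcTable(library_labels=libs, rank_labels=ranks)
        n_cols = len(header)
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(cells)}"
                )
            coverages = {
                lib: float(cells[3 + i]) for i, lib in enumerate(libs)
            }
            taxa = {
                rank: cells[3 + len(libs) + i] for i, rank in enumerate(ranks)
            }
            table.rows.append(
                TagcRow(
                    seqid=cells[0],
                    length=int(cells[1]),
                    gc=float(cells[2]),
                    coverages=coverages,
                    taxa=taxa,
                )
            )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

FastqRecord = Tuple[str, str, str]  # (id, residues, qualities)


def read_fastq(path: PathLike) -> Iterator[FastqRecord]:
    """Yield (id, residues, qualities) from a 4-line-record FASTQ file."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            head = fh.readline()
            if not head:
                return
            lineno += 1
            if not head.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header, got {head!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"{path}: truncated record at line {lineno}")
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno + 2}: expected '+' separator")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}:{lineno}: sequence/quality length mismatch"
                )
            lineno += 3
            yield head[1:].rstrip("\n"), seq, qual


def read_fastq_pairs(
    path1: PathLike, path2: PathLike
) -> Iterator[Tuple[FastqRecord, FastqRecord]]:
    """Iterate two FASTQ files in lock-step, checking pair synchrony."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    for idx, (rec1, rec2) in enumerate(zip(it1, it2)):
        if normalize_read_id(rec1[0]) != normalize_read_id(rec2[0]):
            raise FormatError(
                f"pair files desynchronized at record {idx}: "
                f"{rec1[0]!r} vs {rec2[0]!r}"
            )
        yield rec1, rec2
    if next(it1, None) is not None or next(it2, None) is not None:
        raise FormatError("pair files have unequal record counts")


def write_fastq(records: Iterable[FastqRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
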