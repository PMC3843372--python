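# tagcplot

Taxon-annotated GC-coverage (TAGC, "blob") plots and binning for
contamination screening of draft assemblies.

Given a preliminary assembly, per-library read alignments and a best-hit
taxonomy table, `tagcplot` collates per-contig GC content, per-library
mean read depth and best-hit taxon labels into a single TSV; renders
GC-vs-log-coverage scatter plots colored by taxon; and bins contigs (and
the reads mapping to them, with mate rescue) so target genomes,
contaminants and symbionts can be reassembled independently.

## Inputs

- assembly contigs — FASTA (may contain N; GC is computed over
  unambiguous bases only)
- one or more alignment files — SAM or BAM, reads mapped against the
  assembly (any mapper producing SAM/BAM works)
- best-hit table — BLAST+ tabular, minimally two columns
  `qseqid staxids` (`-outfmt '6 qseqid staxids'`); optional columns 3–4
  are read as evalue and bitscore
- taxonomy — NCBI-style `nodes.dmp` / `names.dmp`
- optionally paired FASTQ for read binning

## CLI

```sh
# assembly summary (contig count, span, mean, N50), 200 bp filter
tagcplot stats assembly.fasta --min-len 200

# build the TAGC table (one cov_ column per library plus cov_total)
tagcplot tagc --assembly assembly.fasta \
    --aln lib1.bam --aln lib2.bam \
    --hits hits.tsv --taxdump taxdump_dir \
    --ranks order -o table.tagc.tsv

# plot: one pane per library, 1% legend rule, sidecar legend manifest
tagcplot plot table.tagc.tsv --rank order --format png -o blobs.png

# select contigs by taxon / GC / coverage / ellipse rules
tagcplot filter-contigs table.tagc.tsv \
    --exclude-taxa Pseudomonadales,Actinomycetales -o keep_ids.txt
tagcplot filter-contigs table.tagc.tsv --gc 0.35:0.55 \
    --cov total:20:500 -o target_ids.txt

# drop read pairs touching the listed contigs (mates rescued);
# --invert keeps only those pairs instead (e.g. a symbiont bin)
tagcplot extract-reads --ids contaminant_ids.txt --aln lib1.bam \
    --fastq R1.fastq R2.fastq -o cleaned

# seeded synthetic fixture bundle with ground truth
tagcplot simulate --preset standard --seed 1 -o fixture_dir
```

All randomized steps (`--subsample`, `simulate`) take an explicit
`--seed` and are fully reproducible; logs go to stderr.

## Python API

The CLI is a thin layer over importable modules:

| module | contents |
|---|---|
| `tagcplot.formats_io` | FASTA/FASTQ/SAM/BAM/hits/taxdump/TAGC-TSV readers and writers |
| `tagcplot.contig_stats` | GC fraction, min-length filter, span/mean/N50 summary |
| `tagcplot.coverage` | per-contig mean depth, mapped fraction, library merging |
| `tagcplot.taxonomy` | best-hit resolution, lineage walks, rank rollup |
| `tagcplot.tagc_builder` | table collation, subsampling, legend rule, relative molarity |
| `tagcplot.selection_binning` | keep/exclude rules, rotated ellipses, conservative discard, mate-rescued read sets, FASTQ filtering |
| `tagcplot.plotting` | PNG/SVG rendering plus machine-readable legend manifest |
| `tagcplot.fixtures` | seeded genome/read/alignment simulator with truth tables |

Notes on semantics:

- coverage counts aligned read **bases** per reference base (cigar
  M/=/X only, primary alignments only, no dedup);
- GC excludes N and other ambiguity codes from numerator and
  denominator;
- N50 is the length-weighted median (first length whose descending
  cumulative sum reaches half the span);
- the legend threshold compares each taxon's contig count against the
  number of *annotated* contigs (taxa exactly at the threshold are
  shown);
- read binning is pair-closed: if either mate maps to a selected
  contig, the whole pair moves together.

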