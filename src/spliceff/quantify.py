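"""Read counting, CPM, and intron retention levels per sample.

The retention level of an intron is the number of reads aligned within the
predicted intron divided by the number of reads aligned to the
corresponding transcript. "Aligned to the intron" means an aligned block
overlaps the intron by at least ``min_overlap`` nt (default 1); reads whose
N gap exactly matches the intron are junction evidence for the spliced
isoform and are counted separately, never as intron reads. "Aligned to the
transcript" means any block overlaps the transcript's genomic span (exons
plus introns), so retained-intron reads stay in the denominator and IR
cannot exceed 1. Read strand is ignored (unstranded libraries assumed).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genome import GenomeModel

logger = logging.getLogger(__name__)

#: CIGAR ops that consume the reference within an aligned block
_BLOCK_OPS = {0, 2, 7, 8}  # M, D, =, X
_SKIP_OP = 3  # N
_QUERY_ONLY_OPS = {1, 4, 5, 6}  # I, S, H, P


@dataclass
class ReadAlignment:
    """A read's aligned blocks and N-skip gaps on the reference."""

    read_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    gaps: list[tuple[int, int]]
    mapq: int = 255

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


def _blocks_from_cigar(pos: int, cigartuples) -> tuple[list, list]:
    blocks, gaps = [], []
    cur = pos
    block_start = pos
    open_block = False
    for op, length in cigartuples:
        if op in _BLOCK_OPS:
            if not open_block:
                block_start = cur
                open_block = True
            cur += length
        elif op == _SKIP_OP:
            if open_block:
                blocks.append((block_start, cur))
                open_block = False
            gaps.append((cur, cur + length))
            cur += length
        elif op in _QUERY_ONLY_OPS:
            continue
        else:
            raise ValueError(f"malformed CIGAR op {op}")
    if open_block:
        blocks.append((block_start, cur))
    if not blocks:
        raise ValueError("alignment with no reference-consuming blocks")
    return blocks, gaps


def iter_alignments(sam_path: str | Path, min_mapq: int = 0) -> Iterator[ReadAlignment]:
    """Parse SAM/BAM records into block/gap form; unmapped reads skipped."""
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.cigartuples is None:
                continue
            if read.mapping_quality < min_mapq:
                continue
            blocks, gaps = _blocks_from_cigar(read.reference_start, read.cigartuples)
            yield ReadAlignment(
                read_id=read.query_name,
                chrom=read.reference_name,
                blocks=blocks,
                gaps=gaps,
                mapq=read.mapping_quality,
            )


@dataclass
class CountTable:
    """Per-sample read counts over transcripts, genes and catalog introns."""

    sample_id: str
    transcript: dict[str, int] = field(default_factory=dict)
    gene: dict[str, int] = field(default_factory=dict)
    intron: dict[str, int] = field(default_factory=dict)  # intron-overlap reads
    junction: dict[str, int] = field(default_factory=dict)  # exact N-gap matches
    intron_transcript: dict[str, int] = field(default_factory=dict)  # denominator
    library_size: int = 0
    n_unknown_chrom: int = 0


class _ModelIndex:
    """Interval lookups over a genome model, built once and cached."""

    def __init__(self, model: GenomeModel):
        self.model = model
        self.tx_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.intron_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.junction_map: dict[tuple[str, int, int], str] = {}
        self.tx_gene: dict[str, str] = {}
        self.catalog = model.intron_catalog()
        for gene in model.genes:
            for tx in gene.transcripts:
                lo, hi = tx.span
                self.tx_trees[tx.chrom].addi(lo, hi, tx.transcript_id)
                self.tx_gene[tx.transcript_id] = gene.gene_id
        for intron in self.catalog:
            self.intron_trees[intron.chrom].addi(intron.start, intron.end, intron)
            self.junction_map[(intron.chrom, intron.start, intron.end)] = intron.intron_id
        # catalog entries grouped by member transcript, for denominator counts
        self.tx_introns: dict[str, list[str]] = defaultdict(list)
        for intron in self.catalog:
            for tid in intron.transcript_ids:
                self.tx_introns[tid].append(intron.intron_id)


_INDEX_CACHE: dict[int, _ModelIndex] = {}


def _index_for(model: GenomeModel) -> _ModelIndex:
    key = id(model)
    if key not in _INDEX_CACHE:
        _INDEX_CACHE.clear()  # keep at most one model indexed
        _INDEX_CACHE[key] = _ModelIndex(model)
    return _INDEX_CACHE[key]


def count_reads(
    alignments: Iterable[ReadAlignment],
    model: GenomeModel,
    min_overlap: int = 1,
    min_mapq: int = 0,
    sample_id: str = "sample",
) -> CountTable:
    """Assign reads to transcripts, introns and junctions.

    A read is assigned to a transcript when any aligned block overlaps the
    transcript's genomic span by >= ``min_overlap`` nt; it counts toward an
    intron when any block overlaps that intron likewise (once per intron,
    however many blocks overlap), and toward an intron's junction when one
    of its N gaps equals the intron interval exactly. The library size is
    the number of distinct assigned reads.
    """
    idx = _index_for(model)
    table = CountTable(sample_id=sample_id)
    tcounts: dict[str, int] = defaultdict(int)
    gcounts: dict[str, int] = defaultdict(int)
    icounts: dict[str, int] = defaultdict(int)
    jcounts: dict[str, int] = defaultdict(int)
    itx_counts: dict[str, int] = defaultdict(int)

    for aln in alignments:
        if aln.mapq < min_mapq:
            continue
        if aln.chrom not in model.chromosomes:
            table.n_unknown_chrom += 1
            continue
        tx_tree = idx.tx_trees.get(aln.chrom)
        assigned: set[str] = set()
        if tx_tree is not None:
            for lo, hi in aln.blocks:
                for iv in tx_tree.overlap(lo, hi):
                    if min(hi, iv.end) - max(lo, iv.begin) >= min_overlap:
                        assigned.add(iv.data)
        if not assigned:
            continue
        table.library_size += 1
        genes_hit = set()
        for tid in assigned:
            tcounts[tid] += 1
            genes_hit.add(idx.tx_gene[tid])
        for gid in genes_hit:
            gcounts[gid] += 1
        # denominator for each catalog intron whose transcripts got this read
        introns_hit: set[str] = set()
        for tid in assigned:
            introns_hit.update(idx.tx_introns.get(tid, ()))
        for iid in introns_hit:
            itx_counts[iid] += 1
        intron_tree = idx.intron_trees.get(aln.chrom)
        if intron_tree is not None:
            overlapped: set[str] = set()
            for lo, hi in aln.blocks:
                for iv in intron_tree.overlap(lo, hi):
                    if min(hi, iv.end) - max(lo, iv.begin) >= min_overlap:
                        overlapped.add(iv.data.intron_id)
            for iid in overlapped:
                icounts[iid] += 1
        for gap in aln.gaps:
            iid = idx.junction_map.get((aln.chrom, gap[0], gap[1]))
            if iid is not None:
                jcounts[iid] += 1

    if table.n_unknown_chrom:
        logger.warning(
            "%s: %d reads on unknown chromosomes skipped",
            sample_id, table.n_unknown_chrom,
        )
    table.transcript = dict(tcounts)
    table.gene = dict(gcounts)
    table.intron = dict(icounts)
    table.junction = dict(jcounts)
    table.intron_transcript = dict(itx_counts)
    return table


def count_sample(
    sam_path: str | Path,
    model: GenomeModel,
    min_overlap: int = 1,
    min_mapq: int = 0,
    sample_id: str | None = None,
) -> CountTable:
    sample_id = sample_id or Path(sam_path).stem
    return count_reads(
        iter_alignments(sam_path, min_mapq=min_mapq),
        model,
        min_overlap=min_overlap,
        min_mapq=min_mapq,
        sample_id=sample_id,
    )


def compute_cpm(table: CountTable) -> dict[str, float]:
    """Counts per million assigned reads, per gene."""
    if table.library_size < 1:
        raise ValueError(f"sample {table.sample_id}: library size is zero")
    scale = 1e6 / table.library_size
    return {gid: n * scale for gid, n in table.gene.items()}


def retention_level(
    tables: Mapping[str, CountTable],
    model: GenomeModel,
    cpm_threshold: float = 10.0,
    require_all_samples: bool = True,
) -> pd.DataFrame:
    """Per-(intron, sample) retention levels with the CPM expression filter.

    IR = n_intron / n_transcript where n_transcript counts distinct reads
    assigned to any transcript carrying the intron; IR is NaN when that
    denominator is zero. ``pass_expression`` is True when the gene's CPM
    meets the (inclusive) threshold in every sample when
    ``require_all_samples``, else in the sample at hand.
    """
    idx = _index_for(model)
    cpm_by_sample = {sid: compute_cpm(t) for sid, t in tables.items()}
    passes: dict[str, dict[str, bool]] = {
        sid: {g.gene_id: cpm.get(g.gene_id, 0.0) >= cpm_threshold for g in model.genes}
        for sid, cpm in cpm_by_sample.items()
    }
    if require_all_samples:
        all_pass = {
            g.gene_id: all(passes[sid][g.gene_id] for sid in tables)
            for g in model.genes
        }
    rows = []
    for sid, table in tables.items():
        cpm = cpm_by_sample[sid]
        for intron in idx.catalog:
            n_tx = table.intron_transcript.get(intron.intron_id, 0)
            n_in = table.intron.get(intron.intron_id, 0)
            n_j = table.junction.get(intron.intron_id, 0)
            ir = n_in / n_tx if n_tx >= 1 else float("nan")
            ok = (
                all_pass[intron.gene_id]
                if require_all_samples
                else passes[sid][intron.gene_id]
            )
            rows.append(
                {
                    "intron_id": intron.intron_id,
                    "gene_id": intron.gene_id,
                    "sample": sid,
                    "n_intron": n_in,
                    "n_junction": n_j,
                    "n_transcript": n_tx,
                    "ir": ir,
                    "cpm": cpm.get(intron.gene_id, 0.0),
                    "pass_expression": ok,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "intron_id", "gene_id", "sample", "n_intron", "n_junction",
            "n_transcript", "ir", "cpm", "pass_expression",
        ],
    )


class IsoformFraction(NamedTuple):
    fraction_retained: float
    fraction_spliced: float
    n_informative: int


def isoform_retention_fraction(
    table: CountTable, intron_id: str, min_informative: int = 10
) -> IsoformFraction | None:
    """Two-isoform PSI-like estimate for one intron from one sample.

    fraction_retained = n_intron / (n_intron + n_junction): the read-level
    fraction supporting the intron-retaining isoform; its complement
    supports the spliced isoform. Returns None below ``min_informative``
    informative reads.
    """
    n_in = table.intron.get(intron_id, 0)
    n_j = table.junction.get(intron_id, 0)
    total = n_in + n_j
    if total < min_informative:
        return None
    fr = n_in / total
    return IsoformFraction(fr, 1.0 - fr, total)


def pooled_isoform_fraction(
    tables: Mapping[str, CountTable], intron_id: str, min_informative: int = 10
) -> IsoformFraction | None:
    """Isoform fractions from counts pooled across samples."""
    n_in = sum(t.intron.get(intron_id, 0) for t in tables.values())
    n_j = sum(t.junction.get(intron_id, 0) for t in tables.values())
    total = n_in + n_j
    if total < min_informative:
        return None
    fr = n_in / total
    return IsoformFraction(fr, 1.0 - fr, total)
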