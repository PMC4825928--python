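"""Intron-aware gene models from GFF3 annotation and genome FASTA.

Genomic coordinates are converted to 0-based half-open intervals at the
single GFF3 entry point (:func:`parse_annotation`); everything downstream —
introns, splice-site windows, branch-point offsets, read alignments — uses
that convention. Introns are derived per transcript as the gaps between
consecutive exons; identical intervals implied by several transcripts of a
gene are merged into one catalog entry carrying all transcript ids.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import gffutils
import numpy as np
import pyfaidx

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> the set of bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Intron:
    """A predicted intron between two consecutive exons of a transcript.

    ``start``/``end`` are 0-based half-open genomic coordinates. ``ordinal``
    counts introns in transcription order (1-based): for a minus-strand
    transcript, ordinal 1 is the intron closest to the transcription start,
    which is the highest-coordinate intron.
    """

    intron_id: str
    ordinal: int
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_ids: tuple[str, ...]
    seq: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError(
                f"intron {self.intron_id} has length {self.length} < 4; "
                "no room for the GT..AG splice dinucleotides"
            )
        if self.ordinal < 1:
            raise ValueError(f"intron {self.intron_id}: ordinal must be >= 1")


@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    introns: list[Intron] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    @property
    def span(self) -> tuple[int, int]:
        lo = min(t.span[0] for t in self.transcripts)
        hi = max(t.span[1] for t in self.transcripts)
        return lo, hi


class GenomeModel:
    """Genes, transcripts and derived introns over a set of chromosomes."""

    def __init__(
        self,
        chromosomes: Mapping[str, int],
        genes: Sequence[Gene],
        sequences: Mapping[str, str] | pyfaidx.Fasta | None = None,
    ):
        self.chromosomes = dict(chromosomes)
        self.genes = list(genes)
        self._sequences = sequences
        self._catalog: list[Intron] | None = None

    # -- sequence access ---------------------------------------------------

    def attach_fasta(self, fasta_path: str | Path) -> None:
        self._sequences = pyfaidx.Fasta(str(fasta_path))
        for name in self._sequences.keys():
            self.chromosomes.setdefault(name, len(self._sequences[name]))

    @property
    def has_sequence(self) -> bool:
        return self._sequences is not None

    def get_seq(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand sequence of [start, end), clipped to the chromosome."""
        if self._sequences is None:
            raise ValueError("no genome sequence attached to this model")
        start = max(0, start)
        end = min(end, self.chromosomes.get(chrom, end))
        if isinstance(self._sequences, pyfaidx.Fasta):
            return str(self._sequences[chrom][start:end]).upper()
        return self._sequences[chrom][start:end].upper()

    # -- intron catalog ----------------------------------------------------

    def intron_catalog(self) -> list[Intron]:
        """Deduplicated introns ordered by (chrom, start, end, transcript_id).

        Identical intervals from several transcripts are merged into a single
        entry carrying the union of transcript ids; the id and ordinal of the
        lexicographically first transcript name the entry.
        """
        if self._catalog is not None:
            return self._catalog
        by_interval: dict[tuple[str, int, int, str], list[Intron]] = defaultdict(list)
        for gene in self.genes:
            for tx in gene.transcripts:
                for intron in tx.introns:
                    by_interval[(intron.chrom, intron.start, intron.end, intron.strand)].append(intron)
        merged = []
        for (chrom, start, end, strand), group in by_interval.items():
            group.sort(key=lambda i: i.transcript_ids[0])
            first = group[0]
            tx_ids = tuple(sorted({t for i in group for t in i.transcript_ids}))
            merged.append(
                Intron(
                    intron_id=first.intron_id,
                    ordinal=first.ordinal,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_id=first.gene_id,
                    transcript_ids=tx_ids,
                    seq=first.seq,
                )
            )
        merged.sort(key=lambda i: (i.chrom, i.start, i.end, i.transcript_ids[0]))
        self._catalog = merged
        return merged

    def catalog_stats(self) -> dict:
        """Mean intron length and the introns-per-gene distribution."""
        catalog = self.intron_catalog()
        per_gene = defaultdict(int)
        for intron in catalog:
            per_gene[intron.gene_id] += 1
        counts = [per_gene.get(g.gene_id, 0) for g in self.genes]
        return {
            "n_introns": len(catalog),
            "mean_intron_length": float(np.mean([i.length for i in catalog])) if catalog else float("nan"),
            "introns_per_gene": counts,
            "n_genes": len(self.genes),
            "n_genes_with_introns": sum(1 for c in counts if c > 0),
        }

    def intron_seq(self, intron: Intron) -> str:
        """Coding-strand sequence of the intron (reverse-complemented on '-')."""
        if intron.seq is not None:
            return intron.seq
        raw = self.get_seq(intron.chrom, intron.start, intron.end)
        return raw if intron.strand == "+" else reverse_complement(raw)


def _derive_introns(tx: Transcript, gene_id: str) -> list[Intron]:
    n = len(tx.exons)
    gaps = [(tx.exons[k][1], tx.exons[k + 1][0]) for k in range(n - 1)]
    if tx.strand == "-":
        # transcription order runs from high to low coordinates
        ordered = list(reversed(gaps))
    else:
        ordered = gaps
    introns = []
    for k, (start, end) in enumerate(ordered, start=1):
        introns.append(
            Intron(
                intron_id=f"{tx.transcript_id}.i{k}",
                ordinal=k,
                chrom=tx.chrom,
                start=start,
                end=end,
                strand=tx.strand,
                gene_id=gene_id,
                transcript_ids=(tx.transcript_id,),
            )
        )
    introns.sort(key=lambda i: i.start)
    return introns


def parse_annotation(
    gff3_path: str | Path, fasta_path: str | Path | None = None
) -> GenomeModel:
    """Parse a GFF3 annotation (and optionally a genome FASTA) into a model.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open
    here, and nowhere else. Exons extending past their chromosome bounds are
    rejected with a warning; transcripts with overlapping exons or exons
    lacking resolvable parents are hard errors.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    chrom_lengths: dict[str, int] = {}
    sequences = None
    if fasta_path is not None:
        sequences = pyfaidx.Fasta(str(fasta_path))
        chrom_lengths = {name: len(sequences[name]) for name in sequences.keys()}
    else:
        for directive in db.directives:
            if directive.startswith("sequence-region"):
                parts = directive.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])

    genes: list[Gene] = []
    for gene_feat in db.features_of_type("gene", order_by="start"):
        transcripts = []
        for tx_feat in db.children(gene_feat, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = []
            for ex in db.children(tx_feat, featuretype="exon", order_by="start"):
                start, end = ex.start - 1, ex.end  # 1-based closed -> half-open
                bound = chrom_lengths.get(ex.seqid)
                if start < 0 or (bound is not None and end > bound):
                    logger.warning(
                        "exon %s:%d-%d of %s outside chromosome bounds; record rejected",
                        ex.seqid, ex.start, ex.end, tx_feat.id,
                    )
                    continue
                exons.append((start, end))
            if not exons:
                raise ValueError(
                    f"transcript {tx_feat.id} has no usable exon children "
                    "(missing parent links or all exons rejected)"
                )
            exons.sort()
            for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"transcript {tx_feat.id} has overlapping exons "
                        f"[{s0},{e0}) and [{s1},{e1})"
                    )
            tx = Transcript(
                transcript_id=tx_feat.id,
                chrom=tx_feat.seqid,
                strand=tx_feat.strand,
                exons=exons,
            )
            tx.introns = _derive_introns(tx, gene_feat.id)
            transcripts.append(tx)
        if not transcripts:
            raise ValueError(f"gene {gene_feat.id} has no mRNA/transcript children")
        genes.append(
            Gene(
                gene_id=gene_feat.id,
                chrom=gene_feat.seqid,
                strand=gene_feat.strand,
                transcripts=transcripts,
            )
        )
    for name in {g.chrom for g in genes}:
        if name not in chrom_lengths:
            chrom_lengths[name] = max(g.span[1] for g in genes if g.chrom == name)

    return GenomeModel(chrom_lengths, genes, sequences)


# -- splice sites ----------------------------------------------------------


class SpliceSites(NamedTuple):
    five_ss: str
    three_ss: str
    clipped: bool


def extract_splice_sites(
    model: GenomeModel,
    intron: Intron,
    five_exonic: int = 3,
    five_intronic: int = 8,
    three_intronic: int = 12,
    three_exonic: int = 3,
) -> SpliceSites:
    """Coding-strand windows around the donor and acceptor sites.

    The 5'ss window is ``five_exonic`` nt of upstream exon followed by
    ``five_intronic`` nt of intron; the 3'ss window is ``three_intronic`` nt
    of intron followed by ``three_exonic`` nt of downstream exon. Windows
    exceeding the intron or the chromosome are clipped and flagged.
    """
    clipped = False
    in5 = min(five_intronic, intron.length)
    in3 = min(three_intronic, intron.length)
    if in5 < five_intronic or in3 < three_intronic:
        clipped = True

    if intron.strand == "+":
        f_lo, f_hi = intron.start - five_exonic, intron.start + in5
        t_lo, t_hi = intron.end - in3, intron.end + three_exonic
        five = model.get_seq(intron.chrom, f_lo, f_hi)
        three = model.get_seq(intron.chrom, t_lo, t_hi)
    else:
        # donor is at the genomic end of a minus-strand intron
        f_lo, f_hi = intron.end - in5, intron.end + five_exonic
        t_lo, t_hi = intron.start - three_exonic, intron.start + in3
        five = reverse_complement(model.get_seq(intron.chrom, f_lo, f_hi))
        three = reverse_complement(model.get_seq(intron.chrom, t_lo, t_hi))

    if len(five) < five_exonic + in5 or len(three) < in3 + three_exonic:
        clipped = True
    return SpliceSites(five, three, clipped)


# -- branch point scan -----------------------------------------------------


@dataclass
class BranchPointCall:
    intron_id: str
    bp_pos: int  # 0-based offset of the branch adenosine within the intron
    score: float
    found: bool


def _iupac_score(window: str, consensus: str) -> float:
    hits = sum(1 for base, code in zip(window, consensus) if base in IUPAC[code])
    return hits / len(consensus)


def find_branch_point(
    intron_seq: str,
    intron_id: str = "",
    consensus: str = "CTRAC",
    search_window: tuple[int, int] = (5, 60),
    min_score: float = 0.8,
) -> BranchPointCall:
    """Scan an intron for the best branch-point consensus match.

    ``consensus`` is an IUPAC string with exactly one literal ``A`` — the
    branch adenosine anchor, which must match exactly; the score is the
    fraction of consensus positions satisfied. ``search_window`` bounds the
    distance (in nt, 0-based offsets from each end: ``length - 1 - bp_pos``)
    from the branch A to the intron's 3' end. Ties go to the candidate
    nearest the 3'ss. ``found`` is False when no candidate reaches
    ``min_score`` or the intron is shorter than the consensus.
    """
    if consensus.count("A") != 1:
        raise ValueError("consensus must contain exactly one literal 'A' anchor")
    anchor = consensus.index("A")
    seq = intron_seq.upper()
    n = len(seq)
    if n < len(consensus):
        return BranchPointCall(intron_id, -1, 0.0, False)

    best_pos, best_score = -1, -1.0
    lo, hi = search_window
    for start in range(0, n - len(consensus) + 1):
        bp = start + anchor
        dist = n - 1 - bp
        if not (lo <= dist <= hi):
            continue
        if bp >= n - 2:  # branch A cannot sit on the terminal AG
            continue
        if seq[bp] != "A":
            continue
        score = _iupac_score(seq[start : start + len(consensus)], consensus)
        if score > best_score or (score == best_score and bp > best_pos):
            best_pos, best_score = bp, score
    if best_pos < 0 or best_score < min_score:
        return BranchPointCall(intron_id, best_pos, max(best_score, 0.0), False)
    return BranchPointCall(intron_id, best_pos, best_score, True)


# -- BED round trip --------------------------------------------------------


def write_intron_bed(catalog: Iterable[Intron], path: str | Path) -> None:
    """BED6 intron catalog: name = intron id, score = intron length."""
    with open(path, "w") as fh:
        for intron in catalog:
            fh.write(
                f"{intron.chrom}\t{intron.start}\t{intron.end}\t"
                f"{intron.intron_id}\t{intron.length}\t{intron.strand}\n"
            )


def read_intron_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            rows.append((chrom, int(start), int(end), name, int(score), strand))
    return rows
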