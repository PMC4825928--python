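"""Toy spliced genomes and read-alignment simulation with known retention.

The simulator emulates a two-condition x two-replicate RNA-seq design: each
gene carries introns with canonical GT..AG boundaries and one embedded
branch-point consensus at a recorded distance from the 3' splice site; each
intron has a true retention fraction theta per condition (the fraction of
molecules in which that intron is unspliced, near zero in the wild type and
elevated in the mutant). Reads are emitted directly as spliced SAM
alignments (M blocks, N gaps over skipped introns), so no aligner sits in
the test loop.

Sampling model: for a gene with introns I, a molecule form is a subset S of
retained introns with probability prod_{i in S} theta_i * prod_{i not in S}
(1 - theta_i); a read picks a form with probability proportional to
P(S) * (number of valid start positions on that form) and then a start
uniformly, making read density uniform per molecule nucleotide. Under this
scheme the probability that a read overlaps intron i by >= 1 nt — the
expected intron retention level — has the exact closed form computed by
:func:`expected_retention` (single intron) and
:func:`expected_retention_multi` (position enumeration over forms).
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Gene, GenomeModel, Intron, Transcript, reverse_complement

logger = logging.getLogger(__name__)

_GENES_PER_CHROM = 25
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design parameters for the toy genome and read simulation.

    Defaults follow the design under study: two conditions ("WT", "mut")
    with two replicates each; wild-type retention near zero (theta 0.02)
    and elevated, variable retention in the mutant; intron lengths centered
    near the genome-wide average of ~83 bp; per-gene expected read counts
    log-uniform over a range wide enough to span the CPM detection filter.
    """

    n_genes: int = 100
    introns_per_gene: tuple[int, int] = (0, 4)  # uniform inclusive range
    exon_len_range: tuple[int, int] = (120, 300)
    intron_len_range: tuple[int, int] = (55, 115)
    expression_range: tuple[float, float] = (0.5, 2000.0)  # expected reads/gene
    theta: Mapping[str, object] = field(
        default_factory=lambda: {
            "WT": 0.02,
            # most introns keep wild-type-level retention; the rest are
            # elevated — emulating a mutant that impairs, not abolishes,
            # splicing of a subset of introns
            "mut": {"mixture": {"p_unaffected": 0.55, "base": 0.02, "range": (0.08, 0.6)}},
        }
    )
    read_len: int = 50
    conditions: tuple[str, ...] = ("WT", "mut")
    replicates: int = 2
    bp_consensus: str = "CTRAC"
    bp_distance_range: tuple[int, int] = (7, 50)  # branch A to 3'ss, 0-based offsets
    minus_strand_fraction: float = 0.5
    gene_spacing: int = 600
    seed: int = 0

    def rng(self, *tags: str) -> np.random.Generator:
        """Deterministic generator derived from the master seed and tags."""
        entropy = [self.seed] + [zlib.crc32(t.encode()) & 0x7FFFFFFF for t in tags]
        return np.random.default_rng(entropy)


@dataclass
class _SimGene:
    gene_id: str
    chrom: str
    strand: str
    exon_lens: list[int]
    intron_lens: list[int]
    # (kind, coding_offset, length, genomic_start, genomic_end) in
    # transcription order; kind is "exon" or an intron index (0-based)
    parts: list[tuple[object, int, int, int, int]]
    intron_ids: list[str]
    expression: float


@dataclass
class ToyGenome:
    """A simulated genome: model + sequences + per-intron ground truth."""

    config: SimulationConfig
    model: GenomeModel
    sequences: dict[str, str]
    sim_genes: list[_SimGene]
    bp_truth: pd.DataFrame  # intron_id, bp_pos, dist_bp_3ss

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")
        return path

    def write_gff3(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.sequences.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for gene in self.model.genes:
                lo, hi = gene.span
                fh.write(
                    f"{gene.chrom}\tspliceff_sim\tgene\t{lo + 1}\t{hi}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}\n"
                )
                for tx in gene.transcripts:
                    fh.write(
                        f"{tx.chrom}\tspliceff_sim\tmRNA\t{tx.span[0] + 1}\t{tx.span[1]}\t.\t"
                        f"{tx.strand}\t.\tID={tx.transcript_id};Parent={gene.gene_id}\n"
                    )
                    for start, end in tx.exons:
                        fh.write(
                            f"{tx.chrom}\tspliceff_sim\texon\t{start + 1}\t{end}\t.\t"
                            f"{tx.strand}\t.\tParent={tx.transcript_id}\n"
                        )
        return path


# -- genome construction ---------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    from .genome import IUPAC

    return "".join(
        code if code in "ACGT" else str(rng.choice(list(IUPAC[code])))
        for code in consensus
    )


def _scrub_spurious_bp(seq: str, consensus: str, planted_start: int, rng: np.random.Generator) -> str:
    """Remove accidental full-score consensus matches so the planted branch
    point is the unique exact match (the intron carries one BP by design)."""
    from .genome import IUPAC

    anchor = consensus.index("A")
    width = len(consensus)
    chars = list(seq)
    for _ in range(10):  # converges fast; bounded for safety
        dirty = False
        for start in range(0, len(chars) - width + 1):
            if start == planted_start:
                continue
            window = chars[start : start + width]
            if all(b in IUPAC[c] for b, c in zip(window, consensus)):
                if planted_start <= start + anchor < planted_start + width:
                    continue  # never touch the planted site
                chars[start + anchor] = str(rng.choice(["C", "G", "T"]))
                dirty = True
        if not dirty:
            break
    return "".join(chars)


def _build_intron_seq(
    length: int, consensus: str, dist_range: tuple[int, int], rng: np.random.Generator
) -> tuple[str, int]:
    """Random GT..AG intron with one planted BP consensus; returns (seq, bp_pos)."""
    width = len(consensus)
    anchor = consensus.index("A")
    # branch A offset: distance to the 3' end within range, consensus inside
    # the interior (after GT, before AG)
    lo = max(dist_range[0], width - anchor)  # room downstream not needed; keep >= 4
    hi = min(dist_range[1], length - 1 - (2 + anchor))
    if hi < lo:
        raise ValueError(
            f"intron length {length} cannot host the BP consensus at "
            f"distance {dist_range} from the 3'ss"
        )
    dist = int(rng.integers(lo, hi + 1))
    bp_pos = length - 1 - dist
    interior = list(_random_seq(rng, length - 4))
    seq = ["G", "T"] + interior + ["A", "G"]
    start = bp_pos - anchor
    seq[start : start + width] = list(_realize_consensus(consensus, rng))
    out = _scrub_spurious_bp("".join(seq), consensus, start, rng)
    assert out[:2] == "GT" and out[-2:] == "AG"
    return out, bp_pos


def build_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Construct a random toy genome; byte-deterministic under the seed."""
    rng = config.rng("genome")
    min_spliced = config.exon_len_range[0] * (config.introns_per_gene[0] + 1)
    if config.read_len >= min_spliced:
        raise ValueError("read_len must be shorter than the shortest spliced transcript")

    chrom_parts: dict[str, list[str]] = {}
    chrom_cursor: dict[str, int] = {}
    sim_genes: list[_SimGene] = []
    genes: list[Gene] = []
    bp_rows = []

    for gi in range(config.n_genes):
        gene_id = f"g{gi:04d}"
        chrom = f"chr{gi // _GENES_PER_CHROM + 1}"
        if chrom not in chrom_parts:
            chrom_parts[chrom] = []
            chrom_cursor[chrom] = 0

        k = int(rng.integers(config.introns_per_gene[0], config.introns_per_gene[1] + 1))
        exon_lens = [int(rng.integers(*config.exon_len_range)) for _ in range(k + 1)]
        intron_lens = [int(rng.integers(*config.intron_len_range)) for _ in range(k)]
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        expression = float(
            np.exp(rng.uniform(np.log(config.expression_range[0]), np.log(config.expression_range[1])))
        )

        pieces: list[tuple[object, str]] = []  # (kind, coding-strand seq)
        bp_pos_by_intron = []
        for j in range(k + 1):
            pieces.append(("exon", _random_seq(rng, exon_lens[j])))
            if j < k:
                iseq, bp_pos = _build_intron_seq(
                    intron_lens[j], config.bp_consensus, config.bp_distance_range, rng
                )
                pieces.append((j, iseq))
                bp_pos_by_intron.append(bp_pos)

        coding = "".join(s for _, s in pieces)
        total = len(coding)
        # leading spacer, then the gene body
        spacer = _random_seq(rng, config.gene_spacing)
        gstart = chrom_cursor[chrom] + config.gene_spacing
        chrom_parts[chrom].append(spacer)
        genomic = coding if strand == "+" else reverse_complement(coding)
        chrom_parts[chrom].append(genomic)
        chrom_cursor[chrom] = gstart + total

        parts = []
        offset = 0
        for kind, s in pieces:
            ln = len(s)
            if strand == "+":
                g0, g1 = gstart + offset, gstart + offset + ln
            else:
                g0, g1 = gstart + total - offset - ln, gstart + total - offset
            parts.append((kind, offset, ln, g0, g1))
            offset += ln

        tx_id = f"{gene_id}.t1"
        exons = sorted((g0, g1) for kind, _, _, g0, g1 in parts if kind == "exon")
        tx = Transcript(transcript_id=tx_id, chrom=chrom, strand=strand, exons=exons)
        intron_ids = []
        for ordinal, (kind, _, ln, g0, g1) in enumerate(
            (p for p in parts if p[0] != "exon"), start=1
        ):
            intron = Intron(
                intron_id=f"{tx_id}.i{ordinal}",
                ordinal=ordinal,
                chrom=chrom,
                start=g0,
                end=g1,
                strand=strand,
                gene_id=gene_id,
                transcript_ids=(tx_id,),
                seq=pieces[2 * ordinal - 1][1],
            )
            tx.introns.append(intron)
            intron_ids.append(intron.intron_id)
            bp_rows.append(
                {
                    "intron_id": intron.intron_id,
                    "length": ln,
                    "bp_pos": bp_pos_by_intron[ordinal - 1],
                    "dist_bp_3ss": ln - 1 - bp_pos_by_intron[ordinal - 1],
                }
            )
        tx.introns.sort(key=lambda i: i.start)
        genes.append(Gene(gene_id=gene_id, chrom=chrom, strand=strand, transcripts=[tx]))
        sim_genes.append(
            _SimGene(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exon_lens=exon_lens,
                intron_lens=intron_lens,
                parts=parts,
                intron_ids=intron_ids,
                expression=expression,
            )
        )

    sequences = {c: "".join(parts) for c, parts in chrom_parts.items()}
    chromosomes = {c: len(s) for c, s in sequences.items()}
    model = GenomeModel(chromosomes, genes, sequences)
    bp_truth = pd.DataFrame(bp_rows, columns=["intron_id", "length", "bp_pos", "dist_bp_3ss"])
    return ToyGenome(config, model, sequences, sim_genes, bp_truth)


# -- retention truth -------------------------------------------------------


def _resolve_theta(spec: object, intron_id: str, rng: np.random.Generator) -> float:
    if isinstance(spec, Mapping) and "mixture" in spec:
        mix = spec["mixture"]
        if rng.random() < float(mix.get("p_unaffected", 0.5)):
            theta = float(mix.get("base", 0.02))
        else:
            lo, hi = mix.get("range", (0.08, 0.6))
            theta = float(rng.uniform(float(lo), float(hi)))
    elif isinstance(spec, Mapping):
        theta = float(spec[intron_id])
    elif isinstance(spec, (tuple, list)):
        theta = float(rng.uniform(spec[0], spec[1]))
    else:
        theta = float(spec)
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta {theta} for {intron_id} outside [0, 1]")
    return theta


def assign_theta(toy: ToyGenome, theta: Mapping[str, object] | None = None) -> pd.DataFrame:
    """Draw per-intron retention fractions per condition and tabulate the
    analytic expected retention level for each (intron, condition)."""
    config = toy.config
    theta = theta if theta is not None else config.theta
    rows = []
    for condition in theta.keys():
        spec = theta[condition]
        rng = config.rng("theta", condition)
        for g in toy.sim_genes:
            if not g.intron_ids:
                continue
            thetas = [_resolve_theta(spec, iid, rng) for iid in g.intron_ids]
            for idx, iid in enumerate(g.intron_ids):
                rows.append(
                    {
                        "intron_id": iid,
                        "gene_id": g.gene_id,
                        "condition": condition,
                        "theta": thetas[idx],
                        "expected_ir": expected_retention_multi(
                            g.exon_lens, g.intron_lens, thetas, config.read_len, idx
                        ),
                    }
                )
    return pd.DataFrame(
        rows, columns=["intron_id", "gene_id", "condition", "theta", "expected_ir"]
    )


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.to_csv(path, sep="\t", index=False)
    return path


def expected_retention(theta: float, intron_len: int, read_len: int, spliced_len: int) -> float:
    """Closed-form expected retention level for a single-intron transcript.

    With m = intron_len, r = read_len, Le = spliced_len, Lu = Le + m and the
    intron interior to the transcript (flanks >= r):

        E[IR] = theta*(m + r - 1) /
                [theta*(Lu - r + 1) + (1 - theta)*(Le - r + 1)]

    Returns NaN when the read does not fit on the spliced form (r > Le).
    """
    m, r, le = intron_len, read_len, spliced_len
    if r > le:
        return float("nan")
    lu = le + m
    num = theta * (m + r - 1)
    den = theta * (lu - r + 1) + (1 - theta) * (le - r + 1)
    return num / den if den > 0 else float("nan")


def expected_retention_multi(
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
    thetas: Sequence[float],
    read_len: int,
    target: int,
) -> float:
    """Expected retention level of intron ``target`` on a multi-intron
    transcript, by enumeration of molecule forms and start positions."""
    k = len(intron_lens)
    if k != len(thetas):
        raise ValueError("one theta per intron required")
    if k > 16:
        raise ValueError("form enumeration limited to 16 introns")
    r = read_len
    exon_total = sum(exon_lens)
    num = den = 0.0
    for form in itertools.product([False, True], repeat=k):
        prob = 1.0
        for inc, th in zip(form, thetas):
            prob *= th if inc else (1.0 - th)
        if prob == 0.0:
            continue
        length = exon_total + sum(m for inc, m in zip(form, intron_lens) if inc)
        n_starts = length - r + 1
        if n_starts <= 0:
            continue
        den += prob * n_starts
        if form[target]:
            # molecule offset of the target intron on this form
            a = sum(exon_lens[: target + 1]) + sum(
                m for inc, m in zip(form[:target], intron_lens[:target]) if inc
            )
            m = intron_lens[target]
            lo = max(a - r + 1, 0)
            hi = min(a + m - 1, length - r)
            if hi >= lo:
                num += prob * (hi - lo + 1)
    return num / den if den > 0 else float("nan")


# -- read simulation -------------------------------------------------------


def _form_geometry(g: _SimGene, form: tuple[bool, ...]) -> list[tuple[object, int, int, int]]:
    """Kept parts of a molecule form: (kind, mol_offset, length, part_index)."""
    kept = []
    offset = 0
    for pi, (kind, _, ln, _, _) in enumerate(g.parts):
        if kind == "exon" or form[kind]:
            kept.append((kind, offset, ln, pi))
            offset += ln
    return kept


def _read_blocks(
    g: _SimGene, kept: list[tuple[object, int, int, int]], s: int, r: int
) -> list[tuple[int, int]]:
    """Genomic intervals covered by molecule interval [s, s + r)."""
    intervals = []
    e = s + r
    for kind, off, ln, pi in kept:
        if off + ln <= s or off >= e:
            continue
        o0, o1 = max(s, off) - off, min(e, off + ln) - off
        _, _, _, g0, g1 = g.parts[pi]
        if g.strand == "+":
            intervals.append((g0 + o0, g0 + o1))
        else:
            intervals.append((g1 - o1, g1 - o0))
    intervals.sort()
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo == merged[-1][1]:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    return [tuple(b) for b in merged]


def simulate_reads(
    toy: ToyGenome,
    truth: pd.DataFrame,
    sample_id: str,
    condition: str,
    out_sam: str | Path,
) -> Path:
    """Simulate one sample's spliced alignments and write a sorted SAM.

    Deterministic under (config.seed, sample_id). Reads are perfect-match,
    MAPQ 255, single-end; skipped introns appear as CIGAR N gaps whose
    intervals exactly match the annotated introns.
    """
    config = toy.config
    rng = config.rng("reads", sample_id)
    r = config.read_len
    theta_map = (
        truth[truth["condition"] == condition].set_index("intron_id")["theta"].to_dict()
    )

    records: list[tuple[str, int, str, str, str]] = []
    for g in toy.sim_genes:
        n_reads = int(rng.poisson(g.expression))
        if n_reads == 0:
            continue
        thetas = [theta_map[iid] for iid in g.intron_ids]
        k = len(thetas)
        forms = list(itertools.product([False, True], repeat=k))
        geoms, weights, starts_per_form = [], [], []
        for form in forms:
            kept = _form_geometry(g, form)
            length = sum(ln for _, _, ln, _ in kept)
            n_starts = length - r + 1
            prob = 1.0
            for inc, th in zip(form, thetas):
                prob *= th if inc else (1.0 - th)
            if n_starts <= 0:
                if prob > 0:
                    logger.warning(
                        "gene %s: molecule form shorter than read length; skipped",
                        g.gene_id,
                    )
                geoms.append(kept)
                weights.append(0.0)
                starts_per_form.append(0)
                continue
            geoms.append(kept)
            weights.append(prob * n_starts)
            starts_per_form.append(n_starts)
        weights = np.asarray(weights)
        total = weights.sum()
        if total <= 0:
            logger.warning("gene %s: no viable molecule form; gene skipped", g.gene_id)
            continue
        form_idx = rng.choice(len(forms), size=n_reads, p=weights / total)
        chrom_seq = toy.sequences[g.chrom]
        for ri, fi in enumerate(form_idx):
            s = int(rng.integers(0, starts_per_form[fi]))
            blocks = _read_blocks(g, geoms[fi], s, r)
            cigar_parts = []
            seq_parts = []
            for bi, (lo, hi) in enumerate(blocks):
                if bi > 0:
                    cigar_parts.append(f"{lo - blocks[bi - 1][1]}N")
                cigar_parts.append(f"{hi - lo}M")
                seq_parts.append(chrom_seq[lo:hi])
            records.append(
                (
                    g.chrom,
                    blocks[0][0],
                    "".join(cigar_parts),
                    "".join(seq_parts),
                    f"{sample_id}.{g.gene_id}.{ri}",
                )
            )

    records.sort(key=lambda t: (t[0], t[1]))
    out_sam = Path(out_sam)
    out_sam.parent.mkdir(parents=True, exist_ok=True)
    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in toy.model.chromosomes.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        fh.write(f"@RG\tID:{sample_id}\n")
        for chrom, pos, cigar, seq, qname in records:
            fh.write(
                f"{qname}\t0\t{chrom}\t{pos + 1}\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )
    return out_sam


def simulate_design(
    toy: ToyGenome,
    truth: pd.DataFrame,
    out_dir: str | Path,
    suppressor_theta: Mapping[str, Mapping[str, object]] | None = None,
) -> pd.DataFrame:
    """Simulate every (condition, replicate) sample — plus optional
    single-sample suppressor conditions — and return the design sheet."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = toy.config
    rows = []
    for condition in config.conditions:
        for rep in range(1, config.replicates + 1):
            sample_id = f"{condition}_r{rep}"
            sam = simulate_reads(toy, truth, sample_id, condition, out_dir / f"{sample_id}.sam")
            rows.append(
                {"sample": sample_id, "condition": condition, "replicate": rep, "sam": str(sam)}
            )
    if suppressor_theta:
        for name, spec in suppressor_theta.items():
            extra = assign_theta(toy, {name: spec})
            sam = simulate_reads(toy, extra, name, name, out_dir / f"{name}.sam")
            rows.append({"sample": name, "condition": name, "replicate": 1, "sam": str(sam)})
    return pd.DataFrame(rows, columns=["sample", "condition", "replicate", "sam"])
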