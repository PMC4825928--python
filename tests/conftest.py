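import pytest

# Toy annotation used throughout: one 3-exon transcript whose introns are
# [100,150) and [250,330) in 0-based half-open coordinates (GFF3 exons
# 1-100, 151-250, 331-430 in 1-based closed coordinates).
TOY_GFF3_PLUS = """##gff-version 3
##sequence-region chr1 1 1000
chr1\ttoy\tgene\t1\t430\t.\t+\t.\tID=geneA
chr1\ttoy\tmRNA\t1\t430\t.\t+\t.\tID=tA;Parent=geneA
chr1\ttoy\texon\t1\t100\t.\t+\t.\tParent=tA
chr1\ttoy\texon\t151\t250\t.\t+\t.\tParent=tA
chr1\ttoy\texon\t331\t430\t.\t+\t.\tParent=tA
"""

TOY_GFF3_MINUS = TOY_GFF3_PLUS.replace("\t+\t", "\t-\t")

TOY_GFF3_SINGLE_EXON = """##gff-version 3
##sequence-region chr1 1 500
chr1\ttoy\tgene\t10\t200\t.\t+\t.\tID=geneS
chr1\ttoy\tmRNA\t10\t200\t.\t+\t.\tID=tS;Parent=geneS
chr1\ttoy\texon\t10\t200\t.\t+\t.\tParent=tS
"""


@pytest.fixture
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3_PLUS)
    return path


@pytest.fixture
def toy_model(toy_gff3):
    from spliceff.genome import parse_annotation

    return parse_annotation(toy_gff3)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A small simulated study: 25 genes, 2 conditions x 2 replicates."""
    from spliceff.simulate import (
        SimulationConfig,
        assign_theta,
        build_toy_genome,
        simulate_design,
    )

    out = tmp_path_factory.mktemp("simstudy")
    cfg = SimulationConfig(
        n_genes=25,
        introns_per_gene=(0, 3),
        expression_range=(50, 800),
        theta={"WT": 0.02, "mut": (0.1, 0.5)},
        seed=7,
    )
    toy = build_toy_genome(cfg)
    truth = assign_theta(toy)
    design = simulate_design(toy, truth, out)
    fasta = toy.write_fasta(out / "genome.fa")
    gff3 = toy.write_gff3(out / "annotation.gff3")
    return {
        "config": cfg,
        "toy": toy,
        "truth": truth,
        "design": design,
        "out": out,
        "fasta": fasta,
        "gff3": gff3,
    }
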