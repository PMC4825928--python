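"""Read counting, CPM, retention levels and the isoform estimator."""

import numpy as np
import pytest

from spliceff.quantify import (
    CountTable,
    ReadAlignment,
    compute_cpm,
    count_reads,
    count_sample,
    isoform_retention_fraction,
    retention_level,
)


def brute_counts(reads, model, min_overlap=1):
    """Independent all-pairs interval-overlap enumerator (no trees)."""
    catalog = model.intron_catalog()
    out = {
        "transcript": {}, "gene": {}, "intron": {}, "junction": {},
        "intron_transcript": {}, "library_size": 0,
    }
    for read in reads:
        if read.chrom not in model.chromosomes:
            continue
        assigned = set()
        for gene in model.genes:
            for tx in gene.transcripts:
                if tx.chrom != read.chrom:
                    continue
                lo, hi = tx.span
                for b0, b1 in read.blocks:
                    if min(hi, b1) - max(lo, b0) >= min_overlap:
                        assigned.add((gene.gene_id, tx.transcript_id))
                        break
        if not assigned:
            continue
        out["library_size"] += 1
        for gid in {g for g, _ in assigned}:
            out["gene"][gid] = out["gene"].get(gid, 0) + 1
        tx_ids = {t for _, t in assigned}
        for tid in tx_ids:
            out["transcript"][tid] = out["transcript"].get(tid, 0) + 1
        for intron in catalog:
            if intron.chrom != read.chrom:
                continue
            if tx_ids & set(intron.transcript_ids):
                out["intron_transcript"][intron.intron_id] = (
                    out["intron_transcript"].get(intron.intron_id, 0) + 1
                )
            if any(
                min(intron.end, b1) - max(intron.start, b0) >= min_overlap
                for b0, b1 in read.blocks
            ):
                out["intron"][intron.intron_id] = (
                    out["intron"].get(intron.intron_id, 0) + 1
                )
            if (intron.start, intron.end) in read.gaps:
                out["junction"][intron.intron_id] = (
                    out["junction"].get(intron.intron_id, 0) + 1
                )
    return out


class TestCountReads:
    def test_manual_three_read_example(self, toy_model):
        # introns are [100,150) and [250,330)
        reads = [
            ReadAlignment("exonic", "chr1", [(10, 60)], []),
            ReadAlignment("retained", "chr1", [(140, 190)], []),  # 10 nt into i1
            ReadAlignment("junction", "chr1", [(80, 100), (150, 200)], [(100, 150)]),
        ]
        table = count_reads(reads, toy_model)
        assert table.transcript["tA"] == 3
        assert table.intron["tA.i1"] == 1
        assert table.junction["tA.i1"] == 1
        assert table.intron.get("tA.i2", 0) == 0
        assert table.junction.get("tA.i2", 0) == 0
        assert table.library_size == 3

    def test_empty_alignments_all_zero(self, toy_model):
        table = count_reads([], toy_model)
        assert table.library_size == 0
        assert table.transcript == {} and table.intron == {}

    def test_near_miss_gap_is_not_a_junction(self, toy_model):
        read = ReadAlignment("r", "chr1", [(80, 100), (149, 200)], [(100, 149)])
        table = count_reads([read], toy_model)
        assert table.junction.get("tA.i1", 0) == 0
        assert table.transcript["tA"] == 1
        # the gap falls one base short, so the final block clips the intron
        assert table.intron["tA.i1"] == 1

    def test_unknown_chromosome_skipped_with_counter(self, toy_model):
        reads = [ReadAlignment("r", "chrZ", [(0, 50)], [])]
        table = count_reads(reads, toy_model)
        assert table.n_unknown_chrom == 1
        assert table.library_size == 0

    def test_matches_brute_force_enumerator_on_random_reads(self, sim_bundle):
        rng = np.random.default_rng(31)
        model = sim_bundle["toy"].model
        catalog = model.intron_catalog()
        chroms = list(model.chromosomes)
        reads = []
        for k in range(200):
            if k % 3 == 0 and catalog:
                intron = catalog[rng.integers(len(catalog))]
                blocks = [
                    (intron.start - 40, intron.start),
                    (intron.end, intron.end + 40),
                ]
                reads.append(
                    ReadAlignment(f"j{k}", intron.chrom, blocks,
                                  [(intron.start, intron.end)])
                )
            else:
                chrom = chroms[rng.integers(len(chroms))]
                start = int(rng.integers(0, model.chromosomes[chrom] - 300))
                if k % 2:
                    reads.append(
                        ReadAlignment(f"s{k}", chrom, [(start, start + 80)], [])
                    )
                else:
                    gap = int(rng.integers(20, 120))
                    reads.append(
                        ReadAlignment(
                            f"g{k}", chrom,
                            [(start, start + 40), (start + 40 + gap, start + 80 + gap)],
                            [(start + 40, start + 40 + gap)],
                        )
                    )
        table = count_reads(reads, model)
        oracle = brute_counts(reads, model)
        assert table.transcript == oracle["transcript"]
        assert table.gene == oracle["gene"]
        assert table.intron == oracle["intron"]
        assert table.junction == oracle["junction"]
        assert table.intron_transcript == oracle["intron_transcript"]
        assert table.library_size == oracle["library_size"]

    def test_conservation_on_simulated_sample(self, sim_bundle):
        design = sim_bundle["design"]
        model = sim_bundle["toy"].model
        sam = design.iloc[1]["sam"]
        table = count_sample(sam, model)
        for intron in model.intron_catalog():
            iid = intron.intron_id
            n = table.intron.get(iid, 0) + table.junction.get(iid, 0)
            assert n <= table.intron_transcript.get(iid, 0)


class TestCpm:
    def test_arithmetic(self):
        table = CountTable("s", gene={"g1": 300, "g2": 700}, library_size=1000)
        cpm = compute_cpm(table)
        assert cpm["g1"] == pytest.approx(3e5)
        assert cpm["g2"] == pytest.approx(7e5)

    def test_ten_reads_in_a_million(self):
        table = CountTable("s", gene={"g": 10}, library_size=10**6)
        assert compute_cpm(table)["g"] == pytest.approx(10.0)

    def test_zero_library_is_an_error(self):
        with pytest.raises(ValueError, match="library"):
            compute_cpm(CountTable("s"))

    def test_threshold_is_inclusive(self, toy_model):
        # CPM 9.99 fails at threshold 10; CPM exactly 10 passes
        def tab(n, lib):
            return CountTable(
                "s",
                gene={"geneA": n},
                transcript={"tA": n},
                intron_transcript={"tA.i1": n, "tA.i2": n},
                library_size=lib,
            )

        low = retention_level({"s": tab(10, 1_001_000)}, toy_model, cpm_threshold=10.0)
        high = retention_level({"s": tab(10, 10**6)}, toy_model, cpm_threshold=10.0)
        assert low["cpm"].iloc[0] == pytest.approx(9.990, abs=1e-3)
        assert not low["pass_expression"].any()
        assert high["cpm"].iloc[0] == pytest.approx(10.0)
        assert high["pass_expression"].all()


class TestRetentionLevel:
    def test_definition_arithmetic(self, toy_model):
        table = CountTable(
            "s",
            gene={"geneA": 100},
            transcript={"tA": 100},
            intron={"tA.i1": 5},
            intron_transcript={"tA.i1": 100, "tA.i2": 100},
            library_size=100,
        )
        ret = retention_level({"s": table}, toy_model, cpm_threshold=0)
        by_id = ret.set_index("intron_id")["ir"]
        assert by_id["tA.i1"] == pytest.approx(0.05)
        assert by_id["tA.i2"] == 0.0

    def test_zero_denominator_is_nan(self, toy_model):
        table = CountTable("s", gene={"geneA": 1}, transcript={"tA": 1},
                           library_size=1)
        ret = retention_level({"s": table}, toy_model, cpm_threshold=0)
        assert ret["ir"].isna().all()

    def test_mean_ir_matches_oracle_at_depth(self, tmp_path):
        from spliceff.simulate import (
            SimulationConfig, assign_theta, build_toy_genome, simulate_reads,
        )

        cfg = SimulationConfig(
            n_genes=1,
            introns_per_gene=(1, 1),
            exon_len_range=(150, 151),
            intron_len_range=(80, 81),
            expression_range=(6000, 6000),
            theta={"WT": 0.5},
            conditions=("WT",),
            seed=3,
        )
        toy = build_toy_genome(cfg)
        truth = assign_theta(toy)
        # geometry theta=0.5, m=80, r=50, Le=300+2... enforced by config
        sam = simulate_reads(toy, truth, "WT_r1", "WT", tmp_path / "x.sam")
        table = count_sample(sam, toy.model)
        ret = retention_level({"WT_r1": table}, toy.model, cpm_threshold=0)
        expected = truth["expected_ir"].iloc[0]
        n = ret["n_transcript"].iloc[0]
        se = np.sqrt(expected * (1 - expected) / n)
        assert n >= 5000
        assert abs(ret["ir"].iloc[0] - expected) <= 3 * se
        assert expected == pytest.approx(0.2216, abs=2e-3)


class TestIsoformFraction:
    def test_definition_arithmetic(self):
        table = CountTable("s", intron={"i": 15}, junction={"i": 85})
        frac = isoform_retention_fraction(table, "i")
        assert frac.fraction_spliced == pytest.approx(0.85)
        assert frac.fraction_retained == pytest.approx(0.15)

    def test_zero_retention(self):
        table = CountTable("s", intron={}, junction={"i": 50})
        assert isoform_retention_fraction(table, "i").fraction_retained == 0.0

    def test_below_min_informative_is_undefined(self):
        table = CountTable("s", intron={"i": 4}, junction={"i": 5})
        assert isoform_retention_fraction(table, "i") is None

    def test_simulation_matches_position_enumeration(self, tmp_path):
        from spliceff.simulate import (
            SimulationConfig, assign_theta, build_toy_genome, simulate_reads,
        )

        theta, m, r = 0.2, 80, 50
        cfg = SimulationConfig(
            n_genes=1,
            introns_per_gene=(1, 1),
            exon_len_range=(150, 151),
            intron_len_range=(m, m + 1),
            expression_range=(8000, 8000),
            theta={"WT": theta},
            conditions=("WT",),
            read_len=r,
            seed=19,
        )
        toy = build_toy_genome(cfg)
        truth = assign_theta(toy)
        sam = simulate_reads(toy, truth, "WT_r1", "WT", tmp_path / "i.sam")
        table = count_sample(sam, toy.model)
        iid = toy.sim_genes[0].intron_ids[0]
        frac = isoform_retention_fraction(table, iid)
        # brute-force expectation: retained reads have m + r - 1 start
        # positions on the unspliced form, junction reads r - 1 on the
        # spliced form, weighted by molecule abundance
        w_ret = theta * (m + r - 1)
        w_jct = (1 - theta) * (r - 1)
        expected = w_ret / (w_ret + w_jct)
        se = np.sqrt(expected * (1 - expected) / frac.n_informative)
        assert abs(frac.fraction_retained - expected) <= 3 * se
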