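# spliceff

Intron retention and splicing-efficiency analysis from spliced RNA-seq
alignments, with a ground-truth spliced-read simulator.

## The problem

When a spliceosomal component is impaired — for example by deleting a
kinase such as Prp4 in a fungus like *Fusarium graminearum* — splicing is
rarely abolished outright. Instead the efficiency of intron removal drops
for a subset of introns, which then appear as *retained introns* in
RNA-seq. Quantifying that shift genome-wide requires counting, for every
predicted intron, the reads that fall inside it versus the reads covering
its host transcript, and then asking which introns got measurably worse in
the mutant, concordantly across replicate experiments.

`spliceff` is for computational biologists who have spliced alignments
(SAM/BAM with `N`-gap CIGARs), a GFF3 annotation and a genome FASTA, and
want a tested, reproducible implementation of that analysis — plus a
simulator that generates alignments with *known* per-intron retention so
every stage can be validated against analytic ground truth.

## The statistic

For intron *i* of transcript *t* in sample *s*, the **intron retention
level** is

```
IR_i(s) = n_intron(i, s) / n_transcript(t(i), s)
```

where `n_intron` counts reads with an aligned block overlapping the intron
by ≥ 1 nt and `n_transcript` counts reads aligned to the transcript's
genomic span. Reads whose `N` gap exactly matches the intron are
*junction reads* — evidence of the spliced isoform — and are tracked
separately (they stay in the transcript denominator but never in the
intron numerator). Genes are filtered by CPM (counts per million assigned
reads; default threshold 10, required in every sample).

Between a test and a reference condition the per-replicate fold change is

```
FC_r = (IR_test,r + ε) / (IR_ref,r + ε),        ε = 0.001
```

and an intron's bin (`<2`, `2-4`, `>4`, `>8`) is assigned from the
**minimum** FC across replicate pairs, so a threshold only counts when met
in every replicate (replicate concordance). An x-fold *reduction in
splicing efficiency* is operationalized as an x-fold *increase* in IR.
Downstream analyses include gene-level summaries, suppressor-strain
recovery percentages (introns > 8-fold deficient whose IR returns to
within 2-fold of wild type), a PSI-like two-isoform estimator
`n_intron / (n_intron + n_junction)`, branch-point scanning with an IUPAC
consensus (default `CTRAC`, 5–60 nt from the 3'ss), and position frequency
matrices of 5'ss / 3'ss / BP motifs with information content in bits.

The simulator draws, per gene, a molecule form (each intron independently
retained with probability θ), picks forms proportional to
`P(form) × (number of valid read starts)` and starts uniformly — under
which the expected retention level has the exact closed form

```
E[IR] = θ(m + r − 1) / [θ(Lu − r + 1) + (1 − θ)(Le − r + 1)]
```

for a single-intron transcript (intron length m, read length r, spliced
length Le, unspliced length Lu = Le + m), generalized to multi-intron
transcripts by position enumeration.

## Worked example

```python
from spliceff import (SimulationConfig, build_toy_genome, assign_theta,
                      count_sample, retention_level, classify_introns,
                      summarize_genes, expected_retention)
from spliceff.simulate import simulate_design

cfg = SimulationConfig(n_genes=40, introns_per_gene=(1, 3),
                       expression_range=(200, 1000), seed=4)
toy = build_toy_genome(cfg)
truth = assign_theta(toy)                      # per-intron theta + E[IR]
design = simulate_design(toy, truth, "demo")   # 2 conditions x 2 replicates
tables = {r["sample"]: count_sample(r["sam"], toy.model, sample_id=r["sample"])
          for _, r in design.iterrows()}
retention = retention_level(tables, toy.model, cpm_threshold=10)
records, summary = classify_introns(retention, design, test="mut", ref="WT")
genes, fractions = summarize_genes(records)
```

This prints (via the obvious f-strings):

```
catalog: 75 introns, mean length 84.3 bp
classified introns: 75
retention up >2-fold (concordant): 44.0% of introns in 60.0% of genes
Welch t p (mut vs WT retention): 1.10e-13
analytic E[IR] at theta=0.5, m=80, r=50, Le=300: 0.2216
```

Reading: the toy genome's 75 introns average 84 bp; under the default
mutant model (≈45% of introns with elevated θ) the pipeline recovers a
concordant > 2-fold retention increase for 44% of introns, spread over 60%
of genes, and the mutant-vs-wild-type IR distributions differ at
p ≈ 10⁻¹³ by Welch's t-test. The last line is the closed-form expected
retention level the estimator is validated against.

The same analysis is scriptable from a shell:

```
spliceff simulate -c sim.yaml -o study/
spliceff run-all -g study/annotation.gff3 -f study/genome.fa \
                 -s study/design.tsv -o report/
```

`run-all` writes `retention.tsv`, `differential.tsv`, `gene_summary.tsv`,
`features.tsv`, `pfms.tsv`, `isoform_fractions.tsv`, `introns.bed` and a
`summary.json`; every file carries a header with the version and the fully
resolved configuration, and a seeded rerun is byte-identical.

## Documentation

`docs/methods.md` describes the model, its assumptions, the tunable
parameters, what the simulator does and does not emulate, and known
limitations.
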