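"""End-to-end orchestration: simulate -> quantify -> compare -> features.

Every output file starts with comment lines naming the software version and
the fully resolved configuration, and the log records each filtering step
with counts before and after (genes detected -> genes with introns ->
introns classified), so a run can be audited and reproduced byte-for-byte
from its outputs plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential import (
    DEFAULT_EPSILON,
    DEFAULT_THRESHOLDS,
    classify_introns,
    recovery_analysis,
    summarize_genes,
)
from .features import build_pfm, compare_feature, compare_pfms, feature_table
from .genome import extract_splice_sites, find_branch_point, parse_annotation, write_intron_bed
from .quantify import count_sample, pooled_isoform_fraction, retention_level
from .simulate import SimulationConfig, assign_theta, build_toy_genome, simulate_design, write_truth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    gff3: str | None = None
    fasta: str | None = None
    sample_sheet: str | None = None
    out_dir: str = "spliceff_out"
    cpm_threshold: float = 10.0
    fold_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    epsilon: float = DEFAULT_EPSILON
    min_overlap: int = 1
    min_mapq: int = 0
    bp_consensus: str = "CTRAC"
    bp_search_window: tuple[int, int] = (5, 60)
    bp_min_score: float = 0.8
    affected_min_fold: float = 4.0
    unaffected_max_fold: float = 2.0
    test_condition: str = "mut"
    ref_condition: str = "WT"
    suppressors: tuple[str, ...] = ()
    feature_test: str = "welch_t"
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.fold_thresholds)
        if any(b <= a for a, b in zip(t, t[1:])) or any(x <= 0 for x in t):
            raise ValueError("fold thresholds must be positive and strictly increasing")
        self.fold_thresholds = t
        if self.cpm_threshold < 0 or self.epsilon <= 0:
            raise ValueError("cpm_threshold must be >= 0 and epsilon > 0")
        for key in ("gff3", "fasta", "sample_sheet"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _header(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return f"# spliceff {__version__}\n# config: {blob}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_simulation(config: RunConfig, sim_config: SimulationConfig | None = None) -> dict:
    """Build a toy genome, simulate every sample, and write the bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sim_config is None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        for key in ("introns_per_gene", "exon_len_range", "intron_len_range",
                    "expression_range", "bp_distance_range", "conditions"):
            if key in sim_kwargs and isinstance(sim_kwargs[key], list):
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_config = SimulationConfig(**sim_kwargs)
    toy = build_toy_genome(sim_config)
    truth = assign_theta(toy)
    fasta = toy.write_fasta(out / "genome.fa")
    gff3 = toy.write_gff3(out / "annotation.gff3")
    write_truth(truth, out / "truth.tsv")
    design = simulate_design(toy, truth, out)
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    logger.info(
        "simulated %d genes, %d introns, %d samples",
        len(toy.model.genes), len(toy.model.intron_catalog()), len(design),
    )
    return {
        "fasta": str(fasta),
        "gff3": str(gff3),
        "truth": str(out / "truth.tsv"),
        "design": str(out / "design.tsv"),
        "toy": toy,
        "truth_df": truth,
        "design_df": design,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Quantify, compare and characterize; write the full report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.gff3 is None or config.sample_sheet is None:
        raise ValueError("pipeline needs gff3 and sample_sheet")

    model = parse_annotation(config.gff3, config.fasta)
    catalog = model.intron_catalog()
    stats = model.catalog_stats()
    logger.info(
        "annotation: %d genes, %d with introns, %d catalog introns, mean length %.1f bp",
        stats["n_genes"], stats["n_genes_with_introns"],
        stats["n_introns"], stats["mean_intron_length"],
    )
    write_intron_bed(catalog, out / "introns.bed")

    design = pd.read_csv(config.sample_sheet, sep="\t")
    if design.empty:
        raise ValueError("sample sheet is empty")
    tables = {}
    for _, row in design.iterrows():
        tables[row["sample"]] = count_sample(
            row["sam"], model,
            min_overlap=config.min_overlap,
            min_mapq=config.min_mapq,
            sample_id=row["sample"],
        )
    retention = retention_level(
        tables, model, cpm_threshold=config.cpm_threshold, require_all_samples=True
    )
    _write_tsv(retention, out / "retention.tsv", config)
    n_pass = retention[retention["pass_expression"]]["gene_id"].nunique()
    logger.info(
        "expression filter (CPM >= %g in all samples): %d of %d genes pass",
        config.cpm_threshold, n_pass, stats["n_genes"],
    )

    records, ttest_summary = classify_introns(
        retention, design,
        test=config.test_condition, ref=config.ref_condition,
        thresholds=config.fold_thresholds, epsilon=config.epsilon,
    )
    logger.info(
        "classification: %d of %d catalog introns classified",
        len(records), stats["n_introns"],
    )
    _write_tsv(records, out / "differential.tsv", config)
    gene_df, fractions = summarize_genes(records, thresholds=config.fold_thresholds)
    _write_tsv(gene_df, out / "gene_summary.tsv", config)

    summary = {
        "version": __version__,
        "config": config.to_dict(),
        "annotation": {k: v for k, v in stats.items() if k != "introns_per_gene"},
        "retention_ttest": ttest_summary,
        "fractions": fractions,
    }

    recovery = {}
    for sup in config.suppressors:
        res = recovery_analysis(
            retention, design,
            wt=config.ref_condition, mutant=config.test_condition, suppressor=sup,
            deficiency_fold=config.fold_thresholds[-1],
            recovered_fold=config.fold_thresholds[0],
            epsilon=config.epsilon,
        )
        recovery[sup] = (
            None
            if res is None
            else {
                "percent_recovered": res.percent_recovered,
                "n_deficient": res.n_deficient,
                "n_recovered": res.n_recovered,
            }
        )
    if recovery:
        summary["suppressor_recovery"] = recovery

    features_out = None
    if model.has_sequence:
        bp_calls = {
            i.intron_id: find_branch_point(
                model.intron_seq(i), i.intron_id,
                consensus=config.bp_consensus,
                search_window=config.bp_search_window,
                min_score=config.bp_min_score,
            )
            for i in catalog
        }
        rows = feature_table(
            catalog, bp_calls, records,
            affected_min_fold=config.affected_min_fold,
            unaffected_max_fold=config.unaffected_max_fold,
        )
        _write_tsv(rows, out / "features.tsv", config)
        features_out = {}
        for feat in ("length", "dist_5ss_bp", "dist_bp_3ss", "introns_in_gene"):
            try:
                cmp_ = compare_feature(rows, feat, test=config.feature_test)
            except ValueError:
                continue
            features_out[feat] = cmp_._asdict()
        summary["feature_comparisons"] = features_out

        # splice-site and BP motifs per class
        by_id = {i.intron_id: i for i in catalog}
        pfm_tables = []
        motif_results = {}
        for site in ("five_ss", "three_ss", "bp"):
            seqs = {"affected": [], "unaffected": []}
            for _, row in rows.iterrows():
                intron = by_id[row["intron_id"]]
                if site == "bp":
                    call = bp_calls[intron.intron_id]
                    if not call.found:
                        continue
                    s = model.intron_seq(intron)
                    lo = call.bp_pos - 4
                    if lo < 0 or call.bp_pos + 3 > len(s):
                        continue
                    seqs[row["klass"]].append(s[lo : call.bp_pos + 3])
                else:
                    ss = extract_splice_sites(model, intron)
                    if ss.clipped:
                        continue
                    seqs[row["klass"]].append(getattr(ss, site))
            if min(len(v) for v in seqs.values()) < 2:
                continue
            pfm_a = build_pfm(seqs["affected"])
            pfm_u = build_pfm(seqs["unaffected"])
            for name, pfm in (("affected", pfm_a), ("unaffected", pfm_u)):
                df = pfm.to_frame()
                df.insert(0, "site", site)
                df.insert(1, "klass", name)
                pfm_tables.append(df)
            cmp_df, no_diff = compare_pfms(pfm_a, pfm_u)
            motif_results[site] = {
                "no_difference": no_diff,
                "min_p_bonferroni": float(cmp_df["chi2_p_bonferroni"].min()),
                "max_jsd_bits": float(cmp_df["jsd_bits"].max()),
                "n_affected": pfm_a.n_sequences,
                "n_unaffected": pfm_u.n_sequences,
            }
        if pfm_tables:
            _write_tsv(pd.concat(pfm_tables, ignore_index=True), out / "pfms.tsv", config)
        summary["motif_comparisons"] = motif_results

    # isoform fractions for every intron with enough informative reads
    iso_rows = []
    for intron in catalog:
        frac = pooled_isoform_fraction(tables, intron.intron_id)
        if frac is None:
            continue
        iso_rows.append(
            {
                "intron_id": intron.intron_id,
                "gene_id": intron.gene_id,
                "fraction_retained": frac.fraction_retained,
                "fraction_spliced": frac.fraction_spliced,
                "n_informative": frac.n_informative,
            }
        )
    iso_df = pd.DataFrame(
        iso_rows,
        columns=["intron_id", "gene_id", "fraction_retained", "fraction_spliced", "n_informative"],
    )
    _write_tsv(iso_df, out / "isoform_fractions.tsv", config)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return summary
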