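"""Fold-change classification of intron retention between genotypes.

An intron's retention fold change between a test and a reference condition
is computed per replicate pair as FC = (IR_test + eps) / (IR_ref + eps),
with a small pseudocount guarding zero denominators. The intron's bin is
assigned from the MINIMUM fold change across replicate pairs — a threshold
counts only if met in every replicate — which is the strict reading of
requiring concordance between replicate experiments. Bins partition the
classified introns: "<2" (min FC <= 2), "2-4" (2 < min FC <= 4), ">4"
(4 < min FC <= 8) and ">8" (min FC > 8); "over x-fold" queries nest via
``min_fc``. An x-fold reduction in splicing efficiency is operationalized
as an x-fold increase in intron retention level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_EPSILON = 1e-3
DEFAULT_THRESHOLDS = (2.0, 4.0, 8.0)
BIN_LABELS = ("<2", "2-4", ">4", ">8")


def fold_change(ir_test: float, ir_ref: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Pseudocount-protected retention ratio; NaN if either IR is undefined."""
    if ir_test is None or ir_ref is None or np.isnan(ir_test) or np.isnan(ir_ref):
        return float("nan")
    return (ir_test + epsilon) / (ir_ref + epsilon)


def assign_bin(min_fc: float, thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> str:
    t2, t4, t8 = thresholds
    if min_fc > t8:
        return ">8"
    if min_fc > t4:
        return ">4"
    if min_fc > t2:
        return "2-4"
    return "<2"


def _check_design(design: pd.DataFrame) -> None:
    required = {"sample", "condition", "replicate"}
    if not required.issubset(design.columns):
        raise ValueError(f"design sheet must have columns {sorted(required)}")


def replicate_pairs(design: pd.DataFrame, test: str, ref: str) -> list[tuple[str, str, object]]:
    """Match test and reference samples by replicate id; error on mismatch."""
    _check_design(design)
    t = design[design["condition"] == test].set_index("replicate")["sample"]
    r = design[design["condition"] == ref].set_index("replicate")["sample"]
    if len(t) == 0 or len(r) == 0:
        raise ValueError(f"conditions {test!r}/{ref!r} absent from design")
    if set(t.index) != set(r.index):
        raise ValueError(
            f"replicate layouts differ between {test!r} ({sorted(t.index)}) "
            f"and {ref!r} ({sorted(r.index)})"
        )
    return [(t[rep], r[rep], rep) for rep in sorted(t.index)]


def _ir_matrix(retention: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Introns x samples IR matrix restricted to expression-passing,
    everywhere-defined introns."""
    sub = retention[retention["sample"].isin(samples)]
    ok = sub.groupby("intron_id")["pass_expression"].all()
    wide = sub.pivot(index="intron_id", columns="sample", values="ir")
    keep = ok[ok].index.intersection(wide.dropna().index)
    return wide.loc[keep, list(samples)]


def classify_introns(
    retention: pd.DataFrame,
    design: pd.DataFrame,
    test: str,
    ref: str,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[pd.DataFrame, dict]:
    """Per-intron differential records plus the global IR comparison.

    Returns (records, summary): ``records`` has one row per intron passing
    the expression filter with defined IR in all samples — per-replicate
    fold changes, the replicate-minimum fold change, its bin, direction and
    concordance; ``summary`` carries Welch t-test comparisons of the IR
    distributions between the two conditions (per replicate pair and
    pooled), mirroring the box-plot comparison of retention levels.
    """
    pairs = replicate_pairs(design, test, ref)
    samples = [s for p in pairs for s in p[:2]]
    wide = _ir_matrix(retention, samples)
    gene_of = retention.drop_duplicates("intron_id").set_index("intron_id")["gene_id"]

    rows = []
    for iid, row in wide.iterrows():
        fcs = {}
        for s_test, s_ref, rep in pairs:
            fcs[rep] = fold_change(row[s_test], row[s_ref], epsilon)
        values = list(fcs.values())
        min_fc, max_fc = min(values), max(values)
        if min_fc > 1.0:
            direction = "increase"
            magnitude = min_fc
        elif max_fc < 1.0:
            direction = "decrease"
            magnitude = 1.0 / max_fc  # weakest inverse fold across replicates
        else:
            direction = "none"
            magnitude = 1.0
        rec = {
            "intron_id": iid,
            "gene_id": gene_of.get(iid),
            "min_fc": min_fc,
            "max_fc": max_fc,
            "magnitude": magnitude,
            "direction": direction,
            "bin": assign_bin(magnitude, thresholds),
            "concordant": magnitude > thresholds[0],
        }
        for s_test, s_ref, rep in pairs:
            rec[f"ir_{test}_r{rep}"] = row[s_test]
            rec[f"ir_{ref}_r{rep}"] = row[s_ref]
            rec[f"fc_r{rep}"] = fcs[rep]
        rows.append(rec)
    records = pd.DataFrame(rows)

    summary: dict = {"test": test, "ref": ref, "n_introns": len(records)}
    per_rep = {}
    for s_test, s_ref, rep in pairs:
        tt = stats.ttest_ind(wide[s_test], wide[s_ref], equal_var=False)
        per_rep[str(rep)] = {"statistic": float(tt.statistic), "p": float(tt.pvalue)}
    t_vals = wide[[p[0] for p in pairs]].to_numpy().ravel()
    r_vals = wide[[p[1] for p in pairs]].to_numpy().ravel()
    if len(t_vals) >= 2:
        pooled = stats.ttest_ind(t_vals, r_vals, equal_var=False)
        summary["welch_t"] = {
            "pooled": {"statistic": float(pooled.statistic), "p": float(pooled.pvalue)},
            "per_replicate": per_rep,
        }
        summary["mean_ir"] = {test: float(np.mean(t_vals)), ref: float(np.mean(r_vals))}
    return records, summary


@dataclass
class GeneSummary:
    gene_id: str
    n_introns: int
    n_affected: int

    @property
    def affected(self) -> bool:
        return self.n_affected >= 1


def summarize_genes(
    records: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, dict]:
    """Fractions of introns and genes affected at each fold threshold.

    An intron is affected at threshold t when its retention increased
    concordantly more than t-fold (min FC > t in every replicate); a gene
    is affected when at least one of its classified introns is. The
    denominators are the introns and genes that passed the expression
    filter and entered classification — they are reported alongside every
    fraction.
    """
    n_introns = len(records)
    genes = records.groupby("gene_id").size()
    n_genes = len(genes)
    fractions: dict = {
        "n_introns_classified": int(n_introns),
        "n_genes_classified": int(n_genes),
    }
    gene_rows = {
        gid: GeneSummary(gene_id=gid, n_introns=int(n), n_affected=0)
        for gid, n in genes.items()
    }
    for t in thresholds:
        up = records[(records["direction"] == "increase") & (records["min_fc"] > t)]
        frac_i = len(up) / n_introns if n_introns else float("nan")
        agenes = up.groupby("gene_id").size()
        frac_g = len(agenes) / n_genes if n_genes else float("nan")
        key = f"{t:g}fold"
        fractions[f"introns_over_{key}"] = int(len(up))
        fractions[f"frac_introns_over_{key}"] = frac_i
        fractions[f"genes_over_{key}"] = int(len(agenes))
        fractions[f"frac_genes_over_{key}"] = frac_g
        if t == thresholds[0]:
            for gid, n in agenes.items():
                gene_rows[gid].n_affected = int(n)
    gene_df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "n_introns": g.n_introns,
                "n_affected": g.n_affected,
                "affected": g.affected,
            }
            for g in gene_rows.values()
        ]
    ).sort_values("gene_id").reset_index(drop=True)
    return gene_df, fractions


@dataclass
class RecoveryResult:
    percent_recovered: float
    n_deficient: int
    n_recovered: int
    deficient: tuple[str, ...]
    recovered: tuple[str, ...]


def recovery_analysis(
    retention: pd.DataFrame,
    design: pd.DataFrame,
    wt: str,
    mutant: str,
    suppressor: str,
    deficiency_fold: float = 8.0,
    recovered_fold: float = 2.0,
    epsilon: float = DEFAULT_EPSILON,
) -> RecoveryResult | None:
    """Percentage of severely splicing-deficient introns recovered in a
    suppressor strain.

    Deficient introns show a concordant more-than-``deficiency_fold``
    retention increase in the mutant versus the wild type (min FC across
    replicate pairs). An intron is recovered when, in EVERY suppressor
    sample, its retention is within ``recovered_fold`` of the wild type
    (FC against the mean wild-type IR < recovered_fold). Returns None when
    no intron is deficient.
    """
    records, _ = classify_introns(retention, design, mutant, wt, epsilon=epsilon)
    deficient = records[
        (records["direction"] == "increase") & (records["min_fc"] > deficiency_fold)
    ]["intron_id"].tolist()
    if not deficient:
        return None

    _check_design(design)
    wt_samples = design.loc[design["condition"] == wt, "sample"].tolist()
    sup_samples = design.loc[design["condition"] == suppressor, "sample"].tolist()
    if not sup_samples:
        raise ValueError(f"no samples for suppressor condition {suppressor!r}")
    wt_ir = (
        retention[retention["sample"].isin(wt_samples)]
        .groupby("intron_id")["ir"]
        .mean()
    )
    sup_ir = retention[retention["sample"].isin(sup_samples)].pivot(
        index="intron_id", columns="sample", values="ir"
    )
    recovered = []
    for iid in deficient:
        base = wt_ir.get(iid, float("nan"))
        fcs = [
            fold_change(
                sup_ir.at[iid, s] if iid in sup_ir.index else float("nan"),
                base,
                epsilon,
            )
            for s in sup_samples
        ]
        if all(np.isfinite(fc) and fc < recovered_fold for fc in fcs):
            recovered.append(iid)
    return RecoveryResult(
        percent_recovered=100.0 * len(recovered) / len(deficient),
        n_deficient=len(deficient),
        n_recovered=len(recovered),
        deficient=tuple(deficient),
        recovered=tuple(recovered),
    )
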