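"""Sequence and structural features of affected vs. unaffected introns.

Builds a per-intron feature table (length, branch-point distances,
introns-per-gene), runs two-sample location tests between the affected and
unaffected classes, and summarizes splice-site / branch-point sequence sets
as position frequency matrices with per-column information content and
divergence comparisons.

Distance convention: both distances are measured to/from the branch
adenosine using 0-based offsets — ``dist_5ss_bp`` is the A's offset from
the intron start and ``dist_bp_3ss`` is ``length - 1 - dist_5ss_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .genome import BranchPointCall, Intron

ALPHABET = "ACGT"


# -- feature table ---------------------------------------------------------


def feature_table(
    catalog: Sequence[Intron],
    bp_calls: Mapping[str, BranchPointCall],
    records: pd.DataFrame,
    affected_min_fold: float = 4.0,
    unaffected_max_fold: float = 2.0,
) -> pd.DataFrame:
    """One row per classified intron with class labels and features.

    ``affected`` introns increased retention concordantly more than
    ``affected_min_fold``-fold; ``unaffected`` stayed under
    ``unaffected_max_fold`` in every replicate. Introns between the cutoffs
    are left out. BP-less introns keep their length but carry null
    distances.
    """
    by_id = {i.intron_id: i for i in catalog}
    per_gene = pd.Series([i.gene_id for i in catalog]).value_counts().to_dict()
    rows = []
    for _, rec in records.iterrows():
        if rec["direction"] == "increase" and rec["min_fc"] > affected_min_fold:
            klass = "affected"
        elif rec["magnitude"] <= unaffected_max_fold:
            klass = "unaffected"
        else:
            continue
        intron = by_id.get(rec["intron_id"])
        if intron is None:
            continue
        call = bp_calls.get(intron.intron_id)
        has_bp = call is not None and call.found
        rows.append(
            {
                "intron_id": intron.intron_id,
                "gene_id": intron.gene_id,
                "klass": klass,
                "length": intron.length,
                "dist_5ss_bp": call.bp_pos if has_bp else np.nan,
                "dist_bp_3ss": (intron.length - 1 - call.bp_pos) if has_bp else np.nan,
                "introns_in_gene": per_gene.get(intron.gene_id, 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "intron_id", "gene_id", "klass", "length",
            "dist_5ss_bp", "dist_bp_3ss", "introns_in_gene",
        ],
    )


class FeatureComparison(NamedTuple):
    feature: str
    test: str
    statistic: float
    p: float
    mean_affected: float
    mean_unaffected: float
    median_affected: float
    median_unaffected: float
    n_affected: int
    n_unaffected: int


def compare_feature(
    rows: pd.DataFrame, feature: str, test: str = "welch_t"
) -> FeatureComparison:
    """Two-sided affected-vs-unaffected comparison of one feature.

    ``test`` is "welch_t" (unequal-variance t) or "mann_whitney".
    """
    a = rows.loc[rows["klass"] == "affected", feature].dropna().to_numpy()
    u = rows.loc[rows["klass"] == "unaffected", feature].dropna().to_numpy()
    if len(a) < 2 or len(u) < 2:
        raise ValueError(
            f"feature {feature!r}: need >= 2 defined values per class "
            f"(affected {len(a)}, unaffected {len(u)})"
        )
    if test == "welch_t":
        res = stats.ttest_ind(a, u, equal_var=False)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, u, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return FeatureComparison(
        feature=feature,
        test=test,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        mean_affected=float(np.mean(a)),
        mean_unaffected=float(np.mean(u)),
        median_affected=float(np.median(a)),
        median_unaffected=float(np.median(u)),
        n_affected=len(a),
        n_unaffected=len(u),
    )


# -- position frequency matrices -------------------------------------------


@dataclass
class PositionFrequencyMatrix:
    """Per-position base frequencies of an aligned sequence set.

    ``counts`` excludes N bases; ``freqs`` columns sum to 1 over ACGT (for
    columns with at least one informative base). Information content per
    column is 2 - Shannon entropy, in bits.
    """

    counts: np.ndarray  # (length, 4) base counts
    n_sequences: int

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def freqs(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.25)

    @property
    def information_content(self) -> np.ndarray:
        f = self.freqs
        with np.errstate(invalid="ignore", divide="ignore"):
            h = -np.where(f > 0, f * np.log2(f), 0.0).sum(axis=1)
        return 2.0 - h

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs, columns=list(ALPHABET))
        df.insert(0, "position", np.arange(self.length))
        df["information_bits"] = self.information_content
        return df


def build_pfm(sequences: Iterable[str]) -> PositionFrequencyMatrix:
    """Count base frequencies per column; N bases carry no column weight."""
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal lengths")
    counts = np.zeros((length, 4), dtype=float)
    index = {b: k for k, b in enumerate(ALPHABET)}
    for s in seqs:
        for pos, base in enumerate(s):
            k = index.get(base)
            if k is not None:
                counts[pos, k] += 1
    return PositionFrequencyMatrix(counts=counts, n_sequences=len(seqs))


def compare_pfms(
    pfm_a: PositionFrequencyMatrix,
    pfm_b: PositionFrequencyMatrix,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, bool]:
    """Per-column Jensen-Shannon divergence (bits) and chi-square p-values.

    Returns (table, no_difference): ``no_difference`` is True when every
    column's chi-square p exceeds alpha after Bonferroni correction across
    columns — the conservative reading of "the motifs do not differ".
    """
    if pfm_a.length != pfm_b.length:
        raise ValueError("matrices must have equal widths")
    rows = []
    for pos in range(pfm_a.length):
        p, q = pfm_a.freqs[pos], pfm_b.freqs[pos]
        jsd = float(jensenshannon(p, q, base=2) ** 2)
        if not np.isfinite(jsd):
            jsd = 0.0
        table = np.vstack([pfm_a.counts[pos], pfm_b.counts[pos]])
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
            chi_p = 1.0  # degenerate column: no contrast to test
        else:
            chi_p = float(stats.chi2_contingency(table)[1])
        rows.append({"position": pos, "jsd_bits": jsd, "chi2_p": chi_p})
    out = pd.DataFrame(rows)
    out["chi2_p_bonferroni"] = np.minimum(out["chi2_p"] * pfm_a.length, 1.0)
    no_difference = bool((out["chi2_p_bonferroni"] > alpha).all())
    return out, no_difference


# -- optional logo rendering ----------------------------------------------

_LOGO_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_logo(pfm: PositionFrequencyMatrix, path: str) -> str:
    """Render a simple information-content-scaled sequence logo (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.text import TextPath
    from matplotlib.transforms import Affine2D

    fp = FontProperties(family="DejaVu Sans", weight="bold")
    fig, ax = plt.subplots(figsize=(max(3, pfm.length * 0.45), 2.4))
    ic = pfm.information_content
    for pos in range(pfm.length):
        y = 0.0
        order = np.argsort(pfm.freqs[pos])
        for k in order:
            h = pfm.freqs[pos, k] * ic[pos]
            if h <= 0:
                continue
            base = ALPHABET[k]
            tp = TextPath((0, 0), base, size=1, prop=fp)
            bb = tp.get_extents()
            tf = (
                Affine2D()
                .translate(-bb.xmin, -bb.ymin)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(pos + 0.05, y)
            )
            ax.add_patch(PathPatch(tf.transform_path(tp), fc=_LOGO_COLORS[base], ec="none"))
            y += h
    ax.set_xlim(0, pfm.length)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xticks(np.arange(pfm.length) + 0.5, [str(i) for i in range(pfm.length)])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
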