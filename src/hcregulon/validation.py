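"""Target-set validation: per-gene hair-cell enrichment ratios, a rank-based
distribution-shift test, ChIP target-list intersections, and generic
hypergeometric gene-set enrichment.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import ExpressionMatrix, GeneSet
from .motif import EnrichmentResult, hypergeom_tail


@dataclasses.dataclass
class HCEnrichmentScore:
    gene: str
    ratio: float            # HC mean / mean of the three cell-type means
    log2_ratio: float


@dataclasses.dataclass
class ShiftTestResult:
    set_label: str
    n_set: int
    n_rest: int
    rank_sum: float          # W of the set group (midranks)
    p: float                 # one-sided: set shifted right
    p_two_sided: float
    median_difference: float
    method: str              # exact / asymptotic


def hc_enrichment_scores(m: ExpressionMatrix,
                         cell_types: tuple[str, ...] = ("HC", "ENHC", "NEC"),
                         focal: str = "HC",
                         per_organ: bool = False) -> pd.DataFrame:
    """Per-gene ratio of focal-cell-type expression to the average of the
    cell-type means (replicate means per cell type, organs pooled by
    default). Values must be floored (> 0) so the log2 ratio is finite.
    """
    present = set(m.design["cell_type"].unique())
    missing = set(cell_types) - present
    if missing:
        raise ValueError(f"missing cell types in design: {sorted(missing)}")
    scopes = ([(o,) for o in m.design["organ"].unique()] if per_organ
              else [None])
    frames = []
    for scope in scopes:
        ct_means = {}
        for ct in cell_types:
            cols = (m.columns_where(cell_type=ct) if scope is None
                    else m.columns_where(cell_type=ct, organ=scope[0]))
            ct_means[ct] = m.values[cols].mean(axis=1)
        mean_of_means = sum(ct_means.values()) / len(cell_types)
        ratio = ct_means[focal] / mean_of_means
        frame = pd.DataFrame({"gene": m.genes.to_numpy(), "ratio": ratio,
                              "log2_ratio": np.log2(ratio)})
        if scope is not None:
            frame["organ"] = scope[0]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def shift_test(scores_set, scores_rest, set_label: str = "set",
               method: str | None = None) -> ShiftTestResult:
    """One-sided Wilcoxon rank-sum test that the set's values are
    stochastically larger than the rest's.

    Exact enumeration when min(n) <= 10 and there are no ties; otherwise
    the normal approximation with midranks, tie correction and continuity
    correction. ``method`` ('exact' / 'asymptotic') overrides the automatic
    branch choice.
    """
    x = np.asarray(scores_set, dtype=float)
    y = np.asarray(scores_rest, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if method is None:
        exact = (min(x.size, y.size) <= 10) and not has_ties
        method = "exact" if exact else "asymptotic"
    elif method == "exact" and has_ties:
        raise ValueError("exact branch requires tie-free data")
    res = scipy.stats.mannwhitneyu(x, y, alternative="greater",
                                   method=method, use_continuity=True)
    res2 = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method, use_continuity=True)
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[:x.size].sum())
    return ShiftTestResult(
        set_label=set_label, n_set=int(x.size), n_rest=int(y.size),
        rank_sum=w, p=float(res.pvalue), p_two_sided=float(res2.pvalue),
        median_difference=float(np.median(x) - np.median(y)),
        method=method)


def chip_intersection(candidates: GeneSet, chip_a: GeneSet, chip_b: GeneSet,
                      universe: GeneSet) -> dict:
    """Overlaps of computational candidates with two ChIP target lists.

    Reports |candidates ∩ (a ∪ b)| and |candidates ∩ a ∩ b| with
    hypergeometric p-values against the universe, plus the a/b overlap
    itself (two antibodies binding largely the same promoters).
    """
    for name, s in (("candidates", candidates), ("chip_a", chip_a),
                    ("chip_b", chip_b)):
        if not s.members <= universe.members:
            raise ValueError(f"{name} is not contained in the universe")
    N = len(universe.members)
    union = chip_a.members | chip_b.members
    both = chip_a.members & chip_b.members
    k_union = len(candidates.members & union)
    k_both = len(candidates.members & both)
    k_ab = len(both)
    return {
        "n_candidates": len(candidates.members),
        "n_chip_a": len(chip_a.members),
        "n_chip_b": len(chip_b.members),
        "bound_by_either": k_union,
        "bound_by_both": k_both,
        "p_either": hypergeom_tail(N, len(union), len(candidates.members),
                                   k_union),
        "p_both": hypergeom_tail(N, len(both), len(candidates.members),
                                 k_both),
        "chip_ab_overlap": k_ab,
        "p_chip_ab": hypergeom_tail(N, len(chip_a.members),
                                    len(chip_b.members), k_ab),
    }


def geneset_enrichment(panel: GeneSet, selected: GeneSet,
                       universe: GeneSet) -> EnrichmentResult:
    """Generic hypergeometric over-representation of a panel within a
    selected set (shares hypergeom_tail and the enrichment-factor
    definition with the motif test)."""
    if not panel.members <= universe.members:
        raise ValueError("panel is not contained in the universe")
    if not selected.members <= universe.members:
        raise ValueError("selected set is not contained in the universe")
    N = len(universe.members)
    K = len(selected.members)
    panel_in = panel.members & universe.members
    n = len(panel_in)
    if n == 0:
        raise ValueError("panel does not intersect the universe")
    k = len(panel_in & selected.members)
    return EnrichmentResult.from_counts(N, K, n, k)


def fold_summary(gene_set: GeneSet, m: ExpressionMatrix,
                 numerator: str, denominator: str) -> dict:
    """Per-gene folds (numerator cell type mean / denominator cell type
    mean, floored values) for a gene set, with min/mean/max."""
    num_cols = m.columns_where(cell_type=numerator)
    den_cols = m.columns_where(cell_type=denominator)
    if not num_cols or not den_cols:
        raise ValueError(f"matrix lacks {numerator} or {denominator} columns")
    gene_rows: dict[str, str] = {}
    for feature in m.values.index:
        gene_rows.setdefault(m.genes.loc[feature], feature)
    folds = {}
    absent = []
    for g in sorted(gene_set.members):
        if g not in gene_rows:
            absent.append(g)
            continue
        row = m.values.loc[gene_rows[g]]
        folds[g] = float(row[num_cols].mean() / row[den_cols].mean())
    if not folds:
        raise ValueError("no gene of the set is present in the matrix")
    arr = np.array(list(folds.values()))
    return {"per_gene": folds, "n_absent": len(absent),
            "min": float(arr.min()), "mean": float(arr.mean()),
            "max": float(arr.max())}
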