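"""Expression stages: detection filtering, normalization, two-way ANOVA
differential expression, pattern clustering, hair-cell-enriched set
construction and strict cell-type marker calling.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneSet

logger = logging.getLogger("hcregulon")


@dataclasses.dataclass
class AnalysisConfig:
    detection_p_expressed: float = 0.01
    min_samples_detected: int = 2
    floor_value: float = 20.0
    fold_threshold: float = 3.0
    marker_high: float = 250.0
    marker_low: float = 120.0
    fdr_level: float = 0.05
    n_pattern_clusters: int = 12
    log_offset: float = 1.0
    cluster_seed: int = 0

    def __post_init__(self) -> None:
        if not self.marker_low < self.marker_high:
            raise ValueError("marker_low must be < marker_high")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")


@dataclasses.dataclass
class DEResult:
    """Per-feature two-way ANOVA statistics with BH-adjusted q-values."""

    table: pd.DataFrame      # F_/p_/q_ per effect + selected flag
    fdr_level: float

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


@dataclasses.dataclass
class MarkerCall:
    gene: str
    cell_type: str
    organ_scope: str                      # both / <organ>_only
    target_mean: float
    max_other: float


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def detection_filter(m: ExpressionMatrix,
                     cfg: AnalysisConfig = AnalysisConfig(),
                     ) -> ExpressionMatrix:
    """Keep features detected (detection p below threshold) in at least
    ``min_samples_detected`` samples; feature order is preserved."""
    if m.detection_p is None:
        raise ValueError(
            "no detection-p table; use a value-threshold fallback (e.g. "
            "filter on values >= a detection cutoff) before this stage")
    detected = (m.detection_p.to_numpy() < cfg.detection_p_expressed)
    keep = detected.sum(axis=1) >= cfg.min_samples_detected
    return m.replace_values(m.values.loc[keep])


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the rank-mean reference distribution.

    After normalization the sorted value vector of each column equals the
    per-rank mean of the sorted input columns; ties within a column receive
    the mean of the reference values spanning their rank range.
    """
    values = m.values.to_numpy(dtype=float)
    n, s = values.shape
    if s < 2:
        logger.warning("quantile_normalize: single sample, returning as is")
        return m
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(s):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # average reference values across tied ranks
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        group_sums = np.add.reduceat(ref, boundaries)
        group_sizes = np.diff(np.r_[boundaries, n])
        group_means = group_sums / group_sizes
        assigned[order] = np.repeat(group_means, group_sizes)
        out[:, j] = assigned
    return m.replace_values(pd.DataFrame(out, index=m.values.index,
                                         columns=m.values.columns))


def normalize_counts(m: ExpressionMatrix,
                     cfg: AnalysisConfig = AnalysisConfig(),
                     ) -> ExpressionMatrix:
    """Quantile normalization followed by a floor (guards fold changes
    against division by near-zero counts)."""
    qn = quantile_normalize(m)
    floored = qn.values.clip(lower=cfg.floor_value)
    return qn.replace_values(floored)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def anova_de(m: ExpressionMatrix, cfg: AnalysisConfig = AnalysisConfig(),
             ) -> DEResult:
    """Per-feature fixed-effects two-way ANOVA (cell type x organ) with
    interaction on log2(x + offset) values, BH-adjusted per effect.

    The design must be balanced (equal replicates per organ x cell-type
    cell); the closed-form sums-of-squares decomposition used here equals
    type-II least squares on balanced data. A feature is selected when any
    of the three adjusted q-values falls below ``fdr_level``.
    """
    design = m.design
    organs = sorted(design["organ"].unique())
    cts = sorted(design["cell_type"].unique())
    a, b = len(organs), len(cts)
    if a < 2 or b < 2:
        raise ValueError("need at least two levels of organ and cell type")
    counts = design.groupby(["organ", "cell_type"]).size()
    if len(counts) != a * b:
        raise ValueError("a design cell has no observations")
    r = int(counts.iloc[0])
    if not (counts == r).all():
        raise ValueError("design is unbalanced; equal replicates required")
    if r < 2:
        raise ValueError("need >=2 replicates per design cell")

    y = np.log2(m.values.to_numpy(dtype=float) + cfg.log_offset)
    n_feat, n_samp = y.shape
    organ_idx = design["organ"].map({o: i for i, o in enumerate(organs)})
    ct_idx = design["cell_type"].map({c: i for i, c in enumerate(cts)})
    cell_idx = (organ_idx * b + ct_idx).to_numpy()

    grand = y.mean(axis=1, keepdims=True)
    cell_means = np.zeros((n_feat, a * b))
    for c in range(a * b):
        cell_means[:, c] = y[:, cell_idx == c].mean(axis=1)
    organ_means = cell_means.reshape(n_feat, a, b).mean(axis=2)
    ct_means = cell_means.reshape(n_feat, a, b).mean(axis=1)

    ss_organ = r * b * ((organ_means - grand) ** 2).sum(axis=1)
    ss_ct = r * a * ((ct_means - grand) ** 2).sum(axis=1)
    inter = (cell_means.reshape(n_feat, a, b)
             - organ_means[:, :, None] - ct_means[:, None, :]
             + grand[:, :, None])
    ss_int = r * (inter ** 2).sum(axis=(1, 2))
    resid = y - cell_means[:, cell_idx]
    ss_err = (resid ** 2).sum(axis=1)

    df = {"organ": a - 1, "cell_type": b - 1,
          "interaction": (a - 1) * (b - 1)}
    df_err = a * b * (r - 1)
    ms_err = ss_err / df_err
    table = pd.DataFrame(index=m.values.index)
    for effect, ss in (("organ", ss_organ), ("cell_type", ss_ct),
                       ("interaction", ss_int)):
        ms = ss / df[effect]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ms / ms_err
        # constant feature: 0/0 -> no evidence of an effect
        f = np.where(ss <= 0, 0.0, f)
        p = np.where(np.isinf(f), 0.0,
                     scipy.stats.f.sf(np.where(np.isfinite(f), f, 0.0),
                                      df[effect], df_err))
        p = np.where(f == 0.0, 1.0, p)
        table[f"F_{effect}"] = f
        table[f"p_{effect}"] = p
        table[f"q_{effect}"] = bh_fdr(p)
    qcols = [c for c in table.columns if c.startswith("q_")]
    table["selected"] = (table[qcols].min(axis=1) < cfg.fdr_level)
    return DEResult(table=table, fdr_level=cfg.fdr_level)


def standardize_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Standardize each row to mean 0 and sample s.d. 1 (n-1 denominator);
    constant rows become all-zeros and are returned as flagged."""
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (x - mean) / safe_sd
    out[constant] = 0.0
    return (pd.DataFrame(out, index=values.index, columns=values.columns),
            values.index[constant])


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_patterns(standardized: pd.DataFrame,
                     cfg: AnalysisConfig = AnalysisConfig(),
                     ) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Seeded k-means over standardized expression profiles.

    Returns (assignment per feature, per-cluster mean profile, per-cluster
    s.d. profile). Deterministic under ``cfg.cluster_seed``.
    """
    k = cfg.n_pattern_clusters
    if k > standardized.shape[0]:
        raise ValueError(f"k={k} exceeds the {standardized.shape[0]} features")
    km = KMeans(n_clusters=k, n_init=50, random_state=cfg.cluster_seed)
    labels = km.fit_predict(standardized.to_numpy())
    assign = pd.Series(labels, index=standardized.index, name="cluster")
    means = standardized.groupby(assign).mean()
    sds = standardized.groupby(assign).std(ddof=1).fillna(0.0)
    return assign, means, sds


def sample_dendrogram(m: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree over samples on 1 - Pearson correlation.

    Returns the scipy linkage matrix and the column labels in order.
    """
    values = m.values.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for a dendrogram")
    sds = values.std(axis=0)
    if (sds == 0).any():
        bad = m.values.columns[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"sample {bad!r} is constant; correlation undefined")
    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = sch.linkage(condensed, method="average")
    return linkage, list(m.values.columns)


def top_split_labels(linkage: np.ndarray, labels: list[str],
                     n_groups: int) -> pd.Series:
    """Cut the tree into ``n_groups`` flat clusters (for inspecting whether
    the top of the tree separates cell types or organs)."""
    flat = sch.fcluster(linkage, t=n_groups, criterion="maxclust")
    return pd.Series(flat, index=labels)


# ---------------------------------------------------------------------------
# Gene set construction and marker calling
# ---------------------------------------------------------------------------

def hc_enriched_set(m: ExpressionMatrix,
                    cfg: AnalysisConfig = AnalysisConfig(),
                    numerator: str = "HC", denominator: str = "ENHC",
                    ) -> GeneSet:
    """Genes elevated >= fold_threshold in HCs vs ENHCs in either organ.

    Means are taken over replicates of floored, normalized values; the
    threshold is inclusive (>=).
    """
    members: set[str] = set()
    organs = list(m.design["organ"].unique())
    for organ in organs:
        num_cols = m.columns_where(organ=organ, cell_type=numerator)
        den_cols = m.columns_where(organ=organ, cell_type=denominator)
        if not num_cols or not den_cols:
            raise ValueError(
                f"missing {numerator}/{denominator} columns in organ {organ}")
        ratio = (m.values[num_cols].mean(axis=1)
                 / m.values[den_cols].mean(axis=1))
        qualifying = m.values.index[ratio >= cfg.fold_threshold]
        members |= set(m.genes.loc[qualifying])
    return GeneSet(name=f"{numerator}_enriched", members=members)


def call_markers(m: ExpressionMatrix,
                 cfg: AnalysisConfig = AnalysisConfig(),
                 ) -> list[MarkerCall]:
    """Strict cell-type markers on the normalized microarray-like scale.

    A gene marks cell type c (scope 'both') when the mean over all c
    samples exceeds ``marker_high`` and every individual non-c sample is
    below ``marker_low``; organ-restricted scopes additionally require all
    samples outside (c, organ) — including the other organ's c samples —
    below ``marker_low``. Deterministic and invariant to column order.
    """
    values = m.values.to_numpy(dtype=float)
    design = m.design
    cell_types = sorted(design["cell_type"].unique())
    organs = sorted(design["organ"].unique())
    col_pos = {c: i for i, c in enumerate(m.values.columns)}
    genes = m.genes.to_numpy()

    # organ-restricted scopes precede the pooled scope: a gene whose signal
    # is confined to one organ (the other organ's same-cell-type samples
    # below marker_low) is reported with its restricted scope even when the
    # pooled mean also clears marker_high
    scopes: list[tuple[str, str, np.ndarray]] = []
    for ct in cell_types:
        if len(organs) > 1:
            for o in organs:
                scopes.append((f"{o}_only", ct, np.array(
                    [col_pos[c]
                     for c in m.columns_where(cell_type=ct, organ=o)])))
        scopes.append(("both", ct, np.array(
            [col_pos[c] for c in m.columns_where(cell_type=ct)])))
    calls: list[MarkerCall] = []
    seen: set[str] = set()
    n_cols = values.shape[1]
    qualifying: list[tuple[int, MarkerCall]] = []
    for rank, (scope, ct, target_idx) in enumerate(scopes):
        if target_idx.size == 0:
            continue
        other_idx = np.setdiff1d(np.arange(n_cols), target_idx)
        t_mean = values[:, target_idx].mean(axis=1)
        max_other = values[:, other_idx].max(axis=1)
        hit = (t_mean > cfg.marker_high) & (max_other < cfg.marker_low)
        for i in np.flatnonzero(hit):
            qualifying.append((rank, MarkerCall(
                gene=str(genes[i]), cell_type=ct, organ_scope=scope,
                target_mean=float(t_mean[i]),
                max_other=float(max_other[i]))))
    qualifying.sort(key=lambda rc: (rc[1].gene, rc[0]))
    for _rank, call in qualifying:
        if call.gene in seen:
            continue
        seen.add(call.gene)
        calls.append(call)
    calls.sort(key=lambda c: c.gene)
    return calls


def validate_markers(markers: list[MarkerCall], rnaseq: ExpressionMatrix,
                     cfg: AnalysisConfig = AnalysisConfig(),
                     min_fold: float = 2.0) -> dict:
    """Check marker folds on a second platform.

    Per marker and organ, fold = mean(target cell type) / mean(all other
    cell types present); a marker passes when its best organ fold is >=
    ``min_fold``. Markers absent from the platform (gene or cell type) are
    excluded and counted.
    """
    organs = list(rnaseq.design["organ"].unique())
    platform_cts = set(rnaseq.design["cell_type"].unique())
    gene_rows = {}
    for feature in rnaseq.values.index:
        gene_rows.setdefault(rnaseq.genes.loc[feature], feature)
    per_marker = []
    excluded = 0
    for call in markers:
        if call.gene not in gene_rows or call.cell_type not in platform_cts:
            excluded += 1
            continue
        row = rnaseq.values.loc[gene_rows[call.gene]]
        folds = {}
        for organ in organs:
            t_cols = rnaseq.columns_where(organ=organ,
                                          cell_type=call.cell_type)
            o_cols = [c for c in rnaseq.columns_where(organ=organ)
                      if c not in t_cols]
            if not t_cols or not o_cols:
                continue
            folds[organ] = float(row[t_cols].mean() / row[o_cols].mean())
        if not folds:
            excluded += 1
            continue
        per_marker.append({"gene": call.gene, "cell_type": call.cell_type,
                           **{f"fold_{o}": f for o, f in folds.items()},
                           "passes": max(folds.values()) >= min_fold})
    frame = pd.DataFrame(per_marker)
    summary = {"n_validated": len(per_marker), "n_excluded": excluded,
               "fraction_passing": (float(frame["passes"].mean())
                                    if len(frame) else float("nan"))}
    for organ in organs:
        col = f"fold_{organ}"
        if len(frame) and col in frame:
            summary[f"mean_fold_{organ}"] = float(frame[col].mean())
    return {"per_marker": frame, "summary": summary}
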