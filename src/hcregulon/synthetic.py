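"""Ground-truthed synthetic inputs for the inner-ear regulon pipeline.

Emulates the statistical structure the analysis assumes: a 2-organ x
3-cell-type x r-replicate expression design whose dominant covariance axis
is cell type, a planted hair-cell (HC) regulon with elevated expression in
HCs, promoters carrying planted motif instances concentrated near the TSS,
ChIP-derived target lists overlapping the regulon, and an ortholog map to a
second synthetic species with partial regulon conservation.

Every generator derives its random stream from ``params.seed`` plus a fixed
per-stage tag, so outputs are byte-identical under a fixed seed and
independent of the order in which stages run.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .io_formats import (GeneSet, OrthologMap, PWM, PromoterWindow,
                         TSSRecord, reverse_complement)

BASES = "ACGT"

# Default planted motif: palindromic 14-mer shaped like an X-box half-site /
# spacer / half-site: sharp 2-column flanks, two-fold degenerate core.
# Column sharpness was chosen so that, scanned at 0.8 of the maximum
# log-odds, a 1.5 kb background promoter carries a hit with probability
# ~0.12 — the moderate information content of real palindromic motifs that
# yields genome-scale enrichment factors in the 2-6 range rather than the
# implausibly clean separation a consensus-only motif would give.
DEFAULT_CONSENSUS = "GTTGCCATGGCAAC"
_COLUMN_KINDS = "SSDDDDDDDDDDSS"


def _default_pwm_probs() -> np.ndarray:
    rows = []
    for base, kind in zip(DEFAULT_CONSENSUS, _COLUMN_KINDS):
        i = BASES.index(base)
        if kind == "S":                       # sharp column
            row = [0.03] * 4
            row[i] = 0.91
        else:                                 # two-fold degenerate column
            row = [0.08] * 4
            row[i] = 0.43
            row[(i + 1) % 4] = 0.41
        rows.append(row)
    return np.array(rows)


def default_pwm() -> PWM:
    return PWM(probs=_default_pwm_probs(), pseudocount=0.0, name="xbox_like")


@dataclasses.dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_genes: int = 5000
    n_regulon: int = 200
    n_markers_per_type: int = 50
    organs: tuple[str, ...] = ("cochlea", "vestibule")
    cell_types: tuple[str, ...] = ("HC", "ENHC", "NEC")
    n_replicates: int = 3

    # expression model (log2 scale)
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.0
    regulon_base_log2_range: tuple[float, float] = (7.5, 9.5)
    celltype_effect: float = 2.0       # regulon boost in HC columns
    organ_effect: float = 0.15         # half-width of per-gene organ effect
    celltype_spread: float = 0.35      # half-width of background cell-type effect
    noise_sd: float = 0.25
    marker_high_level: float = 600.0
    marker_low_level: float = 60.0
    detection_threshold: float = 125.0

    # promoters and motif
    window: PromoterWindow = dataclasses.field(default_factory=PromoterWindow)
    flank: int = 50
    motif_insert_rate_target: float = 0.8
    motif_insert_rate_background: float = 0.05
    motif_position_mean: float = -50.0
    motif_position_sd: float = 30.0
    consensus_bias: float = 0.7        # P(base = column consensus) when planting
    gc_content: float = 0.5

    # validation inputs
    chip_sensitivity: float = 0.7
    chip_extra: int = 100
    ortholog_conservation: float = 0.7

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("motif_insert_rate_target", "motif_insert_rate_background",
                     "consensus_bias", "chip_sensitivity",
                     "ortholog_conservation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        n_planted = self.n_regulon + self.n_markers_per_type * len(self.cell_types)
        if n_planted > self.n_genes:
            raise ValueError(
                f"regulon + markers ({n_planted}) exceed n_genes "
                f"({self.n_genes})")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates per condition")

    @property
    def base_composition(self) -> np.ndarray:
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


@dataclasses.dataclass
class TruthRecord:
    """Planted ground truth used to score the pipeline's recovery."""

    regulon: GeneSet
    markers: dict[str, GeneSet]
    motif_positions: dict[str, list[int]]
    chip_targets: GeneSet | None = None
    conserved_regulon: GeneSet | None = None
    pwm_used: PWM | None = None
    consensus: str = DEFAULT_CONSENSUS


_STAGE_TAGS = {"truth": 11, "expression": 12, "expression_counts": 13,
               "genome": 14, "chip_a": 15, "chip_b": 16, "ortholog": 17,
               "genome_b": 18}


def _rng(params: SimulationParams, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed,
                               spawn_key=(_STAGE_TAGS[stage],)))


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

def generate_truth(params: SimulationParams) -> TruthRecord:
    """Sample disjoint regulon and per-cell-type marker sets."""
    rng = _rng(params, "truth")
    genes = params.gene_names()
    order = rng.permutation(params.n_genes)
    pos = 0
    regulon = {genes[i] for i in order[pos:pos + params.n_regulon]}
    pos += params.n_regulon
    markers: dict[str, GeneSet] = {}
    for ct in params.cell_types:
        members = {genes[i] for i in order[pos:pos + params.n_markers_per_type]}
        pos += params.n_markers_per_type
        markers[ct] = GeneSet(name=f"markers_{ct}", members=members)
    return TruthRecord(regulon=GeneSet(name="regulon", members=regulon),
                       markers=markers, motif_positions={},
                       pwm_used=default_pwm(), consensus=DEFAULT_CONSENSUS)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _design_frame(params: SimulationParams, cell_types: tuple[str, ...]):
    import pandas as pd
    rows = []
    for organ in params.organs:
        for ct in cell_types:
            for rep in range(1, params.n_replicates + 1):
                rows.append({"sample_id": f"{organ}_{ct}_r{rep}",
                             "organ": organ, "cell_type": ct,
                             "replicate": rep})
    return pd.DataFrame(rows)


def generate_expression_matrix(params: SimulationParams, truth: TruthRecord,
                               platform: str = "array"):
    """Simulate a genes x samples matrix under a log-normal model.

    log2 x = base_g + cell-type effect + organ effect + N(0, noise_sd).
    Background genes receive bounded random per-cell-type and per-organ
    offsets (cell-type spread > organ spread, so samples cluster by cell
    type first). Regulon genes get +celltype_effect in HC columns; marker
    genes sit at ``marker_high_level`` in their own cell type and at
    ``marker_low_level`` elsewhere. ``platform='array'`` covers all cell
    types and attaches detection p-values; ``platform='counts'`` covers HC
    and ENHC only (a count-like validation platform, no detection table).
    """
    import pandas as pd
    from .io_formats import ExpressionMatrix

    if platform not in ("array", "counts"):
        raise ValueError(f"unknown platform {platform!r}")
    rng = _rng(params, "expression" if platform == "array"
               else "expression_counts")
    cell_types = (params.cell_types if platform == "array"
                  else tuple(ct for ct in params.cell_types
                             if ct in ("HC", "ENHC")))
    design = _design_frame(params, cell_types)
    genes = params.gene_names()
    n, s = len(genes), len(design)

    gene_index = {g: i for i, g in enumerate(genes)}
    regulon_idx = np.array(sorted(gene_index[g]
                                  for g in truth.regulon.members), dtype=int)
    marker_ct = np.full(n, -1)
    for ct, gs in truth.markers.items():
        if ct not in cell_types:
            # markers of a cell type absent from this platform behave as
            # near-floor background on it
            pass
        for g in gs.members:
            marker_ct[gene_index[g]] = params.cell_types.index(ct)

    base = rng.normal(params.base_log2_mean, params.base_log2_sd, size=n)
    lo, hi = params.regulon_base_log2_range
    base[regulon_idx] = rng.uniform(lo, hi, size=len(regulon_idx))

    ct_eff = rng.uniform(-params.celltype_spread, params.celltype_spread,
                         size=(n, len(params.cell_types)))
    org_eff = rng.uniform(-params.organ_effect, params.organ_effect,
                          size=(n, len(params.organs)))
    planted = marker_ct >= 0
    ct_eff[planted] = 0.0
    ct_eff[regulon_idx] = 0.0

    log2x = np.empty((n, s))
    hc_col = params.cell_types.index("HC")
    for j, row in design.iterrows():
        ct_i = params.cell_types.index(row["cell_type"])
        org_i = params.organs.index(row["organ"])
        col = base + ct_eff[:, ct_i] + org_eff[:, org_i]
        if ct_i == hc_col and len(regulon_idx):
            col = col.copy()
            col[regulon_idx] += params.celltype_effect
        # planted markers: fixed levels, organ effect still applies
        high = marker_ct == ct_i
        lowm = planted & ~high
        col[high] = math.log2(params.marker_high_level) + org_eff[high, org_i]
        col[lowm] = math.log2(params.marker_low_level) + org_eff[lowm, org_i]
        log2x[:, j] = col
    if params.noise_sd > 0:
        log2x += rng.normal(0.0, params.noise_sd, size=(n, s))

    values = pd.DataFrame(np.exp2(log2x), index=genes,
                          columns=list(design["sample_id"]))
    detection = None
    if platform == "array":
        detection = pd.DataFrame(
            np.where(values.to_numpy() >= params.detection_threshold,
                     0.001, 0.5),
            index=genes, columns=values.columns)
    return ExpressionMatrix(values=values, design=design,
                            detection_p=detection)


# ---------------------------------------------------------------------------
# Genome and promoters
# ---------------------------------------------------------------------------

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _draw_bases(rng: np.random.Generator, shape, comp: np.ndarray,
                ) -> np.ndarray:
    """i.i.d. base indices (0..3) from a composition vector."""
    cum = np.cumsum(comp)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(shape)).astype(np.int8)


def _to_seq(idx: np.ndarray) -> str:
    return _ASCII[idx.astype(np.int64)].tobytes().decode("ascii")


def _sample_motif_instance(pwm: PWM, bias: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Consensus-biased draw: each base is the column consensus with
    probability ``bias``, otherwise sampled from the PWM column."""
    out = np.empty(pwm.width, dtype=np.int8)
    for j, row in enumerate(pwm.probs):
        if rng.random() < bias:
            out[j] = int(row.argmax())
        else:
            out[j] = rng.choice(4, p=row / row.sum())
    return out


def generate_genome_and_promoters(params: SimulationParams,
                                  truth: TruthRecord,
                                  target_genes: set[str] | None = None,
                                  stage: str = "genome",
                                  gene_names: list[str] | None = None,
                                  record_positions: bool = True,
                                  ) -> tuple[dict[str, str], list[TSSRecord]]:
    """One synthetic contig per gene, with planted promoter motif instances.

    Target genes (the regulon by default) receive an instance with
    probability ``motif_insert_rate_target`` at a TSS-relative position
    ~ Normal(position_mean, position_sd) clamped inside the window;
    background genes with probability ``motif_insert_rate_background`` at a
    uniform position. Planted positions are recorded in
    ``truth.motif_positions`` (transcription-direction coordinates).
    """
    pwm = truth.pwm_used or default_pwm()
    u, d = params.window.upstream, params.window.downstream
    w = pwm.width
    if w > u + d:
        raise ValueError("motif is wider than the promoter window")
    rng = _rng(params, stage)
    genes = gene_names if gene_names is not None else params.gene_names()
    targets = (target_genes if target_genes is not None
               else truth.regulon.members)
    comp = params.base_composition
    length = u + d
    n = len(genes)
    contigs: dict[str, str] = {}
    records: list[TSSRecord] = []
    positions: dict[str, list[int]] = {}

    # bulk draws in a fixed order keep the stream reproducible
    proms = _draw_bases(rng, (n, length), comp)
    flanks = _draw_bases(rng, (n, 2 * params.flank), comp)
    strand_draw = rng.random(n)
    insert_draw = rng.random(n)
    normal_pos = rng.normal(params.motif_position_mean,
                            params.motif_position_sd, size=n)
    uniform_pos = rng.integers(-u, d - w + 1, size=n)

    for i, g in enumerate(genes):
        prom = proms[i]
        is_target = g in targets
        rate = (params.motif_insert_rate_target if is_target
                else params.motif_insert_rate_background)
        if insert_draw[i] < rate:
            rel = (int(round(normal_pos[i])) if is_target
                   else int(uniform_pos[i]))
            rel = min(max(rel, -u), d - w)
            inst = _sample_motif_instance(pwm, params.consensus_bias, rng)
            prom[rel + u:rel + u + w] = inst
            positions.setdefault(g, []).append(rel)
        prom_seq = _to_seq(prom)
        flank5 = _to_seq(flanks[i, :params.flank])
        flank3 = _to_seq(flanks[i, params.flank:])
        chrom = f"chr_{g}"
        if strand_draw[i] < 0.5:
            strand = "+"
            contigs[chrom] = flank5 + prom_seq + flank3
            tss = params.flank + u
        else:
            strand = "-"
            contigs[chrom] = flank5 + reverse_complement(prom_seq) + flank3
            tss = params.flank + d - 1
        records.append(TSSRecord(gene=g, chrom=chrom, tss=tss, strand=strand))
    if record_positions:
        truth.motif_positions.update(positions)
    return contigs, records


# ---------------------------------------------------------------------------
# ChIP targets and orthologs
# ---------------------------------------------------------------------------

def generate_chip_targets(params: SimulationParams, truth: TruthRecord,
                          stage: str = "chip_a") -> GeneSet:
    """ChIP-derived target list: each regulon gene is bound with probability
    ``chip_sensitivity``; ``chip_extra`` uniform non-regulon genes are
    added (off-target and non-HC-context binding)."""
    rng = _rng(params, stage)
    genes = params.gene_names()
    members = {g for g in sorted(truth.regulon.members)
               if rng.random() < params.chip_sensitivity}
    non_regulon = [g for g in genes if g not in truth.regulon.members]
    extra = rng.choice(len(non_regulon), size=params.chip_extra, replace=False)
    members |= {non_regulon[i] for i in extra}
    gs = GeneSet(name=stage, members=members)
    if stage == "chip_a":
        truth.chip_targets = gs
    return gs


def generate_ortholog_map(params: SimulationParams, truth: TruthRecord,
                          ) -> tuple[OrthologMap, dict[str, str],
                                     list[TSSRecord]]:
    """Ortholog map to a second species plus that species' promoters.

    Every species-A gene maps one-to-one to a species-B gene. A fraction
    ``ortholog_conservation`` of the regulon is conserved: the B-side
    promoters of conserved genes carry planted motifs at the target rate,
    all other B promoters at the background rate.
    """
    rng = _rng(params, "ortholog")
    genes = params.gene_names()
    width = max(4, len(str(params.n_genes - 1)))
    perm = rng.permutation(params.n_genes)
    pairs = {g: f"zg{perm[i]:0{width}d}" for i, g in enumerate(genes)}
    omap = OrthologMap(pairs=pairs)

    conserved = {g for g in sorted(truth.regulon.members)
                 if rng.random() < params.ortholog_conservation}
    truth.conserved_regulon = GeneSet(name="conserved_regulon",
                                      members=conserved)
    b_targets = {pairs[g] for g in conserved}
    b_genes = [pairs[g] for g in genes]
    contigs_b, tss_b = generate_genome_and_promoters(
        params, truth, target_genes=b_targets, stage="genome_b",
        gene_names=sorted(b_genes), record_positions=False)
    return omap, contigs_b, tss_b
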