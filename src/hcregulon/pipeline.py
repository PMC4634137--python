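"""End-to-end orchestration: simulate inputs, run every analysis stage in
order, write per-stage outputs and a seeded, hash-stamped run manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import expression as expr
from . import motif as mot
from . import validation as val
from .io_formats import (ExpressionMatrix, GeneSet, NARROWED_WINDOW,
                         PromoterWindow, extract_promoters, read_gene_list,
                         read_expression_table, read_genome_fasta,
                         read_ortholog_map, read_pwm_meme, read_tss_table,
                         write_expression_table, write_gene_list,
                         write_genome_fasta, write_ortholog_map,
                         write_pwm_meme, write_results, write_tss_table)
from .synthetic import (SimulationParams, TruthRecord, generate_chip_targets,
                        generate_expression_matrix, generate_genome_and_promoters,
                        generate_ortholog_map, generate_truth)

logger = logging.getLogger("hcregulon")


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "hcregulon_out"
    seed: int = 0
    log_level: str = "INFO"

    analysis: expr.AnalysisConfig = dataclasses.field(
        default_factory=expr.AnalysisConfig)
    theta: float = 0.8
    both_strands: bool = True
    window: PromoterWindow = dataclasses.field(default_factory=PromoterWindow)
    narrowed: PromoterWindow = dataclasses.field(
        default_factory=lambda: NARROWED_WINDOW)
    kmer_size: int = 8
    run_kmer_discovery: bool = True

    sim: SimulationParams = dataclasses.field(default_factory=SimulationParams)

    # input paths (filled by `simulate`, or provided for real data)
    expression_array: str | None = None
    design_array: str | None = None
    detection_p: str | None = None
    expression_counts: str | None = None
    design_counts: str | None = None
    genome: str | None = None
    tss: str | None = None
    pwm: str | None = None
    chip_a: str | None = None
    chip_b: str | None = None
    ortholog_map: str | None = None
    genome_b: str | None = None
    tss_b: str | None = None

    _PATH_KEYS = ("expression_array", "design_array", "detection_p",
                  "expression_counts", "design_counts", "genome", "tss",
                  "pwm", "chip_a", "chip_b", "ortholog_map", "genome_b",
                  "tss_b")

    def scan_config(self, window: PromoterWindow | None = None,
                    ) -> mot.ScanConfig:
        return mot.ScanConfig(threshold_fraction=self.theta,
                              both_strands=self.both_strands,
                              window=window or self.window)

    def config_hash(self) -> str:
        payload = _round_floats(dataclasses.asdict(self))
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key = value (TOML) config file."""
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_flat(data)

    @classmethod
    def from_flat(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        top_fields = {f.name for f in dataclasses.fields(cls)}
        analysis_fields = {f.name for f in
                           dataclasses.fields(expr.AnalysisConfig)}
        sim_fields = {f.name for f in dataclasses.fields(SimulationParams)}
        for key, value in data.items():
            if key in ("window_upstream", "window_downstream",
                       "narrowed_upstream", "narrowed_downstream"):
                side = key.rsplit("_", 1)[1]
                attr = "window" if key.startswith("window") else "narrowed"
                current = getattr(cfg, attr)
                kwargs = {"upstream": current.upstream,
                          "downstream": current.downstream, side: int(value)}
                setattr(cfg, attr, PromoterWindow(**kwargs))
            elif key in top_fields:       # seed/out_dir shadow sim fields
                setattr(cfg, key, value)
            elif key in analysis_fields:
                setattr(cfg.analysis, key, value)
            elif key in sim_fields:
                setattr(cfg.sim, key, value)
            else:
                raise KeyError(f"unknown config key {key!r}")
        cfg.sim.__post_init__()
        cfg.analysis.__post_init__()
        return cfg


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return float(f"{obj:.{ndigits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{ndigits}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _setup_logging(level: str, out_dir: Path) -> None:
    logger.setLevel(level.upper())
    logger.handlers = [h for h in logger.handlers
                       if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(sh)
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


# ---------------------------------------------------------------------------
# Simulation entry point
# ---------------------------------------------------------------------------

def simulate(config: PipelineConfig) -> tuple[PipelineConfig, TruthRecord]:
    """Write a ground-truthed synthetic input bundle under out_dir/inputs
    and return the config with all input paths filled, plus the truth."""
    out = Path(config.out_dir)
    inputs = out / "inputs"
    truth_dir = out / "truth"
    inputs.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config.log_level, out)

    params = dataclasses.replace(config.sim, seed=config.seed,
                                 window=config.window)
    config.sim = params
    truth = generate_truth(params)

    array = generate_expression_matrix(params, truth, platform="array")
    write_expression_table(array, inputs / "expression_array.tsv",
                           design_path=inputs / "design_array.tsv",
                           detection_path=inputs / "detection_p.tsv")
    counts = generate_expression_matrix(params, truth, platform="counts")
    write_expression_table(counts, inputs / "expression_counts.tsv",
                           design_path=inputs / "design_counts.tsv")

    contigs, tss = generate_genome_and_promoters(params, truth)
    write_genome_fasta(contigs, inputs / "genome_a.fasta")
    write_tss_table(tss, inputs / "tss_a.bed")
    write_pwm_meme(truth.pwm_used, inputs / "pwm.meme")

    chip_a = generate_chip_targets(params, truth, stage="chip_a")
    chip_b = generate_chip_targets(params, truth, stage="chip_b")
    write_gene_list(chip_a, inputs / "chip_a.txt")
    write_gene_list(chip_b, inputs / "chip_b.txt")

    omap, contigs_b, tss_b = generate_ortholog_map(params, truth)
    write_ortholog_map(omap, inputs / "orthologs.tsv")
    write_genome_fasta(contigs_b, inputs / "genome_b.fasta")
    write_tss_table(tss_b, inputs / "tss_b.bed")

    write_gene_list(truth.regulon, truth_dir / "regulon.txt")
    for ct, gs in truth.markers.items():
        write_gene_list(gs, truth_dir / f"markers_{ct}.txt")
    write_gene_list(truth.conserved_regulon,
                    truth_dir / "conserved_regulon.txt")
    pos_rows = [{"gene": g, "position": p}
                for g, ps in sorted(truth.motif_positions.items())
                for p in ps]
    pd.DataFrame(pos_rows).to_csv(truth_dir / "motif_positions.tsv",
                                  sep="\t", index=False)
    (truth_dir / "consensus.txt").write_text(truth.consensus + "\n")

    config.expression_array = str(inputs / "expression_array.tsv")
    config.design_array = str(inputs / "design_array.tsv")
    config.detection_p = str(inputs / "detection_p.tsv")
    config.expression_counts = str(inputs / "expression_counts.tsv")
    config.design_counts = str(inputs / "design_counts.tsv")
    config.genome = str(inputs / "genome_a.fasta")
    config.tss = str(inputs / "tss_a.bed")
    config.pwm = str(inputs / "pwm.meme")
    config.chip_a = str(inputs / "chip_a.txt")
    config.chip_b = str(inputs / "chip_b.txt")
    config.ortholog_map = str(inputs / "orthologs.tsv")
    config.genome_b = str(inputs / "genome_b.fasta")
    config.tss_b = str(inputs / "tss_b.bed")
    logger.info("simulated inputs for %d genes under %s",
                params.n_genes, inputs)
    return config, truth


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute every stage in order and write a report bundle.

    Stages: detection filter -> quantile normalization -> two-way ANOVA DE
    (+BH) -> standardize -> pattern clustering -> sample dendrogram ->
    HC-enriched set -> marker calling (+cross-platform validation) ->
    promoter extraction -> motif enrichment (full window) -> positional
    analysis -> narrowed re-test -> k-mer discovery -> ChIP intersection ->
    cross-species test -> HC-enrichment scores + shift test. A cached
    report is returned when the manifest's config hash matches (no silent
    recomputation: the cache hit is logged).
    """
    out = Path(config.out_dir)
    res = out / "results"
    res.mkdir(parents=True, exist_ok=True)
    _setup_logging(config.log_level, out)
    cfg_hash = config.config_hash()

    manifest_path = res / "manifest.json"
    if manifest_path.exists() and not force:
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == cfg_hash:
            logger.info("cached results match config hash %s; reusing",
                        cfg_hash[:12])
            return json.loads((res / "report.json").read_text())

    report: dict = {"seed": config.seed}
    stage = "load_inputs"
    try:
        for key in ("expression_array", "design_array", "expression_counts",
                    "design_counts", "genome", "tss", "pwm"):
            path = getattr(config, key)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"required input {key!r} missing "
                                        f"({path})")
        array = read_expression_table(config.expression_array,
                                      config.design_array,
                                      detection_path=config.detection_p)
        counts_raw = read_expression_table(config.expression_counts,
                                           config.design_counts)

        stage = "detection_filter"
        detected = expr.detection_filter(array, config.analysis)
        report["n_features_input"] = int(array.values.shape[0])
        report["n_features_detected"] = int(detected.values.shape[0])

        stage = "quantile_normalize"
        normed = expr.quantile_normalize(detected)
        write_expression_table(normed, res / "normalized_array.tsv")

        stage = "normalize_counts"
        counts = expr.normalize_counts(counts_raw, config.analysis)
        write_expression_table(counts, res / "normalized_counts.tsv")

        stage = "anova_de"
        de = expr.anova_de(normed, config.analysis)
        de.table.to_csv(res / "de_table.tsv", sep="\t")
        report["n_de_selected"] = int(de.table["selected"].sum())

        stage = "cluster_patterns"
        standardized, constant = expr.standardize_rows(
            normed.values.loc[de.selected])
        standardized = standardized.drop(index=constant)
        assign, cmeans, csds = expr.cluster_patterns(standardized,
                                                     config.analysis)
        assign.to_csv(res / "clusters.tsv", sep="\t")
        cmeans.to_csv(res / "cluster_mean_profiles.tsv", sep="\t")
        csds.to_csv(res / "cluster_sd_profiles.tsv", sep="\t")
        report["cluster_sizes"] = assign.value_counts().sort_index().tolist()

        stage = "sample_dendrogram"
        linkage, labels = expr.sample_dendrogram(normed)
        pd.DataFrame(linkage, columns=["left", "right", "height", "size"]
                     ).to_csv(res / "sample_linkage.tsv", sep="\t",
                              index=False)
        split = expr.top_split_labels(linkage, labels,
                                      normed.design["cell_type"].nunique())
        ct_of = dict(zip(normed.design["sample_id"],
                         normed.design["cell_type"]))
        purity = (pd.DataFrame({"cluster": split,
                                "cell_type": [ct_of[s] for s in split.index]})
                  .groupby("cluster")["cell_type"]
                  .agg(lambda s: s.value_counts().iloc[0] / len(s)))
        report["dendrogram_celltype_purity"] = float(purity.mean())

        stage = "hc_enriched_set"
        hc_set = expr.hc_enriched_set(counts, config.analysis)
        write_gene_list(hc_set, res / "hc_enriched.txt")
        report["n_hc_enriched"] = len(hc_set)

        stage = "call_markers"
        markers = expr.call_markers(normed, config.analysis)
        pd.DataFrame([dataclasses.asdict(c) for c in markers]
                     ).to_csv(res / "markers.tsv", sep="\t", index=False)
        by_type = {}
        for c in markers:
            by_type.setdefault(c.cell_type, 0)
            by_type[c.cell_type] += 1
        report["n_markers"] = {k: int(v) for k, v in sorted(by_type.items())}

        stage = "validate_markers"
        mval = expr.validate_markers(markers, counts, config.analysis)
        mval["per_marker"].to_csv(res / "marker_validation.tsv", sep="\t",
                                  index=False)
        report["marker_validation"] = mval["summary"]

        stage = "extract_promoters"
        genome = read_genome_fasta(config.genome)
        tss = read_tss_table(config.tss)
        promoters = extract_promoters(genome, tss, config.window)
        pwm = read_pwm_meme(config.pwm)

        stage = "motif_enrichment_full"
        background = GeneSet(
            name="expressed",
            members=set(counts.genes) & set(promoters.sequences))
        targets = GeneSet(name="hc_enriched",
                          members=hc_set.members & background.members)
        scan_full = config.scan_config(config.window)
        hits = mot.scan_promoters(promoters, pwm, scan_full)
        hit_rows = [dataclasses.asdict(h)
                    for hs in hits.values() for h in hs]
        pd.DataFrame(hit_rows).to_csv(res / "motif_hits.tsv", sep="\t",
                                      index=False)
        enrich_full = mot.motif_enrichment_test(promoters, targets,
                                                background, pwm, scan_full,
                                                hits=hits)
        write_results(enrich_full, res / "enrichment_full.json")
        report["motif_enrichment_full"] = dataclasses.asdict(enrich_full)

        stage = "positional_analysis"
        target_hits = {g: hits[g] for g in targets.members if g in hits}
        hist = mot.positional_distribution(target_hits, config.window)
        hist_frame = pd.DataFrame(
            {"bin_start": [iv.left for iv in hist.index],
             "bin_end": [iv.right for iv in hist.index],
             "n_genes": hist.to_numpy()})
        hist_frame.to_csv(res / "positional_histogram.tsv", sep="\t",
                          index=False)
        peak = mot.detect_tss_peak_and_narrow(hist, config.window,
                                              config.narrowed)
        report["positional_mode_bin"] = list(peak["mode_bin"])

        stage = "motif_enrichment_narrowed"
        scan_narrow = config.scan_config(config.narrowed)
        hits_narrow = mot.scan_promoters(promoters, pwm, scan_narrow)
        enrich_narrow = mot.motif_enrichment_test(promoters, targets,
                                                  background, pwm,
                                                  scan_narrow,
                                                  hits=hits_narrow)
        write_results(enrich_narrow, res / "enrichment_narrowed.json")
        report["motif_enrichment_narrowed"] = dataclasses.asdict(enrich_narrow)

        candidates = GeneSet(
            name="putative_targets",
            members={g for g in targets.members if hits_narrow.get(g)})
        write_gene_list(candidates, res / "putative_targets.txt")
        report["n_putative_targets"] = len(candidates)

        stage = "kmer_discovery"
        if config.run_kmer_discovery:
            kd = mot.kmer_discovery(promoters, targets, background,
                                    k=config.kmer_size, cfg=scan_narrow)
            kd["table"].to_csv(res / "kmer_table.tsv", sep="\t", index=False)
            write_pwm_meme(kd["derived_pwm"], res / "denovo_pwm.meme")
            report["top_kmer"] = kd["top_kmer"]
            report["kmer_min_p_bonferroni"] = kd["min_p_bonferroni"]

        stage = "chip_intersection"
        if config.chip_a and config.chip_b:
            chip_a = read_gene_list(config.chip_a, "chip_a")
            chip_b = read_gene_list(config.chip_b, "chip_b")
            universe = GeneSet(name="universe",
                               members=background.members
                               | chip_a.members | chip_b.members
                               | candidates.members)
            inter = val.chip_intersection(candidates, chip_a, chip_b,
                                          universe)
            write_results(inter, res / "chip_intersection.json")
            report["chip_intersection"] = inter

        stage = "cross_species"
        if config.ortholog_map and config.genome_b and config.tss_b:
            omap = read_ortholog_map(config.ortholog_map)
            genome_b = read_genome_fasta(config.genome_b)
            tss_b = read_tss_table(config.tss_b)
            promoters_b = extract_promoters(genome_b, tss_b, config.window)
            background_b = GeneSet(name="expressed_b",
                                   members=set(promoters_b.sequences))
            xsp = mot.cross_species_test(candidates, omap, promoters_b,
                                         background_b, pwm, scan_full)
            write_results(xsp, res / "cross_species.json")
            report["cross_species"] = dataclasses.asdict(xsp)

        stage = "shift_test"
        scores = val.hc_enrichment_scores(array_floored(array, config))
        scores.to_csv(res / "hc_enrichment_scores.tsv", sep="\t", index=False)
        if config.chip_a:
            chip_set = read_gene_list(config.chip_a, "chip_a").members
            in_set = scores["gene"].isin(chip_set)
            shift = val.shift_test(scores.loc[in_set, "log2_ratio"],
                                   scores.loc[~in_set, "log2_ratio"],
                                   set_label="chip_targets")
            write_results(shift, res / "shift_test.json")
            report["shift_test"] = dataclasses.asdict(shift)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = _round_floats(report)
    report_text = json.dumps(report, indent=2, sort_keys=True)
    (res / "report.json").write_text(report_text + "\n")
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": cfg_hash,
        "report_hash": hashlib.sha256(report_text.encode()).hexdigest(),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    logger.info("pipeline complete; report hash %s",
                manifest["report_hash"][:12])
    return report


def array_floored(array: ExpressionMatrix, config: PipelineConfig,
                  ) -> ExpressionMatrix:
    """Detection-filtered, quantile-normalized, floored microarray matrix
    used for the per-gene HC-enrichment ratios (floor keeps ratios finite)."""
    detected = expr.detection_filter(array, config.analysis)
    normed = expr.quantile_normalize(detected)
    floored = normed.values.clip(lower=config.analysis.floor_value)
    return normed.replace_values(floored)
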