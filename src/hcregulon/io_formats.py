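"""Readers, writers and promoter extraction for the pipeline's file formats.

All coordinates are 0-based, half-open (BED convention). Promoter sequences
are reported 5'->3' in the direction of transcription, with relative
position 0 at the TSS base.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("hcregulon")

CELL_TYPES = ("HC", "ENHC", "NEC")
ORGANS = ("cochlea", "vestibule")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an aligned sample design.

    ``values`` is a DataFrame indexed by feature id; ``design`` has one row
    per column of ``values`` with fields sample_id, organ, cell_type,
    replicate. ``feature_to_gene`` maps feature ids to gene symbols
    (identity when features are genes). ``detection_p`` is an optional
    matrix of per-measurement detection p-values with the same shape.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    feature_to_gene: pd.Series | None = None
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be non-negative")
        if len(self.design) != self.values.shape[1]:
            raise ValueError(
                f"design rows ({len(self.design)}) do not match sample "
                f"columns ({self.values.shape[1]})")
        if list(self.design["sample_id"]) != list(self.values.columns):
            raise ValueError("design sample_ids do not match value columns")
        if self.design["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        if self.feature_to_gene is None:
            self.feature_to_gene = pd.Series(
                self.values.index, index=self.values.index)
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError("detection_p shape mismatch")
            dp = self.detection_p.to_numpy()
            if ((dp < 0) | (dp > 1)).any():
                raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def genes(self) -> pd.Series:
        return self.feature_to_gene.loc[self.values.index]

    def columns_where(self, **criteria: str) -> list[str]:
        """Sample ids whose design matches all given field values."""
        mask = np.ones(len(self.design), dtype=bool)
        for field, value in criteria.items():
            mask &= (self.design[field] == value).to_numpy()
        return list(self.design.loc[mask, "sample_id"])

    def replace_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        dp = self.detection_p
        if dp is not None:
            dp = dp.loc[values.index, values.columns]
        return ExpressionMatrix(
            values=values,
            design=self.design.reset_index(drop=True),
            feature_to_gene=self.feature_to_gene.loc[values.index],
            detection_p=dp,
        )


@dataclasses.dataclass(frozen=True)
class TSSRecord:
    """Transcription start site of one gene (0-based genomic coordinate)."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene}")


@dataclasses.dataclass(frozen=True)
class PromoterWindow:
    """TSS-relative window: ``upstream`` nt before and ``downstream`` after."""

    upstream: int = 1000
    downstream: int = 500

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window sides must be non-negative")
        if self.upstream + self.downstream < 1:
            raise ValueError("window must cover at least one base")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream


NARROWED_WINDOW = PromoterWindow(upstream=200, downstream=100)


@dataclasses.dataclass
class PromoterSet:
    """Strand-aware promoter sequences in transcription-direction coords.

    ``offsets[gene]`` is the relative coordinate of the first base
    (normally ``-window.upstream``; larger if clipped at a contig edge).
    """

    sequences: dict[str, str]
    offsets: dict[str, int]
    strands: dict[str, str]
    window: PromoterWindow
    clipped: set[str] = dataclasses.field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequences)

    def genes(self) -> list[str]:
        return list(self.sequences)


@dataclasses.dataclass
class PWM:
    """Position weight matrix over ACGT with background composition."""

    probs: np.ndarray            # width x 4, rows sum to 1
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a width x 4 matrix")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")
        # add pseudocount, renormalize
        self.probs = self.probs + self.pseudocount
        self.probs = self.probs / self.probs.sum(axis=1, keepdims=True)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError("PWM probabilities must be positive")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2(p / background) per column and base; width x 4."""
        return np.log2(self.probs / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(probs=self.probs[::-1, ::-1],
                   background=self.background[::-1],
                   pseudocount=0.0, name=self.name + "_rc")


@dataclasses.dataclass
class GeneSet:
    name: str
    members: set[str]

    def __post_init__(self) -> None:
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclasses.dataclass
class OrthologMap:
    """One-to-one map from species-A gene symbols to species-B symbols."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        values = list(self.pairs.values())
        if len(set(values)) != len(values):
            raise ValueError("ortholog map is not one-to-one after resolution")

    def map_set(self, genes: Iterable[str]) -> tuple[set[str], int]:
        """Map genes through; returns (mapped set, number unmapped)."""
        mapped, unmapped = set(), 0
        for g in genes:
            if g in self.pairs:
                mapped.add(self.pairs[g])
            else:
                unmapped += 1
        return mapped, unmapped


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_design_table(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "organ", "cell_type", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return design


def read_expression_table(path: str | Path, design_path: str | Path,
                          detection_path: str | Path | None = None,
                          gene_map_path: str | Path | None = None,
                          ) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its sample-design table.

    The first column holds feature ids; all other columns must be numeric.
    A companion detection-p table (same layout) is read when given.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate feature id: {dup!r}")
    for col in raw.columns:
        bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
        if bad.any() or raw[col].isna().any():
            row = raw.index[bad | raw[col].isna()][0]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
    values = raw.astype(float)

    design = read_design_table(design_path)
    if set(design["sample_id"]) != set(values.columns):
        raise ValueError("design sample_ids do not cover the value columns")
    design = design.set_index("sample_id").loc[list(values.columns)]
    design = design.reset_index()

    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col=0)
        detection = detection.loc[values.index, values.columns].astype(float)

    gene_map = None
    if gene_map_path is not None:
        gm = pd.read_csv(gene_map_path, sep="\t", index_col=0)
        gene_map = gm.iloc[:, 0].reindex(values.index)
        gene_map = gene_map.fillna(pd.Series(values.index, index=values.index))

    return ExpressionMatrix(values=values, design=design,
                            feature_to_gene=gene_map, detection_p=detection)


def read_pwm_meme(path: str | Path, pseudocount: float = 1e-3) -> PWM:
    """Read the first motif from a MEME minimal-format file.

    Rows of the letter-probability matrix must sum to 1 within 0.01 before
    the pseudocount is applied; a second motif in the file is ignored with
    a warning.
    """
    lines = Path(path).read_text().splitlines()
    alphabet_seen = any(
        ln.strip().upper().startswith("ALPHABET") and "ACGT" in ln.upper()
        for ln in lines)
    if not alphabet_seen:
        raise ValueError("MEME file lacks an 'ALPHABET= ACGT' line")

    background = np.full(4, 0.25)
    for i, ln in enumerate(lines):
        if ln.strip().lower().startswith("background letter frequencies"):
            fields = lines[i + 1].split()
            background = np.array([float(fields[j]) for j in (1, 3, 5, 7)])

    motif_idx = [i for i, ln in enumerate(lines)
                 if ln.strip().startswith("MOTIF")]
    if not motif_idx:
        raise ValueError("MEME file contains no MOTIF block")
    if len(motif_idx) > 1:
        logger.warning("MEME file has %d motifs; loading the first",
                       len(motif_idx))
    name = lines[motif_idx[0]].split()[1]

    rows = []
    started = False
    for ln in lines[motif_idx[0] + 1:]:
        s = ln.strip()
        if s.startswith("letter-probability"):
            started = True
            continue
        if not started:
            continue
        if not s or s.startswith(("MOTIF", "URL")):
            break
        row = [float(x) for x in s.split()]
        if len(row) != 4:
            raise ValueError(f"expected 4 probabilities per row, got {s!r}")
        if abs(sum(row) - 1.0) > 0.01:
            raise ValueError(f"PWM row sums to {sum(row):.4f}, not 1: {s!r}")
        rows.append(row)
    if not rows:
        raise ValueError("MOTIF block has no letter-probability rows")
    return PWM(probs=np.array(rows), background=background,
               pseudocount=pseudocount, name=name)


def write_pwm_meme(pwm: PWM, path: str | Path) -> None:
    w = pwm.width
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "Background letter frequencies",
        "A {:.5f} C {:.5f} G {:.5f} T {:.5f}".format(*pwm.background), "",
        f"MOTIF {pwm.name}",
        f"letter-probability matrix: alength= 4 w= {w} nsites= 20 E= 0",
    ]
    for row in pwm.probs:
        lines.append(" ".join(f"{p:.6f}" for p in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read TSS records from a BED6 file (0-based, half-open).

    TSS = start for + strand genes, end - 1 for - strand genes. On
    duplicate gene names the first record wins, with a warning.
    """
    records: list[TSSRecord] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        fields = ln.split("\t")
        if len(fields) < 6:
            raise ValueError(f"BED line {lineno} has fewer than 6 fields")
        chrom, start, end, name, _score, strand = fields[:6]
        start, end = int(start), int(end)
        if end <= start:
            raise ValueError(f"BED line {lineno}: end <= start")
        if strand not in ("+", "-"):
            raise ValueError(f"BED line {lineno}: bad strand {strand!r}")
        if name in seen:
            logger.warning("duplicate gene %r in %s; keeping first", name, path)
            continue
        seen.add(name)
        tss = start if strand == "+" else end - 1
        records.append(TSSRecord(gene=name, chrom=chrom, tss=tss,
                                 strand=strand))
    return records


def write_tss_table(records: list[TSSRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        start, end = r.tss, r.tss + 1
        lines.append(f"{r.chrom}\t{start}\t{end}\t{r.gene}\t0\t{r.strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_promoters(genome: Mapping[str, str] | str | Path,
                      tss_records: list[TSSRecord],
                      window: PromoterWindow = PromoterWindow(),
                      ) -> PromoterSet:
    """Extract strand-aware promoter sequences around each TSS.

    For a + strand gene the genomic interval [tss-u, tss+d) is taken as is;
    for a - strand gene the interval [tss-d+1, tss+u+1) is taken and
    reverse-complemented, so position 0 is always the TSS base read in the
    direction of transcription. Intervals falling off a contig edge are
    clipped (never padded) and the gene is flagged.
    """
    if not isinstance(genome, Mapping):
        genome = read_genome_fasta(genome)
    u, d = window.upstream, window.downstream
    sequences: dict[str, str] = {}
    offsets: dict[str, int] = {}
    strands: dict[str, str] = {}
    clipped: set[str] = set()
    for rec in tss_records:
        if rec.chrom not in genome:
            raise KeyError(f"chromosome {rec.chrom!r} not in genome "
                           f"(gene {rec.gene})")
        contig = genome[rec.chrom]
        if rec.strand == "+":
            lo, hi = rec.tss - u, rec.tss + d
            clo, chi = max(lo, 0), min(hi, len(contig))
            seq = contig[clo:chi]
            offset = -(rec.tss - clo)
        else:
            lo, hi = rec.tss - d + 1, rec.tss + u + 1
            clo, chi = max(lo, 0), min(hi, len(contig))
            seq = reverse_complement(contig[clo:chi])
            offset = -(chi - 1 - rec.tss)
        if clo != lo or chi != hi:
            clipped.add(rec.gene)
        if not seq:
            continue
        sequences[rec.gene] = seq
        offsets[rec.gene] = offset
        strands[rec.gene] = rec.strand
    if not sequences:
        raise ValueError("no promoters could be extracted")
    return PromoterSet(sequences=sequences, offsets=offsets, strands=strands,
                       window=window, clipped=clipped)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set from a plain-text file, one symbol per line.

    '#' comment lines are skipped; symbols are case-sensitive and
    deduplicated.
    """
    members = []
    for ln in Path(path).read_text().splitlines():
        s = ln.strip()
        if not s or s.startswith("#"):
            continue
        members.append(s)
    if not members:
        raise ValueError(f"gene list {path} is empty")
    return GeneSet(name=name or Path(path).stem, members=set(members))


def write_gene_list(genes: GeneSet | Iterable[str], path: str | Path) -> None:
    members = genes.members if isinstance(genes, GeneSet) else set(genes)
    Path(path).write_text("\n".join(sorted(members)) + "\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of (species-A gene, species-B gene) pairs.

    Many-to-many raw pairs are resolved to one-to-one: the first pair per
    A gene wins, and B genes already assigned are skipped.
    """
    pairs: dict[str, str] = {}
    used_b: set[str] = set()
    n_dropped = 0
    for ln in Path(path).read_text().splitlines():
        s = ln.strip()
        if not s or s.startswith("#"):
            continue
        fields = s.split("\t")
        if len(fields) < 2:
            raise ValueError(f"ortholog map line lacks two columns: {s!r}")
        a, b = fields[0], fields[1]
        if a in pairs or b in used_b:
            n_dropped += 1
            continue
        pairs[a] = b
        used_b.add(b)
    if n_dropped:
        logger.warning("ortholog map: dropped %d many-to-many pairs",
                       n_dropped)
    return OrthologMap(pairs=pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    lines = [f"{a}\t{b}" for a, b in sorted(omap.pairs.items())]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    return obj


def write_results(results, path: str | Path) -> None:
    """Serialize a pipeline record to JSON (records) or TSV (matrices).

    ExpressionMatrix values round-trip exactly through
    ``read_expression_table``; records are written with deterministic key
    order.
    """
    path = Path(path)
    if isinstance(results, ExpressionMatrix):
        write_expression_table(results, path)
        return
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, sep="\t")
        return
    payload = _jsonable(results)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_expression_table(m: ExpressionMatrix, path: str | Path,
                           design_path: str | Path | None = None,
                           detection_path: str | Path | None = None) -> None:
    path = Path(path)
    m.values.to_csv(path, sep="\t", index_label="feature_id",
                    float_format="%.17g")
    if design_path is not None:
        m.design.to_csv(design_path, sep="\t", index=False)
    if detection_path is not None and m.detection_p is not None:
        m.detection_p.to_csv(detection_path, sep="\t",
                             index_label="feature_id", float_format="%.17g")
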