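"""Promoter motif analysis: PWM log-odds scanning, hypergeometric
over-representation with an enrichment factor, TSS positional analysis and
window narrowing, simplified k-mer seed discovery, and cross-species
enrichment through an ortholog map.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import logsumexp

from .io_formats import (GeneSet, OrthologMap, PWM, PromoterSet,
                         PromoterWindow, NARROWED_WINDOW)

logger = logging.getLogger("hcregulon")

_ENCODE = np.full(256, 4, dtype=np.int8)   # N and anything else -> 4
for i, base in enumerate("ACGT"):
    _ENCODE[ord(base)] = i
    _ENCODE[ord(base.lower())] = i


def encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclasses.dataclass(frozen=True)
class MotifHit:
    gene: str
    position: int          # match start, transcription-direction coords, TSS=0
    strand: str            # + = promoter orientation, - = reverse complement
    score: float


@dataclasses.dataclass
class EnrichmentResult:
    """Hypergeometric set-test record shared by every enrichment stage."""

    N: int                 # background universe size
    K: int                 # universe genes carrying the property
    n: int                 # target-set size
    k: int                 # target genes carrying the property
    p: float
    enrichment_factor: float
    n_missing: int = 0     # genes dropped (no promoter / unmapped)

    @classmethod
    def from_counts(cls, N: int, K: int, n: int, k: int,
                    n_missing: int = 0) -> "EnrichmentResult":
        p = hypergeom_tail(N, K, n, k)
        ef = float("nan") if K == 0 or n == 0 else (k / n) / (K / N)
        return cls(N=N, K=K, n=n, k=k, p=p, enrichment_factor=ef,
                   n_missing=n_missing)


@dataclasses.dataclass
class ScanConfig:
    threshold_fraction: float = 0.8    # of the maximum achievable log-odds
    both_strands: bool = True
    window: PromoterWindow = dataclasses.field(default_factory=PromoterWindow)

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Hypergeometric tail (single source of truth for all set tests)
# ---------------------------------------------------------------------------

def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    N: universe size, K: property-carrying genes, n: draws, k: observed.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if k > K:
        raise ValueError(f"k={k} exceeds K={K}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    support = np.arange(k, hi + 1)
    logp = scipy.stats.hypergeom.logpmf(support, N, K, n)
    p = float(np.exp(logsumexp(logp)))
    # the log-space sum is finite even when exp() underflows; keep p > 0
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def pwm_log_odds(pwm: PWM, window_seq: str) -> float:
    """Log2-odds score of one width-length window; N bases contribute 0."""
    if len(window_seq) != pwm.width:
        raise ValueError(
            f"window length {len(window_seq)} != PWM width {pwm.width}")
    lo = np.hstack([pwm.log_odds(), np.zeros((pwm.width, 1))])
    idx = encode_sequence(window_seq)
    return float(lo[np.arange(pwm.width), idx].sum())


def _window_scores(lo5: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Scores of all windows: lo5 is width x 5 log-odds (5th column = N)."""
    w = lo5.shape[0]
    nwin = enc.size - w + 1
    if nwin <= 0:
        return np.empty(0)
    scores = np.zeros(nwin)
    for j in range(w):
        scores += lo5[j][enc[j:j + nwin]]
    return scores


def scan_sequence(pwm: PWM, seq: str, cfg: ScanConfig = ScanConfig(),
                  gene: str = "", offset: int = 0) -> list[MotifHit]:
    """All positions where the PWM log-odds reaches
    ``threshold_fraction * max_score`` on the forward strand or (if
    configured) on the reverse complement. Positions are reported relative
    to the sequence start plus ``offset``; overlapping hits all count.
    """
    enc = encode_sequence(seq)
    threshold = cfg.threshold_fraction * pwm.max_score()
    lo5 = np.hstack([pwm.log_odds(), np.zeros((pwm.width, 1))])
    hits: list[MotifHit] = []
    fwd = _window_scores(lo5, enc)
    for i in np.flatnonzero(fwd >= threshold - 1e-12):
        hits.append(MotifHit(gene=gene, position=int(i) + offset,
                             strand="+", score=float(fwd[i])))
    if cfg.both_strands:
        rc = pwm.reverse_complement()
        lo5_rc = np.hstack([rc.log_odds(), np.zeros((rc.width, 1))])
        rev = _window_scores(lo5_rc, enc)
        for i in np.flatnonzero(rev >= threshold - 1e-12):
            hits.append(MotifHit(gene=gene, position=int(i) + offset,
                                 strand="-", score=float(rev[i])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _restrict(seq: str, offset: int, window: PromoterWindow,
              ) -> tuple[str, int]:
    """Clip a promoter sequence to a (possibly narrower) scan window."""
    start_rel = max(offset, -window.upstream)
    end_rel = min(offset + len(seq), window.downstream)
    if end_rel <= start_rel:
        return "", start_rel
    return seq[start_rel - offset:end_rel - offset], start_rel


def scan_promoters(promoters: PromoterSet, pwm: PWM,
                   cfg: ScanConfig = ScanConfig(),
                   ) -> dict[str, list[MotifHit]]:
    """Per-gene motif hits inside ``cfg.window`` (TSS-relative)."""
    hits: dict[str, list[MotifHit]] = {}
    for gene, seq in promoters.sequences.items():
        sub, start = _restrict(seq, promoters.offsets[gene], cfg.window)
        if len(sub) < pwm.width:
            hits[gene] = []
            continue
        hits[gene] = scan_sequence(pwm, sub, cfg, gene=gene, offset=start)
    return hits


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def motif_enrichment_test(promoters: PromoterSet, targets: GeneSet,
                          background: GeneSet, pwm: PWM,
                          cfg: ScanConfig = ScanConfig(),
                          hits: dict[str, list[MotifHit]] | None = None,
                          ) -> EnrichmentResult:
    """Presence/absence hypergeometric test of motif carriage in targets
    versus an expressed-gene background. Genes without promoters are
    dropped and counted in ``n_missing``; precomputed ``hits`` (from
    ``scan_promoters`` with the same config) are reused when given.
    """
    if not targets.members <= background.members:
        raise ValueError("targets must be a subset of the background")
    universe = [g for g in background.members if g in promoters.sequences]
    n_missing = len(background.members) - len(universe)
    target_universe = [g for g in universe if g in targets.members]
    if not target_universe:
        raise ValueError("no target gene has a promoter sequence")
    if hits is None:
        sub = PromoterSet(
            sequences={g: promoters.sequences[g] for g in universe},
            offsets={g: promoters.offsets[g] for g in universe},
            strands={g: promoters.strands[g] for g in universe},
            window=promoters.window, clipped=promoters.clipped)
        hits = scan_promoters(sub, pwm, cfg)
    present = {g for g in universe if hits.get(g)}
    N, K = len(universe), len(present)
    n = len(target_universe)
    k = sum(1 for g in target_universe if g in present)
    return EnrichmentResult.from_counts(N, K, n, k, n_missing=n_missing)


# ---------------------------------------------------------------------------
# Positional analysis
# ---------------------------------------------------------------------------

def positional_distribution(hits: dict[str, list[MotifHit]],
                            window: PromoterWindow, bin_size: int = 25,
                            ) -> pd.Series:
    """Histogram of best-hit (maximum score) positions per gene over
    ``bin_size``-nt bins covering [-upstream, downstream)."""
    edges = np.arange(-window.upstream, window.downstream + bin_size,
                      bin_size)
    edges = edges[edges - bin_size < window.downstream]
    counts = np.zeros(len(edges) - 1, dtype=int)
    for gene_hits in hits.values():
        if not gene_hits:
            continue
        best = max(gene_hits, key=lambda h: (h.score, -h.position))
        b = int(np.searchsorted(edges, best.position, side="right")) - 1
        if 0 <= b < len(counts):
            counts[b] += 1
    index = pd.IntervalIndex.from_breaks(edges, closed="left")
    return pd.Series(counts, index=index, name="n_genes")


def detect_tss_peak_and_narrow(hist: pd.Series, window: PromoterWindow,
                               narrowed: PromoterWindow = NARROWED_WINDOW,
                               ) -> dict:
    """Locate the modal bin of the positional histogram and return the
    narrowed scan window (the pipeline re-runs enrichment on it)."""
    if hist.sum() == 0:
        raise ValueError("positional histogram is empty; cannot narrow")
    counts = hist.to_numpy()
    mode_i = int(counts.argmax())          # first maximal bin on ties
    tie = int((counts == counts[mode_i]).sum()) > 1
    if tie:
        logger.warning("positional histogram mode is tied; using first bin")
    interval = hist.index[mode_i]
    return {"narrowed_window": narrowed,
            "mode_bin": (int(interval.left), int(interval.right)),
            "mode_count": int(counts[mode_i]),
            "tied": tie}


# ---------------------------------------------------------------------------
# Simplified de-novo k-mer discovery (seed-enumeration stand-in for a full
# motif-discovery tool; no EM refinement)
# ---------------------------------------------------------------------------

def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Codes of all k-windows without N; base-4 big-endian."""
    nwin = enc.size - k + 1
    if nwin <= 0:
        return np.empty(0, dtype=np.int64)
    valid = np.ones(nwin, dtype=bool)
    codes = np.zeros(nwin, dtype=np.int64)
    for j in range(k):
        sl = enc[j:j + nwin].astype(np.int64)
        valid &= sl < 4
        codes = codes * 4 + np.where(sl < 4, sl, 0)
    return codes[valid]


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_discovery(promoters: PromoterSet, targets: GeneSet,
                   background: GeneSet, k: int = 8,
                   cfg: ScanConfig | None = None,
                   top: int = 20) -> dict:
    """Exhaustive k-mer presence/absence enrichment over target promoters.

    Every k-mer is collapsed with its reverse complement into one class
    (palindromes are their own class); per class, an upper-tail
    hypergeometric p over target vs background promoter presence is
    Bonferroni-corrected by the number of distinct classes observed in the
    background. The top class's occurrences in target promoters are stacked
    into a count-matrix PWM (pseudocount 1).
    """
    if not targets.members <= background.members:
        raise ValueError("targets must be a subset of the background")
    window = cfg.window if cfg is not None else promoters.window
    universe = [g for g in sorted(background.members)
                if g in promoters.sequences]
    if not universe:
        raise ValueError("no background gene has a promoter")
    min_len = min(len(promoters.sequences[g]) for g in universe)
    if k > min_len:
        raise ValueError(f"k={k} exceeds the shortest promoter ({min_len})")

    # unique canonical classes per gene
    gene_ids, class_codes = [], []
    for gi, g in enumerate(universe):
        sub, _ = _restrict(promoters.sequences[g], promoters.offsets[g],
                           window)
        enc = encode_sequence(sub)
        codes = _kmer_codes(enc, k)
        if codes.size == 0:
            continue
        canon = np.minimum(codes, _revcomp_codes(codes, k))
        canon = np.unique(canon)
        gene_ids.append(np.full(canon.size, gi, dtype=np.int64))
        class_codes.append(canon)
    gene_ids = np.concatenate(gene_ids)
    class_codes = np.concatenate(class_codes)

    target_mask = np.array([g in targets.members for g in universe])
    N = len(universe)
    n = int(target_mask.sum())
    if n == 0:
        raise ValueError("no target gene has a promoter")

    uniq, inv = np.unique(class_codes, return_inverse=True)
    K_c = np.bincount(inv, minlength=uniq.size)
    k_c = np.bincount(inv, weights=target_mask[gene_ids].astype(float),
                      minlength=uniq.size).astype(int)
    n_classes = int(uniq.size)

    with np.errstate(divide="ignore"):
        pvals = scipy.stats.hypergeom.sf(k_c - 1, N, K_c, n)
    bonf = np.minimum(pvals * n_classes, 1.0)

    order = np.lexsort((K_c, pvals))
    rows = []
    for idx in order[:top]:
        code = int(uniq[idx])
        kmer = _code_to_kmer(code, k)
        rows.append({"kmer": kmer,
                     "kmer_rc": _code_to_kmer(
                         int(_revcomp_codes(np.array([code]), k)[0]), k),
                     "K": int(K_c[idx]), "k": int(k_c[idx]),
                     "p": float(pvals[idx]),
                     "p_bonferroni": float(bonf[idx])})
    table = pd.DataFrame(rows)

    top_code = int(uniq[order[0]])
    derived = _pwm_from_occurrences(promoters, targets, top_code, k, window)
    return {"table": table, "n_classes": n_classes, "N": N, "n": n,
            "min_p_bonferroni": float(bonf[order[0]]),
            "top_kmer": table.iloc[0]["kmer"], "derived_pwm": derived}


def _pwm_from_occurrences(promoters: PromoterSet, targets: GeneSet,
                          top_code: int, k: int,
                          window: PromoterWindow) -> PWM:
    counts = np.ones((k, 4))           # pseudocount 1
    rc_code = int(_revcomp_codes(np.array([top_code]), k)[0])
    for g in sorted(targets.members):
        if g not in promoters.sequences:
            continue
        sub, _ = _restrict(promoters.sequences[g], promoters.offsets[g],
                           window)
        enc = encode_sequence(sub)
        nwin = enc.size - k + 1
        if nwin <= 0:
            continue
        codes = np.zeros(nwin, dtype=np.int64)
        valid = np.ones(nwin, dtype=bool)
        for j in range(k):
            sl = enc[j:j + nwin].astype(np.int64)
            valid &= sl < 4
            codes = codes * 4 + np.where(sl < 4, sl, 0)
        for i in np.flatnonzero(valid):
            code = int(codes[i])
            if code == top_code:
                occ = enc[i:i + k]
            elif code == rc_code:
                occ = 3 - enc[i:i + k][::-1]
            else:
                continue
            counts[np.arange(k), occ] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    return PWM(probs=probs, pseudocount=0.0,
               name=f"denovo_{_code_to_kmer(top_code, k)}")


# ---------------------------------------------------------------------------
# Cross-species
# ---------------------------------------------------------------------------

def cross_species_test(targets_a: GeneSet, omap: OrthologMap,
                       promoters_b: PromoterSet, background_b: GeneSet,
                       pwm: PWM, cfg: ScanConfig = ScanConfig(),
                       hits_b: dict[str, list[MotifHit]] | None = None,
                       ) -> EnrichmentResult:
    """Map targets through the ortholog map (unmapped genes dropped and
    counted) and test motif enrichment against the species-B background."""
    mapped, n_unmapped = omap.map_set(targets_a.members)
    mapped &= background_b.members
    if not mapped:
        raise ValueError("no target gene maps into the species-B background")
    result = motif_enrichment_test(
        promoters_b, GeneSet(name=targets_a.name + "_orthologs",
                             members=mapped),
        background_b, pwm, cfg, hits=hits_b)
    result.n_missing += n_unmapped
    return result
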