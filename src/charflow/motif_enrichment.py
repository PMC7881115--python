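"""Known-motif enrichment with a matched background (HOMER-style).

Background windows are non-differential ChARs (|log2FC| below threshold,
p above threshold) at least 2000 bp away from every clustered ChAR, extended
500 bp around their centres — matching how the clustered target windows are
built. Each PWM is scanned over target and background sequences by log-odds
score; enrichment of hit-bearing sequences is tested with the hypergeometric
upper tail. Downstream reporting keeps motifs with p < 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from charflow.intervals import GenomicInterval
from charflow.region_algebra import ChAR

DEFAULT_THRESHOLD_FRACTION = 0.8  # of the maximum achievable log-odds score
PROB_FLOOR = 1e-4
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix with background frequencies and a score threshold.

    ``matrix`` holds per-position probabilities over (A, C, G, T); each row
    must sum to 1 (tolerance 1e-6). The default score threshold is
    ``DEFAULT_THRESHOLD_FRACTION`` x the maximum achievable log-odds score.
    """

    name: str
    matrix: np.ndarray
    background: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")
        if self.score_threshold is None:
            self.score_threshold = DEFAULT_THRESHOLD_FRACTION * self.max_score
        if not np.isfinite(self.score_threshold):
            raise ValueError(f"PWM {self.name}: non-finite threshold")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        bg = np.array([self.background[b] for b in "ACGT"])
        return np.log2(np.maximum(self.matrix, PROB_FLOOR) / bg)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_consensus(cls, name: str, consensus: str, strength: float = 0.97) -> "PWM":
        """Near-degenerate PWM putting ``strength`` probability on the consensus
        base at each position."""
        mat = np.full((len(consensus), 4), (1 - strength) / 3)
        for i, base in enumerate(consensus.upper()):
            mat[i, _BASE_INDEX[base]] = strength
        return cls(name=name, matrix=mat)


@dataclass
class MotifEnrichmentResult:
    motif: str
    target_hits: int
    target_n: int
    background_hits: int
    background_n: int
    p_value: float

    @property
    def fraction_target(self) -> float:
        return self.target_hits / self.target_n


def select_background(
    all_chars: list[ChAR],
    differential: pd.DataFrame,
    clustered_chars: list[ChAR],
    lfc_max: float = 1.0,
    p_min: float = 0.05,
    min_distance: int = 2000,
    flank: int = 500,
) -> list[GenomicInterval]:
    """Matched background windows for motif testing.

    Keeps ChARs with |log2FC| < ``lfc_max`` and p > ``p_min`` (from
    ``differential``, indexed or keyed by feature_id) whose edge distance to
    every clustered ChAR is >= ``min_distance`` bp, and emits centre +/- flank
    windows. Raises when the background comes out empty.
    """
    stats = differential.set_index("feature_id") if "feature_id" in differential else differential
    clustered_by_chrom: dict[str, list[GenomicInterval]] = {}
    for ch in clustered_chars:
        clustered_by_chrom.setdefault(ch.interval.chrom, []).append(ch.interval)

    out: list[GenomicInterval] = []
    for ch in all_chars:
        if ch.id not in stats.index:
            continue
        row = stats.loc[ch.id]
        if abs(float(row["log2FC"])) >= lfc_max or float(row["p_value"]) <= p_min:
            continue
        iv = ch.interval
        too_close = any(
            (g := iv.gap_to(other)) is not None and g < min_distance
            for other in clustered_by_chrom.get(iv.chrom, [])
        )
        if too_close:
            continue
        c = iv.center
        out.append(GenomicInterval(iv.chrom, max(0, c - flank), c + flank))
    if not out:
        raise ValueError(
            "empty motif background; relax lfc_max/p_min or reduce min_distance"
        )
    return out


def _scan_scores(seq: str, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset of one strand; N contributes 0."""
    w = log_odds.shape[0]
    n = len(seq)
    if n < w:
        return np.empty(0)
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    idx = np.full(n, -1, dtype=np.int64)
    for base, k in _BASE_INDEX.items():
        idx[codes == ord(base)] = k
    # per-position contribution table: row j gives score of base at motif pos j
    contrib = np.zeros((w, n))
    for j in range(w):
        valid = idx >= 0
        contrib[j, valid] = log_odds[j, idx[valid]]
    scores = np.zeros(n - w + 1)
    for j in range(w):
        scores += contrib[j, j : j + n - w + 1]
    return scores


def pwm_scan(
    sequences: list[str], pwm: PWM, both_strands: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Scan sequences for PWM hits.

    Returns (per-sequence hit boolean, per-sequence hit count). A hit is any
    offset (on either strand when ``both_strands``) whose log-odds score
    reaches the PWM's threshold. ``N`` bases contribute 0 (background odds).
    """
    hits = np.zeros(len(sequences), dtype=bool)
    counts = np.zeros(len(sequences), dtype=np.int64)
    lo = pwm.log_odds
    thr = pwm.score_threshold
    for i, seq in enumerate(sequences):
        n_hit = int((_scan_scores(seq, lo) >= thr).sum())
        if both_strands:
            rc = seq.translate(_COMPLEMENT)[::-1]
            n_hit += int((_scan_scores(rc, lo) >= thr).sum())
        counts[i] = n_hit
        hits[i] = n_hit > 0
    return hits, counts


def motif_enrichment_test(
    target_hits: int, target_n: int, background_hits: int, background_n: int, name: str = ""
) -> MotifEnrichmentResult:
    """Hypergeometric upper-tail enrichment of hit sequences in the target set.

    Population N = target_n + background_n sequences of which
    K = target_hits + background_hits carry the motif; p = P[X >= target_hits]
    for X ~ Hypergeometric(N, K, target_n).
    """
    if target_n == 0:
        raise ValueError("empty target set")
    if target_hits > target_n or background_hits > background_n:
        raise ValueError("hit counts exceed sequence counts")
    n_pop = target_n + background_n
    k_pop = target_hits + background_hits
    p = float(hypergeom.sf(target_hits - 1, n_pop, k_pop, target_n))
    return MotifEnrichmentResult(
        motif=name,
        target_hits=target_hits,
        target_n=target_n,
        background_hits=background_hits,
        background_n=background_n,
        p_value=min(max(p, 0.0), 1.0),
    )


def enrich_motifs(
    target_seqs: list[str],
    background_seqs: list[str],
    pwms: list[PWM],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Scan and test every PWM against target vs background sequences."""
    rows = []
    for pwm in pwms:
        t_hit, _ = pwm_scan(target_seqs, pwm, both_strands)
        b_hit, _ = pwm_scan(background_seqs, pwm, both_strands)
        res = motif_enrichment_test(
            int(t_hit.sum()), len(target_seqs), int(b_hit.sum()), len(background_seqs),
            name=pwm.name,
        )
        rows.append(
            {
                "motif": res.motif,
                "target_hits": res.target_hits,
                "target_n": res.target_n,
                "background_hits": res.background_hits,
                "background_n": res.background_n,
                "fraction_target": res.fraction_target,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def extract_sequences(genome: dict[str, str], windows: list[GenomicInterval]) -> list[str]:
    """Pull window sequences from an in-memory genome (chrom -> sequence)."""
    out = []
    for iv in windows:
        seq = genome[iv.chrom][iv.start : iv.end]
        out.append(seq)
    return out
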