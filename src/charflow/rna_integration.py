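"""RNA-seq integration: DEG calling, signatures, preranked GSEA, ChAR-gene pairs.

GSEA follows the classic weighted Kolmogorov-Smirnov statistic on a
preranked list: walking down the ranking, member genes add
|score|^p / sum_set |score|^p and non-members subtract 1/(N - |S|); the
enrichment score (ES) is the maximal-magnitude deviation of this running sum.
Significance comes from gene-label permutations: NES = ES / mean |permuted ES
of the same sign| and p is the fraction of same-sign permuted ES at least as
extreme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from charflow.genome_annotation import UniqueGeneModel
from charflow.region_algebra import ChAR


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    n_permutations: int


def call_degs(
    rna_differential: pd.DataFrame,
    rpkm: pd.DataFrame,
    fc_threshold: float = 1.5,
    q_threshold: float = 0.05,
    rpkm_filter: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Up/down differentially expressed genes.

    Genes must pass the expression filter (>= ``rpkm_filter`` RPKM in at least
    one sample), reach |FC| >= ``fc_threshold`` (i.e. |log2FC| >= log2 t) and
    q < ``q_threshold``.
    """
    lfc_t = np.log2(fc_threshold)
    expressed = set(rpkm.index[(rpkm >= rpkm_filter).any(axis=1)])
    df = rna_differential
    ok = df["feature_id"].isin(expressed) & (df["q_value"] < q_threshold)
    up = df.loc[ok & (df["log2FC"] >= lfc_t), "feature_id"].tolist()
    down = df.loc[ok & (df["log2FC"] <= -lfc_t), "feature_id"].tolist()
    return up, down


def build_signatures(
    de_table: pd.DataFrame,
    rule: str,
    n: int = 150,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> list[str]:
    """Build a gene signature from a reference differential-expression table.

    rule ``"top_n_up"``: the n most-upregulated significant genes (descending
    log2FC among q < alpha); fewer than n qualifying genes returns all of them.
    rule ``"thresholded_up"``: every gene with log2FC >= t and q < alpha.
    """
    if de_table.empty:
        raise ValueError("empty differential table")
    sig = de_table[de_table["q_value"] < q_threshold]
    if rule == "top_n_up":
        up = sig[sig["log2FC"] > 0].sort_values(
            "log2FC", ascending=False, kind="stable"
        )
        return up["feature_id"].head(n).tolist()
    if rule == "thresholded_up":
        return sig.loc[sig["log2FC"] >= lfc_threshold, "feature_id"].tolist()
    raise ValueError(f"unknown signature rule {rule!r}")


def _running_es(scores: np.ndarray, member: np.ndarray, weight_p: float) -> float:
    """ES of one (ranked scores, membership) configuration."""
    n = len(scores)
    n_hit = int(member.sum())
    n_miss = n - n_hit
    if n_hit == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if n_miss == 0:
        raise ValueError("gene set covers the entire ranked list (no misses possible)")
    w = np.abs(scores) ** weight_p
    hit_sum = w[member].sum()
    if hit_sum == 0:
        w = np.ones(n)
        hit_sum = float(n_hit)
    steps = np.where(member, w / hit_sum, -1.0 / n_miss)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(
    ranked: pd.Series | dict[str, float],
    gene_set: list[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA of one gene set.

    ``ranked`` maps gene -> score; genes are sorted by descending score (ties
    broken by gene id for determinism). The null is a gene-label permutation:
    membership is reassigned to random positions of the same ranked list.
    """
    if isinstance(ranked, dict):
        ranked = pd.Series(ranked)
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranking scores must be finite")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    scores = ranked.loc[order].to_numpy(dtype=float)
    members = set(gene_set)
    member = np.array([g in members for g in order])
    es = _running_es(scores, member, weight_p)

    rng = np.random.default_rng(seed)
    n_hit = int(member.sum())
    perm_es = np.empty(n_perm)
    idx = np.arange(len(order))
    for b in range(n_perm):
        perm_member = np.zeros(len(order), dtype=bool)
        perm_member[rng.choice(idx, size=n_hit, replace=False)] = True
        perm_es[b] = _running_es(scores, perm_member, weight_p)

    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if len(same_sign) == 0:
        nes = np.nan
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same_sign))
        p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (len(same_sign) + 1)
    return GseaResult(set_name="", es=es, nes=float(nes), p_value=float(p), n_permutations=n_perm)


def char_gene_pairs(
    up_degs: pd.DataFrame,
    down_degs: pd.DataFrame,
    chars: list[ChAR],
    char_differential: pd.DataFrame,
    gene_models: dict[str, UniqueGeneModel],
    tcf1_flags: dict[str, bool] | None = None,
    pairing_limit: int = 15_000,
    top_n: int = 50,
    char_p_threshold: float = 0.05,
    rank_by: str = "log2FC",
) -> pd.DataFrame:
    """Diamond-plot table: top up/down DEGs paired with nearby differential ChARs.

    DEGs are ranked by |log2FC| (or q with ``rank_by="q_value"``) within each
    direction; the top ``top_n`` genes per direction that have at least one
    differential ChAR (p < ``char_p_threshold``) within ``pairing_limit`` bp
    (edge-to-edge to the gene span, 0 when overlapping) are kept, one row per
    qualifying ChAR-gene pair. Each row carries the ChAR's accessibility
    log2FC and the gene's expression log2FC.
    """
    stats = char_differential.set_index("feature_id")
    diff_chars = [
        ch for ch in chars
        if ch.id in stats.index and float(stats.loc[ch.id, "p_value"]) < char_p_threshold
    ]

    def gene_distance(ch: ChAR, model: UniqueGeneModel) -> int | None:
        return ch.interval.gap_to(model.span)

    rows = []
    for direction, table in (("top50_up", up_degs), ("top50_down", down_degs)):
        if table.empty:
            continue
        if rank_by == "log2FC":
            ranked = table.reindex(
                table["log2FC"].abs().sort_values(ascending=False, kind="stable").index
            )
        elif rank_by == "q_value":
            ranked = table.sort_values("q_value", kind="stable")
        else:
            raise ValueError(f"unknown rank_by {rank_by!r}")
        kept = 0
        for _, gene_row in ranked.iterrows():
            if kept >= top_n:
                break
            gid = gene_row["feature_id"]
            model = gene_models.get(gid)
            if model is None:
                continue
            pairs = []
            for ch in diff_chars:
                d = gene_distance(ch, model)
                if d is not None and d <= pairing_limit:
                    pairs.append((ch, d))
            if not pairs:
                continue
            kept += 1
            for ch, d in pairs:
                rows.append(
                    {
                        "char_id": ch.id,
                        "gene_id": gid,
                        "distance": d,
                        "char_log2FC": float(stats.loc[ch.id, "log2FC"]),
                        "gene_log2FC": float(gene_row["log2FC"]),
                        "gene_rank_group": direction,
                        "tcf1_bound": bool((tcf1_flags or {}).get(gid, False)),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "char_id", "gene_id", "distance", "char_log2FC", "gene_log2FC",
            "gene_rank_group", "tcf1_bound",
        ],
    )


def scale_unit(values: np.ndarray) -> np.ndarray:
    span = values.max() - values.min()
    if span == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.min()) / span


def module_expression_summary(
    cluster_labels: dict[str, int],
    chars: list[ChAR],
    expression: pd.DataFrame,
    tcf1_flags: dict[str, bool] | None = None,
    max_gene_distance: int = 50_000,
) -> pd.DataFrame:
    """Per-module distribution of unit-scaled gene expression.

    For every module, genes assigned to the module's ChARs (within
    ``max_gene_distance``) are collected; a gene hit by several ChARs of one
    module appears once. Expression (columns = conditions) is scaled 0-1 per
    gene. Output has one row per (module, gene, condition) plus the gene's
    TCF-1 flag.
    """
    tcf1_flags = tcf1_flags or {}
    by_id = {ch.id: ch for ch in chars}
    module_genes: dict[int, list[str]] = {}
    for cid, lab in cluster_labels.items():
        ch = by_id.get(cid)
        if ch is None or ch.assigned_gene is None:
            continue
        if ch.distance_to_gene is not None and ch.distance_to_gene > max_gene_distance:
            continue
        genes = module_genes.setdefault(lab, [])
        if ch.assigned_gene not in genes:  # dedupe within module
            genes.append(ch.assigned_gene)

    rows = []
    for lab in sorted(module_genes):
        for gid in module_genes[lab]:
            if gid not in expression.index:
                continue
            scaled = scale_unit(expression.loc[gid].to_numpy(dtype=float))
            for cond, val in zip(expression.columns, scaled):
                rows.append(
                    {
                        "module": lab,
                        "gene_id": gid,
                        "condition": cond,
                        "scaled_expression": float(val),
                        "tcf1_bound": bool(tcf1_flags.get(gid, False)),
                    }
                )
    df = pd.DataFrame(
        rows, columns=["module", "gene_id", "condition", "scaled_expression", "tcf1_bound"]
    )
    if df.empty:
        import logging

        logging.getLogger(__name__).warning("no genes mapped to any module")
    return df
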