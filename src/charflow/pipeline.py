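"""Config-driven end-to-end runner.

Stages (in dependency order): ``qc`` (library complexity + FRiP per ATAC
sample), ``merge`` (consensus ChARs + genomic-context annotation), ``diff``
(counting, TMM, NB exact tests per comparison, MDS), ``cluster``
(accessibility modules + reference-peakset z-scores), ``motif``
(matched-background PWM enrichment per module), ``gsea`` (RNA DEGs + preranked
gene-set enrichment), ``integrate`` (gene assignment, TCF-1 flags, diamond
table, module expression summaries). Every stage writes TSV/JSON outputs under
the run directory and a manifest records parameters and input hashes.

One consensus ChAR set is pooled over all samples so ChAR ids are shared
across comparisons (the module-selection step needs "differential in at least
one comparison" over a common region universe).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from charflow.atac_quant import (
    CountMatrix,
    count_fragments_in_regions,
    library_qc,
    mds_coordinates,
    normalize_counts,
)
from charflow.chromatin_clustering import (
    build_coverage_matrix,
    hierarchical_modules,
    refset_zscore_profile,
    scale_rows_unit,
    silhouette_summary,
)
from charflow.differential import call_differential, nb_exact_test
from charflow.genome_annotation import build_unique_gene_models, parse_gtf
from charflow.io import (
    read_bed,
    read_fragments_bed6,
    read_gmt,
    read_meme,
    read_narrowpeak,
    write_tsv,
)
from charflow.intervals import GenomicInterval
from charflow.motif_enrichment import enrich_motifs, extract_sequences, select_background
from charflow.region_algebra import (
    ChAR,
    annotate_regions,
    annotation_fractions,
    assign_nearest_gene,
    flag_tcf1_bound,
    pool_and_merge,
    shift_tn5,
)
from charflow.rna_integration import (
    call_degs,
    char_gene_pairs,
    gsea_preranked,
    module_expression_summary,
)

logger = logging.getLogger(__name__)

STAGES = ("qc", "merge", "diff", "cluster", "motif", "gsea", "integrate")


@dataclass
class RunConfig:
    """Validated run configuration; paths are resolved against ``base_dir``."""

    base_dir: Path
    genome_fasta: Path
    gtf: Path
    peaks: dict[str, Path]
    fragments: dict[str, Path]
    rna_counts: Path
    motifs: Path
    tcf1_sites: Path
    refsets: dict[str, Path]
    gene_sets: Path
    atac_groups: dict[str, str]
    rna_groups: dict[str, str]
    comparisons: list[tuple[str, str]]
    clustering_comparisons: list[str]
    rna_comparison: tuple[str, str]
    thresholds: dict[str, float]
    seed: int = 0
    apply_tn5_shift: bool = False
    merge_mode: str = "intersection"
    clustering_linkage: str = "ward"  # robust to replicate noise; "complete" mirrors hclust defaults

    DEFAULT_THRESHOLDS = {
        "atac_lfc": 1.0,
        "rna_fc": 1.5,
        "q": 0.05,
        "k_modules": 5,
        "gene_max_distance": 50_000,
        "pairing_limit": 15_000,
        "tcf1_window": 10_000,
        "rpkm_filter": 1.0,
        "motif_min_distance": 2000,
        "flank": 500,
        "n_perm": 1000,
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        thresholds = dict(cls.DEFAULT_THRESHOLDS)
        thresholds.update(raw.get("thresholds", {}))
        cfg = cls(
            base_dir=base,
            genome_fasta=base / raw["genome_fasta"],
            gtf=base / raw["gtf"],
            peaks={s: base / p for s, p in raw["peaks"].items()},
            fragments={s: base / p for s, p in raw["fragments"].items()},
            rna_counts=base / raw["rna_counts"],
            motifs=base / raw["motifs"],
            tcf1_sites=base / raw["tcf1_sites"],
            refsets={n: base / p for n, p in raw["refsets"].items()},
            gene_sets=base / raw["gene_sets"],
            atac_groups=dict(raw["atac_groups"]),
            rna_groups=dict(raw["rna_groups"]),
            comparisons=[tuple(c) for c in raw["comparisons"]],
            clustering_comparisons=list(raw["clustering_comparisons"]),
            rna_comparison=tuple(raw["rna_comparison"]),
            thresholds=thresholds,
            seed=int(raw.get("seed", 0)),
            apply_tn5_shift=bool(raw.get("apply_tn5_shift", False)),
            merge_mode=raw.get("merge_mode", "intersection"),
            clustering_linkage=raw.get("clustering_linkage", "ward"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("atac_lfc", "rna_fc", "q", "k_modules", "pairing_limit"):
            if self.thresholds.get(key, 0) <= 0:
                raise ValueError(f"threshold {key} must be positive")
        atac_counts: dict[str, int] = {}
        for s, g in self.atac_groups.items():
            atac_counts[g] = atac_counts.get(g, 0) + 1
        rna_counts: dict[str, int] = {}
        for s, g in self.rna_groups.items():
            rna_counts[g] = rna_counts.get(g, 0) + 1
        for a, b in self.comparisons:
            for g in (a, b):
                if atac_counts.get(g, 0) < 2:
                    raise ValueError(
                        f"comparison {b}_vs_{a}: group {g} has "
                        f"{atac_counts.get(g, 0)} ATAC replicates (need >= 2)"
                    )
        for g in self.rna_comparison:
            if rna_counts.get(g, 0) < 2:
                raise ValueError(f"RNA group {g} has fewer than 2 replicates")
        missing = [
            str(p)
            for p in (
                [self.genome_fasta, self.gtf, self.rna_counts, self.motifs,
                 self.tcf1_sites, self.gene_sets]
                + list(self.peaks.values())
                + list(self.fragments.values())
                + list(self.refsets.values())
            )
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError("missing inputs: " + ", ".join(missing))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _read_genome(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def comparison_name(a: str, b: str) -> str:
    return f"{b}_vs_{a}"


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns a dict of in-memory results and writes the
    result bundle plus ``manifest.json`` under ``out_dir``.

    Any stage failure aborts with the stage name in the exception; outputs
    written so far are kept and a ``FAILED`` marker file names the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import charflow

    results: dict = {}
    manifest: dict = {
        "charflow_version": charflow.__version__,
        "seed": config.seed,
        "thresholds": config.thresholds,
        "merge_mode": config.merge_mode,
        "stages": [],
        "input_sha256": {},
    }
    current_stage = "setup"
    try:
        for p in [config.gtf, config.rna_counts, config.motifs, config.tcf1_sites,
                  config.gene_sets, *config.peaks.values()]:
            manifest["input_sha256"][str(Path(p).name)] = _sha256(Path(p))

        q_thr = float(config.thresholds["q"])
        flank = int(config.thresholds["flank"])

        # shared annotation
        transcripts = parse_gtf(config.gtf)
        gene_models = build_unique_gene_models(transcripts, coding_only=True)

        fragments = {
            s: read_fragments_bed6(p) for s, p in sorted(config.fragments.items())
        }
        if config.apply_tn5_shift:
            fragments = {s: shift_tn5(fr) for s, fr in fragments.items()}

        # ---- qc ------------------------------------------------------------
        current_stage = "qc"
        qc_rows = []
        for s in sorted(fragments):
            peaks_s = read_narrowpeak(config.peaks[s])
            rep = library_qc(fragments[s], peaks_s)
            qc_rows.append({"sample": s, **rep.to_dict()})
        qc_df = pd.DataFrame(qc_rows)
        write_tsv(qc_df, out / "qc_report.tsv")
        with open(out / "qc_report.json", "w") as fh:
            json.dump(qc_rows, fh, indent=1, sort_keys=True, default=str)
        results["qc"] = qc_df
        manifest["stages"].append("qc")

        # ---- merge ----------------------------------------------------------
        current_stage = "merge"
        peaksets = [read_narrowpeak(config.peaks[s]) for s in sorted(config.peaks)]
        chars = pool_and_merge(peaksets, merge_mode=config.merge_mode)
        chars = annotate_regions(chars, gene_models)
        results["chars"] = chars
        manifest["n_chars"] = len(chars)
        manifest["annotation_fractions"] = annotation_fractions(chars)
        manifest["stages"].append("merge")

        # ---- diff ------------------------------------------------------------
        current_stage = "diff"
        sample_ids = sorted(fragments)
        count_cols, libs = [], []
        for s in sample_ids:
            col, lib = count_fragments_in_regions(fragments[s], chars)
            count_cols.append(col)
            libs.append(lib)
        atac_matrix = CountMatrix(
            feature_ids=[ch.id for ch in chars],
            sample_ids=sample_ids,
            counts=np.column_stack(count_cols),
            library_sizes=np.array(libs),
            sample_meta={s: (config.atac_groups[s], i) for i, s in enumerate(sample_ids)},
        )
        write_tsv(
            atac_matrix.to_frame().reset_index().rename(columns={"index": "char_id"}),
            out / "atac_counts.tsv",
        )
        logcpm = normalize_counts(atac_matrix, "logCPM")
        mds_coords, mds_dist = mds_coordinates(logcpm, top_n=500)
        write_tsv(mds_coords.reset_index().rename(columns={"index": "sample"}),
                  out / "mds_coordinates.tsv")
        write_tsv(mds_dist.reset_index().rename(columns={"index": "sample"}),
                  out / "mds_distances.tsv")

        diff_tables: dict[str, pd.DataFrame] = {}
        for a, b in config.comparisons:
            name = comparison_name(a, b)
            samples = [s for s in sample_ids if config.atac_groups[s] in (a, b)]
            sub = atac_matrix.subset_samples(samples)
            labels = [config.atac_groups[s] for s in samples]
            res = nb_exact_test(sub, labels, groups=(a, b))
            res = call_differential(
                res, lfc_threshold=float(config.thresholds["atac_lfc"]), q_threshold=q_thr
            )
            write_tsv(res, out / f"atac_differential_{name}.tsv")
            diff_tables[name] = res
        results["atac_differential"] = diff_tables
        results["atac_matrix"] = atac_matrix
        manifest["stages"].append("diff")

        # ---- cluster ----------------------------------------------------------
        current_stage = "cluster"
        selected_ids: set[str] = set()
        for name in config.clustering_comparisons:
            t = diff_tables[name]
            sel = t[(t["log2FC"].abs() >= float(config.thresholds["atac_lfc"]))
                    & (t["q_value"] < q_thr)]
            selected_ids.update(sel["feature_id"])
        selected = [ch for ch in chars if ch.id in selected_ids]
        lib_sizes = {s: int(atac_matrix.library_sizes[sample_ids.index(s)])
                     for s in sample_ids}
        k = int(config.thresholds["k_modules"])
        if len(selected) >= k:
            cov = build_coverage_matrix(selected, fragments, lib_sizes, flank=flank)
            scaled = scale_rows_unit(cov)
            assignment = hierarchical_modules(scaled, k=k, method=config.clustering_linkage)
            write_tsv(
                pd.DataFrame(
                    {"char_id": list(assignment.labels),
                     "module": [assignment.labels[c] for c in assignment.labels]}
                ),
                out / "cluster_assignment.tsv",
            )
            write_tsv(scaled.reset_index().rename(columns={"index": "char_id"}),
                      out / "heatmap_matrix.tsv")
            (out / "dendrogram.nwk").write_text(assignment.to_newick() + "\n")
            sil = silhouette_summary(scaled)
            write_tsv(sil, out / "silhouette_by_k.tsv")
        else:
            logger.warning("only %d selected ChARs; skipping module cut", len(selected))
            assignment = None
        results["cluster"] = assignment
        results["selected_chars"] = selected

        refset_z: dict[str, pd.DataFrame] = {}
        for refname in sorted(config.refsets):
            ref_ivs = read_bed(config.refsets[refname])
            ref_chars = [
                ChAR(interval=iv, id=f"{refname}_{i}") for i, iv in enumerate(ref_ivs)
            ]
            cols = {}
            for s in sample_ids:
                col, _ = count_fragments_in_regions(fragments[s], ref_chars)
                cols[s] = col / lib_sizes[s] * 1e6
            ref_counts = pd.DataFrame(cols, index=[c.id for c in ref_chars])
            z = refset_zscore_profile(ref_counts)
            write_tsv(z.reset_index().rename(columns={"index": "ref_peak"}),
                      out / f"refset_zscores_{refname}.tsv")
            refset_z[refname] = z
        results["refset_zscores"] = refset_z
        manifest["stages"].append("cluster")

        # ---- motif -------------------------------------------------------------
        current_stage = "motif"
        genome = _read_genome(config.genome_fasta)
        pwms = read_meme(config.motifs)
        motif_tables = []
        if assignment is not None:
            # background: non-differential in every clustering comparison
            bg_stats = None
            for name in config.clustering_comparisons:
                t = diff_tables[name][["feature_id", "log2FC", "p_value"]]
                if bg_stats is None:
                    bg_stats = t.copy()
                else:
                    m = bg_stats.merge(t, on="feature_id", suffixes=("", "_2"))
                    m["log2FC"] = m[["log2FC", "log2FC_2"]].abs().max(axis=1)
                    m["p_value"] = m[["p_value", "p_value_2"]].min(axis=1)
                    bg_stats = m[["feature_id", "log2FC", "p_value"]]
            background = select_background(
                chars, bg_stats, selected,
                lfc_max=float(config.thresholds["atac_lfc"]),
                p_min=0.05,
                min_distance=int(config.thresholds["motif_min_distance"]),
                flank=flank,
            )
            bg_seqs = extract_sequences(genome, background)
            by_id = {ch.id: ch for ch in selected}
            for module in range(1, assignment.k + 1):
                member_ids = assignment.members(module)
                windows = []
                for cid in member_ids:
                    iv = by_id[cid].interval
                    c = iv.center
                    windows.append(
                        GenomicInterval(iv.chrom, max(0, c - flank), c + flank)
                    )
                seqs = extract_sequences(genome, windows)
                table = enrich_motifs(seqs, bg_seqs, pwms)
                table.insert(0, "module", module)
                motif_tables.append(table)
            motif_df = pd.concat(motif_tables, ignore_index=True)
            manifest["n_motif_background"] = len(background)
        else:
            motif_df = pd.DataFrame()
        write_tsv(motif_df, out / "motif_enrichment.tsv")
        results["motif"] = motif_df
        manifest["stages"].append("motif")

        # ---- gsea ---------------------------------------------------------------
        current_stage = "gsea"
        rna_df = pd.read_csv(config.rna_counts, sep="\t", index_col=0)
        rna_samples = [s for s in rna_df.columns]
        rna_matrix = CountMatrix(
            feature_ids=rna_df.index.tolist(),
            sample_ids=rna_samples,
            counts=rna_df.to_numpy(),
            library_sizes=rna_df.to_numpy().sum(axis=0),
            sample_meta={s: (config.rna_groups[s], i) for i, s in enumerate(rna_samples)},
        )
        gene_lengths = np.array(
            [
                gene_models[g].exonic_length if g in gene_models else 1000
                for g in rna_matrix.feature_ids
            ]
        )
        rpkm = normalize_counts(rna_matrix, "RPKM", feature_lengths=gene_lengths)
        a, b = config.rna_comparison
        samples = [s for s in rna_samples if config.rna_groups[s] in (a, b)]
        sub = rna_matrix.subset_samples(samples)
        labels = [config.rna_groups[s] for s in samples]
        rna_res = nb_exact_test(sub, labels, groups=(a, b))
        rna_res = call_differential(
            rna_res,
            lfc_threshold=float(np.log2(config.thresholds["rna_fc"])),
            q_threshold=q_thr,
        )
        write_tsv(rna_res, out / f"rna_differential_{comparison_name(a, b)}.tsv")
        up, down = call_degs(
            rna_res, rpkm,
            fc_threshold=float(config.thresholds["rna_fc"]),
            q_threshold=q_thr,
            rpkm_filter=float(config.thresholds["rpkm_filter"]),
        )
        results["degs"] = {"up": up, "down": down}
        results["rna_differential"] = rna_res
        results["rpkm"] = rpkm

        expressed = rna_res[rna_res["feature_id"].isin(
            set(rpkm.index[(rpkm >= float(config.thresholds["rpkm_filter"])).any(axis=1)])
        )]
        ranked = pd.Series(
            expressed["log2FC"].to_numpy(), index=expressed["feature_id"]
        )
        write_tsv(
            pd.DataFrame({"gene": ranked.index, "score": ranked.to_numpy()}),
            out / "ranked_list.tsv",
        )
        gene_sets = read_gmt(config.gene_sets)
        gsea_rows = []
        for i, (set_name, members) in enumerate(sorted(gene_sets.items())):
            inset = [g for g in members if g in ranked.index]
            if not inset or len(inset) >= len(ranked):
                logger.warning("gene set %s skipped (empty or full overlap)", set_name)
                continue
            res = gsea_preranked(
                ranked, inset,
                n_perm=int(config.thresholds["n_perm"]),
                seed=config.seed + 101 + i,
            )
            gsea_rows.append(
                {"set": set_name, "ES": res.es, "NES": res.nes,
                 "p_value": res.p_value, "n_genes": len(inset)}
            )
        gsea_df = pd.DataFrame(gsea_rows)
        write_tsv(gsea_df, out / "gsea_results.tsv")
        results["gsea"] = gsea_df
        manifest["stages"].append("gsea")

        # ---- integrate -------------------------------------------------------------
        current_stage = "integrate"
        chars = assign_nearest_gene(
            chars, gene_models, max_distance=int(config.thresholds["gene_max_distance"])
        )
        char_rows = [
            {
                "char_id": ch.id,
                "chrom": ch.interval.chrom,
                "start": ch.interval.start,
                "end": ch.interval.end,
                "annotation": ch.annotation,
                "assigned_gene": ch.assigned_gene or "",
                "distance_to_gene": -1 if ch.distance_to_gene is None else ch.distance_to_gene,
            }
            for ch in chars
        ]
        write_tsv(pd.DataFrame(char_rows), out / "char_table.tsv")

        tcf1_sites = read_bed(config.tcf1_sites)
        tcf1_flags = flag_tcf1_bound(
            gene_models, tcf1_sites, window=int(config.thresholds["tcf1_window"])
        )

        rna_name = comparison_name(*config.rna_comparison)
        atac_for_pairs = diff_tables.get(rna_name)
        if atac_for_pairs is None:
            atac_for_pairs = diff_tables[list(diff_tables)[-1]]
        up_df = rna_res[rna_res["feature_id"].isin(up)]
        down_df = rna_res[rna_res["feature_id"].isin(down)]
        diamond = char_gene_pairs(
            up_df, down_df, chars, atac_for_pairs, gene_models,
            tcf1_flags=tcf1_flags,
            pairing_limit=int(config.thresholds["pairing_limit"]),
        )
        write_tsv(diamond, out / "diamond_table.tsv")
        results["diamond"] = diamond

        if assignment is not None:
            cond_means = {}
            groups_order = []
            for s in rna_samples:
                g = config.rna_groups[s]
                cond_means.setdefault(g, []).append(s)
                if g not in groups_order:
                    groups_order.append(g)
            expr_by_cond = pd.DataFrame(
                {g: rpkm[cols].mean(axis=1) for g, cols in cond_means.items()}
            )[groups_order]
            summary = module_expression_summary(
                assignment.labels, chars, expr_by_cond,
                tcf1_flags=tcf1_flags,
                max_gene_distance=int(config.thresholds["gene_max_distance"]),
            )
        else:
            summary = pd.DataFrame()
        write_tsv(summary, out / "module_expression.tsv")
        results["module_expression"] = summary
        results["tcf1_flags"] = tcf1_flags
        results["gene_models"] = gene_models
        manifest["stages"].append("integrate")

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {current_stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
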