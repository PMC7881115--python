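"""Self-contained synthetic fixture bundle with planted ground truth.

The generator emulates the study design the pipeline targets: four groups of
brain-infiltrating CD8+ T cells — V_E/V_L (viral infection, early day 7 /
late day 21) and A_E/A_L (autoimmunity, early/late) — with 2 ATAC replicates
and 3 RNA replicates per group. It emits every file format the pipeline
consumes (genome FASTA, GTF, per-sample narrowPeak + fragment BED6, RNA count
TSV, MEME motif file, TCF-1 site BED, reference peakset BEDs, gene sets GMT,
a ready-to-run YAML config) plus a ground-truth JSON recording which peaks
and genes carry planted effects.

Planted structure
-----------------
* A fraction of peaks is differential, cycling through five accessibility
  behaviour classes (early opening, late closing, late opening, closed in
  autoimmunity at both time points, early closing) with multiplicative
  effects of 2^planted_log2fc on the affected groups' NB means.
* Each differential peak sits inside a host gene; with probability
  ``peak_gene_coupling`` the host gene is a DEG with concordant sign in the
  comparison where the peak is differential.
* A consensus motif is written into a fraction of autoimmune-opening peak
  windows (and at a low rate into stable background windows).
* A fraction of genes carries a TCF-1 binding site inside the gene span.
* Reference peaksets mimic published exhaustion/effector region lists:
  ~90% autoimmune-opening (resp. closing) peaks plus a stable remainder.

Everything is drawn from one seeded generator; the same spec and seed give a
byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from charflow.intervals import GenomicInterval

GROUPS = ("V_E", "A_E", "V_L", "A_L")

# class name -> {group: planted log2FC applied to that group's mean}
BEHAVIOR_CLASSES: dict[str, dict[str, float]] = {
    "early_open": {"A_E": +1.0, "A_L": +1.0},
    "late_close": {"A_L": -1.0},
    "late_open": {"A_L": +1.0},
    "closed_both": {"A_E": -1.0, "A_L": -1.0},
    "early_close": {"A_E": -1.0},
}
CLASS_CYCLE = ("early_open", "late_close", "late_open", "closed_both", "early_close")

COMPARISONS = (
    ("V_E", "A_E"),  # reported as A_E_vs_V_E: log2FC of A_E over V_E
    ("V_L", "A_L"),
    ("V_E", "V_L"),
    ("A_E", "A_L"),
)

MEAN_FLOOR = 1e-8
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic bundle (defaults sized for fast generation)."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 300
    n_peaks: int = 400
    groups: tuple[str, ...] = GROUPS
    n_atac_reps: int = 2
    n_rna_reps: int = 3
    fraction_differential_peaks: float = 0.10
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.8, 1.2)  # per-sample scale factors
    base_peak_mean: tuple[float, float] = (100.0, 250.0)  # keeps effective consensus-region means >= 50 after edge trimming
    background_fragment_rate: float = 0.15  # off-peak fragments / peak fragments
    rna_base_mean: tuple[float, float] = (100.0, 600.0)
    rna_planted_log2fc: float = 2.0
    fraction_extra_degs: float = 0.05
    fraction_low_expression: float = 0.05
    motif_consensus: str = "TGACGTCATC"  # 10 bp: chance hits (~2e-3/kb window) stay far below the planted rates
    motif_target_rate: float = 0.6
    motif_background_rate: float = 0.05
    n_decoy_motifs: int = 10
    fraction_tcf1_genes: float = 0.3
    peak_gene_coupling: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "fraction_differential_peaks", "motif_target_rate",
            "motif_background_rate", "fraction_tcf1_genes", "peak_gene_coupling",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.planted_log2fc <= 0:
            raise ValueError("planted_log2fc must be > 0")

    @property
    def atac_samples(self) -> list[str]:
        return [f"{g}_r{i+1}" for g in self.groups for i in range(self.n_atac_reps)]

    @property
    def rna_samples(self) -> list[str]:
        return [f"{g}_rna{i+1}" for g in self.groups for i in range(self.n_rna_reps)]


def simulate_counts(
    mean_profile: np.ndarray,
    planted_effects: np.ndarray,
    dispersion: float,
    libraries: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Negative-binomial count matrix (features x samples).

    Expected count of feature i in sample j is
    ``mean_profile[i] * 2^planted_effects[i, j] * libraries[j]``; means are
    floored at a small epsilon. ``dispersion`` is the NB dispersion phi
    (variance = mu + phi mu^2); phi ~ 0 falls back to Poisson.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_profile = np.maximum(np.asarray(mean_profile, dtype=float), MEAN_FLOOR)
    mu = mean_profile[:, None] * (2.0 ** np.asarray(planted_effects, dtype=float))
    mu = mu * np.asarray(libraries, dtype=float)[None, :]
    mu = np.maximum(mu, MEAN_FLOOR)
    if dispersion < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def plant_motifs(
    genome: dict[str, np.ndarray],
    target_windows: list[GenomicInterval],
    background_windows: list[GenomicInterval],
    consensus: str,
    target_rate: float,
    background_rate: float,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> dict:
    """Write the consensus substring into a fraction of windows in place.

    Returns a placement ledger: window ids (``chrom:start-end``) that received
    the motif, per set. A placement colliding with an earlier one in an
    overlapping window is re-drawn up to ``max_retries`` times, then skipped.
    """
    motif = np.frombuffer(consensus.upper().encode(), dtype=np.uint8)
    w = len(consensus)
    occupied: dict[str, list[tuple[int, int]]] = {}

    def place(iv: GenomicInterval) -> bool:
        lo, hi = iv.start, iv.end - w
        if hi <= lo:
            return False
        for _ in range(max_retries):
            off = int(rng.integers(lo, hi))
            span = (off, off + w)
            if any(s < span[1] and span[0] < e for s, e in occupied.get(iv.chrom, [])):
                continue
            genome[iv.chrom][span[0]:span[1]] = motif
            occupied.setdefault(iv.chrom, []).append(span)
            return True
        return False

    ledger = {"target_planted": [], "background_planted": [], "consensus": consensus}
    for iv in target_windows:
        if rng.random() < target_rate and place(iv):
            ledger["target_planted"].append(str(iv))
    for iv in background_windows:
        if rng.random() < background_rate and place(iv):
            ledger["background_planted"].append(str(iv))
    return ledger


def _write_fasta(genome: dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_gtf(genes: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            gid, chrom, strand = g["gene_id"], g["chrom"], g["strand"]
            attrs = (
                f'gene_id "{gid}"; transcript_id "{gid}.t1"; '
                f'transcript_biotype "{g["biotype"]}";'
            )
            for ex_start, ex_end in g["exons"]:
                fh.write(
                    f"{chrom}\tsynthetic\texon\t{ex_start + 1}\t{ex_end}\t.\t{strand}\t.\t{attrs}\n"
                )


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Generate the full fixture bundle under ``out_dir``; returns ground truth.

    The ground truth is also serialized to ``out_dir/ground_truth.json``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "peaks").mkdir(exist_ok=True)
        (out / "fragments").mkdir(exist_ok=True)
        (out / "refsets").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    rng = np.random.default_rng(spec.seed)

    chroms = [f"chr{i+1}" for i in range(spec.n_chromosomes)]
    genome = {c: _BASES[rng.integers(0, 4, size=spec.chromosome_length)] for c in chroms}

    # ---- gene layout: fixed slots along each chromosome -------------------
    genes_per_chrom = spec.n_genes // spec.n_chromosomes
    slot = (spec.chromosome_length - 4000) // genes_per_chrom
    genes: list[dict] = []
    for ci, chrom in enumerate(chroms):
        n_here = genes_per_chrom + (spec.n_genes % spec.n_chromosomes if ci == 0 else 0)
        for gi in range(n_here):
            idx = len(genes)
            gstart = 2000 + gi * slot + int(rng.integers(0, 200))
            glen = int(rng.integers(2400, 4000))
            gend = gstart + glen
            strand = "+" if (idx % 2 == 0) else "-"
            exons = [(gstart, gstart + 300), (gend - 300, gend)]
            genes.append(
                {
                    "gene_id": f"gene_{idx:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "start": gstart,
                    "end": gend,
                    "exons": exons,
                    "slot": gi,
                    "biotype": "protein_coding",
                }
            )
    # a few non-coding transcripts to exercise the coding-only filter
    for k in range(3):
        g = genes[k]
        genes.append(
            {
                "gene_id": g["gene_id"] + "_nc",
                "chrom": g["chrom"],
                "strand": g["strand"],
                "start": g["start"],
                "end": g["end"],
                "exons": [(g["start"], g["end"])],
                "slot": g["slot"],
                "biotype": "lncRNA",
            }
        )
    coding = [g for g in genes if g["biotype"] == "protein_coding"]

    # ---- peak layout ------------------------------------------------------
    n_diff = round(spec.n_peaks * spec.fraction_differential_peaks)
    by_chrom = {c: [g for g in coding if g["chrom"] == c] for c in chroms}
    peaks: list[dict] = []
    peaks_per_chrom = [spec.n_peaks // spec.n_chromosomes] * spec.n_chromosomes
    peaks_per_chrom[0] += spec.n_peaks % spec.n_chromosomes
    diff_quota = [n_diff // spec.n_chromosomes] * spec.n_chromosomes
    diff_quota[0] += n_diff % spec.n_chromosomes
    diff_assigned = 0
    for ci, chrom in enumerate(chroms):
        cgenes = by_chrom[chrom]
        diff_here = 0
        for j in range(peaks_per_chrom[ci]):
            pid = f"peak_{len(peaks):04d}"
            width = int(rng.integers(350, 550))
            zone_a = j < len(cgenes)
            g = cgenes[j % len(cgenes)]
            is_diff = diff_here < diff_quota[ci] and zone_a
            if is_diff:
                klass = CLASS_CYCLE[diff_assigned % len(CLASS_CYCLE)]
                diff_assigned += 1
                diff_here += 1
                mid = (g["start"] + g["end"]) // 2
                start = mid - width // 2
            elif zone_a:
                if j % 2 == 0:  # promoter peak at the TSS
                    tss = g["start"] if g["strand"] == "+" else g["end"]
                    start = tss - width // 2
                else:  # inside the gene body
                    start = g["start"] + (g["end"] - g["start"]) // 4 - width // 2
                klass = "stable"
            else:  # intergenic gap downstream of the slot's gene
                gap_lo = g["end"] + 2500
                gap_hi = 2000 + (g["slot"] + 1) * slot - 1200
                start = int(rng.integers(gap_lo, max(gap_lo + 1, gap_hi)))
                klass = "stable"
            start = max(0, start)
            peaks.append(
                {
                    "id": pid,
                    "chrom": chrom,
                    "start": start,
                    "end": start + width,
                    "class": klass,
                    "gene_id": g["gene_id"] if klass != "stable" or zone_a else None,
                    "base_mean": float(rng.uniform(*spec.base_peak_mean)),
                }
            )
    diff_peaks = [p for p in peaks if p["class"] != "stable"]

    # ---- planted ATAC effects and per-comparison truth --------------------
    group_index = {g: i for i, g in enumerate(spec.groups)}
    effects = np.zeros((len(peaks), len(spec.groups)))
    for i, p in enumerate(peaks):
        if p["class"] == "stable":
            continue
        for grp, sign in BEHAVIOR_CLASSES[p["class"]].items():
            effects[i, group_index[grp]] = sign * spec.planted_log2fc

    def comparison_name(a: str, b: str) -> str:
        return f"{b}_vs_{a}"

    peak_truth: dict[str, dict] = {}
    for i, p in enumerate(peaks):
        lfc = {}
        for a, b in COMPARISONS:
            delta = effects[i, group_index[b]] - effects[i, group_index[a]]
            lfc[comparison_name(a, b)] = float(delta)
        peak_truth[p["id"]] = {
            "chrom": p["chrom"],
            "start": p["start"],
            "end": p["end"],
            "class": p["class"],
            "gene_id": p["gene_id"] if p["class"] != "stable" else None,
            "lfc": lfc,
        }

    # ---- ATAC fragments ---------------------------------------------------
    atac_samples = spec.atac_samples
    lib_scale = {
        s: float(rng.uniform(*spec.library_size_range)) for s in atac_samples
    }
    sample_group = {s: s.rsplit("_r", 1)[0] for s in atac_samples}
    frag_files: dict[str, Path] = {}
    atac_lib_sizes: dict[str, int] = {}
    for s in atac_samples:
        gi = group_index[sample_group[s]]
        mu = np.array([p["base_mean"] for p in peaks]) * (2.0 ** effects[:, gi])
        counts = simulate_counts(
            mu, np.zeros((len(peaks), 1)), spec.nb_dispersion,
            np.array([lib_scale[s]]), rng,
        )[:, 0]
        lines: list[tuple[str, int, int, str]] = []
        for i, p in enumerate(peaks):
            n = int(counts[i])
            if n == 0:
                continue
            frag_len = rng.integers(50, 120, size=n)
            lo = max(0, p["start"] - 100)
            hi = np.maximum(lo + 1, p["end"] + 100 - frag_len)
            starts = rng.integers(lo, hi)
            strands = rng.integers(0, 2, size=n)
            for st, fl, sd in zip(starts, frag_len, strands):
                lines.append((p["chrom"], int(st), int(st + fl), "+" if sd else "-"))
        n_bg = int(spec.background_fragment_rate * len(lines))
        bg_chrom = rng.integers(0, len(chroms), size=n_bg)
        bg_start = rng.integers(0, spec.chromosome_length - 150, size=n_bg)
        bg_len = rng.integers(50, 120, size=n_bg)
        bg_strand = rng.integers(0, 2, size=n_bg)
        for c, st, fl, sd in zip(bg_chrom, bg_start, bg_len, bg_strand):
            lines.append((chroms[int(c)], int(st), int(st + fl), "+" if sd else "-"))
        lines.sort()
        path = out / "fragments" / f"{s}.bed"
        with open(path, "w") as fh:
            for k, (c, st, en, sd) in enumerate(lines):
                fh.write(f"{c}\t{st}\t{en}\tfrag_{k}\t0\t{sd}\n")
        frag_files[s] = path
        atac_lib_sizes[s] = len(lines)

    # per-sample peak calls: planted peaks with jittered boundaries
    peak_files: dict[str, Path] = {}
    for s in atac_samples:
        path = out / "peaks" / f"{s}.narrowPeak"
        with open(path, "w") as fh:
            for p in peaks:
                j1 = int(rng.integers(-25, 26))
                j2 = int(rng.integers(-25, 26))
                start = max(0, p["start"] + j1)
                end = max(start + 50, p["end"] + j2)
                fh.write(
                    f"{p['chrom']}\t{start}\t{end}\t{p['id']}\t0\t.\t0\t-1\t-1\t-1\n"
                )
        peak_files[s] = path

    # ---- RNA counts -------------------------------------------------------
    rna_samples = spec.rna_samples
    rna_scale = {s: float(rng.uniform(*spec.library_size_range)) for s in rna_samples}
    gene_ids = [g["gene_id"] for g in coding]
    base_mean = rng.uniform(*spec.rna_base_mean, size=len(gene_ids))
    gene_effects = np.zeros((len(gene_ids), len(spec.groups)))
    gene_idx = {gid: i for i, gid in enumerate(gene_ids)}

    gene_truth: dict[str, dict] = {
        gid: {"deg": {}, "coupled_peak": None, "low_expression": False}
        for gid in gene_ids
    }
    pairs: list[dict] = []
    coupled_genes: set[str] = set()
    for p in diff_peaks:
        gid = p["gene_id"]
        if rng.random() >= spec.peak_gene_coupling:
            continue
        coupled_genes.add(gid)
        gi = gene_idx[gid]
        for grp, sign in BEHAVIOR_CLASSES[p["class"]].items():
            gene_effects[gi, group_index[grp]] = sign * spec.rna_planted_log2fc
        gene_truth[gid]["coupled_peak"] = p["id"]
        al_vl = peak_truth[p["id"]]["lfc"]["A_L_vs_V_L"]
        if al_vl != 0:
            pairs.append(
                {"peak_id": p["id"], "gene_id": gid, "sign": "up" if al_vl > 0 else "down"}
            )

    free = [g for g in gene_ids if g not in coupled_genes]
    n_extra = round(spec.fraction_extra_degs * len(gene_ids))
    extra = list(rng.choice(free, size=min(n_extra, len(free)), replace=False))
    for k, gid in enumerate(extra):
        sign = 1.0 if k % 2 == 0 else -1.0
        gene_effects[gene_idx[gid], group_index["A_L"]] = sign * spec.rna_planted_log2fc
    n_low = round(spec.fraction_low_expression * len(gene_ids))
    low = list(
        rng.choice([g for g in free if g not in extra], size=n_low, replace=False)
    )
    for gid in low:
        base_mean[gene_idx[gid]] = 0.05
        gene_truth[gid]["low_expression"] = True

    for gid in gene_ids:
        gi = gene_idx[gid]
        degs = {}
        for a, b in COMPARISONS:
            delta = gene_effects[gi, group_index[b]] - gene_effects[gi, group_index[a]]
            degs[comparison_name(a, b)] = (
                None if delta == 0 else ("up" if delta > 0 else "down")
            )
        gene_truth[gid]["deg"] = degs

    rna_effects = np.zeros((len(gene_ids), len(rna_samples)))
    rna_libs = np.array([rna_scale[s] for s in rna_samples])
    for j, s in enumerate(rna_samples):
        grp = s.rsplit("_rna", 1)[0]
        rna_effects[:, j] = gene_effects[:, group_index[grp]]
    rna_counts = simulate_counts(base_mean, rna_effects, spec.nb_dispersion, rna_libs, rng)
    with open(out / "rna_counts.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(rna_samples) + "\n")
        for i, gid in enumerate(gene_ids):
            fh.write(gid + "\t" + "\t".join(str(int(x)) for x in rna_counts[i]) + "\n")

    # ---- motifs -----------------------------------------------------------
    opening = [p for p in diff_peaks if p["class"] in ("early_open", "late_open")]
    stable = [p for p in peaks if p["class"] == "stable"]

    def window(p: dict, half: int = 300) -> GenomicInterval:
        c = (p["start"] + p["end"]) // 2
        return GenomicInterval(p["chrom"], max(0, c - half), c + half)

    ledger = plant_motifs(
        genome,
        [window(p) for p in opening],
        [window(p) for p in stable],
        spec.motif_consensus,
        spec.motif_target_rate,
        spec.motif_background_rate,
        rng,
    )
    win_to_peak = {str(window(p)): p["id"] for p in opening + stable}
    motif_truth = {
        "consensus": spec.motif_consensus,
        "target_peaks": [p["id"] for p in opening],
        "background_peaks": [p["id"] for p in stable],
        "planted_target_peaks": sorted(
            win_to_peak[w] for w in ledger["target_planted"]
        ),
        "planted_background_peaks": sorted(
            win_to_peak[w] for w in ledger["background_planted"]
        ),
    }

    from charflow.motif_enrichment import PWM
    from charflow.io import write_meme

    pwms = [PWM.from_consensus("planted_" + spec.motif_consensus, spec.motif_consensus)]
    bases = "ACGT"
    k = 0
    while len(pwms) < 1 + spec.n_decoy_motifs:
        cons = "".join(bases[int(b)] for b in rng.integers(0, 4, len(spec.motif_consensus)))
        if cons == spec.motif_consensus:
            continue
        pwms.append(PWM.from_consensus(f"decoy_{k:02d}_{cons}", cons))
        k += 1
    write_meme(pwms, out / "motifs.meme")

    _write_fasta(genome, out / "genome.fa")
    _write_gtf(genes, out / "annotation.gtf")

    # ---- TCF-1 sites ------------------------------------------------------
    n_tcf1 = round(spec.fraction_tcf1_genes * len(coding))
    seeded = sorted(
        rng.choice([g["gene_id"] for g in coding], size=n_tcf1, replace=False).tolist()
    )
    gene_by_id = {g["gene_id"]: g for g in coding}
    sites: list[tuple[str, int, int]] = []
    for gid in seeded:
        g = gene_by_id[gid]
        pos = int(rng.integers(g["start"], g["end"] - 15))
        sites.append((g["chrom"], pos, pos + 15))
    sites.sort()
    with open(out / "tcf1_sites.bed", "w") as fh:
        for c, st, en in sites:
            fh.write(f"{c}\t{st}\t{en}\ttcf1_site\t0\t.\n")
    # truth by an independent window scan (10 kb around the gene span)
    tcf1_bound = sorted(
        g["gene_id"]
        for g in coding
        if any(
            c == g["chrom"] and st < g["end"] + 10_000 and en > g["start"] - 10_000
            for c, st, en in sites
        )
    )

    # ---- reference peaksets ----------------------------------------------
    def write_refset(members: list[dict], fillers: list[dict], path: Path) -> list[str]:
        # ~90% planted members: fillers are at most a ninth of the member count
        n_fill = max(1, len(members) // 9) if members else 1
        chosen = members + fillers[:n_fill]
        rows = []
        for p in chosen:
            j = int(rng.integers(-40, 41))
            rows.append((p["chrom"], max(0, p["start"] + j), p["end"] + j, p["id"]))
        rows.sort()
        with open(path, "w") as fh:
            for c, st, en, pid in rows:
                fh.write(f"{c}\t{st}\t{en}\t{pid}\n")
        return [p["id"] for p in chosen]

    closing = [p for p in diff_peaks if p["class"] in ("late_close", "closed_both")]
    exhaustion_ids = write_refset(opening, stable, out / "refsets" / "exhaustion.bed")
    effector_ids = write_refset(closing, stable[5:], out / "refsets" / "effector.bed")

    # ---- gene sets --------------------------------------------------------
    from charflow.io import write_gmt

    up_al = [g for g in gene_ids if gene_truth[g]["deg"]["A_L_vs_V_L"] == "up"]
    down_al = [g for g in gene_ids if gene_truth[g]["deg"]["A_L_vs_V_L"] == "down"]
    neutral = [
        g for g in gene_ids
        if all(v is None for v in gene_truth[g]["deg"].values())
        and not gene_truth[g]["low_expression"]
    ]
    random_set = sorted(rng.choice(neutral, size=min(30, len(neutral)), replace=False).tolist())
    write_gmt(
        {
            "planted_up_A_L_vs_V_L": up_al,
            "planted_down_A_L_vs_V_L": down_al,
            "random_control": random_set,
        },
        out / "gene_sets.gmt",
    )

    truth = {
        "spec": asdict(spec),
        "samples": {"atac": atac_samples, "rna": rna_samples},
        "atac_library_sizes": atac_lib_sizes,
        "comparisons": [comparison_name(a, b) for a, b in COMPARISONS],
        "peaks": peak_truth,
        "n_differential_peaks": len(diff_peaks),
        "modules": {p["id"]: p["class"] for p in diff_peaks},
        "genes": gene_truth,
        "pairs_A_L_vs_V_L": sorted(pairs, key=lambda r: r["peak_id"]),
        "motif": motif_truth,
        "tcf1_seeded_genes": seeded,
        "tcf1_bound_genes": tcf1_bound,
        "refsets": {"exhaustion": exhaustion_ids, "effector": effector_ids},
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    _write_run_config(spec, out)
    return truth


def _write_run_config(spec: FixtureSpec, out: Path) -> None:
    """Emit a ready-to-run pipeline config pointing at the bundle's files."""
    import yaml

    config = {
        "genome_fasta": "genome.fa",
        "gtf": "annotation.gtf",
        "peaks": {s: f"peaks/{s}.narrowPeak" for s in spec.atac_samples},
        "fragments": {s: f"fragments/{s}.bed" for s in spec.atac_samples},
        "rna_counts": "rna_counts.tsv",
        "motifs": "motifs.meme",
        "tcf1_sites": "tcf1_sites.bed",
        "refsets": {
            "exhaustion": "refsets/exhaustion.bed",
            "effector": "refsets/effector.bed",
        },
        "gene_sets": "gene_sets.gmt",
        "atac_groups": {s: s.rsplit("_r", 1)[0] for s in spec.atac_samples},
        "rna_groups": {s: s.rsplit("_rna", 1)[0] for s in spec.rna_samples},
        "comparisons": [[a, b] for a, b in COMPARISONS],
        "clustering_comparisons": ["A_E_vs_V_E", "A_L_vs_V_L"],
        "rna_comparison": ["V_L", "A_L"],
        "thresholds": {
            "atac_lfc": 1.0,
            "rna_fc": 1.5,
            "q": 0.05,
            "k_modules": 5,
            "gene_max_distance": 50000,
            "pairing_limit": 15000,
            "tcf1_window": 10000,
        },
        "seed": spec.seed,
    }
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def match_chars_to_peaks(chars, peak_truth: dict[str, dict]) -> dict[str, list[str]]:
    """Map ChAR id -> overlapping planted peak ids (>= 1 bp overlap)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for pid, rec in peak_truth.items():
        trees.setdefault(rec["chrom"], IntervalTree()).addi(
            rec["start"], rec["end"], pid
        )
    out: dict[str, list[str]] = {}
    for ch in chars:
        tree = trees.get(ch.interval.chrom)
        if tree is None:
            continue
        hits = sorted(h.data for h in tree.overlap(ch.interval.start, ch.interval.end))
        if hits:
            out[ch.id] = hits
    return out
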