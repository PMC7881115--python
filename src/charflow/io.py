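"""Readers and writers for the plain-text formats the pipeline consumes.

BED and narrowPeak are 0-based half-open. PWMs are read from MEME minimal
format; gene sets from GMT.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from charflow.intervals import GenomicInterval
from charflow.region_algebra import TaggedRead


def read_bed(path: str | Path, min_cols: int = 3) -> list[GenomicInterval]:
    """Read intervals from a BED file (columns beyond chrom/start/end ignored
    except strand in column 6 when present)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ValueError(f"{path}: line {lineno}: fewer than {min_cols} columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def read_narrowpeak(path: str | Path) -> list[GenomicInterval]:
    """Read peak intervals from a narrowPeak file (extra columns unused)."""
    return read_bed(path, min_cols=3)


def read_fragments_bed6(path: str | Path) -> list[TaggedRead]:
    out: list[TaggedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 requires 6 columns")
            out.append(
                TaggedRead(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
                )
            )
    return out


def write_bed(intervals, path: str | Path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else str(iv)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            members = [g for g in fields[2:] if g]
            seen: list[str] = []
            for g in members:  # preserve order, drop duplicates
                if g not in seen:
                    seen.append(g)
            sets[fields[0]] = seen
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def read_meme(path: str | Path) -> list:
    """Read PWMs from MEME minimal format.

    Returns :class:`charflow.motif_enrichment.PWM` objects with the file's
    background frequencies (uniform if absent).
    """
    from charflow.motif_enrichment import PWM

    background = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    pwms = []
    name = None
    rows: list[list[float]] = []
    expecting = 0
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            vals = lines[i].split()
            background = {vals[j]: float(vals[j + 1]) for j in range(0, len(vals), 2)}
        elif line.startswith("MOTIF"):
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            rows = []
            expecting = 0
            toks = line.replace("=", " ").split()
            for j, t in enumerate(toks):
                if t == "w":
                    expecting = int(toks[j + 1])
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                parts = lines[i].split()
                if len(parts) >= 4:
                    rows.append([float(x) for x in parts[:4]])
                i += 1
                if expecting and len(rows) == expecting:
                    break
            pwms.append(PWM(name=name, matrix=np.asarray(rows), background=dict(background)))
            continue
        i += 1
    return pwms


def write_meme(pwms, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[b]:.5f}" for b in "ACGT") + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.matrix.shape[0]} "
                f"nsites= 20 E= 0\n"
            )
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
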