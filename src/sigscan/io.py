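"""File-format boundaries: FASTA, VCF v4.2, BED and TSV tables.

Coordinates are 0-based half-open in memory and only converted at the
format boundary (VCF and BED writers/readers handle this via pysam and
plain TSV conventions respectively).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .genome import Genome


def write_vcf(variants: pd.DataFrame, path, genome: Genome, sample: str | None = None) -> None:
    """Write somatic calls as an uncompressed VCF v4.2 (one file per sample).

    The generating-process tag (if present) is carried in INFO/PROCESS.
    """
    header = pysam.VariantHeader()
    for ctg in genome:
        header.contigs.add(ctg, length=genome.length(ctg))
    header.add_line(
        '##INFO=<ID=PROCESS,Number=1,Type=String,Description="Generating process tag">'
    )
    header.add_line(
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Tumor sample label">'
    )
    sub = variants if sample is None else variants[variants["sample"] == sample]
    sub = sub.sort_values(["contig", "pos"], kind="stable")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in sub.itertuples(index=False):
            rec = vf.new_record(
                contig=row.contig,
                start=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            rec.info["SAMPLE"] = str(row.sample)
            if hasattr(row, "process"):
                rec.info["PROCESS"] = str(row.process)
            vf.write(rec)


def read_vcf(path, sample: str | None = None) -> pd.DataFrame:
    """Read a VCF into the internal variant table (0-based positions)."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            smp = rec.info.get("SAMPLE", sample or Path(path).stem)
            rows.append(
                (
                    rec.contig,
                    rec.start,
                    rec.ref,
                    rec.alts[0] if rec.alts else ".",
                    smp,
                    rec.info.get("PROCESS", None),
                )
            )
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "sample", "process"]
    )


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    out = df[["contig", "start", "end"]].copy()
    if name_col is not None:
        out["name"] = df[name_col]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("contig", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_repeats_bed(runs: pd.DataFrame, path) -> None:
    """BED of repeat runs with name = unit:length:kind."""
    out = runs.copy()
    out["name"] = (
        out["unit"] + ":" + out["length"].astype(str) + ":" + out["kind"]
    )
    write_bed(out, path, name_col="name")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_marker_matrix(matrix: pd.DataFrame, truth: pd.Series | None, path) -> None:
    out = matrix.copy()
    if truth is not None:
        out.insert(0, "truth", truth.astype(int))
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_marker_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col="sample")
    truth = None
    if "truth" in df.columns:
        truth = df.pop("truth").astype(bool)
    return df, truth
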