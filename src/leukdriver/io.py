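"""Readers and writers for the standard formats the toolkit consumes.

VCF via pysam; FASTA via pyfaidx (reading) and plain text (writing);
SEG-like TSV, BEDPE and BED as pandas tables; truth tables as JSON.
Coordinate conventions: VCF and SEG are 1-based, BED/BEDPE 0-based
half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "write_vcf",
    "read_vcf",
    "read_fasta",
    "write_fasta",
    "read_bed_masks",
    "write_cohort",
]


def write_vcf(
    variants: pd.DataFrame,
    path: str | Path,
    contig_lengths: Mapping[str, int],
    *,
    af_info_key: str = "POPMAX_AF",
) -> None:
    """Write a variant table to an uncompressed VCF.

    Expected columns: contig, pos (1-based), ref, alt, filter, vaf, and
    optionally popmax_af, sample_id, region_id (stored as INFO fields).
    """
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=int(length))
    header.filters.add("FAIL", None, None, "failed caller QC")
    header.info.add("VAF", 1, "Float", "variant allele frequency")
    header.info.add(af_info_key, 1, "Float", "maximum population allele frequency")
    header.info.add("SAMPLE", 1, "String", "tumour sample id")
    header.info.add("REGION", 1, "String", "overlapping region id")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        ordered = variants.sort_values(["contig", "pos"], kind="mergesort")
        for row in ordered.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.contig,
                start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
            )
            filt = getattr(row, "filter", "PASS")
            rec.filter.add("PASS" if filt in ("PASS", ".", None) else "FAIL")
            vaf = getattr(row, "vaf", None)
            if vaf is not None and not pd.isna(vaf):
                rec.info["VAF"] = float(vaf)
            af = getattr(row, "popmax_af", None)
            if af is not None and not pd.isna(af):
                rec.info[af_info_key] = float(af)
            sample = getattr(row, "sample_id", None)
            if sample is not None and not pd.isna(sample):
                rec.info["SAMPLE"] = str(sample)
            rid = getattr(row, "region_id", None)
            if rid is not None and not pd.isna(rid):
                rec.info["REGION"] = str(rid)
            vcf.write(rec)


def read_vcf(path: str | Path, *, af_info_key: str = "POPMAX_AF") -> pd.DataFrame:
    """Read a VCF into the toolkit's variant table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filt = list(rec.filter)
            rows.append(
                {
                    "sample_id": rec.info.get("SAMPLE", None),
                    "contig": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "filter": filt[0] if filt else "PASS",
                    "vaf": float(rec.info["VAF"]) if "VAF" in rec.info else np.nan,
                    "popmax_af": float(rec.info[af_info_key])
                    if af_info_key in rec.info
                    else np.nan,
                    "region_id": rec.info.get("REGION", None),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "contig", "pos", "ref", "alt", "filter", "vaf",
            "popmax_af", "region_id",
        ],
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into a contig -> sequence dict (pyfaidx-backed)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed_masks(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED file into per-contig interval trees (0-based half-open)."""
    masks: dict[str, IntervalTree] = {}
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end"], usecols=[0, 1, 2],
    )
    for contig, grp in bed.groupby("contig"):
        tree = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            if e > s:
                tree.addi(int(s), int(e))
        masks[str(contig)] = tree
    return masks


def write_cohort(cohort, outdir: str | Path) -> dict[str, Path]:
    """Serialize a synthetic cohort to standard text formats.

    Writes variants.vcf, segments.seg (1-based inclusive TSV), svs.bedpe
    (0-based half-open), regions.bed, expression.tsv, ccf_clusters.tsv,
    samples.tsv and truth.json; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contig_lengths = {c.name: c.length for c in cohort.config.genome}
    paths = {}

    paths["vcf"] = outdir / "variants.vcf"
    write_vcf(cohort.variants, paths["vcf"], contig_lengths)

    paths["seg"] = outdir / "segments.seg"
    cohort.segments.to_csv(paths["seg"], sep="\t", index=False)

    paths["bedpe"] = outdir / "svs.bedpe"
    svs = cohort.svs
    bedpe = pd.DataFrame(
        {
            "chrom1": svs["chrom1"],
            "start1": svs["pos1"] - 1,
            "end1": svs["pos1"],
            "chrom2": svs["chrom2"],
            "start2": svs["pos2"] - 1,
            "end2": svs["pos2"],
            "name": svs["sv_id"],
            "score": ".",
            "strand1": svs["strand1"],
            "strand2": svs["strand2"],
            "svtype": svs["svtype"],
            "vaf": svs["vaf"],
            "ccf": svs["ccf"],
            "callers": svs["callers"],
            "complex": svs["complex"],
            "sample_id": svs["sample_id"],
        }
    )
    bedpe.to_csv(paths["bedpe"], sep="\t", index=False)

    paths["bed"] = outdir / "regions.bed"
    cohort.regions[["contig", "start", "end", "region_id"]].to_csv(
        paths["bed"], sep="\t", index=False, header=False
    )
    paths["regions"] = outdir / "regions.tsv"
    cohort.regions.to_csv(paths["regions"], sep="\t", index=False)

    paths["expression"] = outdir / "expression.tsv"
    cohort.expression.to_csv(paths["expression"], sep="\t")

    paths["clusters"] = outdir / "ccf_clusters.tsv"
    cohort.ccf_clusters.to_csv(paths["clusters"], sep="\t", index=False)

    paths["samples"] = outdir / "samples.tsv"
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        fh.write(cohort.to_json_truth())
    return paths
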