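"""Readers and writers for the formats the pipeline consumes and produces.

Supported inputs: VCF 4.x with per-sample allele depths (AD), a plain
tabular SNV format, delimited marker genotype tables, GFF3/BED12 gene
models, FASTA sequence, delimited qPCR Ct tables, and YAML configuration.

All readers emit deterministic orderings: variants sorted by
(chrom lexicographic, pos ascending), gene models by (chrom, start).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .types import (
    DEFAULT_CODE_MAP,
    GeneModel,
    MarkerGenotypeTable,
    PooledVariant,
    QpcrMeasurement,
    sort_variants,
)

logger = logging.getLogger("bsrmap")

TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "mut_ref", "mut_alt", "wt_ref", "wt_alt"]


def configure_logging(verbose: bool = False) -> None:
    """Route package logging to stderr; --verbose lowers the level to DEBUG."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t" if "\t" in first else ","


# ---------------------------------------------------------------------------
# Pooled variants
# ---------------------------------------------------------------------------

def read_pooled_variants(
    path: str | Path,
    format: str = "auto",
    mut_sample: str = "mut",
    wt_sample: str = "wt",
    keep_multiallelic: bool = False,
) -> list[PooledVariant]:
    """Read per-bulk SNV allele counts from a VCF (AD fields) or a table.

    Only biallelic SNVs are returned; multiallelic records and indels are
    skipped by default (counts logged). Output is sorted by (chrom, pos).
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz") else "table"
    if format == "vcf":
        variants = _read_vcf(path, mut_sample, wt_sample, keep_multiallelic)
    elif format == "table":
        variants = _read_variant_table(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return sort_variants(variants)


def _read_vcf(
    path: Path, mut_sample: str, wt_sample: str, keep_multiallelic: bool
) -> list[PooledVariant]:
    import pysam

    variants: list[PooledVariant] = []
    n_multi = n_noad = n_indel = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in (mut_sample, wt_sample):
            if s not in samples:
                raise ValueError(f"sample {s!r} not in VCF (found {samples})")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                if not keep_multiallelic:
                    continue
            if len(rec.ref) != 1 or any(len(a) != 1 for a in alts[:1]):
                n_indel += 1
                continue
            try:
                ad_mut = rec.samples[mut_sample]["AD"]
                ad_wt = rec.samples[wt_sample]["AD"]
            except KeyError:
                n_noad += 1
                continue
            if ad_mut is None or ad_wt is None or ad_mut[0] is None or ad_wt[0] is None:
                n_noad += 1
                continue
            variants.append(
                PooledVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                    mut_ref_count=int(ad_mut[0]),
                    mut_alt_count=int(ad_mut[1]),
                    wt_ref_count=int(ad_wt[0]),
                    wt_alt_count=int(ad_wt[1]),
                )
            )
    if n_multi:
        logger.warning("skipped %d multiallelic record(s)", n_multi)
    if n_indel:
        logger.warning("skipped %d indel record(s)", n_indel)
    if n_noad:
        logger.warning("skipped %d record(s) without usable AD fields", n_noad)
    return variants


def _read_variant_table(path: Path) -> list[PooledVariant]:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return [
        PooledVariant(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            mut_ref_count=int(r.mut_ref),
            mut_alt_count=int(r.mut_alt),
            wt_ref_count=int(r.wt_ref),
            wt_alt_count=int(r.wt_alt),
        )
        for r in df.itertuples()
    ]


def write_pooled_variants(variants: Sequence[PooledVariant], path: str | Path) -> None:
    """Write the tabular SNV format (tab-delimited, header = TABLE_COLUMNS)."""
    df = pd.DataFrame(
        [
            (v.chrom, v.pos, v.ref_allele, v.alt_allele,
             v.mut_ref_count, v.mut_alt_count, v.wt_ref_count, v.wt_alt_count)
            for v in sort_variants(variants)
        ],
        columns=TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker genotype tables
# ---------------------------------------------------------------------------

def read_marker_table(
    path: str | Path,
    code_map: dict[str, str] | None = None,
    recessive_only: bool = True,
) -> MarkerGenotypeTable:
    """Read a delimited marker genotype table.

    Layout: row 1 = marker ids (first cell is a label for the id column),
    row 2 = marker chromosomes, row 3 = marker positions, remaining rows =
    one individual each. Symbols outside the {A,H,B,U} alphabet are mapped
    through ``code_map`` (default :data:`DEFAULT_CODE_MAP`); anything still
    unknown becomes U with a warning.
    """
    code_map = dict(DEFAULT_CODE_MAP if code_map is None else code_map)
    delim = _sniff_delimiter(path)
    with open(path) as fh:
        rows = [line.rstrip("\n").split(delim) for line in fh if line.strip()]
    if len(rows) < 4:
        raise ValueError("marker table needs marker/chrom/pos rows plus >= 1 individual")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"ragged row {i + 1}: expected {width} fields, got {len(row)}")
    markers = rows[0][1:]
    chroms = rows[1][1:]
    pos = [int(p) for p in rows[2][1:]]
    individuals = [r[0] for r in rows[3:]]
    n_unknown = 0
    calls = np.empty((len(individuals), len(markers)), dtype="<U1")
    for i, row in enumerate(rows[3:]):
        for j, sym in enumerate(row[1:]):
            mapped = code_map.get(sym.strip())
            if mapped is None:
                n_unknown += 1
                mapped = "U"
            calls[i, j] = mapped
    if n_unknown:
        logger.warning("mapped %d unknown genotype symbol(s) to U", n_unknown)
    return MarkerGenotypeTable(
        individuals=individuals,
        markers=markers,
        marker_chroms=chroms,
        marker_pos=pos,
        calls=calls,
        recessive_only=recessive_only,
    )


def write_marker_table(table: MarkerGenotypeTable, path: str | Path, delim: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delim.join(["id", *table.markers]) + "\n")
        fh.write(delim.join(["chrom", *table.marker_chroms]) + "\n")
        fh.write(delim.join(["pos", *(str(p) for p in table.marker_pos)]) + "\n")
        for ind, row in zip(table.individuals, table.calls):
            fh.write(delim.join([ind, *row]) + "\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, format: str = "auto") -> list[GeneModel]:
    """Read gene models from GFF3 or BED12, sorted by (chrom, start).

    For GFF3 genes with several mRNAs the first (by feature id) supplies the
    CDS, and the choice is logged. CDS outside gene bounds is fatal.
    """
    path = Path(path)
    if format == "auto":
        format = "bed" if path.suffix in (".bed", ".bed12") else "gff3"
    if format == "gff3":
        genes = _read_gff3(path)
    elif format == "bed":
        genes = _read_bed12(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return sorted(genes, key=lambda g: (g.chrom, g.gene_start))


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
        if len(mrnas) > 1:
            logger.info("gene %s has %d mRNAs; using %s", gene.id, len(mrnas), mrnas[0].id)
        parent = mrnas[0] if mrnas else gene
        cds = [(c.start, c.end) for c in db.children(parent, featuretype="CDS")]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                gene_start=gene.start,
                gene_end=gene.end,
                cds_segments=cds,
            )
        )
        if not genes[-1].frame_ok:
            logger.warning("gene %s CDS length %d not divisible by 3",
                           gene.id, genes[-1].cds_length)
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, start0, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_start0, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            segments = []
            for size, off in zip(sizes, offsets):
                # block in 1-based inclusive coords, clipped to the thick (CDS) range
                s = max(start0 + off + 1, thick_start0 + 1)
                e = min(start0 + off + size, thick_end)
                if s <= e:
                    segments.append((s, e))
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    gene_start=start0 + 1,
                    gene_end=end,
                    cds_segments=segments,
                )
            )
    return genes


def write_regions_bed(intervals: Iterable, path: str | Path) -> None:
    """Write genomic intervals as BED3 (half-open, 0-based) lines."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# FASTA and Ct tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load FASTA into a chrom -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_ct_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read a delimited Ct table with columns
    sample_id, group, tissue, ct_target, ct_reference."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "group", "tissue", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return [
        QpcrMeasurement(
            sample_id=str(r.sample_id),
            group=str(r.group),
            tissue=str(r.tissue),
            ct_target=float(r.ct_target),
            ct_reference=float(r.ct_reference),
        )
        for r in df.itertuples()
    ]


def write_ct_table(measurements: Sequence[QpcrMeasurement], path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.group, m.tissue, m.ct_target, m.ct_reference) for m in measurements],
        columns=["sample_id", "group", "tissue", "ct_target", "ct_reference"],
    )
    df.to_csv(path, sep="\t", index=False)
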