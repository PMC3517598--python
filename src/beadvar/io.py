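"""Readers and writers for every external format the pipeline touches.

Formats: GenomeStudio-style sample-probe TSV (``PROBE_ID``,
``<sample>.AVG_Signal`` and optional ``<sample>.Detection Pval``
columns), covariate TSV with a YAML type sidecar, minimal VCF v4.2 with
a DS (dosage) FORMAT field, FASTA, BED12 transcript models, and the
annotation TSV.

All validation happens here; genomic coordinates are converted between
the 1-based VCF/BED conventions and the internal 0-based half-open
convention at this boundary only.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ExpressionMatrix, FactorTable, GenotypeMatrix, TranscriptModel, Variant

logger = logging.getLogger(__name__)

AVG_SUFFIX = ".AVG_Signal"
DET_SUFFIX = ".Detection Pval"


# ---------------------------------------------------------------------------
# expression profiles


def write_expression_profile(expression: ExpressionMatrix, path,
                             detection: pd.DataFrame | None = None) -> None:
    """Write a GenomeStudio-style sample-probe TSV."""
    blocks = []
    for s in expression.sample_ids:
        blocks.append(expression.values[s].rename(f"{s}{AVG_SUFFIX}"))
        if detection is not None:
            blocks.append(detection[s].rename(f"{s}{DET_SUFFIX}"))
    out = pd.concat(blocks, axis=1)
    out.index.name = "PROBE_ID"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_profile(path) -> tuple[ExpressionMatrix, pd.DataFrame | None]:
    """Read a GenomeStudio-style TSV into a raw-scale matrix.

    Returns ``(expression, detection)``; ``detection`` is None when the
    file carries no ``Detection Pval`` columns.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "PROBE_ID":
        raise ValueError(f"{path}: first column must be PROBE_ID, got {raw.columns[0]!r}")
    probe_ids = raw["PROBE_ID"]
    dup = probe_ids[probe_ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate probe id {dup.iloc[0]!r}")
    avg_cols = [c for c in raw.columns if c.endswith(AVG_SUFFIX)]
    det_cols = [c for c in raw.columns if c.endswith(DET_SUFFIX)]
    if not avg_cols:
        raise ValueError(f"{path}: no {AVG_SUFFIX} columns found")

    def to_numeric(cols, suffix):
        block = raw[cols].copy()
        for c in cols:
            converted = pd.to_numeric(block[c], errors="coerce")
            bad = converted.isna() & block[c].notna()
            if bad.any():
                r = bad.idxmax()
                raise ValueError(
                    f"{path}: non-numeric value {block[c][r]!r} at probe "
                    f"{probe_ids[r]!r}, column {c!r}")
            block[c] = converted
        block.columns = [c[: -len(suffix)] for c in cols]
        block.index = probe_ids
        return block

    values = to_numeric(avg_cols, AVG_SUFFIX)
    expression = ExpressionMatrix(values, scale="raw")
    detection = None
    if det_cols:
        detection = to_numeric(det_cols, DET_SUFFIX)
        detection = detection[list(values.columns)]
    return expression, detection


# ---------------------------------------------------------------------------
# covariates


def write_factor_table(factors: FactorTable, path) -> None:
    """Write covariates as TSV plus a ``<path>.types.yaml`` sidecar."""
    path = Path(path)
    factors.table.to_csv(path, sep="\t", index_label="sample_id")
    with open(f"{path}.types.yaml", "w") as fh:
        yaml.safe_dump({name: factors.types[name] for name in factors.table.columns}, fh)


def read_factor_table(path) -> FactorTable:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col="sample_id")
    with open(f"{path}.types.yaml") as fh:
        types = yaml.safe_load(fh)
    for name, kind in types.items():
        if kind == "categorical":
            table[name] = table[name].astype(str)
    return FactorTable(table, types)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with a DS (dosage) FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=IQ,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        chroms = dict.fromkeys(v.chrom for v in genotypes.variants)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        for v, row in zip(genotypes.variants, genotypes.dosages):
            info = f"IQ={v.imputation_quality:.4g}" if v.imputation_quality is not None else "."
            fields = [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", "PASS",
                      info, "DS"] + [f"{d:.6g}" for d in row]
            fh.write("\t".join(fields) + "\n")


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def read_genotype_dosages(vcf_path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic dosages from a VCF (DS field, or GT converted to 0/1/2).

    Multiallelic records are skipped with a logged count. ``region`` is
    ``chrom`` or ``chrom:start-end`` (1-based inclusive, as printed).
    """
    from cyvcf2 import VCF

    chrom = lo = hi = None
    if region is not None:
        m = _REGION_RE.match(region)
        if not m:
            raise ValueError(f"malformed region {region!r}")
        chrom = m.group(1)
        if m.group(2):
            lo, hi = int(m.group(2)), int(m.group(3))
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad files
        raise ValueError(f"cannot open VCF {vcf_path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for v in vcf:
        if chrom is not None and v.CHROM != chrom:
            continue
        if lo is not None and not (lo <= v.POS <= hi):
            continue
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ds = v.format("DS")
        if ds is not None:
            dosage = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(v.genotypes, dtype=int)[:, :2]
            if (gts < 0).any():
                raise ValueError(f"{v.CHROM}:{v.POS}: record has neither DS nor called GT")
            dosage = gts.sum(axis=1).astype(float)
        iq = v.INFO.get("IQ")
        af = np.clip(dosage.mean() / 2.0, 0.0, 1.0)
        variants.append(Variant(chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0],
                                maf=float(min(af, 1 - af)),
                                variant_id=v.ID or ".",
                                imputation_quality=float(iq) if iq is not None else None))
        rows.append(dosage)
    if n_multi:
        logger.info("skipped %d multiallelic records in %s", n_multi, vcf_path)
    dosages = np.array(rows) if rows else np.empty((0, len(sample_ids)))
    return GenotypeMatrix(variants=variants, dosages=dosages, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BED12 transcript models


def write_bed12(models: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(b - a) for a, b in m.exons) + ","
            starts = ",".join(str(a - m.start) for a, _ in m.exons) + ","
            fh.write("\t".join([
                m.chrom, str(m.start), str(m.end), m.transcript_id, "0", m.strand,
                str(m.start), str(m.end), "0", str(len(m.exons)), sizes, starts,
            ]) + f"\t{m.gene_id}\n")


def read_transcript_models(bed12_path, fasta_path) -> list[TranscriptModel]:
    """Read BED12 transcript models and attach mRNA sequences.

    The FASTA must contain one record per BED name. Each sequence length
    must equal the sum of the exon block lengths; for minus-strand
    models the stored sequence is taken to be the reverse complement of
    the concatenated genomic blocks (5'->3' of the transcript).
    """
    seqs = read_fasta(fasta_path)
    models: list[TranscriptModel] = []
    with open(bed12_path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{bed12_path}:{ln}: expected >= 12 BED12 fields")
            chrom, start, _end, name, _score, strand = fields[:6]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{bed12_path}:{ln}: blockCount inconsistent with block lists")
            if name not in seqs:
                raise ValueError(f"{bed12_path}:{ln}: transcript {name!r} missing from FASTA")
            seq = seqs[name]
            if sum(sizes) != len(seq):
                raise ValueError(
                    f"{bed12_path}:{ln}: blockSizes sum {sum(sizes)} != sequence "
                    f"length {len(seq)} for {name!r}")
            gstart = int(start)
            exons = [(gstart + s, gstart + s + L) for s, L in zip(starts, sizes)]
            gene_id = fields[12] if len(fields) > 12 else name
            models.append(TranscriptModel(
                transcript_id=name, gene_id=gene_id, chrom=chrom, strand=strand,
                exons=exons, sequence=seq))
    return models


# ---------------------------------------------------------------------------
# annotation table

ANNOTATION_COLUMNS = ["probe_id", "transcript_id", "gene_id", "chromosome", "strand",
                      "start", "end", "n_exons_spanned", "mapping_class"]


def write_annotation(table: pd.DataFrame, path, build: str = "synthetic") -> None:
    """Write the probe annotation TSV (coordinates 0-based half-open)."""
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    with open(path, "w") as fh:
        fh.write(f"# genome_build={build}; coordinates 0-based half-open\n")
        table[ANNOTATION_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
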