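"""Probe reannotation by exact sequence matching to transcripts.

Each probe (a 50-mer targeting mRNA) is searched as an exact
sense-strand substring of every transcript's mRNA sequence. Hits are
classified by uniqueness (single mRNA / single gene / ambiguous /
unmapped), projected through the transcript's exon blocks to genomic
coordinates, and written to an annotation table. Reverse-complement
hits are not part of the standard scan (probes target mRNA) but can be
enabled for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import TranscriptModel

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MAPPING_CLASSES = ("unique_mrna", "unique_gene", "ambiguous", "unmapped")


@dataclass
class AnnotationRecord:
    probe_id: str
    mapping_class: str
    transcript_id: str | None = None
    gene_id: str | None = None
    chromosome: str | None = None
    strand: str | None = None
    start: int | None = None   # genomic, 0-based half-open envelope
    end: int | None = None
    n_exons_spanned: int | None = None
    offset_in_transcript: int | None = None


def map_probe_to_transcripts(
    probe_sequence: str,
    transcripts: list[TranscriptModel],
    include_reverse_complement: bool = False,
) -> list[tuple[str, int]]:
    """All exact sense-strand substring hits across all transcripts.

    Returns ``(transcript_id, offset)`` pairs (0-based offsets within
    the mRNA); multiple offsets within one transcript are all reported.
    """
    probe_sequence = probe_sequence.upper()
    if len(probe_sequence) < 10:
        raise ValueError("probe sequence shorter than 10 nt")
    bad = set(probe_sequence) - set("ACGT")
    if bad:
        raise ValueError(f"probe sequence contains non-ACGT characters: {sorted(bad)}")
    queries = [probe_sequence]
    if include_reverse_complement:
        queries.append(probe_sequence.translate(_COMPLEMENT)[::-1])
    hits: list[tuple[str, int]] = []
    for model in transcripts:
        seq = model.sequence.upper()
        for q in queries:
            start = seq.find(q)
            while start != -1:
                hits.append((model.transcript_id, start))
                start = seq.find(q, start + 1)
    return hits


def classify_mapping(hits: list[tuple[str, int]], gene_of: dict[str, str]) -> str:
    """Uniqueness class of a hit list.

    No hit: unmapped. One transcript, one offset: unique_mrna. Several
    transcripts of one gene: unique_gene. Several genes, or repeated
    hits within one transcript (ill-defined coordinates): ambiguous.
    """
    if not hits:
        return "unmapped"
    by_tx: dict[str, int] = {}
    for tid, _ in hits:
        by_tx[tid] = by_tx.get(tid, 0) + 1
    if any(c > 1 for c in by_tx.values()):
        return "ambiguous"
    if len(by_tx) == 1:
        return "unique_mrna"
    genes = {gene_of[tid] for tid in by_tx}
    return "unique_gene" if len(genes) == 1 else "ambiguous"


def genomic_coordinates(
    offset: int, model: TranscriptModel, probe_length: int
) -> tuple[tuple[int, int], int]:
    """Project a transcript-relative interval through the exon blocks.

    ``offset`` counts from the transcript 5' end; for minus-strand
    models the mRNA is the reverse complement of the concatenated
    genomic blocks, so offsets count from the right edge of the last
    block. Returns the genomic envelope (0-based half-open) and the
    number of exon blocks the probe intersects.
    """
    total = model.length
    if offset < 0 or offset + probe_length > total:
        raise ValueError(
            f"offset {offset}+{probe_length} outside mRNA of length {total}")
    # interval in concatenated-block (genomic-order) coordinates
    if model.strand == "+":
        c0, c1 = offset, offset + probe_length
    else:
        c0, c1 = total - offset - probe_length, total - offset
    lo = hi = None
    n_exons = 0
    cum = 0
    for a, b in model.exons:
        size = b - a
        s, e = max(c0, cum), min(c1, cum + size)
        if s < e:  # probe overlaps this block
            n_exons += 1
            gs = a + (s - cum)
            ge = a + (e - cum)
            lo = gs if lo is None else min(lo, gs)
            hi = ge if hi is None else max(hi, ge)
        cum += size
    return (lo, hi), n_exons


def annotate_all(
    probe_sequences: dict[str, str],
    transcripts: list[TranscriptModel],
) -> tuple[list[AnnotationRecord], dict]:
    """Annotate every probe; return records plus summary counts.

    For a ``unique_gene`` probe the coordinates of the first transcript
    (by identifier order) are reported. The summary gives counts per
    mapping class and the percentage of probes mapped uniquely to one
    mRNA or gene.
    """
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    model_of = {t.transcript_id: t for t in transcripts}
    records: list[AnnotationRecord] = []
    for pid, seq in probe_sequences.items():
        hits = map_probe_to_transcripts(seq, transcripts)
        cls = classify_mapping(hits, gene_of)
        if cls in ("unique_mrna", "unique_gene"):
            tid, off = sorted(hits)[0]
            model = model_of[tid]
            (start, end), n_ex = genomic_coordinates(off, model, len(seq))
            records.append(AnnotationRecord(
                probe_id=pid, mapping_class=cls, transcript_id=tid,
                gene_id=gene_of[tid], chromosome=model.chrom, strand=model.strand,
                start=start, end=end, n_exons_spanned=n_ex,
                offset_in_transcript=off))
        else:
            records.append(AnnotationRecord(probe_id=pid, mapping_class=cls))
    counts = {c: 0 for c in MAPPING_CLASSES}
    for r in records:
        counts[r.mapping_class] += 1
    n_unique = counts["unique_mrna"] + counts["unique_gene"]
    summary = {"counts": counts, "n_probes": len(records),
               "pct_unique": 100.0 * n_unique / len(records) if records else 0.0}
    return records, summary


def annotation_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Records as the annotation-table schema used by the TSV writer."""
    rows = [{
        "probe_id": r.probe_id, "transcript_id": r.transcript_id,
        "gene_id": r.gene_id, "chromosome": r.chromosome, "strand": r.strand,
        "start": r.start, "end": r.end, "n_exons_spanned": r.n_exons_spanned,
        "mapping_class": r.mapping_class,
    } for r in records]
    return pd.DataFrame(rows)
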