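"""Core in-memory containers shared by every stage of the pipeline.

The central object is the :class:`ExpressionMatrix` (probes x samples),
accompanied by a typed per-sample :class:`FactorTable`, a
:class:`GenotypeMatrix` of biallelic dosages and a list of
:class:`TranscriptModel` records describing transcript exon structure.

Genomic coordinates are 0-based half-open on the forward strand
everywhere inside the package; conversion to/from the 1-based inclusive
convention of VCF happens at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("raw", "log2", "vst")


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with a scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns are sample ids.
    scale
        One of ``raw`` (positive intensities), ``log2`` or ``vst``.
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.scale == "raw" and np.any(arr <= 0):
            g, s = np.argwhere(arr <= 0)[0]
            raise ValueError(
                f"raw-scale intensity must be positive; probe {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r} has value {arr[g, s]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], scale=self.scale)


@dataclass
class FactorTable:
    """Per-sample covariates, each typed continuous or categorical.

    ``table`` is indexed by sample id; ``types`` maps every column to
    ``"continuous"`` or ``"categorical"``.
    """

    table: pd.DataFrame
    types: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.table.columns) - set(self.types)
        if missing:
            raise ValueError(f"columns without a declared type: {sorted(missing)}")
        for name, kind in self.types.items():
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"factor {name!r}: type must be continuous or categorical, got {kind!r}")
            if name in self.table.columns and kind == "continuous":
                if not np.issubdtype(self.table[name].dtype, np.number):
                    raise ValueError(f"continuous factor {name!r} has non-numeric values")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample id in factor table")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def factor_names(self) -> list[str]:
        return list(self.table.columns)

    def is_categorical(self, name: str) -> bool:
        return self.types[name] == "categorical"

    def column(self, name: str) -> pd.Series:
        return self.table[name]

    def align_to(self, sample_ids) -> "FactorTable":
        sub = self.table.loc[list(sample_ids)]
        return FactorTable(sub, dict(self.types))


@dataclass
class Variant:
    """A biallelic SNP. ``pos`` is 1-based as printed in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float = float("nan")
    variant_id: str = "."
    imputation_quality: float | None = None

    @property
    def pos0(self) -> int:
        """0-based position of the variant base."""
        return self.pos - 1


@dataclass
class GenotypeMatrix:
    """Biallelic variants x samples alt-allele dosages in [0, 2]."""

    variants: list[Variant]
    dosages: np.ndarray  # (n_variants, n_samples)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError("dosage matrix shape inconsistent with variants/samples")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        last: dict[str, int] = {}
        for v in self.variants:
            if v.chrom in last and v.pos <= last[v.chrom]:
                raise ValueError(f"positions not strictly increasing on {v.chrom} at {v.pos}")
            last[v.chrom] = v.pos

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class TranscriptModel:
    """Transcript exon structure on the genome plus its mRNA sequence.

    Exon blocks are 0-based half-open genomic intervals sorted by start.
    The mRNA sequence is the concatenation of the blocks in genomic
    order, reverse-complemented for minus-strand transcripts, so that
    ``sequence[0]`` is the transcript's 5' base.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"empty or inverted exon block ({a}, {b})")
        for (a0, b0), (a1, b1) in zip(exons, exons[1:]):
            if a1 < b0:
                raise ValueError("overlapping exon blocks")
        self.exons = exons
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"sum of exon block lengths {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site: the 5' end on the transcript's strand (0-based)."""
        return self.start if self.strand == "+" else self.end - 1
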