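"""Shared paths and study parameters for the analysis scripts.

The analysis chain is file-based: 01 writes a complete synthetic study
in the external formats (sample-probe TSV, covariate TSV, VCF, FASTA,
BED12) under scratch/study/, and the later scripts consume those files
through the package readers, so the whole pipeline including I/O is
exercised. Small result tables land in results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

STUDY_SEED = 7  # the one default study every analysis script uses

# detected-probe threshold scaled to the synthetic panel: the cohort
# rule (6000 of ~48k probes) corresponds to ~1/8 of the panel
MIN_DETECTED = 600

FILES = {
    "expression": SCRATCH / "expression.tsv",
    "controls": SCRATCH / "negative_controls.tsv",
    "factors": SCRATCH / "factors.tsv",
    "vcf": SCRATCH / "genotypes.vcf",
    "probe_fasta": SCRATCH / "probes.fasta",
    "transcript_fasta": SCRATCH / "transcripts.fasta",
    "bed12": SCRATCH / "transcripts.bed12",
    "qn_l2t": SCRATCH / "expression_qn_l2t.tsv",
    "annotation": SCRATCH / "annotation.tsv",
}


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
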