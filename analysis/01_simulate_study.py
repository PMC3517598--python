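"""Generate the default synthetic study and write it in external formats.

The study emulates a bead-array expression cohort: 192 samples on
16 twelve-array chips nested in two 96-well plates, 1000 probes with a
log-normal intensity distribution over a noisy background, planted
factor-specific variance shares dominated by technical batches,
genotypes in LD blocks, and in-probe SNPs with planted mismatch
effects. Everything downstream reads these files.
"""

import pandas as pd

from beadvar import io as bio
from beadvar.containers import ExpressionMatrix
from beadvar.simulate import SimulationConfig, generate_study

from common import FILES, RESULTS, STUDY_SEED, ensure_dirs


def main() -> None:
    ensure_dirs()
    cfg = SimulationConfig(seed=STUDY_SEED)
    study = generate_study(cfg)

    bio.write_expression_profile(study.expression, FILES["expression"])
    bio.write_expression_profile(
        ExpressionMatrix(study.negative_controls, scale="raw"), FILES["controls"])
    bio.write_factor_table(study.factors, FILES["factors"])
    bio.write_vcf(study.genotypes, FILES["vcf"])
    bio.write_fasta(study.probe_sequences, FILES["probe_fasta"])
    bio.write_fasta({m.transcript_id: m.sequence for m in study.transcript_models},
                    FILES["transcript_fasta"])
    bio.write_bed12(study.transcript_models, FILES["bed12"])

    planted = pd.DataFrame(
        [{"factor": k, "planted_fraction": v}
         for k, v in cfg.variance_fractions.items()])
    planted.to_csv(RESULTS / "planted_variance_fractions.tsv", sep="\t", index=False)

    n_eff = sum(1 for e in study.truth.snp_effects if e.beta != 0)
    print(f"study: {study.expression.n_probes} probes x "
          f"{study.expression.n_samples} samples, "
          f"{study.genotypes.n_variants} variants "
          f"({n_eff} planted mismatch effects of "
          f"{cfg.mismatch_effect_size} log2/allele, "
          f"{len(study.truth.snp_effects) - n_eff} null in-probe SNPs)")
    print(f"planted variance fractions: {cfg.variance_fractions}")
    print(f"files written under {FILES['expression'].parent}")


if __name__ == "__main__":
    main()
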