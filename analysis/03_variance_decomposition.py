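"""PCA and Eigen-R-squared attribution of expression variance to factors.

Reports how much of the total variation the first components carry
(uncentered PCA is dominated by the shared mean profile), attributes
variance to each technical and biological factor with Eigen-R-squared,
scans the first 50 PCs for factor associations, and shows how removing
the technical factors collapses the dominant components.
"""

import pandas as pd

from beadvar import io as bio
from beadvar.pca import (
    compute_pca,
    eigen_r2,
    pc_factor_scan,
    remove_technical_effects,
    variance_explained,
)
from beadvar.preprocess import (
    detection_pvalues,
    filter_probes_by_detection,
    log2_transform,
)

from common import FILES, RESULTS, ensure_dirs

TECHNICAL = ["chip", "amplification_plate", "isolation_plate", "storage_time"]


def main() -> None:
    ensure_dirs()
    l2t, _ = bio.read_expression_profile(FILES["qn_l2t"])
    l2t.scale = "log2"
    factors = bio.read_factor_table(FILES["factors"])
    factors = factors.align_to(l2t.sample_ids)

    pca_u = compute_pca(l2t, "none")
    pca_c = compute_pca(l2t, "probe")
    print(f"uncentered PCA: PC1 explains {100 * variance_explained(pca_u, 1):.1f}% "
          f"of total variation (shared mean profile), "
          f"first 10 PCs {100 * variance_explained(pca_u, 10):.1f}%")

    rows = []
    for name in factors.factor_names:
        res = eigen_r2(pca_c, factors.column(name), factors.types[name])
        rows.append({"factor": name, "eigen_r2_pct": 100 * res.eigen_r2,
                     "n_components": res.n_components_used})
    table = pd.DataFrame(rows).sort_values("eigen_r2_pct", ascending=False)
    table.to_csv(RESULTS / "eigen_r2.tsv", sep="\t", index=False)
    print("Eigen-R2 by factor (%):")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

    scan = pc_factor_scan(pca_c, factors, n_pcs=50)
    scan_out = pd.DataFrame({
        "factor": scan.best_component.index,
        "best_pc": scan.best_component.to_numpy(),
        "min_p": scan.pvalues.min(axis=1).to_numpy(),
        "significant": scan.pvalues.min(axis=1).to_numpy() < scan.bonferroni_threshold,
    })
    scan_out.to_csv(RESULTS / "pc_factor_scan.tsv", sep="\t", index=False)
    n_sig = int(scan_out["significant"].sum())
    print(f"PC-factor scan: {n_sig}/{len(scan_out)} factors below the "
          f"Bonferroni threshold {scan.bonferroni_threshold:.2e}")

    cleaned = remove_technical_effects(l2t, factors, TECHNICAL)
    pca_after = compute_pca(cleaned, "probe")
    before1 = 100 * variance_explained(pca_c, 1)
    after1 = 100 * variance_explained(pca_after, 1)
    summary = pd.DataFrame([
        {"quantity": "pc1_pct_uncentered", "value": 100 * variance_explained(pca_u, 1)},
        {"quantity": "pc10_pct_uncentered", "value": 100 * variance_explained(pca_u, 10)},
        {"quantity": "pc1_pct_centered", "value": before1},
        {"quantity": "pc1_pct_centered_after_technical_removal", "value": after1},
    ])
    summary.to_csv(RESULTS / "pca_summary.tsv", sep="\t", index=False)
    print(f"removing {TECHNICAL} drops centered PC1 from {before1:.1f}% "
          f"to {after1:.1f}% of variance")


if __name__ == "__main__":
    main()
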