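#!/usr/bin/env python
"""Downstream statistics: phospho-signalling tables and DSS inference.

Generates the synthetic phospho-marker median-fluorescence table (20
ascites stimulations x 31 markers, IgG control), normalises to IgG,
tests each marker against the unstimulated control with Holm correction,
and computes the Holm-corrected Pearson correlation matrix.  On the DSS
table from the screen: two-way ANOVA (cell line + ascites condition) with
Tukey HSD against media, and Ward-d2 clustering of the condition profiles
exported as Newick.
"""

from pathlib import Path

import pandas as pd

from aafscreen import stats
from aafscreen.synthetic import default_marker_truth, generate_marker_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20240908


def main() -> None:
    # --- signalling ------------------------------------------------------
    mtruth = default_marker_truth(seed=SEED)
    table = generate_marker_table(mtruth, n_samples=20)
    fc = stats.normalize_markers(table.table)
    fc.to_csv(RESULTS / "marker_fold_changes.csv")

    tests = stats.marker_tests(fc)
    tests.to_csv(RESULTS / "marker_tests.csv", index=False)
    sig = tests[tests.significant].sort_values("p_holm")
    print(f"{len(sig)}/{len(tests)} markers significant vs control "
          "(Holm-adjusted p < 0.05); strongest:")
    print(sig.head(5)[["marker", "mean_diff", "p_holm"]].to_string(index=False))

    r, p_adj, sig_mask = stats.correlation_matrix(fc)
    r.to_csv(RESULTS / "marker_correlations.csv")
    p_adj.to_csv(RESULTS / "marker_correlation_p_adj.csv")
    print(f"\nSTAT3-STAT5 correlation r = "
          f"{r.loc['STAT3_pY705', 'STAT5_pY694']:.2f} "
          f"(significant: {bool(sig_mask.loc['STAT3_pY705', 'STAT5_pY694'])})")

    # --- DSS inference ---------------------------------------------------
    fits = pd.read_csv(RESULTS / "monotherapy_fits.csv",
                       keep_default_na=False, na_values=[])
    anova, tukey = stats.anova2_tukey(fits.dropna(subset=["dss"]))
    anova.to_csv(RESULTS / "dss_anova.csv")
    tukey.to_csv(RESULTS / "dss_tukey.csv", index=False)
    print("\ntwo-way ANOVA on DSS (cell line + condition):")
    print(anova[["F", "PR(>F)"]].round(4).to_string())
    vs_media = tukey[(tukey.level_a == "media") | (tukey.level_b == "media")]
    print("\nTukey HSD, conditions vs media:")
    print(vs_media[["level_a", "level_b", "diff", "p_adj", "reject"]]
          .round(4).to_string(index=False))

    wide = pd.read_csv(RESULTS / "dss_wide.csv",
                       index_col=[0, 1]).dropna(axis=1)
    wide.index = [f"{c}:{m}" for c, m in wide.index]
    clust = stats.cluster_ward(wide)
    (RESULTS / "dss_dendrogram.nwk").write_text(clust.newick + "\n")
    (RESULTS / "dss_leaf_order.txt").write_text("\n".join(clust.leaf_order) + "\n")
    print(f"\nWard-d2 clustering of {len(wide)} condition profiles written "
          "(Newick + leaf order)")


if __name__ == "__main__":
    main()
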