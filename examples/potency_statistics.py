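"""Statistics for hotspot-potency experiments.

Replicate counts here are invented for illustration: each variant records
how many independent replicates re-evolved the selected phenotype via the
focal hotspot T->G mutation versus any other mutation.
"""

from gntmotif import (
    PotencyCount,
    fisher_exact_2x2,
    potency_fold_changes,
    spearman_rho,
    tract_length_regression,
)

counts = [
    PotencyCount("CTG4TC", 10, 40),   # reference motif
    PotencyCount("GAG4TC", 45, 5),
    PotencyCount("TAG4TT", 15, 35),
]

res = fisher_exact_2x2(45, 5, 10, 40)
print(f"GAG4TC vs CTG4TC: p = {res.p_value:.2e}, "
      f"OR = {res.odds_ratio:.1f} (95% CI {res.ci_low:.1f}-{res.ci_high:.1f})")

folds = potency_fold_changes(counts, reference_label="CTG4TC")
for label, f in folds.items():
    print(f"{label}: fold change {f.odds_ratio:.2f} vs reference")

# potency rises with G-tract length: proportion of replicates using the
# hotspot, regressed on tract length
slope, intercept, r2 = tract_length_regression(
    [(1, 2, 29), (3, 40, 112), (4, 300, 434), (5, 40, 47)]
)
print(f"tract-length regression: slope {slope:.3f}/G, R^2 = {r2:.2f}")

# agreement between two rate datasets, as rank correlation with exact p
lab = [1.0, 4.1, 22.0, 130.0, 980.0]
natural = [5.6, 18.0, 41.0, 129.0, 1112.0]
rho = spearman_rho(lab, natural)
print(f"Spearman rho = {rho.rho:.2f}, exact p = {rho.p_value:.4f}")
# rho near 1 means the two datasets rank the motifs' mutabilities the same way.
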