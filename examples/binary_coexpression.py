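"""Detect differential coexpression between two phenotype groups.

Simulates a two-group experiment in which the 20-gene set is uncorrelated in
group 1 but the first half of the genes become strongly correlated in
group 2 (with redrawn variances), then tests the set with the SAVE-based
statistic T and inspects which genes carry the signal.
"""

import numpy as np

import sdrgsa as sg

scenario = sg.BinaryScenario(
    n=40, p=20, variance_mode="heterogeneous", gamma=0.5, rho=0.8
)
expr, pheno = sg.simulate_binary(scenario, seed=7)

cfg = sg.PermutationConfig(n_permutations=999, seed=7, statistic_name="T")
res = sg.permutation_test(expr, pheno, cfg)

print(f"statistic T = {res.statistic:.3f}, permutation p = {res.p_value:.4f}")
print(f"(standardization mode: {res.mode}, H = {res.H} slices)")

top = np.argsort(res.gene_fractions)[::-1][:5]
print("top gene contributions (T_i / T):")
for j in top:
    print(
        f"  {res.gene_ids[j]:>4}  fraction {res.gene_fractions[j]:.3f}  "
        f"gene-level p {res.gene_p_values[j]:.3f}"
    )
print(
    "A small set-level p-value says the within-group covariance of the set\n"
    "differs between phenotype groups; genes g1-g10 (the coexpressed half)\n"
    "should dominate the per-gene fractions."
)
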