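"""Zebrafish enteric-phenotype statistics.

Simulates multinomial category counts (I = unaffected ENS through V =
no neurons in mid/distal gut) for control and gene-disrupted larvae,
compares the category-I proportion with the "N-1" chi-squared test,
and compares neuron densities (neurons per 100 um of gut) against the
control group with Monte-Carlo Dunnett adjustment.
"""

import numpy as np

from enscnv import dunnett_vs_control, n1_chisq_category_table, neuron_density
from enscnv.synthetic import SimConfig, simulate_phenotype_counts

cfg = SimConfig(seed=11, n_larvae_per_condition=60)
counts = simulate_phenotype_counts(cfg)
print("phenotype category counts per condition:")
print(counts)

for cond in ("ret_mo", "candidate_crispants"):
    stat, p = n1_chisq_category_table(counts, cond, "control")
    print(f'\n"N-1" chi-squared, {cond} vs control (category I vs II-V): '
          f"statistic = {stat:.2f}, p = {p:.4f}")

rng = np.random.default_rng(11)
densities = {
    "control": [neuron_density(c, l) for c, l in
                zip(rng.poisson(60, 20), rng.normal(600, 40, 20))],
    "crispant": [neuron_density(c, l) for c, l in
                 zip(rng.poisson(42, 20), rng.normal(600, 40, 20))],
}
res = dunnett_vs_control(densities, "control", n_mc=100_000, seed=11)
print("\nneuron densities (per 100 um), Dunnett-adjusted vs control:")
print(res.round(4))
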