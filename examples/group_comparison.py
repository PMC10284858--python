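"""Compare genomic properties between thermal and non-thermal genomes.

Simulates the full 12 vs 18 study design, profiles every proteome,
attaches group-specific genome sizes, and runs a two-sided Wilcoxon
rank-sum test per property plus the genome-size-vs-OGT correlation.
"""

import numpy as np

from thermotrait import (
    CohortSpec, Habitat, compare_cohort, correlate, profile_cohort,
    profiles_table, simulate_cohort,
)

spec = CohortSpec(seed=7, residues_per_genome=20_000)
proteomes, labels = simulate_cohort(spec)
table = profiles_table(profile_cohort(proteomes, labels))

rng = np.random.default_rng(7)
table["size_bp"] = [
    rng.normal(spec.size_mean_thermal, spec.size_sd_thermal)
    if labels[g] is Habitat.thermal
    else rng.normal(spec.size_mean_nonthermal, spec.size_sd_nonthermal)
    for g in table["genome_id"]
]

props = ("size_bp", "ogt_pred_c", "ivywrel", "polar", "nonpolar",
         "charged")
for c in compare_cohort(table, properties=props):
    print(f"{c.property_name:16s} p={c.p_two_sided:.2e} "
          f"({c.method}) direction={c.direction}")

corr = correlate(table["size_bp"], table["ogt_pred_c"], "pearson")
print(f"\nsize vs predicted OGT: r={corr.r:.3f}, p={corr.p_two_sided:.3g}")
print("Small p-values flag the properties that separate the thermal "
      "group; the negative r reflects genome-size reduction in hotter "
      "habitats.")
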