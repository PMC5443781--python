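"""Worldwide-novelty classification against a reference allele set.

Simulates a survey in which some queen alleles are fresh slippage mutants,
snapshots the non-mutant pool as the "already described worldwide" reference
and asks: are never-before-seen alleles concentrated among the rare ones
(found in a single apiary)?  A yes is the signature of alleles generated
recently that have not yet spread.
"""

import numpy as np

from csdpop import classify_novelty, rare_frequent_table
from csdpop.synthetic import (
    SimConfig,
    make_allele_pool,
    maternal_observations,
    simulate_population,
    snapshot_reference,
)

cfg = SimConfig(
    n_alleles=60, n_apiaries=10, colonies_per_apiary=8, mutation_prob=0.1, seed=3
)
rng = np.random.default_rng(cfg.seed)
pool, truth = make_allele_pool(cfg, rng)
drones, records, truth = simulate_population(cfg, pool, truth, rng)
obs = maternal_observations(drones)
reference = snapshot_reference(records, truth, fraction=0.8, rng=rng)

by_id = {r.id: r for r in records}
seen = obs["allele_id"].unique()
n_apiaries = obs.groupby("allele_id")["apiary_id"].nunique().to_dict()
table = classify_novelty([by_id[a] for a in seen], reference, n_apiaries)
counts, props = rare_frequent_table(table)

print(f"Surveyed alleles: {len(table)} distinct "
      f"({int(table['is_unique'].sum())} not in the reference set)")
print(counts)
print(f"\nProportion worldwide-unique among one-apiary alleles:   "
      f"{props['one_apiary']:.2f}")
print(f"Proportion worldwide-unique among multi-apiary alleles: "
      f"{props['multi_apiary']:.2f}")
print(
    "\nSlippage mutants are novel by construction and almost always confined\n"
    "to a single apiary, so the rare-allele subgroup is enriched in\n"
    "worldwide-unique sequences."
)
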