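"""Protocol arithmetic on the published essential-hypertension inputs.

The original study expanded 69 hypertension seed genes against a STRING
v9.0 snapshot that is no longer distributable, so its network itself is
not recomputable here. Its protocol arithmetic is: the shipped 69-gene
list, omission-plan combinatorics, the 5% backbone cutoff, and the
aggregation of the published per-group robustness rows.
"""

import ppinet as pp
from ppinet import reference

seeds = reference.seed_gene_list()
ref = reference.published_reference()

plan = pp.build_omission_plan(seeds, ref["central_gene"],
                              k_max=ref["k_max"],
                              draws_per_k=ref["draws_per_k"], rng_seed=0)
print(f"seed genes: {len(seeds)} ({seeds.symbols[0]} ... {seeds.symbols[-1]})")
print(f"omission plan: {plan.n_configurations} test networks "
      f"({[len(plan.groups[k]) for k in sorted(plan.groups)]})")
print(f"ordered omit-3 combinations: {pp.ordered_omission_count(len(seeds), 3)}")
print(f"5% BC cutoff on the {ref['giant_nodes']}-node giant: "
      f"{pp.cutoff_count(ref['giant_nodes'], ref['high_bc_fraction'])} nodes")

summary = reference.published_robustness_summary()
print(f"overall backbone accuracy: {summary.overall_accuracy:.5f} "
      f"(unweighted mean of the 7 per-depth accuracies)")
print(f"largest-BC frequency totals: "
      f"{ref['central_gene']}={summary.frequency_totals[ref['central_gene']]}, "
      f"KNG1={summary.frequency_totals['KNG1']} "
      f"of {summary.total_networks} test networks")
comp = ref["seed_subnetwork_composition"]
print(f"seed subnetwork partition {tuple(comp.values())} sums to {sum(comp.values())}")
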