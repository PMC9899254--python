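"""Simulate an allotetraploid clade with known truth.

Two diploid parents (PA, PB) merge into an allotetraploid whose descendants
speciate under a known tree; the recessive subgenome loses genes faster than
the dominant one. The printed counts show the fractionation footprint: each
polyploid tip carries fewer than 2x the ancestral gene count, outgroups stay
diploid.
"""

from allophylo import SimulationScenario, simulate_clade

scenario = SimulationScenario(n_chromosomes=2, genes_per_chromosome=100, seed=1)
dataset = simulate_clade(scenario)

ancestral = scenario.n_chromosomes * scenario.genes_per_chromosome
print(f"ancestral loci: {ancestral}")
print(f"true organismal tree: {dataset.truth.true_tree.strip()}")
for tip in dataset.truth.crown_tips:
    n = dataset.annotations[tip].n_genes
    n_a = sum(v == "A" for g, v in dataset.truth.subgenome_origin.items()
              if g in dataset.cds[tip])
    print(f"  {tip}: {n} genes ({n_a} from subgenome A, {n - n_a} from B; "
          f"2x ancestral would be {2 * ancestral})")
for og in dataset.truth.outgroups:
    print(f"  {og}: {dataset.annotations[og].n_genes} genes (diploid outgroup)")
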