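"""Refine the synaptic parameters with the steady-state GA (small demo).

Starts from the reference synapse table, breeds a small population for a
few generations against synthetic targets, and prints the fitness
trajectory.  Production fits use the configured defaults (population 100,
up to 200 generations, optionally a second narrowed-bounds stage).
"""

import electromotor as em
from electromotor.ga import GAConfig, default_bounds, evolve

cfg = em.load_reference_config()
targets = em.generate_all_targets(rng_seed=1, settings=cfg.generator)
protocols = cfg.protocols.build_all()

evaluate = em.network_evaluator(cfg.network, protocols, targets, sim_seed=1)
seed_genome = em.genome_from_synapses(cfg.network.synapses)
print(f"reference fitness: {evaluate(seed_genome).total:.4f}")

ga_cfg = GAConfig(
    bounds=default_bounds(seed_genome),
    population_size=6,          # demo size; default is 100
    max_generations=3,
    seed=0,
    perturb_scale=0.02,
    mutation_scale=0.02,
    stop_fitness_ratio=1e9,
)
best, history = evolve(ga_cfg, lambda g: evaluate(g).total, seed_genome)

for _, row in history.iterrows():
    print(f"generation {int(row.generation)}: best {row.best:.4f} "
          f"mean {row['mean']:.4f}")
print("\nThe best fitness never decreases (elitist truncation); already a")
print("few generations nudge the hand-tuned reference towards the targets.")
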