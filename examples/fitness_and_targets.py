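"""Score the reference model against synthetic target displays.

Generates the four synthetic target sets, simulates the four display
cases, transforms simulated and target sequences into comparable shape
profiles (normalise to 1,000 units, interpolate at 50 points,
difference), and prints the per-pattern fitness 1/(1+MSE) together with
the four-pattern total (a perfect reproduction of every display would
score 4).
"""

import electromotor as em
from electromotor.network import display_spi, protocol_display_window

cfg = em.load_reference_config()
targets = em.generate_all_targets(rng_seed=1, settings=cfg.generator)
protocols = cfg.protocols.build_all()

simulated = {}
for pattern in em.PATTERNS:
    result = em.simulate(cfg.network, protocols[pattern], seed=1)
    onset, end = protocol_display_window(protocols[pattern])
    simulated[pattern] = display_spi(result, onset, end)

report = em.fitness_total(simulated, targets)
for pattern in em.PATTERNS:
    mse, f = report.per_pattern[pattern]
    print(f"{pattern:13s} closest-exemplar MSE = {mse:8.2f}   f = {f:.3f}")
print(f"{'total':13s} f(I) = {report.total:.3f}  (4 = perfect on all displays)")
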