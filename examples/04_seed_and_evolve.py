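"""Recover known Prony parameters from synthetic data with the full pipeline.

Generates a noiseless 168-tuple frequency sweep from a known N=1 ground
truth, builds the frozen validation curves from the truth's own simulated
ramp and hysteresis data, seeds with multi-start interior-point optimization
and evolves a small genetic population.  The best individual should land on
the generating parameters.
"""

import numpy as np

from pronyfit import (GroundTruth, PronySeries, SimulationSettings,
                      build_validation_curves, equation_objective,
                      make_dma_dataset, make_validation_series)
from pronyfit.genetic import GAConfig, decode, run

truth = GroundTruth(prony=PronySeries(g=[0.4], tau=[0.1]))
rng = np.random.default_rng(0)
data = make_dma_dataset(truth, rng=rng)
ramps, loop = make_validation_series(truth, rng=rng)
curves = build_validation_curves(ramps, loop)
sim = SimulationSettings(ogden=truth.ogden)

cfg = GAConfig(order=1, num_iteration=5, num_in_gen=6, population_size=33,
               rng_seed=11, seed_restarts=4, elite_count=3)
records = run(data, curves, cfg, sim)

for rec in records:
    b = rec.best_so_far
    print(f"gen {rec.generation_index:2d}: best equation error "
          f"{b['equation_error']:.3e}, best mean model error "
          f"{b['mean_error_pct']:.3f} %")

best = decode(np.asarray(records[-1].best_so_far["chromosome"]))
print(f"\nrecovered g   = {best.g[0]:.4f}  (truth 0.4)")
print(f"recovered tau = {best.tau[0]:.4f} s (truth 0.1)")
print(f"objective at recovered parameters: "
      f"{equation_objective(best, data):.3e}")
# The interior-point seeds already sit at the data-generating optimum, so the
# equation error starts ~1e-17 and elitism keeps the best mean model error
# non-increasing; the residual ~0.4 % mean error is the lack-of-fit of the
# two-parameter log/exp validation forms, not a parameter error.
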