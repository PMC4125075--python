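"""Reverse-engineer growth dynamics with the particle swarm.

First refits the growth ODE's ten kinetic constants to its own noiseless
growth-rate curve (parameter search only), then searches a small structure
space — three candidate production terms for the growth modulator — for
the equation component that best explains data generated by one of them.
"""

import numpy as np

from phenosig import (GrowthModelStructure, SearchConfig, SwarmConfig,
                      simulate_growth, swarm_fit_params, swarm_search_structure)
from phenosig.swarm_search import StructureSpace, Term

# --- parameter fit ---------------------------------------------------------
sim = simulate_growth()
fit = swarm_fit_params(GrowthModelStructure(), sim.mu[1:],
                       SwarmConfig(n_particles=50, n_iters=300, seed=1), dt=1 / 6)
print(f"self-fit mean |mu error| per time point: {fit.fitness:.4f} 1/h")

# --- structure search ------------------------------------------------------
base = {
    "N": [Term("product", ("N", "G"), -1)],
    "P": [Term("product", ("N", "G"), +1), Term("linear", ("P",), -1)],
    "Q": [Term("linear", ("G",), +1), Term("linear", ("Q",), -1)],
    "G": [Term("product", ("Q", "G"), -1)],
}
options = (Term("linear", ("P",), +1),          # c P
           Term("product", ("P", "G"), +1),     # c P G  (the truth)
           Term("mm", ("P",), +1))              # c P / (K + P)
space = StructureSpace(base=base, slots=(("G", options),), x0=(1, 0, 0, 0.02))

truth = space.build((1,))
times = np.arange(0, 18 + 1e-9, 1 / 6)
mu_data = truth.mu_batch(np.array([[0.6, 2.5, 0.35, 0.8, 0.5, 3.0, 2.2]]), times)[0]

res = swarm_search_structure(
    mu_data[1:], space,
    SearchConfig(n_models=3, n_outer_iters=1, seed=0,
                 inner=SwarmConfig(n_particles=30, n_iters=120, restarts=2)),
    dt=1 / 6,
)
names = ["c*P", "c*P*G", "c*P/(K+P)"]
print(f"selected production term: {names[res.choices[0]]} "
      f"(fitness {res.fitness:.4f} 1/h)")
print("per-structure fitness in the final round:")
for choices, f in res.history[-1]:
    print(f"  {names[choices[0]]:10s} {f:.4f}")
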