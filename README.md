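# phenosig

**Wavelet phenotypic signatures from unbalanced bacterial growth curves.**

When bacteria grow in batch culture, nutrient depletion continually changes
their physiology and the specific growth rate μ(t) = (1/OD)·dOD/dt
fluctuates instead of holding a clean exponential plateau.  Those
fluctuations are usually discarded as a nuisance; `phenosig` treats them as
a quantitative phenotype.  The package is for microbiologists and systems
biologists who have plate-reader growth curves (or other well-resolved
temporal readouts such as promoter activities) and want to:

* **fingerprint strains** — transform each growth-rate series into a
  scaleogram |W(p, t)| of Daubechies-4 wavelet-coefficient amplitudes over
  periods p and times t, select the most informative period by the
  Davies–Bouldin cluster-quality score, and classify strains by
  average-linkage hierarchical clustering of the coefficient rows
  (with a leave-one-out stability analysis and a raw-curve baseline);
* **understand why unbalanced growth helps system identification** — two
  simulation studies on random network models compare a constant input
  against a *cell-coupled* input (a nutrient the cells consume): local
  parameter identifiability scored from correlations of transfer-function
  sensitivities H_j = ∂g/∂k_j, and network-inference accuracy n/m of a
  linear regression estimator dy/dt = Ay on noisy trajectories with the
  edge rule |A_ij| > 0.005;
* **reverse-engineer growth dynamics** — fit and evolve compact ODE growth
  models (states: nutrient N, molecular groups P and Q, growth modulator G
  with μ = G) with a particle swarm over kinetic parameters and a
  structure-level swarm over a library of 12 basic equation components
  (polynomial and Michaelis–Menten rate laws as production or consumption).

No public dataset accompanies these analyses, so a first-class synthetic
data module generates strain panels (perturbable by plasmid load, low
temperature, low nutrient) and regulon-structured expression datasets with
the statistical properties the pipelines assume.  See `docs/methods.md`
for the models, assumptions and numerical choices.

## A worked example

```bash
python examples/signatures_from_growth_curves.py
```

```
panel: 12 growth curves, 4 strains
chosen wavelet period: 23.83 h (Davies-Bouldin score 0.037)
misclassified strains, wavelet signatures: 0
misclassified strains, raw growth rates:   4
leave-one-out runs with zero errors: 12/12
```

The panel holds four synthetic strains with jittered kinetics, three
replicates each, sampled every 10 minutes for 24 h with 2% multiplicative
measurement noise.  Central differences of the optical densities give
fluctuating growth-rate series; at the automatically selected ~24 h period
the wavelet coefficient rows cluster all twelve curves into their correct
strains (0 misclassified, and still 0 in every leave-one-out replicate),
while Euclidean clustering of the raw growth-rate vectors — whose
pointwise noise swamps the strain differences — misplaces 4 of 12.  The
low Davies–Bouldin score (≪ 1) says the strain clusters are tight relative
to their separation.

The other example scripts follow the same pattern, one per capability:
`identifiability_study.py`, `network_inference_study.py`,
`growth_model_perturbations.py`, `swarm_reverse_engineering.py`,
`expression_promoter_clustering.py`.

There is also a small CLI for shell use (`phenosig synth | signatures |
simstudy | growthmodel | swarm`); every command is seed-deterministic and
writes a `config_snapshot.json` beside its outputs.  The on-disk formats
are a wide CSV (a `time` column in hours plus one column per well) and a
JSON/YAML plate layout mapping wells to `(strain, condition)`.

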