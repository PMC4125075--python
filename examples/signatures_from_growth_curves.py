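"""Classify bacterial strains by wavelet signatures of their growth rates.

Builds a synthetic 4-strain plate (3 replicates each, 10-minute sampling),
computes specific growth rates by central differences, transforms each
growth-rate series into a (period, time) wavelet-coefficient map, selects
the period whose coefficient rows best separate the strains
(Davies-Bouldin score), and clusters — comparing against clustering the raw
growth-rate vectors.
"""

import numpy as np

from phenosig import StrainPanelSpec, make_strain_panel, signature_study

curves = make_strain_panel(StrainPanelSpec(seed=0))
study = signature_study(curves, run_loo=True)

print(f"panel: {len(curves)} growth curves, "
      f"{len(set(c.strain for c in curves))} strains")
print(f"chosen wavelet period: {study.chosen_period:.2f} h "
      f"(Davies-Bouldin score {study.clustering.db_score:.3f})")
print(f"misclassified strains, wavelet signatures: {study.n_misclassified}")
print(f"misclassified strains, raw growth rates:   {study.n_misclassified_raw}")
print(f"leave-one-out runs with zero errors: "
      f"{np.sum(study.loo_counts == 0)}/{len(study.loo_counts)}")

# The wavelet features concentrate the strain-specific slow dynamics into a
# single coefficient row, which separates the strains cleanly where the
# noisy raw growth-rate vectors do not.
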