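"""Network inference accuracy with constant versus cell-coupled inputs.

Random six-link nonlinear models (mass action, Michaelis-Menten activation
and repression, multiplicative reactions) over nutrient N and components
P, Q, R are simulated, corrupted with 20% multiplicative noise, and fit by
linear regression of central-difference derivatives on the states; entries
of the fitted reaction matrix above 0.005 are read as links and scored as
the fraction n/m of true influences recovered.
"""

from phenosig import compare_ensembles

cmp_ = compare_ensembles(n_models=100, seed=0, noise_level=0.20, threshold=0.005)

print(f"mean n/m accuracy, constant nutrient:     {cmp_.acc_constant.mean():.3f}")
print(f"mean n/m accuracy, cell-coupled nutrient: {cmp_.acc_cell_coupled.mean():.3f}")
print(f"Mann-Whitney one-sided p = {cmp_.mannwhitney_pvalue():.2e}")
print(f"models regenerated after integration failure: {cmp_.n_regenerated}")

# When the nutrient is clamped, every reaction it feeds looks like a
# constant flux and its links are invisible to the regression; letting the
# cells consume the nutrient turns those links into observable dynamics.
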