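"""Why a cell-coupled nutrient input identifies more model parameters.

Generates random linear flux networks over three cellular components and
compares local parameter identifiability — scored from correlations of
transfer-function sensitivities — between a constant, experimenter-set
input flux and a cell-coupled nutrient that the network consumes.
"""

from phenosig import compare_input_modes

cmp_ = compare_input_modes(n_models=100, seed=0)
values, counts = cmp_.histogram()

print("identifiable parameters per model:")
print(f"  constant input:     mean {cmp_.n_constant.mean():.2f}")
print(f"  cell-coupled input: mean {cmp_.n_cell_coupled.mean():.2f}")
print("delta histogram (cell-coupled minus constant):")
for v, c in zip(values, counts):
    print(f"  delta {v:+d}: {c} models")
print(f"one-sided sign test p = {cmp_.sign_test_pvalue():.2e}")

# A positive delta means the fluctuating, cell-coupled nutrient signal lets
# the analyst pin down more kinetic constants than a constant input does —
# here including the nutrient-consumption rate itself.
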