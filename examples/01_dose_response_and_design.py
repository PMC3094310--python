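"""Fit a log-logistic dose-response curve, invert it to ECx, and build the
equitoxic mixture design.

Simulates a nickel-like LMS curve (plateau 100% labilization time, EC50
0.77 mg/L), fits it, and prints the fitted parameters and the binary design:
a 1.0-TU equitoxic mixture pairs the two EC25 concentrations, a 0.5-TU
mixture the two EC12.5 concentrations.
"""

from mixtoxsys import datasets
from mixtoxsys.doseresponse import (
    DoseResponseModel,
    design_equitoxic_mixture,
    ec_x,
    fit_loglogistic,
)
from mixtoxsys.synthetic_data import gen_dose_response

truth = DoseResponseModel(theta_max=100.0, ec50=0.77, beta=2.0, chemical_id="Ni")
data = gen_dose_response(
    truth, doses=[0.05, 0.1, 0.25, 0.77, 2.0, 6.0], n_per_dose=8, noise_sd=6.0, seed=7
)
model, stats = fit_loglogistic(data)
print(f"fitted EC50 = {model.ec50:.3f} mg/L (truth 0.770), "
      f"beta = {model.beta:.2f}, R2 = {stats.r2:.3f}, n = {stats.n}")
for x in (12.5, 25, 50):
    print(f"  EC{x:<5} = {ec_x(model, x).concentration:.3f} mg/L")

for tu in (0.5, 1.0):
    design = design_equitoxic_mixture(ecx_table=datasets.ecx_table(), tu_level=tu)
    comps = ", ".join(f"{c} {v:.3f} mg/L" for c, v in design.component_concentrations.items())
    print(f"{tu} TU equitoxic mixture (per-component EC{design.effect_level_per_component:g}): {comps}")
# The design concentrations are the published effect concentrations: each
# component contributes half the mixture's nominal toxic-unit level.
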