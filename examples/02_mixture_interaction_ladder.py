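"""Detect an antagonistic interaction with the nested CA deviation ladder.

Generates a 49-point fixed-ray dataset from a Concentration-Addition surface
with an injected antagonistic deviation (a = 3: the mixture is less toxic
than the dilution principle predicts), then runs reference -> SA -> DL and
prints the ladder the way interaction tables are usually reported.
"""

from mixtoxsys.mixture_models import CA, SA, SurfaceParams, classify_interaction
from mixtoxsys.synthetic_data import gen_mixture_ray

truth = SurfaceParams(
    theta_max=100.0, ec50_1=0.77, beta_1=2.0, ec50_2=4.5, beta_2=1.5,
    deviation=SA, a=3.0,
)
points, _ = gen_mixture_ray(truth, CA, noise_sd=5.0, seed=11)
analysis = classify_interaction(points, CA, alpha=0.05)

print(f"n = {analysis.fit_ref.n}")
print(f"Fit of CA      R2 = {analysis.fit_ref.r2:.2f}   p = {analysis.p_reference:.2e}")
print(f"CA vs A        R2 = {analysis.fit_sa.r2:.2f}   chi2 p = {analysis.ref_vs_sa.p:.2e}   "
      f"a_hat = {analysis.fit_sa.params.a:+.2f}")
print(f"A vs DL        R2 = {analysis.fit_dl.r2:.2f}   chi2 p = {analysis.sa_vs_dl.p:.2f}")
print(f"verdict: {analysis.verdict.pattern}"
      f" (dose-level dependent: {analysis.verdict.dose_level_dependent})")
# A small reference-vs-A p with a_hat > 0 reads as overall antagonism; a large
# A-vs-DL p means no evidence that the deviation changes sign with dose level.
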