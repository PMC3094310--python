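"""Fit first-order depuration curves and derive elimination half-lives.

Simulates tissue-concentration time courses over a 6-day clean-water phase
using the published elimination constants as ground truth, refits them and
prints k, R2 and the half-life per condition.
"""

from mixtoxsys import datasets
from mixtoxsys.synthetic_data import gen_elimination
from mixtoxsys.toxicokinetics import fit_elimination

print(f"{'condition':<8} {'true k':>8} {'fitted k':>9} {'R2':>6} {'t1/2 (d)':>9}")
for row in datasets.elimination_constants().itertuples(index=False):
    series = gen_elimination(row.k_per_day, c0=20.0, noise_cv=0.10, seed=3,
                             chemical_id=row.chemical)
    fit = fit_elimination(series)
    half = f"{fit.half_life:9.1f}" if fit.half_life else "      n/a"
    print(f"{row.chemical:<8} {row.k_per_day:8.4f} {fit.k:9.4f} {fit.r2:6.2f} {half}")
# Slow nickel elimination (k ~ 0.008/d, half-life ~3 months) versus fast
# chlorpyrifos clearance (k ~ 0.047/d, half-life ~2 weeks); in-mixture rates
# barely change for the pesticide, which argues against a toxicokinetic
# explanation of the reduced joint toxicity.  Note the low R2 for nickel:
# a 6-day window resolves only ~4% of its decay, so at 10% measurement CV
# the rate is barely identifiable -- the point estimate, not the fit
# quality, carries the interpretation.
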