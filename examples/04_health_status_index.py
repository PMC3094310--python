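"""Grade stress syndromes with the biomarker expert system.

Builds two synthetic panels of the four-biomarker battery (LMS as the guide
biomarker) -- one unexposed, one heavily stressed -- tests each biomarker
against its control (Mann-Whitney, alpha = 0.05), discretizes significant
changes into alteration levels and prints the resulting A-E grade.
"""

from mixtoxsys.health_status import health_status_index
from mixtoxsys.synthetic_data import default_biomarker_scenario, gen_biomarker_panel

for label, shifts in [
    ("control-like", {}),
    ("high dose", {"LMS": -0.6, "LYS/CYT": 3.0, "NL": 2.0, "AChE": -0.8}),
]:
    panel, _ = gen_biomarker_panel(default_biomarker_scenario(shifts), n=10, seed=21)
    result = health_status_index(panel)
    detail = ", ".join(
        f"{name}: AL{al.value} (p={al.p:.3f})" for name, al in result.per_biomarker.items()
    )
    print(f"{label:>12}: grade {result.grade}  [{detail}]")
    print(f"{'':>12}  first matching rule: {result.triggered_rules[0]}")
# Grade A means no biomarker moved; E requires a severe guide-biomarker
# alteration (membrane destabilization beyond 50%) plus at least two further
# severe alterations -- the pathological end of the scale.
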