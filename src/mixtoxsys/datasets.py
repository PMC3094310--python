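"""Bundled reference inputs from a published nickel/chlorpyrifos mussel
mixture-exposure assessment (Mytilus galloprovincialis, 4-day semi-static
exposures; digestive gland endpoints).

These small printed tables are consumed as *inputs* by the analysis layer:
the ECx lookup table driving the equitoxic design, the fitted elimination
constants, the 12-gene microarray/Q-PCR comparison panel, and the DEG overlap
structure used to parameterize the synthetic DEG generator.  The raw
measurements behind them were never published, so they are lookup fixtures,
not recompute targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ecx_table",
    "elimination_constants",
    "qpcr_array_comparison",
    "deg_overlap_structure",
    "surface_test_evidence",
]

NICKEL = "Ni"
CHLORPYRIFOS = "Chlorpyrifos"
MIXTURE = "Mix"


def ecx_table() -> dict:
    """LMS effect concentrations (mg/L) per chemical: {x% effect -> conc}."""
    return {
        NICKEL: {12.5: 0.022, 25.0: 0.135, 50.0: 0.770},
        CHLORPYRIFOS: {12.5: 0.300, 25.0: 0.610, 50.0: 4.500},
    }


def elimination_constants() -> pd.DataFrame:
    """First-order elimination constants (per day) and fit R2 per condition."""
    return pd.DataFrame(
        {
            "chemical": ["Ni", "mixNi", "CHP", "mixCHP"],
            "k_per_day": [0.0076, 0.0012, 0.0470, 0.0440],
            "R2": [0.87, 0.93, 0.95, 0.75],
        }
    )


# 12-gene comparison panel: Q-PCR relative expression (signed; significance
# flagged), microarray M (log2 ratio) and B (log-odds) per condition.  The
# mt-20 metallothionein has no array probe (missing M/B throughout).
_QPCR_ROWS = [
    # gene_id, description,
    #   (Ni: qpcr, sig, M, B), (CHP: ...), (Mix: ...)
    ("mt10b", "metallothionein isoform mt-10b",
     (2.8, True, 1.46, 11.5), (-0.3, False, -0.1, -6.3), (1.8, True, 0.9, 4.4)),
    ("mt20", "metallothionein isoform mt-20-IV",
     (0.6, False, None, None), (-0.1, False, None, None), (0.0, False, None, None)),
    ("gm2ap_a", "gm2 ganglioside activator protein",
     (13.6, True, 2.63, 7.0), (-0.7, False, -0.3, -5.4), (-7.6, True, 0.5, -1.3)),
    ("gm2ap_b", "gm2 ganglioside activator protein",
     (-4.4, True, -0.87, 9.7), (5.6, True, -0.6, -5.0), (6.7, True, 0.4, 0.1)),
    ("apolipophorin", "apolipophorin precursor",
     (0.8, True, 0.56, 5.1), (0.3, False, -0.1, -6.1), (-0.6, False, -0.0, -6.4)),
    ("chitinase_a", "chitinase",
     (1.7, False, -0.08, -7.2), (6.4, True, 1.9, 12.2), (6.6, True, 1.7, 4.7)),
    ("chitinase_b", "chitinase",
     (1.5, False, -0.41, 2.3), (5.4, True, 1.9, 9.9), (5.6, True, 2.0, 0.4)),
    ("chitinase_c", "chitinase",
     (0.9, False, -0.52, 3.6), (5.7, True, 1.6, 4.5), (6.0, True, 1.7, 1.8)),
    ("chitinase_1", "chitinase 1",
     (0.4, False, -0.8, 7.5), (5.1, True, 3.2, 11.5), (6.2, True, 2.0, 0.3)),
    ("hexosaminidase", "beta-n-acetyl-hexosaminidase",
     (-0.1, False, 0.03, -7.5), (-0.4, False, -0.3, -6.1), (2.9, True, 1.1, -5.7)),
    ("actin", "actin",
     (-0.0, False, -0.05, -6.9), (0.4, False, 0.1, -6.3), (0.6, True, 0.5, 2.7)),
    ("p53_like", "p-53 like",
     (0.1, False, -0.11, -7.2), (-0.4, False, 0.3, -6.3), (-0.1, False, -0.6, -3.9)),
]

_CONDITIONS = (NICKEL, CHLORPYRIFOS, MIXTURE)


def qpcr_array_comparison(condition: str | None = None) -> pd.DataFrame:
    """The 12-gene Q-PCR vs microarray comparison panel.

    Long format: gene_id, condition, qpcr_value, qpcr_significant, M, B.
    Pass a condition ("Ni", "Chlorpyrifos", "Mix") to get that slice.
    """
    records = []
    for gene, desc, *cells in _QPCR_ROWS:
        for cond, (q, sig, m, b) in zip(_CONDITIONS, cells):
            records.append(
                {
                    "gene_id": gene,
                    "description": desc,
                    "condition": cond,
                    "qpcr_value": q,
                    "qpcr_significant": sig,
                    "M": np.nan if m is None else m,
                    "B": np.nan if b is None else b,
                }
            )
    df = pd.DataFrame(records)
    if condition is not None:
        if condition not in _CONDITIONS:
            raise KeyError(f"condition must be one of {_CONDITIONS}")
        df = df[df["condition"] == condition].reset_index(drop=True)
    return df


def deg_overlap_structure() -> dict:
    """DEG list sizes and exclusive overlap/trend structure of the study.

    Pairwise counts exclude the triple intersection; trend splits give the
    number of shared genes moving in the same vs the opposite direction.
    Feeds :func:`mixtoxsys.synthetic_data.gen_deg_study` directly.
    """
    return {
        "list_sizes": {NICKEL: 135, CHLORPYRIFOS: 43, MIXTURE: 103},
        "exclusive_overlaps": {
            (CHLORPYRIFOS, MIXTURE): 15,
            (NICKEL, MIXTURE): 19,
            (NICKEL, CHLORPYRIFOS): 15,
        },
        "triple": 8,
        "trend_split": {
            (CHLORPYRIFOS, MIXTURE): {"same": 11, "opposite": 4},
            (NICKEL, MIXTURE): {"same": 5, "opposite": 14},
            (NICKEL, CHLORPYRIFOS): {"same": 5, "opposite": 10},
        },
    }


def surface_test_evidence() -> dict:
    """Published deviation-ladder evidence for the LMS endpoint under CA:
    the reference-vs-SA and SA-vs-DL p-values with a fitted antagonistic
    (positive) deviation.  Used to replay the classification rule."""
    return {"framework": "CA", "n": 49, "p_ref_vs_A": 1.27e-3, "p_A_vs_DL": 0.30,
            "a_hat_sign": 1.0}
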