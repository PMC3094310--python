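"""Seeded generators emulating every input the assessment pipeline consumes.

Each generator takes an explicit integer seed, draws from its own
``numpy.random.default_rng`` stream (no global state), and reports its
generating parameters in a provenance dictionary so that closed-loop recovery
tests can compare estimates against ground truth.  Identical arguments and
seed give bit-identical output.

Noise models: additive Gaussian on biomarker/response scales, multiplicative
lognormal on tissue concentrations.  Dose placement follows the equitoxic
fixed-ray convention of the study design: single-chemical doses at EC(50*TU)
and mixture components at EC(50*TU_share) of their own marginal curve.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .doseresponse import DECREASING, DoseResponseData, DoseResponseModel, ec_x
from .exceptions import ValidationError
from .go_enrichment import AnnotationSet, GODag
from .health_status import CELL, DECREASE, INCREASE, TISSUE, BiomarkerRecord
from .mixture_models import SurfaceParams, predict_surface
from .toxicokinetics import EliminationSeries

__all__ = [
    "gen_dose_response",
    "gen_mixture_ray",
    "gen_elimination",
    "gen_deg_study",
    "gen_annotation",
    "gen_biomarker_panel",
    "default_biomarker_scenario",
]


def gen_dose_response(
    model: DoseResponseModel,
    doses: Sequence[float],
    n_per_dose: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponseData:
    """Responses on a log-logistic curve plus iid Gaussian noise.

    A control group at c = 0 is always included.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    doses = sorted(set(float(d) for d in doses) | {0.0})
    rng = np.random.default_rng(seed)
    c = np.repeat(doses, n_per_dose)
    y = model.predict(c) + rng.normal(0.0, noise_sd, size=c.size)
    return DoseResponseData(
        chemical_id=model.chemical_id or "synthetic",
        concentrations=c,
        responses=y,
        provenance={
            "generator": "gen_dose_response",
            "seed": seed,
            "noise_sd": noise_sd,
            "n_per_dose": n_per_dose,
            "model": {
                "theta_max": model.theta_max,
                "theta_min": model.theta_min,
                "ec50": model.ec50,
                "beta": model.beta,
                "direction": model.direction,
            },
        },
    )


def _marginal(params: SurfaceParams, which: int) -> DoseResponseModel:
    ec50 = params.ec50_1 if which == 1 else params.ec50_2
    beta = params.beta_1 if which == 1 else params.beta_2
    return DoseResponseModel(
        theta_max=params.theta_max, ec50=ec50, beta=beta, direction=DECREASING
    )


def gen_mixture_ray(
    surface: SurfaceParams,
    model_type: str,
    tu_levels: Sequence[float] = (0.25, 0.5, 1.0),
    mixture_tu_levels: Sequence[float] = (0.5, 1.0),
    ray_ratio: float = 0.5,
    n_per_point: int = 5,
    n_control: Optional[int] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """Fixed-ray equitoxic mixture design sampled from a CA or IA surface.

    Single-chemical axis points are dosed at EC(50*TU) of each marginal;
    mixture points at total level T place component 1 at EC(50*ray_ratio*T)
    and component 2 at EC(50*(1-ray_ratio)*T) of their own curves.  The
    default layout (3 single-chemical levels per chemical, two mixtures,
    5 replicates per treated condition, 9 controls) gives n = 49.

    Returns ``(DataFrame[c1, c2, response], provenance)``.
    """
    if not 0 < ray_ratio < 1:
        raise ValidationError("ray_ratio must lie in (0, 1)")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    for tu in tu_levels:
        if not 0 < 50.0 * tu < 100:
            raise ValidationError(f"axis TU level {tu} maps outside (0, 100)% effect")
    for tu in mixture_tu_levels:
        if not 0 < 50.0 * max(ray_ratio, 1 - ray_ratio) * tu < 100:
            raise ValidationError(f"mixture TU level {tu} maps outside (0, 100)% effect")
    n_control = n_per_point + 4 if n_control is None else n_control

    m1 = _marginal(surface, 1)
    m2 = _marginal(surface, 2)
    pts = [(0.0, 0.0)] * n_control
    for tu in tu_levels:
        c = ec_x(m1, 50.0 * tu).concentration
        pts += [(c, 0.0)] * n_per_point
        c = ec_x(m2, 50.0 * tu).concentration
        pts += [(0.0, c)] * n_per_point
    for tu in mixture_tu_levels:
        c1 = ec_x(m1, 50.0 * ray_ratio * tu).concentration
        c2 = ec_x(m2, 50.0 * (1 - ray_ratio) * tu).concentration
        pts += [(c1, c2)] * n_per_point

    c1 = np.array([p[0] for p in pts])
    c2 = np.array([p[1] for p in pts])
    rng = np.random.default_rng(seed)
    y = predict_surface(surface, model_type, c1, c2) + rng.normal(0, noise_sd, c1.size)
    df = pd.DataFrame({"c1": c1, "c2": c2, "response": y})
    prov = {
        "generator": "gen_mixture_ray",
        "seed": seed,
        "model_type": model_type,
        "tu_levels": list(tu_levels),
        "mixture_tu_levels": list(mixture_tu_levels),
        "ray_ratio": ray_ratio,
        "n_per_point": n_per_point,
        "n_control": n_control,
        "noise_sd": noise_sd,
        "surface": {
            "theta_max": surface.theta_max,
            "ec50_1": surface.ec50_1, "beta_1": surface.beta_1,
            "ec50_2": surface.ec50_2, "beta_2": surface.beta_2,
            "deviation": surface.deviation, "a": surface.a, "b": surface.b,
        },
    }
    df.attrs["provenance"] = prov
    return df, prov


def gen_elimination(
    k: float,
    c0: float,
    times: Sequence[float] = (0.125, 0.25, 0.5, 1.0, 3.0, 6.0),
    noise_cv: float = 0.0,
    n_per_time: int = 3,
    seed: int = 0,
    chemical_id: str = "synthetic",
) -> EliminationSeries:
    """Exponential depuration curve with multiplicative lognormal noise.

    C_t = C0 * exp(-k t) * exp(eps), eps ~ Normal(0, ln(1 + noise_cv)), drawn
    independently per replicate.  The default sampling grid mirrors a
    3 h / 6 h / 12 h / 1 d / 3 d / 6 d depuration schedule (in days) with
    triplicate chemical measurements per sampling time.
    """
    if k < 0:
        raise ValidationError("k must be non-negative")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be non-negative")
    if n_per_time < 1:
        raise ValidationError("n_per_time must be at least 1")
    t = np.repeat(np.asarray(sorted(times), dtype=float), n_per_time)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, math.log1p(noise_cv), size=t.size)
    c = c0 * np.exp(-k * t) * np.exp(eps)
    return EliminationSeries(
        chemical_id=chemical_id,
        times=t,
        concentrations=c,
        provenance={
            "generator": "gen_elimination",
            "seed": seed,
            "k": k,
            "C0": c0,
            "noise_cv": noise_cv,
            "n_per_time": n_per_time,
            "times": t.tolist(),
        },
    )


def _normalize_pair(pair) -> tuple:
    return tuple(sorted(pair))


def gen_deg_study(
    list_sizes: Mapping[str, int],
    exclusive_overlaps: Mapping[tuple, int],
    triple: int,
    trend_split: Optional[Mapping[tuple, Mapping[str, int]]] = None,
    m_range: Tuple[float, float] = (0.5, 3.0),
    b_range: Tuple[float, float] = (1.0, 12.0),
    n_background: int = 100,
    seed: int = 0,
) -> Tuple[Dict[str, pd.DataFrame], dict]:
    """Three DEG tables with an exact prescribed overlap/trend structure.

    ``exclusive_overlaps`` are pairwise counts excluding the triple
    intersection; the requested structure is realized as set identities, not
    in expectation.  Shared genes split into same/opposite trend per
    ``trend_split`` (default: all same trend).  Every gene (including
    ``n_background`` never-called genes) appears in every condition's table,
    with B above the threshold for members and below for non-members.

    Returns ``({condition: DataFrame[gene_id, M, B]}, provenance)``.
    """
    names = list(list_sizes)
    if len(names) != 3:
        raise ValidationError("gen_deg_study requires exactly three conditions")
    if triple < 0 or any(v < 0 for v in exclusive_overlaps.values()):
        raise ValidationError("overlap counts must be non-negative")
    pairs = {_normalize_pair(k): int(v) for k, v in exclusive_overlaps.items()}
    import itertools as _it

    all_pairs = [_normalize_pair(p) for p in _it.combinations(names, 2)]
    for p in pairs:
        if p not in all_pairs:
            raise ValidationError(f"overlap pair {p} not among conditions {names}")
    pairs = {p: pairs.get(p, 0) for p in all_pairs}
    uniques = {}
    for cond in names:
        u = list_sizes[cond] - sum(v for p, v in pairs.items() if cond in p) - triple
        if u < 0:
            raise ValidationError(
                f"infeasible spec: condition {cond!r} would need {u} unique genes"
            )
        uniques[cond] = u
    splits = {}
    for p, spec in (trend_split or {}).items():
        p = _normalize_pair(p)
        if p not in pairs:
            raise ValidationError(f"trend_split pair {p} unknown")
        same, opp = int(spec.get("same", 0)), int(spec.get("opposite", 0))
        if same + opp != pairs[p]:
            raise ValidationError(
                f"trend_split for {p} ({same}+{opp}) must sum to the pair count {pairs[p]}"
            )
        splits[p] = (same, opp)
    for p, count in pairs.items():
        splits.setdefault(p, (count, 0))

    rng = np.random.default_rng(seed)
    counter = 0

    def new_genes(n):
        nonlocal counter
        ids = [f"g{counter + i:05d}" for i in range(n)]
        counter += n
        return ids

    # membership and trends per condition
    member_sign: Dict[str, Dict[str, int]] = {c: {} for c in names}
    for cond in names:
        for g in new_genes(uniques[cond]):
            member_sign[cond][g] = int(rng.choice((-1, 1)))
    for p, count in pairs.items():
        a, b = p
        same, opp = splits[p]
        for i, g in enumerate(new_genes(count)):
            s = int(rng.choice((-1, 1)))
            member_sign[a][g] = s
            member_sign[b][g] = s if i < same else -s
    for g in new_genes(triple):
        s = int(rng.choice((-1, 1)))
        for cond in names:
            member_sign[cond][g] = s
    background = new_genes(n_background)
    universe = [f"g{i:05d}" for i in range(counter)]

    tables = {}
    for cond in names:
        signs = member_sign[cond]
        m = np.empty(len(universe))
        b = np.empty(len(universe))
        for i, g in enumerate(universe):
            if g in signs:
                m[i] = signs[g] * rng.uniform(*m_range)
                b[i] = rng.uniform(*b_range)
            else:
                m[i] = rng.normal(0.0, 0.2)
                b[i] = rng.uniform(-8.0, -1.0)
        tables[cond] = pd.DataFrame({"gene_id": universe, "M": m, "B": b})
    prov = {
        "generator": "gen_deg_study",
        "seed": seed,
        "list_sizes": dict(list_sizes),
        "exclusive_overlaps": {" & ".join(p): v for p, v in pairs.items()},
        "triple": triple,
        "uniques": uniques,
        "n_background": n_background,
        "universe_size": len(universe),
    }
    return tables, prov


def gen_annotation(
    universe_size: int = 1673,
    dag_depth: int = 4,
    n_terms: int = 40,
    spike_odds: float = 1.0,
    study_size: int = 100,
    baseline_prevalence: float = 0.05,
    seed: int = 0,
) -> Tuple[AnnotationSet, GODag, set, dict]:
    """Random GO DAG + annotations with one term enriched in a study list.

    All terms except the spiked one are annotated independently of the study
    list; the spiked term's annotation odds are multiplied by ``spike_odds``
    inside the study list.  Ground truth is recorded in the provenance.

    Returns ``(AnnotationSet, GODag, study_set, provenance)``.
    """
    if universe_size <= 0:
        raise ValidationError("universe_size must be positive")
    if spike_odds < 1:
        raise ValidationError("spike_odds must be >= 1")
    if not 0 < study_size <= universe_size:
        raise ValidationError("study_size must be in (0, universe_size]")
    if n_terms < dag_depth + 1:
        raise ValidationError("need at least one term per DAG level")
    rng = np.random.default_rng(seed)

    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    root = terms[0]
    levels = [[root]]
    rest = terms[1:]
    per_level = [rest[i::dag_depth] for i in range(dag_depth)]
    parents = {root: set()}
    for depth, level_terms in enumerate(per_level, start=1):
        prev = levels[-1]
        for t in level_terms:
            n_par = 1 + int(rng.random() < 0.3 and len(prev) > 1)
            parents[t] = {
                str(p) for p in rng.choice(prev, size=min(n_par, len(prev)), replace=False)
            }
        levels.append(level_terms)
    dag = GODag(
        parents,
        namespace={t: "biological_process" for t in terms},
        name={t: f"synthetic term {i}" for i, t in enumerate(terms)},
    )

    genes = [f"s{i:05d}" for i in range(universe_size)]
    study = set(rng.choice(genes, size=study_size, replace=False))
    spiked_term = levels[-1][-1] if levels[-1] else terms[-1]

    annotations: Dict[str, set] = {g: set() for g in genes}
    for t in terms[1:]:
        if t == spiked_term:
            continue
        prev = rng.uniform(0.01, 0.10)
        mask = rng.random(universe_size) < prev
        for g, hit in zip(genes, mask):
            if hit:
                annotations[g].add(t)
    p0 = baseline_prevalence
    odds1 = spike_odds * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    draws = rng.random(universe_size)
    for g, d in zip(genes, draws):
        if d < (p1 if g in study else p0):
            annotations[g].add(spiked_term)
    annot = AnnotationSet(
        annotations={g: t for g, t in annotations.items() if t}, universe=set(genes)
    )
    prov = {
        "generator": "gen_annotation",
        "seed": seed,
        "universe_size": universe_size,
        "dag_depth": dag_depth,
        "n_terms": n_terms,
        "spiked_term": spiked_term,
        "spike_odds": spike_odds,
        "baseline_prevalence": p0,
        "study_probability": p1,
        "study_size": study_size,
    }
    return annot, dag, study, prov


def default_biomarker_scenario(shifts: Optional[Mapping[str, float]] = None) -> dict:
    """The study's four-biomarker battery: lysosomal membrane stability (guide,
    harmful decrease, severe below -50%), lysosome/cytoplasm volume ratio and
    neutral-lipid accumulation (harmful increase), and gill
    acetylcholinesterase activity (tissue level, harmful decrease)."""
    shifts = dict(shifts or {})
    return {
        "LMS": {"level": CELL, "harmful_direction": DECREASE,
                "severity_threshold": 0.5, "shift": shifts.get("LMS", 0.0), "guide": True},
        "LYS/CYT": {"level": CELL, "harmful_direction": INCREASE,
                    "severity_threshold": 1.0, "shift": shifts.get("LYS/CYT", 0.0)},
        "NL": {"level": CELL, "harmful_direction": INCREASE,
               "severity_threshold": 1.0, "shift": shifts.get("NL", 0.0)},
        "AChE": {"level": TISSUE, "harmful_direction": DECREASE,
                 "severity_threshold": 1.0, "shift": shifts.get("AChE", 0.0)},
    }


def gen_biomarker_panel(
    scenario: Optional[Mapping[str, Mapping]] = None,
    n: int = 10,
    baseline: float = 100.0,
    cv: float = 0.10,
    seed: int = 0,
) -> Tuple[list, dict]:
    """Replicated exposed/control biomarker panels with requested mean shifts.

    ``scenario`` maps biomarker name -> {shift, level, harmful_direction,
    severity_threshold, guide}; the default is the four-biomarker battery with
    no shifts.  Replicates are Normal(mean, cv*baseline) with exposed mean
    baseline*(1+shift).  Nominal ground-truth alteration levels (assuming the
    shift is detected) are recorded in the provenance.

    Returns ``(list[BiomarkerRecord], provenance)``.
    """
    if n < 3:
        raise ValidationError("need at least 3 replicates per group")
    scenario = scenario or default_biomarker_scenario()
    rng = np.random.default_rng(seed)
    sd = cv * baseline
    panel = []
    truth = {}
    for name, spec in scenario.items():
        shift = float(spec.get("shift", 0.0))
        direction = spec.get("harmful_direction", DECREASE)
        threshold = float(spec.get("severity_threshold", 1.0))
        control = rng.normal(baseline, sd, size=n)
        exposed = rng.normal(baseline * (1.0 + shift), sd, size=n)
        panel.append(
            BiomarkerRecord(
                name=name,
                level=spec.get("level", CELL),
                exposed=exposed,
                control=control,
                harmful_direction=direction,
                severity_threshold=threshold,
                guide=bool(spec.get("guide", False)),
            )
        )
        harmful = -shift if direction == DECREASE else shift
        truth[name] = 0 if shift == 0 else (2 if harmful >= threshold else 1)
    prov = {
        "generator": "gen_biomarker_panel",
        "seed": seed,
        "n": n,
        "baseline": baseline,
        "cv": cv,
        "scenario": {k: dict(v) for k, v in scenario.items()},
        "nominal_alteration_levels": truth,
    }
    return panel, prov
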