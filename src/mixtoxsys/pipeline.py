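"""Orchestration of the full assessment from a single config.

A :class:`RunConfig` names the input tables for any subset of stages; absent
stages are simply skipped, so a config with only toxicokinetic inputs yields a
report containing only the toxicokinetic block.  Stage failures are isolated
per endpoint and reported in the block instead of aborting the run.  The
report is a plain JSON-serializable dict with provenance (package version,
seeds, config hash) and is deterministic given config + seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__, io
from .doseresponse import DECREASING, design_equitoxic_mixture, ec_x, fit_loglogistic
from .exceptions import MixtoxError, ValidationError
from .expression_compare import call_degs, concordance, overlap_accounting
from .go_enrichment import AnnotationSet, GODag, enrich, lowest_nodes
from .health_status import DEFAULT_RULES, health_status_index, load_rules
from .mixture_models import classify_interaction
from .toxicokinetics import fit_elimination

log = logging.getLogger("mixtoxsys.pipeline")

__all__ = ["RunConfig", "run_assessment"]


@dataclass
class MixtureEndpoint:
    name: str
    path: str
    frameworks: List[str] = field(default_factory=lambda: ["CA"])


@dataclass
class RunConfig:
    """Paths and thresholds for a full or partial assessment run."""

    alpha: float = 0.05
    b_threshold: float = 0.0
    seed: int = 0
    output_dir: Optional[str] = None

    dose_response: Optional[str] = None           # chemical,concentration,response
    dose_response_direction: str = DECREASING
    design_tu_levels: List[float] = field(default_factory=lambda: [0.5, 1.0])
    mixtures: List[MixtureEndpoint] = field(default_factory=list)
    toxicokinetics: Optional[str] = None          # chemical,time_days,concentration
    biomarkers: Optional[str] = None              # biomarker,level,group,value
    rules: Optional[str] = None                   # YAML rule table
    deg_tables: Dict[str, str] = field(default_factory=dict)  # condition -> path
    concordance_table: Optional[str] = None
    enrichment_study: Optional[str] = None        # one gene id per line
    enrichment_annotations: Optional[str] = None  # seq_id<TAB>GO:ID
    enrichment_obo: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        self.mixtures = [
            m if isinstance(m, MixtureEndpoint) else MixtureEndpoint(**m)
            for m in self.mixtures
        ]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = [
            self.dose_response, self.toxicokinetics, self.biomarkers, self.rules,
            self.concordance_table, self.enrichment_study,
            self.enrichment_annotations, self.enrichment_obo,
            *[m.path for m in self.mixtures],
            *self.deg_tables.values(),
        ]
        missing = [p for p in paths if p is not None and not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input files: {missing}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_assessment(config: RunConfig) -> dict:
    """Execute all configured stages in dependency order; returns the report."""
    config.validate_paths()
    report: dict = {
        "provenance": {
            "package": "mixtoxsys",
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "config_hash": config.config_hash(),
        }
    }

    if config.dose_response:
        block: dict = {}
        models = {}
        for chem, data in io.load_dose_response(config.dose_response).items():
            try:
                model, stats_ = fit_loglogistic(data, config.dose_response_direction)
                models[chem] = model
                block[chem] = {
                    "theta_max": model.theta_max,
                    "theta_min": model.theta_min,
                    "ec50": model.ec50,
                    "beta": model.beta,
                    "direction": model.direction,
                    "R2": stats_.r2,
                    "n": stats_.n,
                    "ecx": {
                        "EC12.5": ec_x(model, 12.5).concentration,
                        "EC25": ec_x(model, 25).concentration,
                        "EC50": ec_x(model, 50).concentration,
                    },
                }
            except MixtoxError as exc:
                log.warning("[%s] dose-response stage failed for %s: %s",
                            config.config_hash(), chem, exc)
                block[chem] = {"error": str(exc)}
        report["dose_response"] = block
        if len(models) >= 2:
            report["mixture_design"] = {
                str(tu): {
                    k: v
                    for k, v in design_equitoxic_mixture(
                        models=models, tu_level=tu
                    ).component_concentrations.items()
                }
                for tu in config.design_tu_levels
            }

    if config.mixtures:
        block = {}
        for endpoint in config.mixtures:
            points = io.load_mixture_points(endpoint.path)
            block[endpoint.name] = {}
            for fw in endpoint.frameworks:
                try:
                    analysis = classify_interaction(points, fw, alpha=config.alpha)
                    block[endpoint.name][fw] = analysis.to_report()
                except MixtoxError as exc:
                    log.warning("[%s] surface stage failed for %s/%s: %s",
                                config.config_hash(), endpoint.name, fw, exc)
                    block[endpoint.name][fw] = {"error": str(exc)}
        report["mixture_interactions"] = block

    if config.toxicokinetics:
        block = {}
        for series in io.load_elimination(config.toxicokinetics):
            try:
                block[series.chemical_id] = fit_elimination(series).to_record()
            except MixtoxError as exc:
                log.warning("[%s] toxicokinetics failed for %s: %s",
                            config.config_hash(), series.chemical_id, exc)
                block[series.chemical_id] = {"error": str(exc)}
        report["toxicokinetics"] = block

    if config.biomarkers:
        rules = load_rules(config.rules) if config.rules else DEFAULT_RULES
        panel = io.load_biomarker_panel(config.biomarkers)
        result = health_status_index(panel, rules=rules, alpha=config.alpha)
        report["health_status"] = {
            "grade": result.grade,
            "triggered_rules": list(result.triggered_rules),
            "per_biomarker": {
                name: {"AL": al.value, "p": al.p, "fractional_change": al.fractional_change}
                for name, al in result.per_biomarker.items()
            },
        }

    if config.deg_tables:
        lists = {
            cond: call_degs(io.load_deg_table(path), b_threshold=config.b_threshold)
            for cond, path in config.deg_tables.items()
        }
        sizes = {cond: len(genes) for cond, genes in lists.items()}
        block = {"deg_counts": sizes}
        if len(lists) == 3:
            acc = overlap_accounting(lists)
            block["overlap"] = {
                "sizes": acc.sizes,
                "pairwise_exclusive": {
                    " & ".join(pair): asdict(ov)
                    for pair, ov in acc.pairwise_exclusive.items()
                },
                "triple": acc.triple,
                "unique": acc.unique,
                "unique_including_opposite": acc.unique_including_opposite,
                "percent": acc.percent,
            }
        report["transcriptomics"] = block

    if config.concordance_table:
        rows = io.read_table(config.concordance_table)
        result = concordance(rows)
        report["concordance"] = {
            "matches": result.matches,
            "total": result.total,
            "fraction": result.fraction,
        }

    if config.enrichment_study and config.enrichment_annotations:
        study = {
            line.strip()
            for line in Path(config.enrichment_study).read_text().splitlines()
            if line.strip()
        }
        pairs = []
        for line in Path(config.enrichment_annotations).read_text().splitlines():
            if line.strip():
                sid, term = line.split("\t")
                pairs.append((sid, term))
        annot = AnnotationSet.from_pairs(pairs)
        annot.universe |= study
        dag = GODag.from_obo(config.enrichment_obo) if config.enrichment_obo else None
        results = enrich(study, annot, dag, alpha=config.alpha)
        sig = {r.term for r in results if r.enriched}
        block = {
            "n_terms_tested": len(results),
            "enriched": [
                {"term": r.term, "name": r.name, "k": r.k, "K": r.K, "p": r.p}
                for r in results
                if r.enriched
            ],
        }
        if dag is not None:
            block["lowest_nodes"] = sorted(lowest_nodes(sig, dag))
        report["go_enrichment"] = block

    if config.output_dir:
        io.write_json(report, Path(config.output_dir) / "assessment_report.json")
    return report
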