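"""Biomarker testing, alteration levels and the rule-based health status index.

Each biomarker's exposed group is compared with its control by a two-sided
Mann-Whitney U test.  A significant change (p < alpha) becomes an alteration
level: AL1 (mild) or AL2 (severe) when the median shifts in the harmful
direction by at least the biomarker's severity threshold.  The panel of
alteration levels is then folded into a single A-E grade by a first-match
rule table keyed on (i) how many biomarkers are altered and how severely,
(ii) the levels of biological organization affected, and (iii) the state of
the designated *guide* biomarker (lysosomal membrane stability by default).

Default rule table (first match wins, conditions are monotone in the ALs so
raising any alteration can never improve the grade):

    E  guide biomarker at AL2 and >= 2 further biomarkers at AL2
    D  AL2 in >= 2 biomarkers spanning >= 2 organization levels
    C  any AL2, or >= 2 altered biomarkers of which >= 1 above the cell level
    B  any alteration (in practice: mild, cell-level-only alterations)
    A  no alteration

Thresholds and the whole rule table are overridable from YAML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import stats

from .exceptions import DomainError, ValidationError

CELL = "cell"
TISSUE = "tissue"
ORGANISM = "organism"
ORGANIZATION_LEVELS = (CELL, TISSUE, ORGANISM)

DECREASE = "decrease"
INCREASE = "increase"

GRADES = ("A", "B", "C", "D", "E")

EXACT = "exact"
NORMAL_APPROX = "normal_approx"
_EXACT_LIMIT = 16  # total sample size up to which labelings are enumerated

__all__ = [
    "BiomarkerRecord", "AlterationLevel", "HSIResult",
    "Rule", "RuleCondition", "RuleTable", "DEFAULT_RULES",
    "mann_whitney_u", "alteration_level", "health_status_index",
    "grade_panel", "PanelEntry", "load_rules",
    "CELL", "TISSUE", "ORGANISM", "DECREASE", "INCREASE",
    "EXACT", "NORMAL_APPROX", "GRADES",
]


@dataclass
class BiomarkerRecord:
    """Replicated exposed/control measurements for one biomarker."""

    name: str
    level: str
    exposed: np.ndarray
    control: np.ndarray
    harmful_direction: str = DECREASE
    severity_threshold: float = 1.0  # fractional median change marking AL2
    guide: bool = False

    def __post_init__(self) -> None:
        self.exposed = np.asarray(self.exposed, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.level not in ORGANIZATION_LEVELS:
            raise ValidationError(f"level must be one of {ORGANIZATION_LEVELS}")
        if self.harmful_direction not in (DECREASE, INCREASE):
            raise ValidationError("harmful_direction must be 'decrease' or 'increase'")
        if self.exposed.size < 3 or self.control.size < 3:
            raise ValidationError("need at least 3 replicates per group")
        if self.severity_threshold <= 0:
            raise ValidationError("severity_threshold must be positive")


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    mode_used: str


def mann_whitney_u(x, y, mode: str = EXACT) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``exact`` enumerates the permutation distribution of U (all C(n+m, n)
    group labelings) for total sample sizes up to 16 and tie-free data; with
    ties, or beyond that size, the tie-corrected normal approximation with
    continuity correction is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if mode not in (EXACT, NORMAL_APPROX):
        raise ValidationError("mode must be 'exact' or 'normal_approx'")

    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    use_exact = mode == EXACT and not has_ties and (x.size + y.size) <= _EXACT_LIMIT
    if mode == EXACT and not use_exact:
        if has_ties:
            warnings.warn(
                "ties present: falling back to the normal approximation", stacklevel=2
            )
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u=float(res.statistic),
        p=float(min(1.0, res.pvalue)),
        mode_used=EXACT if use_exact else NORMAL_APPROX,
    )


@dataclass(frozen=True)
class AlterationLevel:
    """Discretized severity of a biomarker change: 0 (none), 1 (mild), 2 (severe)."""

    value: int
    p: float
    fractional_change: float

    @property
    def label(self) -> str:
        return f"AL{self.value}"


def alteration_level(record: BiomarkerRecord, alpha: float = 0.05) -> AlterationLevel:
    """Convert a tested biomarker into an alteration level.

    AL0 iff p >= alpha.  Otherwise the fractional median change
    (median_exposed - median_control)/median_control, signed toward the
    harmful direction, is compared with the severity threshold: AL2 when the
    change is harmful and at least as large as the threshold, AL1 otherwise.
    """
    med_c = float(np.median(record.control))
    if med_c == 0:
        raise DomainError(f"{record.name}: zero control median, cannot normalize")
    med_e = float(np.median(record.exposed))
    fc = (med_e - med_c) / abs(med_c)
    test = mann_whitney_u(record.exposed, record.control)
    if test.p >= alpha:
        return AlterationLevel(0, test.p, fc)
    harmful = -fc if record.harmful_direction == DECREASE else fc
    if harmful >= record.severity_threshold:
        return AlterationLevel(2, test.p, fc)
    return AlterationLevel(1, test.p, fc)


# ---------------------------------------------------------------------------
# Rule engine

@dataclass(frozen=True)
class RuleCondition:
    """Monotone predicate over a panel of alteration levels (AND of clauses)."""

    guide_al2: bool = False
    min_al2: int = 0
    min_al2_excluding_guide: int = 0
    min_al2_levels: int = 0
    min_altered: int = 0
    min_altered_above_cell: int = 0

    def matches(self, entries: Sequence["PanelEntry"]) -> bool:
        al2 = [e for e in entries if e.al >= 2]
        altered = [e for e in entries if e.al >= 1]
        if self.guide_al2 and not any(e.guide and e.al >= 2 for e in entries):
            return False
        if len(al2) < self.min_al2:
            return False
        if len([e for e in al2 if not e.guide]) < self.min_al2_excluding_guide:
            return False
        if len({e.level for e in al2}) < self.min_al2_levels:
            return False
        if len(altered) < self.min_altered:
            return False
        if len([e for e in altered if e.level != CELL]) < self.min_altered_above_cell:
            return False
        return True

    @property
    def is_catch_all(self) -> bool:
        return self == RuleCondition()


@dataclass(frozen=True)
class Rule:
    id: str
    grade: str
    when: RuleCondition

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValidationError(f"grade must be one of {GRADES}")


@dataclass(frozen=True)
class PanelEntry:
    name: str
    level: str
    al: int
    guide: bool = False


class RuleTable:
    """Ordered first-match rule table; must end with a catch-all rule."""

    def __init__(self, rules: Sequence[Rule]):
        rules = list(rules)
        if not rules:
            raise ValidationError("empty rule table")
        ids = [r.id for r in rules]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate rule ids")
        if not rules[-1].when.is_catch_all:
            raise ValidationError(
                "rule table is not exhaustive: last rule must be unconditional"
            )
        self.rules = rules

    def __iter__(self):
        return iter(self.rules)


DEFAULT_RULES = RuleTable([
    Rule("E-guide-severe", "E", RuleCondition(guide_al2=True, min_al2_excluding_guide=2)),
    Rule("D-multi-severe", "D", RuleCondition(min_al2=2, min_al2_levels=2)),
    Rule("C-any-severe", "C", RuleCondition(min_al2=1)),
    Rule("C-spread-mild", "C", RuleCondition(min_altered=2, min_altered_above_cell=1)),
    Rule("B-any-mild", "B", RuleCondition(min_altered=1)),
    Rule("A-healthy", "A", RuleCondition()),
])


@dataclass(frozen=True)
class HSIResult:
    grade: str
    triggered_rules: tuple
    per_biomarker: dict


def grade_panel(entries: Sequence[PanelEntry], rules: RuleTable = DEFAULT_RULES) -> HSIResult:
    """Grade a panel of already-discretized alteration levels."""
    if not entries:
        raise ValidationError("empty panel")
    if sum(1 for e in entries if e.guide) > 1:
        raise ValidationError("at most one guide biomarker per panel")
    matched = [r.id for r in rules if r.when.matches(entries)]
    grade = next(r.grade for r in rules if r.when.matches(entries))
    return HSIResult(
        grade=grade,
        triggered_rules=tuple(matched),
        per_biomarker={e.name: e.al for e in entries},
    )


def health_status_index(
    panel: Sequence[BiomarkerRecord],
    rules: RuleTable = DEFAULT_RULES,
    alpha: float = 0.05,
) -> HSIResult:
    """Test a biomarker panel, discretize to alteration levels, and grade it.

    If no record is flagged as the guide biomarker, a record named "LMS"
    (lysosomal membrane stability) is promoted to guide when present.
    """
    if not panel:
        raise ValidationError("empty biomarker panel")
    guides = [r for r in panel if r.guide]
    if len(guides) > 1:
        raise ValidationError("at most one guide biomarker per panel")
    guide_name = guides[0].name if guides else ("LMS" if any(r.name == "LMS" for r in panel) else None)

    als = {}
    entries = []
    for rec in panel:
        al = alteration_level(rec, alpha=alpha)
        als[rec.name] = al
        entries.append(PanelEntry(rec.name, rec.level, al.value, guide=rec.name == guide_name))
    result = grade_panel(entries, rules)
    return HSIResult(
        grade=result.grade,
        triggered_rules=result.triggered_rules,
        per_biomarker=als,
    )


def load_rules(path) -> RuleTable:
    """Load a rule table from YAML: a list of {id, grade, when: {clause: value}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError("rule file must contain a list of rules")
    rules = []
    valid = set(RuleCondition.__dataclass_fields__)
    for item in raw:
        when = item.get("when") or {}
        unknown = set(when) - valid
        if unknown:
            raise ValidationError(f"unknown rule clauses: {sorted(unknown)}")
        rules.append(Rule(str(item["id"]), str(item["grade"]), RuleCondition(**when)))
    return RuleTable(rules)
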