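"""GO-term over-representation analysis of DEG lists against the array
background: hypergeometric tail probabilities after ancestor propagation over
the is_a DAG, optional Benjamini-Hochberg correction, and per-branch
lowest-node summarization (the antichain of significant terms with no
significant descendant).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from graphlib import CycleError, TopologicalSorter
from typing import Dict, Iterable, Mapping, Optional, Set

import numpy as np
from scipy import stats

from .exceptions import ValidationError

_TERM_RE = re.compile(r"^GO:\d{7}$")

BIOLOGICAL_PROCESS = "biological_process"
MOLECULAR_FUNCTION = "molecular_function"
CELLULAR_COMPONENT = "cellular_component"

__all__ = [
    "AnnotationSet",
    "GODag",
    "EnrichmentResult",
    "propagate_ancestors",
    "enrich",
    "lowest_nodes",
]


@dataclass
class AnnotationSet:
    """Per-sequence GO annotations over a fixed background universe."""

    annotations: Dict[str, Set[str]]
    universe: Set[str]

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        self.annotations = {k: set(v) for k, v in self.annotations.items()}
        stray = set(self.annotations) - self.universe
        if stray:
            raise ValidationError(
                f"{len(stray)} annotated ids outside the universe (e.g. {sorted(stray)[:3]})"
            )
        for sid, terms in self.annotations.items():
            for t in terms:
                if not _TERM_RE.match(t):
                    raise ValidationError(f"invalid GO term id {t!r} on {sid!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], universe: Optional[Iterable[str]] = None):
        """Build from (seq_id, term) pairs, e.g. a two-column annotation export."""
        annot: Dict[str, Set[str]] = {}
        for sid, term in pairs:
            annot.setdefault(str(sid), set()).add(str(term))
        uni = set(universe) if universe is not None else set(annot)
        return cls(annotations=annot, universe=uni)


class GODag:
    """is_a parent map with term names and namespaces; validated acyclic."""

    def __init__(
        self,
        parents: Mapping[str, Set[str]],
        namespace: Optional[Mapping[str, str]] = None,
        name: Optional[Mapping[str, str]] = None,
    ):
        self.parents: Dict[str, Set[str]] = {t: set(p) for t, p in parents.items()}
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, set())
        self.namespace = dict(namespace or {})
        self.name = dict(name or {})
        try:
            tuple(TopologicalSorter(self.parents).static_order())
        except CycleError as exc:
            raise ValidationError(f"GO DAG contains a cycle: {exc.args}") from exc
        self._anc_cache: Dict[str, frozenset] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset:
        """All strict ancestors of a term (transitive is_a closure)."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out: Set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            cached = self._anc_cache.get(cur)
            if cached is not None:
                out |= cached
            else:
                stack.extend(self.parents.get(cur, ()))
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    @property
    def roots(self) -> Set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    @classmethod
    def from_obo(cls, path) -> "GODag":
        """Read an OBO file keeping only id / name / namespace / is_a."""
        import obonet

        graph = obonet.read_obo(path)
        parents: Dict[str, Set[str]] = {}
        namespace = {}
        name = {}
        for node, data in graph.nodes(data=True):
            parents.setdefault(node, set())
            if "namespace" in data:
                namespace[node] = data["namespace"]
            if "name" in data:
                name[node] = data["name"]
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents.setdefault(child, set()).add(parent)
        return cls(parents, namespace, name)


def propagate_ancestors(annot: AnnotationSet, dag: GODag) -> AnnotationSet:
    """Annotate every sequence with the ancestor closure of its terms.

    Terms absent from the DAG are kept as-is.  Idempotent.
    """
    new = {}
    for sid, terms in annot.annotations.items():
        closure = set(terms)
        for t in terms:
            if t in dag:
                closure |= dag.ancestors(t)
        new[sid] = closure
    return AnnotationSet(annotations=new, universe=set(annot.universe))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int          # study sequences carrying the term
    K: int          # background sequences carrying the term
    n: int          # study size
    N: int          # background size
    p: float
    p_adjusted: float
    enriched: bool
    name: str = ""


def enrich(
    study: Set[str],
    annot: AnnotationSet,
    dag: Optional[GODag] = None,
    alpha: float = 0.05,
    correction: str = "none",
    propagate: bool = True,
    under: bool = False,
):
    """One-sided hypergeometric over-representation test per GO term.

    ``study`` must be a subset of the annotation universe.  With a DAG and
    ``propagate`` (default), annotations are first closed over ancestors so
    parent terms count every sequence annotated below them.  ``correction``
    is 'none' (raw p < alpha, the conventional choice here) or 'BH'.
    ``under=True`` tests under-representation instead.

    Returns a list of :class:`EnrichmentResult` sorted by p.
    """
    study = set(study)
    if not study:
        raise ValidationError("empty study set")
    if not study <= annot.universe:
        extra = sorted(study - annot.universe)[:3]
        raise ValidationError(f"study ids outside the universe (e.g. {extra})")
    if correction not in ("none", "BH"):
        raise ValidationError("correction must be 'none' or 'BH'")
    if propagate and dag is not None:
        annot = propagate_ancestors(annot, dag)

    term_members: Dict[str, Set[str]] = {}
    for sid, terms in annot.annotations.items():
        for t in terms:
            term_members.setdefault(t, set()).add(sid)

    N = len(annot.universe)
    n = len(study)
    results = []
    for term, members in term_members.items():
        K = len(members)
        k = len(members & study)
        if under:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append((term, k, K, p))
    results.sort(key=lambda r: (r[3], r[0]))

    ps = np.array([r[3] for r in results])
    if correction == "BH" and ps.size:
        p_adj = stats.false_discovery_control(ps, method="bh")
    else:
        p_adj = ps
    out = []
    for (term, k, K, p), pa in zip(results, p_adj):
        out.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N, p=p, p_adjusted=float(pa),
                enriched=bool(pa < alpha),
                name=dag.name.get(term, "") if dag is not None else "",
            )
        )
    return out


def lowest_nodes(sig_terms: Set[str], dag: GODag) -> Set[str]:
    """Significant terms with no significant descendant (per-branch leaves).

    The returned antichain, together with the ancestor closures of its
    members, covers the whole significant set.
    """
    sig = set(sig_terms)
    missing = {t for t in sig if t not in dag}
    if missing:
        raise ValidationError(f"terms not in DAG: {sorted(missing)[:3]}")
    covered_ancestors: Set[str] = set()
    for t in sig:
        covered_ancestors |= dag.ancestors(t) & sig
    return sig - covered_ancestors
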