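"""Transcriptomic comparison layer: DEG calling from moderated-statistics
tables, exclusive overlap/trend accounting across three exposure conditions,
microarray vs Q-PCR concordance scoring, and efficiency-corrected relative
expression with a randomization test.

Conventions
-----------
* A gene is a DEG when its log-odds of differential expression B exceeds the
  threshold (default 0); its trend is the sign of the log2 ratio M.
* Pairwise overlap counts are *exclusive* of the triple intersection, so for
  every condition:  unique + sum(exclusive pairwise) + triple = list size.
* Concordance rule (reconstructed so that it reproduces the published match
  statistics exactly): a gene is concordant iff the array calls it (B > 0),
  the Q-PCR change is significant and both platforms agree in sign -- or the
  array does not call it and the Q-PCR change is not significant.
* Relative expression is the efficiency-corrected ratio
  E_t^(dCt_t) / geomean_r E_r^(dCt_r) with dCt = mean Ct(control) - mean
  Ct(exposed), geometrically normalized over the reference genes; with all
  efficiencies equal to 2 this reduces to the classic 2^(-ddCt) method.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError

__all__ = [
    "call_degs",
    "OverlapAccounting",
    "PairOverlap",
    "overlap_accounting",
    "ConcordanceResult",
    "concordance",
    "relative_expression",
    "RandomizationResult",
    "randomization_test",
]


def call_degs(
    table: pd.DataFrame,
    b_threshold: float = 0.0,
    zero_m: str = "error",
) -> Dict[str, int]:
    """Call differentially expressed genes from a (gene_id, M, B) table.

    Returns ``{gene_id: sign(M)}`` for genes with B > b_threshold.  Rows with
    missing (NaN) M or B are ignored.  A called gene with M == 0 has no trend:
    ``zero_m`` selects 'error' (default) or 'drop'.
    """
    required = {"gene_id", "M", "B"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"DEG table missing columns {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id in DEG table: {dup!r}")
    if zero_m not in ("error", "drop"):
        raise ValidationError("zero_m must be 'error' or 'drop'")
    rows = table.dropna(subset=["M", "B"])
    called = rows[rows["B"] > b_threshold]
    out: Dict[str, int] = {}
    for gene, m in zip(called["gene_id"], called["M"]):
        if m == 0:
            if zero_m == "error":
                raise ValidationError(
                    f"gene {gene!r} called (B > {b_threshold}) but M == 0: trend undefined"
                )
            warnings.warn(f"dropping called gene {gene!r} with M == 0", stacklevel=2)
            continue
        out[str(gene)] = 1 if m > 0 else -1
    return out


@dataclass(frozen=True)
class PairOverlap:
    count: int
    same_trend: int
    opposite_trend: int


@dataclass(frozen=True)
class OverlapAccounting:
    """Exclusive overlap structure of three trend-tagged DEG sets."""

    sizes: Dict[str, int]
    pairwise_exclusive: Dict[Tuple[str, str], PairOverlap]
    triple: int
    unique: Dict[str, int]
    unique_including_opposite: Dict[str, int]
    focal: str
    percent: Dict[str, float]

    def pair(self, a: str, b: str) -> PairOverlap:
        key = tuple(sorted((a, b)))
        return self.pairwise_exclusive[key]


def overlap_accounting(
    lists: Mapping[str, Mapping[str, int]],
    focal: Optional[str] = None,
) -> OverlapAccounting:
    """Exclusive-overlap and trend accounting for three named DEG sets.

    ``lists`` maps condition name -> {gene_id: trend sign (+1/-1)}.  Pairwise
    counts exclude the triple intersection.  Percentages are reported relative
    to the *focal* condition's list size (default: the last-named condition,
    conventionally the mixture) for rows involving it, and relative to the
    union of all DEGs for the remaining pair.
    """
    if len(lists) != 3:
        raise ValidationError("overlap accounting requires exactly three DEG sets")
    names = list(lists)
    focal = focal if focal is not None else names[-1]
    if focal not in names:
        raise ValidationError(f"focal condition {focal!r} not among {names}")
    sets = {}
    for name, genes in lists.items():
        genes = dict(genes)
        if any(s not in (1, -1) for s in genes.values()):
            raise ValidationError(f"{name}: trends must be +1 or -1")
        sets[name] = set(genes)
    trends = {name: dict(genes) for name, genes in lists.items()}

    triple_set = sets[names[0]] & sets[names[1]] & sets[names[2]]
    pairwise: Dict[Tuple[str, str], PairOverlap] = {}
    for a, b in itertools.combinations(names, 2):
        shared = (sets[a] & sets[b]) - triple_set
        same = sum(1 for g in shared if trends[a][g] == trends[b][g])
        pairwise[tuple(sorted((a, b)))] = PairOverlap(
            count=len(shared), same_trend=same, opposite_trend=len(shared) - same
        )

    unique = {}
    unique_incl = {}
    for name in names:
        others = [n for n in names if n != name]
        uniq = sets[name] - sets[others[0]] - sets[others[1]]
        unique[name] = len(uniq)
        opp = sum(
            pairwise[tuple(sorted((name, other)))].opposite_trend for other in others
        )
        unique_incl[name] = len(uniq) + opp

    union_size = len(set().union(*sets.values()))
    percent = {}
    for (a, b), ov in pairwise.items():
        if focal in (a, b):
            denom = len(sets[focal])
        else:
            denom = union_size
        percent[f"{a}&{b}"] = 100.0 * ov.count / denom if denom else 0.0
    percent["triple"] = 100.0 * len(triple_set) / union_size if union_size else 0.0
    percent[f"unique_{focal}"] = (
        100.0 * unique[focal] / len(sets[focal]) if sets[focal] else 0.0
    )
    percent[f"unique_{focal}_including_opposite"] = (
        100.0 * unique_incl[focal] / len(sets[focal]) if sets[focal] else 0.0
    )

    return OverlapAccounting(
        sizes={name: len(sets[name]) for name in names},
        pairwise_exclusive=pairwise,
        triple=len(triple_set),
        unique=unique,
        unique_including_opposite=unique_incl,
        focal=focal,
        percent=percent,
    )


@dataclass(frozen=True)
class ConcordanceResult:
    matches: int
    total: int
    fraction: float
    per_gene: Dict[str, bool]


def concordance(rows: pd.DataFrame) -> ConcordanceResult:
    """Score microarray/Q-PCR agreement over comparison rows.

    Expects columns gene_id, qpcr_value, qpcr_significant, M, B; rows with
    missing array values (NaN M or B) are excluded from the totals.  The
    fraction is rounded to two decimals.
    """
    required = {"gene_id", "qpcr_value", "qpcr_significant", "M", "B"}
    missing = required - set(rows.columns)
    if missing:
        raise ValidationError(f"concordance table missing columns {sorted(missing)}")
    usable = rows.dropna(subset=["M", "B"])
    if usable.empty:
        raise ValidationError("no rows with array data to compare")
    per_gene: Dict[str, bool] = {}
    matches = 0
    for row in usable.itertuples(index=False):
        sig = bool(row.qpcr_significant)
        if row.B > 0:
            ok = sig and np.sign(row.M) == np.sign(row.qpcr_value) and row.M != 0
        else:
            ok = not sig
        per_gene[str(row.gene_id)] = ok
        matches += ok
    total = len(usable)
    return ConcordanceResult(
        matches=matches,
        total=total,
        fraction=round(matches / total, 2),
        per_gene=per_gene,
    )


def _delta_ct(ct: pd.DataFrame, gene: str, control: str, exposed: str) -> float:
    sub = ct[ct["gene_id"] == gene]
    ct_c = sub.loc[sub["group"] == control, "Ct"]
    ct_e = sub.loc[sub["group"] == exposed, "Ct"]
    if ct_c.empty or ct_e.empty:
        raise ValidationError(f"gene {gene!r} missing in one of the groups")
    return float(ct_c.mean() - ct_e.mean())


def _check_ct(ct: pd.DataFrame) -> None:
    required = {"gene_id", "group", "replicate", "Ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns {sorted(missing)}")


def relative_expression(
    ct: pd.DataFrame,
    targets: Sequence[str],
    references: Sequence[str],
    efficiencies: Mapping[str, float],
    control: str = "control",
    exposed: str = "exposed",
) -> Dict[str, dict]:
    """Efficiency-corrected relative expression, geometrically normalized over
    the reference genes:  ratio = E_t^(dCt_t) / geomean_r(E_r^(dCt_r))."""
    _check_ct(ct)
    if not references:
        raise ValidationError("at least one reference gene is required")
    for gene in list(targets) + list(references):
        if gene not in efficiencies:
            raise ValidationError(f"no amplification efficiency for {gene!r}")
        if not 1.0 < efficiencies[gene] <= 2.0:
            raise ValidationError(f"efficiency for {gene!r} must be in (1, 2]")
    ref_factors = []
    for ref in references:
        d = _delta_ct(ct, ref, control, exposed)
        ref_factors.append(efficiencies[ref] ** d)
    norm = float(np.exp(np.mean(np.log(ref_factors))))
    out = {}
    for gene in targets:
        d = _delta_ct(ct, gene, control, exposed)
        ratio = efficiencies[gene] ** d / norm
        out[gene] = {"ratio": ratio, "log2_ratio": math.log2(ratio), "delta_ct": d}
    return out


@dataclass(frozen=True)
class RandomizationResult:
    p: float
    n_perm: int
    exhaustive: bool
    observed_log_ratio: float


def randomization_test(
    ct: pd.DataFrame,
    target: str,
    references: Sequence[str],
    efficiencies: Mapping[str, float],
    n_perm: int = 2000,
    seed: Optional[int] = None,
    control: str = "control",
    exposed: str = "exposed",
    exhaustive: str = "auto",
) -> RandomizationResult:
    """Fixed-reallocation randomization test on the normalized expression ratio.

    Sample (group, replicate) units are reassigned to the two groups (keeping
    group sizes) and the |log ratio| recomputed; p is the fraction of
    reallocations at least as extreme as the observed one.  All C(n_c+n_e, n_c)
    splits are enumerated when that count is at most 10,000 (or always when
    ``exhaustive=True``); otherwise ``n_perm`` random reallocations are drawn
    with the given seed, the observed allocation counted among them.
    """
    _check_ct(ct)
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    genes = [target] + list(references)
    # pivot to gene x sample matrix of Ct means over technical replicates
    sub = ct[ct["gene_id"].isin(genes)]
    piv = sub.pivot_table(index="gene_id", columns=["group", "replicate"], values="Ct")
    if piv.isna().any().any():
        raise ValidationError("incomplete Ct table: every gene needs every sample")
    samples = list(piv.columns)
    groups = np.array([g for g, _ in samples])
    n_c = int((groups == control).sum())
    n_e = int((groups == exposed).sum())
    if n_c == 0 or n_e == 0:
        raise ValidationError("both groups must be present")
    mat = piv.to_numpy()
    gene_index = {g: i for i, g in enumerate(piv.index)}
    log_eff = np.array([math.log(efficiencies[g]) for g in piv.index])

    def log_ratio(ctrl_mask: np.ndarray) -> float:
        d = mat[:, ctrl_mask].mean(axis=1) - mat[:, ~ctrl_mask].mean(axis=1)
        log_factors = log_eff * d  # ln E^dCt per gene
        ref_idx = [gene_index[r] for r in references]
        t_idx = gene_index[target]
        return float(log_factors[t_idx] - np.mean(log_factors[ref_idx]))

    obs_mask = groups == control
    observed = log_ratio(obs_mask)

    total = math.comb(n_c + n_e, n_c)
    do_exhaustive = exhaustive is True or (exhaustive == "auto" and total <= 10_000)
    if do_exhaustive:
        count = 0
        for combo in itertools.combinations(range(n_c + n_e), n_c):
            mask = np.zeros(n_c + n_e, dtype=bool)
            mask[list(combo)] = True
            count += abs(log_ratio(mask)) >= abs(observed) - 1e-12
        p = count / total
        return RandomizationResult(p=p, n_perm=total, exhaustive=True,
                                   observed_log_ratio=observed)
    rng = np.random.default_rng(seed)
    count = 1  # the observed allocation
    for _ in range(n_perm - 1):
        perm = rng.permutation(n_c + n_e)
        mask = np.zeros(n_c + n_e, dtype=bool)
        mask[perm[:n_c]] = True
        count += abs(log_ratio(mask)) >= abs(observed) - 1e-12
    return RandomizationResult(p=count / n_perm, n_perm=n_perm, exhaustive=False,
                               observed_log_ratio=observed)
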