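"""Hypergeometric pathway enrichment and per-term RPKM aggregation.

The enrichment P value is the upper tail P(X >= m), i.e.

    P = 1 - sum_{i=0}^{m-1} C(M, i) * C(N-M, n-i) / C(N, n)

for population size N, successes-in-population M, sample size n and
observed overlap m.  Significance uses a raw cutoff (default 0.05,
strict); Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.05


@dataclass(frozen=True)
class EnrichmentInput:
    n_pop: int
    m_succ: int
    n_sample: int
    m_obs: int

    def __post_init__(self) -> None:
        if self.n_pop <= 0:
            raise ValueError("population size N must be positive")
        if not 0 <= self.m_succ <= self.n_pop:
            raise ValueError(
                f"successes M={self.m_succ} outside [0, N={self.n_pop}]"
            )
        if not 0 <= self.n_sample <= self.n_pop:
            raise ValueError(
                f"sample size n={self.n_sample} outside [0, N={self.n_pop}]"
            )
        if self.m_obs < 0 or self.m_obs > min(self.m_succ, self.n_sample):
            raise ValueError(
                f"observed m={self.m_obs} outside [0, min(M={self.m_succ}, "
                f"n={self.n_sample})]"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    p_value: float
    m_obs: int
    n_sample: int
    m_succ: int
    n_pop: int
    rpkm_sum: float
    significant: bool
    p_adjusted: Optional[float] = None


def hypergeom_p(inp: EnrichmentInput) -> float:
    """Upper-tail hypergeometric probability P(X >= m_obs)."""
    if inp.m_obs == 0:
        return 1.0
    p = float(hypergeom.sf(inp.m_obs - 1, inp.n_pop, inp.m_succ, inp.n_sample))
    return min(max(p, 0.0), 1.0)


def _bh_adjust(pvals: Sequence[float]) -> List[float]:
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        val = min(prev, pvals[idx] * n / rank)
        adj[idx] = val
        prev = val
    return adj.tolist()


def enrich_pathways(
    pathway_map: Mapping[str, Iterable[str]],
    sample: Set[str],
    population: Optional[Set[str]] = None,
    cutoff: float = DEFAULT_CUTOFF,
    population_mode: str = "mapped",
    rpkms: Optional[Mapping[str, float]] = None,
    bh: bool = False,
) -> List[EnrichmentResult]:
    """One hypergeometric test per pathway.

    ``pathway_map`` maps pathway id -> member protein ids.  ``sample``
    is the gene set under test.  The population is either the union of
    all mapped proteins (``population_mode='mapped'``, default) or an
    explicit ``population`` set (``population_mode='all'``); both
    readings of the population definition are supported because the
    prose and the formula admit either.  Results are sorted by P value.
    """
    if not pathway_map:
        raise ValueError("pathway map is empty")
    members = {pid: set(prots) for pid, prots in pathway_map.items()}
    if population_mode == "mapped":
        pop = set().union(*members.values())
    elif population_mode == "all":
        if population is None:
            raise ValueError("population_mode='all' requires a population set")
        pop = set(population)
    else:
        raise ValueError(f"unknown population_mode {population_mode!r}")
    sample_in = sample & pop
    results = []
    for pid in sorted(members):
        in_pop = members[pid] & pop
        m_succ = len(in_pop)
        m_obs = len(in_pop & sample_in)
        if m_succ == 0:
            logger.warning("pathway %s has zero mapped proteins; P = 1", pid)
            p = 1.0
        else:
            p = hypergeom_p(
                EnrichmentInput(len(pop), m_succ, len(sample_in), m_obs)
            )
        rpkm_sum = (
            sum(rpkms.get(prot, 0.0) for prot in in_pop) if rpkms else 0.0
        )
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                p_value=p,
                m_obs=m_obs,
                n_sample=len(sample_in),
                m_succ=m_succ,
                n_pop=len(pop),
                rpkm_sum=rpkm_sum,
                significant=p < cutoff,
            )
        )
    if bh:
        adj = _bh_adjust([r.p_value for r in results])
        results = [
            EnrichmentResult(
                r.pathway_id, r.p_value, r.m_obs, r.n_sample, r.m_succ,
                r.n_pop, r.rpkm_sum, a < cutoff, p_adjusted=a,
            )
            for r, a in zip(results, adj)
        ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def aggregate_rpkm_by_category(
    annotations: Mapping[str, Iterable[str]],
    rpkms: Mapping[str, float],
) -> Dict[str, Dict[str, float]]:
    """Per-term (rpkm_sum, protein_count, rpkm_mean) over an annotation
    map {protein_id: [terms...]}.  A protein annotated to several terms
    contributes fully to each."""
    agg: Dict[str, Dict[str, float]] = {}
    for prot, terms in annotations.items():
        if prot not in rpkms:
            raise KeyError(f"annotation references unknown protein {prot!r}")
        for term in terms:
            entry = agg.setdefault(term, {"rpkm_sum": 0.0, "protein_count": 0})
            entry["rpkm_sum"] += rpkms[prot]
            entry["protein_count"] += 1
    for term, entry in agg.items():
        entry["rpkm_mean"] = (
            entry["rpkm_sum"] / entry["protein_count"]
            if entry["protein_count"]
            else 0.0
        )
    return agg
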