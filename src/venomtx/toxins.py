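"""Toxin-like protein discovery by three evidence channels.

1. homology — best hit against a known-toxin reference set;
2. domain — exact ordered domain-architecture match;
3. cys_pattern — cysteine-spacing skeleton match.

A cysteine pattern is the ordered list of inter-cysteine gaps (number of
non-Cys residues between consecutive cysteines).  In the rendered
dialect '#' stands for exactly three non-Cys residues and '.' for one,
so any gap length is representable; the canonical form is the gap list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

logger = logging.getLogger(__name__)

CATEGORIES = ("neurotoxin", "assistant", "protease", "protease_inhibitor", "unknown")

#: Fixed family -> functional category map.  Neurotoxins act on the
#: nervous system directly; assistant toxins enhance them; proteases
#: digest; TY-domain protease inhibitors protect; the rest are unknown.
FAMILY_CATEGORY: Dict[str, str] = {
    "ANK": "neurotoxin",
    "SCP": "neurotoxin",
    "lycotoxin": "neurotoxin",
    "theriditoxin": "assistant",
    "trypsin": "protease",
    "ctenitoxin": "protease_inhibitor",
    "scorpion_toxin_like": "unknown",
    "orphan": "unknown",
}


@dataclass(frozen=True)
class CysteinePattern:
    """Ordered inter-cysteine spacings; k gaps describe k+1 cysteines."""

    id: str
    gaps: Tuple[int, ...]
    source_toxin_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gaps):
            raise ValueError(f"pattern {self.id!r}: negative gap")

    @property
    def is_empty(self) -> bool:
        return len(self.gaps) == 0

    @property
    def n_cysteines(self) -> int:
        return 0 if self.is_empty else len(self.gaps) + 1


def extract_cys_pattern(aa_sequence: str, pattern_id: str = "") -> CysteinePattern:
    """Gap list between consecutive cysteines of a protein.

    Residues before the first and after the last cysteine are ignored.
    Sequences with fewer than two cysteines yield the empty-pattern
    sentinel (no gaps).
    """
    if not aa_sequence:
        raise ValueError("empty sequence")
    positions = [i for i, ch in enumerate(aa_sequence) if ch == "C"]
    if len(positions) < 2:
        return CysteinePattern(pattern_id, ())
    gaps = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)
    )
    return CysteinePattern(pattern_id, gaps)


def render_pattern(pattern: CysteinePattern) -> str:
    """Render as the '#' dialect: '#' = three non-Cys, '.' = one."""
    if pattern.is_empty:
        return ""
    parts = ["C"]
    for gap in pattern.gaps:
        parts.append("#" * (gap // 3) + "." * (gap % 3))
        parts.append("C")
    return "".join(parts)


def parse_pattern(text: str, pattern_id: str = "") -> CysteinePattern:
    """Inverse of render_pattern ('#' counts 3, any other non-C char 1)."""
    if not text:
        return CysteinePattern(pattern_id, ())
    segments = text.split("C")
    if len(segments) < 3 and text.count("C") < 2:
        return CysteinePattern(pattern_id, ())
    inner = segments[1:-1]
    gaps = tuple(
        sum(3 if ch == "#" else 1 for ch in seg) for seg in inner
    )
    return CysteinePattern(pattern_id, gaps)


def match_pattern(
    candidate_aa: str, pattern: CysteinePattern, tolerance: int = 0
) -> List[int]:
    """Residue offsets (position of the anchoring cysteine) at which the
    candidate's cysteine-gap subsequence equals the pattern's gaps with
    each gap differing by at most ``tolerance``."""
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    if pattern.is_empty:
        logger.warning("match_pattern called with empty-pattern sentinel")
        return []
    positions = [i for i, ch in enumerate(candidate_aa) if ch == "C"]
    if len(positions) < pattern.n_cysteines:
        return []
    cand_gaps = [
        positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)
    ]
    k = len(pattern.gaps)
    matches = []
    for j in range(len(cand_gaps) - k + 1):
        if all(
            abs(cand_gaps[j + t] - pattern.gaps[t]) <= tolerance
            for t in range(k)
        ):
            matches.append(positions[j])
    return matches


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered domain annotation of one protein."""

    protein_id: str
    domains: Tuple[Tuple[str, int, int], ...]  # (domain_id, start, end)

    @property
    def domain_ids(self) -> Tuple[str, ...]:
        return tuple(d[0] for d in self.domains)


def load_domain_table(rows: Iterable[Sequence]) -> Dict[str, DomainArchitecture]:
    """Build architectures from (protein_id, domain_id, start, end[, score])
    rows; overlapping intervals are resolved by keeping the higher-score
    (or first-listed) interval."""
    by_protein: Dict[str, List[Tuple[str, int, int, float, int]]] = {}
    for i, row in enumerate(rows):
        pid, dom = str(row[0]), str(row[1])
        start, end = int(row[2]), int(row[3])
        score = float(row[4]) if len(row) > 4 else 0.0
        by_protein.setdefault(pid, []).append((dom, start, end, score, i))
    out = {}
    for pid, items in by_protein.items():
        # higher score wins overlaps; earlier row wins ties
        items.sort(key=lambda t: (-t[3], t[4]))
        kept: List[Tuple[str, int, int]] = []
        for dom, start, end, _score, _i in items:
            if any(start < e and end > s for _d, s, e in kept):
                continue
            kept.append((dom, start, end))
        kept.sort(key=lambda t: t[1])
        out[pid] = DomainArchitecture(pid, tuple(kept))
    return out


def split_annotation(arch: DomainArchitecture, gap_threshold: int = 50) -> str:
    """Run-length annotation of domain repeats: consecutive domains with a
    gap of at least ``gap_threshold`` residues between them are split,
    e.g. 20 domains with one large gap after the 14th -> '14+6'."""
    if not arch.domains:
        return ""
    runs = [1]
    for (d_prev, s_prev, e_prev), (d, s, e) in zip(arch.domains, arch.domains[1:]):
        if s - e_prev >= gap_threshold:
            runs.append(1)
        else:
            runs[-1] += 1
    return "+".join(str(r) for r in runs)


@dataclass(frozen=True)
class ArchitectureMatch:
    reference_id: str
    family: str
    split: str


def match_domain_architecture(
    candidate: DomainArchitecture,
    references: Mapping[str, Sequence[str]],
    reference_families: Optional[Mapping[str, str]] = None,
    gap_threshold: int = 50,
) -> Optional[ArchitectureMatch]:
    """Exact ordered domain-ID equality against a reference architecture
    set {reference_id: [domain ids...]}; returns the first match in
    sorted reference order, with the candidate's split annotation."""
    if not references:
        raise ValueError("reference architecture set is empty")
    ids = candidate.domain_ids
    for ref_id in sorted(references):
        if tuple(references[ref_id]) == ids:
            family = (
                reference_families.get(ref_id, ref_id)
                if reference_families
                else ref_id
            )
            return ArchitectureMatch(
                reference_id=ref_id,
                family=family,
                split=split_annotation(candidate, gap_threshold),
            )
    return None


@dataclass
class ToxinCall:
    protein_id: str
    evidence: Set[str]
    family: str
    category: str
    rpkm: Optional[float] = None
    pattern_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("toxin call with no evidence channel")


def call_toxins(
    proteins: Mapping[str, str],
    toxin_hits: Optional[Mapping[str, str]] = None,
    hit_families: Optional[Mapping[str, str]] = None,
    architectures: Optional[Mapping[str, DomainArchitecture]] = None,
    reference_architectures: Optional[Mapping[str, Sequence[str]]] = None,
    reference_families: Optional[Mapping[str, str]] = None,
    patterns: Optional[Sequence[CysteinePattern]] = None,
    family_category: Optional[Mapping[str, str]] = None,
    rpkms: Optional[Mapping[str, float]] = None,
    tolerance: int = 0,
) -> List[ToxinCall]:
    """Union of the three discovery strategies over ``proteins``
    ({protein_id: aa sequence}).

    ``toxin_hits`` maps protein_id -> best known-toxin prey id (homology
    channel) and ``hit_families`` maps prey id -> family.  Family is
    taken from homology first, then architecture, else 'orphan'; the
    functional category comes from the family map.
    """
    if not (toxin_hits or (architectures and reference_architectures) or patterns):
        raise ValueError("at least one evidence source must be supplied")
    fam_cat = dict(FAMILY_CATEGORY)
    if family_category:
        fam_cat.update(family_category)

    calls: Dict[str, ToxinCall] = {}

    def ensure(pid: str) -> ToxinCall:
        if pid not in calls:
            calls[pid] = ToxinCall(pid, evidence={"_pending"}, family="orphan",
                                   category="unknown")
            calls[pid].evidence.clear()
        return calls[pid]

    for pid in sorted(proteins):
        if toxin_hits and pid in toxin_hits:
            call = ensure(pid)
            call.evidence.add("homology")
            prey = toxin_hits[pid]
            if hit_families and prey in hit_families:
                call.family = hit_families[prey]
            else:
                call.family = prey
        if architectures and reference_architectures and pid in architectures:
            m = match_domain_architecture(
                architectures[pid], reference_architectures, reference_families
            )
            if m is not None:
                call = ensure(pid)
                call.evidence.add("domain")
                if call.family == "orphan":
                    call.family = m.family
        if patterns:
            hit_ids = []
            for pat in patterns:
                if pat.is_empty:
                    continue
                if match_pattern(proteins[pid], pat, tolerance=tolerance):
                    hit_ids.append(pat.id)
            if hit_ids:
                call = ensure(pid)
                call.evidence.add("cys_pattern")
                call.pattern_ids = tuple(hit_ids)

    out = []
    for pid in sorted(calls):
        call = calls[pid]
        if call.family not in fam_cat:
            logger.warning(
                "family %r not in category map; category set to unknown",
                call.family,
            )
            call.category = "unknown"
        else:
            call.category = fam_cat[call.family]
        if rpkms is not None:
            call.rpkm = rpkms.get(pid)
        out.append(call)
    return out


def category_rpkm_sums(calls: Iterable[ToxinCall]) -> Dict[str, float]:
    """Per-category sums of RPKM over toxin calls (calls without an RPKM
    contribute nothing)."""
    sums = {cat: 0.0 for cat in CATEGORIES}
    for call in calls:
        if call.rpkm is not None:
            sums[call.category] += call.rpkm
    return sums
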