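"""Homology-hit quality metrics, tiered confidence filters, best-candidate
selection, redundancy merging and reference (EST) QC.

Metric vocabulary: for one bait-vs-prey hit, ML is the matched-region
length, BL the bait length, PL the prey length; the ratios ML/BL and
ML/PL proxy assembly accuracy and sequence integrity, and identity is
the percent identity over aligned columns.  All tier thresholds are
strict inequalities.

A minimal internal Smith-Waterman search (seed-and-extend over shared
k-mers, match +1 / mismatch -1 / gap -2) is provided so the pipeline and
tests run without an external BLAST binary; the tabular reader is the
production path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .orfs import ProteinCandidate

DEFAULT_E_CUT = 1e-5


@dataclass(frozen=True)
class HomologyHit:
    """One bait-vs-prey match; the unit of all QC filtering."""

    bait_id: str
    prey_id: str
    ml: int  # aligned-region length (columns)
    bl: int  # bait length
    pl: int  # prey length
    identity: float  # percent in [0, 100]
    evalue: float

    def __post_init__(self) -> None:
        if self.bl <= 0 or self.pl <= 0:
            raise ValueError(
                f"hit {self.bait_id}->{self.prey_id}: nonpositive length "
                f"(BL={self.bl}, PL={self.pl})"
            )
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(
                f"hit {self.bait_id}->{self.prey_id}: identity "
                f"{self.identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be nonnegative")

    @property
    def ml_bl(self) -> float:
        # local alignments with gaps can exceed BL in the tabular
        # "length" column; ratios are capped at 1.0
        return min(self.ml / self.bl, 1.0)

    @property
    def ml_pl(self) -> float:
        return min(self.ml / self.pl, 1.0)


@dataclass(frozen=True)
class ConfidenceTier:
    """Minimum (ML/BL, ML/PL, identity%) thresholds, strict."""

    name: str
    min_ml_bl: float
    min_ml_pl: Optional[float]
    min_identity: float


TIERS: Dict[str, ConfidenceTier] = {
    "core": ConfidenceTier("core", 0.5, 0.5, 30.0),
    "high": ConfidenceTier("high", 0.8, 0.8, 50.0),
    "full_length_unique": ConfidenceTier("full_length_unique", 0.5, 0.5, 80.0),
    # EST strict match: >80% bait-side coverage and >95% identity
    "est_match_strict": ConfidenceTier("est_match_strict", 0.8, None, 95.0),
}


def compute_hit_metrics(
    row: Sequence[str], bait_len: int, prey_len: int
) -> HomologyHit:
    """Build a HomologyHit from one BLAST tabular (12-column) row.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.
    """
    if bait_len <= 0 or prey_len <= 0:
        raise ValueError("bait/prey length must be positive")
    return HomologyHit(
        bait_id=row[0],
        prey_id=row[1],
        ml=int(row[3]),
        bl=bait_len,
        pl=prey_len,
        identity=float(row[2]),
        evalue=float(row[10]),
    )


def read_blast_tab(
    path,
    bait_lengths: Mapping[str, int],
    prey_lengths: Mapping[str, int],
) -> List[HomologyHit]:
    """Read a 12-column BLAST tabular file into HomologyHits."""
    hits: List[HomologyHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            row = line.split("\t")
            bait, prey = row[0], row[1]
            if bait not in bait_lengths:
                raise KeyError(f"unknown bait id {bait!r} in {path}")
            if prey not in prey_lengths:
                raise KeyError(f"unknown prey id {prey!r} in {path}")
            hits.append(
                compute_hit_metrics(row, bait_lengths[bait], prey_lengths[prey])
            )
    return hits


def classify(hit: HomologyHit, tier: ConfidenceTier) -> bool:
    """True iff the hit strictly exceeds every threshold of the tier."""
    if hit.ml_bl <= tier.min_ml_bl:
        return False
    if tier.min_ml_pl is not None and hit.ml_pl <= tier.min_ml_pl:
        return False
    return hit.identity > tier.min_identity


def _hit_rank(hit: HomologyHit) -> Tuple[float, float, int, str]:
    # best = lowest e-value, ties by highest identity, then longest ML,
    # then lexicographic prey id for determinism
    return (hit.evalue, -hit.identity, -hit.ml, hit.prey_id)


def best_hits(hits: Iterable[HomologyHit]) -> Dict[str, HomologyHit]:
    """Best hit per bait id."""
    best: Dict[str, HomologyHit] = {}
    for hit in hits:
        cur = best.get(hit.bait_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.bait_id] = hit
    return best


def select_best_candidate(
    candidates: Sequence[ProteinCandidate],
    hits: Iterable[HomologyHit],
    e_cut: float = DEFAULT_E_CUT,
) -> ProteinCandidate:
    """Pick one translation product for a transcript.

    The longest candidate with any homologue below ``e_cut`` wins; if no
    candidate has such a hit, the longest overall is taken.  Ties are
    broken by full-length over fragment, then lexicographic candidate id.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    with_hit = {h.bait_id for h in hits if h.evalue < e_cut}

    def key(c: ProteinCandidate):
        return (len(c), c.is_full_length, _reverse_lex(c.candidate_id))

    homologous = [c for c in candidates if c.candidate_id in with_hit]
    pool = homologous if homologous else list(candidates)
    return max(pool, key=key)


class _reverse_lex(str):
    # makes max() prefer the lexicographically *smaller* string
    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


@dataclass
class CoreRecord:
    """One entry of the merged core dataset."""

    protein_id: str
    candidate: ProteinCandidate
    prey_id: Optional[str]
    members: int = 1
    n_full_length: int = 0
    n_fragment: int = 0

    @property
    def aa_sequence(self) -> str:
        return self.candidate.aa_sequence


def merge_redundant(
    selected: Sequence[Tuple[ProteinCandidate, Optional[str]]],
) -> List[CoreRecord]:
    """Collapse proteins sharing a best-matching prey to one representative.

    The representative is the longest member (ties: full-length
    preferred, then lexicographic candidate id); proteins without hits
    pass through unmerged.  Idempotent and order-independent.
    """
    groups: Dict[str, List[ProteinCandidate]] = {}
    orphans: List[ProteinCandidate] = []
    for cand, prey in selected:
        if prey is None:
            orphans.append(cand)
        else:
            groups.setdefault(prey, []).append(cand)

    def rep_key(c: ProteinCandidate):
        return (len(c), c.is_full_length, _reverse_lex(c.candidate_id))

    out: List[CoreRecord] = []
    for prey in sorted(groups):
        members = groups[prey]
        rep = max(members, key=rep_key)
        out.append(
            CoreRecord(
                protein_id=rep.transcript_id,
                candidate=rep,
                prey_id=prey,
                members=len(members),
                n_full_length=sum(1 for m in members if m.is_full_length),
                n_fragment=sum(1 for m in members if not m.is_full_length),
            )
        )
    for cand in sorted(orphans, key=lambda c: c.candidate_id):
        out.append(
            CoreRecord(
                protein_id=cand.transcript_id,
                candidate=cand,
                prey_id=None,
                members=1,
                n_full_length=int(cand.is_full_length),
                n_fragment=int(not cand.is_full_length),
            )
        )
    return out


def floor_percent(numerator: int, denominator: int) -> int:
    """Integer percent, floored (961/1015 -> 94)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (100 * numerator) // denominator


@dataclass
class QCReport:
    n_baits: int
    matched: int
    matched_percent: int
    strict: int
    strict_percent: int
    shorter_than_prey: int
    longer_than_prey: int
    equal_length: int
    reversed_matched: Optional[int] = None


def qc_against_reference(
    best_est_hits: Mapping[str, HomologyHit],
    n_baits: int,
    e_cut: float = DEFAULT_E_CUT,
    reversed_hits: Optional[Mapping[str, HomologyHit]] = None,
) -> QCReport:
    """EST-vs-assembly quality report.

    ``best_est_hits`` maps each EST bait with at least one hit to its
    best hit.  Matched = e-value below ``e_cut``; strict additionally
    requires bait-side coverage (ML/BL) > 0.8 and identity > 95.  Length
    comparison is restricted to pairs with both ML/BL and ML/PL > 0.5.
    """
    if n_baits <= 0:
        raise ValueError("empty EST set")
    matched = [h for h in best_est_hits.values() if h.evalue < e_cut]
    strict = [h for h in matched if h.ml_bl > 0.8 and h.identity > 95.0]
    comparable = [h for h in matched if h.ml_bl > 0.5 and h.ml_pl > 0.5]
    shorter = sum(1 for h in comparable if h.bl < h.pl)
    longer = sum(1 for h in comparable if h.bl > h.pl)
    equal = len(comparable) - shorter - longer
    reversed_matched = None
    if reversed_hits is not None:
        reversed_matched = sum(
            1 for h in reversed_hits.values() if h.evalue < e_cut
        )
    return QCReport(
        n_baits=n_baits,
        matched=len(matched),
        matched_percent=floor_percent(len(matched), n_baits),
        strict=len(strict),
        strict_percent=floor_percent(len(strict), len(matched)) if matched else 0,
        shorter_than_prey=shorter,
        longer_than_prey=longer,
        equal_length=equal,
        reversed_matched=reversed_matched,
    )


# ---------------------------------------------------------------------------
# Internal fallback aligner (no external BLAST needed for tests/pipeline)
# ---------------------------------------------------------------------------

_PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"


def _make_aligner() -> Align.PairwiseAligner:
    n = len(_PROTEIN_ALPHABET)
    mat = substitution_matrices.Array(_PROTEIN_ALPHABET, dims=2)
    for i, a in enumerate(_PROTEIN_ALPHABET):
        for j, b in enumerate(_PROTEIN_ALPHABET):
            if a == b and a not in "X*":
                mat[a, b] = 1.0
            else:
                # X never matches anything, including X
                mat[a, b] = -1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _make_aligner()


def local_align(
    bait_id: str, bait_seq: str, prey_id: str, prey_seq: str
) -> Optional[HomologyHit]:
    """Smith-Waterman alignment of two protein sequences.

    The e-value surrogate is ``m * n * 2^-score`` (a bit-score style
    threshold, not Karlin-Altschul statistics).
    """
    try:
        aln = _ALIGNER.align(bait_seq, prey_seq)[0]
    except (IndexError, ValueError):
        return None
    score = aln.score
    if score <= 0:
        return None
    # alignment length incl. gaps, and identities over aligned columns
    qa, sa = aln[0], aln[1]
    ml = len(qa)
    ident = sum(
        1 for a, b in zip(qa, sa) if a == b and a not in "-X*"
    )
    evalue = len(bait_seq) * len(prey_seq) * math.pow(2.0, -score)
    return HomologyHit(
        bait_id=bait_id,
        prey_id=prey_id,
        ml=ml,
        bl=len(bait_seq),
        pl=len(prey_seq),
        identity=100.0 * ident / ml,
        evalue=evalue,
    )


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search(
    baits: Mapping[str, str],
    preys: Mapping[str, str],
    k: int = 8,
    e_max: float = 10.0,
) -> List[HomologyHit]:
    """All-vs-all protein search: shared-k-mer prefilter, then SW.

    Pairs sharing no exact k-mer are skipped, which keeps the quadratic
    search tractable for the synthetic datasets the pipeline handles.
    """
    index: Dict[str, List[str]] = {}
    for pid, pseq in preys.items():
        for kmer in _kmer_set(pseq, k):
            index.setdefault(kmer, []).append(pid)
    hits: List[HomologyHit] = []
    for bid, bseq in baits.items():
        candidates = set()
        for kmer in _kmer_set(bseq, k):
            candidates.update(index.get(kmer, ()))
        for pid in sorted(candidates):
            hit = local_align(bid, bseq, pid, preys[pid])
            if hit is not None and hit.evalue <= e_max:
                hits.append(hit)
    return hits
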