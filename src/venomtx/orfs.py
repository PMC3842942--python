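"""Six-frame ORF enumeration and full-length / fragment classification.

An ORF starts at an ATG and runs to the first in-frame stop codon
(full-length) or to the end of the sequence (fragment).  All ATG starts
are emitted, including nested ones; deduplication happens at the
candidate-pool level.  Coordinates are 0-based half-open on the forward
strand of the input transcript; the stop codon is included in the
nucleotide span but not in the amino-acid sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping

logger = logging.getLogger(__name__)

VALID_NT = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code, nuclear.
CODON_TABLE: Dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing N yields 'X'."""
    if "N" in codon:
        return "X"
    return CODON_TABLE[codon]


@dataclass(frozen=True)
class Transcript:
    """An assembled cDNA sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")


@dataclass(frozen=True)
class ProteinCandidate:
    """A translated ORF.

    ``nt_start``/``nt_end`` are 0-based half-open on the forward strand
    of the source transcript.  ``is_full_length`` is True when the ORF
    terminates at a stop codon (the stop is inside the nt span).
    """

    transcript_id: str
    frame: int
    strand: str
    aa_sequence: str
    nt_start: int
    nt_end: int
    is_full_length: bool

    @property
    def candidate_id(self) -> str:
        tag = "F" if self.is_full_length else "Frag"
        return (
            f"{self.transcript_id}|{self.strand}|{self.frame}"
            f"|{self.nt_start}-{self.nt_end}|{tag}"
        )

    def __len__(self) -> int:
        return len(self.aa_sequence)


def _validate_sequence(transcript: Transcript) -> None:
    for pos, ch in enumerate(transcript.sequence):
        if ch not in VALID_NT:
            raise ValueError(
                f"transcript {transcript.id!r}: invalid character "
                f"{ch!r} at position {pos}"
            )


def six_frame_orfs(
    transcript: Transcript, min_len_aa: int = 40
) -> List[ProteinCandidate]:
    """Enumerate every ATG-initiated ORF on both strands.

    Returns all candidates of at least ``min_len_aa`` residues,
    full-length (reaching an in-frame stop) or fragment (running off the
    sequence end).  Trailing partial codons are not part of the span.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    _validate_sequence(transcript)
    seq = transcript.sequence.upper()
    n = len(seq)
    out: List[ProteinCandidate] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for start in range(n - 2):
            if s[start : start + 3] != "ATG":
                continue
            aa_chars: List[str] = []
            pos = start
            full = False
            while pos + 3 <= n:
                codon = s[pos : pos + 3]
                if "N" not in codon and codon in STOP_CODONS:
                    full = True
                    pos += 3
                    break
                aa_chars.append(translate_codon(codon))
                pos += 3
            if len(aa_chars) < min_len_aa:
                continue
            end = pos  # includes stop codon when full-length
            if strand == "+":
                nt_start, nt_end = start, end
            else:
                nt_start, nt_end = n - end, n - start
            out.append(
                ProteinCandidate(
                    transcript_id=transcript.id,
                    frame=start % 3,
                    strand=strand,
                    aa_sequence="".join(aa_chars),
                    nt_start=nt_start,
                    nt_end=nt_end,
                    is_full_length=full,
                )
            )
    return out


def translate_set(
    transcripts: Iterable[Transcript], min_len_aa: int = 40
) -> Dict[str, List[ProteinCandidate]]:
    """Translate a transcript set into a per-transcript candidate pool.

    Candidates with identical amino-acid sequences within one transcript
    are deduplicated, keeping the longest nucleotide span (ties broken
    by candidate id for determinism).
    """
    pool: Dict[str, List[ProteinCandidate]] = {}
    seen_ids = set()
    empty = True
    for tx in transcripts:
        empty = False
        if tx.id in seen_ids:
            raise ValueError(f"duplicate transcript id {tx.id!r}")
        seen_ids.add(tx.id)
        candidates = six_frame_orfs(tx, min_len_aa=min_len_aa)
        best: Dict[str, ProteinCandidate] = {}
        for cand in candidates:
            prev = best.get(cand.aa_sequence)
            if prev is None:
                best[cand.aa_sequence] = cand
                continue
            key_new = (cand.nt_end - cand.nt_start, cand.candidate_id)
            key_old = (prev.nt_end - prev.nt_start, prev.candidate_id)
            if (key_new[0], key_new[1]) > (key_old[0], key_old[1]):
                best[cand.aa_sequence] = cand
        pool[tx.id] = sorted(best.values(), key=lambda c: c.candidate_id)
    if empty:
        logger.warning("translate_set called on empty transcript input")
    return pool
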