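"""Plain-text readers and writers for the formats the pipeline exchanges.

FASTA is read through Biopython; writing is done directly (60-column
wrap) so outputs are byte-stable across library versions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from Bio import SeqIO

from .orfs import ProteinCandidate, Transcript


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def read_transcripts(path: str | Path) -> List[Transcript]:
    return [Transcript(i, s) for i, s in read_fasta(path).items()]


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_candidates(
    fasta_path: str | Path,
    manifest_path: str | Path,
    pool: Mapping[str, Sequence[ProteinCandidate]],
) -> None:
    """Write a candidate pool as FASTA (structured headers) + TSV manifest."""
    records = {}
    rows = []
    for tid in pool:
        for cand in pool[tid]:
            records[cand.candidate_id] = cand.aa_sequence
            rows.append(
                (
                    cand.candidate_id,
                    cand.transcript_id,
                    cand.strand,
                    str(cand.frame),
                    str(cand.nt_start),
                    str(cand.nt_end),
                    "F" if cand.is_full_length else "Frag",
                    str(len(cand)),
                )
            )
    write_fasta(fasta_path, records)
    header = (
        "candidate_id\ttranscript_id\tstrand\tframe\tnt_start\tnt_end"
        "\tstatus\taa_len"
    )
    write_tsv(manifest_path, header, rows)


def read_candidates(manifest_path: str | Path, fasta_path: str | Path) -> Dict[str, List[ProteinCandidate]]:
    seqs = read_fasta(fasta_path)
    pool: Dict[str, List[ProteinCandidate]] = {}
    with open(manifest_path) as fh:
        header = fh.readline()
        for line in fh:
            cid, tid, strand, frame, s, e, status, _ = line.rstrip("\n").split("\t")
            cand = ProteinCandidate(
                transcript_id=tid,
                frame=int(frame),
                strand=strand,
                aa_sequence=seqs[cid],
                nt_start=int(s),
                nt_end=int(e),
                is_full_length=(status == "F"),
            )
            pool.setdefault(tid, []).append(cand)
    return pool


def write_tsv(path: str | Path, header: str, rows: Iterable[Tuple[str, ...]]) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_counts_tsv(path: str | Path) -> Dict[str, int]:
    """Per-transcript read-count table (transcript_id, count)."""
    counts: Dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            tid, c = line.rstrip("\n").split("\t")[:2]
            counts[tid] = int(c)
    return counts


def read_two_column_map(path: str | Path) -> Dict[str, List[str]]:
    """Membership map TSV (key, value) -> {key: [values...]}, header optional."""
    out: Dict[str, List[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if i == 0 and parts[1] in {"term_id", "pathway_id", "term"}:
                continue
            out.setdefault(parts[0], []).append(parts[1])
    return out
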