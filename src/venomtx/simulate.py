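"""Synthetic transcriptomes, reference databases, domain tables, pathway
maps and reads with known ground truth.

Every transcript carries exactly one planted principal ORF (ATG ... stop,
or ATG ... sequence-end for planted fragments) on a recorded strand.
Reference "known" proteins are the planted translations mutated at a
per-site divergence rate; toxin genes embed a cysteine-spacing scaffold
and a domain architecture.  Reads are drawn multinomially over
transcripts by abundance-weight x length with uniform start positions.

Flanking sequence outside the planted ORF is i.i.d. uniform over ACGT
but rejected where it would introduce an ATG on either strand, so the
planted ORF is the unique long translation product of its transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .orfs import CODON_TABLE, revcomp
from .toxins import FAMILY_CATEGORY

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_CYS = AA_ALPHABET.replace("C", "")

CODONS_BY_AA: Dict[str, List[str]] = {}
for codon, aa in CODON_TABLE.items():
    if aa != "*":
        CODONS_BY_AA.setdefault(aa, []).append(codon)
for _codons in CODONS_BY_AA.values():
    _codons.sort()
STOPS = ("TAA", "TAG", "TGA")

#: family -> reference domain architecture planted for toxin genes
TOXIN_ARCHITECTURES: Dict[str, Tuple[str, ...]] = {
    "ctenitoxin": ("TY", "TY"),
    "ANK": ("ANK", "ANK", "ANK", "ANK", "ANK", "ANK"),
    "trypsin": ("Tryp_SPc",),
    "SCP": ("SCP",),
    "lycotoxin": ("Toxin_35",),
    "theriditoxin": ("LMWP",),
    "scorpion_toxin_like": ("Knot1",),
}
TOXIN_FAMILIES = tuple(TOXIN_ARCHITECTURES)

# fixed offsets deriving independent RNG streams from one seed
_STREAM_TRANSCRIPTOME = 0
_STREAM_DIVERGENCE = 104729
_STREAM_READS = 1299709
_STREAM_PATHWAYS = 15485863


@dataclass
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 50
    length_range: Tuple[int, int] = (450, 900)
    n_toxin_genes: int = 8
    toxin_scaffolds: Tuple[Tuple[int, ...], ...] = (
        (3, 3, 6, 3),
        (6, 3, 3, 3, 6),
        (3, 10, 3, 3, 3),
    )
    divergence: float = 0.1
    mutate_cys: bool = False
    abundance_law: float = 1.5
    read_length: int = 50
    n_reads: int = 20000
    error_rate: float = 0.0
    fragment_fraction: float = 0.2
    n_pathways: int = 12
    #: when True, the extra term PW_ENRICHED is attached to the most
    #: abundant transcripts so a truly enriched pathway exists
    enriched_pathway: bool = True

    def validate(self) -> None:
        lo, hi = self.length_range
        if lo < 150:
            raise ValueError(
                f"length_range minimum {lo} < 150 bp: cannot host a >=40 aa ORF"
            )
        if hi < lo:
            raise ValueError("length_range max < min")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_toxin_genes > self.n_transcripts:
            raise ValueError("n_toxin_genes exceeds n_transcripts")
        if not self.toxin_scaffolds and self.n_toxin_genes:
            raise ValueError("toxin genes requested but no scaffolds given")
        if self.read_length < 1 or self.n_reads < 0:
            raise ValueError("invalid read parameters")


@dataclass
class GroundTruth:
    """Planted truth for one simulated run.

    ``orfs`` maps transcript id -> (nt_start, nt_end, strand) with
    0-based half-open coordinates on the forward strand; ``weights``
    are normalized abundance weights; ``toxins`` maps toxin transcript
    ids to (scaffold_id, family); ``pathways`` maps transcript ids to
    their term memberships; ``proteins`` holds the planted translations.
    """

    weights: Dict[str, float]
    orfs: Dict[str, Tuple[int, int, str]]
    toxins: Dict[str, Tuple[str, str]]
    pathways: Dict[str, List[str]]
    proteins: Dict[str, str]
    full_length: Dict[str, bool]


def _random_protein(rng: np.random.Generator, length: int, cys_rate: float = 0.025) -> str:
    """Random protein starting with M; cysteines appear at ``cys_rate``."""
    chars = ["M"]
    for _ in range(length - 1):
        if rng.random() < cys_rate:
            chars.append("C")
        else:
            chars.append(AA_NO_CYS[rng.integers(len(AA_NO_CYS))])
    return "".join(chars)


def _embed_scaffold(
    rng: np.random.Generator, protein: str, gaps: Sequence[int]
) -> str:
    """Insert a cysteine skeleton (C, gap non-Cys residues, C, ...) into a
    cysteine-free protein body so the skeleton is literally present."""
    block_chars = ["C"]
    for gap in gaps:
        for _ in range(gap):
            block_chars.append(AA_NO_CYS[rng.integers(len(AA_NO_CYS))])
        block_chars.append("C")
    block = "".join(block_chars)
    body = "".join(ch for ch in protein if ch != "C")
    if len(body) < len(block) + 10:
        body = body + "".join(
            AA_NO_CYS[rng.integers(len(AA_NO_CYS))]
            for _ in range(len(block) + 10 - len(body))
        )
    pos = int(rng.integers(5, len(body) - len(block) - 4))
    return body[:pos] + block + body[pos + len(block):]


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        options = CODONS_BY_AA[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


_NT = "ACGT"


def _random_flank(rng: np.random.Generator, length: int) -> str:
    """Random nucleotides containing no ATG on either strand (no 'ATG'
    or 'CAT' substring)."""
    chars: List[str] = []
    while len(chars) < length:
        chars.append(_NT[rng.integers(4)])
        if len(chars) >= 3:
            tail = "".join(chars[-3:])
            if tail in ("ATG", "CAT"):
                chars.pop()
    return "".join(chars)


def _safe_flank_junctions(five: str, orf: str, three: str) -> Tuple[str, str]:
    """Adjust flank edges so no ATG (either strand) spans a junction.

    The ORF region starts with ATG, so the only forward start that can
    form across the 5' junction is the planted one; a reverse-strand
    start ('CAT' on the forward strand) forms there only when the flank
    ends with C.  Across the 3' junction (ORF region ends with a stop
    codon) a forward ATG forms only when the stop ends in A and the
    flank begins 'TG'.
    """
    if five.endswith("C"):
        five = five[:-1] + "A"
    if orf.endswith("A") and three.startswith("TG"):
        three = "C" + three[1:]
    return five, three


def generate_transcriptome(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], Dict[str, str], Dict[str, Tuple[str, str]], GroundTruth]:
    """Generate (transcripts, reference proteins, reference metadata,
    ground truth).

    Reference proteins are the planted translations mutated at the
    configured per-site divergence; reference metadata maps reference id
    -> (family, category) with empty strings for non-toxin references.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + _STREAM_TRANSCRIPTOME)
    div_rng = np.random.default_rng(config.seed + _STREAM_DIVERGENCE)
    path_rng = np.random.default_rng(config.seed + _STREAM_PATHWAYS)

    n = config.n_transcripts
    toxin_idx = set(
        rng.choice(n, size=config.n_toxin_genes, replace=False).tolist()
    )

    transcripts: Dict[str, str] = {}
    references: Dict[str, str] = {}
    ref_meta: Dict[str, Tuple[str, str]] = {}
    weights: Dict[str, float] = {}
    orf_coords: Dict[str, Tuple[int, int, str]] = {}
    toxins: Dict[str, Tuple[str, str]] = {}
    pathways: Dict[str, List[str]] = {}
    proteins: Dict[str, str] = {}
    full_length_flag: Dict[str, bool] = {}

    ranks = rng.permutation(n)
    raw_w = (ranks + 1.0) ** (-config.abundance_law)
    raw_w /= raw_w.sum()

    terms = [f"PW{i:03d}" for i in range(config.n_pathways)]

    for i in range(n):
        tid = f"T{i:05d}"
        lo, hi = config.length_range
        length = int(rng.integers(lo, hi + 1))
        is_toxin = i in toxin_idx
        is_fragment = rng.random() < config.fragment_fraction

        max_aa = (length - 6) // 3
        min_aa = max(40, int(0.6 * max_aa))
        aa_len = int(rng.integers(min_aa, max_aa + 1))
        protein = _random_protein(rng, aa_len)
        scaffold_id = ""
        family = ""
        if is_toxin:
            k = int(rng.integers(len(config.toxin_scaffolds)))
            gaps = config.toxin_scaffolds[k]
            scaffold_id = f"SC{k:02d}"
            protein = _embed_scaffold(rng, protein, gaps)
            family = TOXIN_FAMILIES[i % len(TOXIN_FAMILIES)]
            toxins[tid] = (scaffold_id, family)

        orf_nt = _back_translate(rng, protein)
        if is_fragment:
            # fragment: the ORF runs to the transcript end without a stop
            orf_region = orf_nt
            flank_total = max(length - len(orf_region), 0)
            five = _random_flank(rng, flank_total)
            five, _ = _safe_flank_junctions(five, orf_region, "")
            seq_fwd = five + orf_region
            start, end = len(five), len(five) + len(orf_region)
            full = False
        else:
            stop = STOPS[rng.integers(3)]
            orf_region = orf_nt + stop
            flank_total = max(length - len(orf_region), 0)
            cut = int(rng.integers(0, flank_total + 1)) if flank_total else 0
            five = _random_flank(rng, cut)
            three = _random_flank(rng, flank_total - cut)
            five, three = _safe_flank_junctions(five, orf_region, three)
            seq_fwd = five + orf_region + three
            start, end = len(five), len(five) + len(orf_region)
            full = True

        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            seq = seq_fwd
            coords = (start, end, "+")
        else:
            seq = revcomp(seq_fwd)
            coords = (len(seq) - end, len(seq) - start, "-")

        # mutate the planted protein into its "known" reference homologue
        ref_aa = _mutate_protein(
            div_rng, protein,
            divergence=config.divergence,
            protect_cys=is_toxin and not config.mutate_cys,
        )
        ref_id = f"REF_{tid}"
        references[ref_id] = ref_aa
        if is_toxin:
            ref_meta[ref_id] = (family, FAMILY_CATEGORY.get(family, "unknown"))
        else:
            ref_meta[ref_id] = ("", "")

        transcripts[tid] = seq
        weights[tid] = float(raw_w[i])
        orf_coords[tid] = coords
        proteins[tid] = protein
        full_length_flag[tid] = full
        n_terms = int(path_rng.integers(1, 3))
        chosen = path_rng.choice(config.n_pathways, size=n_terms, replace=False)
        pathways[tid] = [terms[j] for j in sorted(chosen.tolist())]

    total = sum(weights.values())
    weights = {tid: w / total for tid, w in weights.items()}
    if config.enriched_pathway:
        k = max(3, n // 8)
        top = sorted(weights, key=lambda t: (-weights[t], t))[:k]
        for tid in top:
            pathways[tid].append("PW_ENRICHED")
    gt = GroundTruth(
        weights=weights,
        orfs=orf_coords,
        toxins=toxins,
        pathways=pathways,
        proteins=proteins,
        full_length=full_length_flag,
    )
    return transcripts, references, ref_meta, gt


def _mutate_protein(
    rng: np.random.Generator,
    protein: str,
    divergence: float,
    protect_cys: bool,
) -> str:
    """Per-site substitution at rate ``divergence``; substituted residues
    always change.  With ``protect_cys`` cysteines are never touched and
    never introduced, so planted scaffolds survive divergence."""
    if divergence == 0.0:
        return protein
    alphabet = AA_NO_CYS if protect_cys else AA_ALPHABET
    chars = list(protein)
    for i, aa in enumerate(chars):
        if protect_cys and aa == "C":
            continue
        if rng.random() < divergence:
            choices = [a for a in alphabet if a != aa]
            chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def domain_tables(
    gt: GroundTruth,
) -> Tuple[List[Tuple[str, str, int, int]], Dict[str, Tuple[str, ...]]]:
    """Planted per-protein domain rows (protein_id, domain, start, end)
    for toxin transcripts, plus the reference architecture map
    {family: domain ids}."""
    rows: List[Tuple[str, str, int, int]] = []
    for tid in sorted(gt.toxins):
        _scaffold, family = gt.toxins[tid]
        arch = TOXIN_ARCHITECTURES[family]
        pos = 5
        for dom in arch:
            width = 30
            rows.append((tid, dom, pos, pos + width))
            pos += width + 5
    return rows, dict(TOXIN_ARCHITECTURES)


def generate_reads(
    transcripts: Mapping[str, str],
    gt: GroundTruth,
    config: SimulationConfig,
) -> Tuple[List[str], Dict[str, int]]:
    """Draw reads and return (SAM lines, per-transcript counts).

    Reads are multinomial over transcripts with probability proportional
    to abundance weight x transcript length; start positions are uniform;
    per-base substitution errors at ``error_rate``.  Counts sum to
    ``n_reads``.
    """
    rng = np.random.default_rng(config.seed + _STREAM_READS)
    tids = sorted(transcripts)
    rl = config.read_length
    for tid in tids:
        if rl > len(transcripts[tid]):
            raise ValueError(
                f"read_length {rl} exceeds length of transcript {tid!r} "
                f"({len(transcripts[tid])} bp)"
            )
    w = np.array([gt.weights[t] * len(transcripts[t]) for t in tids])
    if w.sum() <= 0:
        raise ValueError("degenerate abundance weights")
    p = w / w.sum()
    counts_arr = rng.multinomial(config.n_reads, p)
    counts = {tid: int(c) for tid, c in zip(tids, counts_arr)}

    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for tid in tids:
        lines.append(f"@SQ\tSN:{tid}\tLN:{len(transcripts[tid])}")
    qual = "I" * rl
    read_no = 0
    for tid in tids:
        seq = transcripts[tid]
        for _ in range(counts[tid]):
            start = int(rng.integers(0, len(seq) - rl + 1))
            read = list(seq[start : start + rl])
            if config.error_rate > 0:
                for j in range(rl):
                    if rng.random() < config.error_rate:
                        alt = [b for b in _NT if b != read[j]]
                        read[j] = alt[rng.integers(3)]
            lines.append(
                "\t".join(
                    (
                        f"R{read_no:07d}",
                        "0",
                        tid,
                        str(start + 1),
                        "255",
                        f"{rl}M",
                        "*",
                        "0",
                        "0",
                        "".join(read),
                        qual,
                    )
                )
            )
            read_no += 1
    return lines, counts


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_run(
    outdir: str | Path,
    config: SimulationConfig,
) -> Dict[str, Path]:
    """Generate a full synthetic run and write every artifact as text.

    Emits transcripts.fasta, references.fasta, reference_meta.tsv,
    domains.tsv, reference_architectures.tsv, pathways.tsv, reads.sam,
    counts.tsv, ground_truth.tsv and sim_config.txt; returns the paths.
    """
    from .io import write_fasta, write_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, references, ref_meta, gt = generate_transcriptome(config)
    sam_lines, counts = generate_reads(transcripts, gt, config)
    dom_rows, ref_arch = domain_tables(gt)

    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "references": outdir / "references.fasta",
        "reference_meta": outdir / "reference_meta.tsv",
        "domains": outdir / "domains.tsv",
        "reference_architectures": outdir / "reference_architectures.tsv",
        "pathways": outdir / "pathways.tsv",
        "sam": outdir / "reads.sam",
        "counts": outdir / "counts.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "config": outdir / "sim_config.txt",
    }
    write_fasta(paths["transcripts"], transcripts)
    write_fasta(paths["references"], references)
    write_tsv(
        paths["reference_meta"],
        "ref_id\tfamily\tcategory\tis_toxin",
        (
            (rid, fam, cat, "1" if fam else "0")
            for rid, (fam, cat) in sorted(ref_meta.items())
        ),
    )
    write_tsv(
        paths["domains"],
        "protein_id\tdomain_id\tstart\tend",
        ((pid, d, str(s), str(e)) for pid, d, s, e in dom_rows),
    )
    write_tsv(
        paths["reference_architectures"],
        "family\tdomains",
        ((fam, ",".join(doms)) for fam, doms in sorted(ref_arch.items())),
    )
    write_tsv(
        paths["pathways"],
        "protein_id\tterm_id",
        (
            (tid, term)
            for tid in sorted(gt.pathways)
            for term in gt.pathways[tid]
        ),
    )
    with open(paths["sam"], "w") as fh:
        fh.write("\n".join(sam_lines) + "\n")
    write_tsv(
        paths["counts"],
        "transcript_id\tcount",
        ((tid, str(counts[tid])) for tid in sorted(counts)),
    )
    write_tsv(
        paths["ground_truth"],
        "transcript_id\tweight\tnt_start\tnt_end\tstrand\tfull_length"
        "\tscaffold_id\tfamily\tprotein",
        (
            (
                tid,
                f"{gt.weights[tid]:.12g}",
                str(gt.orfs[tid][0]),
                str(gt.orfs[tid][1]),
                gt.orfs[tid][2],
                "1" if gt.full_length[tid] else "0",
                gt.toxins.get(tid, ("", ""))[0],
                gt.toxins.get(tid, ("", ""))[1],
                gt.proteins[tid],
            )
            for tid in sorted(gt.weights)
        ),
    )
    with open(paths["config"], "w") as fh:
        for key, value in sorted(vars(config).items()):
            fh.write(f"{key}={value}\n")
    return paths
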