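"""End-to-end orchestration: simulate (optional) -> translate -> homology
filter -> merge -> quantify -> toxin discovery -> enrichment -> report.

Every stage writes a standalone text artifact into the output directory,
and the final report is a deterministic JSON document (no timestamps),
so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import enrichment as enrich_mod
from . import homology, io, orfs, quantify, simulate, toxins

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "venomtx_out"
    seed: int = 0
    # inputs (any may be produced by the simulate stage instead)
    transcripts: Optional[str] = None
    references: Optional[str] = None
    reference_meta: Optional[str] = None
    blast_tab: Optional[str] = None
    sam: Optional[str] = None
    counts: Optional[str] = None
    domains: Optional[str] = None
    reference_architectures: Optional[str] = None
    pathways: Optional[str] = None
    # thresholds (defaults are the pipeline's canonical values)
    min_len_aa: int = 40
    e_cut: float = 1e-5
    enrichment_cutoff: float = 0.05
    pattern_tolerance: int = 0
    sample_top_fraction: float = 0.25
    domain_gap_threshold: int = 50
    # simulate stage
    simulate: bool = False
    sim: Optional[simulate.SimulationConfig] = None

    def validate(self) -> None:
        if not self.simulate and self.transcripts is None:
            raise ValueError("either simulate=True or a transcripts FASTA is required")
        if not 0 < self.sample_top_fraction <= 1:
            raise ValueError("sample_top_fraction must be in (0, 1]")
        if self.min_len_aa < 1:
            raise ValueError("min_len_aa must be >= 1")
        for name in ("transcripts", "references", "blast_tab", "sam",
                     "counts", "domains", "reference_architectures",
                     "pathways", "reference_meta"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ValueError(f"input file for {name!r} not found: {value}")


def summarize_counts(
    transcript_lengths: Sequence[int],
    read_count: Optional[int] = None,
    read_length: Optional[int] = None,
    tier_counts: Optional[Mapping[str, int]] = None,
) -> Dict[str, object]:
    """Run-statistics block: transcript totals, mean length, long-transcript
    count, and total sequenced bases = read count x average read length."""
    n = len(transcript_lengths)
    out: Dict[str, object] = {
        "n_transcripts": n,
        "mean_transcript_length": (sum(transcript_lengths) / n) if n else 0.0,
        "n_transcripts_gt_2000bp": sum(1 for L in transcript_lengths if L > 2000),
    }
    if read_count is not None and read_length is not None:
        out["total_read_count"] = read_count
        out["read_length"] = read_length
        out["total_bases"] = read_count * read_length
    if tier_counts is not None:
        out["tier_counts"] = dict(tier_counts)
    return out


def _read_architecture_tsv(path) -> Dict[str, Tuple[str, ...]]:
    out: Dict[str, Tuple[str, ...]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            fam, doms = line.rstrip("\n").split("\t")[:2]
            out[fam] = tuple(doms.split(","))
    return out


def _read_domain_tsv(path) -> List[Tuple[str, str, int, int]]:
    rows = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[0], parts[1], int(parts[2]), int(parts[3])))
    return rows


def _read_reference_meta(path) -> Dict[str, Tuple[str, str]]:
    out = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = (parts[1], parts[2])
    return out


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full flow and return the run report (also written to
    ``<outdir>/report.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {"seed": config.seed, "stages": {}}
    stages: Dict[str, object] = report["stages"]

    # ---- simulate -------------------------------------------------------
    if config.simulate:
        t0 = time.perf_counter()
        sim_cfg = config.sim or simulate.SimulationConfig(seed=config.seed)
        sim_paths = simulate.write_run(outdir / "sim", sim_cfg)
        config.transcripts = str(sim_paths["transcripts"])
        config.references = str(sim_paths["references"])
        config.reference_meta = str(sim_paths["reference_meta"])
        config.sam = str(sim_paths["sam"])
        config.counts = str(sim_paths["counts"])
        config.domains = str(sim_paths["domains"])
        config.reference_architectures = str(sim_paths["reference_architectures"])
        config.pathways = str(sim_paths["pathways"])
        logger.info("simulate: wrote %d artifacts in %.2fs",
                    len(sim_paths), time.perf_counter() - t0)
        stages["simulate"] = {"n_transcripts": sim_cfg.n_transcripts,
                              "n_reads": sim_cfg.n_reads}

    # ---- translate ------------------------------------------------------
    t0 = time.perf_counter()
    transcripts = io.read_transcripts(config.transcripts)
    if not transcripts:
        raise PipelineError("translate", f"empty transcript FASTA: {config.transcripts}")
    try:
        pool = orfs.translate_set(transcripts, min_len_aa=config.min_len_aa)
    except ValueError as exc:
        raise PipelineError("translate", str(exc)) from exc
    n_candidates = sum(len(v) for v in pool.values())
    io.write_candidates(outdir / "candidates.fasta", outdir / "candidates.tsv", pool)
    logger.info("translate: %d transcripts -> %d candidates in %.2fs",
                len(transcripts), n_candidates, time.perf_counter() - t0)
    stages["translate"] = {"n_transcripts": len(transcripts),
                           "n_candidates": n_candidates}

    # ---- homology filter ------------------------------------------------
    t0 = time.perf_counter()
    cand_seqs = {c.candidate_id: c.aa_sequence
                 for cands in pool.values() for c in cands}
    hits: List[homology.HomologyHit] = []
    references: Dict[str, str] = {}
    if config.references:
        references = io.read_fasta(config.references)
    if config.blast_tab:
        bait_lengths = {cid: len(seq) for cid, seq in cand_seqs.items()}
        prey_lengths = {rid: len(seq) for rid, seq in references.items()}
        hits = homology.read_blast_tab(config.blast_tab, bait_lengths, prey_lengths)
    elif references:
        hits = homology.search(cand_seqs, references)
    best = homology.best_hits(hits)

    selected: List[Tuple[orfs.ProteinCandidate, Optional[str]]] = []
    for tid in sorted(pool):
        if not pool[tid]:
            continue
        tx_hits = [best[c.candidate_id] for c in pool[tid] if c.candidate_id in best]
        chosen = homology.select_best_candidate(pool[tid], tx_hits, e_cut=config.e_cut)
        best_hit = best.get(chosen.candidate_id)
        prey = best_hit.prey_id if (best_hit and best_hit.evalue < config.e_cut) else None
        selected.append((chosen, prey))

    core = homology.merge_redundant(selected)
    tier_counts = {name: 0 for name in homology.TIERS}
    for record in core:
        hit = best.get(record.candidate.candidate_id)
        if hit is None:
            continue
        for name, tier in homology.TIERS.items():
            if homology.classify(hit, tier):
                tier_counts[name] += 1
    io.write_tsv(
        outdir / "core.tsv",
        "protein_id\tcandidate_id\tprey_id\tmembers\tn_full_length"
        "\tn_fragment\taa_sequence",
        (
            (r.protein_id, r.candidate.candidate_id, r.prey_id or "",
             str(r.members), str(r.n_full_length), str(r.n_fragment),
             r.aa_sequence)
            for r in core
        ),
    )
    logger.info("filter: %d selected -> %d core records in %.2fs",
                len(selected), len(core), time.perf_counter() - t0)
    stages["homology_filter"] = {
        "n_hits": len(hits),
        "n_selected": len(selected),
        "n_core": len(core),
        "n_full_length": sum(r.n_full_length for r in core),
        "n_fragment": sum(r.n_fragment for r in core),
        "tier_counts": tier_counts,
    }

    # ---- quantify -------------------------------------------------------
    t0 = time.perf_counter()
    lengths = {t.id: len(t.sequence) for t in transcripts}
    records: List[quantify.RpkmRecord] = []
    if config.sam:
        try:
            records = quantify.rpkm_from_sam(config.sam, lengths)
        except KeyError as exc:
            raise PipelineError("quantify", str(exc)) from exc
    elif config.counts:
        counts = io.read_counts_tsv(config.counts)
        try:
            records = quantify.rpkm_from_counts(counts, lengths)
        except KeyError as exc:
            raise PipelineError("quantify", str(exc)) from exc
    rpkm_by_transcript = {r.transcript_id: r.rpkm for r in records}
    if records:
        io.write_tsv(
            outdir / "rpkm.tsv",
            "transcript_id\tcount\tlength\trpkm",
            ((r.transcript_id, str(r.count), str(r.length), f"{r.rpkm:.6f}")
             for r in records),
        )
        stages["quantify"] = quantify.summarize_rpkm(records)
    logger.info("quantify: %d records in %.2fs", len(records),
                time.perf_counter() - t0)

    # rpkm per core protein (protein id == representative transcript id)
    rpkms = {r.protein_id: rpkm_by_transcript.get(r.protein_id, 0.0)
             for r in core}

    # ---- toxin discovery ------------------------------------------------
    t0 = time.perf_counter()
    proteins = {r.protein_id: r.aa_sequence for r in core}
    ref_meta = (_read_reference_meta(config.reference_meta)
                if config.reference_meta else {})
    toxin_refs = {rid for rid, (fam, _cat) in ref_meta.items() if fam}
    hit_families = {rid: fam for rid, (fam, _cat) in ref_meta.items() if fam}
    toxin_hits = {r.protein_id: r.prey_id for r in core
                  if r.prey_id in toxin_refs}
    architectures = None
    ref_arch = None
    if config.domains and config.reference_architectures:
        architectures = toxins.load_domain_table(_read_domain_tsv(config.domains))
        ref_arch = _read_architecture_tsv(config.reference_architectures)
    patterns = []
    for rid in sorted(toxin_refs):
        pat = toxins.extract_cys_pattern(references[rid], pattern_id=f"PAT_{rid}")
        if not pat.is_empty:
            patterns.append(pat)
    calls: List[toxins.ToxinCall] = []
    if toxin_hits or patterns or (architectures and ref_arch):
        calls = toxins.call_toxins(
            proteins,
            toxin_hits=toxin_hits,
            hit_families=hit_families,
            architectures=architectures,
            reference_architectures=ref_arch,
            patterns=patterns,
            rpkms=rpkms,
            tolerance=config.pattern_tolerance,
        )
    io.write_tsv(
        outdir / "toxins.tsv",
        "protein_id\tevidence\tfamily\tcategory\trpkm\tpattern_ids",
        (
            (c.protein_id, ",".join(sorted(c.evidence)), c.family, c.category,
             "" if c.rpkm is None else f"{c.rpkm:.6f}",
             ",".join(c.pattern_ids))
            for c in calls
        ),
    )
    evidence_counts: Dict[str, int] = {}
    category_counts: Dict[str, int] = {}
    for call in calls:
        for ev in call.evidence:
            evidence_counts[ev] = evidence_counts.get(ev, 0) + 1
        category_counts[call.category] = category_counts.get(call.category, 0) + 1
    logger.info("toxins: %d calls in %.2fs", len(calls), time.perf_counter() - t0)
    stages["toxin_discovery"] = {
        "n_calls": len(calls),
        "by_evidence": evidence_counts,
        "by_category": category_counts,
        "category_rpkm_sums": toxins.category_rpkm_sums(calls),
    }

    # ---- enrichment -----------------------------------------------------
    if config.pathways:
        t0 = time.perf_counter()
        protein_terms = io.read_two_column_map(config.pathways)
        term_members: Dict[str, set] = {}
        for prot, terms in protein_terms.items():
            for term in terms:
                term_members.setdefault(term, set()).add(prot)
        mapped = {p for p in protein_terms if p in proteins}
        ranked = sorted(mapped, key=lambda p: (-rpkms.get(p, 0.0), p))
        n_top = max(1, int(len(ranked) * config.sample_top_fraction))
        sample = set(ranked[:n_top])
        results = enrich_mod.enrich_pathways(
            {t: m & set(proteins) for t, m in term_members.items()},
            sample,
            cutoff=config.enrichment_cutoff,
            rpkms=rpkms,
        )
        io.write_tsv(
            outdir / "enrichment.tsv",
            "term_id\tm_obs\tn_sample\tM\tN\tp_value\tsignificant\trpkm_sum",
            (
                (r.pathway_id, str(r.m_obs), str(r.n_sample), str(r.m_succ),
                 str(r.n_pop), f"{r.p_value:.6g}",
                 "1" if r.significant else "0", f"{r.rpkm_sum:.4f}")
                for r in results
            ),
        )
        logger.info("enrichment: %d pathways in %.2fs", len(results),
                    time.perf_counter() - t0)
        stages["enrichment"] = {
            "n_pathways": len(results),
            "n_significant": sum(1 for r in results if r.significant),
            "top": [
                {"term": r.pathway_id, "p": r.p_value, "m": r.m_obs,
                 "rpkm_sum": round(r.rpkm_sum, 4)}
                for r in results[:10]
            ],
        }

    # ---- summary --------------------------------------------------------
    report["summary"] = summarize_counts(
        [len(t.sequence) for t in transcripts],
        tier_counts=tier_counts,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
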