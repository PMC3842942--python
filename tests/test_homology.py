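"""Tests for hit metrics, tier classification, best-candidate selection,
redundancy merging and the EST-style QC report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomtx import simulate
from venomtx.homology import (
    TIERS,
    ConfidenceTier,
    HomologyHit,
    best_hits,
    classify,
    compute_hit_metrics,
    floor_percent,
    local_align,
    merge_redundant,
    qc_against_reference,
    read_blast_tab,
    search,
    select_best_candidate,
)
from venomtx.orfs import ProteinCandidate


def make_hit(bait="b", prey="p", ml=90, bl=100, pl=120, identity=50.0, evalue=1e-10):
    return HomologyHit(bait, prey, ml, bl, pl, identity, evalue)


def make_candidate(tid="t", aa="M" * 50, full=True, start=0, strand="+"):
    return ProteinCandidate(
        transcript_id=tid,
        frame=start % 3,
        strand=strand,
        aa_sequence=aa,
        nt_start=start,
        nt_end=start + 3 * len(aa) + (3 if full else 0),
        is_full_length=full,
    )


class TestMetrics:
    def test_tabular_row_example(self):
        # qseqid sseqid pident length mismatch gapopen qs qe ss se evalue bits
        row = ["b", "p", "50", "90", "45", "0", "1", "90", "1", "90", "1e-20", "180"]
        hit = compute_hit_metrics(row, bait_len=100, prey_len=120)
        assert hit.ml_bl == pytest.approx(0.9)
        assert hit.ml_pl == pytest.approx(0.75)
        assert hit.identity == 50.0

    def test_identity_case_self_alignment(self):
        seq = "MKWCACDEFGHIKLMNPQRSTVWYAVILK"
        hit = local_align("a", seq, "b", seq)
        assert hit.ml_bl == 1.0 and hit.ml_pl == 1.0
        assert hit.identity == 100.0

    def test_ratios_capped_at_one(self):
        hit = make_hit(ml=130, bl=100, pl=120)
        assert hit.ml_bl == 1.0
        assert hit.ml_pl == 1.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="nonpositive length"):
            make_hit(bl=0)

    def test_divergence_03_median_identity(self):
        cfg = simulate.SimulationConfig(
            seed=5, n_transcripts=60, n_toxin_genes=6, divergence=0.3,
            length_range=(600, 900),
        )
        _tx, refs, _meta, gt = simulate.generate_transcriptome(cfg)
        planted = {f"Q_{tid}": aa for tid, aa in gt.proteins.items()}
        hits = best_hits(search(planted, refs))
        idents = [h.identity for h in hits.values()]
        assert len(idents) >= 55
        assert abs(np.median(idents) - 70.0) <= 5.0


class TestClassify:
    def test_core_boundary_true(self):
        hit = make_hit(ml=51, bl=100, pl=100, identity=31.0)
        assert classify(hit, TIERS["core"])

    def test_core_boundary_strict_false(self):
        hit = make_hit(ml=50, bl=100, pl=100, identity=99.0)
        hit2 = HomologyHit("b", "p", 90, 100, 100, 99.0, 1e-9)
        assert not classify(hit, TIERS["core"])  # ML/BL == 0.5 exactly
        assert classify(hit2, TIERS["core"])

    def test_high_tier_example(self):
        hit = make_hit(ml=85, bl=100, pl=92, identity=55.0)
        assert hit.ml_bl == pytest.approx(0.85)
        assert classify(hit, TIERS["high"])

    def test_est_strict_ignores_prey_side(self):
        hit = make_hit(ml=85, bl=100, pl=1000, identity=96.0)
        assert classify(hit, TIERS["est_match_strict"])

    @settings(max_examples=300, deadline=None)
    @given(
        ml=st.integers(1, 200),
        bl=st.integers(1, 200),
        pl=st.integers(1, 200),
        ident=st.floats(0, 100),
        bump=st.floats(0, 50),
        tier=st.sampled_from(list(TIERS)),
    )
    def test_monotone_in_metrics(self, ml, bl, pl, ident, bump, tier):
        hit = HomologyHit("b", "p", ml, bl, pl, ident, 1e-9)
        better = HomologyHit(
            "b", "p", ml + int(bump), bl, pl, min(100.0, ident + bump), 1e-9
        )
        if classify(hit, TIERS[tier]):
            assert classify(better, TIERS[tier])


class TestSelectBestCandidate:
    def test_longest_with_homologue_wins(self):
        short = make_candidate(aa="M" * 50, start=0)
        long = make_candidate(aa="W" * 80, start=300)
        hits = [make_hit(bait=short.candidate_id, evalue=1e-10)]
        assert select_best_candidate([short, long], hits) is short

    def test_no_hits_longest_overall(self):
        short = make_candidate(aa="M" * 50, start=0)
        long = make_candidate(aa="W" * 80, start=300)
        assert select_best_candidate([short, long], []) is long

    def test_hit_above_cutoff_ignored(self):
        short = make_candidate(aa="M" * 50, start=0)
        long = make_candidate(aa="W" * 80, start=300)
        hits = [make_hit(bait=short.candidate_id, evalue=1e-3)]
        assert select_best_candidate([short, long], hits) is long

    def test_tie_prefers_full_length(self):
        frag = make_candidate(aa="M" * 50, full=False, start=0)
        full = make_candidate(aa="W" * 50, full=True, start=300)
        assert select_best_candidate([frag, full], []) is full

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError, match="empty"):
            select_best_candidate([], [])

    def test_agrees_with_brute_force_rescan(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 8))
            candidates = [
                make_candidate(
                    aa="A" * int(rng.integers(40, 120)),
                    full=bool(rng.integers(2)),
                    start=120 * i,
                )
                for i in range(n)
            ]
            hits = []
            for c in candidates:
                if rng.random() < 0.5:
                    hits.append(
                        make_hit(
                            bait=c.candidate_id,
                            evalue=float(10.0 ** rng.uniform(-12, 0)),
                        )
                    )
            chosen = select_best_candidate(candidates, hits, e_cut=1e-5)
            # oracle: exhaustive scan with explicit tie-breaking
            with_hit = {h.bait_id for h in hits if h.evalue < 1e-5}
            pool = [c for c in candidates if c.candidate_id in with_hit]
            if not pool:
                pool = candidates
            best = sorted(
                pool,
                key=lambda c: (-len(c), not c.is_full_length, c.candidate_id),
            )[0]
            assert chosen is best


class TestMergeRedundant:
    def test_shared_prey_collapsed_to_longest(self):
        cands = [
            (make_candidate(tid=f"t{i}", aa="A" * L, start=0), "X")
            for i, L in enumerate([100, 90, 80])
        ]
        merged = merge_redundant(cands)
        assert len(merged) == 1
        rec = merged[0]
        assert len(rec.aa_sequence) == 100
        assert rec.members == 3

    def test_distinct_preys_pass_through(self):
        cands = [
            (make_candidate(tid=f"t{i}", aa="A" * 50, start=0), f"p{i}")
            for i in range(5)
        ]
        assert len(merge_redundant(cands)) == 5

    def test_no_hit_passthrough_counts(self):
        cands = [
            (make_candidate(tid="a", aa="A" * 50, full=True), None),
            (make_candidate(tid="b", aa="A" * 60, full=False), None),
        ]
        merged = merge_redundant(cands)
        assert len(merged) == 2
        assert sum(r.n_full_length for r in merged) == 1
        assert sum(r.n_fragment for r in merged) == 1

    def test_idempotent_and_order_independent(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 12))
            cands = []
            for i in range(n):
                prey = None if rng.random() < 0.3 else f"p{int(rng.integers(4))}"
                cands.append(
                    (
                        make_candidate(
                            tid=f"t{i}",
                            aa="A" * int(rng.integers(40, 90)),
                            full=bool(rng.integers(2)),
                        ),
                        prey,
                    )
                )
            merged = merge_redundant(cands)
            sig = [(r.protein_id, r.prey_id, r.members) for r in merged]
            # idempotency: merging the merged output changes nothing
            again = merge_redundant(
                [(r.candidate, r.prey_id) for r in merged]
            )
            assert [(r.protein_id, r.prey_id) for r in again] == [
                (r.protein_id, r.prey_id) for r in merged
            ]
            # order independence
            perm = [cands[j] for j in rng.permutation(n)]
            assert [
                (r.protein_id, r.prey_id, r.members)
                for r in merge_redundant(perm)
            ] == sig

    def test_two_transcripts_one_gene_merge(self, zero_divergence_sim):
        # duplicate a transcript under a second id: both best-match the
        # same reference, so the core dataset has one record for them
        _cfg, transcripts, refs, _meta, gt = zero_divergence_sim
        tid = sorted(transcripts)[0]
        cand = make_candidate(tid=tid, aa=gt.proteins[tid])
        cand2 = make_candidate(tid=tid + "_dup", aa=gt.proteins[tid])
        merged = merge_redundant([(cand, f"REF_{tid}"), (cand2, f"REF_{tid}")])
        assert len(merged) == 1 and merged[0].members == 2


class TestQC:
    def _hits(self, n_matched, n_total, strict=0):
        hits = {}
        for i in range(n_matched):
            ident = 99.0 if i < strict else 60.0
            ml = 95 if i < strict else 60
            hits[f"e{i}"] = HomologyHit(f"e{i}", "a", ml, 100, 110, ident, 1e-9)
        for i in range(n_matched, n_total):
            hits[f"e{i}"] = HomologyHit(f"e{i}", "a", 60, 100, 110, 60.0, 1.0)
        return hits

    def test_printed_percentage_arithmetic(self):
        report = qc_against_reference(self._hits(961, 1015), n_baits=1015)
        assert report.matched == 961
        assert report.matched_percent == 94  # floored

    def test_all_identical_gives_100(self):
        hits = {
            f"e{i}": HomologyHit(f"e{i}", "a", 100, 100, 100, 100.0, 1e-30)
            for i in range(10)
        }
        report = qc_against_reference(hits, n_baits=10)
        assert report.matched_percent == 100
        assert report.strict == 10

    def test_length_comparison_counts(self):
        hits = {
            "short": HomologyHit("short", "a", 90, 100, 150, 80.0, 1e-9),
            "long": HomologyHit("long", "a", 90, 150, 100, 80.0, 1e-9),
            "lowcov": HomologyHit("lowcov", "a", 10, 100, 150, 80.0, 1e-9),
        }
        report = qc_against_reference(hits, n_baits=3)
        assert report.shorter_than_prey == 1
        assert report.longer_than_prey == 1

    def test_empty_est_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            qc_against_reference({}, n_baits=0)

    def test_reversed_negative_control(self, small_sim):
        _cfg, _tx, refs, _meta, gt = small_sim
        baits = {f"Q_{tid}": aa for tid, aa in gt.proteins.items()}
        reversed_baits = {bid: aa[::-1] for bid, aa in baits.items()}
        fwd = best_hits(search(baits, refs))
        rev = best_hits(search(reversed_baits, refs))
        report = qc_against_reference(
            fwd, n_baits=len(baits), reversed_hits=rev
        )
        assert report.matched == len(baits)
        assert report.reversed_matched == 0


class TestFloorPercent:
    def test_examples(self):
        assert floor_percent(961, 1015) == 94
        assert floor_percent(824, 961) == 85  # counts, not the printed ~90%
        assert floor_percent(1, 3) == 33

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            floor_percent(1, 0)


def test_read_blast_tab(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "# comment\n"
        "b1\tp1\t88.5\t90\t10\t0\t1\t90\t5\t94\t1e-30\t180\n"
        "b1\tp2\t40.0\t50\t30\t1\t1\t50\t1\t50\t0.5\t40\n"
    )
    hits = read_blast_tab(path, {"b1": 100}, {"p1": 120, "p2": 60})
    assert len(hits) == 2
    assert hits[0].identity == 88.5 and hits[0].ml == 90
    best = best_hits(hits)
    assert best["b1"].prey_id == "p1"
    with pytest.raises(KeyError, match="unknown bait"):
        read_blast_tab(path, {}, {"p1": 120, "p2": 60})
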