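"""Best-alignment filtering, rearrangement calling, chimera validation."""

from itertools import combinations

import pytest

from nanosurvey import (
    DefectPlan,
    KmerIndex,
    VariantPlan,
    align_pair,
    align_to_genome,
    annotate_junctions,
    chimera_check,
    derive_isolate,
    detect_rearrangements,
    filter_best_alignments,
    get_preset,
    make_assembly,
    map_features,
    simulate_reads,
)
from nanosurvey.core import AlignmentRecord
from nanosurvey.sv import Segment


def coord_rec(qid, qlen, qs, qe, tid, tlen, ts, te, ident=0.99, strand="+"):
    return AlignmentRecord(qid, qlen, qs, qe, strand, tid, tlen, ts, te,
                           _identity_hint=ident)


def exhaustive_best_subset(records, max_overlap_frac=0.5):
    """Oracle: max-score subset with pairwise overlaps <= 50% (no trimming)."""
    best_score = 0.0
    for r in range(len(records) + 1):
        for combo in combinations(records, r):
            ok = True
            for a, b in combinations(combo, 2):
                for (s0, e0, s1, e1, ida, idb) in [
                    (a.q_start, a.q_end, b.q_start, b.q_end,
                     a.query_id, b.query_id),
                    (a.t_start, a.t_end, b.t_start, b.t_end,
                     a.target_id, b.target_id),
                ]:
                    if ida != idb:
                        continue
                    ov = max(0, min(e0, e1) - max(s0, s1))
                    if ov > max_overlap_frac * min(e0 - s0, e1 - s1):
                        ok = False
                if not ok:
                    break
            if ok:
                score = sum(x.identity * (x.q_end - x.q_start) for x in combo)
                best_score = max(best_score, score)
    return best_score


class TestFilterBestAlignments:
    def test_unique_alignment_kept_intact(self):
        recs = [coord_rec("c", 50_000, 0, 50_000, "chr1", 60_000, 0, 50_000)]
        chains = filter_best_alignments(recs)
        (seg,) = chains["c"]
        assert (seg.q_start, seg.q_end) == (0, 50_000)

    def test_higher_identity_wins_overlap(self):
        recs = [
            coord_rec("c", 50_000, 0, 40_000, "chr1", 90_000, 0, 40_000, 0.99),
            coord_rec("c", 50_000, 0, 40_000, "chr2", 90_000, 0, 40_000, 0.90),
        ]
        chains = filter_best_alignments(recs)
        (seg,) = chains["c"]
        assert seg.target_id == "chr1"

    def test_repeat_triple_mapping_keeps_one(self):
        # one 12 kb query region mapping to three reference loci
        recs = [
            coord_rec("c", 12_000, 0, 12_000, "chr1", 99_000, t0, t0 + 12_000,
                      ident)
            for t0, ident in ((10_000, 0.98), (40_000, 0.97), (70_000, 0.96))
        ]
        chains = filter_best_alignments(recs)
        assert sum(len(v) for v in chains.values()) == 1
        assert chains["c"][0].t_start == 10_000

    def test_matches_exhaustive_on_repeat_instances(self, rng):
        """On tiling-plus-repeat instances (the delta-filter use case: a
        1-to-1 tiling with repeat-induced alternate mappings), the greedy
        score equals the exhaustive optimum over <= 10 segments."""
        for trial in range(25):
            recs = []
            n_tiles = int(rng.integers(2, 5))
            q = 0
            alt_slot = 0
            for i in range(n_tiles):
                ln = int(rng.integers(12_000, 30_000))
                ts = 35_000 * i + int(rng.integers(0, 4_000))
                ident = float(rng.uniform(0.95, 1.0))
                recs.append(coord_rec("c", 200_000, q, q + ln,
                                      "chr1", 700_000, ts, ts + ln, ident))
                # repeat-induced alternate mappings at lower identity,
                # in reference territory disjoint from everything else
                for _ in range(int(rng.integers(0, 3))):
                    alt = 300_000 + 35_000 * alt_slot
                    alt_slot += 1
                    recs.append(
                        coord_rec("c", 200_000, q, q + ln, "chr1", 700_000,
                                  alt, alt + ln,
                                  ident - float(rng.uniform(0.01, 0.1)))
                    )
                q += ln + int(rng.integers(0, 2_000))
            recs = recs[:10]
            chains = filter_best_alignments(recs)
            got = sum(s.score for segs in chains.values() for s in segs)
            opt = exhaustive_best_subset(recs)
            assert got == pytest.approx(opt)

    def test_no_heavy_pairwise_overlap_in_output(self, rng):
        recs = []
        for i in range(12):
            qs = int(rng.integers(0, 40_000))
            recs.append(coord_rec("c", 80_000, qs, qs + 30_000,
                                  "chr1", 99_000, qs, qs + 30_000,
                                  ident=float(rng.uniform(0.9, 1.0))))
        chains = filter_best_alignments(recs)
        segs = [s for v in chains.values() for s in v]
        for a, b in combinations(segs, 2):
            ov = max(0, min(a.q_end, b.q_end) - max(a.q_start, b.q_start))
            assert ov <= 0.5 * min(len(a), len(b)) + 1


@pytest.fixture(scope="module")
def rearranged_isolate(small_ref):
    plan = VariantPlan(
        translocations=(("chr1", 40_000, "chr2", 35_000, True, False),),
        inversions=(("chr3", 20_000, 45_000),),
        snp_density=0.002,
    )
    iso = derive_isolate(small_ref, plan, seed=3)
    asm = make_assembly(iso.genome, DefectPlan(), features=iso.features)
    indexes = [KmerIndex(r.seq) for r in small_ref.genome]
    alns = []
    for c in asm.contigs:
        alns.extend(align_to_genome(c, small_ref.genome, indexes=indexes))
    return iso, asm, alns


class TestDetectRearrangements:
    def test_planted_events_recovered(self, rearranged_isolate):
        iso, _asm, alns = rearranged_isolate
        chains = filter_best_alignments(alns)
        events = detect_rearrangements(chains)
        by_type = {e.type: e for e in events}
        assert set(by_type) == {"translocation", "inversion"}
        tr = by_type["translocation"]
        assert {tr.chromA, tr.chromB} == {"chr1", "chr2"}
        truth_tr = next(t for t in iso.sv_truth if t.type == "translocation")
        pos = {tr.chromA: tr.posA, tr.chromB: tr.posB}
        assert abs(pos["chr1"] - truth_tr.posA) <= 1_000
        assert abs(pos["chr2"] - truth_tr.posB) <= 1_000
        assert tr.n_junctions == 2  # reciprocal: deduplicated from 2 junctions
        inv = by_type["inversion"]
        assert abs(inv.posA - 20_000) <= 1_000
        assert abs(inv.posB - 45_000) <= 1_000
        assert abs(inv.length - 25_000) <= 1_000

    def test_rearrangement_free_isolate_is_clean(self, small_ref):
        asm = make_assembly(small_ref.genome, DefectPlan())
        indexes = [KmerIndex(r.seq) for r in small_ref.genome]
        alns = []
        for c in asm.contigs:
            alns.extend(align_to_genome(c, small_ref.genome, indexes=indexes))
        events = detect_rearrangements(filter_best_alignments(alns))
        assert events == []

    def test_contig_order_invariance(self, rearranged_isolate):
        _iso, _asm, alns = rearranged_isolate
        a = detect_rearrangements(filter_best_alignments(alns))
        b = detect_rearrangements(filter_best_alignments(alns[::-1]))
        key = lambda e: (e.type, e.chromA, e.posA // 100)
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestAnnotateJunctions:
    def test_te_junction_annotated(self, small_ref):
        te = next(f for f in small_ref.features if f.kind == "TE")
        from nanosurvey.sv import SVEvent
        ev = SVEvent("translocation", "c", te.target_id,
                     te.start + len(te) // 2, "chrX", 5)
        te_lib = [small_ref.library[f] for f in ("Ty1", "Ty2", "Ty3", "Ty4", "Ty5")]
        hits = map_features(te_lib, small_ref.genome)
        annotate_junctions([ev], hits)
        assert te.family in ev.junction_features

    def test_background_breakpoint_empty(self, small_ref):
        from nanosurvey.sv import SVEvent
        ev = SVEvent("translocation", "c", "chr1", 1_000, "chr2", 1_000)
        annotate_junctions([ev], [], window=0)
        assert ev.junction_features == []

    def test_zero_window_requires_containment(self, small_ref):
        te = next(f for f in small_ref.features if f.kind == "TE")
        te_lib = [small_ref.library[te.family]]
        hits = map_features(te_lib, small_ref.genome)
        from nanosurvey.sv import SVEvent
        inside = SVEvent("translocation", "c", te.target_id,
                         te.start + 10, "chrX", 5)
        outside = SVEvent("translocation", "c", te.target_id,
                          te.end + 10, "chrX", 5)
        annotate_junctions([inside, outside], hits, window=0)
        assert inside.junction_features == [te.family]
        assert outside.junction_features == []


@pytest.fixture(scope="module")
def chimera_setup(small_ref):
    return _build_chimera_setup(small_ref)


def _build_chimera_setup(small_ref):
    asm = make_assembly(
        small_ref.genome, DefectPlan(chimeric_joins=(("chr1", "chr2"),)),
        features=small_ref.features,
    )
    (chim,) = asm.chimeras
    ctg = next(c for c in asm.contigs if c.id == chim.contig_id)
    reads, _ = simulate_reads(small_ref.genome, get_preset("perfect"),
                              seed=4, coverage=4)
    idx = KmerIndex(ctg.seq)
    alns = []
    for rd in reads:
        alns.extend(align_pair(rd, ctg, index=idx))
    return chim, ctg, alns


class TestChimeraCheck:

    def test_chimeric_junction_has_no_support(self, chimera_setup):
        chim, ctg, alns = chimera_setup
        ev = chimera_check(ctg, chim.junction, alns)
        assert ev.read_support == 0
        assert ev.type == "chimera"

    def test_genuine_region_is_supported(self, chimera_setup):
        chim, ctg, alns = chimera_setup
        ev = chimera_check(ctg, chim.junction // 2, alns)
        assert ev.read_support > 0
        assert ev.type != "chimera"

    def test_anchor_larger_than_arm_errors(self, chimera_setup):
        chim, ctg, alns = chimera_setup
        with pytest.raises(ValueError, match="outside"):
            chimera_check(ctg, 500, alns, anchor=1_000)
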