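"""Genome forge: planted-feature bookkeeping, isolate derivation, defects."""

import numpy as np
import pytest

from nanosurvey import (
    DefectPlan,
    ForgeConfig,
    VariantPlan,
    build_reference,
    derive_isolate,
    forge_cohort,
    make_assembly,
)
from nanosurvey.core import revcomp


class TestBuildReference:
    def test_feature_bookkeeping(self, small_ref, small_config):
        cfg = small_config
        assert [len(r.seq) for r in small_ref.genome] == list(cfg.chrom_lengths)
        tes = small_ref.features_of("TE")
        by_family = {}
        for f in tes:
            by_family[f.family] = by_family.get(f.family, 0) + 1
        assert by_family == dict(cfg.te_families)
        assert len(small_ref.features_of("centromere")) == cfg.n_chrom
        assert len(small_ref.features_of("telomere")) == 2 * cfg.n_chrom
        assert len(small_ref.features_of("gene")) == cfg.n_genes

    def test_tandem_array_span(self, small_ref):
        arr = next(f for f in small_ref.features
                   if f.kind == "tandem_array" and f.family == "CUP1")
        assert len(arr) == 1_000 * 7

    def test_features_planted_verbatim(self, small_ref):
        for f in small_ref.features_of("TE")[:3]:
            chrom = next(r for r in small_ref.genome if r.id == f.target_id)
            planted = chrom.seq[f.start: f.end]
            lib = small_ref.library[f.family].seq
            assert planted == (lib if f.strand == "+" else revcomp(lib))

    def test_same_seed_byte_identical(self, small_config, small_ref):
        again = build_reference(small_config)
        assert all(a.seq == b.seq for a, b in zip(small_ref.genome, again.genome))
        assert small_ref.features == again.features

    def test_overfull_chromosome_errors(self):
        cfg = ForgeConfig(seed=1, chrom_lengths=(8_000,), te_length=3_000,
                          rdna_unit_length=500, rdna_copies=4,
                          tandem_arrays=(), n_genes=0)
        with pytest.raises(ValueError, match="chr1"):
            build_reference(cfg)


class TestDeriveIsolate:
    def test_reciprocal_translocation_conserves_bases(self, small_ref):
        plan = VariantPlan(
            translocations=(("chr1", 40_000, "chr2", 30_000, True, False),)
        )
        iso = derive_isolate(small_ref, plan, seed=1)
        ref_total = sum(len(r.seq) for r in small_ref.genome)
        assert sum(len(r.seq) for r in iso.genome) == ref_total
        lens = {r.id: len(r.seq) for r in iso.genome}
        assert lens["chr1"] == 40_000 + (80_000 - 30_000)
        assert lens["chr2"] == 30_000 + (90_000 - 40_000)

    def test_inversion_is_reverse_complement(self, small_ref):
        plan = VariantPlan(inversions=(("chr3", 10_000, 30_000),))
        iso = derive_isolate(small_ref, plan, seed=1)
        ref = small_ref.genome[2].seq
        der = next(r for r in iso.genome if r.id == "chr3").seq
        assert der[:10_000] == ref[:10_000]
        assert der[30_000:] == ref[30_000:]
        assert der[10_000:30_000] == revcomp(ref[10_000:30_000])

    def test_snp_count_within_binomial_bounds(self, small_ref):
        d = 0.0062
        iso = derive_isolate(small_ref, VariantPlan(snp_density=d), seed=2)
        n = sum(len(r.seq) for r in small_ref.genome)
        mean, sd = n * d, np.sqrt(n * d * (1 - d))
        assert abs(len(iso.snps) - mean) < 3 * sd

    def test_tandem_cnv_resizes_array(self, small_ref):
        iso = derive_isolate(small_ref, VariantPlan(tandem_cnv=(("CUP1", 3),)),
                             seed=1)
        arr = next(f for f in small_ref.features
                   if f.kind == "tandem_array" and f.family == "CUP1")
        chrom_ref = next(r for r in small_ref.genome if r.id == arr.target_id)
        chrom_iso = next(r for r in iso.genome if r.id == arr.target_id)
        assert len(chrom_iso.seq) == len(chrom_ref.seq) - 4 * 1_000

    def test_breakpoint_inside_prior_event_errors(self, small_ref):
        plan = VariantPlan(
            inversions=(("chr1", 20_000, 40_000),),
            translocations=(("chr1", 30_000, "chr2", 30_000, True, False),),
        )
        with pytest.raises(ValueError):
            derive_isolate(small_ref, plan, seed=1)

    def test_projection_round_trip(self, small_ref):
        plan = VariantPlan(inversions=(("chr3", 10_000, 30_000),))
        iso = derive_isolate(small_ref, plan, seed=1)
        # inside the inversion, projection flips strand
        portions = iso.project("chr3", 15_000, 15_100)
        assert portions == [("chr3", 24_900, 25_000, "-")]
        # outside, identity mapping
        assert iso.project("chr3", 5_000, 5_100) == [("chr3", 5_000, 5_100, "+")]


class TestMakeAssembly:
    def test_no_defects_contigs_equal_chromosomes(self, small_ref):
        asm = make_assembly(small_ref.genome, DefectPlan())
        assert [c.seq for c in asm.contigs] == [r.seq for r in small_ref.genome]

    def test_forced_homopolymer_deletions(self, small_ref):
        asm = make_assembly(small_ref.genome,
                            DefectPlan(consensus_hp_del_rate=1.0), seed=3)
        truth = {c: [] for c, _, _ in asm.hp_deletions}
        for cid, pos, run_len in asm.hp_deletions:
            assert run_len >= 4
        # every run >= 4 in the source lost exactly one base
        src = small_ref.genome[0].seq
        contig = asm.contigs[0].seq
        n_runs = sum(1 for cid, _, _ in asm.hp_deletions
                     if cid == asm.contigs[0].id)
        assert len(contig) == len(src) - n_runs
        assert "AAAAA" not in contig or "AAAAA" in src  # shrunk, not grown

    def test_chimeric_join_records_truth(self, small_ref):
        asm = make_assembly(small_ref.genome,
                            DefectPlan(chimeric_joins=(("chr1", "chr2"),)),
                            features=small_ref.features)
        (chim,) = asm.chimeras
        ctg = next(c for c in asm.contigs if c.id == chim.contig_id)
        chr1 = small_ref.genome[0].seq
        chr2 = small_ref.genome[1].seq
        assert ctg.seq[: chim.junction] == chr1[: chim.junction]
        assert ctg.seq[chim.junction:] == chr2[-(len(ctg.seq) - chim.junction):]

    def test_chimeric_join_requires_shared_te(self, small_ref):
        # with chr2's TE annotation removed, no shared family remains
        feats = [f for f in small_ref.features
                 if not (f.kind == "TE" and f.target_id == "chr2")]
        with pytest.raises(ValueError, match="shared TE"):
            make_assembly(small_ref.genome,
                          DefectPlan(chimeric_joins=(("chr1", "chr2"),)),
                          features=feats)

    def test_rdna_fragmentation(self, small_ref):
        asm = make_assembly(small_ref.genome, DefectPlan(fragment_at_rdna=True),
                            features=small_ref.features)
        assert len(asm.contigs) == len(small_ref.genome) + 1
        assert len(asm.breaks) == 1


class TestForgeCohort:
    def test_shapes_and_determinism(self, small_ref):
        m1, sites1 = forge_cohort(small_ref, 6, 0.005, seed=4)
        m2, sites2 = forge_cohort(small_ref, 6, 0.005, seed=4)
        assert m1.n_isolates == 6
        assert m1.n_sites == sum(len(r.seq) for r in small_ref.genome)
        assert np.array_equal(m1.matrix, m2.matrix)
        assert np.array_equal(sites1, sites2)
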