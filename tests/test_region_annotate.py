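"""Consequence classification, CRE partitioning and region tallies."""

import numpy as np
import pytest

from conftest import make_variant
from thymito.region_annotate import (
    HotspotTable,
    MitoRegionMap,
    Transcript,
    TranscriptAnnotation,
    classify_coding,
    classify_noncoding,
    cohort_recurrence_tally,
    lookup_known_hotspots,
    mito_region_tally,
    partition_cre,
)
from thymito.variant_io import GenomicInterval, IntervalSet, ReferenceGenome


class TestClassifyCoding:
    # toy CDS at chr1:100-115 (0-based): ATG CGA TGG TTT TAA

    def test_synonymous_third_position(self, toy_coding_setup):
        genome, ann = toy_coding_setup
        # CGA -> CGG, both Arg under the standard code
        v = make_variant(chrom="chr1", pos=106, ref="A", alt="G")
        assert classify_coding(v, ann, genome) == "synonymous"

    def test_nonsynonymous(self, toy_coding_setup):
        genome, ann = toy_coding_setup
        # TTT (Phe) -> TCT (Ser)
        v = make_variant(chrom="chr1", pos=111, ref="T", alt="C")
        assert classify_coding(v, ann, genome) == "nonsynonymous"

    def test_stop_causing_standard_code(self, toy_coding_setup):
        genome, ann = toy_coding_setup
        # TGG (Trp) -> TGA = stop under the standard code
        v = make_variant(chrom="chr1", pos=109, ref="G", alt="A")
        assert classify_coding(v, ann, genome) == "stop_causing"

    def test_tga_is_tryptophan_in_vertebrate_mito_code(self, toy_coding_setup):
        genome, ann = toy_coding_setup
        # same TGG -> TGA change on chrM is Trp -> Trp: synonymous, not stop
        v = make_variant(chrom="chrM", pos=109, ref="G", alt="A")
        assert classify_coding(v, ann, genome) == "synonymous"

    def test_stop_loss(self, toy_coding_setup):
        genome, ann = toy_coding_setup
        # TAA -> CAA (Gln) under the standard code
        v = make_variant(chrom="chr1", pos=113, ref="T", alt="C")
        assert classify_coding(v, ann, genome) == "stop_loss"

    def test_outside_transcripts_signals_not_coding(self, toy_coding_setup):
        genome, ann = toy_coding_setup
        v = make_variant(chrom="chr1", pos=350, ref="A", alt="C")
        assert classify_coding(v, ann, genome) is None

    def test_splice_windows_per_strand(self):
        seq = "ACGT" * 300
        genome = ReferenceGenome(sequences={"chr1": seq})
        fwd = Transcript(
            "F", "chr1", "+", exons=[(100, 202), (400, 502)],
            cds=[(100, 202), (400, 502)],
        )
        rev = Transcript(
            "R", "chr1", "-", exons=[(700, 802), (1000, 1102)],
            cds=[(700, 802), (1000, 1102)],
        )
        ann = TranscriptAnnotation([fwd, rev])
        # 1 bp into the intron after the first exon (donor side on +)
        assert (
            classify_coding(make_variant(pos=203), ann, genome)
            == "splice_donor"
        )
        assert (
            classify_coding(make_variant(pos=399), ann, genome)
            == "splice_acceptor"
        )
        # on the minus strand the roles swap
        assert (
            classify_coding(make_variant(pos=803), ann, genome)
            == "splice_acceptor"
        )
        assert (
            classify_coding(make_variant(pos=999), ann, genome)
            == "splice_donor"
        )

    def test_reverse_strand_codon_decoding(self):
        # CDS on '-' strand: genome holds the reverse complement of
        # ATG AAA TAA -> genome segment TTA TTT CAT at 100..109
        seq = "G" * 100 + "TTATTTCAT" + "G" * 100
        genome = ReferenceGenome(sequences={"chr1": seq})
        ann = TranscriptAnnotation(
            [Transcript("R", "chr1", "-", exons=[(100, 109)], cds=[(100, 109)])]
        )
        # genome pos 105 (0-based 104) is the middle T of TTT = AAA (Lys);
        # T->G on genome = A->C on transcript: AAA -> ACA (Thr)
        v = make_variant(chrom="chr1", pos=105, ref="T", alt="G")
        assert classify_coding(v, ann, genome) == "nonsynonymous"
        # genome 0-based 106: transcript codon 2 third base (AAA -> AAG Lys)
        v = make_variant(chrom="chr1", pos=104, ref="T", alt="C")
        assert classify_coding(v, ann, genome) == "synonymous"


class TestClassifyNoncoding:
    def test_intron_and_intergenic(self, toy_coding_setup):
        genome, ann = toy_coding_setup
        seq = "ACGT" * 300
        g = ReferenceGenome(sequences={"chr1": seq})
        ann2 = TranscriptAnnotation(
            [
                Transcript(
                    "G1", "chr1", "+", exons=[(100, 160), (400, 460)],
                    cds=[(100, 160), (400, 460)],
                )
            ]
        )
        assert classify_noncoding(make_variant(pos=300), ann2) == "intron"

    def test_far_from_genes_is_intergenic(self, toy_coding_setup):
        genome, ann = toy_coding_setup
        v = make_variant(chrom="chr1", pos=50_000)
        assert classify_noncoding(v, ann) == "intergenic"

    def test_upstream_downstream_windows(self):
        seq = "ACGT" * 3000
        genome = ReferenceGenome(sequences={"chr1": seq})
        ann = TranscriptAnnotation(
            [
                Transcript(
                    "G", "chr1", "+", exons=[(5000, 5120)], cds=[(5000, 5120)]
                )
            ]
        )
        assert classify_noncoding(make_variant(pos=4500), ann) == "upstream"
        assert classify_noncoding(make_variant(pos=6000), ann) == "downstream"
        assert classify_noncoding(make_variant(pos=2500), ann) == "intergenic"

    def test_utr_labels(self):
        seq = "ACGT" * 100
        genome = ReferenceGenome(sequences={"chr1": seq})
        ann = TranscriptAnnotation(
            [
                Transcript(
                    "G", "chr1", "+", exons=[(100, 220)], cds=[(130, 190)]
                )
            ]
        )
        assert classify_noncoding(make_variant(pos=110), ann) == "5'UTR"
        assert classify_noncoding(make_variant(pos=210), ann) == "3'UTR"

    def test_uniform_variants_follow_interval_length_fractions(
        self, small_reference
    ):
        ref = small_reference
        rng = np.random.default_rng(17)
        chrom = "chr1"
        n = 10_000
        length = len(ref.genome.sequences[chrom])
        counts: dict[str, int] = {}
        from thymito.region_annotate import classify_coding as cc

        n_noncoding = 0
        for pos in rng.integers(1, length + 1, n):
            v = make_variant(chrom=chrom, pos=int(pos))
            if cc(v, ref.annotation, ref.genome) is not None:
                continue
            n_noncoding += 1
            label = classify_noncoding(v, ref.annotation)
            counts[label] = counts.get(label, 0) + 1
        sizes = ref.annotation.label_footprints(ref.genome)
        noncoding_total = sum(v for k, v in sizes.items() if k != "coding")
        for label, observed in counts.items():
            frac = observed / n_noncoding
            expect = sizes[label] / noncoding_total
            se = np.sqrt(expect * (1 - expect) / n_noncoding)
            assert abs(frac - expect) < max(5 * se, 0.02), label


class TestPartitionCre:
    def test_variant_at_cre_midpoint(self):
        ccre = IntervalSet([GenomicInterval("chr1", 100, 200, "E")])
        v = make_variant(pos=150)
        cre, nonf = partition_cre([v], ccre)
        assert cre == [v] and nonf == []

    def test_empty_cre_set_all_nonfunctional(self):
        vs = [make_variant(pos=p) for p in (10, 20)]
        cre, nonf = partition_cre(vs, IntervalSet())
        assert cre == [] and nonf == vs

    def test_split_matches_quadratic_oracle(self):
        rng = np.random.default_rng(4)
        ivs = []
        for _ in range(200):
            s = int(rng.integers(0, 100_000))
            ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 500))))
        ccre = IntervalSet(ivs)
        vs = [
            make_variant(pos=int(p))
            for p in rng.integers(1, 100_500, 1000)
        ]
        cre, nonf = partition_cre(vs, ccre)
        oracle_cre = [
            v
            for v in vs
            if any(iv.start <= v.pos - 1 < iv.end for iv in ivs)
        ]
        assert cre == oracle_cre
        assert len(cre) + len(nonf) == len(vs)


class TestHotspots:
    def test_planted_hit_is_the_only_hit(self, small_reference, tmp_path):
        hotspots = small_reference.hotspots
        iv = next(iter(hotspots))
        v = make_variant(chrom=iv.chrom, pos=(iv.start + iv.end) // 2 + 1)
        hits = lookup_known_hotspots([v], hotspots)
        assert len(hits) >= 1
        assert hits[0].region == iv.label
        assert hits[0].source == hotspots.sources[iv.label]

    def test_no_overlap_empty(self, small_reference):
        v = make_variant(chrom="chrZ", pos=5)
        assert lookup_known_hotspots([v], small_reference.hotspots) == []

    def test_malformed_row_fatal_with_row_number(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("chrom\tstart\tend\tname\tsource\nchr1\t5\t5\tx\tproj\n")
        with pytest.raises(ValueError, match="row 2"):
            HotspotTable.from_tsv(p)


class TestCohortRecurrence:
    def test_shared_position_reported_with_count(self):
        per_patient = {
            "p1": [make_variant(pos=100)],
            "p2": [make_variant(pos=100)],
            "p3": [make_variant(pos=999)],
        }
        df = cohort_recurrence_tally(per_patient)
        exact = df[df.kind == "exact"]
        assert len(exact) == 1
        assert exact.iloc[0].pos == 100 and exact.iloc[0].n_patients == 2

    def test_all_unique_is_empty(self):
        per_patient = {
            "p1": [make_variant(pos=100)],
            "p2": [make_variant(pos=90_000)],
        }
        assert len(cohort_recurrence_tally(per_patient)) == 0

    def test_planted_three_patient_site_recovered(self):
        per_patient = {
            f"p{i}": [make_variant(pos=5000)] for i in range(3)
        }
        per_patient["p9"] = [make_variant(pos=70_000)]
        df = cohort_recurrence_tally(per_patient)
        exact = df[df.kind == "exact"]
        assert exact.iloc[0].n_patients == 3

    def test_window_recurrence_within_21bp(self):
        per_patient = {
            "p1": [make_variant(pos=1000)],
            "p2": [make_variant(pos=1010)],
        }
        df = cohort_recurrence_tally(per_patient, window=21)
        assert (df.kind == "window").any()
        assert not (df.kind == "exact").any()


class TestMitoRegionMap:
    def test_hvr1_position_is_dloop_with_sub_region(self):
        m = MitoRegionMap.default()
        assert m.assign(16258) == "D-loop"
        assert "HVR1" in m.sub_regions(16258)
        # m.16527 is D-loop but beyond HVR I
        assert m.assign(16527) == "D-loop"
        assert "HVR1" not in m.sub_regions(16527)

    def test_gene_lookup(self):
        m = MitoRegionMap.default()
        assert m.assign(15000) == "MT-CYB"
        assert m.assign(3500) == "MT-ND1"

    def test_dloop_wraps_origin(self):
        m = MitoRegionMap.default()
        for pos in (16024, 16569, 1, 576):
            assert m.assign(pos) == "D-loop"
        assert m.assign(577) == "MT-TF"

    def test_position_beyond_contig_fatal(self):
        m = MitoRegionMap.default()
        with pytest.raises(ValueError):
            m.assign(16570)

    def test_published_region_counts_sum_to_43(self):
        m = MitoRegionMap.default()
        planted = {
            "D-loop": (16100, 17),
            "MT-CYB": (14800, 5),
            "MT-ND4": (11000, 5),
            "MT-ND1": (3400, 3),
            "MT-ND5": (12400, 3),
            "MT-CO2": (7600, 3),
            "MT-RNR1": (700, 7),  # tallied under its own region; the
        }  # test groups non-listed regions as "other"
        variants = []
        for name, (base, count) in planted.items():
            for i in range(count):
                variants.append(make_variant(chrom="chrM", pos=base + i))
        tally = mito_region_tally(variants, m, n_patients=10)
        assert tally.total == 43
        named = ("D-loop", "MT-CYB", "MT-ND4", "MT-ND1", "MT-ND5", "MT-CO2")
        for name in named:
            assert tally.counts[name] == planted[name][1]
        other = tally.total - sum(tally.counts[n] for n in named)
        assert other == 7

    def test_rate_halves_when_size_doubles(self):
        m = MitoRegionMap.default()
        variants = [make_variant(chrom="chrM", pos=16100 + i) for i in range(4)]
        tally = mito_region_tally(variants, m, n_patients=2)
        r1 = tally.rate_per_mb("D-loop")
        tally.sizes_bp["D-loop"] *= 2
        assert tally.rate_per_mb("D-loop") == pytest.approx(r1 / 2)

    def test_count_conservation(self):
        m = MitoRegionMap.default()
        rng = np.random.default_rng(8)
        variants = [
            make_variant(chrom="chrM", pos=int(p))
            for p in rng.integers(1, 16570, 300)
        ]
        tally = mito_region_tally(variants, m)
        assert tally.total == 300
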