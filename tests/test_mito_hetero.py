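"""Heteroplasmy, shift classes, density, dN/dS and group comparisons."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_variant
from thymito.mito_hetero import (
    MITO_KB,
    DnDsResult,
    MitoVariant,
    classify_cds_change,
    classify_shift,
    dnds,
    dnds_from_variants,
    expected_sites,
    heteroplasmy,
    heteroplasmy_by_group,
    mutation_density,
    region_group,
)
from thymito.region_annotate import (
    STANDARD_CODE,
    VERTEBRATE_MITO_CODE,
    MitoRegionMap,
    translate_codon,
)


class TestHeteroplasmy:
    def test_fraction(self):
        assert heteroplasmy(18, 360) == pytest.approx(0.05)
        assert heteroplasmy(360, 360) == 1.0

    def test_zero_depth_signalled(self):
        with pytest.raises(ValueError):
            heteroplasmy(0, 0)

    def test_binomial_estimate_unbiased(self):
        rng = np.random.default_rng(12)
        c, h, reps = 368, 0.3, 1000
        estimates = rng.binomial(c, h, reps) / c
        se = math.sqrt(h * (1 - h) / c / reps)
        assert abs(estimates.mean() - h) < 3 * se


class TestShiftClass:
    def test_examples(self):
        assert classify_shift(0.40, 0.00) == "tumour-specific"
        assert classify_shift(0.40, 0.06) == "tumour-enriched"
        assert classify_shift(0.40, 0.45) == "no-shift"

    def test_500_simulated_pairs_match_conditional_recheck(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            ht, hn = rng.uniform(0, 1, 2)
            got = classify_shift(ht, hn)
            if hn < 0.05:
                assert got == "tumour-specific"
            elif ht > hn:
                assert got == "tumour-enriched"
            else:
                assert got == "no-shift"

    def test_mitovariant_shift_and_levels(self):
        v = MitoVariant(
            chrom="chrM", pos=100, ref="A", alt="G", qscore=30,
            filter_status="PASS", t_depth=360, t_alt=144, n_depth=300,
            n_alt=0, region="D-loop",
        )
        assert v.h_tumour == pytest.approx(0.4)
        assert v.h_normal == 0.0
        assert v.shift_class == "tumour-specific"


class TestMutationDensity:
    def test_published_cohort_arithmetic(self):
        assert mutation_density(43, MITO_KB, 10) == pytest.approx(
            0.2595, abs=5e-4
        )
        assert round(mutation_density(43, MITO_KB, 10), 2) == 0.26

    def test_zero_mutations(self):
        assert mutation_density(0, 16.569, 10) == 0.0

    def test_linear_scaling(self):
        d = mutation_density(10, 100.0, 5)
        assert mutation_density(20, 100.0, 5) == pytest.approx(2 * d)
        assert mutation_density(10, 100.0, 10) == pytest.approx(d / 2)

    def test_zero_denominators_fatal(self):
        with pytest.raises(ValueError):
            mutation_density(1, 0, 10)
        with pytest.raises(ValueError):
            mutation_density(1, 16.569, 0)


def brute_force_sites(cds, table_id):
    """Independent 9-changes-per-codon enumeration."""
    N = S = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = translate_codon(codon, table_id)
        for j in range(3):
            for alt in "ACGT":
                if alt == codon[j]:
                    continue
                mut = codon[:j] + alt + codon[j + 1 :]
                if translate_codon(mut, table_id) == aa:
                    S += 1 / 3
                else:
                    N += 1 / 3
    return N, S


class TestDnDs:
    def test_single_phe_codon_matches_exhaustive_enumeration(self):
        # TTT: TTC is synonymous (Phe); the other 8 changes are not
        N, S = expected_sites("TTT", STANDARD_CODE)
        bN, bS = brute_force_sites("TTT", STANDARD_CODE)
        assert (N, S) == pytest.approx((bN, bS))
        assert S == pytest.approx(1 / 3)
        assert N == pytest.approx(8 / 3)

    @pytest.mark.parametrize("table_id", [STANDARD_CODE, VERTEBRATE_MITO_CODE])
    def test_site_conservation_random_genes(self, table_id):
        rng = np.random.default_rng(5)
        for _ in range(5):
            cds = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
            N, S = expected_sites(cds, table_id)
            assert N + S == pytest.approx(90.0)
            bN, bS = brute_force_sites(cds, table_id)
            assert (N, S) == pytest.approx((bN, bS))

    def test_zero_nonsynonymous_gives_omega_zero(self):
        res = DnDsResult(Nd=0, Sd=2, N=60, S=30)
        assert res.omega == 0.0

    def test_sd_zero_flagged_infinite(self):
        res = DnDsResult(Nd=3, Sd=0, N=60, S=30)
        assert math.isinf(res.omega)

    def test_observed_counts_classified_through_code_table(self):
        cds = "ATGCGATTTTAA"  # M R F stop
        res = dnds(
            [("g", 5, "G"), ("g", 8, "C")],  # CGA->CGG syn; TTT->TTC syn
            {"g": cds},
            STANDARD_CODE,
        )
        assert res.Sd == 2 and res.Nd == 0
        res2 = dnds([("g", 3, "T")], {"g": cds}, STANDARD_CODE)  # CGA->TGA stop
        assert res2.Nd == 1

    def test_positive_selection_recovered_on_biased_draws(self):
        # mutations drawn with a 3:1 nonsynonymous excess over the neutral
        # per-site expectation give omega > 1 in >= 95% of seeds
        rng_master = np.random.default_rng(77)
        cds = "".join(
            "ACGT"[i] for i in rng_master.integers(0, 4, 300)
        )
        N, S = expected_sites(cds, VERTEBRATE_MITO_CODE)
        syn_changes, nonsyn_changes = [], []
        for off in range(len(cds)):
            for alt in "ACGT":
                if alt == cds[off]:
                    continue
                kind = classify_cds_change(cds, off, alt, VERTEBRATE_MITO_CODE)
                (syn_changes if kind == "synonymous" else nonsyn_changes).append(
                    (off, alt)
                )
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng([77, seed])
            # neutral rates proportional to site counts; 3x on nonsynonymous
            w_n, w_s = 3 * N, S
            muts = []
            for _ in range(30):
                if rng.random() < w_n / (w_n + w_s):
                    off, alt = nonsyn_changes[
                        int(rng.integers(0, len(nonsyn_changes)))
                    ]
                else:
                    off, alt = syn_changes[int(rng.integers(0, len(syn_changes)))]
                muts.append(("g", off, alt))
            res = dnds(muts, {"g": cds}, VERTEBRATE_MITO_CODE)
            if res.omega > 1:
                hits += 1
        assert hits >= 95


class TestHeteroplasmyByGroup:
    def _mv(self, h, region="D-loop", consequence="other"):
        depth = 1000
        return MitoVariant(
            chrom="chrM", pos=int(1 + h * 1000), ref="A", alt="G", qscore=30,
            filter_status="PASS", t_depth=depth, t_alt=int(h * depth),
            n_depth=depth, n_alt=0, region=region, consequence=consequence,
        )

    def test_identical_groups_p_near_one(self):
        vs = [
            self._mv(h, consequence=c)
            for c in ("synonymous", "nonsynonymous")
            for h in (0.2, 0.4, 0.6)
        ]
        cmp = heteroplasmy_by_group(vs, grouping="consequence")
        assert cmp.p_value == pytest.approx(1.0, abs=0.05)

    def test_shifted_groups_detected_with_power(self):
        detections = 0
        for seed in range(100):
            rng = np.random.default_rng([55, seed])
            a = np.clip(rng.normal(0.3, 0.12, 20), 0.01, 0.99)
            b = np.clip(rng.normal(0.6, 0.12, 20), 0.01, 0.99)
            vs = [self._mv(h, consequence="synonymous") for h in a]
            vs += [self._mv(h, consequence="nonsynonymous") for h in b]
            cmp = heteroplasmy_by_group(vs, grouping="consequence")
            if cmp.p_value < 0.05:
                detections += 1
        assert detections >= 80

    def test_u_statistic_matches_exhaustive_pair_counting(self):
        from scipy.stats import mannwhitneyu

        a = [0.1, 0.3, 0.5, 0.7, 0.9]
        b = [0.2, 0.4, 0.6, 0.8, 0.85]
        u_pairs = sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x, y in itertools.product(a, b)
        )
        stat = mannwhitneyu(a, b, alternative="two-sided")
        assert stat.statistic == pytest.approx(u_pairs)

    def test_single_group_comparison_skipped_with_notice(self):
        vs = [self._mv(0.4, consequence="nonsynonymous")]
        cmp = heteroplasmy_by_group(vs, grouping="consequence")
        assert cmp.p_value is None and "skipped" in cmp.notice

    def test_five_region_display_grouping(self):
        assert region_group("D-loop") == "D-loop"
        assert region_group("MT-ND4") == "complex I"
        assert region_group("MT-CYB") == "complex III/IV"
        assert region_group("MT-TF") == "rRNA/tRNA"
        assert region_group("other") == "other"


def test_dnds_from_variants_routes_through_annotation(toy_coding_setup):
    genome, ann = toy_coding_setup
    from thymito.region_annotate import TranscriptAnnotation

    nuclear_ann = TranscriptAnnotation(
        [tx for tx in ann.transcripts if tx.chrom == "chr1"]
    )
    syn = make_variant(chrom="chr1", pos=106, ref="A", alt="G")  # CGA->CGG
    non = make_variant(chrom="chr1", pos=111, ref="T", alt="C")  # Phe->Ser
    res = dnds_from_variants([syn, non], nuclear_ann, genome)
    assert res.Sd == 1 and res.Nd == 1
    assert res.N + res.S == pytest.approx(15.0)
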