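"""Z-score statistic, tier assignment, annotation and the summary crosstab."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popaf import prioritize, simulate
from popaf.cohort_af import AFPanel, GenotypeMatrix, InputError, build_panel
from popaf.prioritize import (
    AFComparison,
    AnnotatedVariant,
    governing_z,
    summarize,
    tier_from_z,
    zscore,
)

probs = st.floats(min_value=0.0, max_value=1.0)
ans = st.integers(min_value=2, max_value=100_000)


class TestZscore:
    def test_equal_proportions_zero(self):
        assert zscore(0.3, 100, 0.3, 5000) == 0.0

    def test_degenerate_pooled_proportion_zero(self):
        assert zscore(0.0, 100, 0.0, 100) == 0.0
        assert zscore(1.0, 100, 1.0, 100) == 0.0

    def test_frozen_arithmetic_oracle(self):
        # exact-fraction evaluation of the pooled formula: pbar = 3/80
        assert zscore(0.05, 2000, 0.025, 2000) == pytest.approx(
            4.161251892882396, abs=1e-12)

    def test_nonpositive_allele_numbers_rejected(self):
        with pytest.raises(InputError):
            zscore(0.1, 0, 0.2, 100)

    @settings(deadline=None, max_examples=100)
    @given(probs, ans, probs, ans)
    def test_antisymmetry(self, p1, n1, p2, n2):
        assert zscore(p1, n1, p2, n2) == pytest.approx(-zscore(p2, n2, p1, n1),
                                                       abs=1e-10)

    @settings(deadline=None, max_examples=100)
    @given(probs, probs, ans, ans, probs)
    def test_monotone_in_p1(self, p1a, p1b, n1, n2, p2):
        lo, hi = sorted((p1a, p1b))
        assert zscore(lo, n1, p2, n2) <= zscore(hi, n1, p2, n2) + 1e-10

    def test_sign_follows_difference(self):
        assert zscore(0.4, 100, 0.2, 100) > 0
        assert zscore(0.1, 100, 0.2, 100) < 0

    def test_vectorized_matches_scalar(self):
        p1 = np.array([0.1, 0.5, 0.0])
        z = zscore(p1, 200, 0.3, 1000)
        for i, p in enumerate(p1):
            assert z[i] == pytest.approx(zscore(float(p), 200, 0.3, 1000))


class TestTiers:
    @pytest.mark.parametrize("z,tier", [
        (-4.0, "rare_strong"), (-4.5, "rare_strong"), (-1.96, "rare"),
        (-2.5, "rare"), (0.0, "neutral"), (1.95, "neutral"),
        (1.96, "common"), (3.99, "common"), (4.0, "common_strong"),
        (None, "unscored"),
    ])
    def test_threshold_ties_fall_in_tail(self, z, tier):
        assert tier_from_z(z) == tier

    def test_tier_partition_exhaustive_disjoint(self):
        zs = np.linspace(-6, 6, 1201)
        tiers = [tier_from_z(float(z)) for z in zs]
        assert set(tiers) == {"rare_strong", "rare", "neutral", "common",
                              "common_strong"}
        # strong tails nest inside weak tails
        for z, t in zip(zs, tiers):
            if t == "rare_strong":
                assert z <= -1.96
            if t == "common_strong":
                assert z >= 1.96


class TestGoverningZ:
    def _comps(self, zs):
        return [AFComparison(f"P{i}", 0.1, 100, 0.1, 100, z)
                for i, z in enumerate(zs)]

    def test_single_comparison_passthrough(self):
        assert governing_z(self._comps([2.5])) == 2.5

    def test_strictest_common_sign_takes_min_magnitude(self):
        assert governing_z(self._comps([5.1, 4.2, 6.0]),
                           mode="strictest_vs_all") == 4.2

    def test_strictest_sign_conflict_is_zero(self):
        assert governing_z(self._comps([3.0, -2.0]),
                           mode="strictest_vs_all") == 0.0

    def test_empty_is_unscored(self):
        assert governing_z([]) is None


def _one_locus_panel(af, an, pop="X", pos=100):
    return AFPanel(pop, pd.DataFrame({"chrom": ["1"], "pos": [pos], "ref": ["A"],
                                      "alt": ["G"], "af": [af], "an": [an]}))


class TestAnnotateVCF:
    def test_equal_afs_give_neutral_tier(self, toy_vcf_writer, tmp_path):
        vcf = toy_vcf_writer(tmp_path / "s.vcf", [("1", 100, "A", "G", 1)])
        local = _one_locus_panel(0.3, 2000)
        ref = _one_locus_panel(0.3, 10_000, "REF")
        (var,) = prioritize.annotate_vcf(vcf, local, [ref])
        assert var.tier == "neutral"
        assert var.z_gov == 0.0

    def test_absent_from_local_panel_is_unscored(self, toy_vcf_writer, tmp_path):
        vcf = toy_vcf_writer(tmp_path / "s.vcf", [("1", 999, "A", "G", 1)])
        local = _one_locus_panel(0.3, 2000)
        (var,) = prioritize.annotate_vcf(vcf, local, [_one_locus_panel(0.3, 100, "R")])
        assert var.tier == "unscored"
        summ = summarize([var])
        assert summ.n_unscored == 1
        assert summ.cells["local_af"]["all"] == 0

    def test_annotated_vcf_info_fields_round_trip(self, toy_vcf_writer, tmp_path):
        import pysam

        vcf = toy_vcf_writer(tmp_path / "s.vcf", [("1", 100, "A", "G", 2)])
        local = _one_locus_panel(0.5, 2000)
        ref = _one_locus_panel(0.1, 10_000, "REF")
        out = tmp_path / "annot.vcf"
        (var,) = prioritize.annotate_vcf(vcf, local, [ref], out=out)
        with pysam.VariantFile(str(out)) as vf:
            (rec,) = list(vf)
        assert rec.info["TIER"] == var.tier == "common_strong"
        assert rec.info["LOCAL_AF"] == pytest.approx(0.5)
        assert rec.info["Z_GOV"] == pytest.approx(var.z_gov, rel=1e-5)

    def test_inflated_loci_reach_strong_common_tier(self, tmp_path, toy_vcf_writer):
        """Loci simulated with an analytic z above 6 are flagged
        common_strong with high power."""
        n_loci, n_local, n_ref_s = 50, 1000, 5000
        p_ref, p_local = 0.10, 0.16  # analytic pooled z ≈ 7.8
        rng = np.random.default_rng(42)
        geno = rng.binomial(2, p_local, size=(n_local, n_loci)).astype(np.int8)
        loci = pd.DataFrame({"chrom": ["1"] * n_loci,
                             "pos": np.arange(1, n_loci + 1) * 10,
                             "ref": ["A"] * n_loci, "alt": ["G"] * n_loci})
        gm = GenotypeMatrix([f"S{i}" for i in range(n_local)], loci, geno)
        local = build_panel(gm, "LOCAL", min_call_rate=0.0)
        ref_af = rng.binomial(2 * n_ref_s, p_ref, size=n_loci) / (2 * n_ref_s)
        ref = AFPanel("REF", loci.assign(af=ref_af, an=2 * n_ref_s))
        vcf = toy_vcf_writer(tmp_path / "s.vcf",
                             [(r.chrom, r.pos, r.ref, r.alt, 1)
                              for r in loci.itertuples(index=False)])
        variants = prioritize.annotate_vcf(vcf, local, [ref])
        n_strong = sum(v.tier == "common_strong" for v in variants)
        assert n_strong >= 45

    def test_missing_reference_an_uses_default(self, toy_vcf_writer, tmp_path):
        vcf = toy_vcf_writer(tmp_path / "s.vcf", [("1", 100, "A", "G", 1)])
        local = _one_locus_panel(0.3, 2000)
        ref = AFPanel("R", pd.DataFrame({"chrom": ["1"], "pos": [100], "ref": ["A"],
                                         "alt": ["G"], "af": [0.2], "an": [np.nan]}))
        (var,) = prioritize.annotate_vcf(vcf, local, [ref])
        assert var.comparisons[0].ref_an == prioritize.DEFAULT_REF_AN


class TestSummarize:
    def test_empty_stream_all_zero(self):
        summ = summarize([])
        assert all(c == 0 for cell in summ.cells.values() for c in cell.values())

    def test_single_pathogenic_common_variant(self):
        v = AnnotatedVariant("1", 1, "A", "G", 1, "SNP", z_gov=5.0, tier="common_strong",
                             clinvar_class="pathogenic_or_risk")
        summ = summarize([v])
        assert summ.cells["clinvar_pathogenic_or_risk"]["z_ge"] == 1
        assert summ.cells["clinvar_non_benign"]["all"] == 1
        assert summ.cells["local_af"]["z_ge"] == 1  # 5.0 >= 4

    def test_matches_bruteforce_tally(self, rng):
        variants = []
        for i in range(20):
            z = float(rng.normal(0, 3))
            variants.append(AnnotatedVariant(
                "1", i + 1, "A", "G", 1, "SNP", z_gov=z, tier=tier_from_z(z),
                clinvar_class=rng.choice(["benign", "non_benign", "pathogenic_or_risk"]),
                sift_deleterious=bool(rng.random() < 0.5),
                polyphen_deleterious=bool(rng.random() < 0.5),
                protein_altering=bool(rng.random() < 0.5)))
        variants.append(AnnotatedVariant("1", 99, "A", "G", 1, "SNP"))  # unscored
        summ = summarize(variants)
        scored = [v for v in variants if v.tier != "unscored"]

        def brute(members, t):
            return {"all": len(members),
                    "z_le": sum(v.z_gov <= -t for v in members),
                    "z_ge": sum(v.z_gov >= t for v in members)}

        assert summ.cells["local_af"] == brute(scored, 4.0)
        assert summ.cells["clinvar_non_benign"] == brute(
            [v for v in scored if v.clinvar_class != "benign"], 1.96)
        assert summ.cells["sift_or_polyphen_deleterious"] == brute(
            [v for v in scored if v.sift_deleterious or v.polyphen_deleterious], 1.96)
        assert summ.cells["protein_altering"] == brute(
            [v for v in scored if v.protein_altering], 1.96)
        assert summ.n_unscored == 1

    def test_tail_counts_bounded_by_all(self, small_cohort, small_sample_vcf):
        gm, truth = small_cohort
        local = build_panel(gm, "LOCAL", min_call_rate=0.0)
        panels = simulate.emit_reference_panels(truth, n_ref=500)
        variants = prioritize.annotate_vcf(small_sample_vcf.path, local,
                                           list(panels.values()))
        summ = summarize(variants)
        for cell in summ.cells.values():
            assert cell["z_le"] + cell["z_ge"] <= cell["all"]


class TestNullCalibration:
    def test_null_tail_fractions(self):
        """With equal true AFs the two-proportion z is calibrated: ~5% of
        loci beyond |z|=1.96 and essentially none beyond |z|=4."""
        m = 100_000
        n1, n2 = 2 * 1000, 2 * 5000  # alleles
        rng = np.random.default_rng(123)
        p = rng.uniform(0.05, 0.95, size=m)
        p1 = rng.binomial(n1, p) / n1
        p2 = rng.binomial(n2, p) / n2
        z = zscore(p1, n1, p2, n2)
        frac_weak = float(np.mean(np.abs(z) >= 1.96))
        frac_strong = float(np.mean(np.abs(z) >= 4.0))
        assert 0.042 <= frac_weak <= 0.058
        assert frac_strong <= 5e-4
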