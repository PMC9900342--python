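import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pirnapipe.io import GenomeInterval, reverse_complement
from pirnapipe.preprocess import MatchCriteria
from pirnapipe.targeting import (
    TargetReport,
    categorize_pirnas,
    ks_compare,
    predict_targets,
    spearman_targets,
    target_load_summary,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCategorize:
    repeats = [(GenomeInterval("chr1", 100, 400), "SINEB1")]
    genes = [(GenomeInterval("chr1", 50, 1000), "geneA")]

    def test_unannotated(self):
        cats, _, _ = categorize_pirnas(
            [("p1", GenomeInterval("chr1", 5000, 5030))], self.repeats, self.genes
        )
        assert cats[0].category == "unannotated"

    def test_re_within_gencode_precedence(self):
        cats, _, _ = categorize_pirnas(
            [("p1", GenomeInterval("chr1", 150, 180))], self.repeats, self.genes
        )
        assert cats[0].category == "RE_within_GENCODE"
        assert cats[0].re_family == "SINEB1"

    def test_re_only(self):
        cats, _, _ = categorize_pirnas(
            [("p1", GenomeInterval("chr1", 150, 180))],
            self.repeats,
            [(GenomeInterval("chr1", 2000, 3000), "geneB")],
        )
        assert cats[0].category == "RE_only"

    def test_gene_only(self):
        cats, _, _ = categorize_pirnas(
            [("p1", GenomeInterval("chr1", 600, 630))], self.repeats, self.genes
        )
        assert cats[0].category == "GENCODE_element"

    def test_missing_chromosome_rejected(self):
        with pytest.raises(ValueError):
            categorize_pirnas(
                [("p1", GenomeInterval("chrX", 0, 30))], self.repeats, self.genes
            )

    def test_precedence_matches_overlap_table_oracle(self, rng):
        repeats = [
            (GenomeInterval("chr1", int(s), int(s) + 100), fam)
            for s, fam in zip(rng.integers(0, 5000, 10), ["LINE1", "SINEB1"] * 5)
        ]
        genes = [
            (GenomeInterval("chr1", int(s), int(s) + 400), f"g{i}")
            for i, s in enumerate(rng.integers(0, 5000, 5))
        ]
        loci = [
            (f"p{i}", GenomeInterval("chr1", int(s), int(s) + 30))
            for i, s in enumerate(rng.integers(0, 5200, 60))
        ]
        cats, _, _ = categorize_pirnas(loci, repeats, genes)
        for (pid, locus), cat in zip(loci, cats):
            re_hit = any(iv.overlaps(locus) for iv, _ in repeats)
            gene_hit = any(iv.overlaps(locus) for iv, _ in genes)
            if re_hit and gene_hit:
                want = "RE_within_GENCODE"
            elif re_hit:
                want = "RE_only"
            elif gene_hit:
                want = "GENCODE_element"
            else:
                want = "unannotated"
            assert cat.category == want

    def test_planted_family_mixture_recovered(self):
        # 47% 5S_rRNA / 40% tRNA / 13% LINE1 planted over 5,000 loci
        rng = np.random.default_rng(99)
        families = rng.choice(
            ["5S_rRNA", "tRNA", "LINE1"], size=5000, p=[0.47, 0.40, 0.13]
        )
        repeats, loci = [], []
        for i, fam in enumerate(families):
            start = 100 * i
            repeats.append((GenomeInterval("chr1", start, start + 60), str(fam)))
            loci.append((f"p{i}", GenomeInterval("chr1", start + 10, start + 40)))
        _, _, fam_props = categorize_pirnas(loci, repeats, [])
        assert fam_props["5S_rRNA"] == pytest.approx(0.47, abs=0.02)
        assert fam_props["tRNA"] == pytest.approx(0.40, abs=0.02)
        assert fam_props["LINE1"] == pytest.approx(0.13, abs=0.02)


class TestPredictTargets:
    def test_antisense_target(self, rng):
        pirna = random_seq(rng, 28)
        tx = random_seq(rng, 100) + reverse_complement(pirna) + random_seq(rng, 100)
        sites, reports = predict_targets([("p1", pirna, 10.0)], [("t1", "g1", tx)])
        assert reports["g1"].is_target
        assert reports["g1"].antisense_sites == 1

    def test_sense_homology_target(self, rng):
        pirna = random_seq(rng, 28)
        tx = random_seq(rng, 50) + pirna + random_seq(rng, 50)
        sites, reports = predict_targets([("p1", pirna, 5.0)], [("t1", "g1", tx)])
        assert reports["g1"].sense_sites == 1

    def test_two_mismatch_site_not_a_target(self, rng):
        from pirnapipe.preprocess import best_ungapped_hit

        pirna = random_seq(rng, 30)
        corrupted = list(pirna)
        corrupted[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[corrupted[5]]
        corrupted[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[corrupted[25]]
        tx = random_seq(rng, 60) + "".join(corrupted) + random_seq(rng, 60)
        criteria = MatchCriteria(orientations=("sense",))
        # exhaustive sliding-window confirmation that no window qualifies
        assert best_ungapped_hit(pirna, tx, criteria) is None
        _, reports = predict_targets([("p1", pirna, 1.0)], [("t1", "g1", tx)], criteria)
        assert not reports["g1"].is_target

    def test_unique_counting_idempotent(self, rng):
        pirna = random_seq(rng, 27)
        # same piRNA hits the same gene in two transcripts and twice in one
        tx1 = pirna + random_seq(rng, 30) + pirna
        tx2 = random_seq(rng, 20) + reverse_complement(pirna) + random_seq(rng, 20)
        _, reports = predict_targets(
            [("p1", pirna, 7.0)], [("t1", "g1", tx1), ("t2", "g1", tx2)]
        )
        assert reports["g1"].n_unique_targeting_pirnas == 1
        assert reports["g1"].summed_targeting_tpm == pytest.approx(7.0)

    def test_summed_tpm_hand_oracle(self, rng):
        pirnas = [(f"p{i}", random_seq(rng, 28), tpm) for i, tpm in enumerate([10.0, 20.0, 30.0])]
        tx = "".join(seq for _, seq, _ in pirnas)
        _, reports = predict_targets(pirnas, [("t1", "g1", tx)])
        assert reports["g1"].n_unique_targeting_pirnas == 3
        assert reports["g1"].summed_targeting_tpm == pytest.approx(60.0)

    def test_untargeted_gene_zeroes(self, rng):
        _, reports = predict_targets(
            [("p1", random_seq(rng, 28), 5.0)], [("t1", "g1", random_seq(rng, 80))]
        )
        assert reports["g1"].n_unique_targeting_pirnas == 0
        assert reports["g1"].summed_targeting_tpm == 0.0

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            predict_targets([("p", "A" * 28, 1.0)], [])


class TestLocusOverlapMode:
    def test_overlap_defines_target(self):
        from pirnapipe.targeting import predict_targets_by_locus

        loci = [("p1", GenomeInterval("chr1", 100, 130)), ("p2", GenomeInterval("chr1", 900, 930))]
        genes = [(GenomeInterval("chr1", 50, 500), "g1"), (GenomeInterval("chr1", 600, 800), "g2")]
        out = predict_targets_by_locus(loci, genes)
        assert out["g1"] == {"p1"}
        assert out["g2"] == set()


class TestTargetLoadSummary:
    def test_summary_fields(self):
        reports = [
            TargetReport("g1", 3, 60.0, is_target=True, modulated=True),
            TargetReport("g2", 0, 0.0, is_target=False, modulated=True),
            TargetReport("g3", 11, 500.0, is_target=True, modulated=False),
        ]
        s = target_load_summary(reports)
        assert s["max_unique_pirnas"] == 11
        assert s["max_summed_tpm"] == 500.0
        assert s["modulated_targets"] == 1
        assert s["modulated_nontargets"] == 1


def ks_oracle_exact_p(a, b):
    """Independent permutation enumeration for the exact two-sample KS p."""

    def d_stat(x, y):
        xs, ys = sorted(x), sorted(y)
        grid = xs + ys
        best = 0.0
        for g in grid:
            fx = sum(1 for v in xs if v <= g) / len(xs)
            fy = sum(1 for v in ys if v <= g) / len(ys)
            best = max(best, abs(fx - fy))
        return best

    pooled = list(a) + list(b)
    d_obs = d_stat(list(a), list(b))
    n1 = len(a)
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        x = [pooled[i] for i in combo]
        y = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if d_stat(x, y) >= d_obs - 1e-12:
            extreme += 1
    return d_obs, extreme / total


class TestKsCompare:
    def test_identical_samples(self):
        d, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_compare([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert d == 1.0

    def test_exact_p_matches_permutation_oracle(self, rng):
        a = list(rng.normal(0, 1, 4))
        b = list(rng.normal(1, 1, 4))
        d, p = ks_compare(a, b)
        d_o, p_o = ks_oracle_exact_p(a, b)
        assert d == pytest.approx(d_o)
        assert p == pytest.approx(p_o)

    def test_exact_p_matches_scipy_exact(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.5, 1, 6)
        d, p = ks_compare(a, b)
        ref = stats.ks_2samp(a, b, method="exact")
        assert d == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_asymptotic_branch_reasonable(self, rng):
        a = rng.normal(0, 1, 300)
        b = rng.normal(0, 1, 300)
        d, p = ks_compare(a, b)
        assert 0 <= d <= 1
        assert 0 <= p <= 1
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestSpearman:
    def test_monotone_rho_one(self):
        rho, _ = spearman_targets([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_antimonotone_rho_minus_one(self):
        rho, _ = spearman_targets([1, 2, 3, 4], [5, 4, 3, 2])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0]
        rho, _ = spearman_targets(x, y)
        rx = stats.rankdata(x)  # average ranks
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_targets([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
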