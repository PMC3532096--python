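import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bdsmap.gblup import ScanResult
from bdsmap.io import GenotypeDataset
from bdsmap.selection import (SelectionIntensityGLS, ase_variance,
                              genes_near_snps, genetic_trend,
                              ld_signed_correlation, prune_perfect_ld,
                              rank_top_snps, read_gene_annotation)
from conftest import make_dataset


class TestAseVariance:
    @pytest.mark.parametrize("p,a,expected", [(0.5, 1.0, 0.5),
                                              (0.0, 3.0, 0.0),
                                              (1.0, -2.0, 0.0),
                                              (0.2, 2.0, 2 * 0.2 * 0.8 * 4)])
    def test_formula(self, p, a, expected):
        assert ase_variance(p, a) == pytest.approx(expected)

    def test_sums_to_direct_genetic_variance(self):
        """Independent loci: sum 2 p q a^2 ~ Var(Z alpha) computed directly."""
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, 400)
        alpha = rng.normal(0, 1, 400)
        M = rng.binomial(2, p, size=(4000, 400)).astype(float)
        direct = np.var(M @ alpha)
        assert ase_variance(p, alpha).sum() == pytest.approx(direct, rel=0.1)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            ase_variance(1.2, 1.0)


def _scan(var, chrom=None, pos=None):
    m = len(var)
    t = pd.DataFrame({
        "snp": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1),
        "freq": 0.5, "ase": np.sqrt(np.asarray(var) / 0.5),
        "var_2pqa2": var})
    return ScanResult(t, kind="gblup")


class TestRankTopSnps:
    def test_fraction_rounds_to_nearest(self):
        scan = _scan(np.linspace(1, 0, 200))
        assert len(rank_top_snps(scan, fraction=0.0211)) == 4  # round(4.22)

    def test_published_fraction_arithmetic(self):
        # 2.11% of 44,817 SNPs rounds to 946; the explicit-k entry point
        # accepts the reported 948 as well
        assert int(np.rint(0.0211 * 44_817)) == 946

    def test_k_equal_m_returns_everything(self):
        scan = _scan([3.0, 1.0, 2.0])
        assert set(rank_top_snps(scan, k=3)) == {"s0", "s1", "s2"}

    def test_zero_variance_snps_never_displace(self):
        base = _scan([5.0, 4.0, 3.0])
        padded = _scan([5.0, 4.0, 3.0, 0.0, 0.0])
        assert rank_top_snps(base, k=2) == rank_top_snps(padded, k=2)

    def test_argument_validation(self):
        scan = _scan([1.0, 2.0])
        with pytest.raises(ValueError):
            rank_top_snps(scan)
        with pytest.raises(ValueError):
            rank_top_snps(scan, k=5)
        with pytest.raises(ValueError):
            rank_top_snps(scan, fraction=0.5, k=1)


class TestLDCorrelation:
    def test_unit_diagonal_and_duplicate_column(self):
        g = make_dataset(50, 5, seed=71)
        calls = g.calls.copy()
        calls[:, 1] = calls[:, 0]
        calls[:, 2] = 2 - calls[:, 0]  # perfect negative correlation
        g = GenotypeDataset(g.animals, g.birth_date, g.loci, calls)
        V = ld_signed_correlation(g, list(g.loci["snp"]))
        assert V.iloc[0, 0] == 1.0
        assert V.iloc[0, 1] == pytest.approx(1.0)
        assert V.iloc[0, 2] == pytest.approx(-1.0)

    def test_matches_brute_force_pairwise(self):
        g = make_dataset(60, 10, seed=72)
        V = ld_signed_correlation(g, list(g.loci["snp"])).to_numpy()
        M = g.dosages()
        for a in range(10):
            for b in range(10):
                r = np.corrcoef(M[:, a], M[:, b])[0, 1]
                assert V[a, b] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected(self):
        g = make_dataset(30, 3, seed=73)
        calls = g.calls.copy()
        calls[:, 1] = 1
        g = GenotypeDataset(g.animals, g.birth_date, g.loci, calls)
        with pytest.raises(ValueError, match="zero-variance"):
            ld_signed_correlation(g, list(g.loci["snp"]))


class TestPrunePerfectLD:
    def test_no_perfect_pairs_unchanged(self):
        g = make_dataset(80, 12, seed=74)
        snps = list(g.loci["snp"])
        assert prune_perfect_ld(g, snps) == snps

    def test_identical_run_keeps_first(self):
        g = make_dataset(40, 6, seed=75)
        calls = g.calls.copy()
        calls[:, 2] = calls[:, 1]
        calls[:, 3] = 2 - calls[:, 1]  # r = -1 also counts as perfect
        g = GenotypeDataset(g.animals, g.birth_date, g.loci, calls)
        snps = list(g.loci["snp"])
        pruned = prune_perfect_ld(g, snps)
        assert pruned == [snps[0], snps[1], snps[4], snps[5]]

    def test_planted_runs_removed_count(self):
        g = make_dataset(50, 20, seed=76)
        calls = g.calls.copy()
        planted = 0
        for start in (3, 11):
            for k in (1, 2):
                calls[:, start + k] = calls[:, start]
                planted += 1
        g = GenotypeDataset(g.animals, g.birth_date, g.loci, calls)
        snps = list(g.loci["snp"])
        assert len(snps) - len(prune_perfect_ld(g, snps)) == planted


class TestIntensityGLS:
    def _inputs(self, seed=0, s=150):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.1, 0.9, s)
        traits = pd.DataFrame({
            "t1": rng.normal(0, 1, s),
            "t2": rng.normal(0, 1, s),
        })
        x1 = p * (1 - p) * traits["t1"] / traits["t1"].std()
        y = 2.0 * x1 + rng.normal(0, 0.05, s)
        return y, traits, p

    def test_identity_v_reduces_to_ols(self):
        import statsmodels.api as sm

        y, traits, p = self._inputs()
        res = SelectionIntensityGLS(y, traits, p).fit()
        x = p * (1 - p) * traits["t1"] / traits["t1"].to_numpy().std()
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res["t1"].i_hat == pytest.approx(ols.params.iloc[1], rel=1e-10)
        assert res["t1"].p_value == pytest.approx(ols.pvalues.iloc[1], rel=1e-8)

    def test_invariant_to_positive_rescaling_of_trait_ases(self):
        y, traits, p = self._inputs(seed=1)
        a = SelectionIntensityGLS(y, traits, p).fit()
        b = SelectionIntensityGLS(y, traits * 37.5, p).fit()
        assert a["t1"].i_hat == pytest.approx(b["t1"].i_hat)
        assert a["t2"].se == pytest.approx(b["t2"].se)

    def test_self_regression_dominates(self):
        """Regressing birth-date ASEs on themselves (as if a trait) explains
        more variance than any genuinely different trait."""
        rng = np.random.default_rng(2)
        y, traits, p = self._inputs(seed=2)
        traits = traits.copy()
        traits["self"] = y / (p * (1 - p))
        res = SelectionIntensityGLS(y, traits, p).fit()
        assert res["self"].adjusted_R2 > res["t1"].adjusted_R2
        assert res["self"].adjusted_R2 > res["t2"].adjusted_R2

    def test_singular_v_rejected(self):
        y, traits, p = self._inputs(seed=3, s=20)
        V = np.ones((20, 20))
        with pytest.raises(np.linalg.LinAlgError, match="prune"):
            SelectionIntensityGLS(y, traits, p, V)

    def test_joint_model_reports_condition_number(self):
        y, traits, p = self._inputs(seed=4)
        res = SelectionIntensityGLS(y, traits, p).fit()
        assert res.condition_number > 0
        assert res.joint_adjusted_R2 <= 1


class TestGeneticTrend:
    def test_noiseless_linear_data(self):
        t = np.linspace(1950, 2000, 60)
        y = 2.81 * (t - 1950)
        fit = genetic_trend(y, t)
        assert fit.linear_slope == pytest.approx(2.81)
        assert abs(fit.quadratic_coef) < 1e-8
        assert fit.linear_adj_r2 == pytest.approx(1.0)

    def test_rise_then_fall_prefers_quadratic(self):
        rng = np.random.default_rng(6)
        t = np.linspace(1950, 2000, 300)
        y = -0.01 * (t - 1985) ** 2 + rng.normal(0, 0.5, 300)
        fit = genetic_trend(y, t)
        assert fit.prefers_quadratic
        assert fit.quadratic_adj_r2 > fit.linear_adj_r2

    def test_permuted_dates_give_uniform_p(self):
        rng = np.random.default_rng(7)
        t = np.linspace(1950, 2000, 120)
        y = 1.5 * (t - 1950) + rng.normal(0, 5, 120)
        ps = [genetic_trend(y, rng.permutation(t)).linear_p
              for _ in range(150)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            genetic_trend([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            genetic_trend([1, 2, 3, 4], [5, 5, 5, 5])


class TestGeneWindows:
    def _genes(self):
        return pd.DataFrame({"gene": ["g1", "g2"], "chrom": ["1", "2"],
                             "start": [100_000, 50_000],
                             "end": [120_000, 60_000]})

    def test_within_window_distance(self):
        snps = pd.DataFrame({"snp": ["a"], "chrom": ["1"], "pos": [10_000]})
        hits = genes_near_snps(snps, self._genes())
        assert len(hits) == 1
        assert hits[0].distance_bp == 90_000

    def test_outside_window_excluded(self):
        snps = pd.DataFrame({"snp": ["a"], "chrom": ["1"], "pos": [250_000]})
        assert genes_near_snps(snps, self._genes()) == []

    def test_inside_gene_distance_zero(self):
        snps = pd.DataFrame({"snp": ["a"], "chrom": ["1"], "pos": [110_000]})
        hits = genes_near_snps(snps, self._genes())
        assert hits[0].distance_bp == 0

    def test_chromosome_mismatch_rejected(self):
        snps = pd.DataFrame({"snp": ["a"], "chrom": ["7"], "pos": [1]})
        with pytest.raises(ValueError, match="absent"):
            genes_near_snps(snps, self._genes())

    def test_bed_and_gff3_coordinate_conventions(self, tmp_path):
        (tmp_path / "g.bed").write_text("1\t99999\t120000\tg1\n")
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100000\t120000\t.\t+\t.\tID=g1;Name=g1\n"
            "1\tsrc\tmRNA\t100000\t120000\t.\t+\t.\tID=t1\n")
        bed = read_gene_annotation(tmp_path / "g.bed", format="bed")
        gff = read_gene_annotation(tmp_path / "g.gff3", format="gff3")
        pd.testing.assert_frame_equal(bed, gff)

    def test_strand_irrelevant(self, tmp_path):
        (tmp_path / "g.gff3").write_text(
            "1\tsrc\tgene\t100\t200\t.\t-\t.\tID=gm\n")
        genes = read_gene_annotation(tmp_path / "g.gff3", format="gff3")
        snps = pd.DataFrame({"snp": ["a"], "chrom": ["1"], "pos": [150]})
        assert genes_near_snps(snps, genes, window=10)[0].distance_bp == 0
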