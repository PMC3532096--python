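import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bdsmap.io import read_genotypes, read_pedigree, qc_filter
from bdsmap.simulate import (FIXTURES, SimConfig, make_fixture_bundle,
                             simulate_confounded_families,
                             simulate_neutral_drift,
                             simulate_selected_population)


def _small_cfg(**kw):
    base = dict(n_founders=60, births_per_year=60, start_year=1950,
                end_year=1965, n_chromosomes=3, n_snps_per_chromosome=20,
                n_qtl=6, n_traits=2, heritabilities=(0.4, 0.4),
                ebv_accuracy_r2=(0.7, 0.7),
                index_eras=[(1950, np.array([1.0, 0.0]))], seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_counts_validated(self):
        with pytest.raises(ValueError):
            _small_cfg(n_founders=0)
        with pytest.raises(ValueError):
            _small_cfg(n_qtl=1000)
        with pytest.raises(ValueError):
            _small_cfg(heritabilities=(1.5, 0.4))

    def test_era_weights_switch_at_boundaries(self):
        cfg = _small_cfg(index_eras=[(1950, np.array([1.0, 0.0])),
                                     (1960, np.array([-1.0, 0.0]))])
        assert cfg.era_weights(1955)[0] == 1.0
        assert cfg.era_weights(1960)[0] == -1.0
        assert cfg.era_weights(1999)[0] == -1.0

    def test_config_logged_verbatim(self, tmp_path):
        cfg = _small_cfg()
        cfg.to_text(tmp_path / "cfg.txt")
        text = (tmp_path / "cfg.txt").read_text()
        assert "n_founders = 60" in text
        assert "generation_interval = 5.0" in text


class TestForwardSimulator:
    def test_fixed_seed_bit_identical(self):
        a = simulate_selected_population(_small_cfg(seed=5))
        b = simulate_selected_population(_small_cfg(seed=5))
        np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
        pd.testing.assert_frame_equal(a.tbv, b.tbv)
        pd.testing.assert_frame_equal(a.pedigree.records, b.pedigree.records)

    def test_offspring_mendelian_consistent(self):
        """Every offspring call must be attainable from one gamete of each
        parent: parent dosage 0 -> gamete 0, 2 -> 1, 1 -> either."""
        pop = simulate_selected_population(_small_cfg(seed=6))
        g = pop.genotypes
        idx = {a: i for i, a in enumerate(g.animals)}
        checked = 0
        for _, r in pop.pedigree.records.iterrows():
            if r["sire"] == "0" or r["animal"] not in idx:
                continue
            kid = g.calls[idx[r["animal"]]]
            s = g.calls[idx[r["sire"]]]
            d = g.calls[idx[r["dam"]]]
            lo = (s == 2).astype(int) + (d == 2).astype(int)
            hi = 2 - (s == 0).astype(int) - (d == 0).astype(int)
            assert ((kid >= lo) & (kid <= hi)).all()
            checked += 1
        assert checked > 500

    def test_random_mating_has_no_genetic_trend(self):
        slopes = []
        for s in range(20):
            cfg = _small_cfg(index_eras=[(1950, np.array([0.0, 0.0]))],
                             sire_usage_skew=0.0, seed=100 + s)
            pop = simulate_selected_population(cfg)
            bd = pop.pedigree.birth_dates()
            tbv = pop.tbv["trait1"]
            slopes.append(np.polyfit(bd.to_numpy(), tbv.to_numpy(), 1)[0])
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean()) < 2 * se + 1e-12

    def test_selection_produces_positive_trend_and_expected_response(self):
        """Truncation selection at 20% on a criterion with accuracy^2 = h2 =
        0.4: the realized frequency change at the largest QTL matches the
        classical prediction i p q a / sigma within 50% on average."""
        ratios, trends = [], []
        for s in range(20):
            cfg = SimConfig(
                n_founders=400, births_per_year=400, start_year=1950,
                end_year=1975, discrete_generations=True,
                n_chromosomes=10, n_snps_per_chromosome=10, n_qtl=10,
                n_traits=1, heritabilities=(0.4,), ebv_accuracy_r2=(0.4,),
                index_eras=[(1950, np.array([1.0]))],
                proportion_sires=0.20, proportion_dams=0.20,
                sire_usage_skew=0.0, seed=s)
            pop = simulate_selected_population(cfg)
            eff = pop.qtl_effects["trait1"]
            q = eff.abs().idxmax()
            a = eff[q]
            traj = pop.trajectories[q].to_numpy()
            sd_g = pop.tbv["trait1"].iloc[:400].std()
            sigma_c = sd_g / np.sqrt(0.4)
            i = stats.norm.pdf(stats.norm.ppf(0.8)) / 0.2
            pred = np.sum(i * traj[:-1] * (1 - traj[:-1]) * a / sigma_c)
            ratios.append((traj[-1] - traj[0]) / pred)
            bd = pop.pedigree.birth_dates()
            trends.append(np.polyfit(bd, pop.tbv["trait1"], 1)[0])
        assert 0.5 < np.mean(ratios) < 1.5
        assert np.mean(trends) > 0

    def test_extinction_reported_with_year(self):
        cfg = _small_cfg(min_parent_age=30, max_parent_age=40)
        with pytest.raises(RuntimeError, match="1951"):
            simulate_selected_population(cfg)

    def test_heterozygosity_decays_at_drift_rate(self):
        """Neutral closed population: H_t ~ H_0 (1 - 1/(2Ne))^t.  A single
        run's decay is dominated by the shared realized pedigree, so the
        fitted rate is averaged over replicate populations."""
        rates = []
        for seed in range(11, 17):
            cfg = SimConfig(
                n_founders=50, births_per_year=50, start_year=1950,
                end_year=2050, discrete_generations=True,
                n_chromosomes=40, n_snps_per_chromosome=5, n_qtl=0,
                n_traits=1, heritabilities=(0.4,), ebv_accuracy_r2=(0.7,),
                index_eras=[(1950, np.array([0.0]))], sire_usage_skew=0.0,
                seed=seed)
            pop = simulate_selected_population(cfg)
            traj = pop.trajectories.to_numpy()
            H = (2 * traj * (1 - traj)).mean(axis=1)
            rates.append(-np.polyfit(np.arange(H.size), np.log(H), 1)[0])
        expected = -np.log(1 - 1 / (2 * 50))
        assert abs(np.mean(rates) - expected) / expected < 0.25

    def test_family_biased_sampling_schedule(self):
        cfg = _small_cfg(n_genotyped_per_year=20,
                         sampling_family_bias={0: {0: 50.0}, 1: {1: 50.0}},
                         seed=12)
        pop = simulate_selected_population(cfg)
        assert pop.genotypes.n_animals < len(pop.pedigree)

    def test_missingness_injection(self):
        pop = simulate_selected_population(_small_cfg(missing_rate=0.05,
                                                      seed=13))
        frac = (pop.genotypes.calls == -1).mean()
        assert 0.02 < frac < 0.08


class TestNeutralDrift:
    def test_variance_matches_binomial(self):
        d = simulate_neutral_drift(200, np.full(100_000, 0.5), 1, seed=1)
        dp = d.trajectories[1] - d.trajectories[0]
        assert np.var(dp) == pytest.approx(0.25 / 400, rel=0.05)

    def test_huge_ne_freezes_frequencies(self):
        d = simulate_neutral_drift(1e7, np.full(1000, 0.5), 1, seed=2)
        assert np.abs(d.trajectories[1] - 0.5).max() < 0.01

    def test_fixation_is_absorbing(self):
        d = simulate_neutral_drift(5, np.full(2000, 0.5), 60, seed=3)
        traj = d.trajectories
        fixed_at = np.argmax((traj == 0) | (traj == 1), axis=0)
        for j in np.flatnonzero(fixed_at > 0):
            tail = traj[fixed_at[j]:, j]
            assert (tail == tail[0]).all()

    def test_cohort_samples_drawn_at_requested_generations(self):
        d = simulate_neutral_drift(100, np.full(50, 0.5), 3,
                                   sample_sizes={0: 10, 3: 20}, seed=4)
        assert d.cohorts[0].shape == (10, 50)
        assert d.cohorts[3].shape == (20, 50)
        assert set(d.cohorts) == {0, 3}

    def test_invalid_start_rejected(self):
        with pytest.raises(ValueError):
            simulate_neutral_drift(100, np.array([0.0]), 1)


class TestConfoundedFamilies:
    def test_birth_dates_track_families(self):
        g = simulate_confounded_families(seed=3)
        assert g.n_animals == 300 and g.n_snps == 1000
        assert not g.has_missing()
        assert (g.allele_freqs() > 0).all() and (g.allele_freqs() < 1).all()


class TestFixtureBundles:
    def test_unknown_name_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture_bundle("nope", tmp_path)

    def test_tiny_qc_has_one_violation_per_filter(self, tmp_path):
        paths = make_fixture_bundle("tiny_qc", tmp_path, seed=1)
        g = read_genotypes(paths["genotypes"], format="counts_csv")
        g2, rep = qc_filter(g)
        assert rep.snps_removed_call_rate == 1
        assert rep.snps_removed_maf == 1
        assert rep.snps_removed_hwe == 1
        assert rep.animals_removed_call_rate == 1

    def test_selected_sweep_round_trips(self, tmp_path):
        paths = make_fixture_bundle("selected_sweep", tmp_path, seed=1)
        g = read_genotypes(paths["genotypes"], format="ped_map")
        ped = read_pedigree(paths["pedigree"])
        truth = pd.read_csv(paths["truth"], sep="\t")
        assert g.n_snps == 500
        assert truth["qtl"].iloc[0] in set(g.loci["snp"])
        assert set(g.animals) <= set(ped.animals)

    def test_all_fixture_names_registered(self):
        assert set(FIXTURES) == {"tiny_qc", "gblup_oracle",
                                 "confounded_sampling", "selected_sweep",
                                 "neutral_null"}
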