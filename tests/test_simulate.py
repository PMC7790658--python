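"""The synthetic generators reproduce the structure the analyses assume."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chi2_contingency, chisquare, spearmanr

import hybridtrace as ht
from hybridtrace.simulate import (PopulationSpec, SimEnvSpec,
                                  SimLandscapeSpec, SimPanelSpec,
                                  simulate_admixed_landscape,
                                  simulate_env_presence,
                                  simulate_reference_panels)


class TestReferencePanels:
    def test_fixed_differences_give_opposite_homozygotes(self):
        spec = SimPanelSpec(n_loci_nuclear=10, n_diagnostic=10, delta=1.0,
                            missing_rate=0.0, include_mtdna=False, seed=1)
        g, s = simulate_reference_panels(spec, n_marmoratus=5, n_pygmaeus=5)
        species = s.species_of(g.individual_ids)
        assert np.all(g.dosage[species == "M"] == 2)
        assert np.all(g.dosage[species == "P"] == 0)

    def test_missing_fraction_within_binomial_ci(self):
        # 238 individuals x 55 loci at the study's 2.3% missing-call rate
        spec = SimPanelSpec(n_loci_nuclear=54, n_diagnostic=54,
                            include_mtdna=True, missing_rate=0.023, seed=2)
        g, _ = simulate_reference_panels(spec)
        n_cells = g.dosage.size
        lo, hi = binom.ppf([0.005, 0.995], n_cells, 0.023) / n_cells
        assert lo <= g.missing_mask.mean() <= hi

    def test_zero_delta_yields_non_diagnostic_markers(self):
        spec = SimPanelSpec(n_loci_nuclear=6, n_diagnostic=6, delta=0.0,
                            missing_rate=0.0, include_mtdna=False, seed=3)
        g, s = simulate_reference_panels(spec)
        kappas = [ht.allele_kappa(g, s, l) for l in g.locus_ids]
        assert np.all(np.abs(kappas) < 0.1)

    def test_missingness_independent_of_genotype(self):
        spec = SimPanelSpec(n_loci_nuclear=40, n_diagnostic=0,
                            background_delta=0.0, missing_rate=0.2,
                            include_mtdna=False, seed=4)
        g, _ = simulate_reference_panels(spec, 400, 400)
        # contingency of missingness vs the (unmasked) column mean halves
        missing_per_ind = g.missing_mask.sum(axis=1)
        mean_dose = np.nanmean(g.dosage, axis=1)
        table = pd.crosstab(missing_per_ind > np.median(missing_per_ind),
                            mean_dose > np.median(mean_dose))
        assert chi2_contingency(table).pvalue > 0.01

    def test_same_seed_same_dataset(self):
        spec = SimPanelSpec(seed=5)
        g1, _ = simulate_reference_panels(spec)
        g2, _ = simulate_reference_panels(spec)
        assert g1 == g2


class TestAdmixedLandscape:
    def _single_pop(self, q_mean, n=200, n_loci=20, seed=0, families=0,
                    q_sd=0.0):
        panel = SimPanelSpec(n_loci_nuclear=n_loci, n_diagnostic=n_loci,
                             delta=1.0, missing_rate=0.0,
                             include_mtdna=False, seed=seed)
        land = SimLandscapeSpec(populations=[
            PopulationSpec("pond", 39.0, -9.0, n, q_mean=q_mean,
                           n_families=families)], q_sd=q_sd, seed=seed)
        return simulate_admixed_landscape(panel, land)

    def test_half_admixture_centres_dosage_at_one(self):
        g, _ = self._single_pop(0.5, n=300)
        mean = g.dosage.mean(axis=0)
        se = np.sqrt(0.5 / 300)  # binomial(2, .5) variance 0.5
        assert np.all(np.abs(mean - 1.0) < 3 * se + 0.05)

    def test_degenerate_tail_gives_pure_p_landscape(self):
        panel = SimPanelSpec(n_loci_nuclear=5, n_diagnostic=5, delta=1.0,
                             missing_rate=0.0, include_mtdna=False, seed=6)
        land = SimLandscapeSpec(populations=[
            PopulationSpec("enclave", 39.4, -9.1, 5, q_mean=0.9),
            PopulationSpec("far", 41.0, -7.0, 5, q_mean=None)],
            q0=0.0, lam=1e-9, q_sd=0.0, seed=6)
        g, s = simulate_admixed_landscape(panel, land)
        far = g.take_individuals(s.individuals_in("far"))
        assert np.all(far.dosage == 0)

    def test_family_sampling_inflates_hwe_rejections(self):
        """Two full-sib families per pond break Hardy-Weinberg more often
        than the nominal 5% of an exact test."""
        rejections = 0
        n_ponds = 500
        for seed in range(n_ponds):
            g, _ = self._single_pop(0.5, n=20, n_loci=1, seed=seed,
                                    families=2, q_sd=0.05)
            d = g.dosage[:, 0]
            counts = (int((d == 2).sum()), int((d == 1).sum()),
                      int((d == 0).sum()))
            rejections += ht.hwe_exact(*counts) <= 0.05
        assert rejections / n_ponds > 0.05

    def test_unrelated_constant_q_conforms_to_hwe(self):
        """Without family structure genotype counts match Hardy-Weinberg."""
        g, _ = self._single_pop(0.4, n=2000, n_loci=1, seed=9)
        d = g.dosage[:, 0]
        counts = np.array([(d == 2).sum(), (d == 1).sum(), (d == 0).sum()])
        q = (2 * counts[0] + counts[1]) / (2 * counts.sum())
        expected = counts.sum() * np.array(
            [q ** 2, 2 * q * (1 - q), (1 - q) ** 2])
        assert chisquare(counts, expected, ddof=1).pvalue > 0.01

    def test_family_size_exceeding_population_errors(self):
        with pytest.raises(ValueError, match="families exceed"):
            PopulationSpec("pond", 39.0, -9.0, 3, q_mean=0.5, n_families=4)

    def test_dosages_within_ploidy_range(self):
        g, _ = self._single_pop(0.7, n=50, seed=10, families=5, q_sd=0.1)
        valid = np.isnan(g.dosage) | np.isin(g.dosage, (0, 1, 2))
        assert valid.all()


class TestEnvPresence:
    def test_steep_logistic_separates_classes_perfectly(self):
        spec = SimEnvSpec(n_localities=500, slope=-1e6, intercept=5e7,
                          seed=1)  # threshold at driver = 50
        table = simulate_env_presence(spec)
        a, _ = ht.auc(table["bio17"], table["species"] == "M")
        assert a == 1.0

    def test_unit_target_is_exact_monotone_transform(self):
        spec = SimEnvSpec(n_localities=200, nuisance={"bio01": 1.0}, seed=2)
        table = simulate_env_presence(spec)
        assert spearmanr(table["bio17"], table["bio01"]).statistic == 1.0

    @pytest.mark.parametrize("target", [0.65, -0.4])
    def test_calibrated_targets_within_tolerance(self, target):
        spec = SimEnvSpec(n_localities=400, nuisance={"x": target}, seed=3)
        table = simulate_env_presence(spec)
        r = spearmanr(table["bio17"], table["x"]).statistic
        assert abs(r - target) <= 0.02

    def test_unattainable_correlation_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            SimEnvSpec(nuisance={"x": 1.5})

    def test_label_frequency_tracks_logistic(self):
        spec = SimEnvSpec(n_localities=20000, seed=4)
        table = simulate_env_presence(spec)
        x = table["bio17"]
        p = 1 / (1 + np.exp(spec.slope * x + spec.intercept))
        in_band = (x > 55) & (x < 65)
        assert abs((table.loc[in_band, "species"] == "M").mean()
                   - p[in_band].mean()) < 0.03
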