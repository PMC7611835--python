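"""Generator behaviour: determinism, sampling laws, and exact noiseless limits."""

import numpy as np
import pandas as pd
import pytest

from conftest import clean_config
from poolvar.synthetic_cohort import (
    SimulationConfig,
    TraitSpec,
    assign_pools,
    default_bmi_spec,
    simulate_cohort,
    simulate_pool_pileups,
    simulate_prs,
    simulate_sanger,
    simulate_trajectories,
)


class TestSimulateCohort:
    def test_seeded_outputs_are_bit_identical(self):
        a = simulate_cohort(SimulationConfig(n_individuals=500, n_duplicates=10, n_missing_id=2,
                                             n_twin_pairs=3, seed=7), {"pLoF": 0.01})
        b = simulate_cohort(SimulationConfig(n_individuals=500, n_duplicates=10, n_missing_id=2,
                                             n_twin_pairs=3, seed=7), {"pLoF": 0.01})
        pd.testing.assert_frame_equal(a.individuals, b.individuals)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)

    def test_zero_prevalence_gives_no_carriers(self):
        cohort = simulate_cohort(clean_config(n_individuals=200, seed=1),
                                 {c: 0.0 for c in ("pLoF", "cLoF", "WT-like", "GoF")})
        assert cohort.genotypes.empty
        assert cohort.variants.empty

    def test_prevalence_over_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            simulate_cohort(clean_config(n_individuals=100, seed=0), {"pLoF": 0.7, "cLoF": 0.5})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown functional classes"):
            simulate_cohort(clean_config(n_individuals=100, seed=0), {"LoF": 0.1})

    def test_carrier_counts_follow_binomial_law(self):
        # N=1000, p=0.01 over many seeds: mean ~ 10 within standard-error bounds
        counts = []
        for seed in range(500):
            c = simulate_cohort(clean_config(n_individuals=1000, seed=seed), {"pLoF": 0.01})
            counts.append(int((c.variants.carrier_count).sum()))
        mean = np.mean(counts)
        se = np.sqrt(1000 * 0.01 * 0.99 / 500)
        assert abs(mean - 10.0) < 4 * se
        assert abs(np.var(counts) - 9.9) < 2.5  # binomial variance npq

    def test_reference_scale_counts_near_printed_prevalences(self):
        prev = {"pLoF": 0.0023, "cLoF": 0.0007, "WT-like": 0.0037, "GoF": 0.0003}
        cohort = simulate_cohort(clean_config(n_individuals=5724, seed=3), prev)
        counts = cohort.variants.groupby("functional_class").carrier_count.sum()
        for cls, expected in (("pLoF", 13), ("cLoF", 4), ("WT-like", 21), ("GoF", 2)):
            sd = np.sqrt(5724 * prev[{"pLoF": "pLoF", "cLoF": "cLoF", "WT-like": "WT-like", "GoF": "GoF"}[cls]])
            assert abs(int(counts.get(cls, 0)) - expected) < 4 * sd + 1

    def test_all_rare_carriers_heterozygous_and_positions_unique(self):
        cohort = simulate_cohort(clean_config(n_individuals=2000, seed=9), {"pLoF": 0.01, "WT-like": 0.01})
        assert (cohort.genotypes.copies == 1).all()
        assert cohort.variants.pos.is_unique
        # one record per (individual, variant)
        assert not cohort.genotypes.duplicated(["individual_id", "variant_id"]).any()


class TestAssignPools:
    def test_reference_design_gives_120_pools(self):
        cohort = simulate_cohort(SimulationConfig(seed=0), class_counts={})
        design = assign_pools(cohort, 50, seed=1)
        assert design.pool_id.nunique() == 120
        assert len(design) == 5993

    def test_single_pool_when_all_fit(self):
        cohort = simulate_cohort(clean_config(n_individuals=50, seed=0), {})
        design = assign_pools(cohort, 50, seed=1)
        assert design.pool_id.nunique() == 1
        assert set(design.individual_id) == set(cohort.individuals.individual_id)

    def test_last_pool_takes_remainder(self):
        cohort = simulate_cohort(clean_config(n_individuals=101, seed=0), {})
        design = assign_pools(cohort, 50, seed=1)
        sizes = sorted(design.groupby("pool_id").size())
        assert sizes == [1, 50, 50]

    def test_every_individual_in_exactly_one_pool(self):
        cohort = simulate_cohort(clean_config(n_individuals=333, seed=2), {})
        design = assign_pools(cohort, 40, seed=3)
        assert design.individual_id.is_unique
        assert set(design.individual_id) == set(cohort.individuals.individual_id)

    def test_small_pool_size_rejected(self):
        cohort = simulate_cohort(clean_config(n_individuals=10, seed=0), {})
        with pytest.raises(ValueError):
            assign_pools(cohort, 1, seed=0)


def _noise_free_config(**kw):
    return clean_config(
        base_error_rate=0.0, contribution_cv=0.0, overdispersion=0.0,
        amplification_bias=1.0, n_fp_sites=0, **kw,
    )


class TestPoolPileups:
    def test_no_carriers_no_error_means_all_alt_zero(self):
        cfg = _noise_free_config(n_individuals=100, seed=5)
        cohort = simulate_cohort(cfg, {})
        # inject a dummy site so there is something to pileup
        cohort.variants.loc[0] = ["v_dummy", "chr18_toy", 10, "A", "T", "WT-like", 0]
        design = assign_pools(cohort, 50, 6)
        pile = simulate_pool_pileups(design, cohort, cfg, seed=7)
        assert (pile.frame.alt_fwd + pile.frame.alt_rev).sum() == 0

    def test_single_het_vaf_is_unbiased_at_one_percent(self):
        # eps=0, cv=0, rho=0: alt ~ Binomial(depth, 1/(2*pool_size)) exactly
        cfg = _noise_free_config(n_individuals=5000, mean_depth=40000, seed=8)
        cohort = simulate_cohort(cfg, class_counts={"pLoF": 100}, carriers_per_variant={1: 1.0})
        design = assign_pools(cohort, 50, 9)
        pile = simulate_pool_pileups(design, cohort, cfg, seed=10)
        frame = pile.frame
        frame["alt"] = frame.alt_fwd + frame.alt_rev
        frame["depth"] = frame.alt + frame.ref_fwd + frame.ref_rev
        carrier_pools = frame[frame.alt > 50]  # pools containing the carrier
        vafs = carrier_pools.alt / carrier_pools.depth
        se = np.sqrt(0.01 * 0.99 / 40000 / len(vafs))
        assert abs(vafs.mean() - 0.01) < 4 * se

    def test_true_positive_vaf_matches_observed_pool_statistics(self):
        # defaults (cv=0.4, bias, eps): mean called VAF in [0.9%, 1.5%] with SD > 0
        cfg = clean_config(n_individuals=2000, seed=11)
        cohort = simulate_cohort(cfg, class_counts={"pLoF": 40}, carriers_per_variant={1: 1.0})
        design = assign_pools(cohort, 50, 12)
        pile = simulate_pool_pileups(design, cohort, cfg, seed=13)
        frame = pile.frame
        frame["alt"] = frame.alt_fwd + frame.alt_rev
        frame["depth"] = frame.alt + frame.ref_fwd + frame.ref_rev
        frame["vaf"] = frame.alt / frame.depth
        tp = frame[(frame.vaf > 0.005)]
        tp = tp[tp.pos.isin(pile.sites[pile.sites.variant_id != ""].pos)]
        assert 0.009 < tp.vaf.mean() < 0.015
        assert tp.vaf.std() > 0

    def test_deterministic_given_seed(self):
        cfg = clean_config(n_individuals=200, seed=14)
        cohort = simulate_cohort(cfg, class_counts={"pLoF": 3})
        design = assign_pools(cohort, 50, 15)
        a = simulate_pool_pileups(design, cohort, cfg, seed=16).frame
        b = simulate_pool_pileups(design, cohort, cfg, seed=16).frame
        pd.testing.assert_frame_equal(a, b)


class TestSanger:
    def test_oracle_reports_truth(self):
        cohort = simulate_cohort(clean_config(n_individuals=100, seed=20), class_counts={"pLoF": 2})
        vid = cohort.variants.variant_id.iloc[0]
        carrier = cohort.carriers_of(vid)[0]
        rec = simulate_sanger(cohort, vid, carrier)
        assert rec.carrier and rec.zygosity == "het"
        non = (set(cohort.individuals.individual_id) - set(cohort.carriers_of(vid))).pop()
        rec2 = simulate_sanger(cohort, vid, non)
        assert not rec2.carrier and rec2.zygosity is None

    def test_total_miss_rate_hides_carriers(self):
        cohort = simulate_cohort(clean_config(n_individuals=100, seed=21), class_counts={"pLoF": 2})
        vid = cohort.variants.variant_id.iloc[0]
        carrier = cohort.carriers_of(vid)[0]
        rec = simulate_sanger(cohort, vid, carrier, miss_rate=1.0, rng=np.random.default_rng(0))
        assert not rec.carrier

    def test_unknown_ids_rejected(self):
        cohort = simulate_cohort(clean_config(n_individuals=10, seed=22), class_counts={"pLoF": 1})
        with pytest.raises(KeyError):
            simulate_sanger(cohort, "nope", cohort.individuals.individual_id.iloc[0])


def _flat_spec(**kw) -> TraitSpec:
    base = dict(
        name="BMI", start_age=1.5, end_age=18.0, knots=(8.0,), intercept=16.84,
        slopes=(0.0, 0.0), sex_effects=(0.0, 0.0, 0.0), carrier_effects=(0.0, 0.0, 0.0),
        random_sd=(0.0,), resid_sd=0.0,
        schedule=((1.5, 1.0), (5.0, 1.0), (8.0, 1.0), (15.0, 1.0), (18.0, 1.0)),
    )
    base.update(kw)
    return TraitSpec(**base)


class TestTrajectories:
    def test_noise_free_flat_spec_returns_intercept_everywhere(self):
        cohort = simulate_cohort(clean_config(n_individuals=50, seed=30), class_counts={"pLoF": 2})
        pheno = simulate_trajectories(cohort, _flat_spec(), seed=31)
        assert np.allclose(pheno.value, 16.84)

    def test_carrier_slope_delta_accrues_exactly(self):
        # +0.5/y on the 8-15y interval: carrier gap at 15y is exactly 3.5
        spec = _flat_spec(carrier_effects=(0.0, 0.0, 0.5))
        cohort = simulate_cohort(clean_config(n_individuals=60, seed=32), class_counts={"pLoF": 3})
        pheno = simulate_trajectories(cohort, spec, seed=33)
        at15 = pheno[pheno.age_years == 15.0]
        gap = at15[at15.carrier == 1].value.mean() - at15[at15.carrier == 0].value.mean()
        assert gap == pytest.approx(0.5 * 7, abs=1e-12)

    def test_default_bmi_anchor_at_18_months(self):
        spec = default_bmi_spec()
        cohort = simulate_cohort(clean_config(n_individuals=4000, seed=34), class_counts={})
        pheno = simulate_trajectories(cohort, spec, seed=35)
        first = pheno[pheno.age_years == 1.5]
        # population mean at the intercept age ~ 16.84 (sex offset is small)
        assert abs(first.value.mean() - 16.84) < 0.15

    def test_noiseless_regression_recovers_generating_coefficients(self):
        from poolvar.growth_models import spline_basis

        spec = _flat_spec(
            slopes=(0.4, -0.2), sex_effects=(0.3, 0.05, -0.1), carrier_effects=(0.1, 0.2, 0.0),
        )
        cohort = simulate_cohort(clean_config(n_individuals=80, seed=36), class_counts={"pLoF": 5})
        pheno = simulate_trajectories(cohort, spec, seed=37)
        basis = spline_basis(pheno.age_years.to_numpy(), spec.knots, spec.start_age)
        male = (pheno.sex == "M").to_numpy(float)[:, None]
        carrier = pheno.carrier.to_numpy(float)[:, None]
        ones = np.ones((len(pheno), 1))
        X = np.hstack([ones, basis, carrier * np.hstack([ones, basis]), male * np.hstack([ones, basis])])
        coef, *_ = np.linalg.lstsq(X, pheno.value.to_numpy(), rcond=None)
        expected = np.concatenate([[spec.intercept], spec.slopes, spec.carrier_effects, spec.sex_effects])
        np.testing.assert_allclose(coef, expected, atol=1e-9)

    def test_knot_outside_range_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            _flat_spec(knots=(20.0,)).validate()

    def test_missingness_schedule_thins_by_age(self):
        spec = _flat_spec(schedule=((1.5, 1.0), (18.0, 0.3)))
        cohort = simulate_cohort(clean_config(n_individuals=2000, seed=38), class_counts={"pLoF": 2})
        pheno = simulate_trajectories(cohort, spec, seed=39)
        frac18 = (pheno.age_years == 18.0).sum() / (pheno.age_years == 1.5).sum()
        assert 0.25 < frac18 < 0.35


class TestPRS:
    def test_moments_and_independence(self):
        cohort = simulate_cohort(clean_config(n_individuals=5000, seed=40), class_counts={"pLoF": 5})
        scores = simulate_prs(cohort, mean=0.0, sd=1.0, seed=41)
        assert abs(scores.mean()) < 4 / np.sqrt(5000)
        assert abs(scores.std() - 1.0) < 0.05
        # zero loading: score uncorrelated with the trait
        pheno = simulate_trajectories(cohort, default_bmi_spec(), seed=42)
        at18 = pheno[pheno.age_years == 18.0].set_index("individual_id")
        r = np.corrcoef(at18.value, scores.loc[at18.index])[0, 1]
        assert abs(r) < 0.05

    def test_loading_dials_in_variance_explained(self):
        # solve prs_beta so the score explains ~10% of BMI variance at 18y
        spec = default_bmi_spec()
        var18 = _trait_variance_at(spec, 18.0)
        target = 0.10
        beta = np.sqrt(target * var18 / (1 - target))
        import dataclasses

        spec = dataclasses.replace(spec, prs_beta=float(beta))
        cohort = simulate_cohort(clean_config(n_individuals=6000, seed=43), class_counts={})
        scores = simulate_prs(cohort, seed=44)
        pheno = simulate_trajectories(cohort, spec, seed=45)
        at18 = pheno[pheno.age_years == 18.0].set_index("individual_id")
        r2 = np.corrcoef(at18.value, scores.loc[at18.index])[0, 1] ** 2
        assert abs(r2 - 0.10) < 0.02

    def test_invalid_sd_rejected(self):
        cohort = simulate_cohort(clean_config(n_individuals=20, seed=46), class_counts={})
        with pytest.raises(ValueError):
            simulate_prs(cohort, sd=0.0)


def _trait_variance_at(spec: TraitSpec, age: float) -> float:
    t = age - spec.start_age
    cov = spec.random_cov()
    z = np.array([1.0, t])[: cov.shape[0]]
    return float(z @ cov @ z + spec.resid_sd**2)
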