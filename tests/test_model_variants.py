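import numpy as np
import pytest
from scipy.stats import norm

from dmdtraj.cohort_io import N_BINS
from dmdtraj.discrepancy import RWParams, gp_loglik
from dmdtraj.model_variants import (
    HibmaParams,
    PatientData,
    VariantSpec,
    build_variant,
    hibma_predict,
    hibma_quantiles,
    sample_individual_params,
    sample_z,
)
from dmdtraj.populations import default_population

OUTCOMES3 = ("nsaa", "walk", "rff")


class TestVariantTable:
    @pytest.mark.parametrize(
        "label, disc, cov, treat",
        [
            ("A", "RW", True, True), ("B", "RW", True, False),
            ("C", "RW", False, True), ("D", "RW", False, False),
            ("E", "GP", True, True), ("F", "GP", True, False),
            ("G", "GP", False, True), ("H", "GP", False, False),
        ],
    )
    def test_label_flag_bijection(self, label, disc, cov, treat):
        s = VariantSpec.from_label(label)
        assert (s.discrepancy, s.covariates, s.treatments) == (disc, cov, treat)

    def test_hibma_label(self):
        assert VariantSpec.from_label("I").is_hibma

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="label"):
            VariantSpec.from_label("Z")


class TestBuildVariant:
    def test_variant_f_parameter_list(self):
        v = build_variant("F", OUTCOMES3)
        names = v.population_parameter_names()
        assert "Corr_alpha" in names and "Corr_beta" in names
        assert any(n.startswith("mu_rho") for n in names)
        assert not any("gamma" in n for n in names)

    def test_variant_d_smallest_among_rw(self):
        from dmdtraj.inference import working_names

        counts = {
            lab: len(working_names(build_variant(lab, OUTCOMES3,
                                                 treatment_names=("steroid",))))
            for lab in "ABCDEFGH"
        }
        # D switches everything off; only its GP twin H matches its size
        assert counts["D"] == min(counts.values())
        assert all(counts["D"] < counts[l] for l in "ABCEFG")

    def test_a_b_differ_by_treatment_family(self):
        a = set(build_variant("A", OUTCOMES3, ("steroid",)).layout.names)
        b = set(build_variant("B", OUTCOMES3, ("steroid",)).layout.names)
        assert a - b == {"gamma:steroid"} and b - a == set()

    def test_treatment_variant_gets_default_treatment(self):
        v = build_variant("C")
        assert v.treatment_names == ("steroid",)


def _make_patient(variant, pop, rng, n_points=8):
    z = sample_z(variant.layout, pop, rng, 1)[0]
    params = variant.z_to_params(z)
    means = variant.mean_paths(params, None)
    bins = np.sort(rng.choice(np.arange(5, 60), size=n_points, replace=False))
    obs = {}
    for k in variant.outcomes:
        y = means[k][bins - 1] + rng.normal(0, 0.2, n_points)
        obs[k] = (bins, y)
    return params, PatientData("p", obs, obs, np.zeros((0, N_BINS)))


class TestIndividualLoglik:
    def test_no_observations_contribute_zero(self, variant_d, pop_d, rng):
        params = sample_individual_params(variant_d, pop_d, rng)
        empty = PatientData("p", {}, {}, np.zeros((0, N_BINS)))
        assert variant_d.individual_loglik(params, empty) == 0.0

    def test_rw_reduces_to_iid_when_innovation_vanishes(self, variant_d, pop_d, rng):
        params, patient = _make_patient(variant_d, pop_d, rng)
        disc = params.disc["nsaa"]
        params.disc["nsaa"] = RWParams(disc.tau_obs, 0.0, disc.eps0)
        ll = variant_d.individual_loglik(params, patient)
        bins, y = patient.obs["nsaa"]
        mu = variant_d.mean_paths(params, None)["nsaa"][bins - 1]
        expected = norm.logpdf(y, mu + disc.eps0, disc.tau_obs).sum()
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_gp_variant_matches_gp_loglik(self, rng):
        v = build_variant("H")
        pop = default_population(v)
        params, patient = _make_patient(v, pop, rng)
        ll = v.individual_loglik(params, patient)
        bins, y = patient.obs["nsaa"]
        mu = v.mean_paths(params, None)["nsaa"][bins - 1]
        assert ll == pytest.approx(gp_loglik(y, mu, bins, params.disc["nsaa"]))

    def test_finite_on_prior_draws(self, rng):
        # no support mismatch between priors and likelihood for any variant
        for label in "ABCDEFGH":
            v = build_variant(label, treatment_names=("steroid",))
            pop = default_population(v)
            params, patient = _make_patient(v, pop, rng)
            assert np.isfinite(v.individual_loglik(params, patient))

    @pytest.mark.parametrize("pair", [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")])
    def test_treatment_pairs_agree_without_treatment(self, pair, rng):
        # identical likelihoods when all indicators are zero
        v_t = build_variant(pair[0], treatment_names=("steroid",))
        v_n = build_variant(pair[1])
        pop_n = default_population(v_n)
        params_n, patient = _make_patient(v_n, pop_n, rng)
        # embed the no-treatment parameters into the treatment variant
        z_t = np.zeros(len(v_t.layout.names))
        for j, name in enumerate(v_t.layout.names):
            if name.startswith("gamma:"):
                z_t[j] = -1.0  # any value: indicators are all zero
            else:
                z_t[j] = params_n.z[v_n.layout.index(name)]
        params_t = v_t.z_to_params(z_t)
        patient_t = PatientData(patient.patient_id, patient.obs, patient.raw,
                                np.zeros((1, N_BINS)))
        assert v_t.individual_loglik(params_t, patient_t) == pytest.approx(
            v_n.individual_loglik(params_n, patient))


class TestSampleIndividualParams:
    def test_degenerate_hierarchy_collapses_to_means(self, variant_d, pop_d, rng):
        pop = pop_d.copy()
        pop.sigma[:] = 1e-12
        p1 = sample_individual_params(variant_d, pop, rng)
        p2 = sample_individual_params(variant_d, pop, rng)
        assert p1.z == pytest.approx(p2.z, abs=1e-9)

    def test_gamma_nonnegative(self, rng):
        v = build_variant("A", OUTCOMES3, ("steroid", "other"))
        pop = default_population(v)
        for _ in range(200):
            params = sample_individual_params(v, pop, rng)
            assert np.all(params.disease.Gamma >= 0)

    def test_identity_corr_gives_uncorrelated_draws(self, rng):
        v = build_variant("F", OUTCOMES3)
        pop = default_population(v)
        for fam in pop.corr:
            pop.corr[fam] = np.eye(3)
        idx = [v.layout.index(f"alpha:{k}") for k in OUTCOMES3]
        Z = sample_z(v.layout, pop, rng, 10_000)
        c = np.corrcoef(Z[:, idx].T)
        off = c[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 3.0 / np.sqrt(10_000))

    def test_marginal_prior_matches_noncov_variant(self, rng):
        # with identity correlations the covariate hierarchy's per-outcome
        # marginals equal an independent-normal hierarchy with the same scale
        v = build_variant("F", OUTCOMES3)
        pop = default_population(v)
        for fam in pop.corr:
            pop.corr[fam] = np.eye(3)
        j = v.layout.index("alpha:walk")
        g = [i for i, (n, _) in enumerate(v.layout.groups) if n == "alpha"][0]
        Z = sample_z(v.layout, pop, rng, 20_000)[:, j]
        assert Z.mean() == pytest.approx(pop.mu[j], abs=4 * pop.sigma[g] / np.sqrt(20_000))
        assert Z.std() == pytest.approx(pop.sigma[g], rel=0.05)


class TestHibma:
    def test_constant_when_rates_zero(self):
        p = HibmaParams(0.0, 0.0, RWParams(1.0, 0.1))
        assert hibma_predict(p, 20.0, 5) == pytest.approx(np.full(5, 20.0))

    def test_hand_recursion(self):
        p = HibmaParams(0.0, 0.01, RWParams(1.0, 0.1))
        out = hibma_predict(p, 30.0, 2)
        assert out == pytest.approx([29.7, 29.106])

    def test_point_prediction_floored_at_zero(self):
        p = HibmaParams(-3.0, 0.0, RWParams(1.0, 0.1))
        out = hibma_predict(p, 1.0, 5)
        assert np.all(out >= 0.0)
        assert out[-1] == 0.0

    def test_quantile_clamping(self, rng):
        p = HibmaParams(2.0, 0.0, RWParams(4.0, 0.5))
        draws = hibma_predict(p, 30.0, 10, rng=rng, n_draws=500)
        q = hibma_quantiles(draws, [0.025, 0.5, 0.975])
        assert np.all(q[0] >= 0.0)
        assert np.all(q[2] <= 34.0)

    def test_rejects_invalid_start(self):
        p = HibmaParams(0.0, 0.0, RWParams(1.0, 0.1))
        with pytest.raises(ValueError):
            hibma_predict(p, 40.0, 5)

    def test_hibma_is_nsaa_only(self):
        with pytest.raises(ValueError):
            build_variant("I", OUTCOMES3)
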