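"""Vital-rate regressions: AICc, nested enumeration, fitting, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangecoex import vital_rates as vr


def _records(n, rng, logit_coefs=(0.5, 1.0), site_effect=0.0):
    z = rng.normal(1.0, 1.0, n)
    site = rng.choice(["890.0", "1400.0", "1900.0"], n)
    eta = logit_coefs[0] + logit_coefs[1] * z
    eta = eta + site_effect * (site == "1900.0")
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {
            "individual_id": np.arange(n).astype(str),
            "size_t": z,
            "site_elevation_m": site,
            "background": "none",
            "year": 0,
            "survived": y,
            "size_t1": z + rng.normal(0, 0.3, n),
            "flowered": y,
            "seeds": 0,
            "is_replacement": 0,
        }
    )


class TestAicc:
    def test_matches_hand_computation(self):
        assert vr.aicc(-10.0, 2, 10) == pytest.approx(24 + 12 / 7)

    def test_rejects_too_few_observations(self):
        with pytest.raises(ValueError, match="n > k\\+1"):
            vr.aicc(-10.0, 5, 6)

    def test_approaches_aic_at_large_n(self):
        assert vr.aicc(-10.0, 3, 10**7) == pytest.approx(26.0, abs=1e-4)

    @given(
        ll=st.floats(-1e4, 0),
        k=st.integers(1, 20),
        n=st.integers(25, 10_000),
    )
    @settings(deadline=None, max_examples=50)
    def test_formula_on_random_grid(self, ll, k, n):
        expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert vr.aicc(ll, k, n) == pytest.approx(expected)


class TestEnumeration:
    def test_single_covariate_gives_two_models(self):
        models = vr.enumerate_nested_models(vr.ModelSpec("growth", frozenset({"z"})))
        assert {m.terms for m in models} == {frozenset(), frozenset({"z"})}

    def test_interaction_hierarchy_enumeration(self):
        full = vr.ModelSpec("survival", frozenset({"z", "site", "z:site"}))
        models = {m.terms for m in vr.enumerate_nested_models(full)}
        assert models == {
            frozenset(),
            frozenset({"z"}),
            frozenset({"site"}),
            frozenset({"z", "site"}),
            frozenset({"z", "site", "z:site"}),
        }

    def test_default_full_model_count_and_hierarchy(self):
        models = vr.enumerate_nested_models(vr.ModelSpec("survival", vr.FULL_TERMS))
        assert len(models) == len({m.terms for m in models})  # no duplicates
        for m in models:
            for t in m.terms:
                if ":" in t:
                    a, b = t.split(":")
                    assert a in m.terms and b in m.terms

    def test_invalid_hierarchy_rejected(self):
        with pytest.raises(ValueError, match="marginality"):
            vr.ModelSpec("survival", frozenset({"z:site"}))


class TestFitting:
    def test_logistic_coefficients_recovered_within_3se(self):
        rng = np.random.default_rng(0)
        rec = _records(2000, rng)
        fit = vr.fit_vital_rate(rec, vr.ModelSpec("survival", frozenset({"z"})))
        se = np.sqrt(np.diag(fit.vcov))
        assert abs(fit.coef[0] - 0.5) < 3 * se[0]
        assert abs(fit.coef[1] - 1.0) < 3 * se[1]

    def test_noiseless_gaussian_gives_zero_variance(self):
        rng = np.random.default_rng(1)
        rec = _records(200, rng)
        rec["size_t1"] = 0.3 + 0.7 * rec["size_t"]  # exact line
        fit = vr.fit_vital_rate(rec, vr.ModelSpec("growth", frozenset({"z"})))
        assert fit.sigma == pytest.approx(0.0, abs=1e-8)
        assert np.abs(fit.vcov).max() < 1e-12
        np.testing.assert_allclose(fit.coef, [0.3, 0.7], atol=1e-8)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(2)
        rec = _records(500, rng)
        spec = vr.ModelSpec("survival", frozenset({"z", "site"}))
        a, b = vr.fit_vital_rate(rec, spec), vr.fit_vital_rate(rec, spec)
        np.testing.assert_array_equal(a.coef, b.coef)

    def test_degenerate_binomial_response_flagged(self):
        rng = np.random.default_rng(3)
        rec = _records(50, rng)
        rec["survived"] = 1
        fit = vr.fit_vital_rate(rec, vr.ModelSpec("survival", frozenset({"z"})))
        assert "degenerate" in fit.flags
        p = fit.predict(pd.DataFrame({"z": [0.0], "site": ["890.0"], "background": ["none"]}))
        assert 0 < p[0] < 1  # clipped, never exactly 1

    def test_probability_predictions_are_clipped(self):
        rng = np.random.default_rng(4)
        rec = _records(500, rng)
        fit = vr.fit_vital_rate(rec, vr.ModelSpec("survival", frozenset({"z"})))
        z = np.array([-1e3, 1e3])
        p = fit.predict(pd.DataFrame({"z": z, "site": "890.0", "background": "none"}))
        assert (p > 0).all() and (p < 1).all()

    def test_vcov_shrinks_roughly_as_one_over_n(self):
        rng = np.random.default_rng(5)
        spec = vr.ModelSpec("survival", frozenset({"z"}))
        v_small = vr.fit_vital_rate(_records(2000, rng), spec).vcov
        v_big = vr.fit_vital_rate(_records(4000, rng), spec).vcov
        ratio = np.diag(v_big) / np.diag(v_small)
        assert (ratio > 0.3).all() and (ratio < 0.8).all()


class TestSelection:
    def test_single_fit_returned(self):
        rng = np.random.default_rng(6)
        fit = vr.fit_vital_rate(_records(200, rng), vr.ModelSpec("survival", frozenset({"z"})))
        assert vr.select_by_aicc([fit]) is fit

    def test_tie_broken_by_fewer_parameters(self):
        def fake(k, terms):
            return vr.VitalRateFit(
                spec=vr.ModelSpec("growth", terms),
                coef=np.zeros(k),
                coef_names=["b"] * k,
                vcov=np.eye(k),
                loglik=-10.0,
                n_obs=100,
                k_params=k,
                aicc=50.0,
            )

        small = fake(2, frozenset({"z"}))
        big = fake(3, frozenset({"z", "site"}))
        assert vr.select_by_aicc([big, small]) is small

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="no valid fits"):
            vr.select_by_aicc([])

    def test_true_model_terms_usually_selected(self):
        # generating model {z, site}: selection should keep both terms
        full = vr.ModelSpec("survival", frozenset({"z", "site", "z:site"}))
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            rec = _records(3000, rng, site_effect=0.5)
            best = vr.select_by_aicc(
                [vr.fit_vital_rate(rec, m) for m in vr.enumerate_nested_models(full)]
            )
            hits += {"z", "site"} <= best.spec.terms
        assert hits >= 18


class TestRecruitment:
    def test_proportions(self):
        t = pd.DataFrame(
            {
                "species": ["A"],
                "site_elevation_m": [890.0],
                "n_sown": [100],
                "n_germinated": [50],
                "n_established": [25],
            }
        )
        out = vr.fit_recruitment(t)
        assert out["g"].iloc[0] == 0.5 and out["e"].iloc[0] == 0.5

    def test_zero_germination_flagged(self):
        t = pd.DataFrame(
            {
                "species": ["A"],
                "site_elevation_m": [890.0],
                "n_sown": [100],
                "n_germinated": [0],
                "n_established": [0],
            }
        )
        out = vr.fit_recruitment(t)
        assert out["g"].iloc[0] == 0.0 and out["e"].iloc[0] == 0.0
        assert bool(out["e_undefined"].iloc[0])

    def test_inconsistent_counts_rejected(self):
        t = pd.DataFrame(
            {
                "species": ["A"],
                "site_elevation_m": [890.0],
                "n_sown": [100],
                "n_germinated": [50],
                "n_established": [60],
            }
        )
        with pytest.raises(ValueError):
            vr.fit_recruitment(t)

    def test_binomial_estimates_within_3se(self, rng):
        n, g, e = 1000, 0.35, 0.22
        germ = rng.binomial(n, g)
        est = rng.binomial(germ, e)
        t = pd.DataFrame(
            {
                "species": ["A"],
                "site_elevation_m": [890.0],
                "n_sown": [n],
                "n_germinated": [germ],
                "n_established": [est],
            }
        )
        out = vr.fit_recruitment(t)
        assert abs(out["g"].iloc[0] - g) < 3 * np.sqrt(g * (1 - g) / n)
        assert abs(out["e"].iloc[0] - e) < 3 * np.sqrt(e * (1 - e) / germ)


class TestDemographyModel:
    def test_vital_rate_set_exposes_all_components(self, fitted_demog):
        vrs = fitted_demog.vital_rate_set("L1", 890.0, None)
        z = np.linspace(-1, 3, 5)
        s, mu, p, f = vrs.survival(z), vrs.growth_mean(z), vrs.flowering(z), vrs.fecundity(z)
        assert ((s > 0) & (s < 1)).all() and ((p > 0) & (p < 1)).all()
        assert np.isfinite(mu).all() and (f >= 0).all()
        assert vrs.growth_sd > 0 and 0 < vrs.germination * vrs.establishment < 1

    def test_unknown_species_raises(self, fitted_demog):
        with pytest.raises(KeyError):
            fitted_demog.vital_rate_set("nope", 890.0, None)

    def test_selection_tables_cover_all_size_dependent_rates(self, fitted_demog):
        tab = fitted_demog.selection_tables["L1"]
        assert set(tab["response"]) == set(vr.SIZE_DEPENDENT)
        assert tab.groupby("response")["selected"].sum().eq(1).all()
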