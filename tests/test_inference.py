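"""Priors, likelihoods, the sampler, convergence diagnostics and DIC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from weedbayes.core import (
    EffectivenessParams,
    GlobalParams,
    ModelVariant,
    SurveyDesign,
)
from weedbayes.datasets import FIELDS_COLUMNS, OBS_COLUMNS, WeedSurveyDataset
from weedbayes.inference import (
    MCMCSettings,
    PriorSpec,
    compute_dic,
    fit_variant,
    gelman_rubin,
    log_likelihood,
    log_prior,
    run_mcmc,
)


def _one_field_dataset(k: int, dose: float = 0.0) -> WeedSurveyDataset:
    fields = pd.DataFrame(
        [("farm01", "farm01_f1", dose, np.nan, np.nan, np.nan)],
        columns=FIELDS_COLUMNS,
    )
    obs = pd.DataFrame(
        [("farm01_f1", 1, f"sp{j:02d}", 1) for j in range(k)],
        columns=OBS_COLUMNS,
    )
    return WeedSurveyDataset(
        fields=fields, observations=obs,
        design=SurveyDesign(n_farms=1, fields_per_farm=1),
    )


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def test_log_prior_reference_value():
    gp = GlobalParams(mu=1.0, a=1.0, b=1.0)  # all logs at 0
    lp = log_prior(gp, EffectivenessParams(), PriorSpec(log_scale_sd=10.0))
    assert lp == pytest.approx(3 * stats.norm(0, 10).logpdf(0.0), abs=1e-12)
    # doubling the sd strictly lowers the density at the origin
    lp_wide = log_prior(gp, EffectivenessParams(), PriorSpec(log_scale_sd=20.0))
    assert lp_wide < lp


def test_log_prior_out_of_support():
    gp = GlobalParams(mu=1.0, a=1.0, b=1.0)
    eta = EffectivenessParams()
    eta.eta_farm = {"f": 0.5}
    eta.eta_farm["f"] = 1.2  # bypass construction check
    assert log_prior(gp, eta, PriorSpec()) == -math.inf


def test_prior_spec_precision_convention():
    assert PriorSpec(log_scale_sd=10.0).sd == 10.0
    assert PriorSpec(log_scale_sd=10.0, sd_is_precision=True).sd == pytest.approx(
        1 / math.sqrt(10)
    )
    with pytest.raises(ValueError):
        PriorSpec(log_scale_sd=0.0)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def test_poisson_loglik_single_field():
    ds = _one_field_dataset(k=3)
    gp = GlobalParams(mu=5.0, a=1.0, b=1.0)  # D = 0 so lambda = mu = 5
    ll = log_likelihood(ds, gp, EffectivenessParams(), ModelVariant.RICH_BASE)
    assert ll == pytest.approx(3 * math.log(5) - 5 - math.log(6), abs=1e-10)


def test_binomial_loglik_single_cell():
    ds = _one_field_dataset(k=0)
    # one species present in 4 of 10 quadrats
    obs = pd.DataFrame(
        [("farm01_f1", q, "sp01", 1) for q in range(1, 5)], columns=OBS_COLUMNS
    )
    ds = WeedSurveyDataset(fields=ds.fields, observations=obs, design=ds.design)
    lam = -math.log(0.7) / 4.0  # presence probability exactly 0.3
    gp = GlobalParams(mu=np.array([lam]), a=1.0, b=1.0)
    ll = log_likelihood(ds, gp, EffectivenessParams(), ModelVariant.AB_BASE)
    expected = math.log(math.comb(10, 4)) + 4 * math.log(0.3) + 6 * math.log(0.7)
    assert ll == pytest.approx(expected, abs=1e-10)


def test_empty_dataset_loglik_zero():
    from weedbayes.experiments import empty_dataset

    gp = GlobalParams(mu=5.0, a=1.0, b=1.0)
    assert log_likelihood(
        empty_dataset(), gp, EffectivenessParams(), ModelVariant.RICH_BASE
    ) == 0.0


# ---------------------------------------------------------------------------
# Gelman-Rubin
# ---------------------------------------------------------------------------

def test_gelman_rubin_hand_value():
    chains = {"x": np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])}
    assert gelman_rubin(chains)["x"] == pytest.approx(math.sqrt(7 / 6), abs=1e-12)


def test_gelman_rubin_identical_and_constant_chains():
    same = np.array([[1.0, 2.0, 3.0]] * 3)
    assert gelman_rubin({"x": same})["x"] == pytest.approx(math.sqrt(2 / 3))
    const = np.ones((3, 5))
    assert gelman_rubin({"x": const})["x"] == 1.0


def test_gelman_rubin_requires_two_chains():
    with pytest.raises(ValueError):
        gelman_rubin({"x": np.ones((1, 5))})


# ---------------------------------------------------------------------------
# settings validation
# ---------------------------------------------------------------------------

def test_settings_validation():
    with pytest.raises(ValueError):
        MCMCSettings(n_iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        MCMCSettings(
            n_iterations=200, burn_in=100, n_chains=2,
            posterior_sample_size=500,
        )
    s = MCMCSettings(n_iterations=200, burn_in=100, n_chains=2,
                     posterior_sample_size=200)
    assert s.n_stored == 100


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def test_run_mcmc_deterministic(tiny_dataset):
    settings = MCMCSettings(
        n_chains=2, n_iterations=300, burn_in=150,
        posterior_sample_size=200, seed=5,
    )
    c1 = run_mcmc(tiny_dataset, ModelVariant.RICH_FARM, PriorSpec(), settings)
    c2 = run_mcmc(tiny_dataset, ModelVariant.RICH_FARM, PriorSpec(), settings)
    for name in c1.draws:
        np.testing.assert_array_equal(c1.draws[name], c2.draws[name])
    np.testing.assert_array_equal(c1.deviance, c2.deviance)


def test_chain_draws_respect_support(tiny_dataset):
    settings = MCMCSettings(
        n_chains=2, n_iterations=300, burn_in=150,
        posterior_sample_size=200, seed=6,
    )
    chains = run_mcmc(tiny_dataset, ModelVariant.AB_FIELD, PriorSpec(), settings)
    eta = chains.natural_draws("logit_eta_farm")
    assert np.all((eta >= 0) & (eta <= 1))
    mu_s = chains.natural_draws("log_mu_s")
    assert np.all(mu_s > 0)
    assert chains.eta_field_draws().shape[-1] == 4


def test_posterior_mean_recovery_no_treatment():
    """With 200 untreated fields at true mean 10, a and b are
    prior-dominated and the posterior mean of mu lands near the truth."""
    rng = np.random.default_rng(0)
    design = SurveyDesign(n_farms=40, fields_per_farm=5)
    farms = np.repeat([f"farm{i:02d}" for i in range(40)], 5)
    field_ids = [f"{f}_f{j % 5 + 1}" for j, f in enumerate(farms)]
    counts = rng.poisson(10.0, 200)
    fields = pd.DataFrame(
        {
            "farm_id": farms, "field_id": field_ids, "dose_D": 0.0,
            "tfi": np.nan, "yield_q_ha": np.nan, "nitrogen": np.nan,
        },
        columns=FIELDS_COLUMNS,
    )
    obs = []
    for fid, k in zip(field_ids, counts):
        for s in range(int(k)):
            obs.append((fid, s % 10 + 1, f"sp{s:03d}", 1))
    ds = WeedSurveyDataset(
        fields=fields, observations=pd.DataFrame(obs, columns=OBS_COLUMNS),
        design=design,
    )
    fit = fit_variant(
        ds, ModelVariant.RICH_BASE, PriorSpec(),
        MCMCSettings(n_chains=3, n_iterations=2000, burn_in=1000,
                     posterior_sample_size=3000, seed=7),
    )
    assert 9.4 <= fit.summary.loc["mu", "mean"] <= 10.6
    assert max(fit.rhat.values()) <= 1.1


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def test_dic_formula_via_plugin(monkeypatch, tiny_dataset):
    """Deviance draws {10, 12} with plug-in deviance 9 give the
    textbook decomposition: mean 11, p_D = 2, DIC = 13."""
    from weedbayes import inference as inf

    settings = MCMCSettings(n_chains=2, n_iterations=300, burn_in=150,
                            posterior_sample_size=200, seed=8)
    chains = run_mcmc(tiny_dataset, ModelVariant.RICH_BASE, PriorSpec(), settings)
    chains.deviance = np.array([[10.0], [12.0]])
    monkeypatch.setattr(
        inf._ModelStructure, "loglik_full", lambda self, state: -4.5
    )
    dic, p_d = compute_dic(chains, tiny_dataset)
    assert (dic, p_d) == (13.0, 2.0)


def test_dic_degenerate_posterior(monkeypatch, tiny_dataset):
    """All draws identical: p_D = 0 and DIC equals the plug-in deviance."""
    from weedbayes import inference as inf

    settings = MCMCSettings(n_chains=2, n_iterations=300, burn_in=150,
                            posterior_sample_size=200, seed=9)
    chains = run_mcmc(tiny_dataset, ModelVariant.RICH_BASE, PriorSpec(), settings)
    chains.deviance = np.full((2, 1), 21.0)
    monkeypatch.setattr(
        inf._ModelStructure, "loglik_full", lambda self, state: -10.5
    )
    dic, p_d = compute_dic(chains, tiny_dataset)
    assert p_d == 0.0 and dic == 21.0


def test_dic_rejects_nonfinite_deviance(tiny_dataset):
    settings = MCMCSettings(n_chains=2, n_iterations=300, burn_in=150,
                            posterior_sample_size=200, seed=10)
    chains = run_mcmc(tiny_dataset, ModelVariant.RICH_BASE, PriorSpec(), settings)
    chains.deviance[0, 3] = np.nan
    with pytest.raises(FloatingPointError, match="chain 0"):
        compute_dic(chains, tiny_dataset)
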