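"""Synthetic-data generator: determinism, calibration, null regimes."""

import numpy as np
import pytest
from scipy import stats

from weedbayes.core import SurveyDesign
from weedbayes.inference import PriorSpec
from weedbayes.simulate import (
    SimConfig,
    calibrate_mu_location,
    draw_from_priors,
    expected_field_richness,
    simulate_dataset,
    simulate_richness_dataset,
)


def test_same_seed_identical_datasets():
    cfg = SimConfig(seed=123, design=SurveyDesign(n_farms=5, fields_per_farm=2))
    a, b = simulate_dataset(cfg), simulate_dataset(cfg)
    assert a.dataset.fields.equals(b.dataset.fields)
    assert a.dataset.observations.equals(b.dataset.observations)
    assert a.dataset.applications.equals(b.dataset.applications)
    c = simulate_dataset(SimConfig(seed=124, design=cfg.design))
    assert not a.dataset.observations.equals(c.dataset.observations)


def test_calibration_hits_target_analytically():
    loc = calibrate_mu_location(9.46, 1.5, 108, 40.0)
    assert expected_field_richness(loc, 1.5, 108, 40.0) == pytest.approx(
        9.46, abs=1e-6
    )


def test_untreated_mean_richness_matches_calibration_target():
    """Across independent species pools at zero dose, mean per-field
    richness agrees with the 9.46 calibration target within 3 SE."""
    design = SurveyDesign(n_farms=5, fields_per_farm=5)
    means = []
    for rep in range(24):
        cfg = SimConfig(
            design=design, dose_range=(0.0, 0.0), seed=1000 + rep,
            n_farms_missing_yield=0,
        )
        means.append(simulate_dataset(cfg).dataset.richness().mean())
    means = np.asarray(means)
    se = means.std(ddof=1) / np.sqrt(len(means))
    assert abs(means.mean() - 9.46) < 3 * se


def test_expected_richness_matches_realized_pool():
    """Conditional on the realized species pool, mean observed richness
    agrees with sum_s (1 - exp(-mu_s * A)) within 3 SE."""
    design = SurveyDesign(n_farms=20, fields_per_farm=5)
    cfg = SimConfig(design=design, dose_range=(0.0, 0.0), seed=7,
                    n_farms_missing_yield=0)
    synth = simulate_dataset(cfg)
    mu_s = np.array(list(synth.truth_species.mu_s.values()))
    expected = np.sum(1 - np.exp(-mu_s * design.surveyed_area))
    r = synth.dataset.richness()
    se = r.std(ddof=1) / np.sqrt(len(r))
    assert abs(r.mean() - expected) < 3 * se


def test_zero_effectiveness_indistinguishable_from_zero_dose():
    """eta = 0 nullifies treatment: richness distributions match the
    zero-dose regime (two-sample KS over independent pools)."""
    design = SurveyDesign(n_farms=5, fields_per_farm=5)
    null_eta, zero_dose = [], []
    for rep in range(20):
        cfg0 = SimConfig(
            design=design, eta_level="field", eta_farm_law=0.0,
            eta_field_law=0.0, seed=2000 + rep, n_farms_missing_yield=0,
        )
        cfg1 = SimConfig(
            design=design, dose_range=(0.0, 0.0), seed=3000 + rep,
            n_farms_missing_yield=0,
        )
        null_eta.extend(simulate_dataset(cfg0).dataset.richness())
        zero_dose.extend(simulate_dataset(cfg1).dataset.richness())
    p = stats.ks_2samp(null_eta, zero_dose).pvalue
    assert p > 0.01


def test_null_yield_coefficients_give_independent_yields():
    """With zero yield coefficients the OLS slope CI of yield on dose
    covers 0 in nearly all replicates."""
    import statsmodels.api as sm

    design = SurveyDesign(n_farms=10, fields_per_farm=5)
    covered = 0
    n_reps = 100
    for rep in range(n_reps):
        cfg = SimConfig(design=design, seed=4000 + rep, n_farms_missing_yield=0)
        f = simulate_dataset(cfg).dataset.fields
        model = sm.OLS(f["yield_q_ha"], sm.add_constant(f["dose_D"])).fit()
        lo, hi = model.conf_int().loc["dose_D"]
        covered += int(lo <= 0.0 <= hi)
    assert covered >= 93


def test_truth_effectiveness_in_unit_interval():
    cfg = SimConfig(
        seed=5, design=SurveyDesign(n_farms=4, fields_per_farm=3),
        eta_level="field",
    )
    synth = simulate_dataset(cfg)
    for m in (
        synth.truth_eta.eta_farm,
        synth.truth_eta.eta_field_component,
        synth.truth_eta.eta_field,
    ):
        assert all(0.0 <= v <= 1.0 for v in m.values())
    composed = synth.truth_eta.eta_field
    for key, v in composed.items():
        assert v <= synth.truth_eta.eta_farm[key[0]] + 1e-12


def test_richness_generator_consistency():
    cfg = SimConfig(
        seed=9, design=SurveyDesign(n_farms=4, fields_per_farm=3),
        eta_level="field",
    )
    synth = simulate_richness_dataset(cfg, mu_richness=9.46)
    # fabricated presences reproduce the drawn richness exactly
    assert (synth.dataset.richness() >= 0).all()
    assert len(synth.truth_eta.eta_field) == 12
    with pytest.raises(ValueError):
        simulate_richness_dataset(
            SimConfig(seed=1, eta_level="species")
        )


def test_missing_yield_farms():
    cfg = SimConfig(seed=11, n_farms_missing_yield=3)
    f = simulate_dataset(cfg).dataset.fields
    missing_farms = f[f["yield_q_ha"].isna()]["farm_id"].nunique()
    assert missing_farms == 3


def test_tfi_consistent_with_applications():
    from weedbayes.descriptive import compute_tfi

    cfg = SimConfig(seed=13, design=SurveyDesign(n_farms=3, fields_per_farm=2))
    ds = simulate_dataset(cfg).dataset
    fid = ds.fields.loc[ds.fields["dose_D"] > 0, "field_id"].iloc[0]
    expected = ds.fields.set_index("field_id").loc[fid, "tfi"]
    assert compute_tfi(ds.applications, fid) == pytest.approx(expected)


def test_draw_from_priors_statistics_and_determinism():
    spec = PriorSpec(log_scale_sd=10.0)
    g1, _ = draw_from_priors(spec, seed=99)
    g2, _ = draw_from_priors(spec, seed=99)
    assert (g1.mu, g1.a, g1.b) == (g2.mu, g2.a, g2.b)

    design = SurveyDesign(n_farms=2, fields_per_farm=1)
    log_a, etas = [], []
    for i in range(4000):
        g, e = draw_from_priors(spec, seed=i, design=design)
        log_a.append(np.log(g.a))
        etas.extend(e.eta_farm.values())
    log_a, etas = np.asarray(log_a), np.asarray(etas)
    assert abs(etas.mean() - 0.5) < 3 * etas.std(ddof=1) / np.sqrt(etas.size)
    assert abs(log_a.std(ddof=1) - 10.0) / 10.0 < 0.05


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(seed=1, eta_level="quadrat")
    with pytest.raises(ValueError):
        SimConfig(seed=1, dose_range=(3.0, 1.0))
    with pytest.raises(ValueError):
        SimConfig(seed=1, eta_farm_law=(0.0, 2.0))
    with pytest.raises(ValueError):
        SimConfig(seed=1, eta_field_law=1.4)
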