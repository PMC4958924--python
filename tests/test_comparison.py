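"""Family fitting, DIC selection, effectiveness and survival summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from weedbayes.comparison import (
    EffectivenessSummary,
    VariantFamily,
    abundance_family,
    eta_yield_association,
    fit_family,
    richness_family,
    select_best,
    summarize_effectiveness,
    survival_profile,
)
from weedbayes.core import ModelVariant
from weedbayes.inference import (
    ChainSet,
    FitResult,
    MCMCSettings,
    PriorSpec,
    _Block,
    fit_variant,
)

FAST = MCMCSettings(
    n_chains=2, n_iterations=300, burn_in=150, posterior_sample_size=200, seed=3
)


def _dummy_fit(variant, dic, n_params):
    blocks = [_Block("x", (n_params,), "log", "species", [f"x{i}" for i in range(n_params)])]
    chains = ChainSet(
        variant=variant,
        draws={"x": np.zeros((2, 2, n_params))},
        deviance=np.zeros((2, 2)),
        blocks=blocks,
        field_ids=[], farm_ids=[], species_ids=[], spec_species=[],
        field_farm=np.zeros(0, dtype=int),
        settings=FAST,
        acceptance={},
    )
    return FitResult(
        variant=variant, summary=pd.DataFrame(), rhat={}, dic=dic,
        p_d=1.0, mean_deviance=dic - 1.0, settings=FAST, chains=chains,
    )


def test_family_definitions():
    assert len(richness_family().members) == 3
    assert len(abundance_family().members) == 4
    with pytest.raises(ValueError):
        VariantFamily("richness", (ModelVariant.AB_BASE,))


def test_select_best_ordering_and_flag():
    fits = [
        _dummy_fit(ModelVariant.RICH_BASE, 100.0, 3),
        _dummy_fit(ModelVariant.RICH_FARM, 90.0, 33),
        _dummy_fit(ModelVariant.RICH_FIELD, 80.0, 183),
    ]
    sel = select_best(fits)
    assert sel.best is ModelVariant.RICH_FIELD
    assert not sel.indistinguishable

    sel = select_best(
        [
            _dummy_fit(ModelVariant.RICH_BASE, 90.5, 3),
            _dummy_fit(ModelVariant.RICH_FARM, 90.0, 33),
        ]
    )
    assert sel.best is ModelVariant.RICH_FARM
    assert sel.indistinguishable

    # exact tie resolves toward fewer parameters
    sel = select_best(
        [
            _dummy_fit(ModelVariant.RICH_FARM, 90.0, 33),
            _dummy_fit(ModelVariant.RICH_BASE, 90.0, 3),
        ]
    )
    assert sel.best is ModelVariant.RICH_BASE


def test_select_best_rejects_mixed_families():
    with pytest.raises(ValueError, match="famil"):
        select_best(
            [
                _dummy_fit(ModelVariant.RICH_BASE, 1.0, 3),
                _dummy_fit(ModelVariant.AB_BASE, 2.0, 3),
            ]
        )
    with pytest.raises(ValueError):
        select_best([_dummy_fit(ModelVariant.RICH_BASE, 1.0, 3)])


def test_fit_family_sizes_and_reproducibility(tiny_dataset):
    fits = fit_family(tiny_dataset, richness_family(), PriorSpec(), FAST)
    assert [f.variant for f in fits] == list(richness_family().members)
    fits2 = fit_family(tiny_dataset, richness_family(), PriorSpec(), FAST)
    for f1, f2 in zip(fits, fits2):
        assert f1.dic == f2.dic


def _eta_chain_fit(values):
    """A farm+field effectiveness ChainSet with constant draws."""
    farms = [f"farm{i:02d}" for i in range(len(values))]
    field_ids = [f"{f}_f1" for f in farms]
    blocks = [
        _Block("logit_eta_farm", (len(farms),), "logit", "farm",
               [f"eta_F[{f}]" for f in farms]),
        _Block("logit_eta_field", (len(farms),), "logit", "field",
               [f"eta_f[{f}]" for f in field_ids]),
    ]
    farm_draws = np.tile(logit(np.asarray(values)), (2, 3, 1))
    field_draws = np.tile(logit(np.full(len(values), 0.999999)), (2, 3, 1))
    chains = ChainSet(
        variant=ModelVariant.RICH_FIELD,
        draws={"logit_eta_farm": farm_draws, "logit_eta_field": field_draws},
        deviance=np.zeros((2, 3)),
        blocks=blocks,
        field_ids=field_ids,
        farm_ids=farms,
        species_ids=[], spec_species=[],
        field_farm=np.arange(len(farms)),
        settings=FAST,
        acceptance={},
    )
    return FitResult(
        variant=ModelVariant.RICH_FIELD, summary=pd.DataFrame(), rhat={},
        dic=0.0, p_d=0.0, mean_deviance=0.0, settings=FAST, chains=chains,
    )


def test_summarize_effectiveness_fractions():
    fit = _eta_chain_fit([0.5, 0.5, 0.5, 0.5])
    s = summarize_effectiveness(fit, threshold=0.2)
    assert s.fraction_below == 0.0
    s = summarize_effectiveness(fit, threshold=1.0)
    assert s.fraction_below == 1.0
    fit = _eta_chain_fit([0.05, 0.1, 0.5, 0.15])
    s = summarize_effectiveness(fit, threshold=0.2)
    assert s.fraction_below == pytest.approx(0.75)


def test_summarize_effectiveness_rejects_base(tiny_dataset):
    fit = fit_variant(tiny_dataset, ModelVariant.RICH_BASE, PriorSpec(), FAST)
    with pytest.raises(ValueError, match="effectiveness"):
        summarize_effectiveness(fit)
    with pytest.raises(ValueError):
        summarize_effectiveness(_eta_chain_fit([0.5]), threshold=1.5)


def test_fraction_below_tracks_designed_effectiveness_regime():
    """The sub-threshold fraction responds to the generating regime in
    the identifiable direction: a widely dispersed effectiveness truth
    (many fields genuinely below 0.2) yields a far larger fraction than
    a uniformly high-effectiveness truth.

    (A truth with *every* effectiveness near 0 is not recoverable: the
    data then carry no information separating a small scale factor from
    small effectiveness, and the posterior stays near its prior.)
    """
    from weedbayes.core import SurveyDesign
    from weedbayes.simulate import SimConfig, simulate_richness_dataset

    fractions = {}
    for name, farm_law, field_law in (
        ("dispersed", (0.5, 0.5), (0.5, 0.5)),
        ("high", 0.95, 0.95),
    ):
        cfg = SimConfig(
            design=SurveyDesign(n_farms=10, fields_per_farm=5),
            eta_level="field", eta_farm_law=farm_law, eta_field_law=field_law,
            dose_range=(2.0, 4.0), true_a=2.0, true_b=1.0, seed=21,
        )
        synth = simulate_richness_dataset(cfg, mu_richness=9.46)
        fit = fit_variant(
            synth.dataset, ModelVariant.RICH_FIELD, PriorSpec(),
            MCMCSettings(n_chains=2, n_iterations=2000, burn_in=1000,
                         posterior_sample_size=2000, seed=22),
        )
        fractions[name] = summarize_effectiveness(fit, threshold=0.2).fraction_below
    assert fractions["dispersed"] > fractions["high"]
    assert fractions["high"] < 0.3


# ---------------------------------------------------------------------------
# survival profile
# ---------------------------------------------------------------------------

def test_survival_profile_structure(tiny_dataset):
    fit = fit_variant(tiny_dataset, ModelVariant.AB_FIELD, PriorSpec(), FAST)
    grid = np.linspace(0.0, 4.0, 9)
    prof = survival_profile(fit, grid, reference_area_W=4000.0,
                            doses_observed=np.array([0.0, 1.0, 2.0, 3.5]))
    # species sorted ascending by untreated abundance
    assert np.all(np.diff(prof.mu_s) >= 0)
    # zero-dose column equals the closed form
    np.testing.assert_allclose(
        prof.matrix[:, 0], 1.0 - np.exp(-4000.0 * prof.mu_s), rtol=1e-12
    )
    # rows non-increasing in dose
    assert np.all(np.diff(prof.matrix, axis=1) <= 1e-12)
    assert prof.dose_quantile_markers[0.9] == pytest.approx(3.05)
    with pytest.raises(ValueError, match="dose grid"):
        survival_profile(fit, [], 4000.0)


def test_survival_profile_requires_abundance(tiny_dataset):
    fit = fit_variant(tiny_dataset, ModelVariant.RICH_FARM, PriorSpec(), FAST)
    with pytest.raises(ValueError, match="abundance"):
        survival_profile(fit, [0.0, 1.0], 4000.0)


# ---------------------------------------------------------------------------
# effectiveness-yield association
# ---------------------------------------------------------------------------

def _summary_from_eta(eta_by_field, farms=None):
    field_ids = list(eta_by_field)
    table = pd.DataFrame(
        {
            "farm_id": farms or ["farmA"] * len(field_ids),
            "field_id": field_ids,
            "mean": list(eta_by_field.values()),
            "q2.5": 0.0,
            "q97.5": 1.0,
        }
    )
    return EffectivenessSummary(
        variant=ModelVariant.RICH_FIELD, farm_table=table.iloc[:0],
        field_table=table, within_farm_sd=None, fraction_below=0.0,
        threshold=0.2,
    )


def test_eta_yield_perfect_rank_agreement():
    eta = {f"f{i}": v for i, v in enumerate(np.linspace(0.1, 0.9, 12))}
    fields = pd.DataFrame(
        {"field_id": list(eta), "yield_q_ha": list(eta.values())}
    )
    res = eta_yield_association(_summary_from_eta(eta), fields, n_boot=100)
    assert res.spearman == pytest.approx(1.0)


def test_eta_yield_constant_yield():
    eta = {f"f{i}": v for i, v in enumerate(np.linspace(0.1, 0.9, 10))}
    fields = pd.DataFrame({"field_id": list(eta), "yield_q_ha": 70.0})
    res = eta_yield_association(_summary_from_eta(eta), fields, n_boot=100)
    assert res.spearman == 0.0
    assert np.ptp(res.smoother["yield_smoothed"]) < 1e-8


def test_eta_yield_missing_yields_rejected():
    eta = {f"f{i}": 0.5 for i in range(10)}
    fields = pd.DataFrame({"field_id": list(eta), "yield_q_ha": np.nan})
    with pytest.raises(ValueError):
        eta_yield_association(_summary_from_eta(eta), fields)
    few = pd.DataFrame({"field_id": ["f0", "f1"], "yield_q_ha": [70.0, 71.0]})
    with pytest.raises(ValueError, match="5 fields"):
        eta_yield_association(_summary_from_eta(eta), few)
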