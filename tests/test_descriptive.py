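"""TFI, weed frequency and the Satterthwaite mixed model."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from weedbayes.descriptive import (
    ApplicationRecord,
    aic_screen,
    compute_tfi,
    pairwise_lmm,
    run_descriptive_stage,
    weed_frequency,
)


def _app(field, product, dose, rec):
    return ApplicationRecord(
        field_id=field, product=product, ai_dose_kg_ha=dose,
        recommended_dose_kg_ha=rec,
    )


def test_tfi_values():
    assert compute_tfi([], "f1") == 0.0
    assert compute_tfi([_app("f1", "p", 1.2, 1.2)], "f1") == pytest.approx(1.0)
    apps = [_app("f1", "p", 0.6, 1.2), _app("f1", "q", 0.9, 1.8)]
    assert compute_tfi(apps, "f1") == pytest.approx(1.0)


def test_tfi_split_invariance():
    one = [_app("f1", "p", 1.0, 2.0)]
    split = [_app("f1", "p", 0.5, 2.0), _app("f1", "p", 0.5, 2.0)]
    assert compute_tfi(one, "f1") == compute_tfi(split, "f1")


def test_tfi_missing_recommended_dose():
    with pytest.raises(ValueError, match="mystery"):
        compute_tfi(
            [ApplicationRecord(field_id="f1", product="mystery",
                               ai_dose_kg_ha=1.0)],
            "f1",
        )


def test_weed_frequency_counts(tiny_dataset):
    obs = tiny_dataset.observations
    assert weed_frequency(obs, "farm01_f1") == 14
    assert weed_frequency(obs, "farm01_f2") == 1
    assert weed_frequency(obs, "no_such_field") == 0


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def _grouped(n_farms=8, fpf=5, seed=0):
    rng = np.random.default_rng(seed)
    farm = np.repeat([f"F{i:02d}" for i in range(n_farms)], fpf)
    field = [f"{f}_x{j % fpf}" for j, f in enumerate(farm)]
    x = rng.uniform(0, 4, n_farms * fpf)
    return farm, field, x, rng


def test_exact_linear_response_recovers_slope():
    farm, field, x, _ = _grouped()
    res = pairwise_lmm(2.0 * x + 1.0, x, farm, field)
    assert res.estimate == pytest.approx(2.0, abs=1e-6)
    assert res.random_structure == "farm_intercept(field_reduced)"


def test_constant_response_flat_slope():
    farm, field, x, _ = _grouped()
    res = pairwise_lmm(np.full_like(x, 7.0), x, farm, field)
    assert res.estimate == pytest.approx(0.0, abs=1e-6)
    assert res.p_value > 0.9


def test_too_few_farms_rejected():
    with pytest.raises(ValueError, match="farms"):
        pairwise_lmm([1, 2, 3, 4], [0, 1, 2, 3], ["a", "a", "b", "b"])


def test_nested_structure_used_with_replicates():
    rng = np.random.default_rng(3)
    farm = np.repeat([f"F{i}" for i in range(6)], 6)
    field = np.repeat([f"F{i}_f{j}" for i in range(6) for j in range(3)], 2)
    x = rng.uniform(0, 4, 36)
    y = 1.0 + 0.5 * x + rng.normal(0, 1, 36)
    res = pairwise_lmm(y, x, farm, field)
    assert res.random_structure == "farm+field_nested"
    assert set(res.sigma2) == {"farm", "field", "residual"}


def test_matches_lmertest_oracle(tmp_path):
    """Estimate, SE, Satterthwaite df, F, p and ML-based AIC agree with
    R lmerTest on the same data."""
    rng = np.random.default_rng(5)
    n_farms, fpf = 10, 5
    farm = np.repeat([f"F{i:02d}" for i in range(n_farms)], fpf)
    x = rng.uniform(0, 4, n_farms * fpf)
    u = rng.normal(0, 3, n_farms)
    y = 50 + 1.5 * x + u[np.repeat(np.arange(n_farms), fpf)] + rng.normal(
        0, 5, n_farms * fpf
    )
    field = [f"{f}_f{j % fpf}" for j, f in enumerate(farm)]
    res = pairwise_lmm(y, x, farm, field)

    csv = tmp_path / "d.csv"
    pd.DataFrame({"y": y, "x": x, "farm": farm}).to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.csv('{csv}')
            m <- lmer(y ~ x + (1|farm), data=d, REML=TRUE)
            a <- anova(m, type=3)
            s <- summary(m)$coefficients
            cat(s['x','Estimate'], s['x','Std. Error'], a$`F value`,
                a$DenDF, a$`Pr(>F)`, AIC(lme4::refitML(m)), sep='\\n')
            """
        )
    )
    out = subprocess.run(
        ["Rscript", str(rscript)], capture_output=True, text=True, check=True
    )
    est, se, f, df, p, aic = map(float, out.stdout.split())
    assert res.estimate == pytest.approx(est, rel=1e-6)
    assert res.se == pytest.approx(se, rel=1e-5)
    assert res.f_stat == pytest.approx(f, rel=1e-5)
    assert res.df_den == pytest.approx(df, rel=1e-3)
    assert res.p_value == pytest.approx(p, rel=1e-3)
    assert res.aic == pytest.approx(aic, rel=1e-6)


def test_injected_slope_covered_by_ci():
    """The 95% Wald CI of the slope covers an injected slope in most
    replicates (farm random effects present)."""
    from scipy import stats

    beta = 0.8
    covered = 0
    n_reps = 25
    for rep in range(n_reps):
        farm, field, x, rng = _grouped(seed=100 + rep)
        u = rng.normal(0, 2, 8)
        y = 10 + beta * x + u[np.repeat(np.arange(8), 5)] + rng.normal(0, 2, 40)
        res = pairwise_lmm(y, x, farm, field)
        tcrit = stats.t.ppf(0.975, res.df_den)
        covered += int(
            res.estimate - tcrit * res.se <= beta <= res.estimate + tcrit * res.se
        )
    assert covered >= 20


def test_aic_screen_rules():
    farm, field, x, rng = _grouped(seed=9)
    y = 5 + x + rng.normal(0, 1, x.size)
    base = pairwise_lmm(y, x, farm, field)

    def fake(aic):
        import dataclasses

        return dataclasses.replace(base, aic=aic)

    assert aic_screen(fake(100.0), fake(99.0)) == "base"
    assert aic_screen(fake(100.0), fake(97.0)) == "covariate"
    assert aic_screen(fake(100.0), fake(100.0)) == "base"
    with pytest.raises(ValueError):
        bad = dataclasses_replace_nobs(base)
        aic_screen(base, bad)


def dataclasses_replace_nobs(res):
    import dataclasses

    return dataclasses.replace(res, n_obs=res.n_obs + 1)


def test_descriptive_stage_table(tiny_dataset):
    # tiny dataset has too few farms for the LMM; use a simulated survey
    from weedbayes.core import SurveyDesign
    from weedbayes.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        design=SurveyDesign(n_farms=8, fields_per_farm=5),
        seed=31, n_farms_missing_yield=1,
    )
    ds = simulate_dataset(cfg).dataset
    table = run_descriptive_stage(ds)
    assert len(table) == 4
    assert set(table.columns) >= {"estimate", "se", "F", "df_den", "p_value", "aic"}
    assert (table["p_value"].between(0, 1)).all()
    # TFI as the herbicide indicator also runs
    table_tfi = run_descriptive_stage(ds, herbicide_indicator="tfi")
    assert len(table_tfi) == 4
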