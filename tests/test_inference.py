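import dataclasses
import json
import math

import numpy as np
import pytest
from scipy.special import expit

import mimicry_risk as mr
from mimicry_risk.errors import EstimabilityError
from mimicry_risk.inference import (
    FixedFactor,
    GlmmSpec,
    ResponseVar,
    fit_binomial_glmm,
    fit_mistake_model,
    population_probability,
)

from _oracles import logit_normal_mean
from conftest import full_trials_for, make_respondents, make_trials


@pytest.fixture(scope="module")
def degenerate_fit():
    """Large-n data generated with both variances 0 and no attitude effect."""
    cfg = mr.GeneratorConfig(
        n_respondents=2000,
        sigma_picture=0.0,
        sigma_respondent=0.0,
        delta_attitude={a: 0.0 for a in mr.Attitude},
        seed=19,
    )
    ds = mr.generate(cfg)
    return cfg, fit_binomial_glmm(ds, GlmmSpec())


def test_degenerate_variance_limit(degenerate_fit):
    cfg, fit = degenerate_fit
    assert fit.var_picture <= 0.01
    assert fit.var_respondent <= 0.01
    truth = {
        "adder": cfg.beta_adder,
        "smooth": cfg.beta_smooth - cfg.beta_adder,
        "grass": cfg.beta_grass - cfg.beta_adder,
    }
    for i, name in enumerate(fit.beta_names):
        se = math.sqrt(fit.vcov_beta[i, i])
        assert abs(fit.beta[i] - truth[name]) < 2 * se


def test_population_probability_arithmetic_identity(degenerate_fit):
    _, fit = degenerate_fit
    for level in fit.beta_names:
        est = population_probability(fit, level)
        idx = fit.beta_names.index(level)
        eta = fit.beta[0] + (fit.beta[idx] if idx > 0 else 0.0)
        c = np.zeros(len(fit.beta_names))
        c[0] = 1.0
        if idx > 0:
            c[idx] = 1.0
        assert est.eta == pytest.approx(eta, rel=1e-12)
        assert est.p == pytest.approx(expit(eta), rel=1e-12)
        assert est.se_eta == pytest.approx(
            math.sqrt(c @ fit.vcov_beta @ c), rel=1e-12
        )


def test_population_probability_half_at_zero_intercept(degenerate_fit):
    _, fit = degenerate_fit
    shifted = dataclasses.replace(fit, beta=np.array([0.0, 0.0, 0.0]))
    assert population_probability(shifted, "adder").p == 0.5


def test_population_probability_unknown_level(degenerate_fit):
    _, fit = degenerate_fit
    with pytest.raises(EstimabilityError, match="viper"):
        population_probability(fit, "viper")


def test_marginal_probability_matches_quadrature_oracle(calibrated_config):
    ds = mr.generate(dataclasses.replace(calibrated_config, n_respondents=300, seed=23))
    fit = fit_binomial_glmm(ds, GlmmSpec())
    for level in fit.beta_names:
        cond = population_probability(fit, level)
        marg = population_probability(fit, level, marginal=True)
        oracle = logit_normal_mean(cond.eta, fit.var_picture + fit.var_respondent)
        assert marg.p == pytest.approx(oracle, abs=1e-6)
        # marginalization pulls probabilities toward 1/2
        assert abs(marg.p - 0.5) <= abs(cond.p - 0.5) + 1e-12


def test_missing_level_after_subset_raises():
    resp = make_respondents(
        [
            ("R1", "", True, "yard", "kill_selective"),
            ("R2", "", True, "yard", "kill_selective"),
            ("R3", "", True, "yard", "no_kill"),
        ]
    )
    # selective respondents never saw grass pictures
    rows = []
    for rid in ("R1", "R2"):
        rows += [r for r in full_trials_for(rid) if r[2] != "grass"]
    rows += full_trials_for("R3")
    ds = mr.SurveyDataset(respondents=resp, trials=make_trials(rows))
    with pytest.raises(EstimabilityError, match="grass"):
        fit_binomial_glmm(
            ds, GlmmSpec(subset_attitude=mr.Attitude.KILL_SELECTIVE)
        )


def test_too_few_respondents_raises():
    resp = make_respondents([("R1", "", True, "yard", "no_kill")])
    ds = mr.SurveyDataset(
        respondents=resp, trials=make_trials(full_trials_for("R1"))
    )
    with pytest.raises(EstimabilityError, match="respondents"):
        fit_binomial_glmm(ds, GlmmSpec())


def test_mistake_model_null_attitude_effect(zero_delta):
    cfg = mr.GeneratorConfig(n_respondents=800, delta_attitude=zero_delta, seed=31)
    fit = fit_mistake_model(mr.generate(cfg))
    assert fit.spec.response is ResponseVar.MISTAKE
    assert fit.spec.fixed_factor is FixedFactor.ATTITUDE
    assert fit.beta_names[0] == "kill_selective"
    for level in ("no_kill", "kill_all"):
        assert abs(fit.wald_z(level)) < 2.0


def test_mistake_model_positive_error_offset():
    # strong error-increasing offset for non-selective respondents
    cfg = mr.GeneratorConfig(
        n_respondents=1500,
        delta_attitude={
            mr.Attitude.NO_KILL: 1.5,
            mr.Attitude.KILL_ALL: 1.5,
            mr.Attitude.KILL_SELECTIVE: 0.0,
        },
        seed=37,
    )
    fit = fit_mistake_model(mr.generate(cfg))
    assert fit.beta[fit.beta_names.index("no_kill")] > 0
    assert fit.beta[fit.beta_names.index("kill_all")] > 0
    assert fit.wald_z("no_kill") > 2.0


def test_mistake_contrast_two_batch_stability():
    """Mean contrast agrees between two independent replicate batches.

    The generator's attitude offset acts on the call-adder scale, so the
    mistake-model contrast has no closed-form truth; the derived check is
    that independent simulation batches estimate the same quantity (within
    2 combined Monte Carlo SEs).
    """
    cfg = mr.GeneratorConfig(n_respondents=1000)

    def batch(base_seed, n_rep=25):
        out = []
        for r in range(n_rep):
            c = dataclasses.replace(cfg, seed=base_seed + r)
            c.delta_attitude = dict(cfg.delta_attitude)
            f = fit_mistake_model(mr.generate(c))
            out.append(f.beta[f.beta_names.index("no_kill")])
        return np.array(out)

    a, b = batch(60_000), batch(70_000)
    se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    assert abs(a.mean() - b.mean()) < 2 * se
    assert a.mean() > 0 and b.mean() > 0  # direction: selective killers err less


def test_glmm_fit_serializes_to_json(tmp_path, calibrated_config):
    ds = mr.generate(calibrated_config)
    fit = fit_binomial_glmm(ds, GlmmSpec())
    p = tmp_path / "fit.json"
    fit.to_json(p)
    d = json.loads(p.read_text())
    assert set(d["beta"]) == {"adder", "smooth", "grass"}
    assert d["var_picture"] >= 0 and d["var_respondent"] >= 0
    assert d["converged"] is True
    assert len(d["vcov_beta"]) == 3


def test_reference_level_validation():
    with pytest.raises(EstimabilityError):
        GlmmSpec(fixed_factor=FixedFactor.SPECIES, reference_level="no_kill")


def test_variance_recovery_and_wald_coverage():
    """Replicate study at n=500, sigma_pic=0.4, sigma_resp=1.0.

    The respondent component (500 levels) is recovered within 15% on
    average. The picture component has only 9 levels: its Laplace-ML
    estimate is strongly biased toward zero (matching lme4's glmer on the
    same data), so only a loose band is asserted, and the Wald coverage for
    the species effects — whose SEs inherit that underestimate — lands below
    the nominal 95% as well.
    """
    cfg = mr.GeneratorConfig(
        n_respondents=500,
        sigma_picture=0.4,
        sigma_respondent=1.0,
        delta_attitude={a: 0.0 for a in mr.Attitude},
    )
    truth_beta = np.array(
        [cfg.beta_adder, cfg.beta_smooth - cfg.beta_adder, cfg.beta_grass - cfg.beta_adder]
    )
    n_rep = 60
    vps, vrs = [], []
    cover = np.zeros(3)
    for r in range(n_rep):
        c = dataclasses.replace(cfg, seed=1000 + r)
        c.delta_attitude = dict(cfg.delta_attitude)
        fit = fit_binomial_glmm(mr.generate(c), GlmmSpec())
        vps.append(fit.var_picture)
        vrs.append(fit.var_respondent)
        se = np.sqrt(np.diag(fit.vcov_beta))
        cover += np.abs(fit.beta - truth_beta) < 1.96 * se
    assert abs(np.mean(vrs) / 1.0 - 1.0) < 0.15
    assert 0.3 * 0.16 < np.mean(vps) < 1.15 * 0.16
    coverage = cover / n_rep
    assert np.all(coverage > 0.70) and np.all(coverage <= 1.0)
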