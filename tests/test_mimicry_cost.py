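import math

import numpy as np
import pytest

from mimicry_risk import (
    KillRiskInputs,
    LinkEstimate,
    Species,
    delta_method_risk_ratio,
    monte_carlo_risk_ratio,
    proportion_estimate,
    risk_ratio,
)
from mimicry_risk.errors import BoundaryError, MimicryRiskError


def make_inputs(k0=10, kv=21, n=102, eps_p=0.677, eps_se=0.39):
    eta = math.log(eps_p / (1 - eps_p))
    return KillRiskInputs(
        mu0=proportion_estimate(k0, n),
        muv=proportion_estimate(kv, n),
        eps={
            Species.SMOOTH: LinkEstimate(p=eps_p, eta=eta, se_eta=eps_se),
            Species.GRASS: LinkEstimate(p=0.072, eta=math.log(0.072 / 0.928), se_eta=0.5),
        },
    )


class TestRiskRatio:
    def test_study_values(self):
        assert risk_ratio(0.098, 0.206, 0.677) == pytest.approx(
            (0.098 + 0.206 * 0.677) / 0.098, rel=1e-12
        )

    def test_no_misidentification_no_cost(self):
        assert risk_ratio(0.098, 0.206, 0.0) == 1.0

    def test_no_selective_killers_no_cost(self):
        assert risk_ratio(0.098, 0.0, 0.677) == 1.0

    def test_zero_baseline_undefined(self):
        with pytest.raises(ZeroDivisionError, match="mu0"):
            risk_ratio(0.0, 0.2, 0.5)

    def test_out_of_range(self):
        with pytest.raises(MimicryRiskError, match="eps_i"):
            risk_ratio(0.1, 0.2, 1.5)

    def test_monotonicity_grid(self):
        grid = np.linspace(0.05, 0.95, 7)
        for muv in grid:
            for eps in grid:
                phis = [risk_ratio(m0, muv, eps) for m0 in grid]
                assert all(a >= b - 1e-12 for a, b in zip(phis, phis[1:]))
        for m0 in grid:
            for muv in grid:
                phis = [risk_ratio(m0, muv, e) for e in grid]
                assert all(b >= a - 1e-12 for a, b in zip(phis, phis[1:]))

    def test_at_least_one_iff(self):
        grid = np.linspace(0.0, 1.0, 6)
        for m0 in grid[1:]:
            for muv in grid:
                for eps in grid:
                    phi = risk_ratio(m0, muv, eps)
                    assert phi >= 1.0
                    assert (phi == 1.0) == (muv * eps == 0.0)


class TestMonteCarlo:
    def test_degenerate_ses_collapse(self):
        inputs = KillRiskInputs(
            mu0=proportion_estimate(10, 102),
            muv=proportion_estimate(21, 102),
            eps={Species.SMOOTH: LinkEstimate(p=0.677, eta=0.74, se_eta=0.0)},
        )
        # zero-SE eps with the real mu SEs is not degenerate; zero them all
        inputs = KillRiskInputs(
            mu0=_zero_se(inputs.mu0),
            muv=_zero_se(inputs.muv),
            eps=inputs.eps,
        )
        est = monte_carlo_risk_ratio(inputs, Species.SMOOTH, seed=1)
        assert est.ci_low == est.phi_median == est.ci_high
        assert est.phi_median == pytest.approx(est.phi_plugin, rel=1e-12)

    def test_bitwise_reproducible(self):
        inputs = make_inputs()
        a = monte_carlo_risk_ratio(inputs, Species.SMOOTH, seed=5)
        b = monte_carlo_risk_ratio(inputs, Species.SMOOTH, seed=5)
        assert a == b

    def test_seed_stability_two_percent(self):
        inputs = make_inputs()
        meds = [
            monte_carlo_risk_ratio(inputs, Species.SMOOTH, seed=s).phi_median
            for s in (1, 2, 3, 4)
        ]
        assert (max(meds) - min(meds)) / np.mean(meds) < 0.02

    def test_interval_ordering_and_floor(self):
        inputs = make_inputs()
        est = monte_carlo_risk_ratio(inputs, Species.SMOOTH, seed=2)
        assert 1.0 <= est.ci_low <= est.phi_median <= est.ci_high

    def test_matches_delta_method_at_small_se(self):
        inputs = _small_se_inputs(0.05)
        est = monte_carlo_risk_ratio(inputs, Species.SMOOTH, n_draws=50_000, seed=3)
        phi_dm, se_log = delta_method_risk_ratio(inputs, Species.SMOOTH)
        assert est.phi_median == pytest.approx(phi_dm, rel=0.01)

    def test_ci_width_matches_delta_method(self):
        for se in (0.05, 0.1):
            inputs = _small_se_inputs(se)
            est = monte_carlo_risk_ratio(inputs, Species.SMOOTH, n_draws=50_000, seed=4)
            phi_dm, se_log = delta_method_risk_ratio(inputs, Species.SMOOTH)
            mc_width = math.log(est.ci_high) - math.log(est.ci_low)
            dm_width = 2 * 1.96 * se_log
            assert mc_width == pytest.approx(dm_width, rel=0.10)

    def test_eps_se_dominant_closed_form_quantiles(self):
        # with mu0 and muv fixed, phi = 1 + c*expit(eta) is monotone in eta,
        # so its Monte Carlo quantiles have a closed form to check against
        inputs = make_inputs(eps_se=1.2)
        inputs = KillRiskInputs(
            mu0=_zero_se(inputs.mu0), muv=_zero_se(inputs.muv), eps=inputs.eps
        )
        est = monte_carlo_risk_ratio(inputs, Species.SMOOTH, n_draws=100_000, seed=6)
        c = inputs.muv.p_hat / inputs.mu0.p_hat
        eta, se = inputs.eps[Species.SMOOTH].eta, 1.2

        def q(z):
            return 1.0 + c / (1.0 + math.exp(-(eta + z * se)))

        assert est.ci_low == pytest.approx(q(-1.96), rel=0.01)
        assert est.phi_median == pytest.approx(q(0.0), rel=0.01)
        assert est.ci_high == pytest.approx(q(1.96), rel=0.01)
        # eps_hat > 1/2: the back-transform compresses the upper tail, so the
        # interval is left-skewed on the log scale
        assert math.log(est.ci_high / est.phi_median) < math.log(
            est.phi_median / est.ci_low
        )

    def test_boundary_proportion_raises_then_corrects(self):
        inputs = KillRiskInputs(
            mu0=proportion_estimate(0, 102),
            muv=proportion_estimate(21, 102),
            eps={Species.SMOOTH: LinkEstimate(p=0.677, eta=0.74, se_eta=0.4)},
        )
        with pytest.raises(BoundaryError, match="continuity"):
            monte_carlo_risk_ratio(inputs, Species.SMOOTH, seed=1)
        est = monte_carlo_risk_ratio(
            inputs, Species.SMOOTH, seed=1, continuity_correction=True
        )
        assert est.phi_median > 1.0

    def test_missing_species(self):
        inputs = make_inputs()
        with pytest.raises(MimicryRiskError, match="adder"):
            monte_carlo_risk_ratio(inputs, Species.ADDER, seed=1)

    def test_mismatched_totals(self):
        with pytest.raises(MimicryRiskError, match="same respondent total"):
            KillRiskInputs(
                mu0=proportion_estimate(10, 102),
                muv=proportion_estimate(21, 103),
                eps={},
            )

    def test_alternative_sampling_schemes_agree_roughly(self):
        inputs = make_inputs()
        base = monte_carlo_risk_ratio(inputs, Species.SMOOTH, seed=7)
        joint = monte_carlo_risk_ratio(
            inputs, Species.SMOOTH, seed=7, joint_attitude=True
        )
        resp = monte_carlo_risk_ratio(inputs, Species.SMOOTH, seed=7, scale="response")
        for est in (joint, resp):
            assert est.phi_median == pytest.approx(base.phi_median, rel=0.15)


class TestDeltaMethod:
    def test_zero_se_zero_variance(self):
        inputs = KillRiskInputs(
            mu0=_zero_se(proportion_estimate(10, 102)),
            muv=_zero_se(proportion_estimate(21, 102)),
            eps={Species.SMOOTH: LinkEstimate(p=0.677, eta=0.74, se_eta=0.0)},
        )
        phi, se_log = delta_method_risk_ratio(inputs, Species.SMOOTH)
        assert se_log == 0.0
        assert phi > 1.0


def _zero_se(est):
    class _Frozen:
        def __init__(self, src):
            self.k, self.n = src.k, src.n
            self.p_hat = src.p_hat
            self.eta_hat = src.eta_hat
            self.se_eta = 0.0

    return _Frozen(est)


def _small_se_inputs(se):
    return KillRiskInputs(
        mu0=_se_override(proportion_estimate(10, 102), se),
        muv=_se_override(proportion_estimate(21, 102), se),
        eps={
            Species.SMOOTH: LinkEstimate(
                p=0.677, eta=math.log(0.677 / 0.323), se_eta=se
            )
        },
    )


def _se_override(est, se):
    frozen = _zero_se(est)
    frozen.se_eta = se
    return frozen
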