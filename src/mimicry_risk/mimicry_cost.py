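"""The mimicry kill-risk ratio and its uncertainty.

The quantity of interest for a harmless species ``i`` is the ratio between
the total probability of being killed upon human encounter — including being
mistaken for a viper — and the baseline attributable merely to being a snake::

    phi_i = (mu_0 + mu_v * eps_i) / mu_0 = 1 + mu_v * eps_i / mu_0

where ``mu_0`` is the probability an encountered human would kill any snake,
``mu_v`` the probability they would kill only vipers, and ``eps_i`` the
probability they would identify species ``i`` as a viper.

Uncertainty is propagated by Monte Carlo: each parameter is drawn from an
independent normal on the logit (link) scale, back-transformed, and pushed
through the ratio; the 95% interval is the 2.5/97.5 percentile of draws.
A first-order delta-method approximation is provided as an independent
cross-check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import BoundaryError, MimicryRiskError
from .estimates import ProportionEstimate
from .inference import LinkEstimate
from .survey_io import Species

#: default seed (survey month, June 2014; arbitrary but documented)
DEFAULT_SEED = 20140601
DEFAULT_N_DRAWS = 10_000


@dataclass(frozen=True)
class KillRiskInputs:
    """Estimated inputs of the risk ratio.

    ``eps`` maps species to the logit-scale estimate (and SE) of the
    probability that a selective killer identifies that species as an adder.
    """

    mu0: ProportionEstimate
    muv: ProportionEstimate
    eps: Mapping[Species, LinkEstimate]

    def __post_init__(self) -> None:
        if self.mu0.n != self.muv.n:
            raise MimicryRiskError(
                "mu0 and muv must derive from the same respondent total "
                f"(got n={self.mu0.n} and n={self.muv.n})"
            )


@dataclass(frozen=True)
class RiskRatioEstimate:
    species: Species
    phi_plugin: float
    phi_median: float
    phi_mean: float
    ci_low: float
    ci_high: float
    n_draws: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "species": self.species.value,
            "phi_plugin": self.phi_plugin,
            "phi_median": self.phi_median,
            "phi_mean": self.phi_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def risk_ratio(mu0: float, muv: float, eps_i: float) -> float:
    """Plug-in kill-risk ratio ``1 + muv * eps_i / mu0``. Exact arithmetic."""
    for name, v in (("mu0", mu0), ("muv", muv), ("eps_i", eps_i)):
        if not 0.0 <= v <= 1.0:
            raise MimicryRiskError(f"{name}={v} outside [0, 1]")
    if mu0 == 0.0:
        raise ZeroDivisionError(
            "phi is undefined at mu0 = 0 (no baseline kill risk to compare "
            "against); use a continuity-corrected mu0 if k was 0"
        )
    return 1.0 + muv * eps_i / mu0


def _link_params(
    est, continuity_correction: bool, name: str
) -> tuple[float, float]:
    """(eta_hat, se_eta) for an estimate, optionally continuity-corrected."""
    eta, se = est.eta_hat if hasattr(est, "eta_hat") else est.eta, est.se_eta
    if not (math.isfinite(eta) and math.isfinite(se)):
        if continuity_correction and isinstance(est, ProportionEstimate):
            cc = est.with_continuity_correction()
            return cc.eta_hat, cc.se_eta
        raise BoundaryError(
            f"{name} has a non-finite logit-scale estimate or SE (boundary "
            "proportion); pass continuity_correction=True to add 1/2 to both "
            "cells"
        )
    return float(eta), float(se)


def monte_carlo_risk_ratio(
    inputs: KillRiskInputs,
    species: Species,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = DEFAULT_SEED,
    scale: str = "link",
    joint_attitude: bool = False,
    continuity_correction: bool = False,
) -> RiskRatioEstimate:
    """Monte Carlo distribution of the kill-risk ratio for one species.

    Per draw, mu0, muv and eps are sampled independently as
    ``Normal(eta_hat, se_eta)`` on the logit scale and back-transformed
    (``scale="response"`` samples on the probability scale, truncated to
    [0, 1], as a sensitivity variant; ``joint_attitude`` instead draws the
    attitude counts from a multinomial bootstrap, respecting their negative
    correlation). Deterministic given ``seed``.
    """
    if species not in inputs.eps:
        raise MimicryRiskError(f"no eps entry for species {species.value!r}")
    if inputs.mu0.k < 1 and not continuity_correction:
        raise BoundaryError(
            "mu0 has zero successes so phi is undefined; pass "
            "continuity_correction=True to add 1/2 to both cells"
        )
    if scale not in ("link", "response"):
        raise MimicryRiskError(f"unknown scale {scale!r}")

    eps_est = inputs.eps[species]
    e_mu0, s_mu0 = _link_params(inputs.mu0, continuity_correction, "mu0")
    e_muv, s_muv = _link_params(inputs.muv, continuity_correction, "muv")
    e_eps, s_eps = _link_params(eps_est, continuity_correction, "eps")

    rng = np.random.default_rng(seed)
    if joint_attitude:
        n = inputs.mu0.n
        rest = n - inputs.mu0.k - inputs.muv.k
        counts = rng.multinomial(
            n, [inputs.mu0.k / n, inputs.muv.k / n, rest / n], size=n_draws
        )
        k0 = counts[:, 0].astype(float)
        kv = counts[:, 1].astype(float)
        # half-count correction on zero draws keeps phi finite
        k0 = np.where(k0 == 0, 0.5, k0)
        mu0_d = k0 / n
        muv_d = kv / n
    elif scale == "link":
        mu0_d = _expit(rng.normal(e_mu0, s_mu0, size=n_draws))
        muv_d = _expit(rng.normal(e_muv, s_muv, size=n_draws))
    else:
        p0, pv = inputs.mu0.p_hat, inputs.muv.p_hat
        se0 = s_mu0 * p0 * (1 - p0)  # delta-method response-scale SDs
        sev = s_muv * pv * (1 - pv)
        mu0_d = np.clip(rng.normal(p0, se0, size=n_draws), 1e-12, 1.0)
        muv_d = np.clip(rng.normal(pv, sev, size=n_draws), 0.0, 1.0)

    if scale == "link":
        eps_d = _expit(rng.normal(e_eps, s_eps, size=n_draws))
    else:
        pe = eps_est.p
        eps_d = np.clip(
            rng.normal(pe, s_eps * pe * (1 - pe), size=n_draws), 0.0, 1.0
        )

    phi_d = 1.0 + muv_d * eps_d / mu0_d
    phi_plugin = 1.0 + _expit(e_muv) * _expit(e_eps) / _expit(e_mu0)
    lo, med, hi = np.percentile(phi_d, [2.5, 50.0, 97.5])
    return RiskRatioEstimate(
        species=species,
        phi_plugin=float(phi_plugin),
        phi_median=float(med),
        phi_mean=float(np.mean(phi_d)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_draws=int(n_draws),
        seed=int(seed),
    )


def delta_method_risk_ratio(
    inputs: KillRiskInputs,
    species: Species,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """First-order (delta-method) SE of log phi; Monte Carlo cross-check.

    With ``phi = (mu0 + muv*eps)/mu0`` and independent logit-scale variances,

        d log(phi) / d eta_j = [d log(phi) / d p_j] * p_j (1 - p_j)

    for ``p_j in {mu0, muv, eps}``, where ``d log(phi)/d mu0 = 1/(mu0 +
    muv*eps) - 1/mu0``, ``d log(phi)/d muv = eps/(mu0 + muv*eps)`` and
    ``d log(phi)/d eps = muv/(mu0 + muv*eps)``. Returns ``(phi_plugin,
    se_log_phi)``.
    """
    eps_est = inputs.eps[species]
    e_mu0, s_mu0 = _link_params(inputs.mu0, continuity_correction, "mu0")
    e_muv, s_muv = _link_params(inputs.muv, continuity_correction, "muv")
    e_eps, s_eps = _link_params(eps_est, continuity_correction, "eps")
    p0, pv, pe = _expit(e_mu0), _expit(e_muv), _expit(e_eps)
    total = p0 + pv * pe
    phi = total / p0
    d0 = (1.0 / total - 1.0 / p0) * p0 * (1.0 - p0)
    dv = (pe / total) * pv * (1.0 - pv)
    de = (pv / total) * pe * (1.0 - pe)
    var = (d0 * s_mu0) ** 2 + (dv * s_muv) ** 2 + (de * s_eps) ** 2
    return float(phi), float(math.sqrt(var))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))
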