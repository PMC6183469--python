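"""Model fitting: intercept-only binomial GLMs and the identification GLMMs.

Three model families:

* :func:`fit_intercept_glm` — intercept-only binomial logit GLM, closed form
  (attitude proportions mu_0 and mu_v).
* :func:`fit_binomial_glmm` — Bernoulli logit GLMM with one fixed factor
  (species or attitude) and crossed picture/respondent random intercepts,
  Laplace-approximate ML.
* :func:`fit_mistake_model` — the attitude-versus-error GLMM, a thin wrapper
  over :func:`fit_binomial_glmm`.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss

from .errors import EstimabilityError
from .estimates import ProportionEstimate, proportion_estimate
from .glmm import CrossedLogitLaplace, LaplaceFitResult
from .survey_io import Attitude, Species, SurveyDataset

Z_95 = 1.959963984540054


class ResponseVar(str, enum.Enum):
    CALLED_ADDER = "called_adder"
    MISTAKE = "mistake"


class FixedFactor(str, enum.Enum):
    SPECIES = "species"
    ATTITUDE = "attitude"


_LEVELS = {
    FixedFactor.SPECIES: [s.value for s in Species],
    FixedFactor.ATTITUDE: [
        Attitude.KILL_SELECTIVE.value,
        Attitude.NO_KILL.value,
        Attitude.KILL_ALL.value,
    ],
}
_DEFAULT_REFERENCE = {
    FixedFactor.SPECIES: Species.ADDER.value,
    FixedFactor.ATTITUDE: Attitude.KILL_SELECTIVE.value,
}


@dataclass
class GlmmSpec:
    """What to fit: response, fixed factor, reference level, subset.

    ``random_factors`` is fixed to (picture, respondent); both are crossed
    random intercepts. ``subset_attitude`` restricts to respondents with
    that attitude before fitting.
    """

    response: ResponseVar = ResponseVar.CALLED_ADDER
    fixed_factor: FixedFactor = FixedFactor.SPECIES
    reference_level: str | None = None
    subset_attitude: Attitude | None = None
    unknown_as_mistake: bool = False
    drop_unknown_for_adder_model: bool = False
    random_factors: tuple[str, str] = ("picture", "respondent")

    def __post_init__(self) -> None:
        if self.reference_level is None:
            self.reference_level = _DEFAULT_REFERENCE[self.fixed_factor]
        if self.reference_level not in _LEVELS[self.fixed_factor]:
            raise EstimabilityError(
                f"reference level {self.reference_level!r} is not a level of "
                f"{self.fixed_factor.value}"
            )

    @property
    def levels(self) -> list[str]:
        """Levels ordered with the reference first."""
        lv = _LEVELS[self.fixed_factor]
        return [self.reference_level] + [l for l in lv if l != self.reference_level]


@dataclass
class GlmmFit:
    """A fitted GLMM: fixed effects, their covariance, variance components.

    ``beta[0]`` is the reference-level intercept; the remaining entries are
    contrasts against it, in ``beta_names`` order.
    """

    spec: GlmmSpec
    beta: np.ndarray
    beta_names: list[str]
    vcov_beta: np.ndarray
    var_picture: float
    var_respondent: float
    loglik: float
    converged: bool
    n_obs: int
    boundary_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.vcov_beta = np.asarray(self.vcov_beta, dtype=float)
        assert self.beta.shape[0] == len(self.beta_names)

    def contrast_vector(self, level: str) -> np.ndarray:
        if level not in self.beta_names:
            raise EstimabilityError(
                f"level {level!r} not in fit (levels: {self.beta_names})"
            )
        c = np.zeros(len(self.beta_names))
        c[0] = 1.0
        idx = self.beta_names.index(level)
        if idx > 0:
            c[idx] = 1.0
        return c

    def level_eta(self, level: str) -> tuple[float, float]:
        """Linear predictor and SE for a level (random effects at zero)."""
        c = self.contrast_vector(level)
        eta = float(c @ self.beta)
        se = float(math.sqrt(c @ self.vcov_beta @ c))
        return eta, se

    def wald_z(self, level: str) -> float:
        """Wald z statistic of the contrast of ``level`` vs the reference."""
        idx = self.beta_names.index(level)
        if idx == 0:
            raise EstimabilityError("reference level has no contrast")
        return float(self.beta[idx] / math.sqrt(self.vcov_beta[idx, idx]))

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response.value,
            "fixed_factor": self.spec.fixed_factor.value,
            "reference_level": self.spec.reference_level,
            "subset_attitude": (
                self.spec.subset_attitude.value if self.spec.subset_attitude else None
            ),
            "beta": dict(zip(self.beta_names, map(float, self.beta))),
            "vcov_beta": [[float(v) for v in row] for row in self.vcov_beta],
            "var_picture": self.var_picture,
            "var_respondent": self.var_respondent,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "boundary_flags": list(self.boundary_flags),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


@dataclass(frozen=True)
class LinkEstimate:
    """A probability with its logit-scale estimate and standard error."""

    p: float
    eta: float
    se_eta: float

    @property
    def ci_low(self) -> float:
        return 1.0 / (1.0 + math.exp(-(self.eta - Z_95 * self.se_eta)))

    @property
    def ci_high(self) -> float:
        return 1.0 / (1.0 + math.exp(-(self.eta + Z_95 * self.se_eta)))

    def to_dict(self) -> dict:
        return {"p": self.p, "eta": self.eta, "se_eta": self.se_eta}


# ---------------------------------------------------------------------------


def fit_intercept_glm(k: int, n: int) -> ProportionEstimate:
    """Intercept-only binomial logit GLM (closed-form ML).

    ``eta_hat = logit(k/n)``, ``se_eta = sqrt(1/k + 1/(n-k))``; boundary
    counts (k = 0 or k = n) yield non-finite ``eta_hat``/``se_eta``.
    """
    return proportion_estimate(k, n)


def _design(spec: GlmmSpec, dataset: SurveyDataset):
    """Build (y, X, picture codes, respondent codes, level names)."""
    data = dataset
    if spec.subset_attitude is not None:
        data = data.subset_by_attitude(spec.subset_attitude)

    if spec.response is ResponseVar.CALLED_ADDER:
        t = data.called_adder(drop_unknown=spec.drop_unknown_for_adder_model)
        y = t["called_adder"].to_numpy(dtype=float)
    else:
        t = data.mistakes(unknown_as_mistake=spec.unknown_as_mistake)
        y = t["is_mistake"].to_numpy(dtype=float)

    if spec.fixed_factor is FixedFactor.SPECIES:
        fac = t["true_species"]
    else:
        att = data.respondents.set_index("respondent_id")["attitude"]
        fac = t["respondent_id"].map(att)

    levels = spec.levels
    present = set(fac.unique())
    missing = [l for l in levels if l not in present]
    if missing:
        raise EstimabilityError(
            f"fixed-factor level(s) with no observations after subsetting: "
            f"{', '.join(missing)}"
        )

    X = np.ones((len(t), len(levels)))
    for j, level in enumerate(levels[1:], start=1):
        X[:, j] = (fac == level).to_numpy(dtype=float)

    g_pic = pd.Categorical(t["picture_id"]).codes.astype(np.intp)
    g_resp = pd.Categorical(t["respondent_id"]).codes.astype(np.intp)
    return y, X, g_pic, g_resp, levels


def fit_binomial_glmm(
    dataset: SurveyDataset,
    spec: GlmmSpec,
    var_picture_fixed: float | None = None,
    var_respondent_fixed: float | None = None,
) -> GlmmFit:
    """Laplace-approximate ML fit of the crossed random-intercept logit GLMM.

    ``var_*_fixed`` pin a variance component instead of estimating it;
    pinning both at 0 reduces to an ordinary logistic GLM.
    """
    y, X, g_pic, g_resp, levels = _design(spec, dataset)
    n_pic = len(np.unique(g_pic))
    n_resp = len(np.unique(g_resp))
    if n_pic < 2 or n_resp < 2:
        raise EstimabilityError(
            f"need >= 2 pictures and >= 2 respondents (got {n_pic}, {n_resp})"
        )
    engine = CrossedLogitLaplace(y, X, g_pic, g_resp)
    res: LaplaceFitResult = engine.fit(
        var1_fixed=var_picture_fixed, var2_fixed=var_respondent_fixed
    )
    return GlmmFit(
        spec=spec,
        beta=res.beta,
        beta_names=levels,
        vcov_beta=res.vcov_beta,
        var_picture=res.var1,
        var_respondent=res.var2,
        loglik=res.loglik,
        converged=res.converged,
        n_obs=res.n_obs,
        boundary_flags=res.boundary_flags,
    )


def population_probability(
    fit: GlmmFit, level: str, marginal: bool = False, n_quad: int = 41
) -> LinkEstimate:
    """Back-transformed probability for a fixed-factor level.

    Default is the conditional prediction (random effects at zero):
    ``invlogit(eta_level)`` with the SE of ``eta_level`` taken from the
    fixed-effect covariance through the contrast vector. With ``marginal``
    the logit-normal integral over both random-effect distributions is
    returned instead (Gauss-Hermite; the reported eta/se stay link-scale
    conditional quantities).
    """
    eta, se = fit.level_eta(level)
    if not marginal:
        p = 1.0 / (1.0 + math.exp(-eta))
        return LinkEstimate(p=p, eta=eta, se_eta=se)
    var = fit.var_picture + fit.var_respondent
    if var <= 0:
        p = 1.0 / (1.0 + math.exp(-eta))
        return LinkEstimate(p=p, eta=eta, se_eta=se)
    nodes, weights = hermegauss(n_quad)  # integral against standard normal
    z = eta + math.sqrt(var) * nodes
    p = float(np.sum(weights / (1.0 + np.exp(-z))) / math.sqrt(2.0 * math.pi))
    return LinkEstimate(p=p, eta=eta, se_eta=se)


def fit_mistake_model(
    dataset: SurveyDataset, unknown_as_mistake: bool = False
) -> GlmmFit:
    """Attitude-versus-misidentification GLMM (mistake response, attitude factor)."""
    spec = GlmmSpec(
        response=ResponseVar.MISTAKE,
        fixed_factor=FixedFactor.ATTITUDE,
        unknown_as_mistake=unknown_as_mistake,
    )
    return fit_binomial_glmm(dataset, spec)
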