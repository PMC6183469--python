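"""Binomial proportion estimates on the logit scale.

The intercept-only binomial GLM with a logit link has a closed-form maximum
likelihood solution: the intercept is ``logit(k/n)`` and its standard error is
``sqrt(1/k + 1/(n-k))`` (the inverse Fisher information ``1/(n p (1-p))``
expanded in counts). :func:`proportion_estimate` implements that solution
exactly; no iterative fit is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import EmptyInputError

Z_95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def inv_logit(eta: float) -> float:
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    e = math.exp(eta)
    return e / (1.0 + e)


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its logit-scale estimate and standard error.

    Attributes
    ----------
    k, n : int
        Successes and trials.
    p_hat : float
        ``k / n``.
    eta_hat : float
        ``logit(p_hat)``; ``±inf`` when ``k`` is 0 or ``n``.
    se_eta : float
        Logit-scale standard error; ``inf`` on the boundary.
    ci_low, ci_high : float
        95% Wald interval on the probability scale.
    """

    k: int
    n: int
    p_hat: float = field(init=False)
    eta_hat: float = field(init=False)
    se_eta: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise EmptyInputError("proportion estimate requires n >= 1")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"k={self.k} outside [0, n={self.n}]")
        p = self.k / self.n
        object.__setattr__(self, "p_hat", p)
        if 0 < self.k < self.n:
            eta = logit(p)
            se = math.sqrt(1.0 / self.k + 1.0 / (self.n - self.k))
            lo = inv_logit(eta - Z_95 * se)
            hi = inv_logit(eta + Z_95 * se)
        else:
            # boundary: MLE on the logit scale is not finite
            eta = math.inf if self.k == self.n else -math.inf
            se = math.inf
            lo, hi = (0.0, 1.0) if self.n == 0 else (float(p), float(p))
            lo, hi = min(lo, p), max(hi, p)
        object.__setattr__(self, "eta_hat", eta)
        object.__setattr__(self, "se_eta", se)
        object.__setattr__(self, "ci_low", lo)
        object.__setattr__(self, "ci_high", hi)

    @property
    def is_boundary(self) -> bool:
        return self.k == 0 or self.k == self.n

    def with_continuity_correction(self) -> "ContinuityCorrected":
        """Add 1/2 to both cells (k+1/2 successes, n-k+1/2 failures)."""
        return ContinuityCorrected(self.k, self.n)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "p_hat": self.p_hat,
            "eta_hat": self.eta_hat,
            "se_eta": self.se_eta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


class ContinuityCorrected:
    """Logit-scale estimate from half-integer corrected counts.

    Used when a raw proportion sits on the boundary and a finite logit-scale
    distribution is still needed (Monte Carlo draws).
    """

    def __init__(self, k: int, n: int):
        kk = k + 0.5
        ff = n - k + 0.5
        self.k, self.n = k, n
        self.p_hat = kk / (kk + ff)
        self.eta_hat = math.log(kk / ff)
        self.se_eta = math.sqrt(1.0 / kk + 1.0 / ff)


def proportion_estimate(k: int, n: int) -> ProportionEstimate:
    """Exact ML fit of the intercept-only binomial logit GLM."""
    return ProportionEstimate(int(k), int(n))
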