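"""Seeded synthetic survey generator.

Emulates the statistical structure the downstream analysis assumes: a
categorical attitude per respondent, and per-picture "called adder" responses
driven by a logit model with a species fixed effect, an attitude-specific
skill offset, and crossed picture/respondent random intercepts. Answers not
called "adder" are filled in by a simple mixing rule (unknown with a fixed
probability, otherwise mostly the correct species).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .estimates import logit
from .survey_io import Attitude, SeenWhere, Species, SurveyDataset

#: study-scale defaults: attitude mix and smooth/grass confusion probabilities
#: match the survey summary this package replicates
DEFAULT_PI = (0.696, 0.098, 0.206)  # no_kill, kill_all, kill_selective


@dataclass
class GeneratorConfig:
    """Ground-truth parameters for a synthetic survey.

    ``beta_*`` are logit-scale intercepts for the probability that a picture
    of that species is called "adder" by a KILL_SELECTIVE respondent of
    average skill. ``delta_attitude`` shifts the call-adder linear predictor
    for the other attitude groups (KILL_SELECTIVE is the reference at 0).
    """

    n_respondents: int = 102
    pi_no_kill: float = DEFAULT_PI[0]
    pi_kill_all: float = DEFAULT_PI[1]
    pi_kill_selective: float = DEFAULT_PI[2]
    beta_adder: float = logit(0.72)
    beta_smooth: float = logit(0.677)
    beta_grass: float = logit(0.072)
    delta_attitude: dict = field(
        default_factory=lambda: {
            Attitude.NO_KILL: 0.8,
            Attitude.KILL_ALL: 0.8,
            Attitude.KILL_SELECTIVE: 0.0,
        }
    )
    sigma_picture: float = 0.37
    sigma_respondent: float = 1.06
    p_unknown: float = 0.10
    p_cross_confusion: float = 0.10
    p_sighting: float = 0.94
    n_pictures_per_species: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.delta_attitude, Mapping):
            self.delta_attitude = {
                Attitude(k): float(v) for k, v in self.delta_attitude.items()
            }

    @property
    def pi(self) -> tuple[float, float, float]:
        return (self.pi_no_kill, self.pi_kill_all, self.pi_kill_selective)

    def validate(self) -> None:
        if self.n_respondents < 1:
            raise ConfigError("n_respondents must be >= 1")
        if self.n_pictures_per_species < 1:
            raise ConfigError("n_pictures_per_species must be >= 1")
        for name in ("pi_no_kill", "pi_kill_all", "pi_kill_selective"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if abs(sum(self.pi) - 1.0) > 1e-12:
            raise ConfigError("pi_no_kill + pi_kill_all + pi_kill_selective must sum to 1")
        for name in ("sigma_picture", "sigma_respondent"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("p_unknown", "p_cross_confusion", "p_sighting"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for att in Attitude:
            if att not in self.delta_attitude:
                raise ConfigError(f"delta_attitude missing level {att.value!r}")

    def beta_for(self, species: Species) -> float:
        return {
            Species.ADDER: self.beta_adder,
            Species.SMOOTH: self.beta_smooth,
            Species.GRASS: self.beta_grass,
        }[species]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta_attitude"] = {a.value: v for a, v in self.delta_attitude.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _picture_ids(n_per_species: int) -> tuple[list[str], list[str]]:
    ids, species = [], []
    for sp in Species:
        for j in range(1, n_per_species + 1):
            ids.append(f"{sp.value}_{j}")
            species.append(sp.value)
    return ids, species


_HARMLESS = {
    Species.ADDER.value: (Species.SMOOTH.value, Species.GRASS.value),
    Species.SMOOTH.value: (Species.GRASS.value,),
    Species.GRASS.value: (Species.SMOOTH.value,),
}

_MUNICIPALITIES = ("M1", "M2", "M3", "M4", "M5")


def generate(config: GeneratorConfig) -> SurveyDataset:
    """Draw one synthetic survey; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents

    attitudes = rng.choice(
        [a.value for a in Attitude], size=n, p=list(config.pi)
    )
    pic_ids, pic_species = _picture_ids(config.n_pictures_per_species)
    n_pic = len(pic_ids)
    a_pic = rng.normal(0.0, config.sigma_picture, size=n_pic)
    b_resp = rng.normal(0.0, config.sigma_respondent, size=n)

    resp_ids = [f"R{i + 1:04d}" for i in range(n)]
    saw = rng.random(n) < config.p_sighting
    where_draw = rng.choice(
        [SeenWhere.YARD.value, SeenWhere.NATURE.value, SeenWhere.BOTH.value],
        size=n,
        p=[0.25, 0.5, 0.25],
    )
    seen_where = np.where(saw, where_draw, SeenWhere.NONE.value)

    beta = np.array([config.beta_for(Species(sp)) for sp in pic_species])
    delta = np.array([config.delta_attitude[Attitude(a)] for a in attitudes])

    # linear predictor for the call-adder process, (n, n_pic)
    eta = beta[None, :] + a_pic[None, :] + delta[:, None] + b_resp[:, None]
    p_call = 1.0 / (1.0 + np.exp(-eta))
    called = rng.random((n, n_pic)) < p_call
    u_unknown = rng.random((n, n_pic))
    u_confuse = rng.random((n, n_pic))

    responses = np.empty((n, n_pic), dtype=object)
    for j, sp in enumerate(pic_species):
        others = _HARMLESS[sp]
        col = np.where(
            called[:, j],
            Species.ADDER.value,
            np.where(
                u_unknown[:, j] < config.p_unknown,
                "unknown",
                _fill_non_adder(sp, others, u_confuse[:, j], config.p_cross_confusion),
            ),
        )
        responses[:, j] = col

    respondents = pd.DataFrame(
        {
            "respondent_id": resp_ids,
            "municipality": [_MUNICIPALITIES[i % 5] for i in range(n)],
            "saw_snake_last_year": saw,
            "seen_where": seen_where,
            "attitude": attitudes,
        }
    )
    trials = pd.DataFrame(
        {
            "respondent_id": np.repeat(resp_ids, n_pic),
            "picture_id": np.tile(pic_ids, n),
            "true_species": np.tile(pic_species, n),
            "response": responses.reshape(-1),
        }
    )
    return SurveyDataset(respondents=respondents, trials=trials)


def _fill_non_adder(
    true_sp: str, others: tuple[str, ...], u: np.ndarray, p_cross: float
) -> np.ndarray:
    """Answer for a not-called-adder, not-unknown trial.

    Harmless pictures: correct species with probability 1 - p_cross, else the
    remaining harmless species. Adder pictures: the two harmless labels split
    evenly (a non-adder answer on an adder picture is always wrong).
    """
    if true_sp == Species.ADDER.value:
        return np.where(u < 0.5, others[0], others[1])
    return np.where(u < p_cross, others[0], true_sp)


def generate_ensemble(
    config: GeneratorConfig, n_replicates: int, base_seed: int
) -> list[SurveyDataset]:
    """Independent replicate surveys; replicate ``r`` uses seed ``base_seed + r``."""
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    out = []
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=base_seed + r)
        cfg.delta_attitude = dict(config.delta_attitude)
        out.append(generate(cfg))
    return out


def true_risk_ratio(config: GeneratorConfig, species: Species) -> float:
    """Analytic kill-risk ratio implied by the generator's ground truth.

    Uses the conditional (random-effects-at-zero, selective-respondent)
    call-adder probability, matching what the estimation pipeline targets.
    """
    eps = 1.0 / (1.0 + math.exp(-config.beta_for(species)))
    return 1.0 + config.pi_kill_selective * eps / config.pi_kill_all


def write_truth(config: GeneratorConfig, path: str | Path) -> None:
    """Write the ground-truth parameters (plus implied risk ratios) as JSON."""
    payload = {
        "config": config.to_dict(),
        "implied": {
            "phi_smooth": true_risk_ratio(config, Species.SMOOTH),
            "phi_grass": true_risk_ratio(config, Species.GRASS),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
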