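"""Survey data model, CSV input/output and structural validation.

The dataset is normalized into two tables:

* ``respondents`` — one row per interviewee: identifier, optional
  municipality, whether a snake was seen in the last year and where, and the
  declared attitude toward killing snakes.
* ``trials`` — one row per respondent x picture identification attempt:
  the picture shown, its true species, and the respondent's answer.

Both tables are plain CSV (UTF-8, comma separated, lowercase categorical
codes, booleans written as ``true``/``false``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    ConsistencyError,
    EmptyInputError,
    ReferentialError,
    SchemaError,
    ValidationError,
)
from .estimates import ProportionEstimate, proportion_estimate


class Species(str, enum.Enum):
    """True species of a pictured snake; ADDER is the modelling reference."""

    ADDER = "adder"
    SMOOTH = "smooth"
    GRASS = "grass"


class Attitude(str, enum.Enum):
    NO_KILL = "no_kill"
    KILL_ALL = "kill_all"
    KILL_SELECTIVE = "kill_selective"


class ResponseKind(str, enum.Enum):
    ADDER = "adder"
    SMOOTH = "smooth"
    GRASS = "grass"
    UNKNOWN = "unknown"


class SeenWhere(str, enum.Enum):
    YARD = "yard"
    NATURE = "nature"
    BOTH = "both"
    NONE = "none"


RESPONDENT_COLUMNS = (
    "respondent_id",
    "municipality",
    "saw_snake_last_year",
    "seen_where",
    "attitude",
)
TRIAL_COLUMNS = ("respondent_id", "picture_id", "true_species", "response")

_ATTITUDES = tuple(a.value for a in Attitude)
_SPECIES = tuple(s.value for s in Species)
_RESPONSES = tuple(r.value for r in ResponseKind)
_SEEN = tuple(s.value for s in SeenWhere)


@dataclass
class SurveyDataset:
    """Respondent attitudes plus identification trials.

    ``respondents`` and ``trials`` are pandas DataFrames with the canonical
    columns (:data:`RESPONDENT_COLUMNS`, :data:`TRIAL_COLUMNS`).
    """

    respondents: pd.DataFrame
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.respondents = self.respondents.reset_index(drop=True)
        self.trials = self.trials.reset_index(drop=True)

    # -- derived columns -------------------------------------------------

    def called_adder(self, drop_unknown: bool = False) -> pd.DataFrame:
        """Trials with a binary ``called_adder`` column.

        UNKNOWN answers count as not-called-adder by default (an unknown is
        not an identification as an adder); with ``drop_unknown`` they are
        removed from the table instead.
        """
        t = self.trials
        if drop_unknown:
            t = t[t["response"] != ResponseKind.UNKNOWN.value]
        t = t.copy()
        t["called_adder"] = (t["response"] == ResponseKind.ADDER.value).astype(int)
        return t

    def mistakes(self, unknown_as_mistake: bool = False) -> pd.DataFrame:
        """Trials with a binary ``is_mistake`` column.

        Default rule: a mistake is a wrong species answer; UNKNOWN answers
        are excluded from the denominator. ``unknown_as_mistake`` keeps them
        and scores them as mistakes.
        """
        t = self.trials
        if not unknown_as_mistake:
            t = t[t["response"] != ResponseKind.UNKNOWN.value]
        t = t.copy()
        t["is_mistake"] = (t["response"] != t["true_species"]).astype(int)
        return t

    def subset_by_attitude(self, attitude: Attitude) -> "SurveyDataset":
        keep = self.respondents[self.respondents["attitude"] == attitude.value]
        ids = set(keep["respondent_id"])
        return SurveyDataset(
            respondents=keep.copy(),
            trials=self.trials[self.trials["respondent_id"].isin(ids)].copy(),
        )

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    def equals(self, other: "SurveyDataset") -> bool:
        return self.respondents.equals(other.respondents) and self.trials.equals(
            other.trials
        )


# ---------------------------------------------------------------------------
# validation


def validate(dataset: SurveyDataset) -> list[str]:
    """Return a list of invariant-violation descriptions (empty if valid)."""
    violations: list[str] = []
    resp, trials = dataset.respondents, dataset.trials

    dup = resp["respondent_id"][resp["respondent_id"].duplicated()]
    for rid in dup.unique():
        violations.append(f"duplicate respondent_id: {rid!r}")

    bad_att = resp.loc[~resp["attitude"].isin(_ATTITUDES), "respondent_id"]
    for rid in bad_att:
        violations.append(f"invalid attitude for respondent {rid!r}")

    bad_seen = resp.loc[~resp["seen_where"].isin(_SEEN), "respondent_id"]
    for rid in bad_seen:
        violations.append(f"invalid seen_where for respondent {rid!r}")

    # seen_where == none iff saw_snake_last_year is false
    mism = resp[
        (resp["seen_where"].eq(SeenWhere.NONE.value))
        != (~resp["saw_snake_last_year"].astype(bool))
    ]
    for rid in mism["respondent_id"]:
        violations.append(
            f"respondent {rid!r}: seen_where must be 'none' exactly when "
            "saw_snake_last_year is false"
        )

    bad_sp = trials.loc[~trials["true_species"].isin(_SPECIES), "picture_id"]
    for pid in bad_sp.unique():
        violations.append(f"invalid true_species for picture {pid!r}")
    bad_resp_val = trials.loc[~trials["response"].isin(_RESPONSES)]
    for _, row in bad_resp_val.iterrows():
        violations.append(
            f"invalid response {row['response']!r} for respondent "
            f"{row['respondent_id']!r}, picture {row['picture_id']!r}"
        )

    known = set(resp["respondent_id"])
    orphans = sorted(set(trials["respondent_id"]) - known)
    if orphans:
        violations.append(
            "trials reference unknown respondent_id(s): " + ", ".join(map(repr, orphans))
        )

    pic_map = trials.groupby("picture_id")["true_species"].nunique()
    for pid in pic_map[pic_map > 1].index:
        violations.append(
            f"picture {pid!r} maps to multiple true_species across trials"
        )

    per_species = trials.groupby(["respondent_id", "true_species"]).size()
    for (rid, sp), count in per_species[per_species > 3].items():
        violations.append(
            f"respondent {rid!r} has {count} {sp} trials (max 3 per species)"
        )
    per_resp = trials.groupby("respondent_id").size()
    for rid, count in per_resp[per_resp > 9].items():
        violations.append(f"respondent {rid!r} has {count} trials (max 9)")

    for att in Attitude:
        if not (resp["attitude"] == att.value).any():
            violations.append(
                f"no respondent with attitude {att.value!r} "
                "(full pipeline requires all three categories)"
            )
    return violations


# ---------------------------------------------------------------------------
# CSV input / output


def _read_table(
    path: str | Path,
    required: Iterable[str],
    column_map: Mapping[str, str] | None,
    value_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = df[[c for c in required]].copy()
    if value_maps:
        for col, vmap in value_maps.items():
            if col in df.columns:
                df[col] = df[col].map(lambda v: vmap.get(v, v))
    return df


def read_survey(
    respondents_path: str | Path,
    trials_path: str | Path,
    column_map: Mapping[str, Mapping] | None = None,
) -> SurveyDataset:
    """Read and validate a two-file survey.

    ``column_map`` allows ingesting files with foreign headers without
    editing them. Layout (all keys optional)::

        respondents:
          columns: {attitude: "Attitude towards snakes", ...}   # canonical -> actual
          values:  {attitude: {"would kill all": "kill_all"}}   # recode cells
        trials:
          columns: {...}
          values:  {...}

    Raises :class:`SchemaError`, :class:`ReferentialError`,
    :class:`ConsistencyError` or :class:`ValidationError`.
    """
    cmap = column_map or {}
    rmap = cmap.get("respondents", {})
    tmap = cmap.get("trials", {})
    resp = _read_table(
        respondents_path,
        RESPONDENT_COLUMNS,
        rmap.get("columns"),
        rmap.get("values"),
    )
    resp["saw_snake_last_year"] = resp["saw_snake_last_year"].map(
        {"true": True, "false": False, "True": True, "False": False}
    )
    if resp["saw_snake_last_year"].isna().any():
        raise SchemaError(
            f"{respondents_path}: saw_snake_last_year must be true/false"
        )
    trials = _read_table(
        trials_path, TRIAL_COLUMNS, tmap.get("columns"), tmap.get("values")
    )
    dataset = SurveyDataset(respondents=resp, trials=trials)

    known = set(resp["respondent_id"])
    orphans = sorted(set(trials["respondent_id"]) - known)
    if orphans:
        raise ReferentialError(
            "trials reference respondent_id(s) absent from respondents: "
            + ", ".join(map(repr, orphans))
        )
    pic_map = trials.groupby("picture_id")["true_species"].nunique()
    bad = list(pic_map[pic_map > 1].index)
    if bad:
        raise ConsistencyError(
            "picture_id(s) map to multiple species: " + ", ".join(map(repr, bad))
        )
    problems = [
        v
        for v in validate(dataset)
        if "full pipeline requires" not in v  # checked by the pipeline itself
    ]
    if problems:
        raise ValidationError("; ".join(problems))
    return dataset


def read_single_file_survey(
    path: str | Path, column_map: Mapping[str, Mapping] | None = None
) -> SurveyDataset:
    """Ingest one wide CSV holding both respondent fields and trial rows.

    The file must contain all canonical columns of both tables; respondent
    attributes are taken from each respondent's first row.
    """
    cmap = (column_map or {}).get("combined", {})
    all_cols = tuple(dict.fromkeys(RESPONDENT_COLUMNS + TRIAL_COLUMNS))
    df = _read_table(path, all_cols, cmap.get("columns"), cmap.get("values"))
    resp = df.drop_duplicates("respondent_id")[list(RESPONDENT_COLUMNS)].copy()
    resp["saw_snake_last_year"] = resp["saw_snake_last_year"].map(
        {"true": True, "false": False}
    )
    trials = df[list(TRIAL_COLUMNS)].copy()
    return SurveyDataset(respondents=resp, trials=trials)


def write_survey(
    dataset: SurveyDataset,
    respondents_path: str | Path,
    trials_path: str | Path,
) -> None:
    resp = dataset.respondents.copy()
    resp["saw_snake_last_year"] = resp["saw_snake_last_year"].map(
        {True: "true", False: "false"}
    )
    resp.to_csv(respondents_path, index=False)
    dataset.trials.to_csv(trials_path, index=False)


# ---------------------------------------------------------------------------
# attitude summaries


def attitude_proportions(dataset: SurveyDataset) -> dict[Attitude, ProportionEstimate]:
    """Per-category attitude proportions as intercept-only binomial GLM fits."""
    n = dataset.n_respondents
    if n == 0:
        raise EmptyInputError("attitude_proportions requires at least one respondent")
    counts = dataset.respondents["attitude"].value_counts()
    return {
        att: proportion_estimate(int(counts.get(att.value, 0)), n) for att in Attitude
    }
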