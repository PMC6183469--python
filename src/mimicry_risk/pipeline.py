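"""End-to-end analysis: attitudes -> GLMMs -> risk ratios -> report.

Stages, in order:

1. attitude proportions (mu_0 = kill-all, mu_v = kill-selective) as
   intercept-only binomial GLMs;
2. identification GLMM (called-adder response, species fixed factor, crossed
   picture/respondent random intercepts) on all respondents;
3. the same GLMM refit on the selective-killer subset — its back-transformed
   species effects are the misidentification probabilities eps_i;
4. mistake-versus-attitude GLMM;
5. Monte Carlo risk ratios phi for the two harmless species.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import PipelineError
from .estimates import ProportionEstimate
from .inference import (
    FixedFactor,
    GlmmFit,
    GlmmSpec,
    LinkEstimate,
    ResponseVar,
    fit_binomial_glmm,
    fit_mistake_model,
    population_probability,
)
from .mimicry_cost import (
    DEFAULT_N_DRAWS,
    DEFAULT_SEED,
    KillRiskInputs,
    RiskRatioEstimate,
    monte_carlo_risk_ratio,
)
from .survey_io import (
    Attitude,
    Species,
    SurveyDataset,
    attitude_proportions,
    validate,
)

logger = logging.getLogger(__name__)

MIMIC_SPECIES = (Species.SMOOTH, Species.GRASS)  # no phi for the model species


@dataclass(frozen=True)
class AnalysisOptions:
    seed: int = DEFAULT_SEED
    n_draws: int = DEFAULT_N_DRAWS
    marginal: bool = False
    joint_attitude: bool = False
    scale: str = "link"
    unknown_as_mistake: bool = False
    drop_unknown_for_adder_model: bool = False
    continuity_correction: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisReport:
    attitude_estimates: dict[Attitude, ProportionEstimate]
    identification_fit_all: GlmmFit
    identification_fit_selective: GlmmFit
    mistake_fit: GlmmFit
    recognition_probs_all: dict[Species, LinkEstimate]
    recognition_probs_selective: dict[Species, LinkEstimate]
    raw_subset_proportions: dict[Species, ProportionEstimate]
    phi: dict[Species, RiskRatioEstimate]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "attitude_estimates": {
                a.value: e.to_dict() for a, e in self.attitude_estimates.items()
            },
            "identification_fit_all": self.identification_fit_all.to_dict(),
            "identification_fit_selective": self.identification_fit_selective.to_dict(),
            "mistake_fit": self.mistake_fit.to_dict(),
            "recognition_probs_all": {
                s.value: e.to_dict() for s, e in self.recognition_probs_all.items()
            },
            "recognition_probs_selective": {
                s.value: e.to_dict()
                for s, e in self.recognition_probs_selective.items()
            },
            "raw_subset_proportions": {
                s.value: e.to_dict() for s, e in self.raw_subset_proportions.items()
            },
            "phi": {s.value: e.to_dict() for s, e in self.phi.items()},
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_analysis(
    dataset: SurveyDataset, options: AnalysisOptions | None = None
) -> AnalysisReport:
    options = options or AnalysisOptions()
    problems = validate(dataset)
    if problems:
        raise PipelineError("dataset invalid: " + "; ".join(problems))

    logger.info(
        "analysis start: %d respondents, %d trials, seed=%d",
        dataset.n_respondents,
        len(dataset.trials),
        options.seed,
    )

    attitudes = attitude_proportions(dataset)
    mu0 = attitudes[Attitude.KILL_ALL]
    muv = attitudes[Attitude.KILL_SELECTIVE]
    if muv.k == 0:
        raise PipelineError(
            "no KILL_SELECTIVE respondents: phi is undefined without the "
            "selective-killer misidentification pathway"
        )

    spec_all = GlmmSpec(
        response=ResponseVar.CALLED_ADDER,
        fixed_factor=FixedFactor.SPECIES,
        drop_unknown_for_adder_model=options.drop_unknown_for_adder_model,
    )
    fit_all = fit_binomial_glmm(dataset, spec_all)
    logger.info(
        "identification GLMM (all): converged=%s var_pic=%.4f var_resp=%.4f",
        fit_all.converged,
        fit_all.var_picture,
        fit_all.var_respondent,
    )

    spec_sel = dataclasses.replace(spec_all, subset_attitude=Attitude.KILL_SELECTIVE)
    fit_sel = fit_binomial_glmm(dataset, spec_sel)
    logger.info(
        "identification GLMM (selective): converged=%s var_pic=%.4f var_resp=%.4f",
        fit_sel.converged,
        fit_sel.var_picture,
        fit_sel.var_respondent,
    )

    mistake_fit = fit_mistake_model(
        dataset, unknown_as_mistake=options.unknown_as_mistake
    )

    rec_all = {
        sp: population_probability(fit_all, sp.value, marginal=options.marginal)
        for sp in Species
    }
    rec_sel = {
        sp: population_probability(fit_sel, sp.value, marginal=options.marginal)
        for sp in Species
    }

    selective = dataset.subset_by_attitude(Attitude.KILL_SELECTIVE)
    sel_trials = selective.called_adder(
        drop_unknown=options.drop_unknown_for_adder_model
    )
    raw_props = {}
    for sp in Species:
        sub = sel_trials[sel_trials["true_species"] == sp.value]
        raw_props[sp] = ProportionEstimate(int(sub["called_adder"].sum()), len(sub))

    # eps enters phi on the link scale: conditional estimate + contrast SE
    eps = {sp: LinkEstimate(**rec_sel[sp].to_dict()) for sp in MIMIC_SPECIES}
    inputs = KillRiskInputs(mu0=mu0, muv=muv, eps=eps)
    phi = {
        sp: monte_carlo_risk_ratio(
            inputs,
            sp,
            n_draws=options.n_draws,
            seed=options.seed,
            scale=options.scale,
            joint_attitude=options.joint_attitude,
            continuity_correction=options.continuity_correction,
        )
        for sp in MIMIC_SPECIES
    }
    for sp, est in phi.items():
        logger.info(
            "phi[%s]: median=%.3f CI=(%.3f, %.3f)",
            sp.value,
            est.phi_median,
            est.ci_low,
            est.ci_high,
        )

    return AnalysisReport(
        attitude_estimates=attitudes,
        identification_fit_all=fit_all,
        identification_fit_selective=fit_sel,
        mistake_fit=mistake_fit,
        recognition_probs_all=rec_all,
        recognition_probs_selective=rec_sel,
        raw_subset_proportions=raw_props,
        phi=phi,
        provenance={
            "version": __version__,
            "seed": options.seed,
            "n_respondents": dataset.n_respondents,
            "n_trials": int(len(dataset.trials)),
            "options": options.to_dict(),
        },
    )


# ---------------------------------------------------------------------------
# report output


def write_report(report: AnalysisReport, path: str | Path, format: str = "json") -> None:
    """Write a report as ``json`` (lossless), a ``csv`` bundle, or ``text``.

    ``json``/``text`` treat ``path`` as a file; ``csv`` treats it as a
    directory and writes one table per report block.
    """
    path = Path(path)
    if format == "json":
        path.write_text(report.to_json())
    elif format == "text":
        path.write_text(render_text(report))
    elif format == "csv":
        _write_csv_bundle(report, path)
    else:
        raise ValueError(f"unknown report format {format!r}")


def render_text(report: AnalysisReport) -> str:
    lines = ["Mimicry kill-risk analysis", "=" * 30, ""]
    lines.append("Attitude proportions:")
    for att, est in report.attitude_estimates.items():
        lines.append(
            f"  {att.value:15s} {est.k:4d}/{est.n:<4d} = {100 * est.p_hat:5.1f}%"
        )
    lines.append("")
    lines.append("Recognition as adder (selective killers, conditional GLMM):")
    for sp, est in report.recognition_probs_selective.items():
        raw = report.raw_subset_proportions[sp]
        lines.append(
            f"  {sp.value:7s} glmm={100 * est.p:5.1f}%  raw={100 * raw.p_hat:5.1f}%"
        )
    lines.append("")
    lines.append("Identification GLMM (all respondents) variance components:")
    fit = report.identification_fit_all
    lines.append(f"  picture     {fit.var_picture:.3f}")
    lines.append(f"  interviewee {fit.var_respondent:.3f}")
    lines.append("")
    lines.append("Mimicry kill-risk ratios:")
    for sp, est in report.phi.items():
        lines.append(
            f"  phi[{sp.value}] = {est.phi_median:.2f} "
            f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f}; "
            f"plug-in {est.phi_plugin:.2f}, mean {est.phi_mean:.2f})"
        )
    lines.append("")
    return "\n".join(lines)


def _write_csv_bundle(report: AnalysisReport, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"attitude": a.value, **e.to_dict()}
            for a, e in report.attitude_estimates.items()
        ]
    ).to_csv(outdir / "attitudes.csv", index=False)
    rows = []
    for label, probs in (
        ("all", report.recognition_probs_all),
        ("kill_selective", report.recognition_probs_selective),
    ):
        for sp, e in probs.items():
            rows.append({"subset": label, "species": sp.value, **e.to_dict()})
    pd.DataFrame(rows).to_csv(outdir / "recognition.csv", index=False)
    pd.DataFrame(
        [
            {"species": s.value, **e.to_dict()}
            for s, e in report.raw_subset_proportions.items()
        ]
    ).to_csv(outdir / "raw_subset_proportions.csv", index=False)
    pd.DataFrame([e.to_dict() for e in report.phi.values()]).to_csv(
        outdir / "phi.csv", index=False
    )
    fits = []
    for name, fit in (
        ("identification_all", report.identification_fit_all),
        ("identification_selective", report.identification_fit_selective),
        ("mistake", report.mistake_fit),
    ):
        d = fit.to_dict()
        fits.append(
            {
                "model": name,
                "var_picture": d["var_picture"],
                "var_respondent": d["var_respondent"],
                "loglik": d["loglik"],
                "converged": d["converged"],
                "n_obs": d["n_obs"],
                **{f"beta[{k}]": v for k, v in d["beta"].items()},
            }
        )
    pd.DataFrame(fits).to_csv(outdir / "model_fits.csv", index=False)
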