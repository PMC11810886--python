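"""End-to-end pipeline: simulate -> summarize -> verify -> estimate ->
equations -> reckoner -> validate, with every artifact written to disk."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as stcr_io
from .basic_params import BasicParameters, estimate_all
from .config import PipelineConfig
from .prescription import EquationSet, build_reckoner, derive_equation, format_reckoner
from .schema import NUTRIENTS
from .synthetic_trial import generate_trial, generate_validation_trial
from .trial_stats import fit_yield_model, summarize_strips, verify_gradient
from .validation import score_validation

logger = logging.getLogger("stcr")

GRADIENT_VARIABLES = ("s_n", "s_p", "s_k")


class GradientNotEstablishedError(RuntimeError):
    """Strip soil-test means are not strictly increasing; the inductive
    method's premise fails and downstream estimation would be meaningless."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineResult:
    plots: pd.DataFrame
    summaries: pd.DataFrame
    gradient: pd.DataFrame
    parameters: BasicParameters
    equations: EquationSet
    reckoners: dict[str, pd.DataFrame]
    validation: pd.DataFrame
    outdir: Path


def setup_logging(verbosity: int = 1) -> None:
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logging.basicConfig(
        level=level,
        stream=sys.stderr,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def run_pipeline(
    config: PipelineConfig, plots: pd.DataFrame | None = None
) -> PipelineResult:
    """Run every stage and write the artifact bundle under ``config.outdir``.

    ``plots`` may carry observed plot data; by default a synthetic trial is
    generated from the configured ground truth.  Outputs are byte-stable for
    a fixed seed and configuration.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = config.ground_truth()

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    if plots is None:
        plots = stage("simulate", lambda: generate_trial(config.design(), truth))
    stcr_io.write_plot_table(plots, outdir / "plots.csv")

    summaries = stage("summarize", lambda: summarize_strips(plots))
    summaries.to_csv(outdir / "strip_summaries.csv", index=False, float_format="%.4f")

    gradient = stage(
        "verify_gradient", lambda: verify_gradient(summaries, GRADIENT_VARIABLES)
    )
    gradient.astype(str).to_csv(outdir / "gradient_report.csv", index=False)
    if not gradient["passed"].all():
        failed = ", ".join(gradient[~gradient["passed"]]["variable"])
        raise GradientNotEstablishedError(
            f"fertility gradient not established for: {failed}; "
            "strip means must increase strictly from strip I to III"
        )

    fit = stage("regress", lambda: fit_yield_model(plots))
    (outdir / "yield_model.json").write_text(
        json.dumps(
            {
                "intercept": fit.intercept,
                "coefficients": fit.coefficients,
                "r_squared": fit.r_squared,
            },
            indent=2,
        )
        + "\n"
    )

    params = stage(
        "estimate",
        lambda: estimate_all(
            plots,
            config.conversions(),
            config.fym_spec(),
            method=config.estimator_method,
            nr_method=config.nr_method,
        ),
    )
    params.to_frame().to_csv(outdir / "parameters.csv", float_format="%.4f")

    equations = stage(
        "equations",
        lambda: derive_equation(
            params, config.conversions(), config.floors, config.caps
        ),
    )
    published_form = equations.rounded()
    (outdir / "equations.txt").write_text(_render_equations(published_form))

    credit_options = config.reckoner_credit_options()
    reckoners = {}
    for j in NUTRIENTS:
        reckoners[j] = stage(
            f"reckoner[{j}]",
            lambda j=j: build_reckoner(
                published_form,
                j,
                config.reckoner_target_q,
                config.reckoner_stv_grids[j],
                credit_options,
            ),
        )
    pd.concat(
        [t.assign(nutrient=j) for j, t in reckoners.items()], ignore_index=True
    ).to_csv(outdir / "reckoner.csv", index=False, float_format="%.1f")
    (outdir / "reckoner.txt").write_text(
        "\n\n".join(
            f"{j.upper()} (target {config.reckoner_target_q:g} q/ha)\n"
            + format_reckoner(t)
            for j, t in reckoners.items()
        )
        + "\n"
    )

    records = stage(
        "validate",
        lambda: generate_validation_trial(
            published_form, truth, config.validation_targets_t_ha
        ),
    )
    report = stage("score_validation", lambda: score_validation(records))
    report.to_csv(outdir / "validation_report.csv", index=False, float_format="%.4f")

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return PipelineResult(
        plots, summaries, gradient, params, equations, reckoners, report, outdir
    )


def _render_equations(eqs: EquationSet) -> str:
    stv_name = {"n": "SN", "p2o5": "SP", "k2o": "SK"}
    o_name = {"n": "ON", "p2o5": "OP", "k2o": "OK"}
    lines = ["Fertilizer prescription equations (kg/ha; T in q/ha)", ""]
    lines += ["Inorganic alone:"]
    for j in NUTRIENTS:
        e = eqs.get(j)
        lines.append(f"  F_{j.upper()} = {e.a:.2f} T - {e.b:.2f} {stv_name[j]}")
    lines += ["", "Integrated (with manure credit O, kg/ha element basis):"]
    for j in NUTRIENTS:
        e = eqs.get(j)
        lines.append(
            f"  F_{j.upper()} = {e.a:.2f} T - {e.b:.2f} {stv_name[j]} - {e.c:.2f} {o_name[j]}"
        )
    lines += [""]
    for j in NUTRIENTS:
        e = eqs.get(j)
        parts = []
        if e.floor is not None:
            parts.append(f"maintenance floor {e.floor:g}")
        if e.cap is not None:
            parts.append(f"maximum {e.cap:g}")
        if parts:
            lines.append(f"  {j.upper()}: " + ", ".join(parts) + " kg/ha")
    return "\n".join(lines) + "\n"
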