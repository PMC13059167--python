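"""End-to-end pipeline: generate/load inputs -> calibrate -> simulate
scenarios -> outcomes and costs -> CEA -> optional DSA/PSA -> reports.

Every stage writes plain CSV (plus a JSON machine summary and a run log
echoing the seed, package version and every parameter actually used), and
every output is re-readable by the package's own readers.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import compare_scenarios, run_scenarios
from .config import RunConfig, config_to_dict
from .model import CostEffectivenessModel
from .outcomes import LifeTable
from .risk import RiskChart
from .synthetic import (
    assign_risk,
    calibrate_mean_risk,
    child_seeds,
    generate_cohort,
    generate_life_table,
    generate_risk_chart,
)
from .uncertainty import ceac as make_ceac, default_dsa_ranges, one_way_dsa, sample_psa


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("inputs")
def prepare_inputs(config: RunConfig):
    """Load CSV inputs when paths are given, otherwise generate synthetic
    ones; calibrate the chart intercept when requested."""
    seeds = child_seeds(config.seed, 4)
    chart = (
        RiskChart.from_csv(config.paths.chart_csv)
        if config.paths.chart_csv
        else generate_risk_chart(config.chart)
    )
    if config.paths.cohort_csv:
        cohort = pd.read_csv(config.paths.cohort_csv)
        cohort["sex"] = cohort["sex"].astype(str)
    else:
        spec = replace(config.cohort, seed=seeds[0])
        cohort = generate_cohort(spec, chart)
    life = (
        LifeTable.from_csv(config.paths.life_table_csv)
        if config.paths.life_table_csv
        else generate_life_table()
    )
    chart_params = config.chart
    if config.flags.calibrate and not config.paths.chart_csv:
        chart_params = calibrate_mean_risk(
            config.flags.calibration_target, cohort, config.chart,
            config.transitions, config.model,
        )
        chart = RiskChart.from_logistic(chart_params)
        cohort = cohort.copy()
        cohort["risk10"] = assign_risk(cohort, chart)
    elif "risk10" not in cohort.columns:
        cohort = cohort.copy()
        cohort["risk10"] = assign_risk(cohort, chart)
    return cohort, chart, life


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns a dict with the in-memory tables ('scenarios', 'cea',
    'dsa', 'psa', 'ceac' as configured) and the output directory.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, chart, life = prepare_inputs(config)
    inputs = config.model_inputs()

    cohort.to_csv(out / "cohort.csv", index=False)
    chart.to_csv(out / "risk_chart.csv")
    life.to_csv(out / "life_table.csv")

    scenario_table = _run_scenarios_stage(cohort, life, inputs)
    scenario_table.to_csv(out / "scenario_summary.csv")
    comparisons = compare_scenarios(scenario_table)
    cea_rows = pd.DataFrame(
        [
            {
                "comparison": label,
                "comparator": r.comparator,
                "intervention": r.intervention,
                "delta_cost": r.delta_cost,
                "dalys_averted": r.dalys_averted,
                "icer": r.icer,
                "classification": r.classification,
            }
            for label, r in comparisons.items()
        ]
    )
    cea_rows.to_csv(out / "cea.csv", index=False)
    results = {"scenarios": scenario_table, "cea": cea_rows, "output_dir": out}

    if config.flags.run_dsa:
        tables = [
            one_way_dsa(cohort, life, inputs, name, low, high)
            for name, (low, high) in default_dsa_ranges(inputs).items()
        ]
        dsa_table = pd.concat(tables, ignore_index=True)
        dsa_table.to_csv(out / "dsa.csv", index=False)
        results["dsa"] = dsa_table

    if config.flags.run_psa:
        psa_seed = child_seeds(config.seed, 4)[1]
        psa_table = sample_psa(
            cohort, life, inputs,
            n_draws=config.flags.psa_draws, seed=psa_seed,
            mode=config.flags.psa_mode,
        )
        psa_table.to_csv(out / "psa.csv", index=False)
        ceac_table = make_ceac(psa_table, settings=config.cea)
        ceac_table.to_csv(out / "ceac.csv", index=False)
        results["psa"] = psa_table
        results["ceac"] = ceac_table

    machine = {
        "icers": {
            label: {
                "delta_cost": r.delta_cost,
                "dalys_averted": r.dalys_averted,
                "icer": r.icer,
                "classification": r.classification,
            }
            for label, r in comparisons.items()
        }
    }
    (out / "summary.json").write_text(json.dumps(machine, indent=2))
    log = {
        "seed": config.seed,
        "version": __version__,
        "parameters": config_to_dict(config),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return results


@_stage("scenarios")
def _run_scenarios_stage(cohort, life, inputs):
    return run_scenarios(cohort, life, inputs)
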