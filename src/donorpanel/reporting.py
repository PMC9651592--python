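"""Full-pipeline report builder: demand -> sizing -> validation -> timeline.

One call runs a complete scenario and writes a machine-readable JSON summary,
CSV table analogues (sizing per success percentage, S-vs-K sweep, timeline
per screening fraction) and a manifest recording every input, parameter and
seed so each number can be recomputed from the underlying operation.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .demand import TargetVector, read_profile
from .sizing import minimal_sample_size
from .synthetic import (
    default_panel_params,
    generate_profile,
    genotype_spec,
    phenotype_spec,
)
from .timeline import maintenance_rate, years_to_target
from .validation import run_validation, sweep_multiples

__all__ = ["RunConfig", "REPORT_SCHEMA", "run_full_analysis", "validate_report"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full analysis run."""

    scenario: str = "genotype"  # genotype | phenotype
    profile_path: str | None = None  # supplied probabilities win over synthetic
    confidence: tuple[float, ...] = (95.0, 85.0)
    sizing_step: int = 100
    multipliers: tuple[float, ...] = (1.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    n_samples: int = 10_000
    fractions: tuple[float, ...] = tuple(f / 100 for f in range(1, 13))
    seed: int = 0
    outdir: str | None = None


#: Minimal JSON-Schema-style description of the report summary.
REPORT_SCHEMA: dict[str, Any] = {
    "type": "object",
    "required": [
        "scenario", "seed", "r", "sizing", "validation", "timeline",
        "maintenance_rate",
    ],
    "properties": {
        "scenario": {"type": "string"},
        "seed": {"type": "integer"},
        "r": {"type": "integer"},
        "sizing": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["C", "S_C", "panel_fraction", "lower", "upper_product"],
            },
        },
        "validation": {
            "type": "object",
            "required": ["S", "n_samples", "min_success_pct",
                         "all_targets_met_fraction"],
        },
        "timeline": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["fraction", "years", "donors_at_attainment"],
            },
        },
        "maintenance_rate": {"type": "number"},
    },
}

_JSON_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
}


def validate_report(report: dict[str, Any], schema: dict[str, Any] = REPORT_SCHEMA) -> None:
    """Check a report against the schema (required keys and types).

    Supports the schema subset used here: type, required, properties, items.
    Raises ``ValueError`` on the first violation.
    """
    expected = _JSON_TYPES[schema.get("type", "object")]
    if not isinstance(report, expected):
        raise ValueError(f"expected {schema['type']}, got {type(report).__name__}")
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub)
    elif isinstance(report, list):
        items = schema.get("items")
        if items:
            for item in report:
                validate_report(item, items)


def _summary_dict(summary) -> dict[str, Any]:
    d = dataclasses.asdict(summary)
    return d


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run demand -> sizing -> Monte Carlo validation -> timeline.

    Returns the report dict; when ``config.outdir`` is set, also writes
    ``manifest.json``, ``report.json`` and CSV tables there.
    """
    if config.profile_path is not None:
        profile = read_profile(config.profile_path)
    else:
        spec = (
            genotype_spec(config.seed)
            if config.scenario == "genotype"
            else phenotype_spec(config.seed)
        )
        profile = generate_profile(spec)
    params = default_panel_params(config.scenario)
    targets = TargetVector([1] * profile.r)  # at-least-one coverage

    sizing_rows = []
    for C in sorted(config.confidence, reverse=True):
        res = minimal_sample_size(
            profile, targets, C=C, step=config.sizing_step,
            panel_size=params.panel_size,
        )
        sizing_rows.append(
            {
                "C": C,
                "S_C": res.S_C,
                "panel_fraction": res.panel_fraction,
                "lower": res.bounds.lower,
                "upper_product": res.bounds.upper_product,
                "upper_exp": res.bounds.upper_exp,
            }
        )
    S_main = sizing_rows[0]["S_C"]

    mc = run_validation(
        S_main, profile, targets, n_samples=config.n_samples, seed=config.seed
    )
    sweep = sweep_multiples(
        profile, targets, config.multipliers,
        n_samples=config.n_samples, seed=config.seed,
    )

    timeline_rows = []
    for fraction in config.fractions:
        res = years_to_target(
            replace(params, screening_fraction=fraction), target=S_main
        )
        timeline_rows.append(
            {
                "fraction": fraction,
                "years": res.years,
                "donors_at_attainment": round(res.D_y) if res.years is not None else None,
                "steady_state": res.steady_state,
            }
        )

    report: dict[str, Any] = {
        "scenario": config.scenario,
        "seed": config.seed,
        "r": profile.r,
        "sizing": sizing_rows,
        "validation": _summary_dict(mc),
        "sweep": [
            {"multiplier": row.multiplier, "S": row.S,
             "min_success_pct": row.min_success_pct}
            for row in sweep
        ],
        "timeline": timeline_rows,
        "maintenance_rate": maintenance_rate(S_main, params.m),
    }
    validate_report(report)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "package": "donorpanel",
            "version": __version__,
            "config": dataclasses.asdict(config),
            "panel_params": dataclasses.asdict(params),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        pd.DataFrame(sizing_rows).to_csv(outdir / "sizing.csv", index=False)
        pd.DataFrame(report["sweep"]).to_csv(outdir / "sweep.csv", index=False)
        pd.DataFrame(timeline_rows).to_csv(outdir / "timeline.csv", index=False)
    return report
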