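"""Human- and machine-readable summaries of comparisons.

The JSON schema is versioned; fields are plain numbers/strings so reports
can be archived and diffed across software versions.
"""
from __future__ import annotations

import json
from typing import Optional

from .model import GammaResult, IGResult

REPORT_SCHEMA_VERSION = 1


def gamma_summary(result: GammaResult) -> dict:
    c = result.criteria
    return {
        "dose_criterion_pct": c.dose_criterion_pct,
        "dta_mm": c.dta_mm,
        "ldt_pct": c.ldt_pct,
        "normalization": c.normalization,
        "norm_dose": result.norm_dose,
        "n_included": result.n_included,
        "n_passed": result.n_passed,
        "gai_pct": result.gai_pct,
    }


def ig_summary(result: IGResult) -> dict:
    return {
        "mode": result.mode.value,
        "fixed_value": result.fixed_value,
        "target_gai_pct": result.target_gai_pct,
        "found_dta_mm": result.found_dta_mm,
        "found_dd_pct": result.found_dd_pct,
        "achieved_gai_pct": result.achieved_gai_pct,
        "status": result.status.value,
        "n_iterations": result.n_iterations,
    }


def comparison_report(
    name: str,
    gamma: Optional[GammaResult] = None,
    inverse: Optional[IGResult] = None,
) -> dict:
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "name": name}
    if gamma is not None:
        report["gamma"] = gamma_summary(gamma)
    if inverse is not None:
        report["inverse"] = ig_summary(inverse)
    return report


def render_text(report: dict) -> str:
    lines = [f"comparison: {report['name']}"]
    if "gamma" in report:
        g = report["gamma"]
        lines.append(
            f"  gamma {g['dose_criterion_pct']:g}%/{g['dta_mm']:g} mm "
            f"(LDT {g['ldt_pct']:g}%): GAI {g['gai_pct']:.2f}% "
            f"({g['n_passed']}/{g['n_included']} points)"
        )
    if "inverse" in report:
        s = report["inverse"]
        found = []
        if s["found_dta_mm"] is not None:
            found.append(f"dta {s['found_dta_mm']:.3g} mm")
        if s["found_dd_pct"] is not None:
            found.append(f"dd {s['found_dd_pct']:.3g}%")
        lines.append(
            f"  inverse ({s['mode']}, fixed {s['fixed_value']:g}, target GAI "
            f"{s['target_gai_pct']:g}%): {', '.join(found)} — "
            f"{s['status']}, achieved {s['achieved_gai_pct']:.2f}% "
            f"in {s['n_iterations']} iterations"
        )
    return "\n".join(lines)


def to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
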