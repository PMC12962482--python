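"""Result tables, run manifests, and the full-report bundle writer.

Display rounding (whole dollars with separators, two-decimal life years)
happens only in the formatted table; CSV/JSON payloads keep full
precision.  Every output directory gets a manifest tying the files to the
config digest, seed, and package version that produced them.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import CEAResult
from .parameters import ParameterSet, serialize
from .psa import ceac, ceac_crossing, default_wtp_grid, run_psa
from .sensitivity import evaluate, one_way, threshold, tornado, two_way
from .tree import StrategyResult, build_model, rollback

__all__ = ["BaseCaseReport", "run_base_case", "run_full_report", "write_manifest"]


def fmt_dollars(x: float) -> str:
    return f"${x:,.0f}"


def fmt_life_years(x: float) -> str:
    return f"{x:.2f}"


@dataclass(frozen=True)
class BaseCaseReport:
    """Per-strategy results plus the incremental comparison."""

    clinician: StrategyResult
    ai_assisted: StrategyResult
    comparison: CEAResult
    wtp: float

    @property
    def cost_effective(self) -> bool:
        from .sensitivity import icer_value

        return icer_value(self.comparison) <= self.wtp

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strategy": "clinician", "cost": self.clinician.cost,
             "incremental_cost": None, "effect": self.clinician.effect,
             "incremental_effect": None, "icer": None},
            {"strategy": "ai_assisted", "cost": self.ai_assisted.cost,
             "incremental_cost": self.comparison.delta_cost,
             "effect": self.ai_assisted.effect,
             "incremental_effect": self.comparison.delta_effect,
             "icer": self.comparison.icer},
        ]
        return pd.DataFrame(rows)

    def formatted(self) -> str:
        c, a, r = self.clinician, self.ai_assisted, self.comparison
        icer_txt = r.dominance or fmt_dollars(r.icer) + "/LY"
        verdict = "cost-effective" if self.cost_effective else "NOT cost-effective"
        return "\n".join([
            "strategy      cost        effect (LY)",
            f"clinician     {fmt_dollars(c.cost):<11} {fmt_life_years(c.effect)}",
            f"ai_assisted   {fmt_dollars(a.cost):<11} {fmt_life_years(a.effect)}",
            f"incremental   {fmt_dollars(r.delta_cost):<11} "
            f"{r.delta_effect:.4f}",
            f"ICER: {icer_txt}   ({verdict} at {fmt_dollars(self.wtp)}/LY)",
        ])


def run_base_case(params: ParameterSet, wtp: float | None = None) -> BaseCaseReport:
    """Roll back the packaged (or overridden) model once."""
    results = rollback(build_model(params))
    comparison = evaluate(params)
    return BaseCaseReport(results["clinician"], results["ai_assisted"],
                          comparison, wtp if wtp is not None else params["wtp"])


def write_manifest(outdir: Path, params: ParameterSet, seed, subcommand: str,
                   artifacts: list[str]) -> dict:
    manifest = {
        "config_digest": params.digest(),
        "seed": seed,
        "subcommand": subcommand,
        "package_version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _oneway_frame(curve) -> pd.DataFrame:
    return pd.DataFrame({
        "value": curve.grid,
        "delta_cost": [r.delta_cost for r in curve.results],
        "delta_effect": [r.delta_effect for r in curve.results],
        "icer": curve.icers,
    })


def run_full_report(params: ParameterSet, seed: int, outdir) -> dict:
    """Base case + tornado + prevalence curve + thresholds + two-way + PSA.

    Writes one CSV/JSON artifact per analysis plus a manifest; returns the
    manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def save(frame: pd.DataFrame, name: str) -> None:
        frame.to_csv(outdir / name, index=False)
        artifacts.append(name)

    serialize(params, outdir / "config.yaml")
    artifacts.append("config.yaml")

    base = run_base_case(params)
    save(base.to_frame(), "base_case.csv")

    entries = tornado(params)
    save(pd.DataFrame([{
        "parameter": e.parameter, "low": e.low, "high": e.high,
        "icer_low": e.icer_low, "icer_high": e.icer_high, "span": e.span,
    } for e in entries]), "tornado.csv")

    save(_oneway_frame(one_way(params, "malignancy_prevalence", 0.01, 0.8, 80)),
         "oneway_prevalence.csv")

    wtp = params["wtp"]
    thresholds = [
        threshold(params, "malignancy_prevalence", wtp, (0.01, 0.8)),
        threshold(params, "malignancy_prevalence", 50_000.0, (0.01, 0.8)),
        threshold(params, "strat_clinician_malignant_high", wtp, (0.2, 0.9)),
    ]
    frame = pd.DataFrame([{
        "parameter": t.parameter, "wtp": t.wtp, "value": t.value,
        "crossed": t.crossed,
    } for t in thresholds])
    save(frame, "thresholds.csv")

    freq_grid = [i / 10 for i in range(11)]
    spec_grid = [0.49 + i * 0.04 for i in range(9)]
    matrix = two_way(params, "p_intermediate_pet", freq_grid,
                     "pet_specificity", spec_grid)
    rows = []
    for f, row in zip(freq_grid, matrix):
        for s, r in zip(spec_grid, row):
            rows.append({"pet_frequency": f, "pet_specificity": s,
                         "delta_cost": r.delta_cost,
                         "delta_effect": r.delta_effect, "icer": r.icer})
    save(pd.DataFrame(rows), "twoway_pet.csv")

    samples = run_psa(params, int(params["psa_draws"]), seed)
    save(pd.DataFrame([{
        "draw": s.index,
        "clinician_cost": s.results["clinician"].cost,
        "clinician_effect": s.results["clinician"].effect,
        "ai_cost": s.results["ai_assisted"].cost,
        "ai_effect": s.results["ai_assisted"].effect,
    } for s in samples]), "psa_draws.csv")

    curve = ceac(samples, default_wtp_grid())
    ceac_frame = pd.DataFrame({
        "wtp": curve.wtp,
        "ai_fraction": curve.ai_fraction,
        "clinician_fraction": curve.clinician_fraction,
    })
    save(ceac_frame, "ceac.csv")
    crossing = ceac_crossing(curve)
    (outdir / "ceac_crossing.json").write_text(json.dumps({
        "crossing_wtp": crossing,
        "ai_fraction_at_wtp": curve.ai_fraction[
            min(range(len(curve.wtp)),
                key=lambda i: abs(curve.wtp[i] - params["wtp"]))
        ],
    }, indent=2))
    artifacts.append("ceac_crossing.json")

    return write_manifest(outdir, params, seed, "full-report", artifacts)
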