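"""End-to-end pipeline driver and report writers.

``run_pipeline`` composes the whole method for one feed scenario: proximate
composition -> feed stream -> flowsheet simulation -> batch schedule ->
annualized material balance -> priced cash flows -> TEA summary.
``write_reports`` serializes the result to CSV/JSON artifacts (material
balance, stream table, Gantt, revenue split, TEA summary).

Masses in the human-facing CSVs are written with two fixed decimals (and
thousands separators for annual totals), and the report itself stores the
same rounded values, so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .composition import (
    FattyAcidProfile,
    ProximateComposition,
    larvae_feed_stream,
    wet_basis_fractions,
)
from .economics import (
    CostModel,
    TeaSummary,
    annual_profit,
    build_cashflows,
    default_cost_model,
    irr,
    irr_report_pct,
    npv,
)
from .flowsheet import SimulationResult, Stream, build_default_flowsheet, simulate
from .scheduling import (
    DEFAULT_ANNUAL_OPERATING_TIME,
    Recipe,
    ScheduleSummary,
    annualize,
    build_gantt,
    default_recipe,
    n_batches,
)
from .synthetic import sample_composition

__all__ = [
    "RunReport",
    "PipelineError",
    "run_pipeline",
    "run_from_config",
    "write_reports",
    "consumables_per_batch",
    "read_material_balance",
]

#: Stream labels billed the waste disposal fee (third-party treatment).
WASTE_STREAMS = ("Wastes 1", "Cellulose waste", "Ash waste", "Wastes 2")

#: Fatty-acid product stream labels and their component keys.
PRODUCT_STREAMS = {
    "Lauric acid product": "lauric_acid",
    "Myristic acid product": "myristic_acid",
    "Palmitic acid product": "palmitic_acid",
    "Stearic acid product": "stearic_acid",
}

# Specific-demand factors for the consumable model (config-grade assumptions).
STEAM_LATENT_KJ_PER_KG = 2100.0       # superheated steam heat duty credit
COOLING_WATER_DT_K = 10.0             # cooling-water temperature rise
COOLING_WATER_CP = 4.186              # kJ/kg K
GRINDER_KWH_PER_KG = 0.02
FREEZE_DRY_KWH_PER_KG_WATER = 1.0
MEMBRANE_LIFE_BATCHES = 100.0         # batches per membrane replacement


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunReport:
    """Everything one pipeline run produces, ready for serialization."""

    scenario_label: str
    schedule: ScheduleSummary
    material_balance: dict[str, dict[str, float]]  # row -> {kg_batch, kg_yr}
    revenue_split: dict[str, float]                # component -> kg/yr
    tea: TeaSummary
    revenue: float
    operating_cost: float
    gross_profit: float
    streams: dict[str, Stream]
    gantt: list[tuple[int, str, float, float]]
    consumables: dict[str, float] = field(default_factory=dict)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        rows = [k for k in self.material_balance if k != "Total"]
        for col in ("kg_batch", "kg_yr"):
            total = sum(self.material_balance[r][col] for r in rows)
            if not math.isclose(total, self.material_balance["Total"][col], rel_tol=0, abs_tol=0.011):
                raise PipelineError(
                    f"[report] material-balance Total {col} "
                    f"{self.material_balance['Total'][col]} != row sum {total}"
                )


def consumables_per_batch(sim: SimulationResult, feed_mass: float) -> dict[str, float]:
    """Estimate per-batch consumable demands from the simulation's duties.

    Steam covers the reboiler duties (half of each tower's recorded total
    duty); cooling water absorbs the condenser-side duties; electricity
    covers grinding and freeze-dryer sublimation; membrane area is amortized
    over its replacement life.
    """
    reboiler_kj = sum(d / 2.0 for u, d in sim.duties.items() if u.startswith("C-"))
    condenser_kj = sum(d / 2.0 for u, d in sim.duties.items() if u.startswith("C-"))
    condenser_kj += sum(d for u, d in sim.duties.items() if u.startswith("HX-"))
    water_removed = sim.streams.get("Drying exhaust")
    dried_kg = water_removed.total if water_removed is not None else 0.0
    return {
        "steam_mt": reboiler_kj / STEAM_LATENT_KJ_PER_KG / 1000.0,
        "cooling_water_m3": condenser_kj / (COOLING_WATER_CP * COOLING_WATER_DT_K) / 1000.0,
        "electricity_kwh": feed_mass * GRINDER_KWH_PER_KG + dried_kg * FREEZE_DRY_KWH_PER_KG_WATER,
        "membrane_m2": sum(sim.areas.values()) / MEMBRANE_LIFE_BATCHES,
    }


def _round2(x: float) -> float:
    return round(x, 2)


def run_pipeline(
    composition: ProximateComposition,
    profile: FattyAcidProfile | None = None,
    cost_model: CostModel | None = None,
    batch_mass: float = 10_000.0,
    enzyme: float = 100.0,
    flowsheet_kwargs: dict | None = None,
    recipe: Recipe | None = None,
    annual_operating_time: float = DEFAULT_ANNUAL_OPERATING_TIME,
    sample_seed: int | None = None,
    gantt_batches: int | None = None,
) -> RunReport:
    """Run the full method for one feed scenario and return a :class:`RunReport`.

    When ``sample_seed`` is given, the composition is first perturbed by the
    scenario sampler (mean +/- SD per analyte); otherwise the row means are
    used.  Deterministic for fixed inputs and seed.  ``gantt_batches`` caps
    the number of batches expanded into the Gantt table (default: all).
    """
    profile = profile or FattyAcidProfile()
    cost_model = cost_model or default_cost_model()
    recipe = recipe or default_recipe()
    fkw = dict(flowsheet_kwargs or {})
    fkw.setdefault("enzyme", enzyme)

    try:
        if sample_seed is not None:
            composition = sample_composition(composition, sample_seed)
        fractions = wet_basis_fractions(composition)
        feed = larvae_feed_stream(batch_mass, fractions, profile)
    except ValueError as exc:
        raise PipelineError(f"[composition] {exc}") from exc

    try:
        fs = build_default_flowsheet(**fkw)
        sim = simulate(fs, feed)
    except ValueError as exc:
        raise PipelineError(f"[flowsheet] {exc}") from exc

    try:
        n = n_batches(annual_operating_time, recipe.batch_time, recipe.cycle_time)
        schedule = ScheduleSummary(
            annual_operating_time=annual_operating_time,
            batch_time=recipe.batch_time,
            cycle_time=recipe.cycle_time,
            n_batches=n,
        )
        gantt = build_gantt(recipe, min(n, gantt_batches) if gantt_batches else n)
    except ValueError as exc:
        raise PipelineError(f"[scheduling] {exc}") from exc

    # Table-8-shaped bulk material balance: the three bulk inputs per batch.
    water_per_batch = sum(
        u.parameters.get(k, 0.0)
        for u in fs.units
        for k in ("wash_water", "dilution_water", "backwash_water")
    )
    per_batch = {
        "Alcalase enzyme": fkw.get("enzyme", enzyme),
        "Fly larvae": batch_mass,
        "Water": water_per_batch,
    }
    per_year = annualize(per_batch, n)
    material_balance = {
        row: {"kg_batch": _round2(per_batch[row]), "kg_yr": _round2(per_year[row])}
        for row in per_batch
    }
    material_balance["Total"] = {
        "kg_batch": _round2(sum(r["kg_batch"] for r in material_balance.values())),
        "kg_yr": _round2(sum(r["kg_yr"] for r in material_balance.values())),
    }

    revenue_split = {
        comp: sim.streams[lbl].total * n for lbl, comp in PRODUCT_STREAMS.items()
    }

    try:
        consumables = consumables_per_batch(sim, feed.total)
        balance = {
            "products": {
                **revenue_split,
                "protein_meal": sim.streams["Protein product"].total * n,
            },
            "wastes": {lbl: sim.streams[lbl].total * n for lbl in WASTE_STREAMS},
            "consumables": {k: v * n for k, v in consumables.items()},
            "enzyme_kg": per_year["Alcalase enzyme"],
        }
        revenue, opex, gross = annual_profit(balance, cost_model)
        cf_before = build_cashflows(gross, cost_model, taxed=False)
        cf_after = build_cashflows(gross, cost_model, taxed=True)
        tea = TeaSummary(
            irr_before_tax=irr(cf_before),
            irr_after_tax=irr(cf_after),
            npv_by_rate={r: npv(cf_after, r) for r in cost_model.discount_rates},
        )
    except ValueError as exc:
        raise PipelineError(f"[economics] {exc}") from exc

    return RunReport(
        scenario_label=composition.scenario_label,
        schedule=schedule,
        material_balance=material_balance,
        revenue_split=revenue_split,
        tea=tea,
        revenue=revenue,
        operating_cost=opex,
        gross_profit=gross,
        streams=sim.streams,
        gantt=gantt,
        consumables=consumables,
        warnings=sim.warnings,
    )


def run_from_config(
    cfg: dict,
    scenario: str | None = None,
    sample_seed: int | None = None,
    gantt_batches: int | None = None,
) -> RunReport:
    """Run the pipeline from a merged configuration dict (see :mod:`.config`)."""
    from .config import composition_from_config, cost_model_from_config, profile_from_config

    scenario = scenario or cfg.get("scenario", "kitchen_waste")
    composition = composition_from_config(cfg, scenario)
    fkw = dict(cfg.get("flowsheet", {}))
    sched = cfg.get("schedule", {})
    return run_pipeline(
        composition=composition,
        profile=profile_from_config(cfg),
        cost_model=cost_model_from_config(cfg),
        batch_mass=cfg.get("batch_mass", 10_000.0),
        flowsheet_kwargs=fkw,
        annual_operating_time=sched.get("annual_operating_time", DEFAULT_ANNUAL_OPERATING_TIME),
        sample_seed=sample_seed,
        gantt_batches=gantt_batches,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _fmt_kg(x: float) -> str:
    return f"{x:,.2f}"


def write_reports(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write the report artifacts into ``out_dir``; returns the paths written.

    Files: material_balance.csv, streams.csv, gantt.csv, gantt.json,
    revenue_split.csv, tea_summary.json.  Masses are fixed to two decimals;
    JSON carries raw machine-readable numbers.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineError(f"[report] cannot create output dir {out}: {exc}") from exc
    paths = []

    p = out / "material_balance.csv"
    with p.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Material", "kg/yr", "kg/batch"])
        for row, vals in report.material_balance.items():
            w.writerow([row, _fmt_kg(vals["kg_yr"]), _fmt_kg(vals["kg_batch"])])
    paths.append(p)

    p = out / "streams.csv"
    with p.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "component", "kg/batch", "temperature_C", "pressure_bar", "phase"])
        for lbl in sorted(report.streams):
            s = report.streams[lbl]
            for comp in sorted(s.masses):
                w.writerow([lbl, comp, _fmt_kg(s.masses[comp]), s.temperature, s.pressure, s.phase])
    paths.append(p)

    p = out / "gantt.csv"
    with p.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["batch_index", "unit_id", "start_h", "end_h"])
        for k, uid, start, end in report.gantt:
            w.writerow([k, uid, f"{start:.2f}", f"{end:.2f}"])
    paths.append(p)

    p = out / "gantt.json"
    p.write_text(json.dumps(
        [{"batch_index": k, "unit_id": uid, "start": start, "end": end}
         for k, uid, start, end in report.gantt],
    ))
    paths.append(p)

    p = out / "revenue_split.csv"
    with p.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["component", "kg/yr"])
        for comp, kg in report.revenue_split.items():
            w.writerow([comp, _fmt_kg(kg)])
    paths.append(p)

    p = out / "tea_summary.json"
    p.write_text(json.dumps({
        "scenario": report.scenario_label,
        "irr_before_tax_pct": irr_report_pct(report.tea.irr_before_tax),
        "irr_after_tax_pct": irr_report_pct(report.tea.irr_after_tax),
        "npv_by_rate": {f"{r:.2f}": v for r, v in report.tea.npv_by_rate.items()},
        "revenue_per_yr": report.revenue,
        "operating_cost_per_yr": report.operating_cost,
        "gross_profit_per_yr": report.gross_profit,
    }, indent=2))
    paths.append(p)
    return paths


def read_material_balance(path: str | Path) -> dict[str, dict[str, float]]:
    """Parse material_balance.csv back into the report's row structure."""
    out: dict[str, dict[str, float]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row, kg_yr, kg_batch in reader:
            out[row] = {
                "kg_yr": float(kg_yr.replace(",", "")),
                "kg_batch": float(kg_batch.replace(",", "")),
            }
    return out
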