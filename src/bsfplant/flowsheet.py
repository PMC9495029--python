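"""Components, streams, unit-operation models and the plant flowsheet solver.

The plant converts washed black soldier fly larvae into four fatty-acid
products (lauric, myristic, palmitic, stearic), a dried protein by-product,
and ash/cellulose waste streams.  Every unit operation is a split-factor
model: mass is routed between outlets by fixed fractions (wash removals,
membrane rejection, sharp distillation cuts), so each unit — and the plant as
a whole — conserves mass to floating-point precision.  Thermal duties
(condensers, reboilers) are shortcut estimates from latent heats and are
reported for costing only; they never alter a mass split.

The flowsheet is a directed acyclic graph of units connected by labelled
streams.  ``simulate`` evaluates units in topological order and verifies
per-unit and plant-wide mass closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "Component",
    "Stream",
    "UnitSpec",
    "Flowsheet",
    "SimulationResult",
    "FlowsheetError",
    "ConfigurationError",
    "TopologyError",
    "PhaseError",
    "AmbiguousCutError",
    "COMPONENTS",
    "wash",
    "grind",
    "hydrolyze",
    "membrane_filter",
    "centrifuge",
    "distill_sharp",
    "condense",
    "adsorb_water",
    "freeze_dry",
    "simulate",
    "build_default_flowsheet",
    "DEFAULT_UTILITY_WATER",
]

MASS_TOL = 1e-9  # relative mass-closure tolerance


class FlowsheetError(ValueError):
    """Base class for flowsheet modelling errors."""


class ConfigurationError(FlowsheetError):
    """Missing or inconsistent unit parameters."""


class TopologyError(FlowsheetError):
    """Cycles or dangling stream connections in the flowsheet graph."""


class PhaseError(FlowsheetError):
    """A unit received a stream in the wrong phase."""


class AmbiguousCutError(FlowsheetError):
    """A distillation cut temperature coincides with a component boiling point."""


# ---------------------------------------------------------------------------
# Component registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """Physical-property record for one simulation component.

    ``boiling_point`` is None for non-volatile solids.  ``latent_heat`` and
    ``heat_capacity`` feed the shortcut condenser/reboiler duty estimates and
    are configurable; the defaults (water 2257 kJ/kg; fatty acids 200 kJ/kg,
    Cp 2.1 kJ/kg K) are generic handbook-order values, so energy results are
    config-dependent.  ``density`` (kg/m3) sizes membrane areas.
    """

    name: str
    boiling_point: float | None
    density: float
    latent_heat: float = 0.0
    heat_capacity: float = 2.1
    role: str = "process"  # one of {revenue, byproduct, waste, process}

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ConfigurationError(f"component {self.name!r}: density must be > 0")


def _default_components() -> dict[str, Component]:
    comps = [
        Component("water", 100.0, 1000.0, latent_heat=2257.0, heat_capacity=4.186),
        Component("lauric_acid", 298.8, 900.0, latent_heat=200.0, role="revenue"),
        Component("myristic_acid", 326.2, 900.0, latent_heat=200.0, role="revenue"),
        Component("palmitic_acid", 348.0, 900.0, latent_heat=200.0, role="revenue"),
        Component("stearic_acid", 361.0, 900.0, latent_heat=200.0, role="revenue"),
        Component("protein", None, 1500.0, role="byproduct"),
        Component("hydrolyzed_protein", None, 1500.0, role="byproduct"),
        Component("denatured_protein", None, 1500.0, role="byproduct"),
        Component("alcalase", None, 1500.0, role="process"),
        Component("cellulose", None, 1500.0, role="waste"),
        Component("ash", None, 1500.0, role="waste"),
        Component("other_organics", None, 1500.0, role="process"),
    ]
    reg = {c.name: c for c in comps}
    fa = [reg[n].boiling_point for n in ("lauric_acid", "myristic_acid", "palmitic_acid", "stearic_acid")]
    if not all(a < b for a, b in zip(fa, fa[1:])):  # pragma: no cover - registry sanity
        raise ConfigurationError("fatty-acid boiling points must be strictly increasing")
    return reg


#: Default component registry (name -> Component).
COMPONENTS: dict[str, Component] = _default_components()


# ---------------------------------------------------------------------------
# Streams
# ---------------------------------------------------------------------------

_PHASES = ("solid-slurry", "liquid", "vapor", "mixed")


@dataclass(frozen=True)
class Stream:
    """A labelled per-batch component mass vector with T, P and phase."""

    label: str
    masses: dict[str, float]
    temperature: float = 25.0
    pressure: float = 1.013
    phase: str = "liquid"

    def __post_init__(self) -> None:
        if self.phase not in _PHASES:
            raise FlowsheetError(f"stream {self.label!r}: unknown phase {self.phase!r}")
        for comp, m in self.masses.items():
            if m < 0:
                raise FlowsheetError(f"stream {self.label!r}: negative mass for {comp}: {m}")

    @property
    def total(self) -> float:
        """Total stream mass, kg/batch."""
        return sum(self.masses.values())

    def mass(self, component: str) -> float:
        return self.masses.get(component, 0.0)

    def with_(self, **kw) -> "Stream":
        return replace(self, **kw)


def _clean(masses: dict[str, float]) -> dict[str, float]:
    """Drop zero entries; clamp tiny negative round-off to zero."""
    out = {}
    for k, v in masses.items():
        if v < 0:
            if v < -1e-9:
                raise FlowsheetError(f"negative mass for {k}: {v}")
            v = 0.0
        if v > 0.0:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# Unit operations (pure split-factor functions)
# ---------------------------------------------------------------------------

def wash(
    feed: Stream,
    wash_water: float,
    ash_removal: float,
    cellulose_removal: float,
) -> tuple[Stream, Stream]:
    """Cold-water larvae wash: removes fixed fractions of ash and cellulose.

    The waste stream carries the removed solids plus all wash water; the
    washed stream keeps everything else (the wash does not dilute the larvae).
    """
    for name, frac in (("ash_removal", ash_removal), ("cellulose_removal", cellulose_removal)):
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(f"{name}={frac} outside [0, 1]")
    if wash_water < 0:
        raise ConfigurationError(f"wash_water={wash_water} must be >= 0")
    ash_out = feed.mass("ash") * ash_removal
    cel_out = feed.mass("cellulose") * cellulose_removal
    waste_masses = _clean({"ash": ash_out, "cellulose": cel_out, "water": wash_water})
    washed_masses = dict(feed.masses)
    if ash_out:
        washed_masses["ash"] = feed.mass("ash") - ash_out
    if cel_out:
        washed_masses["cellulose"] = feed.mass("cellulose") - cel_out
    washed = Stream("washed", _clean(washed_masses), feed.temperature, feed.pressure, "solid-slurry")
    waste = Stream("wash waste", waste_masses, feed.temperature, feed.pressure, "solid-slurry")
    return washed, waste


def grind(feed: Stream, throughput: float) -> tuple[Stream, float]:
    """Mechanical size reduction: composition-preserving, duration = mass/throughput (h)."""
    if throughput <= 0:
        raise ConfigurationError(f"throughput={throughput} must be > 0")
    duration = feed.total / throughput
    return feed.with_(label="ground"), duration


def hydrolyze(feed: Stream, enzyme: float, conversion: float) -> Stream:
    """Alcalase protein hydrolysis in the incubated bioreactor (60 C, pH ~9.5).

    The enzyme mass is added to the batch; a ``conversion`` fraction of the
    protein is re-labelled "hydrolyzed_protein" (same mass, tracked so the
    downstream separation can be reported against the extent of proteolysis).
    """
    if enzyme < 0:
        raise ConfigurationError(f"enzyme={enzyme} must be >= 0")
    if not 0.0 <= conversion <= 1.0:
        raise ConfigurationError(f"conversion={conversion} outside [0, 1]")
    masses = dict(feed.masses)
    protein = masses.get("protein", 0.0)
    hydrolyzed = protein * conversion
    if hydrolyzed:
        masses["protein"] = protein - hydrolyzed
        masses["hydrolyzed_protein"] = masses.get("hydrolyzed_protein", 0.0) + hydrolyzed
    masses["alcalase"] = masses.get("alcalase", 0.0) + enzyme
    return Stream("slurry", _clean(masses), temperature=60.0, pressure=feed.pressure, phase="solid-slurry")


def membrane_filter(
    feed: Stream,
    rejected_component: str,
    rejection: float,
    denaturation: float,
    flux: float,
    max_density: float,
    retained_water: float | None = None,
    duration: float = 1.0,
    components: dict[str, Component] = COMPONENTS,
) -> tuple[Stream, Stream, float, list[str]]:
    """Dead-end membrane split of one rejected component from the slurry.

    The retentate carries ``rejection`` of the rejected component plus
    retained water; everything else crosses into the permeate.  When
    ``retained_water`` (kg) is not given, the minimum water that keeps the
    retentate solids concentration at or below ``max_density`` (g/L of
    retentate volume) is used.  A ``denaturation`` fraction of the protein
    crossing the membrane is re-labelled "denatured_protein"
    (mass-conserving).  Membrane area (m2) = feed volumetric flow (L/h, from
    component densities and the filtration ``duration``) / ``flux`` (L/m2 h).

    Returns (permeate, retentate, area_m2, warnings).
    """
    if rejected_component not in feed.masses and rejected_component not in components:
        raise ConfigurationError(f"unknown rejected component {rejected_component!r}")
    for name, frac in (("rejection", rejection), ("denaturation", denaturation)):
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(f"{name}={frac} outside [0, 1]")
    if flux <= 0:
        raise ConfigurationError(f"flux={flux} must be > 0")
    warnings: list[str] = []

    solids = feed.mass(rejected_component) * rejection
    rho_s = components[rejected_component].density / 1000.0 if rejected_component in components else 1.5
    c_max = max_density / 1000.0  # kg/L of retentate volume
    if retained_water is None:
        # minimum water so that solids / (V_water + V_solids) <= c_max
        retained_water = max(0.0, solids * (1.0 / c_max - 1.0 / rho_s)) if solids > 0 else 0.0
    retained_water = min(retained_water, feed.mass("water"))
    if solids > 0:
        vol_l = retained_water / 1.0 + solids / rho_s
        if vol_l > 0 and solids / vol_l > c_max * (1 + 1e-12):
            warnings.append(
                f"retentate solids concentration {1000 * solids / vol_l:.0f} g/L "
                f"exceeds max density {max_density:.0f} g/L"
            )

    retentate_masses = _clean({rejected_component: solids, "water": retained_water})
    permeate_masses = dict(feed.masses)
    if solids:
        permeate_masses[rejected_component] = feed.mass(rejected_component) - solids
    if retained_water:
        permeate_masses["water"] = feed.mass("water") - retained_water
    # Shear/pressure denaturation of protein crossing the membrane.
    for key in ("protein", "hydrolyzed_protein"):
        crossing = permeate_masses.get(key, 0.0)
        if crossing and denaturation:
            lost = crossing * denaturation
            permeate_masses[key] = crossing - lost
            permeate_masses["denatured_protein"] = permeate_masses.get("denatured_protein", 0.0) + lost

    feed_vol_l = sum(
        m / (components[c].density / 1000.0) if c in components else m
        for c, m in feed.masses.items()
    )
    area = (feed_vol_l / duration) / flux if feed.total > 0 else 0.0

    permeate = Stream("permeate", _clean(permeate_masses), feed.temperature, feed.pressure, "solid-slurry")
    retentate = Stream("retentate", retentate_masses, feed.temperature, feed.pressure, "solid-slurry")
    return permeate, retentate, area, warnings


def centrifuge(
    feed: Stream,
    phase_map: dict[str, str],
    carryover: float = 0.0,
    water_to_light: float = 0.0,
    water_to_heavy: float = 0.0,
) -> tuple[Stream, Stream, Stream]:
    """Three-way disc-stack split into light (oil), heavy (protein) and aqueous outlets.

    ``phase_map`` assigns each non-water component to an outlet; water is split
    by the ``water_to_light`` / ``water_to_heavy`` fractions (remainder to the
    aqueous outlet), since the wet protein cake and the crude oil both carry
    moisture in practice.  A ``carryover`` fraction of each fatty acid leaks
    into the heavy (protein) outlet, modelling imperfect density separation.
    """
    if not 0.0 <= carryover <= 1.0:
        raise ConfigurationError(f"carryover={carryover} outside [0, 1]")
    if water_to_light < 0 or water_to_heavy < 0 or water_to_light + water_to_heavy > 1.0:
        raise ConfigurationError("water split fractions must be >= 0 and sum to <= 1")
    outs: dict[str, dict[str, float]] = {"light": {}, "heavy": {}, "aqueous": {}}
    fatty = {"lauric_acid", "myristic_acid", "palmitic_acid", "stearic_acid"}
    for comp, m in feed.masses.items():
        if comp == "water":
            outs["light"]["water"] = m * water_to_light
            outs["heavy"]["water"] = m * water_to_heavy
            outs["aqueous"]["water"] = m - outs["light"]["water"] - outs["heavy"]["water"]
            continue
        dest = phase_map.get(comp)
        if dest not in ("light", "heavy", "aqueous"):
            raise ConfigurationError(f"centrifuge: component {comp!r} not mapped to an outlet")
        if comp in fatty and dest == "light" and carryover:
            outs["heavy"][comp] = m * carryover
            outs["light"][comp] = m * (1.0 - carryover)
        else:
            outs[dest][comp] = outs[dest].get(comp, 0.0) + m
    t, p = feed.temperature, feed.pressure
    return (
        Stream("oil feed", _clean(outs["light"]), t, p, "liquid"),
        Stream("wet protein", _clean(outs["heavy"]), t, p, "solid-slurry"),
        Stream("aqueous", _clean(outs["aqueous"]), t, p, "liquid"),
    )


def distill_sharp(
    feed: Stream,
    heavy_key_cut: float,
    reflux_ratio: float,
    stages: int,
    bottoms_phase: str = "liquid",
    components: dict[str, Component] = COMPONENTS,
) -> tuple[Stream, Stream, float, float, list[str]]:
    """Sharp-split fractionation: components boiling below the cut go entirely overhead.

    Shortcut duties: condenser = (R + 1) x distillate mass x mass-weighted
    latent heat; reboiler = condenser (total-condenser shortcut).  ``stages``
    and the reflux ratio are carried from the tower design but only the
    reflux ratio enters the duty; no tray-by-tray calculation is attempted.

    Returns (distillate, bottoms, condenser_duty_kJ, reboiler_duty_kJ, warnings).
    """
    if feed.total <= 0:
        raise FlowsheetError("distillation feed is empty")
    if reflux_ratio < 0:
        raise ConfigurationError(f"reflux_ratio={reflux_ratio} must be >= 0")
    warnings: list[str] = []
    dist: dict[str, float] = {}
    bot: dict[str, float] = {}
    for comp, m in feed.masses.items():
        bp = components[comp].boiling_point if comp in components else None
        if bp is not None and math.isclose(bp, heavy_key_cut, abs_tol=1e-9):
            raise AmbiguousCutError(
                f"cut temperature {heavy_key_cut} coincides with boiling point of {comp}"
            )
        if bp is not None and bp < heavy_key_cut:
            dist[comp] = m
        else:
            bot[comp] = m
    if not dist or not bot:
        side = "distillate" if not dist else "bottoms"
        warnings.append(f"degenerate cut at {heavy_key_cut} C: empty {side}")
    dist_mass = sum(dist.values())
    if dist_mass > 0:
        latent = sum(m * components[c].latent_heat for c, m in dist.items()) / dist_mass
    else:
        latent = 0.0
    condenser_duty = (reflux_ratio + 1.0) * dist_mass * latent
    reboiler_duty = condenser_duty
    distillate = Stream("distillate", _clean(dist), heavy_key_cut, feed.pressure, "vapor")
    bottoms = Stream("bottoms", _clean(bot), heavy_key_cut, feed.pressure, bottoms_phase)
    return distillate, bottoms, condenser_duty, reboiler_duty, warnings


def condense(
    vapor: Stream,
    outlet_temp: float,
    components: dict[str, Component] = COMPONENTS,
) -> tuple[Stream, float]:
    """Total condensation of a vapor stream plus sensible cooling to ``outlet_temp``.

    cooling_duty (kJ) = sum over components of m x latent_heat
    + m x Cp x (boiling_point - outlet_temp).
    """
    if vapor.phase != "vapor":
        raise PhaseError(f"condenser input {vapor.label!r} has phase {vapor.phase!r}, not vapor")
    duty = 0.0
    for comp, m in vapor.masses.items():
        c = components[comp]
        bp = c.boiling_point if c.boiling_point is not None else outlet_temp
        duty += m * c.latent_heat + m * c.heat_capacity * max(bp - outlet_temp, 0.0)
    liquid = vapor.with_(label=vapor.label, temperature=outlet_temp, phase="liquid")
    return liquid, duty


def adsorb_water(feed: Stream, backwash_water: float = 0.0) -> tuple[Stream, Stream]:
    """Backwash adsorption polishing: all water leaves with the backwash stream."""
    if feed.phase != "liquid":
        raise PhaseError(f"adsorber input {feed.label!r} has phase {feed.phase!r}, not liquid")
    if backwash_water < 0:
        raise ConfigurationError(f"backwash_water={backwash_water} must be >= 0")
    water = feed.mass("water")
    dry_masses = {c: m for c, m in feed.masses.items() if c != "water"}
    dry = Stream("dry product", _clean(dry_masses), feed.temperature, feed.pressure, "liquid")
    reusable = Stream(
        "reusable water", _clean({"water": water + backwash_water}),
        feed.temperature, feed.pressure, "liquid",
    )
    return dry, reusable


def freeze_dry(
    feed: Stream,
    final_moisture: float,
    sublimation_rate: float = 10.0,
    tray_depth: float = 10.0,
) -> tuple[Stream, Stream, float, list[str]]:
    """Lyophilization of the wet protein cake down to ``final_moisture`` mass fraction.

    The drying front recedes at ``sublimation_rate`` mm/h through a tray of
    ``tray_depth`` mm, so duration = depth / rate regardless of load (layer
    model).  Returns (meal, exhaust, duration_h, warnings).
    """
    if not 0.0 <= final_moisture < 1.0:
        raise ConfigurationError(f"final_moisture={final_moisture} outside [0, 1)")
    if sublimation_rate <= 0 or tray_depth <= 0:
        raise ConfigurationError("sublimation_rate and tray_depth must be > 0")
    warnings: list[str] = []
    water = feed.mass("water")
    solids = feed.total - water
    target_water = solids * final_moisture / (1.0 - final_moisture)
    if water <= target_water:
        warnings.append(
            f"feed moisture {water / feed.total if feed.total else 0:.3f} already at or "
            f"below target {final_moisture}; freeze dryer is a no-op"
        )
        removed = 0.0
    else:
        removed = water - target_water
    meal_masses = dict(feed.masses)
    if removed:
        meal_masses["water"] = water - removed
    duration = tray_depth / sublimation_rate
    meal = Stream("meal", _clean(meal_masses), 12.0, feed.pressure, "solid-slurry")
    exhaust = Stream("exhaust", _clean({"water": removed}), 12.0, feed.pressure, "vapor")
    return meal, exhaust, duration, warnings


# ---------------------------------------------------------------------------
# Flowsheet graph and solver
# ---------------------------------------------------------------------------

_UNIT_KINDS: dict[str, set[str]] = {
    "washer": {"wash_water", "ash_removal", "cellulose_removal"},
    "grinder": {"throughput"},
    "reactor": {"enzyme", "conversion"},
    "membrane_filter": {"rejected_component", "rejection", "denaturation", "flux", "max_density"},
    "centrifuge": {"phase_map"},
    "distillation": {"heavy_key_cut", "reflux_ratio", "stages"},
    "condenser": {"outlet_temp"},
    "adsorber": set(),
    "freeze_dryer": {"final_moisture"},
    "transport": set(),
}


@dataclass(frozen=True)
class UnitSpec:
    """One parameterized unit: id, kind, named parameters, input/output stream labels."""

    unit_id: str
    kind: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _UNIT_KINDS:
            raise ConfigurationError(f"{self.unit_id}: unknown unit kind {self.kind!r}")
        missing = _UNIT_KINDS[self.kind] - set(self.parameters)
        if missing:
            raise ConfigurationError(
                f"{self.unit_id} ({self.kind}): missing parameters {sorted(missing)}"
            )


@dataclass
class Flowsheet:
    """A DAG of units connected by uniquely-produced stream labels."""

    units: list[UnitSpec]
    components: dict[str, Component] = field(default_factory=lambda: dict(COMPONENTS))

    def __post_init__(self) -> None:
        producers: dict[str, str] = {}
        for u in self.units:
            for lbl in u.outputs:
                if lbl in producers:
                    raise TopologyError(
                        f"stream {lbl!r} produced by both {producers[lbl]} and {u.unit_id}"
                    )
                producers[lbl] = u.unit_id
        self._producers = producers
        g = nx.DiGraph()
        g.add_nodes_from(u.unit_id for u in self.units)
        for u in self.units:
            for lbl in u.inputs:
                if lbl in producers:
                    g.add_edge(producers[lbl], u.unit_id, label=lbl)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise TopologyError(f"flowsheet contains a cycle: {cycle}")
        self.graph = g

    @property
    def feed_labels(self) -> list[str]:
        """Stream labels consumed but never produced — the plant's feed ports."""
        consumed = {lbl for u in self.units for lbl in u.inputs}
        return sorted(consumed - set(self._producers))

    @property
    def product_labels(self) -> list[str]:
        """Stream labels produced but never consumed — products, by-products, wastes."""
        consumed = {lbl for u in self.units for lbl in u.inputs}
        return sorted(set(self._producers) - consumed)


@dataclass
class SimulationResult:
    """All resolved streams plus per-unit metadata from one flowsheet pass."""

    streams: dict[str, Stream]
    durations: dict[str, float] = field(default_factory=dict)   # h, by unit
    duties: dict[str, float] = field(default_factory=dict)      # kJ, by unit
    areas: dict[str, float] = field(default_factory=dict)       # m2, by membrane unit
    utility_inputs: dict[str, float] = field(default_factory=dict)  # kg, by unit
    warnings: list[tuple[str, str]] = field(default_factory=list)
    closure_residual: float = 0.0  # relative plant-wide mass imbalance


def _eval_unit(unit: UnitSpec, ins: list[Stream], comps: dict[str, Component], res: SimulationResult) -> list[Stream]:
    p = unit.parameters
    kind = unit.kind
    if kind == "washer":
        washed, waste = wash(ins[0], p["wash_water"], p["ash_removal"], p["cellulose_removal"])
        res.utility_inputs[unit.unit_id] = p["wash_water"]
        return [washed, waste]
    if kind == "grinder":
        out, duration = grind(ins[0], p["throughput"])
        res.durations[unit.unit_id] = duration
        return [out]
    if kind == "reactor":
        feed = ins[0]
        dilution = p.get("dilution_water", 0.0)
        if dilution:
            masses = dict(feed.masses)
            masses["water"] = masses.get("water", 0.0) + dilution
            feed = feed.with_(masses=masses)
        res.utility_inputs[unit.unit_id] = p["enzyme"] + dilution
        return [hydrolyze(feed, p["enzyme"], p["conversion"])]
    if kind == "membrane_filter":
        permeate, retentate, area, warns = membrane_filter(
            ins[0], p["rejected_component"], p["rejection"], p["denaturation"],
            p["flux"], p["max_density"], p.get("retained_water"),
            p.get("duration", 1.0), comps,
        )
        res.areas[unit.unit_id] = area
        res.warnings.extend((unit.unit_id, w) for w in warns)
        return [permeate, retentate]
    if kind == "centrifuge":
        return list(centrifuge(
            ins[0], p["phase_map"], p.get("carryover", 0.0),
            p.get("water_to_light", 0.0), p.get("water_to_heavy", 0.0),
        ))
    if kind == "distillation":
        distillate, bottoms, qc, qr, warns = distill_sharp(
            ins[0], p["heavy_key_cut"], p["reflux_ratio"], p["stages"],
            p.get("bottoms_phase", "liquid"), comps,
        )
        res.duties[unit.unit_id] = qc + qr
        res.warnings.extend((unit.unit_id, w) for w in warns)
        return [distillate, bottoms]
    if kind == "condenser":
        liquid, duty = condense(ins[0], p["outlet_temp"], comps)
        res.duties[unit.unit_id] = duty
        return [liquid]
    if kind == "adsorber":
        backwash = p.get("backwash_water", 0.0)
        dry, reusable = adsorb_water(ins[0], backwash)
        res.utility_inputs[unit.unit_id] = backwash
        return [dry, reusable]
    if kind == "freeze_dryer":
        meal, exhaust, duration, warns = freeze_dry(
            ins[0], p["final_moisture"], p.get("sublimation_rate", 10.0), p.get("tray_depth", 10.0),
        )
        res.durations[unit.unit_id] = duration
        res.warnings.extend((unit.unit_id, w) for w in warns)
        return [meal, exhaust]
    if kind == "transport":
        shipment = p.get("shipment_size", 20000.0)
        res.durations[unit.unit_id] = math.ceil(ins[0].total / shipment) if ins[0].total else 0
        return [ins[0]]
    raise ConfigurationError(f"{unit.unit_id}: unhandled kind {kind!r}")  # pragma: no cover


def simulate(flowsheet: Flowsheet, feeds: dict[str, Stream] | Stream) -> SimulationResult:
    """Evaluate every unit in topological order and check mass closure.

    ``feeds`` maps feed-port labels to streams (a single Stream is accepted
    when the flowsheet has exactly one feed port).  Every unit must conserve
    mass to 1e-9 relative; plant-wide, feed plus utility inputs must equal
    the sum of all terminal outputs to the same tolerance.
    """
    if isinstance(feeds, Stream):
        ports = flowsheet.feed_labels
        if len(ports) != 1:
            raise TopologyError(
                f"single feed stream given but flowsheet has feed ports {ports}"
            )
        feeds = {ports[0]: feeds}
    missing = set(flowsheet.feed_labels) - set(feeds)
    if missing:
        raise TopologyError(f"missing feed streams: {sorted(missing)}")

    res = SimulationResult(streams={})
    for lbl, s in feeds.items():
        res.streams[lbl] = s.with_(label=lbl)

    by_id = {u.unit_id: u for u in flowsheet.units}
    for unit_id in nx.topological_sort(flowsheet.graph):
        unit = by_id[unit_id]
        try:
            ins = [res.streams[lbl] for lbl in unit.inputs]
            if all(s.total == 0.0 for s in ins):
                # An idle unit passes nothing through and draws no utilities.
                outs = [Stream(lbl, {}) for lbl in unit.outputs]
            else:
                outs = _eval_unit(unit, ins, flowsheet.components, res)
        except FlowsheetError as exc:
            raise type(exc)(f"[{unit_id}] {exc}") from exc
        m_in = sum(s.total for s in ins) + res.utility_inputs.get(unit_id, 0.0)
        m_out = sum(s.total for s in outs)
        scale = max(m_in, m_out, 1.0)
        if abs(m_in - m_out) > MASS_TOL * scale:
            raise FlowsheetError(
                f"[{unit_id}] mass imbalance: in {m_in!r} kg, out {m_out!r} kg"
            )
        for lbl, s in zip(unit.outputs, outs):
            res.streams[lbl] = s.with_(label=lbl)

    total_in = sum(s.total for s in feeds.values()) + sum(res.utility_inputs.values())
    total_out = sum(res.streams[lbl].total for lbl in flowsheet.product_labels)
    res.closure_residual = abs(total_in - total_out) / max(total_in, 1.0)
    if res.closure_residual > MASS_TOL:
        raise FlowsheetError(
            f"plant-wide mass imbalance: in {total_in!r} kg, out {total_out!r} kg"
        )
    return res


# ---------------------------------------------------------------------------
# Default plant
# ---------------------------------------------------------------------------

#: Default per-batch utility water inputs (kg).  Their sum is the plant's
#: bulk water demand per batch — 36,058.03 kg, i.e. an annual demand of
#: 103,775,015 kg spread over the campaign's 2878 batches.  The three-way
#: split between washing, reactor dilution and adsorber backwash is a
#: configuration choice (only the sum is balance-defining).
DEFAULT_UTILITY_WATER = {
    "wash": 20000.0,
    "dilution": 15000.0,
    "backwash": 103_775_015.0 / 2878.0 - 35000.0,
}


def build_default_flowsheet(
    wash_water: float = DEFAULT_UTILITY_WATER["wash"],
    dilution_water: float = DEFAULT_UTILITY_WATER["dilution"],
    backwash_water: float = DEFAULT_UTILITY_WATER["backwash"],
    enzyme: float = 100.0,
    conversion: float = 0.9,
    fat_carryover: float = 0.0,
    water_to_light: float = 0.002,
    water_to_heavy: float = 0.08,
) -> Flowsheet:
    """Construct the default larvae fatty-acid plant.

    Mechanical pre-treatment (wash, grind), enzymatic hydrolysis, two
    microfiltration waste removals, centrifugation into oil / wet protein /
    aqueous phases, a three-tower sharp-split fatty-acid fractionation train
    with condensers and an adsorptive water polish on the lauric cut, protein
    freeze-drying and bulk transport, and ultrafiltration recovering reusable
    water from the aqueous phase.
    """
    phase_map = {
        "lauric_acid": "light", "myristic_acid": "light",
        "palmitic_acid": "light", "stearic_acid": "light",
        "protein": "heavy", "hydrolyzed_protein": "heavy",
        "denatured_protein": "heavy", "alcalase": "heavy",
        "cellulose": "aqueous", "ash": "aqueous", "other_organics": "heavy",
    }
    units = [
        UnitSpec("WSH-101", "washer", ("Larvae feed",), ("S-104", "Wastes 1"),
                 {"wash_water": wash_water, "ash_removal": 0.66, "cellulose_removal": 0.38}),
        UnitSpec("GR-101", "grinder", ("S-104",), ("Crude suspension",),
                 {"throughput": 9174.0}),
        UnitSpec("BR-101", "reactor", ("Crude suspension",), ("Sludge",),
                 {"enzyme": enzyme, "conversion": conversion, "dilution_water": dilution_water}),
        UnitSpec("MF-101", "membrane_filter", ("Sludge",), ("S-108", "Cellulose waste"),
                 {"rejected_component": "cellulose", "rejection": 0.999, "denaturation": 0.05,
                  "flux": 20.0, "max_density": 1100.0}),
        UnitSpec("MF-102", "membrane_filter", ("S-108",), ("Slurry", "Ash waste"),
                 {"rejected_component": "ash", "rejection": 0.999, "denaturation": 0.05,
                  "flux": 20.0, "max_density": 1100.0}),
        UnitSpec("DC-101", "centrifuge", ("Slurry",),
                 ("Oil feed", "Wet protein meals", "S-112"),
                 {"phase_map": phase_map, "carryover": fat_carryover,
                  "water_to_light": water_to_light, "water_to_heavy": water_to_heavy}),
        UnitSpec("UF-101", "membrane_filter", ("S-112",), ("Reusable water 1", "Wastes 2"),
                 {"rejected_component": "cellulose", "rejection": 0.999, "denaturation": 0.05,
                  "flux": 20.0, "max_density": 1200.0}),
        UnitSpec("C-101", "distillation", ("Oil feed",), ("Impure product 1", "S-103"),
                 {"heavy_key_cut": 310.0, "reflux_ratio": 14.404, "stages": 22}),
        UnitSpec("HX-101", "condenser", ("Impure product 1",), ("S-110",),
                 {"outlet_temp": 80.0}),
        UnitSpec("GAC-101", "adsorber", ("S-110",),
                 ("Lauric acid product", "Reusable water 2"),
                 {"backwash_water": backwash_water}),
        UnitSpec("C-102", "distillation", ("S-103",), ("S-105", "S-106"),
                 {"heavy_key_cut": 335.0, "reflux_ratio": 1.186, "stages": 43}),
        UnitSpec("HX-104", "condenser", ("S-105",), ("Myristic acid product",),
                 {"outlet_temp": 80.0}),
        UnitSpec("C-103", "distillation", ("S-106",), ("Impure product 2", "S-111"),
                 {"heavy_key_cut": 352.0, "reflux_ratio": 0.984, "stages": 43,
                  "bottoms_phase": "vapor"}),
        UnitSpec("HX-102", "condenser", ("Impure product 2",), ("Palmitic acid product",),
                 {"outlet_temp": 80.0}),
        UnitSpec("HX-103", "condenser", ("S-111",), ("Stearic acid product",),
                 {"outlet_temp": 80.0}),
        UnitSpec("FDR-101", "freeze_dryer", ("Wet protein meals",),
                 ("Dried protein meal", "Drying exhaust"),
                 {"final_moisture": 0.05, "sublimation_rate": 10.0, "tray_depth": 10.0}),
        UnitSpec("P-11", "transport", ("Dried protein meal",), ("Protein product",),
                 {"shipment_size": 20000.0}),
    ]
    return Flowsheet(units=units)
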