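"""Discounted-cash-flow feasibility assessment of the plant.

Annualized product, by-product, waste and consumable balances are priced
with a :class:`CostModel`, producing an annual gross profit.  A 20-year
cash-flow series (year 0 = capital outlay) is then assessed by net present
value at configured discount rates and by internal rate of return before and
after a 6% flat tax on positive gross profit.  A plant whose cash flows
never turn positive has no IRR; the conventional report value for that case
is -100%.

Product and waste prices, consumable tariffs and the capital cost are not
physical constants of the process — they are market inputs, shipped here as
documented configurable defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CostModel",
    "CashFlowSeries",
    "TeaSummary",
    "EconomicsError",
    "annual_profit",
    "build_cashflows",
    "npv",
    "irr",
    "irr_report_pct",
    "default_cost_model",
]


class EconomicsError(ValueError):
    """Invalid cost-model parameters or missing prices."""


@dataclass(frozen=True)
class CostModel:
    """Prices, fees, capital and fiscal settings for the feasibility assessment.

    Units: prices in currency/kg (products, enzyme, waste fees); consumable
    tariffs per the consumable's own unit — steam per metric tonne, cooling
    water per m3, electricity per kWh, membranes per m2 of replaced area.
    ``tax_rate`` is a flat fraction of positive gross profit.
    """

    product_prices: dict[str, float]
    waste_fee: float = 0.05
    steam_price: float = 30.0
    cooling_water_price: float = 0.08
    electricity_price: float = 0.12
    membrane_price: float = 150.0
    enzyme_price: float = 6.0
    capital_cost: float = 60_000_000.0
    tax_rate: float = 0.06
    project_years: int = 20
    discount_rates: tuple[float, ...] = (0.07, 0.09, 0.11)

    def __post_init__(self) -> None:
        for name, price in self.product_prices.items():
            if price < 0:
                raise EconomicsError(f"product price for {name!r} is negative")
        for name in ("waste_fee", "steam_price", "cooling_water_price",
                     "electricity_price", "membrane_price", "enzyme_price", "capital_cost"):
            if getattr(self, name) < 0:
                raise EconomicsError(f"{name} is negative")
        if not 0.0 <= self.tax_rate < 1.0:
            raise EconomicsError(f"tax_rate={self.tax_rate} outside [0, 1)")
        if self.project_years < 1:
            raise EconomicsError(f"project_years={self.project_years} must be >= 1")


@dataclass(frozen=True)
class CashFlowSeries:
    """Yearly net cash flows: year 0 = -capital, then one entry per project year."""

    yearly_net: tuple[float, ...]
    gross_profit: float
    tax_paid: float

    def __post_init__(self) -> None:
        if len(self.yearly_net) < 2:
            raise EconomicsError("cash-flow series needs year 0 plus at least one project year")


@dataclass(frozen=True)
class TeaSummary:
    """IRR before/after tax (None when the project never pays back) and NPV by rate."""

    irr_before_tax: float | None
    irr_after_tax: float | None
    npv_by_rate: dict[float, float]


def annual_profit(
    balance: dict,
    model: CostModel,
) -> tuple[float, float, float]:
    """Price an annualized balance: returns (revenue, operating_cost, gross_profit).

    ``balance`` keys:

    - ``products``: component -> kg/yr sold (fatty acids, protein meal)
    - ``wastes``: stream label -> kg/yr charged the flat waste fee
    - ``consumables``: ``steam_mt``, ``cooling_water_m3``, ``electricity_kwh``,
      ``membrane_m2`` per year
    - ``enzyme_kg``: alcalase consumption per year

    A nonzero product mass without a configured price raises
    :class:`EconomicsError`.
    """
    products = balance.get("products", {})
    wastes = balance.get("wastes", {})
    consumables = balance.get("consumables", {})
    enzyme_kg = balance.get("enzyme_kg", 0.0)

    revenue = 0.0
    for comp, kg in products.items():
        if kg == 0.0:
            continue
        if comp not in model.product_prices:
            raise EconomicsError(f"no price configured for product {comp!r} ({kg} kg/yr)")
        revenue += kg * model.product_prices[comp]

    operating_cost = enzyme_kg * model.enzyme_price
    operating_cost += sum(wastes.values()) * model.waste_fee
    operating_cost += consumables.get("steam_mt", 0.0) * model.steam_price
    operating_cost += consumables.get("cooling_water_m3", 0.0) * model.cooling_water_price
    operating_cost += consumables.get("electricity_kwh", 0.0) * model.electricity_price
    operating_cost += consumables.get("membrane_m2", 0.0) * model.membrane_price
    return revenue, operating_cost, revenue - operating_cost


def build_cashflows(gross_profit: float, model: CostModel, taxed: bool = True) -> CashFlowSeries:
    """Constant-profit cash-flow series over the project horizon.

    Year 0 is the capital outlay; each following year nets the gross profit
    less the flat tax (charged only on positive profit; no tax credit on
    losses, no depreciation shield).
    """
    tax = model.tax_rate * max(gross_profit, 0.0) if taxed else 0.0
    net = gross_profit - tax
    series = (-model.capital_cost,) + (net,) * model.project_years
    return CashFlowSeries(yearly_net=series, gross_profit=gross_profit, tax_paid=tax)


def npv(cashflows: CashFlowSeries, rate: float) -> float:
    """Net present value: sum of yearly_net[t] / (1 + rate)^t."""
    if rate <= -1.0:
        raise EconomicsError(f"discount rate {rate} must be > -1")
    return sum(cf / (1.0 + rate) ** t for t, cf in enumerate(cashflows.yearly_net))


_IRR_LO, _IRR_HI = -0.999, 10.0


def irr(cashflows: CashFlowSeries, tol_scale: float = 1e-6) -> float | None:
    """Internal rate of return: the root of NPV(rate) on (-0.999, 10].

    Finds a sign change by scanning the bracket, then bisects (deterministic,
    derivative-free) until |NPV| < tol_scale x |year-0 outlay|.  Returns None
    when NPV never changes sign on the bracket — the project has no internal
    rate of return (e.g. all cash flows negative).
    """
    f = lambda r: npv(cashflows, r)
    scale = max(abs(cashflows.yearly_net[0]), 1.0)
    tol = tol_scale * scale

    n_scan = 200
    grid = [_IRR_LO + (_IRR_HI - _IRR_LO) * i / n_scan for i in range(n_scan + 1)]
    vals = [f(r) for r in grid]
    lo = hi = None
    for (r1, v1), (r2, v2) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
        if v1 == 0.0:
            return r1
        if v1 * v2 < 0:
            lo, hi, vlo = r1, r2, v1
            break
    else:
        return None

    mid = 0.5 * (lo + hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        vm = f(mid)
        if (hi - lo) < 1e-12 * max(1.0, abs(mid)):
            break
        if vlo * vm < 0:
            hi = mid
        else:
            lo, vlo = mid, vm
    if abs(f(mid)) > tol:  # pragma: no cover - bracketing guarantees convergence
        return None
    return mid


def irr_report_pct(rate: float | None) -> float:
    """IRR as a report percentage; the no-IRR case is reported as -100%."""
    return -100.0 if rate is None else 100.0 * rate


def default_cost_model(**overrides) -> CostModel:
    """The documented default market assumptions (currency: USD-like units).

    Fatty-acid prices sit in the commodity oleochemical range (1.5-2.5 /kg),
    the protein meal at feed-ingredient level, industrial alcalase at bulk
    enzyme pricing, and utilities at generic industrial tariffs.  None of
    these are measured quantities; sensitivity analysis perturbs them.
    """
    prices = {
        "lauric_acid": 2.2,
        "myristic_acid": 2.4,
        "palmitic_acid": 1.8,
        "stearic_acid": 1.9,
        "protein_meal": 0.8,
    }
    prices.update(overrides.pop("product_prices", {}))
    return CostModel(product_prices=prices, **overrides)
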