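"""Synthetic scenario generator for compositions and price sets.

Measured larval compositions come with per-analyte standard deviations but
no deposited raw data, and market prices are external inputs.  This module
samples both so the full pipeline is testable end to end and price/
composition sensitivity analyses can run without any external data:

- compositions: independent truncated normals per analyte around a
  scenario's (mean, SD) row — no covariance is published, so fields are
  sampled independently (a documented limitation);
- prices: log-normal multiplicative perturbations around a base cost model,
  keeping prices positive with a controlled coefficient of variation.

All sampling is driven by ``numpy.random.default_rng`` seeds and is
reproducible: the same seed yields the identical sample set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .composition import FattyAcidProfile, ProximateComposition
from .economics import CostModel

__all__ = ["ScenarioSample", "sample_composition", "sample_prices", "generate_scenario_set"]

_FIELDS = (
    ("dry_matter_pct", "dry_matter_sd"),
    ("ash_pct", "ash_sd"),
    ("organic_matter_pct", "organic_matter_sd"),
    ("crude_protein_pct", "crude_protein_sd"),
    ("ndf_pct", "ndf_sd"),
    ("adf_pct", "adf_sd"),
    ("ether_extract_pct", "ether_extract_sd"),
)

_MAX_RESAMPLES = 100


@dataclass(frozen=True)
class ScenarioSample:
    """One sampled study condition: a composition, a fatty-acid profile and prices."""

    scenario_label: str
    composition: ProximateComposition
    profile: FattyAcidProfile
    prices: CostModel
    seed: int


def sample_composition(
    scenario: ProximateComposition,
    seed: int | np.random.Generator,
) -> ProximateComposition:
    """Draw one proximate composition from a scenario's mean +/- SD row.

    Each analyte is drawn independently from a normal with the row's mean and
    SD, truncated at 0 and capped at 100 (percentages are physical).  In the
    rare event the drawn row violates composition validation (the dry-matter
    analytes summing past the sanity bound), the whole row is redrawn — the
    rejection is deterministic under the generator state.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(_MAX_RESAMPLES):
        draws = {}
        for mean_f, sd_f in _FIELDS:
            mean, sd = getattr(scenario, mean_f), getattr(scenario, sd_f)
            draws[mean_f] = float(min(max(rng.normal(mean, sd), 0.0), 100.0))
        try:
            return replace(scenario, **draws)
        except ValueError:
            continue
    raise RuntimeError(
        f"could not draw a valid composition for {scenario.scenario_label!r} "
        f"in {_MAX_RESAMPLES} attempts"
    )


def sample_prices(base: CostModel, price_cv: float, rng: np.random.Generator) -> CostModel:
    """Multiplicative log-normal perturbation of every price in the model.

    Each price is multiplied by lognormal(mu=-sigma^2/2, sigma) with
    sigma^2 = ln(1 + cv^2), so the perturbed price is unbiased in expectation
    and its coefficient of variation equals ``price_cv``.
    """
    if price_cv < 0:
        raise ValueError(f"price_cv={price_cv} must be >= 0")
    if price_cv == 0.0:
        return base
    sigma = math.sqrt(math.log1p(price_cv**2))
    mu = -0.5 * sigma**2

    def jitter() -> float:
        return float(rng.lognormal(mu, sigma))

    return replace(
        base,
        product_prices={k: v * jitter() for k, v in base.product_prices.items()},
        waste_fee=base.waste_fee * jitter(),
        steam_price=base.steam_price * jitter(),
        cooling_water_price=base.cooling_water_price * jitter(),
        electricity_price=base.electricity_price * jitter(),
        membrane_price=base.membrane_price * jitter(),
        enzyme_price=base.enzyme_price * jitter(),
        capital_cost=base.capital_cost * jitter(),
    )


def generate_scenario_set(
    n: int,
    scenarios: list[ProximateComposition],
    base_prices: CostModel,
    price_cv: float = 0.0,
    seed: int = 0,
    profile: FattyAcidProfile | None = None,
) -> list[ScenarioSample]:
    """Draw ``n`` independent (composition, prices) samples per scenario.

    Deterministic under ``seed``: the full sample set is a pure function of
    the arguments.  Each :class:`ScenarioSample` records the master seed.
    """
    if n < 1:
        raise ValueError(f"n={n} must be >= 1")
    rng = np.random.default_rng(seed)
    profile = profile or FattyAcidProfile()
    out: list[ScenarioSample] = []
    for scenario in scenarios:
        for _ in range(n):
            comp = sample_composition(scenario, rng)
            prices = sample_prices(base_prices, price_cv, rng)
            out.append(
                ScenarioSample(
                    scenario_label=scenario.scenario_label,
                    composition=comp,
                    profile=profile,
                    prices=prices,
                    seed=seed,
                )
            )
    return out
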