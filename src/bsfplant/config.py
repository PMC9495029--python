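"""YAML configuration loading for the pipeline and CLI.

The packaged ``data/default_config.yaml`` carries the full default study
setup: the four feed-scenario proximate rows, the fatty-acid profile, the
flowsheet water/enzyme inputs, the batch timing, and the cost model.  A user
config file overrides any subset of it (deep merge).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .composition import FattyAcidProfile, ProximateComposition
from .economics import CostModel

__all__ = [
    "load_config",
    "composition_from_config",
    "profile_from_config",
    "cost_model_from_config",
]


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load the packaged defaults, deep-merged with an optional user YAML file."""
    with resources.files("bsfplant.data").joinpath("default_config.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def composition_from_config(cfg: dict, scenario: str) -> ProximateComposition:
    """Build a ProximateComposition from a config's scenario table."""
    try:
        row = cfg["scenarios"][scenario]
    except KeyError:
        raise KeyError(
            f"scenario {scenario!r} not in config; available: {sorted(cfg.get('scenarios', {}))}"
        ) from None
    return ProximateComposition(
        scenario_label=scenario,
        dry_matter_pct=row["dry_matter"][0], dry_matter_sd=row["dry_matter"][1],
        ash_pct=row["ash"][0], ash_sd=row["ash"][1],
        organic_matter_pct=row["organic_matter"][0], organic_matter_sd=row["organic_matter"][1],
        crude_protein_pct=row["crude_protein"][0], crude_protein_sd=row["crude_protein"][1],
        ndf_pct=row["ndf"][0], ndf_sd=row["ndf"][1],
        adf_pct=row["adf"][0], adf_sd=row["adf"][1],
        ether_extract_pct=row["ether_extract"][0], ether_extract_sd=row["ether_extract"][1],
    )


def profile_from_config(cfg: dict) -> FattyAcidProfile:
    p = cfg.get("fatty_acid_profile", {})
    return FattyAcidProfile(
        lauric=p.get("lauric", 0.50),
        myristic=p.get("myristic", 0.20),
        palmitic=p.get("palmitic", 0.20),
        stearic=p.get("stearic", 0.10),
    )


def cost_model_from_config(cfg: dict) -> CostModel:
    e = dict(cfg.get("economics", {}))
    rates = e.pop("discount_rates", None)
    kwargs = {k: v for k, v in e.items() if k != "product_prices"}
    if rates is not None:
        kwargs["discount_rates"] = tuple(rates)
    return CostModel(product_prices=dict(e.get("product_prices", {})), **kwargs)
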