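"""Larval proximate compositions and their conversion to simulation components.

Black soldier fly larvae are modelled as a five-component mixture — water,
ash, protein, cellulose and crude fat — derived from standard proximate
analysis of the larvae reared on a given feed substrate.  Proximate rows are
reported on a dry-matter basis (ash, crude protein, neutral/acid detergent
fiber, ether extract, each as % of dry matter) alongside the dry-matter
fraction of the wet larvae.  Because the reported dry-matter fractions
overlap (organic matter subsumes protein, fiber and fat; ADF is contained in
NDF), only the four non-overlapping analytes {ash, crude protein, NDF,
ether extract} are used as simulation components, renormalized to fill the
dry matter; NDF maps to the "cellulose" component and ether extract to
"crude fat".  ADF and organic matter are carried for reporting only.

The crude fat is further split into the four fatty acids the plant
fractionates (lauric, myristic, palmitic, stearic) according to a
configurable :class:`FattyAcidProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .flowsheet import Stream

__all__ = [
    "ProximateComposition",
    "ComponentFractions",
    "FattyAcidProfile",
    "CompositionError",
    "wet_basis_fractions",
    "split_crude_fat",
    "larvae_feed_stream",
    "TABLE_SCENARIOS",
]

_FRACTION_TOL = 1e-9


class CompositionError(ValueError):
    """Raised for invalid proximate data (out-of-range percentages, zero dry matter)."""


@dataclass(frozen=True)
class ProximateComposition:
    """Proximate analysis of larvae from one feed scenario.

    ``dry_matter_pct`` is a percentage of wet mass; every other analyte is a
    percentage of dry matter.  Each mean is paired with a standard deviation
    (``*_sd``) used by the scenario sampler.
    """

    scenario_label: str
    dry_matter_pct: float
    ash_pct: float
    crude_protein_pct: float
    ndf_pct: float
    adf_pct: float
    ether_extract_pct: float
    organic_matter_pct: float
    dry_matter_sd: float = 0.0
    ash_sd: float = 0.0
    crude_protein_sd: float = 0.0
    ndf_sd: float = 0.0
    adf_sd: float = 0.0
    ether_extract_sd: float = 0.0
    organic_matter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "dry_matter_pct",
            "ash_pct",
            "crude_protein_pct",
            "ndf_pct",
            "adf_pct",
            "ether_extract_pct",
            "organic_matter_pct",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise CompositionError(
                    f"{self.scenario_label!r}: {name}={v} outside [0, 100]"
                )
        for name in (
            "dry_matter_sd",
            "ash_sd",
            "crude_protein_sd",
            "ndf_sd",
            "adf_sd",
            "ether_extract_sd",
            "organic_matter_sd",
        ):
            if getattr(self, name) < 0.0:
                raise CompositionError(f"{self.scenario_label!r}: {name} < 0")
        # Soft sanity bound: the four measured dry-matter analytes overlap a
        # little (proximate fractions are assayed independently), so their sum
        # may run somewhat past 100 — the spent-grain row reaches 112.5 — but
        # far larger sums indicate corrupt input.
        s = self.ash_pct + self.crude_protein_pct + self.ndf_pct + self.ether_extract_pct
        if s > 120.0:
            raise CompositionError(
                f"{self.scenario_label!r}: dry-matter components sum to {s:.1f} > 120"
            )


@dataclass(frozen=True)
class ComponentFractions:
    """Wet-basis mass fractions of the five larval simulation components."""

    water: float
    ash: float
    protein: float
    cellulose: float
    crude_fat: float
    other_organics: float = 0.0

    def __post_init__(self) -> None:
        total = 0.0
        for name in ("water", "ash", "protein", "cellulose", "crude_fat", "other_organics"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CompositionError(f"fraction {name}={v} outside [0, 1]")
            total += v
        if abs(total - 1.0) > _FRACTION_TOL:
            raise CompositionError(f"fractions sum to {total!r}, not 1")


@dataclass(frozen=True)
class FattyAcidProfile:
    """Mass split of the crude-fat component over the four product fatty acids.

    The default is lauric-dominant, matching the plant's lead product (the
    first fractionation tower is the lauric tower); the split is configurable
    per feed scenario since measured profiles vary with the rearing substrate.
    """

    lauric: float = 0.50
    myristic: float = 0.20
    palmitic: float = 0.20
    stearic: float = 0.10

    def __post_init__(self) -> None:
        total = 0.0
        for name in ("lauric", "myristic", "palmitic", "stearic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CompositionError(f"fatty-acid fraction {name}={v} outside [0, 1]")
            total += v
        if abs(total - 1.0) > _FRACTION_TOL:
            raise CompositionError(f"fatty-acid fractions sum to {total!r}, not 1")


def wet_basis_fractions(pc: ProximateComposition) -> ComponentFractions:
    """Convert a proximate row to wet-basis simulation component fractions.

    Water is ``1 - DM/100``.  The four measured dry-matter analytes
    {ash, crude protein, NDF, ether extract} are renormalized to fill the dry
    matter exactly, so the six fractions sum to 1.  ``other_organics`` is 0
    under this renormalization.

    Raises
    ------
    CompositionError
        If the four dry-matter analytes are all zero while dry matter is
        positive (degenerate composition).
    """
    dm = pc.dry_matter_pct / 100.0
    water = 1.0 - dm
    s = pc.ash_pct + pc.crude_protein_pct + pc.ndf_pct + pc.ether_extract_pct
    if dm == 0.0:
        return ComponentFractions(water=1.0, ash=0.0, protein=0.0, cellulose=0.0, crude_fat=0.0)
    if s == 0.0:
        raise CompositionError(
            f"{pc.scenario_label!r}: dry matter {pc.dry_matter_pct}% but all "
            "dry-matter components are zero"
        )
    ash = dm * pc.ash_pct / s
    protein = dm * pc.crude_protein_pct / s
    cellulose = dm * pc.ndf_pct / s
    crude_fat = dm * pc.ether_extract_pct / s
    # Absorb renormalization round-off into water so the invariant holds exactly.
    water = 1.0 - (ash + protein + cellulose + crude_fat)
    return ComponentFractions(
        water=water, ash=ash, protein=protein, cellulose=cellulose, crude_fat=crude_fat
    )


def split_crude_fat(fat_mass: float, profile: FattyAcidProfile) -> dict[str, float]:
    """Split a crude-fat mass (kg) into the four fatty-acid masses (kg).

    The last component takes the closure remainder so the masses sum to
    ``fat_mass`` exactly.
    """
    if fat_mass < 0.0:
        raise CompositionError(f"fat_mass={fat_mass} must be >= 0")
    lauric = fat_mass * profile.lauric
    myristic = fat_mass * profile.myristic
    palmitic = fat_mass * profile.palmitic
    stearic = fat_mass - lauric - myristic - palmitic
    return {
        "lauric_acid": lauric,
        "myristic_acid": myristic,
        "palmitic_acid": palmitic,
        "stearic_acid": stearic,
    }


def larvae_feed_stream(
    batch_mass: float,
    cf: ComponentFractions,
    profile: FattyAcidProfile | None = None,
    label: str = "Larvae feed",
) -> Stream:
    """Build the per-batch larvae feed stream (kg of each component).

    The crude-fat fraction is expanded into the four fatty acids via
    :func:`split_crude_fat`; the stream total equals ``batch_mass`` to within
    1e-9 relative.
    """
    if batch_mass <= 0.0:
        raise CompositionError(f"batch_mass={batch_mass} must be > 0")
    profile = profile or FattyAcidProfile()
    masses: dict[str, float] = {}
    for comp in ("water", "ash", "protein", "cellulose", "other_organics"):
        m = batch_mass * getattr(cf, comp)
        if m > 0.0:
            masses[comp] = m
    fat = batch_mass * cf.crude_fat
    for name, m in split_crude_fat(fat, profile).items():
        if m > 0.0:
            masses[name] = m
    return Stream(label=label, masses=masses, temperature=25.0, pressure=1.013, phase="solid-slurry")


def _row(label, dm, ash, om, cp, ndf, adf, ee) -> ProximateComposition:
    return ProximateComposition(
        scenario_label=label,
        dry_matter_pct=dm[0], dry_matter_sd=dm[1],
        ash_pct=ash[0], ash_sd=ash[1],
        organic_matter_pct=om[0], organic_matter_sd=om[1],
        crude_protein_pct=cp[0], crude_protein_sd=cp[1],
        ndf_pct=ndf[0], ndf_sd=ndf[1],
        adf_pct=adf[0], adf_sd=adf[1],
        ether_extract_pct=ee[0], ether_extract_sd=ee[1],
    )


#: Published proximate compositions of black soldier fly larvae per feed
#: scenario (mean, SD).  Chicken-manure larvae are included for composition
#: work but the economic comparison covers kitchen waste, spent grain and
#: control only.
TABLE_SCENARIOS: dict[str, ProximateComposition] = {
    "chicken_manure": _row(
        "chicken_manure",
        (80.7, 1.2), (9.3, 1.8), (59.8, 0.4), (41.1, 0.3), (21.9, 0.6), (12.6, 0.3), (30.1, 0.4),
    ),
    "kitchen_waste": _row(
        "kitchen_waste",
        (87.7, 1.0), (9.6, 1.6), (90.4, 1.6), (33.0, 1.0), (20.4, 0.6), (13.2, 0.1), (34.3, 0.4),
    ),
    "spent_grain": _row(
        "spent_grain",
        (83.1, 1.6), (11.6, 0.5), (88.4, 0.5), (41.3, 0.5), (28.6, 1.0), (15.0, 0.8), (31.0, 0.4),
    ),
    "control": _row(
        "control",
        (32.7, 5.0), (15.9, 3.1), (84.0, 1.4), (44.7, 3.4), (10.6, 4.2), (19.0, 2.2), (9.7, 3.3),
    ),
}
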