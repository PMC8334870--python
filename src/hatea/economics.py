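"""Cost model: batch trace -> capital, materials, consumables, labor, CoG.

Cost structure
--------------
* **Capital** — purchased-equipment cost from the power-law/linear curves,
  multiplied by a facility (Lang-type) factor covering installation and
  building, then straight-line amortised over the plant life and the number
  of batches run per year.
* **Materials** — fermentation media plus the process additives
  (isopropanol by density, sodium acetate, silica gel), at bulk catalogue
  prices with an optional across-the-board discount.
* **Consumables** — single-use vessel inlet filters, plus membrane
  cartridges/cassettes priced per m^2 and amortised over a configured
  number of reuse cycles.
* **Labor** — charged as a fixed fraction (default 15%) of the total cost
  of goods, i.e. ``total = (capital + materials + consumables) / (1 - f)``.

CoG/g is the total batch cost divided by the HA mass leaving the train.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Mapping

from .process import BatchResult

__all__ = [
    "EquipmentCostModel",
    "PriceList",
    "ConsumableModel",
    "EconomicAssumptions",
    "EconomicDataset",
    "CostBreakdown",
    "equipment_cost",
    "materials_cost",
    "consumables_cost",
    "capital_charge_per_batch",
    "assemble_cog",
    "cost_of_batch",
]


@dataclass(frozen=True)
class CostCurve:
    """One purchased-equipment cost curve.

    forms: ``power`` a*size^b; ``scaled_power`` a*(size/ref)^b;
    ``linear`` slope*size + intercept.
    """

    form: str
    a: float = 0.0
    b: float = 0.0
    ref: float = 1.0
    slope: float = 0.0
    intercept: float = 0.0

    def __call__(self, size: float) -> float:
        if size <= 0:
            raise ValueError("equipment size must be positive")
        if self.form == "power":
            return self.a * size**self.b
        if self.form == "scaled_power":
            return self.a * (size / self.ref) ** self.b
        if self.form == "linear":
            return self.slope * size + self.intercept
        raise ValueError(f"unknown cost-curve form {self.form!r}")


@dataclass(frozen=True)
class EquipmentCostModel:
    curves: Mapping[str, CostCurve]

    def cost(self, kind: str, size: float) -> float:
        try:
            curve = self.curves[kind]
        except KeyError:
            raise KeyError(f"no cost curve for equipment kind {kind!r}") from None
        return curve(size)


class PriceList(Mapping[str, float]):
    """Material name -> USD/kg; every price must be positive."""

    def __init__(self, prices: Mapping[str, float]):
        for name, price in prices.items():
            if price <= 0:
                raise ValueError(f"price for {name!r} must be positive, got {price}")
        self._prices = dict(prices)

    def __getitem__(self, name: str) -> float:
        try:
            return self._prices[name]
        except KeyError:
            raise KeyError(f"no price listed for material {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._prices)

    def __len__(self) -> int:
        return len(self._prices)

    def __eq__(self, other) -> bool:
        return isinstance(other, PriceList) and self._prices == other._prices

    def __repr__(self) -> str:
        return f"PriceList({len(self._prices)} materials)"


@dataclass(frozen=True)
class ConsumableModel:
    """Consumable cost rules.

    Vessel filters are single-use; membrane consumables cost a fixed USD/m^2
    and are replaced every ``*_lifetime_batches`` batches, so the per-batch
    charge is area * unit cost / lifetime.
    """

    vessel_filter_slope: float = 0.3058
    vessel_filter_intercept: float = 45.334
    flowthrough_cost_per_m2: float = 575.0
    flowthrough_lifetime_batches: int = 50
    uf_cost_per_m2: float = 4621.0
    uf_lifetime_batches: int = 50

    def __post_init__(self):
        if min(
            self.vessel_filter_slope,
            self.vessel_filter_intercept,
            self.flowthrough_cost_per_m2,
            self.uf_cost_per_m2,
        ) < 0:
            raise ValueError("consumable cost parameters must be >= 0")
        if self.flowthrough_lifetime_batches < 1 or self.uf_lifetime_batches < 1:
            raise ValueError("consumable lifetimes must be >= 1 batch")

    def vessel_filter(self, volume_L: float) -> float:
        return self.vessel_filter_slope * volume_L + self.vessel_filter_intercept

    def membrane(self, kind: str, area_m2: float) -> float:
        """Per-batch charge for one membrane consumable."""
        if kind == "tangential_ultrafilter":
            return self.uf_cost_per_m2 * area_m2 / self.uf_lifetime_batches
        if kind == "flowthrough_filter":
            return (
                self.flowthrough_cost_per_m2 * area_m2 / self.flowthrough_lifetime_batches
            )
        raise KeyError(f"no membrane consumable for equipment kind {kind!r}")


@dataclass(frozen=True)
class EconomicAssumptions:
    facility_factor: float = 6.0
    depreciation_years: float = 10.0
    labor_fraction: float = 0.15
    operating_days: int = 200
    ipa_density_kg_per_L: float = 0.785
    dsp_overhead_h_per_op: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.labor_fraction < 1.0:
            raise ValueError("labor_fraction must lie in [0, 1)")
        if self.facility_factor < 1.0:
            raise ValueError("facility_factor must be >= 1")
        if self.depreciation_years <= 0 or self.operating_days <= 0:
            raise ValueError("depreciation_years and operating_days must be positive")


@dataclass(frozen=True)
class EconomicDataset:
    equipment: EquipmentCostModel
    prices: PriceList
    consumables: ConsumableModel
    assumptions: EconomicAssumptions

    def with_assumptions(self, **changes) -> "EconomicDataset":
        return replace(self, assumptions=replace(self.assumptions, **changes))


@dataclass(frozen=True)
class CostBreakdown:
    """Per-batch cost components (USD) and the headline CoG/g."""

    capital_charge: float
    materials: float
    consumables: float
    labor: float
    total: float
    cog_per_g: float
    batch_mass_g: float

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "capital": self.capital_charge / self.total,
            "materials": self.materials / self.total,
            "consumables": self.consumables / self.total,
            "labor": self.labor / self.total,
        }


def equipment_cost(model: EquipmentCostModel, kind: str, size: float) -> float:
    """Purchased cost (USD) of one piece of equipment of the given size."""
    return model.cost(kind, size)


def materials_cost(
    batch: BatchResult,
    prices: PriceList,
    discount: float = 0.0,
    ipa_density_kg_per_L: float = 0.785,
) -> float:
    """Raw-material bill for one batch at the (discounted) bulk prices."""
    if not 0.0 <= discount < 1.0:
        raise ValueError("discount must lie in [0, 1)")
    total = sum(kg * prices[name] for name, kg in batch.materials_kg.items())
    if batch.isopropanol_L:
        total += batch.isopropanol_L * ipa_density_kg_per_L * prices["isopropanol"]
    return total * (1.0 - discount)


def consumables_cost(batch: BatchResult, model: ConsumableModel) -> float:
    total = sum(model.vessel_filter(v) for v in batch.vessel_volumes)
    total += sum(model.membrane(kind, area) for _, kind, area in batch.filter_areas)
    return total


def capital_charge_per_batch(
    batch: BatchResult,
    econ: EconomicDataset,
    capital_multiplier: float = 1.0,
    n_batches_per_year: float | None = None,
) -> float:
    """Installed-capital charge allocated to one batch.

    Sum of purchased-equipment costs sized from the batch trace, scaled by
    the facility factor and the study's capital multiplier, amortised over
    ``depreciation_years * batches_per_year``.  Amortisation is
    duration-proportional: each batch carries its share of the annual
    capital charge through the *effective* (fractional) batches per year,
    so the charge is a smooth function of the process time.  The whole-
    batch ``floor`` only applies to saleable annual production.
    """
    if capital_multiplier <= 0:
        raise ValueError("capital multiplier must be positive")
    if n_batches_per_year is None:
        n_batches_per_year = (
            econ.assumptions.operating_days * 24.0 / batch.batch_duration_h
        )
    if n_batches_per_year <= 0:
        raise ValueError("batches per year must be positive")
    purchased = sum(econ.equipment.cost(kind, size) for _, kind, size in batch.equipment)
    installed = purchased * econ.assumptions.facility_factor * capital_multiplier
    return installed / (econ.assumptions.depreciation_years * n_batches_per_year)


def assemble_cog(
    capital_charge: float,
    materials: float,
    consumables: float,
    assumptions: EconomicAssumptions,
    batch_mass_g: float,
) -> CostBreakdown:
    """Combine components; labor is a fixed fraction of the grossed-up total."""
    if batch_mass_g <= 0:
        raise ValueError("batch mass must be positive")
    subtotal = capital_charge + materials + consumables
    total = subtotal / (1.0 - assumptions.labor_fraction)
    labor = total * assumptions.labor_fraction
    return CostBreakdown(
        capital_charge=capital_charge,
        materials=materials,
        consumables=consumables,
        labor=labor,
        total=total,
        cog_per_g=total / batch_mass_g,
        batch_mass_g=batch_mass_g,
    )


def cost_of_batch(
    batch: BatchResult,
    econ: EconomicDataset,
    capital_multiplier: float = 1.0,
    discount: float = 0.0,
) -> CostBreakdown:
    """Full cost breakdown for one executed batch."""
    capital = capital_charge_per_batch(batch, econ, capital_multiplier)
    materials = materials_cost(
        batch, econ.prices, discount, econ.assumptions.ipa_density_kg_per_L
    )
    consumables = consumables_cost(batch, econ.consumables)
    return assemble_cog(
        capital, materials, consumables, econ.assumptions, batch.final_mass_g
    )
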