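"""Built-in study data: upstream options, downstream train, economics, design.

The package ships the published study inputs as YAML documents under
``hatea/data`` — six upstream fermentation options, the eleven-operation
process train, the economic dataset (equipment cost curves, bulk prices,
consumable rules, global assumptions) and the default variation design.
:func:`load_study_fixtures` returns them as validated objects; user configs
with the same schema can override any section, and the whole set
round-trips losslessly through :func:`write_config` / :func:`load_config`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .economics import (
    ConsumableModel,
    CostCurve,
    EconomicAssumptions,
    EconomicDataset,
    EquipmentCostModel,
    PriceList,
)
from .process import FIXED_YIELDS, VARIABLE_OPS, ProcessTrain, UnitOperation

__all__ = [
    "ConfigError",
    "UpstreamOption",
    "VariationDesign",
    "Fixtures",
    "load_study_fixtures",
    "load_config",
    "write_config",
    "build_train",
    "export_tables",
]

#: Process additives that must be priced even though no medium contains them.
REQUIRED_EXTRA_PRICES = ("isopropanol", "sodium acetate", "silica gel")


class ConfigError(ValueError):
    """A configuration document violates the fixture schema."""


@dataclass(frozen=True)
class UpstreamOption:
    """One published fermentation strategy (titer, duration, media recipe)."""

    option_id: int
    source: str  # "endogenous" | "recombinant"
    organism: str
    titer_g_per_L: float
    duration_h: float
    media_g_per_L: tuple[tuple[str, float], ...]

    def __post_init__(self):
        if self.source not in ("endogenous", "recombinant"):
            raise ConfigError(f"option {self.option_id}: unknown source {self.source!r}")
        if self.titer_g_per_L <= 0 or self.duration_h <= 0:
            raise ConfigError(f"option {self.option_id}: titer and duration must be > 0")
        for name, conc in self.media_g_per_L:
            if conc <= 0:
                raise ConfigError(
                    f"option {self.option_id}: media component {name!r} "
                    f"concentration must be > 0"
                )

    @property
    def media(self) -> dict[str, float]:
        return dict(self.media_g_per_L)


@dataclass(frozen=True)
class VariationDesign:
    """Levels of the one-at-a-time and simultaneous-variation studies."""

    multiplier_levels: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 10.0)
    scale_levels_L: tuple[float, ...] = (1.0, 10.0, 50.0, 100.0, 250.0, 500.0, 1000.0)
    discount_levels: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
    yield_levels: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    n_variable_ops: int = 5
    base_scale_L: float = 100.0
    n_sweep_titers: int = 25

    def __post_init__(self):
        for y in self.yield_levels:
            if not 0.0 < y <= 1.0:
                raise ConfigError(f"yield level {y} outside (0, 1]")
        for m in self.multiplier_levels:
            if m <= 0:
                raise ConfigError(f"multiplier level {m} must be > 0")
        for d in self.discount_levels:
            if not 0.0 <= d < 1.0:
                raise ConfigError(f"discount level {d} outside [0, 1)")
        if self.base_scale_L not in self.scale_levels_L:
            raise ConfigError("base scale must be one of the scale levels")

    @property
    def n_oat_settings(self) -> int:
        """Titer + capital + time multipliers, scales and discounts."""
        return 3 * len(self.multiplier_levels) + len(self.scale_levels_L) + len(
            self.discount_levels
        )

    @property
    def n_yield_combinations(self) -> int:
        return len(self.yield_levels) ** self.n_variable_ops


@dataclass(frozen=True)
class Fixtures:
    """The full study configuration."""

    upstream_options: tuple[UpstreamOption, ...]
    downstream: dict[str, Any]  # raw train section (ops 2-11 + flux)
    economics: EconomicDataset
    design: VariationDesign

    def option(self, option_id: int) -> UpstreamOption:
        for opt in self.upstream_options:
            if opt.option_id == option_id:
                return opt
        raise KeyError(f"no upstream option {option_id}")


# ---------------------------------------------------------------------------
# parsing


def _parse_upstream(doc: Mapping[str, Any]) -> tuple[UpstreamOption, ...]:
    try:
        raw = doc["options"]
    except KeyError:
        raise ConfigError("upstream section needs an 'options' list") from None
    options = tuple(
        UpstreamOption(
            option_id=int(o["option_id"]),
            source=o["source"],
            organism=o["organism"],
            titer_g_per_L=float(o["titer_g_per_L"]),
            duration_h=float(o["duration_h"]),
            media_g_per_L=tuple((k, float(v)) for k, v in o["media_g_per_L"].items()),
        )
        for o in raw
    )
    by_source = {s: [o.option_id for o in options if o.source == s]
                 for s in ("endogenous", "recombinant")}
    if sorted(o.option_id for o in options) == list(range(1, 7)):
        if by_source["endogenous"] != [1, 2, 3] or by_source["recombinant"] != [4, 5, 6]:
            raise ConfigError("options 1-3 must be endogenous and 4-6 recombinant")
    return options


def _parse_unit_operation(raw: Mapping[str, Any], flux: float) -> UnitOperation:
    op_id = int(raw["op_id"])
    yield_raw = raw.get("recovery_yield")
    if yield_raw == "variable":
        yield_class, recovery = "variable", None
        if op_id not in VARIABLE_OPS:
            raise ConfigError(f"op {op_id} may not have a variable yield")
    else:
        yield_class, recovery = "fixed", float(yield_raw)
        if op_id in FIXED_YIELDS and recovery != FIXED_YIELDS[op_id]:
            raise ConfigError(
                f"op {op_id}: fixed yield must be {FIXED_YIELDS[op_id]}, got {recovery}"
            )
    solid = raw.get("solid_additive")
    if solid is not None:
        basis = solid.get("basis", "volume_in")
        if basis not in ("volume_in", "volume_out"):
            raise ConfigError(f"op {op_id}: unknown additive basis {basis!r}")
        solid = (solid["name"], float(solid["dose_g_per_L"]), basis)
    kind = raw["equipment"]
    return UnitOperation(
        op_id=op_id,
        name=raw["name"],
        equipment_kind=kind,
        yield_class=yield_class,
        recovery_yield=recovery,
        volume_rule=raw.get("volume_rule", "none"),
        duration_h=float(raw.get("duration_h", 1.0)),
        flux_L_per_m2_h=flux if kind.endswith("filter") else None,
        concentration_factor=(
            float(raw["concentration_factor"]) if "concentration_factor" in raw else None
        ),
        resuspension_ratio=float(raw.get("resuspension_ratio", 1.0)),
        diavolumes=float(raw.get("diavolumes", 0.0)),
        liquid_additive=raw.get("liquid_additive"),
        solid_additive=solid,
    )


def _parse_economics(doc: Mapping[str, Any]) -> EconomicDataset:
    curves = {
        kind: CostCurve(**params) for kind, params in doc["equipment_cost"].items()
    }
    prices = PriceList(doc["prices_usd_per_kg"])
    cons = doc["consumables"]
    consumables = ConsumableModel(
        vessel_filter_slope=cons["vessel_filter"]["slope_usd_per_L"],
        vessel_filter_intercept=cons["vessel_filter"]["intercept_usd"],
        flowthrough_cost_per_m2=cons["flowthrough_filter"]["cost_usd_per_m2"],
        flowthrough_lifetime_batches=cons["flowthrough_filter"]["lifetime_batches"],
        uf_cost_per_m2=cons["uf_membrane"]["cost_usd_per_m2"],
        uf_lifetime_batches=cons["uf_membrane"]["lifetime_batches"],
    )
    a = doc["assumptions"]
    assumptions = EconomicAssumptions(
        facility_factor=float(a["facility_factor"]),
        depreciation_years=float(a["depreciation_years"]),
        labor_fraction=float(a["labor_fraction"]),
        operating_days=int(a["operating_days_per_year"]),
        ipa_density_kg_per_L=float(a["ipa_density_kg_per_L"]),
        dsp_overhead_h_per_op=float(a.get("dsp_overhead_h_per_op", 0.0)),
    )
    return EconomicDataset(
        equipment=EquipmentCostModel(curves),
        prices=prices,
        consumables=consumables,
        assumptions=assumptions,
    )


def _parse_design(doc: Mapping[str, Any]) -> VariationDesign:
    return VariationDesign(
        multiplier_levels=tuple(doc["multiplier_levels"]),
        scale_levels_L=tuple(doc["scale_levels_L"]),
        discount_levels=tuple(doc["discount_levels"]),
        yield_levels=tuple(doc["yield_levels"]),
        n_variable_ops=int(doc["n_variable_ops"]),
        base_scale_L=float(doc.get("base_scale_L", 100.0)),
        n_sweep_titers=int(doc.get("n_sweep_titers", 25)),
    )


def _validate(fixtures: Fixtures) -> Fixtures:
    # every medium component and every process additive must be priced
    prices = fixtures.economics.prices
    for opt in fixtures.upstream_options:
        for name, _ in opt.media_g_per_L:
            if name not in prices:
                raise ConfigError(
                    f"option {opt.option_id}: no price for media component {name!r}"
                )
    for name in REQUIRED_EXTRA_PRICES:
        if name not in prices:
            raise ConfigError(f"no price for required process additive {name!r}")
    # the train must build for at least one option
    build_train(fixtures, fixtures.upstream_options[0].option_id)
    return fixtures


# ---------------------------------------------------------------------------
# public API


def _default_documents() -> dict[str, Any]:
    data = importlib.resources.files("hatea.data")
    return {
        "upstream": yaml.safe_load((data / "upstream.yaml").read_text()),
        "downstream": yaml.safe_load((data / "downstream.yaml").read_text()),
        "economics": yaml.safe_load((data / "economics.yaml").read_text()),
        "design": yaml.safe_load((data / "design.yaml").read_text()),
    }


def _from_documents(docs: Mapping[str, Any]) -> Fixtures:
    try:
        fixtures = Fixtures(
            upstream_options=_parse_upstream(docs["upstream"]),
            downstream=docs["downstream"],
            economics=_parse_economics(docs["economics"]),
            design=_parse_design(docs["design"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"malformed configuration: {exc}") from exc
    return _validate(fixtures)


def load_study_fixtures() -> Fixtures:
    """Load the built-in study dataset (no external files required)."""
    return _from_documents(_default_documents())


def load_config(path: str | Path | None = None) -> Fixtures:
    """Load fixtures, overriding built-in sections from a user YAML file.

    The file may contain any subset of the top-level sections
    ``upstream``, ``downstream``, ``economics`` and ``design``.
    """
    docs = _default_documents()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(docs)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        docs.update(user)
    return _from_documents(docs)


def _economics_document(econ: EconomicDataset) -> dict[str, Any]:
    curves = {}
    for kind, curve in econ.equipment.curves.items():
        if curve.form == "power":
            curves[kind] = {"form": "power", "a": curve.a, "b": curve.b}
        elif curve.form == "scaled_power":
            curves[kind] = {
                "form": "scaled_power", "a": curve.a, "ref": curve.ref, "b": curve.b,
            }
        else:
            curves[kind] = {
                "form": "linear", "slope": curve.slope, "intercept": curve.intercept,
            }
    a = econ.assumptions
    c = econ.consumables
    return {
        "equipment_cost": curves,
        "prices_usd_per_kg": dict(econ.prices),
        "consumables": {
            "vessel_filter": {
                "slope_usd_per_L": c.vessel_filter_slope,
                "intercept_usd": c.vessel_filter_intercept,
            },
            "flowthrough_filter": {
                "cost_usd_per_m2": c.flowthrough_cost_per_m2,
                "lifetime_batches": c.flowthrough_lifetime_batches,
            },
            "uf_membrane": {
                "cost_usd_per_m2": c.uf_cost_per_m2,
                "lifetime_batches": c.uf_lifetime_batches,
            },
        },
        "assumptions": {
            "facility_factor": a.facility_factor,
            "depreciation_years": a.depreciation_years,
            "labor_fraction": a.labor_fraction,
            "operating_days_per_year": a.operating_days,
            "ipa_density_kg_per_L": a.ipa_density_kg_per_L,
            "dsp_overhead_h_per_op": a.dsp_overhead_h_per_op,
        },
    }


def to_documents(fixtures: Fixtures) -> dict[str, Any]:
    """Serialise fixtures back to the config document structure."""
    design = asdict(fixtures.design)
    design = {
        "multiplier_levels": list(design["multiplier_levels"]),
        "scale_levels_L": list(design["scale_levels_L"]),
        "discount_levels": list(design["discount_levels"]),
        "yield_levels": list(design["yield_levels"]),
        "n_variable_ops": design["n_variable_ops"],
        "base_scale_L": design["base_scale_L"],
        "n_sweep_titers": design["n_sweep_titers"],
    }
    return {
        "upstream": {
            "options": [
                {
                    "option_id": o.option_id,
                    "source": o.source,
                    "organism": o.organism,
                    "titer_g_per_L": o.titer_g_per_L,
                    "duration_h": o.duration_h,
                    "media_g_per_L": dict(o.media_g_per_L),
                }
                for o in fixtures.upstream_options
            ]
        },
        "downstream": fixtures.downstream,
        "economics": _economics_document(fixtures.economics),
        "design": design,
    }


def write_config(fixtures: Fixtures, path: str | Path) -> None:
    """Write the full configuration to one YAML file (round-trip safe)."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_documents(fixtures), fh, sort_keys=False)


def build_train(fixtures: Fixtures, option_id: int) -> ProcessTrain:
    """Assemble the full train for one upstream option."""
    opt = fixtures.option(option_id)
    flux = float(fixtures.downstream.get("flux_L_per_m2_h", 4.0))
    try:
        ops = tuple(
            _parse_unit_operation(raw, flux) for raw in fixtures.downstream["operations"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"malformed downstream section: {exc}") from exc
    return ProcessTrain(
        operations=ops,
        titer_g_per_L=opt.titer_g_per_L,
        scale_L=fixtures.design.base_scale_L,
        source=opt.source,
        ferm_duration_h=opt.duration_h,
        media_g_per_L=opt.media,
    )


def export_tables(fixtures: Fixtures, outdir: str | Path) -> dict[str, Path]:
    """Dump the fixture tables as CSV files; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    upstream = pd.DataFrame(
        [
            {
                "option_id": o.option_id,
                "source": o.source,
                "organism": o.organism,
                "titer_g_per_L": o.titer_g_per_L,
                "duration_h": o.duration_h,
                "media": "; ".join(f"{k}={v} g/L" for k, v in o.media_g_per_L),
            }
            for o in fixtures.upstream_options
        ]
    )
    train_rows = []
    train = build_train(fixtures, 1)
    for op in train.operations:
        train_rows.append(
            {
                "op_id": op.op_id,
                "name": op.name,
                "equipment": op.equipment_kind,
                "yield_class": op.yield_class,
                "recovery_yield": op.recovery_yield,
                "volume_rule": op.volume_rule,
                "duration_h": op.duration_h,
            }
        )
    prices = pd.DataFrame(
        sorted(fixtures.economics.prices.items()), columns=["material", "usd_per_kg"]
    )
    d = fixtures.design
    design = pd.DataFrame(
        {
            "level_kind": ["multiplier"] * len(d.multiplier_levels)
            + ["scale_L"] * len(d.scale_levels_L)
            + ["discount"] * len(d.discount_levels)
            + ["yield"] * len(d.yield_levels),
            "value": list(d.multiplier_levels)
            + list(d.scale_levels_L)
            + list(d.discount_levels)
            + list(d.yield_levels),
        }
    )
    for name, frame in {
        "upstream_options": upstream,
        "process_train": pd.DataFrame(train_rows),
        "prices": prices,
        "variation_design": design,
    }.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths
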