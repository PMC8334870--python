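"""Unit-operation mass balance for the hyaluronic acid bioprocess.

The model tracks a single product stream — broth volume, HA concentration
``C`` (g/L) and HA mass (g) — through fermentation followed by ten
recovery/purification steps (water dilution, biomass removal, isopropanol
precipitation, precipitate recovery, sodium-acetate resuspension, silica-gel
polish, silica removal, activated-carbon filtration, ultra/diafiltration and
sterile filtration).  Each step applies a recovery yield to the HA mass and
a volume rule to the liquid phase; the concentration is recomputed as

    C_out = V_in * C_in * yield / V_out.

Two sizing quantities drive the downstream capital costs: centrifuge flow
rate ``Y = V_in / t`` (the whole feed is processed in one nominal hour) and
membrane area ``Z = V_in / (flux * t)`` at a constant flux of 4 L m^-2 h^-1.

Volume rules never touch the product mass, so the final batch output is
always ``titer * scale * overall_yield`` regardless of how intermediate
volumes evolve — volumes only matter for equipment sizing and material
consumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "EQUIPMENT_KINDS",
    "VOLUME_RULES",
    "VARIABLE_OPS",
    "FIXED_YIELDS",
    "StreamState",
    "UnitOperation",
    "ProcessTrain",
    "OpTrace",
    "BatchResult",
    "propagate",
    "centrifuge_flow_rate",
    "membrane_area",
    "overall_yield",
    "run_batch",
    "batches_per_year",
    "annual_production",
]

EQUIPMENT_KINDS = (
    "bioreactor",
    "stainless_tank",
    "centrifuge",
    "flowthrough_filter",
    "tangential_ultrafilter",
)
VOLUME_RULES = (
    "none",
    "add_equal_volume",
    "resuspend_to_reference",
    "concentration_factor",
)

#: Downstream operations whose recovery yield is a study variable (symbol X).
VARIABLE_OPS = (4, 6, 7, 9, 10)

#: Fixed recovery yields of the generic downstream operations.
FIXED_YIELDS = {2: 0.95, 3: 0.90, 5: 0.90, 8: 0.90, 11: 0.95}

#: Nominal per-operation processing time (h) used for flow/area sizing.
NOMINAL_OP_HOURS = 1.0

#: Default membrane flux (L m^-2 h^-1) for flow-through and tangential filters.
DEFAULT_FLUX = 4.0


@dataclass(frozen=True)
class StreamState:
    """Product stream between unit operations.

    ``ha_mass`` is redundant with ``volume * ha_conc``; when supplied it is
    checked to 1e-9 relative tolerance, otherwise it is derived.
    """

    volume: float
    ha_conc: float
    ha_mass: float | None = None

    def __post_init__(self):
        if self.volume < 0 or self.ha_conc < 0:
            raise ValueError("stream volume and concentration must be >= 0")
        derived = self.volume * self.ha_conc
        if self.ha_mass is None:
            object.__setattr__(self, "ha_mass", derived)
        elif not math.isclose(self.ha_mass, derived, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"inconsistent stream: mass {self.ha_mass} != volume*conc {derived}"
            )


@dataclass(frozen=True)
class UnitOperation:
    """One step of the train.

    ``recovery_yield`` is ``None`` while a variable-yield operation is
    unbound; :func:`run_batch` binds the five variable yields before
    propagating.  ``solid_additive`` is ``(name, dose g/L, basis)`` where
    basis selects the volume the dose applies to; ``liquid_additive`` names
    a 1:1 volume addition that must be purchased (isopropanol) — the 1:1
    water addition is left unnamed and uncosted.
    """

    op_id: int
    name: str
    equipment_kind: str
    yield_class: str = "fixed"  # "fixed" | "variable"
    recovery_yield: float | None = None
    volume_rule: str = "none"
    duration_h: float = 1.0
    flux_L_per_m2_h: float | None = None
    concentration_factor: float | None = None
    resuspension_ratio: float = 1.0
    diavolumes: float = 0.0
    liquid_additive: str | None = None
    solid_additive: tuple[str, float, str] | None = None

    def __post_init__(self):
        if self.equipment_kind not in EQUIPMENT_KINDS:
            raise ValueError(f"unknown equipment kind {self.equipment_kind!r}")
        if self.volume_rule not in VOLUME_RULES:
            raise ValueError(f"unknown volume rule {self.volume_rule!r}")
        if self.yield_class not in ("fixed", "variable"):
            raise ValueError(f"unknown yield class {self.yield_class!r}")
        if self.recovery_yield is not None and not 0.0 < self.recovery_yield <= 1.0:
            raise ValueError(
                f"op {self.op_id}: recovery yield must lie in (0, 1], "
                f"got {self.recovery_yield}"
            )
        if self.volume_rule == "concentration_factor" and (
            self.concentration_factor is None or self.concentration_factor <= 0
        ):
            raise ValueError("concentration_factor rule needs a positive factor")

    def bound(self, recovery_yield: float) -> "UnitOperation":
        """Return a copy with the (variable) yield bound to a value."""
        return replace(self, recovery_yield=recovery_yield)


@dataclass(frozen=True)
class ProcessTrain:
    """Fermentation plus the ordered downstream operations.

    The train is self-contained: it carries the fermentation titer,
    duration and media recipe of the upstream option it was built from, so
    the economics never need to look the option up again.
    """

    operations: tuple[UnitOperation, ...]
    titer_g_per_L: float
    scale_L: float = 100.0
    source: str = "endogenous"
    ferm_duration_h: float = 24.0
    media_g_per_L: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.titer_g_per_L <= 0 or self.scale_L <= 0:
            raise ValueError("titer and scale must be positive")
        ids = [op.op_id for op in self.operations]
        if ids != list(range(2, 12)):
            raise ValueError("train must hold downstream operations 2..11 in order")
        variable = tuple(op.op_id for op in self.operations if op.yield_class == "variable")
        if variable != VARIABLE_OPS:
            raise ValueError(f"variable-yield ops must be {VARIABLE_OPS}, got {variable}")

    @property
    def variable_ops(self) -> tuple[int, ...]:
        return VARIABLE_OPS

    def with_scale(self, scale_L: float) -> "ProcessTrain":
        return replace(self, scale_L=scale_L)

    def with_titer(self, titer_g_per_L: float) -> "ProcessTrain":
        return replace(self, titer_g_per_L=titer_g_per_L)


@dataclass(frozen=True)
class OpTrace:
    """Stream snapshot and sizing record for one executed operation."""

    op_id: int
    name: str
    equipment_kind: str
    volume_in: float
    volume_out: float
    conc_out: float
    mass_in: float
    mass_out: float
    recovery_yield: float
    flow_rate_L_per_h: float | None = None
    membrane_area_m2: float | None = None


@dataclass
class BatchResult:
    """Everything the economics layer needs about one executed batch."""

    trace: list[OpTrace]
    final_mass_g: float
    overall_yield: float
    batch_duration_h: float
    scale_L: float
    titer_g_per_L: float
    source: str
    #: (op_id, equipment_kind, size) — L for vessels, L/h for centrifuges,
    #: m^2 for filters.
    equipment: list[tuple[int, str, float]]
    #: volumes (L) of vessels that receive a single-use inlet filter.
    vessel_volumes: list[float]
    #: (op_id, kind, area m^2) for membrane consumables.
    filter_areas: list[tuple[int, str, float]]
    #: purchased solids, kg (media components and process additives).
    materials_kg: dict[str, float]
    isopropanol_L: float
    diafiltration_buffer_L: float

    def trace_frame(self) -> pd.DataFrame:
        """Batch trace as a tidy table, one row per unit operation."""
        return pd.DataFrame([vars(t) for t in self.trace])


def centrifuge_flow_rate(volume_in: float, operation_hours: float = NOMINAL_OP_HOURS) -> float:
    """Flow rate Y (L/h) that pushes the whole feed through in one operation."""
    if volume_in <= 0:
        raise ValueError("volume_in must be positive")
    return volume_in / operation_hours


def membrane_area(
    volume_in: float,
    flux: float = DEFAULT_FLUX,
    process_hours: float = NOMINAL_OP_HOURS,
) -> float:
    """Membrane area Z (m^2) at constant flux and fixed process time."""
    if volume_in <= 0:
        raise ValueError("volume_in must be positive")
    if flux <= 0:
        raise ValueError("flux must be positive")
    return volume_in / (flux * process_hours)


def _volume_out(op: UnitOperation, volume_in: float, reference_volume: float) -> float:
    if op.volume_rule == "none":
        return volume_in
    if op.volume_rule == "add_equal_volume":
        return 2.0 * volume_in
    if op.volume_rule == "resuspend_to_reference":
        return reference_volume * op.resuspension_ratio
    # concentration_factor
    return volume_in / op.concentration_factor


def propagate(
    op: UnitOperation,
    stream_in: StreamState,
    reference_volume: float | None = None,
) -> tuple[StreamState, OpTrace]:
    """Apply one unit operation to a stream.

    Returns the output stream and the trace row (including Y/Z sizing for
    centrifuges and filters).  ``reference_volume`` is the resuspension
    basis (by default the fermentation volume); it is required only for the
    ``resuspend_to_reference`` rule.
    """
    if stream_in.volume <= 0:
        raise ValueError(f"op {op.op_id}: input volume must be positive")
    if op.recovery_yield is None:
        raise ValueError(f"op {op.op_id}: variable yield not bound")
    if op.volume_rule == "resuspend_to_reference" and reference_volume is None:
        raise ValueError(f"op {op.op_id}: resuspension needs a reference volume")

    v_out = _volume_out(op, stream_in.volume, reference_volume or 0.0)
    mass_out = stream_in.ha_mass * op.recovery_yield
    conc_out = stream_in.volume * stream_in.ha_conc * op.recovery_yield / v_out

    flow = area = None
    if op.equipment_kind == "centrifuge":
        flow = centrifuge_flow_rate(stream_in.volume)
    elif op.equipment_kind in ("flowthrough_filter", "tangential_ultrafilter"):
        area = membrane_area(stream_in.volume, op.flux_L_per_m2_h or DEFAULT_FLUX)

    trace = OpTrace(
        op_id=op.op_id,
        name=op.name,
        equipment_kind=op.equipment_kind,
        volume_in=stream_in.volume,
        volume_out=v_out,
        conc_out=conc_out,
        mass_in=stream_in.ha_mass,
        mass_out=mass_out,
        recovery_yield=op.recovery_yield,
        flow_rate_L_per_h=flow,
        membrane_area_m2=area,
    )
    return StreamState(v_out, conc_out), trace


def _bind_yields(
    train: ProcessTrain, variable_yields: Sequence[float]
) -> list[UnitOperation]:
    if len(variable_yields) != len(VARIABLE_OPS):
        raise ValueError(f"expected {len(VARIABLE_OPS)} variable yields")
    for y in variable_yields:
        if not 0.0 < y <= 1.0:
            raise ValueError(f"variable yield {y} outside (0, 1]")
    mapping = dict(zip(VARIABLE_OPS, variable_yields))
    return [
        op.bound(mapping[op.op_id]) if op.yield_class == "variable" else op
        for op in train.operations
    ]


def overall_yield(train: ProcessTrain, variable_yields: Sequence[float]) -> float:
    """Product of the ten post-fermentation recovery yields."""
    ops = _bind_yields(train, variable_yields)
    result = 1.0
    for op in ops:
        result *= op.recovery_yield
    return result


def run_batch(
    train: ProcessTrain,
    titer_multiplier: float = 1.0,
    scale: float | None = None,
    variable_yields: Sequence[float] = (1.0,) * 5,
    time_multiplier: float = 1.0,
    dsp_overhead_h_per_op: float = 0.0,
) -> BatchResult:
    """Run one batch through the full train and collect sizing/material data.

    ``time_multiplier`` stretches every operation duration (fermentation and
    downstream) and therefore the batch cadence; sizing keeps the nominal
    1 h basis so that equipment is dimensioned for the design throughput.
    """
    if titer_multiplier <= 0 or time_multiplier <= 0:
        raise ValueError("multipliers must be positive")
    scale = train.scale_L if scale is None else scale
    if scale <= 0:
        raise ValueError("scale must be positive")

    titer = train.titer_g_per_L * titer_multiplier
    ops = _bind_yields(train, variable_yields)

    stream = StreamState(scale, titer)
    ferm_trace = OpTrace(
        op_id=1,
        name="Fermentation",
        equipment_kind="bioreactor",
        volume_in=scale,
        volume_out=scale,
        conc_out=titer,
        mass_in=stream.ha_mass,
        mass_out=stream.ha_mass,
        recovery_yield=1.0,
    )

    trace = [ferm_trace]
    equipment: list[tuple[int, str, float]] = [(1, "bioreactor", scale)]
    vessel_volumes = [scale]
    filter_areas: list[tuple[int, str, float]] = []
    materials_kg: dict[str, float] = {
        name: conc * scale / 1000.0 for name, conc in train.media_g_per_L.items()
    }
    isopropanol_L = 0.0
    buffer_L = 0.0
    duration = train.ferm_duration_h

    for op in ops:
        volume_in = stream.volume
        stream, row = propagate(op, stream, reference_volume=scale)
        trace.append(row)
        duration += op.duration_h + dsp_overhead_h_per_op

        if op.equipment_kind == "stainless_tank":
            equipment.append((op.op_id, "stainless_tank", row.volume_out))
            vessel_volumes.append(row.volume_out)
        elif op.equipment_kind == "centrifuge":
            equipment.append((op.op_id, "centrifuge", row.flow_rate_L_per_h))
        else:
            equipment.append((op.op_id, op.equipment_kind, row.membrane_area_m2))
            filter_areas.append((op.op_id, op.equipment_kind, row.membrane_area_m2))

        if op.liquid_additive is not None:
            # 1:1 volume addition purchased by volume (density applied later).
            isopropanol_L += volume_in
        if op.solid_additive is not None:
            name, dose, basis = op.solid_additive
            basis_volume = volume_in if basis == "volume_in" else row.volume_out
            materials_kg[name] = materials_kg.get(name, 0.0) + dose * basis_volume / 1000.0
        if op.diavolumes:
            buffer_L += op.diavolumes * volume_in

    duration *= time_multiplier
    final_mass = trace[-1].mass_out
    return BatchResult(
        trace=trace,
        final_mass_g=final_mass,
        overall_yield=final_mass / (titer * scale),
        batch_duration_h=duration,
        scale_L=scale,
        titer_g_per_L=titer,
        source=train.source,
        equipment=equipment,
        vessel_volumes=vessel_volumes,
        filter_areas=filter_areas,
        materials_kg=materials_kg,
        isopropanol_L=isopropanol_L,
        diafiltration_buffer_L=buffer_L,
    )


def batches_per_year(batch_duration_h: float, operating_days: int = 200) -> int:
    """Whole batches that fit in the operating year (serial scheduling)."""
    if batch_duration_h <= 0:
        raise ValueError("batch duration must be positive")
    return math.floor(operating_days * 24.0 / batch_duration_h)


def annual_production(
    batch_mass_g: float, batch_duration_h: float, operating_days: int = 200
) -> float:
    """Annual output in kg at the plant's batch cadence."""
    return batches_per_year(batch_duration_h, operating_days) * batch_mass_g / 1000.0
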