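"""Scenario spaces and their evaluation.

Three designs are generated from a :class:`~hatea.fixtures.VariationDesign`:

* the full factorial over the five variable recovery yields
  (5 levels ^ 5 operations = 3,125 vectors);
* the one-at-a-time (OAT) sensitivity design — each of the 27 settings
  (5 titer + 5 capital + 5 time multipliers, 7 scales, 5 discounts, the
  base level included in each list) crossed with every yield vector,
  27 x 3,125 = 84,375 scenarios;
* the simultaneous titer x scale sweep — 175 (titer multiplier, scale)
  pairs, each crossed with every yield vector, 175 x 3,125 = 546,875
  scenarios.  The default pairs form a deterministic 25 x 7 grid
  (titer multipliers log-spaced over [0.1, 10]); a seeded random mode
  draws the 175 pairs uniformly instead.

Evaluation exploits the model's structure: the batch cost is independent
of the variable yields and of the titer multiplier (volume rules, sizing
and material draws depend only on scale and the cost multipliers), so a
whole block of scenarios sharing one cost setting is priced with a single
batch simulation and the CoG/g follows from the per-scenario product mass.
A scalar :meth:`ScenarioEvaluator.evaluate` runs the full per-scenario
path; the two routes agree exactly and are cross-checked in the tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import cost_of_batch
from .fixtures import Fixtures, VariationDesign, build_train, load_study_fixtures
from .process import ProcessTrain, batches_per_year, run_batch

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "yield_factorial",
    "oat_settings",
    "oat_scenarios",
    "titer_scale_sweep",
    "ScenarioEvaluator",
]

YIELD_COLUMNS = ["y_op4", "y_op6", "y_op7", "y_op9", "y_op10"]
SETTING_COLUMNS = [
    "titer_multiplier",
    "capital_multiplier",
    "time_multiplier",
    "scale_L",
    "discount",
]

#: Upstream options carried into the full process model (the least
#: expensive endogenous and recombinant fermentations).
SELECTED_OPTIONS = {"endogenous": 2, "recombinant": 5}


@dataclass(frozen=True)
class ScenarioSpec:
    """One point of the variation space."""

    source: str = "endogenous"
    titer_multiplier: float = 1.0
    capital_multiplier: float = 1.0
    time_multiplier: float = 1.0
    scale_L: float = 100.0
    discount: float = 0.0
    variable_yields: tuple[float, ...] = (1.0,) * 5

    def __post_init__(self):
        if min(self.titer_multiplier, self.capital_multiplier, self.time_multiplier) <= 0:
            raise ValueError("multipliers must be positive")
        if self.scale_L <= 0:
            raise ValueError("scale must be positive")


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    overall_yield: float
    batch_mass_g: float
    annual_kg: float
    cog_per_batch: float
    cog_per_g: float


def yield_factorial(design: VariationDesign) -> np.ndarray:
    """Cartesian product of yield levels over the variable operations.

    Rows are in lexicographic order; shape (levels^ops, ops).
    """
    combos = itertools.product(design.yield_levels, repeat=design.n_variable_ops)
    return np.array(list(combos), dtype=float)


def oat_settings(design: VariationDesign) -> pd.DataFrame:
    """The 27 one-at-a-time cost settings (base levels included)."""
    base = {
        "titer_multiplier": 1.0,
        "capital_multiplier": 1.0,
        "time_multiplier": 1.0,
        "scale_L": design.base_scale_L,
        "discount": 0.0,
    }
    rows = []
    for variable, column, levels in [
        ("titer", "titer_multiplier", design.multiplier_levels),
        ("capital", "capital_multiplier", design.multiplier_levels),
        ("time", "time_multiplier", design.multiplier_levels),
        ("scale", "scale_L", design.scale_levels_L),
        ("discount", "discount", design.discount_levels),
    ]:
        for level in levels:
            row = dict(base, variable=variable)
            row[column] = level
            rows.append(row)
    return pd.DataFrame(rows)[["variable"] + SETTING_COLUMNS]


def _cross_with_yields(settings: pd.DataFrame, yields: np.ndarray) -> pd.DataFrame:
    """Cross join: every setting row with every yield vector."""
    n_settings, n_yields = len(settings), len(yields)
    out = settings.loc[settings.index.repeat(n_yields)].reset_index(drop=True)
    tiled = np.tile(yields, (n_settings, 1))
    for j, col in enumerate(YIELD_COLUMNS):
        out[col] = tiled[:, j]
    return out


def oat_scenarios(design: VariationDesign) -> pd.DataFrame:
    """Full OAT design: 27 settings x 3,125 yield vectors = 84,375 rows."""
    return _cross_with_yields(oat_settings(design), yield_factorial(design))


def titer_scale_sweep(
    design: VariationDesign,
    mode: str = "grid",
    seed: int | None = None,
    titer_spacing: str = "log",
) -> pd.DataFrame:
    """Simultaneous titer x scale sweep crossed with all yield vectors.

    ``grid`` mode pairs ``n_sweep_titers`` log-spaced titer multipliers over
    [min, max multiplier] with every scale level (25 x 7 = 175 pairs);
    ``random`` mode draws the same number of pairs uniformly (titer on a
    log or linear axis per ``titer_spacing``) from the same ranges, seeded.
    """
    lo, hi = min(design.multiplier_levels), max(design.multiplier_levels)
    n_pairs = design.n_sweep_titers * len(design.scale_levels_L)
    if mode == "grid":
        titers = np.geomspace(lo, hi, design.n_sweep_titers)
        pairs = [(t, s) for t in titers for s in design.scale_levels_L]
    elif mode == "random":
        rng = np.random.default_rng(seed)
        if titer_spacing == "log":
            titers = np.exp(rng.uniform(np.log(lo), np.log(hi), n_pairs))
        elif titer_spacing == "linear":
            titers = rng.uniform(lo, hi, n_pairs)
        else:
            raise ValueError(f"unknown titer spacing {titer_spacing!r}")
        s_lo, s_hi = min(design.scale_levels_L), max(design.scale_levels_L)
        scales = rng.uniform(s_lo, s_hi, n_pairs)
        pairs = list(zip(titers, scales))
    else:
        raise ValueError(f"unknown sweep mode {mode!r}")

    settings = pd.DataFrame(pairs, columns=["titer_multiplier", "scale_L"])
    settings["capital_multiplier"] = 1.0
    settings["time_multiplier"] = 1.0
    settings["discount"] = 0.0
    settings = settings[SETTING_COLUMNS]
    return _cross_with_yields(settings, yield_factorial(design))


class ScenarioEvaluator:
    """Prices scenarios for one or both HA sources.

    Holds the base trains (endogenous option 2, recombinant option 5 by
    default) and the economic dataset.  Evaluation is pure: the same spec
    always yields the same result.
    """

    def __init__(self, fixtures: Fixtures | None = None,
                 selected_options: dict[str, int] | None = None):
        self.fixtures = fixtures or load_study_fixtures()
        selected = selected_options or SELECTED_OPTIONS
        self.trains: dict[str, ProcessTrain] = {
            source: build_train(self.fixtures, option_id)
            for source, option_id in selected.items()
        }
        self.econ = self.fixtures.economics

    # -- scalar path -------------------------------------------------------

    def evaluate(self, spec: ScenarioSpec) -> ScenarioResult:
        """Full per-scenario simulation (batch propagation + costing)."""
        train = self.trains[spec.source]
        batch = run_batch(
            train,
            titer_multiplier=spec.titer_multiplier,
            scale=spec.scale_L,
            variable_yields=spec.variable_yields,
            time_multiplier=spec.time_multiplier,
            dsp_overhead_h_per_op=self.econ.assumptions.dsp_overhead_h_per_op,
        )
        cost = cost_of_batch(
            batch, self.econ,
            capital_multiplier=spec.capital_multiplier,
            discount=spec.discount,
        )
        n_batches = batches_per_year(
            batch.batch_duration_h, self.econ.assumptions.operating_days
        )
        return ScenarioResult(
            spec=spec,
            overall_yield=batch.overall_yield,
            batch_mass_g=batch.final_mass_g,
            annual_kg=n_batches * batch.final_mass_g / 1000.0,
            cog_per_batch=cost.total,
            cog_per_g=cost.cog_per_g,
        )

    # -- vectorised path ---------------------------------------------------

    def evaluate_frame(self, scenarios: pd.DataFrame, source: str) -> pd.DataFrame:
        """Evaluate a scenario table; returns it with result columns added.

        The input needs the five setting columns (missing ones are filled
        with base values) and the five yield columns.  The batch cost of a
        scenario does not depend on its yields or titer multiplier, so each
        unique cost setting is simulated once and the per-gram costs are
        broadcast over the block.
        """
        train = self.trains[source]
        out = scenarios.reset_index(drop=True).copy()
        for col, default in zip(SETTING_COLUMNS, (1.0, 1.0, 1.0, 100.0, 0.0)):
            if col not in out.columns:
                out[col] = default

        yields = out[YIELD_COLUMNS].to_numpy()
        variable_product = yields.prod(axis=1)
        fixed_product = 1.0
        for op in train.operations:
            if op.yield_class == "fixed":
                fixed_product *= op.recovery_yield
        out["overall_yield"] = fixed_product * variable_product

        cog_batch = np.empty(len(out))
        annual_batches = np.empty(len(out))
        cost_cols = ["capital_multiplier", "time_multiplier", "scale_L", "discount"]
        for key, block in out.groupby(cost_cols, sort=False):
            cap_mult, time_mult, scale, discount = key
            batch = run_batch(
                train,
                titer_multiplier=1.0,
                scale=scale,
                variable_yields=(1.0,) * 5,
                time_multiplier=time_mult,
                dsp_overhead_h_per_op=self.econ.assumptions.dsp_overhead_h_per_op,
            )
            cost = cost_of_batch(
                batch, self.econ, capital_multiplier=cap_mult, discount=discount
            )
            n_batches = batches_per_year(
                batch.batch_duration_h, self.econ.assumptions.operating_days
            )
            cog_batch[block.index] = cost.total
            annual_batches[block.index] = n_batches

        titer = train.titer_g_per_L * out["titer_multiplier"].to_numpy()
        mass = titer * out["scale_L"].to_numpy() * out["overall_yield"].to_numpy()
        out["source"] = source
        out["titer_g_per_L"] = titer
        out["batch_mass_g"] = mass
        out["annual_kg"] = annual_batches * mass / 1000.0
        out["cog_per_batch"] = cog_batch
        out["cog_per_g"] = cog_batch / mass
        return out
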