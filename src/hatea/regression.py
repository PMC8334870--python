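"""Regression summary of the sweep and the endogenous/recombinant contrast.

The simultaneous sweep is summarised by an ordinary least-squares fit

    CoG/g [USD] = b0 + b1 * titer [g/L] + b2 * overall yield [%] + b3 * scale [L]

The response surface is strongly nonlinear (roughly hyperbolic in each
driver), so the fit is a deliberately crude summary: the coefficient
magnitudes rank how hard each variable pulls on the CoG/g over the design
region, and their signs record the direction.  Yield enters the model as a
fraction internally and is reported per percentage point.

The break-even analysis asks how far the recombinant fermentation titer
must rise for its CoG/g to match endogenous production at the base
scenario (1X multipliers, 100 L, no discount), and answers by bisection on
the titer multiplier after verifying that CoG/g is decreasing in titer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scenarios import ScenarioEvaluator, ScenarioSpec

__all__ = [
    "RegressionResult",
    "BreakEvenResult",
    "fit_cog_regression",
    "break_even_titer",
    "compare_sources",
]

ALPHA = 0.01


@dataclass(frozen=True)
class RegressionResult:
    """OLS coefficients of the CoG/g summary plane.

    b2 is expressed per percentage point of overall recovery yield.
    """

    beta0: float
    beta1_titer: float
    beta2_yield_pct: float
    beta3_scale: float
    pvalues: dict[str, float]
    significant: dict[str, bool]
    r_squared: float
    n_obs: int

    @property
    def slopes(self) -> dict[str, float]:
        return {
            "titer": self.beta1_titer,
            "yield": self.beta2_yield_pct,
            "scale": self.beta3_scale,
        }


@dataclass(frozen=True)
class BreakEvenResult:
    break_even_multiplier: float | None
    reference_cog_per_g: float
    bracket: tuple[float, float]
    rel_tolerance: float
    n_iterations: int

    @property
    def found(self) -> bool:
        return self.break_even_multiplier is not None


def fit_cog_regression(results: pd.DataFrame) -> RegressionResult:
    """Fit the linear CoG/g summary to evaluated sweep results.

    ``results`` needs ``titer_g_per_L``, ``overall_yield`` (fraction) and
    ``scale_L`` regressors plus the ``cog_per_g`` response; at least four
    distinct design points are required.
    """
    needed = ["titer_g_per_L", "overall_yield", "scale_L", "cog_per_g"]
    missing = set(needed) - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns {sorted(missing)}")
    X = results[["titer_g_per_L", "overall_yield", "scale_L"]].to_numpy(float)
    X[:, 1] *= 100.0  # fraction -> percent
    if len(np.unique(X, axis=0)) < 4:
        raise ValueError("need at least 4 distinct design points")
    y = results["cog_per_g"].to_numpy(float)

    model = sm.OLS(y, sm.add_constant(X)).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    names = ["const", "titer", "yield", "scale"]
    pvalues = {k: float(p) for k, p in zip(names, model.pvalues)}
    return RegressionResult(
        beta0=float(model.params[0]),
        beta1_titer=float(model.params[1]),
        beta2_yield_pct=float(model.params[2]),
        beta3_scale=float(model.params[3]),
        pvalues=pvalues,
        significant={k: bool(p < ALPHA) for k, p in pvalues.items()},
        r_squared=float(model.rsquared),
        n_obs=int(model.nobs),
    )


def break_even_titer(
    evaluator: ScenarioEvaluator,
    source: str = "recombinant",
    reference_source: str = "endogenous",
    base_spec: ScenarioSpec | None = None,
    bracket: tuple[float, float] = (0.1, 10.0),
    rel_tolerance: float = 1e-6,
    max_iterations: int = 200,
) -> BreakEvenResult:
    """Titer multiplier at which ``source`` matches the reference CoG/g.

    The reference is the ``reference_source`` evaluated at ``base_spec``
    (default: 1X multipliers, 100 L, 0% discount, all yields 100%).
    Bisection runs until the CoG/g gap is below ``rel_tolerance`` relative
    to the reference.  If CoG/g never crosses the reference inside the
    bracket the result reports no break-even (multiplier ``None``).
    """
    base_spec = base_spec or ScenarioSpec()
    reference = evaluator.evaluate(replace(base_spec, source=reference_source))
    ref_cog = reference.cog_per_g

    def gap(multiplier: float) -> float:
        spec = replace(base_spec, source=source, titer_multiplier=multiplier)
        return evaluator.evaluate(spec).cog_per_g - ref_cog

    lo, hi = sorted(bracket)
    f_lo, f_hi = gap(lo), gap(hi)
    if f_lo < f_hi:
        raise ValueError("CoG/g must be decreasing in the titer multiplier")
    if f_lo < 0 or f_hi > 0:
        return BreakEvenResult(None, ref_cog, (lo, hi), rel_tolerance, 0)

    iterations = 0
    while iterations < max_iterations:
        mid = 0.5 * (lo + hi)
        f_mid = gap(mid)
        iterations += 1
        if abs(f_mid) < rel_tolerance * ref_cog:
            return BreakEvenResult(mid, ref_cog, (lo, hi), rel_tolerance, iterations)
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    return BreakEvenResult(0.5 * (lo + hi), ref_cog, (lo, hi), rel_tolerance, iterations)


def compare_sources(
    evaluator: ScenarioEvaluator, spec: ScenarioSpec | None = None
) -> dict[str, object]:
    """Evaluate both sources under identical conditions.

    Returns both :class:`ScenarioResult` objects plus the CoG/g difference
    (endogenous minus recombinant) and ratio (endogenous / recombinant).
    """
    spec = spec or ScenarioSpec()
    endo = evaluator.evaluate(replace(spec, source="endogenous"))
    rec = evaluator.evaluate(replace(spec, source="recombinant"))
    return {
        "endogenous": endo,
        "recombinant": rec,
        "delta_cog_per_g": endo.cog_per_g - rec.cog_per_g,
        "ratio_cog_per_g": endo.cog_per_g / rec.cog_per_g,
    }
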