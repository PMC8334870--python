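# Methods

## Scope and intent

`hatea` models the production economics of hyaluronic acid (HA) from two
sources — the natural producer *Streptococcus equi* subsp. *zooepidemicus*
and recombinant hosts — through one shared recovery train. It is a
decision-support model, not an accounting tool: the absolute dollar values
depend on facility assumptions that published data do not pin down, so the
model's reliable outputs are *relative* and *structural* — which variables
dominate the cost, where the break-even between sources sits, how the cost
surface bends over titer, scale and yield.

## Process model

The stream state is (volume L, HA concentration g/L, HA mass g), with
mass ≡ volume × concentration enforced to 1e-9 relative. Operation 1 is
the fermentation of the selected upstream option; operations 2–11 are the
recovery train (dilution, biomass removal, isopropanol precipitation,
precipitate recovery, sodium-acetate resuspension, silica-gel polish,
silica removal, activated-carbon filtration, ultra/diafiltration, sterile
filtration). Each applies a recovery yield to mass and a volume rule to
the liquid; concentration is recomputed from the balance. Consequences the
test-suite relies on:

* the final batch mass is exactly titer × scale × overall yield, whatever
  the intermediate volumes do;
* the overall yield is the plain product of the ten downstream yields
  (0.95·0.90·X₄·0.90·X₆·X₇·0.90·X₉·X₁₀·0.95), giving the 0.02%–66% span
  when the five variable yields sit on the {20..100}% grid.

Sizing: centrifuge flow = feed volume / 1 h; membrane area = feed volume /
(4 L m⁻² h⁻¹ × 1 h). Sizing always uses the nominal 1 h basis — the
process-time multiplier stretches the schedule (and therefore capital
amortisation per batch) but does not shrink the equipment, which remains
dimensioned for design throughput.

Choices where the source data is silent:

* **Resuspension volume (op 6)** defaults to one fermentation volume,
  restoring the concentration to a comparable basis; the ratio is
  configurable.
* **Op 10** runs at a 1X concentration factor (volume unchanged) and
  consumes 5 diavolumes of buffer, tracked as a quantity only (buffer
  water is not costed).
* **Batch duration** = fermentation + 10 × 1 h downstream; prep/clean
  time is off the product path by default, with a configurable
  `dsp_overhead_h_per_op` for stricter readings. Batches are serial (no
  USP/DSP overlap, no turnaround time).
* **Option 2's biphasic feed schedule** is collapsed to a single 20 h
  fermentation at the reported 6.6 g/L final titer; media cost uses the
  printed initial concentrations (no feed totals are published).

## Economics

Per batch: `total = (capital + materials + consumables) / (1 − 0.15)`,
with labor the remaining 15% — a standard aggregate for bioprocesses of
this class. CoG/g divides by the final batch mass.

* **Capital**: purchased-equipment cost from the published regression
  curves (bioreactor 34,854·V^0.4058; centrifuge 426,720·(Q/600)^0.4;
  tank 42.195·V + 3,052.2; flow-through holder 2,229.6·A^0.4539; UF skid
  91,036·A^0.3741), times a facility factor, amortised straight-line over
  the plant life. Amortisation uses *fractional* batches per year
  (operating hours / batch duration) so the charge is smooth in process
  time; the whole-batch `floor` applies only to saleable annual output
  (200 operating days/year).
* **Materials**: media at bulk catalogue prices (USD/kg), isopropanol by
  density (0.785 kg/L) on the 1:1 added volume, sodium acetate at 30 g/L
  of resuspension volume, silica gel at 3% w/v of the feed to the polish
  step. The bulk-discount variable scales this component only. The
  dilution water is free. Na₂HPO₄·12H₂O is priced at the anhydrous
  catalogue entry (no hydrate price is published).
* **Consumables**: single-use vessel inlet filters (0.3058·V + 45.334 USD
  each); membrane consumables at 575 USD/m² (flow-through cartridges) and
  4,621 USD/m² (UF cassettes), linear in area and amortised over a reuse
  lifetime (default 100 batches). Charging a full cassette per batch is
  not credible — it would make consumables ~90% of the cost of goods and
  put the base cost an order of magnitude above any published figure for
  this process class; membrane reuse over 50–100 cycles is standard
  practice.
* **Excluded**: utilities/energy, GMP or biosafety facility premiums,
  clinical trials, packaging/distribution, taxes. These are absorbed by
  the calibration (below) or explicitly out of scope.

### Calibrated defaults

Two economic parameters are not observable from published data: the
facility factor (installed capital / purchased equipment) and the
depreciation horizon. Classic Lang factors for fluid-processing plants
span roughly 3–6; bioprocess facilities sit at the high end. The package
calibrates once against the qualitative structure this process class is
known to exhibit — capital-dominant cost at the 100 L base, bioreactor
scale as the highest-impact variable followed by titer, base CoG/g of
order tens of USD/g — and freezes **facility factor 6.0, depreciation
10 years, membrane lifetime 100 batches**. Under these defaults the base
endogenous CoG/g computes to ≈$29.9/g, the impact ranking is scale >
titer > capital ≈ time > discount for both sources, and the break-even
titer multiplier is ≈1.40. The regression's all-negative slope pattern is
insensitive to the facility factor across {2, 4, 6}; the scale-vs-titer
ranking flips below ≈5, which is why the ranking is asserted only under
the documented defaults.

## Scenario engines

* **Yield factorial**: Cartesian product of the 5 yield levels over the 5
  variable operations, in lexicographic order (3,125 vectors).
* **OAT design**: 27 settings — 5 titer + 5 capital + 5 time multipliers,
  7 scales, 5 discounts, each list containing its base level so duplicate
  base scenarios are kept and the 27 × 3,125 = 84,375 arithmetic holds —
  each crossed with all yield vectors. Impacts are max − min CoG/g per
  (variable, overall-yield value); yield "bins" are the exact distinct
  products, since yields live on a grid. The ranking is computed at the
  all-100% yield vector, ties broken alphabetically.
* **Titer × scale sweep**: default is a deterministic grid (25 log-spaced
  titer multipliers over [0.1, 10] × 7 scales = 175 pairs) so the
  546,875-scenario count is exactly reproducible; a seeded random mode
  draws the 175 pairs uniformly instead (titer on a log axis by default,
  linear available). Each pair crosses all 3,125 yield vectors.

Evaluation exploits structure: batch cost is independent of the variable
yields and the titer multiplier, so each unique cost setting is simulated
once and broadcast over its yield block. The scalar per-scenario path is
retained and cross-checked against the vectorised path to 1e-12 in the
tests. The full pipeline (all stages, both sources) runs in well under a
minute on one CPU; the desk-scale problem sizes are the full published
design sizes.

## Regression and break-even

The sweep is summarised by OLS: CoG/g on titer (g/L), overall yield
(internally a fraction, reported per percentage point) and scale (L). The
surface is strongly hyperbolic, so R² is low by construction; the fit is
used only for the sign pattern and the magnitude ranking |β_yield| >
|β_titer| > |β_scale|, which hold on the default sweep for both sources.
Coefficients are labelled β₁ titer, β₂ yield, β₃ scale.

Break-even: with costs fixed, CoG/g is proportional to 1/titer, so the
crossing with the endogenous base reference (1X, 100 L, 0% discount,
yields 100%) is unique; bisection on [0.1, 10] runs until the CoG/g gap is
below 1e-6 of the reference. Degenerate cases (no sign change in the
bracket) are reported as "no break-even", never extrapolated.

## What the tests do and do not show

All inputs are the published study values shipped with the package; there
is no measured data. Passing tests therefore demonstrate internal
consistency (mass balance, count identities, monotonicity, oracle
equivalence between independent code paths) and that the calibrated model
reproduces the qualitative economics of the process class — not that the
dollar values predict any real facility. Known limitations: no kinetic
fermentation model, no molecular-weight tracking, no scheduling overlap,
no utilities, and single-point prices with a crude linear discount.
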