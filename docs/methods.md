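# Methods

## Assay model

The pipeline analyses a phenotypic screen in which macrophage-like cells
carrying a gain-of-function NLRP3 mutation secrete IL-1β on LPS priming
alone. IL-1β is the target readout; IL-6, which is induced by LPS through
NF-κB independently of the inflammasome, is the counter-screen: a compound
that suppresses (or boosts) both cytokines is acting upstream of the
inflammasome, nonspecifically, or by killing the cells, and is not a
selective inflammasome inhibitor.

Cytokines are measured by a homogeneous time-resolved FRET (HTRF)
immunoassay read as two emission channels; the analyte-tracking signal is
the ratio `10000 × Em665/Em620`. Working on the ratio cancels well-to-well
variation in donor loading and excitation; percent inhibition then cancels
plate-to-plate variation in absolute signal, because each compound well is
normalized to its own plate's control means:

    inhibition% = 100 · (μ_hc − x) / (μ_hc − μ_lc)

with μ_hc / μ_lc the means of the stimulated and unstimulated DMSO control
wells of the same plate and analyte. 0 % is "no effect", 100 % is "signal
reduced to background", and negative values are enhancement. The exact
normalized form was an open choice; this one is the standard in plate-based
screening and maps naturally onto a −100..100 display range.

## Control statistics and outliers

Each 384-well plate carries 16 high and 16 low controls per analyte.
Control means for *normalization* are cleaned by a single outlier pass:
mean and SD (n−1 denominator throughout) are computed on all 16 values,
values outside mean ± 3 SD are excluded, and the statistics are recomputed
once. The pass is not iterated — with 16 points, iterated 3-sigma trimming
can cascade — and re-running it on the cleaned set is a tested no-op for
the fixtures used.

Plate *quality* metrics intentionally use the uncleaned statistics, so that
Z′ and S/B describe the assay as it performed, outliers included:

    Z′ = 1 − (3σ_hc + 3σ_lc) / (μ_hc − μ_lc)        S/B = μ_hc / μ_lc

A plate passes QC when Z′ strictly exceeds 0.5 (the conventional
"excellent assay" cut). Failing plates are flagged and reported; excluding
their compounds from triage is a config switch (`exclude_failing_plates`),
off by default.

## Triage cascade

Stages, in order, on the 1 μM primary-screen data (defaults in
parentheses; all configurable and echoed in the manifest):

1. keep IL-1β inhibition strictly above the threshold (30 %);
2. exclude |IL-6 %| above the band (50 %) — enhancement excludes as well
   as inhibition, and the band is looser than the IL-1β cut because the
   IL-6 assay window (S/B ≈ 4.3 vs 9.0) is narrower;
3. exclude annotated steroids (broad anti-inflammatories);
4. collapse each duplicate group to its strongest IL-1β inhibitor.

Stages 1 and 2 are per-compound predicates, so their order cannot change
the selected set (property-tested); the order shown is kept for the stage
counts to read as a cascade. Ties at either printed cut-off fall on the
excluded side (strict inequalities). Every compound receives exactly one
terminal category, and categories partition the input — the conservation
invariant checked on every fixture.

The IL-6 band of 50 % and the confirmation predominance rule are genuinely
under-determined by any published account; both are therefore explicit
configuration with conservative defaults rather than constants, and the
downstream cascade counts are treated as configurable outcomes, not as
reproduction targets.

## Dose–response confirmation

Responses at five half-log doses (0.1–10 μM, 4 replicate wells each, all
configurable) are fitted per compound and analyte with the increasing
four-parameter logistic

    r(d) = bottom + (top − bottom) / (1 + (IC50/d)^h)

by least squares in log10-dose space over all replicate points.
Initialization: bottom/top at the extreme mean responses, IC50 at the dose
nearest the half-maximal mean, h = 1. Bounds: IC50 within
[min dose/10, max dose×10], h in [0.1, 10], plateaus in ±1000 %.
Numerical fallbacks, in order: a mean-response range under 10 percentage
points is flagged flat (no IC50); a fit pinned to the IC50 bound is
degenerate (no plateau inside the dose range) and reverts, like an
optimizer failure, to the model-free 50 % crossing of the mean curve
interpolated linearly in log-dose. The `method` field records which route
produced each IC50.

A dose shows *predominant* IL-1β inhibition when the mean IL-1β response
exceeds the mean IL-6 response by ≥ 30 points and itself reaches ≥ 30 %
(margin and floor mirror the primary-screen threshold; both configurable).
A compound is confirmed when IL-1β IC50 < 10 μM (strict) and ≥ 2 doses are
predominant; the first failing rule is the recorded rejection reason.

## Synthetic screens

The generator emulates the screen's geometry: 16 plates × 384 wells, 16
high + 16 low controls per plate (placed in the last two columns by the
generator, but consumers take the layout from the plate map, never from
geometry), 4,825 compounds at 1 μM filling 352 compound wells per plate
sequentially, trailing wells empty. Per well and analyte the target ratio is

    ratio = μ_lc + (1 − f)·(μ_hc − μ_lc) + Normal(0, σ)

where f is the compound's true fractional inhibition (0 for high controls,
1 for low controls) and σ is the matching control SD — σ_hc for stimulated
wells (high controls and compound wells), σ_lc for low controls. The ratio
is floored at 0 (counts cannot be negative). The emission channels are then
emitted as em620 ~ Normal(20000, 1000) truncated positive and
em665 = ratio·em620/10000, so the analysis recovers the ratio exactly.

Default calibration (ratio units): IL-1β μ_hc = 8980, μ_lc = 1000,
σ_hc = 450, σ_lc = 160 → population Z′ = 0.771, S/B = 8.98; IL-6
μ_hc = 4290, μ_lc = 1000, σ_hc = 430, σ_lc = 150 → Z′ = 0.471, S/B = 4.29.
These are chosen so an excellent-window target assay and a narrower
counter-assay emerge from the closed-form statistics; with 16 controls per
group the across-plate mean of the *sample* Z′ sits within a few thousandths
of the population value (small upward bias from E[s] < σ at n = 16, checked
by Monte Carlo).

Compound effects: inactive (f = 0); selective inhibitor (IC50 log-uniform
on 0.05–0.6 μM, hill 1, IL-6 untouched — the upper end keeps true 1 μM
inhibition ≥ 62 %); nonspecific inhibitor (same f on both cytokines);
enhancer (f = −0.5 both); cytotoxic (f = 0.9 both, apparent inhibition
through cell death). Default mixture: 94 % inactive, 1 % selective, 2 %
nonspecific, 1 % enhancer, 2 % cytotoxic; `deterministic_classes` makes the
counts exact (largest-remainder rounding) for recovery tests, and
`planted_screen_config(n_selective=50)` is the spike-in design used for the
planted-hit benchmark: exactly 50 selective inhibitors among otherwise
inactive compounds. One numpy Generator seeded from the config drives every
draw; outputs are bit-identical under a fixed seed, and each manifest
records the seed and a config hash.

What the generator does *not* emulate: spatial artefacts (edge effects,
dispense gradients — an optional log-normal plate-effect multiplier exists
for robustness testing but is off by default), non-Gaussian well noise,
compound fluorescence interference, and partial-efficacy curves
(top < 100 %). Tests passing on these simulations therefore validate the
decision logic and its calibration, not robustness to real-plate artefacts,
which the pipeline deliberately does not correct (no B-score or positional
normalization).

## Problem sizes

The test suite runs the full study-scale configuration (16 plates, 4,825
compounds, both cytokines) for the end-to-end and recovery checks — the
screen is small enough that nothing needs scaling down — plus 100-replicate
fit-recovery and 600-plate Monte-Carlo studies; the whole suite completes
in a few seconds.

## Known limitations

- The percent-inhibition formula and the cleaned-versus-raw control choice
  for normalization follow the standard reading of the assay description;
  the cleaned choice for normalization (and raw for QC) is the one
  consistent with flagging control outliers "except when" computing
  Z′/S-B, but no published formula settles it.
- IC50s carry no confidence intervals (no profile likelihood/bootstrap),
  and the 4PL is the only curve model (no 5PL asymmetry).
- The workbook reader matches headers heuristically; a spreadsheet with
  entirely unrecognizable column names is rejected rather than guessed at.
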