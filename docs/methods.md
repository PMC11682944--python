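# Methods

## Dietary risk quotients

The risk stage scores each pesticide compound detected in a pooled apiary
sample against acute and chronic oral toxicity endpoints. Daily dietary
intake per adult worker is the two-matrix sum

I = C_nectar × 140×10⁻⁶ kg/bee/day + C_pollen × 9.6×10⁻⁶ kg/bee/day,

with residue concentrations C in µg/kg. RQ_acute = I / LD50 (acute oral,
µg/bee); RQ_chronic = I / endpoint (chronic 10-day LC50 or LDD50,
µg/bee/day). The formula is linear, so RQs are homogeneous of degree 1 in
the residues and antitone in the endpoint; both properties are asserted in
the test suite, and site-level results are cross-checked against an
independent brute-force per-record recomputation.

Scoping and conventions:

- A (site, year, time point, compound) group is scored only if at least one
  matrix record is a detection (`detected` or `below_loq`). A table with no
  detections yields an empty result set, not zeros.
- Non-detects contribute zero exposure under the default `zero` censoring
  policy. A `half_lod` policy substitutes LOD/2 for censored records; it
  requires a per-compound LOD mapping because the residue CSV stores only
  concentrations and censoring flags.
- A matrix that was not sampled is treated as residue 0 — in a pooled design
  it is indistinguishable from a non-detect.
- When both chronic endpoints exist the smaller one is used by default
  (`min` policy: conservative, larger RQ), overridable per compound or
  globally (`lc50` / `ldd50`).
- Detected compounds without a usable endpoint are collected in a
  skipped-compounds report instead of aborting the run.
- Threshold comparison is strict (`RQ > threshold`) against the levels of
  concern 0.4 (acute cage), 0.2 (acute field) and 0.03 (chronic); boundary
  equality is reported as a non-exceedance. Exceedance counts are distinct
  sites per compound, a site counting once however many time points exceed.
- Total RQ per (site, year, time point) sums the per-compound RQs of one
  kind in a fixed sort order (effects treated as additive); groups without
  results are absent rather than zero.

Near-vs-far hypothesis testing (GLM/GLMM fits) is deliberately out of scope;
the package produces the RQ tables such fits would consume.

## Synthetic residue surveys

The generator emulates the structure of a two-year near/far field study:
10 sites within the foraging radius of the focal crop and 10 beyond it, two
sampling time points (T2, mid-bloom; T3, end of bloom), two matrices
(pollen, nectar), one pooled sample per apiary, and ~20 compounds. Each
record is drawn independently: a Bernoulli detection (per-compound
`detection_prob`), then a lognormal concentration with per-matrix log-mean
and log-sd, multiplied by `far_site_multiplier` at far sites, then censored
against the compound's LOD/LOQ (below LOD → stored 0 and flagged
`below_lod`; between LOD and LOQ → value kept, flagged `below_loq`).
Non-detects are stored as 0 with a flag, rather than as missing, because the
risk stage treats them as zero exposure.

Default parameters: 20 compounds with detection frequencies mirroring a
typical survey (ubiquitous fungicides near 0.4–0.6, most others below 0.1),
log-sd 0.9 throughout, LOD 0.1 / LOQ 0.5 µg/kg, and the two systemic
neonicotinoids elevated at far sites (multipliers 3–4) with log-means placed
so far-site chronic RQs straddle the 0.03 level of concern while acute RQs
stay below 0.2 — the qualitative pattern such surveys report. The default
seed is 2021; a fixed seed makes the emitted CSV byte-identical across runs.

A `planted` list can deterministically overwrite chosen
(compound, site, matrix, time point) records with a specified concentration.
Exact exceedance patterns (e.g. a chronic exceedance at exactly 8 of 20
sites) are impossible to guarantee from a stochastic draw; planting makes
them constructible for validation.

What the generator does *not* emulate: spatial correlation among sites,
within-season temporal correlation between T2 and T3, correlated occurrence
of compounds applied together, or matrix-specific censoring limits. Passing
tests therefore demonstrate correctness of the computation chain, not
calibration to any real landscape.

The packaged toxicity reference covers the 20 default compounds with
synthetic placeholder endpoints (so labelled in `source_note`): acute LD50s
at realistic orders of magnitude per chemical class (~0.004–0.005 µg/bee for
the neonicotinoids, ~0.05–3 for organophosphates, ~50–200 for fungicides and
herbicides), chronic endpoints only for clothianidin and thiamethoxam —
chronic dietary risk assessment typically focuses on the systemic
neonicotinoids. Real analyses must substitute a literature-sourced table.

## Colony profit model

Per-colony seasonal profit: π = (1 − h)·P·Q + RF − (Cop + Crep). The health
variable h ∈ [0, 1] scales honey revenue only (not the rental fee),
representing indirect behavioural/physiological impairment; h = 0 is no
indirect impact and h = 1 total loss of honey productivity. Defaults
(pound basis): P = $8.42/lb, Q = 59 lbs full crop, RF = $124, Cop = $400,
Crep = $240 (package), $55 (split + purchased queen) or $28.75 (split +
in-house queen).

Numerical choices:

- All currency arithmetic is `decimal.Decimal`; results are quantized to the
  cent with half-up rounding. No binary-float drift can appear in printed
  dollar values.
- The computation basis is $/lb × whole pounds. The equivalent metric values
  ($18.56/kg × 27 kg) are rounded display figures and do not reproduce the
  cent-exact results ($18.56 × 27 = $501.12 ≠ $8.42 × 59 = $496.78).
- Direct yield effects: sublethal exposure manifesting in early summer cuts
  the crop 30 % (the colony is impaired all season), in fall 7 %; a colony
  that dies in fall is assumed to have produced 18.5 % less (the midpoint)
  before failing; a colony that dies in early summer produces nothing.
  Reduced yields are rounded half-up to whole pounds *before* revenue is
  computed (41, 55, 48 lbs at the defaults) — cent-exact reproduction of the
  reference figures requires whole-pound rounding.
- Replacement cost is charged identically whether the colony dies in summer
  or fall (a split costs the same labor either way; a package is bought at
  the spring market price).
- Break-even health h* = 1 − (Cop + Crep − RF)/(P·Q), reported to 4 decimals
  (half-up). The exact root zeroes profit identically; the 4-decimal value
  can leave a residual up to P·Q × 5×10⁻⁵ (≈ one cent at the defaults), so
  the solver exposes `rounded=False` for the exact value. Sentinels: a cell
  unprofitable even at h = 0 reports "none (<0)"; one profitable even at
  h = 1 reports "any". Break-even is undefined (an error) when honey revenue
  is zero, and not reported for the baseline (no pesticide effect) or the
  early-summer lethal cells (h is pinned at 1 there: the colony is dead).

The scenario grid evaluates the baseline plus timing × effect × replacement
cells at h = 0 and h = 1 with the break-even h per cell. The sensitivity
analysis re-evaluates the grid under single-parameter (ceteris paribus)
overrides: honey output at 10/50/90 % of the full crop (6, 30, 53 lbs — a
fraction override replaces the effective yield with round(base × fraction)
in every cell whose baseline yield is nonzero, while an early-summer-lethal
colony still yields nothing), rental fee reduced to $62 or $93, and
replacement via split with an in-house queen ($28.75).

Mapping risk to scenarios: the pipeline flags a site for scenario evaluation
when any chronic RQ there exceeds 0.03 (chronic exceedance is taken to imply
likely colony mortality plus sublethal effects on survivors). The mapping of
an exceedance to a specific h value is left to the user, since no empirical
dose-response for h exists; the profit-vs-h curve (`profit_curve`, linear
with slope −P·Q) supports reading off outcomes for any assumed h.

## Pipeline and reproducibility

One `RunConfig` drives a full run (synthetic or CSV input mode). Outputs are
unit-labelled CSVs plus a JSON run summary embedding a SHA-256 hash of the
analytical configuration (output location and log level excluded), the
package version, the flagged-site list and the headline profit figures, so a
single artifact carries everything a downstream check needs. Any stage
failure writes a `FAILED.json` marker naming the stage before re-raising.
Fixed seed + fixed config ⇒ byte-identical tables and an identical summary.

Problem sizes throughout (20 sites × 2 years × 2 time points × 2 matrices ×
20 compounds = 3 200 records per synthetic survey; a 1 300-site single-
compound table for the Monte-Carlo check of the far-site multiplier) were
chosen so the full test suite and the acceptance script each complete in
seconds; the profit results are closed-form and independent of any seed.

## Known limitations

- Placeholder toxicity endpoints: RQ magnitudes from the packaged reference
  are structurally realistic but not literature values.
- Additivity of total RQs ignores synergistic mixture toxicity.
- The profit model is single-colony, single-season: no portfolio effects,
  no overwintering dynamics, no stochastic mortality, no queen-rearing
  economics beyond the three replacement-cost constants.
- h is an exogenous scalar; the model does not infer it from RQ magnitudes.
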