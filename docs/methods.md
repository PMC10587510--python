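# Methods

## Data model and censoring

Concentration tables are tidy records `(sample, compartment, element,
state, value, unit)` over a fixed 29-element ICP-MS panel and three
compartments: raw tobacco, combustion ash, bowl water. A cell is
*observed*, *censored* (`<LOD`, the stored value being the detection
limit), or *missing* (not reported). ppm/ppb are interpreted as
mass-per-mass for solids and mass-per-volume for water — the only
physically coherent reading for a bowl-water sample — and normalization
brings every solid record to mg/kg and every water record to mg/L,
scaling LODs identically.

Censored cells enter sums by substitution: **0** (default), **LOD/2**, or
**LOD**. Zero is the default because totals and macro-element shares
computed that way reproduce the bundled study's printed percentages to
one decimal; half-LOD is the conventional sensitivity variant, and the
two bracket the truth (`lod` ≥ `half_lod` ≥ `zero`, element-wise, an
invariant the tests assert). Missing cells are excluded from every sum —
with no replicate information there is no defensible imputation.

The bundled fixtures are transcriptions of a published five-tobacco
study. A few printed rows run adjacent columns' digits together; the
transcription adopts the unique split that keeps each value inside its
column's cross-sample range, and marks the genuinely ambiguous cells
(`note=low_confidence`). No headline number depends on those cells. Two
printed raw-tobacco share percentages (Blueberry, Orange) are not
consistent with their own concentration rows and are therefore not used
as checks anywhere.

## Composition shares

Per (sample, compartment): total concentration, per-element fractions of
the total over non-missing elements, and the joint percentage of the five
macro-elements Ca, K, Na, Mg, P. Shares are computed on mass
concentrations (not moles) at full precision; display rounding is
one decimal, half away from zero. Trace elements reported in ppb enter
after normalization, so As/Cd/Hg contribute at the mg/kg scale.

## Mass balance

The smoke burden is defined by difference: whatever left the raw charge
and is in neither the ash nor the water is attributed to smoke. The
subtraction is made dimensionally coherent through three session
parameters — ash yield *y* (mass fraction), bowl-water volume *V* (L),
tobacco charge *m* (kg) — because concentrations in three different
matrices (mg/kg, mg/kg, mg/L) cannot be subtracted directly. These
parameters are **required inputs with no defaults**: the fixture study
reports none of them, so any partition of that data is conditional on
user-stated values (a commented example YAML ships with the package, its
values labelled as assumptions: y = 0.25, V = 0.8 L, m = 15 g). For the
same reason the package makes no claim of reproducing the study's printed
smoke-percentage table, which is under-determined by its printed inputs.

Differences outside [0, 100] % (possible under measurement noise, e.g.
ash concentrations exceeding raw) are clipped and flagged, never silently
propagated. Censoring substitution happens before balancing; a raw cell
that is zero or missing after substitution makes the smoke share
undefined and the row is skipped and logged rather than divided by zero.

## Risk indices

CDI = CF·IR·EF·ED / (BW·AT), HQ = CDI/RfD (flag strictly above 1),
CR = CDI·CSF, banded: negligible iff CR ≤ 1×10⁻⁶ (boundary inclusive),
high iff CR > 1×10⁻⁴, tolerable between. AT is in days so EF·ED (days)
matches. All three indices are homogeneous of degree 1 in CF; the band
map is monotone — both are asserted as properties.

Exposure scenarios are mandatory configuration. The example scenario
(IR 10 g/day, EF 365 d/y, ED 30 y, BW 70 kg, AT 70 y × 365 d) is a
plausible habitual-smoker profile, labelled an assumption. Elements whose
toxicity entry is absent ("ND") yield `not_applicable`, never a zero
risk. The CF source is either the raw-tobacco concentration or, more
realistically for inhalation, the raw concentration scaled by the
mass-balance smoke fraction.

## Group comparisons

The Friedman statistic is implemented from first principles (within-block
mid-ranks, rank-sum formula, tie correction 1 − Σ(t³−t)/(n(k³−k))); an
all-tied design returns Q = 0 with a degeneracy flag. p-values are χ²
(df = k−1) or exact by enumerating all (k!)ⁿ within-block orderings for
n·k ≤ 12. Tests verify the statistic against both an independent
brute-force oracle and `scipy.stats.friedmanchisquare` (scipy defines it
only for k ≥ 3; k = 2 is covered by the oracle). Note the χ²
approximation is poor at these tiny n away from the tail — on 4×3
designs it undershoots the exact p by up to ~0.18 at mid-range p values,
though within 0.05 in the rejection-relevant region (exact p ≤ 0.15) —
hence exact p-values are the default in the study-sized comparisons.

`compare_conditions` reports, per element and for the per-sample total
concentration:

- **time contrast** (raw vs ash): Friedman with samples as blocks, k = 2
  (equivalent to a sign test), exact p.
- **type contrast** (traditional vs Maassel): this is an unpaired
  contrast, outside the Friedman design, so it uses an exact two-sided
  Mann–Whitney rank-sum test. Each sample contributes both its raw and
  its ash value. This pooling treats within-sample compartments as
  replicate burden measurements — pseudo-replication that anticonservative
  readers should note — and is what makes the contrast resolvable at all
  at the fixture's group sizes: with 2-vs-3 samples and one value each,
  the smallest achievable exact two-sided p is 0.2, above any reasonable
  α; pooled 4-vs-6, complete separation gives p ≈ 0.0095.
- direction labels from group medians, reported only when the
  corresponding p ≤ α (default α = 0.10, the study's level);
- an **interaction note**: descriptive text comparing the per-type median
  raw→ash change. No formal interaction test is defined for this design.

No multiple-testing correction is applied across the 29 elements,
matching the source analysis; p-values should be read per element.

## Synthetic-study generator

Raw concentrations are lognormal per element — concentrations are
positive and spread over orders of magnitude across the panel, and a
two-parameter positive model is the minimal fit — with a multiplicative
type effect on traditional samples. Ash and water concentrations derive
from the *same* mass balance the analysis inverts
(c·t_ash/y, c·t_water·m/V), so partition recovery is exact by
construction when censoring is off and the parameters match; this is
deliberate — the generator tests the pipeline's algebra and statistics,
not combustion chemistry. Cells below their threshold are written as
censored, closing the loop through the parser.

Defaults define the emulated study conditions:

- per-element log-means = log median Maassel raw concentration of the
  bundled tables (half-LOD substitution keeps censored trace elements
  positive); per-element type effect = traditional/Maassel median ratio;
- log-sd 0.5 for every element — with three samples per type a
  per-element spread cannot be estimated; 0.5 gives a geometric
  two-sigma range of ~7×, consistent with the between-sample spread
  visible in the tables;
- transfer fractions t_ash = 0.2, t_water = 0.05 (75 % to smoke, inside
  the 69.5–93 % range the fixture study reports);
- session parameters y = 0.25, V = 0.8 L, m = 15 g as in the example
  YAML;
- censoring thresholds from the instrument's solution LODs: ×50 to mg/kg
  for solids (0.5 g digested to 25 mL) and read as mg/L for water. Under
  these defaults solids are mostly observed while trace water values are
  heavily censored — the pattern of the real tables — and the overall
  censored fraction is strictly inside (0, 1).

All randomness flows from one `numpy` Generator seeded by the config, so
a fixed seed reproduces byte-identical CSVs.

What the generator does **not** emulate: element-specific volatility,
temperature-dependent transfer, correlated multi-element noise,
instrument drift, or matrix effects. Passing closed-loop tests therefore
demonstrates correctness of the computations, not fidelity of any
particular transfer-fraction choice to real combustion.

## Problem sizes

The default test and acceptance runs use small synthetic studies (panels
of 2–6 elements, 2–5 samples per type, 100 replicates for the
planted-effect detection rate) — ample for exact rank tests, which are
the binding factor at study scale; the full 29-element generator path is
exercised by the CLI round-trip tests.

## Known limitations

- The smoke compartment is a residual; negative residuals are clipped,
  so systematic transcription or measurement bias shows up as clipped
  flags, not as diagnostics.
- Left-censoring is handled by substitution, not by maximum-likelihood or
  Kaplan–Meier censored estimators; with the fixture's censoring rates
  (trace elements only) the substitution bounds are tight.
- The type contrast's raw+ash pooling trades independence for power, as
  discussed above.
- Risk indices inherit every scenario assumption linearly; they should be
  read as scenario-conditional indices, not as population risk estimates.
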