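# hookahrisk

Elemental mass balance and inhalation risk indices for hookah (water-pipe)
tobacco studies.

Hookah sessions burn a charge of tobacco — flavored "Maassel" or
traditional unflavored leaf — and the metals in that charge end up in one
of three places: the ash residue, the bowl water, or the inhaled smoke.
Studies of this exposure route measure multi-element ICP-MS panels
(here a fixed 29-element panel, Al…Zn) on the raw tobacco, its ash, and
the bowl water, with trace elements frequently reported as `<LOD`
(left-censored) and some cells not reported at all. `hookahrisk` turns
such censored concentration tables into:

- **composition profiles** — per-compartment totals and the joint share of
  the five macro-elements Ca, K, Na, Mg, P,
- a **mass balance** that partitions each element's per-session burden
  across ash, water, and (by difference) smoke,
- **chronic risk indices** — chronic daily intake (CDI), hazard quotient
  (HQ) and incremental lifetime cancer risk (CR) with the standard
  negligible / tolerable / high bands,
- **nonparametric group comparisons** (a from-scratch Friedman rank test
  with exact small-sample p-values) of raw-vs-ash and
  traditional-vs-Maassel contrasts,
- and a **synthetic-study generator** with known ground truth, so the whole
  pipeline is testable end to end without lab data.

A transcription of a published five-tobacco study (three Maassel flavors,
two traditional leaf tobaccos) ships as the bundled fixture dataset.

## The model

**Censoring.** A cell is observed, censored at its detection limit, or
missing. Sums substitute censored cells by 0 (default), LOD/2, or LOD;
missing cells are excluded, never imputed.

**Mass balance.** With tobacco charge $m$ (kg), ash yield $y$, and bowl
water volume $V$ (L), an element with concentrations $c_{raw}, c_{ash}$
(mg/kg) and $c_{water}$ (mg/L) has session burdens
$m\,c_{raw}$, $y\,m\,c_{ash}$, $V\,c_{water}$ (mg), and the smoke share is

$$\text{smoke\%} = 100\,\frac{m\,c_{raw} - y\,m\,c_{ash} - V\,c_{water}}{m\,c_{raw}}$$

clipped into [0, 100] with a flag when measurement noise pushes it outside.

**Risk.** For exposure-point concentration CF (mg/kg),

$$\mathrm{CDI} = \frac{\mathrm{CF}\cdot\mathrm{IR}\cdot\mathrm{EF}\cdot\mathrm{ED}}{\mathrm{BW}\cdot\mathrm{AT}},\qquad
\mathrm{HQ} = \frac{\mathrm{CDI}}{\mathrm{RfD}},\qquad
\mathrm{CR} = \mathrm{CDI}\cdot\mathrm{CSF}$$

with HQ > 1 flagged, and CR banded negligible (≤ 10⁻⁶), tolerable, or
high (> 10⁻⁴). Elements without a published RfD or slope factor are
`not_applicable`, never zero.

**Friedman test.** $Q = \frac{12}{nk(k+1)}\sum_j R_j^2 - 3n(k+1)$ over
within-block mid-ranks, tie-corrected, with χ² or exact permutation
p-values (all $(k!)^n$ rank tables for $nk \le 12$).

## Worked example

```pycon
>>> import hookahrisk as hr
>>> table = hr.load_study_tables()
>>> table
ConcentrationTable(5 samples x 3 compartments x 29 elements)
>>> hr.main_element_share(table, "Apple", "ash")     # % of total in Ca,K,Na,Mg,P
97.60447...
>>> scenario = hr.ExposureScenario(IR=0.01, EF=365, ED=30, BW=70, AT=25550)
>>> tox = hr.load_toxicity_fixture()
>>> rt = hr.risk_table(table, tox, scenario)
>>> rt[(rt.sample_id == "Khansar") & (rt.element == "As")].iloc[0]
CF      0.462        # mg/kg after ppb -> ppm normalization
CDI     2.83e-05     # mg per kg body weight per day
HQ      0.236        # fraction of the reference dose
CR      0.00424      # lifetime cancer probability
band    high         # CR > 1e-4
>>> v = hr.compare_conditions(table, hr.load_study_meta())
>>> v[v.element == "Total concentration"].iloc[0][["p_value_type", "direction_type"]]
p_value_type      0.00952
direction_type    traditional>maassel
```

Reading: the five macro-elements carry 97.6 % of the Apple ash's
elemental mass; under the example smoker scenario (10 g/day, 30 years,
70 kg, lifetime-averaged) arsenic in Khansar tobacco stays below its
reference dose (HQ 0.24) but its cancer-risk index 4.2 × 10⁻³ sits in the
high band; and traditional tobaccos carry significantly more total
elemental mass than Maassel ones (exact rank-sum p ≈ 0.0095).

The same stages are exposed as a CLI
(`hookahrisk validate|profile|balance|risk|compare|simulate`); the
mass-balance and risk stages take their session parameters and exposure
scenario from YAML files — commented examples with clearly-labelled
assumed values ship in `src/hookahrisk/data/`.

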